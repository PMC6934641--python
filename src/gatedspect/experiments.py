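"""Desk-scale analogs of the three-part gated-SPECT dyssynchrony study.

Part 1: across a synthetic population, correlate the normalized standard
deviation of the accepted R-R intervals (SD_R-R, the HRV index) with the
activity ratio (AR) of OSEM reconstructions — HRV should drive last-bin data
shortage.  Part 2: for subjects thinned to prescribed AR levels, compare the
phase-analysis indices between the reference level and each reduced level
with Lin's CCC, separately for OSEM and TOSEM — TOSEM should stay reliable.
Part 3: at native AR, correlate AR with the OSEM→TOSEM changes of the
indices — larger shortage should mean larger change, with TOSEM never below
OSEM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gatedspect.gating import (
    AcceptanceResult,
    AcquisitionTimeMap,
    GateConfig,
    GatedSinogram,
    count_activity_ratio,
    thin_last_bin,
)
from gatedspect.phantom import (
    BeatSeries,
    LVPhantomSpec,
    generate_rr_series,
    simulate_gated_sinogram,
)
from gatedspect.phase import PhaseAnalysisResult, midwall_grid, phase_analysis
from gatedspect.projector import CDRModel, Geometry, Projector, paper_scale_geometry
from gatedspect.recon import (
    GatedImageSeries,
    ReconConfig,
    cylinder_mask,
    postprocess,
    reconstruct_series,
)
from gatedspect.stats import activity_ratio, ccc, delta_params, pearson_r

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationSpec",
    "Subject",
    "Part1Result",
    "Part2Result",
    "Part3Result",
    "build_subjects",
    "postprocess_for_phantom",
    "simulate_subject",
    "run_part1",
    "run_part2",
    "run_part3",
]

#: frames per cardiac cycle used to quantize phantom phases in the simulator
PHASE_CACHE = 256


@dataclass(frozen=True)
class PopulationSpec:
    """Deterministic synthetic population layout.

    Subjects span the HRV range and the dyssynchrony-delay range on even
    grids (so every population covers the study conditions), while mean R-R
    intervals are drawn per subject from ``mean_rr_range``.  The delay is
    applied to one angular sector of the phantom (the "inferior" sector).
    """

    n_subjects: int = 14
    mean_rr_range: tuple[float, float] = (0.75, 1.05)
    hrv_range: tuple[float, float] = (0.02, 0.12)
    delay_range_deg: tuple[float, float] = (0.0, 90.0)
    delayed_sector: int = 2
    wall_activity: float = 8.0
    background_activity: float = 0.4
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass(frozen=True)
class Subject:
    """One synthetic patient: phantom, rhythm parameters, private seeds."""

    index: int
    phantom: LVPhantomSpec
    mean_rr: float
    sd_rr_norm: float
    beat_seed: np.random.SeedSequence = field(repr=False)
    noise_seed: np.random.SeedSequence = field(repr=False)
    thin_seed: np.random.SeedSequence = field(repr=False)


def build_subjects(
    pop: PopulationSpec, geometry: Geometry | None = None
) -> list[Subject]:
    geometry = geometry if geometry is not None else Geometry()
    n = pop.n_subjects
    hrv = np.linspace(*pop.hrv_range, n)
    delays = np.linspace(*pop.delay_range_deg, n)
    root = np.random.SeedSequence(pop.master_seed)
    subject_seeds = root.spawn(n)
    subjects = []
    for i in range(n):
        beat_ss, noise_ss, thin_ss, draw_ss = subject_seeds[i].spawn(4)
        rng = np.random.default_rng(draw_ss)
        mean_rr = float(rng.uniform(*pop.mean_rr_range))
        sector_delays = [0.0] * 4
        sector_delays[pop.delayed_sector] = float(delays[i])
        phantom = LVPhantomSpec(
            grid_shape=geometry.grid_shape,
            voxel_size_mm=geometry.voxel_size_mm,
            wall_activity=pop.wall_activity,
            background_activity=pop.background_activity,
            sector_phase_delays=tuple(sector_delays),
        )
        subjects.append(
            Subject(
                index=i,
                phantom=phantom,
                mean_rr=mean_rr,
                sd_rr_norm=float(hrv[i]),
                beat_seed=beat_ss,
                noise_seed=noise_ss,
                thin_seed=thin_ss,
            )
        )
    return subjects


def simulate_subject(
    subject: Subject,
    projector: Projector,
    gate_cfg: GateConfig = GateConfig(),
    dwell_time: float = 30.0,
) -> tuple[GatedSinogram, AcquisitionTimeMap, AcceptanceResult, BeatSeries]:
    geometry = projector.geometry
    beats = generate_rr_series(
        subject.mean_rr,
        subject.sd_rr_norm * subject.mean_rr,
        geometry.n_angles * dwell_time + subject.mean_rr,
        np.random.default_rng(subject.beat_seed),
    )
    sino, tau, _ = simulate_gated_sinogram(
        subject.phantom,
        beats,
        geometry,
        gate_cfg,
        seed=np.random.default_rng(subject.noise_seed),
        dwell_time=dwell_time,
        projector=projector,
        phase_cache=PHASE_CACHE,
    )
    from gatedspect.gating import accept_beats

    return sino, tau, accept_beats(beats, gate_cfg), beats


def _default_projector(geometry: Geometry | None, scale: str = "desk") -> Projector:
    if geometry is None:
        geometry = paper_scale_geometry() if scale == "paper" else Geometry()
    return Projector(geometry, CDRModel())


def postprocess_for_phantom(spec: LVPhantomSpec, series: GatedImageSeries) -> GatedImageSeries:
    """Standard post-processing for a known phantom: sigma=1 smoothing and a
    cylindrical extracardiac mask 10 mm beyond the epicardium."""
    lo, hi = spec.z_extent
    mask = cylinder_mask(
        spec.grid_shape,
        spec.voxel_size_mm,
        radius_mm=spec.epicardial_radius_mm + 10.0,
        z_range=(max(lo - 1, 0), min(hi + 1, spec.grid_shape[2])),
    )
    return postprocess(series, sigma_voxels=1.0, mask=mask)


@dataclass
class Part1Result:
    table: pd.DataFrame
    r: float | None  # None when AR has no variance (e.g. zero-HRV population)


def run_part1(
    pop: PopulationSpec,
    geometry: Geometry | None = None,
    gate_cfg: GateConfig = GateConfig(),
    recon_cfg: ReconConfig = ReconConfig(),
    dwell_time: float = 30.0,
    projector: Projector | None = None,
) -> Part1Result:
    """Correlate SD_R-R with the AR of OSEM reconstructions, per subject."""
    proj = projector if projector is not None else _default_projector(geometry)
    rows = []
    for subj in build_subjects(pop, proj.geometry):
        sino, tau, acc, _ = simulate_subject(subj, proj, gate_cfg, dwell_time)
        series = reconstruct_series(sino, None, "osem", recon_cfg, projector=proj)
        series = postprocess_for_phantom(subj.phantom, series)
        ar = activity_ratio(series)
        rows.append(
            {
                "subject": subj.index,
                "sd_rr_norm": acc.sd_rr_normalized,
                "ar_pct": ar.ar_pct,
                "count_ratio": count_activity_ratio(sino),
            }
        )
        logger.info(
            "part1 subject %d: SD_R-R %.4f, AR %.1f%%",
            subj.index, acc.sd_rr_normalized, ar.ar_pct,
        )
    table = pd.DataFrame(rows)
    if (
        len(table) < 3
        or np.ptp(table["ar_pct"].to_numpy()) < 1e-9
        or np.ptp(table["sd_rr_norm"].to_numpy()) < 1e-9
    ):
        logger.warning("AR or SD_R-R has zero variance; correlation undefined")
        return Part1Result(table=table, r=None)
    r = pearson_r(table["sd_rr_norm"].to_numpy(), table["ar_pct"].to_numpy())
    return Part1Result(table=table, r=r)


@dataclass
class Part2Result:
    #: long table: subject, mode, level ("ref" or the target ratio), BW/StD/ENT
    table: pd.DataFrame
    #: ccc[mode][level][index] between the reference level and that level
    ccc: dict[str, dict[float, dict[str, float]]]
    excluded: list[int]
    reference_level: float


def run_part2(
    pop: PopulationSpec,
    ar_levels: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5),
    modes: tuple[str, ...] = ("osem", "tosem"),
    reference_level: float = 0.9,
    reference_policy: str = "exclude",
    geometry: Geometry | None = None,
    gate_cfg: GateConfig = GateConfig(),
    recon_cfg: ReconConfig = ReconConfig(),
    dwell_time: float = 30.0,
    projector: Projector | None = None,
) -> Part2Result:
    """Thin to target AR levels, reconstruct, and compare indices with CCC.

    ``reference_policy="exclude"`` drops subjects whose native count ratio is
    below the highest requested level (the paper's subject-selection rule);
    ``"clamp"`` instead thins such subjects only as far as their native ratio
    allows (retaining the full population).
    """
    if reference_policy not in ("exclude", "clamp"):
        raise ValueError("reference_policy must be 'exclude' or 'clamp'")
    levels = tuple(sorted(set(ar_levels), reverse=True))
    proj = projector if projector is not None else _default_projector(geometry)
    clamp = reference_policy == "clamp"
    top = max((reference_level, *levels))

    rows = []
    excluded: list[int] = []
    per_mode_index: dict[str, dict[str | float, dict[int, dict[str, float]]]] = {
        m: {lvl: {} for lvl in ("ref", *levels)} for m in modes
    }
    for subj in build_subjects(pop, proj.geometry):
        sino, tau, acc, _ = simulate_subject(subj, proj, gate_cfg, dwell_time)
        native = count_activity_ratio(sino)
        if not clamp and native < top:
            logger.info(
                "part2 subject %d excluded: native ratio %.3f < %.3f",
                subj.index, native, top,
            )
            excluded.append(subj.index)
            continue
        grid = midwall_grid(subj.phantom)
        thin_rng = np.random.default_rng(subj.thin_seed)
        targets: list[tuple[str | float, float]] = [("ref", reference_level)]
        targets += [(lvl, lvl) for lvl in levels]
        # one thinning draw per distinct target: a level equal to the
        # reference compares identical data (self-comparison, CCC = 1)
        thinned_cache: dict[float, tuple] = {}
        for label, target in targets:
            if target not in thinned_cache:
                thinned_cache[target] = thin_last_bin(
                    sino, tau, target, thin_rng, clamp=clamp
                )
            t_sino, t_tau = thinned_cache[target]
            for mode in modes:
                series = reconstruct_series(
                    t_sino, t_tau, mode, recon_cfg, projector=proj
                )
                series = postprocess_for_phantom(subj.phantom, series)
                res = phase_analysis(series, grid)
                per_mode_index[mode][label][subj.index] = res.indices()
                rows.append(
                    {
                        "subject": subj.index,
                        "mode": mode,
                        "level": label,
                        "native_ratio": native,
                        **res.indices(),
                    }
                )

    if len(per_mode_index[modes[0]]["ref"]) < 3:
        raise ValueError(
            "fewer than 3 subjects survived selection; CCC is not computable"
        )

    ccc_out: dict[str, dict[float, dict[str, float]]] = {}
    for mode in modes:
        ccc_out[mode] = {}
        ref_vals = per_mode_index[mode]["ref"]
        subjects = sorted(ref_vals)
        for lvl in levels:
            ccc_out[mode][lvl] = {}
            for key in ("BW", "StD", "ENT"):
                x = np.array([ref_vals[s][key] for s in subjects])
                y = np.array([per_mode_index[mode][lvl][s][key] for s in subjects])
                ccc_out[mode][lvl][key] = ccc(x, y).ccc
    return Part2Result(
        table=pd.DataFrame(rows),
        ccc=ccc_out,
        excluded=excluded,
        reference_level=reference_level,
    )


@dataclass
class Part3Result:
    table: pd.DataFrame
    correlations: dict[str, float]


def run_part3(
    pop: PopulationSpec,
    geometry: Geometry | None = None,
    gate_cfg: GateConfig = GateConfig(),
    recon_cfg: ReconConfig = ReconConfig(),
    dwell_time: float = 30.0,
    projector: Projector | None = None,
) -> Part3Result:
    """Reconstruct every subject with both modes at native AR; correlate the
    OSEM→TOSEM index changes with AR."""
    proj = projector if projector is not None else _default_projector(geometry)
    rows = []
    for subj in build_subjects(pop, proj.geometry):
        sino, tau, acc, _ = simulate_subject(subj, proj, gate_cfg, dwell_time)
        grid = midwall_grid(subj.phantom)
        results: dict[str, PhaseAnalysisResult] = {}
        ar_pct = None
        for mode in ("osem", "tosem"):
            series = reconstruct_series(sino, tau, mode, recon_cfg, projector=proj)
            series = postprocess_for_phantom(subj.phantom, series)
            if mode == "osem":
                ar_pct = activity_ratio(series).ar_pct
            results[mode] = phase_analysis(series, grid)
        d = delta_params(results["osem"], results["tosem"])
        rows.append(
            {
                "subject": subj.index,
                "sd_rr_norm": acc.sd_rr_normalized,
                "ar_pct": ar_pct,
                "d_bw": d.d_bw,
                "d_std": d.d_std,
                "d_ent": d.d_ent,
            }
        )
        logger.info(
            "part3 subject %d: AR %.1f%%, dBW %.1f, dStD %.1f, dENT %.1f",
            subj.index, ar_pct, d.d_bw, d.d_std, d.d_ent,
        )
    table = pd.DataFrame(rows)
    corr = {}
    ar = table["ar_pct"].to_numpy()
    for col in ("d_bw", "d_std", "d_ent"):
        v = table[col].to_numpy()
        usable = len(table) >= 3 and np.ptp(v) > 0 and np.ptp(ar) > 0
        corr[col] = pearson_r(ar, v) if usable else np.nan
    return Part3Result(table=table, correlations=corr)
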