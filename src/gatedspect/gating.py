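"""Fixed forward ECG gating.

Each R-R interval is divided into ``n_bins`` bins of fixed length Δ starting
at the leading R wave, where Δ is one n_bins-th of the mean duration of the
beats accepted by the ±window rule.  Beats shorter than ``n_bins·Δ`` do not
fill the last bin, so under heart-rate variability the last bin accumulates
less acquisition time — the "data shortage" that the time-modified
reconstruction compensates.  This module also provides the binomial last-bin
thinning used to emulate list-mode rebinning to prescribed activity-ratio
levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from gatedspect.phantom import BeatSeries

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "AcceptanceResult",
    "AcquisitionTimeMap",
    "GatedSinogram",
    "EventStream",
    "GatingError",
    "accept_beats",
    "compute_tau",
    "bin_events",
    "thin_last_bin",
    "count_activity_ratio",
]


class GatingError(ValueError):
    """Raised when gating cannot proceed (e.g. no beat accepted)."""


@dataclass(frozen=True)
class GateConfig:
    """Fixed forward gating configuration: bin count and acceptance window."""

    n_bins: int = 8
    acceptance_window: float = 0.20

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not 0.0 < self.acceptance_window < 1.0:
            raise ValueError("acceptance_window must be in (0, 1)")


@dataclass(frozen=True)
class AcceptanceResult:
    """Beat acceptance mask and summary statistics of the accepted beats.

    ``sd_rr_normalized`` is the sample standard deviation of the accepted
    R-R intervals divided by their mean (the heart-rate-variability index),
    and ``bin_length`` is ``mean_accepted_rr / n_bins``.
    """

    accepted: np.ndarray = field(repr=False)
    mean_accepted_rr: float
    sd_accepted_rr: float
    sd_rr_normalized: float
    bin_length: float
    n_bins: int


@dataclass(frozen=True)
class AcquisitionTimeMap:
    """Seconds of accepted acquisition per (projection angle, ECG bin)."""

    tau: np.ndarray = field(repr=False)  # (L, n_bins)

    def __post_init__(self) -> None:
        t = np.asarray(self.tau, dtype=float)
        if t.ndim != 2:
            raise ValueError("tau must be a 2-D (angles x bins) array")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("tau must be finite and non-negative")
        object.__setattr__(self, "tau", t)

    @property
    def n_angles(self) -> int:
        return self.tau.shape[0]

    @property
    def n_bins(self) -> int:
        return self.tau.shape[1]


@dataclass(frozen=True)
class GatedSinogram:
    """Measured counts per (projection angle, ECG bin, detector bin).

    ``counts`` has shape ``(L, n_bins, U, V)`` with non-negative integers.
    """

    counts: np.ndarray = field(repr=False)
    angles_deg: tuple[float, ...]
    det_bin_mm: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 4:
            raise ValueError("counts must be 4-D (angle, bin, u, v)")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            c = np.round(c).astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if c.shape[0] != len(self.angles_deg):
            raise ValueError("counts first axis must match the angle list")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def n_angles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def bin_totals(self) -> np.ndarray:
        """Total counts per ECG bin, summed over angles and detector bins."""
        return self.counts.sum(axis=(0, 2, 3))


@dataclass(frozen=True)
class EventStream:
    """List-mode events: timestamp, acquisition angle index, detector bin."""

    times: np.ndarray = field(repr=False)
    angle_index: np.ndarray = field(repr=False)
    u: np.ndarray = field(repr=False)
    v: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return len(self.times)


def accept_beats(beats: "BeatSeries | Sequence[float]", cfg: GateConfig) -> AcceptanceResult:
    """Apply the ±window acceptance rule and summarize the accepted beats.

    The reference is the single-pass arithmetic mean of *all* R-R intervals;
    beat ``i`` is accepted iff ``|RR_i - mean| <= window * mean``.  Statistics
    (sample SD, ``n-1`` denominator) are computed over accepted beats only.
    """
    rr = np.asarray(getattr(beats, "rr_intervals", beats), dtype=float)
    if rr.size < 2:
        raise GatingError("need at least 2 beats to gate")
    ref = rr.mean()
    accepted = np.abs(rr - ref) <= cfg.acceptance_window * ref + 1e-12
    if not np.any(accepted):
        raise GatingError("no beat accepted by the gating window")
    acc = rr[accepted]
    mean_acc = float(acc.mean())
    sd_acc = float(acc.std(ddof=1)) if acc.size > 1 else 0.0
    return AcceptanceResult(
        accepted=accepted,
        mean_accepted_rr=mean_acc,
        sd_accepted_rr=sd_acc,
        sd_rr_normalized=sd_acc / mean_acc,
        bin_length=mean_acc / cfg.n_bins,
        n_bins=cfg.n_bins,
    )


def compute_tau(
    rr_per_angle: Sequence[np.ndarray],
    bin_length: float,
    n_bins: int,
) -> AcquisitionTimeMap:
    """Integrate accepted beat time into per-(angle, bin) acquisition times.

    ``τ[l, b] = Σ_i |[(b-1)Δ, bΔ] ∩ [0, RR_i]|`` over the accepted beats at
    angle ``l``; beat time beyond ``n_bins·Δ`` is discarded (fixed forward
    gating keeps no frame past the last bin).
    """
    if bin_length <= 0:
        raise ValueError("bin_length must be positive")
    edges = np.arange(n_bins + 1) * bin_length
    tau = np.zeros((len(rr_per_angle), n_bins))
    for l, rrs in enumerate(rr_per_angle):
        rrs = np.asarray(rrs, dtype=float)
        if rrs.size == 0:
            continue
        lo = np.minimum(rrs[:, None], edges[None, :-1])
        hi = np.minimum(rrs[:, None], edges[None, 1:])
        tau[l] = (hi - lo).sum(axis=0)
    return AcquisitionTimeMap(tau=tau)


def bin_events(
    events: EventStream,
    beats: "BeatSeries",
    acceptance: AcceptanceResult,
    cfg: GateConfig,
    detector_shape: tuple[int, int],
    angles_deg: Sequence[float],
    det_bin_mm: float = 4.0,
) -> GatedSinogram:
    """Bin a list-mode event stream into a gated sinogram.

    An event at time ``t`` inside accepted beat ``i`` goes to bin
    ``floor((t - trigger_i)/Δ)`` (0-based) if that is below ``n_bins``;
    events in rejected beats, events past the last bin of a long beat, and
    events before the first trigger are discarded (the discard count is
    logged).
    """
    t = np.asarray(events.times, dtype=float)
    triggers = np.asarray(beats.trigger_times, dtype=float)
    delta = acceptance.bin_length
    n_beats = len(beats.rr_intervals)

    beat_idx = np.searchsorted(triggers, t, side="right") - 1
    early = beat_idx < 0
    if np.any(early):
        logger.info("discarding %d events before the first trigger", early.sum())
    in_series = (~early) & (beat_idx < n_beats)
    rel = np.where(in_series, t - triggers[np.clip(beat_idx, 0, n_beats - 1)], -1.0)
    bin_idx = np.floor(rel / delta).astype(np.int64)
    acc_mask = np.zeros(n_beats + 1, dtype=bool)
    acc_mask[:n_beats] = acceptance.accepted
    keep = (
        in_series
        & acc_mask[np.clip(beat_idx, 0, n_beats)]
        & (bin_idx >= 0)
        & (bin_idx < cfg.n_bins)
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("discarded %d of %d events during gating", n_drop, t.size)

    U, V = detector_shape
    L = len(angles_deg)
    counts = np.zeros((L, cfg.n_bins, U, V), dtype=np.int64)
    np.add.at(
        counts,
        (
            np.asarray(events.angle_index)[keep],
            bin_idx[keep],
            np.asarray(events.u)[keep],
            np.asarray(events.v)[keep],
        ),
        1,
    )
    return GatedSinogram(counts=counts, angles_deg=tuple(angles_deg), det_bin_mm=det_bin_mm)


def count_activity_ratio(sino: GatedSinogram) -> float:
    """Last-bin / mean(first five bins) total-count ratio (dimensionless)."""
    totals = sino.bin_totals().astype(float)
    if totals.size < 6:
        raise ValueError("need at least 6 ECG bins for the count activity ratio")
    denom = totals[:5].mean()
    if denom <= 0:
        raise ValueError("first-bin counts are zero; ratio undefined")
    return float(totals[-1] / denom)


def thin_last_bin(
    sino: GatedSinogram,
    tau: AcquisitionTimeMap,
    target_ratio: float,
    seed: int | np.random.Generator,
    clamp: bool = False,
) -> tuple[GatedSinogram, AcquisitionTimeMap]:
    """Binomially thin the last ECG bin towards a target activity ratio.

    Emulates list-mode rebinning in which a fraction of the last-bin events
    is discarded uniformly across all projection angles.  The retention
    probability ``p = target_ratio * mean(totals of bins 1..5) / total(last
    bin)`` is calibrated on raw counts; each last-bin count is thinned
    binomially with probability ``p`` and the last-bin acquisition times are
    scaled by ``p``.  All other bins are untouched.

    With ``clamp=True`` a target above the current ratio is clamped to it
    (``p = 1``, data unchanged) instead of raising.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    current = count_activity_ratio(sino)
    p = target_ratio / current
    if p > 1.0 + 1e-9:
        if not clamp:
            raise ValueError(
                f"target ratio {target_ratio:.3f} exceeds current ratio "
                f"{current:.3f}; thinning cannot add counts"
            )
        logger.info(
            "target ratio %.3f above current %.3f; clamped (no thinning)",
            target_ratio,
            current,
        )
        p = 1.0
    p = min(p, 1.0)

    counts = sino.counts.copy()
    counts[:, -1] = rng.binomial(sino.counts[:, -1], p)
    new_tau = tau.tau.copy()
    new_tau[:, -1] *= p
    thinned = replace(sino, counts=counts)
    return thinned, AcquisitionTimeMap(tau=new_tau)
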