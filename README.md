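# gatedspect

Time-modified OSEM (TOSEM) reconstruction and dyssynchrony phase analysis
for ECG-gated myocardial perfusion SPECT, with a synthetic beating
left-ventricle phantom so the whole chain runs with no external data.

## The problem

Fixed forward ECG gating divides each R-R interval into bins of fixed
length Δ = mean(accepted R-R)/8 starting at the R wave.  Heart-rate
variability (HRV) means many beats are shorter than 8Δ, so the **last ECG
bin collects less acquisition time** than the others.  Ordinary OSEM assumes
equal time everywhere and reconstructs the last bin with artificially low
activity.  First-Fourier-harmonic (FFH) phase analysis — which fits
`A0 + A1·cos(θ − φ)` to each myocardial sample's time-activity curve and
summarizes the fitted phases by histogram bandwidth (BW), phase standard
deviation (StD) and entropy (ENT) — is skewed by that dip, and the apparent
degree of left-ventricular dyssynchrony shrinks as the data shortage grows.

TOSEM fixes this inside the reconstruction.  With the system matrix
block-structured per projection angle, OSEM uses `H^l = P^l R^l` (Gaussian-
interpolation rotation, then forward projection with distance-dependent
Gaussian collimator response), while TOSEM uses

```
H^l = τ^l P^l R^l
```

where `τ^l` is the measured acquisition time of angle `l` (per ECG bin).
Since τ also enters the sensitivity `Σ Hᵀ1`, every bin lands on a common
activity-rate scale and no retrospective rescaling is needed.

The package provides, as library modules with a thin `gatedspect` CLI on
top: the beating-LV phantom and acquisition simulator (`phantom`), fixed
forward gating with beat acceptance, τ maps and last-bin thinning
(`gating`), the rotation-based projector (`projector`), OSEM/TOSEM
(`recon`), FFH phase analysis (`phase`), activity-ratio/Pearson/Lin-CCC
statistics (`stats`), and the three study-part pipelines (`experiments`).
It targets physicists and methods researchers studying gating artifacts in
emission tomography.

## Worked example

Simulate one subject with moderate HRV and a 60° contraction delay in one
sector, thin the last ECG bin to half activity (emulating severe data
shortage), then reconstruct both ways and run phase analysis:

```python
from gatedspect import (
    LVPhantomSpec, GateConfig, Geometry, Projector,
    generate_rr_series, simulate_gated_sinogram, thin_last_bin,
    reconstruct_series, activity_ratio,
)
from gatedspect.experiments import postprocess_for_phantom
from gatedspect.phase import midwall_grid, phase_analysis

geometry = Geometry()                      # 32 angles, 48x48x16, 4 mm
projector = Projector(geometry)
phantom = LVPhantomSpec(sector_phase_delays=(0.0, 0.0, 60.0, 0.0))
beats = generate_rr_series(mean_rr=0.9, sd_rr=0.05 * 0.9,
                           total_time=geometry.n_angles * 30.0 + 1, seed=42)
sino, tau, _ = simulate_gated_sinogram(phantom, beats, geometry, GateConfig(),
                                       seed=43, projector=projector,
                                       phase_cache=256)
thin_sino, thin_tau = thin_last_bin(sino, tau, target_ratio=0.5, seed=44)
grid = midwall_grid(phantom)
for mode in ("osem", "tosem"):
    series = reconstruct_series(thin_sino, thin_tau, mode, projector=projector)
    series = postprocess_for_phantom(phantom, series)
    res = phase_analysis(series, grid)
    ar = activity_ratio(series)
    print(f"{mode:6s}  AR {ar.ar_pct:5.1f}%   BW {res.bw_deg:5.1f} deg   "
          f"StD {res.std_deg:5.2f} deg   ENT {res.ent_pct:5.2f} %")
```

Output:

```
osem    AR  50.8%   BW  36.0 deg   StD 11.66 deg   ENT 53.01 %
tosem   AR 100.3%   BW  70.0 deg   StD 22.90 deg   ENT 63.82 %
```

Read: with half the last-bin data gone, the OSEM activity ratio mirrors the
count shortage (≈51%) and the dyssynchrony indices are pulled down — the
delayed sector looks better synchronized than it is.  TOSEM restores the
last bin to the common activity scale (AR ≈ 100%) and reports the larger
indices consistent with the programmed 60° delay.

The same steps are scriptable from the shell:

```sh
gatedspect simulate --seed 42 --out sino.h5
gatedspect gate sino.h5 --target-ar 0.5 --seed 44 --out thin.h5
gatedspect reconstruct thin.h5 --mode tosem --out series.nii
gatedspect phase series.nii
gatedspect experiment part2 --n-subjects 14 --seed 1
```

## Scope

No attenuation or scatter correction (not modelled in the reconstructions
being compared), no vendor list-mode formats or DICOM, no transaxial→
short-axis reorientation (the phantom is short-axis native), no
repeated-measures ANOVA machinery.  `docs/methods.md` documents the models,
defaults and limitations in detail.
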