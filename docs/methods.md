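# Methods

## Problem and model

In ECG-gated myocardial perfusion SPECT with fixed forward gating, each
accepted R-R interval is divided into `n_bins` bins of fixed length
Δ = mean(accepted R-R)/`n_bins`, starting at the R wave.  Beats shorter than
`n_bins`·Δ contribute no data to the trailing bins, so under heart-rate
variability (HRV) the last ECG bin is acquired for less total time than the
first bins.  Standard OSEM reconstruction assumes a constant acquisition
time per projection angle and bin; the last-bin image therefore comes out
with reduced total activity, which distorts the time-activity curves used by
first-Fourier-harmonic (FFH) phase analysis of left-ventricular mechanical
dyssynchrony.

TOSEM (time-modified OSEM) repairs this inside the reconstruction.  With the
transition matrix block-structured over projection angles,
`H = [[H¹]ᵀ, …, [H^L]ᵀ]ᵀ`, the OSEM block is `H^l = P^l R^l` (rotation to
the detector frame, then forward projection with collimator-detector
response modelling), and the TOSEM block is `H^l = τ^l P^l R^l`, where `τ^l`
is the acquisition time of angle `l` — generalized here to per-(angle, bin)
times `τ^{l,b}`, which within a single-bin reconstruction play exactly the
role of `τ^l`.  Because τ enters both the forward model and the sensitivity
`Σ Hᵀ1`, each bin is reconstructed on a common activity-rate scale and the
HRV-starved last bin is automatically normalized.  No retrospective
rescaling is applied anywhere; the phase indices are computed on the
reconstructions at native count scale in both modes.

## Projector

Rotation-based parallel-beam model (parallel-hole LEHR-class collimator):

- **Rotation `R^l`** — Gaussian-interpolation resampling: each rotated-grid
  voxel is a row-normalized Gaussian-weighted (`w ∝ exp(−r²/2σ_r²)`,
  σ_r = 0.42 voxel ≈ 1-voxel FWHM) average of source voxels within 3σ_r of
  its back-rotated centre.  When a back-rotated centre coincides with a
  lattice node (within 1e−9 voxel) the row degenerates to the exact
  permutation, so angle 0° is the identity and multiples of 90° are exact on
  square grids.  Like any value-interpolating rotation, the operator
  preserves constants (rows sum to 1), not point masses: a single-voxel
  impulse rotated off-lattice gains ~20% apparent mass, while smooth
  activity distributions are preserved to well under 1%.  Off-lattice angles
  additionally blur by ≈σ_r; the round-trip rotate(θ)∘rotate(−θ) error on a
  5-voxel-σ blob is ≈1.2% relative L2.
- **CDR `P^l`** — each plane at constant distance `d` from the collimator
  face is convolved (transverse and axial) with a Gaussian of
  σ(d) = (FWHM₀ + k·d)/2.3548; defaults FWHM₀ = 3 mm, k = 0.045
  (≈7.5 mm FWHM at 10 cm, LEHR-like), zero boundary (blur past the detector
  edge is lost, as physically).  The blur is implemented as precomputed
  per-depth symmetric Toeplitz matrices applied as batched dense
  contractions — symmetric, hence exactly self-adjoint, and fast enough for
  the OSEM inner loop.
- **Backprojector** — the exact adjoint (broadcast along rays, same blur
  matrices, transposed rotation).  A matched pair guarantees monotone
  Poisson likelihood for MLEM.
- **Orbit** — circular by default (radius 200 mm desk-scale); a per-angle
  radius array supports noncircular orbits.

Default desk-scale geometry: 32 angles over 180°, 48×48×16 grid, 4 mm
voxels.  The clinical-scale preset (64 angles, 96×96, 6.22 mm) is available
through `paper_scale_geometry()` / `--scale paper`.  Desk scale keeps a full
study-part run in minutes on one core; all structural claims tested here are
resolution-independent, but absolute index values are not comparable between
scales.

## Reconstruction

OSEM update per ordered subset `S_n`:
`f ← (f / Σ_{l∈S_n} H^{lᵀ}1) ⊙ Σ_{l∈S_n} H^{lᵀ}(g^l / max(H^l f, ε))`,
ε = 1e−12 guarding empty projections, uniform positive initialization
(value 1), voxels with zero subset sensitivity frozen at 0.  Defaults: 10
iterations × 8 subsets; subsets are the angle classes `l ≡ s (mod N)`
processed in bit-reversed order to maximize angular separation between
consecutive subsets.  Post-processing: 3-D Gaussian smoothing (σ = 1 voxel,
mirror boundary) followed by a binary cylindrical mask around the known LV
centre (extracardiac removal).  An all-empty ECG bin is a hard error in
TOSEM mode rather than a silent zero image.

## Synthetic beating-LV phantom

The phantom stands in for patient acquisitions (which are not available) and
is first-class code:

- **Geometry** — a short-axis annular wall, end-diastolic endocardial/
  epicardial radii 22/32 mm, axially uniform over a 12-slice slab.
- **Kinetics** — local wall thickness in angular sector `s` at cardiac phase
  θ: `t = t_ED·(1 + cf·(1 − cos(θ − delay_s))/2)` with peak thickening
  cf = 0.5; `delay_s` programs regional dyssynchrony (default: four 90°
  sectors, one delayed).  Contraction peaks at θ = 180° + delay
  (end-systole) and vanishes at the R wave.
- **Incompressibility** — activity density in the wall is uniform and the
  mid-wall radius contracts as `r_mid = r_mid,ED·t_ED/t`, so each sector's
  ring area — hence total tracer activity — is conserved over the cycle, as
  tracer mass is in a real myocardium.  The radial activity integral is then
  ∝ t, and the partial-volume count brightening of the thickened wall that
  phase analysis measures emerges from the finite reconstruction resolution
  rather than being painted onto the phantom.  Conservation is what makes
  the activity ratio a pure data-shortage probe (AR → 100% as HRV → 0).
- **Rhythm** — R-R intervals i.i.d. Gaussian (mean 0.9 s by default — a
  plausible resting rate, not a literature-derived value) truncated below at
  0.3·mean, with the normalized SD as the HRV dial.
- **Acquisition** — sequential: each of the L angles consumes a fresh
  contiguous `dwell_time` (30 s) stretch of the beat series, as on a real
  dual-detector camera stepping through its orbit.  For every accepted beat,
  each gating bin's overlap with `[0, RR]` is integrated at its midpoint
  phase (midpoint-rule quadrature; error is second order in bin width); the
  time-weighted frames are accumulated in image space and forward-projected
  once per (angle, bin) — identical, by linearity, to projecting each
  sub-interval separately.  Observed counts are Poisson draws of the
  expected counts; exact per-(angle, bin) acquisition times τ are returned
  alongside.  The experiments layer quantizes frame phases to 256 points per
  cycle (≤0.7° quantization, well below the midpoint-rule error; verified
  <1% against exact midpoints).
- **Count level** — wall activity 8 counts·s⁻¹·voxel⁻¹, background 5%,
  giving ≈2.5 M counts per ECG bin over all 32 angles — a high-quality rest
  acquisition.  Simulated counts drive Poisson noise; no other noise source
  (no scatter, attenuation, motion blur within a bin, detector effects) is
  modelled, so passing tests demonstrate the HRV/data-shortage mechanism and
  the reconstruction contracts, not clinical image quality.
- An optional beat-resolved list-mode event stream (with events in rejected
  beats and beyond the last bin) exercises the full gating discard logic;
  re-binning it reproduces the bin-level expected counts within Poisson
  tolerance.

## Gating

The acceptance reference is the single-pass arithmetic mean of all R-R
intervals; beat `i` is accepted iff `|RR_i − mean| ≤ window·mean`
(window 20%).  The trigger device's true running estimate is unknowable, and
the global mean is the simplest defensible reading.  SD_R-R uses the sample
(n−1) standard deviation of accepted beats, normalized by their mean.  Bins
are half-open `[(b−1)Δ, bΔ)`.  τ[l,b] integrates the bin-beat overlap per
angle; beat time beyond `n_bins·Δ` is discarded.

**Last-bin thinning** emulates the list-mode rebinning that produces
prescribed activity-ratio levels: retention probability
`p = target · mean(counts, bins 1–5) / counts(last bin)` applied binomially
and uniformly across angles, with τ[·, last] scaled by p.  Calibration is on
raw counts (reconstruction totals are proportional to counts to within ~1%,
verified by the totals-invariance test); no iterative recalibration against
reconstructed AR is performed by default.

## Phase analysis

Sampling replaces proprietary myocardial surface detection with
phantom-aware mid-wall sampling: up to 1008 points (36 angles × 12 slices by
default) on the end-diastolic mid-wall circle, each reading the maximum
trilinearly-interpolated activity along a radial search segment wide enough
to follow the systolic inward excursion.  External gated series users supply
their own sampling grid.

Per point, the FFH `A0 + A1·cos(θ − φ)` is fitted by the K-point DFT with
bin-centre sample phases θ_k = 360(k+½)/K and φ the phase of the TAC
maximum (0° at the R wave); recovery is exact for pure DC + first-harmonic
signals.  Constant TACs get an undefined-phase flag; they are discarded
first and count toward the 5% lowest-amplitude rejection
(⌈0.05·n⌉ points, amplitude ties broken toward lower index).  Retained
phases fill a 360-bin (1°) histogram summarized by:

- **BW** — length of the narrowest contiguous circular arc of whole-degree
  bins holding ≥95% of the phases (the coverage is configurable; commercial
  definitions are not published, so absolute agreement with any vendor's
  numbers is not claimed);
- **StD** — sample SD after re-centring each phase into
  (μ_c − 180°, μ_c + 180°] about the circular mean μ_c (wrap-around safe);
- **ENT** — Shannon entropy of the histogram normalized by log₂360, in %.

## Statistics

Activity ratio AR = 100 × (last-bin total)/(mean of bins 1–5 totals),
computed on post-processed OSEM reconstructions in the pipelines.  Lin's
concordance correlation coefficient
`CCC = r·C_b = (σ_xy/σ_xσ_y) · 2σ_xσ_y/(σ_x² + σ_y² + (μ_x − μ_y)²)` uses
population (1/n) moments (Lin's original estimator; a sample-moment mode
exists behind a flag).  Δ indices are TOSEM − OSEM.  Repeated-measures
ANOVA machinery is deliberately out of scope.

## Study-part pipelines

A population spreads subjects evenly over the HRV range (0.02–0.12
normalized) and the delay range (0–90° on one sector), with per-subject mean
R-R drawn from 0.75–1.05 s; all randomness derives from one master seed via
spawned seed sequences, making every pipeline bit-reproducible.

- **Part 1** — per subject: simulate, gate, OSEM-reconstruct, compute
  (SD_R-R, AR); report the scatter and Pearson r.
- **Part 2** — thin each subject's last bin to a reference level and to
  reduced levels, reconstruct with OSEM and/or TOSEM, phase-analyse, and
  compute per-index CCC between reference and each level across subjects.
  Subject selection follows the exclusion rule (native ratio must reach the
  top level) by default; a clamp policy instead thins only as far as the
  native ratio allows, retaining populations whose HRV range puts most
  subjects below 90% — the regime the default population deliberately
  covers.  One thinning draw per distinct target level, so a level equal to
  the reference is a true self-comparison (CCC = 1).
- **Part 3** — both reconstructions at native AR; Δ indices and their
  Pearson correlations with AR.

Programmed-delay verification averages fitted phases per sector with
amplitude weighting over sector interiors (±20° of the sector centre),
excluding boundary points whose phases are mixed by tangential
reconstruction blur; at desk resolution a 45° programmed delay is recovered
within ~3°.

## Numerical choices and limitations

- ε = 1e−12 in both EM ratio denominators; zero-count handling is an
  implementation choice, stated as such.
- Blur kernels truncate at 4σ; rotation kernels at 3σ_r.
- The phantom omits attenuation, scatter, apex geometry, perfusion defects,
  breathing, and intra-bin motion blur; its sectors have hard angular
  boundaries.  Conclusions about real patient data are limited accordingly:
  the package demonstrates the mechanism and the estimator contracts, not
  clinical accuracy, and population-specific published values (index means,
  CCC tables, regression slopes) are not reproduction targets.
- At desk scale the wall (10 mm) is ~2.5 voxels; phase-index absolute values
  are resolution-dependent, while their concordance structure is not.
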