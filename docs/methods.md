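# Methods

This note documents the models, parameter choices and numerical decisions
behind nbquant, and what the synthetic-data tests do and do not establish
about real microscope data.

## Image model and units

All analysis runs on 8-bit intensity grids (a.u. in [0, 255]) with a
physical voxel size (dz, dy, dx) in µm, axis order Z, Y, X, 0-based
indices. 16-bit sources are linearly min–max rescaled per channel on input
and the scale factors are logged; "0–256 a.u." thresholds are interpreted
on the standard 8-bit range with 256 as an exclusive bound. Confocal
sampling is anisotropic (dz ≥ dx typically); every physical parameter is
converted per axis and no step assumes isotropy.

## Stage 1: nuclei

* Whole-nucleus threshold 12 a.u. and dense-chromatin threshold 28 a.u.
  are the published protocol values; comparisons are inclusive (a voxel at
  exactly the threshold is kept).
* Components are 26-connected, matching the ImageJ 3D convention of the
  plugin family the original workflow used.
* Holes are filled slice-wise and then in 3D because nucleoli are DAPI-dark
  but belong to the nucleus.
* `min_nucleus_volume` (default 50 µm³) is an artifact of this package, not
  the protocol: it rejects debris far below any mammalian nucleus and is
  exposed in the config. There is no upper size filter and no watershed
  splitting — touching nuclei merge and are expected to be removed by QC,
  as the original manual selection did.
* Border-touching nuclei are flagged (`border_auto`), not dropped; with
  `exclude_border` they are excluded from analysis rows but remain in the
  table. An optional saturation flag excludes nuclei with > 1% saturated
  protein voxels.

## Stage 2: bodies

Chain: blur → maxima → seeded segmentation → size filter.

* **Blur.** σ = 1 µm (protocol value), per-axis kernel σ/voxel-pitch,
  reflect boundary handling (conserves the mean to < 0.1% away from
  borders).
* **Maxima.** A candidate is a 26-neighbourhood local maximum (restricted
  to the nucleus mask) whose threshold-image value is ≥ 16 a.u. The noise
  tolerance 0.25 a.u. is a prominence rule: a candidate survives iff it
  exceeds its highest saddle to any *higher candidate* by ≥ 0.25.
  Prominence is measured against higher candidates, not against arbitrary
  higher voxels: on a smooth dome carrying sub-tolerance noise wrinkles,
  the wrinkles must not be able to absorb the dome's one legitimate seed.
  The rule is computed exactly by a union-find sweep in decreasing
  intensity order (topological persistence), with ties broken by ascending
  (z, y, x) so one seed survives per plateau and results are deterministic.
  The sweep is restricted, provably without effect on the result, to
  voxels above (weakest candidate − tolerance). A brute-force oracle
  (per-candidate flood search over all saddle paths) confirms equivalence
  on small grids. Seeds closer than 0.5 µm in XY *and* 0.5 µm in Z keep
  only the brighter member.
* **Threshold placement.** The protocol lists blur → maxima → segmentation
  with a threshold of 16 a.u. but does not say whether the threshold acts
  on the raw or the blurred image. The package defaults to the **raw**
  image for both seed validation and the segmentation domain, because the
  blurred alternative is dimensionally untenable: a physically sized
  σ = 1 µm kernel spreads a body's intensity over ≈ (2π)^{3/2}σ³ ≈ 16 µm³,
  so even a 1-µm body at the 8-bit maximum (integrated intensity
  ≤ 255·(π/6) ≈ 134 a.u.·µm³) peaks below 9 a.u. after blurring — no real
  body could ever pass 16. On the raw image the threshold is meaningful,
  while the blurred image (where smoothing divides the noise floor by
  ~50) is exactly where a 0.25 a.u. noise tolerance makes sense. The
  blurred-threshold variant remains available (`threshold_on="blurred"`).
* **Segmentation.** Domain voxels are assigned to the seed with the
  smallest anisotropy-weighted geodesic distance through the domain
  (multi-source Dijkstra over the 26-connected domain graph; equidistant
  voxels settle deterministically by (distance, index) heap order);
  unreachable domain voxels are dropped. A watershed-on-blurred-intensity
  mode is available behind `assignment="watershed"`. "Minimum object size
  0.1 µm" is dimensionally ambiguous in the protocol (length vs volume);
  it is applied to the mean XY bounding-box extent — the same definition
  as the diameter metric, keeping one size notion throughout.

## Stage 3: morphometry

Diameter = (X extent + Y extent)/2 with inclusive voxel extents
((max − min + 1)·pitch), so a single voxel has the size of one voxel; the
Z extent never enters. Maximum gray value is read from the raw image, so
it is not bounded below by the segmentation threshold. Per-nucleus means
are plain arithmetic means and are *absent* (empty CSV fields), never
zero, for body-free nuclei. A Rayleigh-limit helper (0.61·λ/NA) defaults
to λ = 530 nm — the Alexa 488 emission region, chosen because the imaging
system's stated limit (~0.26 µm at 40×/1.25 NA) back-computes to that
wavelength — and flags sizes below optical meaning.

## Quality control

Exclusions mirror a manual workflow: an explicit id list (artifacts,
cytoplasmic-overlap cells) plus the automatic border/saturation flags.
Excluded rows stay in the table with `excluded=True`; statistics consume
only non-excluded rows, and the summary reports the percentage excluded to
one decimal. The cytoplasmic flag — median protein intensity in a 3-voxel
shell outside the nucleus ≥ 0.5× the median inside — is a reproducible
surrogate for a visual judgement; it feeds the categorical analysis only
and never auto-excludes. The 0.5 ratio is a package default with no
protocol counterpart; the flagged set shrinks monotonically as the ratio
rises.

## Statistics

* Exact r×c test: full enumeration of tables with the observed margins;
  two-sided p sums the probabilities of tables no more probable than the
  observed one (relative tolerance 1e-12 on the comparison). Enumerated
  probabilities sum to 1 to 1e-9. For 2×2 this equals classical Fisher.
* Mann–Whitney: U counts first-sample wins plus half-ties (U + U′ = n₁n₂).
  Exact p (two-sided around n₁n₂/2) via the shift algorithm on doubled
  midranks whenever n₁n₂ ≤ 400 — exact under ties — otherwise a
  tie-corrected normal approximation without continuity correction.
* Jonckheere–Terpstra: JT = Σ_{i<j} U_{ij} with "later group greater"
  wins, tie-corrected null mean and variance (verified against exhaustive
  enumeration), two-sided p; decreasing trends give z < 0. Degenerate
  all-tied data yield z = 0, p = 1. Exact-enumeration and seeded
  permutation modes exist alongside the normal approximation; under an
  exchangeable Poisson null at group sizes 54/33/42 the normal-approximate
  test rejects at 5.4% for α = 0.05 (2000 simulations). JT runs only when
  group medians are monotone in the declared order (the trend-consistency
  gate), overridable with `always_run_jt`.
* Kendall τ-b with tie corrections on both variables, computed per nucleus
  on (group rank, value); two-sided tie-corrected normal p. Undefined
  (reported absent) for constant values.
* Shapiro–Wilk delegates to scipy's published implementation. All
  Bonferroni adjustments are min(1, m·p).

## Synthetic data: what it emulates and what it does not

The generator renders ellipsoidal nuclei (DAPI ≈ 20 a.u. nucleoplasm —
between the two DAPI thresholds — with dense blobs at +40), a protein
channel with 10 a.u. nucleoplasm, isotropic-in-µm Gaussian bodies, optional
cytoplasmic haze (+18 outside the nucleus) for flagged cells, and additive
Gaussian noise (σ = 2), on 0.5 × 0.2 × 0.2 µm voxels. Cohorts follow the
study design: three ordered groups of 54/33/42 nuclei with Poisson body
counts of means 8/6/4.5 (old-group median ≈ 4.5), cytoplasmic-labeling
probabilities 16.7%/15.2%/0%, and ≤ 8 nuclei per field, which yields
exactly 18 images for 129 nuclei. Everything is reproducible byte-for-byte
from (spec, seed).

A planted body's "diameter" is defined operationally as the width at which
its rendered profile crosses the default segmentation threshold
(σ_spot = d / (2√(2 ln(peak/(16 − nucleoplasm))))), so a perfect
segmentation recovers the planted value; peaks are drawn from 210–255 a.u.
(SNR ≥ 100 against the σ = 2 noise).

Two regimes matter:

* **Default regime** — nuclei ~12–14 µm wide, bodies 1.2–1.6 µm at ≥ 2 µm
  centre separation. Under the σ = 1 µm blur, bodies closer than ~3 µm
  merge into one detected maximum, so pipeline counts *undercount* planted
  truth here (e.g. 552 detected vs 802 planted on one seed) while the
  ordinal structure (decreasing medians, negative JT z, categorical flag
  pattern) survives intact. This mirrors a genuine optical-scale
  limitation of the published parameter set, not an implementation bug.
* **Recovery regime** (`recovery_spec()`) — same spot model at ≥ 3.2 µm
  separation inside proportionally larger synthetic nuclei (scaled so that
  up to 33 mutually resolvable bodies fit; these are deliberately larger
  than real cumulus-cell nuclei). Here exact count recovery holds for
  ≥ 95% of nuclei over k ∈ {0..33} and planted diameters are recovered
  within ±2 lateral voxels. Count-recovery claims exclude cells with
  cytoplasmic haze: haze bleeding across the nuclear rim can create
  spurious rim candidates, which is precisely why the original workflow
  excluded cells with overlapping cytoplasmic label from quantification.

The simulator is not optics-accurate: no PSF anisotropy beyond voxel
anisotropy, no photobleaching, no spectral crosstalk, hard-edged nuclei.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under a controlled image model, not segmentation accuracy on
any particular microscope's data.

Sub-micron bodies (0.2–1.0 µm), though biologically typical of Cajal
bodies, are *not* planted by default: under a physical σ = 1 µm blur an
8-bit sub-micron spot cannot clear the 0.25 a.u. prominence rule once
neighbours are nearby (see the threshold-placement analysis above). With a
smaller blur (e.g. `sigma_um=0.25`, plausibly the effective setting of
pixel-calibrated workflows) sub-micron spots are recoverable; the config
exposes this, but defaults follow the stated protocol values.

## Problem sizes used in the shipped checks

Enumeration oracles run at n ≤ 8 per group; JT calibration uses 2000
simulations at the study's group sizes; spot recovery uses 100 rendered
nuclei with k uniform on {0..33}; end-to-end determinism uses a 14-nucleus
cohort processed twice. The full default cohort (18 images, 129 nuclei)
renders and processes in well under a minute on one CPU.

## Known limitations

* Touching nuclei are not split; they merge and should be excluded by QC.
* The exact maxima-suppression internals of the original ImageJ plugin are
  unpublished; equivalence is claimed only against this package's stated
  prominence definition (and its brute-force oracle), not against the
  plugin binary.
* Whether the original per-cell intensity aggregates by the mean of
  per-body maxima (as here) or the per-cell maximum is not documented;
  the mean is used.
* The Kendall correlation is computed on per-nucleus (group rank, value)
  pairs; per-animal aggregation is not supported.
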