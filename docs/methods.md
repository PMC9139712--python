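# Methods

This note records the models, parameter choices and numerical decisions
behind `acidox`, and what the synthetic data do and do not establish.

## CEST quantification

A z-spectrum is the normalized saturated signal Z(Δω) = S(Δω)/S₀ over
frequency offsets Δω (ppm from water). The pH-sensitive readout is the
band-averaged asymmetry at the amine resonance,

MTR_asym = 100·(⟨S(−Δω)⟩ − ⟨S(+Δω)⟩)/S₀ with Δω averaged over 3.0 ± 0.5 ppm.

Band averaging (default halfband 0.5 ppm) is used rather than a point
evaluation because it is robust to noise and offset-grid placement; a point
mode (`halfband_ppm=0`) is available. Negative values are retained — the
downstream per-patient features are medians and are robust to them.

**B₀ handling.** Static-field inhomogeneity shifts each voxel's spectrum;
uncorrected, a 0.3 ppm shift biases MTR_asym by several percentage points.
The per-voxel offset is estimated from the direct-water-saturation dip in
two stages: a dense cubic-spline argmin, then refinement by mirror-symmetry
matching — the center c minimizing Σₓ (S(c+x) − S(c−x))² over x ∈
0.15–1.0 ppm. The dip is an even function of Δω − B₀, so the symmetry
objective locates it far below the offset spacing (≈10⁻³ ppm on 0.25 ppm
grids); crucially its small residual bias (from the asymmetric amine
shoulder) is independent of the shift itself, so re-estimating after
correction returns ≈0 and a second correction changes MTR_asym by <10⁻³ %.
A plain argmin does not have this property. Flat spectra get offset 0 and a
low-confidence flag.

**Correction.** Each spectrum is re-interpolated (cubic spline; linear for
<5 offsets) at the shifted offsets. A voxel is invalidated — never
extrapolated — when an offset inside the ±(2.5–3.5) ppm asymmetry band
would leave the acquired range; unused edge offsets are edge-held. The
default acquisition grid therefore spans ±4 ppm in 0.25 ppm steps, keeping
the band valid for |B₀| ≤ 0.5 ppm.

## SAGE relaxometry

The two-regime model (gradient-echo decay at rate R₂* before TE_SE/2, mixed
decay at rate 2R₂ − R₂* after, with the inter-regime amplitude δ) is fit
per voxel by Levenberg–Marquardt on the untransformed residual, initialized
by exact log-linear regression per regime. The initialization is exact on
noiseless data, giving machine-precision round trips; on noisy data the
refinement matters because log-domain fitting would weight low-signal
echoes incorrectly. δ is a free parameter by default (slice-profile
mismatch); `pin_delta=True` fixes δ = 1 and is used for phantom pipelines
where the generator's truth is δ = 1. Default echo times are 8, 28, 60, 80
and 100 ms with the spin echo at 100 ms — two echoes per regime is the
structural minimum and is validated on construction. R₂′ = R₂* − R₂ may be
negative under noise and is reported unclamped. Voxels with non-positive
signals are masked; failed refinements keep the log-linear estimate and are
flagged.

## DSC perfusion

Signal is converted to ΔR₂*(t) = −ln(S/S̄_base)/TE against the pre-bolus
baseline (≥5 timepoints). rCBV is the trapezoidal integral of ΔR₂* over the
acquisition (configurable window), divided by the NAWM median — making the
NAWM median exactly 1, an assertable invariant, and the map invariant to
global signal scaling. Leakage correction (default on) follows the
two-regressor linear-fitting approach: each voxel's curve is regressed on
the NAWM median curve and on minus its running integral, and the fitted
leakage term is added back before integration. No arterial-input
deconvolution is attempted: the pipeline reports relative blood volume
only.

## Segmentation

The three tumor compartments are mutually exclusive by construction: CET =
voxels above `subtraction_hi` on the NAWM-normalized post-minus-pre T₁
subtraction map (26-connected components ≥ 0.1 cm³, restricted to
components touching an optional seed mask — the semi-automated
interaction); necrosis = voxels below `subtraction_lo` inside the filled
CET hull; NET = FLAIR-hyperintense voxels minus both. Thresholds default to
reference-tissue statistics (mean ± 2·SD), all config-exposed. The NAWM
reference mask is the brain minus the tumor dilated by 2 voxels, with
extreme FLAIR intensities (CSF-like or lesion-like) trimmed. Volumes are
voxel counts × voxel volume, in cm³.

## Per-patient features

Medians of MTR_asym, R₂′, rCBV and the voxelwise product MTR_asym × R₂′
over CET ∪ NET (necrosis excluded); tumor volume; acidic tumor volume =
volume of tumor voxels with MTR_asym above atlas mean + k·SD (default
k = 2, atlas statistics from NAWM for synthetic runs, accepted as config
for real data). The combined feature is median-of-product by default
because the product is a map first; product-of-medians is available via
`product_of_medians=True` since on heterogeneous tissue the two differ.
Missing modalities (e.g. single-echo scans without R₂′) propagate as NaN —
never zero — and drop the patient from affected analyses only.

## Statistics

Two-group comparisons are gated on Shapiro–Wilk normality (α = 0.05 per
group): Welch's t when both pass (unequal variances assumed for
robustness), Mann–Whitney U otherwise, exact for n ≤ 20 without ties and
normal-approximated with tie correction beyond. Tissue-type comparisons use
Kruskal–Wallis with Tukey–Kramer contrasts on pooled-rank means via the
studentized-range distribution. ROC analysis sweeps unique score values
(higher score = positive class); AUC is the trapezoidal area, identical to
tie-corrected pairwise concordance; the operating cutoff maximizes Youden's
J with ties broken toward higher specificity (max-accuracy optional). All
tests are two-sided at α = 0.05; no multiplicity correction is applied
across feature–genotype pairs.

Cox models maximize the Efron-tie partial likelihood (via lifelines) with
Wald CIs and p-values; constant covariates and non-convergence (e.g.
separation) raise diagnostics naming the covariate. Kaplan–Meier curves and
the log-rank chi-square stratify continuous variables at the median (ties
to the low group; degenerate splits are errors). The survival report mirrors
the clinical analysis design: univariate fits for age, treatment status and
IDH; univariate plus clinical-covariate-adjusted fits for each imaging
feature, with per-row n reflecting missing features. 1p/19q and EGFR are
not used as covariates (incomplete and collinear with IDH).

## Synthetic data

**Single-patient phantoms** place concentric jittered ellipsoids
(non-enhancing rim ⊃ enhancing shell ⊃ necrotic core) in an ellipsoidal
white-matter brain on a 48×48×16 grid of 2×2×4 mm voxels. Class parameters
(MTR_asym 1.0/2.2/1.8/1.5 %, R₂′ 4/7/5.5/3 1/s, CBV 1/2/1.3/0.25 for
NAWM/CET/NET/necrosis) are class-constant and chosen in the ranges reported
for gliomas, with anatomical intensities that make the compartments
threshold-separable. The z-spectrum generator is a 3-pool Lorentzian sum
(water FWHM 2.2 ppm, amine at +3.0 ppm FWHM 1.6 ppm, broad symmetric MT
pool); the amine amplitude is calibrated per voxel so the noiseless
band-averaged asymmetry on the acquisition grid equals the true MTR_asym,
which is what makes simulator→estimator a strict identity. Noise is
additive Gaussian (SD = noise_sigma·S₀) with a Rician option; at the
simulated SNRs the distinction is second-order. B₀ fields are smooth
low-order cosine mixtures.

**Cohorts** draw per-patient median features from genotype-group normal
distributions — defaults are the IDH-mutant vs wild-type group statistics
(MTR_asym 1.48 ± 0.45 vs 1.73 ± 0.50 %; R₂′ 5.17 ± 1.74 vs 5.94 ± 1.54
1/s; rCBV 1.19 ± 0.44 vs 1.69 ± 0.85) at group sizes 70/89. The combined
feature is the product of the two draws (independent within genotype).
Survival times follow an exponential-baseline proportional-hazards model;
default log-hazards mirror the clinical directions (age +0.034/yr centered
at 52, active treatment +1.32, IDH mutation −2.37, combined feature +0.13
for OS), with baseline hazards set for a median OS of roughly 500 days in a
typical wild-type patient. Censoring is independent exponential with
per-patient rate λᵢ·c/(1−c), which makes each patient's censoring
probability exactly c (OS default 0.60, PFS 0.50, matching the cohort's
event counts). Everything is deterministic given the spec seed.

**What the phantom does not model:** Bloch–McConnell exchange dynamics,
EPI distortion and motion, partial-volume mixing at class boundaries,
realistic arterial input functions, spatial noise correlation, and any
correlation structure between imaging features beyond the shared genotype.
Passing tests therefore establish the correctness of the estimators and
statistics under the stated generative models — not clinical performance
on patient data.

## Problem sizes and determinism

Round-trip identities run on parameter grids (the full integer R₂ × R₂′
grid, 416 voxels; MTR_asym 0–4 %); noisy estimator checks use 10²–10³
voxels; power and calibration properties use 200–1000 replicates at the
cohort sizes above. These sizes make every Monte-Carlo assertion stable at
the fixed seeds used in the test suite. All generators take explicit seeds
and are reproducible bit-for-bit.

## Known limitations

- The B₀ estimator assumes a dominant, locally symmetric water dip; heavy
  overlap from large solute pools would bias it.
- The SAGE fit assumes the two-regime piecewise model exactly; echoes in
  the transition region are assigned by TE thresholding.
- Leakage correction uses the NAWM median curve as the reference response,
  which is a first-order model of extravasation.
- Threshold segmentation has no spatial regularization beyond
  connected-component filtering; heavily overlapping intensity
  distributions will degrade Dice even at the oracle-best threshold.
- The acidic-volume threshold rule (atlas mean + k·SD, k = 2) is a
  documented stand-in; k is config-exposed.
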