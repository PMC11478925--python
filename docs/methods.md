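# Methods

`mrsdss` implements a complete, self-contained analogue of a clinical
single-voxel proton MRS (¹H-MRS) decision-support pipeline for the three
major childhood cerebellar tumours — pilocytic astrocytoma (PA),
ependymoma (EP) and medulloblastoma (MB): forward simulation of
short-echo PRESS acquisitions, linear-combination metabolite
quantification with Cramér–Rao quality control, a linear-discriminant
classifier with posterior probabilities, the rendered decision-support
output, and the reader-study statistics used to quantify added
diagnostic value.

## Signal model and synthesis

Acquisition defaults model a 1.5 T PRESS protocol: TE 30 ms, TR
1500 ms, 2048 complex points at 2097.152 Hz (1.024 Hz per point), cubic
voxel, 128 water-suppressed averages and an 8-average unsuppressed
water reference. The transmitter is on-resonance with water, mapped to
4.7 ppm; internal spectra are frequency-ascending and only display code
reverses the axis.

The basis holds 26 components: 16 metabolites (Ala, Asp, Cr, GPC, PCh,
Glc, Gln, Glu, Gua, Gly, Ins, Lac, NAA, NAAG, Scyllo, Tau), nine broad
macromolecule/lipid components (MM09–MM20, Lip09–Lip20) and a negative
creatine-CH₂ correction singlet at 3.94 ppm. Multiplets are fixed peak
lists (chemical shift, proton-weighted amplitude, linewidth,
Lorentzian/Gaussian tag) — no density-matrix simulation; amplitudes are
normalised so each component's FID starts at unit signed amplitude per
mM, which makes fitted amplitudes concentration-like by construction.
MM components are wide Gaussians (24–30 Hz), lipids narrower
(12–22 Hz); each MM/lipid component carries a group tag (MMLip09/13/20)
assigned to the nearest of 0.9, 1.3 and 2.0 ppm.

A simulated FID is the concentration-weighted sum of component FIDs,
subjected in order to: a frequency-linear phase error (pivot 3.0 ppm,
applied in the frequency domain), a zero-order phase error plus an
exponentially decaying eddy-current phase `A·exp(−t/τ)`, and complex
Gaussian noise (per-quadrature SD). The water reference carries a
single 4.7 ppm resonance scaled by the assumed water concentration
(35,880 mM), the *same* eddy phase, and noise scaled by
`sqrt(n_averages / n_water_averages)`. Applying the linear phase before
the eddy phase is a modelling choice that makes the pointwise
water-reference correction an exact inverse of the eddy term.

Class-conditional cohorts draw concentrations from a per-class
multivariate normal (YAML-configured means, diagonal covariance with
22% CV), resampling (not clipping) negative draws; artifact parameters
are uniform within configured ranges (φ0 ∈ ±30°, φ1 ∈ ±5°/ppm, eddy
amplitude 0–0.8 rad, decay 20–80 ms, noise SD 0.5). The class means
encode the qualitative tumour patterns: MB with high total choline,
taurine present and low myo-inositol; EP with high myo-inositol and
creatine; PA with low creatine and prominent NAA-region signal. These
profiles are emulation targets chosen to reproduce the qualitative
class patterns; they are not patient measurements.

What the generator does *not* emulate: per-metabolite frequency
shifts and J-modulation, B0 inhomogeneity lineshape distortion,
residual water, motion/frequency drift, scanner-dependent lineshapes,
and the biological covariance structure between metabolites (the
covariance is diagonal). Passing tests therefore demonstrate
correctness of the estimators under the stated model, not performance
on arbitrary in-vivo data.

## Preprocessing

* **Eddy-current correction** is the classical pointwise phase
  subtraction: each FID sample is rotated by −arg(water_ref). Samples
  whose reference magnitude falls below 1e−8 of the maximum inherit the
  previous reliable phase.
* **Fourier transform** with optional zero-filling (×1/2/4) and an
  optional 700 ms half-Hann apodization reproducing the scanner-display
  processing; the analysis path applies none.
* **Automatic phasing.** Conventional criteria failed on these
  spectra: the negative-real-area criterion is exactly degenerate
  (crowded absorption spectra remain non-negative over tens of degrees
  of misphasing), and entropy- or area-maximisation criteria inherit
  degree-level biases from the slowly decaying (1/Δf) dispersion tails
  that overlap neighbouring lines. The implemented estimator instead
  *models* the dispersion: peaks are detected on the magnitude
  spectrum, each line's sub-bin centre and width obtained from the
  local 1/|S|² parabola (exact for Lorentzians), and a small complex
  model — the exact discrete-FT lineshape of a one-sided exponential
  plus a Gaussian (Faddeeva) alternative per line and a free complex
  constant — is fitted to the complex spectrum with (φ0, φ1) and the
  line centres as nonlinear parameters and non-negative amplitudes
  (which pins the 180° ambiguity). On resolved synthetic spectra the
  constructed phases are recovered to better than 0.1°; on heavily
  overlapped tumour spectra a residual first-order bias of a few
  degrees/ppm remains and is absorbed by the quantifier's in-model
  phase parameters (below). Pivot for φ1 is 3.0 ppm throughout.
* **Water normalization** divides by the maximum magnitude in the
  4.2–5.2 ppm window (robust to residual phase) and tags the spectrum,
  refusing double normalization. It is used for display/mean-spectra;
  absolute quantification uses the water amplitude, not this peak
  maximum.

## Quantification

The fitter models the real part of the phased spectrum over
0.2–4.0 ppm as a non-negative linear combination of basis spectra
regenerated through the same FFT pipeline, plus a cubic B-spline
baseline with knots every 0.15 ppm and a second-difference curvature
penalty. Nonlinear nuisance parameters — a shared frequency shift
(±0.05 ppm), shared Lorentzian broadening (0–5 Hz) and zero/first-order
phase (±45°, ±20°/ppm) — wrap the linear subproblem (variable
projection): for any nuisance setting the penalized spline is profiled
out analytically, leaving a plain NNLS over amplitudes. A small grid
seeds a Nelder–Mead polish. The shift/broadening are shared rather
than per-component for runtime; the bounds are configuration. Fitting
the phase inside the model mirrors standard linear-combination fitters
and removes the residual auto-phase bias on crowded spectra. The
−CrCH₂ component's negative sign lives in its basis shape; its fitted
amplitude is non-negative like every other.

The baseline penalty weight is chosen by generalized cross-validation
on the unconstrained problem over a log-spaced grid, with a fixed
fallback (λ = 100) if GCV fails; baseline off and λ overrides are
configuration.

**CRLBs.** The information matrix contains every free parameter —
amplitudes, spline coefficients and the nuisance terms (finite
difference columns) — with the baseline curvature penalty added as
prior information (`F = JᵀJ + λDᵀD`), as in regularized fitters;
without it the spline/MM overlap drives cond(F) beyond 1e14 and no
bound is finite. CRLB% = 100·sqrt([F⁻¹]cc)·σ/|a_c|, reported as 999%
when undefined or non-identifiable (exact collinearity triggers a
pseudo-inverse plus null-space flagging). With the baseline off the
expression reduces exactly to the closed-form single-parameter bound,
which the tests verify to 1e−6. Noise SD is estimated from the fit
residual in the 0.2–0.5 ppm portion of the window (sparsest region of
the synthetic spectra); configurable.

**Diagnostics.** SNR = (maximum of the fitted signal)/(2·noise SD).
FWHM is measured on the strongest *single* metabolite component of the
fitted model, so broad MM humps and multiplet-cluster envelopes cannot
masquerade as the spectral resolution.

**Water referencing** uses the water amplitude in FID units — the
t = 0 value, recovered as |Σ spectrum|/N — and
conc = a/A_water × 35,880 mM, with an optional per-component proton
correction (default 1: the synthetic basis is per-proton normalised).
Relaxation corrections are out of scope.

**Feature vector.** The 16 metabolite concentrations pass through; the
nine MM/lipid concentrations collapse into MMLip09/13/20 by group tag;
−CrCH₂ is dropped — 19 variables. Feature order is canonical (sorted
metabolites, then the three groups), so it cannot depend on basis
component order. A group's CRLB is the minimum over members: the group
is considered quantifiable if any member is.

## Quality control

Spectrum level: fail if SNR < 4, FWHM > 0.1 ppm, or the fit did not
converge (reason codes returned). These gates are conventional
defaults, exposed in `QCCriteria`. Feature level: a feature is kept iff
its CRLB is below 30% in at least two subjects of the cohort —
deliberately strict inequality on the threshold and `≥` on the count.

## Classifier

Features are standardized by training means and SDs (ddof = 1). The
pooled within-class covariance is optionally shrunk toward its
diagonal (λ = 0.1 default, guaranteeing positive definiteness in the
n ≈ 34, p ≤ 19 regime; λ = 0 is classical LDA). Discriminants
`g_k(z) = zᵀS⁻¹m_k − ½m_kᵀS⁻¹m_k + log π_k`; posteriors are the softmax
of the g_k, identical to normalized Gaussian class densities. Priors
default to uniform; training frequencies or explicit values are
options. Ties break lexicographically (EP < MB < PA).

The canonical (DF) projection takes the two leading generalized
eigenvectors of the between-class scatter against the pooled
covariance, normalised so DF-space within-class covariance is the
identity and signed so the largest loading is positive. For three
classes this plane spans all between-class mean differences in the
whitened metric, so posteriors computed from DF coordinates equal the
full-space posteriors and the decision boundaries drawn in the DF
plane (straight lines per class pair, kept where that pair is top-two)
are exact; a property test enforces the equivalence. Two-class models
have a 1-D canonical space, padded with a zero axis for plotting.

Reported accuracy is the percentage of correct diagnoses, rounded
half-up to an integer (30/33 → 91%), with the exact fraction retained.

## Decision-support output

Class mean spectra are computed point-wise on baseline-subtracted,
water-normalized spectra with t-based 95% CIs (bootstrap percentile
bands behind a flag; the band is widened to contain the mean). The
three-panel report shows the case's standardized feature z-scores (the
exact values entering the classifier), the DF scatter with boundaries,
training scores and the index case, and the index spectrum over the
class means (0.5–4.3 ppm, ppm decreasing rightward). A JSON sidecar
carries posteriors, DF scores and the predicted class; rendering never
mutates its inputs.

## Reader-study statistics

Certainty tables hold one (PA, EP, MB) percentage triple summing to
100 per rater × case × stage (imaging, imaging+MRS, imaging+MRS+DSS).
Two deliberately distinct correctness predicates are used: diagnostic
*accuracy* requires certainty on the true class strictly above 50%,
while *certainty-when-correct* strata require the true class to hold
the strict maximum (so a 40/35/25 call on the true class counts as
correct there despite being ≤ 50). SDs use ddof = 1 (0 for singleton
strata).

Per-case certainty changes between stages feed a Wilcoxon signed-rank
test: zeros dropped by default (Pratt variant by flag), full 2ⁿ sign
enumeration for n ≤ 15 (handles ties exactly), otherwise the tie- and
continuity-corrected normal approximation; the Hodges–Lehmann estimate
and Walsh-average CI accompany the p-value. Levene's test defaults to
the median-centred Brown–Forsythe variant (mean-centred by flag);
Kruskal–Wallis is tie-corrected with optional exact enumeration for
total n ≤ 10; metabolite comparisons use one-way ANOVA plus pairwise
t-tests with Bonferroni adjustment.

The synthetic reader tables draw a baseline truth-class certainty
(normal, mean 45, SD 12), add a configured median shift plus noise
(SD 8) per stage transition, round to integers and split the remainder
between the other two classes; clipping at 0/100 makes large
configured shifts compress near the boundary, which the generator does
not correct for.

## Problem sizes and numerical choices

The default tests and the acceptance script use: 50 spectra for the
recovery benchmark (noise SD 1.2, giving reported SNR ≈ 10, on a fixed
benchmark profile with NAA 8, Cr 6, GPC+PCh 3 mM — healthy-brain-like
marker levels chosen so the benchmark measures estimator accuracy
rather than the information limit of near-absent tumour NAA, whose CRLB
at this SNR already exceeds 10%); training/testing cohorts of 34/33 at
the study case mix for the pipeline run; 2000 test draws against a
Monte-Carlo Bayes oracle for classifier calibration; 100 seeded
replicates of the n = 33 reader study. Unit tests that need many fits
drop to 512-point acquisitions. All sampling is through
`numpy.random.default_rng` seeded from function arguments; identical
seeds give bit-identical outputs end to end.

## Known limitations

* The linear-combination fitter is an analogue of the LCModel approach,
  not a re-implementation: control parameters, regularization and basis
  provenance of the original software are proprietary or unpublished.
* Shared (not per-component) shift/damping cannot capture differential
  frequency drift between metabolites.
* Auto-phase retains a few-degrees/ppm first-order bias on heavily
  overlapped spectra; downstream fitting compensates, but standalone
  use on crowded in-vivo data should treat φ1 as approximate.
* The diagonal class covariance understates real metabolite
  correlations, making synthetic classification easier than the
  clinical task; classifier evaluation here validates the machinery,
  not the clinical accuracy figure.
* No relaxation, tissue-water or partial-volume corrections are
  applied to concentrations.
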