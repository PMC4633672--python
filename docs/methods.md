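# Methods

## Forward model (simulator)

Each synthetic subject lives on a 4×48×48 grid scanned for 60 frames at
TR = 2.22 s, TE = 36 ms, with 8 pre-bolus baseline frames — a standard
low-grade-glioma DSC protocol at desk scale. The arterial bolus is a
peak-normalized gamma-variate,

    Ca(t) = A · ((t−t0)/(αβ))^α · exp(α − (t−t0)/β),   t > t0,

with α = 3, β = 1.5 s, t0 = 10·TR, and peak amplitude A = 20 s⁻¹ (a
mid-range arterial peak ΔR2* at this echo time). Any smooth unimodal bolus
would do; the gamma-variate is the field standard and has closed-form
moments. Tissue follows the indicator-dilution model
C(t) = CBF·(Ca ⊗ R)(t) with an exponential residue R(t) = exp(−t/MTT),
chosen for its closed-form checks; the central volume theorem CBV = CBF·MTT
then holds exactly, and because the concentration-to-ΔR2* proportionality is
set to 1 (only *relative* CBV is ever reported), the ground-truth rCBV of a
voxel is literally cbf·mtt. MTT is drawn from a discrete 3.0–6.0 s grid
(0.05 s steps) so the simulator convolves once per unique value; the
convolution runs on an internal fine grid (TR/16) and is sampled at frame
times, which keeps the trapezoidal discretization error of all area ratios
well under 1%.

Non-tumor parenchyma draws rCBV uniformly from 0.5–0.9: in raw
tissue-to-arterial AUC-ratio units, normal white/gray matter sits below 1,
and tumor values rise above it. A 2×4×4 corner block (~0.3% of voxels, a
realistic vascular fraction) carries arterial kinetics — arrival 2·TR
earlier and a narrower bolus (β = 1 s) whose frame-sampled area is matched
exactly to the tissue-generating bolus, so the curve the detector finds is
the self-consistent normalizer for the AUC-ratio rCBV. The block is large
enough that the detection filters cannot statistically exterminate it at the
default noise level.

Signal is S = S0·exp(−TE·ΔR2*) with S0 = 1000; Gaussian noise of
sd `noise_sd` (default 20, i.e. baseline SNR 50) is added and the magnitude
taken, since MR magnitude data are Rician and never negative. The FLAIR
volume is 100 (background) / 150 (tumor, +50%) with 2% texture noise in the
noisy regime and none in the noise-free regime.

### Genotype classes

Subject-level tumor rCBV medians are log-normal per class, fitted to the
target median and IQR (mutant 1.09, 0.80–1.47; wild-type 2.08, 1.49–2.57):
μ = ln(median), σ = ln(q₃/q₁)/(2·z₀.₇₅). Within a subject, voxel rCBV is
Gamma-distributed, rescaled so its population median equals the subject
median — right-skewed and strictly positive, matching observed tumor rCBV
histograms. The Gamma shape differs by class: 4 for mutant, 2 for
wild-type. Wild-type gliomas are angiogenically heterogeneous, with
high-rCBV hotspots; the heavier wild-type tail concentrates the class
separation in the upper histogram percentiles, which is exactly the regime
in which the upper percentiles are the best discriminators. Class sizes
default to 59 mutant / 14 wild-type, the mutant predominance typical of
treatment-naive low-grade and anaplastic glioma cohorts. Leakage (below) is
injected into a configurable fraction (default 25%) of tumor voxels with
K2 ~ U(0.01, 0.1) s⁻¹. Tumor size is a configuration knob
(`tumor_radii`, default ≈ 416 voxels across two slices); no claim is made
that any particular voxel count is representative.

## Quantification

**Concentration.** ΔR2*(t) = −ln(S(t)/S0)/TE with S0 the per-voxel mean of
the baseline frames — the universal DSC relation. The log argument is
floored at 10⁻³·max(S0) so that noise troughs in magnitude data cannot
produce infinities; negative ΔR2* values (noise, T1 effects) are preserved.

**AIF detection.** Candidates are in-brain voxels (i) in the top quartile of
curve AUC, (ii) whose post-bolus tail returns to within 2 baseline-noise SDs
of zero (leakage-affected voxels drift away from baseline and must not seed
the arterial cluster), and (iii) whose tail roughness (sum of squared second
differences over the final third of the series) is at or below the candidate
median. Roughness is measured on the tail because it is a *noise* filter:
over the first pass, the artery is legitimately the sharpest curve in the
image. Candidate curves are normalized to unit area and clustered by
k-means (k = 5, fixed seed); the cluster with the earliest mean first moment
(computed on the positive part of each curve) is kept and re-clustered once
more, provided at least 5k voxels remain — re-clustering a small homogeneous
arterial cluster would only split it along noise. The AIF is the mean raw
curve of the final members.

**rCBV.** Per voxel, the trapezoidal AUC of ΔR2* over the first-pass window
— baseline end to baseline end + 50 s — divided by the AIF's AUC over the
same window; negative ratios are floored at 0, consistent with histogramming
on [0, 7.5). The window covers bolus transit plus washout for tissue MTTs up
to ~6 s (truncation < 0.1%) while not accumulating baseline-S0 estimation
noise over the whole series, and it is configurable (`window=`) for
acquisitions where recirculation behaves differently. No
normal-appearing-white-matter normalization is applied: rCBV is the raw AUC
ratio.

**Leakage correction.** The reference curve is the mean ΔR2* over non-tumor
in-brain voxels whose tails return to baseline (rule as above, with a 10⁻⁸
absolute floor so the criterion stays meaningful in the noise-free limit).
Each voxel is fit by linear least squares to
measured(t) ≈ K1·ref(t) − K2·∫₀ᵗref, and corrected(t) = measured(t) +
K2·∫₀ᵗref. The simulator injects leakage through the same linear model
against the same reference definition, so the correction is exactly
invertible on model-consistent voxels — a designed property that the tests
exploit — while tumor voxels with their own kinetics are corrected
approximately, as in real data. When no tumor mask is supplied the
tail-return rule alone selects the reference.

**Deconvolution.** The AIF is zero-padded to 2T and embedded in an L×L
circulant matrix A with A[i,j] = Δt·Ca((i−j) mod L); singular values below
λ·σ_max are zeroed and CBF is the maximum of the solved residue — invariant
under circular shifts of the tissue curve, hence delay-insensitive (measured
change < 10⁻⁹ under shifts of up to 3 frames). The truncation threshold
trades noise robustness against systematic underestimation: with the default
λ = 0.10, noise-free CBF is underestimated by roughly a third with this
bolus shape (the known truncation bias of fraction-threshold deconvolution);
at λ = 0.01 the noise-free error is about −5%, and below the operator's
condition floor the inversion is exact. Accuracy checks therefore run at
small λ in the noise-free regime; λ = 0.10 remains the default for noisy
maps. The MTT map is rCBV/CBF (central volume) and inherits the CBF bias;
rCBV itself never passes through the deconvolution, so the histogram
analysis is unaffected.

## Segmentation

Region growing from an operator seed, in-plane with 8-connectivity, with a
fixed inclusion band (1±tolerance)·m₀ around the mean m₀ of the seed's 3×3
in-plane neighborhood (default tolerance 0.2); converged slices seed their
vertical neighbors, and iteration continues to a fixpoint with deterministic
raster scan order. A fixed band — rather than a running region mean — makes
the mask monotone in the tolerance (nested bands give nested reachable
sets) and anchors the region to the tissue class the operator clicked: a
running mean drifts when a wide band floods into background and then
excludes tumor voxels a narrower band accepted. Operator vetoes (e.g.
leukoaraiosis that would otherwise merge with the tumor) enter as an
explicit exclusion mask rather than an automated rule. In the pipeline, the
operator's click is emulated by the maximum of a lightly smoothed FLAIR
volume. Growth is 2-D with inter-slice propagation, matching slice-by-slice
manual workflows; a full 3-D flood would differ only for tumors whose slices
connect exclusively out-of-plane.

## Statistics

Histograms use 50 half-open bins of width 0.15 on [0.0, 7.5); frequencies
are relative to *all* tumor voxels, so voxels at or above 7.5 lower the row
sum instead of being silently renormalized away, and the same voxels still
contribute to percentiles. Percentiles use type-7 linear interpolation.

Group comparisons use the Mann-Whitney U with midranks, tie-corrected
normal variance, no continuity correction; positive z means wild-type
higher. An exact mode enumerates all rank assignments for small samples and
is cross-checked in the tests against an independently coded enumeration.

For each percentile level, a single-predictor logistic model (IRLS/Newton;
mutant = positive class) provides the full-data odds ratio per one-unit
rCBV with Wald CI and p — reported also as (1−OR)·100, the percent decrease
in mutation odds. Classification metrics (accuracy, PPV, NPV at predicted
probability 0.5) come from leave-one-out cross-validation, each fold refit
from the full-data estimate; a fold with perfect separation falls back to a
ridge-stabilized fit (penalty 10⁻⁴) with a logged warning. The AUC is the
nonparametric ROC area of the marker itself with the orientation fixed a
priori by the biology (higher rCBV ⇒ wild-type); it equals U/(n₁n₂), and
its 95% CI comes from DeLong's structural components. Pooled leave-one-out
probabilities are *not* ranked for the AUC: each fold's slope is
anti-correlated with its left-out label, which drives the null AUC far
below ½ (measured ≈ 0.36 at n = 200) — a pure artifact of pooling
cross-validated scores, not a property of the marker. No multiple-testing
correction is applied across percentile levels; p < 0.05 is the declared
threshold and full-precision p-values are always reported.

## Pipeline

Stages run simulate → segment → quantify → analyze. Segmentation precedes
quantification because the leakage corrector excludes the segmented tumor
from its reference tissue, and the FLAIR it needs exists as soon as
simulation ends; the stages otherwise touch only their declared files. One
global seed derives all stage seeds through a seed sequence; repeated runs
are byte-identical in every tabular output. The effective configuration and
a per-stage SHA-256 manifest are written next to the outputs.

## What the synthetic data do and do not show

The generator reproduces the bolus kinetics, leakage contamination, class
rCBV distributions, and FLAIR contrast that the analysis consumes, with
exact ground truth for every map. It does not simulate motion, partial
volume, slice timing, recirculation, prebolus T1 physiology, or anatomy
(the "brain" fills the grid; the artery is a block; the tumor is an
ellipsoid). Passing tests therefore demonstrate that the algorithms recover
known truth under the stated forward model and noise — they do not certify
performance on patient data, where registration error, dispersed AIFs, and
heterogeneous T1/T2* leakage mixtures are the dominant failure modes.

## Problem sizes

Desk-scale defaults keep every experiment reproducible in minutes on one
core: 4×48×48×60 subjects (~0.25 s to simulate, ~0.5 s to quantify),
73-subject cohorts for the study-scale analysis, 200-replicate cohort
sweeps and 500-replicate permutation nulls for calibration checks.
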