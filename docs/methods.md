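# Methods

This note records the models implemented in `clonoscreen`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want written down.

## 1. The screen model and the SRF statistic

A well seeded with `n` cells at plating efficiency `PE` forms colonies as

    count ~ Poisson(n · PE · S)

with the survival term factorized as

    S_drug(x) = 1 / (1 + (x / IC50)^h)          (Hill survival)
    S_IR(D)   = exp(−(αD + βD²))                (linear-quadratic)
    S_combo   = S_drug(x) · exp(−f·(αD + βD²))

The radiosensitization factor `f` multiplies the radiation *log-kill* in
drug-containing irradiated wells. This parameterization was chosen because
it makes the expected SRF analytically computable: the drug term cancels
and

    E[SRF(x)] ≈ S_IR(D)^(1−f),

so `f = 1` (independence) gives SRF = 1 exactly, and `f = 2` at 2 Gy with
the default α = 0.3 Gy⁻¹, β = 0.03 Gy⁻² gives SRF = e^0.72 ≈ 2.05, safely
above the 1.5 hit threshold. Nothing in the screen literature prescribes a
generative interaction mechanism; a log-kill multiplier is the simplest
model whose null is exactly multiplicative independence.

Defaults mirror the screen design throughout: 50 cells/well, triplicate,
seven ten-fold concentrations 10 µM → 10 pM, a single 2 Gy arm, PE = 0.8
(a realistic plating efficiency for an aggressively growing line),
drug IC50 = 1 nM with Hill slope 2 for the generic compound. Counts are
Poisson (independent plating); a negative-binomial switch
(`overdispersion=k`, variance μ + μ²/k) is available and off by default.

**Analysis contract.** Replicate counts are averaged *before* any ratio is
taken (mean of replicates, then normalize) — per-well ratios are never
averaged. Controls are matched per plate; a plate without its own control
is a hard error, never silently pooled. Algebraically
SRF = m_IR·m_drug/(m_combo·m_control): the control mean enters once and
does **not** cancel, so SRF is invariant to rescaling *all* counts by a
common factor but not to changing the control arm alone (the test suite
pins both facts).

**Detectability.** A concentration is undetectable when the drug-only or
combination mean count falls below `min_mean` (default 3 colonies) or the
combination mean is zero. No quantitative rule exists in screening practice
for "SRF unavailable"; 3 expected colonies is the regime where a ratio of
Poisson means becomes dominated by its denominator noise. The hit fraction
is the percentage of *detectable* concentrations with SRF ≥ 1.5 and is
undefined (NaN) when nothing is detectable.

**Estimator bias.** SRF is a ratio of small Poisson means, so the estimate
carries a positive bias of roughly 1/(3·m_combo) + 1/(3·m_control) at
triplicate wells. At the default design's smallest detectable combination
means (~10 colonies) this is a few percent; across 200 simulated
independent plates the mean detectable SRF measures ≈ 1.05. Consequently
hit calling against a 1.5 threshold is conservative-safe for the null but
slightly liberal near threshold; screens wanting unbiased SRF should raise
seeding density or replicate number. An optional seeded bootstrap over
replicate wells (percentile CI, off by default) quantifies per-entry
uncertainty.

## 2. Logit-method ICx

Viability fractions are regressed as logit(v) on log₁₀(dose) by unweighted
least squares (no weighting information is available in typical CCK-8
reports). ICx is read off the fitted line at viability 1 − x/100, so
IC30 < IC50 on a decreasing curve, and IC50 = 10^(−intercept/slope).
Viability is clipped to [0.01, 0.99] before the transform; clipped points
stay in the fit and are flagged. The fit is exact on noiseless logistic
data only when no point is clipped; wide dose ranges with steep slopes
shrink the fitted slope symmetrically, which leaves IC50 (the curve
centre) intact but pulls ICx≠50 toward IC50 — a documented property of the
logit method, not a defect of the implementation.

The CCK-8 generator's Hill slope for the reference cell lines is fixed by
their reported IC30/IC50 ratio, h = ln(3/7)/ln(IC30/IC50) ≈ 1.99 and 1.93
— the unique slope for which the generating curve passes through both
printed ICx values. Noise is additive Gaussian on the viability scale
(default SD 0.05), clipped to [0, 1.2] since absorbance ratios can mildly
exceed 1.

## 3. Linear-quadratic survival

SF = colonies/(seeded · PE_control). Fitting is done in log space,
ln SF = −αD − βD², by nonnegative least squares (`scipy.optimize.nnls`),
which is the exact constrained least-squares solution; α, β ≥ 0 guarantees
a non-increasing fitted curve. Replicate SFs are averaged per dose first.
SF = 0 points cannot enter a log fit; they are excluded and reported. The
(α, β) covariance is the unconstrained linearization s²(XᵀX)⁻¹ and is
reported as NaN when a coefficient sits on the zero boundary (the
linearization is invalid there).

Iso-survival doses solve αD + βD² = −ln S via the numerically stable
positive root 2k/(α + √(α² + 4βk)). The sensitizer enhancement ratio is
SER(S) = D_control(S)/D_treated(S). Note that doubling both α and β does
*not* give a constant SER (the quadratic breaks dose-scaling); SER = 2 at
every level corresponds to (α, β) → (2α, 4β). For drug + IR combinations,
`analyze_clonogenic` normalizes each arm by its own dose-0 plating
efficiency by default (standard practice: drug-alone toxicity is divided
out so the curve isolates the radiation response); a flag disables this.

## 4. Flow cytometry

**Apoptosis.** Events are gated into four quadrants by one cut per
channel. Automatic cuts are placed at the KDE-density valley between the
two highest log₁₀-intensity modes (Scott bandwidth, hence scale-
equivariant), with the range midpoint as a unimodal fallback; manual cuts
override. The apoptosis rate counts all Annexin-positive events
(early + late) by default — reports rarely state which quadrants were
summed — with an `early_only` switch. The generator draws four bivariate
log-normal clusters (log₁₀ centres 1.0/2.5 per channel, SD 0.25), well
separated as in a compensated two-colour experiment.

**Cell cycle.** The DNA-content histogram is fit with a three-component
mixture: Gaussian G0/G1 at the 2N position, Gaussian G2/M constrained
within ±15 % of twice the G1 mean, and an S-phase bridge modelled as a
uniform density between the two peak means convolved with the G1 width
(closed form via normal CDFs). Weights, means and SDs are estimated by EM
(≤200 iterations, relative log-likelihood tolerance 1e-8); phase fractions
are the converged weights and sum to 1 exactly. Peak location uses
*mode pairing* rather than "G1 = global mode": all KDE modes are scanned
for a pair (m, ≈2m) and the pair with the largest summed density wins.
This matters because after an arresting treatment G2/M can hold >60 % of
events, making the 4N peak the global mode; a single usable mode is taken
as 2N (the diploid reference) by convention. Degenerate noiseless input
(two delta peaks) is classified exactly without EM. This is a pragmatic
mixture, not Dean–Jett–Fox: no aggregate/debris terms, no doublet model.

## 5. Imaging

Colony counting: global threshold (Otsu by default — relative to the
histogram, so counts are invariant to global intensity scaling) →
connected components → discard objects below `min_area`. The ≥50-cell
colony rule is mapped to pixels as 50 cells × 200 µm²/cell ÷ (pixel
size)², a configurable proxy for a proprietary instrument rule; at
10 µm/px this is 100 px². Touching colonies are not split (no watershed);
overlaps are flagged by the renderer. Focus counting per nucleus: white
top-hat (radius 3 px) removes the smooth nuclear stain, then pixels above
max(0.2, median + 10·robust-SD) within each mask form foci counted as
components. The renderers draw anti-aliased discs (1-px linear edge ramp)
with Gaussian background noise; foci are placed on an intra-nuclear ring
so ground-truth counts are unambiguous.

## 6. In vivo

V = (π/6)·L·W² with L ≥ W (axes swapped with a warning otherwise). A
`literal_formula` switch computes L·W²/(π/6) — a variant that appears in
print and differs by (6/π)² — so reports can emit either; the default is
the standard modified-ellipsoid formula. Group curves are mean ± SEM per
day (available-case on unbalanced days, flagged); comparisons are a
two-way (group × day) type-II ANOVA plus pairwise Welch t-tests at the
last common day. Volumes past the 1000 mm³ humane endpoint are flagged,
never dropped. The generator grows volumes exponentially per group-effect
multiplier with median-preserving log-normal noise and back-solves caliper
L, W at a fixed aspect ratio φ = L/W = 1.25 (arbitrary but realistic for
subcutaneous flank tumors) so the volume formula reproduces the trajectory
exactly.

## 7. Statistics

Mean ± SEM (SEM = SD/√n, ddof = 1). Welch's unequal-variance t-test is the
analysis default; the pooled-variance switch exists because the exact
identities hold for it: one-way ANOVA with two groups satisfies F = t²
(pooled) to 1e-9, and the pooled test's type-I error is exactly calibrated
(measured 0.049 at n = 3/group over 10⁴ Gaussian null replicates) whereas
Welch at n = 3 is conservative (≈0.033) due to the Satterthwaite df. Two
zero-variance samples with equal means return p = 1 by convention. Two-way
ANOVA uses type-II sums of squares (order-invariant on unbalanced
layouts). No multiple-testing correction is applied anywhere.

## 8. Reproduction analyses and problem sizes

`scripts/acceptance.py` / `clonoscreen reproduce` rerun, from one seed:

* screen hit fraction: 50 simulated plates of the maytansine-like profile
  (survival IC50 20 pM, Hill 2, f = 2), majority vote of per-plate hit
  fractions — single plates at 50 cells/well are noisy enough that a
  minority of seeds drop below 100 %, which is why the summary is a vote;
* ICx recovery: 100 plates each, 8 half-log doses centred on the true
  IC50, triplicate, 5 % noise, mean recovered IC50 in nM;
* apoptosis: 50 clouds of 10⁴ events, apoptotic mass split evenly between
  early and late, 5 % necrotic; mean gated rate;
* G2/M: 50 histograms of 10⁴ events at 4 % CV, companion G0/G1 fractions
  0.25 (G2-dominant case) and 0.50; mean recovered G2/M.

These sizes complete in ~20 s on one CPU while holding Monte-Carlo error
well below each quantity's tolerance.

## 9. What the generators do not emulate

Synthetic data are idealized: no edge/evaporation effects or spatial plate
gradients, no colony merging or satellite colonies, no spectral spillover
or autofluorescence in flow data, no debris/doublets in DNA histograms, no
illumination gradients in images, no cage effects or dropout in animal
data. Passing recovery tests therefore demonstrates correctness of the
*analysis* under its stated model, not robustness to every instrument
artifact. The detectability floor, hit threshold, clip bounds, area proxy
and gating windows are all exposed as parameters so real-data users can
recalibrate them.
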