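# Methods

`fgsquant` implements the quantitative image-analysis workflow used to
compare fluorescence-guided-surgery (FGS) contrast agents — in particular a
near-infrared (NIR) protease-activated probe against 5-ALA–induced PPIX —
on coronal brain sections, tissue homogenates, and ex-vivo tissue
fragments.  Because such comparisons are normally made on animal and human
tissue, every estimator here is validated instead on synthetic phantoms
with known ground truth; this note documents the models, parameter
choices, and the limits of what phantom-based validation can show.

## Tumor-to-normal ratio (TNR)

The primary contrast metric is

    TNR = mean fluorescence over the tumor ROI
          ─────────────────────────────────────
          mean fluorescence over the normal-brain ROI

with arithmetic means over mask pixels and no background subtraction.  The
tumor ROI is derived from the nuclear-dye channel, where the tumor appears
as a region of high cellular density: Otsu's two-class threshold
(between-class-variance maximization), morphological opening with a disk
of radius 1 px, removal of components below 25 px, and selection of the
largest connected component (8-connectivity).  The radius and minimum area
are configurable; the defaults suppress single-pixel noise while provably
leaving a rasterized ellipse of realistic size unchanged, so noiseless
phantoms are recovered exactly.  Thresholding, component selection and all
ratio readouts are invariant to a positive gain on the intensities, which
is what makes TNRs comparable across instruments with different linear
sensitivities.

The normal-brain reference is the mirror image of the tumor mask across
the hemispheric midline column (pixel at column c maps to 2·m − c,
0-based).  Mirroring gives a same-size, anatomically matched contralateral
ROI and is the least arbitrary reading of "contralateral hemisphere"; the
alternative reading — all tissue pixels of the whole contralateral
hemisphere, with tissue defined as nuclear intensity above a low (5%)
quantile — is provided as `normal_roi="hemisphere"`.  Masks are
transferred between channels by pure translation (sections are
co-registered); a transfer losing more than 10% of mask pixels, or a
mirror losing more than 1%, is refused rather than silently degraded.

Per-animal TNR over multiple sections is the mean of per-section TNRs
(each section one observation), not a pixel pool; pooling is available as
`aggregation="pooled"`.  Between-section consistency is summarized by the
coefficient of variation with the sample (n−1) standard deviation.

## Discriminative RGB→gray projection for PPIX

Under blue light PPIX-rich tumor appears red-pink over a blue background;
a fixed luminance conversion can cancel that hue contrast entirely.  Each
RGB pixel is therefore mapped to a scalar product with a unit *projection
vector* v chosen to maximize the separation |v·m_T − v·m_N| of the
channel-wise median colors m_T (tumor) and m_N (normal).  Maximizing a
linear functional over the unit sphere has the closed form

    v = (m_T − m_N) / ‖m_T − m_N‖,

signed so the tumor projects higher.  The unit-norm constraint is what
makes the problem bounded; the closed form is verified in the tests
against a dense brute-force search over ≥10⁶ quasi-uniform directions
(agreement within 1°, typically ≤0.13°).  Medians are marginal per-channel
medians with the midpoint rule for even counts, not geometric medians.
Per-sample vectors are averaged and re-normalized to give one cohort-level
conversion; antipodal vectors whose mean has no direction raise an error.

Projected values can be negative.  By default they are clamped at zero
before the TNR (PPIX-specific signal cannot meaningfully be negative, and
the TNR needs a positive denominator); the `offset` mode instead shifts
the projected image up by its global minimum, which is the right choice
when the separation is purely hue-based and the background itself projects
negative.  The choice is recorded in the output metadata.  A
non-negativity constraint on v (clip the median difference at zero, or
fall back to the best coordinate axis) is available but off by default.

## Statistics

Cohorts in this setting are small (4–19 animals), so the Mann-Whitney U
and Wilcoxon signed-rank tests use exact permutation distributions where
feasible: the U distribution by rank-sum counting when n+m ≤ 12 without
ties, and the signed-rank distribution over all 2ⁿ sign patterns (valid
with midranks) when the number of non-zero differences is ≤ 20.  Zero
differences are discarded (classic Wilcoxon convention, not Pratt's).
Outside the exact regime a normal approximation with tie and continuity
corrections is used; `TestResult.method` records which path was taken.
All p-values are two-sided; α = 0.05 is used only for flagging, never
inside a computation.  The paired t statistic uses mean(d)/(sd(d)/√n)
with the t distribution on n−1 degrees of freedom.

## Synthetic phantoms

A phantom section is a 192×192 px (tests and the acceptance script use
96×96 for speed) image triple: nuclear channel (tumor 1.0 AU over 0.1 AU
background), NIR channel (normal level 1.0 AU, tumor level ρ AU with ρ
the true contrast, default 30 — the order of magnitude reported for
cathepsin-activated ICG probes in homogenates), and an RGB channel with a
red-pink tumor (0.80, 0.20, 0.24) over a blue-grey background
(0.20, 0.20, 0.45), whose optimal projection implies a projected PPIX
contrast of ≈17, in the range reported for 5-ALA.  The tumor is a single
ellipse in the right hemisphere (echoing the implantation side); an
optional margin band of configurable width ramps the signal linearly (in
Euclidean distance from the tumor edge) down to background, standing in
for an infiltrating-cell margin without rendering single cells.

Noise is additive zero-mean Gaussian with one standard deviation in AU
shared by the nuclear and NIR channels (default 0.05 AU, i.e. 5% of the
nuclear tumor level), with the resulting image clipped at zero; RGB
channels get clipped per-channel jitter (sd 0.02).  A Poisson noise model
was considered and rejected as adding nothing to contrast-recovery tests
at these signal levels.  Note that clipping makes the noise slightly
non-zero-mean where the signal is within ~2 sd of zero; at the default
noise scale this bias is negligible (the normal-level mean shifts by
<10⁻⁴ relative), which is why the noise scale is defined relative to the
nuclear tumor level rather than the NIR tumor level — at sd comparable to
the NIR normal level the clipping bias would dominate any estimator based
on region means.

Between-animal variability multiplies ρ by a lognormal factor
(median-preserving, CV as requested, floored at ρ = 1 since an
activatable probe is never dimmer in tumor than in normal brain);
lognormal because TNRs are strictly positive and reported SDs are large
relative to means (e.g. 30.1 ± 16.5 → CV ≈ 0.55, the default).  For
paired two-agent cohorts both agents are coadministered to the same
animal, so per-animal contrasts share a lognormal biological factor
(default CV 0.35, about half the smaller agent's log-variance) with
agent-specific factors absorbing the remainder; this reproduces the
positive within-animal correlation a paired design exploits.

Homogenate tables pair one tumor and one normal record per animal with
weights uniform on 10–30 mg and per-mg tumor fluorescence equal to
true TNR × normal per-mg level × mean-one lognormal noise, so the
expected recovered TNR equals the ground truth.  Ex-vivo fragments follow
a saturating activation curve t/(t+10 min) sampled at 2, 5, 10 and
120 minutes, with the GBM amplitude a fixed fold (default 1.91) above the
PRE (pharmacoresistant-epilepsy, i.e. non-malignant) amplitude and a
reference group (healthy mouse brain processed alongside) always present;
normalization divides each reading by the reference mean of the same
experiment and timepoint, removing between-experiment batch factors.

What the phantoms deliberately omit: 3-D structure, histological texture,
optical physics (scattering, depth attenuation), instrument spectral
response, and non-elliptical or multifocal tumors.  Passing tests
therefore demonstrate that the estimators are correct and well calibrated
under the stated generative model — not that segmentation or projection
would meet the same fidelity on real cryosections.

## Numerical choices and degenerate inputs

* Seeds are explicit everywhere; no global random state.  Identical
  (config, seed) pairs produce byte-identical output files, so no output
  contains timestamps.
* Otsu threshold ties are resolved deterministically by the histogram
  implementation; component-size ties by lowest label id.
* Constant images, empty or overlapping masks, non-positive reference
  means, identical median colors, antipodal projection vectors, all-zero
  paired differences and zero-variance differences each raise a typed
  error rather than returning NaN.
* Ratio readouts are bitwise gain-invariant for lossless (power-of-two)
  gains; for arbitrary gains the per-element rounding of the scaled
  inputs limits agreement to ~1 ulp, and tests assert 10⁻¹² relative.
* CSV floats are written with `%.17g` and read with round-trip precision.

## Problem sizes

Simulation-based checks use 96×96 px sections; 10 sections per contrast
level for recovery, 50 phantoms for segmentation fidelity, 100 animals ×
3 sections for the CV property, 100 cohorts of 10 animals for
directionality, and 5000 replicates for test calibration — sizes at which
the Monte-Carlo error of each check is comfortably below the margin being
asserted.
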