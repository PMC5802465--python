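# Methods

## The cohesion index

The Network Cohesion Index treats the $m = n(n-1)/2$ pairwise Pearson
correlations of a network's $n$ node signals inside a sliding window as a
sample, Fisher-z-transforms them, and summarises them with the one-sample
t-statistic against zero (sample standard deviation, $m - 1$ degrees of
freedom). The t-statistic itself is the index; no p-value is attached to
it, because it is used as a *descriptive* probe of within-network coupling
whose distribution over subjects is then compared nonparametrically.

Networks must have at least three nodes: two nodes give a single
correlation and an undefined t-statistic, so `NetworkSpec` rejects them at
construction.

Numerical policy:

- Correlations of magnitude exactly 1 (possible in synthetic fixtures)
  are clipped to $1 - 10^{-10}$ before `arctanh`, with a warning.
- A window in which a node has zero variance, or in which all pairwise
  z-values are exactly equal (zero spread, detected by exact range rather
  than a floating-point standard deviation), is flagged *degenerate*; the
  value carries a NaN or signed-infinity sentinel. Degenerate windows are
  excluded per window from rank tests and symptom correlations, and
  subjects with any degenerate window are dropped (with a log message)
  from the cross-correlation bootstrap and rejected by the classifier's
  feature builder, which cannot tolerate missing coordinates.

## Time base and window grid

All series live on the TR grid (3 s per sample by default). The first
5 TRs are discarded to avoid stimulus-onset transients; windows are
half-open index ranges $[s, s + w)$ of length $w = 10$ advancing by 1 TR
(90 % overlap), identified by their start index on the trimmed series.
With a 165-TR acquisition this yields $160 - 10 + 1 = 151$ windows — the
step of 1 is forced by that count, which is why "90 % overlap" is resolved
as step = window/10.

The 10 Hz rating traces (0–21 scale, seven labelled intensity levels of
three units) are averaged inside each 30-sample TR interval, trimmed by
the same 5 TRs (i.e. their first 150 samples), and averaged inside each
window, so rating and NCI series share one clock and one length. The
within-window aggregate is the mean; the group-level contrast is
median-based through the rank-sum test, so any location-equivariant
aggregate gives the same inference.

## Group inference

Per window, the two groups are contrasted with the two-sample Wilcoxon
rank-sum statistic in its normal approximation with midranks and the
standard tie correction, and *without* continuity correction — the Z value
is the plain standardized rank sum, which is the quantity conventionally
reported in this literature. Orientation is fixed control − patient
(Z > 0 when controls tend larger). Two-sided p-values are
Benjamini–Hochberg corrected over the comparison span.

Two spans are supported: the full 151 windows, and the lag-truncated
central span of $151 - 2 \times 10 = 131$ windows that the
cross-correlation stage uses for every lag. The truncated span is the
default comparison span so that the per-window group tests and the
cross-correlation stage count the same 131 comparisons; window labels keep
their original start indices either way. An amplitude control contrast
(z-scored node signals averaged across nodes, then within windows) runs
through the identical machinery to check that group differences are
specific to *coupling* rather than activity level.

## Lagged cross-correlation and its null

The NCI group-difference Z series is Spearman-correlated with the rating
group-difference Z series at integer shifts $-10 \dots +10$. Every lag is
evaluated on the identical central 131-window span (symmetric truncation;
the central span is the unique choice that treats both shift directions
equally), so all 21 coefficients are computed on equally sized series.
Positive lag means the NCI series precedes the rating series.

Significance: a phase-randomization bootstrap. Each iteration replaces
every subject's NCI series (both groups) by a Fourier surrogate — random
phases on all non-DC (and non-Nyquist) bins, original amplitude spectrum,
hence preserved mean, variance and autocorrelation — recomputes the
per-window rank-sum Z series, and re-evaluates all 21 lagged correlations
against the *fixed* observed rating series. The two-sided p-value per lag
is $(\#\{|\rho_{null}| \ge |\rho_{obs}|\} + 1)/(n_{boot} + 1)$, BH-FDR
corrected over the 21 lags. Iterations whose surrogate Z series is
constant are discarded and logged. The default $n_{boot}$ is 1000;
desk-scale runs use 500, which already resolves p to 0.002.

Because both Z series are heavily autocorrelated (overlapping windows),
this null is deliberately conservative relative to an i.i.d. shuffle: high
$|\rho|$ arises easily between smooth series, and the surrogate null
reproduces exactly that smoothness.

## Symptom association

For each network × PANSS subscale (positive, negative, general), patients'
per-window NCI values are Spearman-correlated with the subscale score; the
p series is BH-corrected over the comparison span's window count,
separately per family (six families, no pooled correction — pooling would
change the hypothesis structure). Windows with fewer than four testable
patients or a constant variable are flagged untestable and excluded from
the correction.

## Classification

Features are the concatenated ES and ToM per-window NCI values
(2 × 151 = 302 with defaults). The classifier is k-nearest-neighbour with
k = 10, Euclidean distance, unweighted majority vote; an even-vote tie is
broken by the single nearest neighbour's label (deterministic and
order-independent). Validation is stratified 5-fold cross-validation —
stratified because at ~25 subjects per class unstratified folds can go
class-empty — repeated (default 1000×) with fresh fold assignments;
metrics (accuracy, sensitivity = patients correct / patients, specificity,
per-class PPV) are computed from each repetition's pooled out-of-fold
predictions and reported as mean ± sd over repetitions. The permutation
test shuffles labels once per permutation and reruns the identical
repeated-CV procedure (at a configurable reduced repetition count for
desk-scale runs); $p = (\#\{\text{perm} \ge \text{orig}\} + 1)/(k+1)$ with
the ≥ comparison.

No feature standardization is applied: NCI values across windows are
already on one t-statistic scale.

## Synthetic cohorts

The generator exists so every stage has a parameter-recovery test; it
produces the *statistical structure the analysis assumes*, not realistic
fMRI. Node signals follow a shared-factor model,
$x_i(t) = \sqrt{c_g(t)}\, f(t) + \sqrt{1 - c_g(t)}\, \varepsilon_i(t)$,
with unit-variance innovations, so the expected pairwise correlation under
constant coupling $c$ is exactly $c$ — chosen precisely because it makes
NCI recovery analytically checkable (the finite-window sample correlation
is slightly biased toward zero; the Monte-Carlo oracle in the tests
quantifies that band). Innovations are white by default; an AR(1) switch
(`ar1_phi`) provides known spectral structure for exercising the
phase-randomization null.

Defaults define the study conditions: 25 subjects per group, 165 TRs at
3 s, a 7-node ToM and a 5-node ES network, baseline coupling 0.2, ES
coupling raised to 0.6 for controls over windows 40–70 (exactly the
samples those windows cover), a +10-TR lag between the coupling difference
and the rating difference (positive = coupling precedes rating), smooth
per-subject rating noise (sd 1.5 on the 0–21 scale, Gaussian-smoothed to
~1 s correlation length, clipped to scale), and patients' general PANSS
subscore equal to $40 + 6 \cdot \mathrm{NCI}_{ToM}(\text{window } 30)$
plus N(0, 3) noise; the remaining subscores are effect-free draws within
plausible PANSS ranges. All planted parameters are returned in a
ground-truth record and written as a JSON sidecar.

What the generator does **not** emulate — hemodynamic convolution,
physiological and scanner noise, drift, motion, voxel-level structure,
inter-network coupling — bounds what passing tests show: they validate the
*inferential machinery* (statistics, nulls, multiplicity control,
recovery of planted effects at realistic group sizes), not robustness to
real fMRI artefacts, which is the province of the upstream preprocessing
this package deliberately does not reimplement.

## Problem sizes in the shipped tests

The test suite and acceptance script run the pipeline at the design scale
of the motivating study (2 × 25 subjects, 151 windows, 21 lags,
302 features) but with reduced resampling counts chosen as the package's
own desk-scale defaults: 500 bootstrap iterations for lag recovery,
100–200 replicate small cohorts (12 per group) for null calibration,
100 permutations × 10 repetitions for classifier significance. All are
configurable upward; the statistics they estimate are resolution-limited,
not biased, by these counts.

## Known limitations

- The rank-sum normal approximation is used at all group sizes; below ~8
  per group its type-I rate drifts from nominal (the null-calibration test
  runs at 12 per group, where it is accurate).
- The bootstrap phase-randomizes both groups' NCI series; randomizing only
  one group is a defensible alternative the package does not implement.
- Degenerate-window policy (exclusion) is one of several reasonable
  choices; imputation is deliberately not offered.
- The comparison span for group tests and symptom correlations defaults to
  the lag-truncated 131 windows for consistency with the cross-correlation
  stage; the full 151-window span is one configuration switch away, and
  results near the span edges depend on that choice.
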