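# netcohesion

Sliding-window **network cohesion** analysis for continuous (naturalistic)
fMRI paradigms: quantify how tightly a predefined brain network's nodes
co-fluctuate over time, compare those dynamics between a patient and a
control group, relate the group difference to continuously reported
emotional experience, to symptom severity, and use the cohesion time
courses to classify subjects.

The package targets researchers studying dynamic functional connectivity in
clinical populations — the motivating case is schizophrenia patients vs.
healthy controls watching an emotionally distressing film, with two social
cognition networks of interest: a 5-node **embodied simulation (ES)**
network (anterior insulae, ACC, dorsal precuneus) and a 7-node **theory of
mind (ToM)** network (mPFC, bilateral STS/TPJ, ventral precuneus). No
clinical data ships with the package; a synthetic-cohort generator with
planted, recoverable effects stands in for it everywhere.

## The statistic

For a network with $n \ge 3$ nodes and a sliding window of $w$ time points,
let $r_1, \dots, r_m$ ($m = n(n-1)/2$) be the pairwise Pearson correlations
of the node signals within the window and $z_i = \operatorname{arctanh}(r_i)$
their Fisher transforms. The **Network Cohesion Index (NCI)** is the
one-sample t-statistic

$$\mathrm{NCI} = \frac{\bar z}{s_z / \sqrt{m}},$$

with $s_z$ the sample ($m-1$) standard deviation. It is large when the mean
pairwise correlation is high *and* its dispersion across pairs is low —
hence "cohesion". With the default acquisition (165 volumes at TR = 3 s,
first 5 volumes trimmed, 10-TR windows advancing 1 TR = 90 % overlap) each
subject yields 151 NCI values per network.

Downstream stages:

- **Group contrast** — per window, a two-sample Wilcoxon rank-sum Z
  (normal approximation, tie-corrected, oriented control − patient) on NCI,
  on the windowed 10 Hz emotion rating, and on a mean-amplitude control
  series; Benjamini–Hochberg FDR over the comparison span.
- **Lagged cross-correlation** — the NCI group-difference Z series vs. the
  rating group-difference Z series, Spearman correlation at window shifts
  −10…+10 (all lags evaluated on the identical central 131-window span);
  significance from a phase-randomization bootstrap that surrogates each
  subject's NCI series and recomputes the Z series per iteration, FDR over
  the 21 lags. Positive lag = NCI precedes rating.
- **Symptom association** — per window, Spearman correlation between
  patients' NCI and each PANSS subscale (positive/negative/general), FDR
  per network × subscale family.
- **Classification** — KNN (k = 10, Euclidean, stratified 5-fold CV,
  repeated with fresh folds) on the concatenated ES + ToM NCI time courses
  (2 × 151 = 302 features); label-permutation p-values via
  $p = (\#\{\text{perm} \ge \text{orig}\} + 1)/(k_{\text{perm}} + 1)$.

## Worked example

Simulate the default study conditions — 25 subjects per group, ES coupling
raised from 0.2 to 0.6 for controls during windows 40–70, and a rating
group difference lagging the coupling difference by +10 TRs — then recover
both effects:

```python
import numpy as np
from netcohesion import (
    SimConfig, generate_cohort, make_window_grid, groupdiff_series,
    crosscorr_bootstrap, trim_onset, SubjectRecord,
)
from netcohesion.inference import measure_matrix
from netcohesion.synthetic import default_networks

cohort, truth = generate_cohort(SimConfig(n_per_group=25, seed=2026))
cohort = [SubjectRecord(s.subject_id, s.group, s.node_labels,
                        trim_onset(s.signals, 5), symptoms=s.symptoms,
                        rating=s.rating) for s in cohort]
grid = make_window_grid(160)
tom, es = default_networks()

gd = groupdiff_series(cohort, "nci", grid, es)
sig = gd.significant_windows(0.05)
print(f"windows: {grid.n_windows}, ES windows with q<=0.05: {len(sig)} "
      f"(range {sig.min()}-{sig.max()}), max Z = {np.nanmax(gd.z):.2f}")

controls = [s for s in cohort if s.group == "control"]
patients = [s for s in cohort if s.group == "patient"]
rating_z = groupdiff_series(cohort, "rating", grid, span="full").z
prof = crosscorr_bootstrap(
    measure_matrix(controls, "nci", grid, es),
    measure_matrix(patients, "nci", grid, es),
    rating_z, n_boot=500, rng=np.random.default_rng(7))
idx = np.flatnonzero(prof.lags == prof.peak_lag)[0]
print(f"ES NCI vs rating: peak rho = {prof.peak_rho:.2f} at lag "
      f"{prof.peak_lag:+d} (q = {prof.q[idx]:.3f}, planted lag "
      f"{truth['rating_lag']:+d})")
```

prints

```
windows: 151, ES windows with q<=0.05: 44 (range 33-76), max Z = 5.69
ES NCI vs rating: peak rho = 0.76 at lag +10 (q = 0.031, planted lag +10)
```

The group difference is found almost exclusively inside the planted
window interval, and the cross-correlation peaks at the planted +10 lag:
the connectivity difference precedes the reported-experience difference.

The same analysis is available from the shell:

```bash
netcohesion simulate --out-dir cohort/ --n-per-group 25 --seed 2026
netcohesion run-all --cohort-dir cohort/ --output-dir results/ --seed 7
```

which writes per-stage TSV/JSON reports (NCI long table, per-window
Z/p/q series, lag profiles, symptom correlations, classifier metrics) with
provenance headers, plus a `run_summary.json`.

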