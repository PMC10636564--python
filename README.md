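# abnmap

Interictal band-power abnormality mapping for epilepsy surgery evaluation:
normative MEG/iEEG maps, per-patient maximum-|Z| abnormality maps, the
*abnormality coverage* and *D*<sub>RS</sub> rank statistics, and a
class-weighted logistic model of post-surgical seizure freedom rendered as
a nomogram.

## The problem

Intracranial EEG (iEEG) is the gold standard for localizing the
epileptogenic zone (EZ) before resective surgery, but electrodes only
record where they are implanted — implantation needs a preconceived
hypothesis of where the EZ is. Resting-state MEG covers the whole
neocortex non-invasively. If quantitative MEG abnormalities mark
epileptogenic tissue, then (i) electrodes implanted *in* the most
MEG-abnormal tissue and (ii) resection of the most abnormal sampled tissue
should both predict post-operative seizure freedom. This package
implements that analysis for region-level relative band-power data and, in
the absence of shareable patient recordings, a synthetic-cohort generator
with the same statistical structure so the whole pipeline is testable.

## Method

**Spectral features.** Regional source time series (default 70 s at
600 Hz) are reduced by Welch's method (2 s Hann windows, 1 s overlap,
per-window linear detrend) to relative band power in delta (1–4 Hz), theta
(4–8), alpha (8–13), beta (13–30) and gamma (30–80) bands; powerline
windows are excluded from gamma (47.5–52.5 Hz for MEG, additionally
57.5–62.5 Hz for iEEG). The five fractions per region form a composition
summing to 1.

**Normative mapping.** For each region *r* and band *b*, a reference
cohort (70 healthy MEG controls; iEEG contacts of 234 non-epileptic-tissue
recordings mapped to regions by minimum Euclidean distance) yields a mean
μ<sub>rb</sub> and sample SD σ<sub>rb</sub>. A patient's abnormality is

    z_rb = (x_rb − μ_rb) / σ_rb,    A_r = max_b |z_rb|

the maximum absolute Z across bands.

**Localization statistics.** Both are Mann–Whitney AUCs over A_r:

- *abnormality coverage* = AUC(implanted vs unimplanted regions); 1 means
  electrodes sampled exclusively the most abnormal neocortex, 0.5 chance.
- *D*<sub>RS</sub> = 1 − AUC(resected vs spared regions), restricted to
  tissue with joint MEG and electrode coverage; 0 means the most abnormal
  sampled tissue was resected. A region counts as resected if its MRI
  volume shrank by more than 10%, or (iEEG definition) if more than 25% of
  its contacts were resected.

**Outcome model.** Seizure freedom (ILAE 1 vs 2+) is modelled by logistic
regression on (coverage, D<sub>RS</sub><sup>MEG</sup>,
D<sub>RS</sub><sup>iEEG</sup>) without standardization, with class weights
w₁ = n₂/N, w₂ = n₁/N so both outcome groups carry equal likelihood mass
(20/32 and 12/32 for a 12-vs-20 cohort). The fit is Newton/IRLS to 1e-10
with a tiny-ridge fallback under separation. The model is rendered as a
nomogram — each feature accrues points proportional to β·range, the most
influential spanning 0–100 — and validated by leave-one-out refitting.
Group differences use one-tailed tests (one-sample t vs 0.5; Mann–Whitney
U, whose normalized statistic is the reported AUC effect size).

## Worked example

Simulate a study-shaped cohort (70 controls, 32 patients, 114 regions) and
run the full pipeline:

```bash
abnmap run --simulate --seed 7 --out demo_out
# [mri>0.1, contacts>0.25] n=32 excluded=0 model AUC=0.944
```

`demo_out/stats.json` then contains (abridged):

```
n_patients : 32          n_seizure_free : 11
t_coverage_seizure_free : 10.138   (one-tailed p < 0.001)
auc_coverage : 0.762     auc_drs_meg : 0.896    auc_drs_ieeg : 0.942
auc_model : 0.944        loo_auc_mean : 0.945
```

Reading: seizure-free patients' electrodes sampled tissue of
above-chance MEG abnormality (t-test of coverage against 0.5); each
feature separates outcome groups (AUC > 0.5 in the hypothesized
direction); the combined model separates them best, and the leave-one-out
mean shows the separation is not driven by single subjects.
`demo_out/features.tsv` holds the per-patient measures,
`model.json`/`nomogram.tsv` the fitted model and its point tables. The
same pipeline runs on real data laid out as TSV tables (see
`abnmap simulate --out <dir>` for the expected layout), and
`abnmap run --mri-threshold 0.05,0.1,0.15,0.2` sweeps the resection
threshold as a sensitivity check. `abnmap plot` renders the nomogram and
ROC curve as SVG.

A library-level entry point does the same in Python:

```python
from abnmap import CohortSimConfig, simulate_cohort
from abnmap.pipeline import analyze_cohort

report = analyze_cohort(simulate_cohort(CohortSimConfig(seed=7)))
report["stats"]["auc_model"]      # 0.944...
```

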