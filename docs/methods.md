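# Methods

This note documents the models and numerical choices behind `abnmap`: the
spectral reduction, the normative Z-scoring, the two rank statistics, the
outcome model, and — since no patient recordings are redistributable — the
generative law of the synthetic cohorts on which everything is tested.

## Spectral reduction

Welch PSDs use 2 s Hann windows with 1 s overlap and per-window linear
detrending (`scipy.signal.welch`, density scaling), giving 0.5 Hz
resolution over a 70 s, 600 Hz epoch. Band intervals are half-open
[lo, hi): a bin at exactly 4 Hz belongs to theta, not delta. Relative band
power divides each band's bin-sum by the total over the five bands
(1–80 Hz minus the powerline exclusion windows), so the five values are a
composition. The denominator choice matters: normalizing over the union of
the analysed bands (rather than the full spectrum) makes the values
scale-invariant and comparable across recording gains, at the cost of
coupling the bands (raising one fraction necessarily lowers the others).
A `log_power` flag applies log10 to PSD bins before summation (off by
default); it changes the weighting of spectral peaks but not the
compositional structure.

Powerline handling: gamma excludes 47.5–52.5 Hz for MEG; the iEEG
normative cohort mixes UK and US recordings, so iEEG gamma additionally
excludes 57.5–62.5 Hz.

## Normative maps and abnormality

Per (region, band), the reference cohort contributes a mean and a *sample*
SD (n−1 denominator). Contact-level values are averaged within subject ×
region first, so every subject contributes at most one value per cell;
cells with fewer than two contributing subjects are excluded and logged.
SDs below 1e-6 of the cell mean are raised to that floor — irrelevant for
real cohorts, but it keeps Z-scores finite on degenerate synthetic ones. A
patient's per-region abnormality is the maximum absolute Z across the five
bands. Maximizing |Z| is deliberately direction-agnostic: both power
excesses and deficits mark abnormal tissue.

iEEG contacts are assigned to the region whose centroid is nearest in
Euclidean distance; exact ties go to the earlier label in the parcellation
order (deterministic). An ROI counts as implanted if at least one contact
is assigned to it.

## Rank statistics

Both statistics are Mann–Whitney AUCs with half-credit for ties, computed
from midranks: coverage compares implanted vs unimplanted regions on the
MEG abnormality map (all 114 regions); DRS = 1 − AUC(resected vs spared)
restricted to implanted regions only, so unsampled tissue never enters.
Resection thresholds are strict inequalities ("exceeded 10%", "more than
25%"): boundary cases are not resected. Patients whose resected or spared
set is empty after restriction have no defined DRS; library calls raise a
ValueError naming the subject, and cohort runs exclude the subject and
count it in `n_excluded` rather than aborting.

## Outcome model

The logistic fit maximizes the class-weighted likelihood with weights
w(class) = n(other)/N, which equalizes the groups' total weight; with all
features constant this forces a zero intercept, a useful identity test.
Features enter untransformed — all three live on [0, 1] with natural
interpretations. The optimizer is damped Newton/IRLS, convergence at a
maximum step of 1e-10. Quasi-separation is a real risk at n = 32; if the
unpenalized fit diverges (non-convergence, singular Hessian, or any
|coefficient| above 30), the fit restarts with ridge λ = 1e-6 on the
slopes and records `separation_fallback` in `fit_meta_`. Rankings are
unaffected by the tiny penalty.

Nomogram: points_i(x) = 100·(β_i·x − min over the observed range of
β_i·x) / max_j(|β_j|·range_j). Total points are an increasing affine
transform of the linear predictor, so the point threshold at which
predicted probability crosses 0.5 classifies identically to the
probability rule; this faithfulness is asserted in the tests.

Leave-one-out: by default each fold's AUC is computed from the refitted
model's scores on its n−1 training subjects (matching the procedure of
refit-then-estimate-AUC); a held-out accumulation variant
(`loo_heldout`) scores only the left-out subjects and computes one AUC at
the end. The train-fold variant carries small-sample optimism (mean ≈ 0.7
under random labels at n = 32); the held-out variant is chance-level under
random labels but has large cohort-to-cohort variance. Both are exposed
because they answer different questions (robustness to outliers vs
out-of-sample separation).

Group tests are one-tailed by design (directional hypotheses): one-sample
t of seizure-free coverage against 0.5, and Mann–Whitney U between outcome
groups with exact enumeration for tie-free samples with n₁·n₂ ≤ 400,
otherwise the tie-corrected normal approximation.

## Synthetic cohorts

The generator emulates the study's data model, not its biophysics.

*Controls.* Each region's five-band composition is drawn from a Dirichlet
law around a resting-state-like base spectrum (0.35, 0.20, 0.20, 0.15,
0.10) with concentration 150 — compositionality is the only hard
constraint the downstream analysis relies on.

*Patients.* Each patient has a contiguous EZ of 6 regions (contiguity on a
synthetic ring adjacency; real cortical geometry is not needed by any
consumer). One band's fraction in the EZ is shifted by
`effect_size_z` × the analytic Dirichlet SD of that band (default |Z| = 4,
a strong but realistic focal band-power abnormality), with the other bands
renormalized.

*Implantation.* Per patient, a hypothesis quality q ~ Beta(κτ, κ(1−τ))
(κ = 2) determines how many of the EZ regions are among the 16 implanted
regions (binomially); the rest are uniform. τ = 1 targets the whole EZ
surely; τ = 0 never targets it; with a null effect the implanted set is
independent of the measured map, so coverage is exactly chance-calibrated.
The per-patient (not per-slot) quality draw is what gives coverage genuine
between-patient variance — with a constant per-slot preference every
implantation succeeds and coverage cannot separate outcome groups.

*Resection.* The surgical decision has its own quality r ~ Beta(κρ,
κ(1−ρ)); implanted regions are ranked by r·(true-EZ rank) + (1−r)·noise
and the top 6 are resected (tissue outside electrode coverage never is).
The decision uses ground-truth abnormality, not the measured map — the
measured map is the evaluation instrument; ranking by it would make even
a "perfect" resection fail whenever the map is noisy, and would couple
the evaluation to itself. MRI volumes are written consistently (30–60%
loss for resected regions, |change| < 10% otherwise), and contact flags
follow the resected regions with 10%/5% flip noise, which is what
differentiates the contact-derived from the MRI-derived mask.

*Outcome.* Seizure-free iff the entire EZ was resected, flipped with
probability ε (default 0.1). A logistic-link variant (`outcome_law =
"logistic"`, p = σ(−5 + 4·fraction of EZ implanted + 6·fraction of EZ
resected)) is provided for parameter-recovery tests where a smooth
outcome law is preferable.

*Defaults.* 70 controls, 32 patients, 114 regions, 234 iEEG normative
subjects mirror the study design. τ = 0.75 and ρ = 0.85 were chosen once
so the default cohort lands near the study's 12-vs-20 outcome split in
expectation: with the all-or-nothing outcome rule, higher targeting
quality caps the achievable failure rate below the observed one. Under
these defaults the simulated statistics show the study's qualitative
pattern — coverage above chance in seizure-free patients, every feature
separating outcome groups (AUC > 0.5), the combined model at least as good
as the best single feature — with effect sizes somewhat stronger than the
real cohort's (e.g. model AUC ≈ 0.89 vs 0.80), as expected of a generative
law whose features are sufficient statistics for its own outcome rule.

*What passing tests do not show.* The simulator makes no claim about
sensor physics, source reconstruction, spatial autocorrelation of real
band-power maps, or the clinical case mix; passing end-to-end tests
demonstrates that the pipeline's statistics recover the structure the
generative law encodes, not that the biomarker works in new patients.

## Problem sizes

Tests run reduced cohorts (e.g. 24–30 controls, 8–16 patients, or 40
regions for the 200-replicate sign-recovery study) chosen to keep each
Monte-Carlo check's sampling error well inside its asserted margin; the
acceptance script uses the full study shape (70/32/114/234) averaged over
10 replicate cohorts.

## Known limitations

- Region-level only: contact-level abnormality is aggregated within
  region before Z-scoring; a per-contact max-|Z| variant would need a
  contact-level normative map.
- The normative iEEG map ignores which subject contributed which region
  beyond the within-subject average (no site/batch effects).
- The nomogram is a faithful affine rendering of one fitted model; no
  calibration analysis or model comparison beyond the three-feature model
  is included.
- Exact Mann–Whitney p-values are only used for small tie-free samples;
  with ties the normal approximation is used at any size.
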