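# rpquant

Quantification of radiation pneumonitis (RP) after thoracic radiotherapy,
from co-registered voxel volumes: a 3D absorbed-dose grid (Gy), a binary
total-lung mask, and one binary pneumonitis-lesion mask per follow-up CT.

Radiation pneumonitis is the inflammatory lung injury that follows curative
thoracic radiotherapy; clinically it is graded on the CTCAE scale (grade ≥ 2
= symptomatic). `rpquant` implements an objective, volume-based companion to
that grading, intended for radiation oncologists and medical physicists
working with conventionally fractionated lung-cancer plans (≥ 56 Gy):

- **DVH metrics** — lung Vx for x = 1..66 Gy (percentage of lung receiving
  ≥ x Gy, inclusive threshold, computed from voxel doses) and mean lung dose
  (MLD).
- **RPv** — lesion volume divided by total lung volume; per patient, *RPv
  max* is the largest RPv among the scans attaining the maximum grade, and
  the interval to grade max is the day of that scan.
- **Isodose coverage** — per candidate level d ∈ 1..66 Gy, the fraction of
  the lesion inside the d-Gy isodose region,
  `cov(d) = |lesion ∩ {dose ≥ d}| / |lesion|`.
- **Dose-level selection** — the highest d such that (a) lung Vd correlates
  with RPv max (Spearman, p < 0.05) and (b) the d-Gy region covers ≥ 80 % of
  the lesion in > 80 % of patients within each of grades 1 and 2. On the
  reference cohort this procedure yields **26 Gy**, the isodose line that
  recognises a lesion as radiation-induced.
- **Statistics** — Kruskal–Wallis with Dunn–Bonferroni post hoc,
  Mann–Whitney U, chi-square, and an ROC with a Youden-index cut-off for
  predicting symptomatic RP from RPv max or MLD.
- **Survival** — Kaplan–Meier, two-group log-rank, and univariate Cox
  (Efron ties) for LRPFS / PFS / OS measured from radiotherapy completion.
- **Synthetic cohorts** — a deterministic phantom generator (two ellipsoidal
  lungs, beam-like dose with Gaussian penumbra, lesions sown above a dose
  threshold θ) so the whole pipeline runs end-to-end with no external data.

Two per-patient reference tables are packaged as CSV fixtures: the grade /
interval table (71 patients) and the 26 Gy lesion-coverage table (36 grade-1
and 32 grade-2 patients).

## Worked example

```bash
rpquant simulate --seed 7 --n 40 --out demo/
rpquant select-level --cohort demo/cohort_metrics.csv \
                     --coverage demo/coverage.csv --out demo/sel
rpquant analyze --cohort demo/cohort_metrics.csv --out demo/analysis
rpquant reproduce-tables
```

The run above prints

```
selected level: 26 Gy
RPv max: AUC 0.965, cutoff 5.20%
```

meaning the dose-level scan recovered the 26 Gy rule on the simulated
cohort, and RPv max discriminated symptomatic from asymptomatic patients
with area under the ROC curve 0.965 at a Youden-optimal cut-off of 5.2 %
(the generative cut-point is 4.8 %). `reproduce-tables` recomputes the
reference-cohort numbers from the packaged fixtures, e.g. the 26 Gy
coverage criterion passing in 29/36 grade-1 (80.6 %) and 26/32 grade-2
(81.3 %) patients, the symptomatic onset interval of 24–190 days, and the
51 % / 45 % / 4 % grade distribution.

The same steps are available as library calls (`compute_dvh`,
`coverage_curve`, `derive_rp`, `select_dose_level`, `roc`, `km_estimate`,
...); see the module docstrings and `docs/methods.md`.

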