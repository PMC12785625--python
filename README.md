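# hetmix

Mixed-cell models of inter-patient tumor heterogeneity: transcriptomic
selection of representative cancer cell lines, and evaluation of drug
combinations on the resulting co-culture model under independent drug
action.

## The problem

Tumors from different patients with the same cancer are molecularly
diverse, and a drug combination can help a diverse cohort even when its
component drugs never interact inside any single cell: each drug benefits
the subset of tumors sensitive to it (*independent drug action*, IDA).
Conventional preclinical practice — screening one homogeneous cell-line
model at a time and aggregating the responses — is structurally blind to
this mechanism.  A *mixed-cell model* instead co-cultures cell lines
rationally chosen to represent the distinct tumor subtypes of a patient
cohort and reads out the mixture as one composite heterogeneous tumor.

`hetmix` implements this workflow end to end for a castration-resistant
prostate cancer (CRPC)-like setting, with a synthetic-data module standing
in for every external dataset so the whole pipeline is testable offline:

1. **Cohort purification** — bulk tumor profiles are mixtures of tumor and
   stromal/immune signal; per-sample cell-type fractions are estimated by
   non-negative least squares against a reference signature, and tumor-only
   expression is recovered as
   `max(0, bulk − Σ_k f_k · sig_k) / f_tumor` on the linear scale.
2. **Integration and clustering** — purified patient profiles are combined
   with cell-line profiles, batch effects removed by parametric
   empirical-Bayes location/scale adjustment, the 5000 most variable genes
   (variance over patients only) selected, and samples clustered with
   Ward's minimum-variance criterion.  Cutting the tree at k = 4 primary
   clusters and choosing, per cluster, the cell line nearest the patient
   centroid yields the mixed-cell panel; AR and neuroendocrine marker
   z-scores characterize each cluster.
3. **IDA combination scoring** — from monotherapy viabilities
   `v_i(d, c)` across a line panel, the predicted combination viability of
   line *i* is `min(v_i(A, cA), v_i(B, cB))` and the combo score is
   `mean_i v_bestmono,i − mean_i v_combo,i`, the improvement over the best
   single agent (non-negative by construction; maximized by collateral
   sensitivity between the drugs).
4. **Co-culture simulation and efficacy analysis** — lines grow
   logistically against a shared carrying capacity with drug effect
   entering as a growth-rate multiplier `g(v) = 2v − 1`; per well and
   fluorescence channel, normalized growth is endpoint area over starting
   area, and the per-channel values summed give mixture proliferation.
   Conditions are compared with the Mann–Whitney U test (exact enumeration
   at small n), Bliss scores quantify within-line interaction, and the
   report contrasts the mixture-level verdict with the conventional
   pooled-per-line analysis.
5. **Resistance screening** — ridge regression of drug response (AUC) on
   cell-line transcriptomes imputes per-drug sensitivities for
   taxane-sensitive and taxane-resistant clones; a t-test screen with
   Benjamini–Hochberg correction nominates resistant-selective drugs.

## Worked example

The headline behavior — a combination whose benefit is visible in the
mixture but invisible to aggregation — in a few lines
(`examples/03_mixture_vs_aggregate.py`):

```python
from hetmix.efficacy import evaluate_combo
from hetmix.presets import complementary_combo_scenario
from hetmix.synthgen import generate_growth_experiment

scenario = complementary_combo_scenario(seed=0)
obs = generate_growth_experiment(
    scenario.params, scenario.seeding, scenario.treatments, n_replicates=6, seed=42
)
report = evaluate_combo(obs)
```

which prints

```
combo: docetaxel-like 3 nM + daporinad-like 5 nM
best monotherapy (by mixture median): mono_a
mixture medians: {'vehicle': 23.33, 'mono_a': 5.2, 'mono_b': 17.77, 'combo': 2.9}
mixture-level   p = 0.0022  combo superior: True
aggregated      p = 0.7397  combo superior: False
per-line p (combo vs best mono): {'22RV1-like': 0.002, 'DU145-like': 0.589, 'R1D567-like': 0.818}
```

Reading: the taxane is the better monotherapy at the mixture level (median
proliferation 5.2 vs 17.8, vehicle 23.3).  Adding the NAMPT-inhibitor
analog nearly halves mixture proliferation again (2.9), a difference the
6-replicate rank-sum test calls decisively (p = 0.0022) — yet pooling the
same per-line normalized growths across lines, as single-model screening
would, finds nothing (p = 0.74), because only the one line each drug
covers moves while between-line differences dominate the pooled variance.
The per-line tests confirm no within-line interaction: in two of three
lines the combo is indistinguishable from that line's best single agent.

The other examples cover representative-line selection (`01`), IDA ranking
(`02`), a synergistic low-dose combination (`04`) and the resistance
screen (`05`); each prints a short table and a comment on what the numbers
mean.

A thin CLI wraps the two workflows:

```bash
hetmix select   --preset unstratified-crpc --seed 17 --out out/
hetmix evaluate --preset unstratified-crpc --seed 17 --out out/
hetmix rank     --table mono.csv --anchor docetaxel-like --anchor-conc 3 --out ranked.csv
```

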