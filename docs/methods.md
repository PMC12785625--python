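# Methods

This note documents the models behind `hetmix`, the parameters that matter,
the numerical conventions, and the decisions taken where the design was
genuinely open.  Nothing here reports an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

A cohort is defined by a set of latent tumor subtypes and non-tumor
compartments (stroma, immune), each with a per-gene mean log2 expression
profile over a shared gene universe.  Every patient biopsy carries one
dominant subtype; its bulk profile is formed **on the linear scale** —
mixtures of cell populations are linear in abundance —

    bulk = f_tumor * sig_subtype + Σ_nt f_nt * sig_nt,

then transformed with log2(x + 1), after which Gaussian measurement noise
of `noise_sd` log2 units is added.  Linear signatures are `2^profile − 1`,
so a noiseless pure-tumor sample round-trips exactly to the subtype
profile.  Tumor content is drawn from Beta(5, 2) (median ≈ 0.73, a
realistic biopsy-purity distribution with a low-purity tail); the non-tumor
remainder is split by a symmetric Dirichlet.

Cell-line columns are subtype profiles transformed by a per-gene batch
shift ~ N(0, 0.3) and scale ~ N(1, 0.05) shared across lines — the
systematic platform offset that the batch-correction stage must remove —
plus the same measurement noise.  Taxane-resistant clones are the parent
profile plus +1 log2 on a 50-gene resistance set, with the taxane IC50
multiplied by a factor drawn uniformly from [10, 100].

All randomness flows from one seed through named substreams
(`hetmix._rng.substream`), so any module can be exercised in isolation and
whole runs are bit-reproducible.

### Default study conditions

The unstratified preset has 208 patients over four subtypes (AR-negative
30%, AR-plus-variant 30%, variant-only 25%, NEPC-like 15%), 20,000 genes,
and one cell line per subtype; the NEPC-like line is flagged excludable
(its culturing requirements bar it from the co-culture).  The
taxane-exposed preset has 79 patients, the three culturable parents and
their three resistant clones.  Doubling times are (28, 56, 56, 70) h —
synthetic values chosen so the seeding-compensation rule reproduces a
1:2:2 ratio for the three-line panel; real doubling times for these
lineages are not published alongside that ratio, so the values are
configurable.

**Marker-set size.** Each subtype over-expresses `markers_per_type = 400`
genes by 2 log2 units (4-fold).  Lineage expression programs span hundreds
of genes, and this size is what makes the subtypes *separable but
non-trivial* after purification: the between-subtype centroid separation
(≈ √(2·400)·2 ≈ 57 in log2 units over the 5000 clustering genes) must
exceed the residual norm of the noisiest retained samples, whose
purification noise is amplified by up to 1/min_tumor_fraction.  With
substantially smaller marker sets the k = 4 cut peels low-purity outlier
patients instead of splitting subtypes.

### What the generator does not emulate

No read-level sequencing simulation, no gene–gene correlation beyond the
block structure, no library-size or GC biases, no intra-tumoral
heterogeneity (one dominant subtype per patient), and no attempt to match
real expression distributions gene by gene.  Passing tests therefore
demonstrate that the pipeline recovers planted structure under realistic
noise, purity and batch distortions — not that it would resolve any
particular real cohort.

## Purification

Fractions are estimated per sample by non-negative least squares of the
linear-scale bulk onto the signature columns, normalized to sum to one;
estimation can be restricted to a marker subset (the signature builder
ranks genes by the fold change of a type's mean over the maximum of the
other types' means and stores the marker union).  Purified tumor
expression is `max(0, bulk − Σ_nt f_nt·sig_nt)/f_tumor`, clipped before the
log2(x + 1) transform.  Samples with estimated tumor fraction below
`min_tumor_fraction = 0.2` are excluded rather than divided by a small
denominator.  This is a transparent surrogate for reference-based
support-vector deconvolution platforms: it returns per-sample purified
profiles only, which is all the clustering stage consumes.

## Batch correction

Standard parametric empirical-Bayes location/scale adjustment: per gene,
standardize by the batch-size-weighted grand mean and pooled within-batch
variance; per batch, estimate location γ̂ and scale δ̂²; shrink toward a
normal / inverse-gamma prior whose hyperparameters come from the method of
moments across genes, via the usual iterative scheme; adjust and
back-transform.  Two conventions: a variance floor of 1e-8 guards
zero-variance genes, and after adjustment each gene is re-centred so its
pooled mean equals the pre-correction pooled mean (the correction removes
*between-batch* structure, not a gene's overall level).  Shrinkage leaves
per-gene residual batch differences of the order of the batch-mean
estimation noise — the Bioconductor reference implementation behaves
identically, and a test compares the two directly through `Rscript`.

## Clustering and representative selection

Variable genes are the top-k (default 5000) by variance **across patient
samples only**, computed after batch correction; cell-line-driven
variability must not select genes.  Clustering is agglomerative with
Ward's criterion on Euclidean distances in log2 space; merge heights are
reported as the increase in within-cluster sum of squares (ΔSSE; two
singletons at distance d merge at d²/2), and the test suite checks the
full merge sequence against an exhaustive ΔSSE-recomputation oracle.  The
primary cut removes the k−1 highest merges (k = 4 by default — the number
of primary clusters is a parameter, not a discovery procedure, since
delimiting "primary" clusters on a dendrogram is a judgment call).  Each
cluster's representative is the non-excluded cell-line member nearest the
cluster's patient centroid — a deterministic operationalization of what is
otherwise a manual choice; excluded lines present in a cluster are
reported, and a cluster without eligible lines is a valid "unrepresented"
outcome.  Signature scores are mean marker z-scores (genes standardized
across all samples, variance-floored); the AR and NEPC marker sets are
inputs (GMT), with the preset providing synthetic ones.

## IDA combination scoring

For a drug pair at fixed doses, per shared line
`v_combo = min(v_A, v_B)`; the best monotherapy is the single (drug, dose)
with the lower **mean** viability across the panel; the score is
`mean best-mono viability − mean combo viability`.  The score is kept
behind one function so an alternative form can be swapped in.  Lines
lacking either measurement are dropped and counted, not imputed.  Ranking
fixes the anchor dose, takes each partner's best score over its tested
doses up to a per-drug cap (the clinically sustainable plasma
concentration, a config input), and breaks ties lexicographically.
Collateral sensitivity is the Spearman correlation of two drugs'
per-cluster efficacies; negative correlation ("collateral") is the pattern
IDA rewards.  Note the score measures improvement *over the best
monotherapy*: it orders combinations the same way as the simulated
mixture's benefit-over-best-mono, not the same way as raw combo
inhibition.

## Growth model

Per-line counts follow a shared-capacity logistic update

    N_i(t+dt) = N_i exp(r_i · g(v_i) · dt · (1 − ΣN/K)),   r_i = ln2/Td_i,

with `g(v) = 2v − 1`: v = 1 is unperturbed growth, v = 0.5 stasis,
v < 0.5 net cell loss — one parameterization covering cytostatic and
cytotoxic phenotypes.  Viabilities come from per-(line, drug) Hill curves
`v = 1 − emax·c^h/(c^h + ic50^h)` held constant over the 5-day exposure
(no pharmacokinetics).  Within-line combinations are configurable:
`ida-min` (minimum viability, no interaction) or `bliss` (product of
viabilities, a synergistic interaction at the growth-rate level).  The
shared capacity K (default 2·10⁶ cells/well ≫ the 50,000-cell seeding)
couples the subpopulations weakly; co-culture interaction strength is not
quantified by available data, so K is a config input.  Seeding splits the
total in proportion to doubling times (`round(Td_i/min Td)`, half-up
rounding, floor 1), so slower lines are seeded more.  dt = 1 h: halving it
changes day-5 counts by < 0.5% (tested).

A consequence worth stating: with exponential growth, a *rate-level*
multiplicative (Bliss-style) interaction compounds into endpoint
inhibition slightly **below** the endpoint Bliss expectation, so per-line
endpoint Bliss scores in the synergy scenario sit just under zero even
though the combination decisively out-inhibits both monotherapies in every
line.  The efficacy tests therefore assert the per-line superiority
directly and treat endpoint Bliss scores as a near-independence
diagnostic.

## Efficacy analysis

Normalized growth is endpoint area / start area per well and channel
(areas are counts × per-line cell-area constants with multiplicative
log-normal well noise, default σ = 0.05); mixture proliferation is the
per-well sum over channels.  The Mann–Whitney U test uses exact
enumeration when both samples have ≤ 8 observations without ties, else the
normal approximation with tie and continuity corrections; U is counted for
the first sample and two-sided p-values double the smaller tail.  Six
technical replicates per condition is the default (five is the accepted
minimum for the rank-sum test and is enforced).  The best monotherapy is
the condition with the lower **median** mixture proliferation.  A
combination is "superior" in an analysis when the two-sided test rejects
at α = 0.05 *and* its median is lower; no multiplicity correction is
applied within one combination evaluation (raw p-values are reported).
The aggregated analysis pools the per-line normalized growths across lines
per condition — not their per-line means — because that is what aggregating
separately-screened models does, and it is exactly this pooling that
inflates variance with between-line differences.  Bliss inhibitions are
computed against the vehicle condition's median normalized growth, clipped
to [0, 1].  A two-way ANOVA variant of the mixture test is not
implemented; the rank-sum test is the primary analysis throughout.

### The complementary scenario

The taxane + NAMPT-inhibitor scenario plants per-line viabilities at the
test doses (taxane 3 nM: 0.41/0.97/0.43; NAMPT analog 5 nM:
0.97/0.64/0.81 for the AR-negative / AR-variant / variant-only lines) such
that each drug covers a different part of the panel, the taxane is the
best mixture-level monotherapy, and the line the taxane misses remains the
fastest-proliferating under every condition.  That last property is what
makes the aggregated analysis blind: the combo's gain shifts that line
*within* its rank band, leaving the pooled rank distribution essentially
unchanged, while the mixture sum registers the full absolute reduction.
IC50s are derived in closed form from these viability targets
(`hill_ic50_for_viability`), not fitted.

## Sensitivity imputation and the resistance screen

Expression→AUC models are ridge regressions on genes standardized with
training statistics (new samples transformed with the stored parameters);
the penalty is selected by efficient leave-one-out cross-validation over a
13-point log grid from 1e-2 to 1e4.  Predictions are on the AUC scale
(lower = more sensitive).  Adding a constant to all training responses
shifts all predictions by that constant; a constant response yields an
intercept-only model with a warning.  The screen compares imputed AUC
between parental and resistant clone groups per drug with a two-sample
Student's t test; replicate variation comes from replicate expression
profiles of each clone (the generator produces five per state), not from
resampling the point predictions — a bootstrap over training lines could
be layered on, but replicate profiles are the more honest noise model.
Benjamini–Hochberg adjustment is applied across drugs (the screen runs
hundreds of simultaneous tests) and reported alongside raw p-values.
"Resistant-selective" means lower mean imputed AUC in the resistant group;
the screen table is sorted most-resistant-selective first (descending t).

In the synthetic screen, each drug's AUC decreases with the mean
expression of its linked gene set (slope 0.3 per log2 unit, AUC noise
0.02 — a strongly pathway-driven drug); resistant clones upregulate their
resistance set by +1 log2, so the pathway-matched drug shows the largest
imputed sensitivity gain.

## Numerical conventions

- Variance floors of 1e-8 wherever a standard deviation is divided by
  (z-scores, standardization, EB scale estimates).
- Linear/log2 round trip is exact: linear = 2^x − 1, log2(x + 1) back.
- Negative purification residuals clip to 0 before the log transform.
- Variable-gene ties break by input gene order (stable sort).
- Ranking ties break lexicographically by partner name.
- Seeding ratios use half-up rounding (2.5 → 3), floor 1.
- Exact Mann–Whitney p-values cap at 1 after doubling the smaller tail.
- Monotherapy viabilities clip to [0, 1] after optional noise.

## Limitations

The pipeline's validation is entirely against planted synthetic structure;
the purification surrogate does not reproduce support-vector deconvolution
or its S-mode batch handling; the growth model is well-mixed and
non-spatial with static drug exposure; per-cluster drug efficacies for the
collateral-sensitivity diagnostic come from the cluster-assigned cell
lines' dose-response curves rather than patient-level imputation; and the
drug analogs' curves are constructions that reproduce qualitative
sensitivity structure, not fits to measured pharmacology.
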