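"""End-to-end workflows: representative selection and combo evaluation.

Two orchestrated pipelines tie the modules together:

``run_selection_pipeline``
    synthetic cohort -> signature construction -> fraction estimation ->
    tumor purification -> integration with the cell-line panel -> batch
    correction -> variable-gene selection -> Ward clustering -> primary-
    cluster cut -> representative-line assignment -> AR/NEPC cluster
    scores.  Artifacts (Newick dendrogram, assignment and score tables, a
    JSON manifest) are written when an output directory is given.

``run_combo_evaluation``
    monotherapy table -> IDA ranking against the anchor drug -> growth
    experiment of the chosen combination on the mixed-cell panel ->
    mixture-vs-aggregate efficacy report, plus the per-cluster collateral-
    sensitivity diagnostic when a cluster assignment is available.

Both are deterministic functions of their configuration: rerunning with
the same config reproduces identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from ._rng import child_seed
from .batch import combat_correct
from .cluster import (
    ClusterAssignment,
    Dendrogram,
    assign_representatives,
    cut_primary_clusters,
    select_variable_genes,
    signature_score,
    ward_cluster,
)
from .datatypes import ExpressionMatrix
from .deconv import build_signature_matrix, estimate_fractions, impute_tumor_expression
from .efficacy import EfficacyReport, evaluate_combo
from .ida import ComboPrediction, collateral_sensitivity, ida_combo_score, rank_combos
from .presets import (
    CSUSTAINED,
    DRUG_DOCETAXEL,
    EXCLUDABLE_LINES,
    TEST_DOSES,
    combo_treatments,
    drug_concentration_grids,
    growth_params,
    marker_sets,
    mixture_seeding,
    taxane_resistant_crpc,
    unstratified_crpc,
)
from .synthgen import (
    CohortConfig,
    ResistantClone,
    generate_cell_line_panel,
    generate_cohort,
    generate_growth_experiment,
    generate_monotherapy_table,
    generate_reference_profiles,
)
from . import io

__all__ = [
    "RunConfig",
    "SelectionResult",
    "ComboEvaluationResult",
    "run_selection_pipeline",
    "run_combo_evaluation",
]

logger = logging.getLogger(__name__)

PRESETS = ("unstratified-crpc", "taxane-resistant-crpc")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    preset: str = "unstratified-crpc"
    seed: int = 0
    k_clusters: int = 4
    n_variable_genes: int = 5000
    n_genes: int = 20000
    n_patients: int | None = None
    n_markers_per_type: int = 50
    min_tumor_fraction: float = 0.2
    anchor_drug: str = DRUG_DOCETAXEL
    anchor_dose: float | None = None
    partner_drug: str | None = None
    partner_dose: float | None = None
    combo_model: str = "ida-min"
    n_replicates: int = 6
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")

    def resolve_preset(self) -> tuple[CohortConfig, tuple[ResistantClone, ...]]:
        kwargs = {"seed": self.seed, "n_genes": self.n_genes}
        if self.n_patients is not None:
            kwargs["n_patients"] = self.n_patients
        if self.preset == "taxane-resistant-crpc":
            return taxane_resistant_crpc(**kwargs)
        return unstratified_crpc(**kwargs), ()

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class SelectionResult:
    """Outputs of the representative-selection pipeline."""

    config: RunConfig
    cohort_config: CohortConfig
    assignment: ClusterAssignment
    dendrogram: Dendrogram
    fractions: pd.DataFrame
    excluded_samples: tuple[str, ...]
    truth: pd.DataFrame
    corrected: ExpressionMatrix
    variable_genes: pd.Index

    @property
    def representatives(self) -> list[str]:
        return sorted(r for r in self.assignment.representatives.values() if r)

    def manifest(self) -> dict:
        labels = self.assignment.labels
        roles = self.corrected.sample_role
        clusters = {}
        for c in sorted(labels.unique()):
            members = labels.index[labels == c]
            clusters[int(c)] = {
                "n_patients": int((roles.loc[members] == "patient").sum()),
                "n_cell_lines": int((roles.loc[members] == "cell-line").sum()),
                "representative": self.assignment.representatives.get(int(c)) or "unrepresented",
            }
        return {
            "package_version": _pkg_version,
            "pipeline": "selection",
            "config": self.config.to_dict(),
            "n_samples_clustered": int(len(labels)),
            "n_low_purity_excluded": len(self.excluded_samples),
            "n_variable_genes": int(len(self.variable_genes)),
            "clusters": clusters,
        }


def run_selection_pipeline(config: RunConfig) -> SelectionResult:
    """Run cohort generation through representative-line assignment."""
    cohort_config, clones = config.resolve_preset()
    logger.info("selection pipeline: preset=%s seed=%d", config.preset, config.seed)

    bulk, truth, _true_signatures = generate_cohort(cohort_config)
    ref_profiles, ref_labels = generate_reference_profiles(cohort_config)
    signature = build_signature_matrix(
        ref_profiles,
        ref_labels,
        tumor_types=cohort_config.subtype_names,
        n_markers_per_type=config.n_markers_per_type,
        keep_all_genes=True,
    )
    fractions = estimate_fractions(bulk, signature)
    purified, excluded = impute_tumor_expression(
        bulk, signature, fractions, min_tumor_fraction=config.min_tumor_fraction
    )
    panel = generate_cell_line_panel(cohort_config, resistant_clones=clones)
    integrated = purified.concat(panel)
    corrected = combat_correct(integrated)
    variable = select_variable_genes(corrected, config.n_variable_genes)
    clustering_matrix = corrected.subset_genes(variable)
    dendrogram = ward_cluster(clustering_matrix)
    labels = cut_primary_clusters(dendrogram, config.k_clusters)
    assignment = assign_representatives(labels, clustering_matrix, EXCLUDABLE_LINES)

    sets = marker_sets(n_genes=config.n_genes)
    score_table = pd.DataFrame(
        {name: signature_score(corrected, genes) for name, genes in sets.items()}
    )
    assignment.scores = score_table.groupby(labels).mean()

    result = SelectionResult(
        config=config,
        cohort_config=cohort_config,
        assignment=assignment,
        dendrogram=dendrogram,
        fractions=fractions,
        excluded_samples=tuple(excluded),
        truth=truth,
        corrected=corrected,
        variable_genes=variable,
    )
    if config.outdir:
        _write_selection_outputs(result)
    return result


def _write_selection_outputs(result: SelectionResult) -> None:
    outdir = Path(result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "dendrogram.nwk").write_text(result.dendrogram.to_newick() + "\n")
    io.write_csv(result.assignment.to_frame(), outdir / "cluster_assignment.csv", index=True)
    io.write_csv(result.assignment.scores, outdir / "cluster_scores.csv", index=True)
    io.write_csv(result.fractions, outdir / "fractions.csv", index=True)
    io.write_gmt(marker_sets(n_genes=result.config.n_genes), outdir / "marker_sets.gmt")
    io.write_json(result.manifest(), outdir / "manifest.json")
    logger.info("selection outputs written to %s", outdir)


@dataclass
class ComboEvaluationResult:
    """Outputs of the combination-evaluation pipeline."""

    config: RunConfig
    monotherapy: pd.DataFrame
    ranked: pd.DataFrame
    prediction: ComboPrediction
    report: EfficacyReport
    collateral: tuple[float, str] | None = None

    def manifest(self) -> dict:
        out = {
            "package_version": _pkg_version,
            "pipeline": "combo-evaluation",
            "config": self.config.to_dict(),
            "anchor": self.prediction.drug_a,
            "partner": self.prediction.drug_b,
            "doses": [self.prediction.conc_a, self.prediction.conc_b],
            "ida_combo_score": self.prediction.score,
            "report": self.report.to_dict(),
        }
        if self.collateral is not None:
            out["collateral"] = {"spearman": self.collateral[0], "verdict": self.collateral[1]}
        return out


def run_combo_evaluation(
    config: RunConfig,
    representatives: list[str] | None = None,
    assignment: ClusterAssignment | None = None,
) -> ComboEvaluationResult:
    """Rank combinations and evaluate the chosen one on the mixed-cell model.

    ``representatives`` defaults to every non-excludable line of the
    preset.  When a cluster ``assignment`` from the selection pipeline is
    supplied, the per-cluster collateral-sensitivity diagnostic of the
    evaluated pair is computed from the cluster-assigned cell lines.
    """
    # growth and dose-response do not depend on the gene universe; use a
    # small one so evaluation stays light
    cohort_config, clones = RunConfig(
        **{**config.to_dict(), "n_genes": min(config.n_genes, 2000)}
    ).resolve_preset()

    table = generate_monotherapy_table(
        cohort_config.subtypes,
        drugs=list(TEST_DOSES),
        conc_grid=drug_concentration_grids(),
        resistant_clones=clones,
        seed=config.seed,
    )
    anchor_dose = config.anchor_dose if config.anchor_dose is not None else TEST_DOSES[config.anchor_drug]
    ranked = rank_combos(
        table,
        anchor_drug=config.anchor_drug,
        anchor_conc=anchor_dose,
        max_conc=CSUSTAINED,
    )

    if config.partner_drug is not None:
        partner = config.partner_drug
    else:
        partner = str(ranked.iloc[0]["partner"])
    partner_dose = config.partner_dose
    if partner_dose is None:
        partner_dose = TEST_DOSES.get(
            partner, float(ranked.set_index("partner").loc[partner, "conc_partner"])
        )
    prediction = ida_combo_score(
        table, config.anchor_drug, partner, anchor_dose, partner_dose
    )

    if representatives is None:
        representatives = [
            line
            for line in cohort_config.line_to_subtype()
            if line not in EXCLUDABLE_LINES
        ]
        if config.preset == "taxane-resistant-crpc":
            # the resistant setting pools the resistant clones, not parents
            representatives = [c.name for c in clones]
    params = growth_params(
        cohort_config,
        lines=representatives,
        combo_model=config.combo_model,
        resistant_clones=clones,
        seed=config.seed,
    )
    obs = generate_growth_experiment(
        params,
        mixture_seeding(params),
        combo_treatments(config.anchor_drug, anchor_dose, partner, partner_dose),
        n_replicates=config.n_replicates,
        seed=child_seed(config.seed, "growth-experiment"),
    )
    report = evaluate_combo(obs)

    collateral = None
    if assignment is not None:
        collateral = _cluster_collateral(
            table, assignment, config.anchor_drug, anchor_dose, partner, partner_dose
        )

    result = ComboEvaluationResult(
        config=config,
        monotherapy=table,
        ranked=ranked,
        prediction=prediction,
        report=report,
        collateral=collateral,
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_csv(ranked, outdir / "ranked_combos.csv")
        io.write_csv(table, outdir / "monotherapy.csv")
        io.write_csv(
            report.per_line_median, outdir / "per_line_median_growth.csv", index=True
        )
        io.write_json(result.manifest(), outdir / "combo_report.json")
        logger.info("combo-evaluation outputs written to %s", outdir)
    return result


def _cluster_collateral(
    table: pd.DataFrame,
    assignment: ClusterAssignment,
    drug_a: str,
    dose_a: float,
    drug_b: str,
    dose_b: float,
) -> tuple[float, str] | None:
    """Per-cluster efficacy anti-correlation of the evaluated drug pair.

    Each cluster's predicted efficacy under a drug is the mean inhibition
    (1 - viability at the test dose) of the cell lines assigned to the
    cluster; excluded lines still contribute here, since prediction does
    not require culturability.  Clusters without any line are skipped.
    """
    va = table[(table["drug"] == drug_a) & np.isclose(table["concentration"], dose_a)]
    vb = table[(table["drug"] == drug_b) & np.isclose(table["concentration"], dose_b)]
    va = va.set_index("cell_line")["viability"]
    vb = vb.set_index("cell_line")["viability"]

    eff_a, eff_b = [], []
    labels = assignment.labels
    roles_lines = [s for s in labels.index if s in set(va.index) & set(vb.index)]
    for cluster in sorted(labels.unique()):
        members = [s for s in labels.index[labels == cluster] if s in roles_lines]
        if not members:
            continue
        eff_a.append(float(1.0 - va.loc[members].mean()))
        eff_b.append(float(1.0 - vb.loc[members].mean()))
    if len(eff_a) < 3:
        logger.warning("fewer than 3 clusters with cell lines: collateral diagnostic skipped")
        return None
    return collateral_sensitivity(eff_a, eff_b)
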