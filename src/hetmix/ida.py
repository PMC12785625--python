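"""Independent-drug-action (IDA) combination efficacy prediction.

Under independent drug action, a combination benefits each tumor through
whichever component drug that tumor is most sensitive to — drugs do not
need to interact within a cell for the combination to help a heterogeneous
population.  Given monotherapy viabilities measured across a cell-line
panel, the predicted combination viability of line *i* at doses
``(cA, cB)`` is ``min(v_i(A, cA), v_i(B, cB))``, and the combination score
is the improvement of the mean combination viability over the best single
agent:

    score = mean_i v_bestmono,i - mean_i v_combo,i

where "best mono" is the single (drug, dose) of the pair with the lower
mean viability across the panel.  The score is non-negative by
construction and grows when the two drugs cover complementary subsets of
the panel — the collateral-sensitivity pattern that makes IDA combinations
effective in diverse cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "ComboPrediction",
    "ida_combo_score",
    "rank_combos",
    "collateral_sensitivity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComboPrediction:
    """Per-panel IDA prediction for one drug pair at fixed doses."""

    drug_a: str
    drug_b: str
    conc_a: float
    conc_b: float
    per_line: pd.DataFrame  # columns: viability_a, viability_b, viability_combo
    mean_combo_viability: float
    best_mono_drug: str
    best_mono_mean_viability: float
    score: float
    n_lines: int
    n_dropped: int


def _viability_vector(
    table: pd.DataFrame, drug: str, conc: float
) -> pd.Series:
    rows = table[(table["drug"] == drug) & np.isclose(table["concentration"], conc)]
    if rows.empty:
        raise KeyError(f"no monotherapy rows for ({drug!r}, {conc})")
    if rows["cell_line"].duplicated().any():
        raise ValueError(f"duplicate (line, drug, conc) rows for ({drug!r}, {conc})")
    return rows.set_index("cell_line")["viability"]


def ida_combo_score(
    table: pd.DataFrame,
    drug_a: str,
    drug_b: str,
    conc_a: float,
    conc_b: float,
) -> ComboPrediction:
    """IDA prediction for one drug pair at fixed doses.

    ``table`` is a tidy monotherapy table with columns
    ``cell_line, drug, concentration, viability``.  Lines lacking either
    measurement are dropped (and counted); no shared line is an error.
    """
    va = _viability_vector(table, drug_a, conc_a)
    vb = _viability_vector(table, drug_b, conc_b)
    shared = va.index.intersection(vb.index)
    n_dropped = len(va.index.union(vb.index)) - len(shared)
    if shared.empty:
        raise ValueError(
            f"no cell lines measured under both ({drug_a!r}, {conc_a}) and ({drug_b!r}, {conc_b})"
        )
    if n_dropped:
        logger.info(
            "combo (%s, %s): dropped %d lines lacking one measurement",
            drug_a, drug_b, n_dropped,
        )
    va, vb = va.loc[shared], vb.loc[shared]
    v_combo = np.minimum(va, vb)

    mean_a, mean_b = float(va.mean()), float(vb.mean())
    if mean_a <= mean_b:
        best_drug, best_mean = drug_a, mean_a
    else:
        best_drug, best_mean = drug_b, mean_b
    mean_combo = float(v_combo.mean())

    per_line = pd.DataFrame(
        {"viability_a": va, "viability_b": vb, "viability_combo": v_combo}
    )
    return ComboPrediction(
        drug_a=drug_a,
        drug_b=drug_b,
        conc_a=float(conc_a),
        conc_b=float(conc_b),
        per_line=per_line,
        mean_combo_viability=mean_combo,
        best_mono_drug=best_drug,
        best_mono_mean_viability=best_mean,
        score=best_mean - mean_combo,
        n_lines=len(shared),
        n_dropped=n_dropped,
    )


def rank_combos(
    table: pd.DataFrame,
    anchor_drug: str,
    anchor_conc: float,
    partner_drugs: Sequence[str] | None = None,
    max_conc: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Rank partner drugs by their best IDA score with a fixed anchor dose.

    For each partner, every tested concentration up to the partner's cap
    (its clinically sustainable plasma concentration, when provided) is
    scored against the anchor at ``anchor_conc``; the partner's best score
    and dose are recorded.  The result is sorted by descending score, ties
    broken lexicographically by partner name.

    Returns a DataFrame with columns
    ``anchor, partner, conc_anchor, conc_partner, score, n_lines``.
    """
    if partner_drugs is None:
        partner_drugs = sorted(set(table["drug"]) - {anchor_drug})
    if not len(partner_drugs):
        raise ValueError("empty partner set")

    records = []
    for partner in partner_drugs:
        concs = np.sort(table.loc[table["drug"] == partner, "concentration"].unique())
        if max_conc is not None and partner in max_conc:
            concs = concs[concs <= max_conc[partner]]
        best = None
        for conc in concs:
            pred = ida_combo_score(table, anchor_drug, partner, anchor_conc, conc)
            if best is None or pred.score > best.score:
                best = pred
        if best is None:
            logger.warning("partner %r has no doses within its cap; skipped", partner)
            continue
        records.append(
            {
                "anchor": anchor_drug,
                "partner": partner,
                "conc_anchor": float(anchor_conc),
                "conc_partner": best.conc_b,
                "score": best.score,
                "n_lines": best.n_lines,
            }
        )
    ranked = pd.DataFrame.from_records(records)
    ranked = ranked.sort_values(
        ["score", "partner"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return ranked


def collateral_sensitivity(
    efficacy_a: Sequence[float], efficacy_b: Sequence[float]
) -> tuple[float, str]:
    """Rank correlation of two drugs' per-cluster efficacies.

    A negative Spearman correlation — the patient groups least responsive
    to one drug being most responsive to the other — is the collateral-
    sensitivity pattern under which an IDA combination covers the cohort.

    Returns ``(rho, verdict)`` with verdict ``"collateral"`` (rho < 0),
    ``"redundant"`` (rho >= 0) or ``"undefined"`` for constant inputs.
    """
    a = np.asarray(efficacy_a, dtype=float)
    b = np.asarray(efficacy_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("efficacy vectors must be 1-D and equally long")
    if len(a) < 3:
        raise ValueError("at least 3 clusters required")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("constant efficacy vector: correlation undefined")
        return float("nan"), "undefined"
    rho = float(scipy.stats.spearmanr(a, b).statistic)
    return rho, ("collateral" if rho < 0 else "redundant")
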