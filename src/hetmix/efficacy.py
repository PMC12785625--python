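"""Growth-area readouts, rank-sum testing, Bliss synergy, combo verdicts.

The analysis layer over well observations from a mixed-cell growth
experiment.  Per well and fluorescence channel, growth is the endpoint
area divided by the area at treatment start (normalizing out seeding
differences); summing the per-channel normalized growths gives the
proliferation of the tumor mixture as a composite entity.  Treatment
conditions are compared with the Mann-Whitney U test (exact enumeration at
small sample sizes), and two complementary analyses of a drug combination
are reported side by side:

* the mixture-level analysis, comparing per-well mixture proliferation of
  the combination against the best monotherapy; and
* the aggregated analysis mirroring conventional practice, pooling the
  per-line normalized growths across lines per condition before testing.

With complementary per-line sensitivities the combination's benefit is
spread across subpopulations: the mixture readout accumulates it, while
pooling inflates variance with between-line differences and misses it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "normalized_growth_area",
    "mixture_proliferation",
    "mann_whitney_u",
    "bliss_synergy",
    "EfficacyReport",
    "evaluate_combo",
]

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 8
_MIN_REPLICATES = 5

CONDITION_KEYS = ("vehicle", "mono_a", "mono_b", "combo")


def normalized_growth_area(obs: pd.DataFrame) -> pd.DataFrame:
    """Append per-well per-channel normalized growth (end / start area).

    ``obs`` must have columns ``condition, replicate, channel, area_start,
    area_end``.  A zero or negative start area is an error naming the
    offending well and channel.
    """
    required = {"condition", "replicate", "channel", "area_start", "area_end"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"missing observation columns: {sorted(missing)}")
    bad = obs[obs["area_start"] <= 0]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"non-positive start area in condition {row['condition']!r}, "
            f"replicate {row['replicate']}, channel {row['channel']!r}"
        )
    out = obs.copy()
    out["norm_growth"] = out["area_end"] / out["area_start"]
    return out


def mixture_proliferation(norm: pd.DataFrame) -> pd.Series:
    """Per-well mixture proliferation: the sum of channel normalized growths.

    Every well (condition x replicate) must report every channel.
    """
    if "norm_growth" not in norm.columns:
        norm = normalized_growth_area(norm)
    channels = set(norm["channel"].unique())
    counts = norm.groupby(["condition", "replicate"])["channel"].agg(set)
    incomplete = counts[counts != channels]
    if len(incomplete):
        cond, rep = incomplete.index[0]
        raise ValueError(
            f"well ({cond!r}, replicate {rep}) is missing channels "
            f"{sorted(channels - incomplete.iloc[0])}"
        )
    return norm.groupby(["condition", "replicate"])["norm_growth"].sum().rename("mixture_proliferation")


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` with ``U`` counted for ``x`` (number of (x, y) pairs
    with x > y, plus half the ties).  The exact null distribution is
    enumerated when both samples have at most 8 observations and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections is used.  Two-sided p-values double the smaller tail,
    capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    if x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def bliss_synergy(e_a: float, e_b: float, e_ab: float, tol: float = 1e-9) -> float:
    """Bliss-independence excess of a combination's inhibition.

    ``e_a``, ``e_b`` and ``e_ab`` are inhibition fractions in [0, 1]
    (1 - growth relative to control).  The score is

        e_ab - (e_a + e_b - e_a * e_b)

    positive for synergy, about zero for independent action, negative for
    antagonism.  Inputs outside [0, 1] beyond ``tol`` are rejected.
    """
    vals = np.array([e_a, e_b, e_ab], dtype=float)
    if (vals < -tol).any() or (vals > 1 + tol).any():
        raise ValueError(f"inhibition fractions outside [0, 1]: {vals.tolist()}")
    e_a, e_b, e_ab = np.clip(vals, 0.0, 1.0)
    expected = e_a + e_b - e_a * e_b
    return float(e_ab - expected)


@dataclass
class EfficacyReport:
    """Full mixture-vs-aggregate evaluation of one drug combination."""

    conditions: dict[str, str]
    best_mono: str  # "mono_a" or "mono_b"
    mixture_medians: dict[str, float]
    mixture_p_combo_vs_best: float
    combo_superior_in_mixture: bool
    aggregate_p_combo_vs_best: float
    combo_superior_in_aggregate: bool
    per_line_median: pd.DataFrame
    per_line_p_combo_vs_best: dict[str, float]
    per_line_p_combo_vs_vehicle: dict[str, float]
    bliss_scores: dict[str, float]
    synergy_flags: dict[str, bool]
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "conditions": self.conditions,
            "best_mono": self.best_mono,
            "alpha": self.alpha,
            "mixture": {
                "medians": self.mixture_medians,
                "p_combo_vs_best_mono": self.mixture_p_combo_vs_best,
                "combo_superior": self.combo_superior_in_mixture,
            },
            "aggregate": {
                "p_combo_vs_best_mono": self.aggregate_p_combo_vs_best,
                "combo_superior": self.combo_superior_in_aggregate,
            },
            "per_line": {
                "median_normalized_growth": {
                    line: {c: float(v) for c, v in row.items()}
                    for line, row in self.per_line_median.iterrows()
                },
                "p_combo_vs_best_mono": self.per_line_p_combo_vs_best,
                "p_combo_vs_vehicle": self.per_line_p_combo_vs_vehicle,
                "bliss_scores": self.bliss_scores,
                "synergy_flags": self.synergy_flags,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def evaluate_combo(
    obs: pd.DataFrame,
    conditions: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> EfficacyReport:
    """Evaluate a four-condition combination experiment.

    Parameters
    ----------
    obs
        Well observations (``condition, replicate, channel, area_start,
        area_end``) covering a vehicle control, two monotherapies and the
        combination, with at least 5 replicates per condition.
    conditions
        Mapping from the logical keys ``vehicle, mono_a, mono_b, combo`` to
        the condition labels in ``obs``; defaults to the identity mapping.
    alpha
        Two-sided significance level for the verdicts.

    The best monotherapy is the one with the lower median mixture
    proliferation.  The combination is "superior" in an analysis when its
    values are significantly different from the best monotherapy's at
    ``alpha`` and its median is lower.
    """
    conditions = dict(conditions) if conditions is not None else {k: k for k in CONDITION_KEYS}
    missing_keys = set(CONDITION_KEYS) - set(conditions)
    if missing_keys:
        raise ValueError(f"condition mapping lacks keys: {sorted(missing_keys)}")
    present = set(obs["condition"].unique())
    missing_conditions = {conditions[k] for k in CONDITION_KEYS} - present
    if missing_conditions:
        raise ValueError(f"conditions absent from observations: {sorted(missing_conditions)}")

    norm = normalized_growth_area(obs)
    norm = norm[norm["condition"].isin(conditions.values())]
    rep_counts = norm.groupby("condition")["replicate"].nunique()
    thin = rep_counts[rep_counts < _MIN_REPLICATES]
    if len(thin):
        raise ValueError(
            f"conditions with fewer than {_MIN_REPLICATES} replicates: "
            f"{sorted(thin.index)}"
        )

    mixture = mixture_proliferation(norm)

    def mix_values(key: str) -> np.ndarray:
        return mixture.loc[conditions[key]].to_numpy()

    med_a = float(np.median(mix_values("mono_a")))
    med_b = float(np.median(mix_values("mono_b")))
    best_key = "mono_a" if med_a <= med_b else "mono_b"

    combo_mix = mix_values("combo")
    best_mix = mix_values(best_key)
    _, p_mix = mann_whitney_u(combo_mix, best_mix)
    mixture_superior = bool(
        p_mix < alpha and np.median(combo_mix) < np.median(best_mix)
    )

    # aggregated analysis: pool per-line normalized growths across lines
    def pooled(key: str) -> np.ndarray:
        return norm.loc[norm["condition"] == conditions[key], "norm_growth"].to_numpy()

    _, p_agg = mann_whitney_u(pooled("combo"), pooled(best_key))
    aggregate_superior = bool(
        p_agg < alpha
        and np.median(pooled("combo")) < np.median(pooled(best_key))
    )

    # per-line medians, tests and Bliss scores
    lines = sorted(norm["channel"].unique())
    label_of = {k: conditions[k] for k in CONDITION_KEYS}
    per_line_median = pd.DataFrame(index=lines, columns=list(CONDITION_KEYS), dtype=float)
    p_line_best: dict[str, float] = {}
    p_line_vehicle: dict[str, float] = {}
    bliss_scores: dict[str, float] = {}
    synergy_flags: dict[str, bool] = {}
    for line in lines:
        sub = norm[norm["channel"] == line]

        def line_values(key: str) -> np.ndarray:
            return sub.loc[sub["condition"] == label_of[key], "norm_growth"].to_numpy()

        for key in CONDITION_KEYS:
            per_line_median.loc[line, key] = float(np.median(line_values(key)))
        _, p_line_best[line] = mann_whitney_u(line_values("combo"), line_values(best_key))
        _, p_line_vehicle[line] = mann_whitney_u(line_values("combo"), line_values("vehicle"))

        vehicle_med = per_line_median.loc[line, "vehicle"]
        inhibition = {
            key: float(np.clip(1.0 - per_line_median.loc[line, key] / vehicle_med, 0.0, 1.0))
            for key in ("mono_a", "mono_b", "combo")
        }
        bliss_scores[line] = bliss_synergy(
            inhibition["mono_a"], inhibition["mono_b"], inhibition["combo"]
        )
        synergy_flags[line] = bool(
            bliss_scores[line] > 0
            and p_line_best[line] < alpha
            and per_line_median.loc[line, "combo"] < per_line_median.loc[line, best_key]
        )

    return EfficacyReport(
        conditions=dict(conditions),
        best_mono=best_key,
        mixture_medians={
            key: float(np.median(mix_values(key))) for key in CONDITION_KEYS
        },
        mixture_p_combo_vs_best=p_mix,
        combo_superior_in_mixture=mixture_superior,
        aggregate_p_combo_vs_best=p_agg,
        combo_superior_in_aggregate=aggregate_superior,
        per_line_median=per_line_median,
        per_line_p_combo_vs_best=p_line_best,
        per_line_p_combo_vs_vehicle=p_line_vehicle,
        bliss_scores=bliss_scores,
        synergy_flags=synergy_flags,
        alpha=alpha,
    )
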