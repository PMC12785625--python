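"""Expression-based drug-sensitivity imputation and differential screening.

Drug sensitivity (area under the dose-response curve, AUC; lower = more
sensitive) is imputed for unscreened samples by regularized linear
regression of measured cell-line AUC values on their transcriptomes:
genes are standardized with training-set statistics, a ridge penalty is
selected by cross-validation over a log-spaced grid, and the fitted
coefficients are applied to new expression profiles.

The differential-sensitivity screen then compares imputed AUC between
drug-sensitive parental clones and their resistant derivatives, drug by
drug, with a two-sample t test and Benjamini-Hochberg correction across
drugs.  A drug is "resistant-selective" when the resistant clones' mean
imputed AUC is lower (more sensitive) than the parents' — the collateral
vulnerabilities acquired alongside resistance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.linear_model import RidgeCV
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SensitivityModel",
    "fit_and_predict",
    "differential_sensitivity",
    "run_screen",
]

logger = logging.getLogger(__name__)

_ALPHA_GRID = np.logspace(-2, 4, 13)
_MIN_SHARED_GENES = 10
_SD_FLOOR = 1e-8


@dataclass
class SensitivityModel:
    """A fitted per-drug linear sensitivity model on standardized genes."""

    genes: tuple[str, ...]
    coef: pd.Series
    intercept: float
    alpha: float
    gene_mean: pd.Series
    gene_sd: pd.Series

    def predict(self, expression: pd.DataFrame) -> pd.Series:
        """Predicted AUC for genes x samples expression (log2 scale)."""
        X = expression.loc[list(self.genes)].T
        Z = (X - self.gene_mean) / self.gene_sd
        return pd.Series(
            Z.to_numpy() @ self.coef.to_numpy() + self.intercept,
            index=expression.columns,
            name="predicted_auc",
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.coef.rename("coefficient").to_frame()
        out.attrs["intercept"] = self.intercept
        out.attrs["alpha"] = self.alpha
        return out


def fit_and_predict(
    X_train: pd.DataFrame,
    auc: pd.Series,
    X_new: pd.DataFrame,
) -> tuple[pd.Series, SensitivityModel]:
    """Fit the expression->AUC ridge model and predict for new samples.

    Parameters
    ----------
    X_train
        Genes x training-samples log2 expression.
    auc
        Per-training-sample drug response (AUC scale; lower = more
        sensitive), aligned with ``X_train.columns``.
    X_new
        Genes x new-samples expression; only genes shared with the
        training matrix are used (at least 10 required).

    Returns the predictions for ``X_new`` columns plus the fitted model.
    The penalty is selected by efficient leave-one-out cross-validation
    over a log-spaced grid; standardization uses training statistics only.
    """
    shared = X_train.index.intersection(X_new.index)
    if len(shared) < _MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} genes shared between train and new matrices "
            f"(>= {_MIN_SHARED_GENES} required)"
        )
    auc = pd.Series(auc).loc[X_train.columns]
    if not np.isfinite(auc.to_numpy()).all():
        raise ValueError("non-finite training responses")

    X = X_train.loc[shared].T  # samples x genes
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).clip(lower=_SD_FLOOR)
    Z = (X - mean) / sd

    if np.ptp(auc.to_numpy()) == 0.0:
        warnings.warn("constant training response: intercept-only model", stacklevel=2)
        coef = pd.Series(0.0, index=shared)
        model = SensitivityModel(
            genes=tuple(shared),
            coef=coef,
            intercept=float(auc.iloc[0]),
            alpha=float("nan"),
            gene_mean=mean,
            gene_sd=sd,
        )
        return model.predict(X_new), model

    ridge = RidgeCV(alphas=_ALPHA_GRID)
    ridge.fit(Z.to_numpy(), auc.to_numpy())
    model = SensitivityModel(
        genes=tuple(shared),
        coef=pd.Series(ridge.coef_, index=shared),
        intercept=float(ridge.intercept_),
        alpha=float(ridge.alpha_),
        gene_mean=mean,
        gene_sd=sd,
    )
    return model.predict(X_new), model


def differential_sensitivity(
    pred_sensitive: pd.DataFrame,
    pred_resistant: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-drug differential sensitivity between clone groups.

    Parameters
    ----------
    pred_sensitive, pred_resistant
        Drugs x replicates tables of imputed AUC for the parental
        (sensitive) and resistant clones; at least 2 replicates per group.

    Returns a DataFrame indexed by drug with columns ``t, p, p_adj,
    direction, significant``: a two-sample Student's t statistic on imputed
    AUC, Benjamini-Hochberg adjusted p-values across drugs, and direction
    ``"resistant-selective"`` when the resistant group's mean AUC is lower.
    """
    drugs = pred_sensitive.index
    if not drugs.equals(pred_resistant.index):
        raise ValueError("sensitive and resistant tables must cover the same drugs")
    if pred_sensitive.shape[1] < 2 or pred_resistant.shape[1] < 2:
        raise ValueError("at least 2 replicates per group required")

    s = pred_sensitive.to_numpy(dtype=float)
    r = pred_resistant.to_numpy(dtype=float)
    t_stats = np.empty(len(drugs))
    p_vals = np.empty(len(drugs))
    for i in range(len(drugs)):
        if np.ptp(s[i]) == 0 and np.ptp(r[i]) == 0:
            # degenerate: both groups constant
            if s[i, 0] == r[i, 0]:
                t_stats[i], p_vals[i] = 0.0, 1.0
            else:
                t_stats[i] = np.inf if s[i, 0] > r[i, 0] else -np.inf
                p_vals[i] = 0.0
            continue
        res = scipy.stats.ttest_ind(s[i], r[i], equal_var=True)
        t_stats[i], p_vals[i] = float(res.statistic), float(res.pvalue)

    _, p_adj, _, _ = multipletests(np.clip(p_vals, 0.0, 1.0), method="fdr_bh")
    direction = np.where(
        r.mean(axis=1) < s.mean(axis=1), "resistant-selective", "sensitive-selective"
    )
    return pd.DataFrame(
        {
            "t": t_stats,
            "p": p_vals,
            "p_adj": p_adj,
            "direction": direction,
            "significant": p_adj < alpha,
        },
        index=drugs,
    )


def run_screen(
    X_train: pd.DataFrame,
    auc: pd.DataFrame,
    X_sensitive: pd.DataFrame,
    X_resistant: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Impute per-drug sensitivities for two clone groups and screen them.

    For every drug (column of ``auc``, training lines x drugs) a ridge
    model is fitted on the training panel and applied to the replicate
    expression profiles of the sensitive and resistant clones; the imputed
    AUC values then enter :func:`differential_sensitivity`.  Returns the
    screen table sorted by ascending t (most resistant-selective first).
    """
    pred_s, pred_r = {}, {}
    for drug in auc.columns:
        preds_s, model = fit_and_predict(X_train, auc[drug], X_sensitive)
        pred_s[drug] = preds_s.to_numpy()
        pred_r[drug] = model.predict(X_resistant).to_numpy()
    table_s = pd.DataFrame(pred_s).T
    table_r = pd.DataFrame(pred_r).T
    screen = differential_sensitivity(table_s, table_r, alpha=alpha)
    # positive t = higher AUC in parents = resistant-selective; rank those first
    return screen.sort_values("t", ascending=False, kind="stable")
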