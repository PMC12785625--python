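"""Tumor-expression purification from bulk profiles.

Bulk tumor biopsies are mixtures of malignant cells with stromal and immune
contamination.  Before patient tumors can be compared transcriptomically
with pure cell lines, the non-tumor signal has to be removed.  This module
implements a transparent purification procedure:

1. build a reference signature matrix from labelled per-cell-type profiles
   (marker genes by fold-change ranking, per-type mean linear expression);
2. estimate per-sample cell-type fractions by non-negative least squares of
   the bulk sample onto the signature columns (coefficients normalized to
   sum to one);
3. subtract the estimated non-tumor signal and rescale by the tumor
   fraction to obtain a per-sample "tumor-only" expression profile.

All arithmetic is done on the linear abundance scale, where mixing is
additive; purified profiles are returned on the log2(x + 1) scale used by
the clustering stage.  Samples whose estimated tumor content falls below
``min_tumor_fraction`` are excluded rather than amplified, since dividing
by a small fraction inflates noise.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .datatypes import (
    ExpressionMatrix,
    SignatureMatrix,
    linear_to_log2,
    log2_to_linear,
)

__all__ = [
    "build_signature_matrix",
    "estimate_fractions",
    "impute_tumor_expression",
]

logger = logging.getLogger(__name__)

_MIN_PROFILES_PER_TYPE = 3


def build_signature_matrix(
    profiles: pd.DataFrame,
    labels: pd.Series,
    tumor_types: Sequence[str],
    n_markers_per_type: int = 50,
    keep_all_genes: bool = False,
) -> SignatureMatrix:
    """Build a reference signature from labelled expression profiles.

    Parameters
    ----------
    profiles
        Genes x profiles table on the log2 scale (single-cell-like reference
        profiles, several per cell type).
    labels
        Per-profile cell-type label, indexed like ``profiles.columns``.
    tumor_types
        Which labels are tumor compartments.
    n_markers_per_type
        Number of marker genes retained per type, ranked by the fold change
        of the type's mean linear expression over the maximum of the other
        types' means.
    keep_all_genes
        If True the signature stores genome-wide per-type means (needed for
        genome-wide purification) and records the marker union separately
        for fraction estimation; if False (the default) the signature is
        restricted to the marker union.
    """
    labels = pd.Series(labels).loc[profiles.columns]
    types = list(dict.fromkeys(labels))
    if len(types) < 2:
        raise ValueError("at least two cell types required")
    counts = labels.value_counts()
    thin = counts[counts < _MIN_PROFILES_PER_TYPE]
    if len(thin):
        raise ValueError(
            f"cell types with fewer than {_MIN_PROFILES_PER_TYPE} profiles: "
            f"{sorted(thin.index)}"
        )
    unknown = set(tumor_types) - set(types)
    if unknown:
        raise ValueError(f"tumor types absent from labels: {unknown}")
    if n_markers_per_type < 1:
        raise ValueError("n_markers_per_type must be >= 1")

    linear = log2_to_linear(profiles)
    means = linear.T.groupby(labels).mean().T  # genes x types
    means = means[types]

    eps = 1e-9
    markers: list[str] = []
    for t in types:
        others = means.drop(columns=t)
        fold = (means[t] + eps) / (others.max(axis=1) + eps)
        top = fold.sort_values(ascending=False, kind="stable").head(n_markers_per_type)
        markers.extend(top.index)
    marker_union = tuple(dict.fromkeys(markers))

    values = means if keep_all_genes else means.loc[list(marker_union)]
    return SignatureMatrix(
        values=values.clip(lower=0.0),
        tumor_types=tuple(tumor_types),
        marker_genes=marker_union,
    )


def estimate_fractions(
    bulk: ExpressionMatrix, signature: SignatureMatrix
) -> pd.DataFrame:
    """Per-sample cell-type fractions by non-negative least squares.

    The bulk sample (linear scale) is regressed onto the signature columns
    over the shared estimation genes; non-negative coefficients are
    normalized to sum to one.  Returns samples x cell types.  A sample that
    is numerically orthogonal to every signature column (all-zero fit)
    raises, since its composition is unidentifiable.
    """
    est_genes = signature.estimation_genes()
    shared = est_genes.intersection(bulk.gene_ids)
    if shared.empty:
        raise ValueError("no shared genes between bulk matrix and signature")
    logger.info(
        "fraction estimation on %d shared genes (%d signature, %d bulk)",
        len(shared), len(est_genes), bulk.n_genes,
    )
    S = signature.values.loc[shared].to_numpy()
    B = log2_to_linear(bulk.values.loc[shared]).to_numpy()

    out = np.zeros((bulk.n_samples, S.shape[1]))
    for j, sample in enumerate(bulk.sample_ids):
        b = B[:, j]
        if not b.any():
            raise ValueError(f"all-zero bulk sample {sample!r}")
        coef, _ = scipy.optimize.nnls(S, b)
        total = coef.sum()
        if total <= 0:
            raise ValueError(
                f"sample {sample!r} is orthogonal to the signature (all-zero fit)"
            )
        out[j] = coef / total
    return pd.DataFrame(out, index=bulk.sample_ids, columns=signature.cell_types)


def impute_tumor_expression(
    bulk: ExpressionMatrix,
    signature: SignatureMatrix,
    fractions: pd.DataFrame,
    min_tumor_fraction: float = 0.2,
) -> tuple[ExpressionMatrix, pd.Index]:
    """Purify tumor-only expression by subtracting the non-tumor signal.

    Per sample, on the linear scale over the genes shared with the
    signature:

        tumor = max(0, bulk - sum_{k not tumor} f_k * sig_k) / f_tumor

    then log2(x + 1).  Samples with estimated tumor fraction below
    ``min_tumor_fraction`` are excluded (returned as the second element)
    rather than divided by a small denominator.
    """
    missing = set(bulk.sample_ids) - set(fractions.index)
    if missing:
        raise ValueError(f"fractions missing for samples: {sorted(missing)[:5]}")
    shared = signature.values.index.intersection(bulk.gene_ids)
    if shared.empty:
        raise ValueError("no shared genes between bulk matrix and signature")

    fractions = fractions.loc[bulk.sample_ids, signature.cell_types]
    tumor_cols = list(signature.tumor_types)
    nontumor_cols = list(signature.nontumor_types)
    f_tumor = fractions[tumor_cols].sum(axis=1)

    keep = f_tumor >= min_tumor_fraction
    excluded = bulk.sample_ids[~keep.to_numpy()]
    if len(excluded):
        logger.warning(
            "excluding %d samples with tumor fraction < %.2f: %s",
            len(excluded), min_tumor_fraction, list(excluded[:5]),
        )
    kept_samples = bulk.sample_ids[keep.to_numpy()]
    if not len(kept_samples):
        raise ValueError("no samples pass the minimum tumor fraction filter")

    B = log2_to_linear(bulk.values.loc[shared, kept_samples]).to_numpy()
    S_nt = signature.values.loc[shared, nontumor_cols].to_numpy() if nontumor_cols else None
    F_nt = fractions.loc[kept_samples, nontumor_cols].to_numpy() if nontumor_cols else None

    if S_nt is not None:
        contamination = S_nt @ F_nt.T
        tumor_linear = B - contamination
    else:
        tumor_linear = B
    tumor_linear = np.clip(tumor_linear, 0.0, None)
    tumor_linear = tumor_linear / f_tumor.loc[kept_samples].to_numpy()[None, :]

    purified = ExpressionMatrix(
        pd.DataFrame(
            linear_to_log2(tumor_linear), index=shared, columns=kept_samples
        ),
        bulk.sample_role.loc[kept_samples],
        bulk.batch.loc[kept_samples],
    )
    return purified, excluded
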