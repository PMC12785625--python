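"""Core in-memory containers shared across the pipeline.

Expression data travel as genes x samples tables on the log2 scale, with a
role (``patient`` or ``cell-line``) and a batch label attached to every
sample.  Signature matrices hold per-cell-type reference profiles on the
linear (abundance) scale, because mixtures of cell populations are linear in
abundance, not in log expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_PATIENT = "patient"
ROLE_CELL_LINE = "cell-line"

__all__ = [
    "ROLE_PATIENT",
    "ROLE_CELL_LINE",
    "ExpressionMatrix",
    "SignatureMatrix",
    "log2_to_linear",
    "linear_to_log2",
]


def log2_to_linear(values: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Invert the log2(x + 1) transform used throughout the package."""
    return np.power(2.0, values) - 1.0


def linear_to_log2(values: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """log2(x + 1) transform of linear-scale abundances."""
    return np.log2(np.asarray(values, dtype=float) + 1.0) if isinstance(values, np.ndarray) else np.log2(values + 1.0)


@dataclass
class ExpressionMatrix:
    """A genes x samples expression table on the log2(x + 1) scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    sample_role
        Per-sample role, either ``"patient"`` or ``"cell-line"``, indexed by
        sample id.
    batch
        Per-sample batch label, indexed by sample id.
    """

    values: pd.DataFrame
    sample_role: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        self.sample_role = pd.Series(self.sample_role, dtype=object)
        self.batch = pd.Series(self.batch, dtype=object)
        for name, series in (("sample_role", self.sample_role), ("batch", self.batch)):
            missing = set(self.values.columns) - set(series.index)
            if missing:
                raise ValueError(f"{name} undefined for samples: {sorted(missing)[:5]}")
        self.sample_role = self.sample_role.loc[self.values.columns]
        self.batch = self.batch.loc[self.values.columns]
        bad = set(self.sample_role.unique()) - {ROLE_PATIENT, ROLE_CELL_LINE}
        if bad:
            raise ValueError(f"unknown sample roles: {bad}")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def linear(self) -> pd.DataFrame:
        """Values back-transformed to the linear abundance scale."""
        return log2_to_linear(self.values)

    # -- subsetting and combination --------------------------------------
    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = pd.Index(genes)
        missing = genes.difference(self.values.index)
        if len(missing):
            raise KeyError(f"genes not in matrix: {list(missing[:5])}")
        return ExpressionMatrix(self.values.loc[genes], self.sample_role, self.batch)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return ExpressionMatrix(
            self.values.loc[:, samples],
            self.sample_role.loc[samples],
            self.batch.loc[samples],
        )

    def patient_samples(self) -> pd.Index:
        return self.sample_ids[self.sample_role == ROLE_PATIENT]

    def cell_line_samples(self) -> pd.Index:
        return self.sample_ids[self.sample_role == ROLE_CELL_LINE]

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Column-wise integration on the shared gene set."""
        shared = self.gene_ids.intersection(other.gene_ids)
        if shared.empty:
            raise ValueError("no shared genes between matrices")
        overlap = self.sample_ids.intersection(other.sample_ids)
        if len(overlap):
            raise ValueError(f"duplicate sample ids on concat: {list(overlap[:5])}")
        values = pd.concat(
            [self.values.loc[shared], other.values.loc[shared]], axis=1
        )
        role = pd.concat([self.sample_role, other.sample_role])
        batch = pd.concat([self.batch, other.batch])
        return ExpressionMatrix(values, role, batch)


@dataclass
class SignatureMatrix:
    """Per-cell-type reference profiles on the linear abundance scale.

    ``values`` is genes x cell types with non-negative entries.  One or more
    columns are tumor subtypes (``tumor_types``); the remaining columns are
    non-tumor compartments (stroma, immune, ...).  ``marker_genes``, when
    set, restricts the genes used for fraction estimation; the full gene set
    is still available for expression purification.
    """

    values: pd.DataFrame
    tumor_types: tuple[str, ...]
    marker_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signature matrix must be non-negative")
        unknown = set(self.tumor_types) - set(self.values.columns)
        if unknown:
            raise ValueError(f"tumor types not in signature columns: {unknown}")
        if not self.tumor_types:
            raise ValueError("at least one column must be marked as tumor")
        if self.marker_genes is not None:
            missing = set(self.marker_genes) - set(self.values.index)
            if missing:
                raise ValueError(f"marker genes absent from signature: {sorted(missing)[:5]}")

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def nontumor_types(self) -> tuple[str, ...]:
        return tuple(c for c in self.values.columns if c not in self.tumor_types)

    def estimation_genes(self) -> pd.Index:
        """Genes used when fitting per-sample fractions."""
        if self.marker_genes is None:
            return self.values.index
        return pd.Index(self.marker_genes)
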