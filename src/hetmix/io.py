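"""Reading and writing the pipeline's file formats.

Expression matrices travel as TSV (genes x samples) with a sidecar TSV of
per-sample role and batch; marker sets as GMT; fraction tables, monotherapy
tables and well observations as tidy CSV; dendrograms as Newick; run
configuration as YAML and run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .datatypes import ExpressionMatrix

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gmt",
    "read_gmt",
    "write_csv",
    "read_csv",
    "write_yaml",
    "read_yaml",
    "write_json",
    "read_json",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".samples.tsv")


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> Path:
    """Write genes x samples TSV plus a ``<path>.samples.tsv`` sidecar."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    meta = pd.DataFrame(
        {"sample_id": matrix.sample_ids, "role": matrix.sample_role.to_numpy(), "batch": matrix.batch.to_numpy()}
    )
    meta.to_csv(_sidecar(path), sep="\t", index=False)
    return path


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(_sidecar(path), sep="\t").set_index("sample_id")
    return ExpressionMatrix(values, meta["role"], meta["batch"])


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> Path:
    """Write gene sets in GMT format (name, description, genes...)."""
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, name, *genes]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_csv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    frame.to_csv(path, index=index)
    return path


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, **kwargs)


def write_yaml(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
    return path


def read_yaml(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=False) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
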