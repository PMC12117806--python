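"""Plain-text readers/writers for the pipeline's tabular artifacts.

Matrices (tag counts, genotypes, relationship matrices) are tab-delimited
with an id header row and ids in the first column; genotypes use empty
cells for missing calls; structured results (configs, truth, fit reports)
are YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinship import GenotypeMatrix, RelationshipMatrix
from .profiles import TagCountMatrix


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, **kwargs)


def write_tag_counts(tcm: TagCountMatrix, path: str | Path) -> None:
    out = tcm.counts.copy()
    out.insert(0, "total_reads", tcm.total_reads)
    out.to_csv(path, sep="\t")


def read_tag_counts(path: str | Path) -> TagCountMatrix:
    df = read_table(path)
    if "total_reads" in df.columns:
        totals = df.pop("total_reads")
    else:
        totals = None
    return TagCountMatrix(counts=df.astype(int), total_reads=totals)


def write_genotypes(geno: GenotypeMatrix | pd.DataFrame, path: str | Path) -> None:
    calls = geno.calls if isinstance(geno, GenotypeMatrix) else geno
    calls.to_csv(path, sep="\t", na_rep="")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = read_table(path)
    return GenotypeMatrix(calls=df.astype(float))


def write_relationship(rel: RelationshipMatrix, path: str | Path) -> None:
    rel.to_frame().to_csv(path, sep="\t")


def read_relationship(path: str | Path, kind: str) -> RelationshipMatrix:
    df = read_table(path)
    return RelationshipMatrix(ids=df.index, values=df.to_numpy(dtype=float),
                              kind=kind)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(obj), fh, sort_keys=False)


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def _to_plain(obj):
    """Recursively convert numpy/pandas scalars and arrays to YAML-safe
    built-ins."""
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _to_plain(obj.tolist())
    if isinstance(obj, pd.Series):
        return _to_plain(obj.to_dict())
    if isinstance(obj, pd.Index):
        return _to_plain(list(obj))
    return obj
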