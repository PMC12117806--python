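"""Lot-based scaling of chamber gas traits and fixed-effect adjustment.

Animals are measured in chambers in lots of 12, and the time a lot has
been off feed scales its gas emissions; dividing by the lot mean and
multiplying by the overall population mean puts every lot on the same
scale and stabilises the heterogeneous variance. The adjusted phenotype
y* is the residual of the scaled trait after removing fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# Overall population means used for lot scaling of the gas traits.
OVERALL_MEANS = {"CH4": 7.5, "CO2": 623.0, "CH4Ratio": 0.032}


@dataclass
class FixedEffectsDesign:
    X: np.ndarray
    names: list[str]
    index: pd.Index

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.X))


def scale_by_lot(values: pd.Series, lot_ids: pd.Series,
                 overall_mean: float) -> pd.Series:
    """scaled_i = overall_mean * y_i / mean(lot of i).

    NaN values are excluded from the lot means (only reliable records
    contribute) and stay NaN in the output. After scaling, the mean of
    every lot equals ``overall_mean`` exactly.
    """
    values = pd.Series(values)
    lot_ids = pd.Series(lot_ids).reindex(values.index)
    if lot_ids.isna().any():
        raise ValueError("every record needs a lot id")
    lot_means = values.groupby(lot_ids).transform("mean")
    if (lot_means.dropna() <= 0).any():
        bad = lot_ids[lot_means <= 0].unique()
        raise ValueError(f"non-positive lot means for lots: {list(bad)[:5]}")
    sizes = values.notna().groupby(lot_ids).transform("sum")
    if (sizes == 1).any():
        warnings.warn(
            "singleton lots present; their scaled values equal the overall "
            "mean",
            stacklevel=2,
        )
    return overall_mean * values / lot_means


def build_design(meta: pd.DataFrame, effect_spec: list[str]) -> FixedEffectsDesign:
    """Fixed-effects incidence matrix from an ordered effect list.

    Entry syntax: ``"C(name)"`` for a class effect (one-hot, first level
    dropped), ``"a*b*c"`` for a contemporary-group class built from the
    concatenation of the named factor columns, a bare column name for a
    covariate if numeric and a class otherwise. An intercept is always
    included; single-level classes are dropped with a warning.
    """
    n = len(meta)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for spec in effect_spec:
        if spec.startswith("C(") and spec.endswith(")"):
            name = spec[2:-1].strip()
            if name not in meta.columns:
                raise KeyError(f"column {name!r} not in metadata")
            _append_class(meta[name].astype(str), name, cols, names)
        elif "*" in spec:
            parts = [s.strip() for s in spec.split("*")]
            for part in parts:
                if part not in meta.columns:
                    raise KeyError(f"column {part!r} not in metadata")
            factor = meta[parts[0]].astype(str)
            for part in parts[1:]:
                factor = factor + "_" + meta[part].astype(str)
            _append_class(factor, spec, cols, names)
        else:
            if spec not in meta.columns:
                raise KeyError(f"column {spec!r} not in metadata")
            col = meta[spec]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(spec)
            else:
                _append_class(col.astype(str), spec, cols, names)
    X = np.column_stack(cols)
    return FixedEffectsDesign(X=X, names=names, index=meta.index)


def _append_class(factor: pd.Series, name: str, cols: list, names: list) -> None:
    levels = sorted(factor.unique())
    if len(levels) < 2:
        warnings.warn(f"class effect {name!r} has a single level; dropped",
                      stacklevel=3)
        return
    for level in levels[1:]:  # first level is the reference
        cols.append((factor == level).to_numpy(dtype=float))
        names.append(f"{name}[{level}]")


def adjust_phenotype(y: pd.Series, design: FixedEffectsDesign) -> pd.Series:
    """y* = y - X (X'X)^- X' y via a rank-revealing least-squares solve.

    The result is orthogonal to every column of X; adjusting y* again with
    the same X returns y* (idempotence).
    """
    y = pd.Series(y)
    X = design.X
    if X.shape[0] != len(y):
        raise ValueError("design and trait rows are not aligned")
    rank = np.linalg.matrix_rank(X)
    if rank == 0:
        raise ValueError("design matrix has rank 0")
    if len(y) <= rank:
        raise ValueError("more independent fixed effects than records")
    beta, *_ = np.linalg.lstsq(X, y.to_numpy(dtype=float), rcond=None)
    resid = y.to_numpy(dtype=float) - X @ beta
    return pd.Series(resid, index=y.index, name=f"{y.name or 'y'}_star")
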