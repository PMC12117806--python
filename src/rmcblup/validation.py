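"""Validation schemes for metagenome- and genome-based trait prediction.

Two schemes mirror how a breeding programme would deploy the proxy:
forward prediction (train on earlier birth years, validate on the latest
year) and cohort-blocked cross-validation (folds are unions of whole
sequencing cohorts, so no fold shares a cohort with its training data and
environmental leakage through the metagenome profile is blocked).

``relative_efficacy`` quantifies the expected selection response from
indirect selection on the proxy relative to direct selection:
rho_g * sqrt(h2_proxy) / sqrt(h2_direct).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd


@dataclass
class SplitPlan:
    scheme: Literal["FP", "CV"]
    assignments: pd.Series  # FP: 'train'/'validate'; CV: fold index
    fold_cohorts: dict | None = None

    def training_ids(self, fold=None) -> pd.Index:
        if self.scheme == "FP":
            return self.assignments.index[self.assignments == "train"]
        return self.assignments.index[self.assignments != fold]

    def validation_ids(self, fold=None) -> pd.Index:
        if self.scheme == "FP":
            return self.assignments.index[self.assignments == "validate"]
        return self.assignments.index[self.assignments == fold]

    @property
    def folds(self) -> list:
        if self.scheme != "CV":
            raise ValueError("folds only defined for CV plans")
        return sorted(self.assignments.unique())


@dataclass
class PredictionResult:
    per_group: pd.DataFrame  # group, n, accuracy, slope
    accuracy: float
    accuracy_se: float
    slope: float
    slope_se: float


def forward_split(meta: pd.DataFrame, validation_year: int) -> SplitPlan:
    """Latest birth year validates; all earlier years train.

    Years after ``validation_year`` would leak future data and are an
    error, as are empty training or validation sides."""
    years = meta["birth_year"]
    if (years > validation_year).any():
        raise ValueError("animals born after the validation year are present")
    val = years == validation_year
    if not val.any():
        raise ValueError(f"no animals born in {validation_year}")
    if val.all():
        raise ValueError("training set is empty (all animals in validation year)")
    assignments = pd.Series(np.where(val, "validate", "train"),
                            index=meta.index, name="split")
    return SplitPlan(scheme="FP", assignments=assignments)


def cv_folds(meta: pd.DataFrame, n_folds: int = 11, seed: int = 0,
             cohort_col: str = "cohort", flock_col: str = "flock") -> SplitPlan:
    """Greedy size-balanced packing of whole cohorts into folds.

    Cohorts of the same flock are co-located where the size balance
    permits, emulating folds that group "similar animals"; cohorts are
    never split across folds. Deterministic given the seed.
    """
    cohorts = meta[cohort_col]
    sizes = cohorts.value_counts()
    if n_folds > len(sizes):
        raise ValueError("more folds than cohorts")
    cohort_flock = meta.groupby(cohort_col)[flock_col].first()
    target = len(meta) / n_folds

    rng = np.random.default_rng(seed)

    fold_sizes = np.zeros(n_folds)
    fold_flocks: list[set] = [set() for _ in range(n_folds)]
    fold_cohorts: dict[int, list] = {f: [] for f in range(n_folds)}
    assign: dict = {}
    big = sizes.max()
    if big > 2 * target:
        warnings.warn("a cohort exceeds twice the target fold size; it is "
                      "still assigned whole", stacklevel=2)
    # Longest-first packing keeps fold sizes balanced; ties between equal
    # cohort sizes are broken by a seeded shuffle, and a fold already
    # holding the cohort's flock is preferred when that costs little.
    order = list(sizes.index)
    rng.shuffle(order)
    order.sort(key=lambda c: -sizes[c])
    for c in order:
        flock = cohort_flock[c]
        same = [
            f for f in range(n_folds)
            if flock in fold_flocks[f]
            and fold_sizes[f] + sizes[c] <= 1.1 * target
        ]
        pool = same if same else range(n_folds)
        f = min(pool, key=lambda f: (fold_sizes[f], f))
        assign[c] = f
        fold_sizes[f] += sizes[c]
        fold_flocks[f].add(flock)
        fold_cohorts[f].append(c)
    assignments = cohorts.map(assign).rename("fold")
    return SplitPlan(scheme="CV", assignments=assignments,
                     fold_cohorts=fold_cohorts)


def evaluate_predictions(pred: pd.Series, y_star: pd.Series,
                         groups: pd.Series, min_group: int = 3,
                         ) -> PredictionResult:
    """Per-group accuracy (Pearson r of prediction with y*) and slope of
    y* regressed on the prediction, summarised by group-size-weighted
    mean and SE.

    Groups below ``min_group`` animals or with zero-variance predictions
    are skipped with a warning. The weighted SE is the weighted sd of the
    group statistics over sqrt(effective number of groups)."""
    pred = pd.Series(pred)
    y_star = pd.Series(y_star).reindex(pred.index)
    groups = pd.Series(groups).reindex(pred.index)
    rows = []
    for g, idx in groups.groupby(groups):
        sub = idx.index
        if len(sub) < min_group:
            warnings.warn(f"group {g!r} has fewer than {min_group} animals; "
                          "skipped", stacklevel=2)
            continue
        x = pred.loc[sub].to_numpy(dtype=float)
        y = y_star.loc[sub].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            warnings.warn(f"group {g!r} has zero-variance predictions or "
                          "phenotypes; skipped", stacklevel=2)
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        xc = x - x.mean()
        slope = float((xc @ (y - y.mean())) / (xc @ xc))
        rows.append({"group": g, "n": len(sub), "accuracy": r, "slope": slope})
    if not rows:
        raise ValueError("no group was large enough to evaluate")
    table = pd.DataFrame(rows).set_index("group")
    w = table["n"].to_numpy(dtype=float)
    acc, acc_se = _weighted_mean_se(table["accuracy"].to_numpy(), w)
    slope, slope_se = _weighted_mean_se(table["slope"].to_numpy(), w)
    return PredictionResult(per_group=table, accuracy=acc, accuracy_se=acc_se,
                            slope=slope, slope_se=slope_se)


def _weighted_mean_se(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    mean = float(np.average(x, weights=w))
    if len(x) < 2:
        return mean, math.nan
    var = float(np.average((x - mean) ** 2, weights=w))
    n_eff = w.sum() ** 2 / np.sum(w**2)
    return mean, math.sqrt(var / n_eff)


def relative_efficacy(rho_g: float, h2_direct: float, h2_proxy: float) -> float:
    """Expected response of indirect selection on the proxy relative to
    direct selection: rho_g * sqrt(h2_proxy) / sqrt(h2_direct).

    Scale-invariant in the traits (depends only on the heritability
    ratios and the genetic correlation)."""
    if h2_direct <= 0:
        raise ValueError("direct heritability must be positive")
    if h2_proxy < 0:
        raise ValueError("proxy heritability must be non-negative")
    if not -1.0 <= rho_g <= 1.0:
        raise ValueError("genetic correlation must lie in [-1, 1]")
    return rho_g * math.sqrt(h2_proxy) / math.sqrt(h2_direct)
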