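"""Relationship matrices: the metagenome relationship matrix (MRM), the
VanRaden genomic relationship matrix (GRM), and PCA diagnostics.

The MRM plays the role of a kinship matrix for microbial effects: entry
(i, j) is the Pearson correlation of the cohort-normalized log tag
profiles of animals i and j. Cohort normalization (z-scoring every tag
within each sequencing-flowcell x flock x birth-year x sex cohort) strips
environmental and flowcell scale effects that would otherwise dominate the
between-animal similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .profiles import TagCountMatrix

DEFAULT_MAF_MIN = 0.01
DEFAULT_CALL_RATE_MIN = 0.70


@dataclass
class RelationshipMatrix:
    ids: pd.Index
    values: np.ndarray
    kind: Literal["MRM", "GRM"]

    def __post_init__(self):
        self.ids = pd.Index(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        r = self.ids.get_indexer(pd.Index(rows))
        if (r < 0).any():
            raise KeyError("ids missing from relationship matrix")
        if cols is None:
            return self.values[np.ix_(r, r)]
        c = self.ids.get_indexer(pd.Index(cols))
        if (c < 0).any():
            raise KeyError("ids missing from relationship matrix")
        return self.values[np.ix_(r, c)]


@dataclass
class GenotypeMatrix:
    """Animals x SNPs calls in {0, 1, 2, NaN}."""

    calls: pd.DataFrame

    def __post_init__(self):
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")

    @property
    def animal_ids(self) -> pd.Index:
        return self.calls.index

    @property
    def snp_ids(self) -> pd.Index:
        return self.calls.columns

    def allele_freqs(self) -> pd.Series:
        return self.calls.mean(axis=0, skipna=True) / 2.0

    def call_rate(self) -> pd.Series:
        return self.calls.notna().mean(axis=0)


def normalize_profiles(tcm: TagCountMatrix, cohorts: pd.Series,
                       normalization: str = "cohort_log10") -> pd.DataFrame:
    """Steps (1)-(3) of the MRM recipe.

    (1) add a pseudocount of 1 and convert to proportions by the sample's
    row total; (2) log10; (3) z-score every tag within each cohort
    (sample sd, n-1 denominator). ``clr`` replaces (1)-(2) with the
    centred log-ratio of the pseudo-counted matrix.

    Tags with zero variance within a cohort carry no information there and
    are set to 0 for that cohort rather than dropped, keeping the tag set
    aligned across cohorts.
    """
    cohorts = pd.Series(cohorts).reindex(tcm.sample_ids)
    if cohorts.isna().any():
        raise ValueError("every sample needs a cohort label")
    X = tcm.counts.to_numpy(dtype=float) + 1.0
    if normalization == "cohort_log10":
        L = np.log10(X / X.sum(axis=1, keepdims=True))
    elif normalization == "clr":
        logx = np.log(X)
        L = logx - logx.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization: {normalization!r}")

    Z = np.empty_like(L)
    n_zero_var = 0
    for cohort, idx in pd.Series(range(len(cohorts)), index=cohorts.index).groupby(cohorts.to_numpy()):
        rows = idx.to_numpy()
        if len(rows) < 2:
            raise ValueError(
                f"cohort {cohort!r} has a single sample; within-cohort sd "
                "is undefined"
            )
        block = L[rows]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = sd == 0
        n_zero_var += int(zero.sum())
        sd = np.where(zero, 1.0, sd)
        zb = (block - mu) / sd
        zb[:, zero] = 0.0
        Z[rows] = zb
    if n_zero_var:
        warnings.warn(
            f"{n_zero_var} (cohort, tag) cells had zero variance; "
            "normalized values set to 0",
            stacklevel=2,
        )
    return pd.DataFrame(Z, index=tcm.sample_ids, columns=tcm.tag_ids)


def build_mrm(tcm: TagCountMatrix, cohorts: pd.Series,
              normalization: str = "cohort_log10") -> RelationshipMatrix:
    """Metagenome relationship matrix: pairwise Pearson correlation across
    tags of the cohort-normalized profiles; diagonal forced to exactly 1."""
    Z = normalize_profiles(tcm, cohorts, normalization).to_numpy()
    with np.errstate(invalid="raise"):
        M = np.corrcoef(Z)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return RelationshipMatrix(ids=tcm.sample_ids, values=M, kind="MRM")


def filter_snps(geno: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN,
                call_rate_min: float = DEFAULT_CALL_RATE_MIN) -> GenotypeMatrix:
    """Drop SNPs with minor allele frequency <= maf_min (strict 'greater
    than' retention) or call rate below call_rate_min."""
    p = geno.allele_freqs()
    maf = np.minimum(p, 1.0 - p)
    keep = (maf > maf_min) & (geno.call_rate() >= call_rate_min)
    return GenotypeMatrix(calls=geno.calls.loc[:, keep])


def build_grm(geno: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN,
              call_rate_min: float = DEFAULT_CALL_RATE_MIN) -> RelationshipMatrix:
    """VanRaden method-1 GRM with pairwise handling of missing genotypes.

    G(i, j) = sum over SNPs non-missing in BOTH i and j of
    (x_ik - 2 p_k)(x_jk - 2 p_k), divided by sum over the same SNPs of
    2 p_k (1 - p_k); allele frequencies come from all non-missing calls of
    the retained SNPs. Restricting the denominator to the shared SNP set
    keeps each entry properly scaled under missingness at random.
    """
    geno = filter_snps(geno, maf_min, call_rate_min)
    if geno.calls.shape[1] == 0:
        raise ValueError("no SNPs remain after MAF/call-rate filtering")
    X = geno.calls.to_numpy(dtype=float)
    p = np.nanmean(X, axis=0) / 2.0
    W = X - 2.0 * p
    obs = ~np.isnan(W)
    weights = 2.0 * p * (1.0 - p)
    if obs.all():
        # Complete data: the denominator is the same scalar for every pair.
        G = (W @ W.T) / weights.sum()
    else:
        W = np.where(obs, W, 0.0)
        num = W @ W.T
        obs_f = obs.astype(float)
        den = (obs_f * weights) @ obs_f.T
        if np.any(den <= 0):
            raise ValueError(
                "some animal pairs share no informative SNPs; cannot scale "
                "their relationship"
            )
        G = num / den
    G = (G + G.T) / 2.0
    return RelationshipMatrix(ids=geno.animal_ids, values=G, kind="GRM")


def pca(rel: RelationshipMatrix, n_components: int):
    """Eigendecomposition-based principal components of a relationship
    matrix.

    Scores are eigenvectors scaled by sqrt(eigenvalue); variance explained
    is relative to the sum of positive eigenvalues. Signs are fixed so the
    largest-magnitude loading of each component is positive.
    Returns (scores DataFrame, variance_explained ndarray).
    """
    n = len(rel.ids)
    if n_components > n:
        raise ValueError("n_components cannot exceed matrix dimension")
    eigval, eigvec = np.linalg.eigh(rel.values)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    total = pos.sum()
    scores = eigvec[:, :n_components] * np.sqrt(pos[:n_components])
    for j in range(n_components):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] = -scores[:, j]
    var_explained = pos[:n_components] / total if total > 0 else pos[:n_components]
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return pd.DataFrame(scores, index=rel.ids, columns=cols), var_explained
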