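"""Relationship matrices against brute-force oracles.

The MRM oracle recomputes the four-step recipe (pseudocount ->
proportions -> log10 -> within-cohort z-score -> pairwise Pearson
correlation) with plain Python loops; the GRM oracle is a dense
textbook VanRaden method-1 computation.
"""

import math

import numpy as np
import pandas as pd
import pytest

from rmcblup import (GenotypeMatrix, RelationshipMatrix, TagCountMatrix,
                     build_grm, build_mrm, pca)
from rmcblup.kinship import filter_snps, normalize_profiles

from conftest import toy_kernel


def mrm_oracle(counts, cohorts):
    """Step-by-step direct arithmetic, no vectorization shared with the
    implementation."""
    n, t = len(counts), len(counts[0])
    adj = [[counts[i][j] + 1 for j in range(t)] for i in range(n)]
    logp = []
    for i in range(n):
        tot = sum(adj[i])
        logp.append([math.log10(adj[i][j] / tot) for j in range(t)])
    z = [[0.0] * t for _ in range(n)]
    for cohort in set(cohorts):
        rows = [i for i in range(n) if cohorts[i] == cohort]
        for j in range(t):
            vals = [logp[i][j] for i in rows]
            mu = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / (len(vals) - 1))
            for i in rows:
                z[i][j] = (logp[i][j] - mu) / sd if sd > 0 else 0.0
    M = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for k in range(n):
            xi, xk = z[i], z[k]
            mi, mk = sum(xi) / t, sum(xk) / t
            num = sum((xi[j] - mi) * (xk[j] - mk) for j in range(t))
            di = math.sqrt(sum((xi[j] - mi) ** 2 for j in range(t)))
            dk = math.sqrt(sum((xk[j] - mk) ** 2 for j in range(t)))
            M[i][k] = 1.0 if i == k else num / (di * dk)
    return np.array(M)


def grm_oracle(X):
    """Dense VanRaden method 1 on complete genotypes."""
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    return W @ W.T / (2.0 * p * (1.0 - p)).sum()


def grm_pairwise_oracle(X):
    """Loop-based pairwise-complete VanRaden entries."""
    n, m = X.shape
    p = np.nanmean(X, axis=0) / 2.0
    G = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            num = den = 0.0
            for k in range(m):
                if np.isnan(X[i, k]) or np.isnan(X[j, k]):
                    continue
                num += (X[i, k] - 2 * p[k]) * (X[j, k] - 2 * p[k])
                den += 2 * p[k] * (1 - p[k])
            G[i, j] = num / den
    return G


def _tcm(counts, sample_ids=None):
    n, t = np.asarray(counts).shape
    idx = sample_ids or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(counts, index=idx, columns=[f"tag{j}" for j in range(t)])
    return TagCountMatrix(counts=df)


class TestMRM:
    COUNTS = [[10, 0, 5], [2, 8, 1], [7, 7, 7], [0, 3, 12]]

    def test_matches_brute_force_oracle_single_cohort(self):
        tcm = _tcm(self.COUNTS)
        cohorts = pd.Series(["c1"] * 4, index=tcm.sample_ids)
        M = build_mrm(tcm, cohorts)
        np.testing.assert_allclose(M.values,
                                   mrm_oracle(self.COUNTS, ["c1"] * 4),
                                   atol=1e-12)

    def test_matches_brute_force_oracle_two_cohorts(self, rng):
        counts = rng.poisson(4.0, size=(6, 8))
        cohorts = ["a", "a", "a", "b", "b", "b"]
        tcm = _tcm(counts)
        M = build_mrm(tcm, pd.Series(cohorts, index=tcm.sample_ids))
        np.testing.assert_allclose(M.values,
                                   mrm_oracle(counts.tolist(), cohorts),
                                   atol=1e-12)

    def test_diagonal_is_exactly_one_and_symmetric(self, small_metagenome,
                                                   small_population):
        _, pheno, _ = small_population
        M = build_mrm(small_metagenome, pheno["cohort"])
        assert (np.diag(M.values) == 1.0).all()
        np.testing.assert_allclose(M.values, M.values.T, atol=1e-12)
        assert np.abs(M.values).max() <= 1.0 + 1e-12

    def test_within_cohort_zscores_have_mean_zero_sd_one(
            self, small_metagenome, small_population):
        _, pheno, _ = small_population
        Z = normalize_profiles(small_metagenome, pheno["cohort"])
        for cohort, block in Z.groupby(pheno.loc[Z.index, "cohort"]):
            np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-8)
            sd = block.std(axis=0, ddof=1).to_numpy()
            np.testing.assert_allclose(sd[sd > 0], 1.0, atol=1e-8)

    def test_permuting_samples_permutes_the_matrix(self, rng):
        counts = rng.poisson(3.0, size=(5, 10))
        tcm = _tcm(counts)
        cohorts = pd.Series(["c"] * 5, index=tcm.sample_ids)
        M = build_mrm(tcm, cohorts)
        perm = [3, 1, 4, 0, 2]
        tcm_p = _tcm(counts[perm], sample_ids=[f"s{i}" for i in perm])
        M_p = build_mrm(tcm_p, cohorts.iloc[perm])
        np.testing.assert_allclose(M_p.values, M.values[np.ix_(perm, perm)],
                                   atol=1e-12)

    def test_singleton_cohort_is_an_error(self):
        tcm = _tcm([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="single sample"):
            build_mrm(tcm, pd.Series(["a", "b"], index=tcm.sample_ids))

    def test_zero_variance_tag_is_neutralised_not_dropped(self):
        counts = [[5, 1, 9], [5, 4, 2], [5, 2, 2], [5, 9, 9]]
        tcm = _tcm(counts)
        cohorts = pd.Series(["c"] * 4, index=tcm.sample_ids)
        # tag0 has identical counts but unequal depths: still varies after
        # the proportion step, so force a truly constant column instead
        Z = normalize_profiles(_tcm([[3, 1], [3, 5], [3, 2]]),
                               pd.Series(["c"] * 3,
                                         index=["s0", "s1", "s2"]))
        assert Z.shape[1] == 2  # kept, not dropped
        M = build_mrm(tcm, cohorts)
        assert np.isfinite(M.values).all()

    def test_log10_and_clr_modes_agree_on_dense_data(self, rng):
        """Off-diagonals of the two normalizations correlate strongly when
        counts are dense (the log10-proportion recipe approximates a
        log-ratio transform)."""
        counts = rng.poisson(60.0, size=(20, 150))
        tcm = _tcm(counts)
        cohorts = pd.Series(["a"] * 10 + ["b"] * 10, index=tcm.sample_ids)
        m1 = build_mrm(tcm, cohorts, normalization="cohort_log10")
        m2 = build_mrm(tcm, cohorts, normalization="clr")
        iu = np.triu_indices(20, 1)
        r = np.corrcoef(m1.values[iu], m2.values[iu])[0, 1]
        assert r > 0.95

    def test_exact_depth_scaling_leaves_mrm_nearly_unchanged(self, rng):
        """Multiplying a sample's counts by a positive integer acts only
        through depth; proportions absorb most of it (pseudocount keeps it
        from being exact)."""
        counts = rng.poisson(50.0, size=(6, 80)) + 1
        tcm1 = _tcm(counts)
        scaled = counts.copy()
        scaled[2] *= 7
        tcm2 = _tcm(scaled)
        cohorts = pd.Series(["c"] * 6, index=tcm1.sample_ids)
        M1 = build_mrm(tcm1, cohorts)
        M2 = build_mrm(tcm2, cohorts)
        np.testing.assert_allclose(M1.values, M2.values, atol=0.02)


class TestGRM:
    def test_matches_dense_vanraden_oracle_on_complete_data(self, rng):
        X = rng.integers(0, 3, size=(20, 200)).astype(float)
        calls = pd.DataFrame(X, index=[f"a{i}" for i in range(20)],
                             columns=[f"snp{k}" for k in range(200)])
        G = build_grm(GenotypeMatrix(calls=calls), maf_min=0.0,
                      call_rate_min=0.0)
        keep = filter_snps(GenotypeMatrix(calls=calls), 0.0, 0.0).calls
        np.testing.assert_allclose(G.values,
                                   grm_oracle(keep.to_numpy()), atol=1e-10)

    def test_duplicated_animal_shares_self_relationship(self, rng):
        X = rng.integers(0, 3, size=(5, 100)).astype(float)
        X[4] = X[0]
        calls = pd.DataFrame(X, index=[f"a{i}" for i in range(5)],
                             columns=[f"s{k}" for k in range(100)])
        G = build_grm(GenotypeMatrix(calls=calls), maf_min=0.0,
                      call_rate_min=0.0)
        assert G.values[0, 4] == pytest.approx(G.values[0, 0], rel=1e-12)
        assert G.values[0, 4] == pytest.approx(G.values[4, 4], rel=1e-12)

    def test_pairwise_missing_worked_example(self):
        X = np.array([
            [0.0, 1.0, 2.0, 1.0],
            [1.0, np.nan, 2.0, 0.0],
            [2.0, 1.0, 1.0, 1.0],
        ])
        calls = pd.DataFrame(X, index=["a", "b", "c"],
                             columns=["s1", "s2", "s3", "s4"])
        G = build_grm(GenotypeMatrix(calls=calls), maf_min=0.0,
                      call_rate_min=0.0)
        np.testing.assert_allclose(G.values, grm_pairwise_oracle(X),
                                   atol=1e-12)

    def test_maf_and_call_rate_filters(self):
        calls = pd.DataFrame(
            {
                "rare": [0.0, 0.0, 0.0, 0.0, 1.0] + [0.0] * 45,  # maf 0.01
                "common": [1.0] * 25 + [0.0] * 25,
                "patchy": [1.0] * 30 + [np.nan] * 20,  # call rate 0.6
            },
            index=[f"a{i}" for i in range(50)],
        )
        kept = filter_snps(GenotypeMatrix(calls=calls))
        assert list(kept.calls.columns) == ["common"]

    def test_disjoint_snp_sets_error(self):
        calls = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]], index=["a", "b"],
            columns=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="share no"):
            build_grm(GenotypeMatrix(calls=calls), maf_min=0.0,
                      call_rate_min=0.0)


class TestPCA:
    def test_rank_one_matrix_explained_by_first_component(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        rel = RelationshipMatrix(ids=list("abcd"), values=np.outer(v, v),
                                 kind="GRM")
        scores, varexp = pca(rel, 2)
        assert varexp[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(scores["PC1"].to_numpy()),
                                   np.abs(v), atol=1e-10)

    def test_component_scores_are_orthogonal(self, rng):
        K = toy_kernel(15, rng)
        rel = RelationshipMatrix(ids=[f"a{i}" for i in range(15)], values=K,
                                 kind="GRM")
        scores, _ = pca(rel, 4)
        S = scores.to_numpy()
        off = S.T @ S - np.diag(np.diag(S.T @ S))
        assert np.abs(off).max() < 1e-8

    def test_too_many_components_rejected(self, rng):
        K = toy_kernel(4, rng)
        rel = RelationshipMatrix(ids=list("abcd"), values=K, kind="GRM")
        with pytest.raises(ValueError):
            pca(rel, 5)

    def test_single_population_mrm_shows_no_clusters(self, small_metagenome,
                                                     small_population):
        """A homogeneous synthetic population should not separate into
        groups in MRM PC space beyond noise (silhouette near 0 against
        random labels)."""
        _, pheno, _ = small_population
        M = build_mrm(small_metagenome, pheno["cohort"])
        scores, _ = pca(M, 2)
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=len(scores))
        X = scores.to_numpy()
        sil = _silhouette(X, labels)
        assert abs(sil) < 0.1


def _silhouette(X, labels):
    from scipy.spatial.distance import cdist
    D = cdist(X, X)
    vals = []
    for i in range(len(X)):
        same = labels == labels[i]
        same[i] = False
        if not same.any():
            continue
        a = D[i, same].mean()
        b = D[i, ~same & (np.arange(len(X)) != i)].mean()
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))
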