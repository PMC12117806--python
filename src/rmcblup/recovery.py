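"""Parameter-recovery simulation studies.

Each protocol simulates data under the model that the corresponding
estimator assumes — genomic (GRM) for heritability, metagenomic (MRM,
built from a freshly simulated cohort-structured tag matrix) for
microbiability, and the Kronecker bivariate structure for the genetic
correlation of a chamber trait with its metagenome proxy — then fits the
estimator and returns the per-replicate estimates. Replicate seeds are
derived from one root seed, so every study is reproducible from a single
integer.
"""

from __future__ import annotations

import math

import numpy as np

from .kinship import GenotypeMatrix, build_grm, build_mrm
from .mixed_models import reml_bivariate, reml_univariate
from .simulate import (SimulationConfig, draw_bivariate_effects,
                       draw_from_kernel, genetic_values, simulate_genotypes,
                       simulate_metagenome, simulate_population)


def replicate_seeds(root_seed: int, n_reps: int) -> np.ndarray:
    """Independent per-replicate seeds (kept below 2**31) from a root seed."""
    return np.random.SeedSequence(root_seed).generate_state(n_reps) % (2**31)


def heritability_recovery(h2_true: float = 0.16, n_reps: int = 30,
                          n_animals: int = 2000, n_snps: int = 5000,
                          overall_mean: float = 7.5,
                          seed: int = 0) -> list[float]:
    """REML heritability estimates over replicates of the genomic model.

    Per replicate: simulate complete genotypes (allele frequencies in
    [0.05, 0.5]), build the VanRaden GRM, construct breeding values from
    marker effects scaled to ``h2_true`` of a unit phenotypic variance,
    add independent residuals, and fit the univariate GRM model with an
    intercept."""
    estimates = []
    for rep_seed in replicate_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        cfg = SimulationConfig(n_animals=n_animals, n_snps=n_snps,
                               missing_rate=0.0, seed=int(rep_seed))
        calls, complete, p = simulate_genotypes(cfg, rng)
        grm = build_grm(GenotypeMatrix(calls=calls))
        g = genetic_values(complete, p, h2_true, rng)
        y = overall_mean + g + rng.normal(0.0, math.sqrt(1.0 - h2_true),
                                          n_animals)
        estimates.append(reml_univariate(y, None, grm).ratio)
    return estimates


def microbiability_recovery(m2_true: float, n_reps: int = 30,
                            n_animals: int = 1000, n_tags: int = 3000,
                            seed: int = 0) -> list[float]:
    """REML microbiability estimates over replicates of the microbial model.

    Per replicate: simulate a cohort-structured population and its sparse
    tag-count matrix, build the MRM via the four-step recipe, draw
    microbial values from N(0, m2_true * M) (unit phenotypic variance),
    add residuals, and fit the univariate MRM model."""
    estimates = []
    for rep_seed in replicate_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        cfg = SimulationConfig(n_animals=n_animals, n_snps=10,
                               n_tags=n_tags, seed=int(rep_seed))
        _, pheno, truth = simulate_population(cfg)
        tcm = simulate_metagenome(truth, cfg)
        mrm = build_mrm(tcm, pheno["cohort"])
        m = draw_from_kernel(mrm.values, m2_true, rng)
        y = m + rng.normal(0.0, math.sqrt(1.0 - m2_true), n_animals)
        estimates.append(reml_univariate(y, None, mrm).ratio)
    return estimates


def implied_bivariate_components(h2_direct: float, h2_proxy: float,
                                 rho_g: float, rho_p: float,
                                 pv_direct: float, pv_proxy: float):
    """(B, C) implied by heritabilities, phenotypic variances and the
    genetic/phenotypic correlations of a trait pair."""
    vu1, vu2 = h2_direct * pv_direct, h2_proxy * pv_proxy
    su12 = rho_g * math.sqrt(vu1 * vu2)
    se12 = rho_p * math.sqrt(pv_direct * pv_proxy) - su12
    B = np.array([[vu1, su12], [su12, vu2]])
    C = np.array([[pv_direct - vu1, se12], [se12, pv_proxy - vu2]])
    return B, C


def genetic_correlation_recovery(h2_direct: float = 0.21,
                                 h2_proxy: float = 0.37,
                                 rho_g: float = 0.75, rho_p: float = 0.40,
                                 pv_direct: float = 2.27,
                                 pv_proxy: float = 0.66,
                                 n_reps: int = 30, n_animals: int = 1000,
                                 n_snps: int = 800,
                                 seed: int = 0) -> list[float]:
    """Bivariate-REML genetic-correlation estimates over replicates.

    Per replicate: simulate genotypes and the GRM, draw paired breeding
    values from G (x) B and residuals from I (x) C with (B, C) implied by
    the supplied parameters, and fit the bivariate model. The default
    marker count (800 for n=1000) is chosen so the GRM carries about as
    much REML information as a family-structured field dataset of the
    same size, gauged by the delta-method standard error of the estimate;
    a panel of unrelated animals at high marker density would be
    unrealistically uninformative."""
    B, C = implied_bivariate_components(h2_direct, h2_proxy, rho_g, rho_p,
                                        pv_direct, pv_proxy)
    Lc = np.linalg.cholesky(C)
    estimates = []
    for rep_seed in replicate_seeds(seed, n_reps):
        rng = np.random.default_rng(rep_seed)
        cfg = SimulationConfig(n_animals=n_animals, n_snps=n_snps,
                               missing_rate=0.0, seed=int(rep_seed))
        calls, _, _ = simulate_genotypes(cfg, rng)
        grm = build_grm(GenotypeMatrix(calls=calls))
        U = draw_bivariate_effects(grm.values, B, rng)
        E = rng.standard_normal((n_animals, 2)) @ Lc.T
        fit = reml_bivariate(U[:, 0] + E[:, 0], U[:, 1] + E[:, 1],
                             grm.values)
        estimates.append(fit.rho_g)
    return estimates
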