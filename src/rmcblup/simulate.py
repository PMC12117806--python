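"""Synthetic sheep populations with known genetic, microbial and cohort structure.

The generator emulates the kind of dataset produced by a national
portable-accumulation-chamber (PAC) methane measurement campaign paired
with restriction-enzyme reduced-representation sequencing of rumen
contents:

* SNP genotypes (0/1/2 with missingness) and additive genetic values
  constructed from marker effects, so that the covariance of the true
  breeding values tracks the realized genomic relationships;
* per-animal latent microbial values correlated with the genetic values,
  driving a sparse, over-dispersed, depth- and batch-confounded tag-count
  matrix (the rumen metagenome community profile);
* a cohort structure (sequencing flowcell x flock x birth year x sex),
  with every cohort sequenced on a single flowcell;
* PAC measurement lots of 12 with multiplicative lot effects (animals in
  a lot share time-off-feed, which scales gas emissions);
* fixed effects (age of dam, birth/rearing rank, birth-date deviation)
  with modest contributions, so the fixed-effect adjustment step has
  something real to remove.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import TagCountMatrix

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Variances are on the scale of the (lot-descaled) trait; the default
    components give a heritability of 0.16 and a microbiability of ~0.54,
    typical of chamber methane in grazing lambs, on a trait with unit
    residual-plus-genetic variance.
    """

    n_animals: int = 1000
    n_snps: int = 3000
    n_tags: int = 2000
    n_flocks: int = 8
    n_years: int = 7
    n_flowcells: int = 6
    lot_size: int = 12
    sigma2_g: float = 0.16
    sigma2_m: float = 1.0
    sigma2_e: float = 0.84
    rho_gm: float = 0.75
    lot_effect_sd: float = 0.10
    depth_log_mean: float = math.log(3e5)
    depth_log_sd: float = 0.4
    missing_rate: float = 0.04
    overall_mean: float = 7.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    tag_signal_sd: float = 0.5
    batch_effect_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("sigma2_g", "sigma2_m", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not -1.0 <= self.rho_gm <= 1.0:
            raise ValueError("rho_gm must lie in [-1, 1]")
        if self.lot_size < 2:
            raise ValueError("lot_size must be at least 2")
        if self.lot_size > self.n_animals:
            raise ValueError("lot_size cannot exceed n_animals")
        for name in ("n_animals", "n_snps", "n_tags", "n_flocks", "n_years",
                     "n_flowcells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.depth_log_sd < 0:
            raise ValueError("depth_log_sd must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth retained for recovery testing."""

    true_g: np.ndarray
    true_m: np.ndarray
    residual: np.ndarray
    lot_factors: pd.Series
    cohort_labels: pd.Series
    flowcell_labels: pd.Series
    true_h2: float
    true_m2: float
    true_rg: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "true_g": self.true_g,
                "true_m": self.true_m,
                "residual": self.residual,
                "cohort": self.cohort_labels,
                "flowcell": self.flowcell_labels,
            },
            index=self.cohort_labels.index,
        )


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator):
    """Draw a SNP matrix: per-SNP allele frequency p_k ~ U(maf_low, maf_high),
    calls ~ Binomial(2, p_k), missing entries NaN at ``missing_rate``.

    Returns (calls DataFrame animals x snps, complete calls ndarray, p).
    """
    p = rng.uniform(config.maf_low, config.maf_high, size=config.n_snps)
    complete = rng.binomial(2, p, size=(config.n_animals, config.n_snps)).astype(float)
    calls = complete.copy()
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan
    animal_ids = [f"an{i:05d}" for i in range(config.n_animals)]
    snp_ids = [f"snp{k:05d}" for k in range(config.n_snps)]
    calls_df = pd.DataFrame(calls, index=animal_ids, columns=snp_ids)
    return calls_df, complete, p


def genetic_values(complete: np.ndarray, p: np.ndarray, sigma2_g: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Additive genetic values from marker effects.

    Effects a_k ~ N(0, sigma2_g / sum(2 p_k (1-p_k))) on centred genotypes
    give cov(g) = sigma2_g * G (VanRaden scaling), so REML with the
    realized GRM is correctly specified.
    """
    if sigma2_g == 0:
        return np.zeros(complete.shape[0])
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    a = rng.normal(0.0, math.sqrt(sigma2_g / denom), size=complete.shape[1])
    return (complete - 2.0 * p) @ a


def _assign_cohorts(config: SimulationConfig, rng: np.random.Generator):
    """Animals -> flock x year x sex cells, each cohort on one flowcell.

    Cell weights are Dirichlet-distributed so cohort sizes are uneven
    (the real campaign had 38 cohorts of 93 +/- 84 animals)."""
    cells = [
        (f, y, s)
        for f in range(1, config.n_flocks + 1)
        for y in range(2014, 2014 + config.n_years)
        for s in ("E", "R")
    ]
    weights = rng.dirichlet(np.full(len(cells), 1.5))
    sizes = rng.multinomial(config.n_animals, weights)
    # Every non-empty cohort needs >=2 members for cohort normalization:
    # merge singleton cells into the currently largest cell.
    while True:
        ones = np.where(sizes == 1)[0]
        if len(ones) == 0:
            break
        j = int(np.argmax(sizes))
        if sizes[j] < 2:  # all cells hold <=1 animal: collapse to one cohort
            total = sizes.sum()
            sizes[:] = 0
            sizes[0] = total
            break
        sizes[ones[0]] = 0
        sizes[j] += 1
    flock, year, sex, cohort, flowcell = [], [], [], [], []
    for (f, y, s), size in zip(cells, sizes):
        if size == 0:
            continue
        fc = int(rng.integers(config.n_flowcells)) + 1
        label = f"fc{fc}_f{f}_{y}_{s}"
        flock += [f] * size
        year += [y] * size
        sex += [s] * size
        cohort += [label] * size
        flowcell += [fc] * size
    return (
        np.array(flock),
        np.array(year),
        np.array(sex),
        np.array(cohort),
        np.array(flowcell),
    )


def simulate_population(config: SimulationConfig):
    """Generate genotypes, a phenotype/metadata table and the ground truth.

    The trait is built as ``y = lot_factor * (overall_mean + fixed + g + m + e)``,
    i.e. multiplicative lot effects on top of an additive decomposition, so
    downstream lot scaling and fixed-effect adjustment are both exercised.

    Returns (GenotypeMatrix calls DataFrame, PhenotypeTable DataFrame,
    SimulationTruth).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    calls_df, complete, p = simulate_genotypes(config, rng)
    n = config.n_animals
    g = genetic_values(complete, p, config.sigma2_g, rng)

    # Microbial values share a latent driver with g so that cor(g, m) = rho_gm.
    z = rng.standard_normal(n)
    if config.sigma2_m == 0:
        m = np.zeros(n)
    elif config.sigma2_g > 0:
        g_std = g / math.sqrt(config.sigma2_g)
        m = math.sqrt(config.sigma2_m) * (
            config.rho_gm * g_std + math.sqrt(1.0 - config.rho_gm**2) * z
        )
    else:
        m = math.sqrt(config.sigma2_m) * z
    e = rng.normal(0.0, math.sqrt(config.sigma2_e), size=n)

    flock, year, sex, cohort, flowcell = _assign_cohorts(config, rng)

    # Sequential measurement lots of lot_size within cohort order.
    n_lots = math.ceil(n / config.lot_size)
    lot_ids = np.array([f"lot{i // config.lot_size:04d}" for i in range(n)])
    lot_factors = pd.Series(
        np.exp(rng.normal(-0.5 * config.lot_effect_sd**2, config.lot_effect_sd,
                          size=n_lots)),
        index=[f"lot{i:04d}" for i in range(n_lots)],
        name="lot_factor",
    )

    # Modest real fixed effects for the adjustment step to remove.
    age_of_dam = rng.integers(1, 4, size=n)
    birth_rank = rng.choice(["11", "21", "22"], size=n, p=[0.3, 0.3, 0.4])
    bdev = np.round(rng.normal(0.0, 10.0, size=n))
    scale = math.sqrt(config.sigma2_g + config.sigma2_e) if (
        config.sigma2_g + config.sigma2_e) > 0 else 1.0
    fixed = (
        0.15 * scale * (age_of_dam - 2)
        + np.where(birth_rank == "11", 0.2 * scale, 0.0)
        + 0.01 * scale * bdev
    )

    base = config.overall_mean + fixed + g + m + e
    y = lot_factors.loc[lot_ids].to_numpy() * base

    animal_ids = calls_df.index
    pheno = pd.DataFrame(
        {
            "animal_id": animal_ids,
            "flock": flock,
            "birth_year": year,
            "sex": sex,
            "flowcell": flowcell,
            "cohort": cohort,
            "lot_id": lot_ids,
            "age_of_dam": age_of_dam,
            "birth_rank": birth_rank,
            "bdev": bdev,
            "y": y,
        }
    ).set_index("animal_id")

    tot_g = config.sigma2_g + config.sigma2_e
    tot_m = config.sigma2_m + config.sigma2_e
    truth = SimulationTruth(
        true_g=g,
        true_m=m,
        residual=e,
        lot_factors=lot_factors,
        cohort_labels=pd.Series(cohort, index=animal_ids, name="cohort"),
        flowcell_labels=pd.Series(flowcell, index=animal_ids, name="flowcell"),
        true_h2=config.sigma2_g / tot_g if tot_g > 0 else 0.0,
        true_m2=config.sigma2_m / tot_m if tot_m > 0 else 0.0,
        true_rg=config.rho_gm,
    )
    return calls_df, pheno, truth


def simulate_tag_sequences(n_tags: int, rng: np.random.Generator,
                           length: int = 65) -> list[str]:
    """Unique random tag sequences over {A,C,G,T}."""
    seqs: set[str] = set()
    while len(seqs) < n_tags:
        block = rng.integers(0, 4, size=(n_tags - len(seqs), length))
        seqs.update("".join(_BASES[row]) for row in block)
    return sorted(seqs)[:n_tags]


def simulate_metagenome(truth: SimulationTruth, config: SimulationConfig,
                        tag_sequences: bool = False) -> TagCountMatrix:
    """Tag counts from a log-linear latent-abundance model.

    Per-animal latent log-abundance of tag t:
    ``eta = baseline_t + batch(cohort, t) + loading_t * m_std + noise``;
    counts are multinomial with a log-normal sequencing depth, so sparsity,
    compositionality and depth confounding all emerge. The cohort batch
    shifts are exactly what the MRM's cohort normalization removes.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = len(truth.true_m)
    t = config.n_tags

    baseline = rng.normal(0.0, 1.5, size=t)  # skewed abundances -> sparsity
    loading = rng.normal(0.0, config.tag_signal_sd, size=t)
    cohorts = truth.cohort_labels.to_numpy()
    uniq = np.unique(cohorts)
    batch = rng.normal(0.0, config.batch_effect_sd, size=(len(uniq), t))
    cohort_idx = {c: i for i, c in enumerate(uniq)}
    rows = np.array([cohort_idx[c] for c in cohorts])

    m = truth.true_m
    sd = m.std()
    m_std = (m - m.mean()) / sd if sd > 0 else np.zeros(n)

    eta = (
        baseline
        + batch[rows]
        + np.outer(m_std, loading)
        + rng.normal(0.0, 0.3, size=(n, t))
    )
    eta -= eta.max(axis=1, keepdims=True)
    probs = np.exp(eta)
    probs /= probs.sum(axis=1, keepdims=True)

    depths = np.exp(rng.normal(config.depth_log_mean, config.depth_log_sd,
                               size=n))
    depths = np.maximum(depths.round().astype(np.int64), 1)
    if np.any(depths <= 0):
        raise ValueError("sequencing depths must be positive")

    counts = np.empty((n, t), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depths[i], probs[i])

    if tag_sequences:
        tag_ids = simulate_tag_sequences(t, rng)
    else:
        tag_ids = [f"tag{j:05d}" for j in range(t)]
    df = pd.DataFrame(counts, index=truth.cohort_labels.index, columns=tag_ids)
    return TagCountMatrix(counts=df, total_reads=df.sum(axis=1))


def simulate_reads(tcm: TagCountMatrix, out_dir: str | Path, seed: int = 0,
                   quality_char: str = "I") -> dict[str, Path]:
    """Write one FASTQ per sample with each tag repeated ``count`` times.

    Tag ids must be sequences over {A,C,G,T}; record order is shuffled per
    seed. ``extract_tags`` on the output reproduces the counts exactly, a
    round trip used as a property test of the tag pipeline.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for tag in tcm.counts.columns:
        if set(tag) - set("ACGT"):
            raise ValueError(f"tag contains non-ACGT characters: {tag[:20]}...")
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}
    tags = np.array(tcm.counts.columns)
    for sample in tcm.counts.index:
        row = tcm.counts.loc[sample].to_numpy()
        reads = np.repeat(tags, row)
        rng.shuffle(reads)
        path = out_dir / f"{sample}.fastq"
        with open(path, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@{sample}_{i}\n{seq}\n+\n{quality_char * len(seq)}\n")
        paths[str(sample)] = path
    return paths


def draw_from_kernel(K: np.ndarray, sigma2: float, rng: np.random.Generator,
                     bend: float = 1e-6) -> np.ndarray:
    """Draw u ~ N(0, sigma2 * K) via a bent Cholesky factor."""
    n = K.shape[0]
    if sigma2 == 0:
        return np.zeros(n)
    L = np.linalg.cholesky(K + bend * np.eye(n))
    return math.sqrt(sigma2) * (L @ rng.standard_normal(n))


def draw_bivariate_effects(K: np.ndarray, B: np.ndarray,
                           rng: np.random.Generator,
                           bend: float = 1e-6) -> np.ndarray:
    """Draw an n x 2 matrix U with cov(U[i, a], U[j, b]) = K[i, j] * B[a, b],

    i.e. vec-stacked trait values distributed MVN(0, B kron K)."""
    n = K.shape[0]
    Lk = np.linalg.cholesky(K + bend * np.eye(n))
    Lb = np.linalg.cholesky(B)
    return Lk @ rng.standard_normal((n, 2)) @ Lb.T


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
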