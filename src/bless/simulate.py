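"""Blueprint logistic simulator for benchmarking SNP-selection methods.

Real small-cohort GWAS panels (a few hundred subjects, 1000–5000
post-filter SNPs) are access-restricted, so the benchmark runs on
synthetic data with the same statistical structure: Hardy–Weinberg-
consistent genotypes at MAF ≥ 0.05, block LD, a set of k "true" SNPs
mutually below an r² threshold, effect sizes drawn around 0.3 (a
realistically small per-allele log-odds), zero intercept, and Bernoulli
outcomes from the logistic blueprint

    logit Pr(y_i = 1) = beta_0 + sum_j beta_j * SNP_ij,

with beta_j = 0 for every panel SNP outside the true set.  Replicates
redraw the effects and outcomes while holding the genotypes fixed, the
way a benchmark built on one real cohort's genotypes would.

Genotypes come from a thresholded latent-Gaussian haplotype model: within
an LD block, each haplotype's allele indicators are an equicorrelated
Gaussian thresholded at the MAF quantile, and a sample's dosage is the
sum of two independent haplotypes — HWE holds by construction, and the
realized dosage correlation tracks (somewhat below) the latent ``r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, ndtri

from bless.io import GenotypeMatrix

__all__ = [
    "GenotypeSimSpec",
    "BlueprintSpec",
    "Replicate",
    "simulate_genotypes",
    "compute_r2",
    "select_blueprint",
    "draw_effects",
    "simulate_outcome",
    "run_replicates",
]


@dataclass(frozen=True)
class GenotypeSimSpec:
    """Panel geometry for the genotype generator.

    Defaults mirror the smaller of the two cohorts the method was designed
    around: 197 subjects, a 1000-SNP post-prefilter panel, MAF uniform on
    [0.05, 0.5] (the QC floor upward), LD blocks of 4 adjacent SNPs with
    latent correlation 0.5.
    """

    n: int = 197
    p: int = 1000
    maf_range: tuple[float, float] = (0.05, 0.5)
    block_size: int = 4
    within_block_r: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.p < 1:
            raise ValueError("n and p must be positive")
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must sit within [0.05, 0.5]")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not 0.0 <= self.within_block_r < 1.0:
            raise ValueError("within_block_r must be in [0, 1)")


@dataclass
class BlueprintSpec:
    """One benchmark's ground truth: which SNPs carry signal, and the panel.

    ``true_snp_ids`` are mutually below the r² threshold; every other
    panel SNP in high LD with a true SNP has been filtered out, so
    ``panel_ids`` ⊇ ``true_snp_ids`` and no panel SNP shadows a true one.
    ``betas`` may be empty until :func:`draw_effects` fills a replicate.
    """

    true_snp_ids: list[str]
    panel_ids: list[str]
    betas: np.ndarray = field(default_factory=lambda: np.empty(0))
    beta0: float = 0.0
    effect_mean: float = 0.3
    effect_sd: float = 0.1
    r2_threshold: float = 0.8

    def __post_init__(self) -> None:
        if not set(self.true_snp_ids) <= set(self.panel_ids):
            raise ValueError("true SNPs must be a subset of the panel")
        if len(self.betas) and len(self.betas) != len(self.true_snp_ids):
            raise ValueError("betas must match the number of true SNPs")


def simulate_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Generate an n×p HWE-consistent dosage matrix with block LD.

    Per block, per haplotype: latent z ~ N(0, Sigma) with equicorrelation
    ``within_block_r``; allele = 1 where z < Phi^{-1}(MAF).  Dosage is the
    sum over the two haplotypes.  SNP IDs are ``snp0001``-style; MAFs are
    drawn uniformly over ``maf_range``.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.p)))
    snps = [f"snp{j + 1:0{width}d}" for j in range(spec.p)]
    mafs = rng.uniform(*spec.maf_range, size=spec.p)
    thresholds = ndtri(mafs)
    dosages = np.zeros((spec.n, spec.p))
    rho = spec.within_block_r
    for start in range(0, spec.p, spec.block_size):
        b = min(spec.block_size, spec.p - start)
        for _hap in range(2):
            # equicorrelated Gaussian: sqrt(rho)*shared + sqrt(1-rho)*own
            shared = rng.standard_normal((spec.n, 1))
            own = rng.standard_normal((spec.n, b))
            z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
            dosages[:, start:start + b] += z < thresholds[start:start + b]
    return GenotypeMatrix([f"s{i + 1:04d}" for i in range(spec.n)], snps, dosages)


def compute_r2(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Squared Pearson correlation of two dosage vectors (composite-LD
    approximation, appropriate for unphased genotypes)."""
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("r2 undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_blueprint(G: GenotypeMatrix, ranking: Sequence[str], k: int = 30,
                     r2_thr: float = 0.8) -> BlueprintSpec:
    """Choose k true SNPs down a ranking, pruning the panel by LD.

    Greedy scan: a SNP joins the true set iff its r² with every SNP
    already accepted stays below ``r2_thr``, until k are accepted.  Every
    non-true SNP with r² ≥ ``r2_thr`` to ANY true SNP is then removed from
    the panel, so no retained null SNP is a near-duplicate of a signal.
    """
    ranking = [str(s) for s in ranking]
    if len(ranking) < k:
        raise ValueError(f"ranking covers {len(ranking)} SNPs; need >= {k}")
    vectors = {s: G.dosage_vector(s) for s in ranking}
    true_set: list[str] = []
    for snp in ranking:
        if all(compute_r2(vectors[snp], vectors[t]) < r2_thr for t in true_set):
            true_set.append(snp)
            if len(true_set) == k:
                break
    if len(true_set) < k:
        raise ValueError(
            f"only {len(true_set)} SNPs satisfy pairwise r2 < {r2_thr}; "
            f"need {k}"
        )
    panel = [s for s in ranking
             if s in true_set
             or all(compute_r2(vectors[s], vectors[t]) < r2_thr
                    for t in true_set)]
    return BlueprintSpec(true_snp_ids=true_set, panel_ids=panel,
                         r2_threshold=r2_thr)


def draw_effects(k: int = 30, mean: float = 0.3, sd: float = 0.1,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw k per-allele log-odds effects ~ N(mean, sd).

    The default N(0.3, 0.1) keeps single-SNP contributions small (the
    realistic regime) while bounding every effect away from zero; all
    other panel SNPs implicitly carry beta = 0.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng() if rng is None else rng
    return rng.normal(mean, sd, size=k)


def simulate_outcome(G_true: np.ndarray, betas: Sequence[float],
                     beta0: float = 0.0,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Bernoulli outcomes from the logistic blueprint on the true-SNP dosages."""
    G_true = np.asarray(G_true, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if G_true.ndim != 2 or G_true.shape[1] != betas.size:
        raise ValueError(
            f"dosage block {G_true.shape} does not match {betas.size} effects"
        )
    if np.isnan(G_true).any():
        raise ValueError("missing dosages are not permitted in the blueprint")
    rng = np.random.default_rng() if rng is None else rng
    prob = expit(beta0 + G_true @ betas)
    return (rng.random(G_true.shape[0]) < prob).astype(int)


@dataclass
class Replicate:
    """One simulated dataset: fresh effects and outcomes, shared genotypes."""

    index: int
    betas: np.ndarray
    outcome: np.ndarray


def run_replicates(G: GenotypeMatrix, blueprint: BlueprintSpec, R: int = 100,
                   seed: int = 0) -> list[Replicate]:
    """Generate R replicates: per replicate, redraw effects ~ N(mean, sd)
    and outcomes, holding genotypes fixed.  Replicate r uses an RNG
    substream seeded by ``(seed, r)``, so any prefix of the collection is
    stable under a larger R."""
    cols = [G.snp_index(s) for s in blueprint.true_snp_ids]
    G_true = G.dosages[:, cols]
    out = []
    for r in range(R):
        rng = np.random.default_rng([seed, r])
        betas = draw_effects(len(cols), blueprint.effect_mean,
                             blueprint.effect_sd, rng)
        y = simulate_outcome(G_true, betas, blueprint.beta0, rng)
        out.append(Replicate(index=r, betas=betas, outcome=y))
    return out
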