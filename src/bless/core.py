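"""The BLESS ensemble: bagged logistic regression for SNP ranking.

Each iteration draws a without-replacement subsample of the observations
and a random subset of the SNPs, fits ONE joint logistic model (intercept
+ all covariates + the sampled SNP dosages) on the subsample, and records
a Wald p-value per sampled SNP.  Across iterations every SNP accumulates a
group of p-values; the group is Benjamini–Hochberg adjusted with a
*dynamic multiplicity* equal to the number of iterations in which that SNP
was actually tested (e.g. a SNP tested in 100 of 1000 iterations is
adjusted as 100 comparisons).  A SNP's score is the minimum adjusted
p-value in its group; SNPs are called significant below ``alpha`` and the
full list is ranked ascending on that minimum.

Subsampling both rows and columns lets many weak base learners see a SNP
in different covariate/SNP contexts, which recovers signal that a single
genome-wide scan penalized by a p-sized multiplicity correction misses,
at the price of extra false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from joblib import Parallel, delayed
from statsmodels.stats.multitest import multipletests

from bless._glm import covariate_design, fit_logit
from bless.io import GenotypeMatrix, ResultRow, SampleTable

__all__ = [
    "BlessConfig",
    "PValueGroup",
    "RankedFeature",
    "subsample_observations",
    "sample_features",
    "fit_base_model",
    "aggregate_groups",
    "adjust_group",
    "summarize",
    "run_bless",
    "ranked_features_to_rows",
]


@dataclass(frozen=True)
class BlessConfig:
    """Tuning parameters of one BLESS run.

    ``subsample_fraction`` of the observations (default 90%) and
    ``n_features`` SNPs (default round(sqrt(p)), resolved at run time when
    None) enter each of ``n_iterations`` base models; ``covariates`` are
    carried into every model and never subsampled.  ``n_jobs`` only
    distributes iterations — per-iteration RNG substreams derived from
    ``(seed, iteration)`` make the output identical for any worker count.
    """

    subsample_fraction: float = 0.9
    n_features: Optional[int] = None
    n_iterations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    covariates: tuple[str, ...] = ()
    fdr_method: str = "fdr_bh"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        if self.fdr_method != "fdr_bh":
            raise ValueError("dynamic adjustment is defined for fdr_bh only")

    def resolve_n_features(self, p: int) -> int:
        m = round(np.sqrt(p)) if self.n_features is None else self.n_features
        m = int(m)
        if m > p:
            raise ValueError(f"n_features={m} exceeds panel size p={p}")
        return max(m, 1)


@dataclass
class PValueGroup:
    """One SNP's pooled raw p-values across the iterations that tested it.

    ``selection_count`` — the dynamic multiplicity — always equals the
    number of stored p-values: iterations where the SNP was drawn but its
    coefficient was not estimable contribute no p-value and no
    multiplicity (they are tallied separately in the run log).
    """

    snp: str
    pvalues: list[float] = field(default_factory=list)
    iterations: list[int] = field(default_factory=list)

    @property
    def selection_count(self) -> int:
        return len(self.pvalues)


@dataclass
class RankedFeature:
    """Final per-SNP summary: minimum adjusted p, multiplicity, call."""

    snp: str
    min_adjusted_p: float
    selection_count: int
    significant: bool
    rank: Optional[int] = None
    median_raw_p: Optional[float] = None


def subsample_observations(n: int, fraction: float,
                           rng: np.random.Generator) -> np.ndarray:
    """Draw ``floor(fraction*n)`` distinct row indices uniformly without
    replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    size = int(np.floor(fraction * n))
    if size == 0:
        raise ValueError(f"fraction {fraction} of n={n} observations is empty")
    return rng.choice(n, size=size, replace=False)


def sample_features(snp_ids: Sequence[str], m: int,
                    rng: np.random.Generator) -> list[str]:
    """Draw ``m`` distinct SNP IDs uniformly without replacement.

    Covariates are never part of this draw; they are appended to every
    base model unconditionally.
    """
    if not 1 <= m <= len(snp_ids):
        raise ValueError(f"m={m} outside [1, {len(snp_ids)}]")
    idx = rng.choice(len(snp_ids), size=m, replace=False)
    return [snp_ids[i] for i in idx]


class IterationDiscarded(Exception):
    """Raised when a subsample cannot support any fit (monomorphic outcome)."""


def fit_base_model(G: GenotypeMatrix, S: SampleTable,
                   obs_idx: Sequence[int], feat_ids: Sequence[str],
                   covariates: Sequence[str] = ()
                   ) -> list[tuple[str, Optional[float], bool, str]]:
    """Fit one joint logistic base model and return per-SNP Wald p-values.

    Design: intercept + covariates + the ``feat_ids`` dosages, all in a
    single model, restricted to ``obs_idx`` rows (complete cases over the
    sampled SNPs).  Returns ``(snp, p, converged, reason)`` per sampled
    SNP; SNPs constant within the subsample, or dropped to restore full
    column rank, are flagged rather than given a p-value.
    """
    obs_idx = np.asarray(obs_idx, dtype=int)
    samples = [G.samples[i] for i in obs_idx]
    cols = [G.snp_index(s) for s in feat_ids]
    D = G.dosages[np.ix_(obs_idx, cols)]
    complete = ~np.isnan(D).any(axis=1)
    D = D[complete]
    samples = [s for s, c in zip(samples, complete) if c]
    y = S.outcome_vector(samples)
    if np.unique(y).size < 2:
        raise IterationDiscarded("outcome monomorphic in subsample")

    results: dict[str, tuple[str, Optional[float], bool, str]] = {}
    active: list[tuple[str, int]] = []
    for j, snp in enumerate(feat_ids):
        if np.unique(D[:, j]).size < 2:
            results[snp] = (snp, None, False, "monomorphic_in_subsample")
        else:
            active.append((snp, j))

    C = covariate_design(S, covariates, samples).to_numpy(dtype=float)
    base = [np.ones(len(samples))] + ([C] if C.size else [])
    X = np.column_stack(base + [D[:, [j for _, j in active]]]) if active else None
    n_base = 1 + (C.shape[1] if C.size else 0)

    if active and X is not None and np.linalg.matrix_rank(X) < X.shape[1]:
        # rank-deficient design: drop later columns dependent on earlier ones
        rank_keep: list[int] = []
        kept = np.empty((X.shape[0], 0))
        for j in range(X.shape[1]):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) > kept.shape[1]:
                kept = cand
                rank_keep.append(j)
            elif j >= n_base:
                snp = active[j - n_base][0]
                results[snp] = (snp, None, False, "collinear_in_subsample")
        X = kept
        active = [a for j, a in enumerate(active) if j + n_base in rank_keep]

    if active and X is not None:
        params, bse, pvals, ok, reason = fit_logit(y, X)
        for pos, (snp, _) in enumerate(active):
            col = n_base + pos
            if ok and np.isfinite(pvals[col]):
                results[snp] = (snp, float(pvals[col]), True, "")
            else:
                results[snp] = (snp, None, False, reason or "nonfinite_pvalue")
    return [results[s] for s in feat_ids]


def aggregate_groups(iteration_results: Sequence[Sequence[tuple]],
                     snp_ids: Sequence[str]
                     ) -> tuple[dict[str, PValueGroup], list[str]]:
    """Pool per-iteration p-values into one group per SNP.

    Returns the nonempty groups plus the list of SNPs never successfully
    tested (never drawn, or flagged every time they were).
    """
    groups = {s: PValueGroup(s) for s in snp_ids}
    for it, res in enumerate(iteration_results):
        for snp, p, converged, _ in res:
            if converged and p is not None:
                groups[snp].pvalues.append(p)
                groups[snp].iterations.append(it)
    never = [s for s in snp_ids if groups[s].selection_count == 0]
    return {s: g for s, g in groups.items() if g.selection_count}, never


def adjust_group(g: PValueGroup) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg within one SNP's group, with multiplicity equal
    to the group size (the SNP's dynamic number of comparisons)."""
    if g.selection_count == 0:
        raise ValueError(f"SNP {g.snp!r} has an empty p-value group")
    adjusted = multipletests(np.asarray(g.pvalues, dtype=float),
                             method="fdr_bh")[1]
    return adjusted, float(adjusted.min())


def summarize(groups: Sequence[PValueGroup], alpha: float = 0.05
              ) -> list[RankedFeature]:
    """Score, call and rank every tested SNP.

    Significant ⇔ minimum adjusted p < ``alpha``.  Ranking is ascending on
    the minimum adjusted p; ties break by selection count descending, then
    median raw p ascending, then SNP ID — so ranks are dense and stable.
    """
    feats = []
    for g in groups:
        _, min_adj = adjust_group(g)
        feats.append(RankedFeature(
            snp=g.snp,
            min_adjusted_p=min_adj,
            selection_count=g.selection_count,
            significant=bool(min_adj < alpha),
            median_raw_p=float(np.median(g.pvalues)),
        ))
    feats.sort(key=lambda f: (f.min_adjusted_p, -f.selection_count,
                              f.median_raw_p, f.snp))
    for i, f in enumerate(feats, start=1):
        f.rank = i
    return feats


def _one_iteration(G: GenotypeMatrix, S: SampleTable, config: BlessConfig,
                   m: int, it: int):
    rng = np.random.default_rng([config.seed, it])
    obs = subsample_observations(G.n_samples, config.subsample_fraction, rng)
    feats = sample_features(G.snps, m, rng)
    try:
        return fit_base_model(G, S, obs, feats, config.covariates)
    except IterationDiscarded as exc:
        return [("__discarded__", None, False, str(exc))]


def run_bless(G: GenotypeMatrix, S: SampleTable, config: BlessConfig
              ) -> tuple[list[RankedFeature], dict]:
    """Run the full ensemble and return the ranked list plus a run log.

    Deterministic given ``config.seed``: iteration ``i`` uses an RNG
    substream seeded by ``(seed, i)``, so results do not depend on
    execution order or ``n_jobs``.  Statistical failures (discarded
    iterations, non-estimable coefficients, never-tested SNPs) are logged
    and survived, never fatal.
    """
    y = S.outcome_vector(G.samples)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary {0,1}; dichotomize first")
    m = config.resolve_n_features(G.n_snps)

    if config.n_jobs == 1:
        iters = [_one_iteration(G, S, config, m, it)
                 for it in range(config.n_iterations)]
    else:
        iters = Parallel(n_jobs=config.n_jobs)(
            delayed(_one_iteration)(G, S, config, m, it)
            for it in range(config.n_iterations))

    discarded = [i for i, res in enumerate(iters)
                 if res and res[0][0] == "__discarded__"]
    kept = [res if (not res or res[0][0] != "__discarded__") else []
            for res in iters]
    failures = sum(1 for res in kept for r in res if not r[2])
    groups, never = aggregate_groups(kept, G.snps)
    ranked = summarize(list(groups.values()), config.alpha)
    counts = [g.selection_count for g in groups.values()]
    log = {
        "n_iterations": config.n_iterations,
        "n_features": m,
        "subsample_fraction": config.subsample_fraction,
        "discarded_iterations": discarded,
        "n_failed_tests": failures,
        "never_tested": never,
        "multiplicity": {
            "min": int(min(counts)) if counts else 0,
            "median": float(np.median(counts)) if counts else 0.0,
            "max": int(max(counts)) if counts else 0,
        },
        "n_significant": sum(f.significant for f in ranked),
    }
    return ranked, log


def ranked_features_to_rows(ranked: Sequence[RankedFeature],
                            marginal_p: Optional[dict[str, float]] = None,
                            method: str = "bless") -> list[ResultRow]:
    """Convert a ranked list to writable :class:`ResultRow`s, optionally
    attaching each SNP's marginal scan p-value for side-by-side reporting."""
    return [ResultRow(
        snp=f.snp,
        statistic=None,
        raw_p=None if marginal_p is None else marginal_p.get(f.snp),
        adjusted_p=f.min_adjusted_p,
        rank=f.rank,
        method=method,
        selection_count=f.selection_count,
    ) for f in ranked]
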