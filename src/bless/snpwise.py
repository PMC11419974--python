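"""The traditional SNP-wise GWAS baseline.

One covariate-adjusted logistic regression per SNP, a Wald two-sided
p-value for the dosage coefficient, multiplicity adjustment across all
SNPs (Benjamini–Hochberg or Bonferroni), and ranking with a top-k
prefilter that feeds the ensemble.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from bless._glm import covariate_design, fit_logit
from bless.io import GenotypeMatrix, SampleTable

__all__ = [
    "MarginalResult",
    "fit_marginal",
    "adjust_pvalues",
    "rank_and_select",
    "snpwise_scan",
]

# conventional Manhattan-plot reference lines, emitted with tabular output
GENOME_WIDE_SIGNIFICANCE = 5e-8
SUGGESTIVE_SIGNIFICANCE = 1e-5


@dataclass
class MarginalResult:
    """Marginal association of one SNP with the outcome."""

    snp: str
    coef: Optional[float]
    se: Optional[float]
    statistic: Optional[float]
    raw_p: Optional[float]
    adjusted_p: Optional[float] = None
    adjust_method: Optional[str] = None
    converged: bool = True
    reason: str = ""


def fit_marginal(G: GenotypeMatrix, S: SampleTable, snp: str,
                 covariates: Sequence[str] = ()) -> MarginalResult:
    """Logistic regression of the binary outcome on one SNP's dosage plus
    covariates; Wald two-sided p-value for the dosage coefficient.

    Samples with a missing dosage for this SNP are dropped for this fit
    only (complete-case per SNP; QC bounds per-SNP missingness).  A SNP
    that is monomorphic among the retained samples, or that separates the
    outcome, is returned with ``converged=False`` and no p-value.
    """
    g = G.dosage_vector(snp)
    y = S.outcome_vector(G.samples)
    keep = ~np.isnan(g)
    g, y = g[keep], y[keep]
    kept_samples = [s for s, k in zip(G.samples, keep) if k]
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary {0,1}; dichotomize first")
    if np.unique(g).size < 2:
        return MarginalResult(snp, None, None, None, None,
                              converged=False, reason="monomorphic")
    C = covariate_design(S, covariates, kept_samples).to_numpy(dtype=float)
    X = np.column_stack([np.ones(g.size), g] + ([C] if C.size else []))
    params, bse, pvals, ok, reason = fit_logit(y, X)
    if not ok:
        return MarginalResult(snp, None, None, None, None,
                              converged=False, reason=reason)
    return MarginalResult(snp, float(params[1]), float(bse[1]),
                          float(params[1] / bse[1]), float(pvals[1]))


def adjust_pvalues(p: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiplicity-adjust a vector of p-values, preserving input order.

    ``fdr_bh`` is the Benjamini–Hochberg step-up adjustment; ``bonferroni``
    is ``min(1, m*p)``.  Missing entries (NaN/None) are excluded from the
    multiplicity ``m`` and returned as NaN.
    """
    if method not in ("fdr_bh", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    arr = np.array([np.nan if v is None else float(v) for v in p], dtype=float)
    obs = ~np.isnan(arr)
    if obs.any():
        vals = arr[obs]
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
        adj = multipletests(vals, method=method)[1]
        out = np.full(arr.size, np.nan)
        out[obs] = adj
        return out
    return arr


def rank_and_select(results: Sequence[MarginalResult], k: int
                    ) -> tuple[list[MarginalResult], list[str]]:
    """Rank converged results ascending on raw p and return the top-k IDs.

    Ties on p are broken by \\|Wald statistic\\| descending, then SNP ID
    lexicographic, so ranks are dense and fully reproducible.  The top-k ID
    set is the usual prefilter feeding the ensemble.
    """
    conv = [r for r in results if r.converged and r.raw_p is not None]
    if k > len(conv):
        raise ValueError(
            f"k={k} exceeds the {len(conv)} converged results "
            f"({len(results) - len(conv)} failed)"
        )
    ordered = sorted(conv, key=lambda r: (r.raw_p, -abs(r.statistic), r.snp))
    for i, r in enumerate(ordered, start=1):
        r.rank = i  # type: ignore[attr-defined]
    return ordered, [r.snp for r in ordered[:k]]


def snpwise_scan(G: GenotypeMatrix, S: SampleTable,
                 covariates: Sequence[str] = (), adjust: str = "fdr_bh"
                 ) -> pd.DataFrame:
    """Marginal scan over every SNP with multiplicity adjustment.

    Returns a Manhattan-ready frame (one row per SNP, input order) with
    columns ``snp, coef, se, statistic, p, adjusted_p, converged, reason``
    and the conventional genome-wide / suggestive thresholds as attributes.
    """
    results = [fit_marginal(G, S, snp, covariates) for snp in G.snps]
    adj = adjust_pvalues([r.raw_p for r in results], method=adjust)
    rows = []
    for r, a in zip(results, adj):
        r.adjusted_p = None if math.isnan(a) else float(a)
        r.adjust_method = adjust
        rows.append({
            "snp": r.snp, "coef": r.coef, "se": r.se, "statistic": r.statistic,
            "p": r.raw_p, "adjusted_p": r.adjusted_p,
            "converged": r.converged, "reason": r.reason,
        })
    df = pd.DataFrame(rows)
    df.attrs["genome_wide_line"] = GENOME_WIDE_SIGNIFICANCE
    df.attrs["suggestive_line"] = SUGGESTIVE_SIGNIFICANCE
    df.attrs["results"] = results
    return df
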