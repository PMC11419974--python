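"""Scoring identified SNPs against a blueprint truth set, and the tuning
grid benchmark (subsample fraction × feature count) over simulated
replicates, with the SNP-wise + BH scan as comparator."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from bless.core import BlessConfig, run_bless
from bless.io import GenotypeMatrix, SampleTable
from bless.simulate import BlueprintSpec, run_replicates
from bless.snpwise import snpwise_scan

__all__ = ["ConfusionCounts", "confusion", "metrics", "benchmark_grid"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Panel-level confusion counts for one identified-SNP list.

    TP: true SNPs identified; FP: identified but not true; FN: true SNPs
    missed; TN: the rest of the panel.  The four counts always partition
    the panel.
    """

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(identified: Sequence[str], truth: Sequence[str],
              panel: Sequence[str]) -> ConfusionCounts:
    """Classify every panel SNP by membership in the identified and truth sets."""
    identified, truth, panel = set(identified), set(truth), set(panel)
    if not identified <= panel:
        raise ValueError(
            f"identified SNPs outside the panel: {sorted(identified - panel)[:5]}"
        )
    if not truth <= panel:
        raise ValueError(
            f"truth SNPs outside the panel: {sorted(truth - panel)[:5]}"
        )
    tp = len(identified & truth)
    fp = len(identified - truth)
    fn = len(truth - identified)
    tn = len(panel) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def metrics(c: ConfusionCounts) -> dict:
    """Recall TP/(TP+FN), precision TP/(TP+FP), accuracy (TP+TN)/total.

    Precision is reported missing (NaN) when nothing was identified —
    an empty list is "found nothing", not "all wrong".
    """
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else np.nan
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else np.nan
    accuracy = (c.TP + c.TN) / c.total
    return {"recall": recall, "precision": precision, "accuracy": accuracy}


def _score(identified, blueprint: BlueprintSpec) -> dict:
    return metrics(confusion(identified, blueprint.true_snp_ids,
                             blueprint.panel_ids))


def benchmark_grid(G: GenotypeMatrix, blueprint: BlueprintSpec,
                   fractions: Sequence[float] = (0.8, 0.9, 1.0),
                   feature_counts: Sequence[int] = (10, 30, 50),
                   R: int = 100, seed: int = 0, n_iterations: int = 1000,
                   alpha: float = 0.05,
                   comparator_adjust: str = "fdr_bh") -> pd.DataFrame:
    """Run BLESS over the tuning grid and the SNP-wise scan, per replicate.

    For every replicate: one SNP-wise + FDR comparator row (identified =
    SNPs with adjusted marginal p < ``alpha``) and one BLESS row per grid
    cell (identified = significant SNPs).  Returns a long-format frame
    with columns ``method, fraction, n_features, replicate, recall,
    precision, accuracy`` suitable for the usual boxplot layout.  Failed
    replicates are recorded with NaN metrics and an ``error`` note rather
    than aborting the grid.
    """
    Gp = G.subset(snps=blueprint.panel_ids)
    replicates = run_replicates(Gp, blueprint, R=R, seed=seed)
    rows = []
    for rep in replicates:
        data = pd.DataFrame({"y": rep.outcome},
                            index=pd.Index(Gp.samples, name="sample"))
        S = SampleTable(data, "y")
        scan = snpwise_scan(Gp, S, adjust=comparator_adjust)
        hits = scan.loc[scan["adjusted_p"] < alpha, "snp"].tolist()
        rows.append({"method": "snpwise", "fraction": np.nan,
                     "n_features": np.nan, "replicate": rep.index,
                     **_score(hits, blueprint), "error": ""})
        for frac in fractions:
            for m in feature_counts:
                cfg = BlessConfig(subsample_fraction=frac, n_features=m,
                                  n_iterations=n_iterations, alpha=alpha,
                                  seed=int(np.random.default_rng(
                                      [seed, rep.index, int(frac * 100), m]
                                  ).integers(2**31)))
                try:
                    ranked, _ = run_bless(Gp, S, cfg)
                    sig = [f.snp for f in ranked if f.significant]
                    rows.append({"method": "bless", "fraction": frac,
                                 "n_features": m, "replicate": rep.index,
                                 **_score(sig, blueprint), "error": ""})
                except Exception as exc:
                    rows.append({"method": "bless", "fraction": frac,
                                 "n_features": m, "replicate": rep.index,
                                 "recall": np.nan, "precision": np.nan,
                                 "accuracy": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
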