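"""Quality control and preprocessing for small-cohort GWAS.

The QC cascade runs in a fixed order on survivors of each step:
missingness (SNPs then samples) → minor allele frequency → Hardy–Weinberg
equilibrium → optional categorical sample exclusion → genotype PCA.  Each
step logs what it removed and why into a :class:`QCReport`, whose counts
always reconcile with the input dimensions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from bless.io import GenotypeMatrix, SampleTable

__all__ = [
    "QCReport",
    "HWECounts",
    "filter_missingness",
    "minor_allele_frequency",
    "hwe_pvalue",
    "hwe_counts",
    "filter_maf",
    "filter_hwe",
    "impute_simple",
    "compute_pcs",
    "dichotomize_cdr",
    "drop_samples_where",
    "run_qc",
]

CDR_SCALE = (0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class QCReport:
    """Ordered log of QC steps with per-axis removal counts."""

    steps: list[dict] = field(default_factory=list)

    def add(self, step: str, *, snps_removed: int = 0, samples_removed: int = 0,
            **details) -> None:
        self.steps.append({
            "step": step,
            "snps_removed": int(snps_removed),
            "samples_removed": int(samples_removed),
            **details,
        })

    def total_removed(self) -> tuple[int, int]:
        return (
            sum(s["snps_removed"] for s in self.steps),
            sum(s["samples_removed"] for s in self.steps),
        )


@dataclass(frozen=True)
class HWECounts:
    """Genotype counts for one biallelic SNP: hom-ref, het, hom-alt."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be nonnegative")
        if self.total == 0:
            raise ValueError("total genotype count must be positive")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


def filter_missingness(G: GenotypeMatrix, S: SampleTable, thr: float = 0.05,
                       report: Optional[QCReport] = None,
                       ) -> tuple[GenotypeMatrix, SampleTable, QCReport]:
    """Drop SNPs, then samples, whose missing-call fraction exceeds ``thr``.

    SNPs are filtered first: removing a badly genotyped SNP can rescue
    samples whose missingness was concentrated in it.  Sample missingness is
    then evaluated over the surviving SNPs only.
    """
    if not 0.0 <= thr <= 1.0:
        raise ValueError(f"missingness threshold {thr} outside [0, 1]")
    report = report if report is not None else QCReport()
    miss = G.missing_mask
    snp_frac = miss.mean(axis=0)
    keep_snps = [s for s, f in zip(G.snps, snp_frac) if f <= thr]
    if not keep_snps:
        raise ValueError(
            f"missingness filter at {thr} removed every SNP; review the threshold"
        )
    G2 = G.subset(snps=keep_snps)
    sample_frac = G2.missing_mask.mean(axis=1)
    keep_samples = [s for s, f in zip(G2.samples, sample_frac) if f <= thr]
    if not keep_samples:
        raise ValueError(
            f"missingness filter at {thr} removed every sample; review the threshold"
        )
    G3 = G2.subset(samples=keep_samples)
    S3 = SampleTable(S.data.loc[[s for s in keep_samples if s in S.data.index]],
                     S.outcome, list(S.covariates), dict(S.categorical_levels))
    report.add("missingness_snps", snps_removed=G.n_snps - G2.n_snps, threshold=thr,
               order="SNPs filtered before samples")
    report.add("missingness_samples", samples_removed=G2.n_samples - G3.n_samples,
               threshold=thr)
    return G3, S3, report


def minor_allele_frequency(dosages: Sequence[float]) -> float:
    """MAF of one SNP from additive dosages: ``min(f, 1-f)`` with
    ``f = sum(dosages) / (2 * n_nonmissing)``."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; MAF undefined")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def hwe_counts(dosages: Sequence[float]) -> HWECounts:
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; genotype counts undefined")
    return HWECounts(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))


def hwe_pvalue(c: HWECounts) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy–Weinberg
    proportions at the estimated allele frequency.

    Monomorphic SNPs (allele frequency 0 or 1) return p = 1 by convention:
    a fixed locus fits HWE trivially and is left to the MAF filter.
    """
    n = c.total
    p_hat = (2 * c.n_AA + c.n_Aa) / (2.0 * n)
    if p_hat in (0.0, 1.0):
        return 1.0
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat**2, n * 2 * p_hat * q_hat, n * q_hat**2])
    observed = np.array([c.n_AA, c.n_Aa, c.n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    # 3 genotype classes − 1 (sum constraint) − 1 (estimated allele freq) = 1 df
    return float(stats.chi2.sf(chi2, df=1))


def filter_maf(G: GenotypeMatrix, thr: float = 0.05,
               report: Optional[QCReport] = None) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs with minor allele frequency below ``thr``."""
    report = report if report is not None else QCReport()
    keep = [s for s in G.snps if minor_allele_frequency(G.dosage_vector(s)) >= thr]
    if not keep:
        raise ValueError(f"MAF filter at {thr} removed every SNP")
    G2 = G.subset(snps=keep)
    report.add("maf", snps_removed=G.n_snps - G2.n_snps, threshold=thr)
    return G2, report


def filter_hwe(G: GenotypeMatrix, thr: float = 1e-6,
               report: Optional[QCReport] = None) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs whose HWE goodness-of-fit p-value falls below ``thr``."""
    report = report if report is not None else QCReport()
    keep = [s for s in G.snps if hwe_pvalue(hwe_counts(G.dosage_vector(s))) >= thr]
    if not keep:
        raise ValueError(f"HWE filter at {thr} removed every SNP")
    G2 = G.subset(snps=keep)
    report.add("hwe", snps_removed=G.n_snps - G2.n_snps, threshold=thr)
    return G2, report


def impute_simple(S: SampleTable) -> SampleTable:
    """Fill missing covariate cells: column mode for categoricals, column
    mean for continuous columns.  Mode ties are broken by the smallest level
    (with a warning); imputation counts are recorded on the returned table.
    """
    df = S.data.copy()
    counts: dict[str, int] = {}
    for c in S.covariates:
        col = df[c]
        n_missing = int(col.isna().sum())
        if n_missing == 0:
            continue
        if col.notna().sum() == 0:
            raise ValueError(f"covariate {c!r} is wholly missing; cannot impute")
        if c in S.categorical_levels or not pd.api.types.is_numeric_dtype(col):
            modes = col.mode(dropna=True)
            if len(modes) > 1:
                warnings.warn(
                    f"mode tie in {c!r}; imputing smallest level {sorted(modes)[0]!r}"
                )
            fill = sorted(modes)[0]
        else:
            fill = col.mean()
        df[c] = col.fillna(fill)
        counts[c] = n_missing
    out = SampleTable(df, S.outcome, list(S.covariates), dict(S.categorical_levels))
    out.imputation_counts = counts  # type: ignore[attr-defined]
    return out


def compute_pcs(G: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal component scores of the column-standardized dosages.

    Missing dosages are mean-imputed per SNP for the PCA only.  Constant
    SNPs are skipped in the standardization.  The sign of each component is
    fixed so its largest-magnitude SNP loading is positive, making scores
    reproducible across runs and platforms.
    """
    if k < 0 or k > min(G.n_samples, G.n_snps):
        raise ValueError(
            f"k={k} outside [0, min(n={G.n_samples}, p={G.n_snps})]"
        )
    if k == 0:
        return pd.DataFrame(index=pd.Index(G.samples, name="sample"))
    X = G.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    nonconst = sd > 0
    X = X[:, nonconst] / sd[nonconst]
    U, svals, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :k] * svals[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=pd.Index(G.samples, name="sample"),
                        columns=[f"PC{j + 1}" for j in range(k)])


def dichotomize_cdr(score, thr: float = 0.5):
    """Map Clinical Dementia Rating scores to binary impairment status.

    CDR is a 5-point ordinal scale {0, 0.5, 1, 2, 3}; scores below ``thr``
    (default 0.5) mean no impairment (0), scores at or above it mean some
    impairment regardless of severity (1).
    """
    arr = np.asarray(score, dtype=float)
    bad = ~np.isin(arr, CDR_SCALE)
    if bad.any():
        raise ValueError(
            f"CDR score(s) {np.unique(arr[bad]).tolist()} outside the 5-point "
            f"scale {list(CDR_SCALE)}"
        )
    out = (arr >= thr).astype(int)
    return int(out) if np.isscalar(score) else out


def drop_samples_where(S: SampleTable, column: str, value,
                       report: Optional[QCReport] = None
                       ) -> tuple[SampleTable, QCReport]:
    """Generic sample exclusion: drop samples where ``column == value``.

    Covers sex-balance exclusions and similar cohort trims without a
    dedicated code path per variable.
    """
    report = report if report is not None else QCReport()
    if column not in S.data.columns:
        raise KeyError(f"column {column!r} not in {list(S.data.columns)}")
    keep = S.data[S.data[column] != value]
    report.add(f"drop[{column}=={value!r}]",
               samples_removed=len(S.data) - len(keep))
    out = SampleTable(keep, S.outcome, list(S.covariates),
                      dict(S.categorical_levels))
    return out, report


def run_qc(G: GenotypeMatrix, S: SampleTable, *, miss_thr: float = 0.05,
           maf_thr: float = 0.05, hwe_thr: float = 1e-6, n_pcs: int = 10,
           drop: Optional[tuple[str, object]] = None,
           ) -> tuple[GenotypeMatrix, SampleTable, QCReport]:
    """Run the full QC cascade and attach PC scores to the sample table.

    Order: missingness → MAF → HWE → optional ``drop`` (column, value)
    sample exclusion → PCA.  Each filter operates on the survivors of the
    previous one; rerunning the cascade on its own output removes nothing.
    """
    report = QCReport()
    G, S, _ = filter_missingness(G, S, miss_thr, report)
    G, _ = filter_maf(G, maf_thr, report)
    G, _ = filter_hwe(G, hwe_thr, report)
    if drop is not None:
        S, _ = drop_samples_where(S, drop[0], drop[1], report)
        G, S = S.align_to(G)
    G, S = S.align_to(G)
    k = min(n_pcs, G.n_samples, G.n_snps)
    pcs = compute_pcs(G, k)
    data = S.data.join(pcs)
    covs = list(S.covariates) + [c for c in pcs.columns if c not in S.covariates]
    report.add("pca", n_pcs=k)
    return G, SampleTable(data, S.outcome, covs, dict(S.categorical_levels)), report
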