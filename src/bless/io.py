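"""Core data containers and the text formats the tool reads and writes.

Genotypes are additive dosages: 0, 1 or 2 copies of a coded allele per
sample, with ``NA`` marking missing calls.  Two input dialects are
supported: the PLINK ``.raw`` additive text export (``FID IID PAT MAT SEX
PHENOTYPE`` metadata columns followed by one ``<rsid>_<allele>`` column per
SNP) and a plain delimited sample×SNP matrix with a header row.  Binary
PLINK files and VCF are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "SampleTable",
    "ResultRow",
    "read_genotypes",
    "read_sample_table",
    "write_ranked_list",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the 0/1/2/NA dosage contract."""


@dataclass
class GenotypeMatrix:
    """An n×p additive-coded genotype matrix with a missingness mask.

    Parameters
    ----------
    samples : ordered sample identifiers (unique).
    snps : ordered SNP identifiers (unique).
    dosages : float array of shape ``(len(samples), len(snps))``; entries are
        0.0, 1.0, 2.0 or NaN (missing).
    coded_allele : optional mapping from SNP ID to the counted allele label,
        populated when reading PLINK ``.raw`` headers such as ``rs123_A``.
    """

    samples: list[str]
    snps: list[str]
    dosages: np.ndarray
    coded_allele: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.samples = [str(s) for s in self.samples]
        self.snps = [str(s) for s in self.snps]
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP IDs")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"non-{{0,1,2}} dosage value {bad!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def snp_index(self, snp: str) -> int:
        try:
            return self.snps.index(snp)
        except ValueError:
            raise KeyError(f"unknown SNP ID {snp!r}") from None

    def dosage_vector(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp)]

    def subset(
        self,
        samples: Optional[Sequence[str]] = None,
        snps: Optional[Sequence[str]] = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given IDs, in the given order."""
        samples = list(self.samples) if samples is None else [str(s) for s in samples]
        snps = list(self.snps) if snps is None else [str(s) for s in snps]
        srow = {s: i for i, s in enumerate(self.samples)}
        scol = {s: j for j, s in enumerate(self.snps)}
        rows = [srow[s] for s in samples]
        cols = [scol[s] for s in snps]
        alleles = None
        if self.coded_allele is not None:
            alleles = {s: self.coded_allele[s] for s in snps if s in self.coded_allele}
        return GenotypeMatrix(samples, snps, self.dosages[np.ix_(rows, cols)], alleles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.snps)


@dataclass
class SampleTable:
    """Per-sample outcome and covariates, indexed by sample ID.

    The outcome column is expected to be binary {0,1} for model fitting;
    raw scales (e.g. the 5-point CDR) are carried as-is until dichotomized
    by the QC layer.  Categorical covariates keep their observed level sets
    so that dummy coding is stable across subsamples.
    """

    data: pd.DataFrame
    outcome: str
    covariates: list[str] = field(default_factory=list)
    categorical_levels: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if self.outcome not in self.data.columns:
            raise KeyError(
                f"outcome column {self.outcome!r} not in "
                f"{list(self.data.columns)}"
            )
        missing = [c for c in self.covariates if c not in self.data.columns]
        if missing:
            raise KeyError(
                f"covariate column(s) {missing} not in {list(self.data.columns)}"
            )
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def outcome_vector(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        s = self.data[self.outcome] if samples is None else self.data.loc[list(samples), self.outcome]
        return np.asarray(s, dtype=float)

    def align_to(self, genotypes: GenotypeMatrix) -> tuple[GenotypeMatrix, "SampleTable"]:
        """Join with a genotype matrix by sample ID (never by row order).

        Returns both objects restricted to the shared samples, in the
        genotype matrix's sample order.
        """
        shared = [s for s in genotypes.samples if s in self.data.index]
        if not shared:
            raise ValueError("no shared sample IDs between genotypes and sample table")
        g = genotypes.subset(samples=shared)
        t = SampleTable(
            self.data.loc[shared],
            self.outcome,
            list(self.covariates),
            dict(self.categorical_levels),
        )
        return g, t


@dataclass
class ResultRow:
    """One row of a ranked association result list."""

    snp: str
    statistic: Optional[float]
    raw_p: Optional[float]
    adjusted_p: Optional[float]
    rank: Optional[int]
    method: str
    selection_count: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("raw_p", "adjusted_p"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def _parse_dosage_frame(df: pd.DataFrame, path) -> np.ndarray:
    """Validate a raw string/numeric frame as {0,1,2,NA} dosages."""
    arr = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        # entries that are neither numeric nor NA-like are parse errors
        na_like = vals.isna() | vals.astype(str).str.strip().isin(["NA", "nan", ""])
        bad = numeric.isna() & ~na_like
        if not bad.any():
            ok = numeric.isin([0, 1, 2]) | numeric.isna()
            bad = ~ok
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise GenotypeParseError(
                f"{path}: invalid dosage {vals.iloc[i]!r} for SNP column "
                f"{col!r}, sample row {df.index[i]!r} (expected 0, 1, 2 or NA)"
            )
        arr[:, j] = numeric.to_numpy(dtype=float)
    return arr


def read_genotypes(path, format: str = "matrix_csv") -> GenotypeMatrix:
    """Read an additive-dosage genotype matrix.

    Parameters
    ----------
    path : file path.
    format : ``"plink_raw"`` for the PLINK ``.raw`` whitespace-delimited
        additive export, or ``"matrix_csv"`` for a delimited sample×SNP
        matrix whose first column holds sample IDs.

    In the ``plink_raw`` dialect the six leading metadata columns are
    consumed (IID becomes the sample ID) and headers of the form
    ``<rsid>_<allele>`` are split into SNP ID and coded allele; a header
    without the suffix is accepted with no allele recorded.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=["NA"])
        missing_meta = [c for c in _PLINK_META_COLS if c not in df.columns]
        if missing_meta:
            raise GenotypeParseError(
                f"{path}: not a PLINK .raw export — missing columns {missing_meta}"
            )
        samples = df["IID"].astype(str).tolist()
        snp_cols = [c for c in df.columns if c not in _PLINK_META_COLS]
        snps, alleles = [], {}
        for c in snp_cols:
            rsid, sep, allele = c.rpartition("_")
            if sep and rsid:
                snps.append(rsid)
                alleles[rsid] = allele
            else:
                snps.append(c)
        dosages = _parse_dosage_frame(df[snp_cols].set_axis(samples, axis=0), path)
        return GenotypeMatrix(samples, snps, dosages, alleles or None)
    if format == "matrix_csv":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str,
                         na_values=["NA"])
        samples = df.index.astype(str).tolist()
        snps = [str(c) for c in df.columns]
        dosages = _parse_dosage_frame(df, path)
        return GenotypeMatrix(samples, snps, dosages)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write a matrix_csv file that :func:`read_genotypes` round-trips exactly."""
    df = G.to_frame()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "sample"
    out.to_csv(path)


def read_sample_table(path, outcome_col: str,
                      covariate_cols: Iterable[str] = ()) -> SampleTable:
    """Read a delimited per-sample table (first column = sample ID).

    Categorical (non-numeric) covariates are recorded with their observed
    level sets.  The outcome is left untouched; dichotomization is a QC
    operation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty sample table")
    covariate_cols = list(covariate_cols)
    missing = [c for c in [outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise KeyError(
            f"{path}: column(s) {missing} not found; available: {list(df.columns)}"
        )
    levels: dict[str, list] = {}
    for c in covariate_cols:
        if not pd.api.types.is_numeric_dtype(df[c]):
            levels[c] = sorted(df[c].dropna().unique().tolist())
    return SampleTable(df, outcome_col, covariate_cols, levels)


def write_ranked_list(rows: Sequence[ResultRow], path,
                      display_threshold: float = 1e-3) -> None:
    """Write a ranked association list as TSV.

    Columns: ``Feature``, ``FDR adjusted p-value`` (display string, values
    below ``display_threshold`` rendered ``<0.001``), ``AdjustedP``
    (full-precision numeric), ``Marginal p-value`` (when any row carries
    one), ``Rank`` and ``SelectionCount`` (when any row carries one).
    Rows must already be ranked 1..n in order.
    """
    rows = list(rows)
    ranks = [r.rank for r in rows]
    if any(r is None for r in ranks) or ranks != sorted(ranks) or (
            rows and ranks != list(range(1, len(rows) + 1))):
        raise ValueError("rows must carry dense ascending ranks 1..n before writing")
    have_marginal = any(r.raw_p is not None for r in rows)
    have_selcount = any(r.selection_count is not None for r in rows)
    cols = ["Feature", "FDR adjusted p-value", "AdjustedP"]
    if have_marginal:
        cols.append("Marginal p-value")
    cols += ["Rank"] + (["SelectionCount"] if have_selcount else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            disp = (
                "<0.001"
                if r.adjusted_p is not None and r.adjusted_p < display_threshold
                else ("" if r.adjusted_p is None else repr(r.adjusted_p))
            )
            fields = [r.snp, disp,
                      "" if r.adjusted_p is None else repr(r.adjusted_p)]
            if have_marginal:
                fields.append("" if r.raw_p is None else repr(r.raw_p))
            fields.append(str(r.rank))
            if have_selcount:
                fields.append("" if r.selection_count is None else str(r.selection_count))
            fh.write("\t".join(fields) + "\n")
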