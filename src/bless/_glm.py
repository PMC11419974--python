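"""Shared logistic-regression plumbing for the SNP-wise baseline and the
ensemble base learners: design-matrix assembly with stable categorical
coding, and a guarded maximum-likelihood fit that reports convergence and
separation instead of fabricating p-values."""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

# |coef| beyond this on the logit scale is treated as (quasi-)separation:
# an odds ratio above e^15 ~ 3e6 is never a finite-MLE outcome at GWAS scale.
SEPARATION_COEF_BOUND = 15.0


def covariate_design(S, covariates: Sequence[str],
                     samples: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Numeric covariate block with dummy coding fixed by the recorded level
    sets, so the same columns appear in every subsample."""
    df = S.data if samples is None else S.data.loc[list(samples)]
    blocks = []
    for c in covariates:
        col = df[c]
        levels = S.categorical_levels.get(c)
        if levels is None and not pd.api.types.is_numeric_dtype(col):
            levels = sorted(col.dropna().unique().tolist())
        if levels is not None:
            # reference level = first; one indicator per remaining level
            for lev in levels[1:]:
                blocks.append(pd.Series((col == lev).astype(float),
                                        name=f"{c}[{lev}]", index=df.index))
        else:
            blocks.append(col.astype(float))
    if not blocks:
        return pd.DataFrame(index=df.index)
    return pd.concat(blocks, axis=1)


def fit_logit(y: np.ndarray, X: np.ndarray, maxiter: int = 100):
    """Fit a logistic regression by Newton's method.

    Returns ``(params, bse, pvalues, ok, reason)``; ``ok`` is False (with
    arrays of NaN) on non-convergence or detected separation.
    """
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation reported via `reason`
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, disp=0,
                                     warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        k = X.shape[1]
        nan = np.full(k, np.nan)
        return nan, nan, nan, False, "separation"
    except Exception as exc:  # singular Hessian etc.
        k = X.shape[1]
        nan = np.full(k, np.nan)
        return nan, nan, nan, False, f"fit_failed:{type(exc).__name__}"
    if not res.mle_retvals.get("converged", False):
        return res.params, res.bse, res.pvalues, False, "nonconvergence"
    if np.any(np.abs(res.params) > SEPARATION_COEF_BOUND) or np.any(
            ~np.isfinite(res.bse)):
        return res.params, res.bse, res.pvalues, False, "separation"
    return res.params, res.bse, res.pvalues, True, ""
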