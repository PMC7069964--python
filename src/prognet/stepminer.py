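"""One-step function fitting for adaptive expression thresholds.

StepMiner-style dichotomization: sort a gene's expression values, fit a
single rising step (low plateau -> high plateau) by least squares over all
possible split positions, and use the midpoint between the two plateau
means as the threshold separating biomarker- from biomarker+ patients.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StepFit", "fit_step", "dichotomize"]


@dataclass(frozen=True)
class StepFit:
    """Result of fitting a one-step function to a sorted value vector.

    ``split_index`` is the number of values assigned to the low plateau
    (1..n-1); ``threshold`` is the midpoint of the two plateau means.
    ``degenerate`` is set when every value is identical, in which case no
    meaningful two-way split exists.
    """

    gene_id: str
    threshold: float
    split_index: int
    low_mean: float
    high_mean: float
    sse: float
    degenerate: bool = False


def fit_step(values, gene_id: str = "") -> StepFit:
    """Fit the least-squares one-step function to ``values``.

    For every split position k (1..n-1) on the ascending-sorted vector the
    step SSE is ``sum((v_i - mean_low)^2, i<=k) + sum((v_i - mean_high)^2,
    i>k)``; the returned fit minimizes this, breaking ties toward the
    smallest k. Requires n >= 2 finite values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("step fit requires at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("step fit requires finite values")
    s = np.sort(v)
    n = s.size
    if s[0] == s[-1]:
        return StepFit(gene_id, float(s[0]), 0, float(s[0]), float(s[0]), 0.0,
                       degenerate=True)
    c = np.cumsum(s)
    csq = np.cumsum(s * s)
    k = np.arange(1, n)
    low_mean = c[:-1] / k
    high_mean = (c[-1] - c[:-1]) / (n - k)
    sse = (csq[:-1] - k * low_mean**2) + (csq[-1] - csq[:-1] - (n - k) * high_mean**2)
    # smallest split index among (numerically) tied minima; the cumsum
    # formula can split exact ties at the 1e-16 level
    tol = 1e-9 * max(1.0, float(np.ptp(s)) ** 2)
    i = int(np.flatnonzero(sse <= sse.min() + tol)[0])
    lo, hi = float(low_mean[i]), float(high_mean[i])
    return StepFit(gene_id, (lo + hi) / 2.0, i + 1, lo, hi, float(max(sse[i], 0.0)))


def dichotomize(expression: pd.DataFrame, gene_id: str) -> pd.Series:
    """Split samples into biomarker+ / biomarker- by the gene's step fit.

    Parameters
    ----------
    expression : DataFrame, genes x samples (log2 units).
    gene_id : row to dichotomize on.

    Returns a boolean Series indexed by sample ID, True = biomarker+
    (expression strictly greater than the fitted threshold). Raises if the
    fit is degenerate; callers should drop such biomarkers.
    """
    if gene_id not in expression.index:
        raise KeyError(f"gene {gene_id!r} not in expression matrix")
    fit = fit_step(expression.loc[gene_id].to_numpy(), gene_id)
    if fit.degenerate:
        raise ValueError(
            f"gene {gene_id!r} has constant expression; drop this biomarker")
    return pd.Series(expression.loc[gene_id].to_numpy() > fit.threshold,
                     index=expression.columns, name=gene_id)
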