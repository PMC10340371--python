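"""Genome-wide univariate Cox scans and p-value distribution summaries.

For each gene, expression is z-scored within the analysis group (so hazard
ratios are per SD of expression and comparable across genes) and a
cohort-stratified univariate Cox model is fitted.  Under the global null,
the resulting p-values are uniform; an excess below 0.05 quantifies how much
of the transcriptome correlates with outcome, which is the baseline any
radiosensitivity signature has to beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import AnalysisGroup, cox_scan


@dataclass
class GeneScanResult:
    """Per-gene hazard ratios from a univariate scan of one group."""

    table: pd.DataFrame          # gene-indexed: hr, log_hr, se, p, converged
    group_label: str
    n_genes_tested: int
    n_failed: int

    def converged_pvals(self) -> np.ndarray:
        ok = self.table["converged"]
        return self.table.loc[ok, "p"].to_numpy()


def univariate_scan(group: AnalysisGroup, expr: pd.DataFrame,
                    ties: str = "efron") -> GeneScanResult:
    """Fit one stratified Cox model per gene over the group's patients.

    Zero-variance and non-converging genes are flagged (``converged=False``)
    and excluded from downstream summaries; their counts are reported.
    """
    if expr.shape[0] == 0:
        raise ValueError("no genes in expression matrix")
    pats = group.patients
    missing = pats.index.difference(expr.columns)
    if len(missing):
        raise ValueError(f"expression missing for patients: {list(missing[:5])}")
    X = expr[pats.index].to_numpy(dtype=float)  # genes x n
    sd = X.std(axis=1, ddof=1)
    usable = sd > 0
    Z = np.zeros((len(pats), X.shape[0]))
    Z[:, usable] = ((X[usable] - X[usable].mean(axis=1, keepdims=True))
                    / sd[usable, None]).T

    beta = np.full(X.shape[0], np.nan)
    se = np.full(X.shape[0], np.nan)
    p = np.full(X.shape[0], np.nan)
    conv = np.zeros(X.shape[0], dtype=bool)
    if usable.any():
        b, s, pv, cv = cox_scan(pats["time"].to_numpy(),
                                pats["event"].to_numpy(),
                                Z[:, usable], pats["cohort_id"].to_numpy(),
                                ties=ties)
        beta[usable], se[usable], p[usable], conv[usable] = b, s, pv, cv

    table = pd.DataFrame(
        {"hr": np.where(conv, np.exp(beta), np.nan),
         "log_hr": np.where(conv, beta, np.nan),
         "se": se, "p": np.where(conv, p, np.nan), "converged": conv},
        index=expr.index)
    return GeneScanResult(table=table, group_label=group.label,
                          n_genes_tested=int(X.shape[0]),
                          n_failed=int((~conv).sum()))


def pvalue_uniformity(pvals) -> tuple[float, float]:
    """One-sample KS test of p-values against U(0, 1).

    Returns (D, p).  Exact small-sample p for n < 50, asymptotic otherwise.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) < 5:
        raise ValueError("need >= 5 p-values")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    method = "exact" if len(p) < 50 else "asymp"
    res = stats.kstest(p, "uniform", method=method)
    return float(res.statistic), float(res.pvalue)


def proportion_significant(pvals, alpha: float = 0.05) -> float:
    """Fraction of p-values strictly below ``alpha``."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if len(p) == 0:
        raise ValueError("empty p-value list")
    return float((p < alpha).mean())
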