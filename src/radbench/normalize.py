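"""Probe-level normalization and the Bland-Altman agreement statistic.

Three normalization-and-summarization pipelines are provided, modelled on
the algorithms used interchangeably in the microarray literature:

* MAS5-style: per-array trimmed-mean scaling to a target intensity, then a
  one-step Tukey biweight summary of log2 probe intensities per gene.
* RMA-style: probe-level quantile normalization across arrays, log2, then a
  per-gene median polish (gene value = overall + array effect).  The RMA
  background-correction convolution model is deliberately out of scope; the
  question addressed here is rank agreement, not absolute accuracy.
* IRON-style: a reference array is chosen by mean Spearman correlation, each
  other array is corrected by a running-median smooth of log-ratio vs mean
  log-intensity fitted on an iteratively pruned rank-invariant probe set,
  then summarized with the same Tukey biweight.

All three emit log2-scale gene x array matrices so downstream within-sample
rank operations are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, trim_mean

from .synthdata import ProbeLevelArraySet

TUKEY_C = 5.0
TUKEY_EPS = 1e-4


@dataclass
class NormalizedExpression:
    expr: pd.DataFrame            # genes x arrays, log2
    method: str                   # mas5_style | rma_style | iron_style
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.expr.to_numpy()).all():
            raise ValueError("normalized expression contains non-finite values")


@dataclass
class AgreementResult:
    """Bland-Altman limits of agreement for paired per-sample scores."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int

    @property
    def width(self) -> float:
        return self.loa_upper - self.loa_lower


def tukey_biweight(x, c: float = TUKEY_C, eps: float = TUKEY_EPS) -> float:
    """One-step Tukey biweight location estimate of a 1-D sample."""
    return float(_biweight_cols(np.asarray(x, dtype=float)[:, None], c, eps)[0])


def _biweight_cols(mat: np.ndarray, c: float = TUKEY_C,
                   eps: float = TUKEY_EPS) -> np.ndarray:
    """One-step biweight down each column of a probes x arrays block."""
    m = np.median(mat, axis=0)
    s = np.median(np.abs(mat - m), axis=0)
    u = (mat - m) / (c * s + eps)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return (w * mat).sum(axis=0) / w.sum(axis=0)


def _summarize_biweight(log2_intensities: pd.DataFrame,
                        probe_to_gene: pd.Series) -> pd.DataFrame:
    """Summarize log2 probe intensities to gene level (biweight per gene)."""
    genes_per_probe = probe_to_gene.loc[log2_intensities.index]
    gene_order = list(pd.unique(genes_per_probe))
    vals = log2_intensities.to_numpy(dtype=float)
    out = np.empty((len(gene_order), vals.shape[1]))
    codes = pd.Categorical(genes_per_probe, categories=gene_order).codes
    for gi in range(len(gene_order)):
        block = vals[codes == gi]
        if block.shape[0] < 1:
            raise ValueError(f"gene {gene_order[gi]} has no probes")
        out[gi] = _biweight_cols(block)
    return pd.DataFrame(out, index=gene_order, columns=log2_intensities.columns)


def normalize_mas5_style(arrays: ProbeLevelArraySet,
                         trim_frac: float = 0.02,
                         target: float = 500.0) -> NormalizedExpression:
    """Trimmed-mean scaling to ``target`` plus one-step biweight summary."""
    inten = arrays.intensities
    if inten.shape[0] < 1:
        raise ValueError("array with no mapped probes")
    vals = inten.to_numpy(dtype=float)
    tm = np.array([trim_mean(vals[:, j], proportiontocut=trim_frac)
                   for j in range(vals.shape[1])])
    scaled = vals * (target / tm)[None, :]
    log2 = pd.DataFrame(np.log2(scaled), index=inten.index, columns=inten.columns)
    expr = _summarize_biweight(log2, arrays.probe_to_gene)
    return NormalizedExpression(expr=expr, method="mas5_style",
                                provenance={"trim_frac": trim_frac,
                                            "target": target})


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Replace each array's sorted values by across-array means of order
    statistics; tied values within an array receive the mean of the
    across-array means at their tied ranks."""
    X = df.to_numpy(dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("quantile normalization requires >= 2 arrays")
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        x = X[:, j]
        order = np.argsort(x, kind="stable")
        col = np.empty(n)
        col[order] = ref
        uniq, inv = np.unique(x, return_inverse=True)
        if len(uniq) < n:  # average within tied blocks
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def median_polish(table: np.ndarray, max_iter: int = 10,
                  tol: float = 0.01) -> tuple[float, np.ndarray, np.ndarray]:
    """Two-way median polish; returns (overall, row effects, col effects)."""
    z = np.asarray(table, dtype=float).copy()
    p, a = z.shape
    overall, row, col = 0.0, np.zeros(p), np.zeros(a)
    oldsum = 0.0
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        overall += delta
        col -= delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        overall += delta
        row -= delta
        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * newsum:
            break
        oldsum = newsum
    return overall, row, col


def normalize_rma_style(arrays: ProbeLevelArraySet,
                        polish_max_iter: int = 10,
                        polish_tol: float = 0.01) -> NormalizedExpression:
    """Quantile normalization, log2, per-gene median polish across arrays."""
    inten = arrays.intensities
    if inten.shape[1] < 2:
        raise ValueError("RMA-style normalization requires >= 2 arrays")
    qn = quantile_normalize(inten)
    log2 = np.log2(qn.to_numpy(dtype=float))

    genes_per_probe = arrays.probe_to_gene.loc[inten.index]
    gene_order = list(pd.unique(genes_per_probe))
    codes = pd.Categorical(genes_per_probe, categories=gene_order).codes
    out = np.empty((len(gene_order), log2.shape[1]))
    for gi in range(len(gene_order)):
        block = log2[codes == gi]
        overall, _, col = median_polish(block, polish_max_iter, polish_tol)
        out[gi] = overall + col
    expr = pd.DataFrame(out, index=gene_order, columns=inten.columns)
    return NormalizedExpression(expr=expr, method="rma_style",
                                provenance={"polish_max_iter": polish_max_iter,
                                            "polish_tol": polish_tol})


def _select_reference(log2: np.ndarray) -> int:
    """Index of the array maximizing mean Spearman correlation with the rest."""
    ranks = rankdata(log2, axis=0)
    corr = np.corrcoef(ranks, rowvar=False)
    np.fill_diagonal(corr, np.nan)
    return int(np.nanargmax(np.nanmean(corr, axis=0)))


def _running_median(sorted_d: np.ndarray, window: int) -> np.ndarray:
    return (pd.Series(sorted_d)
            .rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def normalize_iron_style(arrays: ProbeLevelArraySet,
                         invariant_frac: float = 0.9,
                         n_prune_iters: int = 3) -> NormalizedExpression:
    """Reference-based rank-invariant normalization with a running-median
    correction curve, then biweight summarization.

    For each non-reference array: probes are pruned ``n_prune_iters`` times,
    keeping the ``invariant_frac`` with smallest absolute rank difference vs
    the reference; the log-ratio vs mean log-intensity relation on the
    surviving probes is smoothed by a running median (window = 5% of the
    invariant probes, at least 11) and the interpolated smooth is subtracted.
    """
    inten = arrays.intensities
    if inten.shape[1] < 2:
        raise ValueError("IRON-style normalization requires >= 2 arrays")
    log2 = np.log2(inten.to_numpy(dtype=float))
    n_probes, n_arrays = log2.shape
    ref = _select_reference(log2)
    y = log2[:, ref]

    corrected = log2.copy()
    for a in range(n_arrays):
        if a == ref:
            continue
        x = log2[:, a]
        idx = np.arange(n_probes)
        for _ in range(n_prune_iters):
            ra = rankdata(x[idx])
            rr = rankdata(y[idx])
            diff = np.abs(ra - rr)
            keep = max(int(np.ceil(invariant_frac * len(idx))), 1)
            idx = idx[np.argsort(diff, kind="stable")[:keep]]
        if len(idx) < 50:
            raise ValueError(
                f"only {len(idx)} invariant probes for array "
                f"{inten.columns[a]!r}; need >= 50 for curve fitting")
        m = (x[idx] + y[idx]) / 2.0
        d = x[idx] - y[idx]
        order = np.argsort(m, kind="stable")
        m_sorted, d_sorted = m[order], d[order]
        window = max(11, int(0.05 * len(idx)))
        smooth = _running_median(d_sorted, window)
        m_all = (x + y) / 2.0
        # np.interp needs strictly usable x-grid; collapse duplicate m values
        grid, first = np.unique(m_sorted, return_index=True)
        correction = np.interp(m_all, grid, smooth[first])
        corrected[:, a] = x - correction

    log2_df = pd.DataFrame(corrected, index=inten.index, columns=inten.columns)
    expr = _summarize_biweight(log2_df, arrays.probe_to_gene)
    return NormalizedExpression(
        expr=expr, method="iron_style",
        provenance={"invariant_frac": invariant_frac,
                    "n_prune_iters": n_prune_iters,
                    "reference": str(inten.columns[ref])})


def bland_altman(scores_a, scores_b) -> AgreementResult:
    """Limits of agreement: mean difference +/- 1.96 SD of differences."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 paired samples")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(mean_diff=mean, sd_diff=sd,
                           loa_lower=mean - 1.96 * sd,
                           loa_upper=mean + 1.96 * sd, n=len(d))
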