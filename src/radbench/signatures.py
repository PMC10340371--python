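"""Radiosensitivity signature models.

Two published model forms are supported:

* ``rank_linear`` — ordinary least squares of SF2 on the within-sample
  rankings of the signature genes (the construction behind the 10-gene
  radiosensitivity index, RSI).  Because only ranks enter, predictions are
  invariant to any strictly increasing per-sample transform of expression;
  normalization methods can only change scores by reordering genes within a
  sample.
* ``pcr`` — principal components regression of SF2 on centered and unit
  scaled expression (used for the 31-gene signature, for which no predictive
  model was ever published).

Signatures are trained on a :class:`~radbench.synthdata.CellLinePanel` and
applied to any gene x sample expression matrix via :func:`score`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthdata import CellLinePanel

MODEL_FORMS = ("rank_linear", "pcr")
RANK_SCOPES = ("signature", "array")


@dataclass
class Signature:
    """A gene list plus a fitted (or pending) predictive model.

    For ``rank_linear``: ``intercept`` and one coefficient per gene rank.
    For ``pcr``: per-gene ``center``/``scale`` vectors, a components x genes
    ``loadings`` matrix, ``intercept`` and per-component ``coefficients``.
    ``coefficients is None`` marks an untrained gene-list stub.
    Rank orientation is fixed low-to-high (1 = lowest expression within the
    sample) and recorded in ``training_meta``.
    """

    signature_id: str
    genes: list[str]
    model_form: str
    intercept: float | None = None
    coefficients: np.ndarray | None = None
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    loadings: np.ndarray | None = None
    n_components: int | None = None
    rank_scope: str = "signature"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_form not in MODEL_FORMS:
            raise ValueError(f"unknown model_form: {self.model_form}")
        if self.rank_scope not in RANK_SCOPES:
            raise ValueError(f"unknown rank_scope: {self.rank_scope}")
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate signature genes: {dupes}")
        if (self.model_form == "rank_linear" and self.coefficients is not None
                and len(self.coefficients) != len(self.genes)):
            raise ValueError("rank_linear needs one coefficient per gene")
        self.training_meta.setdefault("rank_orientation", "1=lowest")

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def is_trained(self) -> bool:
        return self.coefficients is not None


@dataclass
class ScoreVector:
    """Per-sample predicted radiosensitivity (SF2 scale, unitless)."""

    values: pd.Series
    signature_id: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("scores contain non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)


def _panel_hash(panel: CellLinePanel) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(panel.expr.to_numpy()).tobytes())
    h.update(np.ascontiguousarray(panel.sf2.to_numpy()).tobytes())
    return h.hexdigest()[:16]


def rank_transform(expr: pd.DataFrame, genes: list[str],
                   rank_scope: str = "signature") -> pd.DataFrame:
    """Within-sample ranks of the signature genes (1 = lowest, ties = mean).

    ``rank_scope='signature'`` ranks the k genes among themselves;
    ``'array'`` ranks within the full matrix and then subsets.
    """
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")
    if rank_scope == "signature":
        sub = expr.loc[list(genes)].to_numpy(dtype=float)
        ranks = rankdata(sub, axis=0)
    elif rank_scope == "array":
        full = rankdata(expr.to_numpy(dtype=float), axis=0)
        pos = [expr.index.get_loc(g) for g in genes]
        ranks = full[pos]
    else:
        raise ValueError(f"unknown rank_scope: {rank_scope}")
    return pd.DataFrame(ranks, index=list(genes), columns=expr.columns)


def train_rank_linear(panel: CellLinePanel, genes: list[str],
                      rank_scope: str = "signature",
                      signature_id: str | None = None) -> Signature:
    """OLS of SF2 on the within-line rankings of ``genes``.

    With ``rank_scope='signature'`` the k rank columns always sum to
    k(k+1)/2 within a line, so intercept and coefficients are identified
    only up to a gauge; the sum-zero-coefficient convention is imposed
    (coefficients sum to 0, the intercept absorbs the rest), which leaves
    predictions untouched and makes coefficients exactly recoverable.
    """
    genes = list(genes)
    k = len(genes)
    n = len(panel.line_ids)
    if n < k + 2:
        raise ValueError(f"need >= k+2 = {k + 2} lines, have {n}")
    R = rank_transform(panel.expr, genes, rank_scope).to_numpy()
    X = np.column_stack([np.ones(n), R.T])
    intrinsic = k if rank_scope == "signature" else k + 1
    if np.linalg.matrix_rank(X) < intrinsic:
        const = [genes[i] for i in range(k) if np.ptp(R[i]) == 0]
        detail = f" (constant-rank genes: {const})" if const else ""
        raise ValueError(f"rank-deficient design{detail}")
    coef, *_ = np.linalg.lstsq(X, panel.sf2.to_numpy(), rcond=None)
    if rank_scope == "signature":
        # gauge fix: shifting all rank coefficients by c and the intercept
        # by -c*k(k+1)/2 leaves predictions unchanged; pick sum(coef)=0
        shift = coef[1:].mean()
        coef = coef.copy()
        coef[1:] -= shift
        coef[0] += shift * (k * (k + 1) / 2.0)
    fitted = X @ coef
    resid = panel.sf2.to_numpy() - fitted
    ss_tot = np.sum((panel.sf2 - panel.sf2.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return Signature(
        signature_id=signature_id or f"rank_linear_k{k}",
        genes=genes, model_form="rank_linear",
        intercept=float(coef[0]), coefficients=coef[1:],
        rank_scope=rank_scope,
        training_meta={"r2": float(r2), "n_lines": n,
                       "panel_hash": _panel_hash(panel)})


def train_pcr(panel: CellLinePanel, genes: list[str],
              variance_threshold: float = 0.8, max_components: int = 10,
              signature_id: str | None = None) -> Signature:
    """Principal components regression of SF2 on centered/scaled expression.

    The number of components is the smallest reaching cumulative explained
    variance >= ``variance_threshold``, capped at ``max_components`` and at
    the data rank.  With all components retained, PCR predictions coincide
    with full OLS on the scaled genes.
    """
    genes = list(genes)
    k = len(genes)
    n = len(panel.line_ids)
    if n < 5:
        raise ValueError(f"need >= 5 lines for PCR, have {n}")
    missing = [g for g in genes if g not in panel.expr.index]
    if missing:
        raise ValueError(f"genes missing from panel: {missing}")
    X = panel.expr.loc[genes].to_numpy().T  # lines x k
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    zero_var = [genes[i] for i in range(k) if scale[i] == 0]
    if zero_var:
        raise ValueError(f"zero-variance genes: {zero_var}")
    Xs = (X - center) / scale
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    pos = S > S[0] * 1e-12 if S[0] > 0 else S > 0
    S, Vt = S[pos], Vt[pos]
    explained = S**2 / (S**2).sum()
    cum = np.cumsum(explained)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, max_components, len(S), n - 1)
    loadings = Vt[:n_comp]
    scores = Xs @ loadings.T
    D = np.column_stack([np.ones(n), scores])
    coef, *_ = np.linalg.lstsq(D, panel.sf2.to_numpy(), rcond=None)
    fitted = D @ coef
    ss_tot = np.sum((panel.sf2 - panel.sf2.mean()) ** 2)
    r2 = (1.0 - np.sum((panel.sf2.to_numpy() - fitted) ** 2) / ss_tot
          if ss_tot > 0 else 1.0)
    return Signature(
        signature_id=signature_id or f"pcr_k{k}",
        genes=genes, model_form="pcr",
        intercept=float(coef[0]), coefficients=coef[1:],
        center=center, scale=scale, loadings=loadings, n_components=n_comp,
        training_meta={"r2": float(r2), "n_lines": n,
                       "explained_variance": explained[:n_comp].tolist(),
                       "variance_threshold": variance_threshold,
                       "panel_hash": _panel_hash(panel)})


def score(sig: Signature, expr: pd.DataFrame) -> ScoreVector:
    """Apply a trained signature to a genes x samples matrix.

    Predictions are not clipped to (0, 1): downstream survival analysis
    z-scores them, so scale and range are irrelevant there.
    """
    if not sig.is_trained:
        raise ValueError(f"signature {sig.signature_id!r} is an untrained stub")
    missing = [g for g in sig.genes if g not in expr.index]
    if missing:
        raise ValueError(f"genes missing from expression matrix: {missing}")
    if sig.model_form == "rank_linear":
        R = rank_transform(expr, sig.genes, sig.rank_scope).to_numpy()
        vals = sig.intercept + sig.coefficients @ R
    else:
        X = expr.loc[sig.genes].to_numpy().T
        Xs = (X - sig.center) / sig.scale
        vals = sig.intercept + (Xs @ sig.loadings.T) @ sig.coefficients
    return ScoreVector(values=pd.Series(vals, index=expr.columns,
                                        name=sig.signature_id),
                       signature_id=sig.signature_id)


def load_published_signature(path, signature_id: str | None = None) -> Signature:
    """Read a signature file: optional ``#key=value;...`` header, then TSV
    rows ``gene_id[<tab>coefficient]``.  A file without coefficients yields
    an untrained stub requiring :func:`train_rank_linear` / :func:`train_pcr`.
    An ``intercept`` header key supplies the intercept for coefficient files.
    """
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for part in line.lstrip("#").split(";"):
                    if "=" in part:
                        key, val = part.split("=", 1)
                        meta[key.strip()] = val.strip()
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"empty signature file: {path}")
    if rows[0][0].lower() in ("gene_id", "gene"):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"signature file has a header but no genes: {path}")
    genes = [r[0] for r in rows]
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate genes in signature file: {dupes}")
    has_coef = all(len(r) >= 2 and r[1] != "" for r in rows)
    model_form = meta.get("model_form", "rank_linear")
    rank_scope = meta.get("rank_scope", "signature")
    sid = signature_id or meta.get("signature_id", f"published_k{len(genes)}")
    if not has_coef:
        return Signature(signature_id=sid, genes=genes, model_form=model_form,
                         rank_scope=rank_scope,
                         training_meta={"source": str(path), "stub": True})
    try:
        coefs = np.array([float(r[1]) for r in rows])
    except ValueError as exc:
        raise ValueError(f"non-numeric coefficient in {path}: {exc}") from exc
    intercept = float(meta.get("intercept", 0.0))
    return Signature(signature_id=sid, genes=genes, model_form="rank_linear",
                     intercept=intercept, coefficients=coefs,
                     rank_scope=rank_scope,
                     training_meta={"source": str(path)})


def write_signature(sig: Signature, path) -> None:
    with open(path, "w") as fh:
        header = f"#model_form={sig.model_form};rank_scope={sig.rank_scope}"
        if sig.is_trained and sig.model_form == "rank_linear":
            header += f";intercept={float(sig.intercept)!r}"
        header += f";signature_id={sig.signature_id}"
        fh.write(header + "\n")
        if sig.is_trained and sig.model_form == "rank_linear":
            for g, c in zip(sig.genes, sig.coefficients):
                fh.write(f"{g}\t{float(c)!r}\n")
        else:
            for g in sig.genes:
                fh.write(f"{g}\n")
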