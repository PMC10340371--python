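"""Gene-set enrichment: ORA, preranked GSEA on hazard ratios, term reduction.

Three complementary analyses connect signature genes and genome-wide scan
results to biological processes:

* Overrepresentation analysis (ORA): hypergeometric upper-tail test of the
  overlap between a signature gene list and each set, requiring a minimum
  overlap (default 2) to suppress false positives from tiny signatures.
* Preranked GSEA: weighted Kolmogorov-Smirnov-style running sum over a list
  of genes ranked by log hazard ratio (or by RT-vs-noRT log-HR differences),
  with an empirical gene-set permutation null.  Phenotype permutation is not
  possible here because the ranking metric is a precomputed per-gene HR.
* Term reduction: greedy clustering of significant sets by Jaccard overlap
  of member genes — a database-free stand-in for GO semantic similarity,
  reusing the conventional 0.7 threshold.

Benjamini-Hochberg adjustment is applied across sets within each analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets plus the scoreable universe."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        if len(set(self.universe)) != len(self.universe):
            raise ValueError("universe contains duplicate gene ids")

    def restricted(self) -> dict[str, list[str]]:
        """Sets intersected with the universe (original order preserved)."""
        uni = set(self.universe)
        return {name: [g for g in members if g in uni]
                for name, members in self.sets.items()}


@dataclass
class EnrichmentResult:
    table: pd.DataFrame          # per-set rows
    method: str                  # "ora" | "gsea"
    params: dict = field(default_factory=dict)


@dataclass
class TermClusterSet:
    """Greedy clusters of significant sets; each row is one cluster."""

    clusters: list[dict]         # {representative, members, score}
    similarity_threshold: float


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if len(p) == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ora(signature_genes, collection: GeneSetCollection,
        min_overlap: int = 2) -> EnrichmentResult:
    """Hypergeometric overrepresentation of a gene list in each set.

    Signature genes outside the universe are dropped with a warning.  Sets
    overlapping the signature in fewer than ``min_overlap`` genes are
    excluded before BH adjustment.
    """
    uni = set(collection.universe)
    if not uni:
        raise ValueError("empty universe")
    sig = list(dict.fromkeys(signature_genes))
    dropped = [g for g in sig if g not in uni]
    if dropped:
        warnings.warn(f"signature genes outside universe dropped: {dropped}")
    sig = [g for g in sig if g in uni]
    M, N = len(uni), len(sig)
    rows = []
    for name, members in collection.restricted().items():
        n = len(members)
        k = len(set(members) & set(sig))
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append({"set": name, "size": n, "overlap": k, "p": p})
    table = pd.DataFrame(rows, columns=["set", "size", "overlap", "p"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, method="ora",
                            params={"min_overlap": min_overlap,
                                    "universe_size": M,
                                    "signature_size": N})


def enrichment_score(metric: np.ndarray, hit_mask: np.ndarray,
                     weight_p: float = 1.0) -> float:
    """Signed GSEA enrichment score for one set on a ranked list.

    The running sum increments by |metric|^weight_p (normalized over hits)
    at hits and decrements by 1/(N - n_set) at misses; ES is the running-sum
    value of largest absolute deviation from zero.
    """
    metric = np.asarray(metric, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N = len(metric)
    n_set = int(hit_mask.sum())
    if n_set == 0 or n_set >= N:
        raise ValueError("set must be a non-empty strict subset of the list")
    w = np.abs(metric) ** weight_p
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit metrics exactly zero: fall back to equal weights
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (N - n_set)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _permutation_es(metric: np.ndarray, n_set: int, weight_p: float,
                    n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """ES values for random same-size gene sets (vectorized over perms)."""
    N = len(metric)
    w = np.abs(metric) ** weight_p
    pick = np.argsort(rng.random((n_perm, N)), axis=1)[:, :n_set]
    hits = np.zeros((n_perm, N), dtype=bool)
    np.put_along_axis(hits, pick, True, axis=1)
    hit_w = np.where(hits, w[None, :], 0.0)
    totals = hit_w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        hit_w[zero] = hits[zero].astype(float)
        totals = hit_w.sum(axis=1, keepdims=True)
    steps = hit_w / totals - (~hits) / (N - n_set)
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def gsea_preranked(ranked_genes, metric, collection: GeneSetCollection,
                   weight_p: float = 1.0, n_perm: int = 1000, seed: int = 0,
                   min_set: int = 5, max_set: int = 500) -> EnrichmentResult:
    """Preranked GSEA with a gene-set permutation null.

    ``ranked_genes`` must be ordered by ``metric`` descending (ties broken
    by stable input order upstream).  NES is ES divided by the mean
    same-sign permutation |ES|; the empirical p compares against same-sign
    permutation scores.
    """
    genes = list(ranked_genes)
    metric = np.asarray(metric, dtype=float)
    if len(genes) != len(metric):
        raise ValueError("ranked_genes and metric length mismatch")
    if not np.isfinite(metric).all():
        raise ValueError("non-finite ranking metric")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: permutation p unreliable")
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, members in collection.restricted().items():
        present = [g for g in members if g in pos]
        n_set = len(set(present))
        if n_set > N:
            raise ValueError(f"set {name} larger than ranked list")
        if not min_set <= n_set <= min(max_set, N - 1):
            continue
        hit = np.zeros(N, dtype=bool)
        hit[[pos[g] for g in present]] = True
        es = enrichment_score(metric, hit, weight_p)
        if n_set not in perm_cache:
            perm_cache[n_set] = _permutation_es(metric, n_set, weight_p,
                                                n_perm, rng)
        perm = perm_cache[n_set]
        same_sign = perm[perm >= 0] if es >= 0 else perm[perm < 0]
        if len(same_sign) == 0:
            p, nes = 1.0, np.nan
        else:
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.abs(same_sign).mean()
        rows.append({"set": name, "size": n_set, "es": es, "nes": nes,
                     "p": float(p),
                     "direction": "top" if es >= 0 else "bottom"})
    table = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p",
                                        "direction"])
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return EnrichmentResult(table=table, method="gsea",
                            params={"weight_p": weight_p, "n_perm": n_perm,
                                    "seed": seed, "min_set": min_set,
                                    "max_set": max_set})


def hr_difference_ranking(scan_rt, scan_nort,
                          scale: str = "log") -> tuple[list[str], np.ndarray]:
    """Genes ranked by RT minus noRT hazard-ratio difference (descending).

    ``scale='log'`` uses log-HR differences (default); ``'hr'`` uses raw HR
    differences.  Genes failing in either scan are dropped.
    """
    shared = scan_rt.table.index.intersection(scan_nort.table.index)
    if len(shared) == 0:
        raise ValueError("scans share no genes")
    ok = (scan_rt.table.loc[shared, "converged"]
          & scan_nort.table.loc[shared, "converged"])
    shared = shared[ok]
    if scale == "log":
        diff = (scan_rt.table.loc[shared, "log_hr"]
                - scan_nort.table.loc[shared, "log_hr"])
    elif scale == "hr":
        diff = (scan_rt.table.loc[shared, "hr"]
                - scan_nort.table.loc[shared, "hr"])
    else:
        raise ValueError(f"unknown scale: {scale}")
    order = np.argsort(-diff.to_numpy(), kind="stable")
    return list(shared[order]), diff.to_numpy()[order]


def jaccard(a, b) -> float:
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 0.0


def reduce_terms(results: EnrichmentResult, collection: GeneSetCollection,
                 similarity_threshold: float = 0.7,
                 alpha: float = 0.05) -> TermClusterSet:
    """Greedy clustering of significant sets by Jaccard similarity.

    The most significant unclustered set seeds a cluster and absorbs every
    unclustered set with Jaccard >= threshold to it; repeat until done.
    """
    if "p_adj" not in results.table.columns:
        raise ValueError("results lack adjusted p-values")
    sig = results.table[results.table["p_adj"] < alpha]
    sig = sig.sort_values(["p_adj", "p", "set"], kind="stable")
    members_map = collection.restricted()
    remaining = list(sig["set"])
    scores = dict(zip(sig["set"], sig["p_adj"]))
    clusters = []
    while remaining:
        seed_name = remaining.pop(0)
        absorbed = [n for n in remaining
                    if jaccard(members_map[seed_name], members_map[n])
                    >= similarity_threshold]
        remaining = [n for n in remaining if n not in absorbed]
        clusters.append({"representative": seed_name,
                         "members": [seed_name] + absorbed,
                         "score": float(scores[seed_name])})
    return TermClusterSet(clusters=clusters,
                          similarity_threshold=similarity_threshold)
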