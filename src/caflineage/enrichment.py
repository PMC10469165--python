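"""Preranked gene-set enrichment with permutation normalization.

The enrichment score is the signed extremum of the weighted
Kolmogorov-Smirnov running sum over a ranked gene list: hits increment the
sum proportionally to |score|^weight (normalized over the set), misses
decrement it uniformly. The null is gene-label permutation (random sets of
the same size drawn from the ranking); NES divides ES by the mean absolute
permuted ES of the same sign, and the nominal p is the same-sign permutation
tail fraction (add-one corrected). Cross-sample consistency is obtained by
averaging NES and nominal p per set over the discovery samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from caflineage.errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p: float
    n_hits: int
    sample: str = ""


def _es_from_positions(
    positions: np.ndarray, scores: np.ndarray, n_genes: int, weight: float
) -> float:
    """ES for hit positions (0-based, sorted) in a ranking of n_genes."""
    k = positions.size
    if k == n_genes:
        return 0.0  # set equals the universe: no misses, ES defined as 0
    w = np.abs(scores[positions]) ** weight
    total = w.sum()
    if total == 0:
        w = np.ones(k)
        total = float(k)
    hit_cum = np.cumsum(w) / total
    miss = 1.0 / (n_genes - k)
    i = np.arange(k)
    after = hit_cum - (positions + 1 - (i + 1)) * miss  # just after each hit
    before = np.concatenate([[0.0], hit_cum[:-1]]) - (positions - i) * miss
    pos_ext = after.max()
    neg_ext = min(before.min(), 0.0)
    if pos_ext - (-neg_ext) > 1e-12:
        return float(pos_ext)
    if (-neg_ext) - pos_ext > 1e-12:
        return float(neg_ext)
    # tie in magnitude (to rounding): the extreme reached first wins
    step_pos = positions[int(np.argmax(after))]
    step_neg = positions[int(np.argmin(before))] - 1
    return float(neg_ext if step_neg < step_pos else pos_ext)


def preranked_gsea(
    ranked_scores: pd.Series,
    gene_set: list[str],
    weight: float = 1.0,
    n_perm: int = 999,
    seed: int = 0,
    name: str = "",
    sample: str = "",
) -> EnrichmentResult:
    """Weighted-KS preranked enrichment of one gene set.

    ``ranked_scores`` is a Series indexed by gene, sorted by decreasing
    score. Requires >= 3 set genes in the ranking.
    """
    if not np.all(np.isfinite(ranked_scores.to_numpy())):
        raise DataError("ranking scores must be finite")
    genes = ranked_scores.index
    hits = np.flatnonzero(genes.isin(set(gene_set)))
    if hits.size == 0:
        raise DataError(f"gene set {name!r} is disjoint from the ranking")
    if hits.size < 3:
        raise DataError(f"gene set {name!r} has fewer than 3 genes in the ranking")
    scores = ranked_scores.to_numpy(dtype=float)
    n = len(genes)
    es = _es_from_positions(hits, scores, n, weight)
    if hits.size == n:
        log.info("gene set %r equals the ranked universe; ES = 0", name)
        return EnrichmentResult(name, 0.0, 0.0, 1.0, int(hits.size), sample)

    rng = np.random.default_rng(seed)
    perm_es = np.empty(n_perm)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=hits.size, replace=False))
        perm_es[i] = _es_from_positions(pos, scores, n, weight)
    same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
    if es == 0:
        nes, p = 0.0, 1.0
    else:
        denom = np.abs(same_sign).mean() if same_sign.size else np.abs(perm_es).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (1 + same_sign.size)
    return EnrichmentResult(name, float(es), float(nes), float(p), int(hits.size), sample)


def rank_genes_for_gsea(de_table: pd.DataFrame) -> pd.Series:
    """Signed significance ranking from a DE table (e.g. marker+ vs marker-).

    score = sign(log2FC) * -log10(p); descending order, deterministic
    tie-break by gene id.
    """
    p = np.clip(de_table["p"].to_numpy(dtype=float), 1e-300, 1.0)
    score = np.sign(de_table["log2fc"].to_numpy()) * -np.log10(p)
    s = pd.Series(score, index=de_table.index, name="score")
    return s.sort_index().sort_values(ascending=False, kind="stable")


def average_enrichment(
    results: list[EnrichmentResult],
    name_contains: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-set mean NES and mean nominal p across samples.

    With ``name_contains`` set, only gene sets whose name contains one of the
    substrings are kept (the mesenchymal/fibroblast-style name filter).
    """
    if not results:
        raise DataError("no enrichment results to average")
    df = pd.DataFrame(
        [
            {"gene_set": r.gene_set, "nes": r.nes, "p": r.p, "sample": r.sample}
            for r in results
        ]
    )
    if name_contains:
        keep = df["gene_set"].str.contains("|".join(name_contains), regex=True)
        df = df[keep]
    out = (
        df.groupby("gene_set")
        .agg(mean_nes=("nes", "mean"), mean_p=("p", "mean"), n_samples=("sample", "count"))
        .sort_values("mean_nes", ascending=False)
    )
    return out
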