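"""Pre-ranked gene-set enrichment with a signed log-p ranking metric.

Genes are ranked by ``-log10(p) * sgn(log2fc)`` so that significantly
upregulated genes sit at the top of the list and significantly
downregulated genes at the bottom.  (The formula is sometimes written
``log(pv) * sgn(lfc)``, which taken literally would invert the list; the
conventional orientation is used here, with ``literal_sign=True``
available for the inverted form.)

The enrichment score is the classic weighted Kolmogorov-Smirnov running
sum with weight exponent 1: walking down the ranked list, hitting a set
member increments the sum by its |score| share, missing decrements by
1/(N-K); ES is the signed maximal deviation from zero.  Significance
comes from a gene-permutation null (size-matched random sets), with the
add-one permutation p-value computed against same-sign null scores and
NES normalized by the mean |null ES| of the same sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import DEResult, bh_adjust

__all__ = [
    "RankedList",
    "EnrichmentTable",
    "rank_metric",
    "enrichment_score",
    "gsea_preranked",
]


@dataclass
class RankedList:
    """Genes ordered by descending score (ties broken by gene id)."""

    genes: np.ndarray
    scores: np.ndarray
    n_pvalues_clamped: int = 0

    @classmethod
    def from_scores(cls, genes, scores, n_pvalues_clamped: int = 0) -> "RankedList":
        genes = np.asarray(genes, dtype=object)
        scores = np.asarray(scores, dtype=float)
        if len(genes) != len(scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(genes)) != len(genes):
            raise ValueError("gene ids must be unique")
        order = np.lexsort((genes, -scores))
        return cls(genes[order], scores[order], n_pvalues_clamped)

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores})


@dataclass
class EnrichmentTable:
    """Per-set enrichment results (one row per retained set)."""

    table: pd.DataFrame
    n_perm: int
    seed: int
    padj_cutoff: float = 0.1
    dropped: list[str] = field(default_factory=list)


def rank_metric(de: DEResult, *, literal_sign: bool = False) -> RankedList:
    """Signed log-p ranking metric from a DE result.

    score = -log10(p) * sgn(log2fc); zero p-values are clamped to the
    smallest positive float and the number of clamps recorded.
    """
    p = de.table["p"].to_numpy(dtype=float)
    lfc = de.table["log2fc"].to_numpy(dtype=float)
    tiny = np.finfo(float).tiny
    n_clamped = int((p < tiny).sum())
    p = np.clip(p, tiny, 1.0)
    score = -np.log10(p) * np.sign(lfc)
    if literal_sign:
        score = -score
    return RankedList.from_scores(
        de.table.index.to_numpy(), score, n_pvalues_clamped=n_clamped
    )


def _es_from_positions(
    positions: np.ndarray, abs_scores_at_hits: np.ndarray, n_total: int
) -> tuple[float, int]:
    """ES and peak prefix length from sorted 0-based hit positions.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit or immediately before one; evaluating only
    those 2K candidate prefixes reproduces the full running sum's signed
    maximal deviation.
    """
    k = len(positions)
    total = abs_scores_at_hits.sum()
    weights = (
        abs_scores_at_hits / total if total > 0 else np.full(k, 1.0 / k)
    )
    d = 1.0 / (n_total - k)
    cum = np.cumsum(weights)
    idx = np.arange(k)
    after_hit = cum - (positions - idx) * d
    before_hit = np.concatenate([[0.0], cum[:-1]]) - (positions - idx) * d
    hi_i = int(np.argmax(after_hit))
    lo_i = int(np.argmin(before_hit))
    hi, lo = after_hit[hi_i], before_hit[lo_i]
    if hi >= -lo:
        return float(hi), int(positions[hi_i]) + 1
    return float(lo), int(positions[lo_i])


def enrichment_score(ranked: RankedList, gene_set) -> tuple[float, int]:
    """Weighted KS enrichment score of one gene set on a ranked list.

    Returns (ES, peak position), the peak being the prefix length at
    which the running sum attains its extreme.  When the maximal
    positive and negative deviations tie exactly in magnitude the
    positive one is returned.  The set must intersect the ranked
    universe and not cover it entirely.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked))
    k = int(hit.sum())
    if k == 0:
        raise ValueError("gene set does not intersect the ranked universe")
    if k == len(ranked):
        raise ValueError("gene set covers the entire ranked universe")
    positions = np.flatnonzero(hit)
    return _es_from_positions(positions, np.abs(ranked.scores[positions]), len(ranked))


def gsea_preranked(
    ranked: RankedList,
    sets: dict,
    n_perm: int = 5000,
    seed: int = 0,
    *,
    min_size: int = 2,
    padj_cutoff: float = 0.1,
) -> EnrichmentTable:
    """Permutation GSEA over a collection of gene sets.

    The null for a set of (post-intersection) size K is ``n_perm``
    size-K random subsets of the ranked universe; the permutation stream
    depends only on (seed, K), so results are independent of set order.
    p = (1 + #{|ES_null| >= |ES_obs|, same sign})/(1 + #same-sign null);
    NES = ES / mean |same-sign null ES|; BH adjustment across retained
    sets; sets smaller than ``min_size`` after intersection are dropped
    with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    universe = set(ranked.genes)
    n = len(ranked)
    abs_scores = np.abs(ranked.scores)

    null_cache: dict[int, np.ndarray] = {}

    def null_es(k: int) -> np.ndarray:
        if k not in null_cache:
            rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, k])
            out = np.empty(n_perm)
            for i in range(n_perm):
                pos = np.sort(rng.choice(n, size=k, replace=False))
                out[i], _ = _es_from_positions(pos, abs_scores[pos], n)
            null_cache[k] = out
        return null_cache[k]

    rows = []
    dropped = []
    for name, members in sets.items():
        inter = set(members) & universe
        if len(inter) < min_size or len(inter) >= n:
            warnings.warn(
                f"gene set {name!r} has {len(inter)} usable members; dropped",
                stacklevel=2,
            )
            dropped.append(name)
            continue
        es, peak = enrichment_score(ranked, inter)
        perm = null_es(len(inter))
        same = perm >= 0 if es >= 0 else perm < 0
        n_same = int(same.sum())
        if n_same == 0:
            p, nes = 1.0, np.nan
        else:
            n_extreme = int((np.abs(perm[same]) >= abs(es)).sum())
            p = (1.0 + n_extreme) / (1.0 + n_same)
            nes = es / np.abs(perm[same]).mean()
        rows.append(
            {
                "name": name,
                "es": es,
                "nes": nes,
                "p": p,
                "size": len(inter),
                "peak": peak,
            }
        )

    table = pd.DataFrame(
        rows, columns=["name", "es", "nes", "p", "size", "peak"]
    ).set_index("name")
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < padj_cutoff
    else:
        table["p_adj"] = []
        table["significant"] = []
    return EnrichmentTable(
        table=table, n_perm=n_perm, seed=seed, padj_cutoff=padj_cutoff, dropped=dropped
    )
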