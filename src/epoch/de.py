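"""Differential expression, senescence signatures, and reversal statistics.

The DE engine is deliberately lightweight: median-of-ratios size-factor
normalization, log2(normalized + 1) transformation, and a two-sided
Welch t-test per gene with Benjamini-Hochberg adjustment.  It stands
behind a narrow interface (:class:`DEResult`) so a negative-binomial GLM
engine can be substituted without touching the signature or reversal
logic, which is the part this package is about.

A senescence signature is the set of genes passing ``p_adj < 0.01`` and
|fold change| > 2 in the senescent-vs-quiescent contrast, split by
direction.  The reversal summary classifies each signature gene under a
treated-vs-senescent contrast: an up-signature gene is *reversed* when
significantly decreased by treatment, *exacerbated* when significantly
increased, otherwise *unchanged* (mirror rule for the down signature);
percentages are rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .sim_counts import CountMatrix

__all__ = [
    "DEResult",
    "SenescenceSignature",
    "ReversalSummary",
    "size_factors",
    "normalized_counts",
    "de_test",
    "bh_adjust",
    "extract_signature",
    "classify_reversal",
    "reversal_percentage",
]


@dataclass
class DEResult:
    """Per-gene two-group differential expression result.

    ``table`` is indexed by gene with columns ``log2fc`` (group B minus
    group A on the log2 scale), ``p``, ``p_adj`` and ``base_mean``
    (mean normalized count over both groups).
    """

    table: pd.DataFrame
    contrast: str

    def __post_init__(self):
        missing = {"log2fc", "p", "p_adj", "base_mean"} - set(self.table.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")


@dataclass
class SenescenceSignature:
    """Directional gene signature with the thresholds that produced it."""

    up: pd.DataFrame  # indexed by gene, column log2fc
    down: pd.DataFrame
    p_adj_cutoff: float
    fc_cutoff: float

    @property
    def up_genes(self) -> list[str]:
        return list(self.up.index)

    @property
    def down_genes(self) -> list[str]:
        return list(self.down.index)


@dataclass
class ReversalSummary:
    """Counts of reversed / exacerbated / unchanged signature genes.

    ``table`` has one row per direction (up, down) with columns total,
    reversed, exacerbated, unchanged and reversed_pct (one decimal).
    """

    table: pd.DataFrame
    p_adj_cutoff: float

    def reversed_pct(self, direction: str) -> float:
        return float(self.table.loc[direction, "reversed_pct"])


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with no zero count in any sample; each
    sample's factor is the median over reference genes of its count
    divided by the gene's geometric mean across samples.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    ref = (arr > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no gene has all-positive counts; size factors undefined")
    ref_arr = arr[ref]
    geomean = np.exp(np.log(ref_arr).mean(axis=1))
    ratios = ref_arr / geomean[:, None]
    return pd.Series(np.median(ratios, axis=0), index=mat.columns, name="size_factor")


def normalized_counts(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts divided per sample by the median-of-ratios size factor."""
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    return mat / size_factors(mat)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = max(y + dif, 1e-8)
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _moderate_variances(s2: np.ndarray, df: float, abundance: np.ndarray):
    """Empirical-Bayes squeeze of per-gene variances toward a mean trend.

    Per-gene sample variances ``s2`` (``df`` residual degrees of freedom
    each) are shrunk toward a lowess trend on mean log expression; the
    prior degrees of freedom ``d0`` are estimated by moment-matching the
    log variances against the scaled-F model of Smyth (2004).  Returns
    (posterior variances, d0).
    """
    s2 = np.clip(s2, 1e-12, None)
    logs2 = np.log(s2)
    if len(s2) >= 30:
        trend = lowess(logs2, abundance, frac=0.4, it=2, return_sorted=False)
    else:  # too few genes for a trend; shrink toward the global level
        trend = np.full_like(logs2, logs2.mean())
    # bias-correct E[log s^2] = log sigma^2 + digamma(df/2) - log(df/2)
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    s0_2 = np.exp(trend - bias)
    e = logs2 - trend
    var_e = float(np.var(e, ddof=1))
    resid = var_e - special.polygamma(1, df / 2.0)
    if resid <= 0:
        d0 = np.inf
        post = s0_2
    else:
        d0 = 2.0 * _trigamma_inverse(resid)
        post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0


def de_test(
    counts: CountMatrix, group_a: str, group_b: str, *, method: str = "moderated"
) -> DEResult:
    """Two-group DE on log2(normalized count + 1), BH-adjusted.

    ``log2fc`` is mean(B) - mean(A).  The default engine is a moderated
    t-test: per-gene pooled variances are squeezed toward a lowess
    mean-variance trend with empirically estimated prior degrees of
    freedom, recovering most of the power a count-model engine with
    dispersion shrinkage would give at small n.  ``method='welch'`` and
    ``method='pooled'`` select the unmoderated two-sample t forms.
    Genes with zero counts in every sample are dropped (log fold change
    undefined); genes with zero variance and zero mean difference get
    p = 1.
    """
    if method not in ("moderated", "welch", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    md = counts.sample_metadata
    for g in (group_a, group_b):
        if g not in set(md["group"]):
            raise ValueError(f"unknown group label {g!r}")
    a_ids = counts.samples_in_group(group_a)
    b_ids = counts.samples_in_group(group_b)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("each group needs >= 2 samples")

    norm = normalized_counts(counts)
    keep = (counts.counts.to_numpy() > 0).any(axis=1)
    norm = norm.loc[keep]
    y = np.log2(norm + 1.0)
    ya = y[a_ids].to_numpy()
    yb = y[b_ids].to_numpy()
    na, nb = ya.shape[1], yb.shape[1]

    log2fc = yb.mean(axis=1) - ya.mean(axis=1)
    if method == "moderated":
        df = float(na + nb - 2)
        s2 = (ya.var(axis=1, ddof=1) * (na - 1) + yb.var(axis=1, ddof=1) * (nb - 1)) / df
        abundance = np.concatenate([ya, yb], axis=1).mean(axis=1)
        post_s2, d0 = _moderate_variances(s2, df, abundance)
        se = np.sqrt(post_s2 * (1.0 / na + 1.0 / nb))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = log2fc / se
        df_total = df + d0
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(yb, ya, axis=1, equal_var=(method == "pooled"))
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "p_adj": bh_adjust(p),
            "base_mean": norm[a_ids + b_ids].mean(axis=1).to_numpy(),
        },
        index=norm.index,
    )
    return DEResult(table=table, contrast=f"{group_b}_vs_{group_a}")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def extract_signature(
    de: DEResult, p_adj_cutoff: float = 0.01, fc_cutoff: float = 2.0
) -> SenescenceSignature:
    """Directional signature at ``p_adj < cutoff`` and |FC| > ``fc_cutoff``."""
    if fc_cutoff <= 0:
        raise ValueError("fc_cutoff must be positive")
    t = de.table
    lfc_cut = np.log2(fc_cutoff)
    sig = t["p_adj"] < p_adj_cutoff
    up = t.loc[sig & (t["log2fc"] > lfc_cut), ["log2fc"]].copy()
    down = t.loc[sig & (t["log2fc"] < -lfc_cut), ["log2fc"]].copy()
    return SenescenceSignature(
        up=up, down=down, p_adj_cutoff=p_adj_cutoff, fc_cutoff=fc_cutoff
    )


def reversal_percentage(n_reversed: int, n_total: int) -> float:
    """Percentage of signature genes reversed, rounded to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_reversed <= n_total:
        raise ValueError("n_reversed must lie in [0, n_total]")
    return round(100.0 * n_reversed / n_total, 1)


def _classify(
    genes: list[str], sign: float, treatment: pd.DataFrame, cutoff: float
) -> dict:
    missing = [g for g in genes if g not in treatment.index]
    if missing:
        raise KeyError(
            f"signature genes missing from treatment DE: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    sub = treatment.loc[genes]
    significant = sub["p_adj"] < cutoff
    toward_baseline = sign * sub["log2fc"] < 0
    n_rev = int((significant & toward_baseline).sum())
    n_exa = int((significant & (sign * sub["log2fc"] > 0)).sum())
    total = len(genes)
    return {
        "total": total,
        "reversed": n_rev,
        "exacerbated": n_exa,
        "unchanged": total - n_rev - n_exa,
        "reversed_pct": round(100.0 * n_rev / total, 1) if total else np.nan,
    }


def classify_reversal(
    sig: SenescenceSignature, treatment_de: DEResult, p_adj_cutoff: float = 0.05
) -> ReversalSummary:
    """Classify every signature gene under the treated-vs-senescent contrast.

    An up-signature gene is reversed when significantly down under
    treatment, exacerbated when significantly up, else unchanged; the
    down signature uses the mirror rule.  The three classes partition
    each signature; ``reversed_pct`` is rounded to one decimal.
    """
    rows = {
        "up": _classify(sig.up_genes, +1.0, treatment_de.table, p_adj_cutoff),
        "down": _classify(sig.down_genes, -1.0, treatment_de.table, p_adj_cutoff),
    }
    table = pd.DataFrame(rows).T
    table.index.name = "direction"
    for c in ("total", "reversed", "exacerbated", "unchanged"):
        table[c] = table[c].astype(int)
    return ReversalSummary(table=table, p_adj_cutoff=p_adj_cutoff)
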