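"""Spearman association between transcriptomic signatures.

A signature is a per-gene table of (log2fc, p) over a shared gene
universe — a cocktail's treatment effect, an aging signature, a
reprogramming signature.  For each pair of signatures the association is
the Spearman rank correlation of their log2 fold changes over the union
of each signature's top-N lowest-p genes (N = 300 by default), and the
off-diagonal p-values of the full matrix are BH-adjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult, bh_adjust

__all__ = [
    "SignatureCollection",
    "AssociationMatrix",
    "spearman_pair",
    "association_matrix",
]


@dataclass
class SignatureCollection:
    """Named signatures, each a DataFrame indexed by gene with log2fc, p."""

    signatures: dict[str, pd.DataFrame]

    def __post_init__(self):
        for name, sig in self.signatures.items():
            missing = {"log2fc", "p"} - set(sig.columns)
            if missing:
                raise ValueError(f"signature {name!r} missing columns {missing}")
            p = sig["p"].to_numpy(dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"signature {name!r} has p-values outside [0, 1]")

    @classmethod
    def from_de_results(cls, results: dict[str, DEResult]) -> "SignatureCollection":
        return cls(
            {name: de.table[["log2fc", "p"]].copy() for name, de in results.items()}
        )

    def names(self) -> list[str]:
        return list(self.signatures)


def _top_genes(sig: pd.DataFrame, top_n: int) -> pd.Index:
    # stable sort by gene id then by p: ties in p broken by gene id
    order = sig.loc[sig.index.sort_values()].sort_values("p", kind="mergesort")
    return order.index[: min(top_n, len(order))]


def spearman_pair(
    sig_a: pd.DataFrame, sig_b: pd.DataFrame, top_n: int = 300
) -> tuple[float, float, int]:
    """Spearman rho of log2fc over the union of both signatures' top genes.

    The union of each signature's ``top_n`` lowest-p genes is intersected
    with the genes present (non-missing log2fc) in both signatures; rho
    and its t-distribution p-value are computed over that set with
    average ranks for ties.  Returns (rho, p, n_genes_used).
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    union = _top_genes(sig_a, top_n).union(_top_genes(sig_b, top_n))
    common = union.intersection(sig_a.index).intersection(sig_b.index)
    a = sig_a.loc[common, "log2fc"].astype(float)
    b = sig_b.loc[common, "log2fc"].astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("fewer than 3 shared genes in the top union")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p), int(len(a))


@dataclass
class AssociationMatrix:
    """Symmetric Spearman association matrix with significance."""

    rho: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_used: pd.DataFrame


def association_matrix(
    collection: SignatureCollection, top_n: int = 300
) -> AssociationMatrix:
    """Pairwise Spearman associations over a signature collection.

    BH adjustment runs across the upper-triangle p-values; the matrices
    are filled symmetrically.  The diagonal is rho = 1 with p = p_adj = 0
    by convention and is excluded from the adjustment.  Failing pairs
    (too few shared genes) become NaN entries with a warning.
    """
    names = collection.names()
    if len(names) < 2:
        raise ValueError("need >= 2 signatures")
    k = len(names)
    rho = pd.DataFrame(np.eye(k), index=names, columns=names)
    p = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    n_used = pd.DataFrame(np.zeros((k, k), dtype=int), index=names, columns=names)

    tri = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            try:
                r, pv, n = spearman_pair(
                    collection.signatures[a], collection.signatures[b], top_n
                )
            except ValueError as exc:
                warnings.warn(f"pair ({a}, {b}) failed: {exc}", stacklevel=2)
                r, pv, n = np.nan, np.nan, 0
            rho.iloc[i, j] = rho.iloc[j, i] = r
            p.iloc[i, j] = p.iloc[j, i] = pv
            n_used.iloc[i, j] = n_used.iloc[j, i] = n
            tri.append((i, j, pv))

    p_adj = pd.DataFrame(np.zeros((k, k)), index=names, columns=names)
    valid = [(i, j) for i, j, pv in tri if np.isfinite(pv)]
    if valid:
        adj = bh_adjust([p.iloc[i, j] for i, j in valid])
        for (i, j), a_ in zip(valid, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a_
    for i, j, pv in tri:
        if not np.isfinite(pv):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = np.nan
    return AssociationMatrix(rho=rho, p=p, p_adj=p_adj, n_used=n_used)
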