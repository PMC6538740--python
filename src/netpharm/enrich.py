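"""Over-representation analysis with Benjamini-Hochberg control.

A query set (genes or metabolites) is tested against each term of an
annotated set collection with the one-sided hypergeometric upper tail:
for a universe of N ids, a term of K members and a query of n ids with k
of them in the term, p = P(X >= k), X ~ Hypergeometric(N, K, n).  Terms
with no overlap are not tested.  P-values are adjusted across the tested
terms by the Benjamini-Hochberg step-up procedure and a term is called
enriched when q < 0.05.

The EASE variant (replace k by k-1 before taking the tail, a
conservative jackknife used by some annotation servers) is available via
``ease=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "hypergeom_tail",
    "bh_adjust",
    "ora",
]


@dataclass
class GeneSetCollection:
    """Named id sets (terms) over a universe.

    ``terms`` maps term_id -> (term_name, frozenset of member ids).  If
    no universe is given it defaults to the union of all members.
    """

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        union = frozenset().union(*(m for _, m in self.terms.values())) if self.terms else frozenset()
        if not self.universe:
            self.universe = union
        elif not union <= self.universe:
            raise ValueError("term members outside the declared universe")

    def __len__(self) -> int:
        return len(self.terms)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: term size, n: query size, k: overlap.
    Returns 1.0 when k == 0.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def ora(
    query,
    collection: GeneSetCollection,
    universe: frozenset[str] | None = None,
    ease: bool = False,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Over-representation analysis of a query set against a collection.

    Query ids outside the universe are dropped with a warning.  One row
    per term with at least one overlapping member; q-values are
    BH-adjusted across the tested terms only; rows sorted by (q, p,
    term_id).
    """
    universe = frozenset(universe) if universe is not None else collection.universe
    query = set(query)
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} query id(s) outside the universe",
            stacklevel=2,
        )
    query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")

    N, n = len(universe), len(query)
    rows = []
    for term_id, (term_name, members) in collection.terms.items():
        members = members & universe
        k = len(query & members)
        if k == 0:
            continue
        k_eff = max(k - 1, 0) if ease else k
        p = hypergeom_tail(k_eff, len(members), n, N) if k_eff else 1.0
        rows.append((term_id, term_name, k, len(members), n, N, p))
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < q_cutoff
    return out.sort_values(["q", "p", "term_id"], kind="mergesort").reset_index(drop=True)
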