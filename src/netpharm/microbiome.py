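"""Downstream 16S statistics on OTU count tables.

Inputs are integer count tables (samples x taxa) with per-sample group
labels and a per-taxon lineage.  Two families of statistics are
provided:

* alpha diversity per sample — Shannon entropy (natural log), Chao1
  (bias-corrected by default) and the abundance-based coverage estimator
  (ACE, rare cut-off 10), all computed from the frequency-of-frequencies
  summary of each sample;
* group-wise differential abundance — taxa aggregated to a taxonomic
  rank on per-sample relative abundances, compared between two groups by
  the two-sided Wilcoxon rank-sum test (exact when both groups have
  <= 10 samples and there are no ties, otherwise the normal
  approximation with tie and continuity corrections), BH-adjusted.

Testing operates on relative abundances rather than rarefied counts; no
rarefaction depth is imposed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_adjust

__all__ = [
    "CountTable",
    "AbundanceSummary",
    "abundance_summary",
    "shannon",
    "chao1",
    "ace",
    "alpha_diversity",
    "diff_abundance",
    "kruskal_multigroup",
]

#: taxonomy ranks ordered domain -> species
RANKS = ["domain", "phylum", "class", "order", "family", "genus", "species"]


@dataclass
class CountTable:
    """Samples x taxa integer counts with groups and taxonomy."""

    counts: pd.DataFrame           # index: sample_id, columns: taxon_id
    groups: pd.Series              # index: sample_id -> group label
    taxonomy: pd.DataFrame = field(default=None)  # index: taxon_id, columns: RANKS

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every sample needs at least one nonzero count")
        self.groups = self.groups.reindex(self.counts.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if self.taxonomy is None:
            self.taxonomy = pd.DataFrame(
                {r: self.counts.columns for r in RANKS}, index=self.counts.columns
            )


@dataclass(frozen=True)
class AbundanceSummary:
    """Frequency-of-frequencies bookkeeping for one sample.

    F[i] is the number of taxa observed exactly i times; the identities
    sum_i F_i = S_obs and sum_i i*F_i = N hold by construction.  Rare
    taxa are those with abundance <= rare_cutoff.
    """

    s_obs: int
    n: int
    f: dict[int, int]
    rare_cutoff: int
    n_rare: int
    s_rare: int
    s_abund: int


def abundance_summary(counts, rare_cutoff: int = 10) -> AbundanceSummary:
    x = np.asarray(counts)
    x = x[x > 0].astype(int)
    if x.size == 0:
        raise ValueError("sample has no observed taxa")
    vals, reps = np.unique(x, return_counts=True)
    f = {int(i): int(c) for i, c in zip(vals, reps)}
    rare = x[x <= rare_cutoff]
    return AbundanceSummary(
        s_obs=int(x.size),
        n=int(x.sum()),
        f=f,
        rare_cutoff=rare_cutoff,
        n_rare=int(rare.sum()),
        s_rare=int(rare.size),
        s_abund=int((x > rare_cutoff).sum()),
    )


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy -sum p_i ln p_i over nonzero taxa (natural log).

    ``base`` switches the logarithm (e.g. 2 for bits).
    """
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("sample has no observed taxa")
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(base) if base else h


def chao1(counts_or_summary, bias_corrected: bool = True) -> float:
    """Chao1 richness estimator from singleton/doubleton counts.

    classic: S_obs + F1^2 / (2 F2)        (requires F2 > 0)
    bias-corrected (default): S_obs + F1 (F1 - 1) / (2 (F2 + 1))
    """
    s = (
        counts_or_summary
        if isinstance(counts_or_summary, AbundanceSummary)
        else abundance_summary(counts_or_summary)
    )
    f1, f2 = s.f.get(1, 0), s.f.get(2, 0)
    if bias_corrected:
        return s.s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        # classic form undefined at F2=0; fall back to the corrected form
        return s.s_obs + f1 * (f1 - 1) / 2.0
    return s.s_obs + f1 * f1 / (2.0 * f2)


def ace(counts_or_summary, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator.

    C = 1 - F1/N_rare; gamma^2 = max(S_rare * sum i(i-1) F_i /
    (C N_rare (N_rare - 1)) - 1, 0); ACE = S_abund + S_rare/C +
    (F1/C) gamma^2.  When every rare taxon is a singleton (C = 0) the
    estimator is undefined and Chao1 is returned with a warning.
    """
    s = (
        counts_or_summary
        if isinstance(counts_or_summary, AbundanceSummary)
        else abundance_summary(counts_or_summary, rare_cutoff)
    )
    if s.rare_cutoff != rare_cutoff:
        raise ValueError("summary was built with a different rare cut-off")
    if s.s_rare == 0:
        return float(s.s_obs)
    f1 = s.f.get(1, 0)
    coverage = 1.0 - f1 / s.n_rare
    if coverage == 0.0:
        warnings.warn(
            "all rare taxa are singletons (coverage 0); falling back to Chao1",
            stacklevel=2,
        )
        return chao1(s)
    ssum = sum(i * (i - 1) * c for i, c in s.f.items() if i <= rare_cutoff)
    if s.n_rare > 1:
        gamma2 = max(
            s.s_rare * ssum / (coverage * s.n_rare * (s.n_rare - 1)) - 1.0, 0.0
        )
    else:
        gamma2 = 0.0
    return s.s_abund + s.s_rare / coverage + (f1 / coverage) * gamma2


def alpha_diversity(table: CountTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample Ace/Chao1/Shannon table (plus S_obs and group)."""
    rows = []
    for sample_id, counts in table.counts.iterrows():
        s = abundance_summary(counts.to_numpy(), rare_cutoff)
        rows.append(
            {
                "sample_id": sample_id,
                "group": table.groups[sample_id],
                "s_obs": s.s_obs,
                "ace": ace(s, rare_cutoff),
                "chao1": chao1(s),
                "shannon": shannon(counts.to_numpy()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null distribution when both groups have <= 10 observations and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if len(x) <= 10 and len(y) <= 10 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def _aggregate_rank(table: CountTable, rank: str) -> pd.DataFrame:
    if rank not in table.taxonomy.columns:
        raise ValueError(f"rank {rank!r} absent from taxonomy (have {list(table.taxonomy.columns)})")
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    labels = table.taxonomy[rank].reindex(table.counts.columns)
    return rel.T.groupby(labels).sum().T


def diff_abundance(
    table: CountTable, rank: str, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-taxon Wilcoxon rank-sum differential abundance at a rank.

    Relative abundances aggregated to ``rank``; effect direction is the
    difference of group mean relative abundances (A minus B); q-values
    BH-adjusted across taxa.
    """
    rel = _aggregate_rank(table, rank)
    in_a = table.groups == group_a
    in_b = table.groups == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for taxon in rel.columns:
        xa = rel.loc[in_a, taxon].to_numpy()
        xb = rel.loc[in_b, taxon].to_numpy()
        rows.append(
            {
                "taxon": taxon,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "delta": float(xa.mean() - xb.mean()),
                "p": wilcoxon_rank_sum(xa, xb),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p", "taxon"], kind="mergesort").reset_index(drop=True)


def kruskal_multigroup(table: CountTable, rank: str) -> pd.DataFrame:
    """Kruskal-Wallis test per taxon across all groups (extra option for
    multi-group tables; no effect-size modelling)."""
    rel = _aggregate_rank(table, rank)
    group_masks = {g: table.groups == g for g in sorted(table.groups.unique())}
    rows = []
    for taxon in rel.columns:
        samples = [rel.loc[m, taxon].to_numpy() for m in group_masks.values()]
        if np.ptp(np.concatenate(samples)) == 0:  # kruskal rejects constant data
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        rows.append({"taxon": taxon, "H": float(h), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p", "taxon"], kind="mergesort").reset_index(drop=True)
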