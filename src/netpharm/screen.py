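"""ADME screening of herbal compound tables.

Multi-herb formulas are screened compound-by-compound on two
database-annotated covariates: oral bioavailability (OB, percent of an
oral dose reaching systemic circulation) and drug-likeness (DL, 0-1
similarity to known drugs).  The conventional candidate filter keeps
compounds with OB > 30 % and DL > 0.18.

A compound may belong to several herbs of the formula; per-herb retained
counts therefore count it once per herb, so herb counts may sum to more
than the number of distinct candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScreenCriteria",
    "ScreenResult",
    "screen_compounds",
    "union_compound_targets",
]

#: column layout of a compound table (``herbs`` holds a frozenset of herb names)
COMPOUND_COLUMNS = ["compound_id", "name", "herbs", "ob_percent", "dl"]


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds of the candidate-compound filter.

    ``strict=True`` uses strict inequalities (OB > 30, DL > 0.18), the
    literal reading of the conventional cut-offs; ``strict=False``
    switches to >= for boundary-sensitivity checks.
    """

    ob_threshold: float = 30.0
    dl_threshold: float = 0.18
    strict: bool = True

    def passes(self, ob: float, dl: float) -> bool:
        if self.strict:
            return ob > self.ob_threshold and dl > self.dl_threshold
        return ob >= self.ob_threshold and dl >= self.dl_threshold


@dataclass
class ScreenResult:
    """Outcome of :func:`screen_compounds`."""

    retained: pd.DataFrame
    herb_counts: dict[str, int]
    n_excluded_missing: int

    def __iter__(self):  # allow tuple-style unpacking
        return iter((self.retained, self.herb_counts))


def _validate_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("compound table is empty")
    missing = [c for c in COMPOUND_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"compound table lacks columns: {missing}")
    dup = table["compound_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate compound_id values: {sorted(table.loc[dup, 'compound_id'])}"
        )


def screen_compounds(
    table: pd.DataFrame, criteria: ScreenCriteria | None = None
) -> ScreenResult:
    """Apply the OB/DL candidate filter to a compound table.

    Parameters
    ----------
    table
        One row per distinct compound with columns
        ``compound_id, name, herbs, ob_percent, dl`` where ``herbs`` is a
        set of herb names.
    criteria
        Thresholds; defaults to OB > 30 and DL > 0.18 (strict).

    Returns
    -------
    ScreenResult
        Retained rows in input order, per-herb retained counts (a
        compound counted once per herb it belongs to), and the number of
        rows excluded for missing OB/DL annotations.
    """
    criteria = criteria or ScreenCriteria()
    _validate_table(table)

    ob = pd.to_numeric(table["ob_percent"], errors="coerce")
    dl = pd.to_numeric(table["dl"], errors="coerce")
    missing_mask = ob.isna() | dl.isna() | ~np.isfinite(ob.fillna(np.inf)) | ~np.isfinite(dl.fillna(np.inf))
    n_missing = int(missing_mask.sum())
    if n_missing:
        ids = table.loc[missing_mask, "compound_id"].tolist()
        warnings.warn(
            f"excluded {n_missing} compound(s) with missing OB/DL: {ids[:10]}",
            stacklevel=2,
        )

    if criteria.strict:
        keep = (ob > criteria.ob_threshold) & (dl > criteria.dl_threshold)
    else:
        keep = (ob >= criteria.ob_threshold) & (dl >= criteria.dl_threshold)
    keep &= ~missing_mask

    retained = table.loc[keep].copy()
    herb_counts: dict[str, int] = {}
    for herbs in retained["herbs"]:
        for herb in herbs:
            herb_counts[herb] = herb_counts.get(herb, 0) + 1
    return ScreenResult(retained, dict(sorted(herb_counts.items())), n_missing)


def union_compound_targets(
    retained: pd.DataFrame, mapping: dict[str, set[str]]
) -> tuple[set[str], int]:
    """Union of putative targets over the retained compounds.

    Returns the deduplicated target set and the number of retained
    compounds with at least one mapped target (compounds absent from the
    mapping are simply uncovered).
    """
    targets: set[str] = set()
    covered = 0
    for cid in retained["compound_id"]:
        hits = mapping.get(cid)
        if hits:
            targets.update(hits)
            covered += 1
    return targets, covered
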