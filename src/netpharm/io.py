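"""Readers and writers for the pipeline's text formats.

All formats are plain UTF-8 text with header rows: compound tables as
CSV (one row per compound-herb membership), interaction edge lists as
2-column TSV (3-column SIF accepted, middle column ignored), gene/
metabolite sets as GMT, OTU tables as taxa x samples TSV with sample
metadata and taxonomy side tables, intensity matrices as CSV with
``sample_id,group,is_qc`` metadata columns, and caliper measurements as
CSV.
"""

from __future__ import annotations

import csv

import pandas as pd

from .enrich import GeneSetCollection
from .microbiome import RANKS, CountTable
from .metabolome import IntensityMatrix

__all__ = [
    "read_compound_table", "write_compound_table",
    "read_edge_list", "write_edge_list",
    "read_id_list", "write_id_list",
    "read_mapping", "write_mapping",
    "read_gmt", "write_gmt",
    "read_count_table", "write_count_table",
    "read_intensity_csv", "write_intensity_csv",
    "read_measurements", "write_measurements",
]


# -- compound tables ---------------------------------------------------------

def read_compound_table(path) -> pd.DataFrame:
    """Compound CSV with columns ``compound_id,name,herb,ob,dl`` (one row
    per compound-herb membership) aggregated to one row per compound
    with a frozenset of herbs."""
    df = pd.read_csv(path, dtype={"compound_id": str, "name": str, "herb": str})
    required = {"compound_id", "name", "herb", "ob", "dl"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    grouped = df.groupby("compound_id", sort=False)
    out = pd.DataFrame(
        {
            "compound_id": [cid for cid, _ in grouped],
            "name": [g["name"].iloc[0] for _, g in grouped],
            "herbs": [frozenset(g["herb"]) for _, g in grouped],
            "ob_percent": [g["ob"].iloc[0] for _, g in grouped],
            "dl": [g["dl"].iloc[0] for _, g in grouped],
        }
    )
    return out


def write_compound_table(table: pd.DataFrame, path) -> None:
    rows = []
    for _, r in table.iterrows():
        for herb in sorted(r["herbs"]):
            rows.append((r["compound_id"], r["name"], herb, r["ob_percent"], r["dl"]))
    pd.DataFrame(rows, columns=["compound_id", "name", "herb", "ob", "dl"]).to_csv(
        path, index=False
    )


# -- edge lists, id lists, mappings -----------------------------------------

def read_edge_list(path) -> list[tuple[str, str]]:
    """2-column TSV edge list; SIF-style 3-column rows accepted with the
    middle (interaction-type) column ignored.  A header row starting
    with ``node`` or ``source`` is skipped."""
    edges = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if i == 0 and parts[0].lower() in ("node", "nodea", "source", "from"):
                continue
            if len(parts) == 2:
                edges.append((parts[0], parts[1]))
            elif len(parts) >= 3:
                edges.append((parts[0], parts[2]))
            else:
                raise ValueError(f"{path}:{i + 1}: expected 2 or 3 columns")
    return edges


def write_edge_list(edges, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("nodeA\tnodeB\n")
        for a, b in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{a}\t{b}\n")


def read_id_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_id_list(ids, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_mapping(path) -> dict[str, set[str]]:
    """2-column TSV ``source<TAB>target``, one pair per row, aggregated
    into source -> target-set."""
    mapping: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if i == 0 and parts[0].lower() in ("compound_id", "source", "from"):
                continue
            if len(parts) != 2:
                raise ValueError(f"{path}:{i + 1}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def write_mapping(mapping: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\n")
        for src in sorted(mapping):
            for tgt in sorted(mapping[src]):
                fh.write(f"{src}\t{tgt}\n")


# -- GMT ---------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """GMT: tab-separated ``term_id<TAB>description<TAB>member...``."""
    terms = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{i + 1}: GMT rows need >= 3 columns")
            terms[parts[0]] = (parts[1], frozenset(p for p in parts[2:] if p))
    return GeneSetCollection(terms)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(collection.terms):
            name, members = collection.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


# -- OTU count tables --------------------------------------------------------

def read_count_table(counts_path, metadata_path, taxonomy_path=None) -> CountTable:
    """Counts as taxa-rows x sample-columns TSV (first column taxon_id);
    metadata TSV ``sample_id,group``; optional taxonomy TSV with columns
    ``taxon_id`` plus ranks domain..species."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).T
    counts.index.name = "sample_id"
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample_id")
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", dtype=str).set_index("taxon_id")
    return CountTable(counts=counts, groups=meta["group"], taxonomy=taxonomy)


def write_count_table(table: CountTable, counts_path, metadata_path, taxonomy_path) -> None:
    table.counts.T.rename_axis("taxon_id").to_csv(counts_path, sep="\t")
    table.groups.rename("group").rename_axis("sample_id").to_frame().to_csv(
        metadata_path, sep="\t"
    )
    table.taxonomy.rename_axis("taxon_id")[RANKS].to_csv(taxonomy_path, sep="\t")


# -- metabolite intensity matrices ------------------------------------------

def read_intensity_csv(path) -> IntensityMatrix:
    """CSV with metadata columns ``sample_id,group,is_qc`` followed by
    one column per metabolite feature."""
    df = pd.read_csv(path)
    meta_cols = ["sample_id", "group", "is_qc"]
    if not set(meta_cols) <= set(df.columns):
        raise ValueError(f"{path}: expected metadata columns {meta_cols}")
    df = df.set_index("sample_id")
    features = [c for c in df.columns if c not in ("group", "is_qc")]
    return IntensityMatrix(
        intensities=df[features].astype(float),
        groups=df["group"].astype(str),
        is_qc=df["is_qc"].astype(bool),
    )


def write_intensity_csv(matrix: IntensityMatrix, path) -> None:
    out = matrix.intensities.copy()
    out.insert(0, "is_qc", matrix.is_qc.astype(bool))
    out.insert(0, "group", matrix.groups)
    out.rename_axis("sample_id").to_csv(path)


# -- caliper measurements ----------------------------------------------------

def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, dtype={"mouse_id": str, "arm": str}
    )
    required = {"mouse_id", "arm", "day", "length_mm", "width_mm"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if df.empty:
        raise ValueError(f"{path}: measurement file has no rows")
    df["day"] = df["day"].astype(int)
    return df


def write_measurements(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL)
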