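"""Pipeline orchestration: configuration, end-to-end flows, manifests.

Three flows wire the stages together:

* :func:`run_netpharm` — ADME screen -> compound-target network ->
  seeded PPI networks for compound targets and disease targets ->
  network combination (intersection by default) -> centralities and
  median-threshold hubs -> pathway over-representation of the hubs;
* :func:`run_omics` — alpha diversity and differential abundance on the
  OTU table; PCA, PLS-DA/VIP selection on the intensity matrix;
* :func:`run_efficacy` — volume summaries, per-arm TGI against the
  control arm, and between-arm statistics.

Every flow writes tab-separated tables plus a ``manifest.json``
recording the configuration hash, input checksums and per-stage row
counts, and a ``summary.json`` of headline numbers.  Fixed inputs and
configuration give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import efficacy as eff
from . import io as pio
from . import metabolome as met
from . import microbiome as mic
from . import network as net
from . import simulate as sim
from .enrich import ora
from .screen import ScreenCriteria, screen_compounds, union_compound_targets

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_netpharm",
    "run_omics",
    "run_efficacy",
    "run_all",
    "simulate_fixture",
]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Input paths and per-stage options for the flows.

    Paths are resolved relative to ``base_dir`` (the config file's
    directory when loaded from YAML).
    """

    base_dir: str = "."
    inputs: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)        # ob_threshold, dl_threshold, strict
    network: dict = field(default_factory=dict)       # expand_neighbors, combine, include_nc
    enrichment: dict = field(default_factory=dict)    # ease, q_cutoff
    microbiome: dict = field(default_factory=dict)    # rank, rare_cutoff, groups
    metabolome: dict = field(default_factory=dict)    # n_components, log_transform, adjust
    efficacy: dict = field(default_factory=dict)      # day, units, tgi_convention, control_arm
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.setdefault("base_dir", str(path.parent))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def path(self, key: str) -> Path:
        if key not in self.inputs:
            raise PipelineError(f"config lacks input path {key!r}")
        return Path(self.base_dir) / self.inputs[key]

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


class _Manifest:
    def __init__(self, config: PipelineConfig, flow: str):
        self.data = {
            "flow": flow,
            "config_hash": config.digest(),
            "inputs": {},
            "stages": {},
            "warnings": [],
        }

    def add_input(self, key: str, path: Path) -> None:
        self.data["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    def add_stage(self, name: str, **counts) -> None:
        self.data["stages"][name] = counts

    def write(self, outdir: Path) -> None:
        _write_json(self.data, outdir / "manifest.json")


def _stage(name: str, fn, *args, manifest: _Manifest | None = None, **kwargs):
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            result = fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    if manifest is not None:
        manifest.data["warnings"] += [f"{name}: {w.message}" for w in caught]
    return result


# -- network-pharmacology flow ----------------------------------------------

def run_netpharm(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(config, "netpharm")

    compounds = _stage(
        "screen", pio.read_compound_table, config.path("compound_table"), manifest=man
    )
    man.add_input("compound_table", config.path("compound_table"))
    criteria = ScreenCriteria(**config.screen)
    result = _stage("screen", screen_compounds, compounds, criteria, manifest=man)
    pio.write_compound_table(result.retained, outdir / "screened_compounds.csv")
    man.add_stage(
        "screen",
        n_input=len(compounds),
        n_retained=len(result.retained),
        herb_counts=result.herb_counts,
    )

    mapping = _stage(
        "targets", pio.read_mapping, config.path("target_map"), manifest=man
    )
    man.add_input("target_map", config.path("target_map"))
    targets, covered = union_compound_targets(result.retained, mapping)
    bip = net.build_bipartite(result.retained["compound_id"], mapping)
    pio.write_edge_list(bip.edges, outdir / "compound_target_edges.tsv")
    man.add_stage("targets", n_targets=len(targets), n_covered_compounds=covered)

    edges = _stage("ppi", pio.read_edge_list, config.path("ppi_edges"), manifest=man)
    man.add_input("ppi_edges", config.path("ppi_edges"))
    disease = _stage(
        "ppi", pio.read_id_list, config.path("disease_targets"), manifest=man
    )
    man.add_input("disease_targets", config.path("disease_targets"))
    expand = bool(config.network.get("expand_neighbors", True))
    g_cmp = _stage("ppi", net.build_ppi, sorted(targets), edges, expand, manifest=man)
    g_dis = _stage("ppi", net.build_ppi, sorted(set(disease)), edges, expand, manifest=man)
    combine = config.network.get("combine", "intersect")
    if combine == "intersect":
        g = net.intersect_networks(g_cmp, g_dis)
    elif combine == "merge":
        g = net.merge_networks(g_cmp, g_dis)
    else:
        raise PipelineError(f"stage 'ppi': unknown combine mode {combine!r}")
    pio.write_edge_list(g.edges, outdir / "combined_network_edges.tsv")
    man.add_stage(
        "ppi",
        compound_net=[g_cmp.number_of_nodes(), g_cmp.number_of_edges()],
        disease_net=[g_dis.number_of_nodes(), g_dis.number_of_edges()],
        combined=[g.number_of_nodes(), g.number_of_edges()],
    )

    if g.number_of_nodes() == 0:
        raise PipelineError("stage 'hubs': combined network is empty")
    table = _stage("hubs", net.centralities, g, manifest=man)
    table.to_csv(outdir / "centrality.tsv", sep="\t")
    crit = net.HubCriteria(include_nc=bool(config.network.get("include_nc", False)))
    hubs, cuts = net.extract_hubs(table, crit)
    pio.write_id_list(hubs, outdir / "hubs.txt")
    man.add_stage("hubs", n_hubs=len(hubs), cutoffs=cuts)

    collection = _stage(
        "enrichment", pio.read_gmt, config.path("gene_sets"), manifest=man
    )
    man.add_input("gene_sets", config.path("gene_sets"))
    query = set(hubs) & collection.universe
    if query:
        enr = _stage(
            "enrichment",
            ora,
            query,
            collection,
            ease=bool(config.enrichment.get("ease", False)),
            q_cutoff=float(config.enrichment.get("q_cutoff", 0.05)),
            manifest=man,
        )
    else:
        enr = pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p", "q", "enriched"]
        )
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    man.add_stage("enrichment", n_tested=len(enr), n_enriched=int(enr["enriched"].sum()) if len(enr) else 0)

    _write_json(
        {
            "n_candidates": len(result.retained),
            "n_targets": len(targets),
            "combined_nodes": g.number_of_nodes(),
            "combined_edges": g.number_of_edges(),
            "n_hubs": len(hubs),
            "n_enriched_terms": int(enr["enriched"].sum()) if len(enr) else 0,
        },
        outdir / "summary.json",
    )
    man.write(outdir)
    return outdir


# -- omics flow --------------------------------------------------------------

def run_omics(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(config, "omics")

    table = _stage(
        "microbiome",
        pio.read_count_table,
        config.path("otu_counts"),
        config.path("otu_metadata"),
        config.path("otu_taxonomy"),
        manifest=man,
    )
    for key in ("otu_counts", "otu_metadata", "otu_taxonomy"):
        man.add_input(key, config.path(key))
    rare = int(config.microbiome.get("rare_cutoff", 10))
    alpha = _stage("microbiome", mic.alpha_diversity, table, rare, manifest=man)
    alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t")
    rank = config.microbiome.get("rank", "species")
    grps = config.microbiome.get("groups")
    if grps is None:
        grps = sorted(table.groups.unique())[:2]
    da = _stage(
        "microbiome", mic.diff_abundance, table, rank, grps[0], grps[1], manifest=man
    )
    da.to_csv(outdir / "diff_abundance.tsv", sep="\t", index=False)
    n_da = int((da["q"] < 0.05).sum())
    man.add_stage("microbiome", n_samples=len(alpha), n_taxa_tested=len(da), n_differential=n_da)

    matrix = _stage(
        "metabolome", pio.read_intensity_csv, config.path("intensities"), manifest=man
    )
    man.add_input("intensities", config.path("intensities"))
    bio = matrix.biological()
    ncomp = int(config.metabolome.get("n_components", 2))
    pca_res = _stage(
        "metabolome",
        met.pca,
        met.impute_half_min(matrix.intensities).apply(pd.to_numeric),
        manifest=man,
    )
    scores = pca_res.scores.iloc[:, : min(5, pca_res.scores.shape[1])].copy()
    scores.insert(0, "group", matrix.groups)
    scores.rename_axis("sample_id").to_csv(outdir / "pca_scores.tsv", sep="\t")
    mgrps = config.metabolome.get("groups")
    if mgrps is None:
        mgrps = sorted(bio.groups.unique())[:2]
    sub = bio.groups.isin(mgrps)
    sel = _stage(
        "metabolome",
        met.select_differential,
        bio.intensities.loc[sub],
        bio.groups.loc[sub],
        n_components=ncomp,
        log_transform=bool(config.metabolome.get("log_transform", True)),
        adjust=bool(config.metabolome.get("adjust", False)),
        manifest=man,
    )
    sel.rename_axis("feature").to_csv(outdir / "metabolite_selection.tsv", sep="\t")
    selected = sorted(sel.index[sel["selected"]])
    pio.write_id_list(selected, outdir / "selected_metabolites.txt")
    man.add_stage("metabolome", n_features=len(sel), n_selected=len(selected))

    _write_json(
        {
            "alpha_diversity_mean_shannon": float(alpha["shannon"].mean()),
            "n_differential_taxa_q05": n_da,
            "n_selected_metabolites": len(selected),
        },
        outdir / "summary.json",
    )
    man.write(outdir)
    return outdir


# -- efficacy flow -----------------------------------------------------------

def run_efficacy(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    man = _Manifest(config, "efficacy")

    meas = _stage(
        "efficacy", pio.read_measurements, config.path("measurements"), manifest=man
    )
    man.add_input("measurements", config.path("measurements"))
    units = config.efficacy.get("units", "mm3")
    summaries = _stage("efficacy", eff.arm_summaries, meas, units, manifest=man)
    summaries.to_csv(outdir / "arm_summaries.tsv", sep="\t", index=False)

    day = int(config.efficacy.get("day", meas["day"].max()))
    control = config.efficacy.get("control_arm", "control")
    convention = config.efficacy.get("tgi_convention", "ratio_of_means")
    at_day = meas[meas["day"] == day]
    vols = {
        arm: sub.groupby("mouse_id")
        .apply(
            lambda g: sum(
                eff.tumour_volume(l, w) for l, w in zip(g["length_mm"], g["width_mm"])
            )
            / len(g),
            include_groups=False,
        )
        .to_numpy()
        for arm, sub in at_day.groupby("arm")
    }
    if control not in vols:
        raise PipelineError(f"stage 'efficacy': control arm {control!r} absent at day {day}")
    tgi_rows = [
        {
            "arm": arm,
            "day": day,
            "tgi_percent": eff.tgi_from_volumes(vols[arm], vols[control], convention),
        }
        for arm in sorted(vols)
        if arm != control
    ]
    tgi_df = pd.DataFrame(tgi_rows)
    tgi_df.to_csv(outdir / "tgi.tsv", sep="\t", index=False)

    stats_df = _stage(
        "efficacy", eff.compare_arms, meas, day, "anova_bh", manifest=man
    )
    stats_df.to_csv(outdir / "arm_statistics.tsv", sep="\t", index=False)
    man.add_stage(
        "efficacy", n_measurements=len(meas), n_arms=len(vols), day=day
    )

    _write_json(
        {
            "day": day,
            "tgi_percent": {r["arm"]: r["tgi_percent"] for r in tgi_rows},
            "anova_p": stats_df.attrs.get("anova_p"),
        },
        outdir / "summary.json",
    )
    man.write(outdir)
    return outdir


def run_all(config: PipelineConfig, outdir) -> Path:
    outdir = Path(outdir)
    run_netpharm(config, outdir / "netpharm")
    run_omics(config, outdir / "omics")
    run_efficacy(config, outdir / "efficacy")
    return outdir


# -- fixture writer ----------------------------------------------------------

def simulate_fixture(spec: sim.SimulationSpec, outdir) -> Path:
    """Write a complete synthetic fixture directory (all inputs, a
    ready-to-run ``config.yaml`` and the planted ground truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    compounds = sim.gen_compound_table(spec)
    pio.write_compound_table(compounds, outdir / "compounds.csv")
    mapping = sim.gen_target_map(spec)
    pio.write_mapping(mapping, outdir / "target_map.tsv")
    g, hubs = sim.gen_ppi(spec)
    pio.write_edge_list(g.edges, outdir / "ppi_edges.tsv")
    disease = sim.gen_disease_targets(spec)
    pio.write_id_list(disease, outdir / "disease_targets.txt")
    protein_sets = sim.gen_protein_sets(spec)
    pio.write_gmt(protein_sets, outdir / "gene_sets.gmt")
    collection, query, planted_terms = sim.gen_gene_sets(spec)
    pio.write_gmt(collection, outdir / "standalone_gene_sets.gmt")
    pio.write_id_list(query, outdir / "query_genes.txt")
    otu, planted_taxa = sim.gen_otu_table(spec)
    pio.write_count_table(
        otu,
        outdir / "otu_counts.tsv",
        outdir / "otu_metadata.tsv",
        outdir / "otu_taxonomy.tsv",
    )
    matrix, planted_features = sim.gen_metabolome(spec)
    pio.write_intensity_csv(matrix, outdir / "intensities.csv")
    meas = sim.gen_growth_data(spec)
    pio.write_measurements(meas, outdir / "measurements.csv")

    _write_json(
        {
            "planted_hubs": hubs,
            "planted_terms": planted_terms,
            "planted_taxa": planted_taxa,
            "planted_metabolites": planted_features,
            "arms": [list(a) for a in spec.arms],
            "seed": spec.seed,
        },
        outdir / "truth.json",
    )
    config = {
        "inputs": {
            "compound_table": "compounds.csv",
            "target_map": "target_map.tsv",
            "ppi_edges": "ppi_edges.tsv",
            "disease_targets": "disease_targets.txt",
            "gene_sets": "gene_sets.gmt",
            "otu_counts": "otu_counts.tsv",
            "otu_metadata": "otu_metadata.tsv",
            "otu_taxonomy": "otu_taxonomy.tsv",
            "intensities": "intensities.csv",
            "measurements": "measurements.csv",
        },
        "seed": spec.seed,
    }
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return outdir
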