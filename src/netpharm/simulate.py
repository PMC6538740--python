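"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates one study design consumed by the pipeline and
plants a known ground truth so that parameter-recovery and
null-calibration tests are possible:

* compound tables with a planted number of ADME passers,
* scale-free protein-interaction graphs (preferential attachment) whose
  earliest nodes are the planted hubs,
* gene-set collections with planted enriched terms and a matching query
  gene list,
* Dirichlet-multinomial OTU count tables with planted fold-changed taxa,
* log-normal metabolite intensity matrices with planted log2 shifts,
* exponential tumour-growth caliper series with per-arm growth-rate
  multipliers and multiplicative log-normal noise.

All randomness flows from the single root seed of the
:class:`SimulationSpec`; each generator draws from its own
deterministically-derived stream, so identical specs give byte-identical
outputs regardless of the order generators are called in.

The ``reference_*`` helpers build fully deterministic synthetic
stand-ins whose marginal counts match the published compound and
disease-target tables (476 compounds / 138 candidates with herb
contributions 18/143/48/280 and 4/36/14/90; disease lists of 47/111/7
ids deduplicating to 150); they contain no real chemistry and exist for
count-level checks only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import GeneSetCollection
from .microbiome import RANKS, CountTable
from .metabolome import IntensityMatrix

__all__ = [
    "InvalidSpecError",
    "SimulationSpec",
    "gen_compound_table",
    "gen_ppi",
    "gen_target_map",
    "gen_disease_targets",
    "gen_gene_sets",
    "gen_protein_sets",
    "gen_otu_table",
    "gen_metabolome",
    "gen_growth_data",
    "reference_compound_table",
    "reference_disease_lists",
    "HERBS",
]

HERBS = ["Radix Puerariae", "Scutellariae Radix", "Coptidis Rhizoma", "Liquorice"]

DEFAULT_ARMS: tuple[tuple[str, float], ...] = (
    ("control", 1.00),
    ("gqd_high", 0.94),
    ("pd1", 0.87),
    ("gqd_pd1", 0.76),
)


class InvalidSpecError(ValueError):
    """A simulation spec with impossible or degenerate parameters."""


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one synthetic study.

    Counts are per the emulated designs: a four-herb compound table of
    476 chemicals of which 138/476 pass the ADME filter; a 300-node
    scale-free interaction graph grown with 3 edges per new node; 50
    annotation terms of which 3 are planted enriched; 12 samples per
    group for the count/intensity designs; 60 taxa with 6 planted at
    4-fold; 200 metabolite features with 10 planted at a 3-log2 shift;
    four treatment arms with growth-rate multipliers ordered like the
    emulated efficacy study; 30 % multiplicative caliper noise.
    """

    seed: int = 0
    n_compounds: int = 476
    frac_pass_adme: float = 138 / 476
    ppi_nodes: int = 300
    ppi_attach_edges: int = 3
    n_gene_sets: int = 50
    n_universe_genes: int = 1000
    planted_enriched_terms: tuple[str, ...] = ("T001", "T002", "T003")
    n_samples_per_group: int = 12
    n_taxa: int = 60
    n_diff_taxa: int = 6
    taxon_fold_change: float = 4.0
    sequencing_depth: int = 20000
    n_metabolites: int = 200
    n_diff_metabolites: int = 10
    metabolite_log2_shift: float = 3.0
    n_qc_samples: int = 3
    arms: tuple[tuple[str, float], ...] = DEFAULT_ARMS
    n_mice_per_arm: int = 8
    noise_cv: float = 0.30
    targets_per_compound: float = 3.0
    n_disease_targets: int = 60

    def __post_init__(self) -> None:
        counts = {
            "n_compounds": self.n_compounds,
            "ppi_nodes": self.ppi_nodes,
            "n_gene_sets": self.n_gene_sets,
            "n_universe_genes": self.n_universe_genes,
            "n_samples_per_group": self.n_samples_per_group,
            "n_taxa": self.n_taxa,
            "n_diff_taxa": self.n_diff_taxa,
            "n_metabolites": self.n_metabolites,
            "n_diff_metabolites": self.n_diff_metabolites,
            "n_qc_samples": self.n_qc_samples,
            "n_mice_per_arm": self.n_mice_per_arm,
            "n_disease_targets": self.n_disease_targets,
        }
        for name, value in counts.items():
            if value < 0:
                raise InvalidSpecError(f"{name} must be >= 0; got {value}")
        if not 0.0 <= self.frac_pass_adme <= 1.0:
            raise InvalidSpecError(
                f"frac_pass_adme must lie in [0, 1]; got {self.frac_pass_adme}"
            )
        if self.noise_cv < 0:
            raise InvalidSpecError(f"noise_cv must be >= 0; got {self.noise_cv}")
        if self.taxon_fold_change <= 0:
            raise InvalidSpecError("taxon_fold_change must be positive")
        if not (self.ppi_nodes > self.ppi_attach_edges >= 1):
            raise InvalidSpecError(
                "require ppi_nodes > ppi_attach_edges >= 1; "
                f"got {self.ppi_nodes}, {self.ppi_attach_edges}"
            )
        if self.n_diff_taxa > self.n_taxa:
            raise InvalidSpecError("n_diff_taxa exceeds n_taxa")
        if self.n_diff_metabolites > self.n_metabolites:
            raise InvalidSpecError("n_diff_metabolites exceeds n_metabolites")


# fixed stream index per generator; keeps outputs independent of call order
_STREAMS = {
    "compounds": 1,
    "ppi": 2,
    "target_map": 3,
    "disease": 4,
    "gene_sets": 5,
    "otu": 6,
    "metabolome": 7,
    "growth": 8,
    "protein_sets": 9,
}


def _rng(spec: SimulationSpec, stream: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(_STREAMS[stream],))
    return np.random.default_rng(ss)


# -- compounds ---------------------------------------------------------------

def gen_compound_table(spec: SimulationSpec) -> pd.DataFrame:
    """Compound table with exactly round(frac_pass_adme * n) ADME passers.

    OB is drawn log-normal and DL beta, then rejection-adjusted so the
    planted compounds satisfy OB > 30 and DL > 0.18 and the rest fail at
    least one criterion.  Herb labels cycle round-robin over the four
    herbs of the formula.
    """
    if spec.n_compounds < 1:
        raise InvalidSpecError("n_compounds must be >= 1")
    rng = _rng(spec, "compounds")
    n = spec.n_compounds
    n_pass = int(round(spec.frac_pass_adme * n))
    passers = set(rng.choice(n, size=n_pass, replace=False).tolist())

    rows = []
    for i in range(n):
        want_pass = i in passers
        while True:
            ob = float(rng.lognormal(mean=np.log(20.0), sigma=0.9))
            dl = float(rng.beta(1.5, 4.0))
            if (ob > 30.0 and dl > 0.18) == want_pass:
                break
        rows.append(
            {
                "compound_id": f"C{i + 1:04d}",
                "name": f"compound-{i + 1}",
                "herbs": frozenset({HERBS[i % len(HERBS)]}),
                "ob_percent": round(ob, 4),
                "dl": round(dl, 4),
            }
        )
    return pd.DataFrame(rows)


# -- interaction graph -------------------------------------------------------

def _protein_id(i: int) -> str:
    return f"P{i + 1:04d}"


def gen_ppi(spec: SimulationSpec) -> tuple[nx.Graph, list[str]]:
    """Scale-free PPI graph by preferential attachment with planted hubs.

    The graph is grown Barabasi-Albert style (each new node attaches
    ``ppi_attach_edges`` edges), giving m*(n-m) edges, and is connected
    and simple.  The planted hubs are the ``ppi_attach_edges`` earliest
    nodes, which have the highest expected degree.
    """
    rng = _rng(spec, "ppi")
    n, m = spec.ppi_nodes, spec.ppi_attach_edges
    g0 = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
    relabel = {i: _protein_id(i) for i in g0.nodes}
    g = nx.relabel_nodes(g0, relabel)
    nx.set_node_attributes(g, "protein", "kind")
    hubs = [_protein_id(i) for i in range(m)]
    return g, hubs


def gen_target_map(spec: SimulationSpec) -> dict[str, set[str]]:
    """Compound -> target mapping onto the PPI node universe.

    Target counts per compound are Poisson(targets_per_compound); some
    compounds map to nothing.  Planted hubs are favoured as targets so
    the seeded PPI subnetwork retains them.
    """
    rng = _rng(spec, "target_map")
    g, hubs = gen_ppi(spec)
    proteins = sorted(g.nodes)
    weights = np.array([g.degree[p] for p in proteins], dtype=float)
    weights /= weights.sum()
    mapping: dict[str, set[str]] = {}
    for i in range(spec.n_compounds):
        k = int(rng.poisson(spec.targets_per_compound))
        if k == 0:
            continue
        k = min(k, len(proteins))
        chosen = rng.choice(len(proteins), size=k, replace=False, p=weights)
        mapping[f"C{i + 1:04d}"] = {proteins[j] for j in chosen}
    return mapping


def gen_disease_targets(spec: SimulationSpec) -> list[str]:
    """Disease-associated target list drawn from the PPI nodes,
    degree-weighted so it overlaps the compound-target neighbourhood."""
    rng = _rng(spec, "disease")
    g, _ = gen_ppi(spec)
    proteins = sorted(g.nodes)
    weights = np.array([g.degree[p] for p in proteins], dtype=float)
    weights /= weights.sum()
    k = min(spec.n_disease_targets, len(proteins))
    chosen = rng.choice(len(proteins), size=k, replace=False, p=weights)
    return sorted(proteins[j] for j in chosen)


# -- gene sets ---------------------------------------------------------------

def gen_gene_sets(
    spec: SimulationSpec,
) -> tuple[GeneSetCollection, list[str], list[str]]:
    """Annotation collection plus a query list enriched for the planted
    terms.

    Returns (collection, query gene list, planted term ids).  The query
    contains ~60 % of each planted term's members plus random background
    genes, so planted terms are strongly over-represented while the
    background is null.
    """
    rng = _rng(spec, "gene_sets")
    universe = [f"G{i + 1:04d}" for i in range(spec.n_universe_genes)]
    term_ids = [f"T{i + 1:03d}" for i in range(spec.n_gene_sets)]
    planted = [t for t in spec.planted_enriched_terms]
    unknown = set(planted) - set(term_ids)
    if unknown:
        raise InvalidSpecError(f"planted term ids outside the collection: {sorted(unknown)}")

    terms = {}
    for tid in term_ids:
        size = int(rng.integers(15, 40))
        members = rng.choice(spec.n_universe_genes, size=size, replace=False)
        terms[tid] = (f"pathway {tid}", frozenset(universe[j] for j in members))

    query: set[str] = set()
    for tid in planted:
        members = sorted(terms[tid][1])
        take = max(int(round(0.6 * len(members))), 1)
        picked = rng.choice(len(members), size=take, replace=False)
        query.update(members[j] for j in picked)
    n_background = 40
    background = rng.choice(spec.n_universe_genes, size=n_background, replace=False)
    query.update(universe[j] for j in background)
    return GeneSetCollection(terms, frozenset(universe)), sorted(query), planted


def gen_protein_sets(spec: SimulationSpec) -> GeneSetCollection:
    """Annotation collection over the PPI protein universe, for the
    end-to-end flow where the enrichment query is the extracted hub set.

    One term per planted hub is seeded with that hub plus a sample of
    high-degree proteins; the remaining terms are random subsets.
    """
    rng = _rng(spec, "protein_sets")
    g, hubs = gen_ppi(spec)
    proteins = sorted(g.nodes)
    by_degree = sorted(proteins, key=lambda p: (-g.degree[p], p))
    top = by_degree[: max(len(proteins) // 10, len(hubs))]
    terms = {}
    for i, hub in enumerate(hubs):
        size = int(rng.integers(10, 20))
        picked = rng.choice(len(top), size=min(size, len(top)), replace=False)
        members = {top[j] for j in picked} | {hub}
        terms[f"PT{i + 1:03d}"] = (f"hub pathway {i + 1}", frozenset(members))
    for i in range(len(hubs), spec.n_gene_sets):
        size = int(rng.integers(10, 30))
        picked = rng.choice(len(proteins), size=min(size, len(proteins)), replace=False)
        terms[f"PT{i + 1:03d}"] = (
            f"protein set {i + 1}",
            frozenset(proteins[j] for j in picked),
        )
    return GeneSetCollection(terms, frozenset(proteins))


# -- OTU counts --------------------------------------------------------------

def gen_otu_table(spec: SimulationSpec) -> tuple[CountTable, list[str]]:
    """Dirichlet-multinomial OTU table with planted fold-changed taxa.

    Base taxon proportions are log-normal; the ``n_diff_taxa`` planted
    taxa (drawn from the upper half of the base-abundance distribution,
    so the planted signal is detectable rather than buried in sampling
    noise) have their base proportions multiplied by
    ``taxon_fold_change`` in the treatment group.  Per-sample
    compositions are Dirichlet (concentration 300) around the group
    proportions and counts are multinomial at the sequencing depth.
    Returns (table, planted species labels).
    """
    if spec.n_samples_per_group < 2:
        raise InvalidSpecError("need at least 2 samples per group")
    rng = _rng(spec, "otu")
    n_taxa = spec.n_taxa
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    props_control = base / base.sum()

    order = np.argsort(props_control)
    upper_half = order[n_taxa // 2:]
    planted_idx = rng.choice(upper_half, size=spec.n_diff_taxa, replace=False)
    mult = np.ones(n_taxa)
    mult[planted_idx] = spec.taxon_fold_change
    props_treat = props_control * mult
    props_treat /= props_treat.sum()

    taxa = [f"OTU{i + 1:03d}" for i in range(n_taxa)]
    concentration = 300.0
    rows, sample_ids, groups = [], [], []
    for group, props in (("control", props_control), ("treatment", props_treat)):
        for s in range(spec.n_samples_per_group):
            p = rng.dirichlet(np.maximum(props, 1e-12) * concentration)
            counts = rng.multinomial(spec.sequencing_depth, p)
            rows.append(counts)
            sample_ids.append(f"{group[0].upper()}{s + 1:02d}")
            groups.append(group)

    counts = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    counts.index.name = "sample_id"
    taxonomy = pd.DataFrame(
        {
            "domain": "Bacteria",
            "phylum": [f"phylum_{i % 4 + 1}" for i in range(n_taxa)],
            "class": [f"class_{i % 8 + 1}" for i in range(n_taxa)],
            "order": [f"order_{i % 12 + 1}" for i in range(n_taxa)],
            "family": [f"family_{i % 20 + 1}" for i in range(n_taxa)],
            "genus": [f"g__{t}" for t in taxa],
            "species": [f"s__{t}" for t in taxa],
        },
        index=pd.Index(taxa, name="taxon_id"),
    )[RANKS]
    table = CountTable(
        counts=counts,
        groups=pd.Series(groups, index=counts.index, name="group"),
        taxonomy=taxonomy,
    )
    planted = sorted(f"s__{taxa[i]}" for i in planted_idx)
    return table, planted


# -- metabolite intensities --------------------------------------------------

def gen_metabolome(spec: SimulationSpec) -> tuple[IntensityMatrix, list[str]]:
    """Log-normal intensity matrix with planted group shifts.

    Per-feature baseline log-intensities are Gaussian; within-group
    variation is Gaussian on the log scale (sd 0.4).  Planted features
    gain ``metabolite_log2_shift`` log2 units in the treatment group.
    Pooled-QC injections sit at the grand mean with small noise.
    Returns (matrix, planted feature ids).
    """
    if spec.n_samples_per_group < 2:
        raise InvalidSpecError("need at least 2 samples per group")
    rng = _rng(spec, "metabolome")
    p = spec.n_metabolites
    features = [f"M{j + 1:04d}" for j in range(p)]
    mu = rng.normal(12.0, 1.0, size=p)
    planted_idx = rng.choice(p, size=spec.n_diff_metabolites, replace=False)
    shift = np.zeros(p)
    shift[planted_idx] = spec.metabolite_log2_shift * np.log(2.0)
    sd = 0.4

    blocks, sample_ids, groups, qc_flags = [], [], [], []
    for group, delta in (("control", 0.0), ("treatment", 1.0)):
        log_int = mu + delta * shift + rng.normal(
            0.0, sd, size=(spec.n_samples_per_group, p)
        )
        blocks.append(log_int)
        sample_ids += [f"{group[0].upper()}M{s + 1:02d}" for s in range(spec.n_samples_per_group)]
        groups += [group] * spec.n_samples_per_group
        qc_flags += [False] * spec.n_samples_per_group
    grand = mu + shift / 2.0
    qc = grand + rng.normal(0.0, 0.1, size=(spec.n_qc_samples, p))
    blocks.append(qc)
    sample_ids += [f"QC{s + 1:02d}" for s in range(spec.n_qc_samples)]
    groups += ["QC"] * spec.n_qc_samples
    qc_flags += [True] * spec.n_qc_samples

    intensities = pd.DataFrame(
        np.exp(np.vstack(blocks)), index=sample_ids, columns=features
    )
    intensities.index.name = "sample_id"
    matrix = IntensityMatrix(
        intensities=intensities,
        groups=pd.Series(groups, index=intensities.index, name="group"),
        is_qc=pd.Series(qc_flags, index=intensities.index, name="is_qc"),
    )
    return matrix, sorted(features[j] for j in planted_idx)


# -- tumour growth -----------------------------------------------------------

#: control growth rate: 50 mm^3 at day 0 reaching ~8500 mm^3 at day 32
_GROWTH_RATE = float(np.log(8496.0 / 50.0) / 32.0)


def gen_growth_data(spec: SimulationSpec) -> pd.DataFrame:
    """Caliper measurement table under exponential volume growth.

    Each arm multiplies the control growth rate by its multiplier;
    volumes carry multiplicative log-normal noise of CV ``noise_cv``;
    length/width come from the volume via a random prolate aspect ratio
    in [1.2, 1.8] and V = length * width^2 / 2.
    """
    if spec.n_mice_per_arm < 2:
        raise InvalidSpecError("need at least 2 mice per arm")
    rng = _rng(spec, "growth")
    sigma = float(np.sqrt(np.log(1.0 + spec.noise_cv**2)))
    days = list(range(0, 33, 4))
    rows = []
    for arm, mult in spec.arms:
        for mouse in range(spec.n_mice_per_arm):
            mouse_id = f"{arm}-{mouse + 1:02d}"
            for day in days:
                v = 50.0 * np.exp(_GROWTH_RATE * mult * day)
                v *= float(np.exp(rng.normal(0.0, sigma)))
                aspect = float(rng.uniform(1.2, 1.8))
                width = (2.0 * v / aspect) ** (1.0 / 3.0)
                length = aspect * width
                rows.append(
                    {
                        "mouse_id": mouse_id,
                        "arm": arm,
                        "day": day,
                        "length_mm": round(length, 3),
                        "width_mm": round(width, 3),
                    }
                )
    return pd.DataFrame(rows)


# -- deterministic printed-marginal stand-ins --------------------------------

def reference_compound_table() -> pd.DataFrame:
    """SYNTHETIC stand-in for the published four-herb compound table.

    Fully deterministic, no real chemistry: 476 distinct compounds whose
    herb memberships sum to 18/143/48/280 (13 compounds shared between
    two herbs) and whose ADME passers number 138 distinct with per-herb
    candidate counts 4/36/14/90 (6 shared passers).  Built for
    count-level checks of the screening stage only.
    """
    herb_sizes = dict(zip(HERBS, [18, 143, 48, 280]))
    herb_pass = dict(zip(HERBS, [4, 36, 14, 90]))
    shared_total, shared_pass = 13, 6  # between Scutellariae Radix and Liquorice
    h2, h4 = HERBS[1], HERBS[3]

    rows = []
    idx = 0

    def add(herbs: frozenset[str], passes: bool) -> None:
        nonlocal idx
        idx += 1
        rows.append(
            {
                "compound_id": f"R{idx:04d}",
                "name": f"ref-compound-{idx}",
                "herbs": herbs,
                "ob_percent": 40.0 + (idx % 50) * 0.1 if passes else 12.0 + (idx % 30) * 0.1,
                "dl": 0.35 if passes else 0.05,
            }
        )

    for _ in range(shared_pass):
        add(frozenset({h2, h4}), True)
    for _ in range(shared_total - shared_pass):
        add(frozenset({h2, h4}), False)
    for herb in HERBS:
        n_shared = shared_total if herb in (h2, h4) else 0
        p_shared = shared_pass if herb in (h2, h4) else 0
        n_unique = herb_sizes[herb] - n_shared
        p_unique = herb_pass[herb] - p_shared
        for _ in range(p_unique):
            add(frozenset({herb}), True)
        for _ in range(n_unique - p_unique):
            add(frozenset({herb}), False)
    return pd.DataFrame(rows)


def reference_disease_lists() -> dict[str, list[str]]:
    """SYNTHETIC stand-in for the three disease-target source lists.

    Deterministic id lists sized 47 (inherited-disease catalogue), 111
    (genetic-association catalogue) and 7 (therapeutic-target catalogue)
    whose union deduplicates to 150 ids: 13 ids shared between the first
    two lists and 2 between the last two.
    """
    omim = [f"D{i + 1:04d}" for i in range(47)]
    gad = [f"D{i + 1:04d}" for i in range(13)] + [
        f"D{i + 1:04d}" for i in range(47, 47 + 98)
    ]
    ttd = [f"D{i + 1:04d}" for i in range(145, 150)] + [
        f"D{i + 1:04d}" for i in range(143, 145)
    ]
    assert len(gad) == 111 and len(ttd) == 7
    return {"omim": omim, "gad": gad, "ttd": ttd}
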