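# Methods

`netpharm` implements the computational core of a multi-herb
network-pharmacology study and its downstream animal-model statistics:
candidate-compound screening, interaction-network hub extraction,
pathway over-representation, xenograft efficacy metrics, 16S
alpha-diversity and differential abundance, and PLS-DA/VIP metabolite
selection.  This note records the models, the defaults and their
rationale, the numerical choices, and what the synthetic-data generators
do and do not emulate.

## Candidate-compound screening

A compound is a candidate when its annotated oral bioavailability
exceeds 30 % and its drug-likeness exceeds 0.18.  Both comparisons are
strict (`>`), the literal reading of the conventional cut-offs; an
inclusive (`>=`) mode exists for boundary-sensitivity checks because
sources rarely state how exact boundary values were handled.  Compounds
shared by several herbs count once in the distinct candidate total but
once per herb in the per-herb counts, which is why herb contributions
can sum to more than the distinct total (e.g. 4+36+14+90 = 144 herb
memberships for 138 distinct candidates).  Rows with missing OB or DL
are excluded with a warning rather than treated as failing, so the
caller can distinguish "screened out" from "not annotated".

## Networks and hub extraction

Networks are undirected simple graphs.  The protein-interaction network
around a seed set is built with first-neighbour expansion by default
(seeds plus all direct interactors, with every edge among included
nodes); expansion is the only way a few hundred seed proteins can yield
a several-thousand-node network, which is the regime this procedure is
meant for.  Combining the compound-target and disease-target networks
defaults to the *intersection* of node and edge sets — the combined
networks this procedure produces are far smaller than either input,
which only intersection explains — with union ("merge") available by
flag.

Hub extraction computes four per-node centralities:

- **DC** — degree;
- **BC** — shortest-path betweenness, normalised by `(n−1)(n−2)/2`;
- **CC** — closeness with the Wasserman–Faust adjustment (per-component
  closeness scaled by the component's share of the graph), so values
  remain comparable on disconnected graphs;
- **NC** — arithmetic mean of neighbour degrees ("neighbourhood
  connectivity"), 0 for isolated nodes.

Hubs are nodes strictly above the network medians of DC, BC and CC.
"Network centrality" is an ambiguous name with no standard definition;
mean neighbour degree is the interpretation used here, and NC is
therefore reported but *not* part of the default hub filter (published
hub screens of this kind quote exactly three median cut-offs).  A flag
adds the NC median as a fourth condition.  Medians are computed on the
network actually being filtered.  All reports are sorted
lexicographically so repeated runs are byte-identical.

The centralities are computed by networkx; the test suite holds them to
exhaustive-enumeration oracles (all shortest paths enumerated for
betweenness, Floyd–Warshall distances for closeness) on 200 random
graphs of up to 8 nodes, exact to 1e−12.

## Over-representation analysis

For a universe of `N` ids, a term with `K` members and a query of `n`
ids overlapping the term in `k`, the p-value is the hypergeometric upper
tail `P(X ≥ k)`; `k = 0` terms are not tested and do not count toward
the number of tests, matching the behaviour of the common annotation
servers.  The EASE variant (test `k−1` instead of `k`; a conservative
jackknife) is available by flag, since some servers apply it silently —
neither variant is asserted to be what any given published table used.
The universe defaults to the union of all collection members and is
configurable; published analyses rarely state their background, and the
choice matters.  Benjamini–Hochberg is the package's own step-up
implementation (`q_(i) = min_{j≥i} m·p_(j)/j`, clipped at 1), verified
against `statsmodels` in the tests; terms are called enriched at
q < 0.05.

## Xenograft efficacy

Tumour volume uses the ellipsoid caliper approximation
`V = length × width² / 2`; if width exceeds length the two are swapped
with a warning (caliper convention: length is the larger diameter).
Tumour growth inhibition is

    TGI (%) = [1 − V_treated / V_control] × 100,

computed by default on arm mean volumes (ratio of means).  A per-mouse
mean-of-ratios convention is also provided because published tables do
not always follow a single convention: on the published day-32 volumes,
the ratio of means reproduces the high-dose arm's printed 26.836 % to
three decimals, while the printed PD-1-arm TGI (48.216 %) is
inconsistent with its own printed volumes (4.847 vs 8.496 cm³ implies
≈ 42.95 %).  The package reports what the volumes imply and does not
guess the intended value.  Between-arm comparisons use unpaired
two-sided Student t-tests (equal-variance per the usual reporting
convention; Welch by flag) or one-way ANOVA followed by BH-adjusted
pairwise tests.  Volumes are internal mm³ with a cm³ display flag.
"Relative tumour volume" in source tables is treated as absolute mean
volume; no baseline normalisation is applied because none is stated
anywhere such tables appear.

## Microbiome statistics

Alpha diversity is computed from the frequency-of-frequencies summary
of each sample (`F_i` = number of taxa seen exactly `i` times; the
identities `Σ F_i = S_obs` and `Σ i·F_i = N` are asserted on every
sample):

- **Shannon** `H = −Σ p_i ln p_i` with natural log (the mothur
  convention); log2 by flag.
- **Chao1**, bias-corrected by default
  (`S_obs + F1(F1−1)/(2(F2+1))`, again the mothur default); the classic
  `S_obs + F1²/(2F2)` form by flag.
- **ACE** with rare cut-off 10 (standard).  When every rare taxon is a
  singleton the coverage estimate is 0 and ACE is undefined; the
  implementation falls back to Chao1 with a warning.

These are hand-authored to pin the exact variants and the degenerate
fall-back, and are cross-checked against scikit-bio in the tests.

Differential abundance aggregates per-sample *relative* abundances to a
taxonomic rank (no rarefaction — no sensible depth can be imposed on
data whose processing depth is unknown) and applies the two-sided
Wilcoxon rank-sum test per taxon: the exact null distribution when both
groups have ≤ 10 samples and the pooled data are tie-free, otherwise
the normal approximation with tie and continuity corrections.  The
exact-by-default rule matters: exhaustive enumeration shows the
continuity-corrected normal p can deviate from the exact p by up to
0.088 for 2-per-group splits and exceeds 0.02 whenever a group has
fewer than ~5 samples; from 5 per group the deviation stays below
0.018.  q-values are BH-adjusted across taxa; effect direction is the
difference in group mean relative abundance.  A Kruskal–Wallis option
covers multi-group tables.  LEfSe-style LDA effect sizes are
deliberately not reimplemented; users who need them should run the
original tool.

## Metabolomics

Intensities are made positive by half-minimum imputation and analysed on
the natural-log scale (standard for LC-MS); a raw-scale flag exists.
PCA is the SVD of the centred, unit-variance-scaled matrix with a
deterministic sign convention (each loading vector's largest-magnitude
entry made positive), so repeated runs and platform changes cannot flip
score plots.  Zero-variance features are dropped with a warning.

PLS-DA is PLS1 fitted by NIPALS on the centred class indicator, with
X-deflation; per-feature importance is

    VIP_j = sqrt( p · Σ_a SSY_a w_ja² / Σ_a SSY_a ),

where `w_a` are unit-norm X-weights and `SSY_a = q_a² t_aᵀt_a` the
response variance explained by component `a`.  The identity
`Σ_j VIP_j² = p` holds for every fit and is asserted at machine
precision.  Two components by default (the score-plot convention);
requests beyond the data's rank are truncated with a warning.  The
NIPALS weights are cross-checked against scikit-learn's PLSRegression in
the tests.  PLS-DA (rather than OPLS-DA) is an assumption of this
package — VIP in metabolomics is conventionally PLS-DA VIP — and the
component count of any given published analysis is usually unstated.

A feature is differential when VIP > 1.0 (strict) AND a two-sided
unpaired t-test on log intensities gives p < 0.05; unadjusted p is the
default because that is how such selections are conventionally phrased,
with BH gating by flag.  Note a property the tests document: under the
null the two conjuncts are strongly dependent (a random group
difference drives both), so the conjunction's null selection rate is
close to the nominal 5 % of the t-test alone — the VIP condition adds
interpretability and effect-size weighting, not extra type-I control.

Contrast set logic (`venn_specific`, `venn_expression`) answers
questions like "common to two contrasts but absent from a third" with
explicit set expressions (`(A & B) - C`) evaluated over named feature
sets; unknown names are an error rather than an empty set.

## Synthetic-data generators

All randomness descends from a single root seed; each generator draws
from its own deterministically derived stream, so outputs are identical
across runs and independent of generator call order.  The defaults are
the package's reference study conditions:

| quantity | default | emulates |
|---|---|---|
| compounds / passer fraction | 476, 138/476 | four-herb formula screening table |
| PPI nodes / attachment edges | 300, 3 | scale-free interactome (desk scale) |
| gene sets / planted enriched | 50, 3 | pathway collection with known signal |
| samples per group | 12 | per-arm 16S / metabolome group sizes |
| taxa / differential / fold | 60, 6, 4× | stool OTU table with planted taxa |
| metabolites / shifted / shift | 200, 10, 3 log2 | plasma features with planted signal |
| arms (growth multipliers) | control 1.0, single-agent 0.94 / 0.87, combination 0.76 | efficacy ordering: combination > checkpoint mono > herb mono |
| caliper noise CV | 0.30 | between-mouse volume variability |

Choices worth explaining:

- **Compound table** — OB log-normal, DL beta, rejection-adjusted so
  exactly `round(frac × n)` compounds pass; herb labels round-robin.
  Separate fully deterministic `reference_*` helpers reproduce the
  *printed marginal counts* of the emulated study's input tables
  (476 distinct compounds with herb memberships 18/143/48/280 via 13
  shared compounds; 138 distinct passers with herb counts 4/36/14/90
  via 6 shared passers; disease-target lists 47/111/7 deduplicating to
  150).  These are synthetic stand-ins for undeposited supplementary
  tables and contain no real chemistry.
- **PPI** — preferential attachment (Barabási–Albert), giving the
  heavy-tailed degree distribution that makes median-threshold hub
  extraction meaningful; `m(n−m)` edges, connected, simple.  The `m`
  earliest nodes are the planted hubs (highest expected degree).
- **OTU counts** — Dirichlet-multinomial (concentration 300, depth
  20 000), the standard overdispersion model for 16S counts.  Planted
  taxa are drawn from the upper half of the base-abundance distribution
  so the planted signal is detectable rather than buried under sampling
  noise.  Because planting a fold change renormalises the composition,
  non-planted taxa also shift slightly — the familiar compositional
  artefact, visible in the tests as extra (true) rejections beyond the
  planted set.  Null calibration therefore uses fold change 1.
- **Metabolome** — Gaussian log-intensities (sd 0.4) with the planted
  log2 shift added in the treatment group; pooled-QC injections at the
  grand mean with sd 0.1, reproducing the tight QC cluster expected in
  PCA score plots.
- **Growth data** — exponential volume growth from 50 mm³ with the
  control rate chosen so untreated tumours reach ≈ 8.5 cm³ by day 32;
  arm multipliers scale the growth rate, log-normal multiplicative noise
  at the specified CV, and length/width are emitted via a random prolate
  aspect ratio in [1.2, 1.8] so `V = L·W²/2` recovers the volume.

What the generators do **not** emulate: raw 16S reads, mass spectra or
chromatograms (all upstream processing is out of scope); real annotation
databases (gene sets are random, so no biological term names are
meaningful); compound chemistry (OB/DL are draws, not predictions);
immune readouts.  Passing recovery tests therefore demonstrates that the
statistics behave correctly under their own modelling assumptions — not
that any particular biological claim reproduces on real data, which for
the emulated study would require undeposited raw data and versioned
external databases.

## Problem sizes and determinism

The default test suite runs the full generator-to-statistics loop at the
reference conditions above, plus calibration loops of 100–200 seeded
replicates at reduced sizes (40–60 features, 8 samples per group) —
sizes chosen so each simulation remains an honest draw from the same
model family while the whole suite stays quick.  Every stochastic test
fixes its seed; hypothesis-based property tests run derandomised.  The
pipeline flows write sorted outputs and content-hashed manifests, and
re-running a flow on identical inputs is asserted to be byte-identical.

## Known limitations

- Published hub/pathway/metabolite *lists* are not reproducible from
  this package alone: they depend on unversioned external databases and
  undeposited raw data.  The package reproduces the procedures and the
  few printed numbers that are recomputable (the day-32 TGI worked
  example; marginal screening counts).
- NC is an interpretation (mean neighbour degree); conclusions that
  depend on NC specifically should not be attributed to any published
  analysis.
- The Wilcoxon normal approximation is inherently inaccurate below ~5
  samples per group (deviations up to 0.088 at 2 per group); the
  implementation sidesteps this by using the exact test for small
  tie-free groups, but callers forcing the approximation on tiny groups
  inherit the inaccuracy.
- PLS-DA VIP depends on the component count; the default of 2 is a
  convention, not an optimum, and rank-deficient data silently reduce
  the effective count (with a warning).
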