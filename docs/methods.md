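# Methods

This note records the statistical and algorithmic choices behind each
pipeline stage, the synthetic-data model the tests run against, and the
known limitations of both.

## Drug-likeness screening

A compound passes when it violates at most one of four descriptor rules —
molecular weight ≤ 500 Da, H-bond acceptors ≤ 10, H-bond donors ≤ 5,
Moriguchi logP ≤ 4.15 — *and* its Abbott oral-bioavailability score is
strictly greater than 0.50. All rule boundaries are inclusive: a compound
sitting exactly at a limit does not violate that rule. The 0.50
bioavailability gate was chosen because 0.55 is the standard Abbott default
for a rule-of-five-compliant molecule, making "> 0.50" the natural
threshold-form of the gate. Bioavailability scores are treated as the
discrete Abbott levels {0.11, 0.17, 0.55, 0.56, 0.85}; the gate only needs
the order, not the continuum.

Descriptors are normally supplied with the input table. When a table lacks
them, an optional RDKit backend computes MW/HBA/HBD from the SMILES; RDKit
has no Moriguchi logP, so the logP slot is filled with Wildman–Crippen
logP and a warning is emitted. Supplied values always win over computed
ones, preserving whatever descriptor provenance the user's table carries.

## Target-set algebra

Gene identity is the normalized symbol string (uppercase, stripped,
deduplicated); no alias or ortholog resolution is attempted, since the
upstream predictors already emit symbols. The two compound-target sources
are intersected; the three disease sources are unioned (duplicate symbols
across disease databases count once). Duplicate (compound, gene) rows
within or across sources collapse to a single link before any degree or
connectivity count — degree semantics everywhere are "distinct partners".

## PPI network and hub centralities

Edge scores may arrive on the STRING integer 0–1000 scale or already in
[0, 1]; any value above 1 switches on the 0–1000 interpretation. The
confidence cutoff (default 0.400, "medium confidence") is applied after
scaling and is inclusive, so a 400/1000 edge survives. Self-loops are
dropped and reversed duplicates collapse keeping the maximum score.

The three hub scores follow the cytoHubba definitions:

* **Degree** `Deg(v) = |N(v)|`;
* **MNC**: the order of the largest connected component of the subgraph
  induced by `N(v)` (v excluded); an isolated node scores 0;
* **MCC**: `Σ (|C| − 1)!` over the *maximal* cliques containing v.
  "Maximal" (not maximum) is the operative reading — it is what the
  plugin actually computes — and it makes an isolated node score
  `0! = 1` through its singleton maximal clique.

Maximal cliques are enumerated with pivoting Bron–Kerbosch (networkx
`find_cliques`); the test suite checks both the enumeration and all three
scores against an independent all-subsets/flood-fill brute force on random
graphs. For every node `MCC(v) ≥ Deg(v) ≥ MNC(v)`: each neighbor shares at
least one maximal clique with v, `(c−1)! ≥ c−1` for every clique size c,
and a neighbor-subgraph component cannot exceed the neighbor count; the
suite asserts the chain across ~1000 generated nodes.

Rankings break ties by ascending symbol so they are fully deterministic;
diameter and radius are computed on the largest connected component (the
study-shaped networks are connected, but degenerate inputs need a rule).
Average neighbors is reported as 2E/N rounded to three decimals.

## M-C-T network

The tripartite network contains one mushroom node, every compound with at
least one link into the common target set, and every common target so
linked; targets outside the common set are excluded. The mushroom-compound
edge is structural provenance and is excluded from the prioritization
degree — including it would shift every compound's degree by one without
changing the ranking, and excluding it makes the reported degree equal the
distinct-target count.

## Enrichment statistics

The per-term statistic is the one-sided hypergeometric upper tail
`P(X ≥ k)` with X ~ Hypergeom(N, K, n) — equivalently the one-sided Fisher
exact test — computed through the survival function, stable to N ~ 1e5.
This is a deliberate, documented substitution for proprietary web-service
scores (e.g. EASE-modified statistics) whose exact backgrounds are not
reproducible offline. Multiple testing uses Benjamini–Hochberg step-up
("Q value"). The significance gate applies to the raw p (< 0.05 by
default) with Q reported alongside. Rich factor is k/K — the standard
bubble-plot definition — and gene percentage is 100·k/n.

The universe defaults to the union of the collection's genes and the
query; supplying an explicit universe restricts both and is the
reproducible option (the default mirrors common practice when no universe
file exists, and guarantees the query is always contained). Terms with
zero overlap are omitted from the results, and Q values are adjusted
across the tested (overlapping) terms only.

Because the hypergeometric distribution is discrete, the achieved
null rejection rate at p < 0.05 is biased slightly below 0.05; the
calibration test therefore uses large terms (200–500 genes of a
1000-gene universe, query 100) where the discreteness gap is small, and
checks the empirical rate against a 3-standard-error band over 1000
simulated null queries.

## Reactivity descriptors

gap = |HOMO − LUMO|, hardness η = gap/2 (reported positive regardless of
the input sign convention — the usual convention makes (HOMO − LUMO)/2
negative, while the descriptor is conventionally quoted positive), and
softness S = 1/η. Zero hardness makes softness undefined; it is reported
as NaN with a warning rather than raised, since a degenerate gap is a data
problem, not a programming error. LUMO below HOMO triggers a warning, not
an error: sign and unit conventions of supplied orbital tables vary, and
the descriptors only depend on |HOMO − LUMO|. Units are carried through
verbatim; no conversion is attempted. A candidate is flagged as
softer-than-all-standards only on strict inequality against the smallest
standard hardness.

## Docking comparison

Per (candidate, target) pose, with the best reference = the most negative
reference score on the same target: *stronger_than_all_references* when
the candidate is strictly below the best reference; *comparable* when
within 0.5 kcal/mol of it; *weaker* otherwise. The 0.5 kcal/mol window is
a documented numeric stand-in for the prose notion of "nearly equal
affinity" and is exposed as configuration. Independently, scores strictly
below −8 kcal/mol are flagged strong binders. The worked-example table in
`docking.py` carries the candidate naphthylcarboxamide and the two
reference NSAIDs on five HIF-1-pathway targets (PDB 1M9J, 1NSI, 3HNG,
3UL7, 5WB7).

## Synthetic-data model

All generators draw from one `numpy.random.Generator` per call, seeded
from the single study seed via `SeedSequence.spawn`; identical
(configuration, seed) pairs produce byte-identical files. Defaults define
the study conditions:

* **Compounds** (27, no violators): descriptors inside physically
  plausible ranges (MW 120–480 Da for compliant rows, the violator rows
  pushed past ≥ 2 limits), bioavailability drawn from the discrete Abbott
  levels; exactly ⌊frac·n⌋ rows violate ≥ 2 rules.
* **Gene universe** (2000): synthetic HGNC-like symbols `G000001`…,
  shuffled by seed. 2000 genes is a deliberately scaled-down universe —
  large enough for stable enrichment statistics, small enough that the
  full suite runs in seconds.
* **Compound-target sources**: two pools of equal size s with designed
  intersection i = 2sJ/(1+J) so the realized Jaccard matches the requested
  overlap (0.5 by default) up to integer rounding; pool genes are spread
  over compounds (3–12 per compound per source) and every pool gene is
  force-assigned at least once, so the realized pooled sets equal the
  designed pools exactly.
* **Disease sources** (700/200/500 of the universe): the union intersects
  the compound-target pool in *exactly* `hit_overlap` (42) genes; all
  fillers come from outside the pool. The 7000-odd disease genes of a
  real aggregate are represented by this scaled union (~1000 distinct
  genes); only the engineered 42-gene overlap matters downstream.
* **PPI network**: the planted hub joins every planted clique (sizes 5,
  4, 3), touches 80% of all nodes with scores ≥ 700 (so the 0.400 cutoff
  never erodes planted structure), and background edges appear with
  probability 0.22 scoring uniformly in [150, 1000]. 0.22 was derived
  analytically so a 42-node network retains ~177 edges after filtering:
  ~44 planted + 0.22 · 817 pairs · P(score ≥ 400) ≈ 171.
* **Annotations** (50 terms, 30–80 genes): background terms sampled
  uniformly; the planted pathway term's query overlap is ⌈fold · Kn/N⌉
  (fold 5 by default), so at fold 1 it is statistically indistinguishable
  from background.
* **Orbitals/docking**: fixed anchor tables for the worked example — the
  candidate's gap is 0.1651 (hardness 0.08255), Aspirin is harder,
  Indomethacin softer; the docking table carries the five-target scores.

The study orchestrator additionally guarantees that the planted hub lies
in both pools and among the 42 common targets, that exactly 21 of the 27
compounds link into the common set (6 orphans never do), that the planted
compound has strictly the most distinct common-target links, and that
every common target is linked by some connected compound.

What the generators do *not* emulate: realistic score distributions of
similarity-ensemble or structure-based target predictors, STRING's
evidence channels beyond `combined_score`, GO's DAG structure (terms are
flat sets; no ancestor propagation), correlated term memberships, or
chemically meaningful SMILES-descriptor relationships (descriptors are
drawn independently of the structure strings). Passing tests therefore
demonstrate correctness of the algebra, statistics and graph algorithms
under controlled conditions — not robustness to the noise structure of
the live databases.

## Orchestration and reproducibility

`run_pipeline` executes the stages in funnel order, writes per-stage
tables, a JSON summary, a Markdown report and a manifest with SHA-256
checksums of every written file; stage outputs are pure functions of
(inputs, configuration, seed), so identical reruns are checksum-identical
and the manifest proves it. Any stage failure aborts with the stage name;
earlier outputs are preserved. Every threshold (0.400 confidence, 0.05
alpha, top-3 consensus, −8 kcal/mol, 0.5 kcal/mol window, Lipinski
limits) is a named configuration key.

## Problem sizes

The test suite and acceptance script run on the scaled study shape
(2000-gene universe, 42-gene query, 50 terms, 42-node networks), with
oracle cross-checks on ≤ 15-node random graphs (all-subsets clique
enumeration is exponential), null calibration on 1000 simulated queries,
and recovery rates over 20–50 generator seeds. These sizes give stable
statistics while keeping the full suite in the seconds range.

## Known limitations

* Database-dependent counts of a real study (hundreds of predicted
  targets, thousands of disease genes, the exact edge list behind a
  published network) are not reproducible without the original exports;
  the pipeline reproduces them *in rule form* on planted synthetic data.
* The enrichment statistic is plain hypergeometric, not any web service's
  modified score; term lists obtained from live annotation releases will
  differ.
* Docking and orbital energies are consumed, never computed; the
  worked-example anchors stand in for engine output.
* The unit label of orbital-energy tables is passed through unchanged;
  magnitudes around 0.1–0.3 are Hartree-like even when source tables
  label them kcal/mol, and the descriptors are unit-agnostic ratios of
  the same column, so no conversion is attempted.
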