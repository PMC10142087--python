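"""Seeded synthetic-data generators for every pipeline input.

The pipeline normally consumes exports from web resources (ADME predictors,
compound-target predictors, disease-gene databases, a PPI database, GO/KEGG
annotation, docking and orbital-energy tables).  This module fabricates all
of them with *planted, recoverable structure* — a planted hub gene wired
into every clique, a planted enriched pathway term, a planted top compound,
controlled source overlaps — so every downstream stage can be tested
end-to-end without network access.

All randomness flows from a single integer seed through one
``numpy.random.Generator`` per generator call; no global state is touched.
Identical (arguments, seed) pairs produce identical outputs.  Gene symbols
are synthetic (``G000001`` ...); the planted hub and planted pathway may
carry real-looking names (``TLR4``, ``HIF-1 signaling pathway``) purely for
readability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .docking import EXAMPLE_CANDIDATE, EXAMPLE_DOCKING_SCORES
from .enrich import AnnotationTerm
from .screen import COMPOUND_COLUMNS, screen_table

__all__ = [
    "GeneratorConfig",
    "StudyData",
    "gen_compounds",
    "gen_gene_universe",
    "gen_associations",
    "gen_disease_sets",
    "gen_ppi",
    "gen_annotations",
    "gen_orbitals",
    "gen_docking",
    "generate_study",
    "write_study",
]

#: Discrete Abbott bioavailability score levels; the screening gate is
#: threshold-based (> 0.50), so only these levels occur in the wild.
ABBOTT_LEVELS = (0.11, 0.17, 0.55, 0.56, 0.85)
_PASSING_LEVELS = (0.55, 0.56, 0.85)

_SMILES_POOL = (
    "CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "C1CCOC1", "CC(C)CC(=O)O",
    "c1ccc2ccccc2c1", "OCC1OC(O)C(O)C(O)C1O", "CC(=O)C", "CCCCCCCC(=O)O",
    "c1ccncc1", "CC1=CC(=O)CC(C)(C)C1", "NC(=O)c1ccccc1",
)

_LIMITS = {"mw": 500.0, "hba": 10, "hbd": 5, "mlogp": 4.15}
_RULES = ("mw", "hba", "hbd", "mlogp")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped configuration for :func:`generate_study`.

    Defaults emulate the reference study's funnel at a scaled-down gene
    universe: 27 metabolites (none failing the drug-likeness gate), two
    compound-target sources with Jaccard ~0.5, three disease sources whose
    union hits the compound targets in exactly 42 genes, 21 of the 27
    compounds connected to those common targets, and a 42-node PPI network
    carrying a planted hub.
    """

    seed: int = 0
    n_compounds: int = 27
    frac_violators: float = 0.0
    n_genes: int = 2000
    source_overlap: float = 0.5
    planted_hub: str = "TLR4"
    planted_term_fold: float = 5.0
    #: chosen so a default 42-node network retains ~177 edges after the
    #: 0.400-confidence filter (planted ~44 + p * 817 pairs * P(score>=400))
    background_edge_prob: float = 0.22
    clique_sizes: tuple[int, ...] = (5, 4, 3)
    hub_coverage: float = 0.8
    per_source_range: tuple[int, int] = (3, 12)
    assoc_pool_size: int | None = None
    disease_sizes: tuple[int, int, int] = (700, 200, 500)
    hit_overlap: int = 42
    n_connected_compounds: int = 21
    n_terms: int = 50
    term_size_range: tuple[int, int] = (30, 80)
    planted_term_id: str = "PW0001"
    planted_term_name: str = "HIF-1 signaling pathway"
    planted_compound_name: str = EXAMPLE_CANDIDATE
    mushroom_id: str = "W.extensa"

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_genes", "hit_overlap", "n_terms",
                     "n_connected_compounds"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("frac_violators", "source_overlap", "background_edge_prob",
                     "hub_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.planted_term_fold < 1.0:
            raise ValueError("planted_term_fold must be >= 1")
        if any(s < 2 for s in self.clique_sizes):
            raise ValueError("clique sizes must be >= 2")
        if self.n_connected_compounds > self.n_compounds:
            raise ValueError("n_connected_compounds exceeds n_compounds")


# ---------------------------------------------------------------------------
# individual generators
# ---------------------------------------------------------------------------

def gen_compounds(
    n: int,
    frac_violators: float = 0.0,
    seed: int = 0,
    names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Synthetic GC-MS-style compound table with ADME descriptors.

    Exactly ``floor(frac_violators * n)`` rows carry >= 2 rule-of-five
    violations (and may draw any Abbott bioavailability level); all other
    rows have at most one violation and a passing (> 0.50) bioavailability
    level, so they survive the drug-likeness gate.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= frac_violators <= 1.0:
        raise ValueError("frac_violators must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=COMPOUND_COLUMNS)

    n_viol = int(math.floor(frac_violators * n))
    violator_idx = set(rng.choice(n, size=n_viol, replace=False).tolist())

    rt = np.sort(rng.uniform(3.0, 40.0, n)).round(3)
    area = (rng.dirichlet(np.ones(n)) * 100).round(2)

    rows = []
    for i in range(n):
        desc = {
            "mw": round(float(rng.uniform(120.0, 480.0)), 2),
            "hba": int(rng.integers(0, 10)),
            "hbd": int(rng.integers(0, 5)),
            "mlogp": round(float(rng.uniform(-2.5, 3.9)), 2),
        }
        if i in violator_idx:
            k = int(rng.integers(2, 5))
            broken = rng.choice(4, size=k, replace=False)
            for r in broken:
                desc[_RULES[r]] = _break_rule(_RULES[r], rng)
            bio = float(rng.choice(ABBOTT_LEVELS))
        else:
            if rng.random() < 0.25:  # one tolerated violation
                r = int(rng.integers(0, 4))
                desc[_RULES[r]] = _break_rule(_RULES[r], rng)
            bio = float(rng.choice(_PASSING_LEVELS, p=[0.6, 0.1, 0.3]))
        rows.append({
            "id": f"C{i + 1:03d}",
            "name": names[i] if names else f"metabolite-{i + 1:02d}",
            "formula": f"C{int(rng.integers(5, 31))}H{int(rng.integers(8, 51))}"
                       f"O{int(rng.integers(0, 9))}",
            "rt_min": float(rt[i]),
            "area_pct": float(area[i]),
            "smiles": _SMILES_POOL[i % len(_SMILES_POOL)],
            **desc,
            "bioavailability": bio,
        })
    return pd.DataFrame(rows, columns=COMPOUND_COLUMNS)


def _break_rule(rule: str, rng: np.random.Generator):
    if rule == "mw":
        return round(float(rng.uniform(520.0, 880.0)), 2)
    if rule == "hba":
        return int(rng.integers(11, 16))
    if rule == "hbd":
        return int(rng.integers(6, 9))
    return round(float(rng.uniform(4.3, 6.9)), 2)  # mlogp


def gen_gene_universe(n: int, seed: int = 0) -> list[str]:
    """``n`` unique uppercase synthetic gene symbols in seed-shuffled order."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    symbols = [f"G{i + 1:06d}" for i in range(n)]
    rng.shuffle(symbols)
    return symbols


def _design_pools(
    universe: Sequence[str],
    overlap: float,
    pool_size: int,
    rng: np.random.Generator,
    must_include: Sequence[str] = (),
) -> tuple[set[str], set[str]]:
    """Two equally sized gene pools with Jaccard index ~``overlap``.

    With pool size s and intersection i, J = i / (2s - i); inverting gives
    i = 2 s J / (1 + J).  The union 2s/(1+J) must fit in the universe, so s
    is clamped accordingly.
    """
    n_uni = len(universe)
    s = min(pool_size, int(n_uni * (1 + overlap) / 2))
    if s < 1:
        raise ValueError("universe too small for any pool")
    i = min(s, round(2 * s * overlap / (1 + overlap)))
    i = max(i, len(must_include))
    union_size = 2 * s - i
    picks = rng.choice(n_uni, size=union_size, replace=False)
    forced = [g for g in must_include if g in universe]
    pool = forced + [universe[j] for j in picks if universe[j] not in set(forced)]
    if len(pool) < union_size:  # forced genes collided with sampled picks
        seen = set(pool)
        pool += [g for g in universe if g not in seen][: union_size - len(pool)]
    pool = pool[:union_size]
    inter = set(pool[:i])
    only_a = set(pool[i:s])
    only_b = set(pool[s:])
    return inter | only_a, inter | only_b


def _assign_source(
    compound_ids: Sequence[str],
    pool: set[str],
    per_range: tuple[int, int],
    rng: np.random.Generator,
    source: str,
    forbidden: dict[str, set[str]] | None = None,
    required: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Distribute every pool gene over compounds as association rows.

    Each compound draws a count in ``per_range`` of allowed genes plus its
    required genes; afterwards every unassigned pool gene is given to a
    random compound allowed to take it, so the realized pooled target set
    equals ``pool`` exactly.
    """
    forbidden = forbidden or {}
    required = required or {}
    pool_sorted = sorted(pool)
    lo, hi = per_range
    assigned: dict[str, set[str]] = {}
    covered: set[str] = set()
    for comp in compound_ids:
        req = required.get(comp, set()) & pool
        allowed = [g for g in pool_sorted
                   if g not in forbidden.get(comp, set()) and g not in req]
        want = int(rng.integers(lo, hi + 1))
        take = min(max(want - len(req), 0), len(allowed))
        picks = set(rng.choice(allowed, size=take, replace=False).tolist()) if take else set()
        assigned[comp] = req | picks
        covered |= assigned[comp]
    for gene in pool_sorted:
        if gene in covered:
            continue
        takers = [c for c in compound_ids if gene not in forbidden.get(c, set())]
        if not takers:
            raise ValueError(f"gene {gene} forbidden for every compound")
        assigned[takers[int(rng.integers(0, len(takers)))]].add(gene)
    rows = [
        {"compound_id": c, "gene_symbol": g, "source": source}
        for c in compound_ids for g in sorted(assigned[c])
    ]
    return pd.DataFrame(rows, columns=["compound_id", "gene_symbol", "source"])


def gen_associations(
    compounds: Sequence[str],
    universe: Sequence[str],
    per_source_range: tuple[int, int] = (3, 12),
    overlap: float = 0.5,
    seed: int = 0,
    pool_size: int | None = None,
    must_include: Sequence[str] = (),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two compound-target association tables (sources "A" and "B").

    The realized Jaccard index of the two pooled target sets lies within
    +-0.1 of ``overlap`` (exact up to integer rounding of the designed
    intersection); every listed gene belongs to ``universe``.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    lo, hi = per_source_range
    if lo > hi or lo < 0:
        raise ValueError(f"bad per_source_range {per_source_range}")
    if (lo > 0 or must_include) and not universe:
        raise ValueError("universe is empty")
    rng = np.random.default_rng(seed)
    if pool_size is None:
        pool_size = min(max(10, 8 * max(len(compounds), 1)), max(len(universe) // 3, 1))
    pool_a, pool_b = _design_pools(universe, overlap, pool_size, rng, must_include)
    df_a = _assign_source(compounds, pool_a, per_source_range, rng, "A")
    df_b = _assign_source(compounds, pool_b, per_source_range, rng, "B")
    return df_a, df_b


DISEASE_SOURCES = ("disgenet", "omim", "malacards")


def gen_disease_sets(
    universe: Sequence[str],
    sizes: tuple[int, int, int],
    hit_overlap: int,
    compound_targets: Iterable[str],
    seed: int = 0,
    must_include: Sequence[str] = (),
) -> list[pd.DataFrame]:
    """Three disease gene lists whose union hits ``compound_targets`` in
    exactly ``hit_overlap`` symbols.

    Hit genes are drawn from ``compound_targets`` and spread over the three
    lists; all remaining slots are filled from outside ``compound_targets``
    so the intersection stays exact.
    """
    targets = sorted(set(compound_targets))
    if len(sizes) != 3:
        raise ValueError("need exactly three source sizes")
    if hit_overlap > len(targets):
        raise ValueError(f"hit_overlap {hit_overlap} exceeds |compound_targets| {len(targets)}")
    if hit_overlap > sum(sizes):
        raise ValueError("hit_overlap exceeds total list capacity")
    if any(s > len(universe) for s in sizes):
        raise ValueError("a source size exceeds the universe")
    rng = np.random.default_rng(seed)

    forced = [g for g in must_include if g in targets]
    rest_pool = [g for g in targets if g not in set(forced)]
    extra = rng.choice(rest_pool, size=hit_overlap - len(forced), replace=False).tolist() \
        if hit_overlap > len(forced) else []
    hits = forced + extra
    rng.shuffle(hits)

    non_targets = sorted(set(universe) - set(targets))
    # spread hits round-robin, respecting each list's capacity
    per_list: list[list[str]] = [[], [], []]
    order = [0, 1, 2]
    for j, gene in enumerate(hits):
        placed = False
        for step in range(3):
            idx = order[(j + step) % 3]
            if len(per_list[idx]) < sizes[idx]:
                per_list[idx].append(gene)
                placed = True
                break
        if not placed:  # pragma: no cover - guarded by capacity check above
            raise ValueError("could not place all hit genes")

    frames = []
    for idx, source in enumerate(DISEASE_SOURCES):
        fill = sizes[idx] - len(per_list[idx])
        if fill > len(non_targets):
            raise ValueError(
                f"source {source!r} needs {fill} non-target genes but only "
                f"{len(non_targets)} exist in the universe"
            )
        fillers = rng.choice(non_targets, size=fill, replace=False).tolist() if fill else []
        genes = sorted(per_list[idx] + fillers)
        frames.append(pd.DataFrame({"gene_symbol": genes, "source": source}))
    return frames


def gen_ppi(
    nodes: Iterable[str],
    planted_hub: str,
    clique_sizes: Sequence[int] = (5, 4, 3),
    background_edge_prob: float = 0.05,
    seed: int = 0,
    hub_coverage: float = 0.8,
) -> pd.DataFrame:
    """STRING-dialect scored edge table with a planted hub.

    The hub is a member of every planted clique and additionally wired to
    ``hub_coverage`` of all other nodes.  Planted edges score in [700, 1000]
    so a medium-confidence (0.400) cutoff never removes planted structure;
    background edges appear independently with probability
    ``background_edge_prob`` and score in [150, 1000].  No self-loops, no
    duplicate unordered pairs.
    """
    node_list = sorted(set(nodes))
    if planted_hub not in node_list:
        raise ValueError(f"planted hub {planted_hub!r} not in node set")
    if not 0.0 <= background_edge_prob <= 1.0:
        raise ValueError("background_edge_prob must lie in [0, 1]")
    if any(s < 2 for s in clique_sizes):
        raise ValueError("clique sizes must be >= 2")
    if any(s > len(node_list) for s in clique_sizes):
        raise ValueError("a clique size exceeds the node count")
    rng = np.random.default_rng(seed)
    others = [v for v in node_list if v != planted_hub]

    edges: dict[tuple[str, str], int] = {}

    def put(a: str, b: str, score: int) -> None:
        key = (a, b) if a <= b else (b, a)
        edges[key] = max(edges.get(key, 0), score)

    for size in clique_sizes:
        members = [planted_hub] + rng.choice(others, size=size - 1, replace=False).tolist()
        for a, b in combinations(sorted(members), 2):
            put(a, b, int(rng.integers(700, 1001)))

    n_wire = math.ceil(hub_coverage * len(others))
    for v in rng.choice(others, size=n_wire, replace=False).tolist():
        if tuple(sorted((planted_hub, v))) not in edges:
            put(planted_hub, v, int(rng.integers(700, 1001)))

    if background_edge_prob > 0:
        for a, b in combinations(node_list, 2):
            if (a, b) in edges:
                continue
            if rng.random() < background_edge_prob:
                put(a, b, int(rng.integers(150, 1001)))

    rows = sorted((a, b, s) for (a, b), s in edges.items())
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def gen_annotations(
    universe: Sequence[str],
    n_terms: int = 50,
    size_range: tuple[int, int] = (30, 80),
    planted_term: str | None = "PW0001",
    query: Iterable[str] = (),
    fold: float = 5.0,
    seed: int = 0,
    planted_name: str = "HIF-1 signaling pathway",
    planted_category: str = "pathway",
) -> list[AnnotationTerm]:
    """Annotation collection with one planted enriched term.

    The planted term's overlap with ``query`` is at least ``fold`` times its
    hypergeometric expectation K*n/N (so at ``fold = 1`` it is statistically
    indistinguishable from the uniformly sampled background terms).  The
    planted term counts toward ``n_terms``.
    """
    if n_terms < 0:
        raise ValueError("n_terms must be non-negative")
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    if n_terms == 0:
        return []
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError("term size range exceeds the universe")
    query_set = sorted(set(query))
    if set(query_set) - set(universe):
        raise ValueError("query must be a subset of the universe")
    rng = np.random.default_rng(seed)
    uni_sorted = sorted(universe)
    terms: list[AnnotationTerm] = []

    n_background = n_terms
    if planted_term is not None and n_terms >= 1 and query_set:
        n_background = n_terms - 1
        K = (lo + hi) // 2
        expected = K * len(query_set) / len(universe)
        if fold > 1.0:
            k = max(1, math.ceil(fold * expected))
        else:
            k = round(expected)
        k = min(k, K, len(query_set))
        inside = rng.choice(query_set, size=k, replace=False).tolist() if k else []
        outside_pool = sorted(set(uni_sorted) - set(query_set))
        outside = rng.choice(outside_pool, size=K - k, replace=False).tolist()
        terms.append(AnnotationTerm(
            planted_term, planted_name, planted_category, frozenset(inside + outside)
        ))

    categories = ("BP", "CC", "MF", "pathway")
    for i in range(n_background):
        K = int(rng.integers(lo, hi + 1))
        genes = rng.choice(uni_sorted, size=K, replace=False).tolist()
        cat = categories[i % 4]
        terms.append(AnnotationTerm(
            f"T{i + 1:04d}", f"background term {i + 1} ({cat})", cat, frozenset(genes)
        ))
    return terms


def gen_orbitals(
    candidate: str = EXAMPLE_CANDIDATE,
    standards: tuple[str, ...] = ("Aspirin", "Indomethacin"),
) -> pd.DataFrame:
    """Frontier-orbital energy table for the worked example.

    The candidate's energies are anchored so that its HOMO-LUMO gap is
    0.1651 (hardness 0.08255); the standards carry plausible fixed values,
    with Aspirin harder and Indomethacin softer than the candidate.  The
    table is deterministic by construction.
    """
    rows = [
        (candidate, -0.224, -0.0589),
        (standards[0], -0.2679, -0.0312),   # gap 0.2367 -> harder
        (standards[1], -0.2105, -0.0655),   # gap 0.1450 -> softer
    ]
    return pd.DataFrame(rows, columns=["compound_id", "homo", "lumo"]).assign(units="hartree")


def gen_docking() -> pd.DataFrame:
    """Docking score table for the worked example (candidate vs references
    on five HIF-1-pathway targets)."""
    return EXAMPLE_DOCKING_SCORES.copy()


# ---------------------------------------------------------------------------
# whole-study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """Everything :func:`generate_study` produced, ready for the pipeline."""

    config: GeneratorConfig
    universe: list[str]
    compounds: pd.DataFrame
    assoc_a: pd.DataFrame
    assoc_b: pd.DataFrame
    disease_sets: list[pd.DataFrame]
    common_compound_targets: list[str]
    common_targets: list[str]
    connected_compounds: list[str]
    orphan_compounds: list[str]
    ppi_edges: pd.DataFrame
    annotations: list[AnnotationTerm] = field(default_factory=list)
    orbitals: pd.DataFrame = field(default_factory=pd.DataFrame)
    docking: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def associations(self) -> pd.DataFrame:
        return pd.concat([self.assoc_a, self.assoc_b], ignore_index=True)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def generate_study(config: GeneratorConfig) -> StudyData:
    """Generate a coherent full-study input bundle.

    Guarantees, by construction:

    * the planted hub is in both compound-target pools and among the common
      targets;
    * exactly ``n_connected_compounds`` screened compounds link into the
      common target set; the rest are orphans with no such link;
    * the planted compound (first compound, renamed) has strictly the most
      distinct common-target links;
    * every common target is linked by at least one connected compound.
    """
    s_uni, s_cmp, s_pool, s_dis, s_asg, s_ppi, s_ann = _child_seeds(config.seed, 7)
    rng = np.random.default_rng(s_asg)

    universe = gen_gene_universe(config.n_genes, s_uni)
    if config.planted_hub not in universe and universe:
        universe[0] = config.planted_hub

    names = [config.planted_compound_name] + [
        f"metabolite-{i + 2:02d}" for i in range(config.n_compounds - 1)
    ] if config.n_compounds else None
    compounds = gen_compounds(config.n_compounds, config.frac_violators, s_cmp, names)
    retained = screen_table(compounds).retained
    comp_ids = retained["id"].tolist()

    pool_size = config.assoc_pool_size or min(
        max(10, 8 * max(len(comp_ids), 1)), max(len(universe) // 3, 1)
    )
    pool_a, pool_b = _design_pools(
        universe, config.source_overlap, pool_size,
        np.random.default_rng(s_pool), must_include=[config.planted_hub],
    )
    c_ab = sorted(pool_a & pool_b)

    disease_sets = gen_disease_sets(
        universe, config.disease_sizes, config.hit_overlap, c_ab, s_dis,
        must_include=[config.planted_hub],
    )
    disease_union = set().union(*(set(d["gene_symbol"]) for d in disease_sets))
    common = sorted(set(c_ab) & disease_union)

    n_conn = min(config.n_connected_compounds, len(comp_ids))
    connected, orphans = comp_ids[:n_conn], comp_ids[n_conn:]
    common_set = set(common)

    forbidden = {c: common_set for c in orphans}
    required_a: dict[str, set[str]] = {}
    required_b: dict[str, set[str]] = {}
    for comp in connected:
        n_common = int(rng.integers(1, 4)) if common else 0
        picks = rng.choice(common, size=min(n_common, len(common)), replace=False)
        for g in picks:
            (required_a if rng.random() < 0.5 else required_b).setdefault(comp, set()).add(g)
        if comp not in required_a and comp not in required_b and common:
            required_a.setdefault(comp, set()).add(common[int(rng.integers(0, len(common)))])

    assoc_a = _assign_source(comp_ids, pool_a, config.per_source_range, rng, "A",
                             forbidden, required_a)
    assoc_b = _assign_source(comp_ids, pool_b, config.per_source_range, rng, "B",
                             forbidden, required_b)

    # make the planted compound strictly top by distinct common-target links
    if connected and common:
        planted = connected[0]
        pairs = set(zip(assoc_a["compound_id"], assoc_a["gene_symbol"])) | \
            set(zip(assoc_b["compound_id"], assoc_b["gene_symbol"]))
        counts = {c: 0 for c in comp_ids}
        for comp, gene in pairs:
            if gene in common_set:
                counts[comp] += 1
        rival = max((n for c, n in counts.items() if c != planted), default=0)
        have = {g for c, g in pairs if c == planted and g in common_set}
        need = min(rival + 1, len(common)) - len(have)
        if need > 0:
            extras = [g for g in common if g not in have][:need]
            add = pd.DataFrame(
                [{"compound_id": planted, "gene_symbol": g, "source": "A"} for g in extras]
            )
            assoc_a = (
                pd.concat([assoc_a, add], ignore_index=True)
                .drop_duplicates()
                .sort_values(["compound_id", "gene_symbol"])
                .reset_index(drop=True)
            )

    ppi_edges = gen_ppi(
        common, config.planted_hub, config.clique_sizes,
        config.background_edge_prob, s_ppi, config.hub_coverage,
    ) if common else pd.DataFrame(columns=["protein1", "protein2", "combined_score"])

    annotations = gen_annotations(
        universe, config.n_terms, config.term_size_range,
        config.planted_term_id, common, config.planted_term_fold, s_ann,
        planted_name=config.planted_term_name,
    )

    return StudyData(
        config=config,
        universe=universe,
        compounds=compounds,
        assoc_a=assoc_a,
        assoc_b=assoc_b,
        disease_sets=disease_sets,
        common_compound_targets=c_ab,
        common_targets=common,
        connected_compounds=connected,
        orphan_compounds=orphans,
        ppi_edges=ppi_edges,
        annotations=annotations,
        orbitals=gen_orbitals(config.planted_compound_name),
        docking=gen_docking(),
    )


def write_study(study: StudyData, outdir: str | Path) -> dict[str, Path]:
    """Write every generated input as plain text; returns name -> path."""
    from .io import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.csv",
        "associations": out / "associations.tsv",
        "disease": out / "disease_genes.tsv",
        "ppi": out / "ppi_edges.tsv",
        "annotations": out / "annotations.gmt",
        "orbitals": out / "orbitals.csv",
        "docking": out / "docking_scores.csv",
        "universe": out / "gene_universe.txt",
    }
    study.compounds.to_csv(paths["compounds"], index=False)
    study.associations.to_csv(paths["associations"], sep="\t", index=False)
    pd.concat(study.disease_sets, ignore_index=True).to_csv(
        paths["disease"], sep="\t", index=False)
    study.ppi_edges.to_csv(paths["ppi"], sep="\t", index=False)
    write_gmt(study.annotations, paths["annotations"])
    study.orbitals.to_csv(paths["orbitals"], index=False)
    study.docking.to_csv(paths["docking"], index=False)
    paths["universe"].write_text("\n".join(study.universe) + "\n")
    return paths
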