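"""End-to-end orchestration of the network-pharmacology workflow.

``run_pipeline`` executes screen -> target-set algebra -> PPI hub ranking ->
M-C-T network -> enrichment -> reactivity -> docking comparison, writing
per-stage tables, a JSON summary, a Markdown report and a checksum manifest.
Inputs come either from the synthetic-study generator (``synthetic=True``)
or from user-supplied files.  Stage outputs are pure functions of (inputs,
config, seed): rerunning with the same configuration reproduces identical
files, and the manifest's SHA-256 checksums prove it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .docking import (COMPARABLE_WINDOW, EXAMPLE_REFERENCES,
                      STRONG_BINDING_THRESHOLD, compare_docking_scores,
                      records_from_table)
from .enrich import bubble_table, enrich, top_by_gene_percentage
from .io import (read_association_tsv, read_compound_csv, read_disease_tsv,
                 read_docking_csv, read_gmt, read_orbitals_csv, read_string_tsv)
from .mct import build_mct, mct_counts, mct_tables, top_compounds_by_degree
from .ppi import (HUB_METHODS, consensus_top, load_interaction_table,
                  network_stats, rank_nodes)
from .reactivity import OrbitalEnergies, reactivity_report
from .screen import screen_table
from .synth import GeneratorConfig, StudyData, generate_study, write_study
from .targets import (SourcedTargetSet, common_disease_targets,
                      compound_connectivity, intersect_compound_sources,
                      union_disease_sources)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All tunable thresholds, each defaulting to the study's value."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_confidence: float = 0.400        # STRING medium confidence
    alpha: float = 0.05                  # raw-p significance gate
    top_k: int = 3                       # consensus hub depth
    strong_threshold: float = STRONG_BINDING_THRESHOLD
    comparable_window: float = COMPARABLE_WINDOW
    docking_references: tuple[str, ...] = EXAMPLE_REFERENCES

    def as_dict(self) -> dict:
        d = asdict(self)
        d["docking_references"] = list(self.docking_references)
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML configuration; missing keys keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen = GeneratorConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.pop("generator", {}).items()
    })
    if "docking_references" in raw:
        raw["docking_references"] = tuple(raw["docking_references"])
    return PipelineConfig(generator=gen, **raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def _load_inputs(inputs: Mapping[str, Any]) -> StudyData:
    """Assemble a StudyData-like bundle from user-supplied file paths."""
    def need(key: str, stage: str) -> Path:
        p = Path(inputs[key]) if key in inputs else None
        if p is None or not p.exists():
            raise PipelineError(f"stage '{stage}' failed: input file for "
                                f"'{key}' not found: {p}")
        return p

    compounds = read_compound_csv(need("compounds", "screen"))
    assoc = read_association_tsv(need("associations", "targets"))
    disease = read_disease_tsv(need("disease", "targets"))
    ppi = read_string_tsv(need("ppi", "hubs"))
    annotations = read_gmt(need("annotations", "enrich"))
    orbitals = read_orbitals_csv(need("orbitals", "reactivity"))
    docking = read_docking_csv(need("docking", "dock-compare"))

    srcs = sorted(assoc["source"].unique())
    if len(srcs) < 2:
        raise PipelineError("stage 'targets' failed: need two association sources")
    assoc_a = assoc[assoc["source"] == srcs[0]].reset_index(drop=True)
    assoc_b = assoc[assoc["source"] == srcs[1]].reset_index(drop=True)
    disease_sets = [
        disease[disease["source"] == s].reset_index(drop=True)
        for s in sorted(disease["source"].unique())
    ]
    universe_path = inputs.get("universe")
    universe = (
        [ln.strip() for ln in Path(universe_path).read_text().splitlines() if ln.strip()]
        if universe_path else []
    )
    return StudyData(
        config=GeneratorConfig(), universe=universe, compounds=compounds,
        assoc_a=assoc_a, assoc_b=assoc_b, disease_sets=disease_sets,
        common_compound_targets=[], common_targets=[], connected_compounds=[],
        orphan_compounds=[], ppi_edges=ppi, annotations=annotations,
        orbitals=orbitals, docking=docking,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path = "netpharm_out",
    synthetic: bool = True,
    inputs: Mapping[str, Any] | None = None,
) -> dict:
    """Run every stage and write the report bundle under ``outdir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    cfg = config or PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, rel: str, sep: str = "\t") -> None:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, sep=sep, index=False)
        written.append(p)

    def save_json(obj: Any, rel: str) -> None:
        p = out / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        written.append(p)

    # --- inputs -----------------------------------------------------------
    if synthetic and inputs is None:
        study = generate_study(cfg.generator)
        for p in write_study(study, out / "inputs").values():
            written.append(p)
    else:
        study = _load_inputs(inputs or {})

    # --- screen -----------------------------------------------------------
    @_stage("screen")
    def _screen():
        res = screen_table(study.compounds)
        save_df(res.retained, "screen/retained.csv", sep=",")
        save_json(res.report, "screen/report.json")
        return res

    screen_res = _screen()
    comp_ids = screen_res.retained["id"].tolist()

    # --- target sets ------------------------------------------------------
    @_stage("targets")
    def _targets():
        a = SourcedTargetSet.from_raw("A", study.assoc_a["gene_symbol"])
        b = SourcedTargetSet.from_raw("B", study.assoc_b["gene_symbol"])
        c_ab, venn = intersect_compound_sources(a, b)
        disease_sets = [
            SourcedTargetSet.from_raw(str(d["source"].iloc[0]) if len(d) else f"D{i}",
                                      d["gene_symbol"])
            for i, d in enumerate(study.disease_sets)
        ]
        disease_union, per_source = union_disease_sources(*disease_sets)
        common = common_disease_targets(c_ab, disease_union)
        assoc = study.associations
        counts, orphans = compound_connectivity(
            assoc[["compound_id", "gene_symbol"]], common, comp_ids)
        save_df(pd.DataFrame({"gene_symbol": common}), "targets/common.tsv")
        save_json({
            "compound_sources_venn": venn.as_dict(),
            "disease_union_size": len(disease_union),
            "disease_per_source": per_source,
            "n_common_targets": len(common),
            "n_connected_compounds": sum(1 for n in counts.values() if n > 0),
            "orphan_compounds": orphans,
        }, "targets/venn.json")
        return common, counts, orphans

    common, conn_counts, orphans = _targets()

    # --- PPI hubs ---------------------------------------------------------
    @_stage("hubs")
    def _hubs():
        net = load_interaction_table(
            study.ppi_edges, cfg.min_confidence, include_nodes=common)
        stats = network_stats(net)
        rankings = [rank_nodes(net, m, max(cfg.top_k, min(10, net.number_of_nodes())))
                    for m in HUB_METHODS]
        consensus = consensus_top(rankings, cfg.top_k)
        save_json(stats.as_dict(), "hubs/stats.json")
        for r in rankings:
            save_df(pd.DataFrame(
                [(i + 1, g, s) for i, (g, s) in enumerate(r.entries)],
                columns=["rank", "gene", "score"]), f"hubs/ranking_{r.method}.tsv")
        save_df(pd.DataFrame({"gene": consensus}), "hubs/consensus.tsv")
        return stats, rankings, consensus

    stats, rankings, consensus = _hubs()

    # --- M-C-T network ----------------------------------------------------
    @_stage("mct")
    def _mct():
        net = build_mct(cfg.generator.mushroom_id,
                        study.associations[["compound_id", "gene_symbol"]], common)
        counts = mct_counts(net)
        nodes, edges = mct_tables(net)
        save_df(nodes, "mct/nodes.tsv")
        save_df(edges, "mct/edges.tsv")
        top = top_compounds_by_degree(net, max(1, len(comp_ids)))
        save_df(pd.DataFrame(top, columns=["compound_id", "target_degree"]),
                "mct/compound_ranking.tsv")
        return counts, top

    counts_mct, top_compounds = _mct()

    # --- enrichment -------------------------------------------------------
    @_stage("enrich")
    def _enrich():
        universe = study.universe or None
        results = enrich(common, study.annotations, universe, cfg.alpha)
        table = pd.DataFrame([
            {
                "term_id": r.term.term_id, "name": r.term.name,
                "category": r.term.category, "overlap": r.overlap,
                "term_size": r.term_size, "p_value": r.p_value,
                "q_value": r.q_value, "rich_factor": r.rich_factor,
                "gene_percentage": r.gene_percentage, "significant": r.significant,
            } for r in results
        ])
        save_df(table, "enrich/results.tsv")
        save_df(bubble_table(results), "enrich/bubble.csv", sep=",")
        return results

    enrich_results = _enrich()

    # --- reactivity -------------------------------------------------------
    @_stage("reactivity")
    def _reactivity():
        refs = set(cfg.docking_references)
        cands, stds = [], []
        for r in study.orbitals.itertuples(index=False):
            e = OrbitalEnergies(str(r.compound_id), float(r.homo), float(r.lumo),
                                getattr(r, "units", "hartree"))
            (stds if e.compound_id in refs else cands).append(e)
        rep = reactivity_report(cands, stds)
        save_df(rep, "reactivity/report.csv", sep=",")
        return rep

    react = _reactivity()

    # --- docking comparison ----------------------------------------------
    @_stage("dock-compare")
    def _dock():
        cls = compare_docking_scores(
            records_from_table(study.docking), cfg.docking_references,
            cfg.strong_threshold, cfg.comparable_window)
        save_df(cls, "docking/classification.csv", sep=",")
        return cls

    dock = _dock()

    # --- summary ----------------------------------------------------------
    sig_pathways = [r for r in enrich_results
                    if r.significant and r.term.category == "pathway"]
    key_compound = top_compounds[0][0] if top_compounds else None
    key_compound_name = None
    if key_compound is not None:
        row = study.compounds.loc[study.compounds["id"] == key_compound]
        key_compound_name = str(row["name"].iloc[0]) if len(row) else key_compound
    summary = {
        "netpharm_version": __version__,
        "seed": cfg.generator.seed,
        "funnel": {
            "compounds_input": int(len(study.compounds)),
            "compounds_druglike": len(comp_ids),
            "compounds_connected": sum(1 for n in conn_counts.values() if n > 0),
            "orphan_compounds": len(orphans),
            "common_targets": len(common),
        },
        "network": stats.as_dict(),
        "key_targets": consensus,
        "key_compound": key_compound,
        "key_compound_name": key_compound_name,
        "top_pathway": sig_pathways[0].term.name if sig_pathways else None,
        "n_significant_pathways": len(sig_pathways),
        "docking": {
            f"{r.ligand}|{r.target}": {
                "score": r.score_kcal_mol,
                "classification": r.classification,
                "strong_binder": bool(r.strong_binder),
            } for r in dock.itertuples(index=False)
        },
        "reactivity": {
            r.compound_id: {
                "hardness": r.hardness, "softness": r.softness,
                "softer_than_all_standards": bool(r.softer_than_all_standards),
            } for r in react.itertuples(index=False)
        },
    }
    save_json(summary, "summary.json")
    (out / "report.md").write_text(_render_report(summary))
    written.append(out / "report.md")

    manifest = {
        "config": cfg.as_dict(),
        "versions": _versions(),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary


def _render_report(s: dict) -> str:
    f = s["funnel"]
    lines = [
        "# Network-pharmacology run summary", "",
        f"- Compounds screened: {f['compounds_input']} -> drug-like: "
        f"{f['compounds_druglike']} -> connected to common targets: "
        f"{f['compounds_connected']} (orphans: {f['orphan_compounds']})",
        f"- Common compound/disease targets: {f['common_targets']}",
        f"- PPI network: {s['network']['nodes']} nodes, {s['network']['edges']} edges, "
        f"average neighbors {s['network']['average_neighbors']}",
        f"- Consensus hub targets (top-{len(s['key_targets'])} of all methods): "
        f"{', '.join(s['key_targets']) or 'none'}",
        f"- Key compound by target degree: {s['key_compound_name']}",
        f"- Top enriched pathway: {s['top_pathway']} "
        f"({s['n_significant_pathways']} significant)",
        "",
    ]
    return "\n".join(lines)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import networkx
    import numpy
    import scipy
    return {
        "netpharm": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "pandas": pd.__version__,
    }
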