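"""Configuration, orchestration and provenance for full pipeline runs.

``run_pipeline`` executes the stages in their analysis order — simulate →
preprocess → diffexpr → kinase → consensus → network → singlecell →
enrichment — writing TSV outputs per stage plus a JSON run report with
counts, seeds, thresholds and a resolved-config hash for provenance.  All
randomness derives from the single configured seed, so two runs with the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from macsig import __version__, diffexpr, enrich, kinase, network, preprocess, singlecell, synth
from macsig.io import (
    GeneSet,
    GeneSetCollection,
    write_feature_table,
    write_gene_sets,
    write_interactions,
    write_sparse_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "macsig_out",
    "conditions": ["M1", "M2c"],
    "stages": {
        "simulate": True,
        "preprocess": True,
        "diffexpr": True,
        "kinase": True,
        "consensus": True,
        "network": True,
        "singlecell": True,
        "enrichment": True,
    },
    "thresholds": {
        "fdr_max": 0.05,
        "abs_log2fc_min": 1.0,
        "min_peptides": 2,
        "min_measured": 2,
        "loc_prob_min": 0.75,
        "impute_shift_high": 0.5,
        "impute_shift_low": 1.8,
        "impute_width": 0.3,
        "moderation": True,
        "kinase_alpha": 0.05,
        "min_posterior": 0.035,
        "pred_top_n": 3,
        "min_substrates": 10,
        "min_datasets": 3,
        "min_ratio": 4.0,
        "dtu_min_fraction": 0.5,
        "combined_score_min": 0.7,
        "confidence_min": 0.7,
        "dtu_max_fraction": 0.75,
        "target_avg_degree": 10.0,
        "min_module_size": 10,
        "ora_min_hits": 5,
        "ora_max_set_size": 300,
        "sc_min_genes": 500,
        "sc_max_genes": 9000,
        "sc_max_mito": 0.10,
        "sc_min_cells_per_gene": 3,
        "sc_min_frac": 0.10,
        "sc_alpha": 0.05,
        "sc_min_avg_log2fc": 0.75,
    },
    "simulate": {
        "n_proteins": 200,
        "sites_per_protein": 4,
        "n_replicates": 4,
        "n_kinases": 20,
        "n_active": 3,
        "substrates_per_kinase": 30,
        "effect_log2": 2.0,
        "noise_sd": 0.5,
        "n_datasets": 6,
        "n_genes_bulk": 2000,
        "frac_de": 0.05,
        "concordance": 0.9,
        "n_blocks": 4,
        "block_size": 40,
        "p_in": 0.3,
        "p_out": 0.01,
        "n_cells": 800,
        "n_genes_sc": 1000,
        "n_signature": 100,
        "sc_shift": 1.5,
    },
}

_RANGES = {
    ("thresholds", "fdr_max"): (0.0, 1.0),
    ("thresholds", "loc_prob_min"): (0.0, 1.0),
    ("thresholds", "kinase_alpha"): (0.0, 1.0),
    ("thresholds", "min_posterior"): (0.0, 1.0),
    ("thresholds", "dtu_min_fraction"): (0.0, 1.0),
    ("thresholds", "dtu_max_fraction"): (0.0, 1.0),
    ("thresholds", "sc_max_mito"): (0.0, 1.0),
    ("thresholds", "sc_alpha"): (0.0, 1.0),
    ("thresholds", "sc_min_frac"): (0.0, 1.0),
    ("simulate", "concordance"): (0.0, 1.0),
    ("simulate", "p_in"): (0.0, 1.0),
    ("simulate", "p_out"): (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Resolved run configuration (defaults merged, values validated)."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def outdir(self) -> str:
        return self.data["outdir"]

    def threshold(self, key: str):
        return self.data["thresholds"][key]

    def sim(self, key: str):
        return self.data["simulate"][key]

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config key {where} must be a mapping")
            out[key] = _merge(base[key], value, where)
        else:
            out[key] = value
    return out


def validate_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config, merge onto defaults, reject unknown keys and bad ranges."""
    user: dict = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    merged = _merge(DEFAULT_CONFIG, user)
    if overrides:
        merged = _merge(merged, overrides)
    for (section, key), (lo, hi) in _RANGES.items():
        v = merged[section][key]
        if not (lo <= v <= hi):
            raise ValueError(f"config value {section}.{key}={v} outside [{lo}, {hi}]")
    cfg = RunConfig(merged)
    logger.info("resolved config %s: %s", cfg.digest(), json.dumps(merged, sort_keys=True))
    return cfg


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _ensure(outdir: str, *parts: str) -> str:
    path = os.path.join(outdir, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages on synthetic data and return the run report."""
    cfg = config
    stages = cfg.data["stages"]
    outdir = cfg.outdir
    os.makedirs(outdir, exist_ok=True)
    th = cfg.data["thresholds"]
    cond_a, cond_b = cfg.data["conditions"]
    report: dict = {
        "version": __version__,
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "thresholds": th,
        "stages": {},
    }
    state: dict = {}

    order = [
        ("simulate", _stage_simulate, []),
        ("preprocess", _stage_preprocess, ["simulate"]),
        ("diffexpr", _stage_diffexpr, ["preprocess"]),
        ("kinase", _stage_kinase, ["diffexpr"]),
        ("consensus", _stage_consensus, ["simulate"]),
        ("network", _stage_network, ["simulate", "consensus"]),
        ("singlecell", _stage_singlecell, ["simulate"]),
        ("enrichment", _stage_enrichment, ["kinase", "network"]),
    ]
    done = set()
    for name, fn, deps in order:
        if not stages.get(name, False):
            continue
        missing = [d for d in deps if d not in done]
        if missing:
            raise RuntimeError(f"stage {name!r} requires disabled/failed stage(s): {missing}")
        t0 = time.monotonic()
        try:
            counts = fn(cfg, state, cond_a, cond_b)
        except Exception as exc:  # halt with a stage-named error
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        counts["seconds"] = round(time.monotonic() - t0, 3)
        report["stages"][name] = counts
        done.add(name)
        logger.info("stage %s done in %.1fs: %s", name, counts["seconds"], counts)

    with open(_ensure(outdir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _stage_simulate(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    seed = cfg.seed
    proteome, phospho, ksmap, truth = synth.gen_phosphoproteome(
        n_proteins=cfg.sim("n_proteins"),
        sites_per_protein=cfg.sim("sites_per_protein"),
        n_replicates=cfg.sim("n_replicates"),
        n_kinases=cfg.sim("n_kinases"),
        n_active=cfg.sim("n_active"),
        substrates_per_kinase=cfg.sim("substrates_per_kinase"),
        effect_log2=cfg.sim("effect_log2"),
        noise_sd=cfg.sim("noise_sd"),
        seed=seed,
        conditions=(cond_a, cond_b),
    )
    de_tables, expr_tables, bulk_truth = synth.gen_bulk_de_tables(
        n_datasets=cfg.sim("n_datasets"),
        n_genes=cfg.sim("n_genes_bulk"),
        frac_de=cfg.sim("frac_de"),
        concordance=cfg.sim("concordance"),
        seed=seed + 1,
    )
    dtu_tables, _, dtu_truth = synth.gen_bulk_de_tables(
        n_datasets=cfg.sim("n_datasets"),
        n_genes=cfg.sim("n_genes_bulk"),
        frac_de=cfg.sim("frac_de"),
        concordance=cfg.sim("concordance"),
        seed=seed + 2,
    )
    records, net_truth = synth.gen_interaction_network(
        n_blocks=cfg.sim("n_blocks"),
        block_size=cfg.sim("block_size"),
        p_in=cfg.sim("p_in"),
        p_out=cfg.sim("p_out"),
        seed=seed + 3,
    )
    cells, signature, cell_truth = synth.gen_single_cells(
        n_cells=cfg.sim("n_cells"),
        n_genes=cfg.sim("n_genes_sc"),
        n_signature=cfg.sim("n_signature"),
        shift=cfg.sim("sc_shift"),
        seed=seed + 4,
    )
    outdir = cfg.outdir
    write_feature_table(proteome, _ensure(outdir, "inputs", "proteome.tsv"))
    write_feature_table(phospho, _ensure(outdir, "inputs", "phospho.tsv"))
    kinase.write_kinase_substrate_map(ksmap, _ensure(outdir, "inputs", "ksmap.tsv"))
    for d, table in enumerate(de_tables):
        table.to_csv(_ensure(outdir, "inputs", f"bulk_de_{d}.tsv"), sep="\t", index=False)
    write_interactions(records, _ensure(outdir, "inputs", "interactions.tsv"))
    write_sparse_counts(cells, os.path.join(outdir, "inputs", "cells"))
    write_gene_sets(
        GeneSetCollection(
            [
                GeneSet("M1_signature", "planted M1 markers", set(signature.m1_genes)),
                GeneSet("M2_signature", "planted M2 markers", set(signature.m2_genes)),
            ]
        ),
        _ensure(outdir, "inputs", "signatures.gmt"),
    )
    state.update(
        proteome=proteome,
        phospho=phospho,
        ksmap=ksmap,
        truth=truth,
        de_tables=de_tables,
        expr_tables=expr_tables,
        bulk_truth=bulk_truth,
        dtu_flags=[
            set(t.loc[(t.adj_p < 0.05) & (t.log2FC.abs() > 2), "gene"]) for t in dtu_tables
        ],
        records=records,
        net_truth=net_truth,
        cells=cells,
        signature=signature,
        cell_truth=cell_truth,
    )
    return {
        "proteome_features": proteome.n_features,
        "phospho_features": phospho.n_features,
        "bulk_datasets": len(de_tables),
        "interaction_records": len(records),
        "cells": cells.n_cells,
    }


def _stage_preprocess(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    prot = preprocess.clean_proteome(state["proteome"], min_peptides=th["min_peptides"])
    analysis, motif = preprocess.clean_phospho(
        state["phospho"], min_measured=th["min_measured"], loc_prob_min=th["loc_prob_min"]
    )
    prot = preprocess.impute_missing(
        preprocess.log2_center(prot),
        seed=cfg.seed + 10,
        shift_high=th["impute_shift_high"],
        shift_low=th["impute_shift_low"],
        width=th["impute_width"],
    )
    analysis_imp = preprocess.impute_missing(
        preprocess.log2_center(analysis),
        seed=cfg.seed + 11,
        shift_high=th["impute_shift_high"],
        shift_low=th["impute_shift_low"],
        width=th["impute_width"],
    )
    write_feature_table(prot, _ensure(cfg.outdir, "preprocess", "proteome_imputed.tsv"))
    write_feature_table(
        analysis_imp, _ensure(cfg.outdir, "preprocess", "phospho_imputed.tsv")
    )
    motif_sites = {
        (p, r)
        for p, r in zip(motif.protein_id, motif.meta["residue"])
        if isinstance(r, str) and r
    }
    state.update(prot_imputed=prot, phospho_imputed=analysis_imp, motif_sites=motif_sites)
    return {
        "proteome_kept": prot.n_features,
        "phospho_analysis": analysis_imp.n_features,
        "phospho_motif_sites": len(motif_sites),
    }


def _stage_diffexpr(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    prot_res = diffexpr.moderated_ttest(
        state["prot_imputed"], cond_a, cond_b, moderation=th["moderation"]
    )
    ph_res = diffexpr.moderated_ttest(
        state["phospho_imputed"], cond_a, cond_b, moderation=th["moderation"]
    )
    diffexpr.attach_fdr(prot_res)
    diffexpr.attach_fdr(ph_res)
    diffexpr.call_significant(prot_res, th["fdr_max"], th["abs_log2fc_min"])
    diffexpr.call_significant(ph_res, th["fdr_max"], th["abs_log2fc_min"])
    ph_res = diffexpr.reconcile_multiplicity(ph_res)
    adjusted = diffexpr.adjust_ptm_all(ph_res, prot_res, alpha=th["fdr_max"])
    raw_sig = {r.site_id for r in ph_res if r.significant}
    kept = diffexpr.apply_keep_rule(adjusted, raw_sig)

    def dump(results, name):
        pd.DataFrame([vars(r) for r in results]).to_csv(
            _ensure(cfg.outdir, "diffexpr", name), sep="\t", index=False
        )

    dump(prot_res, f"proteome_{cond_b}_vs_{cond_a}.tsv")
    dump(ph_res, f"phospho_{cond_b}_vs_{cond_a}.tsv")
    dump(adjusted, "phospho_ptm_adjusted.tsv")
    state.update(prot_res=prot_res, ph_res=ph_res, adjusted=adjusted, kept_sites=kept)
    return {
        "proteins_tested": len(prot_res),
        "proteins_significant": sum(r.significant for r in prot_res),
        "phospho_significant": len(raw_sig),
        "phospho_driven_kept": len(kept),
    }


def _site_tuple(site_id: str) -> tuple:
    protein, residue = site_id.rsplit("_", 1)
    return protein, residue


def _stage_kinase(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    motif = state["motif_sites"]
    up_sites = {
        _site_tuple(r.site_id)
        for r in state["ph_res"]
        if r.site_id in state["kept_sites"] and r.log2fc > 0
    } & motif
    measured = {_site_tuple(r.site_id) for r in state["ph_res"]} & motif
    enrichments = kinase.enrich_curated_substrates(
        up_sites, measured, state["ksmap"], alpha=th["kinase_alpha"]
    )
    upregulated_kinases = {e.kinase for e in enrichments if e.significant}
    net = kinase.build_signaling_network(
        upregulated_kinases=upregulated_kinases,
        measured_kinases=state["ksmap"].kinases,
        ksmap=state["ksmap"],
        filtered_preds=[],
        upregulated_sites=up_sites,
        tf_list=set(),
        mode="focused",
    )
    pd.DataFrame([vars(e) for e in enrichments]).to_csv(
        _ensure(cfg.outdir, "kinase", "enrichment.tsv"), sep="\t", index=False
    )
    kinase.write_signaling_network(
        net,
        _ensure(cfg.outdir, "kinase", "signaling_edges.tsv"),
        _ensure(cfg.outdir, "kinase", "signaling.graphml"),
    )
    state.update(kinase_enrichments=enrichments, upregulated_kinases=upregulated_kinases)
    return {
        "kinases_tested": len(enrichments),
        "kinases_significant": len(upregulated_kinases),
        "network_edges": net.number_of_edges(),
    }


def _stage_consensus(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    results = network.consensus_de(
        state["de_tables"],
        state["expr_tables"],
        min_datasets=th["min_datasets"],
        fdr_max=th["fdr_max"],
        min_ratio=th["min_ratio"],
    )
    dtu_genes = network.consensus_dtu(state["dtu_flags"], min_fraction=th["dtu_min_fraction"])
    pd.DataFrame([vars(r) for r in results]).to_csv(
        _ensure(cfg.outdir, "consensus", "consensus_de.tsv"), sep="\t", index=False
    )
    pd.Series(sorted(dtu_genes)).to_csv(
        _ensure(cfg.outdir, "consensus", "consensus_dtu.tsv"),
        sep="\t",
        index=False,
        header=["gene"],
    )
    state.update(
        consensus_genes={r.gene for r in results if r.consensus}, dtu_genes=dtu_genes
    )
    return {
        "genes_seen": len(results),
        "consensus_genes": len(state["consensus_genes"]),
        "dtu_genes": len(dtu_genes),
    }


def _stage_network(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    edges = network.merge_interactions(
        state["records"],
        combined_score_min=th["combined_score_min"],
        confidence_min=th["confidence_min"],
    )
    # evidence layers for the interaction nodes: deterministic assignment
    rng = np.random.default_rng(cfg.seed + 20)
    nodes = sorted(state["net_truth"].planted_modules)
    layer_draw = rng.random(len(nodes))
    hits_by_layer = {"proteome": set(), "phospho": set(), "transcript": set(), "dtu": set()}
    for n, u in zip(nodes, layer_draw):
        if u < 0.40:
            hits_by_layer["proteome"].add(n)
        elif u < 0.70:
            hits_by_layer["transcript"].add(n)
        elif u < 0.90:
            hits_by_layer["phospho"].add(n)
        elif u < 0.97:
            hits_by_layer["dtu"].add(n)
        # remaining nodes carry no evidence and drop out
    net = network.build_integrative_network(
        edges, hits_by_layer, dtu_max_fraction=th["dtu_max_fraction"]
    )
    if net.number_of_nodes() < 3:
        raise RuntimeError("integrative network empty after filtering")
    centrality = network.current_flow_betweenness(net)
    partition = network.detect_modules(
        net,
        target_avg_degree=th["target_avg_degree"],
        min_module_size=th["min_module_size"],
        seed=cfg.seed + 21,
    )
    network.write_node_table(
        net, centrality, partition, _ensure(cfg.outdir, "network", "nodes.tsv")
    )
    state.update(integrative_net=net, centrality=centrality, partition=partition)
    return {
        "merged_edges": len(edges),
        "network_nodes": net.number_of_nodes(),
        "network_edges": net.number_of_edges(),
        "modules": len(partition.modules),
        "avg_within_degree": round(partition.avg_within_degree, 2),
    }


def _stage_singlecell(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    filtered = singlecell.qc_filter(
        state["cells"],
        min_genes=th["sc_min_genes"],
        max_genes=th["sc_max_genes"],
        max_mito=th["sc_max_mito"],
        min_cells_per_gene=th["sc_min_cells_per_gene"],
    )
    norm = singlecell.normalize_log(filtered)
    sig = state["signature"]
    s1 = singlecell.score_signature(norm, sig.m1_genes, seed=cfg.seed + 30)
    s2 = singlecell.score_signature(norm, sig.m2_genes, seed=cfg.seed + 31)
    annotations = singlecell.classify_macrophages(norm.cell_ids, s1, s2)
    m1_cells = [a.cell_id for a in annotations if a.state == "M1-like"]
    m2_cells = [a.cell_id for a in annotations if a.state == "M2-like"]
    de = pd.DataFrame()
    if len(m1_cells) >= 2 and len(m2_cells) >= 2:
        de = singlecell.sc_differential_expression(
            norm,
            m2_cells,
            m1_cells,
            min_frac=th["sc_min_frac"],
            alpha=th["sc_alpha"],
            min_avg_log2fc=th["sc_min_avg_log2fc"],
        )
    pd.DataFrame([vars(a) for a in annotations]).to_csv(
        _ensure(cfg.outdir, "singlecell", "annotations.tsv"), sep="\t", index=False
    )
    de.to_csv(_ensure(cfg.outdir, "singlecell", "de_m1_vs_m2.tsv"), sep="\t", index=False)
    state.update(annotations=annotations, sc_de=de, sc_norm=norm)
    return {
        "cells_after_qc": filtered.n_cells,
        "m1_like": len(m1_cells),
        "m2_like": len(m2_cells),
        "na": sum(a.state == "Na" for a in annotations),
        "sc_de_significant": int(de["significant"].sum()) if len(de) else 0,
    }


def _stage_enrichment(cfg: RunConfig, state: dict, cond_a: str, cond_b: str) -> dict:
    th = cfg.data["thresholds"]
    # kinase substrate proteins double as "pathways" for the synthetic run
    sets = GeneSetCollection(
        [
            GeneSet(f"substrates_{k}", f"substrate proteins of {k}", {p for p, _ in v})
            for k, v in sorted(state["ksmap"].substrates_of.items())
        ]
    )
    background = {p for p, _ in state["motif_sites"]}
    hits = {_site_tuple(s)[0] for s in state["kept_sites"]} & background
    results = enrich.hypergeometric_ora(hits, background, sets)
    enrich.prune_and_filter(
        results,
        min_hits=th["ora_min_hits"],
        max_set_size=th["ora_max_set_size"],
        fdr_max=th["fdr_max"],
    )
    pd.DataFrame(
        [{k: v for k, v in vars(r).items() if k != "hit_members"} for r in results]
    ).to_csv(_ensure(cfg.outdir, "enrichment", "phospho_ora.tsv"), sep="\t", index=False)
    retained = [r for r in results if r.retained]
    state.update(ora_results=results)
    return {"sets_tested": len(results), "sets_retained": len(retained)}
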