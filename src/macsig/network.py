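"""Cross-dataset consensus, interaction merging, and integrative network analysis.

Bulk transcriptome evidence is consolidated across independently analyzed
datasets (a gene is a consensus hit when significant in at least three
datasets; a two-study union mode covers comparisons with only two available
datasets).  Interaction edges from a combined-score source, a
physical-interaction source and a confidence-scored source are filtered and
merged, restricted to multi-omics hit nodes, and the largest surviving
connected component is analyzed with current-flow betweenness centrality and
resolution-tuned modularity decomposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity

from macsig.io import InteractionRecord

__all__ = [
    "ConsensusDEResult",
    "ModulePartition",
    "consensus_de",
    "consensus_dtu",
    "merge_interactions",
    "build_integrative_network",
    "current_flow_betweenness",
    "detect_modules",
]


@dataclass
class ConsensusDEResult:
    gene: str
    significant_in: list
    n_significant_datasets: int
    consensus: bool
    direction_consistent: bool
    eligible: bool = True


@dataclass
class ModulePartition:
    """Disjoint node modules covering the analyzed component, sorted by size."""

    modules: dict  # module_id -> set of nodes
    quality: float  # modularity at the selected resolution
    resolution: float
    avg_within_degree: float
    sub_threshold: set = field(default_factory=set)  # module_ids below min size

    def label_of(self) -> dict:
        return {n: mid for mid, nodes in self.modules.items() for n in nodes}


# ---------------------------------------------------------------------------
# Bulk consensus
# ---------------------------------------------------------------------------


def consensus_de(
    tables: list,
    expr_tables: list | None = None,
    min_datasets: int = 3,
    fdr_max: float = 0.05,
    min_ratio: float = 4.0,
    mode: str = "intersect",
) -> list[ConsensusDEResult]:
    """Cross-dataset consensus of per-dataset differential-expression tables.

    Each table needs columns ``gene``, ``log2FC``, ``adj_p``.  A gene is
    *eligible* when its expression is above the dataset median in at least
    ``min_datasets`` datasets (skipped when ``expr_tables`` is None);
    *significant* in a dataset when adj_p < ``fdr_max`` and the fold ratio
    exceeds ``min_ratio`` (|log2FC| > log2(min_ratio)); and a *consensus*
    hit when significant in >= ``min_datasets`` datasets (``mode="union"``:
    in >= 1 dataset, for two-study comparisons).
    """
    if mode not in ("intersect", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "intersect" and len(tables) < min_datasets:
        raise ValueError(
            f"{len(tables)} datasets cannot reach a >= {min_datasets}-dataset consensus"
        )
    lfc_min = math.log2(min_ratio)

    eligible: dict = {}
    if expr_tables is not None:
        above: dict = {}
        for expr in expr_tables:
            med = float(np.median(list(expr.values())))
            for g, x in expr.items():
                above[g] = above.get(g, 0) + (x > med)
        for g, n in above.items():
            eligible[g] = n >= min_datasets

    genes: dict = {}
    for d, table in enumerate(tables):
        for row in table.itertuples(index=False):
            sig = (row.adj_p < fdr_max) and (abs(row.log2FC) > lfc_min)
            rec = genes.setdefault(row.gene, {"sig": [], "signs": []})
            if sig:
                rec["sig"].append(d)
                rec["signs"].append(np.sign(row.log2FC))

    needed = 1 if mode == "union" else min_datasets
    results = []
    for gene in sorted(genes):
        rec = genes[gene]
        ok = eligible.get(gene, True) if expr_tables is not None else True
        n_sig = len(rec["sig"])
        results.append(
            ConsensusDEResult(
                gene=gene,
                significant_in=rec["sig"],
                n_significant_datasets=n_sig,
                consensus=ok and n_sig >= needed,
                direction_consistent=len(set(rec["signs"])) <= 1,
                eligible=ok,
            )
        )
    return results


def consensus_dtu(gene_flags: list, min_fraction: float = 0.5) -> set:
    """Genes with differential-transcript-usage evidence in >= half the comparisons.

    ``gene_flags`` is a list of per-dataset gene sets that already passed
    the upstream two-stage screening.
    """
    if not gene_flags:
        return set()
    needed = math.ceil(min_fraction * len(gene_flags))
    counts: dict = {}
    for flags in gene_flags:
        for g in flags:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= needed}


# ---------------------------------------------------------------------------
# Interaction merging and the integrative network
# ---------------------------------------------------------------------------


def merge_interactions(
    records: list,
    combined_score_min: float = 0.7,
    confidence_min: float = 0.7,
) -> dict:
    """Filter per-source and merge into undirected simple edges.

    Combined-score records survive with confidence > ``combined_score_min``;
    physical-interaction records survive iff a confidence value is present
    (any value); confidence-scored records survive with confidence >
    ``confidence_min``.  Returns a map of sorted node pairs to the list of
    supporting source labels.
    """
    edges: dict = {}
    for r in records:
        if r.source == "combined_score":
            keep = r.confidence is not None and r.confidence > combined_score_min
        elif r.source == "physical":
            keep = r.confidence is not None
        elif r.source == "confidence_scored":
            keep = r.confidence is not None and r.confidence > confidence_min
        else:
            raise ValueError(f"unknown interaction source {r.source!r}")
        if not keep or r.node_a == r.node_b:
            continue
        key = tuple(sorted((r.node_a, r.node_b)))
        sources = edges.setdefault(key, [])
        if r.source not in sources:
            sources.append(r.source)
    return edges


def build_integrative_network(
    edges: dict,
    hits_by_layer: dict,
    dtu_max_fraction: float = 0.75,
) -> nx.Graph:
    """Restrict merged edges to multi-omics hits and keep the largest component.

    ``hits_by_layer`` maps layer names (subset of proteome / phospho /
    transcript / dtu) to significant-gene sets.  Only edges with both
    endpoints significant in at least one layer survive.  Connected
    components in which more than ``dtu_max_fraction`` of nodes carry only
    DTU evidence are discarded.  Returns the largest remaining component
    (possibly empty).
    """
    unknown = set(hits_by_layer) - {"proteome", "phospho", "transcript", "dtu"}
    if unknown:
        raise ValueError(f"unknown evidence layers: {sorted(unknown)}")
    layers_of: dict = {}
    for layer, hits in hits_by_layer.items():
        for g in hits:
            layers_of.setdefault(g, set()).add(layer)

    g = nx.Graph()
    for (a, b), sources in edges.items():
        if a in layers_of and b in layers_of:
            g.add_edge(a, b, sources=list(sources))
    for n in g.nodes:
        g.nodes[n]["layers"] = sorted(layers_of[n])

    best = nx.Graph()
    for comp in nx.connected_components(g):
        dtu_only = sum(1 for n in comp if layers_of[n] == {"dtu"})
        if len(comp) and dtu_only / len(comp) > dtu_max_fraction:
            continue
        if len(comp) > best.number_of_nodes():
            best = g.subgraph(comp).copy()
    return best


# ---------------------------------------------------------------------------
# Centrality and modules
# ---------------------------------------------------------------------------


def current_flow_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized current-flow betweenness centrality per node.

    For every source–target pair a unit current is injected/extracted and
    the Laplacian system solved; a node's score sums its current
    throughput over all pairs, with endpoints excluded.  On trees this
    equals shortest-path betweenness (all current follows the unique
    path).
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("current-flow betweenness needs at least 3 nodes")
    if not nx.is_connected(graph):
        raise ValueError(
            "graph is disconnected; analyze each connected component separately"
        )
    scores = nx.current_flow_betweenness_centrality(graph, normalized=False)
    return {n: max(float(s), 0.0) for n, s in scores.items()}


def detect_modules(
    graph: nx.Graph,
    target_avg_degree: float = 10.0,
    min_module_size: int = 10,
    seed: int = 0,
    max_iter: int = 30,
    degree_tolerance: float = 0.25,
) -> ModulePartition:
    """Greedy modularity decomposition tuned to a target within-module degree.

    Multi-level (Louvain) modularity optimization with seeded tie-breaking;
    the resolution parameter is scanned by bisection so the mean
    within-module degree (2 x intra-module edges / nodes) approaches
    ``target_avg_degree``.  The degree target guides granularity coarsely:
    among all partitions whose average degree lies within
    ``degree_tolerance`` (relative) of the target, the one with the
    highest resolution-1 modularity — the actual optimization objective —
    is returned; only when no partition reaches the band does the closest
    one win.  The achieved average degree is reported.  Modules are
    numbered by decreasing size; modules smaller than ``min_module_size``
    are flagged sub-threshold.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("cannot decompose an empty graph")

    def partition_at(res: float):
        comms = louvain_communities(graph, resolution=res, seed=seed)
        intra = sum(graph.subgraph(c).number_of_edges() for c in comms)
        avg_deg = 2.0 * intra / graph.number_of_nodes()
        return comms, avg_deg

    # average within-module degree decreases as resolution grows
    lo, hi = 1e-3, 50.0
    candidates = []
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        comms, avg_deg = partition_at(mid)
        candidates.append((comms, avg_deg, mid))
        if avg_deg >= target_avg_degree:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3:
            break
    band = [
        c for c in candidates
        if abs(c[1] - target_avg_degree) <= degree_tolerance * target_avg_degree
    ]
    if band:
        comms, avg_deg, res = max(band, key=lambda c: modularity(graph, c[0]))
    else:
        comms, avg_deg, res = min(
            candidates, key=lambda c: abs(c[1] - target_avg_degree)
        )
    ordered = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    modules = {i: set(c) for i, c in enumerate(ordered)}
    return ModulePartition(
        modules=modules,
        quality=modularity(graph, ordered),
        resolution=res,
        avg_within_degree=avg_deg,
        sub_threshold={i for i, c in modules.items() if len(c) < min_module_size},
    )


def write_node_table(graph: nx.Graph, centrality: dict, partition, path) -> None:
    """TSV node table with evidence layers, centrality and module label."""
    label = partition.label_of() if partition is not None else {}
    rows = []
    for n in sorted(graph.nodes):
        rows.append(
            {
                "node": n,
                "layers": ",".join(graph.nodes[n].get("layers", [])),
                "centrality": centrality.get(n, float("nan")),
                "module": label.get(n, -1),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
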