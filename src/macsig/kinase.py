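"""Kinase-activity footprint inference and kinase–kinase signaling networks.

A kinase's *footprint* is the set of measured class-I phosphosites it is
known (curated substrate maps) or predicted (site-level kinase-family
predictions) to recognize.  Activity is inferred by asking whether the
kinase's footprint is over-represented among the upregulated phosphosites
relative to all other measured sites — a two-sided Fisher's exact test on
the 2x2 table (upregulated x recognized).

Sites are ``(protein, residue)`` pairs with residues like ``"S176"``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import scipy.stats as st

from macsig.diffexpr import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "KinaseSubstrateMap",
    "SitePrediction",
    "KinaseEnrichment",
    "enrich_curated_substrates",
    "filter_site_predictions",
    "enrich_predicted_families",
    "build_signaling_network",
    "read_kinase_substrate_map",
    "write_kinase_substrate_map",
    "read_site_predictions",
    "write_signaling_network",
]

_RESIDUE_RE = re.compile(r"^[STY]\d+$")


@dataclass
class KinaseSubstrateMap:
    """Curated kinase → substrate-site relations with an evidence label each.

    ``substrates_of`` maps a kinase symbol to a set of ``(protein,
    residue)`` sites; ``evidence`` maps ``(kinase, site)`` to a source
    label.
    """

    substrates_of: dict = field(default_factory=dict)
    evidence: dict = field(default_factory=dict)

    def add(self, kinase: str, site: tuple, source: str = "curated") -> None:
        protein, residue = site
        if not _RESIDUE_RE.match(residue):
            raise ValueError(f"invalid residue {residue!r} (expected S/T/Y + position)")
        self.substrates_of.setdefault(kinase, set()).add((protein, residue))
        self.evidence[(kinase, (protein, residue))] = source

    @property
    def kinases(self) -> set:
        return set(self.substrates_of)


@dataclass(frozen=True)
class SitePrediction:
    """One kinase-family prediction for one phosphosite."""

    site: tuple
    kinase_family: str
    posterior: float
    prior: float

    def __post_init__(self) -> None:
        if not (0 <= self.posterior <= 1 and 0 <= self.prior <= 1):
            raise ValueError("posterior and prior must lie in [0, 1]")


@dataclass
class KinaseEnrichment:
    """2x2 footprint enrichment of one kinase (or kinase family).

    a = upregulated and recognized, b = upregulated not recognized,
    c = other measured and recognized, d = other measured not recognized.
    """

    kinase: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    fdr: float = math.nan
    significant: bool = False


def _fisher_table(kinase, recognized, upregulated, measured) -> KinaseEnrichment:
    other = measured - upregulated
    a = len(upregulated & recognized)
    b = len(upregulated - recognized)
    c = len(other & recognized)
    d = len(other - recognized)
    odds, p = st.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return KinaseEnrichment(kinase, a, b, c, d, float(odds), float(p))


def enrich_curated_substrates(
    upregulated_sites: set,
    measured_sites: set,
    ksmap: KinaseSubstrateMap,
    alpha: float = 0.05,
    correct: bool = False,
) -> list[KinaseEnrichment]:
    """Per-kinase two-sided Fisher test of curated footprints.

    Both site sets must come from the class-I (motif) analysis set and
    ``upregulated_sites`` must be a subset of ``measured_sites``.  Kinases
    recognizing no measured site are excluded (logged).  Significance uses
    the raw p-value by default; ``correct=True`` switches to BH-adjusted
    values across kinases.
    """
    if not upregulated_sites <= measured_sites:
        raise ValueError("upregulated sites must be a subset of measured sites")
    results = []
    excluded = []
    for kinase in sorted(ksmap.substrates_of):
        recognized = ksmap.substrates_of[kinase] & measured_sites
        if not recognized:
            excluded.append(kinase)
            continue
        results.append(
            _fisher_table(kinase, recognized, upregulated_sites, measured_sites)
        )
    if excluded:
        logger.info("kinases with no recognized measured site excluded: %s", excluded)
    if correct:
        for r, q in zip(results, bh_adjust([r.p for r in results])):
            r.fdr = q
            r.significant = (q < alpha) and (r.odds_ratio > 1)
    else:
        for r in results:
            # a kinase is *upregulated*: over-representation direction required
            r.significant = (r.p < alpha) and (r.odds_ratio > 1)
    return results


def filter_site_predictions(
    preds: list[SitePrediction],
    min_posterior: float = 0.035,
    top_n: int = 3,
) -> list[SitePrediction]:
    """Filter site-level kinase-family predictions.

    Keeps predictions with posterior > ``min_posterior`` and posterior
    strictly above the prior, then per site retains the ``top_n`` families
    with the highest posterior (ties at the cut rank all kept).
    """
    passing = [p for p in preds if p.posterior > min_posterior and p.posterior > p.prior]
    by_site: dict = {}
    for p in passing:
        by_site.setdefault(p.site, []).append(p)
    kept = []
    for site in by_site:
        ranked = sorted(by_site[site], key=lambda p: (-p.posterior, p.kinase_family))
        if len(ranked) > top_n:
            cutoff = ranked[top_n - 1].posterior
            ranked = [p for p in ranked if p.posterior >= cutoff]
        kept.extend(ranked)
    return kept


def enrich_predicted_families(
    filtered_preds: list[SitePrediction],
    upregulated_sites: set,
    measured_sites: set,
    min_substrates: int = 10,
    alpha: float = 0.05,
) -> list[KinaseEnrichment]:
    """Footprint enrichment per predicted kinase family, BH-corrected.

    A family is significant iff it has at least ``min_substrates``
    upregulated recognized sites AND its BH-adjusted p-value is below
    ``alpha``.
    """
    if not upregulated_sites:
        return []
    recognized_by: dict = {}
    for p in filtered_preds:
        if p.site in measured_sites:
            recognized_by.setdefault(p.kinase_family, set()).add(p.site)
    results = []
    for family in sorted(recognized_by):
        results.append(
            _fisher_table(family, recognized_by[family], upregulated_sites, measured_sites)
        )
    for r, q in zip(results, bh_adjust([r.p for r in results])):
        r.fdr = q
        r.significant = (r.a >= min_substrates) and (q < alpha) and (r.odds_ratio > 1)
    return results


# ---------------------------------------------------------------------------
# Signaling network assembly
# ---------------------------------------------------------------------------


def build_signaling_network(
    upregulated_kinases: set,
    measured_kinases: set,
    ksmap: KinaseSubstrateMap,
    filtered_preds: list[SitePrediction],
    upregulated_sites: set,
    tf_list: set,
    mode: str = "focused",
    family_members: dict | None = None,
) -> nx.DiGraph:
    """Assemble the directed kinase–kinase / kinase–TF signaling network.

    An edge kinase → target is drawn only when the target protein carries
    an upregulated site that the kinase recognizes (curated relations give
    ``evidence="curated"``, filtered predictions ``evidence="predicted"``;
    predicted families expand to member kinases through
    ``family_members``, or act as single nodes when no mapping is given).

    Node inclusion: upregulated kinases always; unmeasured kinases iff
    they bridge at least one upregulated kinase to another measured
    kinase; TFs with upregulated substrate sites.  In ``mode="large"``,
    measured non-upregulated kinases are added when they connect two or
    more upregulated kinases.
    """
    if mode not in ("focused", "large"):
        raise ValueError(f"unknown mode {mode!r}")
    family_members = family_members or {}

    candidate = nx.DiGraph()
    kinase_universe = set(ksmap.kinases) | set(measured_kinases) | set(upregulated_kinases)

    def add_edge(src, site, evidence):
        protein, residue = site
        if protein in kinase_universe or protein in tf_list:
            candidate.add_edge(src, protein, evidence=evidence, site=residue)

    for kin, sites in ksmap.substrates_of.items():
        for site in sites & upregulated_sites:
            add_edge(kin, site, "curated")
    for pred in filtered_preds:
        if pred.site not in upregulated_sites:
            continue
        for kin in family_members.get(pred.kinase_family, [pred.kinase_family]):
            kinase_universe.add(kin)
            add_edge(kin, pred.site, "predicted")

    undirected = candidate.to_undirected()

    def neighbors(n):
        return set(undirected.neighbors(n)) if n in undirected else set()

    include = set(upregulated_kinases)
    for n in candidate.nodes:
        if n in tf_list:
            if any(candidate.has_edge(src, n) for src in candidate.predecessors(n)):
                include.add(n)
            continue
        if n in include:
            continue
        nb = neighbors(n)
        if n not in measured_kinases:
            # unmeasured kinase: bridge one upregulated and one other measured kinase
            if nb & set(upregulated_kinases) and (nb & set(measured_kinases)) - {n}:
                include.add(n)
        elif mode == "large":
            # larger networks admit non-upregulated measured kinases only as
            # connectors of two or more upregulated kinases
            if len(nb & set(upregulated_kinases)) >= 2:
                include.add(n)
        else:
            # focused: measured kinases adjacent to an upregulated kinase
            # (e.g. carrying an upregulated substrate site) stay in
            if nb & set(upregulated_kinases):
                include.add(n)

    net = nx.DiGraph()
    for n in include:
        net.add_node(
            n,
            upregulated=n in upregulated_kinases,
            measured=n in measured_kinases,
            bridging=(n not in measured_kinases) and (n not in tf_list) and n not in upregulated_kinases,
            is_tf=n in tf_list,
        )
    for u, v, data in candidate.edges(data=True):
        if u in include and v in include:
            net.add_edge(u, v, **data)
    return net


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def read_kinase_substrate_map(path) -> KinaseSubstrateMap:
    """Read a TSV with columns kinase, protein, residue[, source]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ksmap = KinaseSubstrateMap()
    for row in df.itertuples(index=False):
        source = getattr(row, "source", "curated") or "curated"
        ksmap.add(row.kinase, (row.protein, row.residue), source)
    return ksmap


def write_kinase_substrate_map(ksmap: KinaseSubstrateMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kinase\tprotein\tresidue\tsource\n")
        for kin in sorted(ksmap.substrates_of):
            for site in sorted(ksmap.substrates_of[kin]):
                src = ksmap.evidence.get((kin, site), "curated")
                fh.write(f"{kin}\t{site[0]}\t{site[1]}\t{src}\n")


def read_site_predictions(path) -> list[SitePrediction]:
    """Read a TSV with columns protein, residue, kinase_family, posterior, prior."""
    df = pd.read_csv(path, sep="\t")
    return [
        SitePrediction(
            site=(row.protein, row.residue),
            kinase_family=row.kinase_family,
            posterior=float(row.posterior),
            prior=float(row.prior),
        )
        for row in df.itertuples(index=False)
    ]


def write_signaling_network(net: nx.DiGraph, tsv_path, graphml_path=None) -> None:
    """Export the network as an edge-attribute TSV (and optionally GraphML)."""
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tevidence\tsite\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('evidence', '')}\t{data.get('site', '')}\n")
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)
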