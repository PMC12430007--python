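"""Seeded synthetic data with the statistical structure of each pipeline input.

Every generator is a pure function of its parameters and a seed, and returns
the ground truth needed for recovery tests alongside the data:

* :func:`gen_phosphoproteome` — two-condition label-free proteome and
  phosphosite matrices (log-normal baselines, Normal(25, 2) on the log2
  scale — a typical LFQ dynamic range), with kinase-driven effects planted
  at the phospho level only, a disjoint set of protein-abundance effects
  (so the PTM adjustment has something to remove), and left-censored
  missingness whose probability decreases logistically with log-intensity.
* :func:`gen_bulk_de_tables` — per-dataset differential-expression result
  tables where truly regulated genes reach significance in each dataset
  independently with a set concordance.
* :func:`gen_interaction_network` — a stochastic-block-model interaction
  graph distributed across three evidence-source roles with confidences
  drawn so a configurable fraction fails the merge thresholds.
* :func:`gen_single_cells` — negative-binomial counts with log-normal
  library sizes, two planted macrophage states separated by signature-gene
  mean shifts, mitochondrial genes, and QC-failing outlier cells.

Each planted phospho effect is attributable to exactly one mechanism:
kinase substrate sites are placed only on proteins without a planted
protein-level change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from macsig.io import FeatureTable, InteractionRecord, SparseCellMatrix
from macsig.kinase import KinaseSubstrateMap
from macsig.singlecell import SignatureSet

__all__ = [
    "MissingParams",
    "GroundTruth",
    "gen_phosphoproteome",
    "gen_bulk_de_tables",
    "gen_interaction_network",
    "gen_single_cells",
]


@dataclass
class MissingParams:
    """Left-censoring model: P(missing | x) = max_rate * expit(-(x - midpoint) * slope).

    ``x`` is the observed log2 intensity; the probability decreases
    monotonically with intensity.  ``enabled=False`` disables censoring.
    """

    enabled: bool = True
    midpoint: float = 22.5
    slope: float = 1.0
    max_rate: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_rate <= 1.0):
            raise ValueError("max_rate must be a probability")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")

    def prob(self, x: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return np.zeros_like(np.asarray(x, dtype=float))
        return self.max_rate * expit(-(np.asarray(x, dtype=float) - self.midpoint) * self.slope)


@dataclass
class GroundTruth:
    """Planted structure behind one synthetic dataset."""

    de_proteins: dict = field(default_factory=dict)  # protein -> log2 effect
    active_kinases: set = field(default_factory=set)
    kinase_substrates: dict = field(default_factory=dict)  # kinase -> {(protein, residue)}
    kinase_driven_sites: set = field(default_factory=set)  # {(protein, residue)}
    abundance_driven_sites: set = field(default_factory=set)
    de_genes: dict = field(default_factory=dict)  # gene -> planted sign
    planted_modules: dict = field(default_factory=dict)  # node -> module id
    cell_state_of: dict = field(default_factory=dict)  # cell -> M1-like / M2-like
    qc_fail_cells: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# Phosphoproteome
# ---------------------------------------------------------------------------


def _censor(log2_values: np.ndarray, params: MissingParams, rng) -> np.ndarray:
    """Return intensities (2^x) with left-censored entries set to NaN."""
    miss = rng.random(log2_values.shape) < params.prob(log2_values)
    intens = np.power(2.0, log2_values)
    intens[miss] = np.nan
    return intens


def gen_phosphoproteome(
    n_proteins: int = 200,
    sites_per_protein: int = 4,
    n_replicates: int = 4,
    n_kinases: int = 20,
    n_active: int = 3,
    substrates_per_kinase: int = 30,
    effect_log2: float = 2.0,
    noise_sd: float = 0.5,
    missing_params: MissingParams | None = None,
    seed: int = 0,
    phospho_noise_frac: float = 0.5,
    frac_protein_de: float = 0.1,
    frac_contaminant: float = 0.02,
    frac_decoy: float = 0.02,
    frac_low_peptide: float = 0.03,
    frac_nonphospho: float = 0.02,
    conditions: tuple = ("M1", "M2c"),
) -> tuple[FeatureTable, FeatureTable, KinaseSubstrateMap, GroundTruth]:
    """Paired two-condition proteome + phosphosite tables with planted effects.

    Substrate sites of active kinases are shifted by ``effect_log2`` in the
    second condition at the phospho level only; a disjoint protein set is
    shifted at the protein level (phosphosites on those proteins inherit
    the shift through protein abundance).  Junk features (contaminants,
    decoys, single-peptide proteins, non-phospho peptides) are appended to
    exercise the cleaning rules; they carry no planted structure.
    """
    if n_active > n_kinases:
        raise ValueError("n_active must not exceed n_kinases")
    if n_replicates < 2:
        raise ValueError("need at least two replicates per condition")
    if effect_log2 == 0 and n_active > 0:
        warnings.warn("effect_log2 = 0 with active kinases: truth is unrecoverable", stacklevel=2)
    missing_params = missing_params or MissingParams()
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    baseline = rng.normal(25.0, 2.0, n_proteins)

    n_de = int(round(frac_protein_de * n_proteins))
    de_idx = set(rng.choice(n_proteins, n_de, replace=False).tolist())
    protein_effect = np.zeros(n_proteins)
    for i in de_idx:
        protein_effect[i] = effect_log2

    # phosphosites, protein-major; residues unique within a protein
    sites = []  # (protein index, residue)
    for i in range(n_proteins):
        positions = rng.choice(np.arange(1, 2000), size=sites_per_protein, replace=False)
        for pos in sorted(positions):
            sites.append((i, f"S{pos}"))

    non_de_sites = [s for s in sites if s[0] not in de_idx]
    needed = n_kinases * substrates_per_kinase
    if needed > len(non_de_sites):
        raise ValueError(
            f"{needed} substrate sites requested but only {len(non_de_sites)} "
            "sites on proteins without a protein-level effect are available"
        )
    shuffled = list(non_de_sites)
    rng.shuffle(shuffled)
    # kinases are themselves proteins (non-regulated ones), so substrate
    # sites can fall on kinase proteins and kinase-kinase edges exist
    non_de_proteins = [proteins[i] for i in range(n_proteins) if i not in de_idx]
    kinases = [
        non_de_proteins[i]
        for i in rng.choice(len(non_de_proteins), n_kinases, replace=False)
    ]
    active = set(np.array(kinases)[rng.choice(n_kinases, n_active, replace=False)].tolist())
    ksmap = KinaseSubstrateMap()
    site_kinase: dict = {}
    for k, kin in enumerate(kinases):
        for p_idx, res in shuffled[k * substrates_per_kinase : (k + 1) * substrates_per_kinase]:
            ksmap.add(kin, (proteins[p_idx], res))
            site_kinase[(p_idx, res)] = kin

    samples = [f"{c}_{r + 1}" for c in conditions for r in range(n_replicates)]
    cond_of = {s: s.rsplit("_", 1)[0] for s in samples}
    in_b = np.array([cond_of[s] == conditions[1] for s in samples])

    # proteome matrix
    prot_log2 = (
        baseline[:, None]
        + protein_effect[:, None] * in_b[None, :]
        + rng.normal(0.0, noise_sd, (n_proteins, len(samples)))
    )
    prot_values = _censor(prot_log2, missing_params, rng)

    def _meta(n, peptide_counts, contaminant, decoy, phospho, mult=np.nan, loc=np.nan, residue=""):
        return pd.DataFrame(
            {
                "peptide_count": peptide_counts,
                "multiplicity": mult,
                "localization_prob": loc,
                "residue": residue,
                "is_contaminant": contaminant,
                "is_decoy": decoy,
                "is_phosphopeptide": phospho,
            }
        )

    # junk proteome rows exercising the cleaning rules
    def _junk_rows(prefix, n, contaminant=False, decoy=False, peptides=None):
        ids = [f"{prefix}{i:03d}" for i in range(1, n + 1)]
        vals = _censor(
            rng.normal(25.0, 2.0, (n, len(samples))) + rng.normal(0, noise_sd, (n, len(samples))),
            missing_params,
            rng,
        )
        peps = peptides if peptides is not None else rng.integers(2, 15, n)
        return ids, vals, peps, contaminant, decoy

    n_cont = int(round(frac_contaminant * n_proteins))
    n_dec = int(round(frac_decoy * n_proteins))
    n_lp = int(round(frac_low_peptide * n_proteins))
    junk = [
        _junk_rows("CONT", n_cont, contaminant=True),
        _junk_rows("REV", n_dec, decoy=True),
        _junk_rows("LP", n_lp, peptides=np.ones(n_lp, dtype=int)),
    ]
    all_ids = list(proteins)
    all_vals = [prot_values]
    all_peps = [rng.integers(2, 15, n_proteins)]
    flags_cont = [np.zeros(n_proteins, bool)]
    flags_dec = [np.zeros(n_proteins, bool)]
    for ids, vals, peps, cont, dec in junk:
        all_ids.extend(ids)
        all_vals.append(vals)
        all_peps.append(np.asarray(peps))
        flags_cont.append(np.full(len(ids), cont))
        flags_dec.append(np.full(len(ids), dec))
    proteome = FeatureTable(
        values=np.vstack(all_vals),
        feature_id=all_ids,
        protein_id=all_ids,
        sample_ids=samples,
        condition_of_sample=cond_of,
        meta=_meta(
            len(all_ids),
            np.concatenate(all_peps),
            np.concatenate(flags_cont),
            np.concatenate(flags_dec),
            phospho=False,
        ),
    )

    # phosphosite matrix
    n_sites = len(sites)
    site_offset = rng.normal(0.0, 1.0, n_sites)
    site_effect = np.array(
        [
            effect_log2 if site_kinase.get(s) in active else 0.0
            for s in sites
        ]
    )
    site_protein_idx = np.array([s[0] for s in sites])
    # matched design: the phosphopeptide inherits its protein's observed
    # per-sample value (shared biological variation), plus a smaller
    # phospho-specific residual noise
    ph_log2 = (
        prot_log2[site_protein_idx]
        + site_offset[:, None]
        + site_effect[:, None] * in_b[None, :]
        + rng.normal(0.0, phospho_noise_frac * noise_sd, (n_sites, len(samples)))
    )
    ph_values = _censor(ph_log2, missing_params, rng)

    loc_prob = np.where(
        np.array([(p, r) in site_kinase for p, r in sites]) | (rng.random(n_sites) < 0.85),
        rng.uniform(0.76, 1.0, n_sites),
        rng.uniform(0.30, 0.75, n_sites),
    )
    ph_ids = [f"{proteins[p]}_{r}_M1" for p, r in sites]
    ph_prot = [proteins[p] for p, r in sites]
    residues = [r for _, r in sites]

    n_np = int(round(frac_nonphospho * n_sites))
    np_ids = [f"NP{i:03d}" for i in range(1, n_np + 1)]
    np_vals = _censor(
        rng.normal(24.0, 2.0, (n_np, len(samples))) + rng.normal(0, noise_sd, (n_np, len(samples))),
        missing_params,
        rng,
    )
    phospho = FeatureTable(
        values=np.vstack([ph_values, np_vals]),
        feature_id=ph_ids + np_ids,
        protein_id=ph_prot + np_ids,
        sample_ids=samples,
        condition_of_sample=cond_of,
        meta=_meta(
            n_sites + n_np,
            np.ones(n_sites + n_np, dtype=int),
            np.zeros(n_sites + n_np, bool),
            np.zeros(n_sites + n_np, bool),
            phospho=np.concatenate([np.ones(n_sites, bool), np.zeros(n_np, bool)]),
            mult=np.concatenate([np.ones(n_sites), np.full(n_np, np.nan)]),
            loc=np.concatenate([loc_prob, np.full(n_np, np.nan)]),
            residue=residues + [""] * n_np,
        ),
    )

    truth = GroundTruth(
        de_proteins={proteins[i]: effect_log2 for i in sorted(de_idx)},
        active_kinases=active,
        kinase_substrates={k: set(v) for k, v in ksmap.substrates_of.items()},
        kinase_driven_sites={
            (proteins[p], r) for (p, r), kin in site_kinase.items() if kin in active
        },
        abundance_driven_sites={
            (proteins[p], r) for p, r in sites if p in de_idx
        },
    )
    return proteome, phospho, ksmap, truth


# ---------------------------------------------------------------------------
# Bulk DE tables
# ---------------------------------------------------------------------------


def gen_bulk_de_tables(
    n_datasets: int = 6,
    n_genes: int = 2000,
    frac_de: float = 0.05,
    concordance: float = 0.9,
    fp_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list, list, GroundTruth]:
    """Per-dataset DE result tables plus matching expression tables.

    Truly regulated genes are significant (adj_p < 0.05, |log2FC| > 2) in
    each dataset independently with probability ``concordance``; null genes
    with probability ``fp_rate``.  Expression tables (gene -> mean
    expression) give regulated genes systematically higher expression so
    they pass the above-median prefilter.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    n_de = int(round(frac_de * n_genes))
    de_set = set(rng.choice(n_genes, n_de, replace=False).tolist())
    signs = {i: int(rng.choice([-1, 1])) for i in de_set}
    expr_base = rng.normal(0.0, 1.0, n_genes)
    for i in de_set:
        expr_base[i] = rng.normal(1.5, 0.5)

    de_tables, expr_tables = [], []
    for _ in range(n_datasets):
        rows = []
        expr = {}
        for i, g in enumerate(genes):
            expr[g] = float(expr_base[i] + rng.normal(0.0, 0.3))
            p_sig = concordance if i in de_set else fp_rate
            if rng.random() < p_sig:
                sign = signs.get(i, int(rng.choice([-1, 1])))
                lfc = sign * (2.0 + rng.exponential(1.0) + 0.1)
                adj_p = rng.uniform(1e-8, 0.049)
            else:
                lfc = rng.normal(0.0, 0.5)
                adj_p = rng.uniform(0.05, 1.0)
            rows.append({"gene": g, "log2FC": lfc, "adj_p": adj_p})
        de_tables.append(pd.DataFrame(rows))
        expr_tables.append(expr)
    truth = GroundTruth(de_genes={genes[i]: signs[i] for i in sorted(de_set)})
    return de_tables, expr_tables, truth


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------


def gen_interaction_network(
    n_blocks: int = 4,
    block_size: int = 40,
    p_in: float = 0.3,
    p_out: float = 0.01,
    frac_below_threshold: float = 0.2,
    seed: int = 0,
) -> tuple[list, GroundTruth]:
    """Stochastic-block-model edge list spread over the three source roles.

    A fraction ``frac_below_threshold`` of records draws a confidence that
    fails the merge thresholds (below 0.7 for scored sources, absent for
    the physical source) to exercise the filtering.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    nodes = [f"N{i:04d}" for i in range(1, n + 1)]
    block = np.repeat(np.arange(n_blocks), block_size)
    records = []
    sources = ["combined_score", "physical", "confidence_scored"]
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if block[i] == block[j] else p_out
            if rng.random() >= p:
                continue
            source = sources[int(rng.integers(3))]
            fails = rng.random() < frac_below_threshold
            if source == "physical":
                conf = None if fails else float(rng.uniform(0.1, 0.99))
            else:
                conf = float(rng.uniform(0.3, 0.699)) if fails else float(rng.uniform(0.705, 0.99))
            records.append(InteractionRecord(nodes[i], nodes[j], source, conf))
    truth = GroundTruth(planted_modules={nodes[i]: int(block[i]) for i in range(n)})
    return records, truth


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------


def gen_single_cells(
    n_cells: int = 1000,
    n_genes: int = 1000,
    n_signature: int = 100,
    shift: float = 1.5,
    nb_dispersion: float = 0.5,
    frac_m1: float = 0.5,
    mito_frac_outliers: float = 0.05,
    low_count_frac: float = 0.02,
    n_mito: int = 10,
    seed: int = 0,
) -> tuple[SparseCellMatrix, SignatureSet, GroundTruth]:
    """Negative-binomial counts with two planted macrophage states.

    Signature genes of a cell's planted state have their means multiplied
    by ``2**shift``.  Library sizes are log-normal; a fraction of cells is
    made to fail QC (``mito_frac_outliers`` with inflated mitochondrial
    counts, ``low_count_frac`` with collapsed library size).
    """
    if n_signature > n_genes / 4:
        raise ValueError("n_signature must not exceed n_genes / 4")
    if n_genes < 2 * n_signature + n_mito:
        raise ValueError("n_genes too small for the signatures plus mito genes")
    rng = np.random.default_rng(seed)

    m1_genes = [f"M1SIG{i:04d}" for i in range(1, n_signature + 1)]
    m2_genes = [f"M2SIG{i:04d}" for i in range(1, n_signature + 1)]
    mito_genes = [f"MT-{i}" for i in range(1, n_mito + 1)]
    n_fill = n_genes - 2 * n_signature - n_mito
    fillers = [f"GENE{i:05d}" for i in range(1, n_fill + 1)]
    gene_ids = m1_genes + m2_genes + fillers + mito_genes

    base = rng.lognormal(0.5, 0.8, n_genes)
    base[-n_mito:] = 7.0  # mitochondrial genes: a few percent of a typical library

    cells = [f"CELL{i:05d}" for i in range(1, n_cells + 1)]
    is_m1 = rng.random(n_cells) < frac_m1
    size_factor = rng.lognormal(0.0, 0.3, n_cells)
    mito_out = rng.random(n_cells) < mito_frac_outliers
    low_out = (~mito_out) & (rng.random(n_cells) < low_count_frac)
    size_factor[low_out] *= 0.05

    mean = base[:, None] * size_factor[None, :]
    mean[:n_signature, is_m1] *= 2.0**shift
    mean[n_signature : 2 * n_signature, ~is_m1] *= 2.0**shift
    mean[-n_mito:, mito_out] *= 10.0

    r = 1.0 / nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    matrix = SparseCellMatrix(
        gene_ids=gene_ids,
        cell_ids=cells,
        counts=sp.csr_matrix(counts),
        mito_flag=np.array([g.startswith("MT-") for g in gene_ids]),
    )
    signature = SignatureSet("planted", m1_genes, m2_genes)
    truth = GroundTruth(
        cell_state_of={
            c: ("M1-like" if m1 else "M2-like") for c, m1 in zip(cells, is_m1)
        },
        qc_fail_cells={c for c, bad in zip(cells, mito_out | low_out) if bad},
    )
    return matrix, signature, truth
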