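"""Single-cell QC, normalization, signature scoring and macrophage assignment.

Cells arrive pre-labeled as macrophages (upstream isolation is not part of
this package).  QC removes outlier cells (<500 or >9000 expressed genes,
>10% mitochondrial counts) and rarely expressed genes (<3 cells); counts are
depth-normalized to 10,000 per cell and natural-log transformed (ln(1+x), so
zeros remain zero).

The module score of a gene signature is the per-cell mean, over signature
genes, of the gene's expression minus the mean expression of 100 control
genes drawn from the same average-expression bin (24 equal-frequency bins
over all genes), which removes the depth/abundance component of the raw
mean.  Cells are assigned M1-like or M2-like when the corresponding score
is the larger of the two and positive, and Na (unknown) when both scores
are non-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from macsig.io import SparseCellMatrix

__all__ = [
    "SignatureSet",
    "CellAnnotation",
    "NormalizedMatrix",
    "qc_filter",
    "normalize_log",
    "score_signature",
    "classify_macrophages",
    "classify_by_marker",
    "sc_differential_expression",
]


@dataclass
class SignatureSet:
    """Paired M1-like / M2-like marker gene lists (disjoint, non-empty)."""

    name: str
    m1_genes: list
    m2_genes: list

    def __post_init__(self) -> None:
        if not self.m1_genes or not self.m2_genes:
            raise ValueError("signature gene lists must be non-empty")
        if set(self.m1_genes) & set(self.m2_genes):
            raise ValueError("M1 and M2 signature lists must be disjoint")


@dataclass
class CellAnnotation:
    cell_id: str
    score_m1: float
    score_m2: float
    state: str  # M1-like | M2-like | Na
    tie: bool = False


@dataclass
class NormalizedMatrix:
    """Dense gene-by-cell matrix of depth-normalized log expression."""

    gene_ids: list
    cell_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match gene/cell lists")


def qc_filter(
    cells: SparseCellMatrix,
    min_genes: int = 500,
    max_genes: int = 9000,
    max_mito: float = 0.10,
    min_cells_per_gene: int = 3,
) -> SparseCellMatrix:
    """Remove outlier cells, then rarely expressed genes.

    Cells with fewer than ``min_genes`` or more than ``max_genes``
    expressed genes are removed (strict inequalities: exactly 500 or 9000
    expressed genes is kept), as are cells whose mitochondrial count
    fraction exceeds ``max_mito``.  Genes expressed in fewer than
    ``min_cells_per_gene`` surviving cells are then dropped.  An empty
    result is returned as an empty matrix, not an error.
    """
    counts = cells.counts.tocsc()
    expressed = (counts > 0).sum(axis=0).A1
    totals = counts.sum(axis=0).A1
    mito_counts = counts[cells.mito_flag].sum(axis=0).A1 if cells.mito_flag.any() else np.zeros_like(totals)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 1.0)
    keep_cells = (expressed >= min_genes) & (expressed <= max_genes) & (mito_frac <= max_mito)

    sub = counts[:, keep_cells].tocsr()
    expressed_in = (sub > 0).sum(axis=1).A1
    keep_genes = expressed_in >= min_cells_per_gene
    return SparseCellMatrix(
        gene_ids=[g for g, k in zip(cells.gene_ids, keep_genes) if k],
        cell_ids=[c for c, k in zip(cells.cell_ids, keep_cells) if k],
        counts=sub[keep_genes],
        mito_flag=cells.mito_flag[keep_genes],
    )


def normalize_log(cells: SparseCellMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Depth-normalize to ``scale_factor`` counts per cell and ln(1+x) transform."""
    totals = np.asarray(cells.counts.sum(axis=0)).ravel()
    if np.any(totals == 0):
        zero = [c for c, t in zip(cells.cell_ids, totals) if t == 0]
        raise ValueError(f"cells with zero total counts (QC should prevent this): {zero}")
    dense = cells.counts.toarray().astype(float)
    return NormalizedMatrix(
        gene_ids=list(cells.gene_ids),
        cell_ids=list(cells.cell_ids),
        values=np.log1p(scale_factor * dense / totals),
    )


def score_signature(
    norm: NormalizedMatrix,
    gene_list: list,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell signature module score with expression-matched controls.

    All genes are ranked by average expression across cells (ties broken
    by gene id) and cut into ``n_bins`` equal-frequency bins.  For each
    signature gene, ``n_ctrl`` control genes are drawn from its bin
    (without replacement when the bin is large enough, with replacement
    otherwise).  The score of a cell is the mean over signature genes of
    (gene expression − mean control expression).
    """
    present = [g for g in gene_list if g in set(norm.gene_ids)]
    if not present:
        missing = sorted(set(gene_list) - set(norm.gene_ids))
        raise ValueError(f"no signature genes in the matrix; missing: {missing}")

    avg = norm.values.mean(axis=1)
    # deterministic ranking: average expression, then gene id
    order = sorted(range(len(norm.gene_ids)), key=lambda i: (avg[i], norm.gene_ids[i]))
    n_genes = len(order)
    bin_of = np.empty(n_genes, dtype=int)
    for rank, i in enumerate(order):
        bin_of[i] = min(rank * n_bins // n_genes, n_bins - 1)
    bins: dict = {}
    for i in order:
        bins.setdefault(bin_of[i], []).append(i)

    gene_index = {g: i for i, g in enumerate(norm.gene_ids)}
    rng = np.random.default_rng(seed)
    diffs = np.zeros((len(present), len(norm.cell_ids)))
    for row, g in enumerate(present):
        i = gene_index[g]
        pool = bins[bin_of[i]]
        ctrl = rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl)
        diffs[row] = norm.values[i] - norm.values[ctrl].mean(axis=0)
    return diffs.mean(axis=0)


def classify_macrophages(
    cell_ids: list,
    score_m1: np.ndarray,
    score_m2: np.ndarray,
) -> list[CellAnnotation]:
    """Assign each cell to M1-like, M2-like or Na from its two signature scores.

    M1-like iff score_m1 > score_m2 and score_m1 > 0; M2-like iff
    score_m2 > score_m1 and score_m2 > 0; Na when both scores are <= 0.
    An exact tie with positive scores is Na with a tie flag.
    """
    annotations = []
    for cid, s1, s2 in zip(cell_ids, score_m1, score_m2):
        s1, s2 = float(s1), float(s2)
        if s1 > s2 and s1 > 0:
            state, tie = "M1-like", False
        elif s2 > s1 and s2 > 0:
            state, tie = "M2-like", False
        elif s1 == s2 and s1 > 0:
            state, tie = "Na", True
        else:
            state, tie = "Na", False
        annotations.append(CellAnnotation(cid, s1, s2, state, tie))
    return annotations


def classify_by_marker(
    norm: NormalizedMatrix,
    marker: str,
    threshold: float = 0.0,
) -> list[CellAnnotation]:
    """Single-marker mode: M2-like iff the marker exceeds ``threshold``, else M1-like.

    The default threshold 0 means "any expression".  Marker expression is
    reported in the ``score_m2`` slot.
    """
    if marker not in norm.gene_ids:
        raise ValueError(f"marker gene {marker!r} not in matrix")
    expr = norm.values[norm.gene_ids.index(marker)]
    return [
        CellAnnotation(cid, 0.0, float(x), "M2-like" if x > threshold else "M1-like")
        for cid, x in zip(norm.cell_ids, expr)
    ]


def sc_differential_expression(
    norm: NormalizedMatrix,
    group_a: list,
    group_b: list,
    min_frac: float = 0.10,
    alpha: float = 0.05,
    min_avg_log2fc: float = 0.75,
) -> pd.DataFrame:
    """Per-gene t-tests between two cell groups with Bonferroni correction.

    Only genes expressed (value > 0) in at least ``min_frac`` of cells of
    either group are tested.  The average log2 fold change is
    log2(mean(expm1(x)) + 1) of group B minus group A.  Significant iff
    the Bonferroni-adjusted p is below ``alpha`` AND the average log2FC
    exceeds ``min_avg_log2fc`` (upregulated in group B, one direction).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least two cells")
    idx = {c: i for i, c in enumerate(norm.cell_ids)}
    ia = np.array([idx[c] for c in group_a])
    ib = np.array([idx[c] for c in group_b])
    a, b = norm.values[:, ia], norm.values[:, ib]

    frac_a = (a > 0).mean(axis=1)
    frac_b = (b > 0).mean(axis=1)
    testable = np.where((frac_a >= min_frac) | (frac_b >= min_frac))[0]

    rows = []
    for i in testable:
        t, p = st.ttest_ind(b[i], a[i], equal_var=True)
        lfc = math.log2(np.mean(np.expm1(b[i])) + 1.0) - math.log2(
            np.mean(np.expm1(a[i])) + 1.0
        )
        rows.append(
            {
                "gene": norm.gene_ids[i],
                "avg_log2fc": lfc,
                "p": 1.0 if math.isnan(p) else float(p),
                "frac_a": float(frac_a[i]),
                "frac_b": float(frac_b[i]),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "avg_log2fc", "p", "frac_a", "frac_b"])
    if len(df):
        df["p_adj"] = np.minimum(df["p"] * len(df), 1.0)  # Bonferroni
        df["significant"] = (df["p_adj"] < alpha) & (df["avg_log2fc"] > min_avg_log2fc)
    else:
        df["p_adj"] = []
        df["significant"] = []
    return df
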