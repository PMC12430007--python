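"""Readers, writers and the shared data model for every format the pipeline touches.

Tabular inputs are TSV with a header row (UTF-8).  Gene sets use the GMT
dialect, single-cell counts use MatrixMarket plus plain-text gene/barcode
lists.  All writers emit a deterministic column order so that identical
in-memory content always serializes to identical bytes.

Conventions baked into the data model:

* An intensity of 0 and an empty cell both mean "missing" — label-free
  zeros are non-detections, not measurements.
* Phosphopeptide features are keyed by the pair (site id, multiplicity):
  singly, doubly and triply phosphorylated forms of the same site are
  separate features and are analyzed separately.
* Symbol matching is case-sensitive exact string match throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "FeatureTable",
    "GeneSet",
    "GeneSetCollection",
    "InteractionRecord",
    "SparseCellMatrix",
    "SchemaError",
    "FormatError",
    "read_feature_table",
    "write_feature_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_interactions",
    "write_interactions",
    "read_sparse_counts",
    "write_sparse_counts",
]


class SchemaError(ValueError):
    """A required column is absent or has the wrong type for the declared schema."""


class FormatError(ValueError):
    """A file does not conform to its format (GMT line arity, MTX dimensions...)."""


# ---------------------------------------------------------------------------
# Feature tables (proteome / phosphoproteome intensity matrices)
# ---------------------------------------------------------------------------

#: per-feature metadata columns, in serialization order
META_COLUMNS = [
    "peptide_count",
    "multiplicity",
    "localization_prob",
    "residue",
    "is_contaminant",
    "is_decoy",
    "is_phosphopeptide",
]


@dataclass
class FeatureTable:
    """Feature-by-sample label-free intensity matrix with metadata.

    ``values`` holds intensities (arbitrary LFQ units before transformation,
    real log2 values after); missing entries are NaN.  ``meta`` is a
    DataFrame with one row per feature and the columns of
    :data:`META_COLUMNS` (``multiplicity``/``localization_prob``/``residue``
    are NaN/empty for proteome tables).
    """

    values: np.ndarray
    feature_id: list
    protein_id: list
    sample_ids: list
    condition_of_sample: dict
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_feat, n_samp = self.values.shape
        if len(self.feature_id) != n_feat or len(self.protein_id) != n_feat:
            raise ValueError("feature metadata length does not match matrix rows")
        if len(self.sample_ids) != n_samp:
            raise ValueError("sample id count does not match matrix columns")
        missing_cond = [s for s in self.sample_ids if s not in self.condition_of_sample]
        if missing_cond:
            raise ValueError(f"samples without a condition: {missing_cond}")
        if len(self.meta) != n_feat:
            raise ValueError("meta rows do not match matrix rows")

    # -- basic introspection -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def conditions(self) -> list:
        """Condition labels in first-appearance sample order."""
        seen: dict = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition_of_sample[s], None)
        return list(seen)

    def sample_indices(self, condition: str) -> np.ndarray:
        idx = [
            i
            for i, s in enumerate(self.sample_ids)
            if self.condition_of_sample[s] == condition
        ]
        if not idx:
            raise KeyError(f"no samples with condition {condition!r}")
        return np.asarray(idx, dtype=int)

    def subset(self, mask) -> "FeatureTable":
        """Return a new table restricted to the features where ``mask`` is true."""
        mask = np.asarray(mask, dtype=bool)
        return FeatureTable(
            values=self.values[mask].copy(),
            feature_id=[f for f, m in zip(self.feature_id, mask) if m],
            protein_id=[p for p, m in zip(self.protein_id, mask) if m],
            sample_ids=list(self.sample_ids),
            condition_of_sample=dict(self.condition_of_sample),
            meta=self.meta.loc[mask].reset_index(drop=True),
        )

    def copy(self) -> "FeatureTable":
        return self.subset(np.ones(self.n_features, dtype=bool))


_REQUIRED = {
    "proteome": ["feature_id", "protein_id", "peptide_count", "is_contaminant", "is_decoy"],
    "phospho": [
        "feature_id",
        "protein_id",
        "peptide_count",
        "multiplicity",
        "localization_prob",
        "residue",
        "is_contaminant",
        "is_decoy",
        "is_phosphopeptide",
    ],
}

_INTENSITY_PREFIX = "intensity:"


def _parse_flag(column: pd.Series) -> np.ndarray:
    return column.astype(str).isin(["+", "True", "true", "1"]).to_numpy()


def read_feature_table(path, schema: str) -> FeatureTable:
    """Read a proteome or phosphosite intensity TSV.

    Sample columns are named ``intensity:<condition>:<sample>`` so the
    condition map round-trips with the matrix.  Zero intensities and empty
    cells are recorded as missing (NaN).
    """
    if schema not in _REQUIRED:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _REQUIRED[schema]:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r} for schema {schema!r}")
    sample_cols = [c for c in df.columns if c.startswith(_INTENSITY_PREFIX)]
    if not sample_cols:
        raise SchemaError(f"{path}: no '{_INTENSITY_PREFIX}<condition>:<sample>' columns")

    sample_ids, condition_of_sample = [], {}
    for col in sample_cols:
        try:
            _, condition, sample = col.split(":", 2)
        except ValueError:
            raise SchemaError(f"{path}: malformed intensity column {col!r}") from None
        sample_ids.append(sample)
        condition_of_sample[sample] = condition

    values = np.full((len(df), len(sample_cols)), np.nan)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            if cell == "":
                continue
            try:
                x = float(cell)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric intensity {cell!r} at row {i + 2}, column {col!r}"
                ) from None
            if x != 0:  # LFQ zero means non-detection
                values[i, j] = x

    is_phospho = schema == "phospho"
    meta = pd.DataFrame(
        {
            "peptide_count": pd.to_numeric(df["peptide_count"]).astype(int),
            "multiplicity": (
                pd.to_numeric(df["multiplicity"]) if is_phospho else np.nan
            ),
            "localization_prob": (
                pd.to_numeric(df["localization_prob"].replace("", "nan"))
                if is_phospho
                else np.nan
            ),
            "residue": df["residue"] if is_phospho else "",
            "is_contaminant": _parse_flag(df["is_contaminant"]),
            "is_decoy": _parse_flag(df["is_decoy"]),
            "is_phosphopeptide": (
                _parse_flag(df["is_phosphopeptide"]) if is_phospho else False
            ),
        }
    )
    return FeatureTable(
        values=values,
        feature_id=df["feature_id"].tolist(),
        protein_id=df["protein_id"].tolist(),
        sample_ids=sample_ids,
        condition_of_sample=condition_of_sample,
        meta=meta,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a :class:`FeatureTable` as TSV (deterministic column order)."""
    out = pd.DataFrame({"feature_id": table.feature_id, "protein_id": table.protein_id})
    for col in META_COLUMNS:
        series = table.meta[col]
        if col.startswith("is_"):
            out[col] = np.where(series.astype(bool), "+", "")
        else:
            out[col] = series
    for j, s in enumerate(table.sample_ids):
        colname = f"{_INTENSITY_PREFIX}{table.condition_of_sample[s]}:{s}"
        col = table.values[:, j]
        out[colname] = ["" if np.isnan(x) else repr(float(x)) for x in col]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    set_id: str
    set_name: str
    members: set


@dataclass
class GeneSetCollection:
    """Ordered collection of gene sets with unique ids."""

    sets: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.set_id for s in self.sets]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate set ids in collection")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line.

    Duplicate members within a set are de-duplicated; an empty file yields
    an empty collection.
    """
    sets = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets.append(GeneSet(fields[0], fields[1], set(fields[2:])))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.set_id, s.set_name, *sorted(s.members)]) + "\n")


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

INTERACTION_SOURCES = ("combined_score", "physical", "confidence_scored")


@dataclass(frozen=True)
class InteractionRecord:
    """One interaction from one evidence source.

    The three source roles mirror the merged databases: a combined-score
    list, a physical-interaction list, and a confidence-scored list.
    """

    node_a: str
    node_b: str
    source: str
    confidence: float | None = None


def read_interactions(path, source: str) -> list:
    """Read a two-column (+optional ``confidence``) edge TSV, dropping self-loops."""
    if source not in INTERACTION_SOURCES:
        raise ValueError(f"unknown interaction source {source!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two node columns")
    has_conf = "confidence" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        conf = None
        if has_conf:
            cell = getattr(row, "confidence")
            if cell != "":
                try:
                    conf = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric confidence {cell!r} at row {i + 2}"
                    ) from None
        records.append(InteractionRecord(a, b, source, conf))
    return records


def write_interactions(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tsource\tconfidence\n")
        for r in records:
            conf = "" if r.confidence is None else repr(float(r.confidence))
            fh.write(f"{r.node_a}\t{r.node_b}\t{r.source}\t{conf}\n")


# ---------------------------------------------------------------------------
# Sparse single-cell count matrices
# ---------------------------------------------------------------------------


@dataclass
class SparseCellMatrix:
    """Gene-by-cell sparse non-negative integer count matrix."""

    gene_ids: list
    cell_ids: list
    counts: sp.csr_matrix
    mito_flag: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids not unique")
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


def read_sparse_counts(directory, mito_prefix: str = "MT-") -> SparseCellMatrix:
    """Read ``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv`` from a directory.

    The mitochondrial flag is set by gene-name prefix (default ``MT-``).
    """
    mtx_path = os.path.join(directory, "matrix.mtx")
    genes_path = os.path.join(directory, "genes.tsv")
    cells_path = os.path.join(directory, "barcodes.tsv")
    with open(genes_path, encoding="utf-8") as fh:
        gene_ids = [line.strip() for line in fh if line.strip()]
    with open(cells_path, encoding="utf-8") as fh:
        cell_ids = [line.strip() for line in fh if line.strip()]
    counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    if counts.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"{mtx_path}: matrix is {counts.shape} but gene list has "
            f"{len(gene_ids)} entries and barcode list has {len(cell_ids)}"
        )
    mito = np.array([g.startswith(mito_prefix) for g in gene_ids])
    return SparseCellMatrix(gene_ids, cell_ids, counts, mito)


def write_sparse_counts(cells: SparseCellMatrix, directory) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "genes.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(cells.gene_ids) + "\n")
    with open(os.path.join(directory, "barcodes.tsv"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(cells.cell_ids) + "\n")
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"), sp.coo_matrix(cells.counts), field="integer"
    )
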