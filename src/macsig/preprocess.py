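"""Cleaning, log2 transformation, centering, and downshifted-normal imputation.

The imputation follows the two-tier left-censoring model used for label-free
intensities: a feature measured in more than half of a condition's replicates
is assumed missing-at-random near its observed abundance and is imputed from
a mildly downshifted normal (mean − 0.5·SD); a feature measured in half or
fewer replicates is assumed below the detection limit and imputed from a
strongly downshifted normal (mean − 1.8·SD).  Both tiers use a width of
0.3·SD.  The reference mean and SD are per-sample (column) statistics over
all present log-intensities in that sample — the convention that remains
defined even when a feature is entirely missing from a condition (such
features are explicitly imputed).  A per-feature reference is available via
``reference="feature"`` for comparison.
"""

from __future__ import annotations

import warnings

import numpy as np

from macsig.io import FeatureTable

__all__ = ["clean_proteome", "clean_phospho", "log2_center", "impute_missing"]


def clean_proteome(table: FeatureTable, min_peptides: int = 2) -> FeatureTable:
    """Drop contaminants, decoy matches, and proteins with < ``min_peptides`` peptides."""
    keep = (
        ~table.meta["is_contaminant"].to_numpy(dtype=bool)
        & ~table.meta["is_decoy"].to_numpy(dtype=bool)
        & (table.meta["peptide_count"].to_numpy() >= min_peptides)
    )
    return table.subset(keep)


def clean_phospho(
    table: FeatureTable,
    min_measured: int = 2,
    loc_prob_min: float = 0.75,
) -> tuple[FeatureTable, FeatureTable]:
    """Clean a phosphosite table and split it into analysis and motif sets.

    Non-phosphorylated peptides (carried through enrichment), contaminants
    and decoys are removed.  A feature enters the *analysis set* iff it has
    at least ``min_measured`` measurements in at least one condition.  The
    *motif set* (class I sites, used for kinase analyses) additionally
    requires localization probability > ``loc_prob_min``.
    """
    keep = (
        table.meta["is_phosphopeptide"].to_numpy(dtype=bool)
        & ~table.meta["is_contaminant"].to_numpy(dtype=bool)
        & ~table.meta["is_decoy"].to_numpy(dtype=bool)
    )
    measured_enough = np.zeros(table.n_features, dtype=bool)
    for cond in table.conditions():
        idx = table.sample_indices(cond)
        if len(idx) < min_measured:
            warnings.warn(
                f"condition {cond!r} has fewer than {min_measured} samples; "
                "the measurement rule cannot bind there",
                stacklevel=2,
            )
        n_present = np.sum(~np.isnan(table.values[:, idx]), axis=1)
        measured_enough |= n_present >= min_measured
    analysis = table.subset(keep & measured_enough)
    loc = analysis.meta["localization_prob"].to_numpy(dtype=float)
    motif = analysis.subset(loc > loc_prob_min)
    return analysis, motif


def log2_center(table: FeatureTable) -> FeatureTable:
    """log2-transform intensities and mean-center each feature over all samples.

    Missing entries stay missing; all present intensities must be positive.
    """
    out = table.copy()
    bad = np.argwhere(out.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity for feature {out.feature_id[i]!r} "
            f"in sample {out.sample_ids[j]!r}"
        )
    logged = np.log2(out.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows stay NaN
        centers = np.nanmean(logged, axis=1, keepdims=True)
    out.values = logged - centers
    return out


def impute_missing(
    table: FeatureTable,
    seed: int,
    shift_high: float = 0.5,
    shift_low: float = 1.8,
    width: float = 0.3,
    reference: str = "sample",
) -> FeatureTable:
    """Impute missing log-intensities from tiered downshifted normals.

    Per condition: a feature measured in more than 50% of that condition's
    replicates draws its missing entries from Normal(mu − shift_high·sd,
    (width·sd)^2); a feature measured in 50% or fewer draws from
    Normal(mu − shift_low·sd, (width·sd)^2).  With ``reference="sample"``
    mu and sd are the mean/SD of the present values in the column being
    imputed; with ``reference="feature"`` they are the feature's own
    statistics within the condition (undefined for fully missing
    conditions, which then raise).

    Draws are consumed in row-major feature order then sample order, so the
    imputed matrix is bit-identical for a given seed regardless of storage
    layout.
    """
    if reference not in ("sample", "feature"):
        raise ValueError(f"unknown imputation reference {reference!r}")
    out = table.copy()
    values = out.values
    rng = np.random.default_rng(seed)

    col_mu = np.full(out.n_samples, np.nan)
    col_sd = np.full(out.n_samples, np.nan)
    for j in range(out.n_samples):
        present = values[~np.isnan(values[:, j]), j]
        if present.size >= 2:
            col_mu[j] = present.mean()
            col_sd[j] = present.std(ddof=1)

    # measured fraction per feature and condition decides the tier
    frac = {}
    for cond in out.conditions():
        idx = out.sample_indices(cond)
        frac[cond] = np.mean(~np.isnan(values[:, idx]), axis=1)

    for i in range(out.n_features):
        for j in range(out.n_samples):
            if not np.isnan(values[i, j]):
                continue
            cond = out.condition_of_sample[out.sample_ids[j]]
            shift = shift_high if frac[cond][i] > 0.5 else shift_low
            if reference == "sample":
                mu, sd = col_mu[j], col_sd[j]
            else:
                idx = out.sample_indices(cond)
                present = values[i, idx][~np.isnan(values[i, idx])]
                if present.size < 2:
                    mu, sd = np.nan, np.nan
                else:
                    mu, sd = present.mean(), present.std(ddof=1)
            if np.isnan(mu) or np.isnan(sd) or sd == 0:
                raise ValueError(
                    f"imputation reference not estimable for feature "
                    f"{out.feature_id[i]!r}, sample {out.sample_ids[j]!r}"
                )
            values[i, j] = rng.normal(mu - shift * sd, width * sd)
    return out
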