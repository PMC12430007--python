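"""Moderated differential testing and the PTM-vs-protein abundance adjustment.

Two-condition comparisons use a pooled-variance two-sample t-test on log2
intensities, optionally with empirical-Bayes variance moderation: per-feature
sample variances are shrunk toward a prior variance ``s0^2`` with prior
degrees of freedom ``d0``, both estimated from the ensemble of feature
variances by moment matching on log variances (the scaled-F model of
moderated t statistics), and the moderated test gains ``d0`` degrees of
freedom.

The PTM adjustment tests whether a phosphopeptide's fold change exceeds the
fold change of its parent protein, i.e. whether the observed regulation is
phosphorylation-driven rather than a protein-abundance effect:

    t = (log2FC_ptm - log2FC_protein) / SE
    SE = SP * sqrt(1/df_protein + 1/df_ptm)
    SP^2 = (SE_protein^2 (df_protein - 1) + SE_ptm^2 (df_ptm - 1))
           / (df_protein + df_ptm - 2)

with df_protein + df_ptm - 2 degrees of freedom for the two-sided p-value
(adopted from the pooled-SD construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.special as sps
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

from macsig.io import FeatureTable

__all__ = [
    "DiffResult",
    "PTMAdjustedResult",
    "moderated_ttest",
    "bh_adjust",
    "call_significant",
    "reconcile_multiplicity",
    "adjust_ptm",
    "adjust_ptm_all",
    "apply_keep_rule",
]


@dataclass
class DiffResult:
    """Per-feature two-condition differential test result.

    ``log2fc`` is oriented as condition B minus condition A (the condition
    listed second minus the one listed first).
    """

    feature_id: str
    log2fc: float
    se: float
    df: float
    t: float
    p: float
    fdr: float = math.nan
    n_a: int = 0
    n_b: int = 0
    significant: bool = False
    protein_id: str = ""
    site_id: str | None = None
    multiplicity: float = math.nan

    def __post_init__(self) -> None:
        if self.site_id is None:
            self.site_id = self.feature_id


@dataclass
class PTMAdjustedResult:
    """Phosphopeptide differential result adjusted for protein-level change."""

    site_id: str
    protein_id: str
    log2fc_ptm: float
    log2fc_protein: float
    se_ptm: float
    se_protein: float
    df_ptm: float
    df_protein: float
    sp: float = math.nan
    se: float = math.nan
    t_adj: float = math.nan
    p_adj: float = math.nan
    fdr_adj: float = math.nan
    phospho_driven: bool = False
    kept: bool = False
    protein_missing: bool = False


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration)."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = sps.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / sps.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match the scaled-F prior (s0^2, d0) from feature variances.

    Uses the distribution of log sample variances: for s^2 ~ s0^2 F(df, d0),
    log s^2 has mean log s0^2 + digamma(df/2) - log(df/2) - digamma(d0/2)
    + log(d0/2) and excess variance trigamma(d0/2) beyond trigamma(df/2).
    Returns (s0_squared, d0); d0 is inf when the variances are no more
    dispersed than chi-square sampling alone explains.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - sps.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    evar_excess = evar - float(sps.polygamma(1, df / 2.0))
    if evar_excess > 0:
        half_d0 = _trigamma_inverse(evar_excess)
        d0 = 2.0 * half_d0
        s0_sq = math.exp(emean + float(sps.digamma(half_d0)) - math.log(half_d0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return s0_sq, d0


def moderated_ttest(
    table: FeatureTable,
    cond_a: str,
    cond_b: str,
    moderation: bool = True,
    prior: tuple | None = None,
) -> list[DiffResult]:
    """Two-sample (moderated) t-test per feature on log2 values.

    Requires a fully imputed matrix (no missing values in the two
    conditions).  With ``moderation=False`` this is the classical
    pooled-variance t-test.  ``prior`` overrides the estimated
    (s0_squared, d0) pair, mainly to probe the d0 -> 0 continuity limit.
    """
    idx_a = table.sample_indices(cond_a)
    idx_b = table.sample_indices(cond_b)
    a = table.values[:, idx_a]
    b = table.values[:, idx_b]
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("moderated_ttest requires imputed (complete) data")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("both conditions need at least two samples")

    log2fc = b.mean(axis=1) - a.mean(axis=1)
    df = float(n_a + n_b - 2)
    s2 = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / df
    scale = 1.0 / n_a + 1.0 / n_b

    if moderation:
        s0_sq, d0 = prior if prior is not None else estimate_variance_prior(s2, df)
        if math.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = math.inf
        else:
            s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = df + d0
    else:
        s2_post = s2
        df_total = df

    se = np.sqrt(s2_post * scale)
    results = []
    for i in range(table.n_features):
        if se[i] > 0:
            t = log2fc[i] / se[i]
            if math.isinf(df_total):
                p = 2.0 * st.norm.sf(abs(t))
            else:
                p = 2.0 * st.t.sf(abs(t), df_total)
        elif log2fc[i] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, log2fc[i]), 0.0
        mult = table.meta["multiplicity"].iloc[i]
        residue = table.meta["residue"].iloc[i] if "residue" in table.meta else ""
        site = (
            f"{table.protein_id[i]}_{residue}"
            if isinstance(residue, str) and residue
            else table.feature_id[i]
        )
        results.append(
            DiffResult(
                feature_id=table.feature_id[i],
                log2fc=float(log2fc[i]),
                se=float(se[i]),
                df=float(df_total),
                t=float(t),
                p=float(p),
                n_a=n_a,
                n_b=n_b,
                protein_id=table.protein_id[i],
                site_id=site,
                multiplicity=float(mult) if mult == mult else math.nan,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Multiple testing and significance calls
# ---------------------------------------------------------------------------


def bh_adjust(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (family = all supplied)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def attach_fdr(results: list[DiffResult]) -> list[DiffResult]:
    """Attach BH-adjusted p-values over the supplied family of results."""
    fdrs = bh_adjust([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = q
    return results


def call_significant(
    results: list[DiffResult],
    fdr_max: float = 0.05,
    abs_log2fc_min: float = 1.0,
) -> list[DiffResult]:
    """Flag results with FDR strictly below ``fdr_max`` and |log2FC| >= ``abs_log2fc_min``."""
    for r in results:
        r.significant = (r.fdr < fdr_max) and (abs(r.log2fc) >= abs_log2fc_min)
    return results


def reconcile_multiplicity(results: list[DiffResult]) -> list[DiffResult]:
    """Drop sites whose multiplicity classes are significant in opposite directions.

    A site is removed (all its multiplicity entries) when at least two of
    its entries are significant with log2 fold changes of opposite sign.
    Discordance involving a non-significant entry does not trigger removal.
    """
    by_site: dict = {}
    for r in results:
        by_site.setdefault(r.site_id, []).append(r)
    discordant = set()
    for site, group in by_site.items():
        signs = {np.sign(r.log2fc) for r in group if r.significant and r.log2fc != 0}
        if 1.0 in signs and -1.0 in signs:
            discordant.add(site)
    return [r for r in results if r.site_id not in discordant]


# ---------------------------------------------------------------------------
# PTM adjustment
# ---------------------------------------------------------------------------


def adjust_ptm(phospho: DiffResult, protein: DiffResult | None) -> PTMAdjustedResult:
    """Adjust one phosphopeptide's fold change for its parent protein's change.

    With no protein-level counterpart the site passes through as
    phospho-driven with a provenance flag: absence of protein evidence
    cannot demonstrate an abundance-driven change.
    """
    if protein is None:
        return PTMAdjustedResult(
            site_id=phospho.site_id,
            protein_id=phospho.protein_id,
            log2fc_ptm=phospho.log2fc,
            log2fc_protein=math.nan,
            se_ptm=phospho.se,
            se_protein=math.nan,
            df_ptm=phospho.df,
            df_protein=math.nan,
            phospho_driven=True,
            protein_missing=True,
        )
    # the pooled-SD construction uses the per-level *sample* degrees of
    # freedom (n_a + n_b - 2), not moderation-inflated df
    def sample_df(r: DiffResult) -> float:
        if r.n_a >= 2 and r.n_b >= 2:
            return float(r.n_a + r.n_b - 2)
        return r.df

    df_ptm, df_prot = sample_df(phospho), sample_df(protein)
    if df_ptm < 2 or df_prot < 2:
        raise ValueError("PTM adjustment requires df >= 2 on both levels")
    sp_sq = (
        protein.se**2 * (df_prot - 1.0) + phospho.se**2 * (df_ptm - 1.0)
    ) / (df_prot + df_ptm - 2.0)
    sp = math.sqrt(sp_sq)
    se = sp * math.sqrt(1.0 / df_prot + 1.0 / df_ptm)
    delta = phospho.log2fc - protein.log2fc
    if se > 0:
        t = delta / se
        p = 2.0 * st.t.sf(abs(t), df_prot + df_ptm - 2.0)
    else:
        t = 0.0 if delta == 0 else math.copysign(math.inf, delta)
        p = 1.0 if delta == 0 else 0.0
    return PTMAdjustedResult(
        site_id=phospho.site_id,
        protein_id=phospho.protein_id,
        log2fc_ptm=phospho.log2fc,
        log2fc_protein=protein.log2fc,
        se_ptm=phospho.se,
        se_protein=protein.se,
        df_ptm=df_ptm,
        df_protein=df_prot,
        sp=sp,
        se=se,
        t_adj=t,
        p_adj=p,
    )


def adjust_ptm_all(
    phospho_results: list[DiffResult],
    protein_results: list[DiffResult],
    alpha: float = 0.05,
) -> list[PTMAdjustedResult]:
    """Adjust every phosphopeptide against its protein; BH across all adjusted tests."""
    by_protein = {r.feature_id: r for r in protein_results}
    adjusted = [adjust_ptm(ph, by_protein.get(ph.protein_id)) for ph in phospho_results]
    testable = [a for a in adjusted if not a.protein_missing]
    fdrs = bh_adjust([a.p_adj for a in testable])
    for a, q in zip(testable, fdrs):
        a.fdr_adj = q
        a.phospho_driven = q < alpha
    return adjusted


def apply_keep_rule(
    adjusted: list[PTMAdjustedResult],
    raw_significant: set,
) -> set:
    """Keep all raw-significant sites of proteins carrying a phospho-driven site.

    ``raw_significant`` holds site ids significant in the unadjusted
    phosphopeptide analysis.  For every protein with at least one
    phospho-driven site, all of that protein's raw-significant sites are
    kept; proteins without a driven site contribute none.  Sets ``kept``
    in place and returns the kept site-id set.
    """
    driven_proteins = {a.protein_id for a in adjusted if a.phospho_driven}
    kept = set()
    for a in adjusted:
        a.kept = a.protein_id in driven_proteins and a.site_id in raw_significant
        if a.kept:
            kept.add(a.site_id)
    return kept
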