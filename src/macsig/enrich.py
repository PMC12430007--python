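"""Hypergeometric over-representation analysis with redundancy and size pruning.

One ORA engine serves every stage (phosphoproteome, network modules,
transcriptome, single-cell hallmark sets).  The background is always an
explicit argument — each stage defines its own universe (e.g. all measured
proteins, or all nodes of the phenotype's full network) and no genome-wide
default exists.  An EASE-style variant (testing overlap − 1) is available
for compatibility with modified-Fisher annotation tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import scipy.stats as st

from macsig.diffexpr import bh_adjust
from macsig.io import GeneSetCollection

__all__ = ["ORAResult", "hypergeometric_ora", "prune_and_filter"]


@dataclass
class ORAResult:
    set_id: str
    overlap: int
    set_size_in_background: int
    n_hits: int
    n_background: int
    p: float
    fdr: float = math.nan
    retained: bool = False
    hit_members: set = field(default_factory=set)
    absorbed_by: str | None = None


def hypergeometric_ora(
    hits: set,
    background: set,
    sets: GeneSetCollection,
    ease: bool = False,
) -> list[ORAResult]:
    """Upper-tail hypergeometric test of ``hits`` against each gene set.

    Sets are intersected with the background before testing; p is
    P(X >= overlap) drawing |hits| from a background containing the set.
    With ``ease=True`` the overlap is decremented by one before the tail
    computation (more conservative, as in modified-Fisher annotation
    tools).
    """
    if not background:
        raise ValueError("empty background")
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    n_bg, n_hits = len(background), len(hits)
    results = []
    for s in sets:
        members = s.members & background
        k = len(members & hits)
        k_test = max(k - 1, 0) if ease else k
        # P(X >= k_test), X ~ Hypergeom(N=n_bg, K=|set|, n=n_hits)
        p = float(st.hypergeom.sf(k_test - 1, n_bg, len(members), n_hits))
        results.append(
            ORAResult(
                set_id=s.set_id,
                overlap=k,
                set_size_in_background=len(members),
                n_hits=n_hits,
                n_background=n_bg,
                p=min(p, 1.0),
                hit_members=members & hits,
            )
        )
    fdrs = bh_adjust([r.p for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = q
    return results


def prune_and_filter(
    results: list[ORAResult],
    min_novel: int = 2,
    min_hits: int = 0,
    max_set_size: int | None = None,
    fdr_max: float = 0.05,
) -> list[ORAResult]:
    """Greedy redundancy pruning of significant ORA results.

    Walking from most to least significant, a set is retained iff it is
    significant (fdr < ``fdr_max``), has at least ``min_hits`` hit members,
    is no larger than ``max_set_size`` in the background, and contributes
    at least ``min_novel`` hit members not already covered by previously
    retained sets.  "Covered" counts hit members of retained sets only.
    Sets ``retained`` / ``absorbed_by`` in place and returns the input.
    """
    covered: set = set()
    covering: dict = {}
    for r in sorted(results, key=lambda r: (r.p, r.set_id)):
        r.retained = False
        r.absorbed_by = None
        if r.fdr >= fdr_max:
            continue
        if r.overlap < min_hits:
            continue
        if max_set_size is not None and r.set_size_in_background > max_set_size:
            continue
        novel = r.hit_members - covered
        if len(novel) < min_novel:
            seen = {covering[g] for g in (r.hit_members & covered)}
            r.absorbed_by = sorted(seen)[0] if seen else None
            continue
        r.retained = True
        for g in novel:
            covering[g] = r.set_id
        covered |= r.hit_members
    return results
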