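"""Regulator co-occurrence and pathway-enrichment statistics.

Both analyses use the cumulative hypergeometric upper tail: TF-motif
pairs are tested for co-occurring on more miRNAs than chance predicts
(Bonferroni over all tested pairs, default alpha 1e-5), and module target
sets are tested for pathway over-representation (uncorrected, default
alpha 0.05, matching the asymmetric regimes of the source analyses).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSetCollection, MotifAnnotation

__all__ = [
    "CooccurrenceResult",
    "EnrichmentCell",
    "hypergeom_tail",
    "motif_cooccurrence_graph",
    "pathway_enrichment",
    "enrichment_matrix",
]


def hypergeom_tail(c_obs: int, m1: int, m2: int, N: int) -> float:
    """Cumulative hypergeometric upper tail.

    P(C >= c_obs) = sum_{i=c_obs}^{min(m1, m2)} C(m1, i) C(N-m1, m2-i)
    / C(N, m2): the chance that two motifs carried by m1 and m2 of N
    miRNAs co-occur on at least c_obs of them.
    """
    if not (0 <= c_obs <= min(m1, m2) <= N) or m1 > N or m2 > N:
        raise ValueError(f"invalid hypergeometric bounds: c_obs={c_obs}, "
                         f"m1={m1}, m2={m2}, N={N}")
    return float(sps.hypergeom.sf(c_obs - 1, N, m1, m2))


@dataclass(frozen=True)
class CooccurrenceResult:
    """One tested motif pair with its co-occurrence significance."""

    motif_a: str
    motif_b: str
    m1: int
    m2: int
    c_obs: int
    N: int
    p: float
    p_bonferroni: float

    def __post_init__(self) -> None:
        if self.c_obs > min(self.m1, self.m2):
            raise ValueError("observed co-occurrence exceeds carrier counts")
        if not 0 < self.p <= 1:
            raise ValueError(f"p outside (0, 1]: {self.p}")


def motif_cooccurrence_graph(
    ann: MotifAnnotation,
    scope: Iterable[str],
    alpha: float = 1.0e-05,
    correction: str = "bonferroni",
) -> tuple[list[CooccurrenceResult], int]:
    """Test all motif pairs present on a scope of miRNAs for significant
    co-occurrence.

    N is the scope size; the Bonferroni denominator is the number of
    tested pairs (returned for auditability).  Returns the pairs passing
    the (corrected) threshold, sorted by p.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    scope = sorted(set(scope))
    unknown = [m for m in scope if m not in ann.motifs_of]
    if unknown:
        raise ValueError(f"scope miRNAs without motif annotation: "
                         f"{unknown[:10]}")
    if len(scope) < 2:
        raise ValueError("co-occurrence needs a scope of >= 2 miRNAs")
    N = len(scope)
    carriers: dict[str, set[str]] = {}
    for mirna in scope:
        for motif in ann.motifs_of[mirna]:
            carriers.setdefault(motif, set()).add(mirna)
    motifs = sorted(carriers)
    tested = list(combinations(motifs, 2))
    n_tested = len(tested)
    results = []
    for a, b in tested:
        ca, cb = carriers[a], carriers[b]
        p = hypergeom_tail(len(ca & cb), len(ca), len(cb), N)
        p_bonf = min(1.0, p * n_tested)
        effective = p_bonf if correction == "bonferroni" else p
        if effective < alpha:
            results.append(CooccurrenceResult(
                motif_a=a, motif_b=b, m1=len(ca), m2=len(cb),
                c_obs=len(ca & cb), N=N, p=p, p_bonferroni=p_bonf))
    results.sort(key=lambda r: (r.p, r.motif_a, r.motif_b))
    return results, n_tested


@dataclass(frozen=True)
class EnrichmentCell:
    """One module x pathway hypergeometric enrichment result."""

    module_id: int | str
    pathway_id: str
    k: int
    K: int
    n: int
    N_bg: int
    p: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("drawn overlap exceeds pathway or module size")
        if not 0 < self.p <= 1:
            raise ValueError(f"p outside (0, 1]: {self.p}")

    @property
    def neglog10p(self) -> float:
        return float(-np.log10(self.p))


def pathway_enrichment(
    genes: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
    module_id: int | str = 0,
) -> tuple[list[EnrichmentCell], int]:
    """Hypergeometric pathway enrichment of one module's target genes.

    For each pathway with K background members, the upper-tail
    probability of drawing >= k pathway genes among the n module targets
    from the N_bg-gene background.  All testable cells are returned (use
    ``alpha`` plus :func:`enrichment_matrix` for significance display);
    pathways with no background overlap are skipped and counted.
    """
    genes = frozenset(genes)
    background = frozenset(background)
    if not background:
        raise ValueError("empty enrichment background")
    if not genes <= background:
        extra = sorted(genes - background)
        raise ValueError(f"module genes outside the background: {extra[:10]}")
    N_bg = len(background)
    n = len(genes)
    cells = []
    n_skipped = 0
    for pid in sorted(sets.sets):
        K = len(sets.sets[pid] & background)
        if K == 0:
            n_skipped += 1
            continue
        k = len(sets.sets[pid] & genes)
        p = float(sps.hypergeom.sf(k - 1, N_bg, K, n))
        cells.append(EnrichmentCell(module_id=module_id, pathway_id=pid,
                                    k=k, K=K, n=n, N_bg=N_bg, p=p))
    return cells, n_skipped


def enrichment_matrix(cells: Iterable[EnrichmentCell],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Modules x pathways matrix of -log10 p for heat-map display.

    Rows (modules) and columns (pathways) with no significant cell at
    ``alpha`` are dropped, mirroring the convention of omitting modules
    and pathways with no mapping at all.
    """
    cells = list(cells)
    if not cells:
        return pd.DataFrame()
    df = pd.DataFrame(
        {"module": c.module_id, "pathway": c.pathway_id,
         "neglog10p": c.neglog10p, "significant": c.p < alpha}
        for c in cells
    )
    mat = df.pivot_table(index="module", columns="pathway",
                         values="neglog10p", fill_value=0.0)
    sig = df.pivot_table(index="module", columns="pathway",
                         values="significant", aggfunc="any",
                         fill_value=False).astype(bool)
    keep_rows = sig.any(axis=1)
    keep_cols = sig.any(axis=0)
    out = mat.loc[keep_rows, keep_cols]
    return out.sort_index(axis=0).sort_index(axis=1)
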