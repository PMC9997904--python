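"""Over-representation analysis and full-vs-truncated collection comparison.

Each set of a family is tested for over-representation of a target
element list (e.g. trait-associated genes) against a background
universe with a one-sided Fisher exact test on the 2×2 table

    a = |P ∩ target|      b = |P \\ target|
    c = |target \\ P|     d = |background \\ (P ∪ target)|

The one-sided (greater) Fisher p-value is the hypergeometric upper
tail P(X ≥ a), computed directly from the hypergeometric distribution.
Raw p-values are corrected with Bonferroni or Benjamini–Hochberg FDR.

``significance_comparison`` reproduces the truncation experiment:
rankings are cut at a grid of fractions, the truncated collections are
re-tested with the multiplicity m equal to the TRUNCATED size (the
practical pay-off of pruning: fewer tests, milder correction), and the
counts of significant sets are compared with the full-collection
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .family import SetFamily
from .ranking import Ranking, select_top

ADJUST_METHODS = ("bonferroni", "fdr_bh")


@dataclass(frozen=True, eq=False)
class EnrichmentReport:
    """Per-set Fisher test results with multiplicity correction.

    ``table`` columns: set_name, a, b, c, d, p_raw, p_adj, significant.
    """

    table: pd.DataFrame
    method: str
    alpha: float
    n_tests: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def fisher_enrichment(
    family: SetFamily,
    target: Iterable[str],
    background: Iterable[str] | None = None,
) -> np.ndarray:
    """One-sided (over-representation) Fisher exact p-value per set.

    The background defaults to the family universe and must contain
    both the universe and the target.  An empty target yields p = 1
    everywhere (no evidence of over-representation).
    """
    target = frozenset(target)
    universe = frozenset(family.universe)
    if background is None:
        background = universe | target
    background = frozenset(background)
    if not target <= background:
        raise ValueError("target list is not contained in the background")
    if not universe <= background:
        raise ValueError("family universe is not contained in the background")

    n_bg = len(background)
    n_target = len(target)
    pvals = np.empty(family.n_sets)
    for i, members in enumerate(family.member_sets):
        a = len(members & target)
        draws = len(members)
        # upper tail P(X >= a) of Hypergeom(N=n_bg, K=n_target, n=draws)
        pvals[i] = stats.hypergeom.sf(a - 1, n_bg, n_target, draws)
    return np.clip(pvals, 0.0, 1.0)


def adjust_pvalues(pvals: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Bonferroni or Benjamini–Hochberg adjusted p-values (order preserved)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ADJUST_METHODS:
        raise ValueError(f"unknown adjustment {method!r}; use one of {ADJUST_METHODS}")
    return multipletests(pvals, method=method)[1]


def enrichment_report(
    family: SetFamily,
    target: Iterable[str],
    background: Iterable[str] | None = None,
    method: str = "fdr_bh",
    alpha: float = 0.05,
) -> EnrichmentReport:
    """Full per-set enrichment table with adjusted p-values and calls."""
    target = frozenset(target)
    p_raw = fisher_enrichment(family, target, background)
    p_adj = adjust_pvalues(p_raw, method=method)
    bg = frozenset(background) if background is not None else (
        frozenset(family.universe) | target
    )
    rows = []
    for i, members in enumerate(family.member_sets):
        a = len(members & target)
        rows.append(
            {
                "set_name": family.names[i],
                "a": a,
                "b": len(members) - a,
                "c": len(target) - a,
                "d": len(bg) - len(members | target),
            }
        )
    table = pd.DataFrame(rows)
    table["p_raw"] = p_raw
    table["p_adj"] = p_adj
    table["significant"] = table["p_adj"] <= alpha
    return EnrichmentReport(
        table=table, method=method, alpha=alpha, n_tests=family.n_sets
    )


@dataclass(frozen=True, eq=False)
class ComparisonResult:
    """Significant-set counts for truncated collections vs the full baseline."""

    table: pd.DataFrame
    baseline: int
    alpha: float
    method: str


def significance_comparison(
    family: SetFamily,
    rankings: Sequence[Ranking],
    target: Iterable[str],
    fractions: Sequence[float],
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
    method: str = "fdr_bh",
) -> ComparisonResult:
    """Count significant sets in ranked truncations of the collection.

    For each ranking and each truncation fraction, the first
    ``round(fraction · N)`` ranked sets are re-tested as a standalone
    collection (the correction multiplicity is the truncated size) and
    the sets with adjusted p ≤ alpha are counted.  The baseline is the
    analogous count over the full collection.
    """
    target = frozenset(target)
    for f in fractions:
        if not 0 < f <= 1:
            raise ValueError(f"truncation fraction {f} outside (0, 1]")
    if background is None:
        background = frozenset(family.universe) | target

    baseline = enrichment_report(
        family, target, background, method=method, alpha=alpha
    ).n_significant

    rows = []
    for ranking in rankings:
        for f in fractions:
            sub = select_top(family, ranking, float(f))
            report = enrichment_report(
                sub, target, background, method=method, alpha=alpha
            )
            rows.append(
                {
                    "method": ranking.method,
                    "fraction": f,
                    "n_sets_tested": sub.n_sets,
                    "n_significant": report.n_significant,
                }
            )
    return ComparisonResult(
        table=pd.DataFrame(rows), baseline=baseline, alpha=alpha, method=method
    )
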