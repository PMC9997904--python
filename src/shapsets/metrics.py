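"""Redundancy, coverage and size-correlation diagnostics for rankings.

Redundancy of a sub-family is the average pairwise Jaccard index
(the *Jaccard score*); coverage is the percentage of the universe
reached by the union of a sub-family.  Both are evaluated prefix-wise
along a ranking to characterise how quickly a method accumulates
redundancy versus universe coverage.  Kendall's τ-b between set size
and ranking earliness quantifies the tendency of a method to put large
sets first.
"""

from __future__ import annotations

import typing
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .family import SetFamily

if typing.TYPE_CHECKING:  # pragma: no cover
    from .ranking import Ranking


@dataclass(frozen=True, eq=False)
class MetricCurve:
    """A metric evaluated on the top-j prefix of a ranking, for each j."""

    positions: np.ndarray
    values: np.ndarray
    metric_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, self.metric_name: self.values}
        )


def jaccard_index(a: Iterable[str], b: Iterable[str]) -> float:
    """|A∩B| / |A∪B| for two non-empty sets.

    0 iff the sets are disjoint, 1 iff they are equal.  Empty inputs are
    rejected (the family model never produces them and the 0/0 case is
    undefined).
    """
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Jaccard index is not defined for empty sets")
    return len(a & b) / len(a | b)


def pairwise_jaccard_matrix(family: SetFamily) -> np.ndarray:
    """Symmetric N×N matrix of pairwise Jaccard indices (diagonal 1)."""
    b = family.incidence.astype(np.int64)
    inter = b @ b.T
    sizes = np.diag(inter)
    union = sizes[:, None] + sizes[None, :] - inter
    return inter / union


def jaccard_score(sets: Sequence[Iterable[str]] | SetFamily) -> float:
    """Average pairwise Jaccard index of a family of at least two sets.

    Equals ``(1/(k(k-1))) Σ_{i≠j} J(P_i, P_j)`` over ordered pairs,
    which by symmetry is the plain mean over unordered pairs.  Zero iff
    the sets are pairwise disjoint, one iff all sets are identical.
    """
    if isinstance(sets, SetFamily):
        k = sets.n_sets
        if k < 2:
            raise ValueError("Jaccard score requires at least two sets")
        jmat = pairwise_jaccard_matrix(sets)
        off = jmat.sum() - np.trace(jmat)
        return off / (k * (k - 1))
    members = [set(s) for s in sets]
    k = len(members)
    if k < 2:
        raise ValueError("Jaccard score requires at least two sets")
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += jaccard_index(members[i], members[j])
    return total / (k * (k - 1) / 2)


def coverage(selected: Sequence[int], family: SetFamily) -> float:
    """Percentage of the universe covered by the union of the selected sets."""
    selected = list(selected)
    if not selected:
        raise ValueError("coverage of an empty selection is undefined")
    covered = family.incidence[selected].any(axis=0).sum()
    return covered * 100.0 / family.universe_size


def coverage_curve(ranking: "Ranking", family: SetFamily) -> MetricCurve:
    """Cumulative coverage (percent of universe) along the ranking.

    Non-decreasing and reaching 100 at the full family.
    """
    order = list(ranking.order)
    covered = np.zeros(family.universe_size, dtype=bool)
    values = np.empty(len(order))
    for j, idx in enumerate(order):
        covered |= family.incidence[idx].astype(bool)
        values[j] = covered.sum() * 100.0 / family.universe_size
    return MetricCurve(
        positions=np.arange(1, len(order) + 1),
        values=values,
        metric_name="coverage_percent",
    )


def jaccard_prefix_curve(ranking: "Ranking", family: SetFamily,
                         upto: int | None = None) -> MetricCurve:
    """Raw Jaccard score of the top-j prefix, for j = 2..upto."""
    order = list(ranking.order)
    n = len(order) if upto is None else int(upto)
    if n < 2:
        raise ValueError("prefix Jaccard curves need at least two positions")
    jmat = pairwise_jaccard_matrix(family)
    values = np.empty(n - 1)
    pair_sum = 0.0
    for j in range(2, n + 1):
        new = order[j - 1]
        pair_sum += sum(jmat[new, order[i]] for i in range(j - 1))
        values[j - 2] = pair_sum / (j * (j - 1) / 2)
    return MetricCurve(
        positions=np.arange(2, n + 1),
        values=values,
        metric_name="jaccard_score",
    )


def rescaled_jaccard_curve(ranking: "Ranking", family: SetFamily,
                           upto: int | None = None) -> MetricCurve:
    """Prefix Jaccard scores re-scaled by the family's maximum pairwise Jaccard.

    The re-scaling makes curves comparable across collections with very
    different absolute overlap levels.  Undefined (and rejected) when no
    two sets of the family overlap at all — report raw scores instead.
    """
    jmat = pairwise_jaccard_matrix(family)
    np.fill_diagonal(jmat, 0.0)
    max_j = jmat.max()
    if max_j == 0.0:
        raise ValueError(
            "re-scaled Jaccard curve undefined: no pair of sets overlaps "
            "(maximum pairwise Jaccard is 0); use jaccard_prefix_curve"
        )
    raw = jaccard_prefix_curve(ranking, family, upto=upto)
    return MetricCurve(
        positions=raw.positions,
        values=raw.values / max_j,
        metric_name="rescaled_jaccard_score",
    )


class SizeRankCorrelation(NamedTuple):
    tau: float
    degenerate: bool


def size_rank_correlation(ranking: "Ranking", family: SetFamily) -> SizeRankCorrelation:
    """Kendall τ-b between set size and ranking earliness.

    Earliness is the reversed position (the first-ranked set has the
    largest earliness), so a method that puts larger sets first yields a
    POSITIVE τ.  τ-b is used because set sizes tie frequently.  When all
    sizes are identical τ is undefined; 0 is returned with the
    ``degenerate`` flag set.
    """
    if family.n_sets < 2:
        raise ValueError("size-rank correlation needs at least two sets")
    sizes = family.sizes.astype(float)
    n = family.n_sets
    earliness = np.empty(n)
    for pos, idx in enumerate(ranking.order, start=1):
        earliness[idx] = n - pos
    if np.all(sizes == sizes[0]):
        return SizeRankCorrelation(tau=0.0, degenerate=True)
    tau = stats.kendalltau(sizes, earliness, variant="b").statistic
    return SizeRankCorrelation(tau=float(tau), degenerate=False)
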