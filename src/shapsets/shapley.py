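"""Shapley values of microarray games.

The family of sets is read as a cooperative game whose players are the
sets themselves.  A coalition ``T`` of sets is worth the fraction of
universe elements whose entire support lies inside ``T``:

    v*(T) = |{g : sp(g) ⊆ T}| / |G|

This game is a sum of unanimity games, one per element (on that
element's support), so the Shapley value of set ``P`` has the closed
form

    ϕ(P) = (1/M) Σ_g 1(P ∈ sp(g)) / |sp(g)|

i.e. each element distributes 1/M of the total value evenly among the
sets containing it.  Scores are non-negative and sum to one
(efficiency).  ``shapley_microarray`` is the production path, linear in
the number of ones of the incidence matrix; ``shapley_bruteforce``
evaluates the classical permutation average over all 2^N coalitions and
exists only as a verification oracle for small games.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Iterable

import numpy as np

from .family import SetFamily, SupportIndex, build_supports

#: Hard cap for the exponential brute-force oracle.
BRUTE_FORCE_LIMIT = 20


@dataclass(frozen=True, eq=False)
class ShapleyResult:
    """Importance scores of one (possibly restricted) microarray game.

    ``scores[i]`` is ϕ(P_i) for the i-th set of the game that produced
    the result; ``game_size`` and ``universe_size`` record that game's
    N and M.
    """

    scores: np.ndarray
    game_size: int
    universe_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))


def value_function(supports: SupportIndex, coalition: Iterable[int]) -> float:
    """Microarray-game value v*(T) of a coalition of set indices.

    Returns the fraction of universe elements whose support is entirely
    contained in ``coalition``; 0 for the empty coalition and 1 for the
    full family.
    """
    coalition = frozenset(coalition)
    m = supports.universe_size
    contained = sum(1 for sp in supports.dictionary if sp <= coalition)
    return contained / m


def shapley_microarray(family: SetFamily) -> ShapleyResult:
    """Closed-form Shapley values of the family's microarray game.

    Each universe element contributes ``1/(M * |sp(g)|)`` to every set
    containing it, so the whole computation is a single weighted row sum
    of the incidence matrix.
    """
    b = family.incidence
    col_support = b.sum(axis=0)  # |sp(g_j)| > 0 by the universe invariant
    scores = (b / col_support).sum(axis=1) / family.universe_size
    return ShapleyResult(
        scores=scores,
        game_size=family.n_sets,
        universe_size=family.universe_size,
    )


def shapley_bruteforce(family: SetFamily) -> ShapleyResult:
    """Shapley values by exhaustive coalition enumeration.

    Implements the permutation-average definition

        ϕ_i = Σ_{T ⊆ N\\{i}} t! (N−t−1)! / N! · (v*(T∪{i}) − v*(T))

    whose weights are the unique ones satisfying efficiency (the
    coefficients sum to one over the coalitions of each marginal
    contribution).  Exponential in N; refuses games larger than
    :data:`BRUTE_FORCE_LIMIT` players.
    """
    n = family.n_sets
    if n > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"brute-force Shapley limited to N <= {BRUTE_FORCE_LIMIT} "
            f"players (got {n}); use shapley_microarray instead"
        )
    m = family.universe_size
    supports = build_supports(family)
    # bitmask per universe element: which sets contain it
    col_masks = [
        sum(1 << i for i in sp) for sp in supports.dictionary
    ]
    full = (1 << n) - 1

    # v*(T) for every coalition bitmask
    values = np.empty(1 << n, dtype=float)
    for mask in range(1 << n):
        absent = full & ~mask
        values[mask] = sum(1 for cm in col_masks if not (cm & absent)) / m

    fact = [factorial(k) for k in range(n + 1)]
    weights = [fact[t] * fact[n - t - 1] / fact[n] for t in range(n)]

    scores = np.zeros(n, dtype=float)
    for i in range(n):
        bit = 1 << i
        for mask in range(1 << n):
            if mask & bit:
                continue
            t = mask.bit_count()
            scores[i] += weights[t] * (values[mask | bit] - values[mask])

    return ShapleyResult(scores=scores, game_size=n, universe_size=m)
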