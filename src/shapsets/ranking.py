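"""Shapley-value rankings of a set family, plain and redundancy-penalized.

Five orderings are provided:

``SV``
    Sets sorted by the Shapley values of the family's microarray game,
    descending.  Blind to overlap: duplicated sets land in adjacent
    positions.
``PO`` / ``POR``
    Greedy penalized ordering.  At each step the Shapley values are
    re-computed on the game restricted to the not-yet-ranked sets
    (restoring efficiency: they sum to 1 over the remaining sets), and
    each candidate is penalized by the ACCUMULATED pairwise Jaccard
    index with every previously ranked set.  ``POR`` additionally
    re-scales the penalty vector each iteration to the interval
    [0, max ϕ], keeping scores non-negative.
``AO`` / ``AOR``
    Same greedy loop, but the penalty is the single Jaccard index with
    the *artificial set* — the running union of all ranked sets — so
    each shared element is penalized exactly once.  ``AOR`` re-scales
    as in ``POR``.

All penalties are zero at the first step, so every method ranks the
argmax-Shapley set first; ties are broken by construction order.
Jaccard penalties are always computed on the ORIGINAL membership of the
sets; restriction applies only to the Shapley game.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .family import SetFamily, restrict_family
from .metrics import coverage, jaccard_index, jaccard_prefix_curve
from .shapley import shapley_microarray

METHODS = ("SV", "PO", "POR", "AO", "AOR")
PENALIZED_METHODS = ("PO", "POR", "AO", "AOR")


@dataclass(frozen=True, eq=False)
class Ranking:
    """A full ordering of a family with its per-iteration score trace.

    ``order`` is a permutation of set indices; ``order[0]`` is the
    first-ranked set.  ``iteration_log`` has one row per position with
    the winning total score, its Shapley component and the (applied)
    penalty component.
    """

    method: str
    order: tuple[int, ...]
    iteration_log: pd.DataFrame

    def positions(self) -> dict[int, int]:
        """Map set index -> 1-based ranking position."""
        return {idx: pos for pos, idx in enumerate(self.order, start=1)}


def rank_sv(family: SetFamily) -> Ranking:
    """Plain Shapley-value ranking (descending ϕ, ties by construction order)."""
    phi = shapley_microarray(family).scores
    order = sorted(range(family.n_sets), key=lambda i: (-phi[i], i))
    log = pd.DataFrame(
        {
            "position": np.arange(1, family.n_sets + 1),
            "set_index": order,
            "score": phi[order],
            "shapley": phi[order],
            "penalty": np.zeros(family.n_sets),
        }
    )
    return Ranking(method="SV", order=tuple(order), iteration_log=log)


def rank_penalized(family: SetFamily, method: str) -> Ranking:
    """Greedy redundancy-penalized ranking (PO, POR, AO or AOR).

    At iteration n the winner maximises ``S_n(P) = ϕ_n(P) − penalty_n(P)``
    over the not-yet-ranked sets, where ϕ_n is the Shapley value of the
    game restricted to those sets.  Negative scores are legitimate for
    the un-rescaled penalties; the argmax is taken regardless of sign.
    When a single set remains it is appended without re-computation
    (its restricted Shapley value is 1 by efficiency).
    """
    method = method.upper()
    if method not in PENALIZED_METHODS:
        raise ValueError(
            f"unknown method {method!r}; expected one of {PENALIZED_METHODS}"
        )
    rescale = method in ("POR", "AOR")
    artificial = method in ("AO", "AOR")

    n = family.n_sets
    member_sets = family.member_sets
    remaining: list[int] = list(range(n))  # kept in construction order
    ranked: list[int] = []
    # raw accumulated pairwise penalties Σ_k J(ranked_k, P), by set index
    accumulated = np.zeros(n)
    artificial_set: set[str] = set()
    rows = []

    for position in range(1, n + 1):
        k = len(remaining)
        if k == 1:
            phi = np.array([1.0])
        else:
            sub = restrict_family(family, remaining)
            phi = shapley_microarray(sub).scores

        if position == 1:
            raw = np.zeros(k)
        elif artificial:
            raw = np.array(
                [jaccard_index(artificial_set, member_sets[p]) for p in remaining]
            )
        else:
            last = ranked[-1]
            for p in remaining:
                accumulated[p] += jaccard_index(member_sets[last], member_sets[p])
            raw = accumulated[remaining]

        applied = raw
        if rescale and raw.size and raw.max() > 0.0:
            applied = raw * (phi.max() / raw.max())

        scores = phi - applied
        win = int(np.argmax(scores))  # first max = earliest construction order
        winner = remaining.pop(win)
        ranked.append(winner)
        artificial_set |= set(member_sets[winner])
        rows.append(
            {
                "position": position,
                "set_index": winner,
                "score": float(scores[win]),
                "shapley": float(phi[win]),
                "penalty": float(applied[win]),
            }
        )

    return Ranking(
        method=method,
        order=tuple(ranked),
        iteration_log=pd.DataFrame(rows),
    )


def rank(family: SetFamily, method: str) -> Ranking:
    """Dispatch to :func:`rank_sv` or :func:`rank_penalized` by label."""
    method = method.upper()
    if method == "SV":
        return rank_sv(family)
    return rank_penalized(family, method)


def resolve_top_n(n: int | float, total: int) -> int:
    """Turn a count or fraction into a prefix length (half-up rounding)."""
    if isinstance(n, float) and 0 < n <= 1:
        n = int(math.floor(n * total + 0.5))
    n = int(n)
    if not 1 <= n <= total:
        raise ValueError(f"top-n selection {n} out of range 1..{total}")
    return n


def select_top(family: SetFamily, ranking: Ranking, n: int | float) -> SetFamily:
    """Restrict the family to the first ``n`` ranked sets, in ranked order.

    ``n`` may be an integer count or a fraction in (0, 1], in which case
    it is multiplied by N and rounded half-up.
    """
    top = resolve_top_n(n, family.n_sets)
    return restrict_family(family, list(ranking.order[:top]))


def ranking_table(family: SetFamily, ranking: Ranking) -> pd.DataFrame:
    """Flat, serialisable view of a ranking with cumulative diagnostics.

    Columns: rank, set_name, set_size, total_score, shapley_component,
    penalty_component, cumulative_coverage_percent,
    cumulative_jaccard_score (NaN at rank 1: no pair yet).
    """
    order = list(ranking.order)
    n = len(order)
    sizes = family.sizes
    log = ranking.iteration_log

    cum_cov = [coverage(order[: j + 1], family) for j in range(n)]
    cum_jac = [np.nan] * n
    if n >= 2:
        curve = jaccard_prefix_curve(ranking, family)
        for pos, val in zip(curve.positions, curve.values):
            cum_jac[pos - 1] = val

    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "set_name": [family.names[i] for i in order],
            "set_size": [int(sizes[i]) for i in order],
            "total_score": log["score"].to_numpy(),
            "shapley_component": log["shapley"].to_numpy(),
            "penalty_component": log["penalty"].to_numpy(),
            "cumulative_coverage_percent": cum_cov,
            "cumulative_jaccard_score": cum_jac,
        }
    )


def write_ranking(path, family: SetFamily, ranking: Ranking) -> None:
    """Serialise a ranking as TSV (see :func:`ranking_table`)."""
    ranking_table(family, ranking).to_csv(path, sep="\t", index=False)


def read_ranking_order(path, family: SetFamily) -> Ranking:
    """Reload a ranking TSV written by :func:`write_ranking`.

    Only the ordering (and logged scores) are recovered; names must all
    resolve against ``family``.
    """
    df = pd.read_csv(path, sep="\t")
    name_to_idx = {name: i for i, name in enumerate(family.names)}
    try:
        order = tuple(name_to_idx[name] for name in df["set_name"])
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"ranking refers to unknown set {exc}") from exc
    if sorted(order) != list(range(family.n_sets)):
        raise ValueError("ranking file is not a permutation of the family")
    log = pd.DataFrame(
        {
            "position": df["rank"],
            "set_index": order,
            "score": df["total_score"],
            "shapley": df["shapley_component"],
            "penalty": df["penalty_component"],
        }
    )
    return Ranking(method="file", order=order, iteration_log=log)
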