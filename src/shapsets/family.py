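"""Canonical in-memory model of a family of named sets.

A *family* is an ordered collection of named, non-empty, finite sets
(in the gene-set application: pathways) over a discrete element universe
(genes).  The universe is the union of all sets; membership is mirrored
in a binary incidence matrix ``B`` with one row per set and one column
per universe element.  The *support* of an element is the collection of
sets that contain it — the central quantity of the microarray game.

Element and set order are fixed at construction in first-appearance
order, which makes every downstream tie-break deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class FamilyValidationError(ValueError):
    """Base class for invalid family constructions."""


class EmptyFamilyError(FamilyValidationError):
    """Raised when a family is built from no sets at all."""


class EmptySetError(FamilyValidationError):
    """Raised when a member set has no elements."""


class DuplicateNameError(FamilyValidationError):
    """Raised when two sets share the same name."""


@dataclass(frozen=True, eq=False)
class SetFamily:
    """An ordered family of named sets over a shared element universe.

    Attributes
    ----------
    names
        Unique set identifiers, in construction order (length ``N``).
    members
        For each set, its elements as a tuple in first-appearance order.
    universe
        All distinct elements across the family, in first-appearance
        order (length ``M``); equals the union of all sets.
    incidence
        ``(N, M)`` binary matrix ``B`` with ``B[i, j] = 1`` iff element
        ``universe[j]`` belongs to set ``i``.
    """

    names: tuple[str, ...]
    members: tuple[tuple[str, ...], ...]
    universe: tuple[str, ...]
    incidence: np.ndarray
    member_sets: tuple[frozenset[str], ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "member_sets", tuple(frozenset(m) for m in self.members)
        )

    @property
    def n_sets(self) -> int:
        return len(self.names)

    @property
    def universe_size(self) -> int:
        return len(self.universe)

    @property
    def sizes(self) -> np.ndarray:
        """Cardinality of each member set, aligned with ``names``."""
        return self.incidence.sum(axis=1)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def __len__(self) -> int:
        return len(self.names)


@dataclass(frozen=True, eq=False)
class SupportIndex:
    """Per-element supports of a family.

    ``supports`` maps each universe element to the set of row indices of
    the sets containing it.  ``dictionary`` lists the same supports in
    universe (column) order, with multiplicity — one entry per element —
    which is exactly the multiset that drives the microarray game.
    """

    supports: dict[str, frozenset[int]]
    dictionary: tuple[frozenset[int], ...]

    @property
    def universe_size(self) -> int:
        return len(self.dictionary)


def build_family(named_sets: Sequence[tuple[str, Iterable[str]]]) -> SetFamily:
    """Validate and assemble a :class:`SetFamily`.

    Parameters
    ----------
    named_sets
        ``(name, elements)`` pairs.  Every set must be non-empty and
        names must be unique; duplicate elements within one set are
        collapsed (first occurrence kept).

    Raises
    ------
    EmptyFamilyError, EmptySetError, DuplicateNameError
    """
    if len(named_sets) == 0:
        raise EmptyFamilyError("a family must contain at least one set")

    names: list[str] = []
    members: list[tuple[str, ...]] = []
    seen_names: set[str] = set()
    universe: list[str] = []
    element_col: dict[str, int] = {}

    for name, elements in named_sets:
        if name in seen_names:
            raise DuplicateNameError(f"duplicate set name: {name!r}")
        seen_names.add(name)
        # de-duplicate within the set, preserving first appearance
        dedup: list[str] = []
        local: set[str] = set()
        for g in elements:
            if g not in local:
                local.add(g)
                dedup.append(g)
        if not dedup:
            raise EmptySetError(f"set {name!r} is empty")
        for g in dedup:
            if g not in element_col:
                element_col[g] = len(universe)
                universe.append(g)
        names.append(name)
        members.append(tuple(dedup))

    incidence = np.zeros((len(names), len(universe)), dtype=np.int8)
    for i, elems in enumerate(members):
        incidence[i, [element_col[g] for g in elems]] = 1

    return SetFamily(
        names=tuple(names),
        members=tuple(members),
        universe=tuple(universe),
        incidence=incidence,
    )


def build_supports(family: SetFamily) -> SupportIndex:
    """Compute the support of every universe element.

    The support ``sp(g)`` of an element ``g`` is the set of (row indices
    of) sets containing ``g``; it is never empty because the universe is
    the union of the family.
    """
    dictionary = tuple(
        frozenset(np.flatnonzero(family.incidence[:, j]).tolist())
        for j in range(family.universe_size)
    )
    supports = {g: sp for g, sp in zip(family.universe, dictionary)}
    return SupportIndex(supports=supports, dictionary=dictionary)


def restrict_family(family: SetFamily, keep: Sequence[int]) -> SetFamily:
    """Return the sub-family containing only the sets in ``keep``.

    ``keep`` is an ordered sequence of distinct set indices; the result
    preserves that order.  The universe shrinks to the union of the kept
    sets, so elements supported only by removed sets vanish.
    """
    keep = list(keep)
    if not keep:
        raise FamilyValidationError("cannot restrict to an empty selection")
    if len(set(keep)) != len(keep):
        raise FamilyValidationError("duplicate indices in restriction")
    for i in keep:
        if not 0 <= i < family.n_sets:
            raise IndexError(f"set index {i} out of range")
    return build_family(
        [(family.names[i], family.members[i]) for i in keep]
    )
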