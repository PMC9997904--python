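"""Seeded generator of MSigDB-like set families with planted redundancy.

The generator emulates the structure of curated gene-set collections:
tens to hundreds of sets with heavy-tailed (log-normal) sizes, grouped
into clusters of highly overlapping sets built around a shared core,
elements private to a single set, and a low-rate background of elements
shared across arbitrary sets.  Every draw is governed by a single
integer seed, so generated families are bit-identical across runs.

The design of a cluster is analytic: two sets of common size ``s``
sharing a core of size ``c`` have Jaccard index ``c / (2s − c)``, so a
target within-cluster Jaccard ``t`` is planted with a core of size
``c = 2 s̄ t / (1 + t)`` where ``s̄`` is the mean set size of the
cluster.  With heterogeneous sizes the realized pairwise index scatters
around the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .family import SetFamily, build_family


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated family.

    Defaults are sized for interactive use and continuous testing:
    100 sets in 20 planted clusters (one per five sets) over a
    5000-element universe budget, with a within-cluster pairwise Jaccard
    target of 0.5 and a 2% rate of background element sharing.
    """

    n_sets: int = 100
    universe_size: int = 5000
    n_clusters: int | None = None  # default: one cluster per five sets
    within_cluster_jaccard: float = 0.5
    size_log_mean: float = 3.3  # median set size ≈ 27
    size_log_sigma: float = 0.6
    min_size: int = 5
    fixed_size: int | None = None
    background_rate: float = 0.02
    background_pool_frac: float = 0.1
    seed: int = 0

    @property
    def resolved_clusters(self) -> int:
        if self.n_clusters is None:
            return max(1, self.n_sets // 5)
        return self.n_clusters

    def validate(self) -> None:
        if self.n_sets < 1:
            raise ValueError("n_sets must be positive")
        if not 1 <= self.resolved_clusters <= self.n_sets:
            raise ValueError("n_clusters must be in 1..n_sets")
        if not 0.0 <= self.within_cluster_jaccard <= 1.0:
            raise ValueError("within_cluster_jaccard must be in [0, 1]")
        if not 0.0 <= self.background_rate < 1.0:
            raise ValueError("background_rate must be in [0, 1)")
        if not 0.0 <= self.background_pool_frac < 1.0:
            raise ValueError("background_pool_frac must be in [0, 1)")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.universe_size < self.n_sets:
            raise ValueError("universe smaller than the number of sets")


def _element_labels(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"g{k:0{width}d}" for k in range(n)])


def _predicted_mean_jaccard(sizes: np.ndarray, core: int) -> float:
    """Expected mean pairwise Jaccard of a cluster with a shared core.

    A set of size ``s`` takes ``min(core, s)`` core elements (a uniform
    subset when s < core), so a pair intersects in about
    ``n_i·n_k/core`` elements.
    """
    if core == 0:
        return 0.0
    n = np.minimum(core, sizes).astype(float)
    total, count = 0.0, 0
    for i in range(len(sizes)):
        for k in range(i + 1, len(sizes)):
            inter = n[i] * n[k] / core
            total += inter / (sizes[i] + sizes[k] - inter)
            count += 1
    return total / count


def _calibrate_core(sizes: np.ndarray, target: float) -> int:
    """Smallest core size whose predicted mean pairwise Jaccard hits the target."""
    if target <= 0.0:
        return 0
    best_c, best_err = 0, target
    for c in range(1, int(sizes.max()) + 1):
        err = abs(_predicted_mean_jaccard(sizes, c) - target)
        if err < best_err:
            best_c, best_err = c, err
    return best_c


def generate_family(spec: SyntheticSpec) -> tuple[SetFamily, np.ndarray]:
    """Generate a family plus ground-truth cluster labels.

    Returns ``(family, labels)`` where ``labels[i]`` is the cluster id
    of set ``i``.  Deterministic given ``spec.seed``.  Raises when the
    universe budget cannot accommodate the requested sizes (infeasible
    spec).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    # sizes: heavy-tailed unless a fixed size is requested
    if spec.fixed_size is not None:
        sizes = np.full(spec.n_sets, int(spec.fixed_size))
    else:
        raw = rng.lognormal(spec.size_log_mean, spec.size_log_sigma, spec.n_sets)
        sizes = np.maximum(spec.min_size, np.rint(raw)).astype(int)

    n_clusters = spec.resolved_clusters
    labels = np.arange(spec.n_sets) % n_clusters

    elements = _element_labels(spec.universe_size)
    n_background = int(round(spec.background_pool_frac * spec.universe_size))
    background_pool = elements[:n_background]

    # per-cluster demand: shared core plus every set's private elements
    t = spec.within_cluster_jaccard
    core_sizes = np.zeros(n_clusters, dtype=int)
    demands = np.zeros(n_clusters, dtype=int)
    for cluster in range(n_clusters):
        idx = np.flatnonzero(labels == cluster)
        if len(idx) > 1:
            core_sizes[cluster] = _calibrate_core(sizes[idx], t)
        n_core = np.minimum(core_sizes[cluster], sizes[idx])
        demands[cluster] = core_sizes[cluster] + int((sizes[idx] - n_core).sum())
    total_demand = n_background + int(demands.sum())
    if total_demand > spec.universe_size:
        raise ValueError(
            f"infeasible spec: requested sizes need {total_demand} distinct "
            f"elements but the universe holds {spec.universe_size}"
        )

    members: list[list[str]] = [[] for _ in range(spec.n_sets)]
    offset = n_background  # cluster pools are carved sequentially by demand
    for cluster in range(n_clusters):
        idx = np.flatnonzero(labels == cluster)
        pool = rng.permutation(elements[offset:offset + demands[cluster]])
        offset += demands[cluster]
        core_size = core_sizes[cluster]
        core = pool[:core_size]
        cursor = core_size  # private elements are consumed past the core
        for i in idx:
            n_core = min(core_size, sizes[i])
            if n_core == core_size:
                chosen_core = core
            else:
                chosen_core = rng.choice(core, size=n_core, replace=False)
            n_private = sizes[i] - n_core
            private = pool[cursor:cursor + n_private]
            cursor += n_private
            members[i] = list(chosen_core) + list(private)

    # low-rate background sharing: swap random member elements for
    # elements of the globally shared pool
    if spec.background_rate > 0.0 and n_background > 0:
        for i in range(spec.n_sets):
            swap = np.flatnonzero(rng.random(sizes[i]) < spec.background_rate)
            if swap.size == 0:
                continue
            k = min(swap.size, n_background)
            shared = rng.choice(background_pool, size=k, replace=False)
            for pos, g in zip(swap[:k], shared):
                members[i][pos] = str(g)
            # swapping may collide with an existing member; dedup keeps
            # first appearance and build_family tolerates it
    name_width = max(3, len(str(spec.n_sets)))
    named = [
        (f"S{i:0{name_width}d}", members[i]) for i in range(spec.n_sets)
    ]
    family = build_family(named)
    return family, labels


def disjoint_spec(n_sets: int, set_size: int = 10, seed: int = 0) -> SyntheticSpec:
    """Spec for a pairwise-disjoint family: one set per cluster, no sharing."""
    return SyntheticSpec(
        n_sets=n_sets,
        n_clusters=n_sets,
        universe_size=max(2 * n_sets * set_size, n_sets),
        fixed_size=set_size,
        within_cluster_jaccard=0.0,
        background_rate=0.0,
        background_pool_frac=0.0,
        seed=seed,
    )


def generate_target(
    family: SetFamily,
    enriched_indices: Iterable[int],
    odds: float,
    seed: int,
    base_rate: float = 0.05,
) -> frozenset[str]:
    """Sample a target element list with planted enrichment.

    Every universe element enters the target with probability
    ``base_rate``; elements of the enriched sets enter with the elevated
    probability ``odds·p0 / (1 + (odds−1)·p0)`` (odds-ratio ``odds`` on
    the inclusion odds).  Deterministic given ``seed``.
    """
    if not odds > 1.0:
        raise ValueError("enrichment odds must exceed 1")
    if not 0.0 < base_rate < 1.0:
        raise ValueError("base_rate must be in (0, 1)")
    enriched_indices = set(enriched_indices)
    for i in enriched_indices:
        if not 0 <= i < family.n_sets:
            raise IndexError(f"set index {i} out of range")

    enriched_elements: set[str] = set()
    for i in enriched_indices:
        enriched_elements |= set(family.member_sets[i])

    p0 = base_rate
    p1 = odds * p0 / (1.0 + (odds - 1.0) * p0)
    rng = np.random.default_rng(seed)
    draws = rng.random(family.universe_size)
    target = {
        g
        for g, u in zip(family.universe, draws)
        if u < (p1 if g in enriched_elements else p0)
    }
    return frozenset(target)
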