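"""Hierarchical grouping of single-scan ICA components into group clusters.

Self-organizing group ICA pairs up components across sessions and subjects
by spatial similarity under a hard constraint: each cluster takes exactly
one component from each contributing component set. We implement this as a
deterministic sequential assignment — clusters are seeded with the first
set's components, and every subsequent set is matched one-to-one to the
running cluster centroids by solving the linear assignment problem that
maximizes summed absolute spatial correlation; centroids (mean of member
maps, re-z-scored) are updated after each set. Set order is the sorted
(subject, day, timepoint) key, so the result is independent of input order.

The two-level hierarchy mirrors a bias-avoiding template construction:
level 1 matches each subject's two baseline scans (FD-T1, WD-T1) and
averages matched pairs into one representative set per subject; level 2
clusters the representatives across subjects. Exhausted-state scans are
never consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .decompose import ComponentSet, zscale_map

logger = logging.getLogger(__name__)

BASELINE_CONDITIONS = ("FD-T1", "WD-T1")


@dataclass(frozen=True)
class ComponentRef:
    """Pointer to one component of one stored ComponentSet.

    ``day``/``timepoint`` are ``None`` for subject-level representative sets
    produced by the within-subject (level-1) averaging step.
    """

    subject: str
    day: str | None
    timepoint: str | None
    index: int


@dataclass
class ComponentCluster:
    """One group cluster: exactly one member per contributing set."""

    label: int
    members: list[ComponentRef]
    member_maps: np.ndarray  # (n_members, V) z-scored maps
    centroid: np.ndarray  # (V,) z-scored mean of member maps

    @property
    def n_members(self) -> int:
        return len(self.members)

    def mean_similarity(self) -> float:
        """Mean member-to-centroid absolute spatial correlation."""
        return float(np.mean([spatial_similarity(m, self.centroid) for m in self.member_maps]))


def spatial_similarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Absolute Pearson correlation of two spatial maps over the mask.

    Sign is ignored because the ICA sign convention is arbitrary per scan.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share the mask")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map has no defined spatial similarity")
    return float(abs(a @ b) / (na * nb))


def _set_key(cs: ComponentSet) -> tuple:
    return (cs.subject, cs.day or "", cs.timepoint or "")


def _similarity_matrix(maps: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """|corr| between each map (rows) and each centroid (columns)."""
    m = maps - maps.mean(axis=1, keepdims=True)
    c = centroids - centroids.mean(axis=1, keepdims=True)
    mn = np.linalg.norm(m, axis=1)
    cn = np.linalg.norm(c, axis=1)
    if (mn == 0).any() or (cn == 0).any():
        raise ValueError("zero-variance map encountered during clustering")
    return np.abs(m @ c.T) / np.outer(mn, cn)


def cluster_sets(sets: list[ComponentSet]) -> list[ComponentCluster]:
    """Cluster K components across sets, one member per set per cluster.

    Deterministic: sets are processed in sorted (subject, day, timepoint)
    order; assignment ties resolve to the lowest component index via the
    assignment solver's stable ordering on an index-penalized copy.
    """
    if not sets:
        raise ValueError("no component sets given")
    k = sets[0].k
    if any(cs.k != k for cs in sets):
        raise ValueError(f"all sets must share K={k}; got {[cs.k for cs in sets]}")
    ordered = sorted(sets, key=_set_key)

    first = ordered[0]
    members: list[list[ComponentRef]] = [
        [ComponentRef(first.subject, first.day, first.timepoint, j)] for j in range(k)
    ]
    member_maps: list[list[np.ndarray]] = [[first.maps[j]] for j in range(k)]
    centroids = first.maps.copy()

    for cs in ordered[1:]:
        sim = _similarity_matrix(cs.maps, centroids)
        # deterministic tie-break: prefer lower component index
        eps = 1e-12
        tilted = sim - eps * np.arange(k)[:, None]
        rows, cols = linear_sum_assignment(-tilted)
        for j, cluster in zip(rows, cols):
            members[cluster].append(ComponentRef(cs.subject, cs.day, cs.timepoint, int(j)))
            member_maps[cluster].append(cs.maps[j])
            stacked = np.stack(member_maps[cluster])
            centroids[cluster] = zscale_map(stacked.mean(axis=0))

    clusters = [
        ComponentCluster(label=c, members=members[c],
                         member_maps=np.stack(member_maps[c]), centroid=centroids[c])
        for c in range(k)
    ]
    logger.info("clustered %d sets into %d clusters of %d members",
                len(sets), k, clusters[0].n_members)
    return clusters


def _representative_set(subject_sets: list[ComponentSet]) -> ComponentSet:
    """Level 1: match a subject's baseline sets, average matched maps."""
    if len(subject_sets) == 1:
        cs = subject_sets[0]
        return ComponentSet(subject=cs.subject, day=None, timepoint=None,
                            maps=cs.maps.copy(), courses=None)
    clusters = cluster_sets(subject_sets)
    maps = np.stack([zscale_map(c.member_maps.mean(axis=0)) for c in clusters])
    return ComponentSet(subject=subject_sets[0].subject, day=None, timepoint=None,
                        maps=maps, courses=None)


def hierarchical_group(sets: list[ComponentSet]) -> list[ComponentCluster]:
    """Two-level grouping of baseline component sets into group clusters.

    Only baseline (T1) sets are accepted; passing any exhausted-state set is
    an error, enforcing by construction that templates cannot be biased by
    the conditions later tested.
    """
    for cs in sets:
        if cs.condition is not None and cs.condition not in BASELINE_CONDITIONS:
            raise ValueError(
                f"hierarchical grouping accepts baseline (T1) sets only, got {cs.condition}"
            )
    subjects: dict[str, list[ComponentSet]] = {}
    for cs in sets:
        subjects.setdefault(cs.subject, []).append(cs)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    representatives = [
        _representative_set(sorted(subject_sets, key=_set_key))
        for _, subject_sets in sorted(subjects.items())
    ]
    return cluster_sets(representatives)
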