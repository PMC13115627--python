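"""DBSCAN breakpoint clustering and SLSMD/MMD sample classification.

Each deletion event is a point ``(b5, b3)`` in breakpoint space; distance
is Euclidean with circular wrap on each axis so junctions straddling the
replication origin co-cluster.  Clusters with more than one supporting read
are *recurrent*.  A sample whose events all fall in one recurrent cluster
carries a single large-scale mtDNA deletion (SLSMD); a sample with two or
more clusters carries multiple deletions (MMD) — single-molecule clusters
count, since real cohorts include MMD samples observed through as little
as one deletion molecule.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .delcall import DeletionSet
from .refmodel import DeletionEvent

NOISE = -1

#: Default radius: HiFi breakpoint jitter is small (a few bp), so 50 bp
#: separates distinct junctions while absorbing alignment wobble.
DEFAULT_EPS = 50.0
#: "More than one read with a deletion" makes a cluster recurrent.
DEFAULT_MIN_PTS = 2


@dataclass(frozen=True)
class ClusterParams:
    eps: float = DEFAULT_EPS
    min_pts: int = DEFAULT_MIN_PTS

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


class Classification(str, enum.Enum):
    SLSMD = "SLSMD"
    MMD = "MMD"
    NEGATIVE = "Negative"
    LOW_EVIDENCE = "LowEvidence"


@dataclass
class DeletionCluster:
    cluster_id: int
    members: list[DeletionEvent]
    rep_b5: int
    rep_b3: int

    @property
    def support(self) -> int:
        return len(self.members)

    @property
    def recurrent(self) -> bool:
        return self.support > 1


@dataclass
class SampleCall:
    sample_id: str
    classification: Classification
    clusters: list[DeletionCluster] = field(default_factory=list)
    heteroplasmy_pct: float | None = None


def circular_axis_distance(a: np.ndarray, b: np.ndarray, length: int) -> np.ndarray:
    """Elementwise wrap-aware distance on one circular axis."""
    d = np.abs(a - b)
    return np.minimum(d, length - d)


def _pairwise_circular(points: np.ndarray, length: int) -> np.ndarray:
    d5 = circular_axis_distance(points[:, None, 0], points[None, :, 0], length)
    d3 = circular_axis_distance(points[:, None, 1], points[None, :, 1], length)
    return np.sqrt(d5.astype(float) ** 2 + d3.astype(float) ** 2)


def dbscan_2d(
    points: Sequence[tuple[int, int]],
    params: ClusterParams,
    length: int,
) -> np.ndarray:
    """Standard DBSCAN labels over breakpoint pairs; noise label is -1."""
    if len(points) == 0:
        return np.empty(0, dtype=int)
    pts = np.asarray(points, dtype=float)
    dist = _pairwise_circular(pts, length)
    model = DBSCAN(eps=params.eps, min_samples=params.min_pts, metric="precomputed")
    return model.fit_predict(dist)


def circular_median(values: Sequence[int], length: int) -> int:
    """Median of positions on a circle, unwrapping origin-straddling sets."""
    vals = np.asarray(values, dtype=float)
    if vals.max() - vals.min() > length / 2:
        vals = np.where(vals < length / 2, vals + length, vals)
    med = float(np.median(vals))
    return int(round(med - 1)) % length + 1


def cluster_deletions(
    dels: DeletionSet,
    params: ClusterParams | None = None,
    length: int = 16569,
) -> list[DeletionCluster]:
    """Cluster a sample's deletion events.

    Noise points become singleton clusters (support 1, not recurrent)
    rather than being discarded: single-molecule deletions still count
    toward a sample's deletion burden.  Representative breakpoints are
    per-coordinate wrap-aware medians of the members.
    """
    params = params or ClusterParams()
    if not dels.events:
        return []
    labels = dbscan_2d([e.junction for e in dels.events], params, length)
    groups: dict[int, list[DeletionEvent]] = {}
    next_noise = -1
    for event, label in zip(dels.events, labels):
        if label == NOISE:
            groups[next_noise] = [event]
            next_noise -= 1
        else:
            groups.setdefault(int(label), []).append(event)
    clusters = []
    for members in groups.values():
        clusters.append(
            DeletionCluster(
                cluster_id=0,
                members=members,
                rep_b5=circular_median([e.b5 for e in members], length),
                rep_b3=circular_median([e.b3 for e in members], length),
            )
        )
    clusters.sort(key=lambda c: (-c.support, c.rep_b5, c.rep_b3))
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return clusters


def classify_sample(
    clusters: list[DeletionCluster],
    dels: DeletionSet,
    min_support: int = 2,
) -> SampleCall:
    """Classify a sample from its breakpoint clusters.

    * no qualifying events -> Negative
    * exactly one cluster, recurrent -> SLSMD
    * exactly one singleton cluster with ``min_support > 1`` -> LowEvidence
    * two or more clusters (any mix of recurrent and singletons) -> MMD
    """
    if not dels.events:
        return SampleCall(dels.sample_id, Classification.NEGATIVE, [])
    if len(clusters) == 1:
        only = clusters[0]
        if only.recurrent or min_support <= 1:
            return SampleCall(dels.sample_id, Classification.SLSMD, clusters)
        return SampleCall(dels.sample_id, Classification.LOW_EVIDENCE, clusters)
    return SampleCall(dels.sample_id, Classification.MMD, clusters)
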