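"""Static dendritic-arbor morphometry.

Total dendritic length, branch-tip counts, Sholl crossing profiles and the
immature/mature classification used to stratify developing tectal neurons
(immature arbors are those shorter than 500 µm total dendritic length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arbors import NeuronArbor

DEFAULT_SHOLL_RADII = np.arange(10.0, 201.0, 10.0)
MATURITY_THRESHOLD_UM = 500.0


@dataclass(frozen=True)
class ShollProfile:
    """Crossing counts of concentric soma-centred spheres.

    ``radii`` are strictly increasing shell radii in µm and ``crossings[i]``
    is the number of times the arbor's segments cross the sphere of radius
    ``radii[i]``.
    """

    radii: np.ndarray
    crossings: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(self, "crossings", np.asarray(self.crossings, dtype=int))


@dataclass(frozen=True)
class MaturityClass:
    value: str  # "immature" | "mature"
    threshold: float = MATURITY_THRESHOLD_UM


def total_dendritic_length(arbor: NeuronArbor) -> float:
    """Sum of 3-D Euclidean lengths over all parent-child segments, in µm."""
    parent, child = arbor.edges_xyz()
    if len(child) == 0:
        return 0.0
    return float(np.linalg.norm(child - parent, axis=1).sum())


def count_branch_tips(arbor: NeuronArbor) -> int:
    """Number of non-soma nodes with no children."""
    return len(arbor.leaf_ids())


def sholl_profile(
    arbor: NeuronArbor,
    radii: np.ndarray | None = None,
    projected: bool = False,
) -> ShollProfile:
    """Exact Sholl crossing counts at the given shell radii.

    For each straight segment the distance-to-soma function is unimodal in
    the segment parameter (a single interior minimum at the foot of the
    perpendicular, if it falls inside the segment).  A segment crosses the
    shell of radius ``r`` once per strict sign change of ``d - r`` over each
    monotone piece; tangencies contribute no crossing.  A segment dipping
    inside a shell and back out therefore counts twice, which is the standard
    Sholl semantics.

    Parameters
    ----------
    radii
        Strictly increasing positive shell radii (µm); defaults to
        10, 20, ..., 200 µm.
    projected
        If true, distances are computed in the xy-plane (z dropped), i.e.
        Sholl on the z-projection rather than in 3-D.
    """
    if radii is None:
        radii = DEFAULT_SHOLL_RADII
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("radii must be non-empty")
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")

    parent, child = arbor.edges_xyz()
    soma = arbor.soma_xyz
    if projected:
        parent, child, soma = parent[:, :2], child[:, :2], soma[:2]
    crossings = np.zeros(radii.shape, dtype=int)
    if len(child) == 0:
        return ShollProfile(radii, crossings)

    a = parent - soma
    b = child - soma
    u = b - a
    uu = np.einsum("ij,ij->i", u, u)
    d1 = np.linalg.norm(a, axis=1)
    d2 = np.linalg.norm(b, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_star = np.where(uu > 0, -np.einsum("ij,ij->i", a, u) / np.where(uu > 0, uu, 1.0), 0.0)
    interior = (t_star > 0) & (t_star < 1)
    d_min = np.where(
        interior,
        np.linalg.norm(a + t_star[:, None] * u, axis=1),
        np.minimum(d1, d2),
    )
    # Monotone pieces per edge: (d1 -> d_min) and (d_min -> d2); for edges
    # without an interior minimum the first piece is degenerate.
    lo1 = np.minimum(d1, d_min)
    hi1 = np.maximum(d1, d_min)
    lo2 = np.minimum(d_min, d2)
    hi2 = np.maximum(d_min, d2)
    for i, r in enumerate(radii):
        c = ((lo1 < r) & (r < hi1)).sum() + ((lo2 < r) & (r < hi2)).sum()
        crossings[i] = int(c)
    return ShollProfile(radii, crossings)


def classify_maturity(
    arbor: NeuronArbor, threshold: float = MATURITY_THRESHOLD_UM
) -> MaturityClass:
    """Immature iff total dendritic length < threshold; the boundary is mature."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    length = total_dendritic_length(arbor)
    return MaturityClass("immature" if length < threshold else "mature", threshold)
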