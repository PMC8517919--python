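"""Burst-coincidence functional connectivity.

Connectivity between two regions is the Jaccard index of their binary
burst trains: the number of samples where both burst divided by the number
where either bursts. A connectome is the symmetric region x region matrix
of these values (diagonal fixed at 0); pairs whose union is empty are
reported as 0 and masked.
"""

from __future__ import annotations

import numpy as np

from .containers import BurstTrain, Connectome


def jaccard(a: BurstTrain, b: BurstTrain) -> tuple[float, bool]:
    """Intersection-over-union of two burst trains.

    Returns ``(J, union_empty)``; an empty union yields ``J = 0`` with the
    mask flag set, keeping group averages well-defined.
    """
    if len(a.b) != len(b.b):
        raise ValueError("trains differ in length")
    x = a.b.astype(bool)
    y = b.b.astype(bool)
    inter = int(np.count_nonzero(x & y))
    union = int(np.count_nonzero(x | y))
    if union == 0:
        return 0.0, True
    return inter / union, False


def connectome(trains: list[BurstTrain],
               labels: list[str] | None = None) -> Connectome:
    """All-pairs Jaccard coincidence matrix (vectorized)."""
    if not trains:
        raise ValueError("no trains supplied")
    T = len(trains[0].b)
    for t in trains:
        if len(t.b) != T:
            raise ValueError("inconsistent train lengths")
    if labels is None:
        labels = [t.region_id for t in trains]
    B = np.stack([t.b for t in trains]).astype(np.float64)
    inter = B @ B.T
    occ = B.sum(axis=1)
    union = occ[:, None] + occ[None, :] - inter
    mask = union == 0
    J = np.where(mask, 0.0, inter / np.where(mask, 1.0, union))
    np.fill_diagonal(J, 0.0)
    np.fill_diagonal(mask, False)
    return Connectome(labels=list(labels), J=J, union_empty_mask=mask)


def top_fraction(c: Connectome | np.ndarray, fraction: float,
                 labels: list[str] | None = None
                 ) -> list[tuple[str, str, float, int]]:
    """The largest ``floor(fraction * n_edges)`` edges of a symmetric matrix.

    Returns (region_a, region_b, value, rank) tuples, rank starting at 1.
    Ties at the cut are broken deterministically by lexicographic label
    order.
    """
    if isinstance(c, Connectome):
        M, labels = c.J, c.labels
    else:
        M = np.asarray(c, dtype=float)
        if labels is None:
            labels = [f"R{i:02d}" for i in range(M.shape[0])]
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    R = M.shape[0]
    if R < 2:
        raise ValueError("matrix has no off-diagonal edges")
    iu, ju = np.triu_indices(R, k=1)
    vals = M[iu, ju]
    n_keep = int(np.floor(fraction * len(vals)))
    pairs = sorted(
        ((float(v), labels[i], labels[j]) for v, i, j in zip(vals, iu, ju)),
        key=lambda t: (-t[0], t[1], t[2]))
    return [(a, b, v, r + 1) for r, (v, a, b) in enumerate(pairs[:n_keep])]


def global_mean_connectivity(c: Connectome) -> float:
    """Mean over the unique off-diagonal edge values."""
    return float(c.edge_values().mean())


def group_difference_matrix(patients: list[Connectome],
                            controls: list[Connectome]) -> np.ndarray:
    """Control-minus-patient mean edge matrix (positive = patient deficit)."""
    P = np.mean([c.J for c in patients], axis=0)
    C = np.mean([c.J for c in controls], axis=0)
    return C - P
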