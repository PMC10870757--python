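"""Minimum-image geometry in orthorhombic periodic boxes.

All distances in the package go through these helpers so the periodic
convention (orthorhombic minimum image, strict ``<`` at cutoffs) is applied
uniformly.  Neighbor queries use a periodic k-d tree rather than all-pairs
scans so contact counting stays near-linear in bead number.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "minimum_image",
    "min_image_distance",
    "wrap_positions",
    "periodic_tree",
    "pairs_within",
    "neighbor_counts",
]


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Map displacement vectors into the minimum-image convention.

    Parameters
    ----------
    disp : (..., 3) array of displacement vectors in Angstrom.
    box : (3,) orthorhombic box lengths in Angstrom.
    """
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


def min_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image Euclidean distance between positions ``a`` and ``b``."""
    d = minimum_image(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into ``[0, box)`` per dimension.

    Guards against the float edge case where ``x % L`` rounds to exactly
    ``L`` for tiny negative ``x`` (cKDTree with ``boxsize`` rejects that).
    """
    box = np.asarray(box, dtype=float)
    out = np.mod(np.asarray(pos, dtype=float), box)
    out[out >= box] = 0.0
    return out


def periodic_tree(pos: np.ndarray, box: np.ndarray) -> cKDTree:
    """k-d tree over wrapped positions with periodic topology."""
    return cKDTree(wrap_positions(pos, box), boxsize=np.asarray(box, dtype=float))


def pairs_within(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    box: np.ndarray,
    cutoff: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i into a, j into b) with min-image distance strictly < cutoff.

    The tree query is inclusive at the radius, so candidates are re-checked
    with an exact strict comparison; a bead pair sitting exactly at the
    cutoff is therefore never counted.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos_a = np.atleast_2d(np.asarray(pos_a, float))
    pos_b = np.atleast_2d(np.asarray(pos_b, float))
    if len(pos_a) == 0 or len(pos_b) == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    tree_b = periodic_tree(pos_b, box)
    lists = tree_b.query_ball_point(wrap_positions(pos_a, box), r=cutoff)
    ii: list[int] = []
    jj: list[int] = []
    for i, cand in enumerate(lists):
        if not cand:
            continue
        cand = np.asarray(cand, dtype=np.intp)
        d = min_image_distance(pos_a[i], pos_b[cand], box)
        keep = cand[d < cutoff]
        ii.extend([i] * len(keep))
        jj.extend(keep.tolist())
    return np.asarray(ii, dtype=np.intp), np.asarray(jj, dtype=np.intp)


def neighbor_counts(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    box: np.ndarray,
    cutoff: float,
) -> np.ndarray:
    """Per-row-of-``a`` count of ``b`` beads strictly within ``cutoff``."""
    ii, _ = pairs_within(pos_a, pos_b, box, cutoff)
    counts = np.zeros(len(np.atleast_2d(pos_a)), dtype=np.intp)
    np.add.at(counts, ii, 1)
    return counts
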