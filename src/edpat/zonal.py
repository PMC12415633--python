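"""Strict geometric labelling of patterns as zonal (2DZone) or 3D.

A pattern is *zonal* exactly when every excited reflection obeys one zone
law h·u + k·v + l·w = 0, i.e. all hkl rows lie in a single reciprocal
plane through the origin.  Because the indices are exact integers, the
test is the integer rank of the hkl matrix — no tolerance parameter
exists anywhere in this module.

Rank 2 → ``2DZone`` with the primitive zone axis [u v w].  Rank 3 →
``3DLaueIntersections``.  Patterns too sparse to form a visible 2D net
(empty, a single spot, or a collinear row: rank ≤ 1) are labelled
``3DLaueIntersections`` and flagged degenerate, since they are useless for
downstream unit-cell determination either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np

__all__ = ["ZONAL", "NON_ZONAL", "ZoneAssignment", "label_pattern",
           "integer_rank", "zonal_fraction"]

ZONAL = "2DZone"
NON_ZONAL = "3DLaueIntersections"


@dataclass(frozen=True)
class ZoneAssignment:
    """Outcome of the strict zonal test for one pattern."""

    label: str
    zone_axis: tuple[int, int, int] | None = None
    n_off_zone: int = 0
    degenerate: bool = False


def _primitive(axis: np.ndarray) -> tuple[int, int, int]:
    """Reduce an integer vector to coprime components, first nonzero positive."""
    u, v, w = (int(x) for x in axis)
    g = gcd(gcd(abs(u), abs(v)), abs(w))
    if g == 0:
        raise ValueError("zero vector has no primitive form")
    u, v, w = u // g, v // g, w // g
    for comp in (u, v, w):
        if comp != 0:
            if comp < 0:
                u, v, w = -u, -v, -w
            break
    return (u, v, w)


def integer_rank(hkl: np.ndarray) -> tuple[int, np.ndarray | None]:
    """Exact rank of an (n, 3) integer matrix, with a normal for rank 2.

    Returns ``(rank, normal)`` where ``normal`` is an (unreduced) integer
    normal of the common plane when rank == 2, else ``None``.  Uses only
    integer cross and dot products, so the result is exact.
    """
    hkl = np.asarray(hkl, dtype=np.int64).reshape(-1, 3)
    nz = hkl[np.any(hkl != 0, axis=1)]
    if len(nz) == 0:
        return 0, None
    r1 = nz[0]
    cross = np.cross(nz, r1)  # zero row ⇔ collinear with r1
    indep = nz[np.any(cross != 0, axis=1)]
    if len(indep) == 0:
        return 1, None
    normal = np.cross(r1, indep[0])
    if np.any(nz @ normal != 0):
        return 3, None
    return 2, normal


def label_pattern(hkl_list) -> ZoneAssignment:
    """Label one excited-reflection set by the strict zonal criterion.

    Parameters
    ----------
    hkl_list
        Iterable of integer Miller-index triples, central beam excluded.

    Returns
    -------
    ZoneAssignment
        ``2DZone`` with the coprime, sign-normalized zone axis when the
        integer rank is exactly 2; otherwise ``3DLaueIntersections``.  For
        rank-3 sets ``n_off_zone`` counts the reflections violating the
        best zone law, minimized over all candidate axes spanned by pairs
        of reflections.
    """
    hkl = np.asarray(list(hkl_list) if not isinstance(hkl_list, np.ndarray)
                     else hkl_list, dtype=np.int64).reshape(-1, 3)
    rank, normal = integer_rank(hkl)
    if rank == 2:
        return ZoneAssignment(label=ZONAL, zone_axis=_primitive(normal),
                              n_off_zone=0, degenerate=False)
    if rank < 2:
        return ZoneAssignment(label=NON_ZONAL, zone_axis=None,
                              n_off_zone=0, degenerate=True)
    return ZoneAssignment(label=NON_ZONAL, zone_axis=None,
                          n_off_zone=_min_off_zone(hkl), degenerate=False)


def _min_off_zone(hkl: np.ndarray) -> int:
    """Fewest reflections violating any single zone law.

    The optimal axis (when the best zone holds ≥ 2 independent reflections)
    is a cross product of two rows, so searching those candidates is exact;
    sparser optima cannot beat n − 1, which the pairwise search also attains.
    """
    n = len(hkl)
    ii, jj = np.triu_indices(n, k=1)
    axes = np.cross(hkl[ii], hkl[jj])
    axes = axes[np.any(axes != 0, axis=1)]
    if len(axes) == 0:  # all rows pairwise collinear; cannot happen at rank 3
        return n - 1
    axes = np.unique(axes, axis=0)
    violations = np.count_nonzero(hkl @ axes.T, axis=0)
    return int(violations.min())


def zonal_fraction(labels) -> float:
    """Fraction of patterns labelled zonal; errors on an empty collection.

    Accepts any iterable of label strings (e.g. a manifest column).
    """
    labels = list(labels)
    if not labels:
        raise ValueError("cannot compute the zonal fraction of an empty dataset")
    return sum(1 for x in labels if x == ZONAL) / len(labels)
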