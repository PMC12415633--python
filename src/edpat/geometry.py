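"""Unit-cell generation, reciprocal bases and systematic absences.

Cells are described by the six lattice parameters (a, b, c in Å; α, β, γ in
degrees).  All vector quantities live in a fixed Cartesian crystal frame:
the direct **a** axis lies along x, **b** lies in the x–y plane, and **c**
completes a right-handed set.  Reciprocal vectors follow the
crystallographic convention without the 2π factor, so aᵢ · a*ⱼ = δᵢⱼ and
the reciprocal cell volume is 1/V.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "ReciprocalBasis",
    "ExtinctionRule",
    "SCREW_21_B",
    "random_unit_cell",
    "cell_volume",
    "direct_basis",
    "reciprocal_basis",
    "apply_extinctions",
]

#: Default triclinic angle sampling window (degrees).
TRICLINIC_ANGLE_RANGE = (75.0, 115.0)
#: Default monoclinic β sampling window (degrees); α = γ = 90 are fixed.
MONOCLINIC_BETA_RANGE = (95.0, 115.0)
#: "Nearly isotropic" length preset (Å, before volume rescaling).
ISOTROPIC_LENGTH_RANGE = (5.0, 12.0)
#: "Strongly anisotropic" length preset (Å, before volume rescaling).
ANISOTROPIC_LENGTH_RANGE = (3.0, 22.0)

_MAX_SAMPLING_ATTEMPTS = 1000


def _angles_admissible(alpha: float, beta: float, gamma: float) -> bool:
    """True when (α, β, γ) close into a valid parallelepiped."""
    if not all(0.0 < x < 180.0 for x in (alpha, beta, gamma)):
        return False
    if alpha + beta + gamma >= 360.0:
        return False
    # each angle strictly less than the sum of the other two
    if alpha >= beta + gamma or beta >= alpha + gamma or gamma >= alpha + beta:
        return False
    ca, cb, cg = np.cos(np.radians([alpha, beta, gamma]))
    return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg > 0.0


@dataclass(frozen=True)
class UnitCell:
    """Direct-space unit cell.

    Parameters
    ----------
    a, b, c
        Axis lengths in Å, strictly positive.
    alpha, beta, gamma
        Inter-axial angles in degrees, each in (0, 180) and jointly
        admissible (the metric determinant must be positive).
    cell_id
        Opaque identifier used in dataset manifests.
    lattice_system
        ``"triclinic"`` or ``"monoclinic"`` (tag only; no constraint is
        re-imposed here beyond angle validity).
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    cell_id: str = "cell"
    lattice_system: str = "triclinic"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0.0:
            raise ValueError(f"cell lengths must be positive, got "
                             f"a={self.a}, b={self.b}, c={self.c}")
        if not _angles_admissible(self.alpha, self.beta, self.gamma):
            raise ValueError(
                f"invalid angle combination α={self.alpha}, β={self.beta}, "
                f"γ={self.gamma}: each angle must lie in (0, 180), be smaller "
                f"than the sum of the other two, and the metric determinant "
                f"must be positive")

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (closed-form triclinic expression)."""
        return cell_volume(self)

    def scaled(self, factor: float) -> "UnitCell":
        """Return a copy with all three lengths multiplied by ``factor``."""
        return UnitCell(self.a * factor, self.b * factor, self.c * factor,
                        self.alpha, self.beta, self.gamma,
                        cell_id=self.cell_id,
                        lattice_system=self.lattice_system)

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "a": self.a, "b": self.b, "c": self.c,
            "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
            "volume": self.volume,
            "lattice_system": self.lattice_system,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitCell":
        return cls(d["a"], d["b"], d["c"], d["alpha"], d["beta"], d["gamma"],
                   cell_id=d.get("cell_id", "cell"),
                   lattice_system=d.get("lattice_system", "triclinic"))


@dataclass(frozen=True)
class ReciprocalBasis:
    """Reciprocal basis vectors a*, b*, c* in Å⁻¹ (crystal Cartesian frame)."""

    astar: np.ndarray
    bstar: np.ndarray
    cstar: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """3×3 matrix with a*, b*, c* as rows; g(hkl) = hkl @ matrix."""
        return np.vstack([self.astar, self.bstar, self.cstar])

    @property
    def volume(self) -> float:
        """Reciprocal cell volume in Å⁻³ (equals 1/V of the direct cell)."""
        return float(abs(np.linalg.det(self.matrix)))


def cell_volume(cell: UnitCell) -> float:
    """Closed-form triclinic volume abc·√(1 − Σcos² + 2·cosα·cosβ·cosγ)."""
    ca, cb, cg = np.cos(np.radians([cell.alpha, cell.beta, cell.gamma]))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0.0:
        raise ValueError(f"invalid angle combination for volume: "
                         f"α={cell.alpha}, β={cell.beta}, γ={cell.gamma}")
    return float(cell.a * cell.b * cell.c * np.sqrt(arg))


def direct_basis(cell: UnitCell) -> np.ndarray:
    """Direct lattice vectors as rows of a 3×3 matrix (Å).

    Convention: a ∥ x, b in the x–y plane, c completing a right-handed set.
    """
    ca, cb, cg = np.cos(np.radians([cell.alpha, cell.beta, cell.gamma]))
    sg = np.sin(np.radians(cell.gamma))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0.0 or sg == 0.0:
        raise ValueError("degenerate cell: cannot build a Cartesian basis")
    v = np.sqrt(arg)
    avec = np.array([cell.a, 0.0, 0.0])
    bvec = np.array([cell.b * cg, cell.b * sg, 0.0])
    cvec = np.array([cell.c * cb,
                     cell.c * (ca - cb * cg) / sg,
                     cell.c * v / sg])
    return np.vstack([avec, bvec, cvec])


def reciprocal_basis(cell: UnitCell) -> ReciprocalBasis:
    """Reciprocal basis dual to :func:`direct_basis` (no 2π factor)."""
    A = direct_basis(cell)
    # rows of inv(A).T are a*, b*, c*: A @ B.T = I
    B = np.linalg.inv(A).T
    return ReciprocalBasis(astar=B[0], bstar=B[1], cstar=B[2])


def random_unit_cell(volume_target: float,
                     length_ranges: Sequence[tuple[float, float]] | None = None,
                     angle_ranges: Sequence[tuple[float, float]] | None = None,
                     lattice_system: str = "triclinic",
                     seed: int | np.random.SeedSequence = 0,
                     cell_id: str | None = None) -> UnitCell:
    """Draw a random unit cell and rescale it to an exact target volume.

    Lengths and angles are sampled uniformly within their ranges; invalid
    angle combinations are rejected and re-drawn.  After sampling, the three
    lengths are rescaled isotropically (angles untouched) so the volume hits
    ``volume_target`` exactly, preserving the sampled shape anisotropy.

    Parameters
    ----------
    volume_target
        Target cell volume in Å³ (> 0).
    length_ranges
        ``[(a_min, a_max), (b_min, b_max), (c_min, c_max)]`` in Å before
        rescaling.  Default: the nearly isotropic preset [5, 12] Å.
    angle_ranges
        ``[(α_min, α_max), (β_min, β_max), (γ_min, γ_max)]`` in degrees.
        Defaults: [75°, 115°] per angle for triclinic; for monoclinic only
        the β range is honoured (default [95°, 115°]) and α = γ = 90.
    lattice_system
        ``"triclinic"`` or ``"monoclinic"``.
    seed
        Integer seed or a :class:`numpy.random.SeedSequence`; the same seed
        reproduces the same cell.

    Raises
    ------
    ValueError
        If the target volume is not positive, the system tag is unknown, or
        no admissible angle combination is found within the attempt budget.
    """
    if volume_target <= 0.0:
        raise ValueError(f"volume_target must be positive, got {volume_target}")
    if lattice_system not in ("triclinic", "monoclinic"):
        raise ValueError(f"unknown lattice_system {lattice_system!r}")
    if length_ranges is None:
        length_ranges = [ISOTROPIC_LENGTH_RANGE] * 3
    if angle_ranges is None:
        if lattice_system == "monoclinic":
            angle_ranges = [(90.0, 90.0), MONOCLINIC_BETA_RANGE, (90.0, 90.0)]
        else:
            angle_ranges = [TRICLINIC_ANGLE_RANGE] * 3
    for lo, hi in list(length_ranges) + list(angle_ranges):
        if hi < lo:
            raise ValueError(f"empty range [{lo}, {hi}]")

    rng = np.random.default_rng(seed)
    for _ in range(_MAX_SAMPLING_ATTEMPTS):
        a, b, c = (rng.uniform(lo, hi) for lo, hi in length_ranges)
        if lattice_system == "monoclinic":
            beta = rng.uniform(*angle_ranges[1])
            alpha, gamma = 90.0, 90.0
        else:
            alpha, beta, gamma = (rng.uniform(lo, hi) for lo, hi in angle_ranges)
        if not _angles_admissible(alpha, beta, gamma):
            continue
        cell = UnitCell(a, b, c, alpha, beta, gamma,
                        cell_id=cell_id or "cell",
                        lattice_system=lattice_system)
        factor = (volume_target / cell.volume) ** (1.0 / 3.0)
        return cell.scaled(factor)
    raise ValueError(
        f"no admissible angle combination found in {_MAX_SAMPLING_ATTEMPTS} "
        f"attempts for angle_ranges={list(angle_ranges)}")


@dataclass(frozen=True)
class ExtinctionRule:
    """Systematic-absence rule applied to integer hkl lists.

    The only supported rule is ``screw_21_b``: a 2₁ screw axis along **b**,
    whose reflection condition 0k0: k = 2n forbids 0k0 with odd k.
    """

    rule_kind: str = "screw_21_b"
    description: str = "0k0 absent for k odd"

    def forbids(self, hkl: np.ndarray) -> np.ndarray:
        """Boolean mask of forbidden rows for an (n, 3) integer array."""
        if self.rule_kind != "screw_21_b":
            raise ValueError(f"unknown extinction rule {self.rule_kind!r}")
        hkl = np.atleast_2d(np.asarray(hkl, dtype=np.int64))
        return ((hkl[:, 0] == 0) & (hkl[:, 2] == 0)
                & (hkl[:, 1] % 2 != 0))


SCREW_21_B = ExtinctionRule()


def apply_extinctions(hkl_list: Iterable[tuple[int, int, int]],
                      rule: ExtinctionRule) -> list[tuple[int, int, int]]:
    """Remove systematically absent reflections, preserving order.

    Idempotent: applying the same rule twice changes nothing further.
    """
    hkl = [tuple(int(x) for x in t) for t in hkl_list]
    if not hkl:
        return []
    mask = rule.forbids(np.array(hkl, dtype=np.int64))
    return [t for t, dead in zip(hkl, mask) if not dead]
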