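"""Kinematic simulation and rendering of serial electron-diffraction snapshots.

A snapshot is defined by a crystal orientation (beam direction drawn from a
Fibonacci-sphere spiral, plus a random in-plane roll of the detector).  A
reflection hkl is *excited* when its reciprocal vector g lies within the
resolution sphere (|g| ≤ g_max) and within the excitation-error band
(|s| ≤ s_max) around the Ewald sphere of radius 1/λ.  The excitation error
s is the signed distance from the lattice point to the sphere surface,
measured along the beam direction (the standard deviation-parameter
convention); for a reflection in the zero-order Laue zone it reduces to the
sphere sag −|g|²·λ/2.

Excited reflections are projected onto a flat detector normal to the beam
and rendered as uniform white discs on black, with a slightly enlarged
central spot marking the primary beam.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .geometry import ExtinctionRule, ReciprocalBasis, UnitCell, reciprocal_basis

__all__ = [
    "Orientation",
    "Reflection",
    "Pattern",
    "RenderSpec",
    "PhysicsConfig",
    "electron_wavelength",
    "fibonacci_sphere",
    "enumerate_candidate_hkl",
    "excitation_errors",
    "excited_reflections",
    "project_to_detector",
    "render_pattern",
    "simulate_patterns",
]

# golden angle in radians: 2π(1 − 1/φ)
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class Orientation:
    """Beam direction (unit vector, crystal frame) plus detector roll."""

    beam_direction: np.ndarray
    inplane_angle: float = 0.0  # degrees
    orientation_id: int = 0

    def __post_init__(self) -> None:
        bd = np.asarray(self.beam_direction, dtype=float)
        n = np.linalg.norm(bd)
        if abs(n - 1.0) > 1e-9:
            bd = bd / n
        object.__setattr__(self, "beam_direction", bd)

    def detector_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Right-handed in-plane basis (e1, e2) perpendicular to the beam.

        The un-rolled e1 follows ẑ × beam (falling back to x̂ when the beam
        is along ±z), then both axes are rotated about the beam by
        ``inplane_angle``.
        """
        b = self.beam_direction
        e1 = np.cross([0.0, 0.0, 1.0], b)
        if np.linalg.norm(e1) < 1e-12:
            e1 = np.array([1.0, 0.0, 0.0])
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(b, e1)
        phi = math.radians(self.inplane_angle)
        c, s = math.cos(phi), math.sin(phi)
        return c * e1 + s * e2, -s * e1 + c * e2


@dataclass(frozen=True)
class Reflection:
    """An excited reflection: indices, reciprocal vector, excitation, projection."""

    hkl: tuple[int, int, int]
    g: np.ndarray            # Å⁻¹, crystal frame
    s: float                 # signed excitation error, Å⁻¹
    detector_xy: np.ndarray  # Å⁻¹, detector frame


@dataclass
class Pattern:
    """One simulated snapshot with its geometric ground truth."""

    pattern_id: str
    cell_id: str
    orientation: Orientation
    reflections: list[Reflection]
    label: str | None = None
    zone_axis: tuple[int, int, int] | None = None
    degenerate: bool = False
    image_path: str | None = None

    @property
    def hkl_array(self) -> np.ndarray:
        if not self.reflections:
            return np.empty((0, 3), dtype=np.int64)
        return np.array([r.hkl for r in self.reflections], dtype=np.int64)


@dataclass(frozen=True)
class RenderSpec:
    """Rendering geometry for the binary pattern images.

    ``gmax_to_edge`` (Å⁻¹) maps to the image half-width, so the full image
    spans ±gmax_to_edge.  The central (primary-beam) spot is always drawn,
    slightly larger than the reflection spots.
    """

    image_size: int = 512
    gmax_to_edge: float = 1.0
    spot_radius: int = 3
    central_spot_radius: int = 6
    foreground: int = 255
    background: int = 0

    def __post_init__(self) -> None:
        if self.spot_radius < 1:
            raise ValueError("spot_radius must be ≥ 1")
        if self.central_spot_radius <= self.spot_radius:
            raise ValueError("central_spot_radius must exceed spot_radius")
        if self.image_size < 2 * self.central_spot_radius:
            raise ValueError("image_size too small for the central spot")


@dataclass(frozen=True)
class PhysicsConfig:
    """Diffraction physics: wavelength (Å), resolution and excitation cutoffs (Å⁻¹)."""

    wavelength: float = 0.0251
    g_max: float = 1.0
    s_max: float = 0.01

    def __post_init__(self) -> None:
        if min(self.wavelength, self.g_max, self.s_max) <= 0:
            raise ValueError("wavelength, g_max and s_max must be positive")


def electron_wavelength(accelerating_voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å for a voltage in kV.

    λ = h / sqrt(2·m₀·e·U·(1 + e·U / (2·m₀·c²))), CODATA constants.
    200 kV gives 0.0251 Å to four decimals.
    """
    if accelerating_voltage_kv <= 0:
        raise ValueError(
            f"accelerating voltage must be positive, got {accelerating_voltage_kv}")
    from scipy.constants import c, e, h, m_e
    U = accelerating_voltage_kv * 1e3
    lam_m = h / math.sqrt(2.0 * m_e * e * U * (1.0 + e * U / (2.0 * m_e * c ** 2)))
    return lam_m * 1e10


def fibonacci_sphere(n: int) -> list[Orientation]:
    """n near-uniform beam directions from the golden-angle spiral.

    Point i sits at z = 1 − (2i + 1)/n (evenly spaced in (−1, 1)) with
    azimuth i times the golden angle.  Deterministic for fixed n; in-plane
    angles are left at 0 (datasets randomize them separately).
    """
    if n < 1:
        raise ValueError(f"need at least one orientation, got n={n}")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = i * _GOLDEN_ANGLE
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return [Orientation(beam_direction=d, inplane_angle=0.0, orientation_id=int(k))
            for k, d in enumerate(dirs)]


def enumerate_candidate_hkl(basis: ReciprocalBasis, g_max: float,
                            cell: UnitCell | None = None) -> np.ndarray:
    """All nonzero integer triples with |g(hkl)| ≤ g_max, as an (n, 3) array.

    The per-index bound uses duality: h = g · a, so |h| ≤ g_max·|a| (and
    likewise for k, l), which cannot miss a reflection however oblique the
    cell.  Direct axis lengths are recovered from the reciprocal basis when
    ``cell`` is not supplied.
    """
    if g_max <= 0:
        raise ValueError("g_max must be positive")
    B = basis.matrix
    if cell is not None:
        lengths = np.array([cell.a, cell.b, cell.c])
    else:
        A = np.linalg.inv(B.T)  # direct basis rows
        lengths = np.linalg.norm(A, axis=1)
    bounds = np.floor(g_max * lengths + 1e-9).astype(int)
    h = np.arange(-bounds[0], bounds[0] + 1)
    k = np.arange(-bounds[1], bounds[1] + 1)
    l = np.arange(-bounds[2], bounds[2] + 1)
    H, K, L = np.meshgrid(h, k, l, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()]).astype(np.int64)
    g = hkl @ B
    keep = (np.einsum("ij,ij->i", g, g) <= g_max * g_max + 1e-12)
    keep &= np.any(hkl != 0, axis=1)
    return hkl[keep]


def excitation_errors(g: np.ndarray, beam_direction: np.ndarray,
                      wavelength: float) -> np.ndarray:
    """Signed excitation error for reciprocal vectors, along the beam.

    The Ewald sphere has radius R = 1/λ and is centred at −R·b̂.  For a
    lattice point g = g∥·b̂ + g⊥, the surface point along the beam through g
    satisfies (g∥ + s + R)² + |g⊥|² = R², giving

        s = −g∥ − R + sqrt(R² − |g⊥|²)

    (the branch on the origin side of the sphere).  For g ⊥ b̂ this is the
    sphere sag s ≈ −|g|²·λ/2.
    """
    g = np.atleast_2d(g)
    R = 1.0 / wavelength
    g_par = g @ beam_direction
    g_perp_sq = np.einsum("ij,ij->i", g, g) - g_par ** 2
    disc = np.maximum(R * R - g_perp_sq, 0.0)
    return -g_par - R + np.sqrt(disc)


def excited_reflections(basis: ReciprocalBasis, orientation: Orientation,
                        wavelength: float, g_max: float, s_max: float,
                        extinctions: Sequence[ExtinctionRule] = (),
                        candidates: np.ndarray | None = None) -> list[Reflection]:
    """Reflections with |g| ≤ g_max and |s| ≤ s_max for one orientation.

    ``candidates`` may carry a precomputed :func:`enumerate_candidate_hkl`
    result to amortize the enumeration across orientations of one cell.
    """
    if candidates is None:
        candidates = enumerate_candidate_hkl(basis, g_max)
    hkl = np.asarray(candidates, dtype=np.int64)
    if hkl.size == 0:
        return []
    keep = np.ones(len(hkl), dtype=bool)
    for rule in extinctions:
        keep &= ~rule.forbids(hkl)
    hkl = hkl[keep]
    g = hkl @ basis.matrix
    s = excitation_errors(g, orientation.beam_direction, wavelength)
    sel = np.abs(s) <= s_max
    hkl, g, s = hkl[sel], g[sel], s[sel]
    e1, e2 = orientation.detector_axes()
    xy = np.column_stack([g @ e1, g @ e2])
    return [Reflection(hkl=tuple(int(x) for x in t), g=gv, s=float(sv),
                       detector_xy=xyv)
            for t, gv, sv, xyv in zip(hkl, g, s, xy)]


def project_to_detector(g: np.ndarray, orientation: Orientation) -> np.ndarray:
    """Component of g perpendicular to the beam, in the rolled detector basis."""
    e1, e2 = orientation.detector_axes()
    g = np.asarray(g, dtype=float)
    return np.array([g @ e1, g @ e2])


def _disc_offsets(radius: int) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    mask = dx * dx + dy * dy <= radius * radius
    return np.column_stack([dy[mask], dx[mask]])


def _stamp(img: np.ndarray, cy: float, cx: float, offsets: np.ndarray,
           value: int) -> None:
    size = img.shape[0]
    py = int(round(cy)) + offsets[:, 0]
    px = int(round(cx)) + offsets[:, 1]
    ok = (py >= 0) & (py < size) & (px >= 0) & (px < size)
    img[py[ok], px[ok]] = value


def render_pattern(reflections: Sequence[Reflection], spec: RenderSpec) -> np.ndarray:
    """Render a binary (uint8, {0, 255}) square image of one pattern.

    Detector coordinates map linearly so ±gmax_to_edge spans the image;
    every reflection is a filled disc of ``spot_radius``; the central spot
    is always drawn at the image centre with the larger radius.  Discs
    falling (partly) outside the canvas are clipped silently.
    """
    size = spec.image_size
    img = np.full((size, size), spec.background, dtype=np.uint8)
    centre = (size - 1) / 2.0
    scale = (size / 2.0) / spec.gmax_to_edge
    spot = _disc_offsets(spec.spot_radius)
    for refl in reflections:
        x, y = refl.detector_xy
        # +y up in detector coordinates, rows grow downwards
        _stamp(img, centre - y * scale, centre + x * scale, spot, spec.foreground)
    _stamp(img, centre, centre, _disc_offsets(spec.central_spot_radius),
           spec.foreground)
    return img


def save_pattern_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(img, mode="L").save(path, format="PNG")


def simulate_patterns(cell: UnitCell, n_orientations: int,
                      physics: PhysicsConfig,
                      extinctions: Sequence[ExtinctionRule] = (),
                      rng: np.random.Generator | None = None) -> list[Pattern]:
    """Simulate the excited-reflection sets of one cell (no rendering).

    Beam directions come from :func:`fibonacci_sphere`; each orientation
    receives a uniformly random in-plane roll from ``rng`` (roll rotates the
    detector about the beam and can never change which reflections are
    excited).  Labels are left unset; see :mod:`edpat.zonal`.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    basis = reciprocal_basis(cell)
    candidates = enumerate_candidate_hkl(basis, physics.g_max, cell=cell)
    rolls = rng.uniform(0.0, 360.0, size=n_orientations)
    patterns = []
    for orient in fibonacci_sphere(n_orientations):
        orient = replace(orient, inplane_angle=float(rolls[orient.orientation_id]))
        refl = excited_reflections(basis, orient, physics.wavelength,
                                   physics.g_max, physics.s_max,
                                   extinctions=extinctions,
                                   candidates=candidates)
        patterns.append(Pattern(
            pattern_id=f"{cell.cell_id}_o{orient.orientation_id:05d}",
            cell_id=cell.cell_id, orientation=orient, reflections=refl))
    return patterns
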