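"""Curvature, ruled-surface and surface-torsion descriptors of helix pairs.

Given two polynomial axis models c₁(u), c₂(u) of the helices flanking a
binding groove, the module computes

- the curvature κ(u) = |c′ × c″| / |c′|³ of a single axis and its integral
  ∫κ ds (the total tangent turning angle — a global bending measure),
- a ruled surface: L = min(N₁, N₂) reference points, equidistant in each
  curve's own parameter, joined by straight rulings X = c₂ − c₁,
- the interhelical distance profile |X| and the triangulated surface area,
- the centre line m = ½(c₁ + c₂) and the surface torsion
  τ = (X × X′)·t / |X|² along it, with integral T = ∫τ du
  (τ > 0: right-handed twist, τ < 0: left-handed, τ = 0: developable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError, SingularGeometryError
from .polynomial import AxisPolynomial

__all__ = [
    "RuledSurface",
    "GrooveDescriptors",
    "curvature",
    "curvature_integral",
    "build_ruled_surface",
    "distance_profile",
    "distance_summary",
    "interhelical_area",
    "centre_line",
    "surface_torsion",
    "compute_groove_descriptors",
]

_ZERO_TANGENT = 1e-12


def curvature(poly: AxisPolynomial, u) -> np.ndarray:
    """Pointwise curvature κ(u) = |c′(u) × c″(u)| / |c′(u)|³ (1/nm)."""
    d1, d2 = poly.derivatives(u)
    d1 = np.atleast_2d(d1)
    d2 = np.atleast_2d(d2)
    speed = np.linalg.norm(d1, axis=-1)
    bad = speed < _ZERO_TANGENT
    if np.any(bad):
        u_bad = np.atleast_1d(np.asarray(u, dtype=float))[bad]
        raise SingularGeometryError(
            f"vanishing tangent c'(u) = 0 at u = {u_bad.tolist()}", u=u_bad
        )
    kappa = np.linalg.norm(np.cross(d1, d2), axis=-1) / speed**3
    return kappa if np.ndim(u) else float(kappa[0])


def curvature_integral(poly: AxisPolynomial, n_points: int = 100) -> float:
    """Total turning angle ∫ κ ds = ∫ κ(u) |c′(u)| du over the domain.

    Composite trapezoidal quadrature at ``n_points`` equidistant parameter
    values (default 100).  Dimensionless; equals the tangent turning angle for
    a planar curve, so a circular arc yields its subtended angle and a
    straight line yields 0.
    """
    if n_points < 2:
        raise InputError("n_points must be >= 2")
    u = np.linspace(poly.domain[0], poly.domain[1], n_points)
    kappa = curvature(poly, u)
    speed = np.linalg.norm(poly.derivative(u), axis=-1)
    return float(np.trapezoid(kappa * speed, u))


@dataclass
class RuledSurface:
    """Two axis polynomials joined by L rulings at matched reference points.

    ``q1``/``q2`` are the two curves reparametrized onto the common parameter
    s ∈ [1, L]; ``orientation_reversed`` records whether helix 2's parameter
    direction was flipped so both run the same way along the groove.
    """

    poly1: AxisPolynomial
    poly2: AxisPolynomial
    L: int
    u_grid1: np.ndarray
    u_grid2: np.ndarray
    q1: AxisPolynomial = field(repr=False)
    q2: AxisPolynomial = field(repr=False)
    orientation_reversed: bool = False
    degenerate_rulings: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def s_grid(self) -> np.ndarray:
        return np.linspace(1.0, float(self.L), self.L)

    @property
    def points1(self) -> np.ndarray:
        return self.q1(self.s_grid)

    @property
    def points2(self) -> np.ndarray:
        return self.q2(self.s_grid)

    @property
    def rulings(self) -> np.ndarray:
        """X(s) = c₂(s) − c₁(s) at the L matched reference points."""
        return self.points2 - self.points1


@dataclass
class GrooveDescriptors:
    """Scalar and profile shape descriptors of one helix pair (one frame)."""

    curvature_integral_1: float
    curvature_integral_2: float
    area: float
    distance_profile: np.ndarray
    torsion_profile: np.ndarray
    torsion_integral: float
    centreline_curvature_integral: float


def _domain_atoms(poly: AxisPolynomial) -> int:
    # domain [1, N] encodes the atom count N of the source helix
    return int(round(poly.domain[1]))


def build_ruled_surface(
    poly1: AxisPolynomial,
    poly2: AxisPolynomial,
    orientation_policy: str = "auto",
    L: Optional[int] = None,
) -> RuledSurface:
    """Match L = min(N₁, N₂) reference points, equidistant in each parameter.

    With ``orientation_policy="auto"`` helix 2's parameter direction is
    reversed whenever the end-to-end vectors of the two curves anti-align
    (negative dot product), so both run N→C of helix 1; ``"keep"`` and
    ``"reverse"`` force the respective choice.
    """
    if L is None:
        L = min(_domain_atoms(poly1), _domain_atoms(poly2))
    if L < 2:
        raise InputError(f"need at least 2 reference points, got L = {L}")

    e1 = poly1(poly1.domain[1]) - poly1(poly1.domain[0])
    e2 = poly2(poly2.domain[1]) - poly2(poly2.domain[0])
    if orientation_policy == "auto":
        reversed2 = bool(np.dot(e1, e2) < 0)
    elif orientation_policy == "keep":
        reversed2 = False
    elif orientation_policy == "reverse":
        reversed2 = True
    else:
        raise InputError(f"unknown orientation policy {orientation_policy!r}")

    u_grid1 = np.linspace(poly1.domain[0], poly1.domain[1], L)
    if reversed2:
        u_grid2 = np.linspace(poly2.domain[1], poly2.domain[0], L)
    else:
        u_grid2 = np.linspace(poly2.domain[0], poly2.domain[1], L)

    new_dom = (1.0, float(L))
    q1 = poly1.reparametrized(new_dom, (u_grid1[0], u_grid1[-1]))
    q2 = poly2.reparametrized(new_dom, (u_grid2[0], u_grid2[-1]))

    rulings = q2(np.linspace(1.0, float(L), L)) - q1(np.linspace(1.0, float(L), L))
    lengths = np.linalg.norm(rulings, axis=1)
    degenerate = np.nonzero(lengths < 1e-9)[0]
    return RuledSurface(
        poly1=poly1,
        poly2=poly2,
        L=L,
        u_grid1=u_grid1,
        u_grid2=u_grid2,
        q1=q1,
        q2=q2,
        orientation_reversed=reversed2,
        degenerate_rulings=degenerate,
    )


def distance_profile(surface: RuledSurface) -> np.ndarray:
    """Interhelical distances |X(u)| at the L matched reference points (nm)."""
    return np.linalg.norm(surface.rulings, axis=1)


def distance_summary(surface: RuledSurface) -> dict:
    """Median, quartiles and extremes of the interhelical distance profile."""
    d = distance_profile(surface)
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(d.min()),
        "max": float(d.max()),
    }


def _triangle_areas(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=-1)


def interhelical_area(surface: RuledSurface) -> float:
    """Area (nm²) of the triangulated ruled surface.

    Each quad between consecutive rulings is split along both diagonals and
    the two triangulations averaged, removing the arbitrariness of the
    diagonal choice; degenerate triangles contribute zero.
    """
    p1, p2 = surface.points1, surface.points2
    a, b = p1[:-1], p1[1:]
    c, d = p2[:-1], p2[1:]
    split1 = _triangle_areas(a, b, c) + _triangle_areas(b, d, c)
    split2 = _triangle_areas(a, b, d) + _triangle_areas(a, d, c)
    return float(0.5 * (split1.sum() + split2.sum()))


def centre_line(surface: RuledSurface) -> AxisPolynomial:
    """Centre line m(s) = ½(c₁(s) + c₂(s)) on the common parameter s ∈ [1, L]."""
    return 0.5 * (surface.q1 + surface.q2)


def surface_torsion(
    surface: RuledSurface, convention: str = "corrected"
) -> tuple[np.ndarray, float]:
    """Surface torsion profile τ(s) along the centre line and its integral T.

    τ(s) = (X × X′)·t / |X|² with X = c₂ − c₁ and t the unit tangent of the
    centre line; T = ∫ τ ds by trapezoidal quadrature on the L-point grid.
    ``convention="corrected"`` uses X′ = c₂′ − c₁′ (consistent with the
    definition of X); ``"printed"`` uses the alternative X′ = c₁′ + c₂′,
    which is parallel to the centre-line tangent and yields τ ≡ 0 — kept only
    for comparison.
    """
    s = surface.s_grid
    X = surface.rulings
    lengths2 = np.einsum("ij,ij->i", X, X)
    if np.any(lengths2 < 1e-18):
        idx = np.nonzero(lengths2 < 1e-18)[0]
        raise SingularGeometryError(
            f"zero-length ruling(s) at grid indices {idx.tolist()}", u=s[idx]
        )
    d1_1 = surface.q1.derivative(s)
    d1_2 = surface.q2.derivative(s)
    if convention == "corrected":
        Xp = d1_2 - d1_1
    elif convention == "printed":
        Xp = d1_2 + d1_1
    else:
        raise InputError(f"unknown torsion convention {convention!r}")
    m_tangent = 0.5 * (d1_1 + d1_2)
    norm_t = np.linalg.norm(m_tangent, axis=1)
    if np.any(norm_t < _ZERO_TANGENT):
        raise SingularGeometryError("vanishing centre-line tangent")
    t = m_tangent / norm_t[:, None]
    tau = np.einsum("ij,ij->i", np.cross(X, Xp), t) / lengths2
    T = float(np.trapezoid(tau, s))
    return tau, T


def compute_groove_descriptors(
    poly1: AxisPolynomial,
    poly2: AxisPolynomial,
    orientation_policy: str = "auto",
    n_points: int = 100,
    torsion_convention: str = "corrected",
) -> GrooveDescriptors:
    """All per-frame shape descriptors of a helix pair."""
    surface = build_ruled_surface(poly1, poly2, orientation_policy)
    tau, T = surface_torsion(surface, convention=torsion_convention)
    mid = centre_line(surface)
    return GrooveDescriptors(
        curvature_integral_1=curvature_integral(poly1, n_points),
        curvature_integral_2=curvature_integral(poly2, n_points),
        area=interhelical_area(surface),
        distance_profile=distance_profile(surface),
        torsion_profile=tau,
        torsion_integral=T,
        centreline_curvature_integral=curvature_integral(mid, n_points),
    )
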