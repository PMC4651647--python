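"""Synthetic α-helix models: ideal linear helices, the four-Cα fragment,
cosine-bent helices with a numeric curvature-integral reference, and hinged
helices with a known hinge angle.

An ideal α-helix is generated from three constants: the pitch ``p`` (axial
advance per residue, 0.15 nm), the helix radius ``r`` (0.23 nm) and the
rotation per residue ``phi`` (100°).  The k-th Cα atom sits at::

    (p·(k−1),  r·cos(phi·(k−1)),  r·sin(phi·(k−1))),   k = 1 … n

so the helix axis coincides with the x-axis.  Bent and hinged variants deform
this construction in controlled ways and carry the exact (or independently
computed high-resolution) value of the quantity a downstream detector is
supposed to recover.  All lengths are nanometres, all angles radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "IdealHelixParams",
    "HelixTrace",
    "HingeModel",
    "BentHelixModel",
    "build_ideal_fragment",
    "build_ideal_helix",
    "build_hinged_helix",
    "build_bent_helix",
    "build_arc_helix",
    "fragment_axis_points",
    "polyline_turning_angle",
]

#: default rotation per residue: 100 degrees, in radians
DEFAULT_PHI = 100.0 * np.pi / 180.0


@dataclass(frozen=True)
class IdealHelixParams:
    """Constants of the ideal α-helix construction.

    Parameters
    ----------
    pitch_p : float
        Axial advance from one Cα to the next, nm.  Default 0.15.
    radius_r : float
        Helix radius, nm.  Default 0.23.
    phi : float
        Rotation per residue about the axis, radians.  Default 100°.
    n_atoms : int
        Number of Cα atoms (≥ 4).
    """

    pitch_p: float = 0.15
    radius_r: float = 0.23
    phi: float = DEFAULT_PHI
    n_atoms: int = 4

    def __post_init__(self):
        if not self.pitch_p >= 0.0:
            raise ParameterError(f"pitch_p must be >= 0, got {self.pitch_p}")
        if not self.radius_r > 0.0:
            raise ParameterError(f"radius_r must be > 0, got {self.radius_r}")
        if self.n_atoms < 4:
            raise ParameterError(f"n_atoms must be >= 4, got {self.n_atoms}")


@dataclass
class HelixTrace:
    """Ordered Cα coordinates (nm) of one helix segment in one frame."""

    coords: np.ndarray
    residue_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ParameterError(
                f"coords must be an (N, 3) array, got shape {self.coords.shape}"
            )
        if self.residue_ids is not None:
            self.residue_ids = np.asarray(self.residue_ids)
            if len(self.residue_ids) != len(self.coords):
                raise ParameterError("residue_ids length must match coords")
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if len(d) and d.min() <= 0.0:
            raise ParameterError("consecutive coordinates must be distinct")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "HelixTrace":
        """Return a copy moved by the rigid motion x ↦ R·x + t."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return HelixTrace(self.coords @ R.T + t, self.residue_ids)

    def to_csv(self, path) -> None:
        from .io import trace_to_csv

        trace_to_csv(self, path)

    def to_pdb(self, path) -> None:
        from .io import write_structure

        write_structure(path, self.coords[None, :, :], residue_ids=self.residue_ids)


@dataclass
class HingeModel:
    """Two ideal helical legs sharing a pivot Cα, meeting at a known angle."""

    trace: HelixTrace
    hinge_index: int
    hinge_angle: float
    #: unit direction of the first leg's axis (analytic)
    leg1_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    #: unit direction of the second leg's axis (analytic)
    leg2_direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    @property
    def turning_angle(self) -> float:
        """Angle between the two analytic leg-axis directions."""
        c = float(np.clip(np.dot(self.leg1_direction, self.leg2_direction), -1.0, 1.0))
        return float(np.arccos(c))


@dataclass
class BentHelixModel:
    """Helix wound around a curved axis, with a reference curvature integral.

    ``reference_curvature_integral`` is the total turning angle of the analytic
    bent axis over the atom-covered arc, obtained from a dense polyline
    (independent of any axis-detection machinery downstream).
    """

    trace: HelixTrace
    reference_curvature_integral: float
    axis_samples: np.ndarray = field(repr=False, default=None)


def fragment_axis_points(params: IdealHelixParams) -> np.ndarray:
    """The three axis points of the four-Cα fragment: initial, intermediate, final."""
    p = params.pitch_p
    return np.array([[0.0, 0.0, 0.0], [1.5 * p, 0.0, 0.0], [3.0 * p, 0.0, 0.0]])


def _ideal_coords(params: IdealHelixParams) -> np.ndarray:
    k = np.arange(params.n_atoms, dtype=float)  # k-1 in 1-based notation
    return np.column_stack(
        [
            params.pitch_p * k,
            params.radius_r * np.cos(params.phi * k),
            params.radius_r * np.sin(params.phi * k),
        ]
    )


def build_ideal_fragment(params: Optional[IdealHelixParams] = None) -> HelixTrace:
    """Ideal one-turn fragment of four Cα atoms, axis on the x-axis."""
    if params is None:
        params = IdealHelixParams()
    if params.n_atoms != 4:
        params = IdealHelixParams(params.pitch_p, params.radius_r, params.phi, 4)
    return HelixTrace(_ideal_coords(params))


def build_ideal_helix(params: Optional[IdealHelixParams] = None, n_atoms: Optional[int] = None) -> HelixTrace:
    """Ideal linear α-helix of ``n_atoms`` Cα atoms along the x-axis."""
    if params is None:
        params = IdealHelixParams(n_atoms=n_atoms if n_atoms is not None else 31)
    elif n_atoms is not None and n_atoms != params.n_atoms:
        params = IdealHelixParams(params.pitch_p, params.radius_r, params.phi, n_atoms)
    return HelixTrace(_ideal_coords(params), residue_ids=np.arange(1, params.n_atoms + 1))


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def build_hinged_helix(
    n_atoms: int = 31,
    hinge_index: int = 10,
    hinge_angle: float = 0.0,
    rotation_axis: Sequence[float] = (0.0, 0.0, 1.0),
    params: Optional[IdealHelixParams] = None,
) -> HingeModel:
    """Ideal helix kinked at one pivot Cα.

    Atoms 1…hinge_index (1-based) keep the ideal-helix positions; atoms
    hinge_index…n_atoms are rigidly rotated about the pivot Cα by
    ``hinge_angle`` around ``rotation_axis`` (must be perpendicular to the
    original x-axis of the helix).  The angle between the two leg axes equals
    ``hinge_angle`` exactly.
    """
    if params is None:
        params = IdealHelixParams(n_atoms=n_atoms)
    else:
        params = IdealHelixParams(params.pitch_p, params.radius_r, params.phi, n_atoms)
    if not (4 <= hinge_index <= n_atoms - 4):
        raise ParameterError(
            f"hinge_index must lie in [4, n_atoms-4] so both legs support a "
            f"fragment fit; got {hinge_index} for {n_atoms} atoms"
        )
    if not (0.0 <= hinge_angle <= np.pi / 2 + 1e-12):
        raise ParameterError(f"hinge_angle must be in [0, pi/2], got {hinge_angle}")
    axis = np.asarray(rotation_axis, dtype=float)
    if abs(axis[0]) > 1e-9 * np.linalg.norm(axis):
        raise ParameterError("rotation_axis must be perpendicular to the helix x-axis")

    coords = _ideal_coords(params)
    pivot = coords[hinge_index - 1]
    R = _rotation_about_axis(axis, hinge_angle)
    moved = coords.copy()
    moved[hinge_index - 1 :] = (coords[hinge_index - 1 :] - pivot) @ R.T + pivot
    trace = HelixTrace(moved, residue_ids=np.arange(1, n_atoms + 1))
    return HingeModel(
        trace=trace,
        hinge_index=hinge_index,
        hinge_angle=float(hinge_angle),
        leg1_direction=np.array([1.0, 0.0, 0.0]),
        leg2_direction=R @ np.array([1.0, 0.0, 0.0]),
    )


def polyline_turning_angle(points: np.ndarray) -> float:
    """Sum of turning angles between successive segments of a polyline.

    For a dense sampling of a smooth curve this converges to ∫κ ds, the total
    tangent turning angle; it is the brute-force reference used for bent-axis
    models.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.diff(pts, axis=0)
    norms = np.linalg.norm(seg, axis=1)
    keep = norms > 0
    seg = seg[keep] / norms[keep][:, None]
    dots = np.clip(np.einsum("ij,ij->i", seg[:-1], seg[1:]), -1.0, 1.0)
    return float(np.arccos(dots).sum())


def _parallel_transport_frames(axis_pts: np.ndarray):
    """Tangents and a rotation-minimizing normal pair along a dense polyline."""
    tangents = np.gradient(axis_pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]
    n1 = np.empty_like(tangents)
    # seed normal: any vector not parallel to the first tangent
    seed = np.array([0.0, 1.0, 0.0])
    if abs(np.dot(seed, tangents[0])) > 0.9:
        seed = np.array([0.0, 0.0, 1.0])
    v = seed - np.dot(seed, tangents[0]) * tangents[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, len(tangents)):
        v = n1[i - 1] - np.dot(n1[i - 1], tangents[i]) * tangents[i]
        n1[i] = v / np.linalg.norm(v)
    n2 = np.cross(tangents, n1)
    return tangents, n1, n2


def _wind_around_axis(axis_pts: np.ndarray, params: IdealHelixParams) -> np.ndarray:
    """Place Cα atoms around a densely sampled axis, preserving local
    pitch/radius/phase via parallel transport of the initial radial frame."""
    seg = np.linalg.norm(np.diff(axis_pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    s_atoms = params.pitch_p * np.arange(params.n_atoms)
    if s_atoms[-1] > s[-1] + 1e-9:
        raise ParameterError("axis sampling too short for the requested helix")
    _, n1, n2 = _parallel_transport_frames(axis_pts)

    def interp(arr):
        return np.column_stack([np.interp(s_atoms, s, arr[:, j]) for j in range(3)])

    centre = interp(axis_pts)
    e1 = interp(n1)
    e2 = interp(n2)
    # renormalize the interpolated frame
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 -= np.einsum("ij,ij->i", e2, e1)[:, None] * e1
    e2 /= np.linalg.norm(e2, axis=1)[:, None]
    k = np.arange(params.n_atoms, dtype=float)
    r = params.radius_r
    return centre + r * np.cos(params.phi * k)[:, None] * e1 + r * np.sin(params.phi * k)[:, None] * e2


def build_bent_helix(
    n_atoms: int = 31,
    bend_amplitude: float = 0.1,
    bend_wavelength: Optional[float] = None,
    params: Optional[IdealHelixParams] = None,
    oracle_samples: int = 20001,
) -> BentHelixModel:
    """Helix whose straight axis is bent along a cosine.

    The straight axis x ↦ (x, 0, 0) is replaced by x ↦ (x, A·cos(2πx/λ), 0);
    by default λ spans the full helix length (one cosine period).  Atoms are
    wound around the curved axis at arc-length spacing ``pitch_p``.  The
    reference curvature integral is the turning-angle sum of a dense polyline
    sampling of the analytic axis over the atom-covered arc.
    """
    if params is None:
        params = IdealHelixParams(n_atoms=n_atoms)
    else:
        params = IdealHelixParams(params.pitch_p, params.radius_r, params.phi, n_atoms)
    if bend_amplitude < 0:
        raise ParameterError(f"bend_amplitude must be >= 0, got {bend_amplitude}")
    length = params.pitch_p * (n_atoms - 1)
    lam = bend_wavelength if bend_wavelength is not None else length
    if lam <= 0:
        raise ParameterError("bend_wavelength must be > 0")

    # oversample in x beyond the straight length: arc length >= x extent
    x = np.linspace(0.0, 1.05 * length + 10 * lam / oracle_samples, oracle_samples)
    axis_pts = np.column_stack(
        [x, bend_amplitude * np.cos(2.0 * np.pi * x / lam), np.zeros_like(x)]
    )
    coords = _wind_around_axis(axis_pts, params)

    # reference: dense polyline turning angle over the atom-covered arc length
    seg = np.linalg.norm(np.diff(axis_pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    covered = axis_pts[s <= params.pitch_p * (n_atoms - 1) + 1e-12]
    reference = polyline_turning_angle(covered)
    return BentHelixModel(
        trace=HelixTrace(coords, residue_ids=np.arange(1, n_atoms + 1)),
        reference_curvature_integral=reference,
        axis_samples=covered,
    )


def build_arc_helix(
    n_atoms: int = 31,
    subtended_angle: float = 0.5,
    params: Optional[IdealHelixParams] = None,
    oracle_samples: int = 20001,
) -> BentHelixModel:
    """Helix wound around a circular arc of known subtended angle.

    The arc radius follows from the helix length: R = L/θ with
    L = p·(n_atoms−1).  The exact curvature integral ∫κ ds of the axis is the
    subtended angle θ, which is stored as the reference.
    """
    if params is None:
        params = IdealHelixParams(n_atoms=n_atoms)
    else:
        params = IdealHelixParams(params.pitch_p, params.radius_r, params.phi, n_atoms)
    if subtended_angle <= 0:
        raise ParameterError("subtended_angle must be > 0")
    length = params.pitch_p * (n_atoms - 1)
    R = length / subtended_angle
    theta = np.linspace(0.0, 1.02 * subtended_angle, oracle_samples)
    axis_pts = np.column_stack(
        [R * np.sin(theta), R * (1.0 - np.cos(theta)), np.zeros_like(theta)]
    )
    coords = _wind_around_axis(axis_pts, params)
    return BentHelixModel(
        trace=HelixTrace(coords, residue_ids=np.arange(1, n_atoms + 1)),
        reference_curvature_integral=float(subtended_angle),
        axis_samples=axis_pts,
    )
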