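"""Trace the axis of an α-helix by fragment fitting.

An ideal one-turn fragment of four Cα atoms is superimposed, in a
least-squares sense, onto every window of four consecutive Cα atoms of the
helix.  The fragment carries three points on its own axis (initial,
intermediate at 1.5·p, final at 3·p); transforming these by each fitted rigid
motion and adopting the initial point of the first window, the intermediate
point of every window, and the final point of the last window yields N−1
estimates a₁ … a_{N−1} of the helix axis, paired with the non-uniform
parameter grid u = 1, 2.5, 3.5, …, N−1.5, N.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InputError
from .synthetic import HelixTrace, IdealHelixParams, build_ideal_fragment, fragment_axis_points

__all__ = [
    "SuperpositionResult",
    "AxisPoints",
    "superpose_points",
    "superpose_fragment",
    "extract_axis",
    "axis_u_grid",
    "helix_axis_statistics",
]


@dataclass
class SuperpositionResult:
    """Proper rigid transform x ↦ R·x + t and the residual RMSD of a fit."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    #: True when the optimal rotation was not unique (degenerate point set)
    degenerate: bool = False

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


@dataclass
class AxisPoints:
    """The N−1 fragment-fitted axis points with their parameter values."""

    points: np.ndarray
    u_values: np.ndarray
    source_n_atoms: int

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.u_values = np.asarray(self.u_values, dtype=float)
        if len(self.points) != len(self.u_values):
            raise InputError("points and u_values must have equal length")
        if len(self.points) != self.source_n_atoms - 1:
            raise InputError("expected N-1 axis points for an N-atom helix")
        if np.any(np.diff(self.u_values) <= 0):
            raise InputError("u_values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "AxisPoints":
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return AxisPoints(self.points @ R.T + t, self.u_values, self.source_n_atoms)

    def to_csv(self, path) -> None:
        from .io import axis_points_to_csv

        axis_points_to_csv(self, path)

    def to_pdb(self, path) -> None:
        from .io import axis_points_to_pdb

        axis_points_to_pdb(self, path)


def axis_u_grid(n_atoms: int) -> np.ndarray:
    """The parameter grid u = 1, 2.5, 3.5, …, N−1.5, N (length N−1)."""
    if n_atoms < 4:
        raise InputError(f"need at least 4 atoms, got {n_atoms}")
    return np.concatenate(
        [[1.0], np.arange(2, n_atoms - 1, dtype=float) + 0.5, [float(n_atoms)]]
    )


def superpose_points(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch) of two matched point sets.

    Returns the proper rotation (det = +1, reflections excluded by the
    determinant correction) and translation minimizing
    Σ|R·mobile_i + t − target_i|², plus the residual RMSD.  The SVD makes the
    result deterministic also for degenerate (e.g. collinear) inputs, which
    are flagged.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise InputError("point sets must be matched (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:  # fully degenerate covariance
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    degenerate = bool(S[-1] <= 1e-12 * max(S[0], 1e-300))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd, degenerate=degenerate)


def superpose_fragment(fragment: HelixTrace, window: HelixTrace) -> SuperpositionResult:
    """Superpose a four-Cα fragment onto a four-Cα window (sequence order kept)."""
    if fragment.n_atoms != 4 or window.n_atoms != 4:
        raise InputError("fragment and window must each have exactly 4 atoms")
    return superpose_points(fragment.coords, window.coords)


def extract_axis(
    helix: HelixTrace, params: Optional[IdealHelixParams] = None
) -> AxisPoints:
    """Fragment-fit the helix and adopt transformed fragment-axis points.

    Window i covers atoms i…i+3 (1-based); the first window contributes its
    transformed initial and intermediate axis points, every window its
    intermediate point, and the last window additionally its final point —
    N−1 points in total for N atoms.
    """
    N = helix.n_atoms
    if N < 4:
        raise InputError(f"axis extraction needs N >= 4 atoms, got {N}")
    if params is None:
        params = IdealHelixParams()
    fragment = build_ideal_fragment(params)
    axis_ref = fragment_axis_points(params)

    points = []
    n_windows = N - 3
    for i in range(n_windows):
        window = helix.coords[i : i + 4]
        fit = superpose_points(fragment.coords, window)
        tp = fit.apply(axis_ref)
        if i == 0:
            points.append(tp[0])
        points.append(tp[1])
        if i == n_windows - 1:
            points.append(tp[2])
    return AxisPoints(np.asarray(points), axis_u_grid(N), source_n_atoms=N)


def helix_axis_statistics(helix: HelixTrace, axis: Optional[AxisPoints] = None) -> dict:
    """Per-helix calibration statistics of the fragment-fitted axis.

    Fits a straight line (degree-1 polynomial) to the axis points and reports

    - ``interior_spacing_nm``: mean distance between consecutive interior axis
      points (the first and last gaps are 1.5× by construction and excluded),
    - ``radius_nm``: mean perpendicular Cα-to-axis distance,
    - ``twist_deg``: mean angle between successive Cα radial vectors about the
      axis, in degrees.

    On an ideal helix these recover pitch, radius and rotation per residue.
    """
    from .polynomial import fit_axis_polynomial

    if axis is None:
        axis = extract_axis(helix)
    gaps = np.linalg.norm(np.diff(axis.points, axis=0), axis=1)
    interior = gaps[1:-1] if len(gaps) > 2 else gaps

    line = fit_axis_polynomial(axis, degree=1)
    origin = line(axis.u_values[0])
    direction = line.derivative(float(axis.u_values[0]))
    direction = direction / np.linalg.norm(direction)

    rel = helix.coords - origin
    radial = rel - np.outer(rel @ direction, direction)
    radii = np.linalg.norm(radial, axis=1)
    unit = radial / radii[:, None]
    dots = np.clip(np.einsum("ij,ij->i", unit[:-1], unit[1:]), -1.0, 1.0)
    twist = np.degrees(np.arccos(dots))
    return {
        "interior_spacing_nm": float(interior.mean()),
        "radius_nm": float(radii.mean()),
        "twist_deg": float(twist.mean()),
    }
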