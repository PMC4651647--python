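"""Polynomial-degree selection study on synthetic bending and hinge motions.

For every combination of motion magnitude and polynomial degree 1–8, a
synthetic helix is built, its axis fragment-fitted, a polynomial of the given
degree fitted and the curvature integral computed at 100 equidistant points.
The relative error against the known reference,

    η_bending = ∫κ_detector / ∫κ_reference − 1
    η_hinge   = ∫κ_detector / α_hinge − 1,

quantifies how well each degree recovers the predefined motion; η = −1 means
the detector returned zero on a nonzero reference (as any degree-1 model
must, since straight lines carry no curvature).
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .axis import extract_axis
from .errors import ParameterError
from .geometry import curvature_integral
from .polynomial import fit_axis_polynomial
from .synthetic import HelixTrace, build_bent_helix, build_hinged_helix

__all__ = [
    "DegreeSweepResult",
    "detector_curvature_integral",
    "bending_sweep",
    "hinge_sweep",
    "default_amplitude_grid",
    "default_angle_grid",
]

DEGREES = tuple(range(1, 9))


def default_amplitude_grid(n: int = 10) -> np.ndarray:
    """Log-spaced cosine-bend amplitudes, 0.02–0.6 nm.

    Spans gentle ripples (reference turning angle ≈ 0.1 rad) to deep bends
    (≈ 3 rad), the same order of magnitude as the hinge-angle grid.
    """
    return np.geomspace(0.02, 0.6, n)


def default_angle_grid(n: int = 10) -> np.ndarray:
    """Equidistant hinge angles in (0, π/2] (0 excluded: η is 0/0 there)."""
    return np.linspace(np.pi / 2 / n, np.pi / 2, n)


@dataclass
class DegreeSweepResult:
    """Tidy table of relative errors η per degree and motion point."""

    motion: str
    table: pd.DataFrame

    def mean_abs_eta(self) -> pd.Series:
        """Mean |η| per polynomial degree over the whole motion grid."""
        return self.table.groupby("degree")["eta"].apply(lambda e: e.abs().mean())

    def summary(self) -> dict:
        return {
            "motion": self.motion,
            "mean_abs_eta_by_degree": {
                int(k): float(v) for k, v in self.mean_abs_eta().items()
            },
        }


def detector_curvature_integral(
    trace: HelixTrace, degree: int, n_points: int = 100
) -> float:
    """Full detection pipeline: fragment-fit axis → polynomial → ∫κ ds."""
    poly = fit_axis_polynomial(extract_axis(trace), degree)
    return curvature_integral(poly, n_points=n_points)


def bending_sweep(
    amplitudes: Optional[Sequence[float]] = None,
    degrees: Sequence[int] = DEGREES,
    n_atoms: int = 31,
    n_points: int = 100,
) -> DegreeSweepResult:
    """Relative error of the detected curvature integral for cosine bends."""
    if amplitudes is None:
        amplitudes = default_amplitude_grid()
    rows = []
    for amp in amplitudes:
        if amp <= 0:
            _warnings.warn(
                f"amplitude {amp} has zero reference; point excluded", stacklevel=2
            )
            continue
        model = build_bent_helix(n_atoms=n_atoms, bend_amplitude=float(amp))
        ref = model.reference_curvature_integral
        for deg in degrees:
            det = detector_curvature_integral(model.trace, deg, n_points)
            rows.append(
                {
                    "degree": deg,
                    "amplitude": float(amp),
                    "reference": ref,
                    "detector": det,
                    "eta": det / ref - 1.0,
                }
            )
    return DegreeSweepResult("bending", pd.DataFrame(rows))


def hinge_sweep(
    hinge_indices: Sequence[int] = tuple(range(5, 16)),
    angles: Optional[Sequence[float]] = None,
    degrees: Sequence[int] = DEGREES,
    n_atoms: int = 31,
    n_points: int = 100,
) -> DegreeSweepResult:
    """Relative error of the detected curvature integral for hinge motions.

    The hinge position sweeps the pivot Cα over ``hinge_indices`` so legs of
    unequal length are probed; the hinge angle α itself is the reference.
    """
    if angles is None:
        angles = default_angle_grid()
    rows = []
    for idx in hinge_indices:
        for ang in angles:
            if ang <= 0:
                _warnings.warn(
                    "hinge angle 0 has zero reference; point excluded", stacklevel=2
                )
                continue
            model = build_hinged_helix(
                n_atoms=n_atoms, hinge_index=int(idx), hinge_angle=float(ang)
            )
            for deg in degrees:
                det = detector_curvature_integral(model.trace, deg, n_points)
                rows.append(
                    {
                        "degree": deg,
                        "hinge_index": int(idx),
                        "hinge_angle": float(ang),
                        "reference": float(ang),
                        "detector": det,
                        "eta": det / float(ang) - 1.0,
                    }
                )
    return DegreeSweepResult("hinge", pd.DataFrame(rows))
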