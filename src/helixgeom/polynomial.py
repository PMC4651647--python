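"""Polynomial models of the helix axis.

Separate least-squares polynomials f_x, f_y, f_z of a common degree m are
fitted to the axis points over their non-uniform parameter grid
u = 1, 2.5, …, N−1.5, N, giving a continuous curve c(u) = (f_x, f_y, f_z)
on the domain [1, N] with analytic first and second derivatives.  The model
has 3·(m+1) parameters.

Internally the fit and all evaluations use a centred/scaled parameter
s = (u − mid)/half ∈ [−1, 1] for numerical conditioning (degree 8 on a raw
u-grid reaching into the tens is badly conditioned); coefficients are
converted to the raw power basis only for export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from numpy.polynomial import polynomial as npoly

from .axis import AxisPoints
from .errors import DomainError, InputError

__all__ = ["AxisPolynomial", "fit_axis_polynomial"]

_DOMAIN_TOL = 1e-9


def _affine_compose(coef: np.ndarray, a: float, b: float) -> np.ndarray:
    """Coefficients (ascending) of p(a + b·t) given those of p(u)."""
    res = np.zeros(1)
    for c in np.asarray(coef, dtype=float)[::-1]:
        res = npoly.polyadd(npoly.polymul(res, [a, b]), [c])
    out = np.zeros(len(coef))
    out[: len(res)] = res
    return out


@dataclass
class AxisPolynomial:
    """Three per-coordinate polynomials of common degree on a domain [u_min, u_max].

    Attributes
    ----------
    scaled_coeffs : (3, m+1) array
        Ascending coefficients in the internal scaled parameter s ∈ [−1, 1].
    domain : (float, float)
        Parameter domain; evaluation outside it raises :class:`DomainError`.
    rss : (3,) array or None
        Residual sum of squares per coordinate, set when produced by a fit.
    """

    scaled_coeffs: np.ndarray
    domain: Tuple[float, float]
    rss: Optional[np.ndarray] = None
    _deriv_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.scaled_coeffs = np.atleast_2d(np.asarray(self.scaled_coeffs, dtype=float))
        if self.scaled_coeffs.shape[0] != 3:
            raise InputError("scaled_coeffs must have shape (3, m+1)")
        lo, hi = self.domain
        if not hi > lo:
            raise InputError("domain must satisfy u_max > u_min")
        self.domain = (float(lo), float(hi))

    # -- basic descriptors -------------------------------------------------
    @property
    def degree(self) -> int:
        return self.scaled_coeffs.shape[1] - 1

    @property
    def n_parameters(self) -> int:
        return 3 * (self.degree + 1)

    @property
    def _mid(self) -> float:
        return 0.5 * (self.domain[0] + self.domain[1])

    @property
    def _half(self) -> float:
        return 0.5 * (self.domain[1] - self.domain[0])

    @property
    def coefficients(self) -> np.ndarray:
        """(3, m+1) raw power-basis coefficients in u, ascending order."""
        a, b = -self._mid / self._half, 1.0 / self._half
        return np.vstack([_affine_compose(c, a, b) for c in self.scaled_coeffs])

    # -- evaluation --------------------------------------------------------
    def _to_s(self, u):
        u = np.asarray(u, dtype=float)
        lo, hi = self.domain
        span = hi - lo
        if np.any(u < lo - _DOMAIN_TOL * span) or np.any(u > hi + _DOMAIN_TOL * span):
            raise DomainError(f"u outside domain [{lo}, {hi}]")
        return (u - self._mid) / self._half

    def evaluate(self, u):
        """c(u); returns (3,) for scalar u, (n, 3) for a grid."""
        s = self._to_s(u)
        vals = np.stack([npoly.polyval(s, c) for c in self.scaled_coeffs], axis=-1)
        return vals

    __call__ = evaluate

    def _deriv_coeffs(self, order: int) -> np.ndarray:
        if order not in self._deriv_cache:
            cs = np.vstack(
                [
                    np.pad(npoly.polyder(c, order), (0, order))
                    for c in self.scaled_coeffs
                ]
            )
            # chain rule: d/du = (1/half) d/ds
            self._deriv_cache[order] = cs / self._half**order
        return self._deriv_cache[order]

    def derivative(self, u, order: int = 1):
        """Analytic derivative d^order c / du^order at u."""
        s = self._to_s(u)
        cs = self._deriv_coeffs(order)
        return np.stack([npoly.polyval(s, c) for c in cs], axis=-1)

    def derivatives(self, u):
        """(c′(u), c″(u)) by analytic differentiation of the coefficients."""
        return self.derivative(u, 1), self.derivative(u, 2)

    # -- algebra on a shared domain ---------------------------------------
    def _check_same_domain(self, other: "AxisPolynomial"):
        if not np.allclose(self.domain, other.domain):
            raise InputError("polynomials must share a domain for arithmetic")

    def __add__(self, other: "AxisPolynomial") -> "AxisPolynomial":
        self._check_same_domain(other)
        m = max(self.degree, other.degree)
        a = np.pad(self.scaled_coeffs, ((0, 0), (0, m - self.degree)))
        b = np.pad(other.scaled_coeffs, ((0, 0), (0, m - other.degree)))
        return AxisPolynomial(a + b, self.domain)

    def __sub__(self, other: "AxisPolynomial") -> "AxisPolynomial":
        return self + (other * -1.0)

    def __mul__(self, scalar: float) -> "AxisPolynomial":
        return AxisPolynomial(self.scaled_coeffs * float(scalar), self.domain)

    __rmul__ = __mul__

    def reparametrized(
        self, new_domain: Tuple[float, float], u_at_ends: Tuple[float, float]
    ) -> "AxisPolynomial":
        """Affine change of parameter: the new parameter runs over
        ``new_domain`` while u runs (affinely) from ``u_at_ends[0]`` to
        ``u_at_ends[1]``.  The curve in space is unchanged."""
        lo, hi = new_domain
        u0, u1 = u_at_ends
        # map new scaled t in [-1,1] -> u -> old scaled s, all affine
        mid_new, half_new = 0.5 * (lo + hi), 0.5 * (hi - lo)

        def u_of_new(x):
            return u0 + (x - lo) * (u1 - u0) / (hi - lo)

        s_at = lambda x: (u_of_new(x) - self._mid) / self._half
        s0 = s_at(mid_new - half_new)
        s1 = s_at(mid_new + half_new)
        alpha, beta = 0.5 * (s0 + s1), 0.5 * (s1 - s0)
        coeffs = np.vstack(
            [_affine_compose(c, alpha, beta) for c in self.scaled_coeffs]
        )
        return AxisPolynomial(coeffs, (lo, hi))

    # -- serialisation -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "degree": self.degree,
            "domain": list(self.domain),
            "coefficients": self.coefficients.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "AxisPolynomial":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls.from_coefficients(np.asarray(payload["coefficients"]), tuple(payload["domain"]))

    @classmethod
    def from_coefficients(cls, raw_coeffs, domain) -> "AxisPolynomial":
        """Build from raw power-basis coefficients in u (ascending, (3, m+1))."""
        raw = np.atleast_2d(np.asarray(raw_coeffs, dtype=float))
        lo, hi = float(domain[0]), float(domain[1])
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        scaled = np.vstack([_affine_compose(c, mid, half) for c in raw])
        return cls(scaled, (lo, hi))


def fit_axis_polynomial(axis: AxisPoints, degree: int) -> AxisPolynomial:
    """Ordinary least squares fit of degree-``degree`` polynomials, one per
    coordinate, over the axis points' own u grid.

    The domain is [u₁, u_{N−1}] = [1, N].  Raises :class:`InputError` when the
    system is underdetermined (< degree+1 points).  The per-coordinate
    residual sums of squares are stored on the result as ``rss``.
    """
    if degree < 1:
        raise InputError(f"degree must be >= 1, got {degree}")
    n = len(axis)
    if n < degree + 1:
        raise InputError(
            f"need at least degree+1 = {degree + 1} axis points, got {n}"
        )
    u = axis.u_values
    lo, hi = float(u[0]), float(u[-1])
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    s = (u - mid) / half
    # polyfit solves via SVD-backed lstsq on the Vandermonde matrix: well
    # behaved also for near-singular normal equations
    coeffs = npoly.polyfit(s, axis.points, degree)
    resid = axis.points - np.stack(
        [npoly.polyval(s, coeffs[:, j]) for j in range(3)], axis=-1
    )
    rss = np.sum(resid**2, axis=0)
    poly = AxisPolynomial(coeffs.T.copy(), (lo, hi), rss=rss)
    return poly
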