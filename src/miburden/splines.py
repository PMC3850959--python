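"""Penalized-spline design for smoothing log rates over the age-group index.

The age covariate is the centred, scaled group index x_i = (i - 10)/19,
i = 1..19.  Smooth curves are written in mixed-model form

    f(x_i) = phi0 + phi1 * x_i + sum_k Z_ik psi_k,

where phi0, phi1 are fixed effects and the psi_k are i.i.d. Normal(0, s^2)
random effects.  Z is the O'Sullivan basis: cubic B-splines on the interior
knots, linearly transformed so the penalty  integral f''(x)^2 dx  equals
||psi||^2.  The constant and linear directions (the penalty's null space)
are removed from Z and live entirely in the fixed part.

Construction follows the standard recipe: build the full cubic B-spline
design B and the exact second-derivative penalty Omega (Gauss-Legendre per
inter-knot interval, exact for the piecewise-quadratic integrand products),
spectrally decompose Omega = U diag(d) U', and set
Z = B U_+ diag(d_+^{-1/2}) over the positive eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .agegrid import AgeGrid

DEFAULT_KNOT_AGES: tuple[float, ...] = (45.0, 55.0, 65.0, 75.0)

_DEGREE = 3  # cubic


def age_index_covariate(indices: np.ndarray) -> np.ndarray:
    """x_i = (i - 10)/19 for 1-based age-group indices i."""
    return (np.asarray(indices, dtype=float) - 10.0) / 19.0


@dataclass(frozen=True)
class SplineBasis:
    """Design pieces for one smoothed age curve.

    x           covariate values, one per fitted age group
    Z           (n_ages, K_b) O'Sullivan random-effect basis
    knot_ages   interior knot positions in years
    age_indices 1-based indices of the age groups covered (19 by default)
    """

    x: np.ndarray
    Z: np.ndarray
    knot_ages: tuple[float, ...]
    age_indices: np.ndarray

    @property
    def K_b(self) -> int:
        return self.Z.shape[1]

    @property
    def n_ages(self) -> int:
        return self.x.shape[0]

    @property
    def X(self) -> np.ndarray:
        """Fixed-effect design [1, x]."""
        return np.column_stack([np.ones_like(self.x), self.x])

    def linear_predictor(self, phi0: float, phi1: float, psi: np.ndarray) -> np.ndarray:
        """phi0 + phi1 * x + Z @ psi, elementwise over the age groups."""
        psi = np.asarray(psi, dtype=float)
        if psi.shape != (self.K_b,):
            raise ValueError(f"psi must have length {self.K_b}, got shape {psi.shape}")
        return phi0 + phi1 * self.x + self.Z @ psi

    def to_frame(self):
        """Export x and Z as a pandas DataFrame for inspection."""
        import pandas as pd

        cols = {"age_index": self.age_indices, "x": self.x}
        for k in range(self.K_b):
            cols[f"Z{k + 1}"] = self.Z[:, k]
        return pd.DataFrame(cols)


def _bspline_design(x: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full cubic B-spline design on [a, b] with the given interior knots.

    Returns (B, t) where t is the padded knot vector.
    """
    a, b = x.min(), x.max()
    t = np.concatenate([[a] * (_DEGREE + 1), knots, [b] * (_DEGREE + 1)])
    B = BSpline.design_matrix(x, t, _DEGREE, extrapolate=False).toarray()
    return B, t


def _second_derivative_penalty(t: np.ndarray) -> np.ndarray:
    """Omega_kl = integral B_k''(x) B_l''(x) dx, exact by Gauss-Legendre."""
    n_basis = len(t) - _DEGREE - 1
    breaks = np.unique(t)
    # 3-point rule integrates the degree-2 x degree-2 product exactly
    gx, gw = np.polynomial.legendre.leggauss(3)
    pts, wts = [], []
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        half = (hi - lo) / 2.0
        pts.append(half * gx + (hi + lo) / 2.0)
        wts.append(half * gw)
    pts = np.concatenate(pts)
    wts = np.concatenate(wts)
    D2 = np.empty((pts.size, n_basis))
    for j in range(n_basis):
        coef = np.zeros(n_basis)
        coef[j] = 1.0
        D2[:, j] = BSpline(t, coef, _DEGREE).derivative(2)(pts)
    return (D2 * wts[:, None]).T @ D2


def build_basis(
    age_grid: AgeGrid,
    knot_ages: tuple[float, ...] = DEFAULT_KNOT_AGES,
    min_age_years: float | None = None,
) -> SplineBasis:
    """Construct the O'Sullivan basis over the age grid.

    Interior knots are placed at the x-values of the age groups containing
    ``knot_ages`` (e.g. 45 years -> group 45-49 -> i = 11).  When
    ``min_age_years`` is given the basis covers only groups whose lower
    bound is at or above it (the boundary must coincide with a group edge).
    """
    if len(knot_ages) < 1:
        raise ValueError("at least one interior knot age is required")
    if list(knot_ages) != sorted(set(knot_ages)):
        raise ValueError("knot ages must be strictly increasing")

    indices = np.arange(1, age_grid.n_groups + 1)
    if min_age_years is not None:
        bounds = np.array([age_grid.lower_bound(i) for i in indices])
        if min_age_years not in bounds:
            raise ValueError(
                f"min_age_years={min_age_years} does not align with an "
                "age-group boundary"
            )
        indices = indices[bounds >= min_age_years]
    x = age_index_covariate(indices)

    knot_idx = np.array([age_grid.group_containing(a) for a in knot_ages])
    if np.any(knot_idx < indices.min()) or np.any(knot_idx > indices.max()):
        raise ValueError(
            f"knot ages {knot_ages} fall outside the fitted age range"
        )
    knots = age_index_covariate(knot_idx)
    if np.any(knots <= x.min()) or np.any(knots >= x.max()):
        raise ValueError("interior knots must lie strictly inside the x range")

    B, t = _bspline_design(x, knots)
    omega = _second_derivative_penalty(t)
    eigval, eigvec = np.linalg.eigh(omega)
    keep = eigval > eigval.max() * 1e-10
    Z = B @ eigvec[:, keep] / np.sqrt(eigval[keep])
    return SplineBasis(x=x, Z=Z, knot_ages=tuple(float(a) for a in knot_ages),
                       age_indices=indices)


def project_to_model_space(curve: np.ndarray, basis: SplineBasis) -> np.ndarray:
    """Least-squares projection of a length-n_ages curve onto span{1, x, Z}."""
    curve = np.asarray(curve, dtype=float)
    if curve.shape != (basis.n_ages,):
        raise ValueError(f"curve must have length {basis.n_ages}")
    design = np.column_stack([basis.X, basis.Z])
    coef, *_ = np.linalg.lstsq(design, curve, rcond=None)
    return design @ coef


__all__ = [
    "DEFAULT_KNOT_AGES",
    "SplineBasis",
    "age_index_covariate",
    "build_basis",
    "project_to_model_space",
]
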