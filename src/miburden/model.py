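"""The joint Bayesian model linking registry incidence, registry mortality,
and national death-survey mortality.

Fitted separately per sex x location stratum.  With age groups i and
registries j, the three likelihood components are

    (a) registry cases_ij  ~ Poisson(exp(alpha_i + u_j) * PY_ij)
    (b) registry deaths_ij ~ Poisson(exp(alpha_i + u_j + beta_i + v_j) * PY_ij)
    (c) national deaths_i  ~ Poisson(exp(gamma_i) * PY_i)

where alpha_i is the log mean age-specific incidence rate, beta_i the log
mean age-specific mortality-to-incidence (MI) ratio, and gamma_i the log
national mortality rate.  Each of alpha, beta, gamma is a penalized spline
over the age index, f = phi0 + phi1 x + Z psi, with phi ~ Normal(0, 1e4)
and psi_k ~ Normal(0, sigma_curve^2); u_j ~ Normal(0, sigma_u^2),
v_j ~ Normal(0, sigma_v^2).  All precisions get Gamma(0.001, 0.001) priors,
one smoothing variance per curve.  National incidence is predicted as
exp(gamma_i - beta_i) x national population.

In the MI <= 1 constrained variant the same fixed + spline structure is
placed on the logit of the MI ratio, so beta_i = log(expit(eta_i)) and every
posterior draw satisfies exp(beta_i) < 1 by construction.

The sampling parametrization theta is fully unconstrained: variances enter
as log sigma^2 with the exact Jacobian term included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gammaln, log_expit

from .datatypes import NationalMortalityTable, RegistryTable
from .splines import SplineBasis

PHI_VARIANCE = 1.0e4          # fixed-effect prior variance
GAMMA_SHAPE = 0.001           # precision hyperprior Gamma(shape, rate)
GAMMA_RATE = 0.001

_CURVES = ("alpha", "beta", "gamma")


@dataclass(frozen=True)
class ParameterLayout:
    """Index map between the flat sampling vector theta and model blocks.

    Per curve (alpha, beta, gamma): phi0, phi1, psi[K], log sigma^2.
    Then u[n], log sigma_u^2, v[n], log sigma_v^2.
    """

    K: int
    n_registries: int

    @property
    def curve_size(self) -> int:
        return self.K + 3

    @property
    def ndim(self) -> int:
        return 3 * self.curve_size + 2 * self.n_registries + 2

    def curve_slices(self, c: int):
        base = c * self.curve_size
        return base, base + 1, slice(base + 2, base + 2 + self.K), base + 2 + self.K

    @property
    def u_slice(self) -> slice:
        base = 3 * self.curve_size
        return slice(base, base + self.n_registries)

    @property
    def lam_u(self) -> int:
        return 3 * self.curve_size + self.n_registries

    @property
    def v_slice(self) -> slice:
        base = 3 * self.curve_size + self.n_registries + 1
        return slice(base, base + self.n_registries)

    @property
    def lam_v(self) -> int:
        return self.ndim - 1

    def names(self) -> list[str]:
        out: list[str] = []
        for c in _CURVES:
            out += [f"phi0_{c}", f"phi1_{c}"]
            out += [f"psi_{c}[{k + 1}]" for k in range(self.K)]
            out += [f"log_var_{c}"]
        out += [f"u[{j + 1}]" for j in range(self.n_registries)]
        out += ["log_var_u"]
        out += [f"v[{j + 1}]" for j in range(self.n_registries)]
        out += ["log_var_v"]
        return out


@dataclass
class ModelParameters:
    """One point in parameter space, in interpretable blocks.

    ``curve_coef[c]`` holds (phi0, phi1, psi) for c in alpha/beta/gamma
    (for beta these parametrize the logit-MI curve when constrained);
    ``variances`` maps alpha/beta/gamma/u/v to its variance.
    """

    curve_coef: dict[str, tuple[float, float, np.ndarray]]
    u: np.ndarray
    v: np.ndarray
    variances: dict[str, float]

    def to_theta(self, layout: ParameterLayout) -> np.ndarray:
        theta = np.empty(layout.ndim)
        for c, name in enumerate(_CURVES):
            i0, i1, sl, il = layout.curve_slices(c)
            phi0, phi1, psi = self.curve_coef[name]
            theta[i0], theta[i1] = phi0, phi1
            theta[sl] = psi
            theta[il] = np.log(self.variances[name])
        theta[layout.u_slice] = self.u
        theta[layout.lam_u] = np.log(self.variances["u"])
        theta[layout.v_slice] = self.v
        theta[layout.lam_v] = np.log(self.variances["v"])
        return theta

    @classmethod
    def from_theta(cls, theta: np.ndarray, layout: ParameterLayout) -> "ModelParameters":
        coef = {}
        variances = {}
        for c, name in enumerate(_CURVES):
            i0, i1, sl, il = layout.curve_slices(c)
            coef[name] = (float(theta[i0]), float(theta[i1]), np.array(theta[sl]))
            variances[name] = float(np.exp(theta[il]))
        variances["u"] = float(np.exp(theta[layout.lam_u]))
        variances["v"] = float(np.exp(theta[layout.lam_v]))
        return cls(curve_coef=coef, u=np.array(theta[layout.u_slice]),
                   v=np.array(theta[layout.v_slice]), variances=variances)


class JointModel:
    """Data-bound joint posterior, vectorized over batches of theta."""

    def __init__(
        self,
        registries: list[RegistryTable],
        national: NationalMortalityTable,
        basis: SplineBasis,
        constrained: bool = False,
    ) -> None:
        if not registries:
            raise ValueError("at least one registry table is required")
        n_ages = basis.n_ages
        idx = basis.age_indices - 1  # rows of the 19-length tables to use
        self.basis = basis
        self.registries = list(registries)
        self.national = national
        self.constrained = bool(constrained)
        self.layout = ParameterLayout(K=basis.K_b, n_registries=len(registries))

        self.Y_inc = np.stack([t.incident_cases[idx] for t in registries], axis=1).astype(float)
        self.Y_mort = np.stack([t.deaths[idx] for t in registries], axis=1).astype(float)
        self.P = np.stack([t.population[idx] for t in registries], axis=1)
        self.logP = np.log(self.P)
        self.y_nds = national.deaths[idx].astype(float)
        self.py_nds = national.person_years[idx]
        self.log_py_nds = np.log(self.py_nds)
        assert self.Y_inc.shape == (n_ages, len(registries))

        if self.Y_inc.sum() == 0:
            raise ValueError(
                "all registry incidence counts are zero; exclude this site "
                "from model fitting"
            )
        self.flags: list[str] = []
        if self.y_nds.sum() == 0:
            self.flags.append("zero_national_deaths")

        # constants: -sum log y! across the three Poisson components
        self._ll_const = -(
            gammaln(self.Y_inc + 1).sum()
            + gammaln(self.Y_mort + 1).sum()
            + gammaln(self.y_nds + 1).sum()
        )

    # -- curves -------------------------------------------------------------

    def curves(self, theta: np.ndarray):
        """(alpha, beta, gamma) with leading batch dims of theta preserved."""
        lay = self.basis, self.layout
        basis, layout = lay
        out = []
        for c in range(3):
            i0, i1, sl, _ = layout.curve_slices(c)
            f = (
                theta[..., i0, None]
                + theta[..., i1, None] * basis.x
                + theta[..., sl] @ basis.Z.T
            )
            out.append(f)
        alpha, beta_lin, gamma = out
        beta = log_expit(beta_lin) if self.constrained else beta_lin
        return alpha, beta, gamma

    # -- posterior ----------------------------------------------------------

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        """Log posterior density (up to no constant: normalizers included
        for priors and the Poisson log y! terms) for theta of shape
        (..., ndim)."""
        theta = np.asarray(theta, dtype=float)
        layout = self.layout
        alpha, beta, gamma = self.curves(theta)
        u = theta[..., layout.u_slice]
        v = theta[..., layout.v_slice]

        with np.errstate(over="ignore", invalid="ignore"):
            eta_inc = alpha[..., :, None] + u[..., None, :]
            eta_mort = eta_inc + beta[..., :, None] + v[..., None, :]
            ll = (
                (self.Y_inc * (eta_inc + self.logP) - np.exp(eta_inc) * self.P).sum((-2, -1))
                + (self.Y_mort * (eta_mort + self.logP) - np.exp(eta_mort) * self.P).sum((-2, -1))
                + (self.y_nds * (gamma + self.log_py_nds) - np.exp(gamma) * self.py_nds).sum(-1)
            )
        lp = ll + self._ll_const + self._log_prior(theta)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def _log_prior(self, theta: np.ndarray) -> np.ndarray:
        layout = self.layout
        out = 0.0
        for c in range(3):
            i0, i1, sl, il = layout.curve_slices(c)
            phi = theta[..., [i0, i1]]
            out = out + _normal_logpdf(phi, PHI_VARIANCE).sum(-1)
            lam = theta[..., il]
            psi = theta[..., sl]
            out = out + _normal_logpdf_var(psi, lam[..., None]).sum(-1)
            out = out + _log_var_prior(lam)
        for sl, il in ((layout.u_slice, layout.lam_u), (layout.v_slice, layout.lam_v)):
            lam = theta[..., il]
            out = out + _normal_logpdf_var(theta[..., sl], lam[..., None]).sum(-1)
            out = out + _log_var_prior(lam)
        return out

    # -- gradient (single theta; used for MAP) -------------------------------

    def neg_log_posterior_and_grad(self, theta: np.ndarray):
        layout = self.layout
        basis = self.basis
        alpha, beta, gamma = self.curves(theta)
        u = theta[layout.u_slice]
        v = theta[layout.v_slice]

        eta_inc = alpha[:, None] + u[None, :]
        eta_mort = eta_inc + beta[:, None] + v[None, :]
        mu_inc = np.exp(eta_inc) * self.P
        mu_mort = np.exp(eta_mort) * self.P
        mu_nds = np.exp(gamma) * self.py_nds

        ll = (
            (self.Y_inc * (eta_inc + self.logP) - mu_inc).sum()
            + (self.Y_mort * (eta_mort + self.logP) - mu_mort).sum()
            + (self.y_nds * (gamma + self.log_py_nds) - mu_nds).sum()
            + self._ll_const
        )
        r_inc = self.Y_inc - mu_inc
        r_mort = self.Y_mort - mu_mort
        g_alpha = (r_inc + r_mort).sum(axis=1)
        g_beta = r_mort.sum(axis=1)
        g_gamma = self.y_nds - mu_nds
        g_u = (r_inc + r_mort).sum(axis=0)
        g_v = r_mort.sum(axis=0)
        grad = np.zeros(layout.ndim)
        curve_grads = [g_alpha, g_beta, g_gamma]
        for c in range(3):
            i0, i1, sl, il = layout.curve_slices(c)
            g_f = curve_grads[c]
            if c == 1 and self.constrained:
                eta_b = theta[i0] + theta[i1] * basis.x + theta[sl] @ basis.Z.T
                g_f = g_f * expit(-eta_b)
            lam = theta[il]
            psi = theta[sl]
            grad[i0] = g_f.sum() - theta[i0] / PHI_VARIANCE
            grad[i1] = (g_f * basis.x).sum() - theta[i1] / PHI_VARIANCE
            grad[sl] = basis.Z.T @ g_f - psi * np.exp(-lam)
            grad[il] = (
                -0.5 * layout.K + 0.5 * (psi ** 2).sum() * np.exp(-lam)
                - GAMMA_SHAPE + GAMMA_RATE * np.exp(-lam)
            )
        lam_u, lam_v = theta[layout.lam_u], theta[layout.lam_v]
        grad[layout.u_slice] = g_u - u * np.exp(-lam_u)
        grad[layout.v_slice] = g_v - v * np.exp(-lam_v)
        grad[layout.lam_u] = (
            -0.5 * layout.n_registries + 0.5 * (u ** 2).sum() * np.exp(-lam_u)
            - GAMMA_SHAPE + GAMMA_RATE * np.exp(-lam_u)
        )
        grad[layout.lam_v] = (
            -0.5 * layout.n_registries + 0.5 * (v ** 2).sum() * np.exp(-lam_v)
            - GAMMA_SHAPE + GAMMA_RATE * np.exp(-lam_v)
        )
        lp = ll + float(self._log_prior(theta))
        return -lp, -grad

    # -- MAP initialization ---------------------------------------------------

    def map_estimate(self, max_iter: int = 500) -> np.ndarray:
        from scipy.optimize import minimize

        bounds = [(None, None)] * self.layout.ndim
        for c in range(3):
            bounds[self.layout.curve_slices(c)[3]] = (-12.0, 6.0)
        bounds[self.layout.lam_u] = (-12.0, 6.0)
        bounds[self.layout.lam_v] = (-12.0, 6.0)

        starts = [self.initial_point()]
        if self.constrained:
            # The likelihood has a near-flat ridge trading the MI curve against
            # a common shift in the v's; from a cold start the optimizer can
            # settle on the MI -> 1 end of it.  Warm-start from the
            # unconstrained MAP with its beta curve mapped through the logit
            # and projected back onto the spline span.
            starts.append(self._constrained_warm_start(max_iter))

        best_x, best_f = None, np.inf
        for theta0 in starts:
            res = minimize(
                self.neg_log_posterior_and_grad, theta0, jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter},
            )
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
        return best_x

    def _constrained_warm_start(self, max_iter: int) -> np.ndarray:
        from scipy.special import logit

        unconstrained = JointModel(
            self.registries, self.national, self.basis, constrained=False
        )
        theta = unconstrained.map_estimate(max_iter)
        sl = self.layout.curve_slices(1)
        coef = theta[sl[0]: sl[2].stop]
        beta = coef[0] + coef[1] * self.basis.x + self.basis.Z @ coef[2:]
        eta = logit(np.clip(np.exp(beta), 1e-6, 1.0 - 1e-6))
        design = np.column_stack([self.basis.X, self.basis.Z])
        proj, *_ = np.linalg.lstsq(design, eta, rcond=None)
        theta = theta.copy()
        theta[sl[0]: sl[2].stop] = proj
        return theta

    def initial_point(self) -> np.ndarray:
        layout = self.layout
        theta = np.zeros(layout.ndim)
        inc_rate = max(self.Y_inc.sum() / self.P.sum(), 1e-8)
        mi = max(self.Y_mort.sum() / max(self.Y_inc.sum(), 1.0), 1e-3)
        nds_rate = max(self.y_nds.sum() / self.py_nds.sum(), 1e-10)
        a0, b0, g0 = layout.curve_slices(0)[0], layout.curve_slices(1)[0], layout.curve_slices(2)[0]
        theta[a0] = np.log(inc_rate)
        if self.constrained:
            mi = min(mi, 0.95)
            theta[b0] = np.log(mi / (1 - mi))
        else:
            theta[b0] = np.log(mi)
        theta[g0] = np.log(nds_rate)
        for c in range(3):
            theta[layout.curve_slices(c)[3]] = np.log(0.05)
        theta[layout.lam_u] = np.log(0.05)
        theta[layout.lam_v] = np.log(0.05)
        return theta


def _normal_logpdf(x, var):
    return -0.5 * (x ** 2) / var - 0.5 * np.log(2.0 * np.pi * var)


def _normal_logpdf_var(x, lam):
    """Normal(0, exp(lam)) log-density."""
    return -0.5 * (x ** 2) * np.exp(-lam) - 0.5 * (np.log(2.0 * np.pi) + lam)


def _log_var_prior(lam):
    """Log density of lam = log sigma^2 when 1/sigma^2 ~ Gamma(a, b).

    p(lam) = b^a / Gamma(a) * exp(-a lam - b exp(-lam)).
    """
    a, b = GAMMA_SHAPE, GAMMA_RATE
    return a * np.log(b) - gammaln(a) - a * lam - b * np.exp(-lam)


def log_posterior(
    params: ModelParameters,
    registries: list[RegistryTable],
    national: NationalMortalityTable,
    basis: SplineBasis,
    constrained: bool = False,
) -> float:
    """Joint log-posterior density at one parameter point."""
    model = JointModel(registries, national, basis, constrained=constrained)
    theta = params.to_theta(model.layout)
    return float(model.log_posterior(theta))


__all__ = [
    "JointModel",
    "ModelParameters",
    "ParameterLayout",
    "log_posterior",
    "PHI_VARIANCE",
    "GAMMA_SHAPE",
    "GAMMA_RATE",
]
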