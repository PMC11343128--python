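"""Beta-binomial regression models for allelic-imbalance testing.

Two maximum-likelihood models in a statsmodels-like shape:

* :class:`BetaBinomialModel` -- y_i ~ BetaBinomial(n_i, mu_i, rho) with
  logit(mu_i) = x_i' beta. Used on pseudobulk (per-individual) counts.
* :class:`BetaBinomialMixedModel` -- adds a per-group (per-individual)
  random intercept b_j ~ Normal(0, sigma_b^2) on the logit scale; the
  marginal likelihood integrates b_j out by adaptive Gauss-Hermite
  quadrature. Used on cell-level counts.

Parameterisation: with shape parameters (a, b) of the beta mixing
distribution, mu = a/(a+b) and rho = 1/(a+b+1), so rho in [0, 1) is the
intra-unit correlation and rho -> 0 recovers the plain binomial.
Internally rho is optimised on the logit scale and sigma_b on the log
scale, keeping the search unconstrained.

The null hypothesis of no allelic imbalance is intercept = 0 (a 50:50
allelic ratio); coefficients are tested with Wald z statistics, with a
likelihood-ratio alternative available via :meth:`~BetaBinomialResults.lr_test`.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

_MU_EPS = 1e-10
_RHO_MIN, _RHO_MAX = 1e-12, 1 - 1e-6


def _expit(x):
    return special.expit(x)


def _judge_convergence(res, grad_tol: float = 1e-3):
    """Classify an optimiser exit.

    BFGS can stop on "precision loss" when float64 cancellation in the
    log-likelihood prevents it from pushing the gradient below gtol; if
    the gradient is nonetheless tiny the optimum is found and the fit is
    accepted with a flag.
    """
    if res.success:
        return True, []
    if np.max(np.abs(res.jac)) < grad_tol:
        return True, ["precision_loss"]
    return False, ["non_convergence"]


def betabin_logpmf(y, n, mu, rho):
    """Log pmf of the beta-binomial in (mu, rho) parameterisation.

    Vectorised over all arguments; rho -> 0 is taken as the binomial
    limit analytically rather than through the beta shapes.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), _MU_EPS, 1 - _MU_EPS)
    if np.ndim(rho) == 0 and rho < 1e-8:
        # binomial limit, evaluated directly: the beta shapes blow up and
        # the gammaln differences lose all precision there
        comb = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
        return comb + y * np.log(mu) + (n - y) * np.log1p(-mu)
    rho = np.clip(np.asarray(rho, dtype=float), _RHO_MIN, _RHO_MAX)
    phi = (1 - rho) / rho  # a + b
    a = mu * phi
    b = (1 - mu) * phi
    comb = special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)
    return (
        comb
        + special.gammaln(y + a)
        + special.gammaln(n - y + b)
        - special.gammaln(n + a + b)
        - special.gammaln(a)
        - special.gammaln(b)
        + special.gammaln(a + b)
    )


def _dlogpmf(y, n, mu, rho, *, curvature=False):
    """First (and optionally second) derivatives of the log pmf.

    Returns (d/d_eta, d/d_zrho[, d2/d_eta2]) where eta = logit(mu) and
    zrho = logit(rho).
    """
    mu = np.clip(mu, _MU_EPS, 1 - _MU_EPS)
    rho = np.clip(rho, _RHO_MIN, _RHO_MAX)
    phi = (1 - rho) / rho
    a = mu * phi
    b = (1 - mu) * phi
    psi_ya = special.digamma(y + a)
    psi_a = special.digamma(a)
    psi_nyb = special.digamma(n - y + b)
    psi_b = special.digamma(b)
    psi_nab = special.digamma(n + a + b)
    psi_ab = special.digamma(a + b)

    dmu = mu * (1 - mu)
    A = (psi_ya - psi_a) - (psi_nyb - psi_b)
    d_eta = phi * dmu * A

    dlp_dphi = mu * (psi_ya - psi_a) + (1 - mu) * (psi_nyb - psi_b) + psi_ab - psi_nab
    # dphi/dzrho = dphi/drho * rho(1-rho) = -(1-rho)/rho
    d_zrho = dlp_dphi * (-(1 - rho) / rho)

    if not curvature:
        return d_eta, d_zrho
    tri = special.polygamma(1, y + a) - special.polygamma(1, a) + special.polygamma(
        1, n - y + b
    ) - special.polygamma(1, b)
    d2_eta = phi * dmu * (1 - 2 * mu) * A + (phi * dmu) ** 2 * tri
    return d_eta, d_zrho, d2_eta


class BetaBinomialResults:
    """Fit results: estimates, uncertainties and Wald tests.

    ``params`` holds the fixed effects on the logit scale; the intercept
    is the allelic-imbalance effect size (log-odds of the
    reference-oriented allele). ``pvalues`` are NaN when the optimiser
    failed to converge.
    """

    def __init__(self, model, full_params, llf, converged, flags=()):
        self.model = model
        self._full = np.asarray(full_params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.flags = tuple(flags)
        p = model.k_fe
        self.params = self._full[:p]
        self.rho = float(_expit(self._full[p]))
        self.sigma_b = float(np.exp(self._full[p + 1])) if model.k_re else None
        self._cov = None

    @property
    def nobs(self):
        return self.model.nobs

    @property
    def exog_names(self):
        return self.model.exog_names

    def cov_params(self):
        if self._cov is None:
            self._cov = self.model._cov_params(self._full)
        return self._cov

    @property
    def bse(self):
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.diag(self.cov_params())[: self.model.k_fe])

    @property
    def zvalues(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self):
        if not self.converged:
            return np.full(self.model.k_fe, np.nan)
        return 2 * special.ndtr(-np.abs(self.zvalues))

    def lr_test(self, restricted: "BetaBinomialResults"):
        """Likelihood-ratio test against a nested restricted fit."""
        df = self.model.k_fe - restricted.model.k_fe
        if df <= 0:
            raise ValueError("restricted model must have fewer fixed effects")
        stat = 2 * (self.llf - restricted.llf)
        from scipy.stats import chi2

        return stat, df, chi2.sf(max(stat, 0.0), df)

    def summary(self) -> str:
        header = [
            f"{type(self.model).__name__}  nobs={self.nobs}  llf={self.llf:.3f}",
            f"rho={self.rho:.4g}"
            + (f"  sigma_b={self.sigma_b:.4g}" if self.sigma_b is not None else "")
            + f"  converged={self.converged}",
        ]
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.zvalues,
                "P>|z|": self.pvalues,
            },
            index=self.exog_names,
        )
        lines = header + [tab.to_string(float_format=lambda v: f"{v:.4f}")]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        return "\n".join(lines)

    def __repr__(self):
        return f"<{type(self).__name__} llf={self.llf:.3f} converged={self.converged}>"


class BetaBinomialModel:
    """Beta-binomial regression on successes out of totals.

    Parameters
    ----------
    endog : array (nobs,) of reference-allele counts y_i
    totals : array (nobs,) of totals n_i = n_ref + n_alt, all > 0
    exog : design matrix including an intercept column
    """

    k_re = 0

    def __init__(self, endog, totals, exog, exog_names: Optional[Sequence[str]] = None):
        self.endog = np.asarray(endog, dtype=float)
        self.totals = np.asarray(totals, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            self.exog = self.exog.T
        if np.any(self.totals <= 0):
            raise ValueError("all totals must be positive")
        if np.any(self.endog < 0) or np.any(self.endog > self.totals):
            raise ValueError("need 0 <= y <= n")
        self.nobs = len(self.endog)
        self.k_fe = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names else [
            f"x{i}" for i in range(self.k_fe)
        ]
        if self.nobs < 2:
            raise ValueError("need at least 2 observations to fit")

    @classmethod
    def from_formula(
        cls, formula: str, data: pd.DataFrame, y_col: str = "n_ref", alt_col: str = "n_alt", **kwargs
    ):
        """Build from a long-format count frame and a patsy RHS formula.

        ``formula`` describes the fixed effects only, e.g. ``"1"`` for an
        intercept-only allelic-imbalance test or ``"condition"`` for a
        differential test.
        """
        design = patsy.dmatrix(formula, data, return_type="dataframe")
        if len(design) != len(data):
            raise ValueError("rows dropped while building the design matrix")
        y = data[y_col].to_numpy()
        n = y + data[alt_col].to_numpy()
        return cls(y, n, design.to_numpy(), exog_names=list(design.columns), **kwargs)

    # -- likelihood ---------------------------------------------------------

    def _unpack(self, params):
        beta = params[: self.k_fe]
        rho = float(_expit(params[self.k_fe]))
        return beta, rho

    def loglike(self, params) -> float:
        beta, rho = self._unpack(np.asarray(params, dtype=float))
        mu = _expit(self.exog @ beta)
        return float(np.sum(betabin_logpmf(self.endog, self.totals, mu, rho)))

    def score(self, params) -> np.ndarray:
        beta, rho = self._unpack(np.asarray(params, dtype=float))
        mu = _expit(self.exog @ beta)
        d_eta, d_zrho = _dlogpmf(self.endog, self.totals, mu, rho)
        return np.concatenate([self.exog.T @ d_eta, [np.sum(d_zrho)]])

    def _start_params(self):
        pooled = (self.endog.sum() + 0.5) / (self.totals.sum() + 1.0)
        beta0 = np.zeros(self.k_fe)
        beta0[0] = special.logit(pooled)
        return np.concatenate([beta0, [special.logit(0.01)]])

    def fit(self, start_params=None, maxiter: int = 500, gtol: float = 1e-6) -> BetaBinomialResults:
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self._start_params()
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        converged, flags = _judge_convergence(res)
        return BetaBinomialResults(self, res.x, -res.fun, converged, flags)

    # -- uncertainty --------------------------------------------------------

    def _cov_params(self, full_params, step: float = 1e-5):
        """Observed-information covariance by central differences of the score."""
        k = len(full_params)
        hess = np.zeros((k, k))
        for j in range(k):
            h = step * max(1.0, abs(full_params[j]))
            up = np.array(full_params, dtype=float)
            dn = np.array(full_params, dtype=float)
            up[j] += h
            dn[j] -= h
            hess[:, j] = (self.score(up) - self.score(dn)) / (2 * h)
        hess = (hess + hess.T) / 2
        try:
            cov = np.linalg.inv(-hess)
            if np.any(np.diag(cov)[: self.k_fe] <= 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            # singular at a variance-component boundary (e.g. rho -> 0):
            # the pseudo-inverse still yields the fixed-effect block
            cov = np.linalg.pinv(-hess)
            bad = np.diag(cov)[: self.k_fe] <= 0
            if np.any(bad):
                cov = np.full((k, k), np.nan)
        return cov


class BetaBinomialMixedModel(BetaBinomialModel):
    """Beta-binomial regression with a per-group Gaussian random intercept.

    logit(mu_cj) = x_cj' beta + b_j,  b_j ~ Normal(0, sigma_b^2).

    The marginal log-likelihood is computed by adaptive Gauss-Hermite
    quadrature: for each group the integrand's mode and curvature are
    located by safeguarded Newton steps and the nodes are centred and
    scaled there. Scores use the Fisher identity (posterior-weighted
    expectations of the complete-data score) under the same nodes.
    """

    k_re = 1

    def __init__(self, endog, totals, exog, groups, exog_names=None, n_quad: int = 20):
        super().__init__(endog, totals, exog, exog_names)
        codes, uniques = pd.factorize(np.asarray(groups))
        if len(uniques) < 2:
            raise ValueError("mixed model needs at least 2 groups")
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        self.n_quad = int(n_quad)
        nodes, weights = hermgauss(self.n_quad)
        self._gh_x = nodes
        self._gh_logw = np.log(weights)
        self._modes = np.zeros(self.n_groups)

    @classmethod
    def from_formula(
        cls,
        formula: str,
        data: pd.DataFrame,
        groups: str = "individual_id",
        y_col: str = "n_ref",
        alt_col: str = "n_alt",
        **kwargs,
    ):
        design = patsy.dmatrix(formula, data, return_type="dataframe")
        if len(design) != len(data):
            raise ValueError("rows dropped while building the design matrix")
        y = data[y_col].to_numpy()
        n = y + data[alt_col].to_numpy()
        return cls(
            y, n, design.to_numpy(), data[groups].to_numpy(),
            exog_names=list(design.columns), **kwargs,
        )

    def _unpack_mixed(self, params):
        beta = params[: self.k_fe]
        rho = float(_expit(params[self.k_fe]))
        sigma = float(np.exp(params[self.k_fe + 1]))
        return beta, rho, sigma

    def _group_sum(self, values):
        return np.bincount(self.group_codes, weights=values, minlength=self.n_groups)

    def _find_modes(self, eta0, rho, sigma, maxiter: int = 50, tol: float = 1e-9):
        """Per-group mode and negative curvature of the log integrand."""
        b = self._modes.copy()
        sigma2 = sigma * sigma
        for _ in range(maxiter):
            mu = _expit(eta0 + b[self.group_codes])
            d1, _, d2 = _dlogpmf(self.endog, self.totals, mu, rho, curvature=True)
            g1 = self._group_sum(d1) - b / sigma2
            g2 = self._group_sum(d2) - 1.0 / sigma2
            g2 = np.minimum(g2, -1e-8)
            step = np.clip(-g1 / g2, -2.0, 2.0)
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        mu = _expit(eta0 + b[self.group_codes])
        _, _, d2 = _dlogpmf(self.endog, self.totals, mu, rho, curvature=True)
        curv = -(self._group_sum(d2) - 1.0 / sigma2)
        curv = np.maximum(curv, 1e-8)
        self._modes = b
        return b, curv

    def _node_log_integrand(self, eta0, rho, sigma, b_nodes):
        """(J, K) log integrand at the quadrature nodes."""
        eta = eta0[:, None] + b_nodes[self.group_codes, :]
        lp = betabin_logpmf(self.endog[:, None], self.totals[:, None], _expit(eta), rho)
        per_group = np.zeros((self.n_groups, self.n_quad))
        np.add.at(per_group, self.group_codes, lp)
        per_group += (
            -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * (b_nodes / sigma) ** 2
        )
        return per_group

    def _quadrature(self, params):
        beta, rho, sigma = self._unpack_mixed(np.asarray(params, dtype=float))
        eta0 = self.exog @ beta
        modes, curv = self._find_modes(eta0, rho, sigma)
        scale = np.sqrt(2.0 / curv)  # (J,)
        b_nodes = modes[:, None] + scale[:, None] * self._gh_x[None, :]
        logf = self._node_log_integrand(eta0, rho, sigma, b_nodes)
        log_terms = self._gh_logw[None, :] + self._gh_x[None, :] ** 2 + logf
        group_ll = special.logsumexp(log_terms, axis=1) + np.log(scale)
        return group_ll, log_terms, b_nodes, eta0, rho, sigma

    def loglike(self, params) -> float:
        group_ll, *_ = self._quadrature(params)
        return float(group_ll.sum())

    def score(self, params) -> np.ndarray:
        group_ll, log_terms, b_nodes, eta0, rho, sigma = self._quadrature(params)
        # posterior node weights per group
        lam = np.exp(log_terms - special.logsumexp(log_terms, axis=1, keepdims=True))
        eta = eta0[:, None] + b_nodes[self.group_codes, :]
        d_eta, d_zrho = _dlogpmf(
            self.endog[:, None], self.totals[:, None], _expit(eta), rho
        )
        cell_w = lam[self.group_codes, :]
        w_eta = np.sum(cell_w * d_eta, axis=1)
        grad_beta = self.exog.T @ w_eta
        grad_zrho = float(np.sum(cell_w * d_zrho))
        # prior contribution: d/dlog sigma of log N(b; 0, sigma^2)
        grad_lsig = float(np.sum(lam * ((b_nodes / sigma) ** 2 - 1.0)))
        return np.concatenate([grad_beta, [grad_zrho, grad_lsig]])

    def _start_params(self):
        # warm start from the pseudobulk fit on per-group aggregates
        y_g = self._group_sum(self.endog)
        n_g = self._group_sum(self.totals)
        keep = n_g > 0
        beta0 = np.zeros(self.k_fe)
        zrho = special.logit(0.05)
        lsig = np.log(0.3)
        if keep.sum() >= 2:
            try:
                agg = BetaBinomialModel(
                    y_g[keep], n_g[keep], np.ones((int(keep.sum()), 1))
                ).fit(gtol=1e-6)
                beta0[0] = agg.params[0]
                zrho = special.logit(np.clip(agg.rho, 1e-4, 0.5))
            except Exception:
                pooled = (self.endog.sum() + 0.5) / (self.totals.sum() + 1.0)
                beta0[0] = special.logit(pooled)
        return np.concatenate([beta0, [zrho, lsig]])

    def fit(self, start_params=None, maxiter: int = 200, gtol: float = 1e-5) -> BetaBinomialResults:
        x0 = np.asarray(start_params, dtype=float) if start_params is not None else self._start_params()
        self._modes = np.zeros(self.n_groups)
        res = optimize.minimize(
            lambda p: -self.loglike(p),
            x0,
            jac=lambda p: -self.score(p),
            method="BFGS",
            options={"maxiter": maxiter, "gtol": gtol},
        )
        converged, flags = _judge_convergence(res, grad_tol=1e-2)
        sigma = float(np.exp(res.x[self.k_fe + 1]))
        if sigma < 1e-4:
            flags = flags + ["sigma_b_boundary"]
        return BetaBinomialResults(self, res.x, -res.fun, converged, flags)
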