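"""Negative-binomial mortality GLMM with growth and count offsets.

The dynamic (growth-mortality allocation) view of self-thinning models the
per-period dead-tree count dN of a plot as

    dN ~ NB(mu, theta)
    log mu = b0 + beta1*log D + beta2*log N + log(dD) + log(N_raw) + climate

where D is the quadratic mean diameter (cm), N the live density (trees/ha),
dD the period QMD increment (the growth offset: mortality is allocated per
unit of stand growth) and N_raw the live count (converting rates to counts).
Both offsets enter with coefficient fixed at exactly 1.  The intercept b0
carries a plot-level Gaussian random effect plus additive MAT terms in one of
two variants:

* ``eq_space_time`` - separate effects of the plot long-term MAT (spatial
  gradient) and the within-plot MAT anomaly (temporal variation);
* ``eq_composite`` - a single effect of the period MAT (their sum).

Estimation maximises the marginal likelihood, integrating the plot random
intercept with adaptive Gauss-Hermite quadrature; uncertainty draws are
parametric samples from the asymptotic covariance of the estimator and feed
the same draw-wise propagation machinery a posterior sample would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

__all__ = ["nb_logpmf", "linear_predictor", "MortalityModel", "MortalityResults"]

VARIANTS = {"eq_space_time": ("beta3", "beta4"), "eq_composite": ("beta5",)}
_ALIASES = {"eq2": "eq_space_time", "eq3": "eq_composite"}


def nb_logpmf(y, mu, theta):
    """Log-pmf of the negative binomial in mean-shape form.

    Variance is mu + mu^2/theta; theta -> inf recovers the Poisson.
    log P(y) = lgamma(y+theta) - lgamma(theta) - lgamma(y+1)
             + theta*log(theta/(theta+mu)) + y*log(mu/(theta+mu)).
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be a non-negative integer count")
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    yf = y.astype(float)
    out = (
        special.gammaln(yf + theta)
        - special.gammaln(theta)
        - special.gammaln(yf + 1.0)
        + theta * (np.log(theta) - np.log(theta + mu))
        + yf * (np.log(mu) - np.log(theta + mu))
    )
    return float(out) if out.ndim == 0 else out


def _canon_variant(variant: str) -> str:
    v = _ALIASES.get(variant, variant)
    if v not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; use one of {sorted(VARIANTS) + sorted(_ALIASES)}")
    return v


def linear_predictor(
    params: dict,
    D,
    N,
    delta_D,
    N_raw,
    variant: str = "eq_composite",
    mat_longterm_c=0.0,
    mat_anomaly=0.0,
    mat_ij_c=0.0,
) -> np.ndarray:
    """log mu for given stand state, parameters and centred MAT covariates.

    The offsets log(delta_D) and log(N_raw) enter with coefficient one.
    """
    variant = _canon_variant(variant)
    D = np.asarray(D, dtype=float)
    N = np.asarray(N, dtype=float)
    delta_D = np.asarray(delta_D, dtype=float)
    N_raw = np.asarray(N_raw, dtype=float)
    if np.any(D <= 0) or np.any(N <= 0) or np.any(N_raw <= 0):
        raise ValueError("D, N and N_raw must be positive")
    if np.any(delta_D <= 0):
        raise ValueError("delta_D must be positive (non-growing periods are filtered upstream)")
    eta = (
        params["beta0"]
        + params["beta1"] * np.log(D)
        + params["beta2"] * np.log(N)
        + np.log(delta_D)
        + np.log(N_raw)
    )
    if variant == "eq_space_time":
        eta = eta + params["beta3"] * np.asarray(mat_longterm_c) + params["beta4"] * np.asarray(mat_anomaly)
    else:
        eta = eta + params["beta5"] * np.asarray(mat_ij_c)
    return eta


class MortalityModel:
    """Growth-mortality allocation model of density-dependent tree death.

    Parameters
    ----------
    delta_n : array of per-period dead-tree counts.
    log_d, log_n : log QMD (cm) and log density (trees/ha) at period start.
    offset : log(delta_D) + log(N_raw), the fixed-coefficient offsets.
    climate : design columns for the chosen variant, already centred -
        ``(mat_longterm_c, mat_anomaly)`` or ``(mat_ij_c,)``.
    plot_ids : group labels for the plot random intercept.
    """

    def __init__(self, delta_n, log_d, log_n, offset, climate, plot_ids,
                 variant: str = "eq_composite", mat_center: float = 0.0):
        self.variant = _canon_variant(variant)
        self.y = np.asarray(delta_n)
        if np.any(self.y < 0) or not np.all(np.equal(np.mod(self.y, 1), 0)):
            raise ValueError("delta_n must be non-negative integer counts")
        self.y = self.y.astype(float)
        climate = [np.asarray(c, dtype=float) for c in climate]
        if len(climate) != len(VARIANTS[self.variant]):
            raise ValueError(f"variant {self.variant} expects {len(VARIANTS[self.variant])} climate columns")
        self.X = np.column_stack([np.ones_like(self.y), np.asarray(log_d, float),
                                  np.asarray(log_n, float), *climate])
        self.offset = np.asarray(offset, dtype=float)
        codes, uniques = pd.factorize(np.asarray(plot_ids))
        self.group = codes
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        if self.n_groups < 2:
            raise ValueError("plot random intercept needs at least two plots")
        if not np.any(self.y > 0):
            raise ValueError("no mortality observed anywhere; theta is unidentifiable")
        self.mat_center = mat_center
        self.param_names = ["beta0", "beta1", "beta2", *VARIANTS[self.variant]]

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, variant: str = "eq_composite",
                       mat_center: float | None = None) -> "MortalityModel":
        """Build from a retained-periods table carrying climate covariates.

        Needs columns delta_N, D_start, N_start, delta_D, N_raw_start,
        plot_id and mat_longterm / mat_anomaly / mat_ij as the variant
        requires.  MAT-scale covariates are centred at ``mat_center``
        (default: mean of mat_longterm over the table).
        """
        variant = _canon_variant(variant)
        if mat_center is None:
            mat_center = float(df["mat_longterm"].mean())
        if variant == "eq_space_time":
            climate = (df["mat_longterm"].to_numpy() - mat_center, df["mat_anomaly"].to_numpy())
        else:
            climate = (df["mat_ij"].to_numpy() - mat_center,)
        return cls(
            delta_n=df["delta_N"].to_numpy(),
            log_d=np.log(df["D_start"].to_numpy()),
            log_n=np.log(df["N_start"].to_numpy()),
            offset=np.log(df["delta_D"].to_numpy()) + np.log(df["N_raw_start"].to_numpy()),
            climate=climate,
            plot_ids=df["plot_id"].to_numpy(),
            variant=variant,
            mat_center=mat_center,
        )

    # -- marginal likelihood ----------------------------------------------
    def _group_mode(self, eta0, theta, sigma2, n_iter=25, tol=1e-9):
        """Newton solve for the per-plot random-intercept mode.

        The integrand is log-concave in b, so damped Newton converges
        globally.  Returns (b_hat, curvature) with curvature = -d2/db2 of the
        log integrand at the mode.
        """
        b = np.zeros(self.n_groups)
        for _ in range(n_iter):
            mu = np.exp(eta0 + b[self.group])
            r = self.y - (theta + self.y) * mu / (theta + mu)
            g = np.bincount(self.group, weights=r, minlength=self.n_groups) - b / sigma2
            w = (theta + self.y) * theta * mu / (theta + mu) ** 2
            h = np.bincount(self.group, weights=w, minlength=self.n_groups) + 1.0 / sigma2
            step = np.clip(g / h, -3.0, 3.0)
            b = b + step
            if np.max(np.abs(step)) < tol:
                break
        mu = np.exp(eta0 + b[self.group])
        w = (theta + self.y) * theta * mu / (theta + mu) ** 2
        h = np.bincount(self.group, weights=w, minlength=self.n_groups) + 1.0 / sigma2
        return b, h

    def nloglike(self, params_vec, quad_points: int = 15) -> float:
        """Negative marginal log-likelihood at (betas, log_sigma, log_theta).

        The plot random intercept is integrated out with Gauss-Hermite
        quadrature adapted to the Laplace mode and curvature of each plot.
        """
        k = self.X.shape[1]
        beta = params_vec[:k]
        sigma = np.exp(params_vec[k])
        theta = np.exp(params_vec[k + 1])
        sigma2 = sigma * sigma
        eta0 = self.X @ beta + self.offset
        b_hat, h = self._group_mode(eta0, theta, sigma2)
        s = 1.0 / np.sqrt(h)  # per-group Laplace scale

        z, w = np.polynomial.hermite.hermgauss(quad_points)
        log_total = np.full(self.n_groups, -np.inf)
        contrib = np.empty((quad_points, self.n_groups))
        for q in range(quad_points):
            b = b_hat + np.sqrt(2.0) * s * z[q]
            mu = np.exp(eta0 + b[self.group])
            ll_obs = nb_logpmf(self.y.astype(int), mu, theta)
            ll_g = np.bincount(self.group, weights=ll_obs, minlength=self.n_groups)
            ll_g += -0.5 * b * b / sigma2 - 0.5 * np.log(2.0 * np.pi * sigma2)
            contrib[q] = ll_g + z[q] ** 2 + np.log(w[q])
        log_total = special.logsumexp(contrib, axis=0) + 0.5 * np.log(2.0) + np.log(s)
        return -float(np.sum(log_total))

    def _start_values(self):
        """Poisson GLM (no random effect) starting values for the betas."""
        import statsmodels.api as sm

        glm = sm.GLM(self.y, self.X, family=sm.families.Poisson(), offset=self.offset)
        try:
            res = glm.fit()
            beta0 = np.asarray(res.params)
        except Exception:
            beta0 = np.zeros(self.X.shape[1])
        return np.concatenate([beta0, [np.log(0.5), np.log(5.0)]])

    def fit(self, n_draws: int = 2000, seed: int | None = None, quad_points: int = 15,
            start=None, maxiter: int = 500) -> "MortalityResults":
        """Maximise the marginal likelihood and build the results object.

        Draws are sampled from the asymptotic normal of (betas, log sigma,
        log theta) with covariance from the finite-difference Hessian at the
        optimum.
        """
        x0 = self._start_values() if start is None else np.asarray(start, float)
        obj = lambda p: self.nloglike(p, quad_points=quad_points)
        res = optimize.minimize(obj, x0, method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-5})
        if not np.isfinite(res.fun):
            raise RuntimeError("mortality GLMM fit diverged")
        # BFGS with numerical gradients often stops on "precision loss" at
        # the optimum; judge convergence by the gradient norm actually reached
        converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-2
        if not converged:
            raise RuntimeError(
                f"mortality GLMM did not converge: {res.message} "
                f"(max |grad| = {np.max(np.abs(res.jac)):.3g})")
        hess = _numeric_hessian(obj, res.x)
        cov = _robust_inverse(hess)
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(res.x, cov, size=n_draws, method="svd")
        return MortalityResults(self, res.x, cov, draws, converged=converged,
                                nll=float(res.fun), optimizer_message=str(res.message))


def _numeric_hessian(f, x, h=1e-4):
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def _robust_inverse(H):
    """Invert a Hessian, flooring non-positive curvature directions."""
    vals, vecs = np.linalg.eigh(H)
    floor = max(1e-8, 1e-8 * np.max(np.abs(vals)))
    vals = np.clip(vals, floor, None)
    return (vecs / vals) @ vecs.T


@dataclass
class MortalityResults:
    """Fitted mortality GLMM: estimates, covariance and parametric draws."""

    model: MortalityModel
    params_vec: np.ndarray
    cov: np.ndarray
    raw_draws: np.ndarray = field(repr=False)
    converged: bool = True
    nll: float = float("nan")
    optimizer_message: str = ""

    def __post_init__(self) -> None:
        k = len(self.model.param_names)
        self.params = {n: float(v) for n, v in zip(self.model.param_names, self.params_vec[:k])}
        self.params["sigma_beta0"] = float(np.exp(self.params_vec[k]))
        self.params["theta"] = float(np.exp(self.params_vec[k + 1]))

    @property
    def variant(self) -> str:
        return self.model.variant

    @property
    def draws(self) -> pd.DataFrame:
        """Parameter draws on the natural scale (one row per draw)."""
        k = len(self.model.param_names)
        d = {n: self.raw_draws[:, i] for i, n in enumerate(self.model.param_names)}
        d["sigma_beta0"] = np.exp(self.raw_draws[:, k])
        d["theta"] = np.exp(self.raw_draws[:, k + 1])
        return pd.DataFrame(d)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        d = self.draws
        return pd.DataFrame({
            "mean": d.mean(), "lower": d.quantile(lo / 100), "upper": d.quantile(hi / 100),
        })

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Mortality GLMM ({self.variant}), NB family, log link",
            f"observations: {len(self.model.y)}   plots: {self.model.n_groups}",
            f"converged: {self.converged}   -loglik: {self.nll:.2f}",
            f"MAT centred at {self.model.mat_center:.3f} degC",
            f"{'param':>12s} {'estimate':>10s} {'mean':>10s} {'2.5%':>10s} {'97.5%':>10s}",
        ]
        for name in list(self.params):
            est = self.params[name]
            lines.append(
                f"{name:>12s} {est:10.4f} {ci.loc[name, 'mean']:10.4f} "
                f"{ci.loc[name, 'lower']:10.4f} {ci.loc[name, 'upper']:10.4f}"
            )
        return "\n".join(lines)

    def predict(self, D, N, delta_D, N_raw, mat_longterm=None, mat_anomaly=None,
                mat_ij=None, level: float = 0.95) -> pd.DataFrame:
        """Expected mortality count and rate with draw-wise intervals.

        Climate inputs are on the raw deg-C scale; the fit's centring constant
        is applied internally.  New plots take the random effect at its
        population mean (zero).
        """
        c = self.model.mat_center
        kwargs = {}
        if self.variant == "eq_space_time":
            kwargs["mat_longterm_c"] = np.asarray(0.0 if mat_longterm is None else mat_longterm) - (0.0 if mat_longterm is None else c)
            kwargs["mat_anomaly"] = 0.0 if mat_anomaly is None else mat_anomaly
        else:
            kwargs["mat_ij_c"] = np.asarray(0.0 if mat_ij is None else mat_ij) - (0.0 if mat_ij is None else c)
        dr = self.draws
        etas = []
        for i in range(len(dr)):
            p = {n: dr.iloc[i][n] for n in self.model.param_names}
            etas.append(linear_predictor(p, D, N, delta_D, N_raw, self.variant, **kwargs))
        mu = np.exp(np.asarray(etas))
        lo, hi = (1 - level) / 2, (1 + level) / 2
        point = np.exp(linear_predictor(self.params, D, N, delta_D, N_raw, self.variant, **kwargs))
        return pd.DataFrame({
            "mu": np.atleast_1d(point),
            "mu_mean": np.atleast_1d(mu.mean(axis=0)),
            "mu_lower": np.atleast_1d(np.quantile(mu, lo, axis=0)),
            "mu_upper": np.atleast_1d(np.quantile(mu, hi, axis=0)),
            "rate": np.atleast_1d(point / np.asarray(N_raw, dtype=float)),
        })

    def thinning_line(self):
        """Derived self-thinning line with draw-wise uncertainty."""
        from .derived import stl_results

        return stl_results(self)
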