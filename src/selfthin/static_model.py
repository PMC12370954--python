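"""Static size-density allometry with a climate-sensitive intercept.

The classical (static) description of carrying capacity regresses the log
stocking of control plots on the log quadratic mean diameter:

    log N_ij ~ Normal(mu_ij, sigma)
    mu_ij = a0_j + a1*log D_ij + a2*covariate_j
    a0_j ~ Normal(a0, sigma_a0)

with a plot-level random intercept absorbing repeated measurements.  The
climate covariate (plot long-term MAT by default, alternatively P, AHMI or
VPD) shifts the line's intercept; a2 < 0 means warmer/more arid plots hold
fewer trees at a given mean size.

Estimation uses a linear mixed-effects model (REML); uncertainty draws for
derived quantities are parametric samples from the estimator covariance of
the fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .climate import CovariateTransform

__all__ = ["StaticThinningModel", "StaticThinningResults"]


class StaticThinningModel:
    """Hierarchical log N ~ log D + covariate model for control plots."""

    def __init__(self, log_n, log_d, covariate, plot_ids, covariate_name: str = "mat",
                 transform: CovariateTransform | None = None):
        self.log_n = np.asarray(log_n, dtype=float)
        self.log_d = np.asarray(log_d, dtype=float)
        cov = np.asarray(covariate, dtype=float)
        if transform is None:
            scheme = "center_scale" if covariate_name in ("p", "ahmi") else "center"
            transform = CovariateTransform(scheme=scheme).fit(cov)
        elif not transform.fitted:
            transform.fit(cov)
        self.transform = transform
        self.cov_t = transform.transform(cov)
        self.covariate_name = covariate_name
        codes, uniques = pd.factorize(np.asarray(plot_ids))
        self.group = codes
        self.group_labels = list(uniques)
        if len(uniques) < 2:
            raise ValueError("plot random intercept needs at least two plots")
        if np.any(~np.isfinite(self.log_n)) or np.any(~np.isfinite(self.log_d)):
            raise ValueError("log N and log D must be finite (positive N, D upstream)")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, covariate: str = "mat_longterm",
                       covariate_name: str | None = None,
                       transform: CovariateTransform | None = None) -> "StaticThinningModel":
        """Build from a control-plot periods table (start snapshots).

        Needs columns N_start, D_start, plot_id and the chosen covariate
        column (default the plot long-term MAT).
        """
        name = covariate_name or ("mat" if "mat" in covariate else covariate)
        return cls(
            log_n=np.log(df["N_start"].to_numpy()),
            log_d=np.log(df["D_start"].to_numpy()),
            covariate=df[covariate].to_numpy(),
            plot_ids=df["plot_id"].to_numpy(),
            covariate_name=name,
            transform=transform,
        )

    def fit(self, reml: bool = True, n_draws: int = 2000, seed: int | None = None) -> "StaticThinningResults":
        exog = np.column_stack([np.ones_like(self.log_n), self.log_d, self.cov_t])
        try:
            res = sm.MixedLM(self.log_n, exog, groups=self.group).fit(reml=reml)
            fe = np.asarray(res.fe_params)
            cov_fe = np.asarray(res.cov_params())[:3, :3]
            sigma_a0 = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
            sigma = float(np.sqrt(res.scale))
            re_means = {self.group_labels[k]: float(np.asarray(v)[0])
                        for k, v in res.random_effects.items()}
            converged = bool(res.converged)
        except np.linalg.LinAlgError:
            # zero-variance boundary (e.g. noiseless data): the mixed model
            # degenerates to ordinary least squares with no plot effect
            ols = sm.OLS(self.log_n, exog).fit()
            fe = np.asarray(ols.params)
            cov_fe = np.asarray(ols.cov_params())
            sigma_a0 = 0.0
            sigma = float(np.sqrt(ols.scale))
            re_means = {g: 0.0 for g in self.group_labels}
            converged = True
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fe, cov_fe, size=n_draws, method="svd")
        return StaticThinningResults(
            model=self, alpha=fe, cov_alpha=cov_fe, raw_draws=draws,
            sigma_alpha0=sigma_a0, sigma=sigma, plot_intercepts=re_means,
            converged=converged,
        )


@dataclass
class StaticThinningResults:
    """Fitted static allometry: fixed effects, variance components, draws."""

    model: StaticThinningModel
    alpha: np.ndarray
    cov_alpha: np.ndarray
    raw_draws: np.ndarray = field(repr=False)
    sigma_alpha0: float = float("nan")
    sigma: float = float("nan")
    plot_intercepts: dict = field(default_factory=dict, repr=False)
    converged: bool = True

    @property
    def params(self) -> dict:
        return {
            "alpha0": float(self.alpha[0]),
            "alpha1": float(self.alpha[1]),
            "alpha2": float(self.alpha[2]),
            "sigma_alpha0": self.sigma_alpha0,
            "sigma": self.sigma,
        }

    @property
    def draws(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha0": self.raw_draws[:, 0],
            "alpha1": self.raw_draws[:, 1],
            "alpha2": self.raw_draws[:, 2],
        })

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, (1 + level) / 2
        d = self.draws
        return pd.DataFrame({"mean": d.mean(), "lower": d.quantile(lo), "upper": d.quantile(hi)})

    def summary(self) -> str:
        ci = self.conf_int()
        t = self.model.transform
        lines = [
            "Static self-thinning allometry (linear mixed model, REML)",
            f"observations: {len(self.model.log_n)}   plots: {len(self.model.group_labels)}",
            f"covariate: {self.model.covariate_name} ({t.scheme}; center={t.center:.4f}, scale={t.scale:.4f})",
            f"{'param':>12s} {'estimate':>10s} {'2.5%':>10s} {'97.5%':>10s}",
        ]
        for i, name in enumerate(["alpha0", "alpha1", "alpha2"]):
            lines.append(f"{name:>12s} {self.alpha[i]:10.4f} {ci.loc[name, 'lower']:10.4f} {ci.loc[name, 'upper']:10.4f}")
        lines.append(f"{'sigma_alpha0':>12s} {self.sigma_alpha0:10.4f}")
        lines.append(f"{'sigma':>12s} {self.sigma:10.4f}")
        return "\n".join(lines)

    def predict_max_log_density(self, D, covariate=None, level: float = 0.95) -> pd.DataFrame:
        """Predicted maximum log stocking at QMD D (cm) and covariate value.

        ``covariate`` on the raw scale (transform applied internally); None
        means the covariate at its centre, where the prediction is
        independent of alpha2.  Interval from the fixed-effect draws.
        """
        D = np.atleast_1d(np.asarray(D, dtype=float))
        if np.any(D <= 0):
            raise ValueError("D must be positive")
        x = 0.0 if covariate is None else self.model.transform.transform(covariate)
        x = np.broadcast_to(np.asarray(x, dtype=float), D.shape)
        point = self.alpha[0] + self.alpha[1] * np.log(D) + self.alpha[2] * x
        dr = self.raw_draws
        pred = dr[:, [0]] + dr[:, [1]] * np.log(D)[None, :] + dr[:, [2]] * x[None, :]
        lo, hi = (1 - level) / 2, (1 + level) / 2
        return pd.DataFrame({
            "D": D,
            "log_n": point,
            "lower": np.quantile(pred, lo, axis=0),
            "upper": np.quantile(pred, hi, axis=0),
        })

    def sdi25(self, covariate=None) -> float:
        """Stand density index: predicted maximum stocking at D = 25 cm."""
        return float(np.exp(self.predict_max_log_density(25.0, covariate)["log_n"].iloc[0]))
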