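"""Self-thinning line derivation, climate effect sizes and warming projections.

The growth-mortality allocation model implies a self-thinning line.  Along
the line, mortality exactly balances growth, which pins down its parameters
as closed forms of the mortality coefficients:

    intercept = beta0/(-beta2) + (log(beta2) - log(beta1 + 1))/(-beta2)
    slope     = (1 + beta1)/(-beta2)

A climate coefficient beta_k on the mortality intercept shifts the line's
intercept by beta_k/(-beta2) per deg C, so a temperature change dT multiplies
the carrying capacity (maximum density at any given QMD) by
exp(dT * beta_k/(-beta2)).  Uncertainty in every derived quantity is obtained
by applying the transform draw-wise to joint parameter draws, never to
summary means.

The module also projects the carbon-stock consequence of a capacity drop and
simulates stand trajectories under transient (heatwave) versus permanent
(warming) temperature shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SelfThinningLine",
    "ProjectionResult",
    "CarbonImpact",
    "Scenario",
    "stl_from_params",
    "intercept_effect",
    "capacity_multiplier",
    "propagate",
    "carbon_impact",
    "stl_results",
    "project_capacity",
    "simulate_trajectory",
]


def stl_from_params(beta0, beta1, beta2):
    """(intercept, slope) of the self-thinning line from mortality coefficients.

    Requires beta2 > 0 and beta1 + 1 > 0 (the log terms).  The intercept is
    log trees/ha at log D = 0; the slope is d log N / d log D.
    """
    beta0 = np.asarray(beta0, dtype=float)
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if np.any(beta2 <= 0):
        raise ValueError("beta2 must be positive to derive the self-thinning line")
    if np.any(beta1 + 1.0 <= 0):
        raise ValueError("beta1 + 1 must be positive to derive the self-thinning line")
    inv = -beta2
    intercept = beta0 / inv + (np.log(beta2) - np.log(beta1 + 1.0)) / inv
    slope = (1.0 + beta1) / inv
    return intercept, slope


def intercept_effect(beta_k, beta2):
    """Per-deg-C additive shift of the thinning-line intercept: beta_k/(-beta2)."""
    beta2 = np.asarray(beta2, dtype=float)
    if np.any(beta2 == 0):
        raise ValueError("beta2 must be nonzero")
    return np.asarray(beta_k, dtype=float) / (-beta2)


def capacity_multiplier(effect, delta_t):
    """Multiplicative change of carrying capacity for a temperature shift.

    exp(effect * delta_t); with a negative effect the multiplier decreases in
    delta_t, and it composes exponentially: m(a+b) = m(a)*m(b).
    """
    return np.exp(np.asarray(effect, dtype=float) * np.asarray(delta_t, dtype=float))


def propagate(draws, transform, level: float = 0.95) -> dict:
    """Summarise a derived quantity by applying ``transform`` draw-wise.

    ``draws`` is a DataFrame (or dict of arrays) of joint parameter draws;
    ``transform`` maps one draw (a row, passed as a dict) to a scalar.  The
    transform is applied to every draw, never to summary means; any draw on
    which it fails (e.g. beta2 <= 0) aborts with the offending indices.
    """
    df = pd.DataFrame(draws)
    if len(df) < 100:
        raise ValueError("propagate needs at least 100 joint draws")
    vals = np.empty(len(df))
    bad = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            v = transform(dict(zip(df.columns, row)))
        except Exception:
            v = np.nan
        if not np.isfinite(v):
            bad.append(i)
        vals[i] = v
    if bad:
        raise ValueError(f"transform undefined on draws {bad[:10]}{'...' if len(bad) > 10 else ''}")
    lo, hi = (1 - level) / 2, (1 + level) / 2
    return {
        "mean": float(np.mean(vals)),
        "lower": float(np.quantile(vals, lo)),
        "upper": float(np.quantile(vals, hi)),
        "draws": vals,
    }


@dataclass
class SelfThinningLine:
    """Derived thinning-line parameters with draw-based uncertainty."""

    intercept: float
    slope: float
    climate_effect: float  # per deg C shift of the intercept
    intercept_ci: tuple[float, float] = (float("nan"), float("nan"))
    slope_ci: tuple[float, float] = (float("nan"), float("nan"))
    effect_ci: tuple[float, float] = (float("nan"), float("nan"))
    draws: pd.DataFrame | None = field(default=None, repr=False)

    def log_n_max(self, d, mat_shift: float = 0.0):
        """Maximum log stocking at QMD d (cm), optionally under a MAT shift."""
        return self.intercept + self.climate_effect * mat_shift + self.slope * np.log(np.asarray(d, dtype=float))

    def summary(self) -> str:
        return (
            "Self-thinning line (derived from mortality model)\n"
            f"  intercept      {self.intercept:8.4f}  [{self.intercept_ci[0]:.4f}, {self.intercept_ci[1]:.4f}]\n"
            f"  slope          {self.slope:8.4f}  [{self.slope_ci[0]:.4f}, {self.slope_ci[1]:.4f}]\n"
            f"  MAT effect/C   {self.climate_effect:8.4f}  [{self.effect_ci[0]:.4f}, {self.effect_ci[1]:.4f}]"
        )


def stl_results(fit, effect_param: str | None = None) -> SelfThinningLine:
    """Derive the self-thinning line from a fitted mortality model.

    ``effect_param`` picks the climate coefficient (default: beta5 for the
    composite variant, beta3 for the space/time variant's spatial effect).
    All summaries propagate draw-wise through the closed forms.
    """
    if effect_param is None:
        effect_param = "beta5" if fit.variant == "eq_composite" else "beta3"
    d = fit.draws
    inter = propagate(d, lambda p: stl_from_params(p["beta0"], p["beta1"], p["beta2"])[0])
    slope = propagate(d, lambda p: stl_from_params(p["beta0"], p["beta1"], p["beta2"])[1])
    eff = propagate(d, lambda p: float(intercept_effect(p[effect_param], p["beta2"])))
    pt_inter, pt_slope = stl_from_params(fit.params["beta0"], fit.params["beta1"], fit.params["beta2"])
    pt_eff = float(intercept_effect(fit.params[effect_param], fit.params["beta2"]))
    return SelfThinningLine(
        intercept=float(pt_inter),
        slope=float(pt_slope),
        climate_effect=pt_eff,
        intercept_ci=(inter["lower"], inter["upper"]),
        slope_ci=(slope["lower"], slope["upper"]),
        effect_ci=(eff["lower"], eff["upper"]),
        draws=pd.DataFrame({"intercept": inter["draws"], "slope": slope["draws"], "effect": eff["draws"]}),
    )


@dataclass
class ProjectionResult:
    """Carrying-capacity change under a temperature shift."""

    delta_t: float
    capacity_multiplier: float
    percent_change: float
    multiplier_ci: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        expected = 100.0 * (self.capacity_multiplier - 1.0)
        if abs(self.percent_change - expected) > 1e-9:
            raise ValueError("percent_change inconsistent with multiplier")


def project_capacity(effect, delta_t, draws=None, effect_col: str = "effect") -> ProjectionResult:
    """Capacity multiplier and percent change for a warming scenario."""
    m = float(capacity_multiplier(effect, delta_t))
    ci = (float("nan"), float("nan"))
    if draws is not None:
        s = propagate(draws, lambda p: float(capacity_multiplier(p[effect_col], delta_t)))
        ci = (s["lower"], s["upper"])
    return ProjectionResult(delta_t=float(delta_t), capacity_multiplier=m,
                            percent_change=100.0 * (m - 1.0), multiplier_ci=ci)


@dataclass
class CarbonImpact:
    """Carbon-stock consequence of a carrying-capacity drop over an area."""

    drop_fraction: float
    carbon_per_ha: float  # t C / ha
    area: float  # ha
    carbon_loss: float = field(init=False)  # t C
    equivalent_area: float = field(init=False)  # ha of forest holding the lost stock

    def __post_init__(self) -> None:
        if not (0 < self.drop_fraction < 1 and self.carbon_per_ha > 0 and self.area > 0):
            raise ValueError("drop_fraction in (0,1), carbon_per_ha and area positive")
        self.carbon_loss = self.drop_fraction * self.carbon_per_ha * self.area
        self.equivalent_area = self.carbon_loss / self.carbon_per_ha

    def car_equivalent_people(self, g_per_km: float = 146.0, km_per_yr: float = 10000.0,
                              years: float = 75.0) -> float:
        """People whose lifetime driving emits the lost carbon.

        Defaults: 146 g C/km, 10,000 km/yr over 75 years.
        """
        per_person = g_per_km * 1e-6 * km_per_yr * years  # t C
        return self.carbon_loss / per_person


def carbon_impact(drop_fraction: float, carbon_per_ha: float, area: float) -> CarbonImpact:
    """Convenience constructor for :class:`CarbonImpact`."""
    return CarbonImpact(drop_fraction=drop_fraction, carbon_per_ha=carbon_per_ha, area=area)


# ---------------------------------------------------------------------------
# trajectory simulation: transient vs permanent warming


@dataclass
class Scenario:
    """Temperature scenario for trajectory simulation.

    kind 'baseline' (no shift), 'transient' (shift of delta_t during
    [start, end]) or 'permanent' (shift from onset on); times in years from
    the start of the simulation.
    """

    kind: str = "baseline"
    delta_t: float = 0.0
    start: float = 0.0
    end: float = float("inf")

    def shift(self, t: float) -> float:
        if self.kind == "baseline":
            return 0.0
        if self.kind == "permanent":
            return self.delta_t if t >= self.start else 0.0
        if self.kind == "transient":
            return self.delta_t if self.start <= t < self.end else 0.0
        raise ValueError(f"unknown scenario kind {self.kind!r}")


def simulate_trajectory(
    params: dict,
    scenario: Scenario | None = None,
    growth=None,
    d0: float = 15.0,
    n0: float = 1500.0,
    area_ha: float = 1.0,
    mat_c: float = 0.0,
    t_max: float = 200.0,
    dt: float = 0.25,
    mode: str = "deterministic",
    seed: int | None = None,
    effect_param: str = "beta5",
) -> pd.DataFrame:
    """Simulate a stand's (t, D, N) path under growth and expected mortality.

    ``params`` holds the mortality coefficients (beta0, beta1, beta2, the
    climate coefficient named by ``effect_param``, and theta for stochastic
    mode).  ``growth`` is an object with ``annual_increment(D, N_per_ha)``
    (default: the synthetic generator's growth submodel driven by the same
    mortality truth); ``mat_c`` is the baseline centred MAT.  In
    deterministic mode the expected count is removed each step; in stochastic
    mode a negative-binomial draw is.  A collapsing stand (fewer than two
    trees) truncates the trajectory with ``collapsed=True``.
    """
    scenario = scenario or Scenario()
    if growth is None:
        from .simulate import GrowthModel, TruthParams

        tp = TruthParams.composite(
            beta0=params["beta0"], beta1=params["beta1"], beta2=params["beta2"],
            beta5=params.get(effect_param, 0.0),
            theta=params.get("theta", 10.0),
        )
        growth = GrowthModel(tp)
    rng = np.random.default_rng(seed)
    eff = params.get(effect_param, 0.0)
    n_raw = n0 * area_ha
    d = d0
    rows = []
    collapsed = False
    t = 0.0
    while t < t_max and not collapsed:
        n_ha = n_raw / area_ha
        rows.append({"t": t, "D": d, "N": n_ha, "N_raw": n_raw,
                     "mat_shift": scenario.shift(t)})
        g = growth.annual_increment(d, n_ha)
        delta_d = max(g * dt, 1e-9)
        log_mu = (params["beta0"] + eff * (mat_c + scenario.shift(t))
                  + params["beta1"] * math.log(d) + params["beta2"] * math.log(n_ha)
                  + math.log(delta_d) + math.log(n_raw))
        mu = math.exp(log_mu)
        if mode == "deterministic":
            dead = mu
        elif mode == "stochastic":
            theta = params.get("theta", 10.0)
            dead = float(rng.negative_binomial(theta, theta / (theta + mu)))
        else:
            raise ValueError("mode must be 'deterministic' or 'stochastic'")
        n_raw = max(n_raw - dead, 0.0)
        d = d + delta_d
        t += dt
        if n_raw < 2.0:  # fewer than two trees left on the plot
            collapsed = True
    out = pd.DataFrame(rows)
    out.attrs["collapsed"] = collapsed
    return out


def density_at_matched_d(trajectory: pd.DataFrame, d: float) -> float:
    """Interpolate a trajectory's density (per ha) at a given QMD.

    Linear in (log D, log N); NaN outside the simulated QMD range.
    """
    tr = trajectory.sort_values("D")
    log_n = np.interp(math.log(d), np.log(tr["D"]), np.log(tr["N"]),
                      left=np.nan, right=np.nan)
    return float(np.exp(log_n))
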