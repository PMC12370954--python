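"""Synthetic stand-dynamics generator with known truth parameters.

Emulates a network of even-aged permanent plots of the kind used to study
self-thinning: ~112 plots (40 unthinned controls) of 400-8000 m^2, censused
every 2-3 years between the late 1940s and 2000, sitting on a spatial mean
annual temperature gradient of roughly 9.5-12.5 deg C with a warming trend of
0.71 deg C across the record and interannual anomalies.  Stand dynamics follow
the growth-mortality allocation model: per period the quadratic mean diameter
increases by a growth increment and the mortality count is drawn from a
negative binomial whose log-mean is linear in log D and log N with the period
QMD increment and the live count entering as fixed offsets, plus a plot
random intercept and additive MAT effects.  Trees that die are, on average, a
fixed fraction (default 0.62) of the size of the live trees.

Every stochastic choice derives from a single master seed through per-plot
substreams, so regenerating with more plots leaves existing plots unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import longterm_mean, period_climate

__all__ = [
    "TruthParams",
    "GeneratorConfig",
    "GrowthModel",
    "SyntheticDataset",
    "gen_climate",
    "gen_stand_trajectory",
    "gen_dataset",
    "truth_stl",
]


@dataclass
class TruthParams:
    """Ground-truth parameters of the generative model.

    The mortality block (beta0..beta4, sigma_beta0, theta) drives the
    negative-binomial mortality draws; beta5 is the composite-MAT effect used
    when generating with space and time effects collapsed (beta3 = beta4 =
    beta5).  The alpha block is the static size-density allometry truth used
    for exact-recovery tests of the static model.  MAT covariates enter
    centred at ``mat_center``.
    """

    # static allometry truth
    alpha0: float = 12.29
    alpha1: float = -1.67
    alpha2: float = -0.09
    sigma_alpha0: float = 0.12
    sigma: float = 0.06
    # mortality truth (space/time decomposition)
    beta0: float = -29.38
    beta1: float = 2.92
    beta2: float = 2.38
    beta3: float = 0.15
    beta4: float = 0.28
    beta5: float = 0.22
    sigma_beta0: float = 0.84
    theta: float = 9.39
    # dead-tree relative size
    k_true: float = 0.62
    k_noise_sd: float = 0.1
    # growth submodel
    g_max: float = 1.2  # cm/yr potential QMD increment of a small open-grown stand
    d_scale: float = 80.0  # cm, e-folding of the size-related growth decline
    c_crowd: float = 0.5  # density-dependence strength (relative to the thinning line)
    g_noise_sd: float = 0.15  # lognormal sd of the period growth draw
    g_floor: float = 0.1  # minimum growth as a fraction of the size-potential
    mat_center: float = 11.0  # deg C, centring constant for MAT covariates

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.sigma_beta0 < 0 or self.sigma <= 0:
            raise ValueError("theta and noise scales must be positive")
        if not 0 < self.k_true < 1:
            raise ValueError("k_true must lie in (0, 1)")

    @classmethod
    def composite(cls, **overrides) -> "TruthParams":
        """Truth with a single composite MAT effect (beta3 = beta4 = beta5).

        Defaults to the composite-model parameterisation (beta0 = -29.61,
        beta1 = 2.95, beta2 = 2.40, beta5 = 0.22, theta = 9.42).
        """
        base = dict(beta0=-29.61, beta1=2.95, beta2=2.40, beta3=0.22, beta4=0.22,
                    beta5=0.22, theta=9.42)
        base.update(overrides)
        return cls(**base)


@dataclass
class GeneratorConfig:
    """Structural configuration of the synthetic plot network."""

    n_plots: int = 112
    n_control: int = 40
    area_range: tuple[float, float] = (400.0, 8000.0)  # m^2, log-uniform (mean ~2600)
    census_interval: tuple[float, float] = (2.0, 3.0)  # years
    start_window: tuple[float, float] = (1955.0, 1975.0)  # first census year
    record_window: tuple[int, int] = (1947, 2000)  # climate record span
    mat_range: tuple[float, float] = (9.5, 12.5)  # deg C spatial gradient
    warming_trend: float = 0.71  # deg C total rise across the record window
    anomaly_sd: float = 0.4  # deg C interannual
    precip_range: tuple[float, float] = (1000.0, 1600.0)  # mm/yr plot means
    precip_sd: float = 100.0  # mm/yr interannual
    vpd_intercept: float = 0.10  # kPa
    vpd_slope: float = 0.06  # kPa per deg C
    vpd_noise_sd: float = 0.015  # kPa
    vpd_start_year: int = 1980
    d0_range: tuple[float, float] = (10.0, 20.0)  # cm initial QMD
    rel_density_range: tuple[float, float] = (0.3, 0.8)  # initial N / N_max
    thin_fraction: float = 0.3  # stems removed at the thinning census

    def __post_init__(self) -> None:
        if self.n_control > self.n_plots:
            raise ValueError("n_control cannot exceed n_plots")
        for name in ("area_range", "census_interval", "start_window", "mat_range",
                     "precip_range", "d0_range", "rel_density_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be a non-degenerate range")


def truth_stl(truth: TruthParams, mat_centered: float = 0.0, b0: float | None = None):
    """(intercept, slope) of the truth self-thinning line at a given centred MAT.

    intercept = b0c/(-beta2) + (log beta2 - log(beta1+1))/(-beta2) with
    b0c = beta0 + beta5 * mat_centered; slope = (1+beta1)/(-beta2).
    """
    b0c = (truth.beta0 if b0 is None else b0) + truth.beta5 * mat_centered
    inv = -truth.beta2
    intercept = b0c / inv + (math.log(truth.beta2) - math.log(truth.beta1 + 1.0)) / inv
    slope = (1.0 + truth.beta1) / inv
    return intercept, slope


@dataclass
class GrowthModel:
    """QMD growth submodel: annual increment declining with size and crowding.

    g = g_max * exp(-D/d_scale) * max(1 - c_crowd * N/N_max(D), g_floor),
    with N_max(D) the truth self-thinning line; a lognormal multiplicative
    noise term is applied to each period draw when an rng is supplied.
    """

    truth: TruthParams
    stl_intercept: float = None  # log N at log D = 0; defaults to truth line
    stl_slope: float = None

    def __post_init__(self) -> None:
        if self.stl_intercept is None or self.stl_slope is None:
            a, s = truth_stl(self.truth)
            self.stl_intercept = a if self.stl_intercept is None else self.stl_intercept
            self.stl_slope = s if self.stl_slope is None else self.stl_slope

    def n_max(self, d: float) -> float:
        return math.exp(self.stl_intercept + self.stl_slope * math.log(d))

    def annual_increment(self, d: float, n_ha: float, rng: np.random.Generator | None = None) -> float:
        t = self.truth
        crowd = max(1.0 - t.c_crowd * n_ha / self.n_max(d), t.g_floor)
        g = t.g_max * math.exp(-d / t.d_scale) * crowd
        if rng is not None:
            g *= math.exp(rng.normal(0.0, t.g_noise_sd))
        return g


def _plot_rng(seed: int, plot_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(plot_index,)))


def gen_climate(config: GeneratorConfig, seed: int, plot_ids=None, baselines=None) -> pd.DataFrame:
    """Generate per-plot annual climate series across the record window.

    Annual MAT = plot baseline + linear trend (totalling ``warming_trend``
    across the window, centred so the window mean stays at the baseline) +
    iid anomaly.  Precipitation is a plot mean with interannual noise.  VPD is
    an affine function of MAT plus small noise, defined only from
    ``vpd_start_year`` onwards.
    """
    y0, y1 = config.record_window
    years = np.arange(y0, y1 + 1)
    frac = (years - y0) / (y1 - y0) - 0.5
    rows = []
    n = config.n_plots if plot_ids is None else len(plot_ids)
    for j in range(n):
        rng = _plot_rng(seed, j)
        # plot-level draws in a fixed order so trajectories can re-derive them
        baseline = rng.uniform(*config.mat_range) if baselines is None else baselines[j]
        pmean = rng.uniform(*config.precip_range)
        mat = baseline + config.warming_trend * frac + rng.normal(0.0, config.anomaly_sd, size=years.size)
        precip = np.clip(pmean + rng.normal(0.0, config.precip_sd, size=years.size), 200.0, None)
        vpd = config.vpd_intercept + config.vpd_slope * mat + rng.normal(0.0, config.vpd_noise_sd, size=years.size)
        vpd = np.where(years >= config.vpd_start_year, vpd, np.nan)
        pid = f"P{j+1:03d}" if plot_ids is None else plot_ids[j]
        rows.append(pd.DataFrame({
            "plot_id": pid, "year": years, "mat_c": mat, "precip_mm": precip, "vpd_kpa": vpd,
        }))
    return pd.concat(rows, ignore_index=True)


def _draw_mortality(mu: float, theta: float, n_raw: int, rng: np.random.Generator) -> int:
    """NB(mu, theta) draw truncated at the live count."""
    draw = int(rng.negative_binomial(theta, theta / (theta + mu)))
    return min(draw, n_raw)


def gen_stand_trajectory(
    plot_id: str,
    plot_index: int,
    truth: TruthParams,
    config: GeneratorConfig,
    climate: pd.DataFrame,
    seed: int,
    control: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one plot's census series under the growth-mortality model.

    Returns (censuses, periods, plot_meta).  ``censuses`` has one row per
    census (date, D, N_raw); ``periods`` one row per intercensus period with
    the realised mortality count, removals, QMD increment and dead-tree QMD.
    The plot rng replays the climate draws first so climate and dynamics stay
    coupled to the same substream.
    """
    rng = _plot_rng(seed, plot_index)
    y0, y1 = config.record_window
    n_years = y1 - y0 + 1
    # replay the climate-generation draws so subsequent draws are fresh
    rng.uniform(*config.mat_range)
    rng.uniform(*config.precip_range)
    rng.normal(0.0, config.anomaly_sd, size=n_years)
    rng.normal(0.0, config.precip_sd, size=n_years)
    rng.normal(0.0, config.vpd_noise_sd, size=n_years)

    area = math.exp(rng.uniform(math.log(config.area_range[0]), math.log(config.area_range[1])))
    area_ha = area / 10000.0
    b0j = truth.beta0 + rng.normal(0.0, truth.sigma_beta0)

    cseries = climate[climate["plot_id"] == plot_id]
    mat_lt = longterm_mean(cseries)
    mat_lt_c = mat_lt - truth.mat_center

    # census dates
    t = rng.uniform(*config.start_window)
    dates = [t]
    while True:
        t = t + rng.uniform(*config.census_interval)
        if t > y1:
            break
        dates.append(t)
    thin_idx = -1
    if not control and len(dates) > 3:
        thin_idx = int(rng.integers(1, max(2, len(dates) - 2)))

    d0 = rng.uniform(*config.d0_range)
    rel = rng.uniform(*config.rel_density_range)
    # initial stocking sits on the population-level line for the plot's
    # climate: establishment density is independent of the plot's latent
    # mortality intercept (which only reveals itself through later deaths)
    a_plot, s_plot = truth_stl(truth, mat_centered=mat_lt_c)
    n0_ha = rel * math.exp(a_plot + s_plot * math.log(d0))
    n_raw = max(10, int(round(n0_ha * area_ha)))
    plot_line = GrowthModel(truth, stl_intercept=a_plot, stl_slope=s_plot)

    cen_rows = [{"plot_id": plot_id, "census_date": dates[0], "D": d0, "N_raw": n_raw}]
    per_rows = []
    d = d0
    for i in range(len(dates) - 1):
        if n_raw < 2:
            break
        start, end = dates[i], dates[i + 1]
        interval = end - start
        mat_ij = period_climate(cseries, start, min(end, y1 + 1 - 1e-9))
        anom = mat_ij - mat_lt
        n_ha = n_raw / area_ha

        # growth draw (always positive by construction)
        delta_d = interval * plot_line.annual_increment(d, n_ha, rng=rng)

        log_mu = (b0j + truth.beta3 * mat_lt_c + truth.beta4 * anom
                  + truth.beta1 * math.log(d) + truth.beta2 * math.log(n_ha)
                  + math.log(delta_d) + math.log(n_raw))
        mu = math.exp(log_mu)
        dead = _draw_mortality(mu, truth.theta, n_raw, rng)
        dead_qmd = float("nan")
        if dead > 0:
            dead_qmd = truth.k_true * d * math.exp(rng.normal(0.0, truth.k_noise_sd))
        removed = 0
        if i == thin_idx:
            removed = int(round(config.thin_fraction * (n_raw - dead)))
        d_end = d + delta_d
        n_raw_end = n_raw - dead - removed
        per_rows.append({
            "plot_id": plot_id, "start": start, "end": end, "interval": interval,
            "D_start": d, "N_start": n_ha, "N_raw_start": n_raw,
            "delta_N": dead, "removed_N": removed, "delta_D": delta_d,
            "dead_qmd": dead_qmd, "area": area, "ba_share_start": 1.0,
            "mu_true": mu, "mat_longterm_true": mat_lt, "mat_ij_true": mat_ij,
        })
        cen_rows.append({"plot_id": plot_id, "census_date": end, "D": d_end, "N_raw": n_raw_end})
        d, n_raw = d_end, n_raw_end

    meta = {"plot_id": plot_id, "area_m2": area, "control": control,
            "thinned_flag": not control, "disturbed_flag": False, "b0j_true": b0j,
            "mat_longterm_true": mat_lt}
    return pd.DataFrame(cen_rows), pd.DataFrame(per_rows), meta


def _materialize_trees(censuses: pd.DataFrame, periods: pd.DataFrame, species: str = "E. regnans") -> pd.DataFrame:
    """Expand stand-level censuses into tree records.

    All live trees carry the stand QMD as their DBH (a deliberate degenerate
    size distribution: the QMD is then insensitive to which tree dies, keeping
    tree records exactly consistent with the stand-level dynamics).  Trees
    that died during the preceding period appear once, at the end census, with
    the period's dead-tree QMD; removed trees appear once with status removed.
    """
    plot_id = censuses["plot_id"].iloc[0]
    n0 = int(censuses["N_raw"].iloc[0])
    alive = [f"{plot_id}_T{k+1:04d}" for k in range(n0)]
    rows = {"tree_id": [], "census_date": [], "dbh_cm": [], "status": []}

    def emit(ids, date, dbh, status):
        rows["tree_id"].extend(ids)
        rows["census_date"].extend([date] * len(ids))
        rows["dbh_cm"].extend([dbh] * len(ids))
        rows["status"].extend([status] * len(ids))

    emit(alive, censuses["census_date"].iloc[0], censuses["D"].iloc[0], "alive")
    pers = periods.reset_index(drop=True)
    for i, p in pers.iterrows():
        dead = [alive.pop() for _ in range(int(p["delta_N"]))]
        removed = [alive.pop() for _ in range(int(p["removed_N"]))]
        date = censuses["census_date"].iloc[i + 1]
        d_end = censuses["D"].iloc[i + 1]
        emit(alive, date, d_end, "alive")
        if dead:
            emit(dead, date, p["dead_qmd"], "dead")
        if removed:
            emit(removed, date, d_end, "removed")
    out = pd.DataFrame(rows)
    out.insert(0, "plot_id", plot_id)
    out["species"] = species
    return out


@dataclass
class SyntheticDataset:
    """A complete synthetic study: inventory, plots, climate, truth."""

    inventory: pd.DataFrame | None
    plots: pd.DataFrame
    climate: pd.DataFrame
    periods: pd.DataFrame  # generator's own period summaries (ground truth)
    censuses: pd.DataFrame
    truth: TruthParams
    config: GeneratorConfig
    seed: int

    def model_frame(self) -> pd.DataFrame:
        """Periods with the generator's own climate covariates attached.

        Equivalent to running the climate-covariate pipeline on the emitted
        files (the generator computes long-term means and period climates
        through the same functions); convenient for fitting directly.
        """
        out = self.periods.rename(columns={
            "mat_longterm_true": "mat_longterm", "mat_ij_true": "mat_ij"})
        out["mat_anomaly"] = out["mat_ij"] - out["mat_longterm"]
        out["year_mid"] = 0.5 * (out["start"] + out["end"])
        return out

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if self.inventory is not None:
            self.inventory.to_csv(out / "inventory.csv", index=False)
        self.plots.to_csv(out / "plots.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.periods.to_csv(out / "periods_truth.csv", index=False)
        payload = {
            "seed": self.seed,
            "truth": dataclasses.asdict(self.truth),
            "config": dataclasses.asdict(self.config),
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=2))


def gen_dataset(
    config: GeneratorConfig | None = None,
    truth: TruthParams | None = None,
    seed: int = 0,
    tree_level: bool = True,
) -> SyntheticDataset:
    """Generate the full synthetic study.

    ``tree_level=False`` skips materialising individual tree records (the
    stand-level dynamics and all random draws are identical either way).
    """
    config = config or GeneratorConfig()
    truth = truth or TruthParams()
    plot_ids = [f"P{j+1:03d}" for j in range(config.n_plots)]
    climate = gen_climate(config, seed, plot_ids=plot_ids)
    inv_frames, per_frames, cen_frames, metas = [], [], [], []
    for j, pid in enumerate(plot_ids):
        control = j < config.n_control
        cen, per, meta = gen_stand_trajectory(pid, j, truth, config, climate, seed, control=control)
        metas.append(meta)
        per_frames.append(per)
        cen_frames.append(cen)
        if tree_level:
            inv_frames.append(_materialize_trees(cen, per))
    inventory = pd.concat(inv_frames, ignore_index=True) if tree_level else None
    nonempty = [f for f in per_frames if len(f)]
    per_cols = ["plot_id", "start", "end", "interval", "D_start", "N_start",
                "N_raw_start", "delta_N", "removed_N", "delta_D", "dead_qmd",
                "area", "ba_share_start", "mu_true", "mat_longterm_true", "mat_ij_true"]
    periods = (pd.concat(nonempty, ignore_index=True) if nonempty
               else pd.DataFrame(columns=per_cols))
    censuses = pd.concat(cen_frames, ignore_index=True)
    return SyntheticDataset(
        inventory=inventory,
        plots=pd.DataFrame(metas),
        climate=climate,
        periods=periods,
        censuses=censuses,
        truth=truth,
        config=config,
        seed=seed,
    )
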