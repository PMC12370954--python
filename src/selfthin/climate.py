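"""Climate covariates for self-thinning models.

Predictors follow a space/time decomposition of mean annual temperature: the
plot-level long-term mean MAT over a reference window (default 1960-2000)
captures spatial climate differences among plots, while the per-period
anomaly (period mean minus long-term mean) captures temporal variation within
a plot.  Their sum, the period MAT, is the composite predictor.  Annual
precipitation P, the annual heat-moisture index AHMI = (MAT+10)/(P/1000)
(an aridity index, higher = more arid) and vapour pressure deficit VPD
(post-1980 only) are carried as alternative covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ahmi",
    "longterm_mean",
    "period_climate",
    "CovariateTransform",
    "build_covariates",
    "read_climate",
]

REFERENCE_WINDOW = (1960, 2000)


def ahmi(mat, p):
    """Annual heat-moisture index (MAT + 10) / (P / 1000).

    ``mat`` in deg C, ``p`` in mm/yr (> 0).  Unitless; increasing in MAT and
    decreasing in P.
    """
    mat = np.asarray(mat, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise ValueError("AHMI requires precipitation > 0")
    out = (mat + 10.0) / (p / 1000.0)
    return float(out) if out.ndim == 0 else out


def longterm_mean(
    series: pd.DataFrame,
    window: tuple[int, int] = REFERENCE_WINDOW,
    var: str = "mat_c",
) -> float:
    """Mean of an annual climate variable over an inclusive year window."""
    lo, hi = window
    sel = series[(series["year"] >= lo) & (series["year"] <= hi)]
    if sel.empty:
        plot = series["plot_id"].iloc[0] if "plot_id" in series.columns and len(series) else "?"
        raise ValueError(f"no climate records in window {window} for plot {plot}")
    return float(sel[var].mean())


def period_climate(
    series: pd.DataFrame,
    start: float,
    end: float,
    var: str = "mat_c",
) -> float:
    """Duration-weighted mean of an annual variable over [start, end].

    Each calendar year y contributes the overlap of [y, y+1) with the period
    as its weight; a period spanning two years equally returns their simple
    mean.
    """
    if not end > start:
        raise ValueError("period end must exceed start")
    years = np.arange(int(np.floor(start)), int(np.ceil(end)))
    w = np.minimum(end, years + 1.0) - np.maximum(start, years.astype(float))
    w = np.clip(w, 0.0, None)
    avail = series.set_index("year")[var]
    missing = [int(y) for y, wy in zip(years, w) if wy > 0 and y not in avail.index]
    if missing:
        raise ValueError(f"climate series missing years {missing}")
    vals = np.array([avail.loc[y] for y in years])
    mask = w > 0
    return float(np.average(vals[mask], weights=w[mask]))


@dataclass
class CovariateTransform:
    """Invertible centre / centre+scale transform with stored constants.

    ``scheme`` is one of ``none``, ``center``, ``center_scale``.  Scaling uses
    the sample (n-1) standard deviation.  The constants are learned from the
    fitting dataset and reused verbatim for prediction on new data.
    """

    scheme: str = "center"
    center: float = 0.0
    scale: float = 1.0
    fitted: bool = field(default=False, repr=False)

    def fit(self, values) -> "CovariateTransform":
        v = np.asarray(values, dtype=float)
        if self.scheme not in ("none", "center", "center_scale"):
            raise ValueError(f"unknown transform scheme {self.scheme!r}")
        if self.scheme == "none":
            self.center, self.scale = 0.0, 1.0
        else:
            self.center = float(np.mean(v))
            if self.scheme == "center_scale":
                sd = float(np.std(v, ddof=1))
                if sd == 0.0 or not np.isfinite(sd):
                    raise ValueError("center_scale transform undefined for zero-variance data")
                self.scale = sd
            else:
                self.scale = 1.0
        self.fitted = True
        return self

    def transform(self, values):
        v = np.asarray(values, dtype=float)
        return (v - self.center) / self.scale

    def inverse(self, values):
        v = np.asarray(values, dtype=float)
        return v * self.scale + self.center


DEFAULT_SCHEMES = {
    "mat": "center",
    "vpd": "center",
    "p": "center_scale",
    "ahmi": "center_scale",
}


def read_climate(path) -> pd.DataFrame:
    """Read an annual climate CSV: plot_id, year, mat_c, precip_mm[, vpd_kpa]."""
    df = pd.read_csv(path, dtype={"plot_id": str})
    required = {"plot_id", "year", "mat_c", "precip_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"climate file missing columns: {sorted(missing)}")
    return df


def build_covariates(
    periods: pd.DataFrame,
    climate: pd.DataFrame,
    window: tuple[int, int] = REFERENCE_WINDOW,
) -> pd.DataFrame:
    """Attach climate covariates to a periods table.

    Adds ``mat_longterm`` (per plot, reference-window mean), ``mat_ij``
    (duration-weighted period mean), ``mat_anomaly`` (= mat_ij - mat_longterm,
    exact by construction), ``p_ij``, ``ahmi_ij`` and, where available,
    ``vpd_ij`` and the period midpoint ``year_mid``.
    """
    out = periods.copy()
    has_vpd = "vpd_kpa" in climate.columns
    lt: dict[str, float] = {}
    for plot_id, grp in climate.groupby("plot_id"):
        lt[str(plot_id)] = longterm_mean(grp, window=window)
    out["mat_longterm"] = out["plot_id"].astype(str).map(lt)

    mats, ps, vpds = [], [], []
    by_plot = {str(k): g for k, g in climate.groupby("plot_id")}
    for row in out.itertuples():
        g = by_plot[str(row.plot_id)]
        mats.append(period_climate(g, row.start, row.end, var="mat_c"))
        ps.append(period_climate(g, row.start, row.end, var="precip_mm"))
        if has_vpd:
            sub = g.dropna(subset=["vpd_kpa"])
            try:
                vpds.append(period_climate(sub, row.start, row.end, var="vpd_kpa"))
            except ValueError:
                vpds.append(float("nan"))
    out["mat_ij"] = mats
    out["p_ij"] = ps
    out["mat_anomaly"] = out["mat_ij"] - out["mat_longterm"]
    out["ahmi_ij"] = ahmi(out["mat_ij"].to_numpy(), out["p_ij"].to_numpy())
    if has_vpd:
        out["vpd_ij"] = vpds
    out["year_mid"] = 0.5 * (out["start"] + out["end"])
    return out
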