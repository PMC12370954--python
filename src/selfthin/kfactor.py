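"""Relative size of dying trees (the k factor).

In self-thinning stands the trees that die are the suppressed ones, so the
quadratic mean diameter of the trees that died in a period is a fraction k
of the live-tree QMD at the period's start:

    k = D_dead / D

A pooled k is estimated by a zero-intercept least-squares regression of
D_dead on D over mortality events (consistent with k being a ratio and with
the 1:1 reference line of the diagnostic plot); events with three or fewer
dead trees are discarded to reduce dispersion of the dead-tree QMD.  Linear
mixed models (plot random intercept) test whether k drifts with climate
(MAT, P, AHMI), calendar year, or stand dominant height.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["MortalityEvent", "extract_events", "fit_k", "test_k_covariates", "dominant_height"]


@dataclass
class MortalityEvent:
    """One period with recorded dead-tree QMD."""

    plot_id: str
    start: float
    end: float
    n_dead: int
    D_live_start: float
    D_dead_end: float

    @property
    def k(self) -> float:
        return self.D_dead_end / self.D_live_start


def extract_events(periods: pd.DataFrame, min_dead: int = 3) -> pd.DataFrame:
    """Mortality events with strictly more than ``min_dead`` dead trees.

    ``periods`` needs delta_N, dead_qmd, D_start (plus plot_id and any
    covariate columns, which are carried through).  Events lacking a
    dead-tree QMD are skipped and counted in ``attrs['skipped_no_qmd']``.
    """
    has_dead = periods["delta_N"] > min_dead
    qmd_ok = periods["dead_qmd"].notna()
    out = periods[has_dead & qmd_ok].copy()
    out["k"] = out["dead_qmd"] / out["D_start"]
    out.attrs["skipped_no_qmd"] = int((has_dead & ~qmd_ok).sum())
    return out


def fit_k(events: pd.DataFrame, intercept: bool = False, level: float = 0.95) -> dict:
    """Pooled k: regression of dead-tree QMD on live-tree QMD.

    Through the origin by default (the slope is the pooled k); ``intercept=
    True`` adds a free intercept.  Returns slope, its confidence interval and
    the fit's n.
    """
    if len(events) < 2:
        raise ValueError("fit_k needs at least two events")
    x = events["D_start"].to_numpy(dtype=float)
    y = events["dead_qmd"].to_numpy(dtype=float)
    if np.allclose(x, 0.0):
        raise ValueError("degenerate events: all live QMDs are zero")
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=1 - level)
    i = 1 if intercept else 0
    return {
        "slope": float(res.params[i]),
        "slope_lower": float(ci[i][0]),
        "slope_upper": float(ci[i][1]),
        "intercept": float(res.params[0]) if intercept else 0.0,
        "n": int(len(events)),
    }


def test_k_covariates(events: pd.DataFrame, covariates: dict[str, str] | None = None,
                      level: float = 0.95) -> pd.DataFrame:
    """Mixed-model tests of k against each covariate, one at a time.

    ``covariates`` maps a label to a column of ``events`` (defaults: MAT, P,
    AHMI, calendar year, and dominant height Ho where present).  Each model
    is k ~ covariate with a plot random intercept; the report says whether
    the coefficient's interval covers zero.  A covariate constant across
    events is flagged as degenerate rather than fitted.
    """
    if covariates is None:
        covariates = {"mat": "mat_ij", "p": "p_ij", "ahmi": "ahmi_ij", "year": "year_mid"}
        if "ho" in events.columns:
            covariates["ho"] = "ho"
    if events["plot_id"].nunique() < 2:
        raise ValueError("covariate tests need events from at least two plots")
    rows = []
    for label, col in covariates.items():
        if col not in events.columns:
            continue
        sub = events.dropna(subset=[col, "k"])
        x = sub[col].to_numpy(dtype=float)
        if len(sub) < 3 or np.std(x) == 0.0:
            rows.append({"covariate": label, "coef": np.nan, "lower": np.nan,
                         "upper": np.nan, "covers_zero": None, "degenerate": True})
            continue
        exog = np.column_stack([np.ones(len(sub)), x - x.mean()])
        codes, _ = pd.factorize(sub["plot_id"])
        res = sm.MixedLM(sub["k"].to_numpy(dtype=float), exog, groups=codes).fit(reml=True)
        coef = float(res.fe_params[1])
        se = float(res.bse_fe[1])
        from scipy import stats

        z = stats.norm.ppf(0.5 + level / 2)
        lo, hi = coef - z * se, coef + z * se
        rows.append({"covariate": label, "coef": coef, "lower": lo, "upper": hi,
                     "covers_zero": bool(lo <= 0.0 <= hi), "degenerate": False})
    return pd.DataFrame(rows)


def dominant_height(heights_m, dbhs_cm, area_m2: float) -> float:
    """Dominant height Ho: mean height of the 100 largest-diameter trees per ha.

    Only computable when tree heights were measured; the number of trees
    entering the mean scales with plot area (100 per hectare).
    """
    h = np.asarray(heights_m, dtype=float)
    d = np.asarray(dbhs_cm, dtype=float)
    if h.size == 0 or h.size != d.size:
        raise ValueError("heights and dbhs must be non-empty and matched")
    n_top = max(1, int(round(100.0 * area_m2 / 10000.0)))
    order = np.argsort(d)[::-1]
    return float(np.mean(h[order[:n_top]]))
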