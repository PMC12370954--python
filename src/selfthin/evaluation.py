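"""Goodness-of-fit metrics and leave-one-plot-out cross-validation.

Accuracy is summarised by the coefficient of determination, root mean
squared error and bias,

    R^2  = 1 - SSE/SST,   RMSE = sqrt(SSE/n),   BIAS = sum(y - yhat)/n,

computed on out-of-sample predictions from leave-one-plot-out
cross-validation: each fold drops one whole plot, refits, and predicts the
held-out plot with the random effect at its population mean (the only
defensible choice for a never-seen plot).  Mortality predictions are scored
as raw counts, counts per hectare, and rates (count / live trees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MetricReport", "compute_metrics", "loo_plot_cv"]


@dataclass
class MetricReport:
    """R^2, RMSE and bias of a set of predictions (response units)."""

    r2: float
    rmse: float
    bias: float
    n: int
    response_label: str = ""
    r2_defined: bool = True


def compute_metrics(y, yhat, response_label: str = "") -> MetricReport:
    """Metric formulas applied to matched observed/predicted vectors."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("y and yhat must be matched vectors of length >= 2")
    err = y - yhat
    sse = float(np.sum(err**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / y.size))
    bias = float(np.sum(err) / y.size)
    if sst == 0.0:
        return MetricReport(r2=float("nan"), rmse=rmse, bias=bias, n=y.size,
                            response_label=response_label, r2_defined=False)
    return MetricReport(r2=1.0 - sse / sst, rmse=rmse, bias=bias, n=y.size,
                        response_label=response_label)


def loo_plot_cv(data: pd.DataFrame, model: str = "eq_composite", mat_center: float | None = None,
                n_draws: int = 200, seed: int | None = None, allow_skip: bool = False,
                fit_kwargs: dict | None = None) -> dict:
    """Leave-one-plot-out cross-validation of the static or mortality model.

    ``model`` is 'static', 'eq_space_time'/'eq2' or 'eq_composite'/'eq3';
    ``data`` is a retained-periods table with climate covariates.  Returns
    pooled :class:`MetricReport` objects per response plus per-fold records.
    A fold whose refit fails aborts the run unless ``allow_skip``.
    """
    from .mortality import MortalityModel
    from .static_model import StaticThinningModel

    fit_kwargs = dict(fit_kwargs or {})
    plots = list(pd.unique(data["plot_id"]))
    if len(plots) < 3:
        raise ValueError("leave-one-plot-out needs at least three plots")
    if mat_center is None:
        mat_center = float(data["mat_longterm"].mean())

    preds, folds = [], []
    for plot in plots:
        train = data[data["plot_id"] != plot]
        test = data[data["plot_id"] == plot]
        try:
            if model == "static":
                m = StaticThinningModel.from_dataframe(train)
                fit = m.fit(n_draws=max(n_draws, 100), seed=seed, **fit_kwargs)
                pred = fit.predict_max_log_density(
                    test["D_start"].to_numpy(), test["mat_longterm"].to_numpy())
                obs = np.log(test["N_start"].to_numpy())
                preds.append(pd.DataFrame({
                    "plot_id": plot, "y_logN": obs, "yhat_logN": pred["log_n"].to_numpy()}))
            else:
                m = MortalityModel.from_dataframe(train, variant=model, mat_center=mat_center)
                fit = m.fit(n_draws=max(n_draws, 100), seed=seed, **fit_kwargs)
                kw = {}
                if fit.variant == "eq_space_time":
                    kw = {"mat_longterm": test["mat_longterm"].to_numpy(),
                          "mat_anomaly": test["mat_anomaly"].to_numpy()}
                else:
                    kw = {"mat_ij": test["mat_ij"].to_numpy()}
                pr = fit.predict(test["D_start"].to_numpy(), test["N_start"].to_numpy(),
                                 test["delta_D"].to_numpy(), test["N_raw_start"].to_numpy(), **kw)
                area_ha = test["area"].to_numpy() / 10000.0
                preds.append(pd.DataFrame({
                    "plot_id": plot,
                    "y_count": test["delta_N"].to_numpy(dtype=float),
                    "yhat_count": pr["mu"].to_numpy(),
                    "y_count_ha": test["delta_N"].to_numpy() / area_ha,
                    "yhat_count_ha": pr["mu"].to_numpy() / area_ha,
                    "y_rate": test["delta_N"].to_numpy() / test["N_raw_start"].to_numpy(),
                    "yhat_rate": pr["rate"].to_numpy(),
                }))
            folds.append({"plot_id": plot, "n_test": len(test), "ok": True})
        except Exception as exc:  # refit failure
            folds.append({"plot_id": plot, "n_test": len(test), "ok": False, "error": str(exc)})
            if not allow_skip:
                raise
    pooled = pd.concat(preds, ignore_index=True)
    reports: dict[str, MetricReport] = {}
    if model == "static":
        reports["logN"] = compute_metrics(pooled["y_logN"], pooled["yhat_logN"], "logN")
    else:
        reports["mortality_count"] = compute_metrics(pooled["y_count"], pooled["yhat_count"], "mortality_count")
        reports["mortality_count_per_ha"] = compute_metrics(
            pooled["y_count_ha"], pooled["yhat_count_ha"], "mortality_count_per_ha")
        reports["mortality_rate"] = compute_metrics(pooled["y_rate"], pooled["yhat_rate"], "mortality_rate")
    return {"metrics": reports, "folds": pd.DataFrame(folds), "predictions": pooled}
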