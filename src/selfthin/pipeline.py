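"""End-to-end helpers chaining inventory processing, filters and covariates."""

from __future__ import annotations

import pandas as pd

from .climate import build_covariates
from .inventory import (FilterCriteria, apply_filters, build_periods,
                        periods_to_frame, snapshots_from_inventory)

__all__ = ["periods_from_inventory", "prepared_dataset", "control_plot_ids"]


def periods_from_inventory(inventory: pd.DataFrame, plots: pd.DataFrame,
                           target_species: str = "E. regnans") -> pd.DataFrame:
    """Tree records -> per-plot snapshots -> intercensus periods table."""
    snaps = snapshots_from_inventory(inventory, plots, target_species=target_species)
    all_periods = []
    for plot_id in sorted(snaps):
        all_periods.extend(build_periods(snaps[plot_id]))
    return periods_to_frame(all_periods)


def control_plot_ids(periods: pd.DataFrame) -> list[str]:
    """Plots that never had a removal (unthinned controls)."""
    removed = periods.groupby("plot_id")["removed_N"].sum()
    return sorted(removed[removed == 0].index)


def prepared_dataset(inventory: pd.DataFrame, plots: pd.DataFrame, climate: pd.DataFrame,
                     criteria: FilterCriteria | None = None,
                     target_species: str = "E. regnans") -> dict:
    """Full preparation: periods, selection filters, climate covariates.

    Returns a dict with the filtered-and-annotated ``periods`` table (only
    retained rows, with covariates), the unfiltered ``all_periods`` table
    (with exclusion reasons), and the list of ``control_plots``.
    """
    per = periods_from_inventory(inventory, plots, target_species=target_species)
    flagged = apply_filters(per, criteria=criteria, plots=plots)
    retained = flagged[flagged["retained"]].reset_index(drop=True)
    with_cov = build_covariates(retained, climate)
    return {
        "periods": with_cov,
        "all_periods": flagged,
        "control_plots": control_plot_ids(per),
    }
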