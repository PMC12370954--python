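"""Permanent-plot inventory processing for even-aged stands.

The raw material of a self-thinning analysis is a network of permanent sample
plots remeasured every few years: each census records the diameter at breast
height (DBH, 1.3 m) and status of every tagged tree.  This module turns those
tree records into the stand-level quantities the models consume — quadratic
mean diameter ``D``, stocking ``N`` (trees per hectare), and per-period
mortality counts — and applies the plot/period selection rules (minimum plot
area, census interval, diameter growth, and basal-area purity of the target
species).

Removals (harvested trees in thinning treatments) are tracked separately from
deaths and never contribute to the mortality count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeRecord",
    "CensusSnapshot",
    "IntercensusPeriod",
    "FilterCriteria",
    "quadratic_mean_diameter",
    "summarize_census",
    "build_periods",
    "apply_filters",
    "periods_to_frame",
    "read_inventory",
    "snapshots_from_inventory",
]

ALIVE = "alive"
DEAD = "dead"
REMOVED = "removed"
_STATUSES = {ALIVE, DEAD, REMOVED}


@dataclass(frozen=True)
class TreeRecord:
    """A single tree observation at one census."""

    tree_id: str
    dbh: float  # cm at 1.3 m
    status: str  # alive | dead | removed
    species: str = "target"

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"unknown status {self.status!r} for tree {self.tree_id}")
        if self.status == ALIVE and not self.dbh > 0:
            raise ValueError(f"alive tree {self.tree_id} must have dbh > 0, got {self.dbh}")


@dataclass
class CensusSnapshot:
    """Stand state of one plot at one census date.

    ``D`` is the quadratic mean diameter of live trees (cm), ``N`` the live
    density in trees/ha and ``N_raw`` the raw live count; ``N`` and ``N_raw``
    satisfy ``N = N_raw * 10000 / area`` exactly.  ``D`` is ``nan`` (with
    ``d_defined=False``) when the plot holds no live trees.
    """

    plot_id: str
    census_date: float  # decimal year
    area: float  # m^2
    trees: Sequence[TreeRecord] = field(default_factory=list, repr=False)
    D: float = float("nan")
    N: float = 0.0
    N_raw: int = 0
    basal_area_share_target: float = float("nan")
    d_defined: bool = False


@dataclass
class IntercensusPeriod:
    """Changes on one plot between two successive censuses.

    ``delta_N`` counts trees alive at the start that were recorded dead at the
    end; removals are bookkept separately.  ``dead_qmd`` is the quadratic mean
    diameter of the dead trees at the end census (nan when no tree died), used
    by the relative-size (k-factor) analysis.
    """

    plot_id: str
    start_date: float
    end_date: float
    interval: float
    delta_N: int
    removed_N: int
    delta_D: float
    D_start: float
    N_start: float
    N_raw_start: int
    dead_qmd: float = float("nan")
    area: float = float("nan")
    ba_share_start: float = float("nan")


@dataclass
class FilterCriteria:
    """Plot/period selection thresholds.

    Defaults follow the standard protocol for pure even-aged stands: >80 %
    basal area in the target species, plots of at least 400 m^2, census
    intervals of at least half a year and annualised QMD growth of at least
    0.1 cm/yr; disturbed plots (fire, insect, storm) are flagged upstream.
    """

    min_ba_share: float = 0.80
    min_area: float = 400.0
    min_interval: float = 0.5
    min_annual_delta_D: float = 0.1
    exclude_disturbed: bool = True

    def __post_init__(self) -> None:
        for name in ("min_ba_share", "min_area", "min_interval", "min_annual_delta_D"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def quadratic_mean_diameter(dbhs: Iterable[float]) -> float:
    """Quadratic mean diameter sqrt(mean(dbh^2)) of a set of DBHs in cm.

    The QMD is the diameter of the tree of average basal area; it is never
    smaller than the arithmetic mean diameter.
    """
    d = np.asarray(list(dbhs), dtype=float)
    if d.size == 0:
        raise ValueError("quadratic_mean_diameter of an empty sequence is undefined")
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError("all DBH values must be positive and finite")
    return float(np.sqrt(np.mean(d * d)))


def summarize_census(
    trees: Sequence[TreeRecord],
    area: float,
    target_species: str = "target",
    plot_id: str = "",
    census_date: float = float("nan"),
) -> CensusSnapshot:
    """Compute stand summaries (D, N, N_raw, target basal-area share).

    Only live trees enter every summary.  A plot with zero live trees yields
    ``N = 0`` and an explicitly flagged undefined ``D`` rather than silently
    propagating NaN.
    """
    if not area > 0:
        raise ValueError("plot area must be positive")
    alive = [t for t in trees if t.status == ALIVE]
    snap = CensusSnapshot(plot_id=plot_id, census_date=census_date, area=area, trees=list(trees))
    snap.N_raw = len(alive)
    snap.N = snap.N_raw * 10000.0 / area
    if alive:
        dbhs = [t.dbh for t in alive]
        snap.D = quadratic_mean_diameter(dbhs)
        snap.d_defined = True
        ba = np.array([math.pi / 4.0 * t.dbh**2 for t in alive])
        is_target = np.array([t.species == target_species for t in alive])
        snap.basal_area_share_target = float(ba[is_target].sum() / ba.sum())
    return snap


def build_periods(snapshots: Sequence[CensusSnapshot]) -> list[IntercensusPeriod]:
    """Pair successive censuses of one plot into intercensus periods.

    For each pair, ``delta_N`` counts trees alive at the start and dead at the
    end; trees with status ``removed`` at the end are counted as removals.
    Trees present at the start but absent from the end census are excluded
    from both counts with a warning (unmatched ids).  ``delta_D`` is the net
    change in live-tree QMD over the period.
    """
    if len({s.plot_id for s in snapshots}) > 1:
        raise ValueError("build_periods expects snapshots from a single plot")
    snaps = sorted(snapshots, key=lambda s: s.census_date)
    dates = [s.census_date for s in snaps]
    if len(set(dates)) != len(dates):
        raise ValueError(f"duplicate census dates in plot {snaps[0].plot_id}: {dates}")

    periods: list[IntercensusPeriod] = []
    for a, b in zip(snaps[:-1], snaps[1:]):
        start_alive = {t.tree_id: t for t in a.trees if t.status == ALIVE}
        end_by_id = {t.tree_id: t for t in b.trees}
        n_dead = 0
        n_removed = 0
        dead_dbhs: list[float] = []
        unmatched = []
        for tid in start_alive:
            if tid not in end_by_id:
                unmatched.append(tid)
                continue
            status = end_by_id[tid].status
            if status == DEAD:
                n_dead += 1
                if end_by_id[tid].dbh > 0:
                    dead_dbhs.append(end_by_id[tid].dbh)
            elif status == REMOVED:
                n_removed += 1
        if unmatched:
            warnings.warn(
                f"plot {a.plot_id}: {len(unmatched)} tree id(s) present at "
                f"{a.census_date} unmatched at {b.census_date}; excluded from counts",
                stacklevel=2,
            )
        delta_d = (b.D - a.D) if (a.d_defined and b.d_defined) else float("nan")
        periods.append(
            IntercensusPeriod(
                plot_id=a.plot_id,
                start_date=a.census_date,
                end_date=b.census_date,
                interval=b.census_date - a.census_date,
                delta_N=n_dead,
                removed_N=n_removed,
                delta_D=delta_d,
                D_start=a.D,
                N_start=a.N,
                N_raw_start=a.N_raw,
                dead_qmd=quadratic_mean_diameter(dead_dbhs) if dead_dbhs else float("nan"),
                area=a.area,
                ba_share_start=a.basal_area_share_target,
            )
        )
    return periods


def apply_filters(
    periods: pd.DataFrame,
    criteria: FilterCriteria | None = None,
    plots: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the selection rules to a periods table.

    ``periods`` needs columns ``area``, ``interval``, ``delta_D`` and
    ``ba_share_start``; a ``plots`` table (``plot_id``, ``disturbed_flag``) may
    supply the disturbance flag.  Returns the table with two added columns:
    boolean ``retained`` and ``exclusion_reason`` (comma-joined list of every
    rule the period violates, empty string when retained).  Because all rules
    are evaluated on every period, the retained set is independent of rule
    order.
    """
    criteria = criteria or FilterCriteria()
    out = periods.copy()
    if plots is not None and "disturbed_flag" in plots.columns:
        flags = plots.set_index("plot_id")["disturbed_flag"]
        disturbed = out["plot_id"].map(flags).fillna(False).astype(bool)
    elif "disturbed_flag" in out.columns:
        disturbed = out["disturbed_flag"].astype(bool)
    else:
        disturbed = pd.Series(False, index=out.index)

    annual_dd = out["delta_D"] / out["interval"]
    checks = {
        "area": out["area"] >= criteria.min_area,
        "interval": out["interval"] >= criteria.min_interval,
        "growth": annual_dd >= criteria.min_annual_delta_D,
        "ba_share": out["ba_share_start"] >= criteria.min_ba_share,
    }
    if criteria.exclude_disturbed:
        checks["disturbed"] = ~disturbed

    reasons = []
    for i in out.index:
        failed = [name for name, ok in checks.items() if not bool(ok.loc[i])]
        reasons.append(",".join(failed))
    out["exclusion_reason"] = reasons
    out["retained"] = [r == "" for r in reasons]
    return out


def periods_to_frame(periods: Sequence[IntercensusPeriod]) -> pd.DataFrame:
    """Convert a list of periods into the tabular interchange format."""
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in periods],
            "start": [p.start_date for p in periods],
            "end": [p.end_date for p in periods],
            "interval": [p.interval for p in periods],
            "D_start": [p.D_start for p in periods],
            "N_start": [p.N_start for p in periods],
            "N_raw_start": [p.N_raw_start for p in periods],
            "delta_N": [p.delta_N for p in periods],
            "removed_N": [p.removed_N for p in periods],
            "delta_D": [p.delta_D for p in periods],
            "dead_qmd": [p.dead_qmd for p in periods],
            "area": [p.area for p in periods],
            "ba_share_start": [p.ba_share_start for p in periods],
        }
    )


def read_inventory(path) -> pd.DataFrame:
    """Read a long-format inventory CSV.

    Columns: plot_id, census_date, tree_id, dbh_cm, status, species.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "tree_id": str})
    required = {"plot_id", "census_date", "tree_id", "dbh_cm", "status", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"inventory file missing columns: {sorted(missing)}")
    return df


def snapshots_from_inventory(
    inventory: pd.DataFrame,
    plots: pd.DataFrame,
    target_species: str = "target",
) -> dict[str, list[CensusSnapshot]]:
    """Build per-plot census snapshots from a long inventory table.

    ``plots`` must carry ``plot_id`` and ``area_m2``.
    """
    areas = plots.set_index("plot_id")["area_m2"]
    out: dict[str, list[CensusSnapshot]] = {}
    for (plot_id, date), grp in inventory.groupby(["plot_id", "census_date"], sort=True):
        trees = [
            TreeRecord(tree_id=str(r.tree_id), dbh=float(r.dbh_cm), status=str(r.status), species=str(r.species))
            for r in grp.itertuples()
        ]
        snap = summarize_census(
            trees,
            area=float(areas.loc[plot_id]),
            target_species=target_species,
            plot_id=str(plot_id),
            census_date=float(date),
        )
        out.setdefault(str(plot_id), []).append(snap)
    for plot_id in out:
        out[plot_id].sort(key=lambda s: s.census_date)
    return out
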