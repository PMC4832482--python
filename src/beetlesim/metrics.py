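"""Emergent-pattern analytics computed from per-beetle / per-tree records.

All functions are pure: they consume the record tables a finished run
exports (``RunResult.beetles`` / ``RunResult.trees``) and return plain
tables or numbers, so every statistic is recomputable from stored CSVs.

Distance handling: a successful beetle is located at its infested tree,
an unsuccessful one at its death/settling position, so the final
displacement column serves both; distance classes are half-open 20-m
bins [0, 20), [20, 40), ...
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SUCCESS_FATE = "success"
UNRESOLVED_FATES = ("flying", "attacking")
DEFAULT_CLASS_WIDTH = 20.0


def _check_resolved(beetles: pd.DataFrame) -> None:
    fates = beetles["fate"].astype(str)
    if fates.isin(UNRESOLVED_FATES).any():
        raise ValueError("run is incomplete: unresolved beetles remain")


def success_rate(beetles: pd.DataFrame) -> float:
    """Fraction of the population that successfully infested a host."""
    _check_resolved(beetles)
    return float((beetles["fate"].astype(str) == SUCCESS_FATE).mean())


def distance_class_stats(
    beetles: pd.DataFrame,
    trees: Optional[pd.DataFrame] = None,
    class_width: float = DEFAULT_CLASS_WIDTH,
    max_distance: Optional[float] = 300.0,
) -> pd.DataFrame:
    """Per-distance-class beetle and tree statistics.

    Returns one row per half-open class ``[k*w, (k+1)*w)`` up to
    ``max_distance`` (None = up to the farthest beetle/tree).  Beetle
    probabilities are per class; tree columns are attached when a tree
    table is given.
    """
    if class_width <= 0:
        raise ValueError("class width must be positive")
    _check_resolved(beetles)
    disp = beetles["displacement_m"].to_numpy(float)
    ok = (beetles["fate"].astype(str) == SUCCESS_FATE).to_numpy()
    limit = max_distance
    if limit is None:
        limit = float(disp.max()) if disp.size else 0.0
        if trees is not None and len(trees):
            limit = max(limit, float(trees["distance_m"].max()))
    n_classes = max(1, int(np.ceil((limit + 1e-9) / class_width)))
    edges = class_width * np.arange(n_classes + 1)
    idx = np.minimum((disp // class_width).astype(int), n_classes)  # overflow bucket dropped below
    in_range = idx < n_classes
    n_success = np.bincount(idx[in_range & ok], minlength=n_classes)[:n_classes]
    n_fail = np.bincount(idx[in_range & ~ok], minlength=n_classes)[:n_classes]
    total = n_success + n_fail
    with np.errstate(invalid="ignore"):
        p_success = np.where(total > 0, n_success / np.maximum(total, 1), np.nan)
    out = pd.DataFrame(
        {
            "class_low_m": edges[:-1],
            "class_high_m": edges[1:],
            "n_successful": n_success,
            "n_unsuccessful": n_fail,
            "p_beetle_success": p_success,
        }
    )
    if trees is not None:
        td = trees["distance_m"].to_numpy(float)
        tidx = (td // class_width).astype(int)
        tin = tidx < n_classes
        inf_mask = (trees["status"].astype(str) == "infested").to_numpy()
        n_trees = np.bincount(tidx[tin], minlength=n_classes)[:n_classes]
        n_inf = np.bincount(tidx[tin & inf_mask], minlength=n_classes)[:n_classes]
        out["n_trees"] = n_trees
        out["n_infested_trees"] = n_inf
        with np.errstate(invalid="ignore"):
            out["p_tree_infested"] = np.where(
                n_trees > 0, n_inf / np.maximum(n_trees, 1), np.nan
            )
    return out


def fraction_within(beetles: pd.DataFrame, distance_m: float) -> float:
    """Fraction of all beetles with final displacement <= ``distance_m``."""
    _check_resolved(beetles)
    disp = beetles["displacement_m"].to_numpy(float)
    return float((disp <= distance_m).mean())


def cohort_stats(beetles: pd.DataFrame) -> pd.DataFrame:
    """Per-cohort success/mortality rates and mean infestation distance.

    Mortality counts every non-success fate (including emigrated and
    censored beetles), so success + mortality = 1 per cohort.  The mean
    infestation distance averages over successful beetles only (NaN for
    a cohort without successes).
    """
    _check_resolved(beetles)
    if "cohort" not in beetles:
        raise ValueError("beetle records lack cohort labels")
    ok = beetles["fate"].astype(str) == SUCCESS_FATE
    grp = beetles.assign(_ok=ok).groupby("cohort", observed=True)
    n = grp.size()
    succ = grp["_ok"].sum()
    dist = beetles.loc[ok].groupby("cohort", observed=True)["displacement_m"].mean()
    out = pd.DataFrame(
        {
            "cohort": n.index.to_numpy(),
            "n_beetles": n.to_numpy(),
            "success_rate": (succ / n).to_numpy(),
            "mortality_rate": (1.0 - succ / n).to_numpy(),
        }
    )
    out["mean_infestation_distance_m"] = (
        out["cohort"].map(dist).to_numpy(float)
    )
    return out.reset_index(drop=True)


def aggregate_cohort_stats(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Mean/min/max of per-cohort statistics over replicate runs."""
    cat = pd.concat(tables, ignore_index=True)
    agg = cat.groupby("cohort").agg(
        success_mean=("success_rate", "mean"),
        success_min=("success_rate", "min"),
        success_max=("success_rate", "max"),
        mortality_mean=("mortality_rate", "mean"),
        mortality_min=("mortality_rate", "min"),
        mortality_max=("mortality_rate", "max"),
        distance_mean=("mean_infestation_distance_m", "mean"),
        distance_min=("mean_infestation_distance_m", "min"),
        distance_max=("mean_infestation_distance_m", "max"),
    )
    return agg.reset_index()


def selectivity_table(trees: pd.DataFrame) -> pd.DataFrame:
    """One row per infested tree: distance to source and its PA."""
    inf = trees[trees["status"].astype(str) == "infested"]
    return inf[["distance_m", "pa"]].reset_index(drop=True)


@dataclass
class DensityStats:
    """Colonization densities of infested trees plus the envelope fit."""

    densities: np.ndarray
    distances: np.ndarray
    mean_density: float
    envelope_a: Optional[float]
    envelope_b: Optional[float]


def colonization_density_stats(
    trees: pd.DataFrame, class_width: float = DEFAULT_CLASS_WIDTH
) -> DensityStats:
    """Mean beetles per infested tree and the ``f = a * x**-b`` envelope.

    The envelope is fitted by least squares of log(maximum density per
    20-m distance class) on log(class midpoint); it traces the
    distance-dependent upper limit rather than the mean.  The fit is
    refused (a = b = None) with fewer than two populated classes.
    """
    inf = trees[trees["status"].astype(str) == "infested"]
    dens = inf["n_attackers"].to_numpy(float)
    dist = inf["distance_m"].to_numpy(float)
    mean_density = float(dens.mean()) if dens.size else float("nan")
    a = b = None
    if dens.size >= 2:
        idx = (dist // class_width).astype(int)
        cls = np.unique(idx)
        if cls.size >= 2:
            mids = class_width * (cls + 0.5)
            maxima = np.array([dens[idx == k].max() for k in cls])
            slope, intercept = np.polyfit(np.log(mids), np.log(maxima), 1)
            a = float(np.exp(intercept))
            b = float(-slope)
    return DensityStats(
        densities=dens,
        distances=dist,
        mean_density=mean_density,
        envelope_a=a,
        envelope_b=b,
    )


def kernel_kurtosis(values, which: str = "all") -> float:
    """Sample excess (Fisher) kurtosis of a displacement distribution.

    ``values`` may be a beetle table or a plain array of displacements;
    ``which`` selects ``"all"`` beetles or ``"successful"`` only.
    """
    if isinstance(values, pd.DataFrame):
        beetles = values
        if which == "successful":
            beetles = beetles[beetles["fate"].astype(str) == SUCCESS_FATE]
        elif which != "all":
            raise ValueError("which must be 'all' or 'successful'")
        disp = beetles["displacement_m"].to_numpy(float)
    else:
        disp = np.asarray(values, dtype=float)
    if disp.size < 4:
        raise ValueError("need at least 4 displacement values")
    if np.ptp(disp) == 0:
        raise ValueError("degenerate (zero-variance) distribution")
    return float(stats.kurtosis(disp, fisher=True, bias=False))


# -- plotting helpers (optional) --------------------------------------


def plot_distance_classes(table: pd.DataFrame, path) -> None:
    """Render a distance-class kernel bar chart to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    mids = (table["class_low_m"] + table["class_high_m"]) / 2
    total = max(1, int((table["n_successful"] + table["n_unsuccessful"]).sum()))
    ax.bar(mids, 100 * table["n_successful"] / total, width=16,
           label="successful", color="0.3")
    ax.bar(mids, 100 * table["n_unsuccessful"] / total, width=16,
           bottom=100 * table["n_successful"] / total,
           label="unsuccessful", color="0.75")
    ax.set_xlabel("distance to source (m)")
    ax.set_ylabel("% of dispersing population")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_colonization_density(stats_: DensityStats, path) -> None:
    """Scatter of per-tree colonization density with the envelope curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(stats_.distances, stats_.densities, ".", color="0.6", ms=3)
    ax.axhline(stats_.mean_density, ls=":", color="k", lw=1)
    if stats_.envelope_a is not None:
        xs = np.linspace(max(1.0, stats_.distances.min()),
                         max(2.0, stats_.distances.max()), 200)
        ax.plot(xs, stats_.envelope_a * xs ** (-stats_.envelope_b),
                "--", color="k", lw=1)
    ax.set_xlabel("distance to source (m)")
    ax.set_ylabel("beetles per infested tree")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
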