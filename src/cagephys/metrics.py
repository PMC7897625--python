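"""Reduction of labeled event streams to behavioral statistics.

Covers the descriptive layer between raw events and group statistics:
per-animal binned time courses (visits/h, licks per visit, median
licking contact time, correctness proportions), day/night splits,
trapezoidal areas under behavior-versus-time curves, the 16-parameter
behavioral feature table used for ordination, and the leader–follower
social graph (which mouse entered a corner right after another left it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import ExperimentMetadata, classify_visits, L_VISIT, NP_VISIT, PLAIN_VISIT
from .tasks import CORRECT, INCORRECT, in_active_window

__all__ = [
    "LIGHT_PHASE",
    "TimeCourse",
    "bin_time_course",
    "auc_trapezoid",
    "FEATURE_NAMES",
    "build_feature_table",
    "leader_follower",
    "is_daytime",
]

#: Light (inactive) phase in wall-clock hours; the dark (active) phase is
#: the complement 19:00-07:00, chosen so the night drinking session
#: (23:00-02:00) falls in darkness under a 12-h light-dark cycle.
LIGHT_PHASE: tuple[float, float] = (7.0, 19.0)

VALID_BIN_H = (1, 3, 12, 24)


@dataclass
class TimeCourse:
    """Per-animal binned series with shared bin edges (hours since start)."""

    bin_edges_h: np.ndarray
    values: pd.DataFrame  # rows: animals, columns: bins
    statistic: str

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.bin_edges_h) - 1:
            raise ValueError("values must have len(bin_edges)-1 columns")

    @property
    def bin_centers_h(self) -> np.ndarray:
        e = np.asarray(self.bin_edges_h, dtype=float)
        return 0.5 * (e[:-1] + e[1:])


def is_daytime(hour: np.ndarray | float) -> np.ndarray:
    """True for wall-clock hours inside the light phase 07:00-19:00."""
    return in_active_window(hour, [LIGHT_PHASE])


def bin_time_course(
    visits: pd.DataFrame,
    bin_h: float,
    statistic: str = "count_per_h",
    nosepokes: pd.DataFrame | None = None,
    labeled: pd.DataFrame | None = None,
    t_end_h: float | None = None,
) -> TimeCourse:
    """Bin the event stream into a per-animal time course.

    Parameters
    ----------
    statistic
        ``count_per_h``   visits per hour (counts normalized by bin width);
        ``licks_per_visit``  total licks / visits per bin (NaN for empty bins);
        ``median_contact_time``  median licking contact time per bin, s;
        ``proportion``    correct-visit proportion per bin (needs ``labeled``).
    t_end_h
        Right edge of the last bin; defaults to the last event rounded up
        to a whole bin.

    Count statistics report 0 in empty bins; ratio statistics report NaN
    there (an empty denominator carries no information).
    """
    if bin_h <= 0:
        raise ValueError("bin_h must be positive")
    if statistic in ("licks_per_visit", "median_contact_time") and nosepokes is None:
        raise ValueError(f"statistic {statistic!r} needs the nosepoke table")
    if statistic == "proportion" and labeled is None:
        raise ValueError("statistic 'proportion' needs labeled visits")

    t = visits["start_time_s"].to_numpy() / 3600.0
    if t_end_h is None:
        t_end_h = float(np.ceil((t.max() + 1e-12) / bin_h) * bin_h) if t.size else bin_h
    edges = np.arange(0.0, t_end_h + 0.5 * bin_h, bin_h)
    nbins = len(edges) - 1
    animals = sorted(visits["animal_tag"].unique())

    v = visits.copy()
    v["_bin"] = np.clip(np.digitize(t, edges) - 1, 0, nbins - 1)

    if statistic in ("licks_per_visit", "median_contact_time"):
        per_visit = nosepokes.groupby("visit_id").agg(
            licks=("lick_count", "sum"), contact=("contact_time_s", "sum")
        )
        v = v.merge(per_visit, left_on="visit_id", right_index=True, how="left")
        v[["licks", "contact"]] = v[["licks", "contact"]].fillna(0.0)
    if statistic == "proportion":
        v = v.merge(labeled[["visit_id", "correctness"]], on="visit_id", how="left")

    rows = np.full((len(animals), nbins), np.nan)
    for i, tag in enumerate(animals):
        sub = v[v["animal_tag"] == tag]
        g = sub.groupby("_bin")
        if statistic == "count_per_h":
            counts = g.size().reindex(range(nbins), fill_value=0)
            rows[i] = counts.to_numpy() / bin_h
        elif statistic == "licks_per_visit":
            licks = g["licks"].sum().reindex(range(nbins))
            n = g.size().reindex(range(nbins))
            rows[i] = licks.to_numpy() / n.to_numpy()
        elif statistic == "median_contact_time":
            med = g["contact"].median().reindex(range(nbins))
            rows[i] = med.to_numpy()
        elif statistic == "proportion":
            scored = sub[sub["correctness"].isin([CORRECT, INCORRECT])]
            gs = scored.groupby("_bin")
            ok = (
                gs["correctness"]
                .apply(lambda s: (s == CORRECT).mean())
                .reindex(range(nbins))
            )
            rows[i] = ok.to_numpy()
        else:
            raise ValueError(f"unknown statistic {statistic!r}")

    values = pd.DataFrame(rows, index=animals, columns=range(nbins))
    return TimeCourse(bin_edges_h=edges, values=values, statistic=statistic)


def auc_trapezoid(t: np.ndarray, y: np.ndarray) -> float:
    """Area under a behavior-versus-time curve, linear trapezoidal rule.

    Missing values are dropped pairwise before integration.  Raises if
    fewer than two valid points remain or times are not strictly
    increasing.  Units: value x hours (or whatever the time axis is).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(t) | np.isnan(y))
    t, y = t[keep], y[keep]
    if t.size < 2:
        raise ValueError("trapezoidal AUC needs at least 2 valid points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


#: Canonical 16-parameter behavioral feature set (configurable; column
#: order is the documented output order).
FEATURE_NAMES = [
    "visits_day",
    "visits_night",
    "nosepokes_day",
    "nosepokes_night",
    "licks_day",
    "licks_night",
    "np_visits",
    "l_visits",
    "plain_visits",
    "licks_per_l_visit",
    "mean_lick_duration_s",
    "mean_contact_time_s",
    "mean_visit_duration_s",
    "nosepokes_per_visit",
    "correct_visit_prop",
    "latency_to_first_visit_h",
]


def build_feature_table(
    visits: pd.DataFrame,
    nosepokes: pd.DataFrame,
    meta: ExperimentMetadata,
    labeled: pd.DataFrame | None = None,
    n_days: float | None = None,
) -> pd.DataFrame:
    """One row per animal, 16 behavioral parameters, plus group label.

    The parameters cover activity (visit/nosepoke/lick counts split by
    light phase, per day), visit-class structure (nosepoke-only visits,
    lick visits, plain visits), goal-directed licking (licks per lick
    visit, lick duration, contact time), efficiency (visit duration,
    nosepokes per visit, correct-visit proportion) and drive (latency
    from experiment start to first visit).  Animals with zero visits get
    their row imputed with the group median and flagged in the
    ``imputed`` column.
    """
    roster = meta.roster
    animals = sorted(roster) if roster else sorted(visits["animal_tag"].unique())
    if n_days is None:
        span_h = visits["end_time_s"].max() / 3600.0 if len(visits) else 24.0
        n_days = max(span_h / 24.0, 1e-9)

    classes = classify_visits(visits, nosepokes)
    per_visit = nosepokes.groupby("visit_id").agg(
        n_pokes=("visit_id", "size"),
        licks=("lick_count", "sum"),
        lick_dur=("lick_duration_s", "sum"),
        contact=("contact_time_s", "sum"),
    )
    v = visits.merge(per_visit, left_on="visit_id", right_index=True, how="left")
    v[["n_pokes", "licks", "lick_dur", "contact"]] = v[
        ["n_pokes", "licks", "lick_dur", "contact"]
    ].fillna(0.0)
    v["day"] = is_daytime(meta.clock_hour(v["start_time_s"].to_numpy()))
    v["cls"] = classes.reindex(v["visit_id"]).to_numpy()
    v["dur"] = v["end_time_s"] - v["start_time_s"]
    if labeled is not None:
        v = v.merge(labeled[["visit_id", "correctness"]], on="visit_id", how="left")

    rows, imputed = {}, []
    for tag in animals:
        sub = v[v["animal_tag"] == tag]
        if len(sub) == 0:
            rows[tag] = None
            imputed.append(tag)
            continue
        day, night = sub[sub["day"]], sub[~sub["day"]]
        lv = sub[sub["cls"] == L_VISIT]
        scored = (
            sub[sub["correctness"].isin([CORRECT, INCORRECT])]
            if labeled is not None
            else sub.iloc[0:0]
        )
        rows[tag] = {
            "visits_day": len(day) / n_days,
            "visits_night": len(night) / n_days,
            "nosepokes_day": day["n_pokes"].sum() / n_days,
            "nosepokes_night": night["n_pokes"].sum() / n_days,
            "licks_day": day["licks"].sum() / n_days,
            "licks_night": night["licks"].sum() / n_days,
            "np_visits": (sub["cls"] == NP_VISIT).sum() / n_days,
            "l_visits": (sub["cls"] == L_VISIT).sum() / n_days,
            "plain_visits": (sub["cls"] == PLAIN_VISIT).sum() / n_days,
            "licks_per_l_visit": lv["licks"].mean() if len(lv) else 0.0,
            "mean_lick_duration_s": lv["lick_dur"].mean() if len(lv) else 0.0,
            "mean_contact_time_s": sub["contact"].mean(),
            "mean_visit_duration_s": sub["dur"].mean(),
            "nosepokes_per_visit": sub["n_pokes"].mean(),
            "correct_visit_prop": (
                (scored["correctness"] == CORRECT).mean() if len(scored) else 0.0
            ),
            "latency_to_first_visit_h": sub["start_time_s"].min() / 3600.0,
        }

    table = pd.DataFrame.from_dict(
        {k: r for k, r in rows.items() if r is not None}, orient="index"
    )[FEATURE_NAMES]
    table["group"] = [roster.get(tag, "") for tag in table.index]
    # impute empty animals with their group median (flat zero if the whole
    # group is empty)
    for tag in imputed:
        grp = roster.get(tag, "")
        peers = table[table["group"] == grp][FEATURE_NAMES]
        fill = peers.median() if len(peers) else pd.Series(0.0, index=FEATURE_NAMES)
        table.loc[tag, FEATURE_NAMES] = fill
        table.loc[tag, "group"] = grp
    table = table.loc[animals]
    table["imputed"] = [tag in imputed for tag in table.index]
    return table


def leader_follower(visits: pd.DataFrame, max_gap_s: float = 30.0) -> pd.DataFrame:
    """Directed leader->follower matrix from corner-entry timing.

    A follow event is a visit by animal B to corner c starting within
    ``max_gap_s`` seconds after a visit by a different animal A to the
    same corner ended; each follower visit is attributed to at most one
    leader — the most recent qualifying exit.  Returns a square count
    matrix (rows: leader, columns: follower) with a zero diagonal.
    """
    animals = sorted(visits["animal_tag"].unique())
    idx = {a: i for i, a in enumerate(animals)}
    mat = np.zeros((len(animals), len(animals)), dtype=int)

    for corner, sub in visits.groupby("corner"):
        sub = sub.sort_values("start_time_s", kind="stable")
        ends = sub["end_time_s"].to_numpy()
        starts = sub["start_time_s"].to_numpy()
        tags = sub["animal_tag"].to_numpy()
        order = np.argsort(ends, kind="stable")
        ends_sorted, tags_by_end = ends[order], tags[order]
        for j in range(len(sub)):
            # most recent exit by another animal within the gap window
            k = np.searchsorted(ends_sorted, starts[j], side="right") - 1
            while k >= 0:
                if starts[j] - ends_sorted[k] > max_gap_s:
                    break
                if tags_by_end[k] != tags[j]:
                    mat[idx[tags_by_end[k]], idx[tags[j]]] += 1
                    break
                k -= 1
    return pd.DataFrame(mat, index=animals, columns=animals)
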