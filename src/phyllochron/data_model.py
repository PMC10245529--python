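"""Ingestion, cleaning and interval-censoring of leaf-count phenology data.

A plant is observed at a set of accumulated-thermal-time (ATT) points; at
each visit the rank of the youngest visible leaf is recorded.  The actual
appearance time ``H_f`` of leaf ``f`` is never observed: the data only say
in which inter-visit interval each leaf appeared.  This module turns raw
long-format observation tables into per-rank censoring intervals
``(L_f, U_f]`` and selects the leaf-rank windows on which the successive
time-to-event model is identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeKey",
    "PlantObservationSeries",
    "CensoringIntervals",
    "LeafRangeWindow",
    "clean_observations",
    "extract_intervals",
    "select_leaf_range",
    "load_observations",
    "save_observations",
    "intervals_to_frame",
    "save_intervals",
]


@dataclass(frozen=True)
class GenotypeKey:
    """Hierarchy labels of a genotype: ancestral line > selection population
    (Early/Late) > genotype id, plus the experiment year.

    The (line, selection, genotype) nesting must be consistent: a genotype id
    maps to exactly one (line, selection) pair.
    """

    line: str
    selection: str
    genotype: str
    year: str

    @property
    def line_key(self) -> tuple:
        return (self.year, self.line)

    @property
    def selection_key(self) -> tuple:
        return (self.year, self.line, self.selection)

    @property
    def genotype_key(self) -> tuple:
        return (self.year, self.line, self.selection, self.genotype)


@dataclass
class PlantObservationSeries:
    """One plant's timed leaf counts.

    ``obs_times`` are ATT values (degree-days, origin = sowing), strictly
    increasing; ``leaf_counts`` are the recorded youngest-visible-leaf ranks.
    ``complete`` distinguishes plants followed to panicle emergence from
    dissected (partially observed) plants.  ``unmodeled_ranks`` is filled by
    :func:`clean_observations` (top-rank trimming) and is a flag, not a
    deletion: raw counts stay exportable.
    """

    plant_id: str
    row_id: str
    key: GenotypeKey
    obs_times: np.ndarray
    leaf_counts: np.ndarray
    complete: bool = True
    sowing_date: object = None
    obs_calendar: np.ndarray | None = None
    unmodeled_ranks: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.leaf_counts = np.asarray(self.leaf_counts, dtype=int)
        if self.obs_times.ndim != 1 or self.leaf_counts.ndim != 1:
            raise ValueError("obs_times and leaf_counts must be 1-D")
        if len(self.obs_times) != len(self.leaf_counts):
            raise ValueError(
                f"plant {self.plant_id}: {len(self.obs_times)} times but "
                f"{len(self.leaf_counts)} counts"
            )
        if len(self.obs_times) == 0:
            raise ValueError(f"plant {self.plant_id}: empty series")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError(f"plant {self.plant_id}: obs_times not strictly increasing")
        if np.any(self.leaf_counts < 0):
            raise ValueError(f"plant {self.plant_id}: negative leaf count")

    @property
    def is_monotone(self) -> bool:
        return bool(np.all(np.diff(self.leaf_counts) >= 0))

    @property
    def max_count(self) -> int:
        return int(self.leaf_counts.max())


@dataclass
class CensoringIntervals:
    """Per-leaf-rank bounds ``(L_f, U_f]`` on appearance times of one plant.

    ``L_f`` is the last observation time at which fewer than ``f`` leaves
    were visible (0 if the plant already had ``f`` leaves at first visit,
    i.e. no observation precedes the appearance).  ``U_f`` is the first
    observation time with at least ``f`` leaves (+inf if never reached).
    Ranks flagged as unmodeled (top-rank trimming) are omitted.
    """

    plant_id: str
    key: GenotypeKey
    row_id: str
    ranks: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    last_time: float
    complete: bool = True

    def __post_init__(self):
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (len(self.ranks) == len(self.lower) == len(self.upper)):
            raise ValueError("ranks/lower/upper length mismatch")
        if np.any(self.lower >= self.upper):
            bad = self.ranks[self.lower >= self.upper]
            raise ValueError(f"plant {self.plant_id}: empty interval at rank(s) {bad}")

    def interval(self, f: int) -> tuple[float, float]:
        """Bounds for rank ``f``; ranks above the highest stored rank are
        right-censored at the last observation time."""
        idx = np.searchsorted(self.ranks, f)
        if idx < len(self.ranks) and self.ranks[idx] == f:
            return float(self.lower[idx]), float(self.upper[idx])
        if len(self.ranks) and f < self.ranks[0]:
            # below lowest stored rank: appeared before first bound we kept
            return 0.0, float(self.upper[0])
        return float(self.last_time), math.inf

    def observed(self, f: int) -> bool:
        """True when rank f has at least one observation strictly before and
        one at/after its appearance (doubly observation-bounded interval)."""
        lo, hi = self.interval(f)
        return lo > 0.0 and math.isfinite(hi)


@dataclass(frozen=True)
class LeafRangeWindow:
    """Modeled leaf-rank window [f_min, f_max]; the cumulated phyllochron
    absorbs all ranks below f_min."""

    f_min: int
    f_max: int
    scope: str = "genotype"

    def __post_init__(self):
        if self.f_min > self.f_max:
            raise ValueError(f"empty window [{self.f_min}, {self.f_max}]")

    @property
    def n_ranks(self) -> int:
        """Number of modeled appearance times H_f (f = f_min..f_max)."""
        return self.f_max - self.f_min + 1

    @property
    def n_instant(self) -> int:
        """Number of instant-phyllochron ranks (f_min, f_max]."""
        return self.f_max - self.f_min

    def instant_ranks(self) -> np.ndarray:
        return np.arange(self.f_min + 1, self.f_max + 1)

    def intersect(self, other: "LeafRangeWindow") -> "LeafRangeWindow":
        f_min = max(self.f_min, other.f_min)
        f_max = min(self.f_max, other.f_max)
        if f_min > f_max:
            raise ValueError("window intersection is empty")
        return LeafRangeWindow(f_min, f_max, scope="common")


# ---------------------------------------------------------------------------
# cleaning


def clean_observations(
    raw: Sequence[PlantObservationSeries], n_top_trim: int = 2
) -> tuple[list[PlantObservationSeries], list[str]]:
    """Apply the data-cleaning rules.

    Plants whose recorded leaf count strictly decreases at any visit are
    measurement errors and are discarded outright (never corrected).  For
    plants followed to completion, the appearance of the top ``n_top_trim``
    leaf ranks is not modeled (leaf emergence slows near panicle emergence
    and the counting criterion degrades): those ranks are flagged, not
    removed from the counts.

    Returns (kept series, discarded plant ids).
    """
    if n_top_trim < 0:
        raise ValueError("n_top_trim must be >= 0")
    raw = list(raw)
    if not raw:
        raise ValueError("no observation series supplied")
    seen: set[tuple[str, float]] = set()
    for s in raw:
        for t in s.obs_times:
            rec = (s.plant_id, float(t))
            if rec in seen:
                raise ValueError(f"duplicate observation record {rec}")
            seen.add(rec)
    kept: list[PlantObservationSeries] = []
    discarded: list[str] = []
    for s in raw:
        if not s.is_monotone:
            discarded.append(s.plant_id)
            continue
        flags = frozenset()
        if s.complete and n_top_trim > 0:
            top = s.max_count
            flags = frozenset(range(max(1, top - n_top_trim + 1), top + 1))
        kept.append(replace(s, unmodeled_ranks=flags))
    return kept, discarded


def extract_intervals(series: PlantObservationSeries) -> CensoringIntervals:
    """Read off the censoring interval of every leaf rank from the counts.

    For rank ``f``: ``L_f`` = last obs time with count < f (0 if none),
    ``U_f`` = first obs time with count >= f (+inf if never reached).  One
    explicit right-censored rank (max count + 1) is stored; higher ranks are
    implied by ``interval``.  Flagged unmodeled ranks are omitted.
    """
    t = series.obs_times
    c = series.leaf_counts
    if not series.is_monotone:
        raise ValueError(f"plant {series.plant_id}: counts not cleaned (decreasing)")
    top = series.max_count
    ranks, lower, upper = [], [], []
    for f in range(1, top + 2):
        if f in series.unmodeled_ranks:
            continue
        below = t[c < f]
        at_or_above = t[c >= f]
        lo = float(below[-1]) if len(below) else 0.0
        hi = float(at_or_above[0]) if len(at_or_above) else math.inf
        if f == top + 1 and series.unmodeled_ranks:
            # the first trimmed rank already covers "right-censored above"
            continue
        ranks.append(f)
        lower.append(lo)
        upper.append(hi)
    return CensoringIntervals(
        plant_id=series.plant_id,
        key=series.key,
        row_id=series.row_id,
        ranks=np.array(ranks, dtype=int),
        lower=np.array(lower, dtype=float),
        upper=np.array(upper, dtype=float),
        last_time=float(t[-1]),
        complete=series.complete,
    )


def counts_from_latent(h_by_rank: Mapping[int, float], obs_times: np.ndarray,
                       f_min: int) -> np.ndarray:
    """Leaf counts implied by latent appearance times at given visit times
    (ranks below ``f_min`` are compressed into the baseline f_min - 1)."""
    ranks = np.array(sorted(h_by_rank))
    h = np.array([h_by_rank[f] for f in ranks])
    obs_times = np.asarray(obs_times, dtype=float)
    return (f_min - 1) + (h[None, :] <= obs_times[:, None]).sum(axis=1)


# ---------------------------------------------------------------------------
# leaf-range selection


def select_leaf_range(
    groups: Mapping[object, Sequence[CensoringIntervals]],
    min_plants: int = 10,
) -> tuple[dict, LeafRangeWindow]:
    """Select, per (year, genotype) group, the largest leaf-rank window
    [f_min, f_max] such that ranks f_min - 1 and f_max are observed on at
    least ``min_plants`` plants, plus the common window (intersection).

    "Observed on a plant" means the plant has at least one observation
    strictly before and one at/after the leaf's appearance, i.e. a doubly
    observation-bounded censoring interval.
    """
    if min_plants < 1:
        raise ValueError("min_plants must be >= 1")
    if not groups:
        raise ValueError("no groups supplied")
    windows: dict = {}
    common: LeafRangeWindow | None = None
    for gkey, plants in groups.items():
        plants = list(plants)
        if not plants:
            raise ValueError(f"group {gkey}: no plants")
        top = max(int(p.ranks.max()) for p in plants if len(p.ranks))
        counts = np.zeros(top + 2, dtype=int)
        for p in plants:
            for f in range(1, top + 2):
                if p.observed(f):
                    counts[f] += 1
        qualifying = np.nonzero(counts >= min_plants)[0]
        if len(qualifying) < 2:
            raise ValueError(
                f"group {gkey}: no leaf-rank window with >= {min_plants} plants"
            )
        w = LeafRangeWindow(int(qualifying.min()) + 1, int(qualifying.max()))
        windows[gkey] = w
        common = w if common is None else common.intersect(w)
    assert common is not None
    return windows, LeafRangeWindow(common.f_min, common.f_max, scope="common")


# ---------------------------------------------------------------------------
# CSV I/O
#
# observations.csv columns:
#   plant_id,row_id,year,line,selection,genotype,date,att_degree_days,leaf_count

_OBS_COLS = [
    "plant_id", "row_id", "year", "line", "selection", "genotype",
    "date", "att_degree_days", "leaf_count",
]


def load_observations(path) -> list[PlantObservationSeries]:
    df = pd.read_csv(path, comment="#", dtype={"plant_id": str, "row_id": str,
                                               "year": str, "genotype": str})
    missing = [c for c in _OBS_COLS if c not in df.columns and c != "date"]
    if missing:
        raise ValueError(f"observations file missing columns: {missing}")
    # nesting consistency: one (line, selection) per genotype id
    nest = df.groupby("genotype")[["line", "selection"]].nunique()
    bad = nest[(nest > 1).any(axis=1)].index.tolist()
    if bad:
        raise ValueError(f"inconsistent (line, selection) nesting for genotypes {bad}")
    out: list[PlantObservationSeries] = []
    complete_col = "complete" in df.columns
    for (pid,), sub in df.groupby(["plant_id"], sort=True):
        sub = sub.sort_values("att_degree_days")
        first = sub.iloc[0]
        key = GenotypeKey(line=str(first["line"]), selection=str(first["selection"]),
                          genotype=str(first["genotype"]), year=str(first["year"]))
        cal = None
        if "date" in sub.columns and sub["date"].notna().all():
            cal = pd.to_datetime(sub["date"]).to_numpy()
        out.append(PlantObservationSeries(
            plant_id=str(pid),
            row_id=str(first["row_id"]),
            key=key,
            obs_times=sub["att_degree_days"].to_numpy(dtype=float),
            leaf_counts=sub["leaf_count"].to_numpy(dtype=int),
            complete=bool(first["complete"]) if complete_col else True,
            obs_calendar=cal,
        ))
    return out


def save_observations(series: Iterable[PlantObservationSeries], path,
                      header_comment: str | None = None) -> None:
    rows = []
    for s in series:
        for i, (t, c) in enumerate(zip(s.obs_times, s.leaf_counts)):
            rows.append({
                "plant_id": s.plant_id, "row_id": s.row_id,
                "year": s.key.year, "line": s.key.line,
                "selection": s.key.selection, "genotype": s.key.genotype,
                "date": (pd.Timestamp(s.obs_calendar[i]).date().isoformat()
                         if s.obs_calendar is not None else ""),
                "att_degree_days": t, "leaf_count": c,
                "complete": s.complete,
            })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def intervals_to_frame(intervals: Iterable[CensoringIntervals]) -> pd.DataFrame:
    rows = []
    for ci in intervals:
        for f, lo, hi in zip(ci.ranks, ci.lower, ci.upper):
            rows.append({"plant_id": ci.plant_id, "leaf_rank": int(f),
                         "lower_dd": lo,
                         "upper_dd": hi if math.isfinite(hi) else "inf"})
    return pd.DataFrame(rows)


def save_intervals(intervals: Iterable[CensoringIntervals], path,
                   header_comment: str | None = None) -> None:
    df = intervals_to_frame(intervals)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)
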