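"""Composite fire chronologies, event rules and fire-interval statistics.

A *composite chronology* is the union of fire years across all sampled
trees, filtered by an event rule.  The rule used throughout is the standard
multi-tree filter: a calendar year is a fire event when at least
``min_trees`` (default 2) trees carry a dated fire scar in that year.
Years scarred on a single tree can additionally be promoted to events when
an unambiguous post-fire cohort — a pulse of tree establishment within a
decade after the scar — corroborates them.

Interval statistics follow the usual composite/point distinction:

* **MFI** (mean fire interval): mean of successive intervals between
  composite fire-event years, equal to span/(n_events - 1).
* **PFI** (point fire interval): the MFI at the tree scale — the mean of
  within-tree successive scar intervals pooled over all trees with at
  least two scars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .fhx import FhxCollection, recorder_depth

VEGETATION_TYPES = ("zonal", "bog_forest", "bog_woodland", "blanket_bog")


class UndefinedIntervalError(ValueError):
    """Raised when an interval statistic is requested from too few events."""


@dataclass(frozen=True)
class FireEvent:
    """One detected fire year in a composite chronology."""

    year: int
    n_scarred_trees: int
    n_recording_trees: int
    plots: frozenset = frozenset()
    cohort_verified: bool = False
    severity_class: str = "low"

    def __post_init__(self):
        object.__setattr__(self, "plots", frozenset(self.plots))
        if self.n_scarred_trees < 1:
            raise ValueError(f"event {self.year}: needs >= 1 scarred tree")
        if self.n_scarred_trees > self.n_recording_trees:
            raise ValueError(
                f"event {self.year}: {self.n_scarred_trees} scarred > "
                f"{self.n_recording_trees} recording trees"
            )
        if self.severity_class not in ("low", "mixed"):
            raise ValueError(f"unknown severity class {self.severity_class!r}")


@dataclass
class CompositeChronology:
    """Ordered fire events at the study-area (or plot) scale."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        years = [e.year for e in self.events]
        if years != sorted(set(years)):
            raise ValueError("events must be strictly increasing in year")

    @property
    def fire_years(self) -> list:
        return [e.year for e in self.events]

    @property
    def period_start(self) -> int:
        if not self.events:
            raise ValueError("empty chronology has no period")
        return self.events[0].year

    @property
    def period_end(self) -> int:
        if not self.events:
            raise ValueError("empty chronology has no period")
        return self.events[-1].year

    def __len__(self):
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": [e.year for e in self.events],
                "n_scarred": [e.n_scarred_trees for e in self.events],
                "n_recording": [e.n_recording_trees for e in self.events],
                "plots": ["|".join(sorted(map(str, e.plots))) for e in self.events],
                "cohort_verified": [e.cohort_verified for e in self.events],
                "severity": [e.severity_class for e in self.events],
            }
        )


@dataclass
class PlotRecord:
    """Attributes of one fire-history plot (topography, culture, vegetation)."""

    plot_id: str
    vegetation_type: str
    elevation: float
    slope: float
    aspect: float
    dist_habitation: float
    dist_shoreline: float
    n_fire_scars: int = 0
    n_fire_events: int = 0
    establishment_years: list = field(default_factory=list)

    def __post_init__(self):
        if self.vegetation_type not in VEGETATION_TYPES:
            raise ValueError(
                f"plot {self.plot_id}: vegetation_type must be one of "
                f"{VEGETATION_TYPES}, got {self.vegetation_type!r}"
            )
        if self.dist_habitation < 0 or self.dist_shoreline < 0:
            raise ValueError(f"plot {self.plot_id}: distances must be >= 0")


def _scarred_series_by_year(collection: FhxCollection) -> dict:
    """year -> list of series ids with a dated (uppercase) fire scar."""
    by_year = {}
    for s in collection.series:
        for y in s.fire_scar_years:
            by_year.setdefault(y, []).append(s.series_id)
    return by_year


def detect_fire_events(
    collection: FhxCollection, min_trees: int = 2
) -> CompositeChronology:
    """Filter scar years into fire events with the multi-tree rule.

    A year qualifies when at least ``min_trees`` distinct trees carry a
    dated fire scar.  The recording (recorder-tree) count for each event
    year comes from :func:`firesync.fhx.recorder_depth`, and burned plots
    from the collection's series-to-plot mapping.
    """
    if min_trees < 1:
        raise ValueError("min_trees must be >= 1")
    if not collection.series:
        raise ValueError("cannot detect events in an empty collection")
    depth = recorder_depth(collection)
    by_year = _scarred_series_by_year(collection)
    events = []
    for year in sorted(by_year):
        sids = by_year[year]
        if len(sids) < min_trees:
            continue
        plots = {
            collection.plot_of_series[s]
            for s in sids
            if s in collection.plot_of_series
        }
        events.append(
            FireEvent(
                year=year,
                n_scarred_trees=len(sids),
                n_recording_trees=int(depth.loc[year]),
                plots=frozenset(plots),
            )
        )
    return CompositeChronology(events=events)


def _flatten_establishment(establishment_years) -> list:
    if isinstance(establishment_years, dict):
        out = []
        for v in establishment_years.values():
            out.extend(v)
        return out
    return list(establishment_years)


def verify_single_scar_events(
    collection: FhxCollection,
    chronology: CompositeChronology,
    establishment_years,
    window: int = 10,
    min_cohort: int = 5,
) -> CompositeChronology:
    """Promote single-scar years corroborated by post-fire cohorts to events.

    A year scarred on exactly one tree (and not already an event) becomes a
    ``cohort_verified`` fire event when at least ``min_cohort``
    establishment (pith) years fall strictly after the scar year and within
    ``window`` years of it, i.e. in ``(year, year + window]`` — cohorts are
    post-fire by definition.  ``establishment_years`` may be a flat
    iterable of pith years or a mapping plot_id -> years.

    Establishment pulses falling within ``window`` of an *existing* event
    are attributed to that event (they verify nothing new) and are excluded
    from single-scar verification.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    est = sorted(_flatten_establishment(establishment_years))
    if not est:
        return chronology
    depth = recorder_depth(collection)
    by_year = _scarred_series_by_year(collection)
    existing = set(chronology.fire_years)
    claimed = set()  # establishment years claimed by an existing event
    for ey in existing:
        claimed.update(y for y in est if ey < y <= ey + window)

    new_events = list(chronology.events)
    for year in sorted(by_year):
        sids = by_year[year]
        if len(sids) != 1 or year in existing:
            continue
        cohort = [y for y in est if year < y <= year + window and y not in claimed]
        if len(cohort) < min_cohort:
            continue
        plots = {
            collection.plot_of_series[s]
            for s in sids
            if s in collection.plot_of_series
        }
        new_events.append(
            FireEvent(
                year=year,
                n_scarred_trees=1,
                n_recording_trees=int(depth.loc[year]),
                plots=frozenset(plots),
                cohort_verified=True,
            )
        )
    new_events.sort(key=lambda e: e.year)
    return CompositeChronology(events=new_events)


def mean_fire_interval(chronology) -> float:
    """Composite MFI: mean of successive differences of event years.

    Accepts a :class:`CompositeChronology` or a plain iterable of event
    years.  With n events spanning S years this equals S/(n-1) exactly.
    """
    years = (
        chronology.fire_years
        if isinstance(chronology, CompositeChronology)
        else sorted(chronology)
    )
    if len(years) < 2:
        raise UndefinedIntervalError(
            "mean fire interval requires at least two events"
        )
    diffs = [b - a for a, b in zip(years, years[1:])]
    return sum(diffs) / len(diffs)


def point_fire_interval(collection: FhxCollection) -> float:
    """PFI: mean within-tree scar interval pooled across trees.

    Trees with fewer than two dated fire scars contribute no intervals; if
    no tree qualifies the statistic is undefined.
    """
    intervals = []
    for s in collection.series:
        years = sorted(s.fire_scar_years)
        intervals.extend(b - a for a, b in zip(years, years[1:]))
    if not intervals:
        raise UndefinedIntervalError(
            "point fire interval requires a tree with >= 2 scars"
        )
    return sum(intervals) / len(intervals)


def classify_severity(
    event: FireEvent, establishment_by_plot: dict, window: int = 10
) -> str:
    """Label an event 'mixed' when a post-fire cohort established in a burned
    plot, else 'low'.

    Scar-only fires that killed no canopy and triggered no recruitment are
    low severity; recruitment pulses indicate canopy openings, hence mixed
    severity.  If the event's burned-plot set is unknown (empty), any plot
    counts.
    """
    plots = event.plots if event.plots else set(establishment_by_plot)
    for p in plots:
        years = establishment_by_plot.get(p, ())
        if any(event.year < y <= event.year + window for y in years):
            return "mixed"
    return "low"


def apply_severity(
    chronology: CompositeChronology, establishment_by_plot: dict, window: int = 10
) -> CompositeChronology:
    """Return a chronology with severity_class filled for every event."""
    events = [
        replace(e, severity_class=classify_severity(e, establishment_by_plot, window))
        for e in chronology.events
    ]
    return CompositeChronology(events=events)


def scar_summary(collection: FhxCollection) -> dict:
    """Headline scar statistics: totals and scars-per-sample.

    Returns a dict with ``n_scarred_trees`` (trees carrying >= 1 dated
    scar), ``n_scars`` (total dated scars), ``scars_per_tree`` (mean) and
    ``scars_per_tree_rounded`` (nearest integer, the figure usually quoted
    in fire-history summaries).
    """
    n_scars = sum(len(s.fire_scar_years) for s in collection.series)
    n_trees = sum(1 for s in collection.series if s.fire_scar_years)
    mean = n_scars / n_trees if n_trees else float("nan")
    return {
        "n_scarred_trees": n_trees,
        "n_scars": n_scars,
        "scars_per_tree": mean,
        "scars_per_tree_rounded": int(round(mean)) if n_trees else 0,
    }


PLOT_CSV_COLUMNS = [
    "plot_id",
    "vegetation_type",
    "elevation_m",
    "slope_deg",
    "aspect_deg",
    "dist_habitation_m",
    "dist_shoreline_m",
]


def read_plot_csv(path_or_buf) -> pd.DataFrame:
    """Read a plot-attribute CSV, validating schema and vegetation labels."""
    df = pd.read_csv(path_or_buf)
    missing = [c for c in PLOT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot CSV missing columns: {missing}")
    bad = set(df["vegetation_type"]) - set(VEGETATION_TYPES)
    if bad:
        raise ValueError(f"unknown vegetation types in plot CSV: {sorted(bad)}")
    if (df[["dist_habitation_m", "dist_shoreline_m"]] < 0).any().any():
        raise ValueError("plot CSV distances must be >= 0")
    df["plot_id"] = df["plot_id"].astype(str)
    return df
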