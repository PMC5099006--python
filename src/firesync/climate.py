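"""Annual reconstructed climate indices and extreme-event year sets.

The analyses treat climate as *events* rather than continuous forcing:
for a reconstructed annual index (PDSI, ENSO, PDO or AO) the k most
extreme years in a chosen phase direction form an event set, and
combinations of index phases are formed by ranking each index in its phase
direction and keeping the k years with the smallest rank sums.  Sign
convention for the PDSI: negative values are dry years, positive values
wet years (typical range -6..+6).

All selections are rank-based, hence invariant under monotone
transformations of the index values, and all ties are broken
deterministically in favour of the earlier year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDEX_NAMES = ("PDSI", "ENSO", "PDO", "AO")

#: Analyses stop at the last detected fire year by default.
DEFAULT_CLIP_END = 1893


def _norm_sign(sign) -> int:
    if sign in ("+", 1, +1, "pos", "positive"):
        return 1
    if sign in ("-", -1, "neg", "negative", "−"):
        return -1
    raise ValueError(f"sign must be '+' or '-', got {sign!r}")


@dataclass
class ClimateSeries:
    """A contiguous annual climate-index series."""

    name: str
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.size != self.values.size:
            raise ValueError(f"{self.name}: years and values differ in length")
        if self.years.size == 0:
            raise ValueError(f"{self.name}: empty series")
        if not np.all(np.diff(self.years) == 1):
            raise ValueError(f"{self.name}: years must be contiguous ascending")

    @property
    def start(self) -> int:
        return int(self.years[0])

    @property
    def end(self) -> int:
        return int(self.years[-1])

    def window(self, start: int, end: int) -> "ClimateSeries":
        mask = (self.years >= start) & (self.years <= end)
        if not mask.any():
            raise ValueError(f"{self.name}: window {start}-{end} outside series")
        return ClimateSeries(self.name, self.years[mask], self.values[mask])

    def value_at(self, year: int) -> float:
        idx = year - self.start
        if idx < 0 or idx >= self.years.size:
            raise KeyError(f"{self.name}: year {year} outside {self.start}-{self.end}")
        return float(self.values[idx])

    @classmethod
    def from_csv(cls, path_or_buf, name: str | None = None) -> "ClimateSeries":
        """Read a year,value CSV; the value column header names the index."""
        df = pd.read_csv(path_or_buf)
        if "year" not in df.columns or df.shape[1] < 2:
            raise ValueError("climate CSV needs a 'year' column and a value column")
        value_col = [c for c in df.columns if c != "year"][0]
        return cls(name or value_col, df["year"].to_numpy(), df[value_col].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"year": self.years, self.name: self.values}).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class ExtremeEventSet:
    """The ranked extreme years of one index phase or a phase combination."""

    source_names: tuple
    phase_signs: tuple
    event_years: frozenset
    k: int
    rank_rule: str  # 'single_topk' or 'combined_rank'
    period: tuple

    @property
    def label(self) -> str:
        return "/".join(
            f"{n}{'+' if s > 0 else '-'}"
            for n, s in zip(self.source_names, self.phase_signs)
        )

    def __len__(self):
        return len(self.event_years)

    def sorted_years(self) -> list:
        return sorted(self.event_years)


def common_period(series_list, clip_start=None, clip_end=DEFAULT_CLIP_END):
    """Intersection of the series' year ranges, clipped to an analysis window.

    The default end clip is 1893, the last detected fire year; pass
    ``clip_end=None`` to disable clipping.
    """
    if not series_list:
        raise ValueError("common_period needs at least one series")
    start = max(s.start for s in series_list)
    end = min(s.end for s in series_list)
    if clip_start is not None:
        start = max(start, clip_start)
    if clip_end is not None:
        end = min(end, clip_end)
    if start > end:
        raise ValueError(f"series share no common period (got {start} > {end})")
    return (start, end)


def _extreme_order(series: ClimateSeries, sign: int) -> np.ndarray:
    """Year indices sorted most-extreme-first in the given phase direction,
    ties broken by earlier year."""
    # lexsort: last key is primary
    return np.lexsort((series.years, -sign * series.values))


def select_extreme_years(
    series: ClimateSeries, sign, k: int = 50, period=None
) -> ExtremeEventSet:
    """The k most extreme years of one index phase within a period.

    ``sign='+'`` selects the largest values (e.g. El Nino years for ENSO),
    ``sign='-'`` the smallest (e.g. drought years for the PDSI).
    """
    s = _norm_sign(sign)
    if period is None:
        period = (series.start, series.end)
    win = series.window(*period)
    if k > win.years.size:
        raise ValueError(
            f"k={k} exceeds period length {win.years.size} for {series.name}"
        )
    order = _extreme_order(win, s)
    years = frozenset(int(y) for y in win.years[order[:k]])
    return ExtremeEventSet(
        source_names=(series.name,),
        phase_signs=(s,),
        event_years=years,
        k=k,
        rank_rule="single_topk",
        period=tuple(period),
    )


def combine_phase_events(
    series_list, signs, k: int = 100, period=None, rule: str = "rank_sum"
) -> ExtremeEventSet:
    """Extreme years of a 2- or 3-way phase combination.

    Each index is ranked within the common period in its phase direction
    (rank 1 = most extreme); with ``rule='rank_sum'`` (default) the k years
    with the smallest rank sums are returned — always exactly k years.
    ``rule='union'``/``'intersection'`` instead combine the per-index
    top-k sets directly (their sizes are data-dependent).
    """
    if not 1 <= len(series_list) <= 3 or len(series_list) != len(signs):
        raise ValueError("combine_phase_events takes 1-3 series with matching signs")
    ss = [_norm_sign(s) for s in signs]
    if period is None:
        period = common_period(series_list, clip_end=None)
    wins = [s.window(*period) for s in series_list]
    n = wins[0].years.size
    if k > n:
        raise ValueError(f"k={k} exceeds common-period length {n}")

    if rule in ("union", "intersection"):
        sets = [
            select_extreme_years(s, sign, k=k, period=period).event_years
            for s, sign in zip(series_list, ss)
        ]
        years = frozenset.union(*sets) if rule == "union" else frozenset.intersection(*sets)
    elif rule == "rank_sum":
        rank_sum = np.zeros(n)
        for win, sign in zip(wins, ss):
            order = _extreme_order(win, sign)
            ranks = np.empty(n)
            ranks[order] = np.arange(1, n + 1)
            rank_sum += ranks
        # smallest rank sum first; ties to the earlier year
        pick = np.lexsort((wins[0].years, rank_sum))[:k]
        years = frozenset(int(y) for y in wins[0].years[pick])
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return ExtremeEventSet(
        source_names=tuple(s.name for s in series_list),
        phase_signs=tuple(ss),
        event_years=years,
        k=k,
        rank_rule="combined_rank" if len(series_list) > 1 else "single_topk",
        period=tuple(period),
    )


def classify_fire_year_moisture(
    pdsi: ClimateSeries,
    fire_years,
    dry_threshold: float = -1.0,
    wet_threshold: float = 1.0,
) -> dict:
    """Split fire years into warm/dry, average and cool/wet by PDSI value.

    A fire year with PDSI <= ``dry_threshold`` is warm/dry, >= ``wet_threshold``
    cool/wet, otherwise average.  Returns counts and proportions.
    """
    fire_years = sorted(fire_years)
    outside = [y for y in fire_years if not pdsi.start <= y <= pdsi.end]
    if outside:
        raise ValueError(f"fire years outside {pdsi.name} series: {outside}")
    counts = {"warm_dry": 0, "average": 0, "cool_wet": 0}
    for y in fire_years:
        v = pdsi.value_at(y)
        if v <= dry_threshold:
            counts["warm_dry"] += 1
        elif v >= wet_threshold:
            counts["cool_wet"] += 1
        else:
            counts["average"] += 1
    n = len(fire_years)
    props = {key: (c / n if n else float("nan")) for key, c in counts.items()}
    return {"counts": counts, "proportions": props, "n": n}
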