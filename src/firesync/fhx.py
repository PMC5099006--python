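"""Reading and writing fire-scar series in the FHX (Fire History Exchange) format.

FHX is the standard plain-text interchange format of fire-history
dendrochronology: a year-by-series character matrix in which each column is
one fire-scarred tree and each row one calendar year.  Cell codes:

========  =====================================================
code      meaning
========  =====================================================
D E M L A dated fire scar with intra-ring (season) position
U         dated fire scar, season undetermined
d e m l a u  other cambial injury (lowercase), season as above
``|``     recording year, no scar (tree able to register fire)
``.``     non-recording year inside the series span, or filler
          outside the span
``[`` ``]``  first/last ring with pith/bark present
``{`` ``}``  first/last ring without pith/bark
========  =====================================================

Dialect conventions of this reader/writer (documented because the format in
circulation varies slightly between programs):

* Both ``FHX2 FORMAT`` and ``FIRE2 FORMAT`` header lines are accepted;
  ``FHX2 FORMAT`` is emitted.
* Every series span is explicitly delimited by a start marker (``[`` or
  ``{``) and an end marker (``]`` or ``}``); cells outside the span are
  ``.``.
* A boundary marker carries no recording information of its own: the
  boundary year inherits the recording status of its interior neighbour
  (a one-year series is non-recording).
* Scar/injury codes imply recording status; a scar embedded in a ``.`` run
  converts that year to a recording year with a logged warning (a scarred
  tree is by definition a recorder in that year).
* Comment lines starting with ``;`` or ``#`` may precede the header; the
  writer uses them to persist the site name and series-to-plot mapping
  (``; site: NAME`` / ``; plot: SERIES PLOT``) so that a collection
  round-trips field-for-field.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Uppercase dated fire-scar codes (intra-ring position classes + undetermined).
SCAR_CODES = frozenset("DEMLA U".replace(" ", ""))
#: Lowercase equivalents marking non-fire cambial injuries.
INJURY_CODES = frozenset("demla u".replace(" ", ""))
EVENT_CODES = SCAR_CODES | INJURY_CODES
START_MARKERS = frozenset("[{")
END_MARKERS = frozenset("]}")
HEADER_LINES = ("FHX2 FORMAT", "FIRE2 FORMAT")


class FhxParseError(ValueError):
    """Raised when an FHX document cannot be parsed; the message names the
    offending line, year or series."""


@dataclass
class TreeSeries:
    """Per-tree annual record of fire scars, injuries and recorder status."""

    series_id: str
    first_year: int
    last_year: int
    pith_at_start: bool = False
    bark_at_end: bool = False
    scar_years: frozenset = frozenset()  # of (year, code) pairs
    recording_years: frozenset = frozenset()

    def __post_init__(self):
        self.scar_years = frozenset(self.scar_years)
        self.recording_years = frozenset(self.recording_years)
        if not self.series_id:
            raise ValueError("series_id must be non-empty")
        if self.first_year > self.last_year:
            raise ValueError(
                f"series {self.series_id}: first_year {self.first_year} "
                f"> last_year {self.last_year}"
            )
        for year, code in self.scar_years:
            if code not in EVENT_CODES:
                raise ValueError(f"series {self.series_id}: unknown code {code!r}")
            if not self.first_year <= year <= self.last_year:
                raise ValueError(
                    f"series {self.series_id}: scar year {year} outside span"
                )
        for year in self.recording_years:
            if not self.first_year <= year <= self.last_year:
                raise ValueError(
                    f"series {self.series_id}: recording year {year} outside span"
                )
        missing = {y for y, _ in self.scar_years} - set(self.recording_years)
        if missing:
            raise ValueError(
                f"series {self.series_id}: scar years {sorted(missing)} "
                "are not recording years"
            )

    @property
    def fire_scar_years(self) -> frozenset:
        """Years carrying a dated fire scar (uppercase codes only)."""
        return frozenset(y for y, c in self.scar_years if c in SCAR_CODES)


@dataclass
class FhxCollection:
    """An ordered set of tree series plus site/plot metadata."""

    site_name: str = ""
    series: list = field(default_factory=list)
    plot_of_series: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.series_id for s in self.series]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate series ids in collection")

    @property
    def year_span(self) -> tuple:
        """(min first_year, max last_year) over all series."""
        if not self.series:
            raise ValueError("empty collection has no year span")
        return (
            min(s.first_year for s in self.series),
            max(s.last_year for s in self.series),
        )

    def __len__(self):
        return len(self.series)


def _cell(series: TreeSeries, year: int) -> str:
    codes = [c for (y, c) in series.scar_years if y == year]
    if year == series.first_year:
        mark = "[" if series.pith_at_start else "{"
        return codes[0] if codes else mark
    if year == series.last_year:
        mark = "]" if series.bark_at_end else "}"
        return codes[0] if codes else mark
    if codes:
        return codes[0]
    return "|" if year in series.recording_years else "."


def write_fhx(collection: FhxCollection) -> str:
    """Serialise a collection as an FHX2 document.

    Raises ``ValueError`` for an (invalid) series with an empty year span.
    A collection with no series produces a header-only document.
    """
    lines = []
    if collection.site_name:
        lines.append(f"; site: {collection.site_name}")
    for sid, plot in collection.plot_of_series.items():
        lines.append(f"; plot: {sid} {plot}")
    lines.append("FHX2 FORMAT")
    if not collection.series:
        return "\n".join(lines) + "\n"

    start, end = collection.year_span
    n = len(collection.series)
    id_len = max(len(s.series_id) for s in collection.series)
    lines.append(f"{start} {n} {id_len}")
    padded = [s.series_id.ljust(id_len) for s in collection.series]
    for j in range(id_len):
        lines.append("".join(p[j] for p in padded))
    lines.append("")
    for year in range(start, end + 1):
        row = "".join(
            _cell(s, year) if s.first_year <= year <= s.last_year else "."
            for s in collection.series
        )
        lines.append(f"{row} {year}")
    return "\n".join(lines) + "\n"


def read_fhx(source) -> FhxCollection:
    """Parse an FHX document from a string, text stream or path-like.

    Returns an :class:`FhxCollection`; malformed input raises
    :class:`FhxParseError` naming the offending line, year or series.
    """
    import os

    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)
    lines = text.splitlines()

    site_name = ""
    plot_of_series = {}
    i = 0
    header_found = False
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.startswith((";", "#")):
            body = line.lstrip(";# ").strip()
            if body.lower().startswith("site:"):
                site_name = body[5:].strip()
            elif body.lower().startswith("plot:"):
                parts = body[5:].split()
                if len(parts) == 2:
                    plot_of_series[parts[0]] = parts[1]
            continue
        if line.upper() in HEADER_LINES:
            header_found = True
            break
        raise FhxParseError(f"line {i}: expected FHX2/FIRE2 header, got {line!r}")
    if not header_found:
        raise FhxParseError("no FHX2/FIRE2 header line found")

    # skip blank lines; EOF here means a header-only (empty) document
    while i < len(lines) and not lines[i].strip():
        i += 1
    if i >= len(lines):
        return FhxCollection(site_name=site_name, series=[],
                             plot_of_series=plot_of_series)

    parts = lines[i].split()
    if len(parts) != 3:
        raise FhxParseError(
            f"line {i + 1}: expected 'first_year n_series id_length', "
            f"got {lines[i]!r}"
        )
    try:
        first_year, n_series, id_len = (int(p) for p in parts)
    except ValueError:
        raise FhxParseError(
            f"line {i + 1}: non-integer field in header line {lines[i]!r}"
        ) from None
    if n_series < 1 or id_len < 1:
        raise FhxParseError(f"line {i + 1}: n_series and id_length must be >= 1")
    i += 1

    id_rows = []
    for j in range(id_len):
        if i >= len(lines):
            raise FhxParseError(f"line {i + 1}: truncated series-id block")
        id_rows.append(lines[i].ljust(n_series))
        i += 1
    series_ids = ["".join(r[k] for r in id_rows).strip() for k in range(n_series)]
    if len(set(series_ids)) != n_series or any(not s for s in series_ids):
        raise FhxParseError("series ids must be unique and non-empty")

    while i < len(lines) and not lines[i].strip():
        i += 1

    matrix = []  # rows of n_series chars
    years = []
    year = first_year
    for line_no in range(i, len(lines)):
        raw = lines[line_no]
        if not raw.strip():
            continue
        if len(raw.rstrip()) < n_series:
            raise FhxParseError(
                f"year {year}: matrix row narrower than {n_series} series"
            )
        matrix.append(raw[:n_series])
        trailing = raw[n_series:].strip()
        if trailing:
            try:
                stated = int(trailing.split()[0])
            except ValueError:
                stated = None
            if stated is not None and stated != year:
                raise FhxParseError(
                    f"year {year}: row labelled {stated}, expected {year}"
                )
        years.append(year)
        year += 1

    series = []
    for k, sid in enumerate(series_ids):
        col = [row[k] for row in matrix]
        s = _column_to_series(sid, col, years)
        if s is not None:
            series.append(s)
    plot_of_series = {
        sid: p for sid, p in plot_of_series.items()
        if sid in {s.series_id for s in series}
    }
    return FhxCollection(site_name=site_name, series=series,
                         plot_of_series=plot_of_series)


def _column_to_series(sid, col, years):
    start_idx = end_idx = None
    for idx, ch in enumerate(col):
        if ch in START_MARKERS and start_idx is None:
            start_idx = idx
        if ch in END_MARKERS:
            end_idx = idx
    if start_idx is None or end_idx is None:
        in_span = [idx for idx, ch in enumerate(col) if ch not in ". "]
        if not in_span:
            return None  # all-filler column: no series data
        start_idx = start_idx if start_idx is not None else in_span[0]
        end_idx = end_idx if end_idx is not None else in_span[-1]
    if end_idx < start_idx:
        raise FhxParseError(f"series {sid}: end marker precedes start marker")

    pith = col[start_idx] == "["
    bark = col[end_idx] == "]"
    scar_years = set()
    recording = {}
    for idx in range(start_idx, end_idx + 1):
        ch = col[idx]
        y = years[idx]
        if ch in EVENT_CODES:
            scar_years.add((y, ch))
            recording[y] = True
        elif ch == "|":
            recording[y] = True
        elif ch == ".":
            recording[y] = False
        elif ch in START_MARKERS or ch in END_MARKERS:
            recording[y] = None  # inherit below
        else:
            raise FhxParseError(f"year {y}, series {sid}: unknown code {ch!r}")
    # boundary years inherit the recording status of the interior neighbour
    ys = sorted(recording)
    for pos, y in enumerate(ys):
        if recording[y] is None:
            if len(ys) == 1:
                recording[y] = False
            elif pos == 0:
                recording[y] = bool(recording[ys[1]])
            else:
                recording[y] = bool(recording[ys[pos - 1]])
    for y, _code in scar_years:
        pos = ys.index(y)
        prev_rec = recording.get(ys[pos - 1], False) if pos > 0 else False
        nxt_rec = recording.get(ys[pos + 1], False) if pos + 1 < len(ys) else False
        if not prev_rec and not nxt_rec and len(ys) > 1:
            logger.warning(
                "series %s: scar at %d inside a non-recording run; "
                "year promoted to recording", sid, y
            )
    return TreeSeries(
        series_id=sid,
        first_year=years[start_idx],
        last_year=years[end_idx],
        pith_at_start=pith,
        bark_at_end=bark,
        scar_years=frozenset(scar_years),
        recording_years=frozenset(y for y, r in recording.items() if r),
    )


def recorder_depth(collection: FhxCollection) -> pd.Series:
    """Number of recording ('recorder') trees per year over the collection span.

    This is the 'sample recorder depth' curve of a composite fire chronology:
    for each calendar year, how many trees were capable of registering a
    fire scar.
    """
    if not collection.series:
        raise ValueError("recorder depth of an empty collection is undefined")
    start, end = collection.year_span
    idx = pd.RangeIndex(start, end + 1, name="year")
    depth = pd.Series(0, index=idx, name="recorder_depth")
    for s in collection.series:
        for y in s.recording_years:
            depth.loc[y] += 1
    return depth


def validate_fhx(source) -> FhxCollection:
    """Parse and validate, returning the collection (errors raise)."""
    return read_fhx(source)
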