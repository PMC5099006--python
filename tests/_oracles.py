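"""Independent brute-force oracles and random-structure generators used by
the test suite.  These deliberately avoid the package's vectorised code
paths: plain loops over definitions."""

from __future__ import annotations

import numpy as np

from firesync.fhx import FhxCollection, TreeSeries


def k_brute(fire_years, climate_years, domain, t_max, edge_correction=True):
    """O(n1*n2*t_max) pair-counting Ripley's K, straight from the definition."""
    start, end = domain
    T = end - start + 1
    n1, n2 = len(fire_years), len(climate_years)
    out = []
    for t in range(t_max + 1):
        total = 0.0
        for f in fire_years:
            if edge_correction:
                w = (min(t, f - start) + 1) / (t + 1)
            else:
                w = 1.0
            for c in climate_years:
                if 0 <= f - c <= t:
                    total += 1.0 / w
        out.append(T / (n1 * n2) * total)
    return np.array(out)


def random_event_sets(rng, T_max=200, n_max=20, t_cap=50):
    """A random K-function test instance on a random integer domain."""
    T = int(rng.integers(20, T_max + 1))
    start = int(rng.integers(0, 2000))
    domain = (start, start + T - 1)
    n1 = int(rng.integers(1, min(n_max, T) + 1))
    n2 = int(rng.integers(1, min(n_max, T) + 1))
    years = np.arange(start, start + T)
    fires = rng.choice(years, size=n1, replace=False)
    climate = rng.choice(years, size=n2, replace=False)
    t_max = int(rng.integers(0, min(t_cap, T - 1) + 1))
    return fires, climate, domain, t_max


def random_collection(rng, n_series=None, span=(1300, 1500)) -> FhxCollection:
    """A random valid FhxCollection conforming to the writer's boundary
    conventions (boundary-year recording matches the interior neighbour;
    no scars in boundary years)."""
    if n_series is None:
        n_series = int(rng.integers(1, 11))
    lo, hi = span
    series = []
    plot_map = {}
    for i in range(n_series):
        first = int(rng.integers(lo, hi - 10))
        last = int(rng.integers(first + 4, hi + 1))
        interior = np.arange(first + 1, last)
        recording = set()
        # a couple of random recording runs
        for _ in range(int(rng.integers(1, 4))):
            a = int(rng.integers(first + 1, last))
            b = min(last - 1, a + int(rng.integers(1, 40)))
            recording.update(range(a, b + 1))
        rec_interior = sorted(recording & set(interior))
        scars = set()
        if rec_interior:
            n_scars = int(rng.integers(0, min(4, len(rec_interior)) + 1))
            for y in rng.choice(rec_interior, size=n_scars, replace=False):
                code = str(rng.choice(list("UDEMLAu")))
                scars.add((int(y), code))
        # boundary recording inherits the interior neighbour
        if (first + 1) in recording:
            recording.add(first)
        if (last - 1) in recording:
            recording.add(last)
        sid = f"T{i + 1:02d}"
        series.append(
            TreeSeries(
                series_id=sid,
                first_year=first,
                last_year=last,
                pith_at_start=bool(rng.integers(0, 2)),
                bark_at_end=bool(rng.integers(0, 2)),
                scar_years=frozenset(scars),
                recording_years=frozenset(recording & set(range(first, last + 1))),
            )
        )
        plot_map[sid] = f"P{int(rng.integers(1, 6))}"
    return FhxCollection(site_name="rand", series=series, plot_of_series=plot_map)
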