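"""Annual-scale fire-frequency analysis: G-tests against equal likelihood.

The question at the annual scale is whether fire years fall
disproportionately inside particular climate phases (or phase
combinations).  Under the null, every year of the common analysis period
is equally likely to burn, so the expected fire count in a category is
proportional to the number of years the category covers.  The test is the
G-test (log-likelihood-ratio) of goodness of fit::

    G = 2 * sum_i O_i * ln(O_i / E_i),   0 * ln 0 = 0

referred to a chi-square distribution with (#categories - 1) degrees of
freedom.  With few fires the expected counts are small, so results flag
any E_i < 5 and an exact Monte Carlo multinomial p-value is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats


@dataclass
class PhaseContingency:
    """Observed fire counts per climate-phase category plus category-year
    coverage, from which the equal-likelihood expecteds follow."""

    categories: tuple
    observed: np.ndarray
    category_years: np.ndarray
    total_years: int

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.category_years = np.asarray(self.category_years, dtype=float)
        if self.observed.size != len(self.categories) or (
            self.category_years.size != len(self.categories)
        ):
            raise ValueError("categories, observed and category_years must align")
        if (self.observed < 0).any():
            raise ValueError("negative observed counts")
        if self.category_years.sum() != self.total_years:
            raise ValueError("category_years must partition the period")

    @property
    def total_fires(self) -> int:
        return int(self.observed.sum())

    @property
    def expected(self) -> np.ndarray:
        return self.total_fires * self.category_years / self.total_years


@dataclass
class GTestResult:
    G: float
    df: int
    p_value: float
    expected: np.ndarray
    small_expected: bool  # any E_i < 5: chi-square approximation suspect
    p_mc: float | None = None
    williams: bool = False


def build_contingency(fire_years, phase_assignment, period) -> PhaseContingency:
    """Tabulate fires by category over ``period`` (inclusive).

    ``phase_assignment`` maps each year of the period to a category label;
    a fire year without a category is an error.
    """
    start, end = period
    years = range(start, end + 1)
    fire_years = [y for y in fire_years if start <= y <= end]
    missing = [y for y in fire_years if phase_assignment.get(y) is None]
    if missing:
        raise ValueError(f"fire years without a phase category: {sorted(missing)}")
    cat_years: dict = {}
    for y in years:
        c = phase_assignment.get(y)
        if c is None:
            raise ValueError(f"year {y} has no phase category")
        cat_years[c] = cat_years.get(c, 0) + 1
    categories = tuple(sorted(cat_years))
    observed = np.zeros(len(categories))
    for y in fire_years:
        observed[categories.index(phase_assignment[y])] += 1
    return PhaseContingency(
        categories=categories,
        observed=observed,
        category_years=np.array([cat_years[c] for c in categories], dtype=float),
        total_years=end - start + 1,
    )


def g_test(
    table: PhaseContingency,
    williams: bool = False,
    mc_pvalue: bool = False,
    n_mc: int = 9999,
    seed=None,
) -> GTestResult:
    """G-test of goodness of fit against the equal-likelihood expecteds.

    Williams' small-sample correction is off by default; ``mc_pvalue``
    adds an exact Monte Carlo multinomial p-value alongside the
    chi-square one.
    """
    obs = table.observed
    exp = table.expected
    if table.total_fires == 0:
        raise ValueError("G-test undefined with zero fires")
    if (exp <= 0).any():
        raise ValueError("all expected counts must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        G = 2.0 * np.sum(special.xlogy(obs, obs / exp))
    df = len(table.categories) - 1
    G_eval = G
    if williams:
        k, n = len(table.categories), table.total_fires
        q = 1.0 + (k**2 - 1.0) / (6.0 * n * df) if df > 0 else 1.0
        G_eval = G / q
    p = float(stats.chi2.sf(G_eval, df)) if df > 0 else 1.0
    p_mc = None
    if mc_pvalue:
        rng = np.random.default_rng(seed)
        probs = table.category_years / table.total_years
        sims = rng.multinomial(table.total_fires, probs, size=n_mc)
        with np.errstate(divide="ignore", invalid="ignore"):
            g_sims = 2.0 * np.sum(
                special.xlogy(sims, sims / exp[None, :]), axis=1
            )
        p_mc = float((1 + np.sum(g_sims >= G - 1e-12)) / (n_mc + 1))
    return GTestResult(
        G=float(G),
        df=df,
        p_value=p,
        expected=exp,
        small_expected=bool((exp < 5).any()),
        p_mc=p_mc,
        williams=williams,
    )


def phase_combination_tests(
    fire_years, event_sets, period, mc_pvalue: bool = False, seed=None
) -> pd.DataFrame:
    """One binary G-test per extreme-event set (in-set vs out-of-set years).

    For each :class:`~firesync.climate.ExtremeEventSet`, years of the
    period are split into 'in the combined extreme set' and 'other', and
    observed fire counts are tested against the equal-likelihood split.
    Three-way combinations are conventionally restricted to a late
    sub-period by passing the appropriate ``period``.
    """
    start, end = period
    rows = []
    rng = np.random.default_rng(seed)
    for es in event_sets:
        in_set = {y for y in es.event_years if start <= y <= end}
        assignment = {
            y: ("extreme" if y in in_set else "other")
            for y in range(start, end + 1)
        }
        table = build_contingency(fire_years, assignment, period)
        res = g_test(
            table,
            mc_pvalue=mc_pvalue,
            seed=int(rng.integers(2**31 - 1)) if mc_pvalue else None,
        )
        obs_in = table.observed[table.categories.index("extreme")] if "extreme" in table.categories else 0.0
        exp_in = res.expected[table.categories.index("extreme")] if "extreme" in table.categories else 0.0
        rows.append(
            {
                "combination": es.label,
                "period": f"{start}-{end}",
                "n_extreme_years": len(in_set),
                "observed_in": obs_in,
                "expected_in": exp_in,
                "G": res.G,
                "df": res.df,
                "p": res.p_value,
                "p_mc": res.p_mc,
                "small_expected": res.small_expected,
            }
        )
    return pd.DataFrame(rows)
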