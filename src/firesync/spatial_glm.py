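"""Spatial controls of the fire regime: Poisson GLMs with AICc selection.

Per-plot fire-scar abundance and fire-event frequency are modelled as
Poisson counts with a log link on topographic and cultural predictors
(distance to former habitation site, distance to shoreline, elevation,
slope, aspect, vegetation type).  Candidate models — by default all
subsets of the six conceptual predictors, with vegetation entering as a
single dummy block (reference level: blanket bog) — are ranked by the
small-sample Akaike information criterion::

    AICc = -2 logL + 2K + 2K(K + 1) / (n - K - 1)

Akaike weights w_i = exp(-dAICc_i / 2) / sum_j exp(-dAICc_j / 2) give
normalised model probabilities, evidence ratios ER_i = w_top / w_i, and a
95% confidence set (smallest top set with cumulative weight >= 0.95) over
which coefficients are model-averaged with shrinkage (a predictor absent
from a model contributes 0).  Fit quality is the deviance-based pseudo-R2,
1 - D_residual / D_null.

Aspect is a circular variable; it enters as northness = cos(aspect) by
default (raw degrees available for strict emulation of legacy analyses).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Conceptual predictors; vegetation expands to a dummy block.
CONCEPTUAL_PREDICTORS = (
    "dist_habitation",
    "dist_shoreline",
    "elevation",
    "slope",
    "aspect",
    "vegetation",
)
VEG_LEVELS = ("zonal", "bog_forest", "bog_woodland")  # reference: blanket_bog
RESPONSE_COLUMNS = {
    "scar_abundance": "n_fire_scars",
    "event_frequency": "n_fire_events",
}

#: Column aliases accepted from the plot-attribute CSV schema.
_COLUMN_ALIASES = {
    "elevation_m": "elevation",
    "slope_deg": "slope",
    "aspect_deg": "aspect",
    "dist_habitation_m": "dist_habitation",
    "dist_shoreline_m": "dist_shoreline",
}


@dataclass
class FitResult:
    """A single Poisson-GLM fit (log-link scale)."""

    predictors: tuple
    params: pd.Series
    bse: pd.Series
    llf: float
    deviance: float
    null_deviance: float
    n: int
    converged: bool

    @property
    def K(self) -> int:
        return len(self.params)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pseudo_r2(self) -> float:
        return 1.0 - self.deviance / self.null_deviance if self.null_deviance > 0 else 0.0


@dataclass
class AveragedCoefficients:
    """Shrinkage model-averaged coefficients over a confidence set."""

    coefficients: pd.Series
    se: pd.Series
    relative_importance: pd.Series
    confidence_set: tuple  # model names, top first
    cumulative_weight: float


def _normalise_columns(data: pd.DataFrame) -> pd.DataFrame:
    df = data.rename(columns=_COLUMN_ALIASES).copy()
    return df


def build_design(
    data: pd.DataFrame,
    predictors,
    aspect_encoding: str = "northness",
) -> pd.DataFrame:
    """Design matrix (with intercept) for a subset of conceptual predictors."""
    df = _normalise_columns(data)
    cols = {"const": np.ones(len(df))}
    for p in predictors:
        if p == "vegetation":
            for lev in VEG_LEVELS:
                cols[f"veg_{lev}"] = (df["vegetation_type"] == lev).astype(float)
        elif p == "aspect":
            if aspect_encoding == "northness":
                cols["aspect_northness"] = np.cos(np.deg2rad(df["aspect"]))
            elif aspect_encoding == "raw":
                cols["aspect"] = df["aspect"].astype(float)
            else:
                raise ValueError(f"unknown aspect encoding {aspect_encoding!r}")
        elif p in df.columns:
            cols[p] = df[p].astype(float)
        else:
            raise ValueError(f"unknown predictor {p!r}")
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns via incremental rank
        aliased, kept = [], []
        for c in X.columns:
            trial = X[kept + [c]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(c)
            else:
                aliased.append(c)
        raise ValueError(f"design is rank-deficient; aliased columns: {aliased}")
    return X


def fit_poisson(counts, X: pd.DataFrame, predictors=()) -> FitResult:
    """Maximum-likelihood Poisson GLM (log link) via IRLS.

    ``counts`` must be non-negative integers; ``X`` a full-rank design with
    an intercept column.  Non-convergence yields ``converged=False`` (such
    fits are excluded from model selection with a logged warning).
    """
    y = np.asarray(counts, dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=100, tol=1e-8)
    return FitResult(
        predictors=tuple(predictors),
        params=res.params,
        bse=res.bse,
        llf=float(res.llf),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        n=len(y),
        converged=bool(res.converged),
    )


def aicc(llf: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined: need n > K + 1 (n={n}, K={K})")
    return -2.0 * llf + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def _model_name(predictors) -> str:
    return " + ".join(predictors) if predictors else "intercept-only"


def default_candidate_sets():
    """All subsets of the six conceptual predictors (vegetation as a block)."""
    out = []
    for r in range(len(CONCEPTUAL_PREDICTORS) + 1):
        out.extend(itertools.combinations(CONCEPTUAL_PREDICTORS, r))
    return out


class FireRegimeSelection:
    """All-subsets AICc selection of Poisson GLMs for per-plot fire counts.

    Parameters
    ----------
    data : DataFrame
        One row per plot; plot-attribute columns (CSV schema or bare
        names) plus the response count column.
    response : str
        'scar_abundance', 'event_frequency', or a column name.
    candidate_sets : sequence of predictor tuples, optional
        Defaults to all subsets of the conceptual predictors.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        candidate_sets=None,
        aspect_encoding: str = "northness",
    ):
        self.data = _normalise_columns(data)
        col = RESPONSE_COLUMNS.get(response, response)
        if col not in self.data.columns:
            raise ValueError(f"response column {col!r} not in data")
        self.response = response
        self.counts = self.data[col].to_numpy()
        self.candidate_sets = (
            [tuple(c) for c in candidate_sets]
            if candidate_sets is not None
            else default_candidate_sets()
        )
        if len(self.candidate_sets) < 2:
            raise ValueError("need at least two candidate models")
        self.aspect_encoding = aspect_encoding

    def fit(self) -> "SelectionResults":
        fits, rows = {}, []
        n = len(self.data)
        for preds in self.candidate_sets:
            name = _model_name(preds)
            try:
                X = build_design(self.data, preds, self.aspect_encoding)
                fr = fit_poisson(self.counts, X, preds)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("model %r excluded: %s", name, exc)
                continue
            if not fr.converged:
                logger.warning("model %r excluded: IRLS did not converge", name)
                continue
            fits[name] = fr
            rows.append(
                {
                    "model": name,
                    "K": fr.K,
                    "pseudo_R2": fr.pseudo_r2,
                    "AICc": aicc(fr.llf, fr.K, n),
                    "predictors": preds,
                }
            )
        if len(rows) < 2:
            raise ValueError("fewer than two candidate models could be fitted")
        table = pd.DataFrame(rows).sort_values("AICc", kind="mergesort")
        table["dAICc"] = table["AICc"] - table["AICc"].iloc[0]
        rel = np.exp(-table["dAICc"] / 2.0)
        table["w"] = rel / rel.sum()
        table["ER"] = table["w"].iloc[0] / table["w"]
        table = table.reset_index(drop=True)
        return SelectionResults(table=table, fits=fits, n=n, response=self.response)


@dataclass
class SelectionResults:
    """Ranked AICc table plus per-model fits; supports model averaging."""

    table: pd.DataFrame
    fits: dict
    n: int
    response: str

    @property
    def top_model(self) -> FitResult:
        return self.fits[self.table["model"].iloc[0]]

    def average(self, confidence: float = 0.95) -> AveragedCoefficients:
        """Shrinkage-average coefficients over the smallest top set of models
        whose cumulative Akaike weight reaches ``confidence``.

        Weights are renormalised within the set; a predictor absent from a
        model contributes 0 to the average.  Averaged standard errors use
        the unconditional (between-model variance inflated) formula, and
        per-predictor relative importance is the renormalised weight sum
        over set models containing that predictor.
        """
        cum = self.table["w"].cumsum()
        n_keep = int(np.searchsorted(cum.to_numpy(), confidence) + 1)
        n_keep = min(n_keep, len(self.table))
        sub = self.table.iloc[:n_keep]
        w = sub["w"].to_numpy()
        w = w / w.sum()
        all_cols: list = []
        for name in sub["model"]:
            for c in self.fits[name].params.index:
                if c not in all_cols:
                    all_cols.append(c)
        b = np.zeros((n_keep, len(all_cols)))
        se = np.zeros_like(b)
        present = np.zeros_like(b, dtype=bool)
        for i, name in enumerate(sub["model"]):
            fr = self.fits[name]
            for j, c in enumerate(all_cols):
                if c in fr.params.index:
                    b[i, j] = fr.params[c]
                    se[i, j] = fr.bse[c]
                    present[i, j] = True
        bbar = w @ b
        # unconditional SE (Buckland et al.): absent models contribute b=0, se=0
        var = (w[:, None] * (se**2 + (b - bbar[None, :]) ** 2)).sum(axis=0)
        importance = (w[:, None] * present).sum(axis=0)
        return AveragedCoefficients(
            coefficients=pd.Series(bbar, index=all_cols),
            se=pd.Series(np.sqrt(var), index=all_cols),
            relative_importance=pd.Series(importance, index=all_cols).drop(
                "const", errors="ignore"
            ),
            confidence_set=tuple(sub["model"]),
            cumulative_weight=float(self.table["w"].iloc[:n_keep].sum()),
        )

    def summary(self, max_rows: int = 10) -> str:
        cols = ["model", "K", "pseudo_R2", "dAICc", "w", "ER"]
        head = self.table[cols].head(max_rows)
        lines = [
            f"Poisson-GLM AICc selection - response: {self.response} "
            f"(n = {self.n} plots, {len(self.table)} candidate models)",
            head.to_string(
                index=False,
                formatters={
                    "pseudo_R2": "{:.2f}".format,
                    "dAICc": "{:.2f}".format,
                    "w": "{:.3f}".format,
                    "ER": "{:.2f}".format,
                },
            ),
        ]
        return "\n".join(lines)


def select_models(
    data: pd.DataFrame,
    response: str,
    candidate_sets=None,
    aspect_encoding: str = "northness",
) -> SelectionResults:
    """Functional wrapper around :class:`FireRegimeSelection`."""
    return FireRegimeSelection(
        data, response, candidate_sets, aspect_encoding
    ).fit()


def model_average(results: SelectionResults, confidence: float = 0.95):
    """Functional wrapper around :meth:`SelectionResults.average`."""
    return results.average(confidence)
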