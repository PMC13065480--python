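"""Contemporaneous and lag-1 odds-ratio analyses between event types.

For every outcome event a separate binomial-logit mixed model is fitted
with the other events as predictors and crossed individual/household
random intercepts:

    E_o ~ E_1 + ... + E_p + (1 | individual) + (1 | household)

Exclusivity handling mirrors the survey design: when the outcome belongs
to a mutual-exclusivity group, the other group members are removed as
predictors of contemporaneous models (they are structurally zero whenever
the outcome occurs), and the group's reference label is dropped as a
predictor in every contemporaneous model.  Lag-1 models regress next
year's outcome on all of this year's events (including the outcome's own
type), attaching the outcome-year household id; previous-year group
events are not collinear, so only the reference label is dropped there.

No multiple-testing correction is applied: significance means the 95%
interval excludes an odds ratio of 1, and with roughly p^2 cells tested a
5% false-positive rate among true nulls is expected by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import EventCatalog
from .glmm import ModelSpec, fit_glmm, profile_ci
from .panel import PanelDataset, lag_align

__all__ = [
    "OddsRatioEstimate",
    "ORMatrix",
    "fit_contemporaneous",
    "fit_lag1",
    "fit_unadjusted",
    "percent_difference",
    "sign_reversals",
]


@dataclass(frozen=True)
class OddsRatioEstimate:
    predictor: str
    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    adjusted: bool
    lagged: bool
    n_obs: int
    warnings: tuple[str, ...] = ()

    @property
    def significant(self) -> bool:
        return self.ci_low > 1.0 or self.ci_high < 1.0


@dataclass
class ORMatrix:
    """Collection of per-cell odds-ratio estimates over a catalog.

    Structurally excluded cells (exclusivity-group pairs, the dropped
    reference category) and cells whose model hit separation are *absent*,
    recorded in ``absent`` with a diagnostic, never reported as OR = 0.
    """

    catalog: EventCatalog
    lagged: bool
    adjusted: bool
    estimates: dict[tuple[str, str], OddsRatioEstimate] = field(default_factory=dict)
    absent: dict[tuple[str, str], str] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def get(self, predictor: str, outcome: str) -> OddsRatioEstimate | None:
        return self.estimates.get((predictor, outcome))

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": e.outcome,
                "predictor": e.predictor,
                "lagged": e.lagged,
                "adjusted": e.adjusted,
                "odds_ratio": e.odds_ratio,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "significant": e.significant,
                "n_obs": e.n_obs,
                "warnings": "; ".join(e.warnings),
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def to_matrix(self) -> pd.DataFrame:
        """Heat-map-ready matrix, rows = predictors, columns = outcomes."""
        events = list(self.catalog.events)
        mat = pd.DataFrame(np.nan, index=events, columns=events)
        for (pred, out), est in self.estimates.items():
            mat.loc[pred, out] = est.odds_ratio
        return mat

    def significance_rate(self) -> float:
        cells = list(self.estimates.values())
        if not cells:
            return np.nan
        return float(np.mean([c.significant for c in cells]))


def _predictor_sets(
    catalog: EventCatalog, outcome: str, lagged: bool
) -> tuple[list[str], dict[str, str]]:
    """Allowed predictors for one outcome model, plus excluded cells with reasons."""
    excluded: dict[str, str] = {}
    predictors = []
    group = catalog.group_of(outcome)
    for e in catalog.events:
        if not lagged and e == outcome:
            excluded[e] = "outcome"
            continue
        if not lagged and group is not None and e in group:
            excluded[e] = "exclusivity group of outcome"
            continue
        if catalog.reference_label is not None and e == catalog.reference_label and e != outcome:
            excluded[e] = "reference category"
            continue
        if lagged and catalog.reference_label == e:
            excluded[e] = "reference category"
            continue
        predictors.append(e)
    return predictors, excluded


def _model_data(panel: PanelDataset, lagged: bool) -> tuple[pd.DataFrame, dict[str, str]]:
    """Model frame and event-column name map (label -> data column)."""
    if lagged:
        pairs = lag_align(panel)
        cols = {e: f"pred_{e}" for e in panel.event_columns}
        out_cols = {e: f"out_{e}" for e in panel.event_columns}
        data = pairs.rename(columns={"id": "individual", "hh_id": "household"})
        data = data.fillna(0.0)
        return data, {"pred": cols, "out": out_cols}
    data = panel.data.rename(columns={"id": "individual", "hh_id": "household"})
    data = data.copy()
    data[panel.event_columns] = data[panel.event_columns].fillna(0.0)
    cols = {e: e for e in panel.event_columns}
    return data, {"pred": cols, "out": cols}


def _fit_matrix(
    panel: PanelDataset,
    catalog: EventCatalog,
    lagged: bool,
    adjusted: bool,
    ci: str = "wald",
    seed: int = 0,
) -> ORMatrix:
    data, colmap = _model_data(panel, lagged)
    result = ORMatrix(catalog=catalog, lagged=lagged, adjusted=adjusted)
    result.metadata = {
        "n_obs": len(data),
        "n_individuals": int(data["individual"].nunique()),
        "n_households": int(data["household"].nunique()),
        "ci": ci,
    }
    for outcome in catalog.events:
        predictors, excluded = _predictor_sets(catalog, outcome, lagged)
        for e, reason in excluded.items():
            result.absent[(e, outcome)] = reason
        ycol = colmap["out"][outcome]
        pred_groups = [predictors] if adjusted else [[p] for p in predictors]
        for preds in pred_groups:
            terms = tuple(colmap["pred"][p] for p in preds)
            work = data[["individual", "household", ycol, *terms]].copy()
            spec = ModelSpec(
                family="binomial",
                response=ycol,
                fixed_terms=terms,
                trials=1,
            )
            try:
                # profiled Laplace (no joint beta refinement): the refinement
                # moves intercept-scale estimates but leaves OR contrasts
                # essentially unchanged, and a full matrix fits ~p^2 models
                fit = fit_glmm(spec, work, seed=seed, refine_beta=False)
            except Exception as err:  # failed cell: absent with diagnostic
                for p in preds:
                    result.absent[(p, outcome)] = f"fit failed: {err}"
                continue
            for p in preds:
                term = colmap["pred"][p]
                if term in fit.flagged:
                    result.absent[(p, outcome)] = "separation: unreliable estimate"
                    continue
                if ci == "profile":
                    lo, hi = profile_ci(fit, term, work)
                else:
                    lo, hi = fit.wald_ci[term]
                result.estimates[(p, outcome)] = OddsRatioEstimate(
                    predictor=p,
                    outcome=outcome,
                    odds_ratio=float(np.exp(fit.coefficients[term])),
                    ci_low=float(np.exp(lo)),
                    ci_high=float(np.exp(hi)),
                    adjusted=adjusted,
                    lagged=lagged,
                    n_obs=fit.n_obs,
                    warnings=tuple(fit.warnings),
                )
    return result


def fit_contemporaneous(
    panel: PanelDataset, catalog: EventCatalog | None = None, ci: str = "wald", seed: int = 0
) -> ORMatrix:
    """Adjusted within-year odds ratios: one model per outcome event with all
    admissible other events as predictors."""
    catalog = catalog or panel.catalog
    if catalog is None or catalog.n_events < 2:
        raise ValueError("co-occurrence analysis needs a catalog with at least 2 events")
    return _fit_matrix(panel, catalog, lagged=False, adjusted=True, ci=ci, seed=seed)


def fit_lag1(
    panel: PanelDataset, catalog: EventCatalog | None = None, ci: str = "wald", seed: int = 0
) -> ORMatrix:
    """Adjusted lag-1 odds ratios: next year's outcome on this year's events,
    diagonal (within-event persistence) included."""
    catalog = catalog or panel.catalog
    if catalog is None or catalog.n_events < 2:
        raise ValueError("co-occurrence analysis needs a catalog with at least 2 events")
    if lag_align(panel).empty:
        raise ValueError("no adjacent-year pairs available for lag-1 analysis")
    return _fit_matrix(panel, catalog, lagged=True, adjusted=True, ci=ci, seed=seed)


def fit_unadjusted(
    panel: PanelDataset,
    catalog: EventCatalog | None = None,
    lagged: bool = False,
    ci: str = "wald",
    seed: int = 0,
) -> ORMatrix:
    """Bivariate sensitivity models: one predictor at a time with the same
    random-effects structure, fitted to the same rows as the adjusted fits."""
    catalog = catalog or panel.catalog
    if catalog is None or catalog.n_events < 2:
        raise ValueError("co-occurrence analysis needs a catalog with at least 2 events")
    return _fit_matrix(panel, catalog, lagged=lagged, adjusted=False, ci=ci, seed=seed)


def percent_difference(or_unadjusted: float, or_adjusted: float) -> float:
    """100 * (OR_unadjusted - OR_adjusted) / OR_adjusted."""
    if or_adjusted <= 0:
        raise ValueError("adjusted odds ratio must be positive")
    return 100.0 * (or_unadjusted - or_adjusted) / or_adjusted


def sign_reversals(
    adjusted: ORMatrix, unadjusted: ORMatrix
) -> list[tuple[str, str]]:
    """Cells significant in the adjusted fit whose unadjusted OR lies on the
    other side of 1 (OR_adj < 1 < OR_unadj or vice versa)."""
    out = []
    for key, adj in adjusted.estimates.items():
        if not adj.significant:
            continue
        una = unadjusted.estimates.get(key)
        if una is None:
            continue
        if (adj.odds_ratio < 1.0 < una.odds_ratio) or (una.odds_ratio < 1.0 < adj.odds_ratio):
            out.append(key)
    return out
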