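"""Person-year panel data model, I/O, filtering, windowing, and descriptives.

The analysis unit throughout is the *person-year*: one individual's record
for one calendar year, holding a binary vector of adverse-life-event
indicators (or, for count-only simulations, a single yearly event count),
the individual's household for that year, and their age.

A :class:`PanelDataset` wraps a long-format :class:`pandas.DataFrame`
(columns ``id, hh_id, year, age``, then one column per catalog event) plus
a boolean missingness mask of the same shape as the event block, retained
after imputation so the imputation rate stays reportable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .catalog import EventCatalog

__all__ = [
    "PanelDataset",
    "read_panel",
    "write_panel",
    "filter_adults",
    "drop_all_missing_rows",
    "impute_missing_as_zero",
    "build_household_ids",
    "consecutive_window",
    "lag_align",
    "count_summaries",
    "joint_conditional_probs",
]

ID_COLUMNS = ["id", "hh_id", "year", "age"]


class PanelError(ValueError):
    """Raised for structurally invalid panel input."""


@dataclass
class PanelDataset:
    """Long-format person-year panel.

    ``data`` holds one row per (individual, year).  For typed panels the
    event block stores floats with NaN marking unobserved cells until
    :func:`impute_missing_as_zero` is applied; ``mask`` records which cells
    were unobserved regardless of imputation.  Count-only panels (from the
    accumulation simulators) carry a single ``count`` column instead of an
    event block.
    """

    data: pd.DataFrame
    catalog: EventCatalog | None = None
    provenance: str = ""
    mask: pd.DataFrame | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in ("id", "hh_id", "year") if c not in self.data.columns]
        if missing:
            raise PanelError(f"panel missing columns {missing}")
        dup = self.data.duplicated(subset=["id", "year"])
        if dup.any():
            keys = self.data.loc[dup, ["id", "year"]].values.tolist()
            raise PanelError(f"duplicate (id, year) pairs: {keys[:5]}")
        if self.catalog is not None:
            absent = [e for e in self.catalog.events if e not in self.data.columns]
            if absent:
                raise PanelError(f"panel missing event columns {absent}")
            if self.mask is None:
                self.mask = self.data[list(self.catalog.events)].isna()
            self._check_exclusivity()

    def _check_exclusivity(self) -> None:
        assert self.catalog is not None
        for group in self.catalog.exclusivity_groups:
            cols = [e for e in self.catalog.events if e in group]
            sums = self.data[cols].sum(axis=1, skipna=True)
            bad = sums > 1
            if bad.any():
                rows = self.data.loc[bad, ["id", "year"]].values.tolist()
                raise PanelError(
                    f"exclusivity violation in group {sorted(group)} at rows {rows[:10]}"
                )

    # -- views -------------------------------------------------------------
    @property
    def event_columns(self) -> list[str]:
        if self.catalog is not None:
            return list(self.catalog.events)
        return []

    @property
    def is_counts(self) -> bool:
        return "count" in self.data.columns and self.catalog is None

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_individuals(self) -> int:
        return self.data["id"].nunique()

    @property
    def n_households(self) -> int:
        return self.data["hh_id"].nunique()

    def yearly_counts(self) -> pd.Series:
        """Number of events per person-year (missing counted as zero)."""
        if self.is_counts:
            return self.data["count"].astype(int)
        block = self.data[self.event_columns]
        return block.sum(axis=1, skipna=True).astype(int)

    def missing_rate(self) -> float:
        if self.mask is None or self.mask.size == 0:
            return 0.0
        return float(self.mask.values.mean())

    def _with(self, data: pd.DataFrame) -> "PanelDataset":
        mask = self.mask.loc[data.index] if self.mask is not None else None
        return replace(self, data=data, mask=mask)


def read_panel(path: str, catalog: EventCatalog) -> PanelDataset:
    """Read a long-format CSV (``id, hh_id, year, age``, one column per event).

    Missing events may be the literal token ``NA`` or an empty cell; both
    are parsed into the missingness mask.  Duplicate (id, year) keys,
    unknown event columns, and exclusivity violations are hard errors.
    """
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=False)
    expected = set(ID_COLUMNS) | set(catalog.events)
    unknown = set(df.columns) - expected
    if unknown:
        raise PanelError(f"unknown columns in panel file: {sorted(unknown)}")
    for ev in catalog.events:
        if ev not in df.columns:
            raise PanelError(f"event column {ev!r} missing from panel file")
        vals = df[ev].dropna().unique()
        if not np.isin(vals, [0, 1]).all():
            raise PanelError(f"event column {ev!r} has non-binary values")
        df[ev] = df[ev].astype(float)
    return PanelDataset(data=df, catalog=catalog, provenance=str(path))


def write_panel(panel: PanelDataset, path: str) -> None:
    df = panel.data.copy()
    if panel.mask is not None and panel.mask.size:
        block = df[panel.event_columns].astype(object)
        block = block.mask(panel.mask, "NA")
        df[panel.event_columns] = block
    df.to_csv(path, index=False, na_rep="NA")


def filter_adults(panel: PanelDataset, min_age: float = 18.0) -> PanelDataset:
    """Drop person-years with age below 18 (boundary inclusive)."""
    keep = panel.data["age"] >= min_age
    return panel._with(panel.data.loc[keep])


def drop_all_missing_rows(panel: PanelDataset) -> PanelDataset:
    """Drop person-years for which every event indicator is unobserved."""
    if panel.mask is None or panel.mask.size == 0:
        return panel._with(panel.data)
    keep = ~panel.mask.all(axis=1)
    return panel._with(panel.data.loc[keep])


def impute_missing_as_zero(panel: PanelDataset) -> PanelDataset:
    """Set unobserved event cells to 0; the audit mask is retained."""
    data = panel.data.copy()
    if panel.event_columns:
        data[panel.event_columns] = data[panel.event_columns].fillna(0.0)
    return replace(panel, data=data, imputed=True)


def build_household_ids(
    waves: dict[int, list[set]] | list[list[set]],
) -> dict[int, list[int]]:
    """Assign cross-wave household ids from per-wave co-residence sets.

    Two wave-households receive the same id iff their member sets are
    exactly equal, so any individual entering or leaving creates a new
    household id.  Returns, per wave, the id of each input household in
    order.  An individual listed in two households within one wave is an
    error.
    """
    if isinstance(waves, list):
        waves = dict(enumerate(waves))
    ids_by_members: dict[frozenset, int] = {}
    out: dict[int, list[int]] = {}
    for wave in sorted(waves):
        members_seen: set = set()
        out[wave] = []
        for household in waves[wave]:
            fs = frozenset(household)
            overlap = members_seen & fs
            if overlap:
                raise PanelError(
                    f"individual(s) {sorted(overlap)} in two households in wave {wave}"
                )
            members_seen |= fs
            if fs not in ids_by_members:
                ids_by_members[fs] = len(ids_by_members)
            out[wave].append(ids_by_members[fs])
    return out


def consecutive_window(panel: PanelDataset, length: int) -> PanelDataset:
    """Keep, per individual, the earliest run of exactly ``length`` consecutive
    observed calendar years; individuals lacking such a run are dropped.
    """
    if length < 2:
        raise ValueError("window length must be at least 2")
    keep_index: list = []
    for _, group in panel.data.groupby("id", sort=False):
        years = group["year"].to_numpy()
        order = np.argsort(years)
        years = years[order]
        idx = group.index.to_numpy()[order]
        # earliest start of a run of `length` consecutive years
        run_start = 0
        found = None
        for j in range(1, len(years) + 1):
            if j == len(years) or years[j] != years[j - 1] + 1:
                if j - run_start >= length:
                    found = run_start
                    break
                run_start = j
        if found is not None:
            keep_index.extend(idx[found : found + length])
    return panel._with(panel.data.loc[keep_index])


def lag_align(panel: PanelDataset) -> pd.DataFrame:
    """Pair each person-year t with the same individual's year t+1.

    Returns one row per adjacent-year pair with predictor-year values
    prefixed ``pred_`` and outcome-year values prefixed ``out_``.  The
    household id attached is that of the outcome year (membership can
    change between years).
    """
    cols = panel.event_columns + (["count"] if panel.is_counts else [])
    df = panel.data.sort_values(["id", "year"])
    nxt = df.groupby("id", sort=False).shift(-1)
    adjacent = nxt["year"] == df["year"] + 1
    pairs = pd.DataFrame(
        {
            "id": df["id"],
            "year": df["year"],
            "hh_id": nxt["hh_id"],  # outcome-year household
            "age": nxt["age"] if "age" in df.columns else np.nan,
        }
    )
    for c in cols:
        pairs[f"pred_{c}"] = df[c]
        pairs[f"out_{c}"] = nxt[c]
    return pairs.loc[adjacent].reset_index(drop=True)


def count_summaries(panel: PanelDataset) -> dict:
    """Descriptive summaries of yearly and cumulative event counts.

    Returns relative event frequencies (summing to 1 over events), the
    distribution of yearly counts, cumulative counts per individual, and
    two dispersion statistics of the cumulative counts under unambiguous
    names: ``sd_over_mean`` (the classical coefficient of variation) and
    ``variance_over_mean`` (the index of dispersion).
    """
    counts = panel.yearly_counts()
    out: dict = {
        "yearly_count_distribution": counts.value_counts(normalize=True).sort_index(),
    }
    if panel.event_columns:
        tallies = panel.data[panel.event_columns].sum(skipna=True)
        total = tallies.sum()
        out["event_frequencies"] = tallies / total if total > 0 else tallies * 0.0
    cumulative = counts.groupby(panel.data["id"]).sum()
    out["cumulative_counts"] = cumulative
    mean = float(cumulative.mean())
    var = float(cumulative.var(ddof=1)) if len(cumulative) > 1 else 0.0
    out["cumulative_mean"] = mean
    out["cumulative_variance"] = var
    out["sd_over_mean"] = float(np.sqrt(var) / mean) if mean > 0 else np.nan
    out["variance_over_mean"] = float(var / mean) if mean > 0 else np.nan
    return out


def joint_conditional_probs(panel: PanelDataset) -> dict[str, pd.DataFrame]:
    """Within-year joint and conditional probabilities over event pairs.

    ``joint.loc[a, b]`` is P(A=1, B=1) across person-years;
    ``conditional.loc[a, b]`` is P(A=1 | B=1) = P(A,B)/P(B).  Cells with
    P(B)=0 are NaN and flagged in ``undefined``.
    """
    events = panel.event_columns
    if not events:
        raise PanelError("joint/conditional probabilities require a typed panel")
    block = panel.data[events].fillna(0.0).to_numpy()
    n = block.shape[0]
    joint = block.T @ block / n
    marginal = np.diag(joint).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        conditional = joint / marginal[None, :]
    undefined = np.broadcast_to(marginal[None, :] == 0, joint.shape)
    conditional = np.where(undefined, np.nan, conditional)
    return {
        "joint": pd.DataFrame(joint, index=events, columns=events),
        "conditional": pd.DataFrame(conditional, index=events, columns=events),
        "undefined": pd.DataFrame(undefined, index=events, columns=events),
    }
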