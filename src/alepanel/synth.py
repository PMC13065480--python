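"""Synthetic household-panel generators.

Real household-panel microdata on adverse life events is access-restricted,
so every downstream analysis here is exercised on synthetic panels that
carry the statistical structure those analyses assume:

* :func:`simulate_poisson_panel` — homogeneous "bad luck" yearly counts.
* :func:`simulate_frailty_panel` — log-normal crossed individual/household
  frailties multiplying a common yearly rate; counts conditionally Poisson.
* :func:`simulate_urn_panel` — a literal Polya urn per person: k draws per
  year, each drawn colour reinforced with c extra balls, urn state
  persisting across years.  By exchangeability the cumulative count after m
  draws is exactly BetaBinomial(m, b/c, w/c).
* :func:`simulate_typed_panel` — yearly binary event vectors with target
  base rates, within-year and lag-1 log-odds-ratio structure, exclusivity
  groups sampled as a single categorical slot, and crossed random
  intercepts.

Randomness: one global seed expands into per-entity substreams via
``SeedSequence(seed, spawn_key=(stream, entity_index))``, so panels of
different sizes share the draws of their common entities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import EventCatalog
from .panel import PanelDataset

__all__ = [
    "FrailtyParams",
    "UrnSpec",
    "AssociationSpec",
    "couple_households",
    "simulate_poisson_panel",
    "simulate_frailty_panel",
    "simulate_urn_panel",
    "simulate_typed_panel",
    "simulate_autocorrelated_panel",
    "inject_missingness",
]

_STREAM_INDIVIDUAL = 1
_STREAM_HOUSEHOLD = 2
_STREAM_PANEL = 3

FIRST_YEAR = 2000


def _entity_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, index)))


@dataclass(frozen=True)
class FrailtyParams:
    """Log-normal crossed-frailty Poisson process parameters.

    rate: mean yearly event rate λ on the natural scale (conditional rate at
    zero random effects); sd_individual / sd_household: SDs of the
    individual and household log-normal random intercepts.
    """

    rate: float
    sd_individual: float = 0.0
    sd_household: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.sd_individual < 0 or self.sd_household < 0:
            raise ValueError("random-intercept SDs must be non-negative")


@dataclass(frozen=True)
class UrnSpec:
    """Polya urn: w white (no-event) and b blue (event) balls, c balls of the
    drawn colour added after every single draw, k draws per year."""

    white: float
    blue: float
    reinforcement: float
    draws_per_year: int

    def __post_init__(self) -> None:
        if self.white <= 0 or self.blue <= 0:
            raise ValueError("initial ball counts must be positive")
        if self.reinforcement < 0:
            raise ValueError("reinforcement must be non-negative")
        if self.draws_per_year < 1:
            raise ValueError("draws_per_year must be at least 1")

    @property
    def initial_risk(self) -> float:
        return self.blue / (self.white + self.blue)


@dataclass
class AssociationSpec:
    """Target dependence structure for typed panels.

    base_logits: per-event marginal logits (at zero random effects and no
    co-occurring events); contemporaneous / lag1: square log-odds-ratio
    matrices over the catalog (row = predictor, column = outcome);
    sd_individual / sd_household: SDs of per-event entity intercepts.
    """

    base_logits: np.ndarray
    contemporaneous: np.ndarray | None = None
    lag1: np.ndarray | None = None
    sd_individual: float = 0.0
    sd_household: float = 0.0

    def validate(self, catalog: EventCatalog) -> None:
        p = catalog.n_events
        self.base_logits = np.asarray(self.base_logits, dtype=float)
        if self.base_logits.shape != (p,):
            raise ValueError(f"base_logits must have length {p}")
        for name in ("contemporaneous", "lag1"):
            mat = getattr(self, name)
            if mat is None:
                setattr(self, name, np.zeros((p, p)))
                continue
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (p, p):
                raise ValueError(f"{name} matrix must be {p}x{p}")
            setattr(self, name, mat)
        # no contemporaneous dependence within an exclusivity group
        for group in catalog.exclusivity_groups:
            idx = [catalog.index(e) for e in group]
            sub = self.contemporaneous[np.ix_(idx, idx)]
            if np.any(sub[~np.eye(len(idx), dtype=bool)] != 0):
                raise ValueError("contemporaneous log-ORs within an exclusivity group must be 0")

    @classmethod
    def from_rates(
        cls,
        catalog: EventCatalog,
        rates: dict[str, float] | None = None,
        **kwargs,
    ) -> "AssociationSpec":
        rates = {**{e: 0.1 for e in catalog.events}, **(rates or catalog.base_rates)}
        logits = np.array([np.log(rates[e] / (1 - rates[e])) for e in catalog.events])
        spec = cls(base_logits=logits, **kwargs)
        spec.validate(catalog)
        return spec


def couple_households(n_individuals: int, mean_size: int = 2) -> np.ndarray:
    """Deterministic household assignment: consecutive blocks of `mean_size`."""
    return np.arange(n_individuals) // mean_size


def _ages(seed: int, n_individuals: int) -> np.ndarray:
    rng = _entity_rng(seed, _STREAM_PANEL, 0)
    return rng.integers(18, 80, size=n_individuals).astype(float)


def _assemble_counts(
    counts: np.ndarray,
    households: np.ndarray,
    ages: np.ndarray,
    provenance: str,
) -> PanelDataset:
    n, t = counts.shape
    years = np.arange(FIRST_YEAR, FIRST_YEAR + t)
    df = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n), t),
            "hh_id": np.repeat(np.asarray(households), t),
            "year": np.tile(years, n),
            "age": np.repeat(ages, t) + np.tile(np.arange(t), n),
            "count": counts.reshape(-1),
        }
    )
    return PanelDataset(data=df, catalog=None, provenance=provenance)


def simulate_poisson_panel(
    rate: float, n_individuals: int, n_years: int, seed: int
) -> PanelDataset:
    """Homogeneous "bad luck" process: yearly counts i.i.d. Poisson(rate)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    counts = np.empty((n_individuals, n_years), dtype=int)
    for i in range(n_individuals):
        rng = _entity_rng(seed, _STREAM_INDIVIDUAL, i)
        counts[i] = rng.poisson(rate, size=n_years)
    households = np.arange(n_individuals)  # singleton households
    return _assemble_counts(
        counts, households, _ages(seed, n_individuals),
        f"poisson(rate={rate}, n={n_individuals}, T={n_years}, seed={seed})",
    )


def simulate_frailty_panel(
    params: FrailtyParams,
    household_map: np.ndarray | dict[int, int],
    n_years: int,
    seed: int,
) -> PanelDataset:
    """Crossed-frailty process: log-rate = log λ + u_i + v_h, counts
    conditionally Poisson given the entity effects."""
    if isinstance(household_map, dict):
        n = len(household_map)
        if set(household_map) != set(range(n)):
            raise ValueError("household_map must assign every individual 0..n-1")
        households = np.array([household_map[i] for i in range(n)])
    else:
        households = np.asarray(household_map)
        n = len(households)
    hh_labels = np.unique(households)
    v = {
        h: _entity_rng(seed, _STREAM_HOUSEHOLD, int(h)).normal(0.0, params.sd_household)
        for h in hh_labels
    }
    counts = np.empty((n, n_years), dtype=int)
    for i in range(n):
        rng = _entity_rng(seed, _STREAM_INDIVIDUAL, i)
        u_i = rng.normal(0.0, params.sd_individual)
        lam = params.rate * np.exp(u_i + v[households[i]])
        counts[i] = rng.poisson(lam, size=n_years)
    return _assemble_counts(
        counts, households, _ages(seed, n),
        f"frailty({params}, T={n_years}, seed={seed})",
    )


def simulate_urn_panel(
    spec: UrnSpec,
    n_individuals: int,
    n_years: int,
    seed: int,
    heterogeneity: float = 0.0,
    household_map: np.ndarray | None = None,
) -> PanelDataset:
    """Literal per-person Polya urn.

    Each individual holds an urn with the spec's initial composition; each
    year ``draws_per_year`` balls are drawn one at a time, each returned
    with ``reinforcement`` extra balls of its colour; the yearly count is
    the number of blue (event) draws; urn state persists across years.

    ``heterogeneity`` > 0 perturbs each entity's initial blue count by a
    log-normal factor exp(N(0, heterogeneity^2)); when a household map is
    given the perturbation is drawn per household (shared initial
    composition), otherwise per individual.
    """
    n, t, k = n_individuals, n_years, spec.draws_per_year
    m = t * k
    u = np.empty((n, m))
    for i in range(n):
        u[i] = _entity_rng(seed, _STREAM_INDIVIDUAL, i).random(m)
    blue = np.full(n, float(spec.blue))
    white = np.full(n, float(spec.white))
    if household_map is None:
        households = np.arange(n)
    else:
        households = np.asarray(household_map)
    if heterogeneity > 0:
        if household_map is None:
            factors = np.array(
                [_entity_rng(seed, _STREAM_HOUSEHOLD, i).normal(0, heterogeneity) for i in range(n)]
            )
        else:
            per_hh = {
                int(h): _entity_rng(seed, _STREAM_HOUSEHOLD, int(h)).normal(0, heterogeneity)
                for h in np.unique(households)
            }
            factors = np.array([per_hh[int(h)] for h in households])
        blue = blue * np.exp(factors)
    events = np.empty((n, m), dtype=bool)
    for j in range(m):
        p = blue / (blue + white)
        hit = u[:, j] < p
        events[:, j] = hit
        blue = blue + spec.reinforcement * hit
        white = white + spec.reinforcement * (~hit)
    counts = events.reshape(n, t, k).sum(axis=2)
    return _assemble_counts(
        counts, households, _ages(seed, n),
        f"urn({spec}, n={n}, T={t}, seed={seed}, heterogeneity={heterogeneity})",
    )


def simulate_typed_panel(
    assoc: AssociationSpec,
    catalog: EventCatalog,
    n_individuals: int,
    n_years: int,
    seed: int,
    household_map: np.ndarray | None = None,
) -> PanelDataset:
    """Binary event vectors with planted log-odds-ratio structure.

    Events are sampled sequentially in catalog order within each year: the
    conditional logit of event j adds ``contemporaneous[l, j]`` for every
    already-sampled event l of the year and ``lag1[l, j]`` for every event
    l of the previous year, plus per-event entity intercepts.  An
    exclusivity group occupies a single categorical slot (multinomial
    logit with a no-event cell), so members never co-occur.
    """
    assoc.validate(catalog)
    p = catalog.n_events
    events = list(catalog.events)
    groups = [frozenset(g) for g in catalog.exclusivity_groups]
    grouped = set().union(*groups) if groups else set()
    # slots in catalog order: a group occupies the slot of its first member
    slots: list[tuple[str, list[int]]] = []
    seen_groups: set[frozenset] = set()
    for j, e in enumerate(events):
        if e in grouped:
            g = next(g for g in groups if e in g)
            if g not in seen_groups:
                seen_groups.add(g)
                slots.append(("group", [catalog.index(x) for x in events if x in g]))
        else:
            slots.append(("single", [j]))

    if household_map is None:
        households = couple_households(n_individuals)
    else:
        households = np.asarray(household_map)
    # entity intercepts: one per (entity, event)
    u = np.empty((n_individuals, p))
    uni = np.empty((n_individuals, n_years, len(slots)))
    for i in range(n_individuals):
        rng = _entity_rng(seed, _STREAM_INDIVIDUAL, i)
        u[i] = rng.normal(0.0, assoc.sd_individual, size=p)
        uni[i] = rng.random((n_years, len(slots)))
    v_by_hh = {
        int(h): _entity_rng(seed, _STREAM_HOUSEHOLD, int(h)).normal(
            0.0, assoc.sd_household, size=p
        )
        for h in np.unique(households)
    }
    v = np.stack([v_by_hh[int(h)] for h in households])

    C, L = assoc.contemporaneous, assoc.lag1
    x = np.zeros((n_individuals, n_years, p), dtype=float)
    prev = np.zeros((n_individuals, p))
    for t in range(n_years):
        cur = np.zeros((n_individuals, p))
        lag_term = prev @ L  # (n, p)
        for s, (kind, idx) in enumerate(slots):
            logits = (
                assoc.base_logits[idx][None, :]
                + u[:, idx]
                + v[:, idx]
                + lag_term[:, idx]
                + cur @ C[:, idx]
            )
            if kind == "single":
                prob = 1.0 / (1.0 + np.exp(-logits[:, 0]))
                cur[:, idx[0]] = (uni[:, t, s] < prob).astype(float)
            else:
                e = np.exp(logits)
                denom = 1.0 + e.sum(axis=1)
                probs = e / denom[:, None]
                cum = np.cumsum(probs, axis=1)
                draw = uni[:, t, s][:, None]
                chosen = (draw < cum).argmax(axis=1)
                hit = draw[:, 0] < cum[:, -1]
                for col, j in enumerate(idx):
                    cur[hit & (chosen == col), j] = 1.0
        x[:, t, :] = cur
        prev = cur

    ages = _ages(seed, n_individuals)
    years = np.arange(FIRST_YEAR, FIRST_YEAR + n_years)
    df = pd.DataFrame(
        {
            "id": np.repeat(np.arange(n_individuals), n_years),
            "hh_id": np.repeat(households, n_years),
            "year": np.tile(years, n_individuals),
            "age": np.repeat(ages, n_years) + np.tile(np.arange(n_years), n_individuals),
        }
    )
    for j, e in enumerate(events):
        df[e] = x[:, :, j].reshape(-1)
    return PanelDataset(
        data=df,
        catalog=catalog,
        provenance=f"typed(n={n_individuals}, T={n_years}, seed={seed})",
    )


def simulate_autocorrelated_panel(
    rate: float,
    lag_coef: float,
    n_individuals: int,
    n_years: int,
    seed: int,
    age_coef: float = 0.0,
    age2_coef: float = 0.0,
    sd_individual: float = 0.0,
    sd_household: float = 0.0,
    household_map: np.ndarray | None = None,
    max_count: int = 13,
) -> PanelDataset:
    """Counts with first-order dependence on the previous year's count.

    log rate_it = log(rate) + age_coef * z_age + age2_coef * z_age^2
                  + lag_coef * y_{i,t-1} + u_i + v_h,
    with z_age the age standardized over the generated panel and counts
    conditionally Poisson.  ``lag_coef`` is on the log scale (a natural
    scale multiplier of exp(lag_coef) per additional prior event).

    The first year is an exogenous initial condition: it is drawn as
    Poisson(rate) *without* the entity effects, so that the likelihood of
    later years conditional on the first is exactly the model a lag-1
    mixed Poisson regression fits (were the initial year itself driven by
    the frailties, conditioning on it would tilt the random-effect
    distribution — the dynamic-panel initial-conditions problem — and no
    estimator of that model could recover the generating coefficient).

    Yearly counts are capped at ``max_count``, mirroring the hard ceiling
    a survey instrument with a fixed number of event types imposes.
    Without a cap the multiplicative feedback loop has a small but
    non-zero probability of runaway trajectories whose extreme counts
    dominate the regression.
    """
    if household_map is None:
        households = couple_households(n_individuals)
    else:
        households = np.asarray(household_map)
    v_by_hh = {
        int(h): _entity_rng(seed, _STREAM_HOUSEHOLD, int(h)).normal(0.0, sd_household)
        for h in np.unique(households)
    }
    v = np.array([v_by_hh[int(h)] for h in households])
    ages0 = _ages(seed, n_individuals)
    ages = ages0[:, None] + np.arange(n_years)[None, :]
    z = (ages - ages.mean()) / ages.std()
    counts = np.zeros((n_individuals, n_years), dtype=int)
    rngs = [_entity_rng(seed, _STREAM_INDIVIDUAL, i) for i in range(n_individuals)]
    u = np.array([r.normal(0.0, sd_individual) for r in rngs])
    prev = np.zeros(n_individuals)
    for t in range(n_years):
        if t == 0:
            log_rate = np.full(n_individuals, np.log(rate))
        else:
            log_rate = (
                np.log(rate) + age_coef * z[:, t] + age2_coef * z[:, t] ** 2
                + lag_coef * prev + u + v
            )
        lam = np.exp(np.clip(log_rate, -30, 8))
        counts[:, t] = np.minimum(
            [rngs[i].poisson(lam[i]) for i in range(n_individuals)], max_count
        )
        prev = counts[:, t].astype(float)
    panel = _assemble_counts(
        counts, households, ages0,
        f"autocorrelated(rate={rate}, lag={lag_coef}, n={n_individuals}, "
        f"T={n_years}, seed={seed})",
    )
    return panel


def inject_missingness(
    panel: PanelDataset, cell_rate: float, full_row_rate: float, seed: int
) -> PanelDataset:
    """Mask event cells at ``cell_rate`` and whole person-years at
    ``full_row_rate`` (masked cells become NaN; the mask records them)."""
    for r in (cell_rate, full_row_rate):
        if not 0 <= r < 1:
            raise ValueError("rates must be in [0, 1)")
    cols = panel.event_columns
    if not cols:
        raise ValueError("missingness injection requires a typed panel")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    n, q = len(panel.data), len(cols)
    cell_mask = rng.random((n, q)) < cell_rate
    row_mask = rng.random(n) < full_row_rate
    mask = cell_mask | row_mask[:, None]
    data = panel.data.copy()
    block = data[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    data[cols] = block
    new_mask = pd.DataFrame(
        (panel.mask.to_numpy() if panel.mask is not None else False) | mask,
        index=data.index,
        columns=cols,
    )
    return PanelDataset(
        data=data,
        catalog=panel.catalog,
        provenance=panel.provenance + f" + missing(cell={cell_rate}, row={full_row_rate})",
        mask=new_mask,
    )
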