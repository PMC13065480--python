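"""Event catalogs: which adverse life events a panel records.

A catalog lists the yearly binary event indicators, any mutual-exclusivity
groups (instruments that record at most one event of a family per year), and
the number of independent "event slots" per person-year, ``k_trials``.  A
mutual-exclusivity group of size g contributes a single slot, so

    k_trials = n_events - sum(g - 1 for each group).

Two presets emulate the instruments of large national household panels: a
Swiss-style catalog (12 events, 7 of which are mutually exclusive
illness/accident subcategories, k = 6) and an Australian-style catalog
(13 independent events, k = 13).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["EventCatalog", "swiss_catalog", "australian_catalog", "read_catalog"]


@dataclass(frozen=True)
class EventCatalog:
    """Ordered event labels plus exclusivity structure.

    Parameters
    ----------
    events
        Ordered event labels; defines column order of event matrices.
    exclusivity_groups
        Disjoint groups of labels that cannot co-occur within a person-year.
    reference_label
        Optional label inside a group used as the dropped reference
        category in regression models.
    """

    events: tuple[str, ...]
    exclusivity_groups: tuple[frozenset[str], ...] = ()
    reference_label: str | None = None
    base_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.events)) != len(self.events):
            raise ValueError("duplicate event labels")
        seen: set[str] = set()
        for group in self.exclusivity_groups:
            if len(group) < 2:
                raise ValueError("exclusivity groups need at least two members")
            unknown = group - set(self.events)
            if unknown:
                raise ValueError(f"exclusivity group members not in catalog: {sorted(unknown)}")
            if group & seen:
                raise ValueError("exclusivity groups must be disjoint")
            seen |= group
        if self.reference_label is not None:
            holders = [g for g in self.exclusivity_groups if self.reference_label in g]
            if len(holders) != 1:
                raise ValueError("reference_label must belong to exactly one exclusivity group")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def k_trials(self) -> int:
        """Independent event slots per person-year."""
        return self.n_events - sum(len(g) - 1 for g in self.exclusivity_groups)

    def group_of(self, label: str) -> frozenset[str] | None:
        for group in self.exclusivity_groups:
            if label in group:
                return group
        return None

    def index(self, label: str) -> int:
        return self.events.index(label)


# Events and approximate per-person-year base rates of the emulated
# instruments (rates are descriptive generator defaults, 0.1%-15%).
_SWISS_EVENTS: dict[str, float] = {
    "illness_close_person": 0.15,
    "death_close_person": 0.12,
    "physical_illness": 0.098,
    "conflicts_related_persons": 0.08,
    "problems_own_children": 0.07,
    "termination_relationship": 0.06,
    "unspecified_illness_accident": 0.0525,
    "mental_illness": 0.01,
    "accident_home_garden": 0.008,
    "road_accident": 0.006,
    "sport_accident": 0.006,
    "work_accident": 0.004,
}

_SWISS_EXCLUSIVE = frozenset(
    {
        "physical_illness",
        "mental_illness",
        "work_accident",
        "road_accident",
        "accident_home_garden",
        "sport_accident",
        "unspecified_illness_accident",
    }
)

_AUSTRALIAN_EVENTS: dict[str, float] = {
    "illness_family_member": 0.12,
    "death_relative": 0.10,
    "personal_injury_illness": 0.08,
    "death_close_friend": 0.07,
    "major_worsening_finances": 0.025,
    "fired_or_redundant": 0.03,
    "separation_spouse": 0.035,
    "victim_property_crime": 0.035,
    "victim_physical_violence": 0.012,
    "weather_disaster": 0.01,
    "family_member_jailed": 0.008,
    "death_spouse_child": 0.007,
    "detained_in_jail": 0.002,
}


def swiss_catalog() -> EventCatalog:
    """12-event catalog with one 7-member illness/accident exclusivity group (k=6)."""
    return EventCatalog(
        events=tuple(_SWISS_EVENTS),
        exclusivity_groups=(_SWISS_EXCLUSIVE,),
        reference_label="unspecified_illness_accident",
        base_rates=dict(_SWISS_EVENTS),
    )


def australian_catalog() -> EventCatalog:
    """13 independent events, no exclusivity groups (k=13)."""
    return EventCatalog(events=tuple(_AUSTRALIAN_EVENTS), base_rates=dict(_AUSTRALIAN_EVENTS))


def read_catalog(path: str) -> EventCatalog:
    """Load a catalog from a YAML config.

    Expected keys: ``events`` (list), optional ``exclusivity_groups``
    (list of lists), ``reference_label``, ``base_rates`` (mapping).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return EventCatalog(
        events=tuple(cfg["events"]),
        exclusivity_groups=tuple(frozenset(g) for g in cfg.get("exclusivity_groups", [])),
        reference_label=cfg.get("reference_label"),
        base_rates=dict(cfg.get("base_rates", {})),
    )


def write_catalog(catalog: EventCatalog, path: str) -> None:
    cfg = {
        "events": list(catalog.events),
        "exclusivity_groups": [sorted(g) for g in catalog.exclusivity_groups],
        "reference_label": catalog.reference_label,
        "base_rates": catalog.base_rates,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
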