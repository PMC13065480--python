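"""Configuration-driven orchestration of the full synthetic study.

A single YAML (or dict) config names the generator, the panel filters and
the analyses to run; one mandatory seed feeds every source of randomness
through named substreams.  Each run writes tidy CSV/JSON outputs plus a
manifest recording parameters, stage timings and SHA-256 hashes of every
output file, so identical configs yield byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accumulate as acc
from . import cooccur as co
from . import tailfit as tf
from .catalog import EventCatalog, australian_catalog, swiss_catalog
from .panel import (
    PanelDataset,
    consecutive_window,
    count_summaries,
    filter_adults,
    impute_missing_as_zero,
    joint_conditional_probs,
    write_panel,
)
from .synth import (
    AssociationSpec,
    FrailtyParams,
    UrnSpec,
    couple_households,
    inject_missingness,
    simulate_frailty_panel,
    simulate_poisson_panel,
    simulate_typed_panel,
    simulate_urn_panel,
)

__all__ = ["RunConfig", "run", "load_config"]

_CATALOGS = {"swiss": swiss_catalog, "australian": australian_catalog}


class RunConfig:
    """Validated run configuration; see ``validate`` for required fields."""

    def __init__(self, raw: dict):
        self.raw = dict(raw)
        self.validate()

    def validate(self) -> None:
        if "seed" not in self.raw:
            raise ValueError("config must set a seed")
        if "generator" not in self.raw:
            raise ValueError("config must set a generator")
        gen = self.raw["generator"]
        if gen.get("model") not in ("poisson", "frailty", "urn", "typed"):
            raise ValueError(f"unknown generator model {gen.get('model')!r}")
        analyses = self.raw.get("analyses", {})
        if "cooccur" in analyses or "autocorrelation" in analyses:
            if gen["model"] in ("poisson", "frailty", "urn") and "cooccur" in analyses:
                raise ValueError("cooccur analysis requires the typed generator")

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def out_dir(self) -> Path:
        return Path(self.raw.get("output_dir", "ale_run"))


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return RunConfig(yaml.safe_load(fh))


def _generate(cfg: RunConfig) -> tuple[PanelDataset, EventCatalog | None]:
    gen = cfg.raw["generator"]
    model = gen["model"]
    params = dict(gen.get("params", {}))
    n = int(gen.get("n_individuals", 500))
    t = int(gen.get("n_years", 20))
    seed = cfg.seed
    if model == "poisson":
        return simulate_poisson_panel(params.get("rate", 0.9), n, t, seed), None
    if model == "frailty":
        fp = FrailtyParams(
            rate=params.get("rate", 0.9),
            sd_individual=params.get("sd_individual", 0.3),
            sd_household=params.get("sd_household", 0.3),
        )
        hh = couple_households(n, int(params.get("household_size", 2)))
        return simulate_frailty_panel(fp, hh, t, seed), None
    if model == "urn":
        spec = UrnSpec(
            white=params.get("white", 150.0),
            blue=params.get("blue", 25.0),
            reinforcement=params.get("reinforcement", 1.0),
            draws_per_year=int(params.get("draws_per_year", 6)),
        )
        hh = couple_households(n, int(params.get("household_size", 2)))
        return (
            simulate_urn_panel(
                spec, n, t, seed,
                heterogeneity=params.get("heterogeneity", 0.0),
                household_map=hh,
            ),
            None,
        )
    catalog = _CATALOGS[gen.get("catalog", "swiss")]()
    assoc = AssociationSpec.from_rates(
        catalog,
        sd_individual=params.get("sd_individual", 0.3),
        sd_household=params.get("sd_household", 0.3),
    )
    panel = simulate_typed_panel(assoc, catalog, n, t, seed)
    miss = params.get("missingness")
    if miss:
        panel = inject_missingness(
            panel, miss.get("cell_rate", 0.0), miss.get("full_row_rate", 0.0), seed
        )
    return panel, catalog


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig | dict | str) -> dict:
    """Execute simulate -> filters -> enabled analyses; return the manifest."""
    if isinstance(config, str):
        config = load_config(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": config.raw,
        "stages": [],
        "outputs": {},
        "failed_stage": None,
    }
    written: list[Path] = []

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as err:
                manifest["failed_stage"] = name
                manifest["error"] = str(err)
                _finalize(manifest, out, written)
                raise
            manifest["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})

        return deco

    state: dict = {}

    @stage("simulate")
    def _():
        panel, catalog = _generate(config)
        state["panel"], state["catalog"] = panel, catalog
        path = out / "panel.csv"
        write_panel(panel, path)
        written.append(path)

    @stage("filters")
    def _():
        panel = state["panel"]
        filters = config.raw.get("filters", {})
        if filters.get("adults", True) and "age" in panel.data.columns:
            panel = filter_adults(panel)
        if panel.event_columns:
            panel = impute_missing_as_zero(panel)
        window = filters.get("window")
        if window:
            panel = consecutive_window(panel, int(window))
        state["panel"] = panel

    analyses = config.raw.get("analyses", {})
    panel_getter = lambda: state["panel"]

    if "descriptives" in analyses:

        @stage("descriptives")
        def _():
            panel = panel_getter()
            summ = count_summaries(panel)
            path = out / "count_distribution.csv"
            summ["yearly_count_distribution"].rename("probability").to_csv(path)
            written.append(path)
            if panel.event_columns:
                fpath = out / "event_frequencies.csv"
                summ["event_frequencies"].rename("frequency").to_csv(fpath)
                written.append(fpath)
                probs = joint_conditional_probs(panel)
                for name in ("joint", "conditional"):
                    p = out / f"{name}_probabilities.csv"
                    probs[name].to_csv(p)
                    written.append(p)

    if "cooccur" in analyses:

        @stage("cooccur")
        def _():
            panel = panel_getter()
            opts = analyses["cooccur"] or {}
            ci = config.raw.get("ci", "wald")
            lagged = bool(opts.get("lagged", False))
            fitter = co.fit_lag1 if lagged else co.fit_contemporaneous
            adjusted = fitter(panel, state["catalog"], ci=ci, seed=config.seed)
            tag = "lag1" if lagged else "contemporaneous"
            path = out / f"or_{tag}.csv"
            adjusted.to_tidy().to_csv(path, index=False)
            written.append(path)
            mpath = out / f"or_{tag}_matrix.csv"
            adjusted.to_matrix().to_csv(mpath)
            written.append(mpath)
            if opts.get("unadjusted", False):
                una = co.fit_unadjusted(
                    panel, state["catalog"], lagged=lagged, ci=ci, seed=config.seed
                )
                upath = out / f"or_{tag}_unadjusted.csv"
                una.to_tidy().to_csv(upath, index=False)
                written.append(upath)

    if "autocorrelation" in analyses:

        @stage("autocorrelation")
        def _():
            fit = acc.fit_autocorrelation(panel_getter(), seed=config.seed)
            path = out / "autocorrelation.json"
            path.write_text(json.dumps(fit.to_dict() | {"meta": fit.meta}, indent=2))
            written.append(path)

    if "accumulation" in analyses:

        @stage("accumulation")
        def _():
            opts = analyses["accumulation"] or {}
            catalog = state["catalog"] or _CATALOGS[opts.get("catalog", "swiss")]()
            comp = acc.compare_accumulation(panel_getter(), catalog, seed=config.seed)
            path = out / "accumulation.csv"
            comp.summary().to_csv(path)
            written.append(path)
            deltas = {
                "poisson_minus_frailty_aic": comp.delta_aic("poisson", "frailty"),
                "poisson_minus_frailty_bic": comp.delta_bic("poisson", "frailty"),
                "frailty_minus_polya_aic": comp.delta_aic("frailty", "polya"),
                "frailty_minus_polya_bic": comp.delta_bic("frailty", "polya"),
                "aic_winner": comp.aic_winner,
                "bic_winner": comp.bic_winner,
            }
            jpath = out / "accumulation_comparison.json"
            jpath.write_text(json.dumps(deltas, indent=2))
            written.append(jpath)
            reps = int(opts.get("reps", 0))
            if reps:
                hist = acc.simulate_fitted(
                    comp.fits[comp.aic_winner],
                    catalog,
                    n_individuals=panel_getter().n_individuals,
                    n_years=int(panel_getter().data.groupby("id").size().max()),
                    reps=reps,
                    seed=config.seed,
                )
                # envelope summary: mean histogram per year
                hpath = out / "envelope_mean_histogram.csv"
                pd.DataFrame(hist.mean(axis=0)).to_csv(hpath)
                written.append(hpath)

    if "tailfit" in analyses:

        @stage("tailfit")
        def _():
            opts = analyses["tailfit"] or {}
            dists = opts.get("distributions", list(tf.DISTRIBUTIONS))
            counts = panel_getter().yearly_counts().groupby(panel_getter().data["id"]).sum()
            positive, removed = tf.exclude_zeros(counts.to_numpy())
            fits = {}
            for d in dists:
                try:
                    fits[d] = tf.estimate_xmin(positive, d)
                except ValueError as err:
                    fits[d] = str(err)
            payload = {
                "zeros_removed": removed,
                "dialect": "discrete powerlaw/poisson, continuous exponential/lognormal",
                "fits": {
                    d: (
                        {
                            "params": f.params,
                            "xmin": f.xmin,
                            "ks": f.ks,
                            "n_tail": f.n_tail,
                            "loglik": f.loglik,
                        }
                        if isinstance(f, tf.TailFit)
                        else {"error": f}
                    )
                    for d, f in fits.items()
                },
                "vuong": {},
            }
            focal = opts.get("compare", "lognormal")
            if isinstance(fits.get(focal), tf.TailFit):
                for d, f in fits.items():
                    if d == focal or not isinstance(f, tf.TailFit):
                        continue
                    v = tf.vuong_compare(fits[focal], f, positive)
                    payload["vuong"][f"{focal}_vs_{d}"] = {
                        "statistic": v.statistic,
                        "p_value": v.p_value,
                        "xmin": v.xmin,
                        "n_tail": v.n_tail,
                    }
            path = out / "tailfit.json"
            path.write_text(json.dumps(payload, indent=2))
            written.append(path)

    _finalize(manifest, out, written)
    return manifest


def _finalize(manifest: dict, out: Path, written: list[Path]) -> None:
    for path in written:
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
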