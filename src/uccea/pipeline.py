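"""End-to-end pipeline: survival inputs -> Markov model -> economics.

Ties the modules into the full analysis: build (or load) survival evidence
per arm and endpoint, derive transition schedules, assemble cost ledgers,
run the discounted cohort, and compare the strategies.  Sensitivity
analyses and the price-threshold search re-evaluate the same model with
parameter overrides; because the varied parameters (costs, utilities) do
not alter transitions, the cohort traces are computed once and reused.

Survival evidence sources
-------------------------
``calibrated``
    Parametric models calibrated directly to the published medians/CIs
    (the default; no digitization error, no refitting noise).
``synthetic_digitized``
    The full published pipeline on synthetic stand-ins: emulate a digitized
    KM plot per arm/endpoint, reconstruct pseudo-IPD, fit all five
    parametric families and select by AIC.
``files``
    User-supplied digitized-curve and risk-table CSVs (e.g. actual trial
    digitizations), reconstructed and fitted the same way.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .costs import (AE_PLACEHOLDER_CHEMO, AE_PLACEHOLDER_COMBO, Body, EconParams,
                    StrategyLedger, build_cost_ledger, gem_cis_regimen,
                    nivo_gem_cis_regimen)
from .economics import (WTP_DEFAULT, IncrementalResult, incremental,
                        price_threshold_search)
from .markov import CohortTrace, Outcomes, UtilitySet, accrue, compute_trace
from .reconstruct import DigitizedCurve, RiskTable, reconstruct
from .sensitivity import (ParamSpec, PSAResult, TornadoEntry, ceac, owsa, psa,
                          tornado_frame)
from .survival import FitResult, fit_all, select_by_aic
from .synthetic import (ARMS, CHECKMATE_901, SyntheticLifeTable, calibrate_family,
                        emulate_digitized_curve, make_life_table)
from .transitions import ModelClock, TransitionSchedule, build_schedule

__all__ = ["RunConfig", "BaseCaseModel", "build_base_case", "published_param_specs",
           "price_threshold", "run"]

_SOURCES = ("calibrated", "synthetic_digitized", "files")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    seed: int = 1
    survival_source: str = "calibrated"
    calibrations: dict = field(default_factory=lambda: dict(CHECKMATE_901))
    curve_files: dict = field(default_factory=dict)  # (arm, endpoint) -> (curve, risk)
    life_table_csv: str | None = None
    reference_n: int = 300
    n0: int = 300
    read_interval_months: float = 1.0
    risk_interval_months: float = 3.0
    jitter_sd: float = 0.002
    start_age: float = 65.0
    clock: ModelClock = field(default_factory=ModelClock)
    discount_annual: float = 0.05
    wtp: float = WTP_DEFAULT
    econ: EconParams = field(default_factory=EconParams)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    ae_combo: dict = field(default_factory=lambda: dict(AE_PLACEHOLDER_COMBO))
    ae_chemo: dict = field(default_factory=lambda: dict(AE_PLACEHOLDER_CHEMO))
    body: Body = field(default_factory=Body)
    wastage: str = "whole_vial"
    second_line_blocks: int = 6
    run_owsa: bool = True
    run_psa: bool = True
    psa_n: int = 5000
    run_threshold: bool = True
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.survival_source not in _SOURCES:
            raise ValueError(f"survival_source must be one of {_SOURCES}")
        if self.wtp <= 0:
            raise ValueError("WTP must be positive")
        if self.survival_source == "files" and not self.curve_files:
            raise ValueError("survival_source 'files' requires curve_files paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "clock" in raw:
            raw["clock"] = ModelClock(**raw["clock"])
        if "utilities" in raw:
            raw["utilities"] = UtilitySet(**raw["utilities"])
        if "body" in raw:
            raw["body"] = Body(**raw["body"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _survival_fits(config: RunConfig, life_table) -> dict:
    """One selected FitResult per (arm, endpoint)."""
    fits = {}
    for i, key in enumerate(sorted(config.calibrations)):
        cal = config.calibrations[key]
        params = calibrate_family(cal, config.reference_n)
        if config.survival_source == "calibrated":
            fits[key] = FitResult.from_params(cal.family, params, config.reference_n)
            continue
        if config.survival_source == "synthetic_digitized":
            horizon = 36.0
            read = np.arange(0.0, horizon + 1e-9, config.read_interval_months)
            em = emulate_digitized_curve(
                cal.family, params, read, n0=config.n0,
                risk_interval=config.risk_interval_months,
                seed=int(np.random.SeedSequence((config.seed, i)).generate_state(1)[0]
                         % 2**31),
                jitter_sd=config.jitter_sd)
            curve, risk = em.curve, em.risk
        else:  # files
            curve_path, risk_path = config.curve_files[key]
            curve = DigitizedCurve.from_csv(curve_path, label=str(key))
            risk = RiskTable.from_csv(risk_path)
        ipd = reconstruct(curve, risk)
        fits[key] = select_by_aic(fit_all(ipd))
    return fits


def published_param_specs(config: RunConfig) -> list[ParamSpec]:
    """Uncertain-parameter specs mirroring the published parameter table.

    Costs carry Gamma distributions with their published ranges; utilities
    carry Beta.  AE incidences are not varied (no published uncertainty).
    """
    e = config.econ
    u = config.utilities
    return [
        ParamSpec("nivolumab_price", e.drugs["nivolumab"].price_usd,
                  999.2576, 1498.886, "gamma", "cost"),
        ParamSpec("gemcitabine_price", e.drugs["gemcitabine"].price_usd,
                  4.4768, 6.7152, "gamma", "cost"),
        ParamSpec("cisplatin_price", e.drugs["cisplatin"].price_usd,
                  0.8472, 1.2708, "gamma", "cost"),
        ParamSpec("administration", e.administration_usd, 30.75, 51.25,
                  "gamma", "cost"),
        ParamSpec("terminal_care", e.terminal_care_usd, 222.57, 333.85,
                  "gamma", "cost"),
        ParamSpec("ae_anemia", e.ae_costs_usd["anemia"], 445.76, 545.54,
                  "gamma", "cost"),
        ParamSpec("ae_neutropenia", e.ae_costs_usd["neutropenia"], 0.0, 1290.65,
                  "gamma", "cost"),
        ParamSpec("ae_neutrophil_count_decreased",
                  e.ae_costs_usd["neutrophil_count_decreased"], 427.52, 641.28,
                  "gamma", "cost"),
        ParamSpec("ae_white_cell_count_decreased",
                  e.ae_costs_usd["white_cell_count_decreased"], 498.02, 747.03,
                  "gamma", "cost"),
        ParamSpec("utility_pfs", u.u_pfs, 0.77, 0.82, "beta", "utility"),
        ParamSpec("utility_pd", u.u_pd, 0.57, 0.85, "beta", "utility"),
    ]


_AE_KEYS = {
    "ae_anemia": "anemia",
    "ae_neutropenia": "neutropenia",
    "ae_neutrophil_count_decreased": "neutrophil_count_decreased",
    "ae_white_cell_count_decreased": "white_cell_count_decreased",
}


def _apply_overrides(econ: EconParams, utilities: UtilitySet,
                     overrides: dict) -> tuple[EconParams, UtilitySet]:
    ae = dict(econ.ae_costs_usd)
    kwargs: dict = {}
    u_pfs, u_pd = utilities.u_pfs, utilities.u_pd
    for name, value in overrides.items():
        if name.endswith("_price"):
            econ = econ.with_price(name[: -len("_price")], value)
        elif name == "administration":
            kwargs["administration_usd"] = value
        elif name == "terminal_care":
            kwargs["terminal_care_usd"] = value
        elif name in _AE_KEYS:
            ae[_AE_KEYS[name]] = value
        elif name == "utility_pfs":
            u_pfs = value
        elif name == "utility_pd":
            u_pd = value
        else:
            raise KeyError(f"unknown parameter {name!r}")
    econ = dataclasses.replace(econ, ae_costs_usd=ae, **kwargs)
    return econ, UtilitySet(u_pfs, u_pd)


@dataclass
class BaseCaseModel:
    """A built model: fixed survival evidence and traces, swappable economics."""

    config: RunConfig
    fits: dict
    life_table: SyntheticLifeTable
    schedules: dict
    traces: dict
    outcomes: dict
    base_result: IncrementalResult

    def ledgers(self, econ: EconParams) -> dict:
        cfg = self.config
        second = gem_cis_regimen(cfg.body)
        second = dataclasses.replace(second, max_blocks=cfg.second_line_blocks)
        return {
            "nivo_combo": build_cost_ledger(
                nivo_gem_cis_regimen(cfg.body), econ, cfg.clock, cfg.ae_combo,
                second_line=second, wastage=cfg.wastage),
            "gem_cis": build_cost_ledger(
                gem_cis_regimen(cfg.body), econ, cfg.clock, cfg.ae_chemo,
                second_line=second, wastage=cfg.wastage),
        }

    def evaluate(self, overrides: dict | None = None) -> IncrementalResult:
        """Re-run the economics with parameter overrides on cached traces."""
        cfg = self.config
        econ, utilities = _apply_overrides(cfg.econ, cfg.utilities, overrides or {})
        ledgers = self.ledgers(econ)
        outs = {
            arm: accrue(self.traces[arm], ledgers[arm], utilities,
                        cfg.discount_annual, cfg.clock)
            for arm in ARMS
        }
        return incremental(outs["nivo_combo"], outs["gem_cis"], cfg.wtp)


def build_base_case(config: RunConfig) -> BaseCaseModel:
    """Build survival evidence, schedules, traces and the base-case result."""
    life_table = (SyntheticLifeTable.from_csv(config.life_table_csv)
                  if config.life_table_csv else make_life_table())
    fits = _survival_fits(config, life_table)
    schedules = {
        arm: build_schedule(fits[(arm, "OS")], fits[(arm, "PFS")], life_table,
                            config.clock, config.start_age, arm=arm)
        for arm in ARMS
    }
    traces = {arm: compute_trace(schedules[arm]) for arm in ARMS}
    model = BaseCaseModel(config, fits, life_table, schedules, traces, {}, None)
    ledgers = model.ledgers(config.econ)
    model.outcomes = {
        arm: accrue(traces[arm], ledgers[arm], config.utilities,
                    config.discount_annual, config.clock)
        for arm in ARMS
    }
    model.base_result = incremental(model.outcomes["nivo_combo"],
                                    model.outcomes["gem_cis"], config.wtp)
    return model


def price_threshold(model: BaseCaseModel, target_wtp: float | None = None,
                    drug: str = "nivolumab",
                    bracket: tuple = (0.0, 1.0)) -> float:
    """Required price reduction for ``drug`` to make the ICER meet the WTP."""
    cfg = model.config
    target = cfg.wtp if target_wtp is None else target_wtp
    base_price = cfg.econ.drugs[drug].price_usd

    def icer_at(mult: float) -> float:
        res = model.evaluate({f"{drug}_price": base_price * mult})
        if res.label == "icer":
            return res.icer_per_qaly
        return -np.inf if res.label in ("dominant", "sw_tradeoff") else np.inf

    return price_threshold_search(icer_at, target, bracket)


def run(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the configured analyses and write all artifacts.

    Writes per-arm trace CSVs and outcome JSON, the incremental comparison,
    tornado/PSA/CEAC CSVs as toggled, and a run manifest (config hash, seed,
    package version).  Returns the result bundle as a dict.
    """
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    model = build_base_case(config)
    bundle: dict = {
        "outcomes": {arm: o.to_dict() for arm, o in model.outcomes.items()},
        "incremental": model.base_result.to_dict(),
        "fits": {f"{arm}/{ep}": model.fits[(arm, ep)].to_dict()
                 for (arm, ep) in model.fits},
    }
    for arm in ARMS:
        model.traces[arm].to_frame().to_csv(out / f"trace_{arm}.csv")
    specs = published_param_specs(config)
    if config.run_owsa:
        entries = owsa(model.evaluate, specs)
        tornado_frame(entries).to_csv(out / "tornado.csv", index=False)
        bundle["tornado_top"] = entries[0].name
    if config.run_psa:
        result = psa(model.evaluate, specs, n=config.psa_n, seed=config.seed)
        result.to_frame().to_csv(out / "psa_draws.csv", index=False)
        grid = np.linspace(0.0, 4.0 * config.wtp, 81)
        ceac(result, grid).to_csv(out / "ceac.csv", index=False)
        bundle["psa"] = {
            "n": result.n,
            "prob_cost_effective_at_wtp": result.prob_cost_effective(config.wtp),
        }
    if config.run_threshold:
        bundle["nivolumab_price_reduction_needed"] = price_threshold(model)
    bundle["manifest"] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": _pkg_version,
    }
    (out / "results.json").write_text(json.dumps(bundle, indent=2))
    return bundle
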