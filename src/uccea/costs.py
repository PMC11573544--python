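"""Per-cycle cost accrual: drug acquisition, administration, AEs, terminal care.

Unit costs reproduce the published parameter table (2022 US$, converted at
$1 = 7.1470 CNY): nivolumab $1249.072 per 100 mg vial, gemcitabine $5.596
per 200 mg vial, cisplatin $1.059 per 10 mg vial, $41 per administration
unit, $278.21 terminal care, plus one-off grade >=3 adverse-event costs.

Chemotherapy doses scale with body surface area (Du Bois formula, default
body 65 kg / 1.65 m).  Dosing follows the trial regimens: nivolumab 360 mg
+ gemcitabine 1000 mg/m2 (d1, d8) + cisplatin 70 mg/m2 (d1) every 3 weeks
for up to six blocks, then maintenance nivolumab 480 mg every 4 weeks until
progression or 2 years; the comparator receives the same chemotherapy
without nivolumab.  Progressed patients in both arms receive second-line
gemcitabine-cisplatin.

.. warning::
   Grade >=3 AE incidences are **synthetic placeholders** (the source
   parameter table prices the AEs but does not print their incidences).
   Override :data:`AE_PLACEHOLDER_COMBO` / :data:`AE_PLACEHOLDER_CHEMO`
   with trial-derived rates for any substantive re-analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .transitions import ModelClock

__all__ = [
    "VialSpec",
    "EconParams",
    "Dose",
    "ScheduleEntry",
    "MaintenanceRule",
    "Regimen",
    "Body",
    "StrategyLedger",
    "AE_PLACEHOLDER_COMBO",
    "AE_PLACEHOLDER_CHEMO",
    "body_surface_area",
    "drug_cost_per_administration",
    "build_cost_ledger",
    "nivo_gem_cis_regimen",
    "gem_cis_regimen",
]

#: Exchange rate used for any CNY-denominated user inputs.
CNY_PER_USD = 7.1470


@dataclass(frozen=True)
class VialSpec:
    vial_mg: float
    price_usd: float

    def __post_init__(self) -> None:
        if self.vial_mg <= 0 or self.price_usd < 0:
            raise ValueError("vial size must be > 0 and price >= 0")


@dataclass(frozen=True)
class EconParams:
    """Unit costs (US$) of the published parameter table."""

    drugs: dict = field(default_factory=lambda: {
        "nivolumab": VialSpec(100.0, 1249.072),
        "gemcitabine": VialSpec(200.0, 5.596),
        "cisplatin": VialSpec(10.0, 1.059),
    })
    administration_usd: float = 41.0
    terminal_care_usd: float = 278.21
    ae_costs_usd: dict = field(default_factory=lambda: {
        "anemia": 500.78,
        "neutropenia": 434.57,
        "neutrophil_count_decreased": 534.4,
        "white_cell_count_decreased": 622.5231,
    })

    def with_price(self, drug: str, price_usd: float) -> "EconParams":
        if drug not in self.drugs:
            raise KeyError(f"unknown drug {drug!r}")
        drugs = dict(self.drugs)
        drugs[drug] = VialSpec(drugs[drug].vial_mg, price_usd)
        return replace(self, drugs=drugs)


#: Placeholder grade >=3 AE incidences per arm (see module warning).
AE_PLACEHOLDER_COMBO = {
    "anemia": 0.22,
    "neutropenia": 0.30,
    "neutrophil_count_decreased": 0.14,
    "white_cell_count_decreased": 0.07,
}
AE_PLACEHOLDER_CHEMO = {
    "anemia": 0.18,
    "neutropenia": 0.27,
    "neutrophil_count_decreased": 0.13,
    "white_cell_count_decreased": 0.06,
}


@dataclass(frozen=True)
class Body:
    weight_kg: float = 65.0
    height_m: float = 1.65

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_m <= 0:
            raise ValueError("body metrics must be positive")


def body_surface_area(weight_kg: float, height_m: float) -> float:
    """Du Bois BSA (m^2): ``0.007184 * height_cm**0.725 * weight_kg**0.425``."""
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError("body metrics must be positive")
    return 0.007184 * (height_m * 100.0) ** 0.725 * weight_kg ** 0.425


@dataclass(frozen=True)
class Dose:
    """``fixed`` mg, ``per_m2`` mg/m^2, or ``per_kg`` mg/kg."""

    kind: str
    amount: float

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "per_m2", "per_kg"):
            raise ValueError("dose kind must be fixed | per_m2 | per_kg")
        if self.amount <= 0:
            raise ValueError("dose must be positive")

    def resolve_mg(self, body: Body) -> float:
        if self.kind == "fixed":
            return self.amount
        if self.kind == "per_m2":
            return self.amount * body_surface_area(body.weight_kg, body.height_m)
        return self.amount * body.weight_kg


@dataclass(frozen=True)
class ScheduleEntry:
    drug: str
    dose: Dose
    days: tuple  # days within the block, 1-based


@dataclass(frozen=True)
class MaintenanceRule:
    drug: str
    dose: Dose
    interval_weeks: int = 4
    start_week: int = 18
    max_week: int = 104  # 2-year stopping rule


@dataclass(frozen=True)
class Regimen:
    """A treatment strategy: repeated blocks plus optional maintenance."""

    entries: tuple
    block_days: int = 21
    max_blocks: int = 6
    maintenance: MaintenanceRule | None = None
    body: Body = Body()
    label: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            for day in e.days:
                if not 1 <= day <= self.block_days:
                    raise ValueError(
                        f"{e.drug} day {day} outside the {self.block_days}-day block")
                if (e.drug, day) in seen:
                    raise ValueError(
                        f"overlapping schedule entries for {e.drug} on day {day}")
                seen.add((e.drug, day))

    @property
    def block_weeks(self) -> int:
        return self.block_days // 7


def nivo_gem_cis_regimen(body: Body = Body()) -> Regimen:
    """Nivolumab 360 mg + gem 1000 mg/m2 (d1, d8) + cis 70 mg/m2 (d1),
    q3w x 6, then nivolumab 480 mg q4w through week 104."""
    return Regimen(
        entries=(
            ScheduleEntry("nivolumab", Dose("fixed", 360.0), (1,)),
            ScheduleEntry("gemcitabine", Dose("per_m2", 1000.0), (1, 8)),
            ScheduleEntry("cisplatin", Dose("per_m2", 70.0), (1,)),
        ),
        maintenance=MaintenanceRule("nivolumab", Dose("fixed", 480.0)),
        body=body,
        label="nivo_combo",
    )


def gem_cis_regimen(body: Body = Body()) -> Regimen:
    """Gemcitabine 1000 mg/m2 (d1, d8) + cisplatin 70 mg/m2 (d1), q3w x 6."""
    return Regimen(
        entries=(
            ScheduleEntry("gemcitabine", Dose("per_m2", 1000.0), (1, 8)),
            ScheduleEntry("cisplatin", Dose("per_m2", 70.0), (1,)),
        ),
        body=body,
        label="gem_cis",
    )


def drug_cost_per_administration(drug: str, dose_mg: float, econ: EconParams,
                                 wastage: str = "whole_vial") -> float:
    """Acquisition cost of one administration.

    ``whole_vial`` rounds the dose up to whole purchasable vials (default);
    ``linear`` prices the exact milligrams.
    """
    if drug not in econ.drugs:
        raise KeyError(f"unknown drug {drug!r}; known: {sorted(econ.drugs)}")
    if dose_mg <= 0:
        raise ValueError("dose must be positive")
    spec = econ.drugs[drug]
    if wastage == "whole_vial":
        return math.ceil(dose_mg / spec.vial_mg - 1e-9) * spec.price_usd
    if wastage == "linear":
        return dose_mg / spec.vial_mg * spec.price_usd
    raise ValueError("wastage policy must be 'whole_vial' or 'linear'")


@dataclass
class StrategyLedger:
    """Per-cycle cost accrual rules for one arm.

    ``pfs_cost[k]`` / ``pd_cost[k]`` are US$ charged per person occupying the
    state during cycle ``k``; ``ae_cost_cycle0`` is a one-time cost at model
    start; ``terminal_cost`` is charged per new death.
    """

    label: str
    pfs_cost: np.ndarray
    pd_cost: np.ndarray
    ae_cost_cycle0: float
    terminal_cost: float
    clock: ModelClock

    def __post_init__(self) -> None:
        n = self.clock.cycles
        if self.pfs_cost.shape != (n,) or self.pd_cost.shape != (n,):
            raise ValueError("cost arrays must have one entry per cycle")
        if (np.any(self.pfs_cost < 0) or np.any(self.pd_cost < 0)
                or self.ae_cost_cycle0 < 0 or self.terminal_cost < 0):
            raise ValueError("costs must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.clock.cycles),
            "pfs_cost_usd": self.pfs_cost,
            "pd_cost_usd": self.pd_cost,
        })


def _admin_units(drugs_on_day: set) -> int:
    """Administration units for one infusion day.

    Co-administered chemotherapy counts as a single infusion visit unit;
    nivolumab's own infusion adds one more.  Configurable convention — the
    source table prices administration 'per unit' without defining the unit.
    """
    chemo = drugs_on_day - {"nivolumab"}
    return (1 if chemo else 0) + (1 if "nivolumab" in drugs_on_day else 0)


def _weekly_block_costs(regimen: Regimen, econ: EconParams, n_cycles: int,
                        wastage: str) -> np.ndarray:
    """Map block-based dosing onto weekly cycles.

    A 21-day block spans 3 weekly cycles: day-1 administrations land in the
    block's first week, day-8 administrations in its second.
    """
    cost = np.zeros(n_cycles)
    bw = regimen.block_weeks
    for b in range(regimen.max_blocks):
        # drugs given on each day of this block
        day_map: dict[int, set] = {}
        for e in regimen.entries:
            for day in e.days:
                day_map.setdefault(day, set()).add(e.drug)
        for day, drugs in day_map.items():
            week = b * bw + (day - 1) // 7
            if week >= n_cycles:
                continue
            for e in regimen.entries:
                if day in e.days:
                    cost[week] += drug_cost_per_administration(
                        e.drug, e.dose.resolve_mg(regimen.body), econ, wastage)
            cost[week] += _admin_units(drugs) * econ.administration_usd
    return cost


def build_cost_ledger(regimen: Regimen, econ: EconParams, clock: ModelClock,
                      ae_profile: dict, second_line: Regimen | None = None,
                      wastage: str = "whole_vial") -> StrategyLedger:
    """Assemble the full per-cycle ledger for one strategy.

    PFS-state cost: first-line blocks in weeks 0-17, then (if the regimen
    has a maintenance rule) maintenance doses every ``interval_weeks`` from
    ``start_week`` through ``max_week``.  PD-state cost: the second-line
    regimen's weekly schedule (default six gemcitabine-cisplatin blocks,
    then 0).  AE costs enter once at cycle 0 as incidence x unit cost;
    terminal care is charged per new death.
    """
    n = clock.cycles
    pfs_cost = _weekly_block_costs(regimen, econ, n, wastage)
    if regimen.maintenance is not None:
        m = regimen.maintenance
        dose_mg = m.dose.resolve_mg(regimen.body)
        c = (drug_cost_per_administration(m.drug, dose_mg, econ, wastage)
             + _admin_units({m.drug}) * econ.administration_usd)
        for week in range(m.start_week, m.max_week + 1, m.interval_weeks):
            if week < n:
                pfs_cost[week] += c
    pd_cost = (np.zeros(n) if second_line is None
               else _weekly_block_costs(second_line, econ, n, wastage))
    unknown = set(ae_profile) - set(econ.ae_costs_usd)
    if unknown:
        raise KeyError(f"AE profile names unknown events: {sorted(unknown)}")
    ae_cost = sum(inc * econ.ae_costs_usd[name] for name, inc in ae_profile.items())
    return StrategyLedger(regimen.label, pfs_cost, pd_cost, float(ae_cost),
                          econ.terminal_care_usd, clock)
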