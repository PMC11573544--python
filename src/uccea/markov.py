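"""Discounted, half-cycle-corrected cohort trace and accrual.

The cohort starts fully progression-free and is propagated through the
per-cycle transition matrices.  Accrual values state membership at cycle
midpoints (trapezoidal half-cycle correction: the mean of start- and
end-of-cycle occupancy) and discounts each cycle at its midpoint with an
annual rate (default 5%).  Life years accrue alive occupancy times cycle
length; QALYs additionally weight by state utility (PFS 0.80, PD 0.71);
costs accrue the ledger's state costs on corrected occupancy, plus the
terminal-care cost on each cycle's death increment (an event cost — by
default discounted at cycle end and not half-cycle corrected).

A patient-level microsimulation oracle with identical accrual rules is
provided for validation: the cohort trace is its n -> infinity limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .costs import StrategyLedger
from .transitions import STATES, ModelClock, TransitionSchedule

__all__ = [
    "UtilitySet",
    "CohortTrace",
    "Outcomes",
    "MicrosimResult",
    "compute_trace",
    "accrue",
    "run_cohort",
    "microsim_oracle",
]


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utilities (1 = perfect health)."""

    u_pfs: float = 0.80
    u_pd: float = 0.71

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")


@dataclass
class CohortTrace:
    """State occupancy over time; row k is the start of cycle k."""

    occupancy: np.ndarray  # (cycles + 1, 3)

    def __post_init__(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must have shape (cycles + 1, 3)")
        if np.max(np.abs(occ.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("occupancy rows must sum to 1")
        if np.any(np.diff(occ[:, 2]) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.occupancy, columns=list(STATES)).rename_axis("cycle")


@dataclass(frozen=True)
class Outcomes:
    """Discounted (and undiscounted) life years, QALYs and cost per person."""

    ly: float
    qaly: float
    cost: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_undiscounted: float

    def to_dict(self) -> dict:
        return {
            "ly": self.ly, "qaly": self.qaly, "cost": self.cost,
            "ly_undiscounted": self.ly_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
            "cost_undiscounted": self.cost_undiscounted,
        }


def compute_trace(schedule: TransitionSchedule) -> CohortTrace:
    """Propagate the cohort, starting at (1, 0, 0), through all cycles."""
    n = schedule.cycles
    occ = np.empty((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for k in range(n):
        occ[k + 1] = occ[k] @ schedule.matrices[k]
    return CohortTrace(occ)


def _discount_factors(n: int, annual_rate: float, cycle_years: float,
                      at: str) -> np.ndarray:
    t = (np.arange(n) + (0.5 if at == "mid" else 1.0)) * cycle_years
    return (1.0 + annual_rate) ** (-t)


def accrue(trace: CohortTrace, ledger: StrategyLedger, utilities: UtilitySet,
           discount_annual: float = 0.05, clock: ModelClock | None = None,
           half_cycle_event_costs: bool = False) -> Outcomes:
    """Accrue discounted LY / QALY / cost over a computed trace."""
    clock = clock or ledger.clock
    n = trace.cycles
    if ledger.clock.cycles != n:
        raise ValueError("ledger clock does not match the trace length")
    occ = trace.occupancy
    corr = 0.5 * (occ[:-1] + occ[1:])  # half-cycle corrected occupancy
    cyc_years = clock.cycle_years
    disc_mid = _discount_factors(n, discount_annual, cyc_years, "mid")
    disc_event = disc_mid if half_cycle_event_costs else _discount_factors(
        n, discount_annual, cyc_years, "end")
    new_deaths = occ[1:, 2] - occ[:-1, 2]

    def totals(dm, de):
        ly = float(np.sum(dm * (corr[:, 0] + corr[:, 1])) * cyc_years)
        qaly = float(np.sum(
            dm * (utilities.u_pfs * corr[:, 0] + utilities.u_pd * corr[:, 1])
        ) * cyc_years)
        cost = float(
            np.sum(dm * (ledger.pfs_cost * corr[:, 0] + ledger.pd_cost * corr[:, 1]))
            + np.sum(de * new_deaths) * ledger.terminal_cost
            + ledger.ae_cost_cycle0
        )
        return ly, qaly, cost

    ones = np.ones(n)
    ly, qaly, cost = totals(disc_mid, disc_event)
    ly0, qaly0, cost0 = totals(ones, ones)
    return Outcomes(ly, qaly, cost, ly0, qaly0, cost0)


def run_cohort(schedule: TransitionSchedule, ledger: StrategyLedger,
               utilities: UtilitySet = UtilitySet(),
               discount_annual: float = 0.05,
               clock: ModelClock | None = None,
               half_cycle_event_costs: bool = False):
    """Deterministic cohort run: returns ``(CohortTrace, Outcomes)``."""
    clock = clock or schedule.clock
    if ledger.clock.cycles != schedule.cycles:
        raise ValueError("schedule and ledger must share the clock")
    trace = compute_trace(schedule)
    out = accrue(trace, ledger, utilities, discount_annual, clock,
                 half_cycle_event_costs)
    return trace, out


@dataclass(frozen=True)
class MicrosimResult:
    outcomes: Outcomes
    se_ly: float
    se_qaly: float
    se_cost: float
    n: int


def microsim_oracle(schedule: TransitionSchedule, ledger: StrategyLedger,
                    utilities: UtilitySet = UtilitySet(),
                    n_individuals: int = 10_000, seed: int = 0,
                    discount_annual: float = 0.05,
                    half_cycle_event_costs: bool = False) -> MicrosimResult:
    """Patient-level Monte Carlo twin of :func:`run_cohort` (validation only).

    Samples individual state paths from the same transition matrices and
    accrues with the same midpoint valuation; returns mean outcomes with
    Monte Carlo standard errors.
    """
    if n_individuals < 1:
        raise ValueError("need n_individuals >= 1")
    if ledger.clock.cycles != schedule.cycles:
        raise ValueError("schedule and ledger must share the clock")
    rng = np.random.default_rng(seed)
    n = n_individuals
    ncyc = schedule.cycles
    cyc_years = schedule.clock.cycle_years
    disc_mid = _discount_factors(ncyc, discount_annual, cyc_years, "mid")
    disc_event = disc_mid if half_cycle_event_costs else _discount_factors(
        ncyc, discount_annual, cyc_years, "end")

    state = np.zeros(n, dtype=np.int8)
    ly = np.zeros(n)
    qaly = np.zeros(n)
    cost = np.full(n, ledger.ae_cost_cycle0)
    ly0 = np.zeros(n)
    qaly0 = np.zeros(n)
    cost0 = np.full(n, ledger.ae_cost_cycle0)
    uvec = np.array([utilities.u_pfs, utilities.u_pd, 0.0])
    for k in range(ncyc):
        u = rng.random(n)
        nxt = np.full(n, 2, dtype=np.int8)
        for s in (0, 1):
            mask = state == s
            if mask.any():
                cum = np.cumsum(schedule.matrices[k, s])
                nxt[mask] = np.searchsorted(cum, u[mask], side="right")
        np.minimum(nxt, 2, out=nxt)
        # midpoint state valuation = trapezoid of start/end indicators
        w_start = np.zeros((n, 3))
        w_start[np.arange(n), state] = 0.5
        w_start[np.arange(n), nxt] += 0.5
        alive_w = w_start[:, 0] + w_start[:, 1]
        util_w = w_start @ uvec
        cost_w = (ledger.pfs_cost[k] * w_start[:, 0]
                  + ledger.pd_cost[k] * w_start[:, 1])
        died = (nxt == 2) & (state != 2)
        ly += disc_mid[k] * alive_w * cyc_years
        qaly += disc_mid[k] * util_w * cyc_years
        cost += disc_mid[k] * cost_w + disc_event[k] * died * ledger.terminal_cost
        ly0 += alive_w * cyc_years
        qaly0 += util_w * cyc_years
        cost0 += cost_w + died * ledger.terminal_cost
        state = nxt
        if (state == 2).all():
            break
    out = Outcomes(float(ly.mean()), float(qaly.mean()), float(cost.mean()),
                   float(ly0.mean()), float(qaly0.mean()), float(cost0.mean()))
    rootn = np.sqrt(n)
    return MicrosimResult(out, float(ly.std(ddof=1) / rootn) if n > 1 else 0.0,
                          float(qaly.std(ddof=1) / rootn) if n > 1 else 0.0,
                          float(cost.std(ddof=1) / rootn) if n > 1 else 0.0, n)
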