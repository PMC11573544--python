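"""Per-cycle transition matrices from fitted survival curves and a life table.

The cohort model has three states — progression-free (PFS), progressed (PD)
and Death — on a weekly cycle over a 10-year horizon (522 cycles).  Fitted
OS and PFS curves are converted to per-cycle exit probabilities with the
standard relation

    tp(t, u) = 1 - S(t) / S(t - u)

evaluated on the weekly grid (curves are fitted in months; one month is
365.25/84 weeks).  Background all-cause mortality from a life table enters
as a floor on the death probability, so extrapolated trial hazards can
never dip below general-population mortality.

Composition of the 3x3 matrix per cycle:

* PFS -> Death: ``d = max(OS cycle probability, background death)``
* PFS -> PD: ``max(0, PFS-exit probability - d)``
* PD -> Death: back-solved each cycle from the current state occupancy so
  that total modelled survival tracks the fitted OS curve (floored at
  ``d``) — a partitioned-survival-consistent Markov construction.
* Death is absorbing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import FitResult
from .synthetic import SyntheticLifeTable

__all__ = [
    "STATES",
    "WEEKS_PER_MONTH",
    "ModelClock",
    "TransitionSchedule",
    "cycle_probability",
    "background_death_prob",
    "build_schedule",
]

log = logging.getLogger(__name__)

STATES = ("pfs", "pd", "death")

#: 1 month = 365.25/12 days = 365.25/84 weeks.
WEEKS_PER_MONTH = 365.25 / 84.0


@dataclass(frozen=True)
class ModelClock:
    """Weekly-cycle clock over the model horizon."""

    cycle_length_weeks: float = 1.0
    horizon_years: float = 10.0

    def __post_init__(self) -> None:
        if self.cycle_length_weeks <= 0 or self.horizon_years <= 0:
            raise ValueError("clock parameters must be positive")

    @property
    def cycles(self) -> int:
        return round(self.horizon_years * 365.25 / 7.0 / self.cycle_length_weeks)

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_weeks * 7.0 / 365.25

    def weeks_to_months(self, weeks) -> np.ndarray:
        return np.asarray(weeks, dtype=float) / WEEKS_PER_MONTH


@dataclass
class TransitionSchedule:
    """Per-cycle 3x3 transition matrices (rows: from-state, cols: to-state)."""

    matrices: np.ndarray  # (cycles, 3, 3)
    clock: ModelClock
    arm: str = ""
    start_age: float = 65.0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = self.matrices
        if m.ndim != 3 or m.shape[1:] != (3, 3):
            raise ValueError("matrices must have shape (cycles, 3, 3)")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.max(np.abs(m.sum(axis=2) - 1.0)) > 1e-12:
            raise ValueError("transition-matrix rows must sum to 1")
        if np.max(np.abs(m[:, 2, :] - np.array([0.0, 0.0, 1.0]))) > 0:
            raise ValueError("Death must be absorbing")

    @property
    def cycles(self) -> int:
        return self.matrices.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Long-format audit export: ``cycle, from, to, p``."""
        c, _, _ = self.matrices.shape
        rows = []
        for k in range(c):
            for i, si in enumerate(STATES):
                for j, sj in enumerate(STATES):
                    rows.append((k, si, sj, self.matrices[k, i, j]))
        return pd.DataFrame(rows, columns=["cycle", "from", "to", "p"])


def cycle_probability(fit: FitResult, t_weeks: float, u_weeks: float) -> float:
    """Probability of the event during ``(t-u, t]`` given event-free at t-u.

    ``1 - S(t)/S(t-u)`` with the fitted curve evaluated in months, clipped to
    [0, 1].  If the curve is already depleted (``S(t-u) = 0``) the
    probability is 1, with a warning.
    """
    if not t_weeks >= u_weeks > 0:
        raise ValueError("need t >= u > 0")
    s = fit.survival(np.array([t_weeks - u_weeks, t_weeks]) / WEEKS_PER_MONTH)
    if s[0] <= 0.0:
        warnings.warn("survival depleted before cycle start; probability 1",
                      stacklevel=2)
        return 1.0
    return float(np.clip(1.0 - s[1] / s[0], 0.0, 1.0))


def background_death_prob(life_table: SyntheticLifeTable, age: float,
                          u_weeks: float = 1.0) -> float:
    """Per-cycle all-cause death probability from an annual life-table rate.

    Converts the annual probability q at (floor of) ``age`` to a
    ``u_weeks``-long cycle via ``1 - (1-q)**(u*7/365.25)``.
    """
    q = life_table.q_at(age)
    if q >= 1.0:
        return 1.0
    return float(-np.expm1(np.log1p(-q) * u_weeks * 7.0 / 365.25))


def build_schedule(os_fit: FitResult, pfs_fit: FitResult,
                   life_table: SyntheticLifeTable, clock: ModelClock = ModelClock(),
                   start_age: float = 65.0, arm: str = "") -> TransitionSchedule:
    """Compose the full per-cycle transition schedule for one arm.

    ``S_PFS <= S_OS`` is enforced on the weekly grid (extrapolated curves can
    cross; crossings are clipped with a logged warning).  The PD death
    probability is back-solved per cycle from the running occupancy so the
    modelled all-state survival reproduces the fitted OS curve wherever the
    background-mortality floor is not binding.
    """
    if not (os_fit.converged and pfs_fit.converged):
        raise ValueError("both fits must be converged")
    u = clock.cycle_length_weeks
    n = clock.cycles
    grid_weeks = np.arange(n + 1) * u
    grid_months = clock.weeks_to_months(grid_weeks)
    s_os = os_fit.survival(grid_months)
    s_os = s_os / s_os[0]
    s_pfs = pfs_fit.survival(grid_months)
    s_pfs = s_pfs / s_pfs[0]
    n_crossed = int(np.sum(s_pfs > s_os + 1e-12))
    if n_crossed:
        log.warning("S_PFS exceeded S_OS at %d of %d grid points; clipped",
                    n_crossed, n + 1)
    s_pfs = np.minimum(s_pfs, s_os)

    mats = np.zeros((n, 3, 3))
    occ = np.array([1.0, 0.0, 0.0])
    n_dprime_clipped = 0
    for k in range(n):
        age = start_age + grid_weeks[k] * 7.0 / 365.25
        bg = background_death_prob(life_table, age, u)
        p_os = 1.0 if s_os[k] <= 0 else float(np.clip(1.0 - s_os[k + 1] / s_os[k], 0, 1))
        x = 1.0 if s_pfs[k] <= 0 else float(np.clip(1.0 - s_pfs[k + 1] / s_pfs[k], 0, 1))
        d = max(p_os, bg)
        pfs_pd = max(0.0, x - d)
        pfs_stay = max(0.0, 1.0 - d - pfs_pd)
        row_pfs = np.array([pfs_stay, pfs_pd, d])
        row_pfs /= row_pfs.sum()

        alive = occ[0] + occ[1]
        target_deaths = max(alive - s_os[k + 1], 0.0)
        if occ[1] > 1e-12:
            d_raw = (target_deaths - occ[0] * row_pfs[2]) / occ[1]
            d_prime = float(np.clip(d_raw, d, 1.0))
            if not (0.0 <= d_raw <= 1.0):
                n_dprime_clipped += 1
        else:
            d_prime = d
        mats[k, 0] = row_pfs
        mats[k, 1] = [0.0, 1.0 - d_prime, d_prime]
        mats[k, 2] = [0.0, 0.0, 1.0]
        occ = occ @ mats[k]
    if n_dprime_clipped:
        log.info("PD death probability clipped into [floor, 1] at %d cycles",
                 n_dprime_clipped)
    return TransitionSchedule(
        mats, clock, arm=arm, start_age=start_age,
        diagnostics={"pfs_os_crossings_clipped": n_crossed,
                     "pd_death_clipped_cycles": n_dprime_clipped},
    )
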