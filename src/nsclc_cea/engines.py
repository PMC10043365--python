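"""Cohort engines: partitioned survival (PartSA) and Markov.

Both engines emit a :class:`CohortTrace` over three health states —
progression-free (PFS), progressed disease (PD) and death — evaluated at
cycle boundaries.  Outcome accumulation (costs, LYs, QALYs) lives in
:mod:`nsclc_cea.econ` and uses the half-cycle mean of successive boundary
occupancies, so the two engines share one correction convention.

PartSA reads occupancy straight off the curves:
``pfs = min(S_pfs, S_os)``, ``pd = max(0, S_os - S_pfs)``,
``dead = 1 - S_os``.

The Markov engine converts the curves into time-dependent transition
probabilities.  PFS exit follows the conditional PFS survival ratio; a
constant per-cycle natural-mortality probability feeds PFS->Death; and the
PD->Death probability is derived residually so that cumulative cohort deaths
track ``1 - S_os``.  New progressors can die within their transition cycle
(the residual death draw applies to the post-progression pool); with natural
mortality set to zero this makes the Markov occupancies reproduce the PartSA
occupancies exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import CYCLE_MONTHS
from .survival import ParametricSurvival

logger = logging.getLogger(__name__)

__all__ = ["CohortTrace", "TransitionRow", "partsa_trace", "transition_probs",
           "markov_trace"]

_OCC_TOL = 1e-9


@dataclass
class CohortTrace:
    """Per-cycle state occupancies plus the flows needed for costing.

    Boundary arrays (``pfs``, ``pd``, ``dead``) have length ``n_cycles + 1``;
    flow arrays (``pd_inflow``: new progressors entering PD during a cycle,
    ``pd_death_frac``: per-cycle death probability of the post-progression
    pool) have length ``n_cycles``.  Discounted increment arrays are filled
    in by :func:`nsclc_cea.econ.accumulate`.
    """

    cycle_len_months: float
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    pd_inflow: np.ndarray
    pd_death_frac: np.ndarray
    cost_inc: Optional[np.ndarray] = field(default=None, repr=False)
    ly_inc: Optional[np.ndarray] = field(default=None, repr=False)
    qaly_inc: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_cycles(self) -> int:
        return len(self.pfs) - 1

    @property
    def times_months(self) -> np.ndarray:
        return np.arange(self.n_cycles + 1) * self.cycle_len_months

    def validate(self) -> None:
        occ = self.pfs + self.pd + self.dead
        if np.any(np.abs(occ - 1.0) > _OCC_TOL):
            raise ValueError("state occupancies must sum to 1 at every cycle")
        for name in ("pfs", "pd", "dead"):
            arr = getattr(self, name)
            if np.any((arr < -_OCC_TOL) | (arr > 1 + _OCC_TOL)):
                raise ValueError(f"{name} occupancy outside [0, 1]")
        if np.any(np.diff(self.dead) < -_OCC_TOL):
            raise ValueError("dead occupancy must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle boundary; increments belong to the interval
        starting at that boundary (zero on the final row)."""
        n = self.n_cycles
        pad = lambda a: np.append(a, 0.0) if a is not None else np.zeros(n + 1)
        return pd.DataFrame({
            "cycle": np.arange(n + 1),
            "time_months": self.times_months,
            "pfs": self.pfs,
            "pd": self.pd,
            "dead": self.dead,
            "disc_cost": pad(self.cost_inc),
            "disc_ly": pad(self.ly_inc),
            "disc_qaly": pad(self.qaly_inc),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _boundary_survival(s_pfs: ParametricSurvival, s_os: ParametricSurvival,
                       n_cycles: int, cycle_len: float) -> tuple[np.ndarray, np.ndarray]:
    t = np.arange(n_cycles + 1) * cycle_len
    return s_pfs.sf(t), s_os.sf(t)


def partsa_trace(s_pfs: ParametricSurvival, s_os: ParametricSurvival,
                 n_cycles: int = 170,
                 cycle_len: float = CYCLE_MONTHS) -> CohortTrace:
    """Partitioned-survival occupancy over ``n_cycles`` boundaries.

    Independently fitted curves can cross (S_pfs > S_os); occupancy is then
    clamped in the standard way (PFS capped at OS), logged once.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    sp, so = _boundary_survival(s_pfs, s_os, n_cycles, cycle_len)
    if np.any(sp > so + 1e-12):
        logger.info("PFS curve exceeds OS curve on part of the horizon; "
                    "clamping PFS occupancy to OS")
    pfs = np.minimum(sp, so)
    pd_ = np.clip(so - sp, 0.0, None)
    dead = 1.0 - so
    inflow = np.maximum(0.0, pfs[:-1] - pfs[1:])
    pool = pd_[:-1] + inflow
    deaths = np.diff(dead)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(pool > 1e-15, deaths / np.where(pool > 1e-15, pool, 1.0), 0.0)
    q = np.clip(q, 0.0, 1.0)
    return CohortTrace(cycle_len_months=cycle_len, pfs=pfs, pd=pd_, dead=dead,
                       pd_inflow=inflow, pd_death_frac=q)


@dataclass(frozen=True)
class TransitionRow:
    """Effective one-cycle transition probabilities (death absorbing)."""

    cycle: int
    p_pfs_stay: float
    p_pfs_to_pd: float
    p_pfs_to_death: float
    p_pd_stay: float
    p_pd_to_death: float

    def __post_init__(self) -> None:
        rows = ((self.p_pfs_stay, self.p_pfs_to_pd, self.p_pfs_to_death),
                (0.0, self.p_pd_stay, self.p_pd_to_death))
        for row in rows:
            if any(p < -1e-12 or p > 1 + 1e-12 for p in row):
                raise ValueError(f"transition probabilities outside [0, 1]: {row}")
            if abs(sum(row) - 1.0) > 1e-12:
                raise ValueError(f"transition row does not sum to 1: {row}")


def transition_probs(s_pfs: ParametricSurvival, s_os: ParametricSurvival,
                     cycle: int, cycle_len: float, p_nat: float,
                     occupancy: tuple[float, float, float]) -> TransitionRow:
    """Time-dependent transition row for one cycle.

    ``occupancy`` is the (pfs, pd, dead) state vector at the start of the
    cycle.  PFS exit comes from the conditional PFS survival ratio over the
    cycle; ``p_nat`` of PFS occupants die of background causes; progression
    takes the remainder of the exits.  PD deaths are set residually so that
    cumulative deaths track ``1 - S_os`` — the residual applies to the PD
    pool *including* this cycle's progressors, and is clamped to [0, 1]
    (clamping logged at debug level).
    """
    if not 0.0 <= p_nat < 1.0:
        raise ValueError("p_nat must be in [0, 1)")
    pfs_occ, pd_occ, dead_occ = occupancy
    t0 = cycle * cycle_len
    sp0, sp1 = s_pfs.sf(t0), s_pfs.sf(t0 + cycle_len)
    so1 = s_os.sf(t0 + cycle_len)
    if sp0 <= 1e-300:
        p_exit = 1.0   # survival exhausted: all PFS mass has already left
    else:
        p_exit = float(np.clip(1.0 - sp1 / sp0, 0.0, 1.0))
    p_prog = max(0.0, p_exit - p_nat)
    pfs_deaths = pfs_occ * p_nat
    pool = pd_occ + pfs_occ * p_prog
    target_dead = 1.0 - so1
    needed = target_dead - dead_occ - pfs_deaths
    if pool > 1e-15:
        q = needed / pool
        if q < 0.0 or q > 1.0:
            logger.debug("cycle %d: residual PD death probability %.3g clamped", cycle, q)
        q = float(np.clip(q, 0.0, 1.0))
    else:
        q = 0.0
    return TransitionRow(
        cycle=cycle,
        p_pfs_stay=max(0.0, 1.0 - p_nat - p_prog),
        p_pfs_to_pd=p_prog * (1.0 - q),
        p_pfs_to_death=p_nat + p_prog * q,
        p_pd_stay=1.0 - q,
        p_pd_to_death=q,
    )


def markov_trace(s_pfs: ParametricSurvival, s_os: ParametricSurvival,
                 n_cycles: int = 170, cycle_len: float = CYCLE_MONTHS,
                 p_nat: float = 0.0) -> CohortTrace:
    """Markov cohort trace; everyone starts progression-free."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    pfs = np.empty(n_cycles + 1)
    pd_ = np.empty(n_cycles + 1)
    dead = np.empty(n_cycles + 1)
    inflow = np.empty(n_cycles)
    qs = np.empty(n_cycles)
    pfs[0], pd_[0], dead[0] = 1.0, 0.0, 0.0
    for i in range(n_cycles):
        row = transition_probs(s_pfs, s_os, i, cycle_len, p_nat,
                               (pfs[i], pd_[i], dead[i]))
        inflow[i] = pfs[i] * max(0.0, 1.0 - row.p_pfs_stay - p_nat)
        qs[i] = row.p_pd_to_death
        pfs[i + 1] = pfs[i] * row.p_pfs_stay
        pd_[i + 1] = pd_[i] * row.p_pd_stay + pfs[i] * row.p_pfs_to_pd
        dead[i + 1] = dead[i] + pd_[i] * row.p_pd_to_death + pfs[i] * row.p_pfs_to_death
        total = pfs[i + 1] + pd_[i + 1] + dead[i + 1]
        if abs(total - 1.0) > 1e-9:
            raise ArithmeticError(
                f"occupancy failed to normalise at cycle {i + 1}: sum={total!r}")
    return CohortTrace(cycle_len_months=cycle_len, pfs=pfs, pd=pd_, dead=dead,
                       pd_inflow=inflow, pd_death_frac=qs)
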