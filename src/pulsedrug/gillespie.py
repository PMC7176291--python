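"""Exact stochastic simulation of the birth-death-mutation process.

The event loop lives in :mod:`pulsedrug._kernel` (numba).  This module wraps
it with typed configuration/outcome containers, Monte-Carlo aggregation of
the extinction probability ``p0`` (fraction of replicates absorbed at total
extinction rather than all-C fixation), and the half-period kill probability
used in the sub-MIC analysis.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import _kernel
from .model_core import AlternationSchedule, ModelParameters, ScheduleMode

__all__ = [
    "RecordMode",
    "OutcomeKind",
    "SimulationConfig",
    "Outcome",
    "Trajectory",
    "EstimateWithCI",
    "EstimationError",
    "run_trajectory",
    "estimate_p0",
    "estimate_half_period_extinction_prob",
]


class RecordMode(enum.Enum):
    NONE = "none"  # absorption only
    EVENTS = "events"  # every event
    SAMPLED = "sampled"  # state at regular sample times


class OutcomeKind(enum.Enum):
    EXTINCT = "EXTINCT"
    C_FIXED = "C_FIXED"
    TIMEOUT = "TIMEOUT"


_CODE_TO_KIND = {
    _kernel.EXTINCT: OutcomeKind.EXTINCT,
    _kernel.C_FIXED: OutcomeKind.C_FIXED,
    _kernel.TIMEOUT: OutcomeKind.TIMEOUT,
}

_ENV_MODE = {
    ScheduleMode.ALTERNATING: _kernel.ENV_ALTERNATING,
    ScheduleMode.ALWAYS_OFF: _kernel.ENV_ALWAYS_OFF,
    ScheduleMode.ALWAYS_ON: _kernel.ENV_ALWAYS_ON,
}


class EstimationError(RuntimeError):
    """Raised when no replicate reached an absorbing state."""


@dataclass(frozen=True)
class SimulationConfig:
    """One-run configuration: parameters, schedule, initial counts and seed."""

    params: ModelParameters
    schedule: AlternationSchedule
    init_S: int = 10
    init_R: int = 0
    init_C: int = 0
    t_max: float = 1e6
    seed: int = 0
    record: RecordMode = RecordMode.NONE
    sample_dt: float = 1.0

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if min(self.init_S, self.init_R, self.init_C) < 0:
            raise ValueError("initial counts must be >= 0")
        if self.record is RecordMode.SAMPLED and self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0 in sampled record mode")


@dataclass(frozen=True)
class Outcome:
    """Per-run absorption classification."""

    kind: OutcomeKind
    t_event: float
    n_events: int

    @property
    def extinct_before_C_fixation(self) -> bool:
        return self.kind is OutcomeKind.EXTINCT


@dataclass(frozen=True)
class Trajectory:
    """Recorded (t, S, R, C) sequence with a drug-presence flag per record."""

    t: np.ndarray
    S: np.ndarray
    R: np.ndarray
    C: np.ndarray
    drug_on: np.ndarray

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "S": self.S, "R": self.R, "C": self.C, "drug_on": self.drug_on}
        )


@dataclass(frozen=True)
class EstimateWithCI:
    """Monte-Carlo estimate with a 95% Wilson confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_rep: int
    counts: dict
    seeds: np.ndarray = field(repr=False)
    mean_t_ext: float = float("nan")
    mean_t_fix: float = float("nan")


def _kernel_args(config: SimulationConfig) -> tuple:
    p = config.params
    nd, d = p.rates_no_drug, p.rates_drug
    if config.schedule.mode is ScheduleMode.ALTERNATING:
        half = config.schedule.period / 2.0
    else:
        half = np.inf
    return (
        config.init_S,
        config.init_R,
        config.init_C,
        nd.f_S,
        nd.g_S,
        d.f_S,
        d.g_S,
        nd.f_R,
        nd.g_R,
        nd.f_C,
        nd.g_C,
        p.K,
        p.mu1,
        p.mu2,
        half,
        _ENV_MODE[config.schedule.mode],
        config.t_max,
    )


def _run_kernel(config: SimulationConfig, seed: int) -> tuple[Outcome, Trajectory | None]:
    args = _kernel_args(config)
    record_mode = {
        RecordMode.NONE: _kernel.REC_NONE,
        RecordMode.EVENTS: _kernel.REC_EVENTS,
        RecordMode.SAMPLED: _kernel.REC_SAMPLED,
    }[config.record]
    cap = 0 if record_mode == _kernel.REC_NONE else 65536
    while True:
        rec_t = np.empty(cap, dtype=np.float64)
        rec_cnt = np.empty((cap, 3), dtype=np.int64)
        rec_env = np.empty(cap, dtype=np.int8)
        code, t_event, n_rec, n_events = _kernel.simulate(
            seed, *args, record_mode, config.sample_dt, rec_t, rec_cnt, rec_env
        )
        if code != _kernel.BUFFER_FULL:
            break
        cap = max(2 * cap, 65536)  # identical seed -> identical path, just re-run
    outcome = Outcome(kind=_CODE_TO_KIND[code], t_event=t_event, n_events=n_events)
    trajectory = None
    if record_mode != _kernel.REC_NONE:
        trajectory = Trajectory(
            t=rec_t[:n_rec].copy(),
            S=rec_cnt[:n_rec, 0].copy(),
            R=rec_cnt[:n_rec, 1].copy(),
            C=rec_cnt[:n_rec, 2].copy(),
            drug_on=rec_env[:n_rec].astype(bool),
        )
    return outcome, trajectory


def run_trajectory(config: SimulationConfig) -> tuple[Outcome, Trajectory | None]:
    """Run one exact stochastic realization.

    Returns the :class:`Outcome` and, unless ``record`` is ``NONE``, the
    recorded :class:`Trajectory`.  An empty initial population is EXTINCT at
    ``t = 0``; reaching ``t_max`` yields a TIMEOUT outcome, not an exception.
    """
    return _run_kernel(config, int(config.seed) & 0xFFFFFFFF)


def replicate_seeds(master_seed: int, n_rep: int) -> np.ndarray:
    """Deterministically spawn per-replicate kernel seeds from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n_rep)


def estimate_p0(config: SimulationConfig, n_rep: int) -> EstimateWithCI:
    """Monte-Carlo estimate of the extinction-before-C-fixation probability.

    Runs ``n_rep`` independent replicates with seeds spawned from
    ``config.seed``.  TIMEOUT replicates are excluded from the estimate with
    a warning.  Also aggregates the mean extinction time over extinct runs
    and the mean fixation time over C-fixed runs.
    """
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    seeds = replicate_seeds(config.seed, n_rep)
    t_ext, t_fix = [], []
    counts = {kind: 0 for kind in OutcomeKind}
    for s in seeds:
        outcome, _ = _run_kernel(config, int(s))
        counts[outcome.kind] += 1
        if outcome.kind is OutcomeKind.EXTINCT:
            t_ext.append(outcome.t_event)
        elif outcome.kind is OutcomeKind.C_FIXED:
            t_fix.append(outcome.t_event)
    n_timeout = counts[OutcomeKind.TIMEOUT]
    n_used = n_rep - n_timeout
    if n_used == 0:
        raise EstimationError(f"all {n_rep} replicates timed out at t_max={config.t_max}")
    if n_timeout:
        warnings.warn(
            f"{n_timeout}/{n_rep} replicates timed out and were excluded from p0",
            UserWarning,
            stacklevel=2,
        )
    n_extinct = counts[OutcomeKind.EXTINCT]
    ci_low, ci_high = proportion_confint(n_extinct, n_used, alpha=0.05, method="wilson")
    return EstimateWithCI(
        estimate=n_extinct / n_used,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_rep=n_rep,
        counts={kind.value: v for kind, v in counts.items()},
        seeds=seeds,
        mean_t_ext=float(np.mean(t_ext)) if t_ext else float("nan"),
        mean_t_fix=float(np.mean(t_fix)) if t_fix else float("nan"),
    )


def estimate_half_period_extinction_prob(
    params: ModelParameters, T: float, n_rep: int, seed: int = 0
) -> EstimateWithCI:
    """Probability that a pure-S population dies out within one half-period.

    Simulates a mutation-free sensitive population (``mu1 = 0``) with drug
    continuously applied, starting from the drug-free equilibrium size
    ``round(K (1 - g_S/f_S))``, and returns the fraction of replicates whose
    extinction time is below ``T/2``.  Replicates still alive at the
    safeguard horizon count as "not within T/2".
    """
    if n_rep < 1:
        raise ValueError(f"n_rep must be >= 1, got {n_rep}")
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    nd = params.rates_no_drug
    if nd.f_S <= nd.g_S:
        raise ValueError("drug-free S rates must satisfy f_S > g_S to define a start size")
    n0 = int(np.floor(params.K * (1.0 - nd.g_S / nd.f_S) + 0.5))
    pure = params.with_(mu1=0.0, mu2=0.0)
    half = T / 2.0
    config = SimulationConfig(
        params=pure,
        schedule=AlternationSchedule.always_on(),
        init_S=n0,
        init_R=0,
        init_C=0,
        t_max=half * 1.0000001,  # only "extinct before T/2" matters
        seed=seed,
    )
    seeds = replicate_seeds(seed, n_rep)
    n_within = 0
    for s in seeds:
        outcome, _ = _run_kernel(config, int(s))
        if outcome.kind is OutcomeKind.EXTINCT and outcome.t_event < half:
            n_within += 1
    ci_low, ci_high = proportion_confint(n_within, n_rep, alpha=0.05, method="wilson")
    return EstimateWithCI(
        estimate=n_within / n_rep,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_rep=n_rep,
        counts={"within_half_period": n_within, "beyond": n_rep - n_within},
        seeds=seeds,
    )
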