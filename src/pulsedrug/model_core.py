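"""Shared model definitions: rates, schedules, propensities and regime reports.

The population holds three genotypes, sensitive (S), resistant (R) and
resistant-compensated (C).  Each individual of genotype X divides at the
logistic rate ``f_X * max(0, 1 - N/K)`` (``N`` is the total population size,
``K`` the carrying capacity) and dies at a constant per-capita rate ``g_X``.
Mutations happen on division, along the one-way chain S -> R -> C, with
probabilities ``mu1`` and ``mu2`` applied to the single daughter cell.

The drug only alters the S rates; R and C carry the same rates with and
without drug.  A perfectly biostatic drug sets the S division rate to zero, a
biocidal one raises the S death rate.  Drug presence follows a square-wave
schedule of period ``T``: absent on ``[kT, kT + T/2)``, present on
``[kT + T/2, (k+1)T)``.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Genotype",
    "EnvironmentRates",
    "ModelParameters",
    "ScheduleMode",
    "AlternationSchedule",
    "PopulationState",
    "RegimeReport",
    "environment_at",
    "propensities",
    "r_ratio",
    "classify_regime",
    "rates_from_r_ratio",
    "CONFIG_DEFAULTS",
    "load_config",
    "config_to_objects",
]


class Genotype(enum.Enum):
    """The three genotypes of the model; mutations flow S -> R -> C only."""

    S = "S"
    R = "R"
    C = "C"


#: allowed mutation edges (no back-mutation, no S -> C shortcut)
MUTATION_EDGES = ((Genotype.S, Genotype.R), (Genotype.R, Genotype.C))

_RATE_FIELDS = ("f_S", "f_R", "f_C", "g_S", "g_R", "g_C")


@dataclass(frozen=True)
class EnvironmentRates:
    """Maximal division rates and death rates of S, R and C in one environment."""

    f_S: float
    f_R: float
    f_C: float
    g_S: float
    g_R: float
    g_C: float

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"rate {name} must be finite and >= 0, got {value}")

    def fitness(self, genotype: Genotype) -> float:
        return {Genotype.S: self.f_S, Genotype.R: self.f_R, Genotype.C: self.f_C}[genotype]

    def death_rate(self, genotype: Genotype) -> float:
        return {Genotype.S: self.g_S, Genotype.R: self.g_R, Genotype.C: self.g_C}[genotype]


@dataclass(frozen=True)
class ModelParameters:
    """All rates and probabilities defining the three-genotype model.

    ``rates_no_drug`` and ``rates_drug`` must agree on the R and C entries
    (the drug acts on sensitive cells only).  The time unit convention is
    ``f_S = 1`` without drug; deviating from it is legal but triggers a
    warning so users can rescale time knowingly.
    """

    rates_no_drug: EnvironmentRates
    rates_drug: EnvironmentRates
    K: float
    mu1: float
    mu2: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.K) or self.K < 1:
            raise ValueError(f"carrying capacity K must be >= 1, got {self.K}")
        for name in ("mu1", "mu2"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        for name in ("f_R", "f_C", "g_R", "g_C"):
            a = getattr(self.rates_no_drug, name)
            b = getattr(self.rates_drug, name)
            if a != b:
                raise ValueError(
                    f"drug must not alter R/C rates: {name} is {a} without drug "
                    f"but {b} with drug"
                )
        if self.rates_no_drug.f_S != 1.0:
            warnings.warn(
                "time unit convention f_S = 1 (without drug) not met; "
                "all times are in units of 1/f_S",
                UserWarning,
                stacklevel=2,
            )

    @classmethod
    def create(
        cls,
        fS: float = 1.0,
        fS_drug: float = 0.0,
        fR: float = 0.9,
        fC: float = 1.0,
        gS: float = 0.1,
        gS_drug: float | None = None,
        gR: float = 0.1,
        gC: float = 0.1,
        K: float = 1000.0,
        mu1: float = 1e-5,
        mu2: float = 1e-3,
    ) -> "ModelParameters":
        """Build parameters from flat keyword rates (defaults mirror Figs 1-2)."""
        if gS_drug is None:
            gS_drug = gS
        return cls(
            rates_no_drug=EnvironmentRates(fS, fR, fC, gS, gR, gC),
            rates_drug=EnvironmentRates(fS_drug, fR, fC, gS_drug, gR, gC),
            K=float(K),
            mu1=float(mu1),
            mu2=float(mu2),
        )

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with flat rate keywords replaced (create() names)."""
        current = dict(
            fS=self.rates_no_drug.f_S,
            fS_drug=self.rates_drug.f_S,
            fR=self.rates_no_drug.f_R,
            fC=self.rates_no_drug.f_C,
            gS=self.rates_no_drug.g_S,
            gS_drug=self.rates_drug.g_S,
            gR=self.rates_no_drug.g_R,
            gC=self.rates_no_drug.g_C,
            K=self.K,
            mu1=self.mu1,
            mu2=self.mu2,
        )
        unknown = set(kwargs) - set(current)
        if unknown:
            raise TypeError(f"unknown parameter(s): {sorted(unknown)}")
        current.update(kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return ModelParameters.create(**current)

    def flat(self) -> dict:
        """Flat dict of the create() keywords (for metadata sidecars)."""
        return dict(
            fS=self.rates_no_drug.f_S,
            fS_drug=self.rates_drug.f_S,
            fR=self.rates_no_drug.f_R,
            fC=self.rates_no_drug.f_C,
            gS=self.rates_no_drug.g_S,
            gS_drug=self.rates_drug.g_S,
            gR=self.rates_no_drug.g_R,
            gC=self.rates_no_drug.g_C,
            K=self.K,
            mu1=self.mu1,
            mu2=self.mu2,
        )


class ScheduleMode(enum.Enum):
    ALTERNATING = "alternating"
    ALWAYS_OFF = "always_off"
    ALWAYS_ON = "always_on"


@dataclass(frozen=True)
class AlternationSchedule:
    """Square-wave drug schedule: absent on [kT, kT+T/2), present after.

    The first drug addition happens at ``T/2``.  The boundary belongs to the
    new phase (half-open intervals), so the environment at exactly
    ``kT + T/2`` is drug-present.
    """

    period: float | None
    mode: ScheduleMode = ScheduleMode.ALTERNATING

    def __post_init__(self) -> None:
        if self.mode is ScheduleMode.ALTERNATING:
            if self.period is None or not math.isfinite(self.period) or self.period <= 0:
                raise ValueError(f"alternating schedule needs a finite period T > 0, got {self.period}")

    @classmethod
    def always_off(cls) -> "AlternationSchedule":
        return cls(period=None, mode=ScheduleMode.ALWAYS_OFF)

    @classmethod
    def always_on(cls) -> "AlternationSchedule":
        return cls(period=None, mode=ScheduleMode.ALWAYS_ON)

    def environment_at(self, t: float) -> tuple[bool, float]:
        return environment_at(self, t)


def environment_at(schedule: AlternationSchedule, t: float) -> tuple[bool, float]:
    """Drug-present flag and time of the next environment switch at time ``t``.

    Returns ``(drug_on, next_switch)``; ``next_switch`` is ``inf`` for the
    constant-environment modes.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if schedule.mode is ScheduleMode.ALWAYS_OFF:
        return False, math.inf
    if schedule.mode is ScheduleMode.ALWAYS_ON:
        return True, math.inf
    half = schedule.period / 2.0
    k = math.floor(t / half)
    # float-boundary guard: t marginally below a multiple of half
    if (k + 1) * half <= t:
        k += 1
    return (k % 2) == 1, (k + 1) * half


@dataclass(frozen=True)
class PopulationState:
    """Genotype counts at one instant; ``N`` is the total size."""

    t: float
    S: int
    R: int
    C: int

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"time must be >= 0, got {self.t}")
        for name in ("S", "R", "C"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")

    @property
    def N(self) -> int:
        return self.S + self.R + self.C


#: order of the propensity vector returned by :func:`propensities`
EVENTS = (
    ("division", Genotype.S),
    ("division", Genotype.R),
    ("division", Genotype.C),
    ("death", Genotype.S),
    ("death", Genotype.R),
    ("death", Genotype.C),
)


def propensities(
    state: PopulationState, rates: EnvironmentRates, params: ModelParameters
) -> np.ndarray:
    """Event rates ``[div_S, div_R, div_C, death_S, death_R, death_C]``.

    Division propensity of genotype X is ``f_X * max(0, 1 - N/K) * count``;
    death propensity is ``g_X * count``.  The logistic factor is clamped at
    zero for ``N >= K``, which makes ``N = K`` a reflecting ceiling for
    births.
    """
    counts = np.array([state.S, state.R, state.C], dtype=float)
    logistic = max(0.0, 1.0 - state.N / params.K)
    f = np.array([rates.f_S, rates.f_R, rates.f_C])
    g = np.array([rates.g_S, rates.g_R, rates.g_C])
    return np.concatenate([f * logistic * counts, g * counts])


def r_ratio(f_prime: float, g_prime: float) -> float:
    """Dimensionless drug-strength ratio ``(g'_S - f'_S) / g'_S``.

    Zero exactly at the MIC, positive above, negative below.
    """
    if g_prime <= 0:
        raise ValueError(f"g'_S must be > 0 to define the drug-strength ratio, got {g_prime}")
    return (g_prime - f_prime) / g_prime


def rates_from_r_ratio(R: float, mode: str, params: ModelParameters) -> ModelParameters:
    """Invert the ratio R into drug-phase S rates (heatmap conventions).

    ``mode='biostatic'`` keeps ``g'_S = g_S`` and sets ``f'_S = g_S (1 - R)``;
    ``mode='biocidal'`` keeps ``f'_S = f_S`` and sets ``g'_S = f_S / (1 - R)``.
    """
    if mode == "biostatic":
        gS = params.rates_no_drug.g_S
        f_prime = gS * (1.0 - R)
        if f_prime < 0:
            raise ValueError(f"R={R} gives a negative biostatic division rate")
        return params.with_(fS_drug=f_prime, gS_drug=gS)
    if mode == "biocidal":
        if R >= 1:
            raise ValueError(f"biocidal inversion needs R < 1, got {R}")
        fS = params.rates_no_drug.f_S
        return params.with_(fS_drug=fS, gS_drug=fS / (1.0 - R))
    raise ValueError(f"mode must be 'biostatic' or 'biocidal', got {mode!r}")


@dataclass(frozen=True)
class RegimeReport:
    """Drug-strength ratio, fast-alternation effective rates and regime flags."""

    r_ratio: float
    f_S_eff: float
    g_S_eff: float
    above_mic: bool
    fast_alternation_decay: bool
    critical_r_biocidal: float


def classify_regime(
    params: ModelParameters, schedule: AlternationSchedule | None = None
) -> RegimeReport:
    """Classify the drug regime from the model parameters.

    Under infinitely fast symmetric alternation the S rates average to
    ``f~_S = (f_S + f'_S)/2`` and ``g~_S = (g_S + g'_S)/2``; the population
    decays over many periods when ``f~_S < g~_S`` (for a pure biocidal drug
    this is ``g'_S > 2 f_S - g_S``).  The corresponding critical ratio for a
    pure biocidal drug is ``R = (f_S - g_S)/(2 f_S - g_S)``.
    """
    nd, d = params.rates_no_drug, params.rates_drug
    ratio = r_ratio(d.f_S, d.g_S) if d.g_S > 0 else math.nan
    f_eff = (nd.f_S + d.f_S) / 2.0
    g_eff = (nd.g_S + d.g_S) / 2.0
    critical = (nd.f_S - nd.g_S) / (2.0 * nd.f_S - nd.g_S)
    return RegimeReport(
        r_ratio=ratio,
        f_S_eff=f_eff,
        g_S_eff=g_eff,
        above_mic=d.g_S > d.f_S,
        fast_alternation_decay=f_eff < g_eff,
        critical_r_biocidal=critical,
    )


# ---------------------------------------------------------------------------
# configuration files

CONFIG_DEFAULTS: dict = {
    "fS": 1.0,
    "fS_drug": 0.0,
    "fR": 0.9,
    "fC": 1.0,
    "gS": 0.1,
    "gS_drug": None,  # None -> same as gS (perfect biostatic default)
    "gR": 0.1,
    "gC": 0.1,
    "K": 1000.0,
    "mu1": 1e-5,
    "mu2": 1e-3,
    "T": 1000.0,
    "init_S": 10,
    "init_R": 0,
    "init_C": 0,
    "t_max": 1e6,
    "n_rep": 100,
    "seed": 0,
}


def load_config(path: str | Path) -> dict:
    """Read a JSON/YAML key-value config file; unknown keys are a hard error."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)  # YAML is a JSON superset
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a key-value mapping")
    unknown = set(raw) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = dict(CONFIG_DEFAULTS)
    cfg.update(raw)
    if cfg["gS_drug"] is None:
        cfg["gS_drug"] = cfg["gS"]
    return cfg


def config_to_objects(cfg: dict) -> tuple[ModelParameters, AlternationSchedule, dict]:
    """Turn a validated config dict into model objects plus run extras."""
    params = ModelParameters.create(
        fS=cfg["fS"],
        fS_drug=cfg["fS_drug"],
        fR=cfg["fR"],
        fC=cfg["fC"],
        gS=cfg["gS"],
        gS_drug=cfg["gS_drug"],
        gR=cfg["gR"],
        gC=cfg["gC"],
        K=cfg["K"],
        mu1=cfg["mu1"],
        mu2=cfg["mu2"],
    )
    schedule = AlternationSchedule(period=float(cfg["T"]))
    extras = {
        "init_S": int(cfg["init_S"]),
        "init_R": int(cfg["init_R"]),
        "init_C": int(cfg["init_C"]),
        "t_max": float(cfg["t_max"]),
        "n_rep": int(cfg["n_rep"]),
        "seed": int(cfg["seed"]),
    }
    return params, schedule, extras
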