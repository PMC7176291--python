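"""Assembly of the extinction probability of the population at drug addition.

A declining sensitive population is "rescued" if a resistant lineage
survives the drug phase.  Rescue can come from mutants already present when
drug is added (Moran occupancy statistics x branching-process early
extinction of each copy number) or, when the drug does not fully stop S
divisions, from mutants appearing during the decay.  The extinction
probability assembles as

    p0 = [1 - pR sum_i pRc(i) (1 - pRe(i))] * [1 - pRa (1 - pRe')],

where the second factor is identically 1 for a perfect biostatic drug.

The branching-process pieces treat the R lineage as a time-inhomogeneous
birth-death process with birth rate ``fR (1 - S(t)/K)`` atop the
deterministic sensitive decay ``S(t)`` and death rate ``gR``; the lineage
extinction probability is the classic time-varying-rate closed form driven
by the exponent ``rho(t) = int_0^t [gR - fR (1 - S(u)/K)] du``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from . import _kernel
from .deterministic_dynamics import DeterministicDecay, equilibrium_size, n_div
from .extinction_times import mean_extinction_time
from .model_core import ModelParameters
from .moran import LineageStats, MoranSpec, lineage_stats, p_preexisting

__all__ = [
    "RescuePrediction",
    "rho",
    "p_extinct_lineage",
    "p_extinct_lineage_after",
    "appearance_time_density",
    "p_extinct_denovo_avg",
    "p0_perfect_biostatic",
    "p0_general",
    "sample_lineage_extinction",
]

_REL_TOL = 1e-8


@dataclass(frozen=True)
class RescuePrediction:
    """All analytic pieces of the assembled extinction probability."""

    p0: float
    p_preexist: float  # probability an R lineage is alive at drug addition
    occupancy: np.ndarray = field(repr=False)  # pRc(i), i = 1..N-1
    p_lineage_extinct: float  # pRe(1): early-extinction prob of one R copy
    rescue_sum: float  # sum_i pRc(i) (1 - pRe(i))
    p_appear: float  # pRa: de-novo appearance probability during decay
    p_denovo_extinct: float  # pRe': averaged early-extinction of de-novo mutants
    n_divisions: float
    tau_S: float
    N0: int
    mode: str  # "perfect-biostatic" | "general"

    def __post_init__(self) -> None:
        for name in ("p0", "p_preexist", "p_lineage_extinct", "p_appear", "p_denovo_extinct"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} = {v} is not a probability")


def rho(t: float, decay: DeterministicDecay, fR: float, gR: float) -> float:
    """Exponent ``int_0^t [gR - fR (1 - S(u)/K)] du`` in closed form."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return (gR - fR) * t + (fR / decay.K) * decay.integral(t)


def _survival_integral(decay: DeterministicDecay, fR: float, gR: float, t0: float = 0.0) -> float:
    """``int_{t0}^inf exp(rho(u) - rho(t0)) du`` with adaptive truncation.

    The exponent slope tends to ``gR - fR < 0`` once S has decayed, so the
    integral converges; the horizon is doubled until the value changes by
    less than the relative tolerance.
    """
    rho0 = rho(t0, decay, fR, gR)

    def integrand(u):
        return math.exp(rho(u, decay, fR, gR) - rho0)

    # initial horizon: time for the asymptotic exponent to fall to ~1e-12
    horizon = t0 + (27.7 / (fR - gR)) * (1.0 + fR / (fR - gR))
    prev = None
    for _ in range(60):
        value, _err = quad(integrand, t0, horizon, epsrel=_REL_TOL, limit=400)
        if prev is not None and abs(value - prev) <= _REL_TOL * max(abs(value), 1e-300):
            return value
        prev = value
        horizon = t0 + 2.0 * (horizon - t0)
    raise RuntimeError("lineage-survival integral did not converge under horizon doubling")


def p_extinct_lineage(i: int, decay: DeterministicDecay, fR: float, gR: float) -> float:
    """Early-extinction probability of an R lineage of ``i`` copies at drug addition.

    Evaluates ``[gR I / (1 + gR I)]^i`` with ``I = int_0^inf e^{rho(u)} du``.
    Copies die independently, hence the i-th power.  A subcritical lineage
    (``fR <= gR``) is extinct with probability 1 regardless of the decay.
    """
    if i < 1:
        raise ValueError(f"copy number must be >= 1, got {i}")
    if fR <= gR:
        return 1.0
    I = _survival_integral(decay, fR, gR, t0=0.0)
    base = gR * I / (1.0 + gR * I)
    return base**i


def p_extinct_lineage_after(
    t0: float, decay: DeterministicDecay, fR: float, gR: float
) -> float:
    """Early-extinction probability of a single R mutant appearing at time ``t0``.

    Same closed form as :func:`p_extinct_lineage` with the exponent integral
    started at ``t0`` (the mutant faces less residual S competition the later
    it appears, so this tends to ``gR/fR`` as ``t0`` grows).
    """
    if t0 < 0:
        raise ValueError(f"t0 must be >= 0, got {t0}")
    if fR <= gR:
        return 1.0
    I = _survival_integral(decay, fR, gR, t0=t0)
    return gR * I / (1.0 + gR * I)


def _decay_truncation_time(decay: DeterministicDecay) -> float:
    """Time past which S(t) is negligible (< 1e-12 of S0)."""
    net = decay.g - decay.f
    if decay.S0 == 0:
        return 1.0
    if net <= 0:
        raise ValueError("appearance-time density needs a decaying S (g' >= f')")
    t = 27.7 / net
    while decay(t) > 1e-12 * decay.S0:
        t *= 2.0
        if t > 1e12:
            raise RuntimeError("could not truncate the decaying S trajectory")
    return t


def appearance_time_density(decay: DeterministicDecay) -> tuple:
    """Normalized density of the appearance time of a de-novo mutant.

    ``w(t0) = S(t0)(1 - S(t0)/K) / int_0^inf S(t)(1 - S(t)/K) dt``: mutants
    appear proportionally to the S division activity during the decay.
    Returns ``(w, t_upper)`` where ``t_upper`` bounds the support
    numerically.
    """
    t_up = _decay_truncation_time(decay)

    def activity(t):
        s = decay(t)
        return s * max(0.0, 1.0 - s / decay.K)

    norm, _ = quad(activity, 0.0, t_up, epsrel=_REL_TOL, limit=400)
    if norm <= 0:
        raise ValueError("degenerate appearance-time density (no S division activity)")

    def w(t0):
        return activity(t0) / norm

    return w, t_up


def p_extinct_denovo_avg(decay: DeterministicDecay, params: ModelParameters) -> float:
    """Appearance-time-averaged early-extinction probability of de-novo mutants.

    Weighs :func:`p_extinct_lineage_after` by the appearance-time density.
    With no S background at all the average degenerates to the constant-rate
    value ``gR/fR`` (warned, since the weighting is then meaningless).
    """
    fR = params.rates_no_drug.f_R
    gR = params.rates_no_drug.g_R
    if fR <= gR:
        return 1.0
    if decay.S0 == 0:
        warnings.warn(
            "S trajectory is identically zero; returning the constant-rate limit gR/fR",
            UserWarning,
            stacklevel=2,
        )
        return gR / fR
    w, t_up = appearance_time_density(decay)
    value, _err = quad(
        lambda t0: p_extinct_lineage_after(t0, decay, fR, gR) * w(t0),
        0.0,
        t_up,
        epsrel=1e-6,
        limit=200,
    )
    return min(value, 1.0)


def _first_factor(
    params: ModelParameters, decay: DeterministicDecay
) -> tuple[float, float, LineageStats, float, int]:
    """Rescue-by-preexisting-mutants factor pieces: (factor, pR, stats, pRe(1), N)."""
    nd = params.rates_no_drug
    N = int(math.floor(params.K * (1.0 - nd.g_S / nd.f_S) + 0.5))
    if params.K * params.mu1 > 0.1:
        warnings.warn(
            f"rare-mutation assumption strained: K*mu1 = {params.K * params.mu1:.3g} > 0.1",
            UserWarning,
            stacklevel=3,
        )
    spec = MoranSpec(
        N=N,
        f_resident=nd.f_S,
        g_resident=nd.g_S,
        f_mutant=nd.f_R,
        g_mutant=nd.g_R,
    )
    stats = lineage_stats(spec, conditioning="extinction")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # N*mu1 warning already issued on K*mu1
        pR = p_preexisting(N, params.mu1, nd.g_S, stats)
    p1 = p_extinct_lineage(1, decay, nd.f_R, nd.g_R)
    i = np.arange(1, N, dtype=float)
    rescue_sum = float(np.sum(stats.occupancy * (1.0 - p1**i)))
    factor = 1.0 - pR * rescue_sum
    return factor, pR, stats, p1, N


def p0_perfect_biostatic(params: ModelParameters) -> RescuePrediction:
    """Extinction probability at drug addition for a perfect biostatic drug.

    Requires ``f'_S = 0`` (S cannot divide under drug, so no de-novo rescue);
    assembles ``p0 = 1 - pR sum_i pRc(i)(1 - pRe(i))`` from the Moran
    occupancy statistics and the branching early-extinction probabilities
    against the exponential decay ``S(t) = K(1 - gS/fS) e^{-g'_S t}``.
    """
    d = params.rates_drug
    if d.f_S != 0.0:
        raise ValueError(
            f"perfect-biostatic assembly requires f'_S = 0, got {d.f_S}; use p0_general"
        )
    nd = params.rates_no_drug
    S0 = equilibrium_size(nd.f_S, nd.g_S, params.K)
    decay = DeterministicDecay(S0=S0, f=0.0, g=d.g_S, K=params.K)
    factor, pR, stats, p1, N = _first_factor(params, decay)
    tau = mean_extinction_time(params)
    return RescuePrediction(
        p0=factor,
        p_preexist=pR,
        occupancy=stats.occupancy,
        p_lineage_extinct=p1,
        rescue_sum=(1.0 - factor) / pR if pR > 0 else 0.0,
        p_appear=0.0,
        p_denovo_extinct=1.0,
        n_divisions=0.0,
        tau_S=tau.tau_S,
        N0=N,
        mode="perfect-biostatic",
    )


def p0_general(params: ModelParameters) -> RescuePrediction:
    """Extinction probability at drug addition for any above-MIC drug.

    Adds the de-novo rescue channel to the preexisting-mutant factor: the
    expected number of S divisions during the decay gives the appearance
    probability ``pRa = Ndiv mu1``, and surviving de-novo lineages are
    weighted by their appearance time.  Reduces exactly to
    :func:`p0_perfect_biostatic` when ``f'_S = 0``.
    """
    d = params.rates_drug
    if d.g_S <= d.f_S:
        raise ValueError(
            f"above-MIC drug required (g'_S > f'_S), got g'={d.g_S}, f'={d.f_S}"
        )
    nd = params.rates_no_drug
    S0 = equilibrium_size(nd.f_S, nd.g_S, params.K)
    decay = DeterministicDecay(S0=S0, f=d.f_S, g=d.g_S, K=params.K)
    factor, pR, stats, p1, N = _first_factor(params, decay)
    tau = mean_extinction_time(params)
    ndiv = n_div(params, tau.tau_S, S0=S0)
    p_appear = ndiv * params.mu1
    if p_appear > 0.1:
        warnings.warn(
            f"rare de-novo appearance assumption strained: Ndiv*mu1 = {p_appear:.3g} > 0.1",
            UserWarning,
            stacklevel=2,
        )
    p_appear = min(p_appear, 1.0)
    if p_appear > 0:
        p_denovo = p_extinct_denovo_avg(decay, params)
    else:
        p_denovo = 1.0
    p0 = factor * (1.0 - p_appear * (1.0 - p_denovo))
    return RescuePrediction(
        p0=p0,
        p_preexist=pR,
        occupancy=stats.occupancy,
        p_lineage_extinct=p1,
        rescue_sum=(1.0 - factor) / pR if pR > 0 else 0.0,
        p_appear=p_appear,
        p_denovo_extinct=p_denovo,
        n_divisions=ndiv,
        tau_S=tau.tau_S,
        N0=N,
        mode="general",
    )


def sample_lineage_extinction(
    decay: DeterministicDecay,
    fR: float,
    gR: float,
    i0: int = 1,
    t0: float = 0.0,
    n_rep: int = 10_000,
    seed: int = 0,
    j_cap: int = 1000,
    t_horizon: float = 1e5,
) -> float:
    """Simulation oracle: fraction of R lineages (atop deterministic S) that die.

    Simulates ``n_rep`` independent lineages exactly (thinning) and returns
    the extinct fraction, directly comparable to :func:`p_extinct_lineage`
    and :func:`p_extinct_lineage_after`.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_rep)
    n_extinct = 0
    for s in seeds:
        n_extinct += _kernel.branching_lineage_extinct(
            int(s), i0, t0, decay.S0, decay.f, decay.g, decay.K, fR, gR, t_horizon, j_cap
        )
    return n_extinct / n_rep
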