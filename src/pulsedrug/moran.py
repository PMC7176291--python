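"""Fixed-size Moran-model quantities for mutant lineages.

The Moran chain used throughout: each individual dies at its genotype's
death rate and is immediately replaced by an offspring drawn proportionally
to fitness, keeping the population size fixed at N.  With mutant count j the
chain moves up at rate ``g_res (N-j) f_mut j / D`` and down at rate
``g_mut j f_res (N-j) / D`` where ``D = f_mut j + f_res (N-j)``.  The
down/up bias per step is the constant ``q = (f_res g_mut)/(f_mut g_res)``,
which reproduces the classic fixation probability ``(1-q)/(1-q^N)`` and a
mutant supply rate ``N mu g_res`` at demographic equilibrium.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from . import _kernel
from .model_core import ModelParameters

__all__ = [
    "MoranSpec",
    "LineageStats",
    "fixation_probability",
    "lineage_stats",
    "p_preexisting",
    "appearance_fixation_time",
    "valley_crossing_time",
    "sample_lineage_lifetimes",
]

_MAX_DENSE_N = 10_000


@dataclass(frozen=True)
class MoranSpec:
    """Fixed population size plus resident and mutant birth/death rates.

    ``N`` may be real-valued for the analytic fixation formula (the chain
    solves require an integer N >= 2).
    """

    N: float
    f_resident: float
    g_resident: float
    f_mutant: float
    g_mutant: float

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"population size must be >= 2, got {self.N}")
        for name in ("f_resident", "g_resident", "f_mutant", "g_mutant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def step_bias(self) -> float:
        """q = (f_res g_mut)/(f_mut g_res); reduces to f_res/f_mut at equal deaths."""
        return (self.f_resident * self.g_mutant) / (self.f_mutant * self.g_resident)


@dataclass(frozen=True)
class LineageStats:
    """Lifetime and occupancy decomposition of a single-mutant lineage.

    ``sojourn[i-1]`` is the mean time spent with exactly i mutants
    (i = 1..N-1) starting from one copy; ``occupancy`` is the normalized
    sojourn vector, i.e. the probability that the lineage holds i copies at
    a uniformly-drawn instant of its lifetime.
    """

    tau_d: float
    sojourn: np.ndarray
    occupancy: np.ndarray
    conditioning: str

    def __post_init__(self) -> None:
        total = float(np.sum(self.occupancy))
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"occupancy must sum to 1, got {total}")


def fixation_probability(spec: MoranSpec) -> float:
    """Probability that a single mutant fixes: ``(1 - q)/(1 - q^N)``.

    ``q`` is the per-step bias of :class:`MoranSpec`; the neutral case
    ``q = 1`` returns ``1/N``.  Evaluated in log space so strongly
    deleterious mutants underflow gracefully instead of overflowing.
    """
    q = spec.step_bias
    N = spec.N
    lq = math.log(q)
    if abs(lq) < 1e-12:
        return 1.0 / N
    if N * lq > 700.0:  # q^N would overflow: p ~ (q-1) q^{-N}
        return math.exp(math.log(q - 1.0) - N * lq)
    return math.expm1(lq) / math.expm1(N * lq)


def _moran_chain_rates(spec: MoranSpec) -> tuple[np.ndarray, np.ndarray]:
    N = int(spec.N)
    j = np.arange(1, N, dtype=float)
    denom = spec.f_mutant * j + spec.f_resident * (N - j)
    up = spec.g_resident * (N - j) * spec.f_mutant * j / denom
    down = spec.g_mutant * j * spec.f_resident * (N - j) / denom
    return up, down


def _extinction_probabilities(q: float, N: int) -> np.ndarray:
    """P(absorb at 0 | j mutants) for j = 0..N, computed stably."""
    j = np.arange(N + 1, dtype=float)
    if abs(q - 1.0) < 1e-12:
        return 1.0 - j / N
    lq = math.log(q)
    if q < 1.0:
        # h_j = (q^j - q^N)/(1 - q^N)
        return (np.exp(j * lq) - math.exp(N * lq)) / (1.0 - math.exp(N * lq))
    # q > 1: divide through by q^N -> h_j = (q^{j-N} - 1)/(q^{-N} - 1)
    num = np.expm1((j - N) * lq)
    den = math.expm1(-N * lq)
    return num / den


def lineage_stats(spec: MoranSpec, conditioning: str = "extinction") -> LineageStats:
    """Mean sojourn times of a single-mutant lineage in each occupancy state.

    Builds the Moran birth-death chain on mutant count j in {0..N} and
    solves the tridiagonal system for the expected time spent in each
    transient state starting from j = 1.  ``conditioning='extinction'``
    restricts to lineages destined to die out (Doob h-transform on the
    absorption-at-0 probability); ``'none'`` keeps both absorbing ends.
    """
    if conditioning not in ("extinction", "none"):
        raise ValueError(f"conditioning must be 'extinction' or 'none', got {conditioning!r}")
    N = int(spec.N)
    if N != spec.N:
        raise ValueError(f"lineage_stats needs an integer population size, got {spec.N}")
    if N > _MAX_DENSE_N:
        raise ValueError(
            f"N={N} exceeds the dense-solve contract ({_MAX_DENSE_N}); a sparse mode is required"
        )
    up, down = _moran_chain_rates(spec)
    if conditioning == "extinction":
        h = _extinction_probabilities(spec.step_bias, N)
        up = up * h[2:] / h[1:N]
        down = down * h[0 : N - 1] / h[1:N]
    m = N - 1
    # A = -Q on transient states; sojourn vector solves A^T x = e_1
    diag = up + down
    ab = np.zeros((3, m))
    # A^T: superdiagonal holds -down_{j+1}, subdiagonal -up_j
    ab[0, 1:] = -down[1:]
    ab[1, :] = diag
    ab[2, :-1] = -up[:-1]
    rhs = np.zeros(m)
    rhs[0] = 1.0
    sojourn = solve_banded((1, 1), ab, rhs)
    tau_d = float(np.sum(sojourn))
    return LineageStats(
        tau_d=tau_d,
        sojourn=sojourn,
        occupancy=sojourn / tau_d,
        conditioning=conditioning,
    )


def p_preexisting(N: float, mu1: float, gS: float, stats: LineageStats) -> float:
    """Probability that a resistant lineage is alive at the moment of drug addition.

    Equals the lineage lifetime over the mutant inter-appearance time,
    ``N mu1 gS tau_d``, valid in the rare-mutation regime ``N mu1 << 1``
    (warned above 0.1); capped at 1 with a warning if the product exceeds 1.
    """
    if mu1 == 0.0:
        return 0.0
    if N * mu1 > 0.1:
        warnings.warn(
            f"rare-mutation assumption strained: N*mu1 = {N * mu1:.3g} > 0.1",
            UserWarning,
            stacklevel=2,
        )
    p = N * mu1 * gS * stats.tau_d
    if p > 1.0:
        warnings.warn(
            f"pre-existence probability {p:.3g} > 1; capped at 1 (outside the rare-mutation regime)",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    return p


def appearance_fixation_time(N: float, mu1: float, g_div: float, p_fix: float) -> float:
    """Mean waiting time for a mutant destined to fix: ``1/(N mu1 g p_fix)``.

    The caller supplies the regime-appropriate population size, division
    (death-balanced) rate and fixation probability.  Any zero factor returns
    ``inf`` (no such mutant ever arrives).
    """
    rate = N * mu1 * g_div * p_fix
    if rate <= 0.0:
        return math.inf
    return 1.0 / rate


def valley_crossing_time(params: ModelParameters) -> float:
    """Mean spontaneous S -> C valley-crossing time by stochastic tunneling.

    ``(f_S - f_R)/(mu1 mu2 g_S)`` with the drug-free rates; requires a real
    fitness valley (``f_S > f_R``) and positive mutation/death rates.
    """
    nd = params.rates_no_drug
    if nd.f_S <= nd.f_R:
        raise ValueError(
            f"no fitness valley: f_S={nd.f_S} must exceed f_R={nd.f_R}"
        )
    if params.mu1 <= 0 or params.mu2 <= 0 or nd.g_S <= 0:
        raise ValueError("mu1, mu2 and g_S must all be > 0")
    return (nd.f_S - nd.f_R) / (params.mu1 * params.mu2 * nd.g_S)


def sample_lineage_lifetimes(
    spec: MoranSpec, n_rep: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Direct stochastic lineage simulations (oracle for :func:`lineage_stats`).

    Returns ``(lifetimes, hit_zero)`` over ``n_rep`` independent lineages
    started from a single mutant.
    """
    N = int(spec.N)
    seeds = np.random.SeedSequence(seed).generate_state(n_rep)
    lifetimes = np.empty(n_rep)
    hit_zero = np.empty(n_rep, dtype=bool)
    for k, s in enumerate(seeds):
        lifetimes[k], hit_zero[k] = _kernel.moran_lineage(
            int(s), N, spec.f_resident, spec.g_resident, spec.f_mutant, spec.g_mutant
        )
    return lifetimes, hit_zero
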