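"""Mean extinction (first-passage) times of the sensitive population.

The sensitive population under drug is a birth-death chain with logistic
birth rates ``f' n max(0, 1 - n/K)`` and linear death rates ``g' n`` on the
finite state space {0, ..., ceil(K)} (births are impossible at the ceiling,
so no further truncation is needed).  Mean absorption times at 0 solve a
tridiagonal linear system; the no-birth limit reduces to the harmonic sum
``tau = (1/g) sum_{i=1}^{N} 1/i``.

The mean time scales as ``tau(f', g') = Phi(R) / g'`` with
``R = (g' - f')/g'``, which is what makes the threshold solves here
comparable across biostatic and biocidal drugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import brentq

from .model_core import ModelParameters, rates_from_r_ratio

__all__ = [
    "ExtinctionTimeResult",
    "tau_pure_death",
    "tau_birth_death_logistic",
    "mean_extinction_time",
    "solve_T_threshold",
    "solve_R_threshold_small_period",
]


@dataclass(frozen=True)
class ExtinctionTimeResult:
    """Mean extinction time, starting size and the method that produced it."""

    tau_S: float
    N0: int
    method: str  # "harmonic" | "linear-solve"


def tau_pure_death(N: int, g: float) -> float:
    """Mean extinction time of ``N`` non-dividing individuals dying at rate ``g``.

    Equals ``(1/g) sum_{i=1}^{N} 1/i`` (summed in ascending order of the
    terms for stability).  ``N = 0`` returns 0 by convention.
    """
    if N < 0 or N != int(N):
        raise ValueError(f"N must be a non-negative integer, got {N}")
    if g <= 0:
        raise ValueError(f"death rate must be > 0, got {g}")
    if N == 0:
        return 0.0
    i = np.arange(int(N), 0, -1, dtype=float)
    return float(np.sum(1.0 / i)) / g


def _chain_rates(f_prime: float, g_prime: float, K: float) -> tuple[np.ndarray, np.ndarray]:
    n_max = int(math.ceil(K))
    n = np.arange(1, n_max + 1, dtype=float)
    lam = f_prime * n * np.clip(1.0 - n / K, 0.0, None)
    mu = g_prime * n
    return lam, mu


def tau_birth_death_logistic(f_prime: float, g_prime: float, K: float, N0: int) -> float:
    """Mean absorption time at 0 of the logistic birth-death chain from ``N0``.

    Solves ``(lam_n + mu_n) tau_n = 1 + lam_n tau_{n+1} + mu_n tau_{n-1}``
    with ``tau_0 = 0`` and no birth at the ceiling, via a banded linear
    solve (O(K) work, valid up to large K).
    """
    if g_prime <= 0:
        raise ValueError(f"g' must be > 0, got {g_prime}")
    if f_prime < 0:
        raise ValueError(f"f' must be >= 0, got {f_prime}")
    n_max = int(math.ceil(K))
    if not 1 <= N0 <= n_max:
        raise ValueError(f"N0 must lie in [1, {n_max}], got {N0}")
    lam, mu = _chain_rates(f_prime, g_prime, K)
    m = n_max
    ab = np.zeros((3, m))
    ab[0, 1:] = -lam[:-1]  # superdiagonal: coefficient of tau_{n+1}
    ab[1, :] = lam + mu
    ab[2, :-1] = -mu[1:]  # subdiagonal: coefficient of tau_{n-1}
    tau = solve_banded((1, 1), ab, np.ones(m))
    return float(tau[N0 - 1])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def equilibrium_start_size(params: ModelParameters) -> int:
    """Nearest integer to the drug-free equilibrium ``K (1 - g_S/f_S)``."""
    nd = params.rates_no_drug
    if nd.f_S <= nd.g_S:
        raise ValueError("drug-free rates must satisfy f_S > g_S")
    return _round_half_up(params.K * (1.0 - nd.g_S / nd.f_S))


def mean_extinction_time(params: ModelParameters, N0: int | None = None) -> ExtinctionTimeResult:
    """Mean time for the S population to die out with drug continuously on.

    Starts from the drug-free equilibrium size unless ``N0`` is given; uses
    the exact harmonic sum when the drug-phase division rate is zero, and the
    banded first-passage solve otherwise.
    """
    if N0 is None:
        N0 = equilibrium_start_size(params)
    d = params.rates_drug
    if d.f_S == 0.0:
        return ExtinctionTimeResult(tau_S=tau_pure_death(N0, d.g_S), N0=N0, method="harmonic")
    tau = tau_birth_death_logistic(d.f_S, d.g_S, params.K, N0)
    return ExtinctionTimeResult(tau_S=tau, N0=N0, method="linear-solve")


def solve_T_threshold(params: ModelParameters) -> float:
    """Alternation period ``T* = 2 tau_S`` above which one drug phase kills.

    ``tau_S`` is evaluated from the rounded drug-free equilibrium size.
    """
    return 2.0 * mean_extinction_time(params).tau_S


def solve_R_threshold_small_period(
    T: float,
    K: float,
    params: ModelParameters,
    mode: str = "biocidal",
    bracket: tuple[float, float] = (-0.9, 0.9),
    xtol: float = 1e-6,
) -> float:
    """Drug-strength ratio ``R*`` solving ``tau_S(R) = T/2``.

    ``mode`` fixes the R-to-rate inversion: biocidal keeps ``f'_S = f_S`` and
    sets ``g'_S = f_S/(1-R)``; biostatic keeps ``g'_S = g_S`` and sets
    ``f'_S = g_S (1-R)``.  ``tau_S(R)`` is strictly decreasing in R, so the
    root is unique on the bracket when it exists; no sign change raises a
    diagnostic error.
    """
    if T <= 0:
        raise ValueError(f"T must be > 0, got {T}")
    base = params.with_(K=K)
    N0 = equilibrium_start_size(base)

    def gap(R: float) -> float:
        p = rates_from_r_ratio(R, mode, base)
        d = p.rates_drug
        return tau_birth_death_logistic(d.f_S, d.g_S, K, N0) - T / 2.0

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no sign change for tau_S(R) - T/2 on R in [{lo}, {hi}]: "
            f"gap({lo})={g_lo:.4g}, gap({hi})={g_hi:.4g}; widen the bracket or change T"
        )
    return float(brentq(gap, lo, hi, xtol=xtol))
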