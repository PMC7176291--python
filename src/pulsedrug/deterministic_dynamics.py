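"""Closed-form deterministic trajectories of the sensitive population.

These feed the analytic rescue formulas: the exponential / logistic decay of
S under drug, the drug-free equilibrium size ``K (1 - g/f)``, and the
expected number of divisions occurring during the decay (which sets the
probability that a resistant mutant appears while drug is present).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .model_core import ModelParameters

__all__ = ["DeterministicDecay", "equilibrium_size", "s_of_t", "n_div"]


def equilibrium_size(f: float, g: float, K: float) -> float:
    """Deterministic equilibrium population size ``K (1 - g/f)``.

    Obtained by balancing the logistic birth rate ``f (1 - N/K)`` against the
    death rate ``g``; only defined for ``f > g >= 0``.
    """
    if g < 0:
        raise ValueError(f"death rate must be >= 0, got {g}")
    if f <= g:
        raise ValueError(f"no positive equilibrium for f={f} <= g={g}")
    return K * (1.0 - g / f)


@dataclass(frozen=True)
class DeterministicDecay:
    """Deterministic solution of ``dS/dt = f S (1 - S/K) - g S`` from ``S0``.

    With ``a = f - g`` and ``b = f/K`` the solution is
    ``S(t) = a S0 e^{at} / (a + b S0 (e^{at} - 1))`` for ``a != 0``,
    ``S(t) = S0 / (1 + b S0 t)`` at the MIC (``a = 0``), and the pure
    exponential ``S0 e^{-gt}`` for a perfect biostatic drug (``f = 0``).
    """

    S0: float
    f: float
    g: float
    K: float

    def __post_init__(self) -> None:
        if self.S0 < 0:
            raise ValueError(f"S0 must be >= 0, got {self.S0}")
        if self.f < 0 or self.g < 0:
            raise ValueError("rates must be >= 0")
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")

    def __call__(self, t):
        """Evaluate S(t); accepts scalars or arrays, t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        a = self.f - self.g
        b = self.f / self.K
        if self.S0 == 0:
            out = np.zeros_like(t)
        elif b == 0.0:
            out = self.S0 * np.exp(np.maximum(a * t, -745.0))
        elif a == 0.0:
            out = self.S0 / (1.0 + b * self.S0 * t)
        else:
            at = np.minimum(a * t, 700.0)  # a > 0 saturates at a/b = K(1-g/f)
            e = np.exp(at)
            out = a * self.S0 * e / (a + b * self.S0 * (e - 1.0))
        return out if out.ndim else float(out)

    def integral(self, t):
        """Closed-form cumulative integral ``int_0^t S(u) du``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        a = self.f - self.g
        b = self.f / self.K
        if self.S0 == 0:
            out = np.zeros_like(t)
        elif b == 0.0:
            if a == 0.0:
                out = self.S0 * t
            else:
                out = (self.S0 / a) * np.expm1(np.maximum(a * t, -745.0))
        elif a == 0.0:
            out = np.log1p(b * self.S0 * t) / b
        else:
            # (1/b) log[(a + b S0 (e^{at} - 1)) / a]; for a > 0 switch to the
            # linear asymptote S -> a/b once e^{at} would overflow
            t_cap = 700.0 / a if a > 0 else np.inf
            tc = np.minimum(t, t_cap)
            e = np.exp(a * tc)
            out = np.log((a + b * self.S0 * (e - 1.0)) / a) / b
            if a > 0:
                out = out + (a / b) * np.maximum(t - t_cap, 0.0)
        return out if out.ndim else float(out)


def s_of_t(decay: DeterministicDecay, t):
    """Evaluate the deterministic sensitive-population size at time ``t``."""
    return decay(t)


def n_div(
    params: ModelParameters,
    tau_S: float,
    S0: float | None = None,
    horizon: float | None = None,
) -> float:
    """Expected number of S divisions between drug addition and extinction.

    Integrates ``f'_S (1 - S(t)/K) S(t)`` from 0 to ``tau_S`` (the mean
    extinction time under drug, supplied by the caller) with the
    deterministic drug-phase decay ``S(t)`` started from the drug-free
    equilibrium size.  ``horizon`` overrides the upper limit (e.g. ``inf``
    for sensitivity checks).  The drug-phase division rate is used in the
    integrand, which makes the result vanish exactly for a perfect biostatic
    drug.
    """
    d = params.rates_drug
    nd = params.rates_no_drug
    if S0 is None:
        S0 = equilibrium_size(nd.f_S, nd.g_S, params.K)
    upper = tau_S if horizon is None else horizon
    if upper is None or upper <= 0:
        raise ValueError(f"integration horizon must be > 0, got {upper}")
    if d.f_S == 0.0:
        return 0.0
    decay = DeterministicDecay(S0=S0, f=d.f_S, g=d.g_S, K=params.K)

    def integrand(t):
        s = decay(t)
        return d.f_S * max(0.0, 1.0 - s / params.K) * s

    if math.isinf(upper):
        value, err = quad(integrand, 0.0, np.inf, epsrel=1e-8, limit=200)
    else:
        value, err = quad(integrand, 0.0, upper, epsrel=1e-8, limit=200)
    if not math.isfinite(value) or (value > 0 and err > 1e-4 * value):
        raise RuntimeError(f"division-count quadrature did not converge (value={value}, err={err})")
    return value
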