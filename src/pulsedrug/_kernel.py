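"""Numba event-loop kernels (internal).

All kernels seed numba's own RNG stream at entry, so a (seed, arguments)
pair maps to a bit-for-bit reproducible path.  The main simulator handles
environment switches exactly: when a drawn exponential waiting time would
cross the next switch, the clock advances to the switch and the waiting time
is re-drawn under the new rates, which is exact because propensities are
piecewise-constant in time given the state.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes
EXTINCT = 0
C_FIXED = 1
TIMEOUT = 2
BUFFER_FULL = 3

# record modes
REC_NONE = 0
REC_EVENTS = 1
REC_SAMPLED = 2

# environment modes
ENV_ALTERNATING = 0
ENV_ALWAYS_OFF = 1
ENV_ALWAYS_ON = 2


@njit(cache=True)
def logistic_decay(t, S0, f, g, K):  # pragma: no cover - exercised via wrappers
    """Deterministic S(t) for dS/dt = f S (1 - S/K) - g S, scalar, njit."""
    if S0 <= 0.0 or t <= 0.0:
        return max(S0, 0.0) if t <= 0.0 else 0.0
    a = f - g
    b = f / K
    if b == 0.0:
        if a * t < -700.0:
            return 0.0
        return S0 * np.exp(a * t)
    if a == 0.0:
        return S0 / (1.0 + b * S0 * t)
    if a > 0.0 and a * t > 700.0:
        return a / b
    e = np.exp(a * t)
    return a * S0 * e / (a + b * S0 * (e - 1.0))


@njit(cache=True)
def simulate(
    seed,
    S0,
    R0,
    C0,
    fS,
    gS,
    fS_drug,
    gS_drug,
    fR,
    gR,
    fC,
    gC,
    K,
    mu1,
    mu2,
    half_period,
    env_mode,
    t_max,
    record_mode,
    sample_dt,
    rec_t,
    rec_cnt,
    rec_env,
):
    """One exact stochastic realization; returns (code, t_event, n_rec, n_events).

    Events: logistic divisions (daughter mutated with probability mu1 for S
    parents, mu2 for R parents; the parent is never altered) and constant-rate
    deaths.  Absorbing states: total extinction, and all-C fixation.  If the
    record buffers fill up, BUFFER_FULL is returned and the caller re-runs
    with larger buffers (same seed, hence the same path).
    """
    np.random.seed(seed)
    s = S0
    r = R0
    c = C0
    t = 0.0
    n_events = 0
    n_rec = 0
    cap = rec_t.shape[0]

    if env_mode == ENV_ALWAYS_ON:
        drug = True
        next_switch = np.inf
    elif env_mode == ENV_ALWAYS_OFF:
        drug = False
        next_switch = np.inf
    else:
        drug = False
        next_switch = half_period

    if record_mode != REC_NONE:
        if cap < 1:
            return BUFFER_FULL, t, n_rec, n_events
        rec_t[0] = 0.0
        rec_cnt[0, 0] = s
        rec_cnt[0, 1] = r
        rec_cnt[0, 2] = c
        rec_env[0] = 1 if drug else 0
        n_rec = 1
    next_sample = sample_dt

    while True:
        n = s + r + c
        if n == 0:
            return EXTINCT, t, n_rec, n_events
        if s == 0 and r == 0:
            return C_FIXED, t, n_rec, n_events

        if drug:
            f_s = fS_drug
            g_s = gS_drug
        else:
            f_s = fS
            g_s = gS
        logistic = 1.0 - n / K
        if logistic < 0.0:
            logistic = 0.0
        a_div_s = f_s * logistic * s
        a_div_r = fR * logistic * r
        a_div_c = fC * logistic * c
        a_die_s = g_s * s
        a_die_r = gR * r
        a_die_c = gC * c
        a_total = a_div_s + a_div_r + a_div_c + a_die_s + a_die_r + a_die_c

        if a_total <= 0.0:
            # frozen state (e.g. all rates zero): advance the clock directly
            if next_switch < t_max:
                t = next_switch
                drug = not drug
                next_switch += half_period
                continue
            return TIMEOUT, t_max, n_rec, n_events

        dt = np.random.exponential(1.0 / a_total)
        t_new = t + dt

        if t_new >= next_switch and next_switch <= t_max:
            if record_mode == REC_SAMPLED:
                while next_sample < next_switch:
                    if n_rec >= cap:
                        return BUFFER_FULL, t, n_rec, n_events
                    rec_t[n_rec] = next_sample
                    rec_cnt[n_rec, 0] = s
                    rec_cnt[n_rec, 1] = r
                    rec_cnt[n_rec, 2] = c
                    rec_env[n_rec] = 1 if drug else 0
                    n_rec += 1
                    next_sample += sample_dt
            t = next_switch
            drug = not drug
            next_switch += half_period
            continue

        if t_new > t_max:
            if record_mode == REC_SAMPLED:
                while next_sample <= t_max:
                    if n_rec >= cap:
                        return BUFFER_FULL, t, n_rec, n_events
                    rec_t[n_rec] = next_sample
                    rec_cnt[n_rec, 0] = s
                    rec_cnt[n_rec, 1] = r
                    rec_cnt[n_rec, 2] = c
                    rec_env[n_rec] = 1 if drug else 0
                    n_rec += 1
                    next_sample += sample_dt
            return TIMEOUT, t_max, n_rec, n_events

        if record_mode == REC_SAMPLED:
            while next_sample < t_new:
                if n_rec >= cap:
                    return BUFFER_FULL, t, n_rec, n_events
                rec_t[n_rec] = next_sample
                rec_cnt[n_rec, 0] = s
                rec_cnt[n_rec, 1] = r
                rec_cnt[n_rec, 2] = c
                rec_env[n_rec] = 1 if drug else 0
                n_rec += 1
                next_sample += sample_dt

        t = t_new
        u = np.random.random() * a_total
        if u < a_div_s:
            if np.random.random() < mu1:
                r += 1
            else:
                s += 1
        elif u < a_div_s + a_div_r:
            if np.random.random() < mu2:
                c += 1
            else:
                r += 1
        elif u < a_div_s + a_div_r + a_div_c:
            c += 1
        elif u < a_div_s + a_div_r + a_div_c + a_die_s:
            s -= 1
        elif u < a_div_s + a_div_r + a_div_c + a_die_s + a_die_r:
            r -= 1
        else:
            c -= 1
        n_events += 1

        if record_mode == REC_EVENTS:
            if n_rec >= cap:
                return BUFFER_FULL, t, n_rec, n_events
            rec_t[n_rec] = t
            rec_cnt[n_rec, 0] = s
            rec_cnt[n_rec, 1] = r
            rec_cnt[n_rec, 2] = c
            rec_env[n_rec] = 1 if drug else 0
            n_rec += 1


@njit(cache=True)
def moran_lineage(seed, N, f_res, g_res, f_mut, g_mut):
    """Lifetime of a single-mutant Moran lineage; returns (lifetime, hit_zero).

    Mutant count j follows the fixed-size Moran chain: a resident dies (rate
    g_res per capita) and is replaced by a mutant offspring with probability
    proportional to mutant fitness, and vice versa.  Runs until absorption at
    j = 0 (hit_zero=True) or j = N (fixation).
    """
    np.random.seed(seed)
    j = 1
    t = 0.0
    while 0 < j < N:
        denom = f_mut * j + f_res * (N - j)
        up = g_res * (N - j) * f_mut * j / denom
        down = g_mut * j * f_res * (N - j) / denom
        total = up + down
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < up:
            j += 1
        else:
            j -= 1
    return t, j == 0


@njit(cache=True)
def branching_lineage_extinct(seed, i0, t0, S0, f_drug, g_drug, K, fR, gR, t_horizon, j_cap):
    """Fate of an R lineage atop the deterministic decaying S background.

    The lineage starts with ``i0`` copies at time ``t0`` (time measured from
    drug addition).  Birth rate per copy is ``fR * max(0, 1 - S(t)/K)`` with
    S(t) the deterministic sensitive trajectory (mutant self-competition
    neglected), death rate ``gR``.  Simulated exactly by thinning against the
    constant bound ``(fR + gR) * j``.  Returns 1 if the lineage dies out, 0
    if it reaches ``j_cap`` copies or survives past ``t_horizon``.
    """
    np.random.seed(seed)
    j = i0
    t = t0
    while j > 0:
        if j >= j_cap or t > t_horizon:
            return 0
        bound = (fR + gR) * j
        t += np.random.exponential(1.0 / bound)
        S = logistic_decay(t, S0, f_drug, g_drug, K)
        logistic = 1.0 - S / K
        if logistic < 0.0:
            logistic = 0.0
        birth = fR * logistic * j
        u = np.random.random() * bound
        if u < birth:
            j += 1
        elif u < birth + gR * j:
            j -= 1
        # else: thinning no-op
    return 1
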