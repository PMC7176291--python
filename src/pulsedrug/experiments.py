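"""Scripted parameter sweeps: p0 vs T, p0 vs K, and T-R heatmaps.

CSV tables are the contract; every cell carries its own seed (spawned
deterministically from the sweep master seed) so any row can be reproduced
bit-for-bit from the JSON metadata sidecar.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import __version__
from .extinction_times import (
    equilibrium_start_size,
    tau_birth_death_logistic,
)
from .gillespie import AlternationSchedule, SimulationConfig, estimate_p0
from .model_core import ModelParameters, rates_from_r_ratio
from .moran import MoranSpec, appearance_fixation_time, fixation_probability, valley_crossing_time
from .rescue import p0_general, p0_perfect_biostatic

__all__ = [
    "SweepSpec",
    "TransitionLines",
    "sweep_p0_vs_T",
    "sweep_p0_vs_K",
    "heatmap_T_R",
    "transition_lines",
    "solve_appearance_threshold",
    "write_outputs",
]


@dataclass(frozen=True)
class SweepSpec:
    """Axis grid, replication and seeding for one sweep."""

    params: ModelParameters
    values: np.ndarray  # grid of the swept axis (T, K or R)
    n_rep: int = 1000
    seed: int = 0
    T: float | None = None  # fixed period when T is not the swept axis
    init: tuple[int, int, int] = (10, 0, 0)
    t_max: float = 1e6
    keep_going: bool = True

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("sweep grid must be non-empty")
        if self.n_rep < 1:
            raise ValueError(f"n_rep must be >= 1, got {self.n_rep}")


@dataclass(frozen=True)
class TransitionLines:
    """Predicted phase boundaries over a grid of drug-strength ratios R.

    ``T_half_kill[k] = 2 tau_S(R[k])`` is the period above which one drug
    phase kills; ``R_appearance`` solves ``tRa = tau_S`` (mode-independent);
    ``R_fast_decay`` is the pure-biocidal fast-alternation criterion
    ``(f_S - g_S)/(2 f_S - g_S)``.
    """

    R: np.ndarray
    T_half_kill: np.ndarray
    R_appearance: float
    R_fast_decay: float

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"R": self.R, "T_half_kill": self.T_half_kill})
        df["R_appearance"] = self.R_appearance
        df["R_fast_decay"] = self.R_fast_decay
        return df


def _cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n_cells)


def _analytic_p0(params: ModelParameters, T: float) -> float:
    """Analytic p0 where the large-period regime applies, else NaN."""
    d = params.rates_drug
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            pred = p0_perfect_biostatic(params) if d.f_S == 0.0 else p0_general(params)
            tau_v = valley_crossing_time(params)
        if pred.tau_S < T / 2.0 < tau_v:
            return pred.p0
    except (ValueError, RuntimeError):
        pass
    return math.nan


def _run_cell(params, T, n_rep, seed, init, t_max):
    config = SimulationConfig(
        params=params,
        schedule=AlternationSchedule(period=T),
        init_S=init[0],
        init_R=init[1],
        init_C=init[2],
        t_max=t_max,
        seed=int(seed),
    )
    return estimate_p0(config, n_rep)


def sweep_p0_vs_T(spec: SweepSpec) -> pd.DataFrame:
    """Simulated (and, in the large-period regime, analytic) p0 per period T."""
    seeds = _cell_seeds(spec.seed, len(spec.values))
    rows = []
    for T, cell_seed in zip(spec.values, seeds):
        row = {"T": float(T), "K": spec.params.K, "cell_seed": int(cell_seed), "status": "ok"}
        try:
            est = _run_cell(spec.params, float(T), spec.n_rep, cell_seed, spec.init, spec.t_max)
            row.update(
                p0=est.estimate,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                n_rep=est.n_rep,
                n_timeout=est.counts["TIMEOUT"],
                mean_t_ext=est.mean_t_ext,
                mean_t_fix=est.mean_t_fix,
            )
        except Exception as exc:  # noqa: BLE001 - per-cell failures are recorded
            if not spec.keep_going:
                raise
            row.update(p0=math.nan, status=f"error: {exc}")
        row["p0_analytic"] = _analytic_p0(spec.params, float(T))
        rows.append(row)
    return pd.DataFrame(rows)


def sweep_p0_vs_K(spec: SweepSpec) -> pd.DataFrame:
    """Simulated and analytic p0 per carrying capacity K at fixed period T."""
    if spec.T is None:
        raise ValueError("sweep_p0_vs_K needs the fixed period spec.T")
    seeds = _cell_seeds(spec.seed, len(spec.values))
    rows = []
    for K, cell_seed in zip(spec.values, seeds):
        params = spec.params.with_(K=float(K))
        row = {"K": float(K), "T": spec.T, "cell_seed": int(cell_seed), "status": "ok"}
        try:
            est = _run_cell(params, spec.T, spec.n_rep, cell_seed, spec.init, spec.t_max)
            row.update(
                p0=est.estimate,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                n_rep=est.n_rep,
                n_timeout=est.counts["TIMEOUT"],
                mean_t_ext=est.mean_t_ext,
                mean_t_fix=est.mean_t_fix,
            )
        except Exception as exc:  # noqa: BLE001
            if not spec.keep_going:
                raise
            row.update(p0=math.nan, status=f"error: {exc}")
        row["p0_analytic"] = _analytic_p0(params, spec.T)
        rows.append(row)
    return pd.DataFrame(rows)


def heatmap_T_R(spec: SweepSpec, R_values: np.ndarray, mode: str) -> pd.DataFrame:
    """Simulated p0 over a (T, R) lattice for one drug mode.

    ``spec.values`` is the T grid.  Biostatic mode varies ``f'_S`` at
    ``g'_S = g_S``; biocidal mode varies ``g'_S`` at ``f'_S = f_S``.
    """
    R_values = np.asarray(R_values, dtype=float)
    if len(R_values) == 0:
        raise ValueError("R grid must be non-empty")
    seeds = _cell_seeds(spec.seed, len(spec.values) * len(R_values))
    rows = []
    k = 0
    for R in R_values:
        params = rates_from_r_ratio(float(R), mode, spec.params)
        for T in spec.values:
            cell_seed = seeds[k]
            k += 1
            row = {
                "T": float(T),
                "R": float(R),
                "mode": mode,
                "cell_seed": int(cell_seed),
                "status": "ok",
            }
            try:
                est = _run_cell(params, float(T), spec.n_rep, cell_seed, spec.init, spec.t_max)
                row.update(p0=est.estimate, ci_low=est.ci_low, ci_high=est.ci_high)
            except Exception as exc:  # noqa: BLE001
                if not spec.keep_going:
                    raise
                row.update(p0=math.nan, status=f"error: {exc}")
            rows.append(row)
    return pd.DataFrame(rows)


def _tau_S_of_R(R: float, mode: str, params: ModelParameters, N0: int) -> float:
    p = rates_from_r_ratio(R, mode, params)
    d = p.rates_drug
    return tau_birth_death_logistic(d.f_S, d.g_S, params.K, N0)


def _t_Ra_of_R(R: float, params: ModelParameters) -> float:
    """Appearance-and-fixation time of a resistant mutant at sub-MIC strength R < 0."""
    if R >= 0:
        return math.inf  # no sub-MIC equilibrium above the MIC
    p = rates_from_r_ratio(R, "biocidal", params)
    d = p.rates_drug
    n_eq = params.K * (1.0 - d.g_S / d.f_S)
    if n_eq < 2:
        return math.inf
    spec = MoranSpec(
        N=n_eq,
        f_resident=d.f_S,
        g_resident=d.g_S,
        f_mutant=d.f_R,
        g_mutant=d.g_R,
    )
    return appearance_fixation_time(n_eq, params.mu1, d.g_S, fixation_probability(spec))


def solve_appearance_threshold(
    params: ModelParameters,
    bracket: tuple[float, float] = (-3.0, -1e-4),
    n_scan: int = 61,
) -> float:
    """Sub-MIC ratio R* where the mutant appearance time equals tau_S.

    Below R* resistance fixes before the population can die out; the
    threshold is the same for biostatic and biocidal drugs because both
    timescales scale as (dimensionless function of R)/g'_S.  Both timescales
    diverge at the bracket edges (no sub-MIC equilibrium near the MIC; no
    practical extinction deep below it), so the bracket is scanned for a
    finite sign change first.  Returns NaN if none exists.
    """
    N0 = equilibrium_start_size(params)

    def gap(R: float) -> float:
        t_ra = _t_Ra_of_R(R, params)
        tau = _tau_S_of_R(R, "biocidal", params, N0)
        if not math.isfinite(t_ra):
            return math.inf  # no mutant supply: extinction side
        if not math.isfinite(tau) or tau <= 0:
            return -math.inf  # extinction unreachable: resistance side
        return math.log(t_ra) - math.log(tau)

    grid = np.linspace(bracket[0], bracket[1], n_scan)
    values = [gap(float(R)) for R in grid]
    for k in range(n_scan - 1):
        a, b = values[k], values[k + 1]
        if math.isfinite(a) and math.isfinite(b) and a * b <= 0:
            return float(brentq(gap, grid[k], grid[k + 1], xtol=1e-6))
    return math.nan


def transition_lines(
    params: ModelParameters, R_values: np.ndarray, mode: str = "biocidal"
) -> TransitionLines:
    """The three predicted phase boundaries over a grid of ratios R."""
    R_values = np.asarray(R_values, dtype=float)
    if len(R_values) == 0:
        raise ValueError("R grid must be non-empty")
    N0 = equilibrium_start_size(params)
    T_line = np.array([2.0 * _tau_S_of_R(float(R), mode, params, N0) for R in R_values])
    nd = params.rates_no_drug
    r_fast = (nd.f_S - nd.g_S) / (2.0 * nd.f_S - nd.g_S)
    return TransitionLines(
        R=R_values,
        T_half_kill=T_line,
        R_appearance=solve_appearance_threshold(params),
        R_fast_decay=r_fast,
    )


def write_outputs(df: pd.DataFrame, csv_path: str | Path, metadata: dict) -> None:
    """Write the CSV table and a JSON metadata sidecar next to it."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(csv_path.suffix + ".meta.json")
    payload = {"software": "pulsedrug", "version": __version__, **metadata}
    sidecar.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, ModelParameters):
        return obj.flat()
    raise TypeError(f"not JSON serializable: {type(obj)}")
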