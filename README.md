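# pulsedrug

Stochastic eco-evolutionary dynamics of a microbial population under a
periodic presence of antimicrobial.

The model tracks three genotypes — sensitive (S), resistant (R) and
resistant-compensated (C) — with logistic division rates `f (1 - N/K)`,
constant death rates, and one-way mutation on division (S→R with probability
`mu1`, R→C with `mu2`). The drug alters only the S rates (biostatic: lower
`f'_S`; biocidal: higher `g'_S`) and follows a square wave of period `T`:
absent on `[kT, kT + T/2)`, present on the second half-period.

The package provides, and cross-validates against each other:

* **an exact event-driven (Gillespie) simulator** (`pulsedrug.gillespie`,
  numba kernel in `pulsedrug._kernel`) that classifies each run as
  extinction vs. fixation of the compensated genotype and estimates the
  extinction probability `p0` with Wilson confidence intervals;
* **analytic predictions**:
  * mean extinction times of the sensitive population with drug —
    harmonic sum for a perfect biostatic drug, banded first-passage solve
    for the general logistic birth-death chain (`pulsedrug.extinction_times`);
  * fixed-size Moran quantities — fixation probabilities, lineage lifetime
    and occupancy decomposition, mutant appearance times, valley-crossing
    time (`pulsedrug.moran`);
  * deterministic drug-phase decay of S and the expected number of divisions
    during it (`pulsedrug.deterministic_dynamics`);
  * branching-process survival of resistant lineages atop the decaying S
    background, and the assembled extinction probability `p0` for perfect
    biostatic and general above-MIC drugs (`pulsedrug.rescue`);
* **figure-level sweeps** — `p0` vs `T`, `p0` vs `K`, `(T, R)` heatmaps with
  predicted transition lines, where `R = (g'_S - f'_S)/g'_S` is the
  drug-strength ratio (zero at the MIC) (`pulsedrug.experiments`).

## CLI

All commands accept a JSON/YAML config file with flat keys
(`fS, fS_drug, fR, fC, gS, gS_drug, gR, gC, K, mu1, mu2, T, init_S, init_R,
init_C, t_max, n_rep, seed`); unknown keys are a hard error; omitted keys
take the documented defaults (perfect biostatic drug, `K = 1000`,
`mu1 = 1e-5`, `mu2 = 1e-3`).

```bash
# one stochastic realization -> TSV trajectory (t, S, R, C, drug_on)
pulsedrug simulate --config cfg.yaml --out traj.tsv --sample-dt 1

# Monte-Carlo extinction probability -> CSV row + JSON sidecar with seeds
pulsedrug estimate-p0 --config cfg.yaml --n-rep 1000 --out p0.csv

# analytics (no simulation)
pulsedrug analytic tau-s --config cfg.yaml
pulsedrug analytic t-threshold --config cfg.yaml       # T* = 2 tau_S
pulsedrug analytic r-threshold --config cfg.yaml --mode biostatic
pulsedrug analytic moran --config cfg.yaml
pulsedrug analytic p0 --config cfg.yaml --mode general # all pieces as JSON
pulsedrug analytic regime --config cfg.yaml

# sweeps (CSV + .meta.json sidecar; every cell reproducible from its seed)
pulsedrug sweep p0-vs-t --config cfg.yaml --t-grid log:10:1e4:8 --fast --out sweep.csv
pulsedrug sweep p0-vs-k --config cfg.yaml --k-grid 100,1000 --out k.csv
pulsedrug sweep heatmap --mode biocidal --t-grid log:1:1e4:9 \
    --r-grid lin:-0.5:0.5:11 --fast --out heat.csv
pulsedrug lines --config cfg.yaml --out lines.csv      # predicted boundaries
```

## Notes

* Simulations are exact: environment switches cap the exponential waiting
  time and the clock is re-drawn under the new rates (valid because
  propensities are piecewise-constant given the state); no tau-leaping.
* Identical seed + configuration reproduces outcomes and trajectories
  bit-for-bit.
* Only **mean** extinction times are computed; extinction-time
  distributions are not (the decaying, far-from-equilibrium population has
  no simple quasi-stationary exponential law, which is why the `T/2 = tau_S`
  boundary slightly overestimates the observed transition).
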