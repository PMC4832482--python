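# beetlesim

Individual-based, spatially explicit simulation of bark-beetle dispersal.
Beetle agents with heterogeneous flight capacity (Gaussian energy budget,
exponential flight efficiency) forage over a gridded forest of
differentially susceptible host trees (5 m x 5 m patches, ~500 ha),
following a correlated random walk until they perceive a sufficiently
attractive host, aggregate under pheromone feedback, and either overwhelm
the tree's resistance threshold or die. A single run simulates one
dispersal wave of 100,000 beetles in 10 staggered cohorts; the package
also ships the replicated scenario experiments (three habitat types x
three individual-variability scenarios) and the emergent-pattern
analytics (distance-class kernels, cohort tables, host selectivity,
colonization-density envelopes, kernel kurtosis).

## Layout

| module                    | contents                                              |
| ------------------------- | ----------------------------------------------------- |
| `beetlesim.habitat`       | lattice forest, PA fields, resistance thresholds      |
| `beetlesim.population`    | trait sampling, variability scenarios S0/S1/S2, cohorts |
| `beetlesim.engine`        | stepping core (numba kernels + reference ops), runs   |
| `beetlesim.experiments`   | scenario matrix, replication, sensitivity grids       |
| `beetlesim.metrics`       | success rates, kernels, cohort/selectivity/density tables |
| `beetlesim.config` / `cli` / `fixtures` | YAML configs, command line, test fixtures |

## Quick start

```python
import beetlesim as bs

result = bs.run_simulation(
    bs.HabitatConfig("resistant"),       # or "scattered" / "susceptible"
    bs.TraitConfig(),                    # Table-style defaults
    "S0",                                # full individual variability
    bs.EngineParams(),                   # calibrated engine defaults
    seed=1,
)
print(result.success_rate)
table = bs.metrics.distance_class_stats(result.beetles, result.trees)
```

Reduced-size runs scale the density parameters alongside the population:

```python
params = bs.EngineParams().scaled(0.1)   # 1/10 population regime
```

## Command line

```bash
beetlesim run  --habitat scattered --scenario S0 --seed 1 --out out/run1
beetlesim metrics --run-dir out/run1 --out out/metrics --plots
beetlesim plan --config plan.yaml --out out/batch      # replicated matrix
beetlesim fixtures --kind tiny_habitat --seed 0 --out out/fx
```

`run` writes `beetles.csv`, `trees.csv` and `summary.json` (config echo,
hash, seed, fate counts); `plan` writes one row per replicate plus a
per-cell mean/min/max aggregate. Config files are flat YAML; CLI flags
override file values; unknown keys are rejected.

## Notes on the engine sub-models

Attack decisions are deterministic: a beetle accepts a host when its
current attractiveness `A` satisfies `A >= 1` and `A >= kappa * E`
(kappa = 0.9), so acceptance relaxes as energy drains. A tree under
attack keeps its kairomone attractiveness until the attackers reach its
resistance threshold (30-200, linear in susceptibility); only then does
the aggregation signal take over (rising with attacker count, ceiling 10,
zero at the 5,000-beetle capacity). Pioneers that fail to attract the
threshold number within the aggregation window (`attack_window`, 300
steps) die to host resistance and the tree re-opens. All of these are
configuration hooks on `EngineParams`; the simpler constant-pheromone /
end-of-wave-resolution variants remain available
(`pheromone_trigger="first_attacker"`, `pheromone_gain=inf`,
`attack_window=inf`, `target_preference="attractiveness"`).
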