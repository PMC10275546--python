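# phylou

Ornstein–Uhlenbeck adaptation models on phylogenies: regime paintings,
grid-ML/GLS fitting with observation error, the Brownian-trend limit,
Mk models with stochastic character mapping, AICc model search, and
simulators for end-to-end testing.

The package fits models of the form

```
y = b·x + u,     du = -α (u − θ(z, g)) dt + σy dBy
```

where the response `y` (e.g. log endocranial volume) adapts at rate
`α = ln 2 / t½` toward an optimum determined by categorical selective
regimes `z` painted on the phylogeny and, optionally, by a
Brownian-motion predictor `g` (e.g. log group size), with a direct
(instantaneous) effect `b` of a second predictor `x` (e.g. log body mass).
Conditionally on the phylogenetic half-life `t½` and the stationary
variance `Vy = σy²/(2α)`, coefficients are estimated by generalized least
squares; `(t½, Vy)` are estimated by maximum likelihood on a log-spaced
grid with local refinement and 2-log-likelihood-unit support sets.  As
`t½ → ∞` the model becomes Brownian motion with regime-specific
deterministic trends, fitted as an explicit boundary case.  Observation
error enters through the squared standard errors of species means (for the
response, and `b²`-scaled for direct-effect predictors, iterated to
convergence).

## Library quick tour

```python
import phylou as p

tree = p.scale_to_unit_height(p.read_tree("tree.nwk"))
table = p.load_species_table("species.csv")

# paint a discrete predictor via an AICc-chosen Mk model + MAP states
from phylou.mk_regimes import fit_mk, map_painting
tips = table.data["mating_system"].to_dict()
painting = map_painting(fit_mk(tree, tips, "auto"), tree, tips)

spec = p.ModelSpec(response="log_ecv", direct=("log_mass",),
                   bm=("log_group_size",), regimes={"mating": painting})
fit = p.profile_fit(spec, tree, table)
print(fit.summary())

allom = p.profile_fit(p.ModelSpec(response="log_ecv",
                                  direct=("log_mass",)), tree, table)
print(p.model_metrics(fit, allom))          # R², residual R², ΔAICc
print(p.contrast(fit, "polygynandry", "spatial_polygyny"))
print(p.effect_transform(1.11, "percent"))  # 303.2...
```

Simulated bundles with the exact statistical structure the estimator
assumes (trees, Mk regimes, Brownian predictors, OU/trend response,
species-mean observation error):

```python
bundle = p.generate_study_like(n_tips=128, seed=1)
bundle.write("out/bundle")   # tree.nwk, data.csv, SIMMAP paintings, config
```

## Command line

```bash
phylou simulate --preset primate --n-tips 128 --seed 1 --out out/bundle
phylou fit    --tree out/bundle/tree.nwk --data out/bundle/data.csv \
              --formula "log_ecv ~ direct(log_mass) + bm(log_group_size) + regime(diet*mating_system)" \
              --seed 1 --out out/fit
phylou search --tree out/bundle/tree.nwk --data out/bundle/data.csv \
              --formula "log_ecv ~ direct(log_mass)" \
              --pool "regime:diet,regime:mating_system,bm:log_group_size" \
              --exclude "mating_system|social_system" \
              --seed 1 --out out/search
phylou simmap --tree out/bundle/tree.nwk --data out/bundle/data.csv \
              --column diet --nmaps 100 --seed 1 --out out/maps
phylou report --fits out/search --out out/report
```

Grids are configurable with `--grid-thalf lo,hi,n` (tree heights) and
`--grid-vy lo,hi,n` (multiples of the response variance).  Every run
writes `provenance.json` (config + seed + version).  Validation failures
(e.g. species in the data but not on the tree) exit with status 2 and name
the offending species.

## Layout

- `src/phylou/phylo_io.py` — trees (Newick/NEXUS via dendropy), unit-height
  scaling, regime paintings (child-state convention), lineage epochs,
  shared-time/distance matrices, diet/group-size coding, species tables
- `src/phylou/mk_regimes.py` — Mk likelihood (Felsenstein pruning),
  ER/SYM/ARD fits with AICc, marginal/MAP ancestral states, stochastic
  character maps (uniformization)
- `src/phylou/ou_engine.py` — regime weights, design matrices, residual
  covariances (incl. the Brownian-predictor adaptation-lag term),
  GLS, grid profile likelihood, support sets, metrics, contrasts,
  effect transforms
- `src/phylou/model_search.py` — exhaustive AICc search with exclusion sets
- `src/phylou/synthetic_data.py` — pure-birth trees, BM/Mk/OU simulators,
  observation error, study-like bundles (also the Monte-Carlo oracle used
  by the tests)
- `src/phylou/cli.py` — `phylou` entry point
- `scripts/acceptance.py` — acceptance report
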