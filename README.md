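# ttrsdm

Process-based species distribution modelling with inverse parameter
estimation, a maxnet-style correlative baseline, and a transferability
evaluation battery — exercised end-to-end on synthetic *virtual species*.

## The problem

Correlative species distribution models (SDMs) such as MaxEnt describe the
statistical association between occurrence records and environmental
covariates. They usually fit the training region very well, but their
response surfaces are unconstrained wherever the environment is novel, so
predictions *transfer* poorly to regions — or future climates — whose
conditions fall outside the training domain. Process-based SDMs instead
predict occurrence from simulated ecological mechanism. This package
implements such a model: plant growth is simulated with a
transport-resistance (shoot/root, carbon/nitrogen substrate) growth model
whose uptake, growth and respiration rates respond to monthly temperature,
soil moisture, solar radiation and soil nitrogen through bounded [0, 1]
modifiers — trapezoids and saturating ramps combined by Liebig's law of the
minimum. The model is run forward under the repeating seasonal cycle until
biomass reaches a steady state `B*`, and

```
P(present) = 1 − exp(−B*/φ)
```

(a complementary log-log link) turns steady-state biomass into occurrence
probability. The physiological parameters (29 in the standard variant) are
*inversely estimated* from presence/pseudoabsence data by maximizing the
Bernoulli likelihood with a differential evolution (DE) genetic algorithm.
A second variant replaces the eight estimated photosynthesis responses with
a fixed Farquhar-type C3 photosynthesis model (von Caemmerer constants,
ambient CO2 = 338 ppm), leaving 21 free parameters.

Because real multi-region occurrence data cannot ship with a package, the
experiment runs on virtual species: a synthetic climate grid with a
training (native) and a test (adventive) region, and species whose true
occurrence probability is generated by a known parameterization of the same
growth model. A `novelty_strength` knob controls how far the test region's
environment departs from the training domain (measured by the NT2
Mahalanobis novelty index; values above 1 flag extrapolation).

## Worked example

```python
from ttrsdm import (generate_environment, default_true_params,
                    make_virtual_species, sample_occurrences,
                    MaxnetSDM, TTRSDM, auc)
from ttrsdm import background
import pandas as pd

grid = generate_environment(60, 40, novelty_strength=2.0, seed=1)
species = make_virtual_species(grid, default_true_params(grid))
presences = sample_occurrences(species, grid, n_presence=150, seed=1)
zones = background.cluster_environments(grid.env_table(), k=24, seed=1)
pseudo = background.sample_pseudoabsences(grid, zones,
                                          n_total=len(presences), seed=1)
occ = pd.concat([presences, pseudo.drop(columns="zone")], ignore_index=True)
X, y = grid.forcing(occ["cell"].to_numpy()), occ["presence"].to_numpy()

correlative = MaxnetSDM(random_state=1).fit(X, y)
process = TTRSDM(variant="standard", random_state=1).fit(X, y)

is_tr = (occ["region"] == "training").to_numpy()
for name, model in [("maxnet-like", correlative), ("ttr-standard", process)]:
    print(name, round(auc(model.predict_suitability(X[is_tr]), y[is_tr]), 3))
```

prints

```
maxnet-like 0.966
ttr-standard 0.839
```

— the correlative model describes the training data better (it is free to
fit any response surface), which is one half of the story. The other half
appears in the test region: running the full experiment
(`ttrsdm experiment --out run/` or `ttrsdm.pipeline.run_experiment`) over
ten virtual species yields mean AUC values like

```
                training   test
maxnet-like        0.976   0.920
ttr-standard       0.909   0.930
```

together with a random-intercept logistic regression of per-record
correctness on NT2 novelty whose slope is markedly more negative for the
correlative model (about −3.4 versus −1.2): the correlative model's skill
collapses precisely where the environment is novel, while the process
model's mechanistic structure degrades gracefully.

The `ttrsdm` command-line tool exposes every stage: `simulate` (grid +
virtual species + occurrences as CSV), `fit` (any of `maxnet-like`,
`ttr-standard`, `ttr-farquhar`; refuses species with fewer than 15 presence
cells), `evaluate` (confusion-matrix metrics, TSS, AUC at the
max-sensitivity+specificity threshold) and `experiment` (the whole battery,
YAML-configurable).

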