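# nichevar

Individual-specialisation analysis for replicated resource-use count
data, built around a 2×2 mesocosm experiment crossing interspecific
competition with perceived predation risk in a generalist fish.

Most populations of "generalists" are collections of partial
specialists: each individual uses only a subset of the resources its
population uses. `nichevar` quantifies that phenomenon from repeated
per-individual counts (stomach-content items from serial gastric
lavage, microhabitat scan sightings) and tests how antagonistic
interactions reshape it. It is written for ecologists analysing
replicated tank or enclosure experiments, but every statistic operates
on a plain individuals × categories count matrix.

## The statistics

For one population with counts `n_ij` (individual *i*, category *j*),
let `p_ij` be individual proportions, `p_i.` each individual's share of
the population total, `q_j` the pooled proportions and
`γ_ij = n_ij / n_.j`. The total niche width partitions additively
(Shannon entropies in nats):

    TNW = H(q)                      total niche width
    WIC = Σ_i p_i. · H(p_i,·)       within-individual component
    BIC = H(p_.) − Σ_j q_j H(γ_·,j) between-individual component
    WIC + BIC = TNW

The index of individual specialisation is `1 − WIC/TNW` (0 = identical
generalists, 1 = pure one-category specialists), tested per population
against a stochastic-generalist Monte Carlo null that redraws every
individual's counts from the pooled proportions at its observed sample
size. Treatment effects are assessed at two levels:

* **composition** — tank mean proportions → Bray–Curtis
  dissimilarities → two-way PERMANOVA (sequential SS, free
  permutations), homogeneity-of-dispersion test on distances to group
  centroids, SIMPER category contributions, and NMDS ordination with
  Kruskal stress-1;
* **niche components** — 2×2 factorial ANOVA on `1 − WIC/TNW`, WIC,
  BIC, TNW per tank, with Type III SS for the interaction, Type II for
  main effects when the interaction is absent, partial eta squared, and
  Tukey HSD cell comparisons with a compact letter display.

A Dirichlet-multinomial generator simulates whole experiments
(36 tanks, 4 fish each, realistic sampling effort, empty stomachs,
mortality-driven attrition) with controllable specialisation and
treatment effects, so the entire chain is testable without any data
download. See `docs/methods.md` for the full model description.

## Worked example

The numbered scripts under `analysis/` run the full study pipeline on a
simulated experiment:

```bash
python analysis/01_simulate_experiment.py   # writes data/synthetic/
python analysis/02_niche_components.py      # WIC/BIC/TNW + null tests
python analysis/03_composition_analysis.py  # PERMANOVA, SIMPER, NMDS
python analysis/04_factorial_anova.py       # 2x2 ANOVA + Tukey HSD
```

Output of steps 2–3 for the default seed:

```
diet: 21/36 tanks retained, mean 1-WIC/TNW = 0.276, 6 tanks with significant specialisation
habitat: 36/36 tanks retained, mean 1-WIC/TNW = 0.226, 30 tanks with significant specialisation
diet: competition pseudo-F = 4.57 (R2 = 0.20, p = 0.002)
diet: top SIMPER category 'Chydorus spp.' (26% of between-group BC)
diet: NMDS stress = 0.117
habitat: competition pseudo-F = 8.70 (R2 = 0.20, p = 0.001)
habitat: NMDS stress = 0.174
```

Reading this: attrition left 21 of 36 tanks usable for diet; the mean
specialisation index 0.276 indicates low-to-moderate diet IS; the
PERMANOVA shows competitor presence shifted population diet composition
(p = 0.002), driven most by the chydorid cladoceran category; and the
2-D ordination represents the Bray–Curtis structure well
(stress ≈ 0.12). Step 4 then prints the factorial table per niche
component; in this particular realisation the habitat index shows the
competition × predation interaction (predation lowers habitat IS only
when the competitor is absent — Tukey letters `a b a a`) while the diet
index effect, detected in ~83% of simulated experiments at these
settings, happens to fall short of significance — per-realisation
sampling variability the simulator makes visible.

The same pipeline runs from the command line (`nichevar simulate`,
`nichevar analyze`, `nichevar components`, `nichevar nullmodel`,
`nichevar permanova`), and `nichevar replicate <dir>` compares a
user-supplied copy of the original experiment's deposited records
side-by-side with its published headline values (no data are
downloaded; the expected files are `diet.csv`, `habitat.csv`,
`design.csv` with a YAML column mapping for other layouts).

As a library:

```python
import numpy as np
from nichevar import decompose, monte_carlo_test

counts = np.array([[3, 1], [1, 3]])          # 2 fish x 2 prey taxa
c = decompose(counts)
# WIC=0.562, BIC=0.131, TNW=0.693, 1-WIC/TNW=0.189
res = monte_carlo_test(counts, n_reps=999, seed=1)
print(c.is_index, res.p_value)
```

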