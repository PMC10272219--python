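# herbivar

Quantifying inter- and intra-forest variability in insect herbivory from
leaf-census data, using the damage-type (DT) system shared by paleobotanical
and modern leaf studies.

Leaf-litter and fossil-leaf censuses record, for every leaf, its plant taxon
and the morphologically distinct insect feeding damage types it carries
(e.g. DT12), each mapped to a functional feeding group (FFG: hole, margin,
skeletonization, surface, piercing-and-sucking, gall, mine) and a
generalized/specialized class.  `herbivar` turns such censuses — real or
simulated — into the quantitative summaries used to compare forests and the
depositional environments and quarries within them:

- **Herbivory metrics** per quarry: damage frequency (fraction of leaves
  with damage of a given class), DT diversity rarefied analytically to a
  standard leaf count *n* via E[S] = Σ_d [1 − C(N−m_d, n)/C(N, n)], plant
  Shannon diversity *H* and Pielou evenness *J = H/ln S*, and the
  empirical-logit transform of frequencies.
- **Probabilistic co-occurrence** of DT pairs at the leaf level: the joint
  count against the exact hypergeometric law
  P(j) = C(N₁, j)·C(N−N₁, N₂−j)/C(N, N₂), classified
  positive/negative/random at a two-tailed α without any randomization.
- **Bootstrap bipartite plant–DT networks** per quarry (resampled to 300
  leaves without replacement, 500 reps): connectance, binary NODF
  nestedness, partner diversity of plants, robustness of DTs to random
  plant removal (area under the secondary-extinction curve), and the
  standardized two-dimensional Shannon specialization
  H2′ = (H2max − H2)/(H2max − H2min) ∈ [0, 1], plus node-level DT degree.
- **Ordination and group tests**: Bray–Curtis dissimilarities on FFG or
  plant composition, non-metric multidimensional scaling (Kruskal
  stress-1), ANOSIM with R = (r̄_between − r̄_within)/(N(N−1)/4), Rosner
  (GESD) outlier screening and Tukey–Kramer comparisons across forests.
- A **synthetic census generator** emulating a three-forest study design
  (two temperate forests plus one wet-tropical forest with a disjoint plant
  pool; 3–4 depositional environments per forest, three ~400-leaf replicate
  quarries per environment) with hierarchical-Dirichlet plant composition,
  generalist/specialist DT host ranges, and an optional *Lymantria
  dispar*-style outbreak scenario that concentrates surface and hole
  feeding on a preferred host.

## Worked example

```python
import pandas as pd
from herbivar import default_study_config, generate_census, aggregate
from herbivar.metrics import metrics_table
from herbivar.community import anosim, bray_curtis, composition_table
from herbivar.networks import bootstrap_networks

census = generate_census(default_study_config(seed=1))
print(census)
# Census(11200 leaves, 28 quarries, 45 DTs)

table = metrics_table(census, n_std=300)
print(table[["forest", "env", "quarry", "n_leaves", "freq_total",
             "freq_specialized", "div_total", "plant_shannon"]].head(4))
#            forest   env quarry  n_leaves  freq_total  freq_specialized  div_total  plant_shannon
# temperate_coastal river     Q1       400       0.730             0.110     35.815          2.014
# temperate_coastal river     Q2       400       0.708             0.078     33.633          2.046
# temperate_coastal river     Q3       400       0.680             0.092     31.516          1.895
# temperate_coastal swamp     Q1       400       0.725             0.088     33.080          1.784
```

Each row summarizes one ~400-leaf quarry: here roughly 70% of leaves carry
some insect damage, ~9–11% carry specialized damage, and a standardized
300-leaf subsample is expected to contain ~32–36 distinct damage types.

Plant communities separate cleanly by forest (the tropical pool shares no
species with the temperate pools), which ANOSIM picks up:

```python
plant = composition_table(census, "plant")
res = anosim(bray_curtis(plant), plant["forest"], n_perm=999, seed=1)
print(round(res.R, 3), res.p)   # 0.999 0.001
```

And one quarry's bootstrap-standardized network metrics (300 leaves x 100
reps):

```python
view = aggregate(census, "quarry")[("temperate_inland", "swamp", "Q1")]
br = bootstrap_networks(view, sample_size=300, n_boot=100, seed=1)
print(br.reps.mean().round(3))
# connectance           0.444
# nodf                 63.433
# partner_diversity     2.196
# robustness            0.729
# h2prime               0.174
```

The same operations are available from the shell:

```sh
herbivar simulate --seed 1 --out sim/
herbivar metrics sim/census.csv sim/catalog.csv --n-std 300 --out metrics.csv
herbivar run --simulate --seed 1 --out run/
herbivar outbreak-experiment --n-seeds 20 --seed 0 --out exp/
```

`herbivar run` writes every stage's CSV plus a JSON manifest recording
seeds and parameters; identical config and seed reproduce byte-identical
artifacts.  `herbivar outbreak-experiment` runs paired outbreak/control
simulations and tabulates, per seed and forest, mean bootstrap H2′,
connectance and total damage frequency — the outbreak shows up as elevated
H2′ in the target forest while total damage frequency barely moves.

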