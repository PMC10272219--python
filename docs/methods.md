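# Methods

## Data model

A census is a set of leaves organized as forest → depositional environment →
quarry → leaf.  Each leaf carries a plant-taxon assignment and a map of
damage-type (DT) incident counts; occurrence of a DT on a leaf is presence of
the key (a 0/1 view derived from the counts), abundance is the count itself
(≥ 1).  Undamaged leaves are stored as rows with no DT so that frequency
denominators are leaves censused, not leaves damaged.  A DT catalog maps each
code to one of seven functional feeding groups (hole, margin,
skeletonization, surface, piercing-and-sucking, gall, mine) and a
generalized/specialized class; the class is input metadata, not inferred.
Duplicate (leaf, DT) rows are summed on ingest, consistent with
incident-count semantics.  Field-level scoring rules (e.g. requiring a
thickened reaction rim to accept chewing damage) are assumed applied
upstream; every recorded incident is treated as valid.

Quarries with fewer leaves than the standardization size (default 300) are
excluded before rarefaction and network bootstrapping, with the removed
quarries and their counts reported.

## Herbivory metrics

Damage frequency for a selector (total, generalized/specialized, or one FFG)
is the fraction of leaves bearing at least one matching DT; a leaf counts
once regardless of incident counts.  DT diversity is standardized for uneven
sampling by analytic sample-based rarefaction to n leaves:

    E[S] = Σ_d [ 1 − C(N − m_d, n) / C(N, n) ],

where m_d is the number of leaves bearing DT d.  This is exactly the mean
richness over all equally likely n-leaf subsets (subsampling without
replacement), evaluated with log-gamma binomials for numerical safety, and
is deterministic; a Monte-Carlo subsampling mode is retained purely as a
cross-check.  Plant diversity is Shannon H in nats on leaf shares per taxon;
evenness is Pielou J = H / ln S, reported as NaN when a single taxon is
present.  Natural logarithms are used throughout.  The logit transform
log[p/(1−p)] replaces boundary frequencies p ∈ {0, 1} by the empirical
adjustment (p(n−1) + 0.5)/n using the view's leaf count, so boundary
quarries stay finite; the adjustment is part of the function contract.

## Probabilistic co-occurrence

For two DTs on N₁ and N₂ of a forest's N leaves, the joint count under
independent random placement is hypergeometric,
P(j) = C(N₁, j) C(N−N₁, N₂−j) / C(N, N₂).  Both tail probabilities include
the observed count; a pair is positive when P(J ≥ j_obs) < α, negative when
P(J ≤ j_obs) < α (default α = 0.05), otherwise random.  The sampling unit is
the leaf — no quarry- or site-level unit is offered, avoiding ambiguity.
Pairs whose expected joint count N₁N₂/N falls below 1.0 are excluded (the
usual convention for this model) and recorded; DTs occurring on a single
leaf can be dropped.  The reported effect size is (j_obs − expected)/N, the
per-leaf excess co-occurrence; DTs present on every leaf admit no variation
and are forced to the random class with a diagnostic.  Tail probabilities
come from `scipy.stats.hypergeom`; classification is validated against
exhaustive placement enumeration for N ≤ 12.

## Bipartite networks

Each quarry's network has plant taxa as rows, DTs as columns, and summed
incident counts as edge weights; taxa or DTs with zero marginals are
dropped and orders are lexicographic so outputs are deterministic.

- **Connectance**: realized links / (rows × columns) on the binary view.
- **Nestedness**: binary NODF — for every ordered pair of rows (and of
  columns) with strictly decreasing fill, the percentage of the
  smaller-fill line's links shared with the larger; averaged over all row
  and column pairs, 0–100.  NODF was chosen over matrix temperature because
  its orientation (higher = more overlapping, generalized structure)
  matches the interpretation the analyses rely on.
- **Partner diversity (plants)**: mean over plant rows of the Shannon
  entropy of the row's normalized weights.
- **Robustness (DTs)**: plants are removed in random order; a DT survives
  while at least one host remains.  Robustness is the trapezoid area under
  the mean curve of surviving DT fraction vs fraction of plants removed
  (anchored at y₀ = 1, y_P = 0).  All P! orders are enumerated for P ≤ 6;
  otherwise 100 random orders are averaged.  A complete network with P
  plants gives exactly 1 − 1/(2P).
- **H2′**: with p_ij = a_ij/m, H2 = −Σ p_ij ln p_ij.  H2max is the entropy
  of an integer matrix as close as possible to the independence expectation
  r_i c_j/m (floor, then assign remaining units to the admissible cell with
  the smallest count — cell entropy is separable concave, so that cell has
  the largest marginal gain — breaking ties by fractional remainder).
  H2min comes from a greedy concentration fill that repeatedly allocates
  min(remaining row, remaining column) to the currently largest marginals.
  H2′ = (H2max − H2)/(H2max − H2min), clipped to [0, 1].  Both fills are
  heuristics in general; they are exact on 2×2 matrices (verified against
  exhaustive enumeration of all marginal-preserving integer matrices with
  total ≤ 8), and clipping absorbs residual slack on larger matrices.
  Degenerate matrices (one row/column, total weight < 2, or
  H2max = H2min) return NaN rather than a fabricated value.

To standardize sampling effort, each quarry is bootstrapped: 300 leaves
drawn without replacement, network rebuilt, metrics recomputed, 500 times
by default.  Reps whose resampled matrix degenerates are counted and
skipped in summaries.  One seed drives both the leaf draws and the
robustness removal orders, and is logged in every output.  DT degree
(number of host taxa with positive weight, per quarry) is reported at the
node level with FFG annotation, with an optional recomputation dropping
single-leaf DTs.

## Community statistics

Quarry compositions are either FFG profiles — the fraction of leaves
bearing each FFG, deliberately not renormalized since a leaf can carry
several FFGs — or plant profiles (leaf shares, summing to 1).  Bray–Curtis
is the default dissimilarity for composition data; NMDS (non-metric MDS
minimizing Kruskal stress-1 with isotonic regression, best of 20 random
restarts, `sklearn.manifold.MDS` as the optimizer) and ANOSIM consume the
same matrix.  ANOSIM ranks all N(N−1)/2 dissimilarities with average ranks
on ties; R = (r̄_between − r̄_within)/(N(N−1)/4) is exactly 1 for complete
separation.  The permutation p-value enumerates all distinct label
arrangements when there are at most 10,000, otherwise uses 999 random
permutations with the (1 + hits)/(1 + n_perm) estimate.  Forests with
disjoint plant pools should be ordinated separately — their between-forest
Bray–Curtis distances are identically 1 and carry no gradient information.

Rosner's generalized extreme Studentized deviate test screens quarry-level
metric vectors: iteratively remove the value farthest from the mean,
compare R_i = max|x − x̄|/s against λ_i = (n−i) t_{p,n−i−1} /
√((n−i−1+t²)(n−i+1)) with p = 1 − α/(2(n−i+1)); the declared outliers are
the largest prefix with R_i > λ_i.  Which metrics are screened, and k_max,
are exposed as explicit options rather than hard-wired.  Cross-forest mean
comparisons use Tukey–Kramer studentized-range tests with pooled
within-group variance and the unbalanced-size correction
(`scipy.stats.studentized_range` supplies the distribution; p-values agree
with `scipy.stats.tukey_hsd` to 1e-9).

## Synthetic censuses

The generator emulates the hierarchical study design the analyses assume.
The packaged configuration has three forests: a temperate-inland forest
with the smallest plant pool (8 taxa) and four depositional environments
(swamp, tributary, river × 3 quarries each, plus one upland quarry), a
temperate-coastal forest (14 taxa, sharing several species with the inland
pool), and a wet-tropical forest (25 taxa, disjoint from both temperate
pools) — 28 quarries of 400 leaves, 11,200 leaves in all.

Plant composition is hierarchical-Dirichlet: the environment draws its
composition around the forest pool with concentration `env_shift` (default
10 — environments differ visibly), and each quarry redraws tightly around
its environment (`quarry_shift`, default 150), so quarries within an
environment are compositionally closer to each other than to other
environments.  This is the simplest generative structure that reproduces
the within-forest clustering ANOSIM should detect.

The 45-DT pool spans all seven FFGs with fixed (seedless) parameters:
generalists get host breadth 0.7–1.0 and per-leaf occurrence 0.02–0.12;
specialists (all mines, most galls) get breadth 0.08–0.2 and occurrence
0.01–0.06.  Host sets are a fixed pseudo-random subset per (forest, DT) —
not redrawn per leaf — so specialists are consistently specialized and
degree/H2′ structure can emerge.  Aggregate rates put total damage
frequency near 70%, a realistic value for temperate/tropical leaf-litter
censuses.  Incident counts are zero-truncated Poisson (the configured
`abundance_mean` is the pre-truncation rate λ), keeping occurrence and
abundance as separate processes and precluding occurrence-with-zero-count
contradictions.  Piercing-and-sucking occurrence is multiplied by a
preservation discount (default 0.5) reflecting its bias in
sediment-derived assemblages.

Every (stage, forest, environment, quarry, DT) draws from its own
seed-derived stream, so identical seeds give byte-identical censuses and
toggling one component never shifts another's draws.  Each DT consumes a
fixed number of uniforms per quarry regardless of its occurrence
probability, so two runs sharing a seed but differing only in rates (e.g.
outbreak vs control) remain coupled draw-for-draw — the paired outbreak
experiment is a genuine common-random-numbers design.

**Outbreak scenario.**  An outbreak elevates two generalized DTs (one
surface, one hole — the feeding signature of early- vs late-instar
defoliating caterpillars) by ×12 on one preferred host (*Quercus rubra* in
the temperate-inland forest) and ×2 on other permitted hosts.  The
intensity values are free parameters, not estimates of any real outbreak;
they were fixed once at values that concentrate a noticeable minority
(~10–15%) of incident mass on the preferred host, the regime of interest
for the detection question.  Because the elevated DTs start at low baseline
occurrence (0.02) and most leaves already carry other damage, the outbreak
barely moves total damage frequency (≈ 2–3 percentage points) while
concentrating network weight — specialization should register in H2′, not
in frequency, and the paired experiment (20 seeds, 300-leaf × 100-rep
bootstraps) checks exactly that.

### What the generator does not emulate

Real leaf assemblages carry taphonomic structure the generator omits:
differential transport and fragmentation by depositional energy, leaf-size
and taxon-specific preservation bias (beyond the single
piercing-and-sucking discount), multi-season time-averaging, and
correlations between DTs on a leaf beyond those induced by shared hosts
(the generator draws DTs independently given the taxon).  Passing tests on
synthetic data therefore demonstrate that the estimators recover known
generative structure — not that any particular field dataset has that
structure.

## Numerical choices and scale

Rarefaction and co-occurrence use log-gamma binomial coefficients, safe to
N ≈ 4,000 leaves.  Bootstrap incidence matrices are assembled from a
CSR-style incident layout, so a 300-leaf rep costs about a millisecond.
The packaged outbreak experiment uses 100 bootstrap reps per quarry (the
package default elsewhere is 500): the Monte-Carlo standard error of a
quarry's mean H2′ scales as 1/√n_boot and is already an order of magnitude
below the outbreak effect at 100 reps, and the experiment averages over 10
quarries and 20 seeds on top.  ANOSIM calibration and null checks in the
test suite use fixed seeds; all stochastic APIs take explicit seeds and
derive independent streams from them.

## Known limitations

- H2max/H2min fills are heuristic beyond 2×2; H2′ can touch the clip
  boundaries on extreme matrices.
- NMDS inherits the local-minimum behavior of iterative stress
  minimization; restarts mitigate but do not eliminate it.
- The co-occurrence model conditions on per-DT totals and assumes
  exchangeable leaves within a forest; strong within-quarry clustering can
  inflate significance.
- Mixed-effects modelling of metric ~ latitude/diversity relationships is
  deliberately out of scope; the per-quarry metric tables are designed to
  feed such models in external tooling.
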