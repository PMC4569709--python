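# Methods

`codaclans` simulates the cultural transmission of coda repertoires in a
population of female sperm whales and asks, with network statistics, under
which learning regimes the population partitions into vocal clans — the
upper tier of the species' multilevel society. This note documents the
model, its parameters, the analysis stack, and the design choices made where
the underlying biology or published modelling literature leaves the form
open.

## 1. Demographic model

The population contains only females (males are quasi-solitary and rarely
produce codas). Each agent carries an age in years, a social-unit label, an
optional predefined-clan label, and a repertoire: a vector of 62 coda-type
usage frequencies, each in [0, 100] (0 = never produced, 100 = always
produced). A year consists of, in order: births, repertoire composition by
calves, unit-membership changes (migration), deaths, unit splitting, ageing.

**Initialization.** `N0` agents (default 1,000) receive ages from a negative
exponential distribution (mean 15 y, truncated at 70 y), so the starting
population is mostly young. Agents are dealt by random permutation into
`round(N0/12)` near-equal social units (12 is the average Pacific unit
size); dealing rather than i.i.d. labelling keeps the realized maximum
initial unit size near the mean, so the split threshold (below) is ~24
rather than an artifact of multinomial extremes. Each initial repertoire has
half its elements (31 of 62) filled with uniform draws from [0, 100];
repertoires of agents aged 3+ are then frozen.

**Mortality.** Adult mortality is senescent: the yearly hazard is Gompertz,
`mu(a) = mu0 * exp((a-3)/s)` with e-folding scale `s = 10` y (a
mammal-typical hazard-doubling time of ~7 y). The baseline `mu0` is solved
by bisection so that the expected age at death of an agent surviving
calfhood equals `mean_lifespan` (default 70 y). Calves (ages 0–2) die at
`calf_mortality_multiplier` (default 3) times the reference rate
`1/(mean_lifespan-2)`, i.e. ~4.4%/y. All hazards are multiplied by the
density factor `(N/K)^theta` (default `theta = 1`), which stabilizes the
population around the carrying capacity `K = N0`. A senescent rather than
constant adult hazard concentrates death ages around the target lifespan;
with a constant hazard the death-age distribution is geometric (sd ≈ 67 y)
and the mean age at death *observed within a 700-year window* is biased
downward by ~9 y through right-censoring of late cohorts. With the Gompertz
schedule the window-measured mean is ~68 y against the 70 y expectation.

**Births.** Females reproduce between ages 9 and 41 (inclusive) with a
constant yearly probability solved from the stationary age structure so that
births balance deaths at `N = K` (≈ 0.036/y under defaults). Calves start in
the mother's unit with an empty repertoire.

**Migration.** Adults move to a uniformly chosen other unit with yearly
probability `c * exp(-(a-3)/35)`: exactly `c = 0.05` for the youngest
adults, declining smoothly with age. Calves never migrate on their own and
follow a migrating mother. Agents moving into a unit adopt its predefined
clan label, so clan-level scenarios experience realistic mixing.

**Unit splitting.** A unit reaching twice the maximum initial unit size
(≈ 24) splits into two random near-equal halves, with mothers and their
dependent calves kept together (the matrilineal atom); the daughter unit
inherits the parent's clan label and symbolic marker. Splits run after
deaths, before year-end bookkeeping.

## 2. Transmission scenarios

Calves compose their repertoire once a year at ages 0, 1 and 2; at age 3 it
is fixed for life. Twenty scenarios combine three mechanisms, three biases
and three social levels:

| ABM | mechanism | biases | level |
|----:|-----------|--------|-------|
| 1 | individual learning | — | — |
| 2 | genetic / vertical | — | — |
| 3–5 | oblique | — | population / unit / predefined clan |
| 6–8 | oblique | homophily | " |
| 9–11 | oblique | conformism | " |
| 12–14 | oblique | symbolic marking | " |
| 15–17 | oblique | homophily + conformism | " |
| 18–20 | oblique | homophily + symbolic | " |

**Individual learning** re-draws 31 random elements from U[0, 100] each
calf-year. **Genetic inheritance** copies the mother's full repertoire at
age 0 (founding calves without recorded mothers keep their initialization).
**Oblique learning** fills all 62 elements at age 0, each element copied
(zeros included) from an independently drawn adult tutor of the pool; at
ages 1–2 a third of the elements (21) are re-sampled the same way. Adults
are agents aged 3+; the pool is the calf's unit, its predefined clan, or the
whole population according to the scenario level. In all scenarios each calf
additionally innovates: `round(62 * ilearn)` random elements (exactly 1 at
the default `ilearn = 0.02`) are replaced by uniform draws each calf-year.

**Conformism.** The published description — calves disproportionately copy
the most common coda types — fixes the direction but not the functional
form. We implement it on the re-sampling step: the elements to refresh are
chosen with probability proportional to `(pool mean frequency)^alpha`
(default `alpha = 2`), and each chosen element adopts the pool's consensus
usage (the rounded pool mean). At `alpha = 0` the element selection is
uniform and the update degrades gracefully toward unbiased oblique learning.

**Homophily.** Behaviourally similar units preferentially interact, so a
homophilous calf's tutor pool is the adults of its own unit together with
those of the single other unit whose mean repertoire (members with nonempty
repertoires, snapshotted at the start of the learning phase) is most similar
to its own unit's; ties break uniformly at random, and at the
predefined-clan level the candidate units are restricted to the calf's clan.
Including the calf's own unit makes paired units converge on a shared
consensus rather than swap repertoires; using the single most-similar unit
(rather than a similarity-weighted sample) follows the natural reading of
"the unit with the highest repertoire similarity". When no other unit holds
adults, the plain level pool is used; if that is empty too, the calf falls
back to individual learning for the year (logged at debug level).

**Symbolic marking.** At year 1 every unit receives a random badge of 6
distinct coda types; all members' frequencies at those types are set to 100,
and every later calf of the unit ends each learning year with the badge
enforced at 100 (enforcement runs after innovation so the invariant "badge
codas are always at 100 after learning" holds exactly). Daughter units keep
the parent's badge; badges are never re-drawn. Adults never relearn badges,
so a migrant carries its natal badge for life — only its calves adopt the
new unit's badge.

## 3. Acoustic similarity and clan detection

Unit repertoires are compared by the adjusted weighted Bray–Curtis
similarity between unit mean repertoires,

    S(x, y) = 1 − Σ|x_i − y_i| / Σ(x_i + y_i),

which is 1 for identical and 0 for disjoint repertoires (undefined, and an
error, for two empty ones). The acoustic network is the complete weighted
graph on units with these similarities as link weights (an optional weight
floor drops weak links). Clans are modules of this network: the Walktrap
algorithm (python-igraph, 4-step random walks by default) produces a merge
dendrogram, and the reported partition is the dendrogram cut maximizing the
weighted modularity

    Q = (1/2m) Σ_ij [A_ij − k_i k_j / (2m)] δ(g_i, g_j),

implemented directly and cross-checked against igraph's modularity in the
test suite. Disconnected networks (possible for null replicates) are
partitioned per connected component.

**Significance.** The observed Q is compared with 1,000 (configurable)
randomized networks that keep the node count, the link count and the exact
multiset of observed link weights, but assign the weights in random order to
a uniformly random simple edge set. Each replicate is scored with its own
best Walktrap partition — re-running detection rather than reusing the
observed partition widens the null interval slightly but treats observed and
null networks identically. Clan emergence means Q above the empirical 97.5th
percentile; values below the 2.5th percentile are flagged separately. The
comparison uses a 1e-9 tolerance because both sides are sums of thousands of
floating-point terms; this suppresses machine-noise flips on structureless
networks (where the best partition is the trivial one and Q = 0 exactly up
to rounding).

## 4. Experiments

`run_scenario` runs one configuration for 700 years (default) and analyses
the final year; `run_grid` repeats this over scenarios and seeds and reports
per-scenario majority-vote significance (default 10 seeds). The sensitivity
analysis perturbs, one at a time, the 6 demographic and 2 learning
parameters shared by all scenarios (population size/carrying capacity, last
reproductive age, migration rate, mean lifespan i.e. mortality, initial age
distribution, initial unit size, innovation rate, repertoire size) to the
extremes of user-supplied ranges. The link bootstrap resamples network links
with replacement (duplicated links add their weights) at sampling fractions
5%…100% in 5% steps, 1,000 iterations by default, re-partitioning each
resample — emulating the incomplete acoustic sampling of field data.

All randomness flows from a single seed: `run_scenario` seeds its generator
with `(seed, abm_id)`, so scenarios are independent streams and any run is
bit-for-bit reproducible from its manifest.

**Problem sizes.** The package's own test battery runs the full experiment
at a reduced scale — 300 agents, 300 years, 10 seeds, 200-replicate null —
which preserves ~35–45 units at the final year and finishes in minutes;
single default-scale runs (1,000 agents, 700 years) are used for the
demographic calibration checks.

## 5. Synthetic fixtures

`make_fixture_network` builds block-structured similarity matrices with
planted modules (within-block similarity `w_in`, between `w_out`, optional
uniform jitter). These validate the detection stack in isolation: Walktrap
recovers planted blocks (verified against exhaustive partition enumeration
up to 9 nodes), and the null benchmark flags them as significant while flat
matrices stay null-consistent. They emulate only the geometry of unit-level
acoustic similarity, not repertoire evolution — passing fixture tests says
nothing about whether the simulation produces block structure.

## 6. Known limitations

- The available descriptions of conformism and homophily fix their direction
  but not their quantitative form. We explored a broad family of operators
  (consensus copying; adoption/drop rules with absolute, relative and
  saturating thresholds; performance-weighted and density-weighted tutor
  draws; hard top-k slot competition; similarity-weighted and
  bounded-confidence tutor-unit choice) before settling on the forms above.
  Under the adopted forms the simulation reproduces the qualitative
  repertoire-similarity pattern — conformist and homophilous scenarios
  homogenize repertoires relative to the drift scenarios, and ABM 15 exceeds
  ABM 1 — but at the reduced test scale none of the 20 scenarios, including
  homophily+conformism, develops network modularity beyond the randomized
  benchmark: the final acoustic networks are near-complete with narrowly
  distributed weights. Emergent, statistically significant clan partitions
  therefore remain an open calibration problem for this implementation; the
  grid-level test encoding that expectation documents the current behaviour
  rather than a verified property.
- Repertoire frequencies are treated as 62 independent bounded scalars; no
  budget couples them, so "usage" is not compositional. A consequence is that
  the six symbol codas pinned at 100 put a ceiling (~0.85) on between-unit
  similarity in the symbolic scenarios, which therefore do not converge all
  the way to a single homogeneous repertoire here.
- Space is implicit. Predefined clans emulate geographic segregation purely
  through learning-pool restriction; migration is global.
- The demographic schedule is parametric (Gompertz adults, constant calf
  multiplier, density on mortality only) and calibrated to two emergent
  targets: conditional life expectancy of 70 y and fluctuation around the
  carrying capacity. Age-specific fertility beyond the 9–41 window is not
  modelled.
- `Agent`/`SocialUnit` views are snapshots; mutation goes through the
  `Population` arrays.
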