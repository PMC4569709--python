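# codaclans

Agent-based simulation of how sperm whale *vocal clans* — sets of social
units sharing a dialect of codas (stereotyped click patterns) — could emerge
from cultural transmission, plus the acoustic-network statistics used to
detect them.

Female sperm whales live in nearly permanent, nearly matrilineal social
units of about a dozen animals; units with similar coda repertoires group
into sympatric clans, forming a multilevel society. `codaclans` implements
an individual-based model of this system: an age-structured,
density-dependent population of female agents whose calves compose a
62-type coda repertoire at ages 0–2 under one of twenty transmission
scenarios — individual learning, genetic/vertical inheritance, or oblique
social learning, the latter optionally biased by **homophily** (learning
preferentially from the most behaviourally similar unit), **conformism**
(disproportionately copying the commonest coda types) and **symbolic
marking** (a six-coda unit badge always sung at full rate), each operating
at the population, social-unit or predefined-clan level.

Whether clans emerge is read off the **acoustic network**: units are nodes,
link weights are adjusted weighted Bray–Curtis similarities between unit
mean repertoires, `S(x,y) = 1 − Σ|x_i−y_i| / Σ(x_i+y_i)`. The best unit
partition is found with the Walktrap algorithm and scored with weighted
modularity

```
Q = (1/2m) Σ_ij [ A_ij − k_i k_j / (2m) ] δ(g_i, g_j)
```

and judged against 1,000 randomized networks with identical size,
connectance and link-weight multiset: clans are "emergent" when Q exceeds
the null 95% interval. A sensitivity analysis (8 parameters, one at a time)
and a link bootstrap (5–100% of links, with replacement) probe robustness.

It is intended for behavioural ecologists and cultural-evolution modellers
who want to simulate multilevel social structure, or to run the
clan-detection stack on their own unit-by-coda frequency tables.

## Worked example

```python
import numpy as np
from codaclans import (DemographyParams, Scenario, run_scenario,
                       make_fixture_network, detect_clans)

# one biased-learning scenario (homophily + conformism, population level)
# at reduced scale: 300 agents, 300 years
res = run_scenario(Scenario.from_abm_id(15), DemographyParams(n0=300),
                   years=300, seed=1, n_null=200)
print(res.n_units, round(res.mean_similarity, 3),
      round(res.q, 4), res.significant)
# -> 45 0.946 -0.0 False

# the detection stack on a similarity matrix with three planted clans
sim = make_fixture_network(3, 4, w_in=0.9, w_out=0.1,
                           rng=np.random.default_rng(0), jitter=0.03)
clans = detect_clans(sim, rng=np.random.default_rng(1), n_null=200)
print(round(clans.q, 3), tuple(round(c, 3) for c in clans.ci95),
      clans.significant, clans.n_clans)
# -> 0.433 (-0.0, 0.216) True 3
```

The first run ends with 45 social units whose mean pairwise repertoire
similarity is 0.946 — biased social learning homogenizes repertoires
relative to pure individual learning (0.861 under the same seed) — while
the final acoustic network is near-complete with narrowly distributed
weights, so its modularity does not exceed the randomized benchmark. On the
planted three-clan fixture the same pipeline recovers all three modules with
Q = 0.433, far outside the null interval (−0, 0.216).

## Command line

```bash
codaclans run --abm 15 --seed 1 --years 700 --n0 1000 --out results/abm15
codaclans grid --seeds 10 --out results/grid
codaclans sensitivity --ranges-file ranges.yaml --abm 15 --abm 16 --abm 17
codaclans bootstrap --network-file results/abm15/edges.tsv --iters 1000
```

Each run writes a population log (CSV), the unit similarity matrix (CSV),
the acoustic network (GraphML + tab-separated edge list), the clan partition
(CSV) and JSON summary/manifest files; the manifest records the seed and all
settings needed to reproduce the run bit-for-bit.

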