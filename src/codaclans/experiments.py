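"""Scenario runner, the 20-ABM grid, sensitivity analysis and link bootstrap.

``run_scenario`` performs one full simulation (demography + learning for a
number of years) and then analyses the final year: unit mean repertoires,
pairwise Bray-Curtis similarity, Walktrap clan detection against the null
benchmark. ``run_grid`` repeats this for every scenario and several seeds,
``sensitivity_analysis`` perturbs one parameter at a time to the extremes of
a biologically meaningful range, and ``bootstrap_links`` resamples network
links with replacement to probe the robustness of modularity to incomplete
sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .demography import DemographyParams, Population, init_population, step_year
from .learning import CALF_AGE_LIMIT, Scenario, assign_symbols, scenario_grid
from .networks import AcousticNetwork, ClanResult, build_network, detect_clans, walktrap_partition, weighted_modularity
from .similarity import SimilarityMatrix, similarity_matrix

__all__ = [
    "RunResult",
    "SENSITIVITY_PARAMETERS",
    "initialize_run",
    "run_scenario",
    "run_grid",
    "sensitivity_analysis",
    "bootstrap_links",
]

logger = logging.getLogger(__name__)

#: The 8 parameters perturbed one at a time by the sensitivity analysis:
#: 6 demographic and 2 learning parameters shared by all 20 scenarios.
SENSITIVITY_PARAMETERS = (
    "n0",                      # population size and carrying capacity
    "last_reproductive_age",   # reproductive age
    "migration_rate_c",        # migration rate
    "mean_lifespan",           # mortality rates (via the derived hazards)
    "init_age_mean",           # initial age distribution
    "init_mean_unit_size",     # initial average social unit size
    "ilearn",                  # individual learning (innovation) rate
    "repertoire_size",         # coda repertoire size
)
_LEARNING_PARAMETERS = {"ilearn", "repertoire_size"}


@dataclass
class RunResult:
    """Outcome of one simulated scenario."""

    scenario: Scenario
    seed: int
    years: int
    clans: ClanResult | None
    mean_similarity: float
    sd_similarity: float
    similarity: SimilarityMatrix | None
    population_log: pd.DataFrame
    n_units: int
    extinct: bool

    @property
    def q(self) -> float:
        return float("nan") if self.clans is None else self.clans.q

    @property
    def significant(self) -> bool:
        return False if self.clans is None else self.clans.significant


def initialize_run(
    scenario: Scenario,
    params: DemographyParams,
    rng: np.random.Generator,
) -> Population:
    """Year-1 population for a scenario: init, symbols, repertoire freezing."""
    pop = init_population(
        params,
        predefined_clans=scenario.predefined_clans,
        rng=rng,
        n_codas=scenario.repertoire_size,
    )
    if "symbolic" in scenario.biases:
        assign_symbols(pop, rng)
    pop.repertoire_fixed |= pop.age >= CALF_AGE_LIMIT
    return pop


def run_scenario(
    scenario: Scenario,
    params: DemographyParams | None = None,
    years: int = 700,
    seed: int = 0,
    n_null: int = 1000,
    walktrap_steps: int = 4,
    detect: bool = True,
) -> RunResult:
    """Simulate one scenario and analyse the final year.

    Deterministic given ``(scenario, params, years, seed)``. Extinction or a
    degenerate final population (< 3 units) yields a flagged result with
    ``clans=None`` instead of raising.
    """
    params = params or DemographyParams()
    rng = np.random.default_rng([int(seed), int(scenario.abm_id)])
    pop = initialize_run(scenario, params, rng)
    for _ in range(years):
        step_year(pop, scenario, rng)
        if pop.n == 0:
            break
    extinct = pop.n == 0
    log = pd.DataFrame(pop.yearly_log)

    sim = None
    mean_sim = sd_sim = float("nan")
    clans = None
    if not extinct and pop.n_units >= 2:
        sim = similarity_matrix(pop)
        iu = np.triu_indices(sim.n, k=1)
        off = sim.values[iu]
        mean_sim, sd_sim = float(off.mean()), float(off.std())
        if detect and pop.n_units >= 3:
            clans = detect_clans(sim, rng=rng, n_null=n_null, steps=walktrap_steps)
    return RunResult(
        scenario=scenario,
        seed=seed,
        years=years,
        clans=clans,
        mean_similarity=mean_sim,
        sd_similarity=sd_sim,
        similarity=sim,
        population_log=log,
        n_units=pop.n_units,
        extinct=extinct,
    )


def run_grid(
    params: DemographyParams | None = None,
    years: int = 700,
    n_seeds: int = 10,
    seeds: list[int] | None = None,
    scenarios: list[Scenario] | None = None,
    n_null: int = 1000,
    walktrap_steps: int = 4,
    progress: bool = False,
) -> tuple[list[RunResult], pd.DataFrame, pd.DataFrame]:
    """Run every scenario for several seeds.

    Returns the individual results, a per-run summary table and a
    per-scenario aggregate with majority-vote significance across seeds.
    """
    scenarios = scenarios or scenario_grid()
    seeds = list(range(n_seeds)) if seeds is None else list(seeds)
    results: list[RunResult] = []
    rows = []
    for scen in scenarios:
        for seed in seeds:
            if progress:
                logger.info("running ABM %d seed %d", scen.abm_id, seed)
            res = run_scenario(
                scen, params, years=years, seed=seed, n_null=n_null, walktrap_steps=walktrap_steps
            )
            results.append(res)
            rows.append(
                {
                    "abm_id": scen.abm_id,
                    "seed": seed,
                    "mean_similarity": res.mean_similarity,
                    "sd_similarity": res.sd_similarity,
                    "q": res.q,
                    "significant": res.significant,
                    "n_clans": 0 if res.clans is None else res.clans.n_clans,
                    "n_units": res.n_units,
                    "extinct": res.extinct,
                }
            )
    summary = pd.DataFrame(rows)
    by_scenario = (
        summary.groupby("abm_id")
        .agg(
            mean_similarity=("mean_similarity", "mean"),
            mean_q=("q", "mean"),
            significant_seeds=("significant", "sum"),
            n_seeds=("seed", "count"),
            median_n_clans=("n_clans", "median"),
        )
        .reset_index()
    )
    by_scenario["majority_significant"] = (
        by_scenario["significant_seeds"] > by_scenario["n_seeds"] / 2
    )
    return results, summary, by_scenario


def _perturbed(
    base_params: DemographyParams, scenario: Scenario, name: str, value
) -> tuple[DemographyParams, Scenario]:
    if name not in SENSITIVITY_PARAMETERS:
        raise ValueError(f"unknown sensitivity parameter {name!r}")
    if name in _LEARNING_PARAMETERS:
        kwargs = {name: int(value) if name == "repertoire_size" else float(value)}
        return base_params, replace(scenario, **kwargs)
    value = int(value) if name == "n0" else value
    return replace(base_params, **{name: value}), scenario


def sensitivity_analysis(
    base_params: DemographyParams,
    param_ranges: dict[str, tuple[float, float]],
    scenarios: list[Scenario] | None = None,
    years: int = 700,
    seed: int = 0,
    n_null: int = 1000,
) -> pd.DataFrame:
    """One-at-a-time perturbation of the 8 shared parameters.

    ``param_ranges`` must provide a (low, high) pair for exactly the
    parameters in :data:`SENSITIVITY_PARAMETERS`. Each scenario is re-run at
    each extreme with everything else held at baseline; the report records
    modularity, the null interval and the significance verdict per cell.
    """
    if set(param_ranges) != set(SENSITIVITY_PARAMETERS):
        missing = set(SENSITIVITY_PARAMETERS) - set(param_ranges)
        extra = set(param_ranges) - set(SENSITIVITY_PARAMETERS)
        raise ValueError(
            f"param_ranges must cover exactly the 8 sensitivity parameters "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    scenarios = scenarios or scenario_grid()
    rows = []
    for name in SENSITIVITY_PARAMETERS:
        low, high = param_ranges[name]
        if not low < high:
            raise ValueError(f"invalid range for {name!r}: ({low}, {high})")
        for extreme, value in (("low", low), ("high", high)):
            for scen in scenarios:
                p, s = _perturbed(base_params, scen, name, value)
                res = run_scenario(s, p, years=years, seed=seed, n_null=n_null)
                rows.append(
                    {
                        "parameter": name,
                        "extreme": extreme,
                        "value": value,
                        "abm_id": scen.abm_id,
                        "q": res.q,
                        "ci_low": float("nan") if res.clans is None else res.clans.ci95[0],
                        "ci_high": float("nan") if res.clans is None else res.clans.ci95[1],
                        "significant": res.significant,
                        "n_clans": 0 if res.clans is None else res.clans.n_clans,
                        "mean_similarity": res.mean_similarity,
                        "extinct": res.extinct,
                    }
                )
    return pd.DataFrame(rows)


def bootstrap_links(
    net: AcousticNetwork,
    fractions: np.ndarray | None = None,
    iters: int = 1000,
    rng: np.random.Generator | None = None,
    walktrap_steps: int = 4,
) -> pd.DataFrame:
    """Modularity under link resampling with replacement.

    For each sampling fraction ``f`` (default 5%..100% in 5% steps),
    ``round(f * L)`` of the ``L`` observed links are drawn with replacement
    (a link drawn twice contributes its weight twice); the induced network is
    re-partitioned with Walktrap and its weighted modularity recorded.
    Returns one row per fraction with the mean and the 2.5/97.5 percentile
    band over iterations.
    """
    rng = np.random.default_rng() if rng is None else rng
    if fractions is None:
        fractions = np.arange(1, 21) * 0.05
    edges = net.edge_list()
    if not edges:
        raise ValueError("bootstrap requires a network with links")
    n = net.n_nodes
    pos = {u: i for i, u in enumerate(net.node_ids)}
    ei = np.array([pos[a] for a, _, _ in edges])
    ej = np.array([pos[b] for _, b, _ in edges])
    ew = np.array([w for _, _, w in edges])
    n_links = ew.size
    rows = []
    for f in fractions:
        k = int(round(f * n_links))
        if k == 0:
            logger.warning("fraction %.2f yields 0 links; skipped", f)
            continue
        qs = np.empty(iters)
        for it in range(iters):
            draw = rng.integers(n_links, size=k)
            a = np.zeros((n, n))
            np.add.at(a, (ei[draw], ej[draw]), ew[draw])
            a += a.T
            rnet = AcousticNetwork(node_ids=list(net.node_ids), adjacency=a)
            qs[it] = weighted_modularity(a, walktrap_partition(rnet, steps=walktrap_steps))
        lo, hi = np.percentile(qs, [2.5, 97.5])
        rows.append(
            {
                "fraction": float(f),
                "n_links": k,
                "mean_q": float(qs.mean()),
                "q_lo": float(lo),
                "q_hi": float(hi),
            }
        )
    return pd.DataFrame(rows)
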