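"""Age-structured, density-dependent demography of female sperm whales.

The population consists of female agents only (males are quasi-solitary,
rarely produce codas, and are not modelled). Agents live in nearly permanent,
nearly matrilineal social units: calves (ages 0--2) always stay in their
mother's unit, adults occasionally migrate between units, and units split in
half once they reach twice the typical initial unit size. Yearly scheduling
is: births, coda-repertoire composition (see :mod:`codaclans.learning`),
migration, deaths, unit splitting, ageing.

Vital rates use a parsimonious parametric schedule. Adult mortality is
senescent (Gompertz): the yearly hazard rises exponentially with age on an
e-folding scale of ``senescence_scale`` years, with its baseline solved
numerically so that the expected age at death of an agent surviving calfhood
equals ``mean_lifespan``. Calves die at ``calf_mortality_multiplier`` times
the reference adult hazard ``1 / (mean_lifespan - 2)``. All hazards are
multiplied by the density factor ``(N / K) ** theta``, and the yearly birth
probability of reproductive females is solved from the stationary age
structure so that births balance deaths at carrying capacity. The resulting
population fluctuates around ``K`` with realistic age composition and a
death-age distribution concentrated around the target lifespan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "CALF_AGE_LIMIT",
    "Agent",
    "SocialUnit",
    "DemographyParams",
    "Population",
    "init_population",
    "births",
    "deaths",
    "migrate",
    "split_units",
    "step_year",
]

#: Agents younger than this are calves: they keep learning codas, never
#: migrate on their own and always follow their mother.
CALF_AGE_LIMIT = 3


@dataclass
class DemographyParams:
    """Demographic parameters of a simulation run.

    Parameters
    ----------
    n0
        Initial population size; also the carrying capacity unless
        ``carrying_capacity`` is given explicitly.
    carrying_capacity
        Population size around which density dependence stabilizes the
        population. ``None`` means "equal to ``n0``".
    maturity_age, last_reproductive_age
        Females reproduce from ``maturity_age`` through
        ``last_reproductive_age`` (inclusive), in years.
    mean_lifespan
        Target expected age at death (years) of agents surviving calfhood.
    migration_rate_c
        Yearly migration probability of the youngest adults; migration
        declines exponentially with age from this baseline.
    migration_age_scale
        e-folding scale (years) of the migration decline with age.
    init_mean_unit_size
        Average social-unit size used to choose the initial unit count.
    split_threshold_factor
        Units split in half once their size reaches this factor times the
        maximum realized initial unit size.
    init_age_mean
        Mean of the negative-exponential initial age distribution (years).
    init_age_max
        Truncation point of the initial age distribution (years).
    calf_mortality_multiplier
        Calf hazard relative to the adult hazard (must exceed 1).
    density_dependence_strength
        Exponent ``theta`` of the density factor ``(N/K)**theta``.
    adult_mortality, birth_rate
        Optional overrides of the derived adult hazard and yearly birth
        probability; ``None`` means "derive from the other parameters".
    """

    n0: int = 1000
    carrying_capacity: int | None = None
    maturity_age: int = 9
    last_reproductive_age: int = 41
    mean_lifespan: float = 70.0
    migration_rate_c: float = 0.05
    migration_age_scale: float = 35.0
    init_mean_unit_size: float = 12.0
    split_threshold_factor: float = 2.0
    init_age_mean: float = 15.0
    init_age_max: int = 70
    calf_mortality_multiplier: float = 3.0
    density_dependence_strength: float = 1.0
    senescence_scale: float = 10.0
    adult_mortality: float | None = None
    birth_rate: float | None = None

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.init_mean_unit_size <= 0:
            raise ValueError("init_mean_unit_size must be positive")
        if not 0.0 <= self.migration_rate_c <= 1.0:
            raise ValueError("migration_rate_c must lie in [0, 1]")
        if not (0 <= self.maturity_age < self.last_reproductive_age):
            raise ValueError("need 0 <= maturity_age < last_reproductive_age")
        if self.mean_lifespan <= CALF_AGE_LIMIT:
            raise ValueError("mean_lifespan must exceed the calf age limit")
        if self.calf_mortality_multiplier <= 1.0:
            raise ValueError("calf_mortality_multiplier must exceed 1")

    @property
    def k(self) -> int:
        """Carrying capacity (defaults to ``n0``)."""
        return self.n0 if self.carrying_capacity is None else self.carrying_capacity

    @property
    def mu_reference(self) -> float:
        """Reference adult hazard ``1/(mean_lifespan - 2)``.

        With a constant hazard ``mu`` from age 3 on, the age at death of an
        agent surviving calfhood would be ``3 + G`` with ``G`` geometric, so
        its expectation is ``3 + (1 - mu)/mu``; solving for the target
        lifespan gives this rate. It anchors the calf hazard; the adult
        hazard itself is senescent (see :meth:`hazard_schedule`).
        """
        if self.adult_mortality is not None:
            return self.adult_mortality
        return 1.0 / (self.mean_lifespan - 2.0)

    @property
    def mu_calf(self) -> float:
        """Baseline yearly calf death probability (strictly above adult)."""
        return min(1.0, self.calf_mortality_multiplier * self.mu_reference)

    def _adult_expected_death_age(self, mu0: float, max_age: int) -> float:
        ages = np.arange(CALF_AGE_LIMIT, max_age)
        mu = np.minimum(1.0, mu0 * np.exp((ages - CALF_AGE_LIMIT) / self.senescence_scale))
        surv = np.concatenate([[1.0], np.cumprod(1.0 - mu[:-1])])
        pdeath = surv * mu
        pdeath /= pdeath.sum()
        return float((ages * pdeath).sum())

    def baseline_adult_hazard(self, max_age: int = 400) -> float:
        """Gompertz baseline ``mu0`` hitting the target mean lifespan.

        Adult hazard at age ``a`` is ``mu0 * exp((a - 3)/senescence_scale)``;
        ``mu0`` is solved by bisection so the expected age at death of an
        agent surviving calfhood equals ``mean_lifespan``.
        """
        if self.adult_mortality is not None:
            return self.adult_mortality
        lo, hi = 1e-8, 1.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self._adult_expected_death_age(mid, max_age) > self.mean_lifespan:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def hazard_schedule(self, max_age: int = 400) -> np.ndarray:
        """Baseline yearly death probability for every age 0..max_age-1.

        Calves (ages 0-2) die at ``calf_mortality_multiplier`` times the
        reference adult rate; adults follow the calibrated Gompertz curve.
        The realized per-year probability is this schedule times the density
        factor ``(N/K)**theta``, clipped to [0, 1].
        """
        cached = getattr(self, "_hazard_cache", None)
        if cached is not None and cached[0] == max_age:
            return cached[1]
        mu0 = self.baseline_adult_hazard(max_age)
        ages = np.arange(max_age)
        if self.adult_mortality is not None:
            haz = np.full(max_age, self.adult_mortality)
        else:
            haz = np.minimum(
                1.0, mu0 * np.exp((ages - CALF_AGE_LIMIT) / self.senescence_scale)
            )
        haz[:CALF_AGE_LIMIT] = self.mu_calf
        self._hazard_cache = (max_age, haz)
        return haz

    def stationary_survivorship(self, max_age: int = 400) -> np.ndarray:
        """Probability of surviving to each age under the baseline hazards."""
        hazards = self.hazard_schedule(max_age)
        surv = np.ones(max_age)
        surv[1:] = np.cumprod(1.0 - hazards[:-1])
        return surv

    def calibrated_birth_rate(self) -> float:
        """Yearly birth probability balancing births and deaths at ``N = K``.

        In the stationary age structure with newborn inflow ``B`` the cohort
        aged ``a`` has size ``B * S(a)`` and total deaths equal ``B``; the
        birth probability that regenerates ``B`` newborns from the
        reproductive ages is therefore ``1 / sum_{a=m}^{l} S(a)``.
        """
        if self.birth_rate is not None:
            return self.birth_rate
        surv = self.stationary_survivorship()
        repro = surv[self.maturity_age : self.last_reproductive_age + 1]
        return float(1.0 / repro.sum())


@dataclass
class Agent:
    """Read-only snapshot of one female agent (see :meth:`Population.agent`)."""

    id: int
    age: int
    unit_id: int
    clan_id: int | None
    mother_id: int | None
    repertoire: np.ndarray
    repertoire_fixed: bool


@dataclass
class SocialUnit:
    """Read-only snapshot of one social unit."""

    id: int
    member_ids: frozenset[int]
    clan_id: int | None
    symbol: tuple[int, ...] | None


@dataclass
class Population:
    """The living population, stored column-wise for speed.

    ``ids`` is strictly increasing (never reused), so agent lookup by id is a
    binary search. ``repertoires`` is an ``(N, n_codas)`` float array of coda
    usage frequencies in [0, 100].
    """

    params: DemographyParams
    n_codas: int = 62
    year: int = 1
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    age: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    unit_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    clan_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    mother_id: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    repertoires: np.ndarray = field(default_factory=lambda: np.empty((0, 62)))
    repertoire_fixed: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    unit_clan: dict[int, int | None] = field(default_factory=dict)
    unit_symbol: dict[int, np.ndarray | None] = field(default_factory=dict)
    split_threshold: int = 24
    next_agent_id: int = 0
    next_unit_id: int = 0
    death_ages: list[int] = field(default_factory=list)
    yearly_log: list[dict] = field(default_factory=list)

    # -- bookkeeping -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def n_units(self) -> int:
        return len(self.unit_clan)

    def index_of(self, agent_ids: np.ndarray) -> np.ndarray:
        """Row indices of the given agent ids (which must be alive)."""
        idx = np.searchsorted(self.ids, agent_ids)
        return idx

    def unit_members(self) -> dict[int, np.ndarray]:
        """Mapping unit id -> row indices of its living members."""
        members: dict[int, np.ndarray] = {uid: np.empty(0, dtype=np.int64) for uid in self.unit_clan}
        if self.n:
            order = np.argsort(self.unit_id, kind="stable")
            uids, starts = np.unique(self.unit_id[order], return_index=True)
            bounds = np.append(starts, self.n)
            for j, uid in enumerate(uids):
                members[int(uid)] = order[bounds[j] : bounds[j + 1]]
        return members

    def agent(self, agent_id: int) -> Agent:
        i = int(np.searchsorted(self.ids, agent_id))
        if i >= self.n or self.ids[i] != agent_id:
            raise KeyError(f"no living agent with id {agent_id}")
        clan = int(self.clan_id[i])
        mother = int(self.mother_id[i])
        return Agent(
            id=int(self.ids[i]),
            age=int(self.age[i]),
            unit_id=int(self.unit_id[i]),
            clan_id=None if clan < 0 else clan,
            mother_id=None if mother < 0 else mother,
            repertoire=self.repertoires[i].copy(),
            repertoire_fixed=bool(self.repertoire_fixed[i]),
        )

    def iter_agents(self) -> Iterator[Agent]:
        for aid in self.ids:
            yield self.agent(int(aid))

    def unit(self, uid: int) -> SocialUnit:
        if uid not in self.unit_clan:
            raise KeyError(f"no unit with id {uid}")
        member_ids = frozenset(int(a) for a in self.ids[self.unit_id == uid])
        symbol = self.unit_symbol.get(uid)
        return SocialUnit(
            id=uid,
            member_ids=member_ids,
            clan_id=self.unit_clan[uid],
            symbol=None if symbol is None else tuple(int(s) for s in symbol),
        )

    def _append(
        self,
        n_new: int,
        age: np.ndarray,
        unit_id: np.ndarray,
        clan_id: np.ndarray,
        mother_id: np.ndarray,
    ) -> np.ndarray:
        new_ids = np.arange(self.next_agent_id, self.next_agent_id + n_new, dtype=np.int64)
        self.next_agent_id += n_new
        self.ids = np.concatenate([self.ids, new_ids])
        self.age = np.concatenate([self.age, age])
        self.unit_id = np.concatenate([self.unit_id, unit_id])
        self.clan_id = np.concatenate([self.clan_id, clan_id])
        self.mother_id = np.concatenate([self.mother_id, mother_id])
        self.repertoires = np.vstack([self.repertoires, np.zeros((n_new, self.n_codas))])
        self.repertoire_fixed = np.concatenate([self.repertoire_fixed, np.zeros(n_new, dtype=bool)])
        return new_ids

    def _remove(self, kill: np.ndarray) -> None:
        keep = ~kill
        self.ids = self.ids[keep]
        self.age = self.age[keep]
        self.unit_id = self.unit_id[keep]
        self.clan_id = self.clan_id[keep]
        self.mother_id = self.mother_id[keep]
        self.repertoires = self.repertoires[keep]
        self.repertoire_fixed = self.repertoire_fixed[keep]

    def prune_empty_units(self) -> None:
        alive = set(int(u) for u in np.unique(self.unit_id)) if self.n else set()
        for uid in [u for u in self.unit_clan if u not in alive]:
            del self.unit_clan[uid]
            self.unit_symbol.pop(uid, None)

    def check_invariants(self) -> None:
        """Raise if structural invariants are violated (used in tests)."""
        if self.n:
            if not np.all(np.diff(self.ids) > 0):
                raise AssertionError("agent ids not strictly increasing")
            if self.repertoires.shape != (self.n, self.n_codas):
                raise AssertionError("repertoire block has wrong shape")
            if self.repertoires.min() < 0 or self.repertoires.max() > 100:
                raise AssertionError("repertoire frequencies outside [0, 100]")
            member_units = set(int(u) for u in np.unique(self.unit_id))
            if not member_units <= set(self.unit_clan):
                raise AssertionError("agent assigned to unregistered unit")


# ---------------------------------------------------------------------------
# operations


def init_population(
    params: DemographyParams,
    predefined_clans: int | None = None,
    rng: np.random.Generator | None = None,
    n_codas: int = 62,
) -> Population:
    """Create the year-1 population.

    Ages are drawn from a negative exponential with mean ``init_age_mean``
    (truncated at ``init_age_max``), so the initial population is mostly
    young. Agents are dealt by random permutation into
    ``round(n0 / init_mean_unit_size)`` near-equal social units, and every
    repertoire is initialized by individual learning at half fill. When
    ``predefined_clans`` is given, units are dealt evenly into that many
    geographically segregated clans. Mature repertoires are frozen at the end
    of the first :func:`step_year` (after optional symbolic marking).
    """
    from .learning import individual_learning  # deferred: learning imports our types

    rng = np.random.default_rng() if rng is None else rng
    n0 = params.n0
    n_units = int(round(n0 / params.init_mean_unit_size))
    if n_units < 1:
        raise ValueError("init_mean_unit_size too large for n0: no units")

    pop = Population(params=params, n_codas=n_codas)
    pop.repertoires = np.empty((0, n_codas))

    ages = np.floor(rng.exponential(params.init_age_mean, size=n0)).astype(np.int64)
    while np.any(ages > params.init_age_max):  # truncated draw: resample the tail
        bad = ages > params.init_age_max
        ages[bad] = np.floor(rng.exponential(params.init_age_mean, size=int(bad.sum())))

    unit_of_agent = rng.permutation(np.arange(n0, dtype=np.int64) % n_units)
    clan_of_unit = np.full(n_units, -1, dtype=np.int64)
    if predefined_clans is not None:
        if predefined_clans < 1:
            raise ValueError("predefined_clans must be positive")
        clan_of_unit = rng.permutation(np.arange(n_units, dtype=np.int64) % predefined_clans)

    pop._append(
        n0,
        age=ages,
        unit_id=unit_of_agent,
        clan_id=clan_of_unit[unit_of_agent],
        mother_id=np.full(n0, -1, dtype=np.int64),
    )
    pop.next_unit_id = n_units
    pop.unit_clan = {
        int(u): (None if clan_of_unit[u] < 0 else int(clan_of_unit[u])) for u in range(n_units)
    }
    pop.unit_symbol = {int(u): None for u in range(n_units)}

    for i in range(n0):
        individual_learning(pop.repertoires[i], rng=rng)

    sizes = np.bincount(unit_of_agent, minlength=n_units)
    pop.split_threshold = int(round(params.split_threshold_factor * sizes.max()))
    return pop


def births(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Add newborn agents; returns their ids.

    Mothers are females aged within ``[maturity_age, last_reproductive_age]``;
    each gives birth with the calibrated yearly probability. Calves start at
    age 0 in the mother's unit (and predefined clan) with an empty repertoire,
    to be composed by the learning phase of the same year.
    """
    b = pop.params.calibrated_birth_rate()
    fertile = (pop.age >= pop.params.maturity_age) & (pop.age <= pop.params.last_reproductive_age)
    mothers = np.flatnonzero(fertile & (rng.random(pop.n) < b))
    if mothers.size == 0:
        return np.empty(0, dtype=np.int64)
    return pop._append(
        mothers.size,
        age=np.zeros(mothers.size, dtype=np.int64),
        unit_id=pop.unit_id[mothers],
        clan_id=pop.clan_id[mothers],
        mother_id=pop.ids[mothers],
    )


def deaths(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Remove dying agents; returns the ids removed.

    The per-agent death probability is the age-specific baseline hazard
    (calves above adults) times the density factor ``(N/K)**theta``. Ages at
    death are appended to ``pop.death_ages``.
    """
    if pop.n == 0:
        return np.empty(0, dtype=np.int64)
    params = pop.params
    density = (pop.n / params.k) ** params.density_dependence_strength
    hazards = params.hazard_schedule()
    p = hazards[np.clip(pop.age, 0, hazards.size - 1)] * density
    p = np.clip(p, 0.0, 1.0)
    kill = rng.random(pop.n) < p
    dead_ids = pop.ids[kill]
    pop.death_ages.extend(int(a) for a in pop.age[kill])
    pop._remove(kill)
    return dead_ids


def migrate(pop: Population, rng: np.random.Generator) -> int:
    """Move adults between units; returns the number of adult movers.

    The yearly movement probability is ``c * exp(-(age - 3)/lambda)``: exactly
    the baseline ``c`` for the youngest adults and non-increasing in age.
    Destinations are uniform among the other units. Dependent calves follow a
    migrating mother; calves never move on their own.
    """
    if pop.n_units < 2 or pop.n == 0:
        return 0
    params = pop.params
    adult = pop.age >= CALF_AGE_LIMIT
    p = params.migration_rate_c * np.exp(
        -(pop.age - CALF_AGE_LIMIT) / params.migration_age_scale
    )
    movers = np.flatnonzero(adult & (rng.random(pop.n) < p))
    if movers.size == 0:
        return 0
    unit_ids = np.fromiter(pop.unit_clan, dtype=np.int64, count=pop.n_units)
    for i in movers:
        others = unit_ids[unit_ids != pop.unit_id[i]]
        dest = int(rng.choice(others))
        pop.unit_id[i] = dest
        clan = pop.unit_clan[dest]
        pop.clan_id[i] = -1 if clan is None else clan
    # dependent calves follow their mothers
    calves = np.flatnonzero(pop.age < CALF_AGE_LIMIT)
    if calves.size:
        mother_idx = np.searchsorted(pop.ids, pop.mother_id[calves])
        mother_idx = np.clip(mother_idx, 0, pop.n - 1)
        alive = pop.ids[mother_idx] == pop.mother_id[calves]
        for c, m in zip(calves[alive], mother_idx[alive]):
            pop.unit_id[c] = pop.unit_id[m]
            pop.clan_id[c] = pop.clan_id[m]
    return int(movers.size)


def split_units(pop: Population, rng: np.random.Generator) -> list[int]:
    """Split oversized units in half; returns the new unit ids.

    A unit splits when its size reaches the threshold (twice the maximum
    initial unit size by default). Members are partitioned into two
    near-equal halves at random, with the constraint that dependent calves
    stay with their mothers; the daughter unit inherits the parent's
    predefined clan and symbolic marker.
    """
    new_units: list[int] = []
    for uid, members in pop.unit_members().items():
        if members.size < pop.split_threshold:
            continue
        # matrilineal atoms: a mother with her dependent calves moves as one
        atom_of = {int(pop.ids[i]): int(pop.ids[i]) for i in members}
        member_ids = set(atom_of)
        for i in members:
            if pop.age[i] < CALF_AGE_LIMIT and int(pop.mother_id[i]) in member_ids:
                atom_of[int(pop.ids[i])] = int(pop.mother_id[i])
        atoms: dict[int, list[int]] = {}
        for aid, root in atom_of.items():
            atoms.setdefault(root, []).append(aid)
        order = list(atoms.values())
        rng.shuffle(order)
        half_a: list[int] = []
        half_b: list[int] = []
        for atom in order:
            (half_a if len(half_a) <= len(half_b) else half_b).extend(atom)
        new_uid = pop.next_unit_id
        pop.next_unit_id += 1
        pop.unit_clan[new_uid] = pop.unit_clan[uid]
        sym = pop.unit_symbol.get(uid)
        pop.unit_symbol[new_uid] = None if sym is None else sym.copy()
        idx = pop.index_of(np.array(sorted(half_b), dtype=np.int64))
        pop.unit_id[idx] = new_uid
        new_units.append(new_uid)
    return new_units


def step_year(
    pop: Population,
    scenario,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one simulated year.

    Sub-processes run in the fixed order births, repertoire composition,
    unit-membership change, deaths; then units split, ages advance, mature
    repertoires freeze, and the yearly log row is appended. ``scenario`` is a
    :class:`codaclans.learning.Scenario` controlling the learning phase.
    """
    from .learning import compose_repertoires

    n_before = pop.n
    n_births = births(pop, rng).size
    compose_repertoires(pop, scenario, rng)
    n_migrations = migrate(pop, rng)
    n_deaths = deaths(pop, rng).size
    split_units(pop, rng)
    pop.prune_empty_units()
    pop.age += 1
    pop.repertoire_fixed |= pop.age >= CALF_AGE_LIMIT
    pop.year += 1
    sizes = [m.size for m in pop.unit_members().values()]
    pop.yearly_log.append(
        {
            "year": pop.year,
            "n": pop.n,
            "births": n_births,
            "deaths": n_deaths,
            "migrations": n_migrations,
            "n_units": pop.n_units,
            "mean_unit_size": float(np.mean(sizes)) if sizes else 0.0,
        }
    )
    if pop.n == 0 and n_before > 0:
        warnings.warn("population went extinct", RuntimeWarning, stacklevel=2)
    return pop
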