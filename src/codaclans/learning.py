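"""Coda-repertoire transmission: mechanisms, biases and the 20-scenario grid.

Calves compose their coda repertoire once a year at ages 0, 1 and 2; at age 3
the repertoire is fixed for life. Three mechanisms are modelled:

``individual``
    random coda types and frequencies, drawn uniformly in [0, 100];
``genetic``
    the calf receives its mother's repertoire verbatim (equivalently, stable
    vertical cultural transmission);
``oblique``
    the calf samples each of its coda elements (zeros included) from adult
    tutors of an earlier generation.

Oblique learning can be biased by *homophily* (tutors come from the social
unit whose mean repertoire is most similar to the calf's unit's),
*conformism* (the calf disproportionately re-samples, and adopts the pool
mean of, the coda types most used in its tutor pool), and *symbolic marking*
(each unit carries a badge of six coda types always sung at frequency 100).
Transmission operates at one of three social levels: the whole population,
the calf's social unit, or its predefined (geographically segregated) clan.

In every scenario calves also innovate: each calf-year, ``round(62 * ilearn)``
randomly chosen elements are replaced by uniform draws in [0, 100].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .demography import CALF_AGE_LIMIT, Population

__all__ = [
    "MECHANISMS",
    "LEVELS",
    "BIAS_NAMES",
    "SYMBOL_SIZE",
    "Scenario",
    "scenario_grid",
    "individual_learning",
    "inherit_from_mother",
    "tutor_pool",
    "oblique_learn",
    "assign_symbols",
    "innovate",
    "compose_repertoire",
    "compose_repertoires",
]

logger = logging.getLogger(__name__)

MECHANISMS = ("individual", "genetic", "oblique")
LEVELS = ("population", "unit", "predefined_clan")
BIAS_NAMES = ("homophily", "conformism", "symbolic")

#: Number of coda types in a symbolic marker.
SYMBOL_SIZE = 6

# Bias combinations of the oblique scenarios, in published order: ABMs 3-5
# are pure oblique learning, each later triple adds the biases listed, and
# within each triple the level runs population, unit, predefined clan.
_BIAS_BLOCKS: tuple[frozenset[str], ...] = (
    frozenset(),
    frozenset({"homophily"}),
    frozenset({"conformism"}),
    frozenset({"symbolic"}),
    frozenset({"homophily", "conformism"}),
    frozenset({"homophily", "symbolic"}),
)


@dataclass(frozen=True)
class Scenario:
    """One of the 20 transmission scenarios (plus its learning parameters).

    ``abm_id`` 1 is pure individual learning and 2 is genetic inheritance
    (both without biases or level); ids 3-20 are oblique social learning with
    the bias/level combination of the published grid. ``ilearn`` is the
    innovation rate; ``conformity_exponent`` and ``replace_fraction`` tune
    the conformist weighting and the share of elements re-sampled at ages
    1-2; ``repertoire_size`` is the number of coda types.
    """

    abm_id: int
    mechanism: str
    biases: frozenset[str] = frozenset()
    level: str | None = None
    ilearn: float = 0.02
    conformity_exponent: float = 2.0
    replace_fraction: float = 1.0 / 3.0
    repertoire_size: int = 62

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not self.biases <= set(BIAS_NAMES):
            raise ValueError(f"unknown biases {set(self.biases) - set(BIAS_NAMES)}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.mechanism == "oblique" and self.level is None:
            raise ValueError("oblique scenarios need a transmission level")
        if self.mechanism != "oblique" and (self.biases or self.level):
            raise ValueError("biases and level are meaningful only for oblique learning")
        if not 0.0 <= self.ilearn <= 1.0:
            raise ValueError("ilearn must lie in [0, 1]")
        if not 0.0 <= self.replace_fraction <= 1.0:
            raise ValueError("replace_fraction must lie in [0, 1]")
        if self.repertoire_size < SYMBOL_SIZE:
            raise ValueError("repertoire_size must be at least the symbol size")

    @property
    def predefined_clans(self) -> int | None:
        """Number of predefined clans required by this scenario (3 or None)."""
        return 3 if self.level == "predefined_clan" else None

    @classmethod
    def from_abm_id(cls, abm_id: int, **overrides) -> "Scenario":
        if abm_id == 1:
            return cls(1, "individual", **overrides)
        if abm_id == 2:
            return cls(2, "genetic", **overrides)
        if not 3 <= abm_id <= 20:
            raise ValueError(f"abm_id must lie in 1..20, got {abm_id}")
        block, level_idx = divmod(abm_id - 3, 3)
        return cls(
            abm_id,
            "oblique",
            biases=_BIAS_BLOCKS[block],
            level=LEVELS[level_idx],
            **overrides,
        )


def scenario_grid(**overrides) -> list[Scenario]:
    """The full published grid of 20 scenarios, in ``abm_id`` order.

    Keyword overrides (``ilearn``, ``conformity_exponent``, ...) are applied
    to every scenario, e.g. for sensitivity analysis.
    """
    return [Scenario.from_abm_id(i, **overrides) for i in range(1, 21)]


# ---------------------------------------------------------------------------
# elementary repertoire updates (operate on a single frequency vector)


def individual_learning(
    repertoire: np.ndarray,
    fill_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
    fixed: bool = False,
) -> np.ndarray:
    """Assign uniform random frequencies to a random subset of coda types.

    ``round(fill_fraction * n)`` elements are chosen at random and set to
    uniform draws in [0, 100]; the remaining elements are untouched (zero at
    initialization). Modifies ``repertoire`` in place and returns it.
    """
    if fixed:
        warnings.warn("repertoire is fixed; individual learning skipped", RuntimeWarning)
        return repertoire
    rng = np.random.default_rng() if rng is None else rng
    n = repertoire.size
    k = int(round(fill_fraction * n))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        repertoire[idx] = rng.uniform(0.0, 100.0, size=k)
    return repertoire


def inherit_from_mother(calf_repertoire: np.ndarray, mother_repertoire: np.ndarray | None) -> np.ndarray:
    """Copy the mother's repertoire element-wise onto the calf's."""
    if mother_repertoire is None:
        raise ValueError("genetic inheritance requires a known, living mother")
    calf_repertoire[:] = mother_repertoire
    return calf_repertoire


def oblique_learn(
    repertoire: np.ndarray,
    age: int,
    pool_repertoires: np.ndarray,
    conformist: bool = False,
    conformity_exponent: float = 2.0,
    replace_fraction: float = 1.0 / 3.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One year of oblique social learning from a pool of adult tutors.

    At age 0 all elements are filled: each element independently copies the
    corresponding frequency (zeros included) of a tutor drawn uniformly from
    the pool. At ages 1 and 2, ``round(replace_fraction * n)`` elements are
    re-sampled the same way.

    With ``conformist=True`` the calf disproportionately copies the commonest
    coda types: the re-sampled elements are chosen with probability
    proportional to ``(pool mean frequency) ** conformity_exponent``, so the
    codas most used by the tutor pool are disproportionately refreshed, and
    each chosen element adopts the pool's consensus usage (the pool mean,
    rounded). An exponent of 0 makes the element selection uniform,
    recovering unbiased oblique learning.
    """
    if pool_repertoires.ndim != 2 or pool_repertoires.shape[0] == 0:
        raise ValueError("tutor pool must be a non-empty 2-D array")
    if age >= CALF_AGE_LIMIT:
        raise ValueError("only calves (age <= 2) learn obliquely")
    rng = np.random.default_rng() if rng is None else rng
    n = repertoire.size
    n_pool = pool_repertoires.shape[0]

    if age == 0:
        idx = np.arange(n)
    else:
        k = int(round(replace_fraction * n))
        if k == 0:
            return repertoire
        if conformist:
            mean = pool_repertoires.mean(axis=0)
            w = mean**conformity_exponent
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                idx = rng.choice(n, size=k, replace=False)
            elif np.count_nonzero(w) >= k:
                idx = rng.choice(n, size=k, replace=False, p=w / total)
            else:
                # pool already concentrated on fewer codas than the resample
                # count: visit all of them, fill up from the absent codas
                nz = np.flatnonzero(w)
                extra = rng.choice(np.flatnonzero(w == 0), size=k - nz.size, replace=False)
                idx = np.concatenate([nz, extra])
            repertoire[idx] = np.round(mean[idx])
            return repertoire
        idx = rng.choice(n, size=k, replace=False)

    tutors = rng.integers(n_pool, size=idx.size)
    repertoire[idx] = pool_repertoires[tutors, idx]
    return repertoire


def innovate(
    repertoire: np.ndarray,
    ilearn: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Replace ``round(n * ilearn)`` random elements by uniform [0, 100] draws.

    With the default rate of 0.02 on 62 coda types this replaces exactly one
    element per calf-year, modelling copying errors and deliberate innovation.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = repertoire.size
    k = int(round(n * ilearn))
    if k:
        idx = rng.choice(n, size=k, replace=False)
        repertoire[idx] = rng.uniform(0.0, 100.0, size=k)
    return repertoire


# ---------------------------------------------------------------------------
# tutor pools, symbols and the per-year driver


def _bray_curtis_rows(x: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Adjusted Bray-Curtis similarity between vector ``x`` and each row."""
    denom = (x + rows).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = 1.0 - np.abs(x - rows).sum(axis=1) / denom
    sim[denom == 0] = np.nan
    return sim


class _YearCaches:
    """Per-year lookups shared by all calves of one learning phase.

    Tutor repertoires are adults' and therefore constant within the phase;
    unit means (used by homophily) are snapshotted at the start of the phase,
    so the outcome does not depend on the order in which calves learn.
    """

    def __init__(self, pop: Population, scenario: Scenario, rng: np.random.Generator):
        self.pop = pop
        self.scenario = scenario
        self.rng = rng
        self.members = pop.unit_members()
        adult = pop.age >= CALF_AGE_LIMIT
        self.adults_by_unit = {
            uid: idx[adult[idx]] for uid, idx in self.members.items()
        }
        self.all_adults = np.flatnonzero(adult)
        self.unit_ids = sorted(self.members)
        self.unit_pos = {uid: j for j, uid in enumerate(self.unit_ids)}
        if "homophily" in scenario.biases:
            means = np.zeros((len(self.unit_ids), pop.n_codas))
            for j, uid in enumerate(self.unit_ids):
                idx = self.members[uid]
                reps = pop.repertoires[idx]
                nonempty = reps.sum(axis=1) > 0
                if nonempty.any():
                    means[j] = reps[nonempty].mean(axis=0)
            self.unit_means = means
        else:
            self.unit_means = None
        self._homophily_target: dict[int, int | None] = {}

    def homophily_target(self, uid: int) -> int | None:
        """Most-similar other unit (holding >= 1 adult) for calves of ``uid``.

        Candidates are restricted to the same predefined clan when the
        scenario operates at clan level. Ties are broken uniformly at random;
        the choice is made once per unit per year.
        """
        if uid in self._homophily_target:
            return self._homophily_target[uid]
        pop = self.pop
        own = self.unit_means[self.unit_pos[uid]]
        cands = []
        for other in self.unit_ids:
            if other == uid or self.adults_by_unit[other].size == 0:
                continue
            if (
                self.scenario.level == "predefined_clan"
                and pop.unit_clan[other] != pop.unit_clan[uid]
            ):
                continue
            cands.append(other)
        target: int | None = None
        if cands and own.sum() > 0:
            sims = _bray_curtis_rows(own, self.unit_means[[self.unit_pos[c] for c in cands]])
            if np.isfinite(sims).any():
                best = np.nanmax(sims)
                ties = [c for c, s in zip(cands, sims) if s == best]
                target = int(ties[self.rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
        self._homophily_target[uid] = target
        return target


def tutor_pool(
    pop: Population,
    calf_index: int,
    level: str,
    homophily: bool,
    rng: np.random.Generator,
    caches: _YearCaches | None = None,
    scenario: Scenario | None = None,
) -> np.ndarray:
    """Row indices of the adult tutors available to one calf this year.

    The pool contains only adults (age >= 3), never the calf itself, and is
    restricted to the calf's unit / predefined clan / whole population
    according to ``level``. With homophily the pool is instead the adults of
    the calf's own unit together with those of the single other unit whose
    mean repertoire is most similar to the calf's unit's mean (see
    :meth:`_YearCaches.homophily_target`): behaviourally similar units
    preferentially interact, so their calves hear — and learn from — both.
    When no other unit qualifies the plain level pool is used. An empty
    result signals the caller to fall back to individual learning for the
    year.
    """
    if caches is None:
        scenario = scenario or Scenario.from_abm_id(3 + LEVELS.index(level))
        if homophily and "homophily" not in scenario.biases:
            scenario = replace(scenario, biases=scenario.biases | {"homophily"})
        caches = _YearCaches(pop, scenario, rng)
    uid = int(pop.unit_id[calf_index])
    if homophily:
        target = caches.homophily_target(uid)
        if target is not None:
            return np.concatenate(
                [caches.adults_by_unit[uid], caches.adults_by_unit[target]]
            )
    if level == "unit":
        return caches.adults_by_unit[uid]
    if level == "predefined_clan":
        clan = pop.clan_id[calf_index]
        adults = caches.all_adults
        return adults[pop.clan_id[adults] == clan]
    return caches.all_adults


def assign_symbols(pop: Population, rng: np.random.Generator) -> None:
    """Give every unit its symbolic marker (called once, at year 1).

    Each unit receives six distinct random coda types; every current member's
    frequency at those types is set to 100, and all later calves of the unit
    copy the symbol after each yearly repertoire update.
    """
    members = pop.unit_members()
    for uid in pop.unit_clan:
        symbol = rng.choice(pop.n_codas, size=SYMBOL_SIZE, replace=False)
        pop.unit_symbol[uid] = symbol
        idx = members[uid]
        if idx.size:
            pop.repertoires[np.ix_(idx, symbol)] = 100.0


def compose_repertoire(
    pop: Population,
    calf_index: int,
    scenario: Scenario,
    rng: np.random.Generator,
    caches: _YearCaches | None = None,
) -> None:
    """One calf's yearly repertoire update under ``scenario``.

    Dispatches to the scenario's mechanism, then applies innovation, then
    (in symbolic scenarios) re-enforces the unit's symbol so the marker codas
    always end the year at frequency 100. Fixed repertoires are untouched.
    """
    if pop.repertoire_fixed[calf_index] or pop.age[calf_index] >= CALF_AGE_LIMIT:
        return
    caches = caches or _YearCaches(pop, scenario, rng)
    rep = pop.repertoires[calf_index]
    age = int(pop.age[calf_index])

    if scenario.mechanism == "individual":
        individual_learning(rep, rng=rng)
    elif scenario.mechanism == "genetic":
        if age == 0:
            mid = int(pop.mother_id[calf_index])
            if mid >= 0:
                j = int(np.searchsorted(pop.ids, mid))
                if j < pop.n and pop.ids[j] == mid:
                    inherit_from_mother(rep, pop.repertoires[j])
            # founding calves have no recorded mother: they keep their
            # individually learned initial repertoire
    else:
        pool = tutor_pool(
            pop,
            calf_index,
            level=scenario.level,
            homophily="homophily" in scenario.biases,
            rng=rng,
            caches=caches,
        )
        if pool.size == 0:
            logger.debug(
                "year %d: empty tutor pool for calf %d; individual learning fallback",
                pop.year,
                int(pop.ids[calf_index]),
            )
            individual_learning(rep, rng=rng)
        else:
            oblique_learn(
                rep,
                age,
                pop.repertoires[pool],
                conformist="conformism" in scenario.biases,
                conformity_exponent=scenario.conformity_exponent,
                replace_fraction=scenario.replace_fraction,
                rng=rng,
            )

    innovate(rep, scenario.ilearn, rng=rng)

    if "symbolic" in scenario.biases:
        symbol = pop.unit_symbol.get(int(pop.unit_id[calf_index]))
        if symbol is not None:
            rep[symbol] = 100.0


def compose_repertoires(pop: Population, scenario: Scenario, rng: np.random.Generator) -> int:
    """Yearly learning phase: update every calf's repertoire; returns count.

    Tutor repertoires and unit means are snapshotted once at the start of the
    phase (adults' repertoires are fixed, so tutors are unaffected by the
    calves' concurrent updates). Calves are processed in id order for
    determinism.
    """
    calves = np.flatnonzero((pop.age < CALF_AGE_LIMIT) & ~pop.repertoire_fixed)
    if calves.size == 0:
        return 0
    caches = _YearCaches(pop, scenario, rng)
    for i in calves:
        compose_repertoire(pop, int(i), scenario, rng, caches=caches)
    return int(calves.size)
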