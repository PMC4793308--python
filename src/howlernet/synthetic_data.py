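"""Synthetic populations, floras, transects, and focal feeding records.

The generator emulates the statistical structure of age/sex-structured
primate foraging data: two habitats with small censused groups split into
six age/sex classes, class-graded diet breadth (adults broadest, infants
narrowest), and a tunable nestedness mechanism — with probability ``nu``
an individual's next food plant is drawn preferentially (by current
popularity) from the plants already used by broader-diet classes, making
narrow diets near-subsets of broad ones; with probability ``1 - nu`` it is
drawn uniformly.  At ``nu = 1`` the subset property holds exactly by
construction; at ``nu = 0`` diets are random and no nestedness beyond the
degree sequence is induced.

All draws are reproducible from a single seed, with separate substreams
for population, flora, diets, records, and transects, so changing the
nestedness knob alters diets only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .io_model import (
    AgeClass,
    Habitat,
    Individual,
    InteractionMatrix,
    Item,
    ObservationRecord,
    Sex,
    TransectRecord,
    class_label,
    load_fixture,
    species_items,
)

__all__ = [
    "SyntheticConfig",
    "Scenario",
    "paper_like_config",
    "generate_scenario",
    "generate_diets",
    "generate_transects",
]


#: census matching the study design: 15 individuals in continuous forest
#: (6 adult F, 4 adult M, 1 juvenile F, 1 juvenile M, 2 infant F, 1 infant M)
#: and 18 in fragments (5 adult F, 4 adult M, 4 juvenile F, 3 juvenile M,
#: 1 infant F, 1 infant M).
PAPER_CENSUS = {
    "continuous": {
        "adult_F": 6, "adult_M": 4,
        "juvenile_F": 1, "juvenile_M": 1,
        "infant_F": 2, "infant_M": 1,
    },
    "fragment": {
        "adult_F": 5, "adult_M": 4,
        "juvenile_F": 4, "juvenile_M": 3,
        "infant_F": 1, "infant_M": 1,
    },
}

#: mean diet breadth as a fraction of the habitat's species pool, ordered
#: adult > juvenile > infant (females slightly above males within age), so
#: adult females realize the broadest diets.
DEFAULT_CLASS_BREADTH = {
    "adult_F": 0.52, "adult_M": 0.42,
    "juvenile_F": 0.32, "juvenile_M": 0.28,
    "infant_F": 0.18, "infant_M": 0.14,
}

#: per-(habitat, age) multiplier on mean bout duration, emulating the
#: observed foraging-time contrasts (adults and juveniles foraging longer
#: in fragments, infants barely foraging there).
DEFAULT_TIME_FACTOR = {
    ("continuous", "adult"): 1.0, ("continuous", "juvenile"): 0.5,
    ("continuous", "infant"): 0.9,
    ("fragment", "adult"): 1.4, ("fragment", "juvenile"): 1.3,
    ("fragment", "infant"): 0.1,
}

#: feeding-time weighting across plant items, used to bias the item drawn
#: for each record within a species' item set.
DEFAULT_ITEM_WEIGHTS = {
    "continuous": {"MF": 0.545, "IL": 0.310, "P": 0.062, "ML": 0.038,
                   "B": 0.023, "IF": 0.012, "FL": 0.0073},
    "fragment": {"IL": 0.562, "MF": 0.376, "IF": 0.050, "ML": 0.008,
                 "P": 0.005, "B": 0.0, "FL": 0.0},
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``flora`` maps habitat -> list of available species; ``items`` maps
    habitat -> species -> consumable item codes there.  ``nu`` is the
    nestedness knob in [0, 1].  ``breadth_sd`` is the lognormal spread of
    individual diet size around the class mean fraction.
    """

    census: dict = field(default_factory=lambda: {h: dict(v) for h, v in PAPER_CENSUS.items()})
    flora: dict = field(default_factory=dict)
    items: dict = field(default_factory=dict)
    class_breadth: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_BREADTH))
    breadth_sd: float = 0.15
    nu: float = 0.8
    mean_records_per_link: float = 3.0
    duration_shape: float = 2.0
    duration_mean: float = 3.0  # minutes per bout
    time_factor: dict = field(default_factory=lambda: dict(DEFAULT_TIME_FACTOR))
    item_weights: dict = field(default_factory=lambda: {h: dict(v) for h, v in DEFAULT_ITEM_WEIGHTS.items()})
    n_sites_per_habitat: int = 3
    n_transects_per_site: int = 10
    trees_per_transect_mean: float = 14.0
    abundance_decay: float = 0.88  # geometric rank-abundance ratio
    site_spacing_m: float = 2000.0
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must lie in [0, 1]")
        for cls, frac in self.class_breadth.items():
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"class breadth for {cls} must lie in (0, 1]")
        for hab, cen in self.census.items():
            Habitat(hab)
            for cls, n in cen.items():
                if n < 0:
                    raise ValueError(f"negative census count for {hab}/{cls}")
        for hab, specs in self.flora.items():
            if len(specs) == 0:
                raise ValueError(f"empty flora for habitat {hab}")


def _generic_flora(rng: np.random.Generator) -> tuple[dict, dict]:
    """Random species pool when the caller supplies none: 37 species, 27
    occupying continuous forest and 30 the fragments (20 shared), each
    with 1-3 random consumable items per habitat."""
    pool = [f"Plant_{i:02d}" for i in range(1, 38)]
    shared = list(rng.choice(pool, size=20, replace=False))
    rest = [s for s in pool if s not in shared]
    rng.shuffle(rest)
    cont = shared + rest[:7]
    frag = shared + rest[7:]
    codes = [i.value for i in Item]
    items = {}
    for hab, specs in (("continuous", cont), ("fragment", frag)):
        items[hab] = {
            s: list(rng.choice(codes, size=int(rng.integers(1, 4)), replace=False))
            for s in specs
        }
    return {"continuous": cont, "fragment": frag}, items


def paper_like_config(seed: int | None = None, nu: float = 0.8, **overrides) -> SyntheticConfig:
    """The study-condition preset: censuses of 15 and 18 individuals in the
    six age/sex classes, and the habitat floras and per-species item sets
    taken from the packaged per-species item table (27 species in
    continuous forest, 30 in fragments, 37 total)."""
    table3 = load_fixture("table3_items")
    flora = {}
    items = {}
    for hab in Habitat:
        by_species = {
            s: lst for s, lst in species_items(table3, hab).items() if lst
        }
        flora[hab.value] = sorted(by_species)
        items[hab.value] = by_species
    cfg = SyntheticConfig(flora=flora, items=items, nu=nu, seed=seed, **overrides)
    cfg.validate()
    return cfg


@dataclass
class Scenario:
    """One generated data set: censused individuals, per-habitat floras,
    focal feeding records, and vegetation transects."""

    individuals: list
    records: list
    transects: list
    flora: dict
    config: SyntheticConfig

    def individuals_in(self, habitat: Habitat | str) -> list:
        habitat = Habitat(habitat)
        return [i for i in self.individuals if i.habitat is habitat]


# ---------------------------------------------------------------------------
# Population


def _generate_individuals(config: SyntheticConfig, rng: np.random.Generator) -> list:
    individuals = []
    for hab_name, cen in config.census.items():
        hab = Habitat(hab_name)
        n_sites = config.n_sites_per_habitat
        counter = 0
        for cls, n in cen.items():
            age_name, sex_name = cls.rsplit("_", 1)
            for _ in range(n):
                counter += 1
                group = f"{hab.value[:4]}_g{counter % n_sites + 1}"
                individuals.append(
                    Individual(
                        individual_id=f"{hab.value[:4]}_{cls}_{counter:02d}",
                        sex=Sex(sex_name),
                        age_class=AgeClass(age_name),
                        habitat=hab,
                        group_id=group,
                    )
                )
    return individuals


# ---------------------------------------------------------------------------
# Diets


def generate_diets(
    individuals: Sequence[Individual],
    flora: Sequence[str],
    nu: float,
    class_breadths: dict,
    rng: np.random.Generator,
    breadth_sd: float = 0.15,
) -> InteractionMatrix:
    """Binary diet matrix for one habitat's individuals over its flora.

    Classes are processed from broadest to narrowest mean breadth.  Each
    individual draws its diet size from a lognormal around its class mean
    fraction of the pool, then picks partners one at a time: with
    probability ``nu`` the most popular plant (highest current partner
    degree, ties broken at random) among those already used by strictly
    broader classes, otherwise a uniform random plant.  At ``nu = 1`` a
    narrow class can never leave the broader classes' plant union (its
    diet is truncated instead), making subset diets exact.
    """
    species = list(flora)
    if not species:
        raise ValueError("empty flora")
    s = len(species)
    order = sorted(
        set(ind.class_label for ind in individuals),
        key=lambda c: -class_breadths.get(c, 0.3),
    )
    degree = np.zeros(s)
    col_index = {sp: j for j, sp in enumerate(species)}
    diets: dict[str, set[int]] = {}
    broader_union: set[int] = set()
    for cls in order:
        members = [ind for ind in individuals if ind.class_label == cls]
        class_cols: set[int] = set()
        frac = class_breadths.get(cls, 0.3)
        for ind in members:
            target = int(np.clip(
                round(frac * s * rng.lognormal(0.0, breadth_sd)), 1, s
            ))
            partners: set[int] = set()
            while len(partners) < target:
                pool = list(broader_union - partners)
                if rng.random() < nu and pool:
                    w = degree[pool]
                    top = [p for p, d in zip(pool, w) if d == w.max()]
                    j = int(top[rng.integers(len(top))])
                elif nu >= 1.0 and broader_union:
                    break  # strict subset: pool exhausted, truncate
                else:
                    rest = [j for j in range(s) if j not in partners]
                    if not rest:
                        break
                    j = int(rest[rng.integers(len(rest))])
                partners.add(j)
                degree[j] += 1
            diets[ind.individual_id] = partners
            class_cols |= partners
        broader_union |= class_cols
    row_ids = sorted(diets)
    weights = np.zeros((len(row_ids), s), dtype=int)
    for i, rid in enumerate(row_ids):
        for j in diets[rid]:
            weights[i, j] = 1
    return InteractionMatrix(weights, row_ids, species)


# ---------------------------------------------------------------------------
# Records


def _choose_item(
    item_set: Sequence[str], weights: dict, rng: np.random.Generator
) -> str:
    w = np.array([max(weights.get(it, 0.0), 1e-6) for it in item_set])
    return str(rng.choice(list(item_set), p=w / w.sum()))


def _generate_records(
    config: SyntheticConfig,
    individuals: Sequence[Individual],
    diets: dict,
    items: dict,
    rng: np.random.Generator,
) -> list:
    by_id = {ind.individual_id: ind for ind in individuals}
    records = []
    counter = 0
    for hab_name in sorted(diets):
        matrix: InteractionMatrix = diets[hab_name]
        hab_items = items[hab_name]
        weights = config.item_weights.get(hab_name, {})
        for i, rid in enumerate(matrix.row_labels):
            ind = by_id[rid]
            factor = config.time_factor.get((hab_name, ind.age_class.value), 1.0)
            scale = config.duration_mean * max(factor, 1e-3) / config.duration_shape
            for j in np.flatnonzero(matrix.weights[i]):
                sp = matrix.col_labels[j]
                item_set = hab_items.get(sp) or [it.value for it in Item]
                n_rec = 1 + int(rng.poisson(max(config.mean_records_per_link - 1, 0)))
                for _ in range(n_rec):
                    counter += 1
                    records.append(
                        ObservationRecord(
                            record_id=f"rec_{counter:06d}",
                            habitat=ind.habitat,
                            site_id=ind.group_id,
                            individual_id=rid,
                            sex=ind.sex,
                            age_class=ind.age_class,
                            plant_species=sp,
                            item=Item(_choose_item(item_set, weights, rng)),
                            duration=float(rng.gamma(config.duration_shape, scale)),
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Transects


def generate_transects(
    config: SyntheticConfig,
    rng: np.random.Generator,
    flora: dict | None = None,
) -> list:
    """Vegetation transects: ``n_transects_per_site`` 50 x 2 m transects in
    each of ``n_sites_per_habitat`` sites per habitat, trees >= 10 cm dbh,
    species drawn from a geometric rank-abundance distribution over the
    habitat flora."""
    flora = flora or config.flora
    transects = []
    for h_idx, hab_name in enumerate(sorted(flora)):
        species = list(flora[hab_name])
        ranks = np.arange(len(species))
        w = config.abundance_decay**ranks
        w /= w.sum()
        for s_idx in range(config.n_sites_per_habitat):
            site = f"{hab_name[:4]}_site{s_idx + 1}"
            sx = s_idx * config.site_spacing_m
            sy = h_idx * 10 * config.site_spacing_m
            for t_idx in range(config.n_transects_per_site):
                tx = sx + rng.uniform(-300, 300)
                ty = sy + rng.uniform(-300, 300)
                n_trees = int(rng.poisson(config.trees_per_transect_mean))
                for _ in range(n_trees):
                    transects.append(
                        TransectRecord(
                            site_id=site,
                            habitat=Habitat(hab_name),
                            transect_id=f"{site}_t{t_idx + 1:02d}",
                            x=tx,
                            y=ty,
                            species=str(rng.choice(species, p=w)),
                            dbh=float(10.0 + rng.gamma(1.5, 10.0)),
                        )
                    )
    return transects


# ---------------------------------------------------------------------------
# Scenario


def generate_scenario(config: SyntheticConfig | None = None) -> Scenario:
    """Generate a full data set from the configuration's seed.

    Population, flora, diets, records, and transects each consume an
    independent substream of the master seed, so e.g. changing ``nu``
    regenerates diets and records but leaves the population, flora, and
    transects untouched.
    """
    config = config or paper_like_config()
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    s_pop, s_flora, s_diet, s_rec, s_tran = ss.spawn(5)

    rng_flora = np.random.default_rng(s_flora)
    if config.flora:
        flora, items = config.flora, config.items
    else:
        flora, items = _generic_flora(rng_flora)

    individuals = _generate_individuals(config, np.random.default_rng(s_pop))

    rng_diet = np.random.default_rng(s_diet)
    diets = {}
    for hab_name in sorted(flora):
        hab_inds = [i for i in individuals if i.habitat.value == hab_name]
        if not hab_inds:
            continue
        diets[hab_name] = generate_diets(
            hab_inds,
            flora[hab_name],
            config.nu,
            config.class_breadth,
            rng_diet,
            breadth_sd=config.breadth_sd,
        )

    records = _generate_records(
        config, individuals, diets, items, np.random.default_rng(s_rec)
    )
    transects = generate_transects(config, np.random.default_rng(s_tran), flora)
    return Scenario(
        individuals=individuals,
        records=records,
        transects=transects,
        flora=flora,
        config=config,
    )
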