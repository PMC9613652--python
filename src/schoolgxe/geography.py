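"""Synthetic geography: a nested residential hierarchy crossed with schools.

Municipalities contain districts, districts contain neighbourhoods (strict
nesting, as in the Norwegian grunnkrets system).  Schools are municipal: each
school belongs to one municipality, but its catchment mixes neighbourhoods and
(through feeder-set mixing) districts, so schools are cross-classified with
the two finer residential levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import GeneratorConfig

# Distinct stream tags keep the per-operation RNGs independent under one seed.
_GEO_STREAM = 101


def _allocate(n_items: int, n_parents: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Spread ``n_items`` over ``n_parents`` with Dirichlet-perturbed weights,
    guaranteeing at least one item per parent."""
    if n_items < n_parents:
        raise ValueError(f"cannot allocate {n_items} items over {n_parents} parents")
    weights = rng.dirichlet(np.full(n_parents, alpha))
    counts = np.ones(n_parents, dtype=np.int64)
    counts += rng.multinomial(n_items - n_parents, weights)
    return counts


def _counts_to_parent(counts: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(len(counts)), counts)


@dataclass(frozen=True)
class Geography:
    """Cluster identifiers and the neighbourhood->school feeder structure."""

    municipality_of_district: np.ndarray  # (n_districts,)
    district_of_neighbourhood: np.ndarray  # (n_neighbourhoods,)
    municipality_of_school: np.ndarray  # (n_schools,)
    district_of_school: np.ndarray  # (n_schools,) home district
    school_weight: np.ndarray  # (n_schools,) attractiveness within feeder sets
    neighbourhood_weight: np.ndarray  # (n_neighbourhoods,) population shares
    feeder_schools: tuple  # per neighbourhood: np.ndarray of candidate schools
    primary_school: np.ndarray  # (n_neighbourhoods,)

    @property
    def n_municipalities(self) -> int:
        return int(self.municipality_of_district.max()) + 1

    @property
    def n_districts(self) -> int:
        return len(self.municipality_of_district)

    @property
    def n_neighbourhoods(self) -> int:
        return len(self.district_of_neighbourhood)

    @property
    def n_schools(self) -> int:
        return len(self.school_weight)

    @property
    def municipality_of_neighbourhood(self) -> np.ndarray:
        return self.municipality_of_district[self.district_of_neighbourhood]

    def validate(self) -> None:
        assert self.district_of_neighbourhood.min() >= 0
        assert self.district_of_neighbourhood.max() < self.n_districts
        assert self.municipality_of_district.min() >= 0
        for nb, feeder in enumerate(self.feeder_schools):
            assert self.primary_school[nb] in feeder


def build_geography(config: GeneratorConfig) -> Geography:
    """Build the cluster tree and feeder sets.

    Deterministic given ``config`` (including ``config.seed``).  Raises if the
    requested sizes are inconsistent (e.g. more schools than students).
    """
    config.validate()
    if config.n_schools > config.n_students:
        raise ValueError(
            f"more schools ({config.n_schools}) than students "
            f"({config.n_students}); every school needs a chance of enrolment"
        )
    rng = np.random.default_rng([_GEO_STREAM, config.seed])

    districts_per_muni = _allocate(
        config.n_districts, config.n_municipalities, config.municipality_alloc_alpha, rng
    )
    municipality_of_district = _counts_to_parent(districts_per_muni)
    nbhd_per_district = _allocate(
        config.n_neighbourhoods, config.n_districts, config.district_alloc_alpha, rng
    )
    district_of_neighbourhood = _counts_to_parent(nbhd_per_district)

    # Population shares per neighbourhood (reused when students are placed,
    # so school counts track where students live and expected school sizes
    # stay near n_students / n_schools everywhere).
    neighbourhood_weight = rng.dirichlet(
        np.full(config.n_neighbourhoods, config.neighbourhood_size_alpha)
    )
    district_mass = np.bincount(
        district_of_neighbourhood, weights=neighbourhood_weight, minlength=config.n_districts
    )
    muni_mass = np.bincount(
        municipality_of_district, weights=district_mass, minlength=config.n_municipalities
    )

    # Schools get a home municipality proportional to population, then a home
    # district within it; every municipality keeps a school when possible.
    if config.n_schools >= config.n_municipalities:
        schools_per_muni = np.ones(config.n_municipalities, dtype=np.int64)
        schools_per_muni += rng.multinomial(
            config.n_schools - config.n_municipalities, muni_mass / muni_mass.sum()
        )
    else:
        which = rng.choice(
            config.n_municipalities,
            size=config.n_schools,
            replace=False,
            p=muni_mass / muni_mass.sum(),
        )
        schools_per_muni = np.bincount(which, minlength=config.n_municipalities)
    municipality_of_school = _counts_to_parent(schools_per_muni)

    district_of_school = np.empty(config.n_schools, dtype=np.int64)
    districts_by_muni = [
        np.flatnonzero(municipality_of_district == m) for m in range(config.n_municipalities)
    ]
    s = 0
    for m, k in enumerate(schools_per_muni):
        if k == 0:
            continue
        local = districts_by_muni[m]
        p = district_mass[local] / max(district_mass[local].sum(), 1e-300)
        district_of_school[s : s + k] = rng.choice(local, size=k, p=p)
        s += k

    school_weight = rng.gamma(config.school_size_alpha, size=config.n_schools)
    school_weight = np.maximum(school_weight, 1e-6)

    schools_by_district = [
        np.flatnonzero(district_of_school == d) for d in range(config.n_districts)
    ]
    schools_by_muni = [
        np.flatnonzero(municipality_of_school == m) for m in range(config.n_municipalities)
    ]

    feeder: list[np.ndarray] = []
    primary = np.empty(config.n_neighbourhoods, dtype=np.int64)
    for nb in range(config.n_neighbourhoods):
        d = district_of_neighbourhood[nb]
        m = municipality_of_district[d]
        cand = schools_by_district[d]
        if cand.size == 0:
            cand = schools_by_muni[m]
        elif config.feeder_mixing > 0 and rng.random() < config.feeder_mixing:
            other = np.setdiff1d(schools_by_muni[m], cand, assume_unique=True)
            if other.size:
                cand = np.append(cand, rng.choice(other))
        if cand.size == 0:  # municipality without schools: global fallback
            cand = rng.choice(config.n_schools, size=min(3, config.n_schools), replace=False)
        cand = np.unique(cand)
        w = school_weight[cand]
        primary[nb] = rng.choice(cand, p=w / w.sum())
        feeder.append(cand)

    geo = Geography(
        municipality_of_district=municipality_of_district,
        district_of_neighbourhood=district_of_neighbourhood,
        municipality_of_school=municipality_of_school,
        district_of_school=district_of_school,
        school_weight=school_weight,
        neighbourhood_weight=neighbourhood_weight,
        feeder_schools=tuple(feeder),
        primary_school=primary,
    )
    geo.validate()
    return geo
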