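"""Configuration objects for the synthetic population generator and CLI runs.

The generator emulates a Norwegian register-linked trio cohort: ~23k genotyped
students spread over ~2.6k schools, with a nested residential hierarchy
(municipality > district > neighbourhood) cross-classified with schools.
Defaults reproduce the descriptive structure of that cohort; every field can be
overridden for smaller experiments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any


def _default_fixed_effects() -> dict[str, float]:
    fe = {
        "child_pgi": 0.22,
        "midparent_pgi": 0.15,
        "parent_edu_years": 0.02,
        "parent_income_rank": 0.10,
        "grade_code": 0.0,
    }
    fe.update({f"pc{i}": 0.0 for i in range(1, 11)})
    return fe


@dataclass
class VarianceComponentsTruth:
    """Generating variance components on the standardized-achievement scale.

    The school level carries a correlated random intercept/slope pair
    (intercept variance ``school_intercept_var``, slope variance
    ``school_slope_var`` for the child-PGI slope, covariance ``school_cov``).
    Residential levels carry intercepts only.  Components (school intercept +
    residential + individual + residual) sum to 1 by default, i.e. the outcome
    is on the scale of a standardized achievement composite at PGI = 0.
    """

    school_intercept_var: float = 0.0254
    school_slope_var: float = 0.001156  # slope SD 0.034
    school_cov: float = -0.0025        # slope-intercept correlation ~ -0.46
    neighbourhood_var: float = 0.01
    district_var: float = 0.005
    municipality_var: float = 0.01
    individual_var: float = 0.45
    residual_var: float = 0.4996

    def validate(self) -> None:
        for name in (
            "school_intercept_var",
            "school_slope_var",
            "neighbourhood_var",
            "district_var",
            "municipality_var",
            "individual_var",
            "residual_var",
        ):
            v = getattr(self, name)
            if not (v >= 0):
                raise ValueError(f"variance component {name!r} must be >= 0, got {v}")
        if self.school_det < -1e-12:
            raise ValueError(
                "school intercept/slope covariance matrix is not positive "
                f"semidefinite (det = {self.school_det:.3g})"
            )

    @property
    def school_det(self) -> float:
        return self.school_intercept_var * self.school_slope_var - self.school_cov**2

    @property
    def school_cov_matrix(self):
        import numpy as np

        return np.array(
            [
                [self.school_intercept_var, self.school_cov],
                [self.school_cov, self.school_slope_var],
            ]
        )

    @property
    def total_at_zero(self) -> float:
        """Sum of all components with the school term evaluated at PGI = 0."""
        return (
            self.school_intercept_var
            + self.neighbourhood_var
            + self.district_var
            + self.municipality_var
            + self.individual_var
            + self.residual_var
        )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class GeneratorConfig:
    """Everything needed to simulate a population, reproducibly.

    Counts default to the study descriptives (23,471 students, 2578 schools,
    408 municipalities, 1440 districts, 7700 neighbourhoods).  ``seed`` drives
    every random draw; identical configs give byte-identical tables.
    """

    n_students: int = 23471
    n_schools: int = 2578
    n_municipalities: int = 408
    n_districts: int = 1440
    n_neighbourhoods: int = 7700

    #: target fraction of (occupied) neighbourhoods whose students all attend
    #: one school; the generator calibrates its cohesion probability so the
    #: realised fraction matches this value in expectation.
    neighbourhood_school_concordance: float = 0.84
    #: spousal correlation of the parental PGIs (assortative mating).
    assortative_corr: float = 0.2
    #: variance of the child's deviation from the mid-parent PGI (random
    #: Mendelian segregation).  ``None`` derives the value that standardizes
    #: the child PGI: 1 - (1 + r)/2.
    mendelian_dev_var: float | None = None
    #: between-school variance of the mid-parent PGI (passive rGE via
    #: parent-driven school sorting; sorting never touches the child deviation).
    school_sort_variance: float = 0.026

    # Dirichlet concentration parameters controlling cluster-size dispersion;
    # small values give the long right tails seen in register data
    # (school sizes 1-66, neighbourhood sizes 1-51).
    school_size_alpha: float = 1.5
    neighbourhood_size_alpha: float = 0.7
    district_alloc_alpha: float = 0.8
    municipality_alloc_alpha: float = 0.6
    #: probability that a neighbourhood's feeder set also includes a school
    #: from another district of the same municipality.
    feeder_mixing: float = 0.3

    fixed_effects: dict[str, float] = field(default_factory=_default_fixed_effects)
    subject_slope_sds: dict[str, float] = field(
        default_factory=lambda: {"maths": 0.035, "reading": 0.027, "english": 0.004}
    )
    vc: VarianceComponentsTruth = field(default_factory=VarianceComponentsTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.vc, dict):
            self.vc = VarianceComponentsTruth(**self.vc)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for name in (
            "n_students",
            "n_schools",
            "n_municipalities",
            "n_districts",
            "n_neighbourhoods",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not (0.0 <= self.neighbourhood_school_concordance <= 1.0):
            raise ValueError("neighbourhood_school_concordance must be in [0, 1]")
        if not (-1.0 <= self.assortative_corr <= 1.0):
            raise ValueError("assortative_corr must be in [-1, 1]")
        if self.mendelian_dev_var is not None and self.mendelian_dev_var < 0:
            raise ValueError("mendelian_dev_var must be >= 0")
        if self.school_sort_variance < 0:
            raise ValueError("school_sort_variance must be >= 0")
        if self.school_sort_variance > self.midparent_var + 1e-12:
            raise ValueError(
                "school_sort_variance cannot exceed the mid-parent PGI variance "
                f"({self.midparent_var:.3f})"
            )
        if not (0.0 <= self.feeder_mixing <= 1.0):
            raise ValueError("feeder_mixing must be in [0, 1]")
        if self.n_districts < self.n_municipalities:
            raise ValueError("need at least one district per municipality")
        if self.n_neighbourhoods < self.n_districts:
            raise ValueError("need at least one neighbourhood per district")
        self.vc.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def midparent_var(self) -> float:
        """Theoretical Var(mid-parent PGI) = (1 + r) / 2 for SD-1 parents."""
        return (1.0 + self.assortative_corr) / 2.0

    @property
    def effective_mendelian_dev_var(self) -> float:
        if self.mendelian_dev_var is not None:
            return self.mendelian_dev_var
        return max(1.0 - self.midparent_var, 0.0)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["vc"] = self.vc.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
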