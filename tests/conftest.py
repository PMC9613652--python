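"""Shared fixtures: small simulated cohorts and replicate studies reused
across test modules (session-scoped so the expensive fits run once)."""

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")

from schoolgxe import (
    CrossClassifiedLMM,
    GeneratorConfig,
    RandomStructure,
    RandomTerm,
    VarianceComponentsTruth,
    aggregate_school,
    run_ladder,
    simulate_students,
)
from schoolgxe.ladder import CORE_LADDER, DEFAULT_FIXED


def small_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_students=2000,
        n_schools=200,
        n_municipalities=40,
        n_districts=120,
        n_neighbourhoods=650,
        seed=42,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def tiny_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_students=60,
        n_schools=8,
        n_municipalities=3,
        n_districts=5,
        n_neighbourhoods=12,
        seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def midsize_config(seed: int, **overrides) -> GeneratorConfig:
    """Scaled-down version of the cohort design used for replicate studies:
    ~10k students over ~1k schools, cluster ratios as in the full design."""
    base = dict(
        n_students=10_000,
        n_schools=1000,
        n_municipalities=174,
        n_districts=613,
        n_neighbourhoods=3280,
        seed=seed,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_records():
    records, truth = simulate_students(small_config())
    return records, truth


@pytest.fixture(scope="session")
def tiny_records():
    records, truth = simulate_students(tiny_config())
    return records, truth


@pytest.fixture(scope="session")
def fixed_effect_columns():
    return list(DEFAULT_FIXED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


# -- shared heavyweight studies ---------------------------------------------

@pytest.fixture(scope="session")
def ladder_cohort():
    records, truth = simulate_students(small_config(seed=71))
    covs = aggregate_school(records[records["grade_code"] == 0])
    return records, covs, truth


@pytest.fixture(scope="session")
def core_ladder_result(ladder_cohort):
    records, _, _ = ladder_cohort
    return run_ladder(records)


@pytest.fixture(scope="session")
def recovery_study():
    """Three replicates of the main recovery experiment at ~10k students /
    ~1k schools: generate under the random-slope truth, refit the slope model
    by ML, collect the headline estimates."""
    rows = []
    for seed in (201, 202, 203):
        cfg = midsize_config(seed)
        records, _ = simulate_students(cfg)
        fixed = [c for c in DEFAULT_FIXED if c in records.columns]
        fit = CrossClassifiedLMM.from_dataframe(
            records, "y", fixed, CORE_LADDER["3a"]
        ).fit()
        sch = fit.vcomp["school"]
        prof = fit.variance_profile(np.array([-2.0, 2.0]))
        rows.append(
            {
                "gamma": float(fit.fe_params["child_pgi"]),
                "s00": sch["intercept_var"],
                "s01": sch["cov"],
                "s11": sch["slope_var"],
                "share_m2": float(prof.share[0] * 100),
                "share_p2": float(prof.share[1] * 100),
                "converged": fit.converged,
            }
        )
    return rows


@pytest.fixture(scope="session")
def residential_icc_study():
    """Two replicates without any PGI-by-context interaction: intercept-only
    truth, refit with the full residential intercept model."""
    rows = []
    vc = VarianceComponentsTruth(school_slope_var=0.0, school_cov=0.0)
    for seed in (301, 302):
        cfg = midsize_config(seed, vc=vc)
        records, _ = simulate_students(cfg)
        fixed = [c for c in DEFAULT_FIXED if c in records.columns]
        fit = CrossClassifiedLMM.from_dataframe(
            records, "y", fixed, CORE_LADDER["2d"]
        ).fit()
        rows.append(
            {
                "icc_muni": float(fit.icc("municipality") * 100),
                "icc_nbhd": float(fit.icc("neighbourhood") * 100),
                "icc_district": float(fit.icc("district") * 100),
                "converged": fit.converged,
            }
        )
    return rows


@pytest.fixture(scope="session")
def pgi_sorting_study():
    """Three replicates of the school-sorting proof of concept: child PGI
    clustering before and after adjusting for the mid-parent PGI."""
    structure = RandomStructure((RandomTerm("school", "school_id"),))
    rows = []
    for seed in (401, 402, 403):
        cfg = midsize_config(seed, n_students=20_000, n_schools=2000,
                             n_municipalities=348, n_districts=1227,
                             n_neighbourhoods=6560)
        records, _ = simulate_students(cfg)
        students = records[records["grade_code"] == 0]
        unadj = CrossClassifiedLMM.from_dataframe(
            students, "child_pgi", [], structure
        ).fit()
        adj = CrossClassifiedLMM.from_dataframe(
            students, "child_pgi", ["midparent_pgi"], structure
        ).fit()
        rows.append(
            {
                "icc_unadj": float(unadj.icc("school") * 100),
                "icc_adj": float(adj.icc("school") * 100),
            }
        )
    return rows
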