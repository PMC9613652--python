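"""Mixed-model core: dense-likelihood oracle equivalence, cross-checks
against an independent implementation, BLUP shrinkage, ICCs, the PGI
variance profile, and model-comparison arithmetic."""

import numpy as np
import pandas as pd
import pytest

from schoolgxe import (
    CrossClassifiedLMM,
    GeneratorConfig,
    RandomStructure,
    RandomTerm,
    VarianceComponentsTruth,
    compare,
    lrt,
    simulate_students,
)
from schoolgxe.ladder import CORE_LADDER, DEFAULT_FIXED

from conftest import small_config, tiny_config

FIXED_SMALL = ["child_pgi", "midparent_pgi", "grade_code"]


def dense_profiled_deviance(model: CrossClassifiedLMM, theta) -> float:
    """Independent oracle: direct dense multivariate-normal evaluation of the
    profiled deviance via V = I + Z Lam Lam' Z'."""
    d = model.design
    lam = d.lambda_(np.asarray(theta, float)).toarray()
    Z = d.Z.toarray()
    V = np.eye(d.n) + Z @ lam @ lam.T @ Z.T
    Vi = np.linalg.inv(V)
    X, y = d.X, d.y
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = (r @ Vi @ r) / d.n
    _, logdetV = np.linalg.slogdet(V)
    return logdetV + d.n * np.log(2 * np.pi * s2) + d.n


@pytest.fixture(scope="module")
def tiny():
    records, _ = simulate_students(tiny_config())
    return records


@pytest.fixture(scope="module")
def small_fits():
    records, _ = simulate_students(small_config())
    fixed = [c for c in DEFAULT_FIXED if c in records.columns]
    fits = {}
    for label in ("1", "2a", "2b", "2c", "2d", "3a"):
        fits[label] = CrossClassifiedLMM.from_dataframe(
            records, "y", fixed, CORE_LADDER[label]
        ).fit()
    return fits


@pytest.mark.parametrize("label", list(CORE_LADDER))
def test_dense_oracle_equivalence(tiny, label):
    """Sparse profiled deviance == dense GLS/MVN evaluation for every ladder
    structure, at several theta points."""
    model = CrossClassifiedLMM.from_dataframe(tiny, "y", FIXED_SMALL, CORE_LADDER[label])
    rng = np.random.default_rng(5)
    for _ in range(3):
        th = model.design.theta_start() * rng.uniform(0.3, 1.7, model.design.n_theta)
        assert model.deviance(th) == pytest.approx(
            dense_profiled_deviance(model, th), abs=1e-6
        )


def test_reml_matches_statsmodels_and_ml():
    """One-level random-intercept fit agrees with statsmodels MixedLM
    (independent implementation) under both ML and REML."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(3)
    m_cl, k = 40, 12
    grp = np.repeat(np.arange(m_cl), k)
    x = rng.standard_normal(m_cl * k)
    y = 1.0 + 0.3 * x + rng.normal(0, 0.5, m_cl)[grp] + rng.normal(0, 1, m_cl * k)
    df = pd.DataFrame({"y": y, "x": x, "g": grp})
    structure = RandomStructure((RandomTerm("grp", "g"),))
    for reml in (False, True):
        ours = CrossClassifiedLMM.from_dataframe(df, "y", ["x"], structure).fit(
            method="REML" if reml else "ML"
        )
        theirs = sm.MixedLM(y, np.column_stack([np.ones(len(y)), x]), groups=grp).fit(
            reml=reml
        )
        assert ours.llf == pytest.approx(theirs.llf, abs=1e-4)
        np.testing.assert_allclose(ours.fe_params.to_numpy(), theirs.fe_params, atol=1e-5)
        assert ours.vcomp["grp"]["intercept_var"] == pytest.approx(
            float(np.asarray(theirs.cov_re)[0, 0]), abs=2e-4
        )
        assert ours.sigma2 == pytest.approx(theirs.scale, abs=2e-4)


def test_aic_identity_exact(small_fits):
    for fit in small_fits.values():
        assert fit.aic == -2.0 * fit.llf + 2.0 * fit.n_params


def test_likelihood_monotone_in_random_terms(small_fits):
    """Adding a random term can only improve the maximised log-likelihood."""
    order = ["1", "2a", "2b", "2c", "2d", "3a"]
    lls = [small_fits[k].llf for k in order]
    for a, b in zip(lls, lls[1:]):
        assert b >= a - 1e-3


def test_zero_school_variance_truth_recovered():
    cfg = small_config(
        vc=VarianceComponentsTruth(
            school_intercept_var=0.0, school_slope_var=0.0, school_cov=0.0
        ),
        seed=61,
    )
    records, _ = simulate_students(cfg)
    fit = CrossClassifiedLMM.from_dataframe(
        records, "y", FIXED_SMALL, CORE_LADDER["3a"]
    ).fit()
    assert fit.vcomp["school"]["intercept_var"] < 5e-3
    assert fit.vcomp["school"]["slope_var"] < 5e-4


def test_blup_shrinkage_and_null_case(small_fits):
    fit = small_fits["3a"]
    re = fit.random_effects("school")
    # predicted slope deviations shrink: their variance cannot exceed the
    # estimated slope variance
    assert re["slope_dev"].var() <= fit.vcomp["school"]["slope_var"] + 1e-10
    assert np.allclose(re["slope"], re["slope_dev"] + fit.fe_params["child_pgi"])


def test_blup_matches_per_cluster_ols_for_large_clusters(rng):
    """With huge balanced clusters and no other structure, shrinkage vanishes
    and BLUP slopes approach per-cluster OLS slopes (the oracle)."""
    m_cl, k = 30, 400
    grp = np.repeat(np.arange(m_cl), k)
    g = rng.standard_normal(m_cl * k)
    u0 = rng.normal(0, 0.5, m_cl)
    u1 = rng.normal(0, 0.3, m_cl)
    y = u0[grp] + (0.2 + u1[grp]) * g + rng.normal(0, 0.5, m_cl * k)
    df = pd.DataFrame({"y": y, "g": g, "school": grp})
    fit = CrossClassifiedLMM.from_dataframe(
        df, "y", ["g"], RandomStructure((RandomTerm("school", "school", slope="g"),))
    ).fit()
    blup = fit.random_effects("school")["slope"]
    ols = df.groupby("school").apply(
        lambda s: np.polyfit(s["g"], s["y"], 1)[0], include_groups=False
    )
    np.testing.assert_allclose(blup.to_numpy(), ols.to_numpy(), atol=0.02)


def test_icc_decomposition_sums_to_one(small_fits):
    fit = small_fits["2d"]
    total_shares = sum(fit.icc(lv) for lv in fit.vcomp) + fit.sigma2 / fit.total_variance()
    assert total_shares == pytest.approx(1.0, abs=1e-12)


def test_school_icc_of_child_pgi_and_within_family_adjustment(pgi_sorting_study):
    """Sorting on parents clusters the child PGI in schools (~2.6%); adjusting
    for the mid-parent PGI removes the clustering (ICC drops to boundary-
    censored noise, SD ~0.3 percentage points per replicate)."""
    unadj = np.array([r["icc_unadj"] for r in pgi_sorting_study])
    adj = np.array([r["icc_adj"] for r in pgi_sorting_study])
    assert unadj.mean() == pytest.approx(2.6, abs=0.8)
    assert (adj < 1.2).all()
    assert adj.mean() < 0.2 * unadj.mean()


def test_variance_profile_quadratic_oracle(small_fits):
    """share(g) recomputed from the fitted components by plain algebra."""
    fit = small_fits["3a"]
    c = fit.vcomp["school"]
    grid = np.array([-2.0, 0.0, 2.0])
    prof = fit.variance_profile(grid)
    for g, var, tot in zip(prof.grid, prof.variance, prof.total):
        var_oracle = c["intercept_var"] + 2 * g * c["cov"] + g**2 * c["slope_var"]
        assert var == pytest.approx(var_oracle, abs=1e-12)
        others = sum(
            fit.vcomp[lv]["intercept_var"] for lv in fit.vcomp if lv != "school"
        )
        assert tot == pytest.approx(var_oracle + others + fit.sigma2, abs=1e-12)
    # minimum of the quadratic sits at g = -cov / slope_var
    if c["slope_var"] > 1e-8:
        g_min = -c["cov"] / c["slope_var"]
        dense = fit.variance_profile(np.linspace(g_min - 1, g_min + 1, 201))
        assert abs(dense.grid[np.argmin(dense.variance)] - g_min) < 0.02


def test_variance_profile_flat_without_slope(small_fits):
    prof = small_fits["2d"].variance_profile(np.linspace(-2, 2, 5))
    assert np.ptp(prof.share) == pytest.approx(0.0, abs=1e-15)


def test_row_permutation_and_relabelling_invariance(tiny):
    fixed = FIXED_SMALL
    base = CrossClassifiedLMM.from_dataframe(tiny, "y", fixed, CORE_LADDER["2b"]).fit()
    shuffled = tiny.sample(frac=1.0, random_state=1).reset_index(drop=True)
    shuffled["school_id"] = shuffled["school_id"].map(lambda s: f"S{s + 1000}")
    other = CrossClassifiedLMM.from_dataframe(shuffled, "y", fixed, CORE_LADDER["2b"]).fit()
    assert other.llf == pytest.approx(base.llf, abs=1e-4)
    assert other.vcomp["school"]["intercept_var"] == pytest.approx(
        base.vcomp["school"]["intercept_var"], abs=1e-5
    )


def test_lrt_identical_fits_and_boundary_mixture(small_fits):
    same = lrt(small_fits["2a"], small_fits["2b"])
    assert same["df"] == 1
    # one variance tested on its boundary: mixture p is half the naive chi2_1 p
    assert same["p_mixture"] == pytest.approx(0.5 * same["p_naive"], abs=1e-12)
    # a model compared against itself: zero statistic, naive p = 1
    class _Fake:
        pass
    a, b = _Fake(), _Fake()
    a.llf, a.n_params = -100.0, 5
    b.llf, b.n_params = -100.0, 7
    out = lrt(a, b)
    assert out["stat"] == 0.0 and out["p_naive"] == 1.0


def test_compare_table_daic(small_fits):
    tab = compare(small_fits)
    assert tab["d_aic"].min() == 0.0
    np.testing.assert_allclose(tab["aic"], -2 * tab["loglik"] + 2 * tab["n_params"])


def test_errors_missing_singular_and_few_clusters(tiny):
    data = tiny.copy()
    data.loc[data.index[0], "child_pgi"] = np.nan
    with pytest.raises(ValueError, match="missing values.*child_pgi"):
        CrossClassifiedLMM.from_dataframe(data, "y", FIXED_SMALL, CORE_LADDER["1"])
    data2 = tiny.copy()
    data2["dup"] = data2["child_pgi"]
    with pytest.raises(ValueError, match="singular|collinear"):
        CrossClassifiedLMM.from_dataframe(
            data2, "y", FIXED_SMALL + ["dup"], CORE_LADDER["1"]
        )
    data3 = tiny.copy()
    data3["one_cluster"] = 0
    with pytest.raises(ValueError, match=">= 2 clusters"):
        CrossClassifiedLMM.from_dataframe(
            data3, "y", FIXED_SMALL,
            RandomStructure((RandomTerm("oc", "one_cluster"),)),
        )
    with pytest.raises(ValueError, match="columns not in data|unknown slope"):
        CrossClassifiedLMM.from_dataframe(
            tiny, "y", FIXED_SMALL,
            RandomStructure((RandomTerm("school", "school_id", slope="nope"),)),
        )
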