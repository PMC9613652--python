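"""Trio transmission, school sorting, and outcome generation.

The genetic model is deliberately simple: parental polygenic indices (PGI) are
standard normal with a spousal correlation (assortative mating); the child PGI
is the mid-parent average plus an independent Mendelian segregation deviation.
School sorting acts on the *parental* PGI only — the child deviation is random
with respect to every cluster — so conditional on the mid-parent PGI the
assignment of children to schools is as-if randomised, mirroring the
within-family identification strategy of the analysis.

Achievement is generated from the random-intercept/random-slope structure that
the analysis fits: fixed effects, a correlated (intercept, PGI-slope) pair per
school, residential intercepts, a stable individual intercept across the three
test grades (codes -4, -1, 0 for grades 5, 8, 9) and an occasion residual.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GeneratorConfig
from .geography import Geography, build_geography

logger = logging.getLogger(__name__)

_TRIO_STREAM = 202
_ASSIGN_STREAM = 303
_COV_STREAM = 404
_ACH_STREAM = 505

GRADE_CODES = (-4, -1, 0)  # grades 5, 8, 9

STUDENT_COLUMNS = [
    "child_id",
    "family_id",
    "school_id",
    "nbhd_id",
    "district_id",
    "muni_id",
    "grade_code",
    "y",
    "y_maths",
    "y_read",
    "y_eng",
    "child_pgi",
    "mother_pgi",
    "father_pgi",
    "midparent_pgi",
    "parent_edu_years",
    "parent_income",
    "parent_income_rank",
    "nonwestern",
    "sex",
    "age",
    "test_age",
] + [f"pc{i}" for i in range(1, 11)]


# ---------------------------------------------------------------------------
# trios
# ---------------------------------------------------------------------------

def simulate_trios(config: GeneratorConfig, n: int | None = None) -> pd.DataFrame:
    """Draw ``n`` independent parent-offspring trios.

    Parents are marginally N(0, 1) with spousal correlation
    ``config.assortative_corr``; ``midparent_pgi`` is exactly the parental
    average; the child adds an independent N(0, mendelian_dev_var) deviation.
    """
    if n is None:
        n = config.n_students
    if n < 1:
        raise ValueError("need at least one trio")
    r = config.assortative_corr
    if not (-1.0 <= r <= 1.0):
        raise ValueError("assortative_corr must be in [-1, 1]")
    rng = np.random.default_rng([_TRIO_STREAM, config.seed])
    z = rng.standard_normal((n, 2))
    mother = z[:, 0]
    father = r * z[:, 0] + np.sqrt(max(1.0 - r**2, 0.0)) * z[:, 1]
    mid = 0.5 * (mother + father)
    dev_var = config.effective_mendelian_dev_var
    child = mid + rng.normal(0.0, np.sqrt(dev_var), size=n) if dev_var > 0 else mid.copy()
    return pd.DataFrame(
        {
            "family_id": np.arange(n),
            "mother_pgi": mother,
            "father_pgi": father,
            "child_pgi": child,
            "midparent_pgi": mid,
        }
    )


# ---------------------------------------------------------------------------
# assignment (geographic placement + parental-PGI sorting)
# ---------------------------------------------------------------------------

def assign_schools(
    geography: Geography, trios: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Place each family in a neighbourhood and a school.

    Two calibrated mechanisms:

    * concordance — a neighbourhood is "cohesive" (all of its students attend
      its primary school) with a probability solved analytically so that the
      expected fraction of occupied single-school neighbourhoods equals
      ``config.neighbourhood_school_concordance`` (non-cohesive students
      scatter over the feeder set, and size-1 neighbourhoods are single-school
      by definition, so the raw cohesion probability is not the target);
    * sorting — schools receive sorting effects with variance
      ``config.school_sort_variance``; families are rank-matched to school
      slots on their mid-parent PGI (a Gaussian-copula assignment), which
      reproduces that between-school parental-PGI variance without ever using
      the child's Mendelian deviation.
    """
    n = len(trios)
    rng = np.random.default_rng([_ASSIGN_STREAM, config.seed])
    n_nbhd = geography.n_neighbourhoods

    sizes = rng.multinomial(n, geography.neighbourhood_weight)
    occupied = np.flatnonzero(sizes)

    # P(all students of nbhd land in one school | independent scatter)
    c = config.neighbourhood_school_concordance
    pi = np.empty(len(occupied))
    for j, nb in enumerate(occupied):
        cand = geography.feeder_schools[nb]
        pw = geography.school_weight[cand]
        pw = pw / pw.sum()
        pi[j] = float(np.sum(pw ** sizes[nb])) if cand.size > 1 else 1.0
    pi_bar = float(pi.mean())
    if pi_bar >= 1.0 - 1e-12:
        p_cohesive = 1.0
    else:
        p_cohesive = float(np.clip((c - pi_bar) / (1.0 - pi_bar), 0.0, 1.0))
    if c < pi_bar - 1e-9:
        logger.warning(
            "requested concordance %.2f below the chance floor %.2f implied by "
            "feeder sets; realised concordance will exceed the target",
            c,
            pi_bar,
        )

    nbhd_of_slot = np.repeat(np.arange(n_nbhd), sizes)
    school_of_slot = np.empty(n, dtype=np.int64)
    pos = np.concatenate([[0], np.cumsum(sizes)])
    cohesive = rng.random(n_nbhd) < p_cohesive
    for nb in occupied:
        lo, hi = pos[nb], pos[nb + 1]
        cand = geography.feeder_schools[nb]
        if cohesive[nb] or cand.size == 1:
            school_of_slot[lo:hi] = geography.primary_school[nb]
        else:
            pw = geography.school_weight[cand]
            school_of_slot[lo:hi] = rng.choice(cand, size=hi - lo, p=pw / pw.sum())

    # sorting: rank-match families to slots on the mid-parent PGI
    s_var = config.school_sort_variance
    var_mid = config.midparent_var
    if s_var > 0:
        delta = rng.normal(0.0, np.sqrt(s_var), size=geography.n_schools)
        target = delta[school_of_slot] + rng.normal(
            0.0, np.sqrt(max(var_mid - s_var, 0.0)), size=n
        )
        slot_order = np.argsort(target, kind="stable")
        fam_order = np.argsort(trios["midparent_pgi"].to_numpy(), kind="stable")
        family_of_slot = np.empty(n, dtype=np.int64)
        family_of_slot[slot_order] = fam_order
    else:
        family_of_slot = rng.permutation(n)

    district = geography.district_of_neighbourhood[nbhd_of_slot]
    out = pd.DataFrame(
        {
            "family_id": trios["family_id"].to_numpy()[family_of_slot],
            "school_id": school_of_slot,
            "nbhd_id": nbhd_of_slot,
            "district_id": district,
            "muni_id": geography.municipality_of_district[district],
        }
    )
    return out.sort_values("family_id", ignore_index=True)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def simulate_covariates(
    trios: pd.DataFrame, assignment: pd.DataFrame, config: GeneratorConfig
) -> pd.DataFrame:
    """Parental SES, demographics, ancestry PCs and an immigrant-origin label.

    Parental education and income correlate moderately with the mid-parent PGI
    (so school sorting induces realistic school-level SES differences); income
    is ranked within birth cohort on the [0, 1] scale downstream models use.
    """
    from .preprocess import income_rank

    rng = np.random.default_rng([_COV_STREAM, config.seed])
    n = len(trios)
    mid_z = trios["midparent_pgi"].to_numpy() / np.sqrt(config.midparent_var)

    edu = 14.0 + 2.5 * (0.35 * mid_z + np.sqrt(1 - 0.35**2) * rng.standard_normal(n))
    income_latent = (
        0.35 * (edu - 14.0) / 2.5 + 0.25 * mid_z + 0.9 * rng.standard_normal(n)
    )
    income = 430.0 * np.exp(0.45 * income_latent)  # kNOK-ish, right-skewed
    birth_year = rng.integers(2002, 2007, size=n)
    rank = income_rank(pd.Series(income), pd.Series(birth_year)).to_numpy()

    # immigrant-origin label clusters by school (prevalence varies by school)
    n_schools = int(assignment["school_id"].max()) + 1
    logit = np.log(0.07 / 0.93) + 0.8 * rng.standard_normal(n_schools)
    p_school = 1.0 / (1.0 + np.exp(-logit))
    nonwestern = (rng.random(n) < p_school[assignment["school_id"].to_numpy()]).astype(int)

    cov = pd.DataFrame(
        {
            "family_id": trios["family_id"].to_numpy(),
            "parent_edu_years": edu,
            "parent_income": income,
            "parent_income_rank": rank,
            "nonwestern": nonwestern,
            "sex": rng.integers(0, 2, size=n),
            "birth_year": birth_year,
            "age": 14.0 + rng.uniform(0.0, 1.0, size=n),  # age at grade 9
        }
    )
    pcs = rng.standard_normal((n, 10))
    for i in range(10):
        cov[f"pc{i + 1}"] = pcs[:, i]
    return cov


# ---------------------------------------------------------------------------
# achievement
# ---------------------------------------------------------------------------

def simulate_achievement(students: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Expand one-row-per-student data to the long grade 5/8/9 table and add
    outcomes.

    ``students`` needs cluster ids, PGI columns and covariates (the output of
    the earlier pipeline stages, merged on ``family_id``).  The composite
    outcome ``y`` uses the variance components in ``config.vc``; per-subject
    outcomes reuse the school intercept but draw subject-specific slope
    effects with SDs ``config.subject_slope_sds`` (English is missing at grade
    9, as in the register data).
    """
    config.vc.validate()  # refuse non-PSD school covariance before sampling
    vc = config.vc
    rng = np.random.default_rng([_ACH_STREAM, config.seed])
    n = len(students)

    n_schools = int(students["school_id"].max()) + 1
    n_nbhd = int(students["nbhd_id"].max()) + 1
    n_dist = int(students["district_id"].max()) + 1
    n_muni = int(students["muni_id"].max()) + 1

    # PSD square root via eigendecomposition (exact zeros stay exact)
    w, V = np.linalg.eigh(vc.school_cov_matrix)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    school_eff = rng.standard_normal((n_schools, 2)) @ root.T  # (u0, u1)
    u_nbhd = rng.normal(0.0, np.sqrt(vc.neighbourhood_var), n_nbhd)
    u_dist = rng.normal(0.0, np.sqrt(vc.district_var), n_dist)
    u_muni = rng.normal(0.0, np.sqrt(vc.municipality_var), n_muni)
    u_ind = rng.normal(0.0, np.sqrt(vc.individual_var), n)

    sid = students["school_id"].to_numpy()
    g = students["child_pgi"].to_numpy()

    fixed_student = np.zeros(n)
    for name, coef in config.fixed_effects.items():
        if name == "grade_code" or coef == 0.0:
            continue
        if name not in students.columns:
            raise KeyError(f"fixed effect {name!r} not among student columns")
        fixed_student += coef * students[name].to_numpy()

    base = (
        fixed_student
        + school_eff[sid, 0]
        + school_eff[sid, 1] * g
        + u_nbhd[students["nbhd_id"].to_numpy()]
        + u_dist[students["district_id"].to_numpy()]
        + u_muni[students["muni_id"].to_numpy()]
        + u_ind
    )

    subj_slopes = {
        subj: rng.normal(0.0, sd, n_schools) if sd > 0 else np.zeros(n_schools)
        for subj, sd in config.subject_slope_sds.items()
    }

    grade_coef = config.fixed_effects.get("grade_code", 0.0)
    rows = []
    for code in GRADE_CODES:
        rec = students.copy()
        rec["grade_code"] = code
        rec["test_age"] = (
            students["age"].to_numpy() + code + rng.normal(0.0, 0.1, n)
        )
        eps = rng.normal(0.0, np.sqrt(vc.residual_var), n)
        rec["y"] = base + grade_coef * code + eps
        for subj, col in (("maths", "y_maths"), ("reading", "y_read"), ("english", "y_eng")):
            eps_s = rng.normal(0.0, np.sqrt(vc.residual_var), n)
            ys = (
                base
                - school_eff[sid, 1] * g  # swap composite slope for subject slope
                + subj_slopes[subj][sid] * g
                + grade_coef * code
                + eps_s
            )
            if subj == "english" and code == 0:
                rec[col] = np.nan
            else:
                rec[col] = ys
        rows.append(rec)

    out = pd.concat(rows, ignore_index=True)
    out["child_id"] = out["family_id"]  # one child per family
    out = out.sort_values(["child_id", "grade_code"], ignore_index=True)
    return out[[c for c in STUDENT_COLUMNS if c in out.columns]]


# ---------------------------------------------------------------------------
# pipeline + on-disk formats
# ---------------------------------------------------------------------------

def simulate_students(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Full generator pipeline: geography -> trios -> assignment -> covariates
    -> achievement.  Returns the long student table and a truth sidecar."""
    geo = build_geography(config)
    trios = simulate_trios(config, config.n_students)
    assignment = assign_schools(geo, trios, config)
    cov = simulate_covariates(trios, assignment, config)
    students = trios.merge(assignment, on="family_id").merge(cov, on="family_id")
    records = simulate_achievement(students, config)
    truth = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "derived": {
            "midparent_var": config.midparent_var,
            "mendelian_dev_var": config.effective_mendelian_dev_var,
            "n_records": int(len(records)),
            "n_students": int(records["child_id"].nunique()),
            "n_schools_occupied": int(records["school_id"].nunique()),
            "n_neighbourhoods_occupied": int(records["nbhd_id"].nunique()),
        },
    }
    return records, truth


def write_students(records: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    records.to_csv(path, sep=sep, index=False)


def read_students(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def write_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
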