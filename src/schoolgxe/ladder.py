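"""The model-fitting ladder: base model, random intercepts level by level,
PGI random slopes level by level, then school-covariate models.

Core ladder (9 models), fitted in order by ML so AICs are comparable:

* 1    — fixed effects + individual random intercept
* 2a-d — + random intercepts for school, then neighbourhood, district,
         municipality (cumulative)
* 3a-d — + child-PGI random slopes for school, then the residential levels
         (cumulative, on top of 2d)

With school covariates supplied, two more models extend 3a's structure:

* 4 — + the five school sociodemographic measures as fixed effects
* 5 — + their five interactions with the child PGI

giving the full 11-model table.  Selection is by strictly lowest AIC among
converged fits; ties (below 1e-6) go to the simpler model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import CrossClassifiedLMM, CrossClassifiedLMMResults, RandomStructure, RandomTerm, compare
from .sociodemo import SCHOOL_MEASURES

logger = logging.getLogger(__name__)

DEFAULT_FIXED = [
    "child_pgi",
    "midparent_pgi",
    "parent_edu_years",
    "parent_income_rank",
    "grade_code",
] + [f"pc{i}" for i in range(1, 11)]

_IND = RandomTerm("individual", "child_id")
_SCHOOL_RI = RandomTerm("school", "school_id")
_SCHOOL_RS = RandomTerm("school", "school_id", slope="child_pgi")
_NBHD_RI = RandomTerm("neighbourhood", "nbhd_id")
_NBHD_RS = RandomTerm("neighbourhood", "nbhd_id", slope="child_pgi")
_DIST_RI = RandomTerm("district", "district_id")
_DIST_RS = RandomTerm("district", "district_id", slope="child_pgi")
_MUNI_RI = RandomTerm("municipality", "muni_id")
_MUNI_RS = RandomTerm("municipality", "muni_id", slope="child_pgi")

CORE_LADDER: dict[str, RandomStructure] = {
    "1": RandomStructure((_IND,)),
    "2a": RandomStructure((_IND, _SCHOOL_RI)),
    "2b": RandomStructure((_IND, _SCHOOL_RI, _NBHD_RI)),
    "2c": RandomStructure((_IND, _SCHOOL_RI, _NBHD_RI, _DIST_RI)),
    "2d": RandomStructure((_IND, _SCHOOL_RI, _NBHD_RI, _DIST_RI, _MUNI_RI)),
    "3a": RandomStructure((_IND, _SCHOOL_RS, _NBHD_RI, _DIST_RI, _MUNI_RI)),
    "3b": RandomStructure((_IND, _SCHOOL_RS, _NBHD_RS, _DIST_RI, _MUNI_RI)),
    "3c": RandomStructure((_IND, _SCHOOL_RS, _NBHD_RS, _DIST_RS, _MUNI_RI)),
    "3d": RandomStructure((_IND, _SCHOOL_RS, _NBHD_RS, _DIST_RS, _MUNI_RS)),
}

#: nested comparisons reported with LRT p-values
LRT_PAIRS = [
    ("1", "2a"),
    ("2a", "2b"),
    ("2b", "2c"),
    ("2c", "2d"),
    ("2d", "3a"),
    ("3a", "3b"),
    ("3b", "3c"),
    ("3c", "3d"),
]


@dataclass
class LadderResult:
    """All fits of one ladder run plus the comparison table."""

    fits: dict[str, CrossClassifiedLMMResults]
    table: pd.DataFrame
    selected: str | None
    failures: dict[str, str] = field(default_factory=dict)
    attenuation: float | None = None

    @property
    def slope_variance_trajectory(self) -> pd.Series:
        vals = {}
        for label, fit in self.fits.items():
            school = fit.vcomp.get("school", {})
            if "slope_var" in school:
                vals[label] = school["slope_var"]
        return pd.Series(vals, name="school_slope_var")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "failures": self.failures,
            "attenuation": self.attenuation,
            "models": {label: fit.to_dict() for label, fit in self.fits.items()},
        }


def _select(table: pd.DataFrame) -> str | None:
    ok = table[table["converged"]]
    if ok.empty:
        logger.warning("ladder: no converged models; nothing selected")
        return None
    if not table["converged"].all():
        logger.warning(
            "ladder: skipping non-converged models in selection: %s",
            list(table.loc[~table["converged"], "model"]),
        )
    best_aic = ok["aic"].min()
    near = ok[ok["aic"] <= best_aic + 1e-6]
    # ties go to the simplest model
    return str(near.sort_values(["n_params", "model"]).iloc[0]["model"])


def _fit_one(
    records: pd.DataFrame,
    fixed: list[str],
    structure: RandomStructure,
    response: str,
    method: str,
    start: np.ndarray | None,
):
    model = CrossClassifiedLMM.from_dataframe(records, response, fixed, structure)
    return model.fit(method=method, start=start)


class _WarmStart:
    """Reuse a fitted model's theta for shared levels; new levels start at
    modest defaults.  Cuts optimiser iterations roughly in half."""

    def __init__(self, prev: CrossClassifiedLMMResults):
        self.prev_theta: dict[tuple[str, int, int], float] = {}
        j = 0
        for td in prev.model.design.terms:
            for jj in range(td.term.n_theta):
                self.prev_theta[(td.term.level, td.term.k, jj)] = prev.theta[j]
                j += 1

    def for_model(self, model: CrossClassifiedLMM) -> np.ndarray:
        start = []
        for td in model.design.terms:
            t = td.term
            if t.k == 1:
                start.append(self.prev_theta.get((t.level, 1, 0), 0.3))
            else:
                # reuse an intercept-only fit's SD for the intercept entry
                d0 = self.prev_theta.get(
                    (t.level, 2, 0), self.prev_theta.get((t.level, 1, 0), 0.3)
                )
                start += [
                    d0,
                    self.prev_theta.get((t.level, 2, 1), 0.0),
                    self.prev_theta.get((t.level, 2, 2), 0.05),
                ]
        return np.array(start)


def run_ladder(
    records: pd.DataFrame,
    school_covariates: pd.DataFrame | None = None,
    fixed: list[str] | None = None,
    response: str = "y",
    method: str = "ML",
) -> LadderResult:
    """Fit the full ladder on preprocessed records.

    Fail-soft: a model that errors is recorded in ``failures`` and the ladder
    continues.  Returns fits, the AIC/LRT comparison table, the selected
    label, and (when covariate models ran) the slope-variance attenuation
    ratio sigma^2_slope(Model 5) / sigma^2_slope(Model 3a).
    """
    if fixed is None:
        fixed = [c for c in DEFAULT_FIXED if c in records.columns]
    fits: dict[str, CrossClassifiedLMMResults] = {}
    failures: dict[str, str] = {}
    warm: _WarmStart | None = None
    for label, structure in CORE_LADDER.items():
        try:
            model = CrossClassifiedLMM.from_dataframe(records, response, fixed, structure)
            start = warm.for_model(model) if warm else None
            fits[label] = model.fit(method=method, start=start)
            warm = _WarmStart(fits[label])
        except Exception as err:  # fail-soft
            logger.warning("ladder: model %s failed: %s", label, err)
            failures[label] = str(err)

    attenuation = None
    if school_covariates is not None:
        cov_fits, cov_failures, attenuation = _covariate_fits(
            records, school_covariates, fixed, response, method, fits.get("3a")
        )
        fits.update(cov_fits)
        failures.update(cov_failures)

    pairs = [(a, b) for a, b in LRT_PAIRS if a in fits and b in fits]
    table = compare(fits, lrt_pairs=pairs) if fits else pd.DataFrame()
    selected = _select(table) if len(table) else None
    if selected is not None:
        table["selected"] = table["model"] == selected
    return LadderResult(
        fits=fits, table=table, selected=selected, failures=failures, attenuation=attenuation
    )


def _covariate_fits(records, school_covariates, fixed, response, method, fit3a):
    data = records.merge(school_covariates, on="school_id", how="left", validate="many_to_one")
    missing = data[SCHOOL_MEASURES].isna().any(axis=1)
    if missing.any():
        logger.warning(
            "covariate models: dropping %d rows from schools without covariates",
            int(missing.sum()),
        )
        data = data[~missing].copy()
    # standardize measures across schools so coefficients are comparable
    for m in SCHOOL_MEASURES:
        x = data[m].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        data[m] = (x - x.mean()) / sd if sd > 0 else 0.0
        data[f"{m}_x_pgi"] = data[m] * data["child_pgi"]

    structure = CORE_LADDER["3a"]
    fits, failures = {}, {}
    fixed4 = list(fixed) + SCHOOL_MEASURES
    fixed5 = fixed4 + [f"{m}_x_pgi" for m in SCHOOL_MEASURES]
    start = np.array(fit3a.theta) if fit3a is not None else None
    for label, fx in (("4", fixed4), ("5", fixed5)):
        try:
            model = CrossClassifiedLMM.from_dataframe(data, response, fx, structure)
            fits[label] = model.fit(method=method, start=start)
            start = fits[label].theta
        except Exception as err:
            logger.warning("ladder: model %s failed: %s", label, err)
            failures[label] = str(err)

    attenuation = None
    if fit3a is not None and "5" in fits:
        v3a = fit3a.vcomp["school"]["slope_var"]
        v5 = fits["5"].vcomp["school"]["slope_var"]
        attenuation = float(v5 / v3a) if v3a > 0 else np.nan
    return fits, failures, attenuation


def covariate_models(
    records: pd.DataFrame,
    school_covariates: pd.DataFrame,
    fit3a: CrossClassifiedLMMResults | None = None,
    fixed: list[str] | None = None,
    response: str = "y",
    method: str = "ML",
) -> LadderResult:
    """Models 4 and 5 alone (school measures, then measure-by-PGI
    interactions), with the attenuation ratio against a supplied Model-3a fit."""
    if fixed is None:
        fixed = [c for c in DEFAULT_FIXED if c in records.columns]
    if fit3a is None:
        model = CrossClassifiedLMM.from_dataframe(records, response, fixed, CORE_LADDER["3a"])
        fit3a = model.fit(method=method)
    fits, failures, attenuation = _covariate_fits(
        records, school_covariates, fixed, response, method, fit3a
    )
    fits = {"3a": fit3a, **fits}
    table = compare(fits, lrt_pairs=[("3a", "4"), ("4", "5")])
    selected = _select(table)
    if selected is not None:
        table["selected"] = table["model"] == selected
    return LadderResult(
        fits=fits, table=table, selected=selected, failures=failures, attenuation=attenuation
    )


def subject_split(
    records: pd.DataFrame,
    fixed: list[str] | None = None,
    method: str = "ML",
) -> pd.Series:
    """Refit the school random-slope model per subject and return the
    between-school SD of PGI slopes for maths, reading and English."""
    if fixed is None:
        fixed = [c for c in DEFAULT_FIXED if c in records.columns]
    out = {}
    for subject, col in (("maths", "y_maths"), ("reading", "y_read"), ("english", "y_eng")):
        sub = records[records[col].notna()].copy()
        model = CrossClassifiedLMM.from_dataframe(sub, col, fixed, CORE_LADDER["3a"])
        fit = model.fit(method=method)
        out[subject] = float(np.sqrt(fit.vcomp["school"]["slope_var"]))
    return pd.Series(out, name="slope_sd")
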