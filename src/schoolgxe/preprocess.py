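"""Transform raw scores and PGIs into the analysis variables.

Pipeline order is fixed: residualise test scores (sex, current age, test age)
-> build grade-wise achievement composites -> standardize composites and PGIs
over the analysis sample.  Rows only disappear through explicit, logged
exclusions (missing parents, all-subject-missing rows).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: subjects entering the composite per grade code; grade 9 (code 0) has no
#: English test, so its composite is maths + reading only.
COMPOSITE_SUBJECTS = {
    -4: ("y_maths", "y_read", "y_eng"),
    -1: ("y_maths", "y_read", "y_eng"),
    0: ("y_maths", "y_read"),
}


def residualize_scores(
    scores: pd.Series | np.ndarray, covariates: pd.DataFrame
) -> pd.Series:
    """Least-squares residuals of ``scores`` on ``covariates`` (plus intercept).

    Constant covariate columns are dropped with a warning; rows with missing
    scores keep their NaN.  The result is orthogonal to every retained
    covariate and has mean zero over the complete cases.
    """
    s = pd.Series(np.asarray(scores, dtype=float), index=covariates.index)
    X = covariates.astype(float).copy()
    for col in list(X.columns):
        if np.nanstd(X[col].to_numpy()) < 1e-12:
            warnings.warn(
                f"covariate {col!r} is constant; dropped from residualisation",
                UserWarning,
                stacklevel=2,
            )
            X = X.drop(columns=[col])
    ok = s.notna() & X.notna().all(axis=1)
    out = pd.Series(np.nan, index=s.index)
    if ok.sum() == 0:
        return out
    M = np.column_stack([np.ones(int(ok.sum()))] + [X.loc[ok, c].to_numpy() for c in X.columns])
    beta, *_ = np.linalg.lstsq(M, s[ok].to_numpy(), rcond=None)
    out[ok] = s[ok].to_numpy() - M @ beta
    return out


def make_composite(records: pd.DataFrame, grade_col: str = "grade_code") -> pd.Series:
    """Grade-wise mean over available subjects, standardized within grade.

    Grade-9 rows ignore English even if a column value is present.  Rows with
    no usable subject at all get NaN (the caller drops them, logged).
    """
    out = pd.Series(np.nan, index=records.index)
    for code, subjects in COMPOSITE_SUBJECTS.items():
        m = records[grade_col] == code
        if not m.any():
            continue
        cols = [c for c in subjects if c in records.columns]
        if not cols:
            raise ValueError(f"no subject columns among {subjects} in records")
        comp = records.loc[m, cols].mean(axis=1, skipna=True)
        mu, sd = comp.mean(), comp.std(ddof=0)
        if sd < 1e-12:
            out[m] = 0.0
        else:
            out[m] = (comp - mu) / sd
    n_bad = int(out.isna().sum() - records[grade_col].isna().sum())
    if n_bad > 0:
        logger.info("composite: %d rows with all subjects missing -> NaN", n_bad)
    return out


def midparent_and_standardize(pgi: pd.DataFrame) -> pd.DataFrame:
    """Mid-parent PGI (average of the parents, computed *before* any
    standardization) and sample-standardized child/mid-parent columns.

    Rows with a missing parent are excluded (trio design).
    """
    df = pgi.copy()
    has_parents = df["mother_pgi"].notna() & df["father_pgi"].notna()
    n_drop = int((~has_parents).sum())
    if n_drop:
        logger.info("midparent: excluding %d rows with a missing parent", n_drop)
    df = df.loc[has_parents].copy()
    df["midparent_pgi"] = 0.5 * (df["mother_pgi"] + df["father_pgi"])
    for col in ("child_pgi", "midparent_pgi"):
        x = df[col].to_numpy(dtype=float)
        df[col] = (x - x.mean()) / x.std(ddof=0)
    return df


def income_rank(income: pd.Series, birth_cohort: pd.Series) -> pd.Series:
    """Within-cohort mid-ranks scaled to [0, 1]: rank (i - 0.5) / n, ties get
    the mean rank, so a fully tied cohort ranks 0.5 everywhere."""
    income = pd.Series(income)
    r = income.groupby(pd.Series(birth_cohort, index=income.index)).rank(method="average")
    n = income.groupby(pd.Series(birth_cohort, index=income.index)).transform("size")
    return (r - 0.5) / n


def load_merge_map(path: str | Path) -> dict:
    """Read a two-column CSV (old_id, new_id) of identifier merges.

    Splits (one old id listed with several targets) are unmappable and dropped
    with a warning; chains/cycles (a target that is itself remapped elsewhere)
    are rejected so that applying the map is idempotent.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("merge map needs two columns: old_id, new_id")
    old, new = df.columns[:2]
    dup = df[old].duplicated(keep=False) & ~df.duplicated([old, new], keep=False)
    split_ids = sorted(df.loc[df[old].duplicated(keep=False), old].unique())
    mapping: dict = {}
    for o, g in df.groupby(old):
        targets = g[new].unique()
        if len(targets) > 1:
            warnings.warn(
                f"identifier {o!r} maps to several targets {list(targets)}; "
                "split left unmapped",
                UserWarning,
                stacklevel=2,
            )
            continue
        mapping[o] = targets[0]
    bad = [o for o, t in mapping.items() if t in mapping and mapping[t] != t]
    if bad:
        raise ValueError(f"merge map contains chained/cyclic remaps via {bad}")
    mapping = {o: t for o, t in mapping.items() if o != t}
    return mapping


def remap_identifiers(ids: pd.Series | np.ndarray, merge_map: dict) -> pd.Series:
    """Apply an identifier-harmonisation map; unmapped ids pass through."""
    s = pd.Series(ids)
    return s.map(lambda x: merge_map.get(x, x))


def preprocess_students(
    records: pd.DataFrame,
    merge_map: dict | None = None,
    response_source: str = "auto",
) -> pd.DataFrame:
    """Analysis-ready table: harmonised ids, residualised subject scores,
    grade-standardized achievement composite, standardized PGIs.

    ``response_source``: "y" standardizes the precomputed composite column,
    "subjects" rebuilds the composite from residualised subject scores,
    "auto" prefers "y" when present.
    """
    df = records.copy()
    if merge_map:
        for col in ("muni_id", "district_id"):
            if col in df.columns:
                df[col] = remap_identifiers(df[col], merge_map)

    demo = [c for c in ("sex", "age", "test_age") if c in df.columns]
    if response_source == "auto":
        response_source = "y" if "y" in df.columns else "subjects"
    if response_source == "subjects":
        for col in ("y_maths", "y_read", "y_eng"):
            if col in df.columns and demo:
                df[col] = residualize_scores(df[col], df[demo])
        df["achievement"] = make_composite(df)
    elif response_source == "y":
        ach = pd.Series(np.nan, index=df.index)
        for code, m in df.groupby("grade_code").groups.items():
            x = df.loc[m, "y"].astype(float)
            ach[m] = (x - x.mean()) / x.std(ddof=0)
        df["achievement"] = ach
    else:
        raise ValueError(f"unknown response_source {response_source!r}")

    n0 = len(df)
    df = df[df["achievement"].notna()].copy()
    if len(df) < n0:
        logger.info("preprocess: dropped %d rows without usable outcome", n0 - len(df))

    pgi = df.drop_duplicates("child_id")[["child_id", "mother_pgi", "father_pgi", "child_pgi"]]
    pgi = midparent_and_standardize(pgi)
    df = df.drop(columns=["child_pgi", "midparent_pgi"], errors="ignore").merge(
        pgi[["child_id", "child_pgi", "midparent_pgi"]], on="child_id", how="inner"
    )
    return df
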