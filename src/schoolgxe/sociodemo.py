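"""School-level sociodemographic covariates: means, Gini inequality, and the
proportion of students of non-western immigrant origin.

These five measures per school feed the covariate models of the ladder
(fixed effects, then their interactions with the child PGI)."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHOOL_MEASURES = [
    "mean_parent_edu",
    "mean_income_rank",
    "gini_edu",
    "gini_income",
    "prop_nonwestern",
]


def gini(values) -> float:
    """Gini coefficient: mean absolute pairwise difference / (2 * mean).

    0 is perfect equality, 1 absolute inequality; scale-invariant.  Computed
    via the O(n log n) sorted form.  Requires non-negative values with at
    least one positive entry.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("gini: no values")
    if (x < 0).any():
        raise ValueError("gini: negative values are not supported")
    total = x.sum()
    if total <= 0:
        raise ValueError("gini: undefined when all values are zero")
    n = x.size
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs) - (n + 1) * total) / (n * total))


def aggregate_school(
    students: pd.DataFrame, peer_parents: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One covariate row per school.

    ``peer_parents`` is the register table for *all* parents of each school's
    students (one row per student: school_id, parent_edu_years, parent_income,
    parent_income_rank, nonwestern).  When absent, the sampled students stand
    in, with a logged downgrade.
    """
    if peer_parents is None:
        logger.info(
            "aggregate_school: no full peer-parent table supplied; "
            "aggregating over sampled students only"
        )
        peer_parents = students
    src = peer_parents.drop_duplicates("child_id") if "child_id" in peer_parents.columns else peer_parents

    income_col = "parent_income" if "parent_income" in src.columns else "parent_income_rank"
    rows = []
    for school, g in src.groupby("school_id"):
        rows.append(
            {
                "school_id": school,
                "mean_parent_edu": g["parent_edu_years"].mean(),
                "mean_income_rank": g["parent_income_rank"].mean(),
                "gini_edu": gini(g["parent_edu_years"]),
                "gini_income": gini(g[income_col]),
                "prop_nonwestern": g["nonwestern"].mean(),
            }
        )
    return pd.DataFrame(rows).sort_values("school_id", ignore_index=True)
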