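"""Cross-classified linear mixed models with correlated random slopes.

The model is the standard multilevel regression

    y = X beta + sum_l Z_l b_l + e,      e ~ N(0, sigma^2 I),

where each random term l is a grouping factor (individual, school,
neighbourhood, district, municipality) contributing a random intercept and,
optionally, a correlated random slope on a covariate (here: the child PGI).
Groupings may be nested or crossed; nothing in the fitter assumes nesting.

Estimation profiles beta and sigma^2 out of the (restricted) likelihood and
optimises the remaining relative-covariance parameters, following the
penalised-least-squares formulation used by lme4: with b = Lambda(theta) u and
u ~ N(0, sigma^2 I_q), each evaluation solves the sparse system

    [Lam' Z'Z Lam + I   Lam' Z'X] [u]   [Lam' Z'y]
    [   X'Z Lam            X'X  ] [b] = [   X'y  ],

giving the profiled deviance  log|Lam'Z'Z Lam + I| + n(1 + log(2 pi r^2/n)).
Lambda is block-diagonal with per-term Cholesky factors whose diagonal is
bounded at zero, so the implied covariance matrices are positive semidefinite
by construction and boundary fits (zero variances) are attainable.

Sparse factorisations use SuperLU with the natural ordering over a
hand-chosen column order (largest intercept factors first, slope factors
last), which mimics a fill-minimising block elimination for this family of
designs (each observation belongs to exactly one cluster per factor).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, sparse, stats
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

__all__ = [
    "RandomTerm",
    "RandomStructure",
    "CrossClassifiedLMM",
    "CrossClassifiedLMMResults",
    "VarianceProfile",
    "compare",
    "lrt",
]


# ---------------------------------------------------------------------------
# random-effects specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomTerm:
    """One grouping factor: a random intercept and an optional correlated
    random slope (slope always comes with the intercept at the same level)."""

    level: str
    cluster: str
    slope: str | None = None

    @property
    def k(self) -> int:
        return 2 if self.slope else 1

    @property
    def n_theta(self) -> int:
        return 3 if self.slope else 1


@dataclass(frozen=True)
class RandomStructure:
    """Ordered collection of random terms (plus the implicit residual)."""

    terms: tuple[RandomTerm, ...]

    def __post_init__(self):
        levels = [t.level for t in self.terms]
        if len(set(levels)) != len(levels):
            raise ValueError(f"duplicate random-effect levels: {levels}")

    def __iter__(self):
        return iter(self.terms)

    def __len__(self):
        return len(self.terms)

    @property
    def n_theta(self) -> int:
        return sum(t.n_theta for t in self.terms)

    def level(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.level == name:
                return t
        raise KeyError(f"no random term for level {name!r}")


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass
class _TermDesign:
    term: RandomTerm
    labels: np.ndarray        # original cluster labels, in code order
    codes: np.ndarray         # 0..m-1 per row
    offset: int               # first column in Z
    width: int                # k * m

    @property
    def m(self) -> int:
        return len(self.labels)


class _Design:
    """Precomputed cross-products; everything the deviance needs per theta."""

    def __init__(self, y, X, xnames, terms_design, Z):
        self.y = y
        self.X = X
        self.xnames = xnames
        self.terms = terms_design
        self.Z = Z
        self.n, self.p = X.shape
        self.q = Z.shape[1]
        Zc = Z.tocsc()
        self.ZtZ = (Zc.T @ Zc).tocsc()
        self.ZtX = np.asarray(Zc.T @ X)
        self.Zty = np.asarray(Zc.T @ y).ravel()
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self._lambda_pattern()

    # Lambda is block diagonal; precompute its sparsity pattern and a map
    # theta-index -> data positions so each evaluation is a data update.
    def _lambda_pattern(self):
        rows, cols, theta_ix = [], [], []
        j = 0
        for td in self.terms:
            t = td.term
            if t.k == 1:
                idx = np.arange(td.offset, td.offset + td.m)
                rows.append(idx)
                cols.append(idx)
                theta_ix.append(np.full(td.m, j))
                j += 1
            else:
                base = td.offset + 2 * np.arange(td.m)
                # (2i, 2i) = th0 ; (2i+1, 2i) = th1 ; (2i+1, 2i+1) = th2
                rows.append(base)
                cols.append(base)
                theta_ix.append(np.full(td.m, j))
                rows.append(base + 1)
                cols.append(base)
                theta_ix.append(np.full(td.m, j + 1))
                rows.append(base + 1)
                cols.append(base + 1)
                theta_ix.append(np.full(td.m, j + 2))
                j += 3
        self.n_theta = j
        self._lam_rows = np.concatenate(rows)
        self._lam_cols = np.concatenate(cols)
        self._lam_theta_ix = np.concatenate(theta_ix)

    def lambda_(self, theta: np.ndarray) -> sparse.csc_matrix:
        data = np.asarray(theta, dtype=float)[self._lam_theta_ix]
        return sparse.csc_matrix(
            (data, (self._lam_rows, self._lam_cols)), shape=(self.q, self.q)
        )

    def theta_bounds(self):
        lb, ub = [], []
        for td in self.terms:
            if td.term.k == 1:
                lb += [0.0]
                ub += [np.inf]
            else:
                lb += [0.0, -np.inf, 0.0]
                ub += [np.inf, np.inf, np.inf]
        return np.array(lb), np.array(ub)

    def theta_start(self) -> np.ndarray:
        """Structure-informed defaults on the relative-SD scale.

        A subject-level factor (about one cluster per few rows, e.g. the
        individual intercept under repeated measures) starts near the
        residual SD; coarser intercept factors start small; slope blocks
        start with a small slope SD — random-slope likelihoods are flat
        ridges when approached from implausibly large slope variances.
        """
        start = []
        for td in self.terms:
            if td.term.k == 1:
                start += [1.0 if td.m >= self.n // 4 else 0.15]
            else:
                start += [0.2, 0.0, 0.05]
        return np.array(start)


def _factorize(A: sparse.csc_matrix):
    # natural ordering: column order already chosen for low fill
    return splu(
        A,
        permc_spec="NATURAL",
        diag_pivot_thresh=0.0,
        options={"SymmetricMode": True},
    )


class _Profiled:
    """One profiled-deviance evaluation (caches the pieces results need)."""

    def __init__(self, design: _Design, theta: np.ndarray, reml: bool):
        d = design
        lam = d.lambda_(theta)
        A = (lam.T @ d.ZtZ @ lam) + sparse.identity(d.q, format="csc")
        lu = _factorize(A.tocsc())
        self.logdet_A = float(np.sum(np.log(np.abs(lu.U.diagonal()))))

        LtZtX = lam.T @ d.ZtX
        LtZty = lam.T @ d.Zty
        rhs = np.column_stack([LtZtX, LtZty])
        sol = lu.solve(rhs)
        Ainv_LtZtX, Ainv_LtZty = sol[:, :-1], sol[:, -1]

        S = d.XtX - LtZtX.T @ Ainv_LtZtX
        S = 0.5 * (S + S.T)
        try:
            cf = sla.cho_factor(S)
        except sla.LinAlgError as err:  # pragma: no cover - collinear X
            raise np.linalg.LinAlgError(
                "singular fixed-effects cross-product; check for collinear "
                f"columns among {list(d.xnames)}"
            ) from err
        beta = sla.cho_solve(cf, d.Xty - LtZtX.T @ Ainv_LtZty)
        u = Ainv_LtZty - Ainv_LtZtX @ beta
        pwrss = d.yty - u @ LtZty - beta @ d.Xty
        pwrss = max(float(pwrss), np.finfo(float).tiny)

        n, p = d.n, d.p
        self.logdet_S = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        if reml:
            df = n - p
            self.sigma2 = pwrss / df
            self.deviance = (
                self.logdet_A
                + self.logdet_S
                + df * (1.0 + np.log(2.0 * np.pi * pwrss / df))
            )
        else:
            self.sigma2 = pwrss / n
            self.deviance = self.logdet_A + n * (1.0 + np.log(2.0 * np.pi * pwrss / n))
        self.beta = beta
        self.u = u
        self.lam = lam
        self.cov_beta_unscaled = sla.cho_solve(cf, np.eye(p))
        self.pwrss = pwrss
        self.theta = np.asarray(theta, dtype=float)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class CrossClassifiedLMM:
    """Linear mixed model with crossed/nested random intercepts and slopes.

    Parameters
    ----------
    endog : (n,) response vector
    exog : (n, p) fixed-effects design (without intercept; one is added)
    exog_names : names for the p columns
    data : the source DataFrame (cluster ids and slope variables are read
        from it per the random structure)
    random : RandomStructure

    Use :meth:`from_dataframe` in normal code.
    """

    def __init__(self, endog, exog, exog_names, data, random: RandomStructure):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.column_stack([np.ones(len(y)), np.asarray(exog, dtype=float)])
        xnames = ["const"] + list(exog_names)
        bad = [xnames[i + 1] for i in range(X.shape[1] - 1) if np.isnan(X[:, i + 1]).any()]
        if np.isnan(y).any():
            bad = ["<response>"] + bad
        if bad:
            raise ValueError(f"missing values in model variables: {bad}")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            _, _, piv = sla.qr(X, mode="economic", pivoting=True)
            dropped = [xnames[j] for j in piv[rank:]]
            raise ValueError(f"fixed-effects design is singular; collinear columns: {dropped}")

        terms_design, blocks = [], []
        # column order for low fill: intercept-only factors by decreasing
        # cluster count, slope factors last
        ordered = sorted(
            random.terms,
            key=lambda t: (t.k, -data[t.cluster].nunique()),
        )
        offset = 0
        n = len(y)
        rows = np.arange(n)
        for t in ordered:
            codes, labels = pd.factorize(data[t.cluster].to_numpy(), sort=True)
            m = len(labels)
            if m < 2:
                raise ValueError(
                    f"random term {t.level!r} needs >= 2 clusters, found {m}"
                )
            if t.k == 1:
                Zb = sparse.csc_matrix(
                    (np.ones(n), (rows, codes)), shape=(n, m)
                )
            else:
                if t.slope not in data.columns:
                    raise ValueError(f"unknown slope variable {t.slope!r}")
                g = data[t.slope].to_numpy(dtype=float)
                if np.isnan(g).any():
                    raise ValueError(f"missing values in slope variable {t.slope!r}")
                cols = np.concatenate([2 * codes, 2 * codes + 1])
                vals = np.concatenate([np.ones(n), g])
                Zb = sparse.csc_matrix(
                    (vals, (np.concatenate([rows, rows]), cols)), shape=(n, 2 * m)
                )
            terms_design.append(
                _TermDesign(term=t, labels=labels, codes=codes, offset=offset, width=t.k * m)
            )
            offset += t.k * m
            blocks.append(Zb)
        Z = sparse.hstack(blocks, format="csc") if blocks else sparse.csc_matrix((n, 0))

        self.random = random
        self.design = _Design(y, X, xnames, terms_design, Z)
        self.exog_names = xnames

    # -- construction -------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed: list[str],
        random: RandomStructure,
    ) -> "CrossClassifiedLMM":
        needed = [response] + list(fixed) + [t.cluster for t in random]
        needed += [t.slope for t in random if t.slope]
        missing_cols = [c for c in needed if c not in data.columns]
        if missing_cols:
            raise ValueError(f"columns not in data: {missing_cols}")
        na_cols = [c for c in dict.fromkeys(needed) if data[c].isna().any()]
        if na_cols:
            raise ValueError(f"missing values in model variables: {na_cols}")
        return cls(
            data[response].to_numpy(),
            data[list(fixed)].to_numpy(dtype=float),
            list(fixed),
            data,
            random,
        )

    # -- likelihood ---------------------------------------------------------
    def deviance(self, theta, reml: bool = False) -> float:
        """Profiled (beta, sigma^2 concentrated out) deviance at theta."""
        return _Profiled(self.design, np.asarray(theta, dtype=float), reml).deviance

    def fit(
        self,
        method: str = "ML",
        start: np.ndarray | None = None,
        restarts: int = 0,
        maxiter: int = 400,
        tol: float = 1e-8,
    ) -> "CrossClassifiedLMMResults":
        """Maximise the profiled (ML or REML) likelihood over theta.

        ``restarts`` adds extra optimisations from perturbed starts; the best
        optimum wins.  A stalled optimiser yields ``converged=False`` on the
        results rather than an exception.
        """
        reml = method.upper() == "REML"
        d = self.design
        lb, ub = d.theta_bounds()
        th0 = d.theta_start() if start is None else np.asarray(start, dtype=float)
        th0 = np.clip(th0, lb, np.where(np.isinf(ub), th0, ub))

        def obj(th):
            try:
                return _Profiled(d, th, reml).deviance
            except np.linalg.LinAlgError:
                return np.inf

        rng = np.random.default_rng(0)
        best, converged = None, False
        starts = [th0] + [
            np.clip(th0 + 0.25 * rng.standard_normal(len(th0)), lb, np.inf)
            for _ in range(restarts)
        ]
        bounds = list(zip(lb, ub))
        opts = {"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9}
        for s0 in starts:
            # chained restarts: refreshing the L-BFGS Hessian approximation
            # escapes the flat ridges these likelihoods produce
            x, f_prev, cand = s0, np.inf, None
            for _ in range(4):
                res = optimize.minimize(
                    obj, x, method="L-BFGS-B", bounds=bounds, options=opts
                )
                x = res.x
                if cand is None or res.fun <= cand.fun:
                    cand = res
                if abs(f_prev - res.fun) < max(tol * abs(res.fun), 1e-6):
                    break
                f_prev = res.fun
            cand_ok = bool(cand.success)
            if not cand_ok:
                # fall back to Nelder-Mead, which is robust when the optimum
                # sits on a variance boundary
                res2 = optimize.minimize(
                    obj,
                    cand.x,
                    method="Nelder-Mead",
                    options={
                        "maxfev": 150 * len(th0),
                        "fatol": max(tol * abs(cand.fun), 1e-9),
                        "xatol": 1e-6,
                    },
                )
                if res2.fun <= cand.fun:
                    cand, cand_ok = res2, bool(res2.success)
            cand_x = np.clip(cand.x, lb, np.inf)
            if best is None or cand.fun < best.fun:
                best = cand
                best_x = cand_x
                converged = cand_ok
        if not converged:
            logger.warning("LMM optimiser did not report convergence")
        prof = _Profiled(d, best_x, reml)
        return CrossClassifiedLMMResults(self, prof, method=method.upper(), converged=converged)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class VarianceProfile:
    """Cluster-level variance as a quadratic function of the PGI value g:
    Var_l(g) = s00 + 2 g s01 + g^2 s11, and its share of the total."""

    level: str
    grid: np.ndarray
    variance: np.ndarray
    total: np.ndarray

    @property
    def share(self) -> np.ndarray:
        return self.variance / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "g": self.grid,
                f"var_{self.level}": self.variance,
                "total": self.total,
                "share": self.share,
            }
        )


class CrossClassifiedLMMResults:
    """Fitted cross-classified mixed model: estimates, variance components,
    BLUPs, ICCs, the PGI variance profile and information criteria."""

    def __init__(self, model: CrossClassifiedLMM, prof: _Profiled, method: str, converged: bool):
        self.model = model
        self.method = method
        self.converged = converged
        self._prof = prof
        d = model.design
        self.nobs = d.n
        self.sigma2 = prof.sigma2
        self.fe_params = pd.Series(prof.beta, index=d.xnames)
        cov = prof.sigma2 * prof.cov_beta_unscaled
        self.bse = pd.Series(np.sqrt(np.diag(cov)), index=d.xnames)
        self.theta = prof.theta

        # per-level covariance matrices (sigma^2 * lambda_l lambda_l')
        self.vcomp: dict[str, dict[str, float]] = {}
        j = 0
        for td in d.terms:
            t = td.term
            if t.k == 1:
                v = prof.sigma2 * prof.theta[j] ** 2
                self.vcomp[t.level] = {"intercept_var": float(v)}
                j += 1
            else:
                L = np.array(
                    [[prof.theta[j], 0.0], [prof.theta[j + 1], prof.theta[j + 2]]]
                )
                C = prof.sigma2 * (L @ L.T)
                self.vcomp[t.level] = {
                    "intercept_var": float(C[0, 0]),
                    "slope_var": float(C[1, 1]),
                    "cov": float(C[0, 1]),
                }
                j += 3

        # log-likelihood / AIC; k = fixed effects + theta + residual variance
        if method == "REML":
            self.llf = -0.5 * prof.deviance
        else:
            self.llf = -0.5 * prof.deviance
        self.n_params = d.p + d.n_theta + 1
        self.aic = -2.0 * self.llf + 2.0 * self.n_params

    # -- random effects -----------------------------------------------------
    def random_effects(self, level: str) -> pd.DataFrame:
        """Empirical-Bayes (BLUP) cluster effects for one level.

        For a slope level, ``slope`` is the *total* cluster slope, i.e. the
        fixed slope coefficient plus the cluster deviation.
        """
        d = self.model.design
        b = np.asarray(self._prof.lam @ self._prof.u).ravel()
        for td in d.terms:
            if td.term.level != level:
                continue
            seg = b[td.offset : td.offset + td.width]
            if td.term.k == 1:
                return pd.DataFrame(
                    {"cluster": td.labels, "intercept": seg}
                ).set_index("cluster")
            out = pd.DataFrame(
                {
                    "cluster": td.labels,
                    "intercept": seg[0::2],
                    "slope_dev": seg[1::2],
                },
            ).set_index("cluster")
            out["slope"] = out["slope_dev"] + self.fe_params.get(td.term.slope, 0.0)
            return out
        raise KeyError(f"no random term for level {level!r}")

    # -- variance decomposition ---------------------------------------------
    def _level_var(self, level: str, g: float = 0.0) -> float:
        c = self.vcomp[level]
        if "slope_var" in c:
            return c["intercept_var"] + 2.0 * g * c["cov"] + g * g * c["slope_var"]
        return c["intercept_var"]

    def total_variance(self, g: float = 0.0) -> float:
        """Sum of all fitted variance components at PGI = g (slope levels are
        evaluated at g; intercept-only levels and the residual are flat)."""
        return sum(self._level_var(lv, g) for lv in self.vcomp) + self.sigma2

    def icc(self, level: str, g: float = 0.0) -> float:
        """Share of total variance at the given level (slopes evaluated at
        g = 0 by default)."""
        return self._level_var(level, g) / self.total_variance(g)

    def variance_profile(self, grid=None, level: str = "school") -> VarianceProfile:
        if grid is None:
            grid = np.linspace(-3.0, 3.0, 121)
        grid = np.asarray(grid, dtype=float)
        var = np.array([self._level_var(level, g) for g in grid])
        tot = np.array([self.total_variance(g) for g in grid])
        return VarianceProfile(level=level, grid=grid, variance=var, total=tot)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Cross-classified LMM ({self.method}); n = {self.nobs}",
            f"logLik = {self.llf:.3f}   AIC = {self.aic:.3f}   "
            f"params = {self.n_params}   converged = {self.converged}",
            "",
            "Fixed effects:",
        ]
        for name in self.fe_params.index:
            est, se = self.fe_params[name], self.bse[name]
            z = est / se if se > 0 else np.nan
            lines.append(f"  {name:<22s} {est:>10.4f}  (SE {se:.4f}, z {z:+.2f})")
        lines.append("")
        lines.append("Variance components:")
        for lv, c in self.vcomp.items():
            if "slope_var" in c:
                corr = (
                    c["cov"] / np.sqrt(c["intercept_var"] * c["slope_var"])
                    if c["intercept_var"] > 0 and c["slope_var"] > 0
                    else np.nan
                )
                lines.append(
                    f"  {lv:<15s} intercept {c['intercept_var']:.5f}  "
                    f"slope {c['slope_var']:.6f} (SD {np.sqrt(c['slope_var']):.4f})  "
                    f"corr {corr:+.2f}"
                )
            else:
                lines.append(f"  {lv:<15s} intercept {c['intercept_var']:.5f}")
        lines.append(f"  {'residual':<15s} {self.sigma2:.5f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "converged": bool(self.converged),
            "nobs": int(self.nobs),
            "loglik": float(self.llf),
            "aic": float(self.aic),
            "n_params": int(self.n_params),
            "fixed_effects": {
                k: {"estimate": float(self.fe_params[k]), "se": float(self.bse[k])}
                for k in self.fe_params.index
            },
            "vc": {lv: {k: float(v) for k, v in c.items()} for lv, c in self.vcomp.items()},
            "residual_var": float(self.sigma2),
            "theta": [float(t) for t in self.theta],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def lrt(smaller: CrossClassifiedLMMResults, larger: CrossClassifiedLMMResults) -> dict:
    """Likelihood-ratio test of nested fits: the naive chi-square p-value and
    the 50:50 mixture (boundary-corrected) p-value for variance parameters
    tested on the edge of their space."""
    df = larger.n_params - smaller.n_params
    if df <= 0:
        raise ValueError("larger model must have more parameters")
    stat = 2.0 * (larger.llf - smaller.llf)
    stat_pos = max(stat, 0.0)
    p_naive = float(stats.chi2.sf(stat_pos, df)) if stat_pos > 0 else 1.0
    lower = float(stats.chi2.sf(stat_pos, df - 1)) if df > 1 else (1.0 if stat_pos == 0 else 0.0)
    p_mix = 0.5 * lower + 0.5 * (float(stats.chi2.sf(stat_pos, df)) if stat_pos > 0 else 1.0)
    return {"stat": float(stat), "df": int(df), "p_naive": p_naive, "p_mixture": float(p_mix)}


def compare(results: dict[str, CrossClassifiedLMMResults], lrt_pairs=None) -> pd.DataFrame:
    """AIC comparison table (and optional LRTs for nested pairs).

    ``lrt_pairs``: iterable of (smaller_label, larger_label).
    """
    rows = []
    for label, r in results.items():
        rows.append(
            {
                "model": label,
                "loglik": r.llf,
                "n_params": r.n_params,
                "aic": r.aic,
                "converged": r.converged,
            }
        )
    tab = pd.DataFrame(rows)
    ok = tab["converged"]
    if not ok.any():
        warnings.warn("no converged fits to compare", UserWarning, stacklevel=2)
        tab["d_aic"] = np.nan
        return tab
    best = tab.loc[ok, "aic"].min()
    tab["d_aic"] = tab["aic"] - best
    if lrt_pairs:
        stats_ = {
            (a, b): lrt(results[a], results[b]) for a, b in lrt_pairs
        }
        tab["lrt_vs"] = [
            next((a for (a, b) in stats_ if b == m), None) for m in tab["model"]
        ]
        tab["lrt_stat"] = [
            next((s["stat"] for (a, b), s in stats_.items() if b == m), np.nan)
            for m in tab["model"]
        ]
        tab["lrt_p_naive"] = [
            next((s["p_naive"] for (a, b), s in stats_.items() if b == m), np.nan)
            for m in tab["model"]
        ]
        tab["lrt_p_mixture"] = [
            next((s["p_mixture"] for (a, b), s in stats_.items() if b == m), np.nan)
            for m in tab["model"]
        ]
    return tab
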