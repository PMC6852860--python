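"""Genotype-phenotype association by fixed-effects linear models.

Each trait is analyzed per marker with an ordinary-least-squares model

    y = mu + beta * age + season + genotype (+ genotype-combination) + e,

where age (days at the trait's reference point) is a covariate and season
and genotype are fixed factors with reference-level dummy coding.  Although
such screening models are often called "mixed", no random term beyond the
residual appears here, so the fit is plain OLS.

Term significance uses partial (Type III) F-tests - the full model against
the model with the whole term dropped - which is order-independent under
the severely unbalanced genotype classes typical of candidate-gene panels.
Least-square means (LSM) are predictions at the covariate grand mean with
equal weight on every season, and post hoc genotype comparisons use the
Tukey-Kramer studentized-range test with a compact letter display.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "FitResult",
    "FTest",
    "TukeyGrouping",
    "SingularDesignError",
    "DegenerateFactorError",
    "IncomparableModelsError",
    "UnknownLevelError",
    "fit_model",
    "least_square_means",
    "tukey_posthoc",
    "fit_interaction",
    "compare_models_r2",
]


class SingularDesignError(ValueError):
    """The design matrix is rank deficient (confounded factor levels)."""


class DegenerateFactorError(ValueError):
    """A factor has fewer than two retained levels."""


class IncomparableModelsError(ValueError):
    """Model comparison requested across different response vectors."""


class UnknownLevelError(KeyError):
    """A factor level absent from the fitted model was requested."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response column, factor of interest, covariates."""

    trait: str
    factor: str = "genotype"
    age_col: str | None = "age"
    season_col: str | None = "season"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class FTest:
    f: float
    df_num: int
    df_den: int
    p: float


@dataclass
class FitResult:
    """A fitted association model with everything downstream stages need."""

    spec: ModelSpec
    params: pd.Series
    cov: pd.DataFrame
    lsm: pd.DataFrame  # index: factor level; columns lsm, se, n
    f_tests: dict[str, FTest]
    r2: float
    r2_adj: float
    n_used: int
    df_resid: int
    sigma2: float
    n_params: int
    season_levels: tuple[str, ...]
    factor_levels: tuple[str, ...]
    age_mean: float
    response: np.ndarray = field(repr=False)
    _design_cols: dict = field(repr=False, default_factory=dict)


def _dummies(values: pd.Series, prefix: str) -> tuple[pd.DataFrame, list[str]]:
    """Reference-coded dummies; reference = first sorted level."""
    levels = sorted(values.astype(str).unique())
    cols = {}
    for lev in levels[1:]:
        cols[f"{prefix}[{lev}]"] = (values.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=values.index), levels


def _design(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Build the full design matrix; returns (X, y, info)."""
    cols = [spec.trait, spec.factor]
    if spec.age_col:
        cols.append(spec.age_col)
    if spec.season_col:
        cols.append(spec.season_col)
    d = data[cols].dropna()
    n_dropped = len(data) - len(d)
    if n_dropped:
        logger.info(
            "fit_model trait=%s factor=%s: dropped %d rows with missing values",
            spec.trait, spec.factor, n_dropped,
        )
    y = d[spec.trait].to_numpy(dtype=float)
    parts = [pd.Series(1.0, index=d.index, name="Intercept")]
    term_cols: dict[str, list[str]] = {}
    age_mean = np.nan
    if spec.age_col:
        age = d[spec.age_col].astype(float)
        age_mean = float(age.mean())
        parts.append(age.rename("age"))
        term_cols["age"] = ["age"]
    season_levels: tuple[str, ...] = ()
    if spec.season_col:
        sd, season_levels = _dummies(d[spec.season_col], "season")
        season_levels = tuple(season_levels)
        if len(season_levels) < 2:
            logger.info(
                "fit_model trait=%s: season has a single level %s; term dropped",
                spec.trait, season_levels,
            )
            season_levels = tuple(season_levels)
        else:
            parts.append(sd)
            term_cols["season"] = list(sd.columns)
    fd, factor_levels = _dummies(d[spec.factor], spec.factor)
    if len(factor_levels) < 2:
        raise DegenerateFactorError(
            f"factor {spec.factor!r} has {len(factor_levels)} retained level(s)"
        )
    parts.append(fd)
    term_cols[spec.factor] = list(fd.columns)
    X = pd.concat(parts, axis=1)
    info = {
        "term_cols": term_cols,
        "season_levels": season_levels,
        "factor_levels": tuple(factor_levels),
        "age_mean": age_mean,
        "n_per_level": d[spec.factor].astype(str).value_counts().to_dict(),
        "n_dropped": n_dropped,
    }
    return X, y, info


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # column-pivoted QR names the aliased columns
        from scipy.linalg import qr

        _, _, piv = qr(arr, pivoting=True, mode="economic")
        aliased = [X.columns[i] for i in piv[rank:]]
        raise SingularDesignError(
            f"design matrix is rank deficient; aliased terms: {aliased}"
        )


def _lsm_row(fit: "FitResult", level: str) -> np.ndarray:
    """Prediction vector for one factor level at the LSM reference point."""
    x = pd.Series(0.0, index=fit.params.index)
    x["Intercept"] = 1.0
    if "age" in x.index:
        x["age"] = fit.age_mean
    k = len(fit.season_levels)
    if k >= 2:
        for lev in fit.season_levels[1:]:
            x[f"season[{lev}]"] = 1.0 / k
    col = f"{fit.spec.factor}[{level}]"
    if level != fit.factor_levels[0]:
        if col not in x.index:
            raise UnknownLevelError(level)
        x[col] = 1.0
    elif level not in fit.factor_levels:
        raise UnknownLevelError(level)
    return x.to_numpy()


def fit_model(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """OLS fit of ``spec`` on ``data`` with Type III term tests and LSMs.

    ``data`` must contain the trait column, the factor column and whichever
    covariate columns the model spec names.  Rows with missing values in any of
    those are dropped (and counted in the log).
    """
    X, y, info = _design(data, spec)
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    if res.df_resid <= 0:
        raise SingularDesignError("no residual degrees of freedom")

    f_tests: dict[str, FTest] = {}
    for term, cols in info["term_cols"].items():
        Xr = X.drop(columns=cols)
        res_r = sm.OLS(y, Xr).fit()
        q = len(cols)
        f = ((res_r.ssr - res.ssr) / q) / (res.ssr / res.df_resid)
        f_tests[term] = FTest(
            f=float(f),
            df_num=q,
            df_den=int(res.df_resid),
            p=float(stats.f.sf(f, q, res.df_resid)),
        )

    fit = FitResult(
        spec=spec,
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        lsm=pd.DataFrame(),
        f_tests=f_tests,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        n_used=int(res.nobs),
        df_resid=int(res.df_resid),
        sigma2=float(res.ssr / res.df_resid),
        n_params=int(X.shape[1]),
        season_levels=info["season_levels"],
        factor_levels=info["factor_levels"],
        age_mean=info["age_mean"],
        response=y,
        _design_cols=info["term_cols"],
    )
    fit.lsm = least_square_means(fit)
    fit.lsm["n"] = [info["n_per_level"].get(lev, 0) for lev in fit.lsm.index]
    return fit


def least_square_means(fit: FitResult, factor: str | None = None) -> pd.DataFrame:
    """Least-square mean and SE per level of the fitted factor.

    The LSM is the model prediction with the age covariate at its grand
    mean and equal 1/k weight on each season level; the SE comes from the
    coefficient covariance.
    """
    if factor is not None and factor != fit.spec.factor:
        raise UnknownLevelError(f"model was fitted with factor {fit.spec.factor!r}")
    rows = {}
    cov = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    for lev in fit.factor_levels:
        x = _lsm_row(fit, lev)
        rows[lev] = {
            "lsm": float(x @ beta),
            "se": float(np.sqrt(x @ cov @ x)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class TukeyGrouping:
    """Tukey-Kramer pairwise comparisons and a compact letter display."""

    pairwise: pd.DataFrame  # level_1, level_2, diff, se, q, p_adj
    letters: dict[str, str]
    alpha: float


def _maximal_cliques(adj: dict[str, set[str]]) -> list[set[str]]:
    """Bron-Kerbosch without pivoting; fine for a handful of levels."""
    cliques: list[set[str]] = []

    def expand(r: set[str], p: set[str], x: set[str]) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            expand(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    expand(set(), set(adj), set())
    return cliques


def tukey_posthoc(fit: FitResult, alpha: float | None = None) -> TukeyGrouping:
    """Tukey-Kramer comparison of all factor-level LSMs.

    The studentized-range statistic for levels i, j is
    q_ij = |LSM_i - LSM_j| * sqrt(2) / SE(diff) with the model's residual
    df.  With two levels this reduces to the two-sided t-test of the
    contrast.  Letters are shared exactly by levels whose adjusted p
    exceeds alpha (maximal cliques of the not-distinguishable graph),
    assigned from the largest LSM downward.
    """
    alpha = fit.spec.alpha if alpha is None else alpha
    levels = list(fit.factor_levels)
    if len(levels) < 2:
        raise DegenerateFactorError("post hoc comparison needs at least 2 levels")
    k = len(levels)
    cov = fit.cov.to_numpy()
    beta = fit.params.to_numpy()
    xrows = {lev: _lsm_row(fit, lev) for lev in levels}
    recs = []
    nsd = {lev: {lev} for lev in levels}
    for i in range(k):
        for j in range(i + 1, k):
            li, lj = levels[i], levels[j]
            l = xrows[li] - xrows[lj]
            diff = float(l @ beta)
            se = float(np.sqrt(l @ cov @ l))
            q = abs(diff) * np.sqrt(2.0) / se
            p_adj = float(stats.studentized_range.sf(q, k, fit.df_resid))
            recs.append(
                {"level_1": li, "level_2": lj, "diff": diff, "se": se, "q": q, "p_adj": p_adj}
            )
            if p_adj >= alpha:
                nsd[li].add(lj)
                nsd[lj].add(li)
    adj = {lev: nsd[lev] - {lev} for lev in levels}
    cliques = _maximal_cliques(adj)
    lsm = fit.lsm["lsm"] if "lsm" in fit.lsm else least_square_means(fit)["lsm"]
    # letters ordered by descending LSM of the clique's largest member,
    # ties broken by level name
    cliques.sort(key=lambda c: (-max(lsm[m] for m in c), tuple(sorted(c))))
    letter_of: dict[str, list[str]] = {lev: [] for lev in levels}
    for idx, clique in enumerate(cliques):
        letter = chr(ord("a") + idx)
        for lev in clique:
            letter_of[lev].append(letter)
    letters = {lev: "".join(sorted(ls)) for lev, ls in letter_of.items()}
    return TukeyGrouping(pairwise=pd.DataFrame(recs), letters=letters, alpha=alpha)


def combine_genotypes(
    data: pd.DataFrame, genotype_cols: Sequence[str], out_col: str = "genotype"
) -> pd.DataFrame:
    """Concatenate per-marker genotype calls into one combination factor."""
    d = data.copy()
    d[out_col] = d[list(genotype_cols)].astype(str).agg("x".join, axis=1)
    return d


def fit_interaction(
    spec: ModelSpec,
    data: pd.DataFrame,
    genotype_cols: Sequence[str],
    min_count: int = 3,
) -> FitResult:
    """Fit the model on a combined multi-locus genotype factor.

    Genotype combinations observed fewer than ``min_count`` times are
    excluded (and logged) before fitting, mirroring the practice of
    dropping very-low-frequency classes from interaction analyses.
    """
    d = combine_genotypes(data, genotype_cols, out_col=spec.factor)
    counts = d[spec.factor].value_counts()
    low = counts[counts < min_count]
    for combo, cnt in low.items():
        logger.info(
            "EXCLUDED_COMBO trait=%s combo=%s n=%d min_count=%d",
            spec.trait, combo, cnt, min_count,
        )
    d = d[~d[spec.factor].isin(low.index)]
    if d[spec.factor].nunique() < 2:
        raise DegenerateFactorError(
            f"fewer than 2 genotype combinations survive min_count={min_count}"
        )
    return fit_model(spec, d)


def compare_models_r2(fits: Sequence[FitResult]) -> FitResult:
    """Choose among candidate fits of the same response by adjusted R^2.

    Ties (to 1e-12) go to the model with fewer parameters, then to the
    earlier candidate; fits of different response vectors are incomparable.
    """
    if len(fits) < 2:
        raise IncomparableModelsError("need at least two candidate fits")
    ref = fits[0].response
    for f in fits[1:]:
        if f.response.shape != ref.shape or not np.allclose(f.response, ref):
            raise IncomparableModelsError("candidate models fit different response vectors")
    best = fits[0]
    for f in fits[1:]:
        if f.r2_adj > best.r2_adj + 1e-12:
            best = f
        elif abs(f.r2_adj - best.r2_adj) <= 1e-12 and f.n_params < best.n_params:
            best = f
    return best
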