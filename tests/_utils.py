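"""Shared independent oracles and simulators for the test suite.

The linear-model oracle here deliberately avoids the package's design
machinery and statsmodels: indicator columns are built by explicit loops
and the fit is solved through the raw normal equations, so agreement with
``fattenassoc.association`` is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def oracle_design(data: pd.DataFrame, use_age: bool, use_season: bool) -> tuple[np.ndarray, list[str]]:
    """Reference-coded design matrix built by hand (sorted levels, drop first)."""
    n = len(data)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["Intercept"]
    if use_age:
        cols.append(data["age"].to_numpy(dtype=float))
        names.append("age")
    if use_season:
        for lev in sorted(data["season"].unique())[1:]:
            cols.append((data["season"] == lev).to_numpy(dtype=float))
            names.append(f"season[{lev}]")
    for lev in sorted(data["genotype"].unique())[1:]:
        cols.append((data["genotype"] == lev).to_numpy(dtype=float))
        names.append(f"genotype[{lev}]")
    return np.column_stack(cols), names


def oracle_ols(X: np.ndarray, y: np.ndarray) -> dict:
    """Normal-equation OLS: coefficients, covariance, SSE, residual df."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    df = len(y) - X.shape[1]
    sigma2 = sse / df
    cov = sigma2 * np.linalg.inv(xtx)
    return {"beta": beta, "cov": cov, "sse": sse, "df": df, "sigma2": sigma2}


def oracle_genotype_ftest(data: pd.DataFrame, trait: str, use_age: bool, use_season: bool) -> dict:
    """Partial F-test of the genotype factor via two explicit fits."""
    y = data[trait].to_numpy(dtype=float)
    X_full, names = oracle_design(data, use_age, use_season)
    full = oracle_ols(X_full, y)
    keep = [i for i, nm in enumerate(names) if not nm.startswith("genotype[")]
    red = oracle_ols(X_full[:, keep], y)
    q = X_full.shape[1] - len(keep)
    f = ((red["sse"] - full["sse"]) / q) / (full["sse"] / full["df"])
    return {
        "full": full,
        "names": names,
        "f": f,
        "p": float(stats.f.sf(f, q, full["df"])),
        "q": q,
    }


def oracle_lsm(data: pd.DataFrame, fit: dict, names: list[str], use_age: bool, use_season: bool) -> dict:
    """Least-square means at the age grand mean with equal season weights."""
    seasons = sorted(data["season"].unique()) if use_season else []
    out = {}
    for lev in sorted(data["genotype"].unique()):
        x = np.zeros(len(names))
        x[names.index("Intercept")] = 1.0
        if use_age:
            x[names.index("age")] = data["age"].mean()
        for s in seasons[1:]:
            x[names.index(f"season[{s}]")] = 1.0 / len(seasons)
        key = f"genotype[{lev}]"
        if key in names:
            x[names.index(key)] = 1.0
        out[lev] = (float(x @ fit["beta"]), float(np.sqrt(x @ fit["cov"] @ x)))
    return out


def random_small_design(rng: np.random.Generator, n_max: int = 30) -> pd.DataFrame:
    """A random unbalanced 3-genotype design with age and season covariates."""
    n = int(rng.integers(12, n_max + 1))
    while True:
        geno = rng.choice(["AA", "AB", "BB"], size=n, p=[0.3, 0.5, 0.2])
        season = rng.choice(["winter", "spring", "summer"], size=n)
        # need every retained level non-confounded; rank is checked by caller
        if len(set(geno)) >= 2 and len(set(season)) >= 2:
            break
    age = rng.normal(300, 25, size=n)
    y = (
        10.0
        + 0.02 * age
        + rng.normal(0, 1, size=n)
        + np.select([geno == "AA", geno == "AB"], [0.5, 0.2], 0.0)
    )
    return pd.DataFrame({"trait": y, "genotype": geno, "season": season, "age": age})


def simulate_null_cohort(rng: np.random.Generator, n: int = 296) -> pd.DataFrame:
    """Phenotypes with age and season structure but no genotype effect."""
    geno = rng.choice(["CC", "CT", "TT"], size=n, p=[0.25, 0.5, 0.25])
    season = rng.choice(["winter", "spring", "summer", "autumn"], size=n)
    age = rng.normal(400, 30, size=n)
    season_eff = pd.Series(season).map(
        {"winter": -0.5, "spring": 0.2, "summer": -0.2, "autumn": 0.5}
    ).to_numpy()
    y = 20.0 + 0.01 * age + season_eff + rng.normal(0, 1.0, size=n)
    return pd.DataFrame({"trait": y, "genotype": geno, "season": season, "age": age})
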