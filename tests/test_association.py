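import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _utils import (
    oracle_design,
    oracle_genotype_ftest,
    oracle_lsm,
    oracle_ols,
    random_small_design,
    simulate_null_cohort,
)
from fattenassoc.association import (
    DegenerateFactorError,
    IncomparableModelsError,
    ModelSpec,
    SingularDesignError,
    combine_genotypes,
    compare_models_r2,
    fit_interaction,
    fit_model,
    tukey_posthoc,
)


def _balanced_one_factor(effects=(0.0, 0.5, 1.0), n_per=8, sd=1.0, seed=1):
    rng = np.random.default_rng(seed)
    rows = []
    for g, eff in zip(["AA", "AB", "BB"], effects):
        for _ in range(n_per):
            rows.append({"trait": 5.0 + eff + sd * rng.normal(), "genotype": g})
    return pd.DataFrame(rows)


class TestFitModel:
    def test_reduces_to_oneway_anova(self):
        """No covariates: LSM = raw group means, F = classical one-way ANOVA F."""
        data = _balanced_one_factor()
        spec = ModelSpec(trait="trait", age_col=None, season_col=None)
        fit = fit_model(spec, data)
        group_means = data.groupby("genotype")["trait"].mean()
        for lev in fit.factor_levels:
            assert fit.lsm.loc[lev, "lsm"] == pytest.approx(group_means[lev], abs=1e-10)
        groups = [g["trait"].to_numpy() for _, g in data.groupby("genotype")]
        f_ref, p_ref = stats.f_oneway(*groups)
        assert fit.f_tests["genotype"].f == pytest.approx(f_ref, rel=1e-10)
        assert fit.f_tests["genotype"].p == pytest.approx(p_ref, rel=1e-10)

    def test_matches_normal_equation_oracle(self):
        """Coefficients, SEs, F and p agree with a hand-built solver to 1e-8."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            data = random_small_design(rng)
            X, names = oracle_design(data, use_age=True, use_season=True)
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            spec = ModelSpec(trait="trait")
            fit = fit_model(spec, data)
            ref = oracle_genotype_ftest(data, "trait", use_age=True, use_season=True)
            assert np.allclose(fit.params.to_numpy(), ref["full"]["beta"], atol=1e-8)
            assert np.allclose(
                np.sqrt(np.diag(fit.cov.to_numpy())),
                np.sqrt(np.diag(ref["full"]["cov"])),
                atol=1e-8,
            )
            assert fit.f_tests["genotype"].f == pytest.approx(ref["f"], abs=1e-8)
            assert fit.f_tests["genotype"].p == pytest.approx(ref["p"], abs=1e-8)
            lsm_ref = oracle_lsm(data, ref["full"], ref["names"], True, True)
            for lev, (m, se) in lsm_ref.items():
                assert fit.lsm.loc[lev, "lsm"] == pytest.approx(m, abs=1e-8)
                assert fit.lsm.loc[lev, "se"] == pytest.approx(se, abs=1e-8)
            checked += 1

    def test_lsm_shift_equivariance(self):
        rng = np.random.default_rng(3)
        data = random_small_design(rng)
        spec = ModelSpec(trait="trait")
        base = fit_model(spec, data)
        shifted = data.assign(trait=data["trait"] + 7.5)
        fit2 = fit_model(spec, shifted)
        assert np.allclose(
            fit2.lsm["lsm"].to_numpy(), base.lsm["lsm"].to_numpy() + 7.5, atol=1e-10
        )

    def test_single_level_factor_rejected(self):
        data = _balanced_one_factor().assign(genotype="AA")
        with pytest.raises(DegenerateFactorError):
            fit_model(ModelSpec(trait="trait", age_col=None, season_col=None), data)

    def test_confounded_factors_raise_singular(self):
        data = _balanced_one_factor()
        data["season"] = data["genotype"].map({"AA": "w", "AB": "s", "BB": "a"})
        with pytest.raises(SingularDesignError, match="aliased"):
            fit_model(ModelSpec(trait="trait", age_col=None), data)

    def test_null_type_one_error(self):
        """Genotype F-test rejects ~5% of null cohorts (quick 300-replicate check)."""
        rng = np.random.default_rng(2718)
        spec = ModelSpec(trait="trait")
        rejections = sum(
            fit_model(spec, simulate_null_cohort(rng)).f_tests["genotype"].p < 0.05
            for _ in range(300)
        )
        assert 0.02 <= rejections / 300 <= 0.08


class TestTukey:
    def test_two_levels_reduce_to_t_test(self):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            {
                "trait": rng.normal(0, 1, 30) + np.repeat([0.0, 0.8], 15),
                "genotype": np.repeat(["AA", "BB"], 15),
            }
        )
        fit = fit_model(ModelSpec(trait="trait", age_col=None, season_col=None), data)
        tk = tukey_posthoc(fit)
        t_ref, p_ref = stats.ttest_ind(
            data.loc[data.genotype == "AA", "trait"],
            data.loc[data.genotype == "BB", "trait"],
        )
        assert tk.pairwise["p_adj"].iloc[0] == pytest.approx(p_ref, abs=1e-9)

    def test_identical_means_share_a_letter(self):
        data = _balanced_one_factor(effects=(0.0, 0.0, 0.0), sd=1.0, seed=5)
        fit = fit_model(ModelSpec(trait="trait", age_col=None, season_col=None), data)
        tk = tukey_posthoc(fit)
        assert set(tk.letters.values()) == {"a"}

    def test_planted_effect_separates_homozygotes(self):
        """A large additive effect (0.2 kg/day vs 0.1 residual SD) splits letters."""
        rng = np.random.default_rng(13)
        separated = 0
        reps = 40
        for _ in range(reps):
            geno = rng.choice(["AA", "AB", "BB"], size=300, p=[0.25, 0.5, 0.25])
            eff = pd.Series(geno).map({"AA": -0.2, "AB": 0.0, "BB": 0.2}).to_numpy()
            data = pd.DataFrame(
                {"trait": 0.9 + eff + rng.normal(0, 0.1, 300), "genotype": geno}
            )
            fit = fit_model(ModelSpec(trait="trait", age_col=None, season_col=None), data)
            tk = tukey_posthoc(fit)
            if not (set(tk.letters["AA"]) & set(tk.letters["BB"])):
                separated += 1
        assert separated / reps >= 0.95

    def test_letters_consistent_with_pairwise(self):
        rng = np.random.default_rng(21)
        data = random_small_design(rng, n_max=30)
        fit = fit_model(ModelSpec(trait="trait"), data)
        tk = tukey_posthoc(fit)
        for rec in tk.pairwise.to_dict("records"):
            shared = set(tk.letters[rec["level_1"]]) & set(tk.letters[rec["level_2"]])
            if rec["p_adj"] < tk.alpha:
                assert not shared
            else:
                assert shared


class TestInteraction:
    def test_min_count_filter_contract(self):
        rng = np.random.default_rng(4)
        n = 40
        data = pd.DataFrame(
            {
                "trait": rng.normal(size=n),
                "g_A": ["AA"] * 20 + ["BB"] * 20,
                "g_B": ["CC"] * 39 + ["TT"],  # one singleton combination
            }
        )
        spec = ModelSpec(trait="trait", age_col=None, season_col=None)
        fit = fit_interaction(spec, data, ["g_A", "g_B"], min_count=3)
        assert "BBxTT" not in fit.factor_levels
        assert fit.n_used == n - 1

    def test_all_but_one_combo_filtered(self):
        data = pd.DataFrame(
            {"trait": np.arange(5.0), "g_A": ["AA"] * 4 + ["BB"], "g_B": ["CC"] * 5}
        )
        spec = ModelSpec(trait="trait", age_col=None, season_col=None)
        with pytest.raises(DegenerateFactorError):
            fit_interaction(spec, data, ["g_A", "g_B"], min_count=3)

    def test_null_interaction_rejects_near_alpha(self):
        rng = np.random.default_rng(99)
        spec = ModelSpec(trait="trait", age_col=None, season_col=None)
        reps, rejections = 200, 0
        for _ in range(reps):
            gA = rng.choice(["AA", "AB", "BB"], size=200, p=[0.25, 0.5, 0.25])
            gB = rng.choice(["CC", "CT", "TT"], size=200, p=[0.25, 0.5, 0.25])
            data = pd.DataFrame({"trait": rng.normal(size=200), "g_A": gA, "g_B": gB})
            fit = fit_interaction(spec, data, ["g_A", "g_B"], min_count=3)
            rejections += fit.f_tests["genotype"].p < 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestModelComparison:
    def test_penalizes_useless_term(self):
        rng = np.random.default_rng(12)
        data = random_small_design(rng)
        data["season"] = rng.choice(["w", "s"], size=len(data))  # pure noise factor
        with_season = fit_model(ModelSpec(trait="trait"), data)
        without = fit_model(ModelSpec(trait="trait", season_col=None), data)
        best = compare_models_r2([with_season, without])
        assert best.n_params <= with_season.n_params

    def test_detects_real_season_effect(self):
        rng = np.random.default_rng(14)
        n = 200
        season = rng.choice(["winter", "summer"], size=n)
        geno = rng.choice(["AA", "AB", "BB"], size=n)
        y = (season == "winter") * 2.0 + rng.normal(0, 1, n)
        data = pd.DataFrame(
            {"trait": y, "genotype": geno, "season": season, "age": rng.normal(300, 10, n)}
        )
        best = compare_models_r2(
            [
                fit_model(ModelSpec(trait="trait", season_col=None), data),
                fit_model(ModelSpec(trait="trait"), data),
            ]
        )
        assert "season" in best.f_tests

    def test_mismatched_responses_rejected(self):
        rng = np.random.default_rng(15)
        d1, d2 = random_small_design(rng), random_small_design(rng)
        f1 = fit_model(ModelSpec(trait="trait"), d1)
        f2 = fit_model(ModelSpec(trait="trait"), d2)
        with pytest.raises(IncomparableModelsError):
            compare_models_r2([f1, f2])

    def test_tie_prefers_fewer_parameters_deterministically(self):
        rng = np.random.default_rng(16)
        data = random_small_design(rng)
        f1 = fit_model(ModelSpec(trait="trait"), data)
        f2 = fit_model(ModelSpec(trait="trait"), data)
        assert compare_models_r2([f1, f2]) is f1


def test_combine_genotypes_labels():
    d = pd.DataFrame({"g_A": ["AA"], "g_B": ["CT"]})
    out = combine_genotypes(d, ["g_A", "g_B"])
    assert out["genotype"].iloc[0] == "AAxCT"
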