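import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.special import expit
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.stats.anova import AnovaRM

from mixqmri.reader_stats import (
    emm_and_tukey,
    fit_clmm,
    min_sample_size,
    rm_anova_tukey,
    simulate_likert,
)

THRESHOLDS = [-2.5, -1.0, 0.5, 2.0]


def small_design(n_spec=10, n_read=3, n_struct=22, seqs=("2D TSE", "MIX", "3D TSE")):
    return {
        "specimen": [f"S{i}" for i in range(n_spec)],
        "reader": [f"R{i}" for i in range(n_read)],
        "structure": [f"St{i}" for i in range(n_struct)],
        "sequence": list(seqs),
    }


class TestMinSampleSize:
    def test_study_design_inputs(self):
        assert min_sample_size(0.5, 0.4, 0.8, 0.01) == 8

    def test_larger_effect_smaller_n(self):
        # ((2.5758 + 0.8416) * 0.4 / 0.8)^2 = 2.92 -> 3
        assert min_sample_size(0.8, 0.4, 0.8, 0.01) == 3

    def test_halving_delta_quadruples_n_before_ceiling(self):
        n1 = min_sample_size(1.0, 0.4, 0.8, 0.01)
        n4 = min_sample_size(0.25, 0.4, 0.8, 0.01)
        assert n4 >= 4 * (n1 - 1)

    @given(
        delta=st.floats(0.1, 2.0),
        sd=st.floats(0.1, 2.0),
        power=st.floats(0.5, 0.95),
        alpha=st.floats(0.001, 0.2),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotonicities(self, delta, sd, power, alpha):
        n = min_sample_size(delta, sd, power, alpha)
        assert n >= 1
        assert min_sample_size(delta * 1.5, sd, power, alpha) <= n
        assert min_sample_size(delta, sd * 1.5, power, alpha) >= n
        assert min_sample_size(delta, sd, power, min(alpha * 1.5, 0.99)) <= n
        assert min_sample_size(delta, sd, min(power * 1.05, 0.99), alpha) >= n

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            min_sample_size(0.0, 0.4, 0.8, 0.01)
        with pytest.raises(ValueError):
            min_sample_size(0.5, 0.4, 1.2, 0.01)
        with pytest.raises(ValueError):
            min_sample_size(0.5, -0.4, 0.8, 0.01)


class TestSimulateLikert:
    def test_saturating_effect_gives_top_scores(self):
        ds = simulate_likert(
            small_design(2, 2, 3, ("A", "B")),
            {"A": 0.0, "B": 50.0},
            THRESHOLDS,
            {"specimen": 0, "reader": 0, "structure": 0},
            seed=1,
        )
        b_scores = ds.data.loc[ds.data["sequence"] == "B", "score"]
        assert (b_scores == 5).all()

    def test_marginal_distribution_matches_closed_form(self):
        """With no random effects the empirical category frequencies match
        the cumulative-logit probabilities within binomial error."""
        n = 100_000
        design = {
            "specimen": [f"S{i}" for i in range(n // 100)],
            "reader": ["R0"],
            "structure": [f"St{i}" for i in range(100)],
            "sequence": ["only"],
        }
        ds = simulate_likert(
            design, {"only": 0.0}, THRESHOLDS,
            {"specimen": 0, "reader": 0, "structure": 0}, seed=7,
        )
        cum = expit(np.asarray(THRESHOLDS))
        probs = np.diff(np.concatenate(([0.0], cum, [1.0])))
        counts = ds.data["score"].value_counts().reindex(range(1, 6), fill_value=0)
        freq = counts.to_numpy() / len(ds.data)
        # 4-sigma binomial tolerance per category
        tol = 4 * np.sqrt(probs * (1 - probs) / len(ds.data))
        assert np.all(np.abs(freq - probs) < tol)

    def test_seed_reproducibility(self):
        kwargs = dict(
            design=small_design(3, 2, 4),
            beta_truth={"2D TSE": 0.0, "MIX": 0.5, "3D TSE": -0.5},
            thresholds=THRESHOLDS,
            re_sd_truth={"specimen": 0.4, "reader": 0.3, "structure": 0.5},
        )
        a = simulate_likert(seed=42, **kwargs)
        b = simulate_likert(seed=42, **kwargs)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_likert(
                small_design(2, 2, 2), {}, [0.0, -1.0, 1.0, 2.0],
                {"specimen": 0, "reader": 0, "structure": 0},
            )


class TestFitClmm:
    def test_fixed_effects_matches_proportional_odds_ml(self):
        """With no random terms the fit is exact ML; statsmodels'
        proportional-odds implementation is the independent oracle."""
        ds = simulate_likert(
            small_design(), {"2D TSE": 0.0, "MIX": 0.5, "3D TSE": -0.5},
            THRESHOLDS, {"specimen": 0, "reader": 0, "structure": 0}, seed=3,
        )
        fit = fit_clmm(ds, random_terms=())
        assert fit.converged
        X = pd.get_dummies(ds.data["sequence"]).astype(float)[list(fit.beta_names)]
        import warnings

        with warnings.catch_warnings():
            # BFGS keeps iterating below its gtol near the optimum; the
            # loglik agreement below is the real convergence check
            warnings.simplefilter("ignore")
            om = OrderedModel(ds.data["score"], X, distr="logit").fit(
                method="bfgs", disp=False, gtol=1e-10, maxiter=500
            )
        assert abs(fit.loglik - om.llf) < 1e-6
        np.testing.assert_allclose(fit.beta, om.params[: len(fit.beta)], atol=1e-4)

    def test_beta_recovery_zero_variance(self):
        """n = 2000 rows, no random effects: beta within 2 SE of truth."""
        design = {
            "specimen": [f"S{i}" for i in range(100)],
            "reader": ["R0"],
            "structure": [f"St{i}" for i in range(10)],
            "sequence": ["ref", "new"],
        }
        ds = simulate_likert(
            design, {"ref": 0.0, "new": 1.0}, THRESHOLDS,
            {"specimen": 0, "reader": 0, "structure": 0}, seed=2024,
        )
        assert len(ds.data) == 2000
        fit = fit_clmm(ds, random_terms=())
        (beta,), (se,) = fit.beta, fit.beta_se
        assert abs(beta - 1.0) < 2 * se

    def test_mixed_fit_recovers_effects_and_sds(self):
        ds = simulate_likert(
            small_design(), {"2D TSE": 0.0, "MIX": 0.5, "3D TSE": -0.5},
            THRESHOLDS, {"specimen": 0.4, "reader": 0.3, "structure": 0.5}, seed=4,
        )
        fit = fit_clmm(ds)
        assert fit.converged
        est = dict(zip(fit.beta_names, fit.beta))
        se = dict(zip(fit.beta_names, fit.beta_se))
        assert abs(est["MIX"] - 0.5) < 3 * se["MIX"]
        assert abs(est["3D TSE"] + 0.5) < 3 * se["3D TSE"]
        assert all(sd >= 0 for sd in fit.re_sd.values())
        assert 0.1 < fit.re_sd["structure"] < 1.2

    def test_thresholds_strictly_increasing(self):
        ds = simulate_likert(
            small_design(4, 2, 6), {"2D TSE": 0.0, "MIX": 0.3, "3D TSE": -0.3},
            THRESHOLDS, {"specimen": 0.3, "reader": 0.2, "structure": 0.4}, seed=6,
        )
        fit = fit_clmm(ds)
        assert np.all(np.diff(fit.thresholds) > 0)

    def test_single_category_rejected(self):
        df = pd.DataFrame(
            {
                "specimen": ["S0", "S1"] * 2,
                "reader": ["R0"] * 4,
                "structure": ["St0"] * 4,
                "sequence": ["A", "A", "B", "B"],
                "score": [3, 3, 3, 3],
            }
        )
        from mixqmri.reader_stats import LikertDataset

        with pytest.raises(ValueError, match="single category"):
            fit_clmm(LikertDataset(df))


@pytest.fixture(scope="module")
def fitted():
    ds = simulate_likert(
        small_design(), {"2D TSE": 0.0, "MIX": 0.6, "3D TSE": -0.6},
        THRESHOLDS, {"specimen": 0.4, "reader": 0.3, "structure": 0.5}, seed=8,
    )
    return emm_and_tukey(fit_clmm(ds), seed=99)


class TestEmmAndTukey:
    def test_contrast_count(self, fitted):
        assert len(fitted.contrasts) == 3  # k(k-1)/2 for k = 3

    def test_adjusted_p_at_least_raw(self, fitted):
        assert (fitted.contrasts["p_tukey"] >= fitted.contrasts["p_raw"] - 1e-12).all()

    def test_p_values_in_unit_interval(self, fitted):
        for col in ("p_raw", "p_tukey"):
            assert fitted.contrasts[col].between(0, 1).all()

    def test_emm_ordering_follows_effects(self, fitted):
        emm = dict(zip(fitted.levels, fitted.emm))
        assert emm["MIX"] > emm["2D TSE"] > emm["3D TSE"]

    def test_null_effects_rarely_significant(self):
        """Equal true level effects: adjusted p-values are large."""
        design = small_design(25, 2, 10, ("A", "B", "C"))
        big = {"A": 0.0, "B": 0.0, "C": 0.0}
        ds = simulate_likert(
            design, big, THRESHOLDS, {"specimen": 0.3, "reader": 0.2, "structure": 0.3},
            seed=55,
        )
        table = emm_and_tukey(fit_clmm(ds), seed=1)
        assert (table.contrasts["p_tukey"] > 0.05).all()


class TestRmAnovaTukey:
    def test_identical_columns(self):
        tab = pd.DataFrame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0], "C": [1.0, 2.0, 3.0]})
        res = rm_anova_tukey(tab)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert (res.tukey["p_tukey"] == 1.0).all()

    def test_hand_computed_table(self):
        """3 specimens x 3 sequences; sums of squares done by hand."""
        tab = pd.DataFrame(
            {"A": [1.0, 6.0, 8.0], "B": [2.0, 4.0, 9.0], "C": [3.0, 5.0, 7.0]},
        )
        res = rm_anova_tukey(tab)
        arr = tab.to_numpy()
        grand = arr.mean()
        ss_seq = 3 * np.sum((arr.mean(axis=0) - grand) ** 2)
        ss_subj = 3 * np.sum((arr.mean(axis=1) - grand) ** 2)
        ss_err = np.sum((arr - grand) ** 2) - ss_seq - ss_subj
        f_manual = (ss_seq / 2) / (ss_err / 4)
        assert res.f_stat == pytest.approx(f_manual, rel=1e-12)
        assert res.df_effect == 2 and res.df_error == 4

    def test_matches_statsmodels_anova_rm(self):
        rng = np.random.default_rng(17)
        tab = pd.DataFrame(rng.normal(0, 1, (8, 3)), columns=["A", "B", "C"])
        res = rm_anova_tukey(tab)
        long = tab.reset_index().melt(id_vars="index", var_name="seq", value_name="y")
        sm_res = AnovaRM(long, "y", "index", within=["seq"]).fit()
        f_sm = float(sm_res.anova_table["F Value"].iloc[0])
        p_sm = float(sm_res.anova_table["Pr > F"].iloc[0])
        assert res.f_stat == pytest.approx(f_sm, rel=1e-9)
        assert res.p_value == pytest.approx(p_sm, rel=1e-9)

    def test_missing_cells_rejected(self):
        tab = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            rm_anova_tukey(tab)

    def test_tukey_pair_count_and_bounds(self):
        rng = np.random.default_rng(18)
        tab = pd.DataFrame(rng.normal(0, 1, (6, 4)), columns=list("ABCD"))
        res = rm_anova_tukey(tab)
        assert len(res.tukey) == 6
        assert res.tukey["p_tukey"].between(0, 1).all()
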