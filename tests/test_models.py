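import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stripelum.models import (
    ModelSpec,
    aicc,
    build_selection_table,
    emm_pairwise,
    fit_gaussian_glm,
    pearson_test,
)
from stripelum.pipeline import candidate_specs
from stripelum.synthetic import EffectSpec, generate_metric_table


def design_table(arenas=2, stimuli=3, sessions=11, reps=1, seed=0):
    """A balanced table with the requested numbers of factor levels."""
    rng = np.random.default_rng(seed)
    rows = []
    arena_levels = ["black", "white"][:arenas]
    stim_levels = ["control", "predatory", "social"][:stimuli]
    ses_levels = [str(i + 1) for i in range(sessions)]
    for a, s in itertools.product(arena_levels, stim_levels):
        for r in range(reps * sessions):
            rows.append(
                {
                    "arena": a,
                    "stimulus": s,
                    "session": ses_levels[r % sessions],
                    "y": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


class TestFitGaussianGlm:
    def test_intercept_only_is_the_mean(self):
        t = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        f = fit_gaussian_glm(t, ModelSpec("y"))
        assert f.params["Intercept"] == pytest.approx(2.0)
        assert f.k == 2

    def test_exp2_global_model_has_17_parameters(self):
        t = design_table()
        spec = ModelSpec(
            "y", ("arena", "stimulus", "session"),
            interactions=(("arena", "stimulus"),),
        )
        f = fit_gaussian_glm(t, spec)
        assert f.k == 17

    @pytest.mark.parametrize(
        "predictors,interactions,sessions,expected_k",
        [
            ((), (), 3, 2),  # null
            (("arena",), (), 3, 3),
            (("session",), (), 3, 4),  # experiment-1 session
            (("arena", "session"), (), 3, 5),
            (("session",), (), 11, 12),  # experiment-2 session
            (("arena", "stimulus"), (), 11, 5),
            (("arena", "stimulus", "session"), (), 11, 15),
            (("arena", "stimulus", "session"), (("arena", "stimulus"),), 11, 17),
        ],
    )
    def test_df_bookkeeping_matches_design(
        self, predictors, interactions, sessions, expected_k
    ):
        """Parameter counts derive every published degrees-of-freedom value
        from the design alone (2 arenas, 3 stimuli, 3 or 11 sessions)."""
        t = design_table(sessions=sessions)
        f = fit_gaussian_glm(t, ModelSpec("y", predictors, interactions))
        assert f.k == expected_k

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame(
            {
                "g": rng.choice(["a", "b", "c"], 40),
                "h": rng.choice(["u", "v"], 40),
                "y": rng.normal(size=40),
            }
        )
        f = fit_gaussian_glm(t, ModelSpec("y", ("g", "h")))
        # independent oracle: hand-built dummy matrix + lstsq
        X = np.column_stack(
            [
                np.ones(40),
                (t.g == "b").astype(float),
                (t.g == "c").astype(float),
                (t.h == "v").astype(float),
            ]
        )
        beta, *_ = np.linalg.lstsq(X, t.y.to_numpy(), rcond=None)
        np.testing.assert_allclose(f.params.to_numpy(), beta, atol=1e-10)
        # and the closed-form Gaussian ML log-likelihood
        rss = float(((t.y.to_numpy() - X @ beta) ** 2).sum())
        n = 40
        assert f.loglik == pytest.approx(
            -n / 2 * (math.log(2 * math.pi * rss / n) + 1), abs=1e-10
        )

    def test_residuals_orthogonal_to_fit(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame({"g": rng.choice(list("abcd"), 60), "y": rng.normal(size=60)})
        f = fit_gaussian_glm(t, ModelSpec("y", ("g",)))
        dm = np.column_stack(
            [np.ones(60)] + [(t.g == l).astype(float) for l in "bcd"]
        )
        fitted = dm @ f.params.to_numpy()
        resid = t.y.to_numpy() - fitted
        assert abs(resid @ fitted) < 1e-8

    def test_rank_deficiency_names_aliased_term(self):
        t = pd.DataFrame(
            {"g": ["a", "a", "b", "b"], "h": ["u", "u", "v", "v"],
             "y": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(ValueError, match="aliased"):
            fit_gaussian_glm(t, ModelSpec("y", ("g", "h")))

    def test_missing_response_rows_dropped(self):
        t = pd.DataFrame({"y": [1.0, np.nan, 3.0, 5.0]})
        f = fit_gaussian_glm(t, ModelSpec("y"))
        assert f.n == 3
        assert f.params["Intercept"] == pytest.approx(3.0)

    def test_undeclared_interaction_predictor_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("y", ("a",), interactions=(("a", "b"),))


class TestAicc:
    def test_toy_table_matches_hand_computed_closed_form(self):
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        f = fit_gaussian_glm(pd.DataFrame({"y": y}), ModelSpec("y"))
        n, k = 10, 2
        rss = float(((y - y.mean()) ** 2).sum())
        ll = -n / 2 * (math.log(2 * math.pi * rss / n) + 1)
        expected = -2 * ll + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(f) == pytest.approx(expected, abs=1e-8)

    def test_converges_to_aic_for_large_n(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=10**6)
        f = fit_gaussian_glm(pd.DataFrame({"y": y}), ModelSpec("y"))
        aic = -2 * f.loglik + 2 * f.k
        assert abs(aicc(f) - aic) < 1e-3

    def test_undefined_below_minimum_n(self):
        f = fit_gaussian_glm(pd.DataFrame({"y": [1.0, 2.0, 3.0]}), ModelSpec("y"))
        assert f.n == 3 and f.k == 2
        with pytest.raises(ValueError, match="undefined"):
            aicc(f)

    def test_monotone_in_rss(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=30)
        fits = [
            fit_gaussian_glm(pd.DataFrame({"y": base * s}), ModelSpec("y"))
            for s in (1.0, 2.0, 5.0)
        ]
        vals = [aicc(f) for f in fits]
        assert vals == sorted(vals)


class TestSelectionTable:
    def test_best_model_has_delta_zero_and_deltas_nondecreasing(self):
        t = generate_metric_table(EffectSpec(group_sizes=8), seed=1)
        sel = build_selection_table(t, candidate_specs("mean_lum", 2))
        d = sel.table.delta_aicc.to_numpy()
        assert d[0] == 0.0
        assert (np.diff(d) >= 0).all()

    def test_identical_specs_tie_flagged(self):
        t = pd.DataFrame({"y": np.random.default_rng(0).normal(size=20)})
        sel = build_selection_table(
            t, [ModelSpec("y", label="m1"), ModelSpec("y", label="m2")]
        )
        assert (sel.table.delta_aicc == 0).all()
        assert sel.table.tied.all()

    def test_strong_effect_prefers_arena_model(self):
        spec = EffectSpec(
            arena_effect=10.0, stimulus_effects={"control": 0.0}, group_sizes=16
        )
        t = generate_metric_table(spec, seed=4)
        sel = build_selection_table(
            t,
            [ModelSpec("mean_lum", ("arena",), label="arena"),
             ModelSpec("mean_lum", label="null")],
        )
        assert sel.verdict == "preferred model: arena"

    def test_null_best_gives_no_supported_predictors(self):
        spec = EffectSpec(
            arena_effect=0.0, stimulus_effects={"control": 0.0}, group_sizes=16
        )
        t = generate_metric_table(spec, seed=6)
        sel = build_selection_table(
            t,
            [ModelSpec("mean_lum", ("session",), label="session"),
             ModelSpec("mean_lum", label="null")],
        )
        assert sel.verdict == "no supported predictors"

    def test_ordering_invariant_to_spec_order(self):
        t = generate_metric_table(EffectSpec(group_sizes=8), seed=2)
        specs = candidate_specs("cw", 2)
        a = build_selection_table(t, specs).table
        b = build_selection_table(t, list(reversed(specs))).table
        pd.testing.assert_frame_equal(a, b)

    def test_supported_needs_margin_over_null(self):
        """A best model within two units of the null is not supported."""
        spec = EffectSpec(
            arena_effect=0.2, stimulus_effects={"control": 0.0},
            residual_sd=3.0, group_sizes=10,
        )
        t = generate_metric_table(spec, seed=8)
        sel = build_selection_table(
            t,
            [ModelSpec("mean_lum", ("arena",), label="arena"),
             ModelSpec("mean_lum", label="null")],
        )
        null_aicc = sel.table.loc[sel.table.is_null, "aicc"].iloc[0]
        for _, row in sel.table.iterrows():
            if row.supported:
                assert row.aicc < null_aicc - 2.0


class TestEmmPairwise:
    def test_balanced_one_factor_equals_group_mean_differences(self):
        rng = np.random.default_rng(7)
        t = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 10), "y": rng.normal(size=30)}
        )
        f = fit_gaussian_glm(t, ModelSpec("y", ("g",)))
        means = t.groupby("g").y.mean()
        results = {c.pair: c for c in emm_pairwise(f, "g")}
        assert results["a - b"].estimate == pytest.approx(means["a"] - means["b"])
        assert results["b - c"].estimate == pytest.approx(means["b"] - means["c"])
        assert results["a - b"].df == 30 - 3

    def test_luminance_contrast_model_df_61(self):
        from stripelum.synthetic import exp2_like_spec

        t = generate_metric_table(exp2_like_spec(), seed=1)
        f = fit_gaussian_glm(t, ModelSpec("cw", ("arena", "stimulus")))
        contrasts = emm_pairwise(f, "stimulus")
        assert all(c.df == 61 for c in contrasts)
        assert len(contrasts) == 3

    def test_recovers_known_stimulus_effect(self):
        spec = EffectSpec(
            stimulus_effects={"control": 0.0, "predatory": 0.0, "social": 3.0},
            residual_sd=1.0, group_sizes=20,
        )
        t = generate_metric_table(spec, seed=3)
        f = fit_gaussian_glm(t, ModelSpec("mean_lum", ("arena", "stimulus")))
        res = {c.pair: c for c in emm_pairwise(f, "stimulus")}
        c = res["control - social"]
        assert abs(c.estimate - (-3.0)) < 2 * c.se

    def test_interaction_triggers_warning(self):
        t = design_table(sessions=2)
        f = fit_gaussian_glm(
            t,
            ModelSpec("y", ("arena", "stimulus"),
                      interactions=(("arena", "stimulus"),)),
        )
        with pytest.warns(UserWarning, match="interaction"):
            emm_pairwise(f, "stimulus")

    def test_single_level_factor_rejected(self):
        t = pd.DataFrame({"g": ["a"] * 10, "y": np.arange(10.0)})
        f = fit_gaussian_glm(t, ModelSpec("y", ("g",)))
        with pytest.raises(ValueError, match="fewer than 2"):
            emm_pairwise(f, "g")

    def test_adjustment_options_ordered(self):
        rng = np.random.default_rng(11)
        t = pd.DataFrame(
            {"g": np.repeat(["a", "b", "c"], 8), "y": rng.normal(size=24)}
        )
        f = fit_gaussian_glm(t, ModelSpec("y", ("g",)))
        p_none = emm_pairwise(f, "g", adjustment="none")[0].p_adjusted
        p_tukey = emm_pairwise(f, "g", adjustment="tukey")[0].p_adjusted
        p_bonf = emm_pairwise(f, "g", adjustment="bonferroni")[0].p_adjusted
        assert p_none <= p_tukey <= p_bonf


class TestPearson:
    def test_identity_gives_r_one(self):
        x = np.arange(10.0)
        res = pearson_test(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.df == 8

    def test_orthogonal_gives_r_zero(self):
        x = np.arange(12.0)
        y = np.random.default_rng(1).normal(size=12)
        y = y - y.mean()
        xc = x - x.mean()
        y = y - (y @ xc) / (xc @ xc) * xc  # orthogonalise against x
        res = pearson_test(x, y)
        assert abs(res.r) < 1e-12

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=65)
        y = 0.5 * x + rng.normal(size=65)
        res = pearson_test(x, y)
        assert res.t == pytest.approx(
            res.r * math.sqrt(63 / (1 - res.r**2)), rel=1e-12
        )
        assert res.df == 63

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [3.0, 4.0])
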