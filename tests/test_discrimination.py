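import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from viewflow import discrimination as disc
from viewflow.errors import (
    DegeneratePredictorError,
    MissingCellError,
    ValidationError,
)
from viewflow.synthetic import simulate_null_factorial


def make_trials(rows):
    frame = pd.DataFrame(
        rows,
        columns=[
            "participant", "object", "axis_type", "base_view",
            "rotation_level", "response", "rt_ms",
        ],
    )
    frame["image_set"] = "rendered"
    return frame


def trial(participant="p1", obj="pig", axis="cardinal", level=0,
          response="same", rt=1000.0, base="front"):
    return (participant, obj, axis, base, level, response, rt)


class TestExclusions:
    def base_trials(self):
        rows = []
        for lvl in (0, 10, 15):
            for i in range(4):
                rows.append(trial(level=lvl, response="same" if lvl == 0 else "different",
                                  rt=800 + i))
        return make_trials(rows)

    def test_fast_trial_excluded(self):
        trials = pd.concat(
            [self.base_trials(), make_trials([trial(level=5, rt=250.0)])],
            ignore_index=True,
        )
        kept, report = disc.apply_exclusions(trials)
        assert report.n_rt_excluded == 1
        assert (kept["rt_ms"] >= 300).all()

    def test_slow_trial_excluded_and_normal_retained(self):
        trials = pd.concat(
            [self.base_trials(),
             make_trials([trial(level=5, rt=6000.0), trial(level=5, rt=1000.0)])],
            ignore_index=True,
        )
        kept, report = disc.apply_exclusions(trials)
        assert report.n_rt_excluded == 1
        assert len(kept) == len(trials) - 1

    def test_low_priming_score_removes_participant(self):
        trials = self.base_trials()
        kept, report = disc.apply_exclusions(
            trials, priming_scores={"p1": 0.70}
        )
        assert kept.empty
        assert report.excluded_participants == {"p1": "priming_performance"}

    def test_low_main_task_performance_removes_participant(self):
        rows = [trial(level=0, response="different", rt=900.0) for _ in range(10)]
        rows += [trial(level=10, response="different", rt=900.0) for _ in range(4)]
        trials = make_trials(rows)
        kept, report = disc.apply_exclusions(trials, priming_scores={"p1": 1.0})
        assert kept.empty
        assert report.excluded_participants == {"p1": "main_task_performance"}

    def test_unknown_participant_in_priming_table(self):
        with pytest.raises(ValidationError, match="missing from priming"):
            disc.apply_exclusions(self.base_trials(), priming_scores={"zz": 1.0})

    def test_order_independence_rules_computed_on_input(self):
        # a participant whose *slow* trials are all errors: performance is
        # judged on the full input, so they fail the 75% floor even though
        # their surviving (fast) trials are perfect
        good = [trial(level=0, response="same", rt=900.0) for _ in range(3)]
        bad = [trial(level=10, response="same", rt=7000.0) for _ in range(9)]
        kept, report = disc.apply_exclusions(make_trials(good + bad))
        assert report.excluded_participants == {"p1": "main_task_performance"}
        assert kept.empty


class TestPsychometricTable:
    def test_proportions(self):
        rows = [trial(level=0, response="same") for _ in range(10)]
        rows += [trial(level=5, response="different") for _ in range(4)]
        rows += [trial(level=5, response="same") for _ in range(6)]
        table = disc.psychometric_table(make_trials(rows))
        t0 = table[table.rotation_level == 0].iloc[0]
        t5 = table[table.rotation_level == 5].iloc[0]
        assert t0.p_same == 1.0
        assert t5.p_different == pytest.approx(0.4)
        assert t5.n_trials == 10

    def test_sign_pooling(self):
        rows = [trial(level=5, response="different") for _ in range(3)]
        rows += [trial(level=5, response="same") for _ in range(2)]
        rows += [trial(level=-5, response="different") for _ in range(1)]
        rows += [trial(level=-5, response="same") for _ in range(4)]
        pooled = disc.psychometric_table(make_trials(rows), pool_sign=True)
        assert pooled.p_different.iloc[0] == pytest.approx(0.4)
        unpooled = disc.psychometric_table(make_trials(rows), pool_sign=False)
        assert set(unpooled.rotation_level) == {-5, 5}

    def test_shuffle_invariance(self, rng):
        rows = [trial(level=lvl, response=resp)
                for lvl in (0, 5, 10) for resp in ("same", "different")] * 3
        trials = make_trials(rows)
        shuffled = trials.sample(frac=1.0, random_state=7)
        a = disc.psychometric_table(trials)
        b = disc.psychometric_table(shuffled)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_absent_cell_not_reported_as_zero(self):
        table = disc.psychometric_table(make_trials([trial(level=0)]))
        assert not (table.rotation_level == 5).any()


def table_from_p(p_card_0, p_card_5, p_non_0, p_non_5, obj="pig"):
    rows = []
    for axis, p0, p5 in (
        ("cardinal", p_card_0, p_card_5),
        ("non-cardinal", p_non_0, p_non_5),
    ):
        rows.append((obj, axis, 0, 10, 1 - p0, p0))
        rows.append((obj, axis, 5, 10, 1 - p5, p5))
    return pd.DataFrame(
        rows,
        columns=["object", "axis_type", "rotation_level",
                 "n_trials", "p_same", "p_different"],
    )


class TestCardinalAxisEffect:
    def test_hand_computed_slopes(self):
        eff = disc.cardinal_axis_effect(table_from_p(0.1, 0.6, 0.1, 0.2), "pig")
        assert eff.slope_cardinal == pytest.approx(0.1)
        assert eff.slope_noncardinal == pytest.approx(0.02)
        assert eff.effect == pytest.approx(0.08)

    def test_identical_axes_give_zero(self):
        eff = disc.cardinal_axis_effect(table_from_p(0.2, 0.5, 0.2, 0.5), "pig")
        assert eff.effect == 0.0

    def test_sign_convention(self):
        eff = disc.cardinal_axis_effect(table_from_p(0.1, 0.2, 0.1, 0.6), "pig")
        assert eff.effect < 0

    def test_antisymmetric_under_axis_swap(self):
        table = table_from_p(0.1, 0.6, 0.1, 0.2)
        swapped = table.copy()
        swapped["axis_type"] = swapped["axis_type"].map(
            {"cardinal": "non-cardinal", "non-cardinal": "cardinal"}
        )
        a = disc.cardinal_axis_effect(table, "pig").effect
        b = disc.cardinal_axis_effect(swapped, "pig").effect
        assert a == pytest.approx(-b)

    def test_missing_cell_raises(self):
        table = table_from_p(0.1, 0.6, 0.1, 0.2)
        with pytest.raises(MissingCellError):
            disc.cardinal_axis_effect(table[table.axis_type == "cardinal"], "pig")


def factorial_data(rng, n_per_cell=12, sigma=1.0, effects=None):
    effects = effects or {}
    rows = []
    for lvl, axis, iset in itertools.product(
        (0, 5, 10, 15), ("cardinal", "non-cardinal"), ("real", "rendered")
    ):
        mu = (
            effects.get("rotation_level", 0.0) * lvl
            + effects.get("axis_type", 0.0) * (1 if axis == "cardinal" else -1)
        )
        for _ in range(n_per_cell):
            rows.append((lvl, axis, iset, rng.normal(mu, sigma)))
    return pd.DataFrame(
        rows, columns=["rotation_level", "axis_type", "image_set", "p_different"]
    )


class TestFGLS:
    def test_homoscedastic_equals_ols_anova(self, rng):
        statsmodels = pytest.importorskip("statsmodels.formula.api")
        data = factorial_data(rng, effects={"rotation_level": 0.05, "axis_type": 0.4})
        fit = disc.fgls_factorial(data, variance_structures=("homoscedastic",))
        d = data.copy()
        d["r"] = d.rotation_level - d.rotation_level.mean()
        d["a"] = np.where(d.axis_type == "cardinal", 1.0, -1.0)
        d["s"] = np.where(d.image_set == "real", 1.0, -1.0)
        ols = statsmodels.ols("p_different ~ r * a * s", data=d).fit()
        t2 = ols.tvalues**2
        name_map = {
            "rotation_level": "r",
            "axis_type": "a",
            "image_set": "s",
            "rotation_level:axis_type": "r:a",
            "rotation_level:image_set": "r:s",
            "axis_type:image_set": "a:s",
            "rotation_level:axis_type:image_set": "r:a:s",
        }
        for stat in fit.stats:
            assert stat.value == pytest.approx(t2[name_map[stat.note]], abs=1e-6)

    def test_injected_effect_matches_closed_form_f(self, rng):
        # balanced two-level factor, known sigma: F ≈ (n/4)*(delta/sigma)^2
        # in expectation; check against the OLS t² computed directly
        delta, sigma, n_per_cell = 0.8, 0.5, 50
        data = factorial_data(
            rng, n_per_cell=n_per_cell, sigma=sigma, effects={"axis_type": delta / 2}
        )
        fit = disc.fgls_factorial(data, variance_structures=("homoscedastic",))
        f_axis = fit.stat_for("axis_type").value
        n = len(data)
        expected_order = n * (delta / 2) ** 2 / sigma**2
        assert f_axis == pytest.approx(expected_order, rel=0.5)
        assert fit.stat_for("axis_type").p < 1e-6

    def test_forced_equal_variances_reproduce_ols_params(self, rng):
        data = factorial_data(rng)
        hom = disc.fgls_factorial(data, variance_structures=("homoscedastic",))
        x, _ = disc._design_matrix(data)
        beta_ols = np.linalg.lstsq(x, data["p_different"], rcond=None)[0]
        np.testing.assert_allclose(hom.params.to_numpy(), beta_ols, atol=1e-10)

    def test_aic_selects_generating_structure(self, rng):
        data = simulate_null_factorial(n_per_cell=300, sigma_by_axis=(1.0, 4.0), seed=5)
        fit = disc.fgls_factorial(data)
        assert fit.variance_structure == "axis_type"

    def test_rank_deficiency_reported(self, rng):
        data = factorial_data(rng)
        data["axis_type"] = "cardinal"
        with pytest.raises(ValidationError, match="two axis_type"):
            disc.fgls_factorial(data)

    def test_null_type_one_error_calibrated(self):
        # fixed-seed null simulation: each marginal F-test should reject at
        # close to the nominal 5% rate despite heteroscedastic groups
        reps = 400
        rejections = np.zeros(7)
        for i in range(reps):
            data = simulate_null_factorial(
                n_per_cell=40, sigma_by_axis=(1.0, 2.0), seed=60_000 + i
            )
            fit = disc.fgls_factorial(data, variance_structures=("axis_type",))
            rejections += [s.p < 0.05 for s in fit.stats]
        rates = rejections / reps
        assert (rates > 0.02).all() and (rates < 0.08).all()


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = disc.simple_regression(x, 2 * x + 1)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        res = disc.simple_regression(x, y)
        # closed-form least squares
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        ssr = slope * sxy
        sse = ((y - y.mean()) ** 2).sum() - ssr
        f_ref = ssr / (sse / 3)
        p_ref = sps.f.sf(f_ref, 1, 3)
        assert res.slope == pytest.approx(slope, abs=1e-12)
        assert res.stat.value == pytest.approx(f_ref, abs=1e-9)
        assert res.stat.p == pytest.approx(p_ref, abs=1e-12)
        assert res.stat.df == (1.0, 3.0)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            disc.simple_regression([1.0, 2.0], [1.0, 2.0])

    def test_constant_predictor(self):
        with pytest.raises(DegeneratePredictorError):
            disc.simple_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedT:
    def test_equal_vectors(self):
        res = disc.paired_t_cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.value == 0.0
        assert res.p == 1.0

    def test_hand_computed(self):
        res = disc.paired_t_cohens_d([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.value == pytest.approx(2 * math.sqrt(3))
        assert res.df == (2.0,)
        assert res.effect_size == pytest.approx(2.0)

    def test_matches_scipy(self, rng):
        a = rng.normal(size=13)
        b = rng.normal(size=13)
        res = disc.paired_t_cohens_d(a, b)
        t_ref, p_ref = sps.ttest_rel(a, b)
        assert res.value == pytest.approx(t_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, abs=1e-12)
        assert res.df == (12.0,)

    def test_zero_variance_flagged_infinite(self):
        res = disc.paired_t_cohens_d([2.0, 2.0], [1.0, 1.0])
        assert math.isinf(res.value)
        assert res.note is not None


class TestWilcoxon:
    def test_exact_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        res = disc.wilcoxon_signed_rank(a, b, mode="exact")
        d = a - b
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count_le = count_ge = 0
        for signs in itertools.product((0, 1), repeat=6):
            w = float(np.dot(signs, ranks))
            count_le += w <= w_obs + 1e-12
            count_ge += w >= w_obs - 1e-12
        p_ref = min(1.0, 2 * min(count_le, count_ge) / 64)
        assert res.p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for n in (8, 10, 12):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = disc.wilcoxon_signed_rank(a, b, mode="exact")
            ref = sps.wilcoxon(a, b, mode="exact")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetric_differences_give_large_p(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = disc.wilcoxon_signed_rank(a, np.zeros(6), mode="exact")
        assert res.p > 0.8

    def test_exact_close_to_normal_approx_at_n12(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        exact = disc.wilcoxon_signed_rank(a, b, mode="exact")
        approx = disc.wilcoxon_signed_rank(a, b, mode="normal-approx")
        assert exact.p == pytest.approx(approx.p, abs=0.02)
        assert exact.effect_size == pytest.approx(approx.effect_size)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValidationError):
            disc.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
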