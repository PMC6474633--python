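"""Streak classification, pre/post contrasts, regressions, exclusion."""

import numpy as np
import pytest

from hierlearn.flat_observer import FlatParams, run_flat
from hierlearn.hallmark import (apparent_learning_rate, classify_streaks,
                                exclusion_filter, first_order_covariates,
                                group_ttest, pre_post_change,
                                residual_confidence_test,
                                streak_type_contrast, subject_regression)
from hierlearn.hier_observer import HierParams, run_hier
from hierlearn.study import model_level_contrast
from hierlearn.taskgen import Streak, find_streaks

from conftest import make_sequence


class TestClassification:
    def test_context_determines_suspicion(self):
        # an alternating context makes a long repetition streak unlikely
        # (suspicious); a repetitive context makes the same streak benign
        suspicious_ctx = [1, 2] * 12 + [1] * 10
        benign_ctx = [1, 1, 1, 2] * 6 + [1] * 10
        params = HierParams(pc=1 / 75, grid_n=50)
        for stim, expected in ((suspicious_ctx, "suspicious"),
                               (benign_ctx, "non_suspicious")):
            seq = make_sequence(stim)
            streaks = find_streaks(seq)
            assert len(streaks) == 1
            classify_streaks(run_hier(seq, params), streaks)
            assert streaks[0].label == expected

    def test_streak_outside_trace_rejected(self):
        seq = make_sequence([1, 2] * 10)
        trace = run_hier(seq, HierParams(grid_n=20))
        with pytest.raises(IndexError):
            classify_streaks(trace, [Streak(start=15, end=25, symbol=1)])

    def test_changeless_observer_is_not_reset_by_streaks(self):
        # with pc=0 there is no change-point mass to redistribute: a
        # context-consistent streak only sharpens the posterior, and even
        # an inconsistent one moves confidence far less than for a
        # change-aware observer
        stim = [1, 1, 1, 2] * 6 + [1] * 10
        seq = make_sequence(stim)
        streaks = find_streaks(seq)
        classify_streaks(run_hier(seq, HierParams(pc=0.0, grid_n=50)),
                         streaks)
        assert streaks[0].label == "non_suspicious"


class TestPrePost:
    def test_identical_values_give_zero(self, small_design_pool):
        design = small_design_pool.designs[0]
        const = np.full(len(design.sequence), 0.4)
        eff = pre_post_change(const, const, design)
        assert len(eff) == 16
        assert np.all(eff.d_conf == 0)
        assert np.all(eff.d_prob == 0)

    def test_missing_report_drops_streak_with_warning(
            self, small_design_pool):
        design = small_design_pool.designs[0]
        conf = np.full(len(design.sequence), 0.4)
        conf[design.prepost_pairs()[0][1]] = np.nan
        with pytest.warns(UserWarning):
            eff = pre_post_change(conf, conf, design)
        assert len(eff) == 15

    def test_hier_effect_flat_null(self, small_design_pool):
        hier = model_level_contrast(small_design_pool, "hier")
        flat = model_level_contrast(small_design_pool, "flat")
        assert hier["conf"].mean > 0.2
        assert abs(flat["conf"].mean) < 0.1
        # suspicious streaks drive a confidence *decrease* in the
        # hierarchical observer
        for design, traces in zip(small_design_pool.designs,
                                  small_design_pool.traces):
            tr = traces["hier"]
            eff = pre_post_change(tr.p_next[:, 0], tr.conf, design)
            assert eff[eff.label == "suspicious"].d_conf.mean() < 0

    def test_flat_confidence_still_decays_during_streaks(
            self, small_design_pool):
        # the flat observer forgets the unobserved transition during any
        # streak: d_conf < 0 for both types, with no type difference
        drops = []
        for design, traces in zip(small_design_pool.designs,
                                  small_design_pool.traces):
            tr = traces["flat"]
            eff = pre_post_change(tr.p_next[:, 0], tr.conf, design)
            drops.append(eff.groupby("label").d_conf.mean())
        by_label = sum(drops) / len(drops)
        assert by_label["suspicious"] < 0
        assert by_label["non_suspicious"] < 0


class TestGroupStats:
    def test_contrast_sign_convention(self):
        import pandas as pd
        eff = pd.DataFrame({
            "label": ["suspicious"] * 2 + ["non_suspicious"] * 2,
            "d_conf": [-1.0, -0.8, -0.1, 0.1],
            "d_prob": [0.0] * 4,
        })
        stat = streak_type_contrast([eff, eff, eff])
        assert stat.mean == pytest.approx(0.9)  # non-susp minus susp

    def test_subject_without_both_types_dropped(self):
        import pandas as pd
        full = pd.DataFrame({"label": ["suspicious", "non_suspicious"],
                             "d_conf": [-1.0, 0.0], "d_prob": [0, 0]})
        partial = pd.DataFrame({"label": ["suspicious"],
                                "d_conf": [-1.0], "d_prob": [0]})
        with pytest.warns(UserWarning):
            stat = streak_type_contrast([full, full, partial])
        assert stat.df == 1

    def test_group_ttest_matches_closed_form(self):
        vals = [0.1, 0.3, 0.2, 0.4, 0.0]
        stat = group_ttest(vals)
        v = np.asarray(vals)
        assert stat.mean == pytest.approx(v.mean())
        assert stat.t == pytest.approx(
            v.mean() / (v.std(ddof=1) / np.sqrt(5)))
        assert stat.df == 4


class TestRegressions:
    def test_identity_regression(self):
        x = np.linspace(0.1, 0.9, 40)
        betas, rhos, stat = subject_regression([x, x], [x, x])
        np.testing.assert_allclose(betas, 1.0)
        np.testing.assert_allclose(rhos, 1.0)

    def test_known_slope_recovered_at_group_level(self, rng):
        true_beta = 0.66
        ys, xs = [], []
        for _ in range(23):
            x = rng.uniform(0.1, 0.9, size=100)
            y = 0.5 + true_beta * (x - 0.5) + 0.1 * rng.standard_normal(100)
            ys.append(y)
            xs.append(x)
        _, _, stat = subject_regression(ys, xs)
        assert abs(stat.mean - true_beta) < 2 * stat.sem + 1e-9

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError):
            subject_regression([np.ones(10)], [np.ones(10)])

    def test_covariates_shapes_and_surprise(self):
        p = np.array([0.9, 0.5])
        nxt = np.array([1, 2])
        cov = first_order_covariates(p, nxt)
        assert cov.shape == (2, 3)
        assert cov[0, 0] == pytest.approx(0.4)
        assert cov[0, 2] == pytest.approx(-np.log(0.9))
        assert cov[1, 2] == pytest.approx(-np.log(0.5))

    def test_residual_confidence_detects_second_order_signal(self, rng):
        # confidence built purely from first-order covariates leaves no
        # residual slope; confidence tracking the optimal conf does
        n_sub, n_q = 20, 90
        pure, informed, opts, covs = [], [], [], []
        for _ in range(n_sub):
            p = rng.uniform(0.05, 0.95, size=n_q)
            nxt = rng.integers(1, 3, size=n_q)
            cov = first_order_covariates(p, nxt)
            opt = rng.normal(3.0, 0.8, size=n_q)
            pure.append(0.3 + 0.5 * cov[:, 0] - 0.1 * cov[:, 1]
                        + 0.02 * rng.standard_normal(n_q))
            informed.append(0.3 + 0.1 * opt
                            + 0.05 * rng.standard_normal(n_q))
            opts.append(opt)
            covs.append(cov)
        null = residual_confidence_test(pure, opts, covs)
        pos = residual_confidence_test(informed, opts, covs)
        # the null slope is negligible next to the informed one
        assert abs(null.mean) < 0.01
        assert pos.t > 4
        assert pos.mean > 0.05

    def test_collinear_covariate_dropped(self, rng):
        ys = [rng.standard_normal(30) for _ in range(2)]
        opts = [rng.standard_normal(30) for _ in range(2)]
        covs = []
        for _ in range(2):
            c = rng.standard_normal(30)
            covs.append(np.column_stack([c, 2 * c + 1]))
        with pytest.warns(UserWarning):
            residual_confidence_test(ys, opts, covs)


class TestExclusion:
    def _subject_with_rho(self, design, trace, rho_target, rng):
        from hierlearn.subjects_io import NoiseModel, generate_subject
        x = trace.p_next[design.question_index, 0]
        sd = x.std() * np.sqrt(1 / rho_target**2 - 1)
        subj = generate_subject(trace, design,
                                NoiseModel(prob_sd=0.0, prob_slope=1.0),
                                rng)
        q = design.question_index
        noise = rng.standard_normal(q.size) * sd
        subj.prob_report[q] = x + noise  # unclipped: controls rho exactly
        return subj

    def test_threshold_is_strict(self, small_design_pool, rng):
        design = small_design_pool.designs[0]
        trace = small_design_pool.traces[0]["hier"]
        subjects, rhos, n_exc = exclusion_filter(
            [self._subject_with_rho(design, trace, r, rng)
             for r in (0.05, 0.95)],
            [trace, trace])
        assert n_exc == 1
        assert len(subjects) == 1
        assert rhos[0] < 0.18 <= rhos[1]

    def test_borderline_rho_included(self, small_design_pool):
        # a subject at exactly rho = 0.18 stays in (strict inequality)
        design = small_design_pool.designs[0]
        trace = small_design_pool.traces[0]["hier"]

        class Stub:
            question_trials = design.question_index
            prob_report = np.full(len(design.sequence), np.nan)

        q = design.question_index
        x = trace.p_next[q, 0]
        resid = np.linalg.qr(
            np.column_stack([np.ones_like(x), x]), mode="complete")[0][:, 2]
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        r = 0.18 + 1e-9  # epsilon above the cut, robust to rounding
        y = r * xc + np.sqrt(1 - r**2) * resid
        Stub.prob_report[q] = y
        included, rhos, n_exc = exclusion_filter([Stub], [trace])
        assert rhos[0] == pytest.approx(0.18)
        assert n_exc == 0 and len(included) == 1


class TestApparentLearningRate:
    def test_static_estimate_gives_zero(self):
        lr = apparent_learning_rate(np.full(10, 0.5),
                                    np.array([1, 0] * 5, dtype=float))
        assert np.all(lr.filled(99) == 0)

    def test_jump_to_observation_gives_one(self):
        # when the estimate moves all the way to the outcome, update
        # equals prediction error
        theta = np.array([0.2, 1.0, 0.0])
        y = np.array([0.3, 1.0, 0.0])
        lr = apparent_learning_rate(theta, y)
        np.testing.assert_allclose(lr.compressed(), [1.0, 1.0])

    def test_delta_rule_has_constant_rate(self, rng):
        alpha = 0.17
        y = (rng.random(200) < 0.6).astype(float)
        theta = np.empty(200)
        theta[0] = 0.5
        for t in range(1, 200):
            theta[t] = theta[t - 1] + alpha * (y[t] - theta[t - 1])
        lr = apparent_learning_rate(theta, y)
        np.testing.assert_allclose(lr.compressed(), alpha, atol=1e-12)

    def test_tiny_prediction_error_masked(self):
        theta = np.array([0.5, 0.6])
        y = np.array([0.0, 0.5 + 1e-9])
        lr = apparent_learning_rate(theta, y)
        assert lr.mask[0]
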