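import numpy as np
import pandas as pd
import pytest

from actisig.accel import BinScheme, WearCriteria
from actisig.pls import autoscale, fit_pls1
from actisig.signature import (
    NullModelError,
    build_signature,
    compare_patterns,
    r_significance_threshold,
    sed_sensitivity,
    selectivity_ratios,
    sr_confidence_intervals,
    target_projection,
    univariate_profile,
    weighted_loadings,
)
from actisig.simulate import SubjectActivitySpec, simulate_epochs


def _fitted(n=60, p=6, seed=0, n_components=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = X @ rng.standard_normal(p) + rng.standard_normal(n)
    Xs, ys, params = autoscale(X, y)
    model = fit_pls1(Xs, ys, n_components)
    model.scaling = params
    return model, Xs, ys


class TestTargetProjection:
    def test_single_component_model_identity(self):
        model, Xs, _ = _fitted(n_components=1)
        tp = target_projection(model, Xs)
        t1 = model.scores[:, 0]
        corr = np.corrcoef(tp.t_tp, t1)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_unit_direction_and_score_definition(self):
        model, Xs, _ = _fitted(seed=1)
        tp = target_projection(model, Xs)
        assert np.linalg.norm(tp.w_tp) == pytest.approx(1.0)
        np.testing.assert_allclose(tp.t_tp, Xs @ tp.w_tp, atol=1e-12)

    def test_rank1_reproduces_full_predictions(self):
        model, Xs, _ = _fitted(seed=2)
        tp = target_projection(model, Xs)
        np.testing.assert_allclose(
            tp.t_tp * np.linalg.norm(model.b), Xs @ model.b, atol=1e-10
        )

    def test_slope_matches_regression_oracle(self):
        model, Xs, ys = _fitted(seed=3)
        tp = target_projection(model, Xs)
        slope = float(ys @ tp.t_tp) / float(tp.t_tp @ tp.t_tp)
        oracle = np.polyfit(tp.t_tp, ys, 1)[0]
        assert slope == pytest.approx(oracle, rel=1e-10)

    def test_orthonormal_design_loading_proportional_to_weight(self):
        rng = np.random.default_rng(4)
        Q, _ = np.linalg.qr(rng.standard_normal((40, 5)))
        Xs = (Q - Q.mean(axis=0)) / Q.std(axis=0, ddof=1)
        # not exactly orthogonal after scaling; orthogonalize then scale variance only
        Q -= Q.mean(axis=0)
        Q2, _ = np.linalg.qr(Q)
        Xs = Q2 / Q2.std(axis=0, ddof=1)
        ys = Xs @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + 0.1 * rng.standard_normal(40)
        ys = (ys - ys.mean()) / ys.std(ddof=1)
        model = fit_pls1(Xs, ys, 3)
        tp = target_projection(model, Xs)
        cross = np.cross(
            tp.p_tp / np.linalg.norm(tp.p_tp), tp.w_tp / np.linalg.norm(tp.w_tp)
        ) if len(tp.p_tp) == 3 else None
        cos = float(tp.p_tp @ tp.w_tp) / (
            np.linalg.norm(tp.p_tp) * np.linalg.norm(tp.w_tp)
        )
        assert abs(cos) == pytest.approx(1.0, abs=1e-6)

    def test_variance_bookkeeping(self):
        model, Xs, _ = _fitted(seed=5)
        tp = target_projection(model, Xs)
        np.testing.assert_allclose(
            tp.v_expl + tp.v_res, Xs.var(axis=0, ddof=1), atol=1e-8
        )
        frac = tp.v_expl.sum() / (tp.v_expl + tp.v_res).sum()
        recon = np.outer(tp.t_tp, tp.p_tp)
        frac_direct = recon.var(axis=0, ddof=1).sum() / Xs.var(axis=0, ddof=1).sum()
        assert frac == pytest.approx(frac_direct, rel=1e-12)

    def test_null_model_signals(self):
        model, Xs, _ = _fitted(seed=6)
        model.b = np.zeros_like(model.b)
        with pytest.raises(NullModelError):
            target_projection(model, Xs)


class TestSelectivityRatios:
    def test_orthogonal_variable_zero_sr(self):
        rng = np.random.default_rng(7)
        t = rng.standard_normal(200)
        x_orth = rng.standard_normal(200)
        x_orth -= t * (x_orth @ t) / (t @ t)  # exactly orthogonal to scores
        X = np.column_stack([t + 0.01 * rng.standard_normal(200), x_orth])
        y = t.copy()
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls1(Xs, ys, 1)
        tp = target_projection(model, Xs)
        sr = selectivity_ratios(tp)
        assert abs(sr[1]) < 0.05
        assert abs(sr[0]) > 10

    def test_proportional_variable_infinite(self):
        rng = np.random.default_rng(8)
        t = rng.standard_normal(50)
        X = np.column_stack([t, t * 2.0])
        y = t.copy()
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls1(Xs, ys, 1)
        sr = selectivity_ratios(target_projection(model, Xs))
        assert np.isinf(sr).all()

    def test_three_variable_bookkeeping_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((80, 3))
        y = X @ np.array([1.0, -0.5, 0.2]) + 0.5 * rng.standard_normal(80)
        Xs, ys, _ = autoscale(X, y)
        model = fit_pls1(Xs, ys, 2)
        tp = target_projection(model, Xs)
        sr = selectivity_ratios(tp)
        t = tp.t_tp
        for j in range(3):
            # brute-force column regression on the TP scores
            coef = float(Xs[:, j] @ t) / float(t @ t)
            explained = coef * t
            resid = Xs[:, j] - explained
            expected = explained.var(ddof=1) / resid.var(ddof=1)
            assert abs(sr[j]) == pytest.approx(expected, rel=1e-10)
            assert np.sign(sr[j]) == np.sign(tp.p_tp[j])


class TestConfidenceIntervals:
    def test_determinism(self, small_cohort):
        X, y, _ = small_cohort
        ci1, sr1 = sr_confidence_intervals(X, y, 2, repetitions=20, seed=5)
        ci2, sr2 = sr_confidence_intervals(X, y, 2, repetitions=20, seed=5)
        np.testing.assert_array_equal(sr1, sr2)
        np.testing.assert_array_equal(ci1, ci2)

    def test_ci_brackets_order(self, small_cohort):
        X, y, _ = small_cohort
        ci, _ = sr_confidence_intervals(X, y, 2, repetitions=30, seed=6)
        assert np.all(ci[:, 0] <= ci[:, 1])

    def test_null_column_ci_straddles_zero(self):
        straddles = 0
        n_cohorts = 50
        for seed in range(n_cohorts):
            rng = np.random.default_rng(1000 + seed)
            t = rng.standard_normal(150)
            X = np.column_stack(
                [
                    t + 0.4 * rng.standard_normal((150, 4)).T[i]
                    for i in range(4)
                ]
                + [rng.standard_normal(150)]  # known-null independent column
            )
            y = t + t.std() * rng.standard_normal(150)
            ci, _ = sr_confidence_intervals(X, y, 1, repetitions=60, seed=seed)
            straddles += ci[4, 0] <= 0 <= ci[4, 1]
        assert straddles >= 0.9 * n_cohorts

    def test_predictive_bin_ci_excludes_zero_at_scale(self):
        rng = np.random.default_rng(99)
        n = 800
        t = rng.standard_normal(n)
        X = np.column_stack([t + 0.5 * rng.standard_normal(n) for _ in range(5)])
        y = t + 0.8 * rng.standard_normal(n)
        ci, _ = sr_confidence_intervals(X, y, 1, repetitions=60, seed=0)
        assert np.all(ci[:, 0] > 0)


class TestWeightedLoadings:
    def _tp_with_loadings(self, p_tp):
        from actisig.signature import TargetProjection

        p_tp = np.asarray(p_tp, dtype=float)
        return TargetProjection(
            w_tp=p_tp / np.linalg.norm(p_tp),
            t_tp=np.zeros(3),
            p_tp=p_tp,
            v_expl=np.ones_like(p_tp),
            v_res=np.ones_like(p_tp),
        )

    def test_sd_ratio(self):
        from actisig.pls import ScalingParams

        tp = self._tp_with_loadings([0.5, 0.5])
        scaling = ScalingParams(
            x_mean=np.zeros(2), x_sd=np.array([10.0, 20.0]), y_mean=0.0, y_sd=1.0
        )
        weighted, unweighted = weighted_loadings(tp, scaling)
        assert weighted[1] / weighted[0] == pytest.approx(2.0)
        np.testing.assert_allclose(unweighted, [0.5, 0.5])

    def test_equal_sds_proportional(self):
        from actisig.pls import ScalingParams

        tp = self._tp_with_loadings([0.2, -0.7])
        scaling = ScalingParams(
            x_mean=np.zeros(2), x_sd=np.array([3.0, 3.0]), y_mean=0.0, y_sd=1.0
        )
        weighted, unweighted = weighted_loadings(tp, scaling)
        np.testing.assert_allclose(weighted, 3.0 * unweighted)


class TestComparePatterns:
    def test_identical(self):
        v = np.array([0.1, -0.2, 0.5, 0.3])
        assert compare_patterns(v, v) == pytest.approx(1.0)

    def test_negated(self):
        v = np.array([0.1, -0.2, 0.5, 0.3])
        assert compare_patterns(v, -v) == pytest.approx(-1.0)

    def test_four_point_manual_oracle(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 1.0, 4.0, 5.0])
        cov = ((a - a.mean()) * (b - b.mean())).sum() / 3
        r_manual = cov / (a.std(ddof=1) * b.std(ddof=1))
        assert compare_patterns(a, b) == pytest.approx(r_manual, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            compare_patterns(np.ones(4), np.ones(4))
        with pytest.raises(ValueError):
            compare_patterns(np.arange(2), np.arange(2))


class TestUnivariateProfile:
    def test_outcome_equal_to_bin(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((100, 4))
        outcomes = pd.DataFrame({"target": X[:, 2]})
        table = univariate_profile(X, outcomes, ["a", "b", "c", "d"])
        assert table.loc["c", ("target", "r")] == pytest.approx(1.0)
        assert table.loc["c", ("target", "significant")]

    def test_independent_bin_small_r(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((2000, 2))
        outcomes = pd.DataFrame({"y": rng.standard_normal(2000)})
        table = univariate_profile(X, outcomes, ["a", "b"])
        assert np.all(np.abs(table.xs("r", level="stat", axis=1).to_numpy()) < 0.08)

    def test_threshold_at_study_scale(self):
        thr = r_significance_threshold(841)
        assert thr == pytest.approx(0.0676, abs=5e-4)
        assert round(thr, 2) == 0.07
        # consistency with the t-transform at the boundary
        from scipy import stats

        t = thr * np.sqrt((841 - 2) / (1 - thr**2))
        assert 2 * stats.t.sf(t, 839) == pytest.approx(0.05, abs=1e-10)


@pytest.fixture(scope="module")
def epoch_cohort():
    streams = [
        simulate_epochs(SubjectActivitySpec(subject_id=f"S{i:02d}"), seed=i)
        for i in range(14)
    ]
    rng = np.random.default_rng(0)
    y = pd.Series(rng.standard_normal(14), index=[f"S{i:02d}" for i in range(14)])
    return streams, y


class TestSedSensitivity:
    def test_edge_100_identical_to_base(self, epoch_cohort):
        streams, y = epoch_cohort
        out = sed_sensitivity(
            streams, y, alt_first_edges=(100,), n_components=1, repetitions=5, seed=1
        )
        base_scheme = BinScheme.default()
        assert out.loc[0, "n_bins"] == base_scheme.n_bins
        out2 = sed_sensitivity(
            streams, y, alt_first_edges=(100,), n_components=1, repetitions=5, seed=2
        )
        assert out.loc[0, "sed_abs_sr"] == pytest.approx(out2.loc[0, "sed_abs_sr"])

    def test_partition_conserves_minutes(self, epoch_cohort):
        from actisig.accel import process_stream

        streams, _ = epoch_cohort
        stream = streams[0]
        for edge in (50, 150, 250):
            scheme = BinScheme.default().with_first_edge(edge)
            spec, _, _ = process_stream(stream, WearCriteria(), scheme)
            assert spec.minutes_per_day.sum() == pytest.approx(
                spec.mean_wear_minutes, abs=1e-9
            )

    def test_variants_stable_without_sed_signal(self, epoch_cohort):
        streams, y = epoch_cohort
        out = sed_sensitivity(
            streams, y, alt_first_edges=(50, 100, 150, 250),
            n_components=1, repetitions=5, seed=3,
        )
        assert len(out) == 4
        # rebinning the SED boundary barely moves the SED-bin SR
        assert out["sed_abs_sr"].max() - out["sed_abs_sr"].min() < 0.25

    def test_too_few_subjects(self, epoch_cohort):
        streams, y = epoch_cohort
        with pytest.raises(ValueError):
            sed_sensitivity(streams[:3], y, alt_first_edges=(100,), n_components=1)


def test_build_signature_profile(small_cohort):
    X, y, labels = small_cohort
    profile = build_signature(X, y, labels, 2, repetitions=25, seed=3)
    frame = profile.to_frame()
    assert list(frame["bin"]) == labels
    assert np.all(frame["ci_low"] <= frame["sr"] + 1e-9)
    assert np.all(frame["sr"] <= frame["ci_high"] + 1e-9)
    np.testing.assert_array_equal(np.sign(profile.sr), np.sign(profile.p_tp))
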