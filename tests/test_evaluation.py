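"""Evaluation metrics against per-sample brute-force oracles: RMSE,
threshold activation accuracy, cycle normalization/averaging, and the
Mann-Whitney U test by exhaustive enumeration."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from distalemg.evaluation import (
    activation_analysis,
    average_cycles,
    compare_groups,
    dependability_analysis,
    extract_cycles,
    normalize_cycle,
    rmse,
)
from distalemg.signals import ParameterError


def activation_oracle(y, yhat, frac):
    """Independent per-sample counting implementation of the activation
    accuracy (thresholds at frac of range above min; sections scanned
    sample by sample)."""

    def thr(trace):
        return min(trace) + frac * (max(trace) - min(trace))

    def sections(mask):
        secs, start = [], None
        for i, on in enumerate(list(mask) + [False]):
            if on and start is None:
                start = i
            elif not on and start is not None:
                secs.append((start, i))
                start = None
        return secs

    m_on = [v > thr(y) for v in y] if max(y) > min(y) else [False] * len(y)
    e_on = [v > thr(yhat) for v in yhat] if max(yhat) > min(yhat) else [False] * len(yhat)
    both = [a and b for a, b in zip(m_on, e_on)]
    Tm, Te, Tc = sum(m_on), sum(e_on), sum(both)
    Vm = sum(max(y[a:b]) for a, b in sections(m_on))
    Ve = sum(max(yhat[a:b]) for a, b in sections(e_on))
    Vc = sum(min(max(y[a:b]), max(yhat[a:b])) for a, b in sections(both))
    Vc = min(Vc, Vm, Ve)
    t_acc = Tc / (Tm + Te - Tc) if Tm + Te - Tc > 0 else 0.0
    s_acc = Vc / (Vm + Ve - Vc) if Vm + Ve - Vc > 0 else 0.0
    return t_acc, s_acc


class TestRmse:
    def test_identical_series_zero(self, rng):
        x = rng.normal(size=30)
        assert rmse(x, x) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(25 / 2))

    def test_matches_direct_loop_oracle(self, rng):
        y = rng.normal(size=100)
        yhat = rng.normal(size=100)
        expected = (sum((a - b) ** 2 for a, b in zip(y, yhat)) / 100) ** 0.5
        assert rmse(y, yhat) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        y, yhat = rng.normal(size=20), rng.normal(size=20)
        assert rmse(y, yhat) == rmse(yhat, y)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            rmse([1.0], [1.0, 2.0])


class TestActivationAnalysis:
    def test_identical_traces_give_unit_accuracies(self, rng):
        y = np.abs(rng.normal(size=200)) + np.sin(np.linspace(0, 6 * np.pi, 200)) ** 2
        res = activation_analysis(y, y.copy())
        assert res.temporal_accuracy == 1.0
        assert res.spatial_accuracy == 1.0
        assert res.Tc == res.Tm == res.Te

    def test_disjoint_bumps_give_zero(self):
        y = np.zeros(100)
        y[10:20] = 1.0
        yhat = np.zeros(100)
        yhat[60:70] = 1.0
        res = activation_analysis(y, yhat)
        assert res.temporal_accuracy == 0.0
        assert res.spatial_accuracy == 0.0
        assert res.Tc == 0 and res.Vc == 0.0

    def test_partial_overlap_matches_counting_oracle(self):
        y = np.array([0.0] * 10 + [5.0] * 20 + [0.0] * 10 + [3.0] * 10 + [0.0] * 10)
        yhat = np.array([0.0] * 20 + [4.0] * 25 + [0.0] * 15)
        res = activation_analysis(y, yhat, 0.2)
        t_exp, s_exp = activation_oracle(list(y), list(yhat), 0.2)
        assert res.temporal_accuracy == pytest.approx(t_exp, abs=1e-12)
        assert res.spatial_accuracy == pytest.approx(s_exp, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 500), frac=st.floats(0.05, 0.9))
    def test_accuracies_bounded_and_match_oracle(self, seed, frac):
        g = np.random.default_rng(seed)
        y = np.round(g.uniform(0, 3, size=40), 1)
        yhat = np.round(g.uniform(0, 3, size=40), 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = activation_analysis(y, yhat, frac)
            t_exp, s_exp = activation_oracle(list(y), list(yhat), frac)
        assert 0.0 <= res.temporal_accuracy <= 1.0
        assert 0.0 <= res.spatial_accuracy <= 1.0
        assert res.temporal_accuracy == pytest.approx(t_exp, abs=1e-9)
        assert res.spatial_accuracy == pytest.approx(s_exp, abs=1e-9)
        assert res.Tc <= min(res.Tm, res.Te)
        assert res.Vc <= min(res.Vm, res.Ve) + 1e-12

    def test_supra_threshold_time_non_increasing_in_threshold(self, rng):
        y = np.abs(rng.normal(size=300))
        yhat = np.abs(rng.normal(size=300))
        fracs = np.linspace(0.05, 0.95, 10)
        tms = [activation_analysis(y, yhat, f).Tm for f in fracs]
        tes = [activation_analysis(y, yhat, f).Te for f in fracs]
        assert all(b <= a for a, b in zip(tms, tms[1:]))
        assert all(b <= a for a, b in zip(tes, tes[1:]))

    def test_flat_trace_warns_and_gives_zero(self):
        y = np.ones(50)
        yhat = np.linspace(0, 1, 50)
        with pytest.warns(UserWarning, match="flat"):
            res = activation_analysis(y, yhat)
        assert res.temporal_accuracy == 0.0
        assert res.spatial_accuracy == 0.0

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            activation_analysis(np.ones(5), np.ones(5), 1.5)


class TestCycles:
    def test_five_period_envelope_yields_four_or_five_cycles(self):
        t = np.linspace(0, 5, 5000, endpoint=False)
        env = 0.5 * (1 - np.cos(2 * np.pi * t)) + 0.05
        cycles = extract_cycles(env, 0.2)
        assert len(cycles) in (4, 5)

    def test_constant_envelope_gives_empty_list(self):
        with pytest.warns(UserWarning):
            assert extract_cycles(np.full(100, 2.0)) == []

    def test_monotone_ramp_gives_no_complete_cycle(self):
        with pytest.warns(UserWarning):
            assert extract_cycles(np.linspace(0, 1, 100)) == []

    def test_normalized_cycle_spans_zero_to_hundred(self, rng):
        cycle = rng.uniform(1, 5, size=137)
        out = normalize_cycle(cycle)
        assert out.min() == pytest.approx(0.0, abs=1e-9)
        assert out.max() == pytest.approx(100.0, abs=1e-9)
        assert out.size == 1001

    def test_idempotent_on_normalized_ramp(self):
        ramp = np.linspace(0.0, 100.0, 1001)
        np.testing.assert_allclose(normalize_cycle(ramp), ramp, atol=1e-9)

    def test_triangle_matches_hand_interpolation(self):
        # 5-point triangle 0,50,100,50,0 on times 0,25,50,75,100
        tri = np.array([0.0, 50.0, 100.0, 50.0, 0.0])
        out = normalize_cycle(tri, grid_points=101)
        for grid_t, expected in [(10.0, 20.0), (50.0, 100.0), (80.0, 40.0)]:
            assert out[int(grid_t)] == pytest.approx(expected, abs=1e-9)

    def test_constant_cycle_rejected(self):
        with pytest.raises(ParameterError):
            normalize_cycle(np.ones(10))

    def test_single_cycle_average_is_itself(self, rng):
        c = normalize_cycle(rng.uniform(0, 1, 50))
        gcs = average_cycles([c])
        np.testing.assert_array_equal(gcs.average, c)
        np.testing.assert_array_equal(gcs.sd, 0.0)

    def test_mirror_cycles_average_to_fifty(self):
        c = np.linspace(0.0, 100.0, 101)
        gcs = average_cycles([c, 100.0 - c])
        np.testing.assert_allclose(gcs.average, 50.0, atol=1e-9)

    def test_average_matches_columnwise_oracle(self, rng):
        cycles = rng.uniform(0, 100, size=(5, 21))
        gcs = average_cycles(cycles)
        for j in range(21):
            assert gcs.average[j] == pytest.approx(sum(cycles[:, j]) / 5, abs=1e-12)


class TestMannWhitney:
    def test_identical_samples_maximal_p(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_complete_separation_gives_zero_u(self):
        stat, p = compare_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert stat == 0.0

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            stat, p = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        a = list(rng.normal(size=4))
        b = list(rng.normal(size=5))
        stat, p = compare_groups(a, b)

        def ustat(x, z):
            return sum((xi > zi) + 0.5 * (xi == zi) for xi in x for zi in z)

        pooled = a + b
        us = []
        for comb in itertools.combinations(range(9), 4):
            ga = [pooled[i] for i in comb]
            gb = [pooled[i] for i in range(9) if i not in comb]
            us.append(ustat(ga, gb))
        us = np.array(us)
        u_low, u_high = min(stat, 20 - stat), max(stat, 20 - stat)
        p_exp = min(1.0, (np.sum(us <= u_low) + np.sum(us >= u_high)) / us.size)
        assert stat == ustat(a, b)  # exact
        assert p == pytest.approx(p_exp, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            compare_groups([], [1.0])


class TestDependability:
    def test_identical_halves_give_identical_rmse(self, rng):
        base = rng.normal(size=(2, 25))
        feats = {("A", 0): np.hstack([base, base])}
        ybase = np.abs(rng.normal(size=(3, 25)))
        targs = {("A", 0): np.hstack([ybase, ybase])}

        def mean_model(X_tr, L_tr, X_te):
            return np.repeat(L_tr.mean(axis=1, keepdims=True), X_te.shape[1], axis=1)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tied comparison expected
            report = dependability_analysis(feats, targs, mean_model)
        firsts = report.table[report.table.model_half == "first"].rmse.to_numpy()
        seconds = report.table[report.table.model_half == "second"].rmse.to_numpy()
        np.testing.assert_array_equal(firsts, seconds)

    def test_one_pair_per_subject_task_muscle(self, rng):
        feats = {("A", "walk"): rng.normal(size=(2, 20)), ("B", "walk"): rng.normal(size=(2, 20))}
        targs = {("A", "walk"): rng.normal(size=(6, 20)), ("B", "walk"): rng.normal(size=(6, 20))}

        def zero_model(X_tr, L_tr, X_te):
            return np.zeros((6, X_te.shape[1]))

        report = dependability_analysis(feats, targs, zero_model)
        counts = report.table.groupby(["subject", "task", "muscle"]).size()
        assert (counts == 2).all()
        assert len(report.table) == 2 * 2 * 6
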