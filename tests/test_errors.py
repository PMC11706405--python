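import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurofit.errors import (
    DegenerateTargetError,
    ErrorComponentSpec,
    ErrorVector,
    FeatureTarget,
    NotApplicableError,
    ahp_depth_error,
    ap_overshoot_error,
    ap_width_error,
    derivative_difference,
    evaluate_error_vector,
    feature_stat_error,
    isi_difference,
    latency_error,
    mse,
    mse_excl_spikes,
    spike_count_during_stimulus,
    spike_count_error,
)
from neurofit.spikes import APShape, SpikeAnalysis, analysis_from_events
from neurofit.traces import EventTrain, StepStimulus, Trace

from conftest import spike_train_trace


def vtrace(values, dt=1.0, stimulus=None):
    return Trace(values=np.asarray(values, dtype=float), dt=dt, unit="mV", stimulus=stimulus)


def shape(amplitude=100.0, base_width=1.0, ahp_depth=5.0, peak_time=10.0):
    return APShape(
        peak_time=peak_time,
        peak_v=amplitude - 55.0,
        threshold_v=-55.0,
        threshold_time=peak_time - 0.5,
        base_width=base_width,
        ahp_depth=ahp_depth,
    )


def analysis(*spikes):
    return SpikeAnalysis(spikes=tuple(spikes), detect_threshold=0.0)


class TestMSE:
    def test_identical_traces_zero(self):
        a = vtrace([0.0, 1.0, 2.0])
        assert mse(a, a) == 0.0

    def test_hand_arithmetic(self):
        assert mse(vtrace([0.0, 1.0]), vtrace([0.0, 2.0])) == pytest.approx(0.125)

    def test_constant_offset_algebra(self):
        # offsetting the model by c on a non-constant target adds exactly
        # c^2 to the numerator mean
        t = vtrace([0.0, 2.0, 4.0])
        m = vtrace([0.0, 2.0, 4.0])
        c = 3.0
        off = vtrace(m.values + c)
        assert mse(off, t) == pytest.approx(c**2 / np.ptp(t.values) ** 2)

    def test_constant_target_rejected(self):
        with pytest.raises(DegenerateTargetError):
            mse(vtrace([0.0, 1.0]), vtrace([5.0, 5.0]))


class TestMSEExclSpikes:
    def test_reduces_to_mse_on_spike_free_traces(self):
        m = vtrace(np.linspace(-65, -60, 50))
        t = vtrace(np.linspace(-64, -61, 50))
        assert mse_excl_spikes(m, t) == pytest.approx(mse(m, t))

    def test_identical_spiking_traces_zero(self):
        tr = spike_train_trace([100.0, 200.0], total_duration=400.0)
        assert mse_excl_spikes(tr, tr) == 0.0

    def test_perturbation_inside_window_is_invisible(self):
        t = spike_train_trace([100.0], total_duration=300.0)
        v = t.values.copy()
        sel = np.abs(t.times - 100.0) <= 4.0  # inside the +-5 ms window
        v[sel] += 3.0
        m = Trace(values=v, dt=t.dt, unit="mV")
        assert mse_excl_spikes(m, t) == 0.0
        assert mse(m, t) > 0.0


class TestDerivativeDifference:
    def test_identical_zero(self):
        a = vtrace([0.0, 2.0, 4.0, 5.0])
        assert derivative_difference(a, a) == 0.0

    def test_offset_invisible(self):
        t = vtrace([0.0, 2.0, 4.0, 5.0])
        m = vtrace(t.values + 7.0)
        assert derivative_difference(m, t) == 0.0

    def test_hand_arithmetic(self):
        # target derivs [2,2,1] (range 1), model derivs [1,1,1]:
        # mean((1,1,0)^2)/1 = 2/3
        t = vtrace([0.0, 2.0, 4.0, 5.0])
        m = vtrace([0.0, 1.0, 2.0, 3.0])
        assert derivative_difference(m, t) == pytest.approx(2.0 / 3.0)


class TestSpikeCounts:
    def test_three_vs_five(self):
        m = spike_train_trace([100, 200, 300])
        t = spike_train_trace([100, 200, 300, 400, 500])
        assert spike_count_error(m, t) == pytest.approx(0.25)

    def test_equal_counts_zero(self):
        m = spike_train_trace([100, 200])
        t = spike_train_trace([150, 250])
        assert spike_count_error(m, t) == 0.0

    def test_both_silent_zero(self, flat_trace):
        assert spike_count_error(flat_trace, flat_trace) == 0.0

    def test_during_stimulus_restriction(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        m = spike_train_trace([100.0], stimulus=stim)  # only before onset
        t = spike_train_trace([250, 350, 450, 550], stimulus=stim)
        assert spike_count_during_stimulus(m, t, stimulus=stim) == pytest.approx(1.0)

    def test_during_stimulus_reduces_to_plain_count(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        m = spike_train_trace([250, 350], stimulus=stim)
        t = spike_train_trace([260, 360, 460], stimulus=stim)
        assert spike_count_during_stimulus(m, t, stimulus=stim) == pytest.approx(
            spike_count_error(m, t)
        )

    def test_missing_stimulus_is_config_error(self, flat_trace):
        with pytest.raises(ValueError):
            spike_count_during_stimulus(flat_trace, flat_trace)


class TestISIDifference:
    def test_identical_trains_zero(self):
        tr = spike_train_trace([100, 150, 220])
        assert isi_difference(tr, tr) == 0.0

    def test_paired_arithmetic(self):
        # model ISIs [10,20], target [12,20], duration 1000 -> 2/1000
        m = spike_train_trace([100, 110, 130])
        t = spike_train_trace([100, 112, 132])
        assert isi_difference(m, t) == pytest.approx(0.002)

    def test_unpaired_isi_counts_whole(self):
        # model ISIs [10], target [10, 30] -> 30/1000
        m = spike_train_trace([100, 110])
        t = spike_train_trace([100, 110, 140])
        assert isi_difference(m, t) == pytest.approx(0.03)


class TestLatencyError:
    def test_identical_zero(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        tr = spike_train_trace([210.0], stimulus=stim)
        assert latency_error(tr, tr, stimulus=stim) == 0.0

    def test_hand_arithmetic(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        m = spike_train_trace([210.0], stimulus=stim)
        t = spike_train_trace([230.0], stimulus=stim)
        assert latency_error(m, t, stimulus=stim) == pytest.approx(4e-4, rel=0.05)

    def test_silent_model_sentinel(self, flat_trace):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        t = spike_train_trace([210.0], stimulus=stim)
        # sentinel latency 1000 vs 10: (990/1000)^2
        assert latency_error(flat_trace, t, stimulus=stim) == pytest.approx(
            0.9801, rel=0.01
        )


class TestAPShapeErrors:
    def test_overshoot_arithmetic(self):
        ma, ta = analysis(shape(amplitude=80.0)), analysis(shape(amplitude=100.0))
        tr = spike_train_trace([10.0], total_duration=50.0)
        val = ap_overshoot_error(tr, tr, model_analysis=ma, target_analysis=ta)
        assert val == pytest.approx(400.0 / 10000.0)

    def test_width_arithmetic(self):
        ma, ta = analysis(shape(base_width=1.0)), analysis(shape(base_width=2.0))
        tr = spike_train_trace([10.0], total_duration=50.0)
        val = ap_width_error(tr, tr, model_analysis=ma, target_analysis=ta)
        assert val == pytest.approx(0.25)

    def test_ahp_arithmetic(self):
        # depths 5 vs 8 mV, subthreshold range 30 mV -> 9/900
        ma, ta = analysis(shape(ahp_depth=5.0)), analysis(shape(ahp_depth=8.0))
        n = 101
        t = Trace(values=np.linspace(-70.0, -40.0, n), dt=1.0, unit="mV")
        val = ahp_depth_error(t, t, model_analysis=ma, target_analysis=ta)
        assert val == pytest.approx(9.0 / 900.0)

    @pytest.mark.parametrize("fn", [ap_overshoot_error, ap_width_error, ahp_depth_error])
    def test_silent_model_penalty_is_one(self, fn, flat_trace):
        t = spike_train_trace([100.0])
        assert fn(flat_trace, t) == 1.0

    @pytest.mark.parametrize("fn", [ap_overshoot_error, ap_width_error, ahp_depth_error])
    def test_spike_free_target_not_applicable(self, fn, flat_trace):
        m = spike_train_trace([100.0])
        with pytest.raises(NotApplicableError):
            fn(m, flat_trace)

    def test_identical_traces_zero(self):
        tr = spike_train_trace([100.0, 200.0])
        assert ap_overshoot_error(tr, tr) == 0.0
        assert ap_width_error(tr, tr) == 0.0
        assert ahp_depth_error(tr, tr) == 0.0


class TestFeatureStat:
    def test_at_mean_zero(self):
        ft = FeatureTarget("spike_count", exp_mean=10.0, exp_std=4.0)
        assert feature_stat_error(10.0, ft) == 0.0

    def test_z_score(self):
        ft = FeatureTarget("spike_count", exp_mean=10.0, exp_std=4.0)
        assert feature_stat_error(12.0, ft) == pytest.approx(0.5)

    def test_undefined_feature_penalty(self):
        ft = FeatureTarget("ap_width", exp_mean=1.0, exp_std=0.2)
        assert feature_stat_error(None, ft) == 250.0
        assert feature_stat_error(np.nan, ft) == 250.0

    def test_std_must_be_positive(self):
        with pytest.raises(ValueError):
            FeatureTarget("x", exp_mean=1.0, exp_std=0.0)


class TestEvaluateErrorVector:
    def test_identical_traces_total_zero(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        tr = spike_train_trace([250.0, 350.0], stimulus=stim)
        spec = [
            ErrorComponentSpec("mse", 1.0),
            ErrorComponentSpec("spike_count", 1.0),
            ErrorComponentSpec("latency", 1.0),
        ]
        ev = evaluate_error_vector(tr, tr, spec, stimulus=stim)
        assert ev.total == 0.0
        assert all(raw == 0.0 for _, raw, _, _ in ev.components)

    def test_uniform_average(self):
        # two components with raw 0.2 and 0.4, equal weights -> total 0.3
        m = vtrace([0.0, 1.0])
        t = vtrace([0.0, 2.0])  # mse raw = 0.125
        spec = [ErrorComponentSpec("mse", 1.0), ErrorComponentSpec("mse", 1.0)]
        ev = evaluate_error_vector(m, t, spec)
        assert ev.total == pytest.approx(0.125)
        raws = [0.2, 0.4]
        total = sum(r * 0.5 for r in raws)
        assert total == pytest.approx(0.3)

    def test_six_component_weight_vector_used_unchanged(self):
        # the benchmark weighting (0.2, 0.4, 0.1, 0.1, 0.1, 0.1) sums to 1
        # and must pass through normalization untouched
        stim = StepStimulus(0.2, 200.0, 600.0, 1000.0)
        tr = spike_train_trace([250.0, 400.0], stimulus=stim)
        weights = [0.2, 0.4, 0.1, 0.1, 0.1, 0.1]
        names = [
            "mse_excl_spikes",
            "spike_count",
            "latency",
            "ap_overshoot",
            "ap_width",
            "ahp_depth",
        ]
        spec = [ErrorComponentSpec(n, w) for n, w in zip(names, weights)]
        ev = evaluate_error_vector(tr, tr, spec, stimulus=stim)
        assert [w for _, _, w, _ in ev.components] == pytest.approx(weights)

    @given(st.floats(0.1, 100.0))
    def test_weight_rescaling_invariance(self, factor):
        m = vtrace([0.0, 1.0, 2.0, 3.0])
        t = vtrace([0.0, 2.0, 4.0, 5.0])
        spec1 = [
            ErrorComponentSpec("mse", 1.0),
            ErrorComponentSpec("derivative_difference", 2.0),
        ]
        spec2 = [
            ErrorComponentSpec("mse", factor),
            ErrorComponentSpec("derivative_difference", 2.0 * factor),
        ]
        ev1 = evaluate_error_vector(m, t, spec1)
        ev2 = evaluate_error_vector(m, t, spec2)
        assert ev1.total == pytest.approx(ev2.total, rel=1e-9)

    def test_time_shift_invariance(self):
        stim = StepStimulus(0.3, 200.0, 500.0, 1000.0)
        tr = spike_train_trace([250.0, 300.0], stimulus=stim)
        m = spike_train_trace([255.0, 310.0], stimulus=stim)
        spec = [ErrorComponentSpec("mse", 1.0), ErrorComponentSpec("isi_difference", 1.0)]
        base = evaluate_error_vector(m, tr, spec, stimulus=stim).total
        shift = 500.0
        m2 = Trace(values=m.values, dt=m.dt, t0=shift, unit="mV")
        t2 = Trace(values=tr.values, dt=tr.dt, t0=shift, unit="mV")
        assert evaluate_error_vector(m2, t2, spec, stimulus=stim).total == pytest.approx(
            base, rel=1e-9
        )

    def test_failing_component_is_named(self, flat_trace):
        spec = [ErrorComponentSpec("mse", 1.0)]
        with pytest.raises(DegenerateTargetError, match="mse"):
            evaluate_error_vector(flat_trace, flat_trace, spec)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError):
            ErrorComponentSpec("not_a_component", 1.0)

    def test_error_vector_total_is_weighted_sum(self):
        m = vtrace([0.0, 1.0, 2.0, 3.0])
        t = vtrace([0.0, 2.0, 4.0, 5.0])
        spec = [
            ErrorComponentSpec("mse", 0.25),
            ErrorComponentSpec("derivative_difference", 0.75),
        ]
        ev = evaluate_error_vector(m, t, spec)
        assert ev.total == pytest.approx(sum(wv for _, _, _, wv in ev.components))
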