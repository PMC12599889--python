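import numpy as np
import pytest

from gaitpert.synthgait import ImuTrace, PerturbationMarker
from gaitpert.windowing import (
    LABEL_GAIT,
    LABEL_PERTURBATION,
    Window,
    WindowingConfig,
    WindowScaler,
    acceleration_norm,
    assemble_condition,
    crop_to_common_grid,
    extract_gait_windows,
    extract_perturbation_windows,
    resample,
    standardize,
    windows_to_arrays,
)


def make_trace(t, channels, pid="P000", pos="L", trial="gait", rate=100.0):
    channels = np.asarray(channels)
    return ImuTrace(pid, pos, trial, t, channels[:3], channels[3:], rate)


def flat_trace(duration=60.0, rate=100.0, value=0.0, trial="gait"):
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    ch = np.full((6, n), value, dtype=float)
    return make_trace(t, ch, trial=trial, rate=rate)


class TestResample:
    def test_identity_on_shared_grid(self):
        rng = np.random.default_rng(0)
        tr = make_trace(np.arange(500) / 100.0, rng.standard_normal((6, 500)))
        out = resample(tr, 100.0)
        np.testing.assert_allclose(out.accel, tr.accel, atol=1e-12)
        np.testing.assert_allclose(out.timestamps, tr.timestamps, atol=1e-12)

    def test_linear_ramp_exact(self):
        t = np.sort(np.random.default_rng(1).uniform(0, 10, 400))
        t[0], t[-1] = 0.0, 10.0
        ch = np.vstack([3.0 * t + i for i in range(6)])
        out = resample(make_trace(t, ch), 50.0)
        for i in range(3):
            np.testing.assert_allclose(out.accel[i], 3.0 * out.timestamps + i, atol=1e-9)

    def test_sinusoid_across_rates(self):
        # analytic reference: 5 Hz sine sampled at 104 Hz -> 100 Hz grid
        t = np.arange(0, 10, 1 / 104.0)
        ch = np.vstack([np.sin(2 * np.pi * 5 * t)] * 6)
        out = resample(make_trace(t, ch, rate=104.0), 100.0)
        ref = np.sin(2 * np.pi * 5 * out.timestamps)
        r = np.corrcoef(out.accel[0], ref)[0, 1]
        assert r >= 0.999

    def test_no_extrapolation(self):
        tr = flat_trace(1.005, 100.0)
        out = resample(tr, 100.0)
        assert out.timestamps[-1] <= tr.timestamps[-1] + 1e-12

    def test_too_short_rejected(self):
        tr = make_trace(np.array([0.0]), np.zeros((6, 1)))
        with pytest.raises(ValueError):
            resample(tr, 100.0)


class TestAccelerationNorm:
    def test_zero(self):
        assert acceleration_norm(flat_trace(1.0))[0] == 0.0

    def test_pythagorean(self):
        ch = np.zeros((6, 3))
        ch[0, 0], ch[1, 0] = 3.0, 4.0
        tr = make_trace(np.arange(3) / 100.0, ch)
        assert acceleration_norm(tr)[0] == pytest.approx(5.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        ch = rng.standard_normal((6, 1000))
        tr = make_trace(np.arange(1000) / 100.0, ch)
        expected = np.array(
            [np.sqrt(sum(ch[i, j] ** 2 for i in range(3))) for j in range(1000)]
        )
        np.testing.assert_allclose(acceleration_norm(tr), expected, atol=1e-12)


class TestGaitWindows:
    def test_count_60s(self, wcfg):
        ws = extract_gait_windows(flat_trace(60.0), wcfg)
        assert len(ws) == 59  # floor((60 - 2)/1) + 1

    def test_exact_boundary(self, wcfg):
        assert len(extract_gait_windows(flat_trace(2.0), wcfg)) == 1

    def test_too_short(self, wcfg, caplog):
        assert extract_gait_windows(flat_trace(1.9), wcfg) == []

    def test_shapes_and_labels(self, wcfg):
        for w in extract_gait_windows(flat_trace(10.0), wcfg):
            assert w.data.shape == (6, wcfg.n_samples)
            assert w.label == LABEL_GAIT


def spiked_trace(spike_time, duration=60.0, rate=100.0, trial="pert1"):
    tr = flat_trace(duration, rate, trial=trial)
    idx = int(round(spike_time * rate))
    tr.accel[0, idx] = 50.0
    return tr


class TestPerturbationWindows:
    def test_one_window_per_marker(self, wcfg):
        tr = flat_trace(120.0, trial="pert1")
        for k in range(9):
            tr.accel[0, 1000 + 1000 * k] = 10.0 + k
        markers = [
            PerturbationMarker("pert1", k + 1, 9.0 + 10.0 * k, 11.0 + 10.0 * k)
            for k in range(9)
        ]
        ws = extract_perturbation_windows(tr, markers, wcfg)
        assert len(ws) == 9
        assert all(w.label == LABEL_PERTURBATION for w in ws)

    def test_center_on_known_spike(self, wcfg):
        tr = spiked_trace(25.0)
        mk = [PerturbationMarker("pert1", 1, 24.0, 26.0)]
        (w,) = extract_perturbation_windows(tr, mk, wcfg)
        assert abs(w.center_time - 25.0) <= 1.0 / wcfg.common_rate + 1e-9
        assert w.data.shape == (6, 200)

    def test_edge_marker_shifted_inward(self, wcfg):
        tr = spiked_trace(59.5)
        mk = [PerturbationMarker("pert1", 1, 59.0, 59.9)]
        (w,) = extract_perturbation_windows(tr, mk, wcfg)
        assert w.data.shape == (6, 200)
        # window must end at the trace boundary, not overrun it
        assert w.start_time == pytest.approx(tr.timestamps[-1] - 1.99, abs=1e-6)

    def test_marker_outside_trace_rejected(self, wcfg):
        tr = flat_trace(30.0, trial="pert1")
        mk = [PerturbationMarker("pert1", 3, 40.0, 41.0)]
        with pytest.raises(ValueError, match="archetype 3"):
            extract_perturbation_windows(tr, mk, wcfg)

    def test_tie_breaks_earliest(self, wcfg):
        tr = flat_trace(60.0, trial="pert1")
        tr.accel[0, 2500] = 7.0
        tr.accel[0, 2550] = 7.0  # equal maximum later
        mk = [PerturbationMarker("pert1", 1, 24.0, 26.0)]
        (w,) = extract_perturbation_windows(tr, mk, wcfg)
        assert w.center_time == pytest.approx(25.0)

    def test_anchor_trace(self, wcfg):
        # anchoring on another sensor's norm dictates the cut location
        tr = flat_trace(60.0, trial="pert1")
        anchor = spiked_trace(25.0)
        mk = [PerturbationMarker("pert1", 1, 24.0, 26.0)]
        (w,) = extract_perturbation_windows(tr, mk, wcfg, anchor_trace=anchor)
        assert w.center_time == pytest.approx(25.0, abs=1.0 / wcfg.common_rate)


class TestAssemble:
    def _windows(self, pos, value, wcfg, n=3):
        tr = flat_trace(10.0, value=value)
        tr.position_id = pos
        return extract_gait_windows(tr, wcfg)[:n]

    def test_channel_arithmetic(self, wcfg):
        by_pos = {
            "LHA": self._windows("LHA", 1.0, wcfg),
            "PP": self._windows("PP", 2.0, wcfg),
        }
        combined = assemble_condition(by_pos, ["LHA", "PP"], "accel_gyro")
        assert combined[0].data.shape[0] == 12
        single = assemble_condition({"LHA": by_pos["LHA"]}, ["LHA"], "accel_only")
        assert single[0].data.shape[0] == 3

    def test_anchor_channels_first(self, wcfg):
        by_pos = {
            "LHA": self._windows("LHA", 1.0, wcfg),
            "PP": self._windows("PP", 2.0, wcfg),
        }
        combined = assemble_condition(by_pos, ["LHA", "PP"], "accel_gyro")
        np.testing.assert_array_equal(
            combined[0].data[:6], by_pos["LHA"][0].data
        )
        np.testing.assert_array_equal(
            combined[0].data[6:], by_pos["PP"][0].data
        )

    def test_key_mismatch_rejected(self, wcfg):
        by_pos = {
            "LHA": self._windows("LHA", 1.0, wcfg, n=3),
            "PP": self._windows("PP", 2.0, wcfg, n=2),
        }
        with pytest.raises(ValueError, match="keys"):
            assemble_condition(by_pos, ["LHA", "PP"])


class TestCropToCommonGrid:
    def test_truncates_to_min(self):
        a = flat_trace(10.0)
        b = flat_trace(10.05)
        out = crop_to_common_grid([a, b])
        assert out[0].n_samples == out[1].n_samples == a.n_samples


class TestStandardize:
    def _random_windows(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            Window(rng.normal(3.0, 2.0, (6, 50)), LABEL_GAIT, "P000", ("L",), "gait", 0.0)
            for _ in range(n)
        ]

    def test_train_statistics(self):
        train = self._random_windows(40)
        out, _, _, scaler = standardize(train)
        stack = np.stack([w.data for w in out])
        np.testing.assert_allclose(stack.mean(axis=(0, 2)), 0.0, atol=1e-9)
        np.testing.assert_allclose(stack.std(axis=(0, 2)), 1.0, atol=1e-9)

    def test_constant_channel_floored(self):
        w = Window(np.full((6, 50), 5.0), LABEL_GAIT, "P000", ("L",), "gait", 0.0)
        out, _, _, _ = standardize([w])
        np.testing.assert_allclose(out[0].data, 0.0)

    def test_test_transform_uses_train_stats(self):
        train = self._random_windows(30, seed=1)
        test = self._random_windows(10, seed=2)
        tr_out, _, te_out, scaler = standardize(train, test=test)
        # manual oracle
        stack = np.stack([w.data for w in train])
        mu = stack.mean(axis=(0, 2))
        sd = stack.std(axis=(0, 2))
        for w_in, w_out in zip(test, te_out):
            np.testing.assert_allclose(
                w_out.data, (w_in.data - mu[:, None]) / sd[:, None], atol=1e-9
            )

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError):
            standardize([])


class TestArrays:
    def test_labels_binary(self):
        a = Window(np.zeros((6, 10)), LABEL_GAIT, "P", ("L",), "gait", 0.0)
        b = Window(np.zeros((6, 10)), LABEL_PERTURBATION, "P", ("L",), "pert1", 0.0)
        x, y = windows_to_arrays([a, b])
        assert x.shape == (2, 6, 10)
        assert list(y) == [0, 1]


class TestConfig:
    def test_sample_count_exact(self):
        assert WindowingConfig().n_samples == 200
        assert WindowingConfig(common_rate=50.0).n_samples == 100

    def test_validation(self):
        with pytest.raises(ValueError):
            WindowingConfig(gait_step=3.0)
        with pytest.raises(ValueError):
            WindowingConfig(channel_set="nope")
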