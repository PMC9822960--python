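import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myolight.errors import ContractError, FormatError
from myolight.preprocessing import (
    balance_classes,
    butterworth_bandpass,
    demultiplex,
    slide_windows,
)
from myolight.simulate import MultiplexedLMG, SessionRecording


def mux_from(samples, states, fs=400.0, toggle_ms=5.0):
    samples = np.asarray(samples, dtype=float)
    t = samples.shape[0]
    return MultiplexedLMG(
        samples, np.asarray(states, dtype="U5"), fs, toggle_ms,
        np.full(t, "rest", dtype="U16"), np.zeros(t, dtype=np.int64),
    )


class TestDemultiplex:
    def test_hand_traced_sample_and_hold(self):
        mux = mux_from(np.array([[1, 1, 9, 9, 1, 1]]).T,
                       ["green", "green", "ir", "ir", "green", "green"])
        rec = demultiplex(mux)
        np.testing.assert_array_equal(rec.signal[:, 0], [1, 1, 1, 1, 1, 1])  # green
        np.testing.assert_array_equal(rec.signal[:, 1], [9, 9, 9, 9, 9, 9])  # ir
        assert rec.channel_names == ("gr01", "ir01")

    def test_constant_input_gives_constant_channels(self):
        t = 200
        mux = mux_from(np.full((t, 5), 3.25),
                       np.tile(np.repeat(["green", "ir"], 2), t // 4))
        rec = demultiplex(mux)
        assert rec.signal.shape == (t, 10)
        assert np.all(rec.signal == 3.25)

    def test_lossless_on_lit_samples(self):
        rng = np.random.default_rng(0)
        t = 240
        states = np.repeat(np.tile(["green", "ir"], 30), 4)
        mux = mux_from(rng.normal(size=(t, 5)), states)
        rec = demultiplex(mux)
        for k, color in enumerate(("green", "ir")):
            mask = states == color
            np.testing.assert_array_equal(
                rec.signal[mask, 5 * k : 5 * k + 5], mux.samples[mask]
            )

    def test_fresh_sample_counts_split_evenly(self):
        t = 400
        states = np.repeat(np.tile(["green", "ir"], t // 20), 10)
        mux = mux_from(np.random.default_rng(1).normal(size=(t, 5)), states)
        fresh_green = (states == "green").sum()
        assert abs(fresh_green - t / 2) <= 10  # within one toggle run

    def test_invalid_led_state_rejected(self):
        mux = mux_from(np.ones((4, 5)), ["green", "red", "ir", "ir"])
        with pytest.raises(FormatError):
            demultiplex(mux)

    def test_cycle_mean_holds_run_averages(self):
        mux = mux_from(np.array([[1, 3, 10, 20, 5, 7]]).T,
                       ["green", "green", "ir", "ir", "green", "green"])
        rec = demultiplex(mux, method="cycle_mean")
        np.testing.assert_array_equal(rec.signal[:, 0], [2, 2, 2, 2, 6, 6])
        np.testing.assert_array_equal(rec.signal[:, 1], [15] * 6)


class TestBandpass:
    fs = 1200.0

    def _sine(self, hz, seconds=4.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        return np.sin(2 * np.pi * hz * t)[:, None]

    def test_passband_tone_preserved(self):
        y = butterworth_bandpass(self._sine(100.0), sample_rate=self.fs)
        steady = y[int(self.fs):, 0]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.05)

    def test_subcorner_tone_attenuated_20db(self):
        y = butterworth_bandpass(self._sine(1.0, 8.0), sample_rate=self.fs)
        steady = y[int(4 * self.fs):, 0]
        assert np.abs(steady).max() < 0.1  # >= 20 dB down

    def test_zero_in_zero_out(self):
        y = butterworth_bandpass(np.zeros((500, 3)), sample_rate=self.fs)
        assert np.all(y == 0.0)

    def test_high_cutoff_clamped_below_nyquist(self, caplog):
        with caplog.at_level("WARNING"):
            y = butterworth_bandpass(self._sine(100.0), high_hz=700.0,
                                     sample_rate=self.fs)
        assert np.all(np.isfinite(y))
        assert any("clamping" in r.message for r in caplog.records)

    def test_invalid_band_rejected(self):
        with pytest.raises(ContractError):
            butterworth_bandpass(np.ones((10, 1)), low_hz=50, high_hz=10,
                                 sample_rate=self.fs)


def session_from(signal, trigger, fs=400.0, reps=None):
    signal = np.asarray(signal, dtype=float)
    t = signal.shape[0]
    return SessionRecording(
        signal, np.asarray(trigger, dtype="U16"),
        np.zeros(t, dtype=np.int64) if reps is None else np.asarray(reps),
        fs, "lmg",
    )


class TestSlideWindows:
    def test_count_formula_example(self):
        s = session_from(np.zeros((6000, 2)), ["rest"] * 6000)
        ws = slide_windows(s, 200.0, 20.0)
        assert len(ws) == 741  # floor((6000 - 80) / 8) + 1

    def test_window_equal_to_session_gives_one_window(self):
        s = session_from(np.arange(80.0)[:, None], ["rest"] * 80)
        ws = slide_windows(s, 200.0, 20.0)
        assert len(ws) == 1
        np.testing.assert_array_equal(ws.windows[0, :, 0], np.arange(80.0))

    def test_window_longer_than_session_yields_zero(self, caplog):
        s = session_from(np.zeros((40, 1)), ["rest"] * 40)
        with caplog.at_level("WARNING"):
            ws = slide_windows(s, 200.0, 20.0)
        assert len(ws) == 0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        t=st.integers(2, 400),
        length=st.integers(1, 400),
        stride=st.integers(1, 50),
    )
    def test_count_matches_bruteforce_enumeration(self, t, length, stride):
        fs = 1000.0  # ms == samples
        s = session_from(np.zeros((t, 1)), ["rest"] * t, fs=fs)
        ws = slide_windows(s, float(length), float(stride))
        brute = len([i for i in range(0, t - length + 1, stride)]) if length <= t else 0
        assert len(ws) == brute

    def test_windows_are_exact_slices_of_source(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(size=(300, 4))
        s = session_from(sig, ["rest"] * 300)
        ws = slide_windows(s, 100.0, 25.0)  # L=40, S=10
        for i in range(len(ws)):
            np.testing.assert_array_almost_equal(
                ws.windows[i], sig[i * 10 : i * 10 + 40], decimal=6
            )

    def test_strict_policy_drops_transition_windows(self):
        trig = ["rest"] * 100 + ["pinch"] * 100
        s = session_from(np.zeros((200, 1)), trig)
        ws = slide_windows(s, 100.0, 10.0, label_policy="strict")
        # every kept window has a single-valued trigger across its span
        assert set(ws.labels) == {"rest", "pinch"}
        assert len(ws) == 2 * (len([i for i in range(0, 61, 4)]))

    def test_majority_policy_keeps_and_votes(self):
        trig = ["rest"] * 50 + ["pinch"] * 30
        s = session_from(np.zeros((80, 1)), trig)
        ws = slide_windows(s, 200.0, 20.0, label_policy="majority")
        assert list(ws.labels) == ["rest"]  # 50 rest vs 30 pinch samples

    def test_targets_reduced_to_window_end(self):
        s = session_from(np.zeros((80, 1)), ["rest"] * 80)
        tgt = np.arange(80.0)
        ws = slide_windows(s, 100.0, 25.0, targets=tgt)  # L=40, S=10
        np.testing.assert_array_equal(ws.targets, [39.0, 49.0, 59.0, 69.0, 79.0])


class TestBalance:
    def _ws(self, counts, seed=0):
        labels = np.concatenate([[lab] * n for lab, n in counts.items()])
        t = len(labels)
        s = session_from(np.arange(t, dtype=float)[:, None], labels, fs=1000.0)
        return slide_windows(s, 1.0, 1.0)

    def test_downsamples_to_minimum_count(self):
        ws = self._ws({"rest": 100, "pinch": 80, "tripod": 80, "power": 80,
                       "extension": 80})
        out = balance_classes(ws, seed=1)
        labs, counts = np.unique(out.labels, return_counts=True)
        assert len(out) == 400
        assert set(counts) == {80}

    def test_already_balanced_is_identity(self):
        ws = self._ws({"a": 50, "b": 50})
        out = balance_classes(ws, seed=1)
        assert out is ws

    def test_same_seed_same_selection_and_order_preserved(self):
        ws = self._ws({"a": 70, "b": 50})
        o1 = balance_classes(ws, seed=9)
        o2 = balance_classes(ws, seed=9)
        np.testing.assert_array_equal(o1.windows, o2.windows)
        assert np.all(np.diff(o1.windows[:, 0, 0]) > 0)  # source order kept

    def test_output_is_submultiset_of_input(self):
        ws = self._ws({"a": 33, "b": 21})
        out = balance_classes(ws, seed=2)
        src = set(ws.windows[:, 0, 0].tolist())
        assert set(out.windows[:, 0, 0].tolist()) <= src

    def test_missing_expected_class_is_named(self):
        ws = self._ws({"a": 10, "b": 10})
        with pytest.raises(ContractError, match="power"):
            balance_classes(ws, expected_labels=("a", "b", "power"))
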