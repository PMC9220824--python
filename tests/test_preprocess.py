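import numpy as np
import pandas as pd
import pytest

from isletpulse.preprocess import (
    PreprocessError, compute_ratio, demultiplex_animals, detrend, segment,
)
from isletpulse.traces import Protocol, StimulusSegment, TraceSet


def _traceset(n=200, dt=6.0, columns=("roiA", "roiB"), fill=1.0, channel="ratio"):
    t = np.arange(n) * dt
    data = pd.DataFrame({c: np.full(n, fill) for c in columns})
    return TraceSet(time=t, channels={channel: data})


class TestComputeRatio:
    def test_quotient(self):
        t = np.arange(10) * 6.0
        ex430 = pd.DataFrame({"r1": np.full(10, 2.0)})
        ex500 = pd.DataFrame({"r1": np.arange(10, dtype=float) + 1.0})
        ts = TraceSet(time=t, channels={"ex430": ex430, "ex500": ex500})
        out = compute_ratio(ts)
        assert np.allclose(out.channel("ratio")["r1"], (np.arange(10) + 1.0) / 2.0)

    def test_passthrough_when_ratio_present(self):
        ts = _traceset()
        assert compute_ratio(ts) is ts

    def test_error_names_roi_and_frame(self):
        t = np.arange(5) * 6.0
        ex430 = pd.DataFrame({"r1": [1.0, 1.0, 0.0, 1.0, 1.0]})
        ex500 = pd.DataFrame({"r1": np.ones(5)})
        ts = TraceSet(time=t, channels={"ex430": ex430, "ex500": ex500})
        with pytest.raises(PreprocessError, match=r"'r1'.*frame 2"):
            compute_ratio(ts)

    def test_missing_channel(self):
        ts = _traceset(channel="ex500")
        with pytest.raises(PreprocessError, match="ex430"):
            compute_ratio(ts)


class TestDemultiplex:
    def _with_infrared(self, levels):
        n = 50
        t = np.arange(n) * 6.0
        cols = {f"roi{i}": np.full(n, v) for i, v in enumerate(levels)}
        ir = pd.DataFrame(cols)
        ratio = pd.DataFrame({c: np.ones(n) for c in cols})
        return TraceSet(time=t, channels={"ratio": ratio, "infrared": ir})

    def test_bimodal_assignment(self):
        ts = self._with_infrared([1.0, 1.2, 0.9, 20.0, 22.0, 19.5])
        out = demultiplex_animals(ts, ("low", "high"))
        assert [out.animal_of[f"roi{i}"] for i in range(6)] == [
            "low", "low", "low", "high", "high", "high"
        ]
        meta = out.metadata["demux"]
        assert meta["centers"][0] < meta["threshold"] < meta["centers"][1]

    def test_unimodal_raises(self):
        rng = np.random.default_rng(0)
        ts = self._with_infrared(rng.normal(1.0, 0.05, 24))
        with pytest.raises(PreprocessError, match="unimodal"):
            demultiplex_animals(ts, ("low", "high"))

    def test_requires_infrared(self):
        with pytest.raises(PreprocessError, match="infrared"):
            demultiplex_animals(_traceset(), ("a", "b"))


class TestDetrend:
    def test_pure_linear_drift_removed_exactly(self):
        n = 400
        t = np.arange(n) * 6.0
        data = pd.DataFrame({"r": 1.0 + 3e-4 * t})
        ts = TraceSet(time=t, channels={"ratio": data})
        out = detrend(ts, window_s=600.0).channel("ratio")["r"].to_numpy()
        assert np.ptp(out) < 1e-9  # a pure line detrends to a constant

    def test_drifting_square_wave_flattened(self):
        n = 400
        t = np.arange(n) * 6.0
        square = (np.arange(n) % 20 < 8).astype(float) * 0.5
        data = pd.DataFrame({"r": 1.0 + square + 3e-4 * t})
        ts = TraceSet(time=t, channels={"ratio": data})
        out = detrend(ts, window_s=600.0).channel("ratio")["r"].to_numpy()
        # the rolling-quantile baseline is a staircase approximation of the
        # drift, so plateaus flatten to within a small residual ripple
        lo = out[np.arange(n) % 20 >= 8]
        hi = out[np.arange(n) % 20 < 8]
        assert np.ptp(lo) < 0.03
        assert np.ptp(hi) < 0.03
        assert hi.mean() - lo.mean() == pytest.approx(0.5, abs=0.02)

    def test_level_preserved_via_median_addback(self):
        n = 300
        t = np.arange(n) * 6.0
        data = pd.DataFrame({"r": np.full(n, 2.5)})
        ts = TraceSet(time=t, channels={"ratio": data})
        out = detrend(ts, window_s=600.0).channel("ratio")["r"]
        assert np.allclose(out, 2.5)

    def test_window_longer_than_recording_raises(self):
        ts = _traceset(n=50)
        with pytest.raises(PreprocessError, match="window"):
            detrend(ts, window_s=1e6)


class TestSegment:
    def _protocol(self, lag=0.0):
        return Protocol(
            segments=[
                StimulusSegment(label="s1", concentration=1.0, units="mM",
                                start_s=0.0, end_s=120.0),
                StimulusSegment(label="s2", concentration=2.0, units="mM",
                                start_s=120.0, end_s=240.0),
            ],
            equilibration_lag_s=lag,
        )

    def test_half_open_boundary(self):
        ts = _traceset(n=40)  # 240 s at 6 s frames
        windows = segment(ts, self._protocol())
        # the frame at exactly 120 s belongs to the second segment
        assert windows[0].time[-1] == 114.0
        assert windows[1].time[0] == 120.0
        assert len(windows[0].time) + len(windows[1].time) == 40

    def test_lag_excluded(self):
        ts = _traceset(n=40)
        windows = segment(ts, self._protocol(lag=30.0))
        assert windows[0].time[0] == 30.0
        assert windows[1].time[0] == 150.0

    def test_window_emptied_by_lag_raises(self):
        ts = _traceset(n=40)
        with pytest.raises(PreprocessError, match="empty"):
            segment(ts, self._protocol(lag=119.0))

    def test_protocol_beyond_recording_raises(self):
        ts = _traceset(n=10)
        with pytest.raises(PreprocessError, match="span"):
            segment(ts, self._protocol())
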