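"""Oscillation detection and the two per-segment scalar statistics:
duty cycle and baseline-subtracted AUC.

The duty cycle is the fraction of time the Ca2+ signal spends elevated
while oscillating. Each detected oscillation is decomposed into a *base*
(the full cycle footprint, one elevated-phase onset to the next) and a
*peak* (the elevated plateau within it); the segment duty cycle is the
ratio of summed peak widths to summed base widths. Windows whose dynamic
range falls below ``min_amplitude`` are *silent* (duty 0) unless the whole
window sits in the elevated band of the preceding segment, in which case
the signal has saturated into a sustained *plateau* (duty 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d


@dataclass(frozen=True)
class Oscillation:
    """One detected cycle: base = full footprint, peak = elevated plateau."""

    base_start_s: float
    base_end_s: float
    peak_start_s: float
    peak_end_s: float

    def __post_init__(self) -> None:
        if not (self.base_start_s <= self.peak_start_s
                and self.peak_end_s <= self.base_end_s):
            raise ValueError("base must contain peak")
        if self.peak_end_s <= self.peak_start_s or self.base_end_s <= self.base_start_s:
            raise ValueError("widths must be positive")

    @property
    def base_width_s(self) -> float:
        return self.base_end_s - self.base_start_s

    @property
    def peak_width_s(self) -> float:
        return self.peak_end_s - self.peak_start_s


@dataclass(frozen=True)
class OscillationParams:
    """Detection parameters.

    smooth_s
        Moving-average window (s) applied before thresholding.
    elevation_fraction
        Elevation threshold as a fraction of the floor-to-ceiling range
        (0.5 = midpoint, the symmetric definition of "elevated").
    min_amplitude
        Minimum floor-to-ceiling range (signal units) for a window to be
        considered oscillating at all.
    min_cycle_s
        Oscillations with a shorter full footprint are merged into their
        successor (suppresses brief threshold re-crossings).
    min_peak_s
        Supra-threshold runs shorter than this are ignored.
    floor_q / ceiling_q
        Quantiles defining floor and ceiling (robust min/max).
    """

    smooth_s: float = 12.0
    elevation_fraction: float = 0.5
    min_amplitude: float = 0.2
    min_cycle_s: float = 30.0
    min_peak_s: float = 6.0
    floor_q: float = 0.08
    ceiling_q: float = 0.98


@dataclass
class DutyCycleRecord:
    """Per-(ROI, segment) duty-cycle statistic.

    ``duty_cycle`` pools widths across cycles (ratio of sums);
    ``duty_cycle_mean`` averages per-cycle ratios and is reported alongside.
    """

    roi: str
    animal: str
    group: str
    segment: str
    concentration: float
    duty_cycle: float
    duty_cycle_mean: float
    n_oscillations: int
    state: str  # silent | oscillating | plateau


@dataclass
class AUCRecord:
    """Per-(ROI, segment) area under the curve above a baseline reference.

    ``auc`` is the net trapezoidal integral of (signal - baseline), in
    signal units x seconds, negative excursions included; ``auc_positive``
    integrates only the positive part.
    """

    roi: str
    group: str
    segment: str
    auc: float
    auc_positive: float
    baseline_value: float


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Half-open index runs of True values."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends))


def detect_oscillations(
    time: np.ndarray,
    values: np.ndarray,
    params: OscillationParams = OscillationParams(),
    plateau_reference: Optional[float] = None,
) -> Tuple[List[Oscillation], str, dict]:
    """Detect slow oscillations in one segment window of one ROI.

    Returns (oscillations, state, diagnostics). ``plateau_reference`` is the
    elevation threshold of the preceding segment: a low-amplitude window
    whose floor exceeds it is a saturated plateau (duty 1) rather than
    silent. Diagnostics carry the floor, ceiling and threshold used, for
    chaining across segments.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and values must be 1-D and equal length")
    if not np.isfinite(y).all():
        raise ValueError("non-finite samples in window")
    if len(t) < 3:
        raise ValueError("window too short")
    dt = float(np.median(np.diff(t)))

    k = max(1, int(round(params.smooth_s / dt)))
    if k % 2 == 0:
        k += 1
    ys = uniform_filter1d(y, size=k, mode="nearest") if k > 1 else y

    floor = float(np.quantile(ys, params.floor_q))
    ceiling = float(np.quantile(ys, params.ceiling_q))
    diag = {"floor": floor, "ceiling": ceiling, "threshold": None, "dt": dt}

    if ceiling - floor < params.min_amplitude:
        if plateau_reference is not None and floor > plateau_reference:
            return [], "plateau", diag
        return [], "silent", diag

    threshold = floor + params.elevation_fraction * (ceiling - floor)
    diag["threshold"] = threshold
    supra = ys >= threshold
    min_peak_frames = max(1, int(round(params.min_peak_s / dt)))
    runs = [(a, b) for a, b in _runs(supra) if b - a >= min_peak_frames]
    # A run already elevated at the window's first frame is a clipped cycle
    # whose onset was not observed; with other cycles present it is dropped
    # rather than measured with an arbitrary base start.
    if len(runs) >= 2 and runs[0][0] == 0:
        runs = runs[1:]
    if not runs:
        if plateau_reference is not None and floor > plateau_reference:
            return [], "plateau", diag
        return [], "silent", diag

    window_end = t[-1] + dt
    n = len(t)
    # Width measurement uses a threshold placed from the raw trace's own
    # quantile range: smoothing shrinks the apparent dynamic range when
    # elevated phases are short, which would drop the smoothed threshold
    # into the noise band.
    floor_raw = float(np.quantile(y, params.floor_q))
    ceiling_raw = float(np.quantile(y, params.ceiling_q))
    threshold_raw = floor_raw + params.elevation_fraction * (ceiling_raw - floor_raw)
    diag["threshold_raw"] = threshold_raw
    supra_raw = y >= threshold_raw
    # Smoothing locates cycles; onsets and elevated widths are refined on
    # the raw trace, whose plateau/baseline separation is sharp, so neither
    # is blurred by the smoothing kernel.
    bounds = []
    for i, (a, b) in enumerate(runs):
        end_idx = runs[i + 1][0] if i + 1 < len(runs) else n
        raw_idx = np.flatnonzero(supra_raw[a:end_idx])
        if len(raw_idx) == 0:
            onset, n_peak = a, b - a
        else:
            onset, n_peak = a + raw_idx[0], len(raw_idx)
        bounds.append((onset, min(n_peak, end_idx - onset)))
    cycles: List[List[float]] = []
    for i, (onset, n_peak) in enumerate(bounds):
        base_start = t[onset]
        base_end = t[bounds[i + 1][0]] if i + 1 < len(bounds) else window_end
        cycles.append([base_start, base_end, t[onset], t[onset] + n_peak * dt])

    # Merge cycles whose footprint is shorter than one plausible period:
    # a brief dip splitting a plateau joins its neighbour, the gap counted
    # as elevated.
    merged: List[List[float]] = []
    for cyc in cycles:
        if merged and merged[-1][1] - merged[-1][0] < params.min_cycle_s:
            prev = merged.pop()
            cyc = [prev[0], cyc[1], prev[2], cyc[3]]
        merged.append(cyc)
    if len(merged) >= 2 and merged[-1][1] - merged[-1][0] < params.min_cycle_s:
        prev = merged.pop()
        last = merged.pop()
        merged.append([last[0], prev[1], last[2], prev[3]])

    oscillations = [
        Oscillation(base_start_s=bs, base_end_s=be, peak_start_s=ps, peak_end_s=pe)
        for bs, be, ps, pe in merged
    ]
    return oscillations, "oscillating", diag


def duty_cycle(
    oscillations: Sequence[Oscillation],
    state: str,
    roi: str = "",
    animal: str = "",
    group: str = "",
    segment: str = "",
    concentration: float = float("nan"),
) -> DutyCycleRecord:
    """Reduce detected oscillations to a duty-cycle record.

    silent -> 0, plateau -> 1; oscillating -> sum(peak widths) / sum(base
    widths), with the per-cycle mean reported alongside.
    """
    if state == "silent":
        dc = dc_mean = 0.0
    elif state == "plateau":
        dc = dc_mean = 1.0
    elif state == "oscillating":
        if not oscillations:
            raise ValueError("oscillating state requires at least one oscillation")
        peaks = sum(o.peak_width_s for o in oscillations)
        bases = sum(o.base_width_s for o in oscillations)
        dc = peaks / bases
        dc_mean = float(np.mean([o.peak_width_s / o.base_width_s for o in oscillations]))
    else:
        raise ValueError(f"unknown state {state!r}")
    return DutyCycleRecord(
        roi=roi, animal=animal, group=group, segment=segment,
        concentration=concentration,
        duty_cycle=float(np.clip(dc, 0.0, 1.0)),
        duty_cycle_mean=float(np.clip(dc_mean, 0.0, 1.0)),
        n_oscillations=len(oscillations), state=state,
    )


def segment_auc(
    time: np.ndarray,
    values: np.ndarray,
    baseline_value: float,
    roi: str = "",
    group: str = "",
    segment: str = "",
) -> AUCRecord:
    """Trapezoidal AUC of (signal - baseline) over a segment window.

    ``baseline_value`` is typically the mean of a designated reference
    segment. The net integral (negative excursions included) is the primary
    statistic; the positive-only integral is reported alongside.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(values, dtype=float)
    if baseline_value is None or not np.isfinite(baseline_value):
        raise ValueError("baseline reference is missing or non-finite")
    if not np.isfinite(y).all():
        raise ValueError("non-finite samples in window")
    d = y - baseline_value
    net = float(np.trapezoid(d, t))
    pos = float(np.trapezoid(np.clip(d, 0.0, None), t))
    return AUCRecord(roi=roi, group=group, segment=segment,
                     auc=net, auc_positive=pos, baseline_value=float(baseline_value))
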