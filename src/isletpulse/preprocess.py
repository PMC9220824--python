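"""Trace preprocessing: ratio computation, animal demultiplexing,
detrending, and segmentation into protocol windows.

The ratiometric readout is R500/430 (emission under 500 nm excitation
divided by emission under 430 nm excitation); because both channels share
the same dye pool, multiplicative artefacts such as photobleaching cancel
in the ratio. Two animals imaged in one chamber are separated by the
near-infrared label channel, whose per-ROI intensities are bimodal.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .traces import Protocol, SegmentWindow, TraceSet


class PreprocessError(ValueError):
    pass


def compute_ratio(traces: TraceSet) -> TraceSet:
    """Add the R500/430 ratio channel; passthrough if already present.

    Raises :class:`PreprocessError` naming the ROI and frame index if the
    denominator channel is not strictly positive anywhere.
    """
    if "ratio" in traces.channels:
        return traces
    for role in ("ex430", "ex500"):
        if role not in traces.channels:
            raise PreprocessError(f"cannot compute ratio: channel {role!r} missing")
    denom = traces.channel("ex430")
    bad = denom.to_numpy() <= 0
    if bad.any():
        frame, col = np.argwhere(bad)[0]
        roi = denom.columns[col]
        raise PreprocessError(
            f"non-positive ex430 value for roi {roi!r} at frame {frame}"
        )
    ratio = traces.channel("ex500") / denom
    return traces.with_channel("ratio", ratio)


def _two_class_split(values: np.ndarray) -> Tuple[float, float, float, float]:
    """Exact 1-D two-class split minimising within-class variance.

    Returns (low centre, high centre, threshold, within-class sd). The
    threshold is the midpoint between the two class means.
    """
    x = np.sort(values)
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x**2)
    best_k, best_ss = None, np.inf
    for k in range(1, n):  # low class = x[:k]
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        ss = (q1 - s1**2 / k) + (q2 - s2**2 / (n - k))
        if ss < best_ss:
            best_ss, best_k = ss, k
    k = best_k
    c1 = float(csum[k - 1] / k)
    c2 = float((csum[-1] - csum[k - 1]) / (n - k))
    within_sd = float(np.sqrt(max(best_ss, 0.0) / n))
    return c1, c2, (c1 + c2) / 2.0, within_sd


def demultiplex_animals(
    traces: TraceSet,
    labels: Tuple[str, str],
    min_separation: float = 3.0,
) -> TraceSet:
    """Assign each ROI to one of two animals from the infrared label channel.

    Per-ROI median infrared intensities are split by the exact 1-D
    two-class (variance-minimising) threshold; the lower-intensity cluster
    receives ``labels[0]``. If the gap between cluster centres is less than
    ``min_separation`` within-class standard deviations, the distribution
    is judged unimodal and an error advises manual assignment.
    """
    if "infrared" not in traces.channels:
        raise PreprocessError("infrared channel missing; cannot demultiplex")
    if len(labels) != 2 or labels[0] == labels[1]:
        raise PreprocessError("exactly two distinct animal labels are required")
    med = traces.channel("infrared").median(axis=0)
    values = med.to_numpy(dtype=float)
    if len(values) < 2:
        raise PreprocessError("need at least two ROIs to demultiplex")
    c1, c2, threshold, within_sd = _two_class_split(values)
    gap = c2 - c1
    if gap <= 0 or gap < min_separation * max(within_sd, 1e-12 * max(abs(c2), 1.0)):
        raise PreprocessError(
            "infrared intensities look unimodal "
            f"(centres {c1:.4g} / {c2:.4g}, within-class sd {within_sd:.4g}); "
            "assign animals manually"
        )
    animal_of: Dict[str, str] = {}
    margins: Dict[str, float] = {}
    for roi, v in med.items():
        animal_of[str(roi)] = labels[1] if v > threshold else labels[0]
        margins[str(roi)] = float(abs(v - threshold))
    out = TraceSet(
        time=traces.time.copy(),
        channels=dict(traces.channels),
        animal_of=animal_of,
        metadata=dict(traces.metadata),
    )
    out.metadata["demux"] = {
        "threshold": threshold,
        "centers": [c1, c2],
        "labels": list(labels),
        "margins": margins,
    }
    return out


def detrend(
    traces: TraceSet,
    window_s: float = 600.0,
    quantile: float = 0.08,
    channel: str = "ratio",
) -> TraceSet:
    """Remove slow baseline drift by rolling low-quantile subtraction.

    Per ROI, a centred rolling ``quantile`` (default 8th percentile) over
    ``window_s`` estimates the baseline; it is subtracted and its median is
    added back so the absolute scale is preserved. Near the edges, where a
    full window does not fit, the baseline is extended by straight-line
    extrapolation of its local trend, so a purely linear drift detrends to
    a constant. The frame grid is never altered. ``window_s`` should exceed
    twice the oscillation period so troughs are sampled in every window.
    """
    data = traces.channel(channel)
    dt = traces.frame_interval
    w = int(round(window_s / dt))
    n = len(data)
    if w > n:
        raise PreprocessError(
            f"detrend window {window_s} s exceeds the recording ({n * dt:g} s)"
        )
    w = max(w, 1)
    baseline = data.rolling(window=w, center=True, min_periods=w).quantile(quantile)

    out = {}
    for roi in data.columns:
        b = baseline[roi].to_numpy(dtype=float)
        valid = np.flatnonzero(np.isfinite(b))
        first, last = valid[0], valid[-1]
        m = max(2, min(w, last - first + 1))
        if first > 0:
            seg = b[first:first + m]
            slope = np.polyfit(np.arange(m), seg, 1)[0] if m > 1 else 0.0
            b[:first] = b[first] - slope * np.arange(first, 0, -1)
        if last < n - 1:
            seg = b[last - m + 1:last + 1]
            slope = np.polyfit(np.arange(m), seg, 1)[0] if m > 1 else 0.0
            b[last + 1:] = b[last] + slope * np.arange(1, n - last)
        y = data[roi].to_numpy(dtype=float)
        out[roi] = y - b + np.median(b)

    detrended = pd.DataFrame(out, columns=data.columns)
    result = traces.with_channel(channel, detrended)
    result.metadata["detrended"] = True
    result.metadata["detrend_window_s"] = window_s
    result.metadata["detrend_quantile"] = quantile
    return result


def segment(
    traces: TraceSet,
    protocol: Protocol,
    channel: str = "ratio",
) -> List[SegmentWindow]:
    """Cut a channel into per-segment windows.

    Each window covers [start_s + equilibration_lag_s, end_s) with frames
    assigned by half-open intervals (a frame exactly on a boundary belongs
    to the later segment). Raises if any window is empty after the lag.
    """
    data = traces.channel(channel)
    t = traces.time
    lo, hi = protocol.span
    if lo < t[0] - traces.frame_interval or hi > t[-1] + traces.frame_interval:
        raise PreprocessError(
            f"protocol span [{lo}, {hi}) exceeds the recording "
            f"[{t[0]}, {t[-1] + traces.frame_interval})"
        )
    windows = []
    for seg in protocol.segments:
        t0 = seg.start_s + protocol.equilibration_lag_s
        mask = (t >= t0) & (t < seg.end_s)
        if not mask.any():
            raise PreprocessError(
                f"segment {seg.label!r} is empty after the equilibration lag"
            )
        windows.append(
            SegmentWindow(
                label=seg.label,
                concentration=seg.concentration,
                start_s=t0,
                end_s=seg.end_s,
                time=t[mask],
                data=data.loc[mask].reset_index(drop=True),
            )
        )
    return windows
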