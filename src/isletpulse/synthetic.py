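"""Synthetic data with known ground truth for every pipeline stage.

Four families of inputs are generated, each alongside its planted truth:

* **Glucose-ramp recordings** — slow oscillatory Ca2+ ratio traces whose
  per-segment duty cycle follows a group-specific 4PL curve of stimulus
  concentration, with baseline drift, optional photobleaching of the raw
  excitation channels, Gaussian noise, and a bimodal infrared label
  channel encoding animal of origin.
* **Plateau-response recordings** — secretagogue segments that rise
  smoothly to a planted plateau amplitude (amino-acid ramps, perifusion),
  with the analytic baseline-subtracted AUC emitted as truth.
* **Genomic fixtures** — gene models, binding peaks and chromatin loops
  with one planted regulatory class per gene (tss / intron / loop / none).
* **TMT-like abundance tables** — log-normal protein x channel tables
  with planted fold changes and deliberately unequal channel loadings.

Oscillations are smoothed rectangular burst trains (sigmoid-edged), not a
mechanistic beta-cell model: the downstream statistic depends only on the
fraction of time spent elevated, so plateau/baseline structure suffices.
The true duty cycle is quantised to the frame grid, with the rounding
error dithered across cycles; the truth tables report the realised value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from .doseresponse import FourPLParams, four_pl
from .genomic import GeneModel, Loop, Peak
from .traces import Protocol, StimulusSegment, TraceSet, ramp_protocol

GLUCOSE_RAMP_MM = (3.0, 4.5, 6.0, 7.5, 8.0, 9.0)

DEFAULT_TRUTH = {
    # Knockout islets are left-shifted (more glucose sensitive) relative
    # to controls; these are the standing study conditions for recovery
    # and power checks.
    "control": FourPLParams(bottom=0.05, top=0.9, ec50=7.5, hill=5.0),
    "knockout": FourPLParams(bottom=0.05, top=0.9, ec50=6.0, hill=5.0),
}


def _check_finite(name: str, *values: float) -> None:
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError(f"non-finite value in {name}")


class TraceSimConfig(BaseModel):
    """Study conditions for the glucose-ramp simulator.

    Defaults mirror the imaging design: 6-second frames, a six-step
    glucose ramp (3, 4.5, 6, 7.5, 8, 9 mM) with 16-minute segments, slow
    oscillations with a 120 s period, and a knockout group whose duty-cycle
    dose response is left-shifted relative to control.
    """

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n_islets_per_group: int = Field(default=30, ge=1)
    n_animals_per_group: int = Field(default=5, ge=1)
    frame_interval: float = Field(default=6.0, gt=0)
    segments: List[Tuple[float, float]] = Field(
        default_factory=lambda: [(960.0, c) for c in GLUCOSE_RAMP_MM],
        description="(duration s, concentration) per segment",
    )
    dose_response_truth: Dict[str, FourPLParams] = Field(
        default_factory=lambda: dict(DEFAULT_TRUTH)
    )
    period: float = Field(default=120.0, gt=0, description="oscillation period, s")
    baseline: float = 1.0
    amplitude: float = Field(default=0.5, gt=0)
    edge_s: float = Field(default=2.0, ge=0, description="sigmoid edge width, s")
    noise_sd: float = Field(default=0.05, ge=0)
    drift_slope: float = Field(default=2e-5, description="ratio units per s")
    bleach_tau: Optional[float] = Field(
        default=7200.0, description="e-folding time of excitation-channel bleach, s"
    )
    infrared_modes: Tuple[float, float] = (1.0, 20.0)
    infrared_cv: float = Field(default=0.2, ge=0)
    equilibration_lag_s: float = Field(
        default=60.0, ge=0,
        description="settling time excluded at the start of each segment",
    )
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "TraceSimConfig":
        for dur, conc in self.segments:
            _check_finite("segments", dur, conc)
            if dur <= 0:
                raise ValueError("segment durations must be positive")
            if conc < 0:
                raise ValueError("concentrations must be non-negative")
        if not self.segments:
            raise ValueError("at least one segment is required")
        for group, p in self.dose_response_truth.items():
            _check_finite(f"truth[{group}]", *p)
            if not (0 <= p.bottom <= 1 and 0 <= p.top <= 1):
                raise ValueError("bottom and top must lie in [0, 1]")
            if p.bottom > p.top:
                raise ValueError("bottom must not exceed top")
            if p.ec50 <= 0 or p.hill <= 0:
                raise ValueError("ec50 and hill must be positive")
        _check_finite(
            "config",
            self.frame_interval, self.period, self.baseline, self.amplitude,
            self.noise_sd, self.drift_slope, self.edge_s,
        )
        if self.bleach_tau is not None:
            _check_finite("bleach_tau", self.bleach_tau)
            if self.bleach_tau <= 0:
                raise ValueError("bleach_tau must be positive")
        if self.period < 2 * self.frame_interval:
            raise ValueError("period must cover at least two frames")
        if self.infrared_modes[0] >= self.infrared_modes[1]:
            raise ValueError("infrared modes must be ordered low < high")
        return self

    def protocol(self, units: str = "mM") -> Protocol:
        segs = []
        t = 0.0
        for dur, conc in self.segments:
            segs.append(
                StimulusSegment(
                    label=f"{conc:g}{units}", concentration=conc, units=units,
                    start_s=t, end_s=t + dur,
                )
            )
            t += dur
        return Protocol(segments=segs, equilibration_lag_s=self.equilibration_lag_s)


def dither_on_frames(
    duty: float, period: float, frame_interval: float, n_cycles: int
) -> np.ndarray:
    """On-frame count per cycle so the realised mean duty tracks ``duty``.

    A single cycle can only realise duties on a 1/n_per grid; distributing
    the rounding error across cycles (cumulative rounding, as in Bresenham's
    algorithm) refines the resolution of the realised mean to
    1/(n_per * n_cycles).
    """
    n_per = int(round(period / frame_interval))
    d = float(np.clip(duty, 0.0, 1.0))
    cum = np.round(d * n_per * np.arange(n_cycles + 1)).astype(int)
    return np.diff(cum)


def realized_duty(
    duty: float,
    period: float,
    frame_interval: float,
    n_cycles: int,
    skip_cycles: int = 0,
) -> float:
    """Mean duty the dithered burst train realises over complete cycles.

    ``skip_cycles`` drops leading cycles that fall (partly) outside the
    analysis window, e.g. during an equilibration lag.
    """
    n_per = int(round(period / frame_interval))
    n_on = dither_on_frames(duty, period, frame_interval, n_cycles)[skip_cycles:]
    if len(n_on) == 0:
        raise ValueError("no complete cycles left after skipping")
    return float(n_on.sum() / (n_per * len(n_on)))


def burst_train(
    t: np.ndarray,
    period: float,
    duty: float,
    frame_interval: float,
    edge_s: float = 2.0,
) -> np.ndarray:
    """Unit-amplitude sigmoid-edged burst train sampled at times ``t``
    (relative to the start of the segment).

    Each cycle's on-block starts at the cycle boundary and lasts a whole
    number of frames, dithered across cycles (:func:`dither_on_frames`) so
    the realised mean duty tracks ``duty`` beyond single-cycle resolution.
    Edges sit half a frame outside the on frames so sampled on-frames stay
    near 1 and off-frames near 0; abutting on-blocks join seamlessly.
    """
    n_per = int(round(period / frame_interval))
    period_eff = n_per * frame_interval
    x = np.asarray(t, dtype=float)
    n_cycles = int(np.floor(x.max() / period_eff)) + 1 if len(x) else 0
    n_on = dither_on_frames(duty, period, frame_interval, n_cycles)
    if len(n_on) and (n_on <= 0).all():
        return np.zeros_like(x)
    if len(n_on) and (n_on >= n_per).all():
        return np.ones_like(x)  # sustained plateau, no edges to render
    s = np.zeros_like(x, dtype=float)
    half = frame_interval / 2.0
    for c, n in enumerate(n_on):
        if n <= 0:
            continue
        start = c * period_eff - half
        end = start + n * frame_interval
        if edge_s <= 0:
            s += ((x >= start) & (x < end)).astype(float)
        else:
            s += expit((x - start) / edge_s) - expit((x - end) / edge_s)
    return np.clip(s, 0.0, 1.0)


def _roi_ids(config: TraceSimConfig) -> List[Tuple[str, str, str]]:
    """(roi, animal, group) triples; islets split evenly across animals."""
    out = []
    for group in sorted(config.dose_response_truth):
        for i in range(config.n_islets_per_group):
            animal = f"{group}-a{i % config.n_animals_per_group + 1:02d}"
            out.append((f"{group}-islet{i + 1:03d}", animal, group))
    return out


def simulate_ramp_traces(config: TraceSimConfig) -> Tuple[TraceSet, pd.DataFrame]:
    """Simulate a glucose-ramp recording plus its ground-truth duty table.

    Returns a :class:`TraceSet` with ``ratio``, ``ex430``, ``ex500`` and
    ``infrared`` channels (ex500/ex430 reproduces the ratio exactly; a
    common bleach factor on the excitation channels cancels in the ratio)
    and a tidy truth table with the frame-quantised duty cycle per
    (roi, segment).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    total = sum(d for d, _ in config.segments)
    t = np.arange(0.0, total - dt / 2, dt)
    rois = _roi_ids(config)

    ratio = {}
    infrared = {}
    truth_rows = []
    starts = np.cumsum([0.0] + [d for d, _ in config.segments])
    low, high = config.infrared_modes
    log_sd = math.log1p(config.infrared_cv)

    for roi, animal, group in rois:
        params = config.dose_response_truth[group]
        clean = np.empty_like(t)
        for (dur, conc), t0 in zip(config.segments, starts):
            mask = (t >= t0) & (t < t0 + dur)
            duty = float(np.clip(four_pl(conc, *params), 0.0, 1.0))
            n_cycles = int(np.floor((dur - dt / 2) / config.period)) + 1
            skip = int(np.ceil(config.equilibration_lag_s / config.period))
            q = realized_duty(duty, config.period, dt, n_cycles, skip_cycles=skip)
            clean[mask] = config.baseline + config.amplitude * burst_train(
                t[mask] - t0, config.period, duty, dt, config.edge_s
            )
            truth_rows.append(
                {
                    "roi": roi, "animal": animal, "group": group,
                    "segment": f"{conc:g}mM", "concentration": conc,
                    "true_duty_cycle": q,
                }
            )
        clean = clean + config.drift_slope * t
        noise = rng.normal(0.0, config.noise_sd, size=t.shape)
        ratio[roi] = clean + noise

        mode = high if group == sorted(config.dose_response_truth)[1] else low
        level = float(rng.lognormal(math.log(mode), log_sd))
        infrared[roi] = level * (1.0 + 0.02 * rng.standard_normal(t.shape))

    ratio_df = pd.DataFrame(ratio)
    bleach = (
        np.exp(-t / config.bleach_tau) if config.bleach_tau is not None else np.ones_like(t)
    )
    ex430 = pd.DataFrame({roi: bleach for roi in ratio_df.columns})
    ex500 = ratio_df.mul(bleach, axis=0)

    traces = TraceSet(
        time=t,
        channels={
            "ratio": ratio_df,
            "ex430": ex430,
            "ex500": ex500,
            "infrared": pd.DataFrame(infrared),
        },
        metadata={
            "simulator": "ramp",
            "seed": config.seed,
            "groups": sorted(config.dose_response_truth),
            "true_animal_of": {roi: animal for roi, animal, _ in rois},
            "group_of": {roi: group for roi, _, group in rois},
        },
    )
    truth = pd.DataFrame(truth_rows)
    return traces, truth


class ResponseSegment(BaseModel):
    """One plateau-response segment with per-group planted amplitudes."""

    label: str
    duration: float = Field(gt=0)
    amplitudes: Dict[str, float]
    concentration: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _finite(self) -> "ResponseSegment":
        _check_finite(f"segment {self.label!r}", self.duration, self.concentration,
                      *self.amplitudes.values())
        return self


class ResponseSimConfig(BaseModel):
    """Study conditions for plateau-response recordings (amino-acid ramps,
    perifusion-style segments). The first segment is the baseline reference."""

    n_islets_per_group: int = Field(default=30, ge=1)
    n_animals_per_group: int = Field(default=5, ge=1)
    frame_interval: float = Field(default=6.0, gt=0)
    segments: List[ResponseSegment] = Field(
        default_factory=lambda: [
            ResponseSegment(label="baseline", duration=300.0,
                            amplitudes={"control": 0.0, "knockout": 0.0},
                            concentration=0.0),
            ResponseSegment(label="aa_1x", duration=300.0,
                            amplitudes={"control": 0.2, "knockout": 0.5},
                            concentration=1.0),
            ResponseSegment(label="aa_3x", duration=300.0,
                            amplitudes={"control": 0.5, "knockout": 1.0},
                            concentration=3.0),
            ResponseSegment(label="aa_10x", duration=300.0,
                            amplitudes={"control": 1.0, "knockout": 1.4},
                            concentration=10.0),
        ]
    )
    baseline: float = 1.0
    rise_tau: float = Field(default=30.0, gt=0, description="rise time constant, s")
    noise_sd: float = Field(default=0.05, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "ResponseSimConfig":
        if not self.segments:
            raise ValueError("at least one segment is required")
        groups = set(self.segments[0].amplitudes)
        for seg in self.segments:
            if set(seg.amplitudes) != groups:
                raise ValueError("all segments must carry the same groups")
        _check_finite("config", self.frame_interval, self.baseline,
                      self.rise_tau, self.noise_sd)
        return self

    @property
    def groups(self) -> List[str]:
        return sorted(self.segments[0].amplitudes)

    def protocol(self) -> Protocol:
        segs = []
        t = 0.0
        for seg in self.segments:
            segs.append(StimulusSegment(
                label=seg.label, concentration=seg.concentration, units="x",
                start_s=t, end_s=t + seg.duration,
            ))
            t += seg.duration
        return Protocol(segments=segs, equilibration_lag_s=0.0)


def plateau_auc_truth(
    amplitude: float, span: float, rise_tau: float = 0.0, t_offset: float = 0.0
) -> float:
    """Closed-form baseline-subtracted AUC of a saturating-rise response
    ``A (1 - exp(-(t - t0)/tau))`` integrated over ``span`` seconds starting
    ``t_offset`` after the segment onset. ``rise_tau = 0`` gives the
    rectangle area ``amplitude * span``."""
    if span < 0:
        raise ValueError("span must be non-negative")
    if rise_tau <= 0:
        return amplitude * span
    a, b = t_offset, t_offset + span
    return amplitude * (span + rise_tau * (math.exp(-b / rise_tau) - math.exp(-a / rise_tau)))


def simulate_response_segments(
    config: ResponseSimConfig,
) -> Tuple[TraceSet, pd.DataFrame]:
    """Simulate plateau-response traces plus the analytic per-segment AUC truth.

    Truth AUCs are the closed-form integral of the noise-free response over
    the span actually sampled by the frame grid (first to last frame of the
    segment), so a trapezoidal estimate on the noise-free trace recovers
    them up to curvature-level discretisation error.
    """
    rng = np.random.default_rng(config.seed)
    dt = config.frame_interval
    total = sum(seg.duration for seg in config.segments)
    t = np.arange(0.0, total - dt / 2, dt)

    rois = []
    for group in config.groups:
        for i in range(config.n_islets_per_group):
            animal = f"{group}-a{i % config.n_animals_per_group + 1:02d}"
            rois.append((f"{group}-islet{i + 1:03d}", animal, group))

    starts = np.cumsum([0.0] + [seg.duration for seg in config.segments])
    values = {}
    truth_rows = []
    for roi, animal, group in rois:
        clean = np.full_like(t, config.baseline)
        for seg, t0 in zip(config.segments, starts):
            mask = (t >= t0) & (t < t0 + seg.duration)
            amp = seg.amplitudes[group]
            tloc = t[mask] - t0
            clean[mask] = config.baseline + amp * (1.0 - np.exp(-tloc / config.rise_tau))
            if mask.any():
                span = float(tloc[-1] - tloc[0])
                auc = plateau_auc_truth(amp, span, config.rise_tau, float(tloc[0]))
            else:
                auc = 0.0
            truth_rows.append(
                {
                    "roi": roi, "animal": animal, "group": group,
                    "segment": seg.label, "concentration": seg.concentration,
                    "true_auc": auc,
                }
            )
        values[roi] = clean + rng.normal(0.0, config.noise_sd, size=t.shape)

    traces = TraceSet(
        time=t,
        channels={"ratio": pd.DataFrame(values)},
        metadata={
            "simulator": "response",
            "seed": config.seed,
            "groups": config.groups,
            "true_animal_of": {roi: animal for roi, animal, _ in rois},
            "group_of": {roi: group for roi, _, group in rois},
            "baseline_segment": config.segments[0].label,
        },
    )
    return traces, pd.DataFrame(truth_rows)


def simulate_dose_points(
    truth: Dict[str, FourPLParams],
    concentrations: Sequence[float] = GLUCOSE_RAMP_MM,
    n_animals: int = 5,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-animal mean duty-cycle points drawn directly from the 4PL truth.

    A lightweight generator for calibrating curve-comparison statistics:
    each (group, animal, concentration) point is the 4PL value plus
    Gaussian animal-level noise, clipped to [0, 1]. ``noise_sd = 0.03``
    reflects the dispersion of by-animal means when each animal averages
    tens of islets.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group in sorted(truth):
        params = truth[group]
        for a in range(n_animals):
            for c in concentrations:
                mu = float(np.clip(four_pl(c, *params), 0.0, 1.0))
                val = float(np.clip(mu + rng.normal(0.0, noise_sd), 0.0, 1.0))
                rows.append(
                    {
                        "group": group, "animal": f"{group}-a{a + 1:02d}",
                        "concentration": float(c), "duty_cycle": val,
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Genomic fixtures
# --------------------------------------------------------------------------

TARGET_CLASSES = ("tss", "intron", "loop", "none")


@dataclass
class GenomicFixture:
    """Gene models, peaks and loops with one planted class per gene.

    All coordinates are 0-based half-open. Every gene sits in its own
    1 Mb block so planted evidence never leaks across genes.
    """

    genes: List[GeneModel]
    peaks: List[Peak]
    loops: List[Loop]
    de_genes: List[str]
    truth_labels: Dict[str, str]

    def class_counts(self) -> Dict[str, int]:
        counts = {c: 0 for c in TARGET_CLASSES}
        for label in self.truth_labels.values():
            counts[label] += 1
        return counts


def make_genomic_fixture(n_genes: int, seed: int = 0) -> GenomicFixture:
    """Plant at least one gene of each class (tss / intron / loop / none).

    * tss: a peak within 1 kbp of the TSS (outside introns),
    * intron: a peak inside an intron that is itself > 1 kbp from the TSS,
    * loop: a loop with one anchor over the TSS and a peak within 500 bp
      of the distal anchor (~200 kbp away),
    * none: a decoy peak > 1 kbp from the TSS, outside introns, plus a
      decoy loop whose anchors are far from the TSS.
    """
    if n_genes < 4:
        raise ValueError("need at least 4 genes to plant every class")
    rng = np.random.default_rng(seed)
    classes = [TARGET_CLASSES[i % 4] for i in range(n_genes)]
    rng.shuffle(classes)

    genes: List[GeneModel] = []
    peaks: List[Peak] = []
    loops: List[Loop] = []
    truth: Dict[str, str] = {}
    block_of_chrom: Dict[str, int] = {}
    peak_n = 0
    loop_n = 0

    for i, cls in enumerate(classes):
        chrom = f"chr{i % 5 + 1}"
        block = block_of_chrom.get(chrom, 0)
        block_of_chrom[chrom] = block + 1
        base = block * 1_000_000 + 100_000
        strand = "+" if rng.random() < 0.5 else "-"
        s = 1 if strand == "+" else -1
        tss = base + 50_000 + int(rng.integers(0, 10_000))
        gid = f"GENE{i + 1:05d}"

        def iv(lo: int, hi: int) -> Tuple[int, int]:
            a, b = tss + s * lo, tss + s * hi
            return (min(a, b), max(a, b))

        introns = sorted([iv(2_000, 4_000), iv(6_000, 9_000)])
        genes.append(GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                               tss=tss, introns=introns))
        truth[gid] = cls

        def add_peak(start: int, end: int) -> str:
            nonlocal peak_n
            peak_n += 1
            pid = f"peak{peak_n:05d}"
            peaks.append(Peak(peak_id=pid, chrom=chrom, start=start, end=end))
            return pid

        def add_loop(a: Tuple[int, int], b: Tuple[int, int]) -> str:
            nonlocal loop_n
            loop_n += 1
            lid = f"loop{loop_n:05d}"
            loops.append(Loop(loop_id=lid, chrom_a=chrom, anchor_a=a,
                              chrom_b=chrom, anchor_b=b))
            return lid

        if cls == "tss":
            gap = int(rng.integers(100, 800))
            side = -1 if rng.random() < 0.5 else 1
            start = tss + gap if side > 0 else tss - gap - 150
            add_peak(start, start + 150)
        elif cls == "intron":
            lo, hi = introns[0] if s > 0 else introns[-1]
            start = int(rng.integers(lo + 100, hi - 300))
            add_peak(start, start + 150)
        elif cls == "loop":
            anchor_a = (tss - 400, tss + 400)
            b0 = tss + 200_000
            anchor_b = (b0, b0 + 1_000)
            add_loop(anchor_a, anchor_b)
            gap = int(rng.integers(50, 450))
            add_peak(b0 + 1_000 + gap, b0 + 1_000 + gap + 150)
        else:  # none: decoy evidence that must not qualify
            d = tss + s * (10_000 + int(rng.integers(0, 2_000)))
            add_peak(min(d, d + s * 150), max(d, d + s * 150))
            a0, b0 = tss + 300_000, tss + 500_000
            add_loop((a0, a0 + 1_000), (b0, b0 + 1_000))
        # Background volume: one far-away peak per gene, harmless to all rules.
        far = tss + 400_000 + int(rng.integers(0, 5_000))
        add_peak(far, far + 150)

    gene_ids = [g.gene_id for g in genes]
    return GenomicFixture(genes=genes, peaks=peaks, loops=loops,
                          de_genes=gene_ids, truth_labels=truth)


# --------------------------------------------------------------------------
# Abundance tables
# --------------------------------------------------------------------------

def make_abundance_table(
    n_proteins: int,
    n_channels: int = 16,
    planted_up: int = 10,
    planted_down: int = 5,
    seed: int = 0,
    fold_change: float = 1.5,
    noise_sd: float = 0.1,
    loading_sd: float = 0.25,
    n_group_a: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """TMT-like protein x channel abundance table with planted fold changes.

    Channels split into a control group (first ``n_group_a`` channels,
    default 10 of 16) and a comparison group. Planted-up proteins carry a
    ``fold_change`` (> 1.25) multiplier in the comparison group, planted-down
    proteins the reciprocal. Log-normal measurement noise (``noise_sd`` on
    the natural-log scale) and per-channel loading factors (unequal column
    sums) are applied; with ``noise_sd = 0`` realised between-group ratios
    equal the planted values exactly, up to one normalisation factor shared
    by every protein (the planted effects themselves shift the column sums).

    Returns (table, truth) where truth lists each protein's direction
    (up / down / null) and planted fold change.
    """
    if planted_up + planted_down > n_proteins:
        raise ValueError("more planted effects than proteins")
    if n_channels < 4:
        raise ValueError("need at least 4 channels (2 per group)")
    if fold_change <= 1:
        raise ValueError("fold_change must exceed 1")
    n_a = n_group_a if n_group_a is not None else max(2, int(round(n_channels * 10 / 16)))
    if not (2 <= n_a <= n_channels - 2):
        raise ValueError("each group needs at least 2 channels")

    rng = np.random.default_rng(seed)
    proteins = [f"P{i + 1:05d}" for i in range(n_proteins)]
    channels = [f"ch{j + 1:02d}" for j in range(n_channels)]
    base = rng.lognormal(mean=8.0, sigma=1.0, size=n_proteins)

    effect = np.ones(n_proteins)
    direction = np.array(["null"] * n_proteins, dtype=object)
    idx = rng.permutation(n_proteins)
    up_idx, down_idx = idx[:planted_up], idx[planted_up:planted_up + planted_down]
    effect[up_idx] = fold_change
    effect[down_idx] = 1.0 / fold_change
    direction[up_idx] = "up"
    direction[down_idx] = "down"

    group = np.array(["a"] * n_a + ["b"] * (n_channels - n_a))
    loading = rng.lognormal(mean=0.0, sigma=loading_sd, size=n_channels)
    mat = np.empty((n_proteins, n_channels))
    for j in range(n_channels):
        mu = base * np.where(group[j] == "b", effect, 1.0)
        noise = (
            rng.lognormal(mean=0.0, sigma=noise_sd, size=n_proteins)
            if noise_sd > 0 else 1.0
        )
        mat[:, j] = mu * noise * loading[j]

    table = pd.DataFrame(mat, index=proteins, columns=channels)
    table.index.name = "protein"
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "direction": direction,
            "planted_fold_change": effect,
        }
    )
    return table, truth


def channel_groups(table: pd.DataFrame, n_group_a: Optional[int] = None) -> Dict[str, str]:
    """Default channel -> group map matching :func:`make_abundance_table`."""
    n_channels = table.shape[1]
    n_a = n_group_a if n_group_a is not None else max(2, int(round(n_channels * 10 / 16)))
    return {
        str(c): ("a" if j < n_a else "b") for j, c in enumerate(table.columns)
    }
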