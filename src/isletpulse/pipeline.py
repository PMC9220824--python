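"""End-to-end analyses composed from the library stages, plus file-based
runners with provenance manifests.

Three analyses mirror the study designs:

* **duty cycle** — ratio -> detrend -> segment -> per-islet duty cycles,
  by-animal means, per-group 4PL dose-response fits compared by the extra
  sum-of-squares F test, and a two-way (group x concentration) ANOVA with
  Šidák post tests on the by-islet values;
* **AUC** — segment -> baseline-referenced AUC per islet and segment, with
  one- or two-way ANOVA and Tukey or Šidák post tests;
* **target calling** — interval rules over gene models, peaks and loops.

Every runner writes a manifest (resolved parameters, input checksums,
package version, seed) sufficient to re-run the analysis; outputs are
byte-reproducible for fixed inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .doseresponse import DoseResponseFit, FTestResult, compare_fits_ess, fit_4pl
from .genomic import (
    TargetParams, call_targets, calls_to_frame, read_bed, read_bedpe,
    read_de_list, read_genes_tsv, read_ortholog_map, summarize_calls,
)
from .oscillations import (
    AUCRecord, OscillationParams, detect_oscillations, duty_cycle, segment_auc,
)
from .preprocess import compute_ratio, demultiplex_animals, detrend, segment
from .stats import PosthocResult, anova_posthoc
from .traces import Protocol, TraceSet

FLOAT_FMT = "%.10g"


class OscillationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    smooth_s: float = 12.0
    elevation_fraction: float = 0.5
    min_amplitude: float = 0.2
    min_cycle_s: float = 30.0
    min_peak_s: float = 6.0
    floor_q: float = 0.08
    ceiling_q: float = 0.98

    def to_params(self) -> OscillationParams:
        return OscillationParams(**self.model_dump())


class RunConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected and
    the resolved defaults are embedded in the output manifest."""

    model_config = ConfigDict(extra="forbid")

    traces_csv: Optional[str] = None
    protocol_json: Optional[str] = None
    membership_tsv: Optional[str] = Field(
        default=None,
        description="TSV with roi_id, animal, group columns; if absent, "
        "ROIs are demultiplexed from the infrared channel into demux_labels",
    )
    genes_tsv: Optional[str] = None
    peaks_bed: Optional[str] = None
    loops_bedpe: Optional[str] = None
    de_tsv: Optional[str] = None
    ortholog_tsv: Optional[str] = None
    abundance_tsv: Optional[str] = None
    groups_tsv: Optional[str] = None

    outdir: str = "results"
    seed: int = 0
    demux_labels: Tuple[str, str] = ("control", "knockout")
    detrend_window_s: float = 600.0
    detrend_quantile: float = 0.08
    oscillation: OscillationSettings = Field(default_factory=OscillationSettings)
    baseline_segment: Optional[str] = None
    posthoc: str = "sidak"
    tss_bp: int = 1000
    loop_bp: int = 500
    loop_tss_bp: Optional[int] = None
    fc_threshold: float = 1.25
    alpha: float = 0.05
    write_plots: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(config: RunConfig, outdir: Path, stage: str,
                    inputs: Mapping[str, Optional[str]]) -> None:
    manifest = {
        "stage": stage,
        "package": "isletpulse",
        "version": __version__,
        "seed": config.seed,
        "parameters": json.loads(config.model_dump_json()),
        "inputs": {
            k: {"path": str(v), "sha256": _sha256(v)}
            for k, v in inputs.items() if v is not None
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def membership_from_traces(
    traces: TraceSet, labels: Tuple[str, str]
) -> pd.DataFrame:
    """Resolve ROI -> (animal, group) from metadata or by demultiplexing."""
    meta = traces.metadata
    if "true_animal_of" in meta and "group_of" in meta:
        rows = [
            {"roi_id": roi, "animal": meta["true_animal_of"][roi],
             "group": meta["group_of"][roi]}
            for roi in traces.rois
        ]
        return pd.DataFrame(rows)
    demuxed = demultiplex_animals(traces, labels)
    rows = [
        {"roi_id": roi, "animal": demuxed.animal_of[roi],
         "group": demuxed.animal_of[roi]}
        for roi in traces.rois
    ]
    return pd.DataFrame(rows)


@dataclass
class DutyAnalysisResult:
    records: pd.DataFrame        # per (islet, segment)
    animal_means: pd.DataFrame   # per (animal, segment)
    fits: Dict[str, DoseResponseFit]
    f_test: Optional[FTestResult]
    posthoc: Optional[PosthocResult]


def analyze_duty_cycle(
    traces: TraceSet,
    protocol: Protocol,
    membership: pd.DataFrame,
    params: OscillationParams = OscillationParams(),
    detrend_window_s: float = 600.0,
    detrend_quantile: float = 0.08,
) -> DutyAnalysisResult:
    """Per-islet duty cycles, by-animal 4PL dose-response fits, and the
    group comparison (extra sum-of-squares F test plus two-way ANOVA with
    Šidák post tests on by-islet values)."""
    traces = compute_ratio(traces)
    traces = detrend(traces, window_s=detrend_window_s, quantile=detrend_quantile)
    windows = segment(traces, protocol)
    info = membership.set_index("roi_id")

    rows = []
    for roi in traces.rois:
        if roi not in info.index:
            raise KeyError(f"roi {roi!r} missing from membership table")
        animal = str(info.loc[roi, "animal"])
        group = str(info.loc[roi, "group"])
        prev_threshold = None
        for w in windows:
            osc, state, diag = detect_oscillations(
                w.time, w.roi(roi), params, plateau_reference=prev_threshold
            )
            if diag["threshold"] is not None:
                prev_threshold = diag["threshold"]
            rec = duty_cycle(osc, state, roi=roi, animal=animal, group=group,
                             segment=w.label, concentration=w.concentration)
            rows.append(vars(rec))
    records = pd.DataFrame(rows)

    animal_means = (
        records.groupby(["group", "animal", "segment", "concentration"],
                        observed=True, as_index=False)["duty_cycle"]
        .mean()
        .sort_values(["group", "animal", "concentration"])
        .reset_index(drop=True)
    )

    fits: Dict[str, DoseResponseFit] = {}
    for group, grp in animal_means.groupby("group", observed=True):
        fits[str(group)] = fit_4pl(grp["concentration"], grp["duty_cycle"])

    f_test = None
    groups = sorted(fits)
    if len(groups) == 2:
        a = animal_means[animal_means.group == groups[0]]
        b = animal_means[animal_means.group == groups[1]]
        f_test, ess_fits = compare_fits_ess(
            a["concentration"], a["duty_cycle"], b["concentration"], b["duty_cycle"]
        )
        fits[groups[0]] = ess_fits["a"]
        fits[groups[1]] = ess_fits["b"]

    posthoc = None
    if len(groups) >= 2 and records["concentration"].nunique() >= 2:
        posthoc = anova_posthoc(records, "duty_cycle",
                                ["group", "concentration"], posthoc="sidak")
    return DutyAnalysisResult(records=records, animal_means=animal_means,
                              fits=fits, f_test=f_test, posthoc=posthoc)


@dataclass
class AUCAnalysisResult:
    records: pd.DataFrame
    baseline: pd.Series
    posthoc: Optional[PosthocResult]


def analyze_auc(
    traces: TraceSet,
    protocol: Protocol,
    membership: pd.DataFrame,
    baseline_segment: Optional[str] = None,
    posthoc: str = "sidak",
    use_positive: bool = False,
) -> AUCAnalysisResult:
    """Baseline-referenced AUC per (islet, segment) with group statistics.

    ``baseline_segment`` (default: the first segment) provides each ROI's
    baseline value (its mean over that window); AUCs are reported for the
    remaining segments. Two groups x several segments are tested by two-way
    ANOVA with Šidák post tests per segment (or Tukey over groups after a
    one-way ANOVA when only one non-baseline segment exists).
    """
    traces = compute_ratio(traces)
    windows = segment(traces, protocol)
    labels = [w.label for w in windows]
    ref_label = baseline_segment if baseline_segment is not None else labels[0]
    if ref_label not in labels:
        raise ValueError(f"baseline segment {ref_label!r} not in protocol")
    ref = next(w for w in windows if w.label == ref_label)
    baseline = ref.data.mean(axis=0)
    info = membership.set_index("roi_id")

    rows = []
    for w in windows:
        if w.label == ref_label:
            continue
        for roi, y in w.iter_rois():
            rec = segment_auc(w.time, y, float(baseline[roi]), roi=roi,
                              group=str(info.loc[roi, "group"]), segment=w.label)
            rows.append(vars(rec))
    records = pd.DataFrame(rows)
    if use_positive:
        records["value"] = records["auc_positive"]
    else:
        records["value"] = records["auc"]

    ph = None
    if records["group"].nunique() >= 2:
        if records["segment"].nunique() >= 2:
            # Tukey post tests follow a one-way design; multi-segment
            # two-group comparisons use Šidák after the two-way ANOVA.
            ph = anova_posthoc(records, "value", ["group", "segment"],
                               posthoc="sidak")
        else:
            ph = anova_posthoc(records, "value", ["group"], posthoc=posthoc)
    return AUCAnalysisResult(records=records, baseline=baseline, posthoc=ph)


# --------------------------------------------------------------------------
# File-based runners
# --------------------------------------------------------------------------

def _fit_to_dict(fit: DoseResponseFit) -> dict:
    return {
        "bottom": fit.bottom, "top": fit.top, "ec50": fit.ec50, "hill": fit.hill,
        "rss": fit.rss, "df": fit.df, "n_points": fit.n_points,
        "converged": fit.converged,
    }


def run_duty_cycle_analysis(config: RunConfig) -> DutyAnalysisResult:
    """Load traces + protocol, run the duty-cycle analysis, write a result
    bundle (per-islet TSV, per-animal TSV, fit/F-test JSON, post-hoc TSV,
    manifest) under ``config.outdir``."""
    if not config.traces_csv or not config.protocol_json:
        raise ValueError("duty-cycle analysis requires traces_csv and protocol_json")
    traces = TraceSet.read_tidy_csv(config.traces_csv)
    protocol = Protocol.from_json(config.protocol_json)
    if config.membership_tsv:
        membership = pd.read_csv(config.membership_tsv, sep="\t")
    else:
        membership = membership_from_traces(traces, config.demux_labels)

    result = analyze_duty_cycle(
        traces, protocol, membership,
        params=config.oscillation.to_params(),
        detrend_window_s=config.detrend_window_s,
        detrend_quantile=config.detrend_quantile,
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "duty_cycle_by_islet.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT)
    result.animal_means.to_csv(outdir / "duty_cycle_by_animal.tsv", sep="\t",
                               index=False, float_format=FLOAT_FMT)
    fits = {g: _fit_to_dict(f) for g, f in result.fits.items()}
    (outdir / "dose_response_fits.json").write_text(
        json.dumps(fits, indent=2, sort_keys=True) + "\n"
    )
    if result.f_test is not None:
        (outdir / "f_test.json").write_text(
            json.dumps(result.f_test._asdict(), indent=2, sort_keys=True) + "\n"
        )
    if result.posthoc is not None:
        result.posthoc.comparisons.to_csv(outdir / "posthoc.tsv", sep="\t",
                                          index=False, float_format=FLOAT_FMT)
    _write_manifest(config, outdir, "duty_cycle", {
        "traces": config.traces_csv, "protocol": config.protocol_json,
        "membership": config.membership_tsv,
    })
    return result


def run_auc_analysis(config: RunConfig) -> AUCAnalysisResult:
    """Load traces + protocol, run the AUC analysis, write the bundle."""
    if not config.traces_csv or not config.protocol_json:
        raise ValueError("AUC analysis requires traces_csv and protocol_json")
    traces = TraceSet.read_tidy_csv(config.traces_csv)
    protocol = Protocol.from_json(config.protocol_json)
    if config.membership_tsv:
        membership = pd.read_csv(config.membership_tsv, sep="\t")
    else:
        membership = membership_from_traces(traces, config.demux_labels)

    result = analyze_auc(traces, protocol, membership,
                         baseline_segment=config.baseline_segment,
                         posthoc=config.posthoc)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(outdir / "auc_by_islet.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT)
    if result.posthoc is not None:
        result.posthoc.comparisons.to_csv(outdir / "auc_posthoc.tsv", sep="\t",
                                          index=False, float_format=FLOAT_FMT)
    _write_manifest(config, outdir, "auc", {
        "traces": config.traces_csv, "protocol": config.protocol_json,
        "membership": config.membership_tsv,
    })
    return result


def run_target_calling(config: RunConfig):
    """Read genomic inputs, call targets, write the call table and summary."""
    for field_name in ("genes_tsv", "de_tsv"):
        if not getattr(config, field_name):
            raise ValueError(f"target calling requires {field_name}")
    genes = read_genes_tsv(config.genes_tsv)
    peaks = read_bed(config.peaks_bed) if config.peaks_bed else []
    loops = read_bedpe(config.loops_bedpe) if config.loops_bedpe else []
    de = read_de_list(config.de_tsv)
    if config.ortholog_tsv:
        ortho = read_ortholog_map(config.ortholog_tsv)
        de = [ortho.get(g, g) for g in de]
    params = TargetParams(tss_bp=config.tss_bp, loop_bp=config.loop_bp,
                          loop_tss_bp=config.loop_tss_bp)
    calls = call_targets(genes, peaks, loops, de, params)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls_to_frame(calls).to_csv(outdir / "target_calls.tsv", sep="\t", index=False)
    summary = summarize_calls(calls)
    known = {c.gene_id for c in calls}
    summary["unknown_de_ids"] = sorted(set(de) - known)
    (outdir / "target_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(config, outdir, "targets", {
        "genes": config.genes_tsv, "peaks": config.peaks_bed,
        "loops": config.loops_bedpe, "de": config.de_tsv,
        "orthologs": config.ortholog_tsv,
    })
    return calls, summary


def run_abundance_screen(config: RunConfig):
    """Read an abundance TSV (+ channel-group TSV), run the screen, write
    the normalised tables and hit lists."""
    from .stats import abundance_screen

    if not config.abundance_tsv or not config.groups_tsv:
        raise ValueError("abundance screen requires abundance_tsv and groups_tsv")
    table = pd.read_csv(config.abundance_tsv, sep="\t", index_col=0)
    gmap = pd.read_csv(config.groups_tsv, sep="\t")
    groups = {str(r[0]): str(r[1]) for r in gmap.itertuples(index=False)}
    result = abundance_screen(table, groups, fc_threshold=config.fc_threshold,
                              alpha=config.alpha)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(outdir / "screen_results.tsv", sep="\t",
                          index=False, float_format=FLOAT_FMT)
    result.relative_abundance.to_csv(outdir / "relative_abundance.tsv", sep="\t",
                                     float_format=FLOAT_FMT)
    (outdir / "screen_summary.json").write_text(
        json.dumps({"n_up": len(result.up), "n_down": len(result.down),
                    "up": result.up, "down": result.down},
                   indent=2, sort_keys=True) + "\n"
    )
    _write_manifest(config, outdir, "screen", {
        "abundance": config.abundance_tsv, "groups": config.groups_tsv,
    })
    return result
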