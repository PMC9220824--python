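# Methods

Model assumptions, parameter defaults and numerical choices, module by
module. All trace times are seconds; glucose concentrations are mM;
genomic coordinates are 0-based half-open on the `+`-strand reference.

## 1. Synthetic recordings (`isletpulse.synthetic`)

### Signal model for glucose-ramp traces

Each islet's ratiometric Ca²⁺ signal in a segment at concentration *c* is

```
ratio(t) = baseline + amplitude · burst(t; period, duty(c)) + drift·t + ε(t)
```

* `duty(c)` follows a group-specific 4PL of concentration (below), clipped
  to [0, 1].
* `burst` is a sigmoid-edged rectangular burst train, not a mechanistic
  β-cell model. The downstream statistic (duty cycle) depends only on the
  fraction of time spent elevated, so plateau/baseline structure is
  sufficient; waveform shape within the plateau is irrelevant to every
  estimator in the package.
* `ε(t)` is i.i.d. Gaussian frame noise. Temporal noise correlation is not
  modelled; the estimator's 3-frame smoothing and quantile thresholds do
  not rely on whiteness, so this is a convenience, not a requirement.

**Frame-grid dithering.** A single 120 s cycle sampled at 6 s frames can
only realise duties on a 1/20 grid, which biases the *planted* curve before
any estimator runs (naive per-cycle rounding shifted the apparent EC50 by
about −7 %). The generator therefore assigns each cycle's on-frame count by
cumulative rounding (Bresenham), so the mean duty over *k* cycles is exact
to 1/(20·k). The truth table reports the **realised** duty over the
complete cycles inside the analysis window (cycles overlapping the
equilibration lag are excluded), which is what an ideal estimator of the
emitted waveform would measure.

**Channels.** `ratio` is the clean signal plus noise; `ex500 = ratio ·
bleach(t)` and `ex430 = bleach(t)` with `bleach(t) = exp(−t/bleach_tau)`,
so the excitation quotient reproduces `ratio` exactly and the common bleach
factor cancels — the property the ratiometric preprocessing step is meant
to exploit. `infrared` is a constant-per-islet label drawn from one of two
log-normal modes (animal-batch encoding) plus 2 % multiplicative jitter.

### Parameters (`TraceSimConfig` defaults)

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `frame_interval` | 6 | s | typical slow-oscillation imaging rate |
| `segments` | 6 × 960 s at 3, 4.5, 6, 7.5, 8, 9 | s, mM | stepped ramp spanning the sigmoid's rise |
| `period` | 120 | s | slow islet Ca²⁺ oscillation period |
| `equilibration_lag_s` | 60 | s | settling time after each concentration switch, excluded from analysis and from the truth |
| `baseline`, `amplitude` | 1.0, 0.5 | ratio units | elevated phase well separated from baseline |
| `noise_sd` | 0.05 | ratio units | 10 % of amplitude — visible but not dominant |
| `drift_slope` | 2 × 10⁻⁵ | ratio units/s | ≈ 0.12 over a 96-min recording, comparable to the signal amplitude's quarter |
| `bleach_tau` | 7200 | s | slow photobleach of the raw excitation channels |
| `infrared_modes`, `infrared_cv` | (1, 20), 0.2 | – | clearly bimodal label with realistic spread |
| `dose_response_truth` | control EC50 7.5, knockout 6.0; bottom 0.05, top 0.9, hill 5 | mM | left-shifted knockout: the study contrast |

### Plateau-response traces

Saturating rise `baseline + A·(1 − exp(−t/τ))` per segment with τ = 30 s
(`rise_tau`), per-group planted amplitudes, Gaussian noise. The truth AUC
is the closed-form integral of the noise-free response over the span the
frame grid actually samples, so a trapezoidal estimate on the noise-free
trace matches it up to curvature-level discretisation error (≲ 0.5
ratio·s at the defaults).

### Genomic fixtures and abundance tables

`make_genomic_fixture` plants one regulatory class per DE gene — `tss`
(peak within 1 kb of the TSS), `intron` (≥ 1 bp overlap with an intron),
`loop` (peak at a distal loop anchor whose other anchor lies near the TSS),
or `none` (all evidence placed beyond the thresholds) — with decoy peaks
and loops, gene spacing wide enough that planted evidence cannot leak onto
a neighbour.

`make_abundance_table` draws log-normal protein intensities, applies
planted fold changes to group-B channels, then multiplies each channel by a
deliberate loading factor (0.7–1.4). With `noise_sd = 0` the realised
between-group ratios equal the planted values up to one normalisation
constant shared by every protein, because the planted effects themselves
shift the column sums.

## 2. Preprocessing (`isletpulse.preprocess`)

* **Ratio**: `ex500 / ex430` elementwise; zero or non-finite denominators
  raise with the ROI and frame named. Passthrough if `ratio` exists.
* **Demultiplexing**: 2-means split of per-ROI median infrared levels on a
  log scale; requires the two centres to be separated by more than twice
  the pooled within-cluster spread, otherwise the channel is declared
  unimodal and the caller must supply an explicit membership table.
* **Detrending**: centred rolling low-quantile (default 8th percentile over
  600 s) is subtracted and its median added back, so the absolute scale is
  preserved. The window should exceed twice the oscillation period (the
  default is five periods) so every window samples inter-burst troughs and
  the baseline tracks drift, not the oscillations; the 8th percentile sits
  below the troughs even at high duty. Near the recording edges the
  baseline is extended by straight-line extrapolation of its local trend,
  so a purely linear drift detrends to an exact constant.
* **Segmentation**: half-open windows `[start + lag, end)` on the frame
  grid — a frame at exactly the boundary belongs to the next segment, so
  segments partition the recording with no frame counted twice.

## 3. Duty cycle (`isletpulse.oscillations`)

States: **silent** (duty 0) when the window's robust range
(q98 − q08 of the smoothed trace) is below `min_amplitude`; **plateau**
(duty 1) when that range is small but the floor sits above the previous
segment's elevation threshold (saturated signal, chained via diagnostics);
otherwise **oscillating**.

For oscillating windows the estimator is a hybrid:

1. **Cycle location on a smoothed trace** (12 s ≈ 3-frame moving average):
   threshold = floor + 0.5·(ceiling − floor) from smoothed quantiles; runs
   of supra-threshold frames ≥ `min_peak_s` (6 s = one frame) become
   candidate cycles. Smoothing suppresses single-frame noise crossings.
2. **Widths and onsets on the raw trace**, with a threshold placed from the
   *raw* trace's own quantile range. Rationale: the moving average shrinks
   the apparent dynamic range when elevated phases are short (a 1-frame
   peak smooths to a third of its height), which would drop a
   smoothed-range threshold into the noise band; and smoothed shoulders can
   tie the threshold exactly, shifting onsets a frame early. The raw
   plateau/baseline separation is sharp, so counting elevated frames on the
   raw trace within each smoothed-located cycle is unbiased.
3. **Bases** run from one cycle's raw onset to the next cycle's raw onset;
   the last base closes at the window end (last frame + dt), consistent
   with half-open frame semantics. A run already elevated at the window's
   first frame is a clipped cycle whose onset was not observed; when other
   cycles are present it is dropped rather than measured with an arbitrary
   base start.
4. Cycles with a footprint shorter than `min_cycle_s` (30 s) merge into
   their neighbour, so a brief mid-plateau dip does not split one cycle
   into two.

The segment duty cycle is Σ peak widths / Σ base widths (ratio of sums) —
the pooled-time estimator, which weights long cycles proportionally and is
what frame counting converges to; the mean of per-cycle ratios is reported
alongside. Resolution limit: at the defaults a true duty of 0.05 is a
single elevated frame per cycle; in a noise-free trace it can fall below
threshold and read silent (error 0.05). With default noise the planted
0.05 is recovered to ≈ 0.015 mean absolute error.

**AUC** is the net trapezoidal integral of (signal − baseline reference)
over the segment, negative excursions included; the positive-only integral
is reported alongside. The baseline reference is the mean of a designated
reference segment.

## 4. Dose–response statistics (`isletpulse.doseresponse`, `isletpulse.stats`)

**4PL**: `y = bottom + (top − bottom)/(1 + (ec50/x)^hill)`, so
`y(ec50) = (bottom + top)/2` exactly and `x → 0` gives `bottom`. Fitting is
bounded trust-region least squares with multi-start initialisation (hill ∈
{1, 3, 6} × ec50 at the 25/50/75 % concentration quantiles; tolerances
1e-14) taking the lowest RSS; ec50 is constrained to [min(x)/3, 3·max(x)].
Flat responses are returned flagged (`converged=False`, hill = NaN) rather
than raising. Requires ≥ 5 points over ≥ 3 distinct positive
concentrations.

**Extra sum-of-squares F test**: shared fit to pooled points vs separate
fits per group; `F = ((SS_sh − SS_sep)/(df_sh − df_sep)) / (SS_sep/df_sep)`
with `df = n − 4` and `n − 8`. Each fit is cross-seeded with the others'
solutions so the nesting `SS_shared ≥ SS_separate` holds at the optima
found (a shared-curve local optimum can otherwise beat two poorly
initialised separate fits). The unit of analysis is the **animal** (islets
within an animal are averaged first): islets from one animal are not
independent, and the F test's degrees of freedom assume independent
points. Calibration at the defaults: type-I error 0.043 over 1000
shared-truth replicates; power 1.0 for the planted 7.5 → 6.0 mM shift.

**Post tests**: Šidák `p_adj = 1 − (1 − p)^m` (independent or positively
dependent comparisons; exact closed form), Tukey HSD via the studentized
range for all-pairwise one-factor comparisons, Benjamini–Hochberg for the
large-m abundance screen where FDR, not FWER, is the relevant control.

**Abundance screen**: channel (column) normalisation to a common sum →
per-protein scaling to relative abundance summing to 100 → Welch's t on
log relative abundances (unequal variances expected between groups) → BH.
Hits require fold change > 1.25 (or < 1/1.25) at adjusted p < 0.05 — the
fold-change gate suppresses statistically significant but biologically
trivial shifts.

## 5. Target calling (`isletpulse.genomic`)

All coordinates 0-based half-open; the gap between intervals is the number
of bases strictly between them (adjacent intervals have gap 0 and do not
overlap; overlap is gap −1 by convention, reported as 0 distance). Rules,
in the order tested (a gene can carry several categories):

* **tss** — peak gap to the TSS point ≤ 1000 bp (`tss_bp`, inclusive).
* **intron** — peak overlaps an intron by ≥ 1 bp. Introns are derived from
  the exon structure; touching (gap 0) does not count.
* **loop** — one loop anchor's gap to the TSS ≤ `tss_bp` and a peak's gap
  to *either* anchor ≤ 500 bp (`loop_bp`); `other_anchor_only=True`
  restricts to the distal anchor. Anchors on a different chromosome from
  the gene are ignored.

Queries run on interval trees widened by 1 bp so threshold-equal gaps are
found; every candidate is then re-checked with exact gap arithmetic, so the
widening cannot admit false positives. The test suite compares the caller
to an independent brute-force quadratic scan (`tests/_oracles.py`) and
requires exact agreement.

## 6. Pipeline and CLI (`isletpulse.pipeline`, `isletpulse.cli`)

Stage order for ramp recordings: ratio → demultiplex (or explicit
membership) → detrend → segment → per-islet duty cycles → per-animal means
→ per-group 4PL fits → F test → post tests. Outputs are TSV/JSON under a
run directory with a `manifest.json` recording the package version, the
effective configuration and SHA-256 digests of inputs and outputs. All
randomness flows from a single integer seed per run; derived seeds are
produced with `numpy.random.SeedSequence` and kept below 2³¹.

## Limitations

* The burst-train generator validates the estimators, not β-cell
  biophysics: no electrical bursting substructure, no amplitude adaptation,
  no cross-islet synchrony, no missing frames.
* Duty-cycle resolution is bounded by the frame grid (one frame per cycle
  = 0.05 at the defaults); sub-frame duties are not observable.
* The F test compares full curves; it does not attribute a difference to a
  specific parameter (a top-asymptote change and an EC50 shift both
  reject). Parameter-wise confidence intervals are out of scope.
* The demultiplexer assumes exactly two animal batches with well-separated
  infrared labels; more than two batches requires an explicit membership
  table.
* Target calling is rule-based evidence aggregation, not a probabilistic
  model; thresholds (1 kb, 500 bp) are conventions, and calls are
  "putative direct targets", not causal claims.
* BH control in the abundance screen assumes the planted-null majority;
  with many true effects the realised FDR is conservative.
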