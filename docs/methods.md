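# Methods

This document describes the computational models implemented in `cmbeat`, the
rationale behind every default parameter, what the synthetic-data generator
does and does not emulate, and the numerical choices that make the results
exactly reproducible.

## 1. Motion estimation (block matching)

### Model

Brightfield videos of a beating cardiomyocyte monolayer show texture that is
displaced by contraction. Motion between consecutive frames `k -> k+1` is
estimated by exhaustive block matching:

- Each frame is divided into square blocks of `N x N` pixels
  (`block_size_px`, default 16). The grid is re-anchored at the frame origin
  for every frame pair; grid dimensions are `floor(H/N) x floor(W/N)`.
- For each block, every integer displacement `(dx, dy)` with
  `|dx|, |dy| <= w` (`search_radius_px`, default 4) is scored with the Mean
  Absolute Difference (MAD) between the reference block in frame `k` and the
  candidate block in frame `k+1`. Candidates that would read outside the
  frame are excluded (the search window is clipped at borders).
- The displacement with the minimum MAD wins. Ties are broken
  deterministically: smallest `dx^2 + dy^2` first, then lexicographically by
  `(dy, dx)`. The zero displacement is therefore preferred on flat or
  ambiguous content.
- Blocks whose intensity standard deviation falls below `min_block_std`
  (default `1e-6`) are masked invalid: MAD is degenerate on flat blocks
  (every offset ties at the same score) and background must not dilute
  motion aggregates.

Coordinates follow image convention: `x` = column index increasing
rightward, `y` = row index increasing downward; `(dx, dy)` means the block
content of frame `k` is found at `origin + (dx, dy)` in frame `k+1`.
Displacements are whole-pixel only; sub-pixel refinement is deliberately out
of scope.

### Defaults

`block_size_px = 16`, `search_radius_px = 4`: a 16-px block comfortably
contains several texture grains (the synthetic texture default is 8 px), and
a +/-4 px window covers the default 3-px beat amplitude with margin. Both are
config-overridable; the generator validates `amplitude_px` against frame
size, and recovery tests keep amplitude within the search radius.

### Implementation

Two engines emit bit-identical results:

- `engine="numpy"`: for each candidate offset, the MAD of all blocks is
  computed vectorized; the running minimum with first-occurrence semantics
  reproduces the tie-break order because candidates are visited sorted by
  `(norm^2, dy, dx)`.
- `engine="numba"` (preferred by `engine="auto"` when numba imports): a
  compiled per-block branch-and-bound scan. Candidates are visited in the
  same tie-break order; the running per-pixel sum is abandoned only when it
  strictly exceeds the current best, which cannot change the argmin.

Equivalence of both engines against a brute-force oracle is part of the test
suite (50 random textured pairs; `tests/test_acceptance.py`).

## 2. Motion trace and beat metrics

### Motion trace

For each frame pair the mean displacement magnitude over valid blocks is
converted to a speed: `mean(hypot(dx, dy)) * pixel_size_um * frame_rate_hz`
(micrometers per second). Samples are placed at frame-pair midpoints
`(k + 0.5) / fps`. The trace also carries the conversion factor
`um_s_per_px_frame = pixel_size_um * frame_rate_hz`, which anchors absolute
thresholds to the 1-pixel displacement quantum; traces not derived from
block matching leave it unset.

### Beat detection

Beats are prominent local maxima of the motion trace. The detector has four
stages, each with a documented reason:

1. **Smoothing.** The trace is boxcar-filtered over `smooth_s` (default
   0.25 s, `scipy.ndimage.uniform_filter1d`, mirror-edge padding so a large
   boundary sample is not replicated into the window).
   Block-matching noise is uncorrelated between frame pairs, while a beat's
   speed pulse spans many samples (about 9 at 30 fps with the default pulse
   width), so smoothing suppresses spurious single-sample prominences
   without moving genuine beats. Set `smooth_s = 0` to disable.
2. **Prominence.** Peaks on the smoothed trace must reach a prominence of
   `prominence_frac` (default 0.3) times the smoothed trace's dynamic range,
   defined as *maximum minus 5th percentile*. The reference deliberately
   uses the maximum rather than a high percentile: for slow beaters the
   beats occupy well under 5% of samples, and any inter-percentile span
   would only measure the inter-beat noise floor.
3. **Refinement and floors.** Each smoothed peak is mapped back to the
   raw-trace maximum within half a smoothing window, so reported beat times
   and heights always come from the raw trace (a tie between two equal raw
   peaks resolves to the earlier sample). Two filters then apply to the raw
   height:
   - an absolute floor of `min_peak_px_per_frame` (default 0.05 px per
     frame pair, converted through `um_s_per_px_frame`). Because block
     displacements are integers, stray single-block mismatches on a
     non-beating recording produce trace values of order `1/n_blocks`
     pixels; a genuine beat displaces a visible fraction of the grid at
     once. The floor is what lets an amplitude-zero control report "not
     beating" even though prominence alone is scale-free. It applies only
     to traces that carry the px conversion.
   - a height-consistency pass: every candidate must reach
     `height_consistency_frac` (default 0.5) of the *median* candidate
     height above the trace's 5th-percentile baseline. Genuine beats of one
     recording have similar peak speeds, while spurious noise prominences
     sit near the baseline; as long as spurious candidates are a minority,
     the median is anchored to the true beats. Limitation: a genuine beat
     whose peak speed is below half the median beat speed of the same
     recording is discarded. Set to 0 to disable.
4. **Refractory sweep.** Surviving peaks are swept in time order; a peak
   closer than `min_interbeat_s` (default 0.25 s, i.e. a 4 Hz ceiling) to
   the last kept one is dropped, so the earlier of two near-coincident
   peaks survives. This merges the contraction/relaxation speed-peak pair of
   a single beat into one event.

### Metrics

- `frequency_hz = (n - 1) / (t_last - t_first)` over detected beat times —
  the inverse mean inter-beat interval. This stays well defined for the few,
  irregular beats of aged cells where an FFT peak would smear. With fewer
  than two beats the frequency is 0 and `is_beating` is false (a single peak
  cannot define a period).
- `velocity_um_s`: mean over beats of the trace value at the beat peak (peak
  systolic aggregate speed).
- `max_displacement_px/_um`: maximum over frame pairs and valid blocks of
  the per-pair displacement magnitude.
- `beat_area_pct`: percentage of ever-valid blocks whose displacement
  amplitude (max magnitude over time) reaches `area_amp_frac` (default 0.2)
  of the largest per-block amplitude; 0% when nothing moves at all.
- Recovery after an insult divides each metric by its own-sample baseline
  value; a zero baseline leaves the ratio undefined rather than infinite.

## 3. Calcium transients

Raw fluorescence traces are normalized to `dF/F0` with
`F0 = percentile(values, 10)` — a robust quiescent-baseline estimate that
ignores the transient peaks. Transients are detected with the same
prominence and refractory rule as motion beats (dynamic range = max minus
5th percentile, refractory `min_interbeat_s`). The dF/F0 trace is *not*
smoothed: the generator's default trace SNR is about 100
(`amplitude_dff * baseline_f0 / noise_sd`), and the closed-form duration
tests depend on exact raw peak samples.

Per transient:

- **onset**: the last sample before the peak at or below 10% of the
  transient's amplitude above its local baseline (the dF/F0 minimum since
  the previous peak). The 10% convention means that for a linear upstroke of
  nominal rise time `ttp`, the detector measures `0.9 * ttp`; the synthetic
  ground truth exposes exactly this quantity (`ttp_from_10pct_s`).
- **ttp_s** = peak time − onset time.
- **apd50_s / apd90_s**: decay-referenced durations from the peak to the
  first crossing of `peak − 0.5 (resp. 0.9) x amplitude`, with the crossing
  linearly interpolated between bracketing samples. Interpolation removes
  sampling-grid quantization; for a pure exponential decay with time
  constant `tau`, `apd50 = tau ln 2`, `apd90 = tau ln 10`, and the
  triangulation ratio `apd90/apd50 = ln 10 / ln 2 ≈ 3.32`, which the test
  suite verifies to 3% across `tau` in `[0.1, 1.0]` s at >= 30 Hz sampling.
- A transient truncated before its 90% decay (end of recording or next
  transient) is excluded from apd90/triangulation with a logged warning.

Recording-level features are medians across transients (robust to
inconsistent peak shape); frequency uses the same `(n-1)/span` estimator
over peak times. The pre/post drug comparison reports absolute and percent
changes per feature and flags a responder when frequency increases by more
than `responder_freq_frac` (default 10%).

## 4. Synthetic data generator

The generator is the test bed standing in for unavailable recordings; its
defaults are the study conditions for the recovery analyses.

### Beating video

- **Texture**: seeded Gaussian white noise smoothed with
  `sigma = texture_grain_px / 2` (default grain 8 px, wrap mode), rescaled
  to mean 128 and SD `texture_contrast = 25`.
- **Motion**: displacement at frame `t`, pixel `(y, x)` is
  `amplitude_px * pulse(t) * envelope(y, x) * direction`, with a random unit
  `direction` per video. The envelope is a centered Gaussian bump
  (`sigma = min(H, W)/4` unless set) or uniform. `pulse` is a raised-cosine
  contraction-relaxation waveform of width `pulse_width_s = 0.3` s, one per
  beat; its speed profile has two humps 0.15 s apart, which the detector's
  0.25-s refractory merges into one event (the width was chosen so the humps
  sit inside the refractory window).
- **Beat times** are drawn with inter-beat coefficient of variation
  `irregularity` (default 0.05) around the period `1/f`, first beat at half
  a period; intervals are clipped below at `1.05 * pulse_width_s`.
- **Rendering**: inverse warping with bilinear interpolation
  (`scipy.ndimage.map_coordinates`, `order=1`, reflect mode) — forward
  splatting would leave holes. Gaussian pixel noise (`noise_sd = 2.5`,
  SNR = `texture_contrast / noise_sd` = 10) is added last. Frames are
  float32.
- **Ground truth** stores the realized beat times, the per-frame pulse
  values, envelope, and direction, so the exact displacement field applied
  at any frame can be materialized and compared (stored, not re-estimated).

Not emulated: photorealistic cell appearance, sarcomere mechanics,
electrophysiology, focal drift, photobleaching, illumination flicker, and
any biochemistry of hypoxia — experimental insults are represented only as
parameter shifts between timepoints.

### Calcium trace

dF/F0 rises linearly over `ttp_s` (default 0.3 s) to `amplitude_dff`
(default 2.0), then decays exponentially with `decay_tau_s` (default
0.4 s); raw signal `F = f0 (1 + dff)` plus Gaussian noise (`noise_sd = 2`
on `f0 = 100`). The config enforces `ttp + 3 tau < 1/f` so transients
resolve between beats. Default sampling is 33.3 Hz for 30 s (a 30-ms
exposure convention).

### Seeding

Per-sample seeds in batch generation derive from
`crc32(f"{master}:{label}:{index}") & 0x7FFFFFFF` — platform-stable
(Python's `hash` is salted per process) and below `2^31` so they are valid
NumPy seeds. Batches are therefore reproducible regardless of generation
order.

## 5. Statistics

- **Summaries**: per-group mean and sample SD (`ddof=1`); a single-value
  group reports SD 0.0 with its `n` making the zero width explicit.
- **One-way ANOVA** is computed from explicit sums of squares
  (`F = (SSB/df_b) / (SSW/df_w)`, p from the F survival function) rather
  than `scipy.stats.f_oneway`, for two reasons: degenerate inputs are given
  defined semantics (zero within-group variance with separated means gives
  `F = inf`, `p = 0.0`; all-constant data flags the result undefined instead
  of NaN), and the implementation can be checked against an independent
  sum-of-squares oracle to 1e-10.
- **Tukey HSD** uses `scipy.stats.tukey_hsd` (studentized range;
  Tukey-Kramer harmonic-mean adjustment for unbalanced groups), with a
  defined-degenerate guard for zero within-group variance. Significance is
  flagged at two-tailed `p < 0.05` on the unrounded value. No correction is
  applied across metrics — only the within-family Tukey adjustment — which
  mirrors per-panel testing and is a documented limitation.
- **Calibration** (test suite): under the null the ANOVA rejects at 0.05 in
  5% +/- 2% of 1000 seeded 3-group batches. For the three-group design with
  means 0.72/0.48/0.25 Hz and SDs 0.24/0.19/0.10 at n = 4, the extreme-pair
  Tukey contrast is significant in roughly three quarters of seeded batches
  (the suite brackets the rate in [0.60, 0.90]) and always at least as often
  as either adjacent pair — useful sensitivity, but far from certainty at
  n = 4.
- **Reports** serialize with sorted keys, fixed schema version, and no
  timestamps, so identical inputs produce byte-identical JSON.

## 6. Numerical and reproducibility choices

- Pixel intensities are handled as floats throughout regardless of source
  bit depth; color inputs are reduced by the unweighted channel mean.
- MAD uses float64 accumulation in both engines; engine equivalence is
  bit-exact because both follow the same candidate order and tie-breaks.
- Frequencies are never inferred from container metadata; the frame rate is
  always user-supplied.
- All JSON emitted by the CLI uses sorted keys; CSV floats use `%.17g`
  (round-trip exact for float64).
- Problem sizes: the full-size recovery runs use 256x256 videos at 30 fps
  for 30-40 s (900-1200 frames; a few seconds per video with the numba
  engine). The in-suite recovery test uses 128x128 frames to keep the suite
  fast; the tolerance is identical.

## 7. Limitations

- Integer displacements floor the measurable amplitude at 1 px; beats
  weaker than that are invisible to the motion trace.
- The frequency estimator assumes the detector finds almost all beats; with
  ~6 beats per recording a single missed or spurious beat shifts the
  estimate by ~20% (still within the absolute 0.05 Hz tolerance at 0.2 Hz).
- The height-consistency pass assumes beats of one recording have similar
  peak speeds and that spurious candidates are a minority.
- Calcium "APD" labels follow the conventional naming for calcium-transient
  durations; they are not electrophysiological action potentials.
- The statistics layer implements fixed-effects one-way designs only; no
  repeated-measures modeling of time courses.
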