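# Methods

## Signal model

The input is one foot's total vertical ground-reaction force sampled
nominally at 100 Hz by a pressure insole, in Newtons, with occasional
dropped samples. Stance phases appear as segments of sustained force
separated by near-zero swing phases. Forces routinely exceed body
weight at the load-bearing peaks because plantar pressure reflects
dynamic acceleration, not static weight.

## Stance segmentation

A stance event is a maximal run of readings strictly above 30 N
("above" is read literally: a reading of exactly 30 N is below). Runs of
up to 3 consecutive *missing values* inside an event are tolerated; 4 or
more terminate it. Missing values cover both absent timestamps
(recording dropouts, counted from the gap width at the nominal 10 ms
period) and sub-threshold readings — the two are not distinguishable in
effect and are counted against the same tolerance, also in mixed runs.
Tolerated sub-threshold samples are retained as ordinary samples (the
spline bridges them); absent timestamps stay absent. Events are trimmed
to start and end on an above-threshold sample, so a tolerated gap never
touches a boundary. Candidates shorter than 300 ms or longer than
2000 ms (first-to-last retained sample, bounds inclusive) are discarded
and logged with a reason. The segmentation is property-tested against a
brute-force run-length oracle on random threshold masks.

## Normalization

Each event's (timestamp, force/body-weight) points — true, possibly
non-uniform timestamps — are fitted with a natural cubic spline (second
derivative zero at both ends) and evaluated at 100 equidistant times
spanning [start, end] inclusive, one sample per percent of stance
duration. Body weight enters as `force_N / (weight_kg × 9.81)`; values
are stored as fractions (1.0 = body weight) although they are
conventionally reported as "%BW". Negative spline excursions are
clamped to zero. A smoothed copy is produced by convolution with a
sampled Gaussian kernel (σ = 3, 7 taps, normalized to sum 1; truncated
and renormalized at the boundaries so constants are preserved). The
smoothed copy is used **only** to localize extrema; every reported value
is read from the unfiltered curve. Whether smoothing should precede or
follow spline resampling is ambiguous in principle; smoothing the
100-sample curve is used here because index re-application requires a
common index space.

## Extremum cascade

Strict local extrema of the smoothed curve (interior indices only;
plateau points are never candidates) are disambiguated, when more than
the expected two maxima + one minimum appear, by four strategies in
order, each applied only while the set is still inconclusive:

1. *time plausibility* — candidates within the first or last 10 indices
   are eliminated;
2. *pool filtering* — same-polarity candidates chained by single-linkage
   with index gaps ≤ 5 form one pool; only the highest-force maximum /
   lowest-force minimum survives (ties → earlier index);
3. *monotony check* — candidates lacking a strictly monotone rise/fall
   over 5 indices on both sides are eliminated (runs truncated by the
   curve boundary cap the distance at the available length);
4. *monotony grace* — if step 3 left fewer than 2 maxima or fewer than
   1 minimum, its casualties are reinstated in descending order of their
   achieved monotony distance. Ties are broken by the stronger filtered
   force, then by the earlier index: with sensor noise, equal-distance
   ties regularly pit a rising-edge ripple against a genuine peak, and
   the earlier-index rule was measured to pick the ripple, inflating
   ordering rejections.

A stance is accepted only if exactly two maxima and one minimum survive
*and* the minimum lies strictly between the maxima. The ordering
requirement is a convention (the canonical M-shape implies it but it is
not forced by the candidate counts); it is a separately logged rejection
reason and can be disabled (`require_ordering=False` / `--no-ordering`).
Values are re-read from the unfiltered curve at the exact surviving
indices, without any local re-search.

## Parameters

All mean windows are inclusive of both endpoint indices ("between X and
Y" carries no half-open convention; the ≤ 1 % sensitivity is inside the
stated tolerances). The loading slope uses the first index from stance
start with a value ≥ 0.8·Fz2; the search starts at index 0, so a curve
already at that level at index 0 has an undefined loading slope — the
stance is flagged and only that parameter is missing, the other eight
are kept. Mirrored rules apply to the unloading slope (first index after
Fz4 below 0.8·Fz4; undefined if absent or equal to the last index).
Slopes multiply force by 100, giving percent body weight per percent
stance duration: peak forces are ≈ 1.2 in body-weight fractions while
slope magnitudes are ≈ 5–11, which is only consistent if force enters
the slope in percent.

## Slope statistics

Per-grade summaries pool both feet. Two pooling modes exist because
group summaries can be computed per-participant-first (default, matching
"averaged over all participants") or step-pooled; the reported means
agree in balanced designs. Each parameter's per-grade means are
expressed as percent of the 0 %-grade mean (plain division, so a
more-negative unloading slope maps above 100 %), and ordinary least
squares of that 9-point series on grade gives the slope, R², F and p
reported in the regression table. R² is defined as 0 when the response
variance is 0. A separate per-step regression ANOVA (value on grade,
all accepted steps) reproduces the qualitative significance pattern;
the significance threshold is 0.05 and no multiple-testing correction
is applied. The published regression table is reproduced from the nine
per-grade means, not from per-step data.

## Synthetic sessions

The generator emits raw series whose accepted-stance parameter
distributions match the reference per-grade means/SDs. Key design
elements, each chosen once:

- **Template.** Each stance is a monotone-shape-preserving cubic
  (PCHIP) through anchor points: boundary levels at 0.09 BW (safely
  above the 30 N threshold for the supported ≥ 45 kg body weights),
  pinned 80 %-crossing anchors straddling the crossing level by
  ±0.02 BW at integer grid indices (so the crossing rule lands on the
  intended index even under noise), symmetric guard anchors ±3 % of
  stance duration around each extremum (8 % of the local peak-to-valley
  range deep, keeping the smoothed peak centered and its monotony
  intact under noise), and free "shoulder" control points.
- **Geometry calibration.** The nine per-grade targets over-determine a
  naive five-anchor curve: the slope targets pin the crossing indices
  and, jointly with the four window means, the peak positions. Peak
  positions near 0.25/0.75 of stance are infeasible for the steepest
  grades (the loading-window mean cannot reach its target), so the peak
  positions and shoulder levels are solved per grade by least squares
  against a smooth window-mean approximation, then the shoulder levels
  are polished so that the *expected* window means over a fixed-seed
  ensemble of per-step draws (boundaries placed where the detector puts
  them) hit the targets exactly. The ensemble is evaluated through a
  batched implementation of the same Fritsch–Carlson derivative rule
  as `scipy.interpolate.PchipInterpolator` (verified to 1e-12 in the
  tests); the emitted curves themselves use scipy's interpolator.
- **Per-step draws.** The three extrema and two slopes are drawn iid
  across steps from truncated normals with the per-grade means/SDs; the
  five values of one step share a "loading intensity" factor carrying
  95 % of the variance (5 % idiosyncratic), which preserves the strong
  empirical coupling between them and keeps strict-M-shape violations
  rare (draws are redrawn until the minimum sits below 90 % of the
  smaller maximum). z-scores are clipped symmetrically at ±2.5. Peak
  positions are jittered ±0.02 of stance duration and stretch with the
  drawn slopes (a shallow loading slope implies a later first peak) so
  the crossing anchors always fit. The mean shift introduced by
  truncation and clamping is removed by a fixed-seed Monte Carlo
  recentering per grade.
- **Noise-aware calibration.** The cascade rejects preferentially
  low-force stances (relative noise is larger there), so the accepted
  population is slightly stronger than the drawn one — the same
  selection that produced excluded events in real recordings. Because
  the targets describe accepted steps, the calibration iterates a
  fixed-point loop per grade on the observable that matters: a
  fixed-seed batch of noisy stances is run through the full chain
  (boundary trimming, spline, smoothing, cascade, parameters) and the
  draw offsets and window targets are shifted by the residual of the
  accepted means against the targets (three rounds; cumulative window
  shifts clamped at ±6 % so a window sitting at a geometric ceiling
  cannot inflate its adjusted target without bound; the peak-position
  solve is re-run warm-started each round). Calibration is therefore
  noise-level-aware and cached per (grade, noise level); all internal
  seeds are fixed constants independent of the session seed.
- **Whole-stance mean level.** With the three extrema, two slopes and
  three window means pinned, the whole-stance mean force has no knob of
  its own — it is the width-weighted combination of the windows plus
  the covariance between per-step window widths and force levels. The
  template family cannot reach the stance-mean target at every grade
  simultaneously with the other eight parameters; the calibration aims
  at a uniform 97.5 % of the per-grade stance target instead, which is
  reachable everywhere and preserves the property the stance mean is
  analyzed for: it carries (almost) no treadmill-grade information.
  Emitted sessions therefore read ≈ 2–3 % below the nominal stance-mean
  level, with a small residual grade asymmetry (uphill grades sit
  ≈ 1 % lower than downhill ones) that is below the per-step noise but
  detectable in very large per-step regressions.
- **Ground truth.** Each emitted stance carries its true parameters:
  the drawn extremum values and grid-discretized slopes, and the window
  means of the noiseless template read at the extremum indices the
  detector finds on its smoothed copy — i.e. exactly what a noise-free
  pipeline run reads off that stance.
- **Session assembly.** Body weights ~ U(55, 95) kg per participant;
  stance durations ~ U(550, 800) ms and swing gaps ~ U(350, 550) ms
  (grid-aligned to 10 ms), matching a comfortable walk at ≈ 4 km/h;
  swing force ~ |N(5, 3)| N clipped to 25 N, always below threshold;
  optional white sensor noise (default SD 0.02 BW) and sample dropout
  (default 1 %, represented as absent rows). One `numpy` generator
  seeded from the session spec drives all randomness; identical specs
  produce byte-identical sessions.

### What the generator does and does not emulate

It emulates the statistical structure of the per-grade parameter
distributions, sensor noise, dropped samples, and the M-curve geometry
consistent with all nine parameters simultaneously. It does **not**
model: between-participant clustering (pseudo-participants differ only
by body weight and random stream — real cohorts carry most of the
between-step variance at the participant level, so participant-level
pooling statistics on synthetic data are not representative);
within-stance force texture beyond the smooth template; asymmetries
between feet; cadence drift, fatigue, or gait pathologies; and the
spatial 16-sensor layout (only the weighted total force is modeled).
Passing closed-loop tests therefore demonstrates correctness of the
pipeline's signal processing and statistics under the stated noise
model, not robustness to every artifact of real insole data.

## Numerical choices and degenerate inputs

- Events with fewer than 4 samples cannot support a cubic spline and
  are rejected with a logged reason, not an exception.
- Exact-threshold readings (30 N) count as below threshold.
- Spline undershoot is clamped at zero before smoothing.
- All cascade ties break deterministically (pool: earlier index; grace:
  stronger force, then earlier index); the pipeline contains no
  randomness.
- Regression with zero response variance reports R² = 0; regression
  requires ≥ 3 grade points and ≥ 2 distinct grades.
- Undefined slopes leave the remaining parameters intact and are
  excluded per-parameter from summaries and regressions.

## Problem sizes

The default validation session used in the tests is 40
pseudo-participants × 9 grades × 2 feet × 25 steps (18 000 stance
events, 50 steps per participant-grade pooled over feet), with sensor
noise 0.02 BW — chosen to mirror one minute of treadmill walking per
grade in the reference protocol. The headline-quantity script uses a
600-event level-walking session (12 participants), enough for ≈ 0.5 %
standard error on the extrema means.

## Known limitations

- The implied slope of each emitted stance is grid-discretized (integer
  crossing indices), so individual drawn slopes are reproduced only to
  a few percent; distribution means are recentered, and the recovered
  slope SDs are mildly compressed relative to the targets.
- The acceptance-selection correction is calibrated at the session's
  noise level; sessions generated at one noise level and analyzed under
  another will show ≈ 1 % parameter-mean offsets.
- Treadmill grade is modeled only through the per-grade parameter
  targets; there is no biomechanical model linking grade to curve shape
  beyond them.
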