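# Methods

## Data model

Spike events (unit, trial, time) and trial records (task, object, correct
flag, six event timestamps) are stored in one canonical time frame —
seconds, session-absolute — and aligned per trial at use time via the
trial's `align_event_s`: movement onset in EXE/OBSb/OBSnb, the No-Go signal
in NOGO.  Incorrect trials travel in the file format but are dropped at
load with a logged count.  Event times must be strictly increasing within a
trial; NOGO trials carry no pulling onset (nullable column).  The CSV
dialect writes floats at `%.17g` and reads them with round-trip precision,
so write→read is bit-exact and the determinism contract extends through the
file layer.

## Preprocessing

Per condition (task × object): spike counts in 20-ms half-open bins
anchored so a bin edge falls exactly on the align event → average across
correct trials → Gaussian smoothing → soft-normalization.  The order is
fixed (bin, average, smooth, normalize) for determinism; smoothing before
normalization changes the divisor only marginally, but one order is
canonical.

- **Window**: −600 to +800 ms around the align event → T = 70 bins.
- **Smoothing**: "60-ms Gaussian kernel" is interpreted as the kernel's
  *standard deviation* (not FWHM); configurable.  The kernel is truncated at
  ±3 s.d. and renormalized over its valid support at the window edges (no
  padding), so constants are preserved exactly and every output value is a
  convex combination of inputs.
- **Soft-normalization**: each unit's rates are divided by its maximum
  absolute *trial-averaged smoothed* rate across all ten conditions plus a
  5-spk/s floor.  The trial-averaged level (rather than single-trial maxima)
  matches the matrix pipeline that consumes the divisor; the floor
  guarantees all normalized magnitudes stay strictly below 1.
- **Net activity**: the baseline is each unit's pre-object-presentation
  rate (500-ms window), estimated per trial and trial-averaged, then
  soft-normalized and subtracted.  Because the analysis matrices are aligned
  to movement while the baseline window is aligned to object presentation
  (≈0.7 s earlier, jittered), the baseline is a per-trial scalar rather
  than a segment of the matrix; re-estimating the baseline of the net
  output returns exactly zero.

## Unit classification and inclusion

A sliding two-sample t test compares each 200-ms window (stepped 20 ms
across −600…+600 ms around the align event, decision indexed to the window
center) against the per-trial baseline rates, one-tailed *in each
direction* at α = 0.05, uncorrected.  The one-tailed test is run both ways
because facilitated and suppressed units must both be detectable; signs are
recorded separately.  A unit is facilitated (suppressed) in a task if at
least five consecutive windows are significantly above (below) baseline; if
both signs have qualifying runs, the earlier run wins.  Degenerate windows
(zero variance, equal means) yield no decision.  Units modulated during
OBSb and/or OBSnb form the analysis population; the rest are accounted as
execution-only or never-active.  The inclusion sliding test pools all
correct trials of a task across objects (more power, and the interval
framing refers to the task, not an object); the facilitated/suppressed
*sign* grouping, the preference test and the ANOVA table use ring-object
trials, the object shared by all four tasks.

Note the five-consecutive-windows rule operates on heavily *overlapping*
windows (adjacent windows share 90% of their data), so its null
"modulated" rate is far above the per-window α — of order 25–30% in
simulation.  That is a property of the published criterion, not a bug; the
acceptance suite pins it by Monte-Carlo cross-batch consistency rather than
by a nominal level.

## Subspace alignment

For a T×N condition matrix, PCA is the eigendecomposition of the unit
covariance of the column-mean-centered matrix with 1/(T−1) normalization
(any consistent scalar cancels in the ratio; fixing it makes oracle tests
exact).  When T < N the same spectrum is computed from the T×T Gram matrix
and the coefficients recovered as X_cᵀu/√((T−1)λ) — cheaper inside the
bootstrap and verified equivalent in tests.  The alignment index is the
captured-variance ratio tr(V_Bᵀ cov(X_A) V_B) / tr(V_Aᵀ cov(X_A) V_A); it is
≤ 1 because the own top-2 plane maximizes captured variance.  (The
literature sometimes frames this via "residual variance"; the implemented
quantity is the captured-variance ratio with endpoints 0 = orthogonal,
1 = aligned, which is what the 0/1 endpoints require.)

Between-task alignment averages the index over ordered object pairs in the
stated direction (task over reference); within-task alignment averages over
ordered pairs of *distinct* objects (self-pairs would inflate the estimate
toward 1) and is undefined for the single-object OBSnb task.

Two reference-plane conventions coexist deliberately: the alignment index
uses per-object-pair planes (each matrix against each reference-object
matrix), while trajectory projection uses the top-2 PCs of the reference
task's *object-averaged* activity.  Each convention matches the display it
feeds; both are exposed.

**Bootstrap**: per iteration one vector of unit indices is drawn with
replacement and applied identically to every matrix (paired resampling —
differences must be computed on the same resampled population), all
requested between/within alignments are recomputed, and per-contrast
differences stored; a contrast is significant when ≥ 97.5% of the 2,000
iterations agree on the sign (two-tailed α = 0.05).  A single seeded
generator drives the whole report and iteration i consumes the i-th draw
block, so adding contrasts does not perturb existing draws and results are
bit-exactly reproducible.  Resamples that leave a matrix without variance
are redrawn and counted.

## Trajectories

Each condition matrix is divided by its unit count N, then by the square
root of its total variance (sum over units of temporal variance), giving
unit total variance before projection — amplitudes are then comparable
across populations of different sizes and modulation depths, and reflect
alignment rather than gain.  Matrices are projected onto the reference
task's object-averaged top-2 plane and averaged across objects into one
T×2 trajectory per task.

## Population statistics

One-way repeated-measures ANOVA (unit as subject; task as the four-level
factor) on ring-trial movement-epoch (0–500 ms) net activity, computed from
the explicit sums-of-squares decomposition; η² is reported as SS_task /
SS_total, matching the conventional effect-size label.  No sphericity
correction is applied and the report flags sphericity as untested.
Tukey–Kramer post hocs use the repeated-measures error term with the
studentized-range distribution.  The OBSb-vs-OBSnb preference of each unit
is a two-tailed paired t (α = 0.05) on per-trial ring-trial epoch values,
trials paired by chronological order within task (equal counts required;
pairing is otherwise undefined).  Preference proportions are compared with
a 1-df goodness-of-fit χ² of the two preference counts against equal
expected frequencies — the only 1-df construction consistent with a single
χ² over one population; units with no significant difference are excluded
from the χ² counts.  A unit whose sign-epoch mean is exactly zero is
labeled facilitated (measure-zero tie, logged choice).

## Synthetic data generator

Each task's population rate is `max(0, baseline + gain · W_task z(t))`:
orthonormal 2-column loading matrices W per task, raised-cosine latent
bumps peaking 200/450 ms after the align event (vanishing before −150 ms so
baseline windows are clean), inhomogeneous-Poisson spikes drawn exactly
(total-count Poisson + inverse-CDF placement on a 1-ms rate grid).
Controllables and defaults, fixed once as realistic premotor values:

| parameter | default | meaning |
|---|---|---|
| n_units | 100 | population size |
| baseline | log-normal, median 10 spk/s, σ=0.5 | per-unit resting rate |
| gain | 80 spk/s per latent unit | modulation depth |
| amplitude | EXE 1.0, OBSb 0.60, OBSnb 0.55, NOGO 0.35 | task latent amplitude (execution exceeds observation) |
| overlap | OBSnb 1.0, EXE 0.0, NOGO 0.25 vs OBSb | target plane overlaps (format-hypothesis structure) |
| n_trials | 10 per task×object | correct trials per condition |
| trial_jitter | 10 ms | event-time jitter s.d. |

Plane overlaps are engineered exactly: each non-reference plane is
cos θ·Q + sin θ·P with cos²θ equal to the target, Q the reference plane and
P a dedicated orthogonal complement — so the achieved captured-variance
overlap equals the target.  Targets are specified against one reference
task; arbitrary simultaneous pairwise targets are generally infeasible and
raise with an explanation when violated beyond 0.05.  Signed loading
entries yield a balanced mix of facilitated and suppressed units; objects
within a task share the task plane but differ in latent amplitude and
phase, so within-task alignment is high but below 1.

What the generator emulates: the trial/event structure, per-condition trial
counts, low-dimensional task subspaces with controllable overlap, Poisson
variability, balanced facilitation/suppression, amplitude ordering across
tasks.  What it does not: refractoriness or spike-history effects,
non-Poisson count dispersion, electrode/sorting artifacts, eye-movement or
EMG confounds, the cue-context period (latents are silent before the align
epoch), and any population-mean task effect — balanced signed loadings make
the *average* net activity nearly task-independent, so on default synthetic
sessions the repeated-measures ANOVA is near-null even though the subspace
effect is large.  Passing tests therefore validate the machinery and the
subspace-level claims, not population-mean effects, which are exercised with
constructed tables instead.

## Numerical choices and degenerate inputs

- Bin edges are half-open [left, right) and anchored on the align event;
  a spike exactly on an edge counts rightward.
- PCA requires ≥ 2 units, ≥ 3 bins, nonzero variance; rank-1 matrices get
  an arbitrary orthonormal second component and a flag.  The pipeline
  aborts below 2 included units.
- Ties in the heatmap ordering break by unit id under a stable sort.
- Zero-variance trajectory normalization is rejected by a relative
  threshold (10⁻¹⁴ of the squared magnitude) rather than exact zero, since
  constant matrices leave O(ε²) rounding residue.
- Problem sizes used by the validation suite: 100-unit sessions with 10
  trials per condition for recovery and headline checks (20 seeds,
  2,000-iteration bootstraps), 1,000–2,000 simulated units for calibration,
  and ≤ 8-unit × 10-bin instances for the 1,000-fold oracle-equivalence
  sweeps — sizes at which every check is exact or Monte-Carlo-stable while
  the suite stays fast.

## Known limitations

- The alignment index is a fixed-dimension (2-component) statistic; the
  component count is configurable in principle but all reported analyses
  use 2.
- The bootstrap resamples units only; trial-level uncertainty enters only
  through trial averaging.
- No multiple-comparison correction in the sliding test (by design,
  matching the published criterion) and no sphericity correction in the
  ANOVA.
- The paired preference test assumes a meaningful chronological pairing of
  ring trials across tasks; with block-ordered acquisition this is a
  convention, not a matched design.
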