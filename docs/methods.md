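# Methods

This note documents the models, conventions and numerical choices behind
`posturokit`, in the order data flows through the package.

## Center-of-pressure extraction (`posturokit.board`)

A four-corner strain-gauge board reports one value per corner per sample:
front-left (FL), front-right (FR), posterior-left (PL), posterior-right (PR),
in uncalibrated board units. The CoP displacements are corner contrasts:

    CPap = (FR + PR) − (FL + PL)
    CPml = (FL + FR) − (PL + PR)

**Axis convention.** As written, the "ap" output carries the right-minus-left
contrast and "ml" the front-minus-back contrast — the reverse of the
anatomical reading of those labels. The default keeps the formulas literal;
`axis_convention="anatomical"` swaps the two outputs. Nothing downstream
depends on the choice except the labels: DOT, ellipse area and TMV are
invariant under the swap, and the per-axis statistics simply exchange names.

**Units and normalization.** The corner values are treated as opaque board
units; no calibration constants (board half-length/half-width, load-cell
gain) are assumed, so outputs are in board units, board-units² and
board-units/s. An optional `normalize="total_load"` divides both axes by the
per-sample channel sum, yielding the dimensionless CoP coordinate familiar
from Wii-board formulas; it is off by default because the extraction formulas
above are defined on raw channels.

**Resampling.** Consumer boards emit irregular inter-sample intervals, so
each raw channel is linearly interpolated onto the grid t₀ + k/f,
k = 0…⌊(t_last − t₀)·f⌋ (default f = 20 Hz), anchored at the first timestamp
with no extrapolation beyond the recorded span. Channels are resampled first
and combined second; because both steps are linear the order is
mathematically irrelevant, but resampling the raw sensor streams mirrors the
acquisition pipeline. A 1e-9 relative guard is applied when counting grid
points so a span that is a whole number of periods up to floating-point
rounding keeps its final grid point. Duplicate timestamps are rejected as a
validation error rather than averaged: deterministic, and it surfaces
acquisition faults instead of hiding them.

## Stabilometry (`posturokit.stabilometry`)

Nine parameters per trial; see the README table for formulas. Deliberate
choices:

* **DOT vs path length.** The DOT formula sums radial distances of each
  sample from the origin; "total displacement of sway" conventionally means
  the path length (sum of increment norms). Both are computed and reported
  (`dot_eq3`, `path_length`) so neither reading is lost. CoP values enter DOT
  exactly as extracted — no implicit recentering — with an explicit
  `recenter` flag (default off) for users who want origin-independent radial
  sums.
* **SD centering.** The per-axis SD is described as dispersion about the mean
  position, which requires mean subtraction; the literal formula omits it.
  Default `center=True` subtracts the mean (text semantics); `center=False`
  evaluates the literal root-mean-square about the origin. Divisor N in both
  modes.
* **Velocity divisor.** Mean velocities use the literal factor f/N over the
  N−1 increments, not f/(N−1); the two differ by (N−1)/N ≈ 0.995 at N = 200.
  Kept literal and documented rather than silently "corrected".
* **95% ellipse.** Area = π · 2.4478² · √(λ₁λ₂) with λₖ the eigenvalues of
  the 2×2 sample covariance (divisor N−1). 2.4478 is √χ²₀.₉₅(2) at the
  precision used throughout (the full value is 2.44774…; the difference is
  below every tolerance in play). Eigenvalues are clipped at zero before the
  square root because round-off can make a degenerate covariance marginally
  negative. Collinear or coincident point sets give area 0; the all-coincident
  case also emits a warning. Validation is by Monte-Carlo coverage: the
  fitted ellipse (center = sample mean, Mahalanobis radius² = 2.4478²)
  contains 94–96% of 10,000 circular-Gaussian draws, with mean coverage over
  20 seeds in [0.945, 0.955].

**Static balance protocol.** Three trials of 10 s each (tolerance ±0.25 s,
configurable); the report carries the per-trial parameters and their
element-wise arithmetic mean — the simplest aggregation, chosen because no
alternative (median, best-of-three) is standard for this test.

## Dynamic balance test (`posturokit.dbt`)

Scoring replays a recorded mediolateral CoP trace against an ordered list of
signed target offsets (alternating ±10 board units by default). Round k uses
the zone [offset_k − h_k, offset_k + h_k] with h_k = h₁ · γ^(k−1); defaults
h₁ = 5 board units, γ = 0.8. A round completes at the first sample ending a
run of ⌈hold · rate⌉ consecutive in-zone samples (60 samples for 3 s at
20 Hz); leaving the zone resets the run; samples exactly on a boundary count
as in-zone (closed interval — a deterministic tie-break that favors the
subject). Scoring stops when the trace or the allotted time (default 60 s)
runs out. Sample i closes the interval ending at time (i+1)/rate, so a
constant-at-target trace completes round 1 at exactly the hold duration.

The geometric narrowing schedule, target magnitudes and total duration are
configuration, not claims: deployed systems vary and publish none of them.
Two results are only comparable (for session-to-session deltas) when their
configuration digests match; the comparison refuses otherwise.

Monotonicity holds by construction: shrinking γ shrinks every zone from
round 2 on, so in-zone runs are subsets and the completed-round count can
only fall — a property the tests verify over a γ grid.

## Kinematics (`posturokit.kinematics`)

Joint angles are interior three-point angles: at vertex landmark v, the angle
between rays v→proximal and v→distal via the arc-cosine of the normalized dot
product, cosine clamped to [−1, 1] so collinear configurations survive
round-off. Full ISB joint coordinate systems are *not* constructed: they
require segment-embedded axes that pose landmarks alone do not define, and
every angle series records the convention used in its metadata instead.
Three-point angles cover the range-of-motion outcomes (elbow flexion,
shoulder elevation angles) but do not resolve axial rotations — a known
limitation.

Angle series are EMA-smoothed (y₀ = x₀; yᵢ = αxᵢ + (1−α)yᵢ₋₁), default
α = 0.9 — light smoothing whose first-order lag on a ramp of slope s is
s·(1−α)/(α·f) ≈ 0.1° for a 90°-in-5-s flexion at 20 Hz, and whose gain at
typical movement frequencies (≤ 0.5 Hz) exceeds 0.999. Derivatives use
`np.gradient`: central differences in the interior, one-sided at the
endpoints; acceleration differences the velocity the same way. Missing
frames are rejected rather than imputed; an explicit gap-interpolation helper
(`LandmarkSeries.interpolate_gaps`) reuses the board resampler per coordinate
when the caller supplies true frame times.

## Synthetic data (`posturokit.synthetic`)

The generators exist so every stage has inputs with known ground truth; they
are fixtures with analytic targets, not physiological models of patients.

* **Sway.** Quiet-stance CoP is simulated as an Ornstein–Uhlenbeck process
  per axis — the standard mean-reverting stand-in in the posturography
  literature — via exact discretization (valid at irregular time steps),
  started from the stationary distribution. Defaults θ = 1 s⁻¹, σ = √2, i.e.
  stationary SD 1 board unit and autocorrelation e^(−τ) at lag τ; duration
  10 s at 20 Hz matches the static-trial protocol. A deterministic sinusoid
  (sine on AP, cosine on ML, so the planar path is a circle) and the OU+sine
  sum are also available.
* **Board inversion.** CoP pairs are mapped to four non-negative corner
  channels under a constant total load L (default 100 board units) with the
  symmetric quarter-split FL = L/4 − ap/4 + ml/4 (etc.), which reproduces
  both contrasts exactly; |ap| + |ml| > L would need a negative channel and
  is refused. Timestamp jitter is Gaussian (default SD 5 ms when enabled,
  emulating the irregular intervals of consumer boards), clipped to just
  under half the nominal interval so timestamps never reorder. At zero jitter
  the simulate → invert → rebuild round trip is exact to machine precision.
* **DBT traces** park the cursor at each scripted target for the scripted
  hold with optional Gaussian wander, inserting a short midline excursion
  between holds so consecutive runs are unambiguous.
* **Landmarks** place a shoulder–elbow–wrist chain (segment lengths 0.30 m
  and 0.25 m) with the wrist positioned so the interior elbow angle follows
  an exact profile: static, linear flexion (180°→90° default), or sinusoid
  (90° ± 20° at 0.25 Hz default).

Every generator is a pure function of (config, seed) using
`numpy.random.default_rng`; the jitter stream is seeded independently of the
sway stream so enabling jitter perturbs times, not the sway sample path.

What the generators do **not** emulate: pathology-specific sway signatures,
load-cell noise and quantization, pose-estimator dropout and depth error,
soft-tissue artifact. Passing tests therefore demonstrate the correctness of
the computations, not clinical validity on patient data.

## Sessions, reports, CLI (`posturokit.session`, `posturokit.cli`)

Reports are written as canonical JSON (sorted keys, full float precision)
plus a plain-text summary at 6 significant digits. Every report embeds its
effective settings and a 16-hex-digit SHA-256 digest of them; longitudinal
aggregation flags sessions whose digest differs from the majority in the
selection instead of silently mixing incomparable numbers. CLI precedence is
flag > config file > built-in default. All commands with a `--seed` are
bit-reproducible for fixed inputs.

## Problem sizes

The verification suite uses 100 random 50-sample trajectories for oracle
equivalence, 20 × 10,000 draws for ellipse coverage, 10,000 simulated seconds
(200,000 samples) for OU parameter recovery, 2,000-sample sinusoids at 200 Hz
for closed-form identities, and 60-second DBT traces — sizes at which the
Monte-Carlo error of each check is several times smaller than its acceptance
band.

## Known limitations

* Board units are never converted to millimetres or newtons; comparisons with
  force-plate stabilometry require calibration constants this package does
  not assume.
* Three-point joint angles cannot measure axial (internal/external) rotation.
* The DBT schedule (narrowing factor, targets, total time) is configurable
  convention, not a published protocol; scores are only comparable within a
  configuration.
* Clinical outcome scales and pre/post statistics on patient cohorts are out
  of scope; the package computes per-session measurements and their trends.
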