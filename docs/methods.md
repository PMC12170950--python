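# Methods

## Angle definitions and conventions

All image geometry lives in raster coordinates (x rightward, y downward).
Every clinical angle is an *elevation over the horizontal*, so vertical
displacements are flipped to up-positive before the angle is taken and
results are reported unsigned in [0°, 180°]; this matches the clinical
definition (e.g. the craniovertebral angle is the elevation of the
C7→tragus line above the horizontal through C7) and means all thresholds
operate on magnitudes. Internally the angle is computed as
`|atan2(Δy_up, Δx)|`, which is algebraically identical to the
`arccos(Δ·(1,0)/‖Δ‖)` form but avoids an explicit normalization.
Coincident landmark points raise an error rather than returning a value.

The shoulder angle's distal operand is configurable. The default ray is
acromion → C7, consistent with a horizontal reference through the lower
neck/shoulder pair; acromion → tragus, which appears in parts of the
forward-head-posture literature, is selectable via
`sa_convention="acromion_to_tragus"` everywhere a shoulder angle is
computed or synthesized. The choice is recorded in output sidecars.

Sensor tilt is `atan2(ax, sqrt(ay² + az²))` rather than `arcsin(ax/g)`:
the two agree exactly for unit-norm gravity, but the atan2 form is
invariant to the vector's magnitude — so a mis-calibrated ‖a‖ biases
nothing and the expression has no domain edge. No filtering is applied to
the acceleration stream; whether a given commercial sensor pre-filters
internally is device-specific, and adding a second filter blind would
distort the noise model. Forward flexion of each sensor's X-axis is
positive, so a kyphotic back produces positive alpha and beta and the
kyphosis angle is their plain sum.

## Fiducial subsystem

The marker dictionary is generated once by seeded rejection sampling:
4×4 payloads are accepted only if they keep a Hamming distance ≥ 4 from
every rotation of every accepted code and from their own non-identity
rotations. The first property allows one bit of error correction during
decoding; the second makes orientation unambiguous. The constant seed
makes the dictionary a pure function of the package version.

Detection binarizes at the midpoint of the frame's intensity range
(frames with an intensity span below 32 levels are treated as markerless
— a deliberate guard for blank frames), labels dark components, fills
holes, and extracts each component's outer contour. A quadrilateral is
fitted by polygon approximation with an escalating tolerance sweep;
corners are then refined by intersecting total-least-squares lines fitted
to the contour points of each edge (points within 2 px of an edge and
clear of its endpoints). Cell values are read through a projective
transform with a 3×3 stencil per cell and majority vote; the border must
be ≥ 90 % dark and the payload must match a dictionary code within 1 bit
under one of four rotations. With 40 px markers this yields centroid
errors well under a pixel and angle errors ≈ 0.1° at the default 300 px
landmark baseline. Each frame is processed independently — no temporal
smoothing or inter-frame tracking — so dropouts degrade to quality flags
rather than propagating state errors.

Rasterization of synthetic markers is nearest-cell (no antialiasing). The
half-pixel ambiguity this leaves in the binary contour can shift a
detected centroid by up to ~0.7 px; the shift is common to all markers in
a frame, so angles — differences of landmark positions — are unaffected,
and the residual position error stays inside the 1 px acceptance used in
tests.

## Stream pairing and sessions

The two wearable sensors have independent clocks with no stated
synchronization mechanism, so pairing is nearest-neighbour on timestamps
with a 0.5 s tolerance (half the 1 Hz sampling interval — the largest
window that cannot skip or double-count a sample). Unmatched upper-back
samples become partial records carrying alpha only; the kyphosis angle is
never interpolated. A static-offset subtraction hook (per-sensor zero
estimated over a declared still period) exists but is off by default, as
the measurement protocol defines no calibration phase.

Sessions are long-format series at 1 Hz. Per-minute aggregation reports
n, min, quartiles, and max per started minute with linear interpolation
between order statistics (the "type 7" rule, recorded in report
metadata); NaN samples are excluded from n and empty minutes are omitted.
Histograms default to 1° bins.

## Classification

Thresholds: CA < 48° labels forward head posture, KA > 40° labels
hyperkyphosis, and SA > 54° is recorded as a corroborating flag. All
inequalities are strict, so boundary values classify as non-pathological.
CA alone decides the head label by default because it is the definitional
measure of forward head posture while shoulder protraction is a secondary
adaptation that may lag or be absent; a strict-conjunction mode
(`require_sa=True`) demands both criteria and returns indeterminate when
SA is missing. Indeterminate labels arise exactly when the required angle
is absent, and summary fractions are taken over determinate samples only.

## Agreement statistics

Pearson r comes from the exact t-reference implementation in scipy;
qualitative bands use the conventional cutpoints on |r| (0.90 / 0.70 /
0.50, closed on the left). R² is reported as 100·r² of the paired series
— note that an R² derived this way cannot disagree with r, whereas
independently fitted regression R² values sometimes do in published
tables; this package reports only the self-consistent quantity. MAPE is
reported as a fraction (0.05 = 5 %); pairs with a zero reference value
are excluded with a logged count because the percentage error is
undefined there, and an all-zero reference raises.

## Synthetic study conditions

The generator's defaults are the bench conditions: a 1080×2048 portrait
canvas, 40 px markers, a 300 px baseline from the anchor landmark
(physical segment lengths of the test rig are unpublished, so the
geometry is parameterized and claims only angular fidelity, not
anthropometry; the tragus-anchored shoulder ray uses twice the baseline
to reflect the longer tragus–acromion segment and keep markers disjoint),
sensor noise σ = 0.2° (the wearable's specified inclination accuracy),
and the two-posture protocol: FHP with kyphosis (CA 40°, SA 55°,
KA 45° = 25° + 20°) for 120 s, a 5 s linear ramp, then normal posture
(CA 55°, SA 50°, KA 20° = 12.5° + 7.5°) to 240 s at 1 Hz. The KA totals
are fixed by the protocol; their alpha/beta split is not, so it is chosen
once with the upper-back share larger, reflecting the cranial
concentration of thoracic curvature. The ramp is linear because the bench
transition is a manual reposition with no specified trajectory. One
seeded generator drives all randomness, making bundles byte-reproducible.

What the generator does *not* emulate: lighting and exposure variation,
motion blur, occlusion, perspective foreshortening of tilted markers,
skin/clothing movement artifacts, sensor drift, and the soft-tissue
variability of real subjects. Passing tests therefore demonstrate
correctness of the measurement chain and its statistics under controlled
geometry — the same role the rigid bench model plays for the physical
system — not field robustness on humans.

## Numerical and size choices

Set-point recovery tolerances are ±1.0° for the marker pipeline (bounded
by marker quantization at the default scale) and ±0.5° for noiseless
inclinometry (closed-form up to float rounding). The acceptance script
uses one rendered frame per posture (rendering is deterministic, so
repetition adds nothing) and 120 s streams, one static phase. End-to-end
tests run the full 240 s default protocol once per test session and share
the bundle across tests. Degenerate inputs are defined errors: empty
sessions, zero-variance correlation inputs, zero-norm acceleration,
coincident landmarks, non-monotone sensor timestamps.

## Known limitations

- Video files are not decoded directly (no bundled ffmpeg plugin);
  sessions are consumed as directories of numbered frames at 1 Hz.
- The detector assumes markers are the dominant dark square components of
  a light scene; cluttered backgrounds may produce candidate quads that
  fail decoding (safe) but cost time.
- At marker sizes below ~16 px the projective cell sampling becomes
  unreliable; the defaults stay well above this.
- Classification is a screening aid on single angles; it is not a
  clinical diagnosis and implements no hysteresis across samples.
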