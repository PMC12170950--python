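# posturekit

Quantifies sitting posture in the sagittal plane for ergonomic screening.
It is aimed at movement scientists, physiotherapists, and occupational
health teams who want continuous, per-second posture indicators from
cheap hardware: a single portrait webcam watching square fiducial markers
taped to anatomical landmarks, plus two wearable accelerometers worn on
the spine as inclinometers.

## What it measures

Three markers are placed on the left sagittal view: the ear tragus, the
C7 spinous process, and the acromion process. With marker centroids
obtained from subpixel corner detection, two angles are computed per
frame against the horizontal unit vector **v**ₕ = (1, 0) of the image
(vertical displacements are flipped to up-positive, since image rows grow
downward):

- **Craniovertebral angle (CA)** — elevation of the C7 → tragus line:
  CA = arccos(Δ · **v**ₕ / ‖Δ‖), Δ = (x_tragus − x_C7, y_C7 − y_tragus).
  CA < 48° flags forward head posture (FHP).
- **Shoulder angle (SA)** — elevation of the acromion → C7 line (the
  acromion → tragus convention is configurable). SA > 54° corroborates
  FHP via shoulder protraction.

Two 3-axis accelerometers between T1/T2 (alpha) and T12/L1 (beta) act as
inclinometers at 1 Hz:

- tilt = atan2(aₓ, √(a_y² + a_z²)), in degrees;
- **Kyphosis angle (KA)** = alpha + beta; KA > 40° flags hyperkyphosis.

On top of the per-second series the package provides clinical labelling
(strict thresholds: boundary values are non-pathological), per-minute
box-plot aggregation and histograms for session reports, and
method-agreement statistics for validating one measurement chain against
another: Pearson r with qualitative bands (≥ 0.90 very high, 0.70–0.89
high, 0.50–0.69 moderate, < 0.50 low), two-tailed p, R², and MAPE as a
fraction (≤ 0.05 is conventionally "excellent agreement").

A synthetic fixture generator closes the loop for testing: it renders
frames whose marker geometry realizes requested CA/SA exactly, simulates
accelerometer streams at requested tilts (Gaussian noise, default 0.2°,
matching the sensors' specified inclination accuracy), and produces a
full two-posture bench session — 120 s of FHP with kyphosis (CA 40°,
SA 55°, KA 45°), a 5 s transition, then normal posture (CA 55°, SA 50°,
KA 20°) to 240 s — with a ground-truth CSV.

The fiducial subsystem is self-contained: a deterministic 4×4/50 marker
dictionary (minimum rotational Hamming distance 4), a rasterizer, and a
detector built on contour quadrilateral extraction, line-intersection
subpixel corners, and projective grid decoding.

## Worked example

Simulate a session, measure it back, and compare against ground truth:

```
$ posturekit simulate --outdir demo --seed 7
wrote bundle under demo (240 s, seed 7)

$ posturekit measure --frames demo/frames --out angles.csv
wrote angles.csv: 240 samples (240 complete)

$ posturekit kyphosis --upper demo/upper_back.csv --mid demo/mid_back.csv --out ka.csv
wrote ka.csv: 240 samples

$ posturekit validate --reference reference.csv --candidate angles.csv --channel ca
{
  "channel": "ca",
  "r": 0.9999989526141388,
  "r_band": "very_high",
  "p_two_tailed": 0.0,
  "r_squared_pct": 99.99979052293747,
  "n": 240,
  "mape": 0.0010445129041330816,
  "mape_pct": 0.10445129041330815
}
```

(`reference.csv` here is the bundle's ground truth with columns renamed
to the measured-series layout.) The detect-and-measure chain tracks the
generating CA to r ≈ 1 and a MAPE of ≈ 0.1% over 240 seconds; the first
120 s classify as FHP/kyphotic and the final 115 s as normal.
`posturekit report --angles angles.csv --kyphosis ka.csv --outdir report`
then writes `report.json`, per-minute box statistics, and 1°-bin
histograms.

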