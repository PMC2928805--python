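# nemaphene

Quantitative phenotyping of *C. elegans* neuromuscular function.

Mutants of the BK potassium channel (SLO-1) and of the dystrophin complex that
localizes it show a characteristic battery of phenotypes: an exaggerated
anterior body bend ("head bending"), altered crawling speed, mislocalized
fluorescent puncta of channel and complex proteins at muscle dense bodies, and
prolonged or shortened evoked synaptic currents at the neuromuscular junction.
`nemaphene` implements the four quantification procedures used to score these
phenotypes as one tested, reusable Python library, together with synthetic
data generators that provide analytic ground truth for every stage — so the
whole pipeline is verifiable without any microscope or amplifier attached.

## What it computes

**Posture — the first supplementary angle** (`nemaphene.posture`).
The worm is segmented in each frame, its midline extracted (skeleton →
longest endpoint-to-endpoint geodesic → subpixel refinement against the
grayscale image), and 13 points are placed at equal arc length from the tip
of the nose to the tail. The head-bend statistic is the *first supplementary
angle*

&nbsp;&nbsp;&nbsp;&nbsp;θ₁ = 180° − ∠(P₁, P₂, P₃),

the turning angle between the two most anterior inter-point segments,
reported at the frame of maximal head-swing extension inside a configurable
analysis window (default 15–60 s).

**Locomotion — average crawling speed** (`nemaphene.locomotion`).
Per-frame centroids of the segmented worm; speed = total path length over
adjacent valid-frame pairs divided by their summed elapsed time (µm/s with a
pixel calibration, px/s without). Invalid frames are flagged, never
interpolated.

**Puncta — linescan quantification** (`nemaphene.puncta`).
Intensity profiles sampled by bilinear interpolation along a polyline path
with perpendicular width-averaging; puncta are local maxima above
median + k·σ (k = 3), and each is reported as
net = peak grey − background, with the background a local low percentile.
Nets are linear in gain and invariant to offsets; pooling images whose
metadata declare different exposure/gain/pinhole settings is refused.

**Electrophysiology — evoked response metrics** (`nemaphene.ephys`).
From a voltage-clamp current trace (2.9 kHz, holding −60 mV) with a known
stimulus onset: baseline, peak amplitude |I − baseline|, half-time decay t½
(peak → 50% of peak deviation, interpolated), charge integral
∫(I − baseline) dt over the response window, and peak-normalized traces.

**Statistics** (`nemaphene.stats`).
Mean ± s.e.m. per group, unpaired two-tailed t-test (Welch default), one-way
ANOVA, and Dunnett's many-to-one comparison with familywise-adjusted p-values
from a seeded Monte Carlo of the joint null of correlated t statistics.

**Synthetic data** (`nemaphene.synthetic`).
Seeded generators for crawling-worm movies (tapered tube around a
turning-angle centerline; the head bend is constructed so the 13-point first
angle equals the requested value exactly), Gaussian-spot puncta images, and
difference-of-exponentials current traces — each with a ground-truth sidecar
computed from the analytic form, never from rendered pixels.

## Worked example

```bash
python examples/01_head_bend_angle.py
```

```
       time_s  angle_deg    ok
frame
0         0.0      28.73  True
1         0.5      29.43  True
2         1.0      27.79  True
3         1.5      28.93  True

max-extension first angle: 29.43 deg (frame 1)
ground-truth head bend:    30.00 deg
```

A worm rendered with a 30° anterior bend at 10% contrast noise is recovered
within ~1° per frame; the summary statistic is the windowed maximum, the
angle at maximal dorsoventral head extension. The other examples
(`02`–`05`) walk through speed recovery, puncta quantification, evoked
current metrics, and an ANOVA + Dunnett group comparison the same way.

A thin CLI wraps the same functions for shell use:

```bash
nemaphene simulate worm --seed 1 --out data/
nemaphene posture --stack data/worm.tif --window 15 60 --out results/
nemaphene speed   --stack data/worm.tif --out results/
nemaphene stats   --table metrics.csv --test anova-dunnett --control WT --out results/
```

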