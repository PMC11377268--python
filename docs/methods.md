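# Methods

This note documents the models and procedures implemented in `gaitxai`,
the assumptions behind them, the choices made where the design was
genuinely open, and what the synthetic study conditions do and do not
establish about real gait data.

## The analysis problem

Gait is measured as spatiotemporal ground-reaction-force (GRF) signals:
per-frame readings from force sensors under the feet (8 insole sensors
per foot plus per-foot sums at 100 frames/s) or from a 116-channel
optical-fiber floor sensor at 20 frames/s. The pipeline asks three
questions in sequence:

1. Can a convolutional network classify gait condition (Parkinson's
   disease severity stage, or walking manner under dual-task cognitive
   load) from fixed windows of these signals?
2. Which parts of the input drive each classification? This is answered
   with layer-wise relevance propagation (LRP), which redistributes the
   pre-softmax class score backward through the network onto the input
   under a conservation constraint, and the resulting heatmaps are
   validated by most-relevant-first (MoRF) perturbation.
3. Which *gait events* do the relevant input regions correspond to? The
   gait cycle (heel strike to heel strike, ~1 s, stance ~60% / swing
   ~40%) is divided into seven named intervals A–G; relevance peaks are
   mapped to events through their phase within detected cycles.

## Gait-cycle model

`GaitPhaseModel` expresses event boundaries as fractions of one cycle:
A heel strike [0, 0.02), B loading response [0.02, 0.10), C mid-stance
[0.10, 0.30), D terminal stance [0.30, 0.50), E pre-swing [0.50, 0.60),
F initial/mid-swing [0.60, 0.87), G terminal swing [0.87, 1.0). The
stance/swing split at 0.60 is fixed by the model; interval durations
inside stance and swing follow standard clinical gait-phase proportions,
since the literature specifies the order of events but not universal
durations. The contralateral foot runs the same cycle offset by half a
period.

## Synthetic gait generator

No raw recordings ship with the package; a generator produces data with
the statistical structure the analysis assumes, so that every stage —
classification, relevance propagation, perturbation, event assignment —
is testable end to end with known ground truth.

**Waveform.** The vertical GRF over stance is the classic double-bump
(M-shaped) curve: a piecewise raised-cosine interpolation through knots
at stance progress 0, ¼, ½, ¾, 1 with values 0, `peak1` (1.0), `valley`
(0.65), `peak2` (0.95), 0. The loading ramp (first quarter of stance)
rises with nonzero slope, emulating the impact-like onset of a real heel
strike; all other transitions are cosine-smooth. Force is exactly zero
throughout swing. Per-cycle cadence jitter (relative sd 0.02) and a
random window start phase decouple windows from cycle boundaries.

**Channels.** For insole-style data each foot's force is distributed
over 8 heel-to-toe sensors with Gaussian activation windows whose
centers advance linearly through stance, reproducing staggered sensor
onsets; the two sum columns are computed from the (noisy, non-negative)
sensor channels so the sum identity holds exactly in every generated
frame. For floor-sensor data the two-foot force field is projected onto
three plies of 22/47/47 channels with per-channel spatial footprints and
ply-specific temporal smoothing. A per-subject body-weight factor
(log-uniform) scales all channels.

**Class effects.** Each non-reference class carries one localized
signature: while the reference foot's phase traverses the class's marker
event interval, all channels are scaled by `amplitude_scale` and
modulated by a tremor-like oscillation (`tremor_amplitude`,
`tremor_hz`), with a short taper at the interval edges and per-cycle
timing jitter. The severity markers follow the clinical pattern the
pipeline is designed to recover — stage 2 at mid-stance C, stage 2.5 at
loading response B, stage 3 at terminal swing G, healthy gait as the
unmodified reference; the dual-task markers are listening→heel strike A,
serial-7 subtraction→toe-off F, texting→terminal swing G (the swing-to-
opposite-heel-strike transition), talking→pre-swing double support E,
with normal walking M1 unmodified. Marker events in swing are carried by
the contralateral foot, which is mid-stance at that point of the
reference cycle — which is also why effects scale *whole frames* rather
than single feet.

A design lesson worth recording: a class whose only signature is force
*attenuation* cannot be recovered by relevance propagation, because LRP
attributes a prediction to input components in proportion to their
contributions a·w — silent frames carry no contribution, so "evidence by
absence" lands on the frames where force is *present* in the other
classes. The generator therefore gives each class an *active* signature
(the oscillation), which is also physiologically defensible: impaired
smoothness of force development is a hallmark of parkinsonian gait.
`amplitude_scale` remains available for experiments on exactly this
failure mode.

**Ground truth.** Every window records the frames its effect actually
modified (including the one-frame smear of the floor-sensor temporal
smoothing) and the reference foot's true heel-strike frames.

**Determinism.** All draws flow from `SeedSequence` spawn keys indexed
by (class, subject, trial, purpose), so per-subject streams are
independent of generation order and output is bit-identical for a fixed
(config, seed).

**The easy regime.** The acceptance-scale study conditions use the
generator with subject-level nuisance switched off: a single body-weight
factor, a common mean cadence, sensor noise sd 0.02, and the default
class effects. The reason is identifiability, not convenience: with
per-subject amplitude/cadence signatures and window-level splits, a
classifier can reach high accuracy by recognizing *subjects* (whose
identity predicts class, severities being subject-disjoint), and its
relevance is then spread over whatever identifies the subject rather
than the planted events. The easy regime makes the planted event
signature the only class information, which is the premise of the
event-recovery check. Passing tests under this regime therefore
demonstrates that the pipeline machinery is sound — not that real
patients' severity is classifiable at these accuracies, and not that
real relevance maps will be as clean; with real data the subject
confound returns (which is exactly why the subject-level split mode
exists).

## Preprocessing

Raw 19-column recordings are parsed from whitespace-delimited text;
the timestamp column is dropped; recordings are cut into consecutive
non-overlapping windows (500 frames at 100 Hz, 100 frames at 20 Hz) with
the trailing remainder discarded; channels are standardized to mean 0 /
sd 1 with *population* (divide-by-N) statistics fitted over the whole
dataset before splitting, matching a dataset-wide pre-processing
standardization. The random split defaults to 60/20/20 at window level;
70/10/20 and subject-level splits (including explicit held-out-subject
lists for transfer experiments) are options. Window-level splits leak
subject identity between train and test; this is deliberate (it mirrors
how such datasets are commonly split in practice) and documented here,
and every experiment that
asks a transfer question uses subject-level splits.

## Network architectures and training

All classifiers share a typed layer DAG over batch-first feature maps,
with true-convolution orientation (cross-correlation with the flipped
kernel — observationally equivalent for learned kernels; unit tests pin
the convention). Windows enter as single-feature-map images
(frames × channels × 1).

* **single** — four 3×3 conv + 2×2 average-pool blocks (16/32/64/64
  filters) and two dense layers: 10 stacked layers.
* **parallel** — inception-style: conv/pool stem, two stages of two
  parallel streams (1×3 then 3×1 convs, pool) fused by concatenation
  with a 1×1 conv after each fusion, then two dense layers: 18 stacked
  layers.
* **quadruplet** — four parallel streams with independent parameters
  (two max-pool paths, two average-pool paths), concatenated into a
  dense head.

"Stacked layers" counts conv, pool and dense layers only — the
convention under which the sequential design tallies 10 layers and the
inception-style design 18. Filter counts and kernel sizes are free
design parameters here; the defaults above are the package's own and
are configurable (`scale` multiplies all filter counts). Every head applies batch normalization
then dropout (rate 0.3) after the flatten and ends in softmax.

Training minimizes categorical cross-entropy with Adam at α=0.002,
β₁=0.9, β₂=0.999, ε=1e−8, batch size 100, 200 epochs by default;
weights start Glorot-uniform with zero biases. Training is deterministic
under a fixed seed on a fixed platform (seeded init, shuffle and
dropout; single-threaded numpy kernels). Scaled-down runs (smaller
filter counts, fewer epochs, batch 50, single precision) are used
throughout the test suite and the acceptance script; the sizes are
stated there and were chosen so the easy-regime problem is comfortably
learnable at small cost. A thin single-layer LSTM classifier is included
as a comparison baseline only (no relevance propagation), alongside
linear-SGD, k-nearest-neighbour and Gaussian-process baselines that
operate on flattened windows via scikit-learn (the GPC is capped at 500
training points).

## Relevance propagation

LRP starts from the pre-softmax score f_c of one class (other logits
zeroed) and applies per-layer rules in reverse topological order:

* **epsilon**: R_j = Σ_k a_j w_jk / (z_k + ε·sign(z_k)) · R_k, with
  sign(0)=+1;
* **alpha-beta** (α−β=1): positive and negative pre-activation
  contributions redistributed with weights α and −β; with α=1, β=0 this
  is the z⁺ / deep-Taylor rule on ReLU networks;
* **flat**: uniform redistribution over each unit's receptive field;
* **z^B box rule** for bounded input layers.

Named composites mirror common toolkit presets; `lrp_spf` ("sequential
preset A, flat") uses epsilon (ε=0.1) on dense layers, α1β0 on
convolutions and the flat rule at the first layer; the parameters follow
the usual toolkit defaults and are configurable. Guided backpropagation and deconvnet are
modified-ReLU gradient backpasses sharing the training engine's backward
machinery.

Numerical choices: bias relevance is absorbed (denominators include the
bias; inputs receive only their a·w shares), so conservation can leak
through biases — the leak is reported as `conservation_residual`, the
relative deviation of ΣR from f_c, rather than hidden. Max-pooling
redirects relevance to the argmax input (ties to the first index, which
matters because standardized signals can tie at zero); average pooling
is treated as a fixed uniform-weight convolution under the surrounding
rule; batch normalization is folded into the next dense layer's
effective weights before rules apply; dropout is identity at inference.
Conservation is exact (to float accuracy) for the flat rule and for
zero-bias α/β propagation; the α1β0 rule can lose the relevance of a
unit whose score has no positive contributions (z⁺=0) — a structural
property of the rule, visible in the residual, not an implementation
error.

## MoRF perturbation

The input window is tiled row-major into 7×7 (frames × channels) blocks,
partial edge blocks kept (a 500×18 window gives 216 regions; 100×116
gives 255). Regions are ranked per sample by summed relevance from that
sample's own map; at step t the t top regions are replaced by Gaussian
noise and the test set is re-predicted. The replacement noise level
matters more than it may seem: with signal-scale noise (sd 1 in
standardized units) the injected blocks themselves resemble
high-frequency force fluctuations, so on oscillation-signature data the
noise can *preserve* the evidence that relevance-guided removal was
supposed to destroy while planting spurious signatures under random
removal — inverting the curves. The experiment protocol therefore uses a
0.1% noise level (sd 0.001), which effectively deletes the region's
signal; `morf_curve` keeps the sd configurable for studying exactly this
artifact. Noise is redrawn each step for the accumulated region set;
curves are deterministic under the seed. The random-order baseline uses
per-sample random permutations. Model selection takes the steepest mean
per-step decline over an early window (default 15 steps); explanation-
method selection takes the largest baseline-minus-curve early decline
with curve means removed, making the ranking invariant to constant
shifts.

## Gait-event assignment

Signals and relevance maps are reduced to spatial-average (SA) curves —
the per-frame mean over the actual channel count. Heel strikes are
detected on the *reference-foot* signal SA (left insole channels, or the
left-dominant channels of the lengthwise floor-sensor ply): the full
18-channel SA peaks twice per cycle (once per foot), which would make
"reference foot" boundaries ambiguous. Detection is an upward crossing
of a relative threshold (20% of the curve's range — hence amplitude-
invariant) with a 0.5 s refractory period, refined by walking back to
the 2%-of-range onset; complete cycles keep only plausible durations
(0.5–2 s). Relevance peaks are local maxima of the lightly smoothed
(3-frame moving average, edge-normalized) relevance SA inside complete
cycles; each peak's phase within its cycle maps it to an event A–G.
Per-class histograms of top-1 peak labels over *true-positive* test
windows support statements of the form "class k's modal event is E_k".
The attribution stage defaults to the deep-Taylor (z+) composite rather
than LRP-SPF: the flat first-layer rule of LRP-SPF spreads each unit's
relevance uniformly over its receptive field, which blurs precisely the
narrow low-force events (notably the 8%-of-cycle loading response) that
the event histogram needs to resolve, whereas the z+ rule keeps the
input-layer attribution proportional to the actual positive
contributions and localizes those events reliably. LRP-SPF remains the
default for heatmaps and perturbation analysis.
At 20 Hz a 100-frame window holds 4–5 cycles at the 1.1 s cognitive-
scenario cycle duration; segmentation is identical with the rate-scaled
refractory.

## Known limitations

* The generator models phase/event structure, not biomechanics: no
  inter-subject GRF shape variability beyond amplitude/cadence factors,
  no left/right asymmetry, no double-support force transfer dynamics.
* Event recovery is only expected when class evidence is an active,
  localized signature; absence-only signatures are structurally
  unattributable by LRP (see above).
* Conservation diagnostics, not guarantees, are provided for composites
  involving the epsilon stabilizer or biases.
* Real-accession replication (subject counts, window counts per group)
  requires downloading the public archive; the readers and counters are
  implemented and tested on same-dialect fixtures, but the published
  counts themselves are not asserted anywhere in the test suite.
* The LSTM baseline is intentionally minimal and not a faithful
  reproduction of any specific recurrent architecture.
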