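# Methods

`spikewta` simulates a three-stage hybrid architecture for continual
learning on 28×28 grayscale images: a supervised convolutional front end, a
combinational pattern-equalization stage, and an unsupervised digital
spiking layer trained on-line by a counter-based form of spike-timing
dependent plasticity (STDP).  The division of labor mirrors the
complementary-learning-systems picture: the convolutional filters hold
consolidated knowledge about a set of *trained* classes, while the spiking
layer plastically clusters the *non-trained* classes that appear only at
inference time, without disturbing what the filters already encode.

## Stage 1 — convolutional filters and feature maps

A bank of 16 integer filters of size 20×20 is applied to each image by
valid cross-correlation (no kernel flip, stride 1), producing a 9×9 integer
response matrix per filter; the maximum response is compared **strictly**
against a per-filter threshold θ to yield one bit.  Pixel values are
unsigned 8-bit, weights signed 8-bit, and the convolution accumulates in
64-bit integers (the extreme |entry| is 400·255·128 ≈ 1.3·10⁷, far inside
the accumulator range), so all responses are exact.

Two filter kinds share the bank, class filters (CFs) first:

* **Class filters** — one per trained class.  Each is a single 20×20
  fully-convolutional unit fit by full-batch gradient descent on the
  max-pooled response with a logistic one-vs-rest loss (the gradient flows
  through the argmax window).  After training the kernel is scaled so its
  absolute peak maps to 127 and rounded to integers; the integer threshold
  is then chosen on a held-out split to maximize Youden's J
  (sensitivity + specificity − 1).  If no threshold achieves J > 0 the
  trainer raises a non-separability error rather than emit a useless filter.
* **Feature filters** — generic shape detectors.  `n + 3` candidate kernels
  are trained jointly as the first layer of a small fully-convolutional
  softmax classifier over the trained classes; the `n` kernels with the
  highest response variance are kept.  Their thresholds sit at the 0.75
  quantile of the training responses, so each filter fires on roughly a
  quarter of the training images — informative but not class-specific.

The 16 bits (CFs first, bank order) form the image's **feature map**.
Trained classes are characterized by their own CF bit; non-trained classes
leave all CF bits low and are described by their combination of FF bits.

The training procedure is deliberately small-scale: the architecture treats
filter training as an offline, replaceable component, and only the binary
responses matter downstream.  Quantization to 8 bits changes held-out CF
decisions on ≤ 5 % of images in the test conditions.

## Stage 2 — density equalization

Feature maps of different classes have different ON densities, which would
bias an integrate-and-fire competition (denser maps drive every neuron
harder).  Each lookup line is therefore re-coded as a 4×4 binary pattern
with exactly 4 ON cells (25 % density), drawn from a bank in which any two
patterns share at most 2 ON cells.  The bank is built greedily: the 1820
candidates (C(16,4)) are scanned in seeded-shuffled order and a candidate is
accepted iff it overlaps every accepted pattern in ≤ 2 cells.  The greedy
scan deterministically finds well over the ~20 patterns a typical run needs
(the densest possible bank, a constant-weight binary code, holds 140).

The lookup table gives every class filter a dedicated pattern.  Among
calibration feature maps whose CF prefix is all zero, the
`redundancy × expected-new-classes` most frequent FF combinations each get
a dedicated pattern; the empirical frequency of a combination is its
appearance rate R_P.  Calibration is unlabeled and defaults to 2,000 maps.
At inference, CF bits have priority (lowest-index firing CF wins; multiple
simultaneous CF bits are counted and logged, since CFs are intended to be
mutually exclusive); if all CF bits are 0 the FF combination addresses the
table.  An unknown combination presents **no frame** by default — the
all-zero output row is unambiguous because a legal pattern always has 4 ON
cells — or, under the configurable `nearest` policy, maps to the stored key
at minimum Hamming distance (ties to the lowest key).

## Noise generation

Background depression in the spiking layer requires uncorrelated noise
frames.  A 4-bit Fibonacci LFSR with maximal taps (4, 3) — the primitive
polynomial x⁴+x³+1, period 15 — supplies a cell index: each noise frame has
exactly **one** ON cell at linear index (register − 1) mod 16, so the
unreachable zero register leaves no coverage hole.  One ON cell out of 16
is the integer realization of a ~5 % noise density.  The seed is a plain
config integer; noise sequences replay exactly.

## Stage 3 — STDP winner-take-all layer

Synapses are 8-bit counters (0–255), one row of 16 per neuron; weights
initialize uniformly at random in [96, 160].  Each frame (pattern or noise)
adds every neuron's synaptic drive `w·frame` to its integrator.  When an
integrator strictly exceeds its neuron's threshold, the neuron with the
largest integrator fires (ties to the lowest index): all integrators reset
to zero (lateral inhibition), the winner's threshold increments by ΔΘ
(spike-frequency adaptation), and the winner's synapses update at the
frame's falling edge — ON synapses +ΔLTP, OFF synapses −ΔLTD, clipped to
[0, 255].  At most one neuron fires per frame.  Integration persists across
frames until some fire resets it.  Sessions alternate pattern slots and
noise frames strictly (50 %/50 % appearance rates); a Bernoulli schedule
with configurable input rate is also available.  Wall-clock frame durations
are modeled as a discrete frame index.

The learning-quality measure is the **synaptic window**: mean weight over a
pattern's ON cells minus mean weight over its OFF cells.  A fully
specialized neuron approaches 255.

### Threshold regime

The defaults are ΔLTP = 16, ΔLTD = 4, θ₀ = 384, ΔΘ = 19 (5 % of θ₀), and a
threshold ceiling θ_max = 960.  Two constraints determine this regime, and
they are the most consequential numerical choices in the package:

1. **θ₀ below the single-frame pattern drive.**  At the mean initial weight
   (128), a 4-ON pattern drives ≈ 512 per frame.  With θ₀ = 0.75·512 = 384,
   a single presentation can trigger a fire, so the winner is selected by
   the match between the *current frame* and each neuron's weights.  That
   frame-selectivity is the positive feedback that lets different neurons
   lock onto different patterns.  If θ₀ exceeds the single-frame drive,
   fires only occur after integrating several frames of a *mixture*, winner
   selection decouples from frame identity, and every neuron converges to a
   blend of the frequent patterns (measured: 0/50 seeds reach distinct
   three-pattern specialization).
2. **A saturating threshold counter, θ_max < 1020.**  The threshold is
   monotone non-decreasing within a run, as a hardware counter is.  An
   unbounded counter inevitably passes 4·255 = 1020 — the drive of a fully
   potentiated pattern — after which even a perfect specialist can no
   longer fire within one presentation and the layer degrades back into
   mixture integration.  Saturating the counter at 960 keeps specialists
   responsive forever while still providing genuine adaptation: each
   neuron's firing rate is non-increasing over a stationary stream, and the
   early climb from 384 to 960 is what rotates activity across neurons and
   drives them apart during the capture race.

With these defaults the three-pattern setting (appearance rates
46 %/28 %/15 %, three neurons, 4,000 frames) yields distinct capture with
zero wrong-neuron pattern fires in the final third in ≈ 98 % of seeded
runs, and the window after a fixed 200-frame budget is ordered by
appearance rate.  Adaptation triggered on every fire is the default; a
variant that increments the threshold only once the winner's window for the
firing frame reaches a reference level (`adaptation="window"`,
`window_ref = 128`) is available, as is `adaptation="off"`.

## Evaluation

The spiking layer is unsupervised, so scoring requires linking neurons to
classes.  During a test phase (100 fire events by default) each neuron's
fires are tallied against input labels; per-neuron accuracy for class c is
100·count_c/total, displayed with truncation toward zero (fires labeled
[1, 2, 2] display 33 % / 66 %) while internal arithmetic stays in exact
integers.  Each neuron links to its argmax-accuracy class (ties to the
lower label; silent neurons stay unlinked and flagged).  Redundant neurons
fold into one predicted class in the confusion matrix.  Two global
accuracies are reported: over fire events only, and a strict per-item rate
in which an item eliciting no fire counts as an error (no-response items
are also tallied separately).

## Synthetic data

The feature-map generator draws class-conditional Bernoulli bits: a trained
class raises its own CF bit at rate 0.95 (others 0.02) with a fixed
class-specific medium-rate FF profile; a non-trained class keeps CF bits at
0.02 and owns two core FF bits at rate 0.92 plus one variant bit at 0.35
(other FF bits 0.03).  Each non-trained class therefore produces one
dominant FF combination and a couple of rarer variants — the structure that
neuronal redundancy exists to absorb — and every class's dominant
combination is distinct.  Class priors are uniform.  The image-level
generator composes 28×28 digit archetypes from line segments with Gaussian
endpoint jitter (σ = 1.2 px), stroke width ≈ 2.6 px, random stroke
intensity in [190, 255] and slight blur (σ = 0.7).

What the generators do **not** emulate: the within-class shape diversity,
style correlations and overlapping strokes of handwritten digits or
clothing photos, correlated bit noise across filters, or class imbalance.
Passing tests therefore demonstrate that the mechanisms work as designed
under controlled statistics, not that a particular accuracy would be
reached on MNIST or Fashion-MNIST.  Runs on real IDX files are supported
(`dataset="idx"`) but never required by the test suite.

## Default run sizes

The benchmark configuration trains on classes {0,1,2,4,7,8,9} with
{3,5,6} non-trained and redundancy 3 (16 LUT lines, 16 neurons): 2,000
calibration maps, 1,500 learning items, a 100-fire linking phase, 800
scoring items.  These sizes put every phase well past its convergence knee
(capture completes within a few hundred frames) while keeping a full run
under a second, so multi-seed statistics stay cheap.

## Known limitations

* Filter training is a compact stand-in tuned for stroke-like synthetic
  data; it makes no attempt to reach state-of-the-art CF/FF quality on real
  datasets.
* The capture race can mis-assign patterns when many LUT lines compete for
  equally many neurons and appearance rates are very uneven; redundancy
  mitigates but does not eliminate this (a small fraction of seeds leave
  one rare variant uncaptured).
* The appearance-rate/window ordering is a transient effect: at long frame
  budgets all captured windows saturate at 255 and the ordering collapses
  to ties.
* The comparison of predictions is event-based; the mapping from fires to
  images assumes one pattern frame plus one noise frame per item.
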