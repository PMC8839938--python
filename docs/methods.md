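# Methods

This note records the modeling and numerical choices behind `ecgfewshot`,
the assumptions they rest on, and what the test suite does and does not
establish.

## Problem setting

A 12-lead, 10-second ECG record is to be assigned one of a small set of
diagnostic classes under a few-shot regime: instead of a fixed-output
classifier, an encoder maps each record to a 20-D embedding, and class
membership is decided by Euclidean distance to class center vectors
(prototypes) computed from a database of labeled embeddings. This mirrors
a clinical deployment in which incoming signals are compared against a
curated archive of professionally labeled ECGs: prototypes are computed
once, and each query needs only one distance per class.

## Consensus R-peak labeling

No single-lead R-peak detector is reliable on every record, so six
classical detector families are run on all 12 leads and reconciled. The
implementations follow the published processing chains — band-pass,
derivative, squaring/rectification and integration stages with each
family's thresholding style — streamlined to deterministic offline form:
Pan–Tompkins and Hamilton use the classic dual running signal/noise level
estimates; Two-Average and the stationary-wavelet detector use
two-moving-average block thresholding (on the squared 8–20 Hz band and on
squared level-3 db3 detail coefficients, respectively); Christov and
Engzee use a local-maximum adaptive threshold over a 2.5 s window. All
detectors snap their detections to the local extremum of the band-passed
lead, so candidates land on the R wave rather than an envelope peak.

The reconciliation is 1-D k-means over pooled candidate sample positions.
The published description of this consensus step leaves k, the
initialization and the cluster filtering open; the choices here are:

* **k = rounded median** of candidate counts over non-empty streams —
  robust to individual streams that over- or under-detect;
* **quantile initialization** (centers at the k evenly spaced quantiles of
  the sorted pool) — deterministic, order-free, no random restarts;
* **spurious-member trimming**: cluster members farther than half the
  refractory period (default 0.2 s → 50 ms) from their cluster's median
  are dropped. With k capped at the median count, a lone extra detection
  cannot form its own cluster; without trimming it would instead shift a
  genuine beat's center by tens of milliseconds;
* **support filtering**: clusters contributing members from fewer than
  `support_frac` (default 0.5) of the non-empty streams are discarded;
* **refractory merging**: centers closer than the refractory period merge,
  keeping the higher-support one.

Consensus positions are cluster means rounded to the nearest sample; they
are not snapped to any lead's extremum, since no reference lead is
defined. The result is invariant to detector/lead ordering, and the
number of consensus peaks never exceeds k.

## Segmentation and beat metadata

Cuts fall at `floor((r_i + r_{i+1})/2)` on the integer sample grid, giving
half-open intervals that partition the record; the first and last (edge)
segments are removed because they contain truncated beats. Retained
segments are resampled per lead to 100 samples by linear interpolation —
deterministic, shape-preserving, and the identity when the segment is
already 100 samples. Each beat's BPM is defined from its own
pre-resampling segment length, `bpm = 60·fs/L`; since the segment spans
mid-RR to mid-RR, `L` approximates one RR interval and this is the only
segment-local definition available. The resampling ratio `L/100`
preserves the information the resampling discards.

## Encoder and set pooling

The per-beat encoder is a four-convolution stack (channel plan
12→24→48→96→2, kernel 3 except the final kernel-1 reduction, LeakyReLU
slope 0.01 after each convolution, 2×2 max-pooling between blocks). The
final kernel-1 convolution is a channel-mixing reduction in the
GoogLeNet style: 96·2·1 = 192 weights collapse the 96-channel map to 2
channels. As printed, the layer table with paddings (1,0,0,0) produces a
2×11 = 22-value output on a 100-sample input, which contradicts the
stated 24-D per-beat feature vector; the third convolution is therefore
padded by 1, giving sequence lengths 100→50→48→24→24→12 and a 2×12 = 24
channel-major flatten. The 24-D target is treated as authoritative
because every downstream dimension (48-D pooled, 48→20 fully connected)
depends on it.

A record's beat set has variable cardinality, so aggregation must be
symmetric: elementwise maximum and mean over the set, concatenated to
48 values, then a fully connected map to the 20-D embedding. The set
dimension is the pooled axis — this is exact set pooling, not spatial
adaptive pooling. Embeddings are consequently invariant to beat order,
and the max head is invariant to beat duplication.

All layers are implemented in float64 numpy with explicit
forward/backward passes; gradients are verified against central finite
differences at tolerance 1e-4 relative. Weights are initialized uniformly
within ±1/√fan-in from an explicit seed, making every training run
bit-reproducible on one platform.

## Training protocol

Both trainers share the protocol: a record-level seeded 70/15/15
train/validation/test split (unstratified; the split seed is recorded),
Adam (defaults lr 1e-3, β = (0.9, 0.999) — unstated in the source
protocol, so library-conventional values are used), an epoch of
⌈N_train/batch⌉ sampled batches (batch default 32), a checkpoint at each
new validation best, and a stop after `patience` epochs (default 50)
without improvement or at the 10,000-epoch cap.

The few-shot trainer minimizes the triplet margin loss with margin m = 1
and Euclidean distance. Batches are homogeneous in beat count: the count
is drawn from the frequency-weighted distribution of beat cardinalities
in the training set, the anchor class from the class-frequency
distribution (a uniform option is exposed), anchor and positive are
distinct records of that class and the negative any record of another
class, all restricted to the drawn count. Infeasible count draws are
retried with a fresh draw, capped at 1,000 attempts. The validation
metric for model selection is proximity accuracy with class centers
estimated from the training split — the only accuracy available to a
model with no output layer. The softmax baseline adds a class-sized
fully connected layer and trains with cross-entropy on per-count record
minibatches under the same homogeneity constraint.

## Evaluation

The database/query split halves each class (floor(n/2) to the database),
truncates database classes to the smallest class's cardinality so
prototypes are estimated from balanced samples, and returns the truncated
members to the query set; "same cardinality" is read as record counts,
because centers are record-level means. ROC scores for the proximity
classifier are negated center distances — monotone in the decision rule,
hence AUC-consistent. Metrics use the standard confusion-count formulas;
with more than two classes, precision/recall/F1/specificity/sensitivity
are macro-averaged one-vs-rest (the averaging scheme is otherwise
unspecified), overall accuracy is trace/total (identical to the binary
(TP+TN)/total formula for two classes), and AUC is the per-class
trapezoidal ROC area macro-averaged over classes present in the truth.
Nearest-center ties break by label-catalog order. Cross-validation trains
five independent repetitions from scratch on freshly drawn splits with
distinct recorded seeds and aggregates avg/min/max/std. The test-subset
ablation fits the downstream classifier (random forest by default) once
on training embeddings and evaluates independent seeded subsets of the
test set at each requested fraction; subsets are independent draws, not
nested.

Downstream classifier heads use the conventional library defaults
(k = 5 and 20 for the nearest-neighbor variants; linear, polynomial, RBF
and sigmoid SVM kernels) with seeds fixed for the stochastic ones.

## Synthetic data

The generator emulates what downstream stages consume: 12-lead,
quasi-periodic PQRST-like records with known R-peak positions. Each beat
is a sum of five Gaussian bumps (P, Q, R, S, T) with per-wave amplitude
(mV), center offset relative to R (s) and width (s), scaled per lead by a
12-vector roughly mimicking the projection of the cardiac vector onto the
standard leads; white noise of configurable standard deviation (default
0.02 mV, a plausible baseline-noise level for a clean resting ECG) is
added on top. RR intervals are drawn uniformly from the class's BPM
range; beats are laid down from half an RR interval after the record
start until one refractory period (0.2 s) before the end, so the ground
truth never contains a half-truncated boundary beat. Per-record RNG
streams are spawned from the root seed by record index, so record i is
identical regardless of dataset size.

The default class specs separate classes by waveform morphology (R/T/P
amplitudes, T width, S depth) while sharing one BPM range. Sharing the
rate range is deliberate: homogeneous-cardinality triplet batching needs
beat counts that overlap across classes, and disjoint rate ranges would
make every count single-class and triplet sampling infeasible — an
interaction worth knowing about when composing fixtures.

This is a fixture model, not a physiological simulator: it has no beat-
to-beat morphology variability, no baseline wander or powerline
interference, no pathological beat types, and its class differences are
parametric caricatures. Passing recovery tests therefore demonstrates
that the pipeline's machinery is correct and self-consistent — detectors
find the peaks that exist, training separates classes that are separable,
evaluation scores what was classified — not that any particular clinical
accuracy would be reached on real ECGs.

## Problem sizes and numerical choices

Recovery experiments in the tests use 2 classes × 12 noiseless records,
batch size 8, at most 200 epochs with patience 20 — sizes at which the
full numpy training loop converges in seconds while still exercising
every code path (both trainers reach 100% validation accuracy well before
the cap). Distance computations guard against zero denominators with an
additive 1e-12 in triplet-loss gradients; midpoints use floor on the
integer grid; k-means runs at most 100 Lloyd iterations (convergence on
these pool sizes takes a handful).

## Known limitations

* The consensus step clusters positions pooled across streams; clustering
  per-beat matched groups is a plausible alternative reading and would
  differ when streams disagree about beat existence.
* WFDB-format input is not implemented; records enter as 12-column CSV
  with a JSON sidecar, and the PTB-XL adapter consumes the metadata
  tables, not the waveform files.
* The six detectors are streamlined offline variants tuned for clarity
  and determinism, not certified reimplementations; on heavily
  pathological or noisy real signals their individual sensitivities will
  differ from the originals (the consensus layer is the mitigation).
* Training is CPU numpy: correct and reproducible, but not sized for the
  full 17k-record clinical dataset without patience.
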