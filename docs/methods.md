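# Methods

This note documents the models and procedures `evobci` implements, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## The decoding model

The classifier is a fully connected MLP on one flattened epoch: with `C`
channels and `S` samples per epoch the input has `C × S` units, ordered
channel-major (all of channel 0's samples, then channel 1's, ...). Hidden
layers (1–3, each 1–500 neurons) use tanh. The only input normalisation
is per-epoch, per-channel mean removal; channel variance is deliberately
left intact because it carries task information. Output class is the
argmax of the output neurons (ties break to the lowest class index).

Two output configurations exist:

* `SOFTMAX_XENT` (default): softmax outputs with mean cross-entropy loss,
  the standard choice for pattern classification;
* `TANH_SSE`: tanh outputs against ±1 targets with a mean
  sum-of-squares loss, provided for fidelity comparisons with older
  pattern-recognition toolboxes.

Weights are initialised Glorot-uniform (±√(6/(fan_in+fan_out))) from a
seeded generator; every training routine is deterministic given data,
seeds and configuration.

### Input scaling

Raw epochs arrive in microvolts. Before training, the decoder facade
divides all inputs by one global scalar — the RMS of the training fold —
and after training folds that scalar back into the first-layer weights,
so saved networks always act on raw microvolt epochs. One shared scalar
preserves every relative channel variance (there is intentionally no
per-channel standardisation) while keeping tanh pre-activations of order
one. Without it, microvolt-scale inputs saturate the hidden layer at
initialisation and the cheapest way for training to grow the decision
margin is through the output layer, leaving the first-layer weights — the
object of the spatial and spectral analyses — essentially at their random
initial values.

## Training: SCG with kappa early stopping

Training minimises the loss on an 80 % training portion of the supplied
data by Møller's scaled conjugate gradient (constants σ = 5·10⁻⁵,
λ₀ = 5·10⁻⁷, Møller's published defaults). The remaining 20 %
(stratified, seeded; fraction configurable) is a validation set scored
with Cohen's kappa after every accepted step. Training stops at
`max_iterations` (default 500), when the gradient vanishes, or after
`patience` (default 6) consecutive steps without a new best validation
kappa; the snapshot with the best validation kappa is returned. Loss on
the training portion is non-increasing across accepted SCG steps by
construction of the comparison parameter.

Early stopping on validation kappa (rather than loss) aligns the training
criterion with the fitness metric used everywhere else. A side effect
worth knowing: because the returned snapshot maximises validation kappa,
its validation score is optimistically biased on small validation sets
(measured ≈ +0.3 with 10 validation epochs under shuffled labels).
Chance-level claims are therefore always checked on held-out data, never
on the internal validation split.

## Simulated annealing augmentation

`sa_train` wraps SCG in an accept/reject loop (default 10 iterations):
perturb every weight `w` by `U(−w, w)` (magnitudes at most double, signs
never flip, zeros stay zero), retrain with SCG, and compare validation
kappa on the *same* split used throughout the call (re-splitting would
confound the comparisons). Improvement is always adopted; degradation is
adopted with probability `exp(−(k+1)/τ)` at iteration `k` (τ = 2 by
default, exposed in `SAConfig`) — an exponentially decreasing schedule.
The best-validation-kappa model ever seen is returned even if a later
iteration rejected it, which is never worse than returning the final
state. With `iterations=0` the result is bit-identical to plain SCG.

## Genetic architecture search

A genome is 29 bits: 2 bits of hidden-layer count (0b00→1, 0b01→2,
0b10→3, 0b11 clamps to 3) followed by three 9-bit neuron fields, each
clamped into [1, 500] (9 bits cover 0–511; the layout is ours — only the
binary representation itself is prescribed). Decoding is total: every
bit string is a valid architecture, so crossover and mutation never
produce invalid offspring; encode/decode is an exact round trip on valid
architectures. Fitness is the validation kappa of the annealed-SCG-trained
network; one genome is trained once per GA run (cached), with the
train/validation split fixed per run so fitness values are comparable
across genomes. Parent selection is roulette-wheel on shifted fitness
`f − min(f) + 10⁻⁶` (kappa can be negative); reproduction is single-point
crossover (cut point uniform on 1..28) followed by a 2 % per-individual
chance of one uniformly chosen bit flip. Each generation keeps the single
fittest network unchanged (elitism) and rebuilds the rest, so the elite
fitness trajectory is non-decreasing. Defaults: population 30,
20 generations, 1 elite — with the initial population stratified to near-
equal counts of 1-, 2- and 3-layer networks (neuron fields uniform on
[1, 500]).

## Evaluation

Cohen's kappa and accuracy are computed from confusion matrices (rows
true, columns predicted). Significance against chance uses the
large-sample z-test with the Fleiss–Cohen–Everitt null standard error

SE₀ = √(p_e + p_e² − Σᵢ pᵢ· p·ᵢ (pᵢ· + p·ᵢ)) / ((1 − p_e) √N),

two-sided normal p-values, and a `**` flag at p < 0.01. Cross-validation
is stratified 5-fold (stratification keeps small per-class counts
trainable in every fold; plain random allocation is available by
shuffling upstream): test folds are disjoint, cover every epoch exactly
once, and are never seen by training or by the internal validation split.
For the 3-class task two conditional accuracies are reported: detection
(movement trials predicted as movement, regardless of side) and
laterality given detection (correct side among movement trials predicted
as movement; a flag switches the denominator to all movement trials).

## Network analysis

* **Spatial map** — mean of |first-layer weight| over time points and
  first-hidden-layer neurons per channel, then min–max normalised to
  [0, 1]; multiple fold models are averaged per channel before
  normalisation. A constant map (no spatial preference) returns 0.5
  everywhere with a warning.
* **Temporal spectrum** — signed first-layer weights averaged over
  channels and neurons give one series per network, read as FIR filter
  coefficients; after mean (DC) removal its one-sided rectangular-window
  periodogram is returned (signed averaging preserves oscillatory
  structure; absolute averaging is available behind a flag). The
  integrated periodogram equals the series variance (Parseval).
* **Layer-count comparison** — two-sided Wilcoxon rank-sum, exact
  enumeration when both groups have ≤ 10 values, otherwise the normal
  approximation with midrank tie correction.
* **Transfer test** — each subject's per-fold networks are scored on
  their own test folds and on the other subject's test folds (fold i
  paired with fold i); a two-tailed paired t-test across folds
  summarises subject specificity. Montages and epoch geometry must
  match.

## EMG labeling

Trailing (causal) sliding-window RMS — alignment is not prescribed by
convention; causal windows avoid pre-onset leakage — with a 500 ms
window. An event is the first sample of each excursion above a per-side
manual threshold (a helper suggests 1.5× the 99th percentile of a marked
baseline); any candidate within the 300 ms refractory period of the last
accepted event is suppressed, and a simultaneous left/right crossing
resolves to LEFT with a logged warning. Movement epochs span
[onset − 100 ms, onset + 300 ms); rest epochs are 400 ms windows tiled
deterministically from the start of every interval that has no event
within ±500 ms, optionally subsampled with a seeded RNG. Class order is
fixed: (LEFT, RIGHT[, NO_MOVEMENT]).

## Synthetic data

`synth_epochs` draws class-conditional epochs: background noise (pink,
1/f-amplitude-shaped, by default; white for unit tests) plus, for each
movement class, a Hann-enveloped 8 Hz carrier of configurable microvolt
amplitude on that class's planted channels, starting at the within-epoch
onset. `synth_stream` embeds the same components in a continuous
recording and adds two EMG channels that are quiet (unit-SD noise) except
for 200 ms amplitude-modulated noise bursts (60× baseline, instant
attack) at the known squeeze onsets. Defaults mirror the recorded-data
operating point: 250 Hz, 0.4 s epochs (0.1 s pre / 0.3 s post), 8 EEG
channels, effects on channels {2, 3} (left) and {5, 6} (right).

The generator produces onset-locked evoked-style components rather than
oscillatory desynchronization, no artifacts (eye blinks, jaw EMG), and
stationary noise. Passing tests therefore demonstrate that the pipeline
recovers planted spatio-temporal structure at realistic SNR — not that it
handles non-stationarity, artifacts, or the physiological variability of
real recordings.

## Experiment scales and conditions

All experiments run on one CPU in minutes; sizes were fixed once, as the
package's desk-scale operating points:

* **Annealing benefit** — 60-epoch sets (30/class), amplitude 3 µV in
  2 µV pink noise, one 8-neuron hidden layer, 20 paired seeds; the
  one-sided paired t-test on validation kappa (SA vs plain SCG) and the
  across-seed SD difference are reported. The moderate SNR and small
  sample are deliberate: with abundant easy data both routes saturate and
  the annealing advantage vanishes.
* **Spatial recovery** — amplitude 2 µV in 2 µV pink noise, 100
  epochs/class, 400 SCG iterations with patience disabled. Near-threshold
  SNR keeps training gradients alive long enough for weight mass to
  accumulate on the informative channels; at very high SNR the network
  separates the classes before its first layer moves far from
  initialisation and the map stays uninformative.
* **Subject specificity** — two 12-channel synthetic subjects with
  disjoint planted channel sets ({2,3}/{4,5} vs {8,9}/{10,11}),
  amplitude 6 µV, 40 epochs/class.
* **End-to-end** — a simulated 2-minute session with 60 alternating
  squeezes, labeled from EMG, decoded with a per-fold GA at population 6
  and 3 generations.

## Known limitations

* The null-SE significance test is asymptotic; at very small N a
  permutation test (used as an oracle in the test suite) is preferable.
* GA fitness evaluates each genome once; kappa noise on small validation
  splits therefore perturbs selection. The elite guarantee applies to the
  recorded fitness, not to an independent re-evaluation.
* The exact rank-sum enumeration ignores tie corrections (relevant only
  for the small layer-count samples it is applied to).
* The EDF writer covers the plain-EDF subset needed for fixtures and
  simulation output (16-bit, uniform record length, no annotations).
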