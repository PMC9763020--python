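# Methods

## Problem setting

`eegstress` classifies trials of multichannel EEG into *stressed* vs
*unstressed* states from DEAP-style recordings: per participant, a
`trials × channels × samples` array (40 × 40 × 8064 at 128 Hz in the full
configuration) with per-trial self-assessment ratings (valence, arousal,
dominance, liking, each on a 1–9 scale). The binary label derives from the
circumplex model of affect: a trial whose valence falls at or below the
scale midpoint (threshold 5, configurable) is labeled stressed; both
arousal branches of the rule yield the same label, so arousal is carried
but non-determining. The boundary value maps to the stressed side — a
documented choice, since the midpoint itself is ambiguous.

The pipeline is a fusion of standard stages whose *combination* is the
object of study: wavelet de-noising and sub-band feature extraction,
correlation-filter feature selection, ADASYN class balancing, and —
the distinctive step — affinity-propagation (AP) clustering used as a
stratified sampler, so that the classifier trains only on cluster
exemplars rather than the full row population.

## Synthetic data generator

Licensed EEG corpora cannot be redistributed, so the package ships a
generator that emulates the DEAP geometry and a known, class-dependent
band-power structure. Each trial is a sum of five band-limited components
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–45 Hz): per
channel, a sinusoid with uniformly drawn in-band frequency, uniform phase,
and ±20 % amplitude jitter, scaled so the component RMS equals the
configured band amplitude. Stressed trials elevate beta (16 vs 7) and
gamma (8 vs 3) and suppress alpha (10 vs 20, arbitrary µV-like units);
slow bands are identical across classes. This encodes the classic frontal
stress correlate and gives the frequency features a real effect to find.
White Gaussian noise (SD 4) and Poisson-count single-sample spike
artifacts (rate 0.5 per channel-trial, amplitude 150) give the de-noiser
measurable work. Valence is drawn uniformly from [1, 4.5] for stressed
and [5.5, 9] for unstressed trials; arousal, dominance and liking are
uniform on [1, 9], making arousal uninformative by construction. The
stressed fraction defaults to 0.3 — deliberately imbalanced so the
balancing stage is exercised — with deterministic rounding of the
per-participant stressed-trial count.

What the generator does *not* emulate: volume conduction and spatial
channel correlation, 1/f spectral shape, non-stationarity within a trial,
realistic artifact morphology (eye blinks, EMG bursts), or inter-subject
variability. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers planted frequency-domain effects; they
do not certify classification performance on real EEG.

Each participant draws from an independent child of the master seed
(`numpy` `SeedSequence.spawn`), so streaming one participant at a time and
materializing the whole list give bitwise-identical data. At full DEAP
scale the dataset is ~6 GB in float32; the streaming iterator is the
intended interface there.

## Wavelet de-noising and sub-band extraction

De-noising is classic wavelet shrinkage: multilevel DWT with the
Daubechies-8 mother wavelet, 8 decomposition levels, symmetric boundary
extension (deterministic, low edge artifacts); soft thresholding
`x → sign(x)·max(|x|−t, 0)` of the detail coefficients; inverse transform
trimmed to the input length. The threshold is the universal threshold
`t = sqrt(2 ln n)` computed per detail level with that level's own
coefficient count `n`. Two threshold modes are exposed: `literal` (the
bare universal threshold, the default) and `sigma_scaled`, which
multiplies by the robust noise estimate `median(|cD1|)/0.6745` from the
finest detail band. The approximation band is never thresholded — the
low-frequency trend is signal, not noise. Without thresholding the
transform reconstructs to ~1e-15, and tests enforce 1e-8.

Sub-band signals are reconstructed from individual coefficient sets of
the *same* decomposition (all other coefficients zeroed), so by linearity
the bands sum exactly to the de-noised signal when the map covers each
coefficient set once. Two band maps ship:

* `TABLE_BAND_MAP` (wavelet-module default): CD5→gamma, CD6→alpha,
  CD7→beta, CD8→theta, CA8→delta, with the nominal 30–60/15–30/8–15/4–8/
  0–4 Hz annotations often quoted with it. At a 128 Hz sampling rate these
  level assignments are not physically consistent with the annotations:
  CD5 spans 2–4 Hz, and all five mapped sets together cover only 0–4 Hz.
* `RATE128_BAND_MAP` (pipeline default): the sampling-rate-consistent
  assignment for 128 Hz data on the same 8-level transform — D1→gamma
  (32–64 Hz), D2→beta (16–32), D3→alpha (8–16), D4→theta (4–8), and the
  union {D5…D8, A8}→delta (0–4).

The pipeline defaults to the rate-consistent map because with the nominal
table map every extracted "band" of a 128 Hz recording carries only
slow-wave content and the alpha/beta/gamma class effects are invisible to
the features. The table map remains available and is the module-level
default for fidelity to the published level convention.

## Feature extraction

Fifteen features per band, 75 columns with five bands, one row per
(participant, trial, channel). Ten time-domain statistics: variance and
standard deviation (N−1 denominator), min, max, mean, RMS, skewness and
kurtosis as population standardized central moments (kurtosis plain —
Gaussian → 3 — not excess; both defined as 0 for a constant signal),
median, and mode. The mode of continuous data is ill-defined, so it is
the midpoint of the most populated bin of a 64-bin fixed-width histogram
over the signal's range (ties resolve to the lowest bin — deterministic).
Five frequency-domain features: energy `Σx²`; absolute power `Σx²/N`;
mean power spectral density, the mean of the one-sided periodogram
`|DFT|²/N` (one-sided so that, by Parseval, it does not collapse into a
duplicate of absolute power); and Shannon and log-energy entropies of the
squared samples normalized to sum 1 (`p_i = x_i²/Σx²`), with the
`0·log 0 := 0` convention — Shannon entropy `−Σ p_i ln p_i` is then
non-negative and bounded by `ln N`.

Column order is deterministic: band-major, fixed feature order within a
band. Feature extraction runs vectorized along the channel axis of one
trial at a time, so full-DEAP-scale matrices (51,200 × 75) build in a few
minutes on one CPU while memory stays at one participant's recording.

## Feature selection

Each feature column is scored by |C|, the absolute Pearson correlation
(direct implementation of the sample formula) against the binary label;
magnitude rather than signed C, because for a binary target relevance is
direction-free. Constant columns score 0. Ranking is pooled at the
feature-name level: the 15 names are scored by their mean |C| across the
five bands, and a selected name is kept in *every* band, so the top-10
selection maps 75 → 50 columns. Ties break by first-seen column order
(stable sort).

Forward selection walks the ranking: the first feature is always kept;
each next feature is kept only if the evaluator's accuracy strictly
improves, and the search stops at the first non-improvement (patience 1)
or at the cap of 10. The default evaluator is stratified 5-fold CV
accuracy of the pipeline's own network with a short training budget
(8 hidden units, 60 epochs) and a fixed seed — the selection is then
deterministic and fast. On strongly redundant synthetic features the
stopping rule often halts well before 10; the cap, not the typical count,
is the contract.

## ADASYN balancing

Adaptive synthetic oversampling closes the class gap by
`G = (majority − minority)·β` synthetic minority points (β = 1 and k = 5
neighbors by default, the algorithm's canonical settings). Features are
standardized to zero mean/unit variance for the neighbor searches only
(the features span ~10 orders of magnitude; Euclidean distance on raw
columns would be meaningless) and synthetic rows are emitted on the
original scale. Each minority point i receives a share of G proportional
to `r_i`, the fraction of majority samples among its k nearest neighbors
(density adaptation: border points get more copies); shares are converted
to integers by largest-remainder rounding so the total is exactly
`round(G)`. A synthetic point is `x_i + u·(x_z − x_i)`, `u ~ U[0,1]`,
with `x_z` drawn from x_i's k nearest *minority* neighbors — every
synthetic point is a convex combination of two original minority rows.
Original rows are never modified; synthetic rows carry sentinel keys
(`participant = trial = −1`, `channel = "synthetic"`). If no minority
point has any majority neighbor (`Σr_i = 0`, fully separated classes)
nothing is synthesized and a warning is issued.

## Affinity-propagation stratified sampling

Similarity is negative squared Euclidean distance; the diagonal
("preference") is the minimum or median of the off-diagonal similarities —
the off-diagonal pool, matching common practice; the mode controls the
exemplar count (min → fewer). The message updates are the standard
responsibility/availability recursions with damping
`new = (1−λ)·computed + λ·previous`, λ ∈ [0.5, 0.9], default 0.5.
A seeded symmetry-breaking noise at relative scale 1e-12 is added to the
similarities, since exactly symmetric inputs make the message dynamics
oscillate; the perturbation is far below any meaningful similarity
difference and keeps runs reproducible. Convergence is declared when the
exemplar set (positive diagonal of the criterion `C = R + A`) is
unchanged for 15 consecutive iterations; hitting the 200-iteration cap
returns the last state with a warning, not an exception.

Exemplar extraction follows the canonical reference procedure: the
criterion diagonal fixes the number of clusters and the criterion row
argmax fixes membership, then within each cluster the representative is
re-picked as the member maximizing the summed within-cluster similarity.
This final refinement is part of the original published implementation
and measurably improves the fixed point's net similarity; exemplars are
always actual data rows. Each exemplar carries the majority class label
of its cluster (ties toward label 0/unstressed — the conservative,
documented choice). AP is an approximate maximizer of net similarity: on
small random instances it almost always attains the exhaustive-search
optimum, but occasional instances exist where the damped message fixed
point (in this implementation *and* in the reference one, identically)
settles on a slightly suboptimal exemplar set; tests therefore validate
the implementation by equivalence with the independent reference rather
than by asserting universal optimality.

K-means (representative = member nearest the centroid) and K-medoid
(alternating medoid update) samplers provide like-for-like baselines
under the same contract; in the pipeline their K defaults to √n since,
unlike AP, they need the count supplied. Davies–Bouldin, Dunn and mean
silhouette indices quantify cluster validity; all three are invariant to
cluster relabeling, and an all-singleton clustering is rejected as
degenerate for the silhouette.

In the pipeline the sampler sees only the *training* portion of the
balanced matrix (standardized for clustering); the held-out test rows
come from the full balanced population, so the classifier is always
evaluated on rows it never saw in any form.

## Classifier and evaluation

The classifier is a single-hidden-layer feed-forward network trained by
full-batch backpropagation on binary cross-entropy: 10 logistic hidden
units (tanh available), sigmoid output, Glorot-uniform seeded
initialization, Adam-style adaptive steps (lr 0.05, 300 epochs by
default). Inputs are standardized internally. Given a seed, training is
deterministic to floating-point reproducibility. Single-class training
data is rejected.

Evaluation reports the five confusion-matrix metrics — accuracy,
precision, recall, specificity, F1 — with stressed (label 1) as the
positive class, over a class-stratified 4:1 (80/20) hold-out split.
Stratified 10-fold cross-validation is available; when the fold count
exceeds the smaller class (the leave-one-out limit) it falls back to
plain K-fold, since per-fold stratification is then impossible.
Zero-denominator metrics are defined as 0. SVM (RBF) and random-forest
baselines wrap scikit-learn under the identical split and metric
contract — they are comparison plumbing, not re-implementations.

## Orchestration and reproducibility

`run_pipeline` executes read/generate → channel selection (10 frontal
channels FC1, FC2, FC5, FC6, F3, F4, F7, F8, FP1, FP2 by default) →
de-noise + features (first 20 trials by default) → selection → balancing
→ split → sampling → classification, logging row/column counts per stage
and aborting with the failing stage named (partial outputs retained).
A single global seed spawns independent child seeds for every stochastic
stage, so one (config, seed) pair reproduces its report exactly. Configs
round-trip through flat YAML; every stage parameter (db8, 8 levels,
λ = 0.5, preference mode, threshold 5, top-10 cap, 20 trials, 80/20
split, k = 5, β = 1) is explicit there.

## Problem sizes used in the shipped checks

The structural check runs at the full synthetic DEAP dimensions
(32 × 40 × 40 × 8064 → 51,200 × 75 matrix; ~3 minutes, one CPU, streamed
one participant at a time). The end-to-end classification checks run at
reduced participant counts (4–6 participants, 20 trials, 10 channels,
800–1,200 rows) — large enough for stable hold-out metrics on the planted
effect, small enough that the AP similarity matrix and message iterations
stay cheap. The planted-feature recovery experiment uses 600 rows with 3
informative features (effect 0.7 SD) among 17 noise features, sized so
each informative addition yields a CV-detectable accuracy gain.

## Known limitations

* The generator's simplifications (above) mean measured metrics
  characterize the machinery, not clinical performance.
* The nominal table band map is kept available for convention fidelity
  despite its physical inconsistency at 128 Hz; analyses of 128 Hz data
  should use the rate-consistent map (the pipeline default).
* ADASYN's synthetic rows inherit no meaningful (participant, trial,
  channel) keys; downstream per-participant analyses must exclude them.
* AP is O(n²) memory and per-iteration time; the pipeline applies it to
  the training split at reduced scale. Sparse or hierarchical AP variants
  are out of scope.
* Exemplar-only training discards within-cluster variance; no weighting
  of exemplars by cluster size is attempted.
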