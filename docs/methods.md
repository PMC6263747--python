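# Methods

This note documents the models implemented in `symhar`, the parameter
defaults and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical conventions that matter for reproducibility.

## Segmentation and normalization

Signals are cut into half-open windows `[start, start + w)` with 0-based
starts at multiples of `stride = round(w · (1 − overlap))`. Window labels use
the majority of per-sample labels (ties broken by the earliest sample in the
window); a `strict` policy discards mixed-label windows instead. Defaults
follow common HAR practice: 1 s windows (`w = fs`) for symbolic methods, 5 s
for baseline features, 50% overlap in the segmentation layer.

Window z-normalization uses the **population** standard deviation (the
convention of the SAX literature). Windows whose deviation falls below
`sd_floor = 1e-8` map to the all-zero vector; with half-open breakpoint bins
this sends constant windows deterministically to the letter whose bin
contains 0 (letter `c` for a 4-letter alphabet).

## SAX

A window is z-normalized, averaged into `l` PAA frames, and each frame mean
is mapped to a letter via standard-normal quantile breakpoints
`β_i = Φ⁻¹(i/c)`. Numerical choices:

- **Half-open bins** `[β_{i−1}, β_i)`: a value exactly at a breakpoint takes
  the higher letter.
- **Fractional PAA frames** when `l` does not divide `w`: boundary samples
  are weighted proportionally to their overlap with the frame, so the result
  is exact block means whenever `l | w` and defined for every window length.
- `sax_mindist` uses the letter-pair cell `0` when letters are at most one
  bin apart, else the gap between the breakpoints separating them, scaled by
  `sqrt(n/l)`. This never exceeds the Euclidean distance between the
  z-normalized raw windows (property-tested on random pairs).

Numerosity reduction keeps the first word of each run of identical
consecutive words. It is lossless given the window stride and the final
start index; `numerosity_expand` inverts it exactly.

## SFA and MCB

The approximation phase keeps the first `l/2` complex Fourier coefficients
(unnormalized forward transform, coefficients indexed from 0) as `l`
interleaved real values. The sliding-window coefficients can be maintained
incrementally via `X_k(p+1) = e^{2πik/w}(X_k(p) − x_p + x_{p+w})`; this
matches a direct transform of every window to ~1e-9 and is property-tested.

Quantization fits one breakpoint row per coefficient column from training
windows **extracted without overlap** (keeping them independent):

- `equi_depth` (default): breakpoints at the `i·N/c`-th order statistics of
  the column. This is the behavior of the established SFA construction; an
  alternative `sorted_prefix` variant (breakpoints from the first `c−1`
  ascending-sorted column values) is kept behind a flag for comparison, but
  it concentrates mass in the top bin and is not recommended.
- Ties are resolved by stable de-duplication (bumping duplicates by a tiny
  epsilon), so breakpoint rows are always strictly increasing and degenerate
  constant columns still define `c` bins spanning the real line.
- `normalize=True` z-normalizes the window before the transform and drops
  the DC term, making words invariant to offset and scale. The default for
  the BOSS-family classifiers is `normalize=False`: for accelerometer data
  the DC coefficient carries gravity orientation, which is exactly what
  separates static postures.

## SFA-W (supervised quantization)

Windows are z-normalized (the F test assumes normal-ish inputs), every
coefficient column the window supports is ranked by a one-way ANOVA F
statistic against the class labels, and the top `l` columns are kept. Each
kept column gets `c − 1` breakpoints by recursive binary information-gain
splitting: every split takes the midpoint between adjacent distinct values
that maximizes label information gain (entropy in bits), and recursion
continues on the partition with the largest remaining label entropy.
Columns with fewer distinct values than `c`, or with no positive-gain cut,
fall back to equi-depth placement over the distinct values.

A caveat worth knowing: the F statistic measures **class-mean** differences
of coefficient columns. A class that differs only through an oscillation
with uniformly random phase has zero-mean real/imaginary coefficients and is
invisible to this selection; phase-consistent structure (as produced by
windows aligned to a trigger, or synthetic data with a stable phase) is what
the supervised selection is designed for.

## Classifiers

- **tf-idf / cosine (SAX-VSM, BOSS-VS).** `tf = log10(1 + f)` for positive
  counts and exactly 0 otherwise; `idf = log10(T / df)` over the `T` class
  bags. Base 10 throughout (configurable). Query weights reuse the training
  idf; words unseen in training contribute 0. A query sharing no word with
  any class raises a no-evidence signal, or falls back to the most frequent
  training class when configured (the default for the end-to-end
  classifiers). Argmax ties keep the first class in order and log a warning.
- **BOSS 1-NN.** Asymmetric distance `Σ_{w: h1(w)>0}(h1(w) − h2(w))²`;
  nearest training histogram wins, ties keep the smallest training index.
- **WEASEL.** Per window size and axis: SFA-W words, unigram counts plus
  bigrams formed by pairing consecutive *non-overlapping* words
  (`w1w2, w3w4, …`). Features are tagged by window size and axis. The
  chi-squared statistic compares a feature's observed per-class counts with
  counts expected from the class priors; **high-statistic
  (class-discriminative) features are kept** (threshold default 2.0; the
  opposite direction is available behind `keep_high=False`). A multinomial
  logistic regression (L2, `C = 1/regularization`, seeded) consumes the kept
  features.

### Windowing defaults per classifier

SAX-VSM uses 1 s windows with 50% overlap. BOSS and BOSS-VS use **dense
stride-1 sliding**, which is how the bag-of-patterns construction builds
per-instance histograms: with only ~9 windows per 5 s instance the
histograms are too sparse for reliable nearest-neighbor matching, while
dense sliding plus numerosity reduction yields stable word distributions.
Both choices are overridable (`overlap=`, `stride=`).

## Axis fusion

- *stack*: words computed per axis with the same window size, tagged by
  axis so per-axis vocabularies never collide; the instance histogram equals
  the sum of the three per-axis histograms (tested as a conservation law).
  An untagged mode is deliberately not offered — tag collisions silently mix
  axis vocabularies.
- *magnitude*: `√(x² + y² + z²)`, rotation-invariant, therefore blind to
  gravity orientation: static postures with equal-norm gravity vectors are
  indistinguishable under this fusion. This is a real weakness of magnitude
  fusion, reproduced by the generator.
- *pca*: 3×3 covariance eigendecomposition of the training samples
  (mean-centered); only the leading component is used. The sign is fixed by
  making the largest-magnitude loading nonnegative. The projection is fit on
  training folds only — refit inside every CV fold.

## Synthetic generator

Harmonic-plus-noise bouts, not a biomechanical simulation: per axis,
`gravity + amplitude · sin(2πf·t + φ) + N(0, σ²)` with a random per-bout
phase and a shared per-bout cadence jitter of ±5%. Defaults (fs = 50 Hz,
5 s bouts, 10 users, 4 bouts per user per class → 160 instances, 40 per
class):

| class | freq (Hz) | amplitude (x,y,z) | gravity | noise sd |
|-------|-----------|-------------------|---------|----------|
| walk  | 2.0       | 0.4, 1.0, 0.4     | (0,−1,0) | 0.10 |
| run   | 3.0       | 0.8, 2.0, 0.8     | (0,−1,0) | 0.15 |
| sit   | —         | 0                 | (0,−1,0) | 0.03 |
| stand | 0.8 sway  | 0.1, 0, 0.3       | (0,0,1)  | 0.03 |

Rationale for the static classes: window z-normalization removes constant
offsets, so a purely constant posture pair would be indistinguishable to
SAX regardless of orientation. Standing humans exhibit low-frequency
postural sway that seated subjects largely lack; the generator gives the
standing class a small 0.8 Hz sway (partly along the gravity axis so it
also survives magnitude fusion) and leaves sitting as pure sensor noise.
The cadence jitter reflects natural step-rate variability and prevents the
walking frequency from being phase-locked to the window stride. Gravity
offsets are unit-norm by default; `distinct_gravity_norms=True` shrinks the
sitting offset to norm 0.6 for magnitude-fusion studies, since magnitude is
orientation-blind by construction.

What passing tests on this generator do **not** show: robustness to device
re-orientation, gait harmonics and impacts, sensor bias/drift, label noise,
or inter-subject variability beyond random phases — real-data accuracy
claims cannot be read off the synthetic numbers. The generator's purpose is
to exercise every discretization and classification path with known ground
truth.

## Evaluation harness

Stratified 10-fold CV at the instance level by default ("user" unit uses
stratified group folds to keep a user's instances in one fold). Every fitted
object (MCB, idf tables, chi-squared mask, PCA fusion, linear model) is fit
inside the training folds only; a recorder test asserts that perturbing
test-fold instances leaves fold fitting unchanged. Reports (fold accuracies,
confusion matrix, timings, config echo, seed) are bit-reproducible given
(data, config, seed).

Cost accounting is canonical rather than in-memory: raw samples cost 8 bytes
per axis; a word costs `ceil(l·log2(c)/8)` letter bytes plus a 4-byte index
(6 bytes for `l=8, c=4`; the 4-letter alphabet uses the 2-bit codes a=00,
b=10, c=11, d=01, round-trip tested); feature tables cost 8 bytes per value.
Wall-clock timings are reported but never asserted — they are
hardware-bound.

Problem sizes used by the test suite and the acceptance script (chosen as
the package's desk-scale defaults): 160 instances of 250 samples, 10-fold
CV, oracle checks on 100–1000 random draws.

## Baseline feature formula ledger

Table-style feature names ship with one documented definition each
(`baseline_features`): amplitude = max − min; amplitude peak = max |x|;
mean absolute deviation about the mean; sum of squared errors about the
mean; population variance/sd; zero-crossing rate = sign changes / (w−1)
(zeros ignored); skewness/kurtosis via standardized moments (0 for constant
windows); lag-1 autocorrelation normalized by the window's own variance;
area / absolute area = trapezoidal sums; signal magnitude area =
mean(|x|+|y|+|z|); Pearson correlation and lag-0 normalized
cross-correlation per axis pair at the instance level. Frequency features
use the magnitude spectrum with Parseval-consistent energy `Σ|F|²/n`,
normalized energy = energy / half-spectrum length, power = energy / w,
spectral centroid in bin units over non-DC bins, normalized Shannon entropy
of the magnitude-squared distribution (0·log 0 := 0), DC = mean, peak =
non-DC bin of maximum magnitude, coefficient sum. The wavelet variant feeds
the same list from a single-level Haar decomposition (orthonormal, so the
energy identity still holds); it is an approximate-fidelity interpretation,
as is the definition of the less standard "area" family.

## Known limitations

- SFA-W's ANOVA selection misses purely phase-random class differences (see
  above); a variance-sensitive statistic would be needed for those.
- The WEASEL classifier underperforms the simpler bag classifiers on the
  fused triaxial synthetic data, mirroring its behavior on fused real
  signals; it is included for completeness, not as the recommended default.
- Magnitude fusion cannot separate static postures whose gravity vectors
  share a norm; this is a property of the transform, not a bug.
- Timing numbers depend on the host; only representation-size claims are
  asserted.
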