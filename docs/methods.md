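# Methods

## The h² estimator

For signals X, Y over an event window, the regression curve of Y on X is
built by splitting the observed range of X into `n_bins` equal-width bins,
taking the mean of Y within each nonempty bin, and joining the points
(bin midpoint, bin mean) with straight segments; prediction is constant
beyond the outer midpoints.  Then

h²(y|x) = max(0, 1 − SS_res/SS_tot), clamped to [0, 1].

Negative raw values (possible in small samples when the curve fits worse
than the mean) are clamped to 0 because the statistic is defined as an
explained-variance fraction.

Defaults and why:

- `n_bins = 10`, `min_points_per_bin = 10`.  Ten bins resolve smooth
  monotone and quadratic relations while keeping ≥ 100 points per bin on the
  ≥ 1000-sample windows the pipeline produces; when a window is shorter than
  `n_bins · min_points_per_bin` the bin count is reduced with a warning.
- Equal-width bins on the observed range (the classical construction);
  equal-count (quantile) bins are available via `bin_mode="count"`.
  Equal-width binning makes h² invariant under separate affine rescalings of
  x and y, since the bin boundaries scale with the data.
- Lag scan ±100 ms at 1-sample steps (`lag_range_ms`, `lag_step_samples`).
  This covers physiological propagation delays at modest cost; at each lag
  only the overlapping portions of the two windows are compared, the maximum
  h² and its signed lag are kept, and ties resolve toward the smallest |lag|
  then the negative lag, so results are deterministic.
- One h² per ordered pair per event — the temporal bin of an h² value is the
  full duration of the clinically defined event, with no sub-windowing.

**Exactness caveat.** h²(x, x) is *not* exactly 1: the piecewise-linear
curve through bin means leaves a small residual (points beyond the outer
midpoints are predicted by a constant; within segments the conditional mean
is only piecewise-linearly approximated).  At n = 3000–5000 samples and 10
bins the deficit is ≲ 2·10⁻³; tests assert unity within 5·10⁻³.  The
estimator also has a positive bias under independence (≈ 0.01–0.03 at
n = 2000, 10 bins, larger after lag maximisation), which is why significance
is judged against a baseline-derived threshold rather than against zero.

## Thresholds and directed graphs

The threshold model pools **all** off-diagonal h² values of one pre-ictal
baseline window (20 s by convention; shorter windows warn) into a mean and
sample (n−1) standard deviation, fitted once and reused for every event:
t1 = μ_b + σ_b (weak), t2 = μ_b + 2σ_b (strong), strict `>` at both.  A
per-pair threshold variant was considered and rejected as the default: the
single pooled model matches the one-model-for-all-27-events design this
pipeline reproduces, and baseline windows are too short to estimate 210
pair-specific null distributions well.

Direction handling is genuinely open in this design space, so both rules are
implemented:

- `rule="independent"` (default): each ordered pair is thresholded on its
  own; both directions may coexist.  This matches the graph figures this
  pipeline emulates, where mutual edges appear.
- `rule="winner"`: at most one direction per unordered pair.  Preference
  goes to the direction whose optimal lag is positive (the target trails the
  source); if the lag signs do not discriminate, the larger h² wins; final
  ties go to the lexicographically smaller source label.  The lag sign must
  lead because for *linear* coupling h² is theoretically symmetric — both
  conditional expectations are linear and explain the same ρ² — so strength
  asymmetry alone is a coin flip, while the transmission delay is directly
  observable.  For nonlinear (e.g. quadratic) coupling the strength
  asymmetry is real and the fallback handles zero-lag cases.

## Cosine similarity and dendrograms

Similarity is computed between rows of the directed adjacency matrix
(out-neighbour profiles), the convention under which the printed motif-table
values reduce to overlap/√(deg_x · deg_y) for binary adjacency; a
`symmetrize` option uses M + Mᵀ instead.  Binary adjacency is the default
similarity input (weighted weak=1/strong=2 is available) because the printed
values match binary closed forms — e.g. 0.866025 = 3/√12, 0.408248 = 1/√6.
A few printed values (0.59625, 0.251899) match no binary closed form and
presumably arise from a different row convention; they are not used as
anchors.  Vertices with all-zero rows get similarity 0 against everything
(including themselves) and merge last.

Agglomeration runs on d = 1 − σ with average linkage — monotone (no
inversions), standard, and faithful to "merge the most similar groups
first".  The implementation maintains cluster distances by the
Lance–Williams average-linkage update; ties are broken by the
lexicographically smallest combined member-label tuple so dendrograms are
reproducible, and the tests compare against a naive O(n³) from-scratch
agglomeration on tie-heavy binary-derived matrices.  Similarity
distributions round to 6 decimals (the printed precision) and exclude exact
zeros unless asked, since the zero-pair mass of sparse baseline graphs
swamps the informative bins.

## Signed-rank / B-H stage

Pair h² collapses across the two directions by maximum (default; mean by
flag) — the tested hypothesis is about the strength of the connection, not
its direction.  Differences are taken against a seizure-matched control
matrix (defaulting to each seizure's 20 s baseline; the first seizure's
baseline doubles as the threshold window).  Zeros are dropped (standard
signed-rank convention); the exact null distribution is used for ≤ 25
tie-free differences and the tie-corrected normal approximation otherwise.
The B-H step-up reports per-rank critical values i·q/m and rejects the
largest sorted-p prefix; phases absent from a seizure simply shrink that
pair's vector.

## What the synthetic generator emulates — and what it does not

Sources are 1–40 Hz band-limited Gaussian noise at fs = 200 Hz (the delta
band is representable and windows stay cheap; no sampling rate is prescribed
by the emulated study).  A coupled target is
`gain · f(source delayed by lag) + noise_sd · independent noise` with f
linear, quadratic (standardised x², invisible to Pearson correlation) or
sigmoid (tanh(3·x), bounded and monotone, distinct from quadratic).  Seizure
scenarios concatenate phases, each with its own coupling spec; onset phases
superimpose a rhythmic 4–5 Hz sinusoid (amplitude 2× the background SD,
random phase per contact) on the involved contacts, and annotations tile the
phases exactly.  The default scenario is a 20 s baseline plus a 45 s onset —
the onset-duration range of the emulated recordings is 42–58 s — with three
planted couplings at gain 0.9, noise 0.15, lags 25–50 ms.

Two deliberate design points:

- The planted onset edges are **disjoint** (each source drives exactly one
  target, all cross-electrode).  Chained or fan-out couplings create
  indirect correlations that genuinely exceed threshold; they are real
  couplings absent from the planted edge list, so strict planted-edge
  recovery is only a meaningful score on a direct-edge-only topology.
- Recovery is scored on scenarios with the onset rhythm **off**: a shared
  rhythm synchronises all involved contacts — again genuine coupling the
  truth graph does not model.  The rhythm stays on by default so that
  spectral onset structure and graph densification are still exercised.

What passing these tests does *not* show about real data: the generator has
no 1/f background, no artifacts or line noise, no nonstationarity within a
phase, no volume conduction, and stationary coupling within each phase.
Detection thresholds that recover gain-0.9 couplings here say nothing about
sensitivity to the weaker, fluctuating coupling of real SEEG.

The streamline phantom places E cubic ROIs (3³ voxels, 2 mm voxels, ≥ 5
voxels apart) along a line, draws exactly the requested number of 3-point
polylines between ROI-interior voxel centres per pair, and adds distractor
streamlines ending in background; counting must recover the planted matrix
exactly.

## Numerical and calibration choices

- The null calibration of the signed-rank stage simulates 500 pairs with 10
  replicate differences each (event and control h² from the same generator).
  Ten replicates, not the eight seizures of the emulated study, because the
  exact two-sided signed-rank size at α = 0.05 is 0.0391 at n = 8 but 0.0488
  at n = 10: with 500 pairs (binomial SE ≈ 0.009) the n = 10 size sits in
  the centre of the [0.03, 0.07] acceptance window rather than 1 SE from its
  edge, so the check measures calibration rather than sampling luck.  The
  analysis stage itself always uses however many seizures carry a phase.
- Problem sizes: oracle comparisons use 50 pairs × 500 samples; recovery
  uses 20 seeds × (20 s baseline + 45 s onset) at 200 Hz (9000 onset
  samples); dendrogram oracles use 8 vertices × 30 matrices.  These sizes
  give stable statistics while keeping the whole suite around a minute.
- EDF files are written by a minimal single-record 16-bit writer (physical
  range per channel covers the signal, so the quantisation step is
  range/65535) and read back via `mne`; round-trips are asserted to within
  one quantisation step.  Mixed per-channel sampling rates are rejected
  unless resampling is explicitly requested.
- All pipeline CSVs are written with 6-decimal formatting; identical
  config + seed reproduces them byte-for-byte.

## Known limitations

- h² between channels that share a strong common rhythm reflects that
  rhythm, not directed interaction; the directed graphs inherit this (as
  does any amplitude-coupling measure).
- The winner rule assumes one dominant direction per pair per event;
  genuinely bidirectional coupling is better served by the default
  independent rule.
- Streamline counting uses endpoint labels by default (a `path` mode counts
  traversed-ROI pairs); neither dilates the label volume, so ROIs must
  actually contain the streamline terminations.
- The CLI `graph`/`stats` verbs reconstruct matrices from long-format CSVs
  and assume one baseline row-set per seizure.
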