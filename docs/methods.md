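# Methods

## Model and assumptions

The decoder is a 3-state hidden Markov model over per-frame observation
vectors z_k = (x, y, L): marker position plus step length, one frame per
0.5 s. It assumes (i) first-order Markov state dynamics, homogeneous in
time and shared across animals; (ii) conditionally independent emissions,
z_k depending only on s_k, each p(z | s) a Gaussian mixture with diagonal
component covariances; (iii) observer labels that are correct, so both model
parts can be estimated supervised — transitions by counting, emissions by EM
on the frames carrying each label. There is no Baum–Welch re-estimation and
no Viterbi: decoding maximizes each frame's *smoothed marginal*
p(s_k | Z_K), which can (rarely) produce state paths with zero joint
probability; per-frame marginal accuracy is the quantity the concordance
metric scores, so the marginal decoder is the matching choice.

Two assumptions are knowingly wrong and accepted: step length is
non-negative and right-skewed, not Gaussian (a gamma or Weibull marginal
would fit better; mixtures absorb much of the misfit), and L(k) uses frame
k+1, so consecutive observations are not strictly conditionally independent.

## Estimation details and numerical choices

* **Transitions.** p̂_ij = count(i→j)/count(i→·) pooled over training
  animals (estrus and non-estrus together). A state with no outgoing
  transitions gets a uniform row; zero cells are floored at ε = 1e−10 and
  the row renormalized, keeping log-probabilities finite without materially
  moving the counts. π is the empirical first-frame label distribution and
  is *not* floored — a state no training animal ever started in keeps prior
  zero, which the log-space recursions handle.
* **Emissions.** sklearn's EM (diagonal covariances, seeded k-means
  initialization, 200 iterations max, tolerance 1e−8, single restart), with
  a variance floor of 1e−6 squared length-units so degenerate coordinates
  keep a finite density. The component count is picked per state by AIC
  with 7m−1 free parameters (m·3 means, m·3 variances, m−1 weights) over a
  default grid m = 1…15; ties go to the smaller m. Non-convergence returns
  the best iterate with a warning flag rather than failing.
* **Recursions.** Forward filtering and Rauch-style backward smoothing run
  in log space with per-step normalization; the normalizers accumulate the
  data log-likelihood. The backward ratio uses a zero-guard (terms with zero
  predictive probability contribute zero). MAP ties break to the smallest
  state index. A brute-force 3^K path-enumeration oracle (K ≤ 10) verifies
  the recursions to ~1e−13; hmmlearn serves as a second, independent
  cross-check in the tests only.
* **Step length at the last frame.** L(K) is undefined by the forward
  difference; the last defined value is carried forward so every frame has a
  full 3-vector and per-animal frame counts are preserved. A "drop" mode is
  available.
* **Concordance.** Frame-level counting with a ±1-frame window (configurable),
  truncated at sequence edges, no event segmentation. PC, FP%, FN% are shares
  of TP+FN+FP, so they sum to 100 per behavior; all-zero counts score
  PC = 100 by convention.
* **t-test.** Budgets are per-animal pairs (same animal, observer vs
  method), so the default is the paired two-sided t-test on differences;
  Welch's unpaired variant is available by configuration. Zero-variance
  differences return a flagged degenerate result instead of raising.
* **Comparators.** Random forest: 500 trees, one feature per split. SVM:
  RBF kernel, grid 10^{−2..5} (kernel width) × 10^{−1..3} (cost) under
  k-fold CV with k = ⌊1 + log2 n⌋ (Sturges; 14 at n = 9600); the selected
  pair is recorded per run rather than hard-coded, and k is capped at the
  smallest class count on toy inputs. Neural network: one hidden layer of
  10 units. SVM and NN inputs are standardized inside a pipeline; the
  forest is scale-free and takes raw features.

## Synthetic cohorts

The generator emulates the structure of the motivating experiment: 16
animals (8 estrus / 8 non-estrus), 1200 frames each, a unit-square pen with
the male paddock adjacent to the x = 0 side (physical 2.5 m scaling is a
config field). States evolve by a Markov chain; positions follow a
state-attracted correlated walk — each frame the animal closes a fraction
(default 0.3) of the gap to its current state's anchor point and adds
Gaussian displacement noise scaled by the state's speed, clipped to the pen.
Anchors are redrawn from the state's position kernel on state entry, so
approaching produces large steps toward small x, standing tiny steps hard
against the male side, and state 0 mid-pen wandering: all three observables
carry state information. Labels equal the generating states, optionally
flipped uniformly at a label-noise rate. Per-animal seeds are
cohort-seed + animal-index.

Defaults (speeds, dwell probabilities, kernel placement) are chosen for
testability — clear but not trivial separation — because the source study
reports no quantitative movement parameters; they are not biological
estimates. The default estrus chain has strong self-transitions
(0.88–0.97) and favors states 1/2; the non-estrus chain dwells in state 0
(self-transition 0.975). Estrus and non-estrus groups therefore need
*different* true transition matrices, so the cohort config carries one
profile per group.

A second factory, `recovery_config()`, defines the parameter-recovery
conditions: one shared true transition matrix for every animal and widely
separated (≳10σ) position kernels with positions drawn i.i.d. per state
("gaussian" mode, matching the decoder's own emission assumptions). The
pooled supervised estimate then has a single well-defined truth; with 8
training animals × 1200 frames the counted transition matrix lands within
~0.005 of it and held-out decoding is essentially exact. What passing these
tests shows is internal consistency — the estimator recovers the generative
process it assumes — not field performance: real tracks have occlusions,
observer error, non-Gaussian step lengths and between-animal heterogeneity
that the generator only reaches via its label-noise and walk modes.

## Experiment orchestration

`run_experiment` trains every requested method on the training animals
(default: first half of each group, mirroring the 4+4 study split), decodes
all animals — training animals included but flagged, as the study reports
them — and writes tidy CSVs (concordance, budgets, t-tests, timings,
summary), the fitted model as JSON (repr-based floats, bit-exact
round-trip), the truth manifest, and a run log of resolved settings.
Summaries are reported pooled and held-out-only, since pooling flatters
frame-wise classifiers that overfit their training animals. Wall-clock
timings are informational only. A failing method is recorded and the run
continues. Reruns with the same config and seed are byte-identical.

## Problem sizes used in the checks

The acceptance script runs the recovery cohort at the study's native scale
(16 animals × 1200 frames, 8 training), 50 random oracle instances at
K ≤ 8, AIC recovery at n = 5000 per mixture, and 1000 t-test null
replicates at n = 8 — a few tens of seconds in total. Unit tests use
shorter tracks (120–400 frames) for the same properties.

## Known limitations

* Gaussian step-length marginals (see above); positive-support distributions
  are the natural refinement.
* Homogeneous, covariate-free transitions; no per-animal random effects.
* The SVM comparator's grid bounds in the source analysis are ambiguous;
  the defaults here bracket the plausible readings and the selected pair is
  logged per run.
* Marker tracking itself (video, detection) is out of scope; the pipeline
  starts at the coordinate table.
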