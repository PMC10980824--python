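# Methods

This note documents the models, conventions and design choices behind
`restdyn`, the way a maintainer would want them recorded: what each
stage assumes, which knobs matter, what the synthetic generator does and
does not emulate, and where genuinely open choices were settled.

## Synthetic data generator

The generator is the package's substitute for non-redistributable
source-space MEG recordings; its defaults encode the study conditions
the pipeline targets.

**Generative model.** A first-order Markov chain s_t ∈ {0..K−1} with
initial distribution π and row-stochastic transition matrix A emits node
envelopes

    x_n(t) = baseline + M[s_t, n] + ε_n(t),   ε_n(t) ~ N(0, σ²)

with optional additions: a linear mixing matrix applied instantaneously
to the node vector (spatial leakage is instantaneous and linear in MEG
theory), and slow shared components (white noise moving-averaged over a
timescale, default 1 s) added to node groups to emulate supra-second
amplitude coupling. The additive-Gaussian observation model matches the
Gaussian observation model the HMM assumes, which makes recovery
benchmarks well-posed: failures indicate pipeline defects, not model
mismatch.

**Defaults (study conditions).** 30 subjects, 7 sessions (RS1..RS7),
126 nodes, K = 8 states, fs = 40 Hz, T = 12000 samples (5 min at
40 Hz). Self-transition 0.85 gives geometric mean lifetimes of
1/(1−0.85) ≈ 6.7 samples ≈ 167 ms, inside the 100–200 ms range typical
of transient envelope states. State patterns are block designs
(amplitude 1 on a state's node group, −1/(K−1) elsewhere) with noise
SD 0.3, i.e. pattern SNR ≈ 3.3. Inter-subject connectome variability
uses edge SD 0.15, a typical between-subject spread of envelope
correlations.

**Seeding.** One top-level seed; every (subject, session) recording
draws from `SeedSequence(seed, spawn_key=(subject, session))`, with the
envelope noise stream a spawned child of the same sequence. Identical
configs are bit-identical; distinct recordings are independent.

**What the generator does not emulate.** No 1 kHz oscillatory carrier
with realistic MEG spectra (envelopes are generated directly at 40 Hz),
no head geometry or realistic leakage kernels, no non-Gaussian envelope
marginals (real Hilbert envelopes are Rayleigh-like), no
autocorrelated observation noise, no session or habituation effects.
Passing recovery tests therefore demonstrates correctness of the
algorithms under their own assumptions, not robustness to real-data
violations of those assumptions.

**Keypress streams.** Presses follow the cyclic 4-1-3-2-4 sequence;
inter-press intervals are exponential (block rate optionally rising
across blocks as `rate·(1 + gain·(1 − e^{−(b−1)/τ}))` to emulate
learning); each press is corrupted to a different key with probability
`error_rate`.

## Envelope preprocessing

- **Hilbert envelope**: modulus of the analytic signal (`scipy.signal.hilbert`).
- **Downsampler**: left-aligned, half-open moving windows, mean over
  [m·step, m·step + win); the output rate is 1/step. With 100 ms
  windows every 25 ms (75 % overlap) the output rate is 40 Hz; the
  partial trailing window is dropped. The operator is linear.
- **Standardisation**: each node channel demeaned per recording, then
  the whole concatenated matrix divided by a single scalar SD ("global
  variance"). The per-channel alternative was rejected because
  demeaning is specified separately and the global scalar preserves
  between-node power ratios, which the state power maps rely on.
- **PCA pre-whitening**: top principal components scaled to unit
  variance (not full ZCA); the basis, mean and scales are retained for
  node-space back-projection. Rank-deficient inputs reduce the retained
  dimension with a warning.

Concatenation is subject-major, session-minor, with half-open
`(subject, session, start, end)` boundary records; every downstream
stage resets at these boundaries.

## Envelope HMM

Gaussian-observation HMM fitted by EM (Baum–Welch, via hmmlearn) with
`n_restarts` seeded random initialisations; the retained model minimises
the negative log-likelihood, the maximum-likelihood analogue of
selecting the lowest variational free energy. Full covariance is the
default (envelope covariance patterns are state-specific); a diagonal
option exists and is exact for the generator's isotropic noise.

Numerical choices:

- **Initialisation**: means/covariances from seeded k-means; the
  transition matrix starts *sticky* (diagonal 0.8). Envelope states
  dwell for several samples, and a uniform transition start lets EM
  fall into a degenerate optimum in which two states model one cluster
  by fast alternation (self-transition ≈ 0 with correct occupancy); the
  sticky start removes this failure mode and roughly halves iteration
  counts.
- **Convergence**: EM stops when the log-likelihood gain drops below
  `rel_tol × n_samples` (default rel_tol 1e-6, i.e. 1e-6 per sample) or
  at 500 iterations.
- **Viterbi**: implemented in log space per recording segment; ties
  break toward the lower state index, so decoding is deterministic.
  Exactly one state is active per sample by construction.
- **Degenerate covariances** are regularised by diagonal loading
  (min_covar = 1e-6); a restart that still fails is skipped, and only
  if all restarts fail does fitting error out.
- **State labels** are arbitrary (0-based). All cross-run comparisons
  first match states by Hungarian assignment on the absolute cosine
  similarity of node-space power maps (or observation means); absolute
  similarity because activation/deactivation sign is also arbitrary.

## State temporal parameters and power maps

Run-length encoding of the per-recording path gives, per state: NO
(number of activation runs), FO (active samples / total), MLT (mean
activation-run length / fs) and MIL (mean length of inactive runs lying
strictly between two activation runs — leading/trailing gaps excluded).
Conventions: an unvisited state has NO = 0, FO = 0, MLT/MIL missing; a
state occupying the whole recording has MIL missing. Missing values
propagate into group statistics by cell-wise exclusion (with per-test n
reported) rather than silent dropping. These identities hold exactly on
integer counts: ΣFO = 1 and MLT·NO = FO·T per recording.

Power maps are partial correlations between a state's indicator and
each standardized (pre-PCA) node envelope, controlling for the other
states' indicators minus one reference (the K indicators sum to one, so
the full set is exactly collinear; the last state serves as reference,
and the first when mapping the last). Signed activation indicators are
used rather than activation-only regressors; with exclusive states the
two parameterisations span the same space. State networks keep nodes
with |map| ≥ fraction × max|map| (default 0.60); the peak node is
always included, and the rule is scale-invariant.

## Connectomes

Slow amplitude-envelope correlation: envelopes are moving-average
smoothed over `smooth_s` seconds (default 1.0 s — the supra-second
timescale; the literature convention is not pinned to a printed
constant, so the window is configurable) and Pearson-correlated. The
126-node reference registry concatenates the 116-region AAL table with
10 motor-literature nodes; the shipped motor-node table is a synthetic
stand-in (the original node list is not redistributable) and the
registry is a user-editable TSV (`id, name, mni_x, mni_y, mni_z,
source`) whose coordinates are metadata only. Node power is the
per-node sample variance, kept alongside the matrix to control for
power-induced connectivity effects.

Leakage correction: the geometric correction scheme needs the MEG
inverse operator, which is out of scope; the package provides pairwise
regression orthogonalization instead (target residualized on seed,
averaged over both directions), default OFF for synthetic data.

Mean connectivity strength of a state network restricts the matrix to
the network's nodes, averages each node's off-diagonal correlations,
then averages the node means — for a symmetric matrix this equals the
grand mean of off-diagonal entries (asserted at 1e-12), and the
diagonal is always excluded (self-correlation is uninformative).

## Network-based statistics

Edge statistics: paired t across matched subjects (zero-variance edges
become missing and never enter components) or Pearson r with a subject
covariate, converted to t = r√((n−2)/(1−r²)) so one threshold scale
(default 3.5) serves both designs. Components are maximal connected
subgraphs of the suprathreshold graph; size = edge count (extent; the
intensity variant is not implemented). Positive and negative tails are
separate one-sided analyses. The permutation null of the *maximum*
component size uses sign-flips of within-subject difference matrices
(exact exchangeability under the paired null) or covariate reshuffles;
p_fwer = (1 + #{perm max ≥ size})/(n_perm + 1), the +1 keeping the
Monte-Carlo estimator valid. Node weights for reporting hubs sum the
absolute suprathreshold statistics incident to each node.

Calibration note: the max-size statistic is integer-valued, so NBS is
conservative whenever no null quantile falls near α. The FWER benchmark
therefore uses a null design (9 nodes → 36 edges, n = 20, t > 3.5)
where P(any suprathreshold edge per permutation) ≈ 0.043, just below
α = 0.05, making the nominal level achievable; with denser graphs the
single-edge rejection region vanishes and the empirical rate collapses
well below nominal — a property of the method, not a defect of the
implementation.

## Scalar statistics

The split-plot ANOVA (up to two within-subject factors, one
between-subject factor) is computed from orthonormal contrast scores:
each within effect is a one-sample/one-way analysis on Helmert-contrast
scores with error pooled within groups, the between effect a one-way
ANOVA on subject means. Group sizes may differ (subject-weighted
means); balanced designs reproduce classical split-plot F values, and
the one-within reduction is cross-checked against pingouin in the test
suite. Sphericity is assessed per effect with Mauchly's test on the
pooled contrast covariance; Greenhouse–Geisser ε multiplies both df
when Mauchly rejects at 0.05 (fractional df are reported). Spearman ρ
uses average ranks with a Fisher-z CI (SE 1/√(n−3)) — the CI method is
a package choice since none is pinned. Wilcoxon signed-rank: W is the
rank sum of positive (a−b) differences (so swapped inputs give
n(n+1)/2 − W), zeros dropped, exact p for n ≤ 25 without ties,
normal approximation with continuity correction otherwise. Bonferroni:
min(1, p × factor), family 21 = (8−1) independent states × (4−1)
independent temporal parameters (one state's activation is determined
by the others; NO is determined by MLT, MIL and FO).

## Pipeline and reproducibility

`run_all` executes simulate → behaviour → envelope → HMM → states →
connectivity → NBS → stats into a run directory; every output carries
the configuration SHA-256 hash and seed, stage failures abort with the
stage name, and a rerun with the identical config is bit-identical. The
session map encodes the three testing windows (T1 boost = RS2/RS3,
T2 silent = RS4/RS5, T3 next day = RS6/RS7; induction = pre/post within
each window), configurable for other designs. Configs without an
explicit seed are refused.

## Benchmark problem sizes

The validation benchmarks (`restdyn.benchmarks`, exercised by the test
suite and `scripts/acceptance.py`) use: HMM recovery — 10 seeds × 10
subjects × 20 000 samples, 20 nodes, 10 PCA components, diagonal
covariance (exact for the generator's noise), 2 restarts; Viterbi — 100
random models, K ≤ 3, T ≤ 10, against exhaustive enumeration; NBS —
500 null replicates and 100 planted-effect replicates at 1000
permutations; ANOVA — 200 null replicates of the 3 × 2 × group design
with 15 subjects per group; Wilcoxon/Spearman — 1000 replicates. These
sizes were chosen so each benchmark's sampling error is small against
its acceptance band while the whole suite stays desk-scale.

## Known limitations

- EM maximum-likelihood selection is not variational-Bayes free energy;
  equivalence of model ranking is not claimed.
- The weighted-means split-plot sums of squares are exact for balanced
  groups; with unequal group sizes interaction terms are Type-I-like
  approximations.
- Pairwise orthogonalization removes only instantaneous linear leakage
  and operates on envelopes, not analytic signals.
- The GPI scoring rule (rate × accuracy) is one monotone-in-both
  choice among several; it sits behind a replaceable scorer interface
  and scores are tagged with the formula name.
- The synthetic motor-node registry and placeholder coordinates carry
  no anatomical meaning; no geometric computation uses them.
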