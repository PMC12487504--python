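# Methods

## Data model

A session is an ordered list of utterances. Client utterances carry an
integer strength score s ∈ [−5, +5]; the talk-type category is determined
by its sign (change / neutral / sustain), and when both are present they
must agree. Therapist turns are kept in the data model but excluded from
all modeling; only client score sequences enter the HMM stages. Sessions
carry a quality label (high / low / unknown).

Two mechanical cleaning rules run before scoring: utterances whose
whitespace-stripped text full-matches a repetitive-noise pattern
(default `(n/a){2,}`, case-insensitive) are dropped, as are consecutive
duplicate lines lacking a category annotation. Survivors are re-indexed
from 0; cleaning is idempotent and order-preserving. Exclusions requiring
human judgment (e.g., a recording too garbled to interpret) are out of
scope — only the two mechanical rules are applied.

## The hidden Markov model

Three latent motivational states with start distribution π, transition
matrix A (rows sum to 1), and per-state emissions over the score scale.
Two emission families:

* **Gaussian** (default): one (μ_k, σ_k) per state. States are
  interpreted through their emission means, so this family is the primary
  one.
* **Categorical** (`categorical11`): a free pmf over the 11 integer
  scores, as a robustness alternative; state means are then pmf means.

**Discretization.** Integer scores on a bounded scale are not draws from a
continuous density: a reported +5 means "at least +5-strength", and a
reported +2 is anything between +1.5 and +2.5. The Gaussian family
therefore evaluates, by default (`discretization="bins"`), the probability
of the unit bin around each score, with the edge bins (−5, +5) open to
±∞, and its M-step uses the corresponding truncated-normal conditional
moments — an exact EM for interval-censored data. This matters: fitting
the plain density to round-and-clipped scores leaves an *asymptotic* bias
of ≈ +0.02 on transitions into the middle state (the boundary point
masses inflate its variance), which we verified disappears under the
binned likelihood. Alternatives: `"censor"` treats only the boundary
scores as Tobit-censored tails (used automatically for non-integer data),
and `"none"` is the plain density, kept for cross-checks against standard
Gaussian-HMM implementations.

**Estimation.** Baum-Welch over multiple sessions: scaled (per-step
normalized) forward-backward per sequence, sufficient statistics summed
across sequences, each sequence restarting from π. Initialization is
deterministic — μ⁰ = (+3, 0, −3) (the expected motivational gradient),
σ⁰ = 1.5, A and π uniform — with optional seeded random restarts keeping
the best final log-likelihood. Convergence: relative log-likelihood change
< 1e−6 or 500 iterations (both configurable); σ² is floored at 1e−2. The
log-likelihood trace is retained and is non-decreasing (tested to 1e−8).
An option `fix_start_from_first_score` pins π to the empirical sign
distribution of first-utterance scores instead of estimating it, for
pipelines where the first state is assigned upstream; by default π is
estimated by EM. Sessions are never concatenated: multi-sequence EM always
respects session boundaries.

**Banked fitting.** The EM core fits M models in parallel over one shared
padded observation array, each model selecting its sequences through a 0/1
weight vector. Padded steps carry emission likelihood 1, which leaves the
scaled recursions and masked statistics exactly equal to the unpadded
computation, and each model's statistics are independent, so a bank fit
reproduces separate fits up to round-off (tested at 1e−8). Permutation
tests and subgroup feature extraction are banked; this is what makes
hundreds of full refits per analysis affordable on one CPU.

**Decoding and labeling.** Viterbi runs in log space with ties broken
toward the lower state index. After fitting, states are sorted by
descending emission mean and labeled (Towards Change, Non-Determined,
Away From Change); π and A are permuted accordingly. `gradient_valid` is
true iff the sorted means are *strictly* decreasing — collapsed or tied
states make the motivational reading uninterpretable, and downstream
stages flag (but do not discard) such fits. The sort is stable, so even
gradient-invalid models canonicalize deterministically and remain
comparable as matrices.

## Group comparison

One pooled HMM per quality group (≥ 2 sessions with ≥ 3 client scores
each). The statistic is the Frobenius norm of the element-wise difference
of the canonical transition matrices, D = ‖A_high − A_low‖_F (for 3×3
stochastic matrices D ≤ √6). Significance: session quality labels are
reshuffled N times with group sizes preserved; both group models are
refitted from scratch and re-canonicalized per shuffle (canonicalization
inside every permutation, so state identity never leaks across fits);
p = #{D_perm ≥ D_obs}/N, with a `(#+1)/(N+1)` smoothed option.
Gradient-invalid or non-converged permuted fits still contribute a D (the
canonical ordering is deterministic) and are counted in
`degenerate_fit_count` rather than discarded, which would bias the null.
EM settings inside permutations may be relaxed independently of the
observed fit. A cheaper variant that permutes per-session matrices is
deliberately not offered: single sessions are too short for stable fits.

## Quality prediction

Subgroups of 7 same-quality sessions are drawn from each quality pool
(sessions may recur across subgroups; a `disjoint_subgroups` option
partitions the pool instead for a strictly leakage-free variant — the
overlapping design is the default because it is the method being
implemented, and its known mild optimism should be kept in mind). Each
subgroup's pooled HMM yields 9 features: the row-major flattened canonical
transition matrix (start probabilities are not included by default).
A logistic regression with a small L2 ridge (C = 1 in the scikit-learn
parameterization; the 9 features are collinear since rows sum to 1, so
some regularization is needed; features are probabilities in [0, 1] and
are not standardized by default) is evaluated by subgroup-level LOOCV.
"Iterations" are independent repetitions of subgroup resampling plus a
full LOOCV under fresh child seeds — LOOCV itself is deterministic given
the subgroups, so between-iteration spread comes from resampling — and
metrics are reported mean ± SD over iterations. Designs: balanced
(30 + 30 subgroups) and imbalanced 3:1 (30 + 10). The positive class for
the ROC is "low" (the clinically critical minority); all threshold
metrics are reported class-wise for both classes anyway. ROC AUC is the
Mann-Whitney rank statistic (ties count ½), which equals the trapezoidal
area (cross-checked against scikit-learn). Folds whose training split is
single-class are skipped and counted. A `permute_labels` control shuffles
subgroup labels per iteration to confirm chance-level behavior.

## Synthetic generator

Sessions are sampled from ground-truth 3-state chains: z₁ ~ π,
z_t ~ A[z_{t−1}], score = round(clip(N(μ_z, σ_z), −5, +5)); categories
follow the score sign and hidden paths are stored in the dataset metadata.
Defaults (invented for this package, not taken from any corpus): emission
μ = (+3, 0, −3), σ = (1, 1, 1); session lengths uniform on [40, 120]
client utterances; study design 30 high + 10 low. The high-quality
profile is *fluid* (every off-diagonal transition ≥ 0.1):

    pi = (0.40, 0.40, 0.20)
    A  = ((0.55, 0.30, 0.15),
          (0.35, 0.40, 0.25),
          (0.30, 0.35, 0.35))

and the low-quality profile is *sticky-Away* (Away self-transition 0.80):

    pi = (0.15, 0.35, 0.50)
    A  = ((0.30, 0.35, 0.35),
          (0.15, 0.40, 0.45),
          (0.05, 0.15, 0.80))

Profiles must be gradient-valid (strictly decreasing means) unless
explicitly overridden, which is how the uninterpretable-fit path is
exercised. What the generator does *not* emulate: utterance text, talking
therapists, session-length/autocorrelation statistics of real corpora, or
rater noise in the scores. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the stated model —
not that real transcripts are this well separated.

## Problem sizes and expected magnitudes

The test suite and `scripts/acceptance.py` use these sizes, chosen as
desk-scale study conditions:

* Oracle checks: ≥ 100 random models, T ≤ 6, agreement to 1e−9 with
  exhaustive 3^T enumeration.
* Parameter recovery: 60 sessions × 80 utterances (4,800 observations).
  Under the binned likelihood the max transition-entry error is typically
  0.03–0.05 (median ≈ 0.033 across seeds) — dominated by estimation noise
  from emission overlap, not bias — and emission means land within 0.3 of
  truth.
* Type-I calibration: 200 null simulations × 99 permutations, sessions of
  30–60 utterances, relaxed EM (10 iterations, tol 1e−4) inside
  permutations; rejection at α = 0.05 stays in [0.02, 0.09] and p-values
  are near-uniform (exchangeability holds regardless of EM convergence
  depth, which is why relaxed settings are safe here).
* Power: 20 replicates of the default 30 + 10 design, 99 permutations.
* Classification: 10 iterations of balanced 30 + 30 subgroup LOOCV
  (accuracy and AUC ≈ 1 under the default separation) plus the
  label-permuted chance control.

## Numerical choices and edge cases

Emission likelihoods are floored at 1e−300 and normal quantiles clamped at
|z| ≤ 37 to avoid underflow; per-step normalizers make session-length
sequences safe. Empty states (zero posterior mass) keep their previous
parameters. Cohen's κ with both raters constant and equal (p_e = 1) is
reported as 1.0 with a `degenerate` flag; κ for no-variation Fleiss tables
is likewise 1.0 under perfect agreement. Undefined precision (no predicted
positives) is reported as 0 with a flag. All randomness flows through
`numpy.random.Generator` seeds; stage seeds derive from one global seed by
`SeedSequence` spawning, and identical configs produce byte-identical
artifacts (JSON keys sorted, no timestamps).

## Known limitations

Strength scores in real pipelines come from an LLM or human rater; the
lexicon mock shares only the interface, so agreement numbers on synthetic
text exercise the formulas, not rater quality. The 3-state count is fixed
by design (no model-order selection). Subgroup overlap leaks mild
dependence into LOOCV under the default design, as discussed above.
Session-level fits on short real sessions are expected to be unstable —
that is the reason the subgroup design exists.
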