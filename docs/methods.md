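# Methods

This note records the model, the conventions the implementation fixes where
names alone would be ambiguous, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter.

## Data model

A *team* is observed through three records: a chat log (timestamped,
sender-attributed messages, optionally with a per-message sentiment in
[−1, 1]), a row in a teams × tasks score table with scores linearly rescaled
to [0, 1] per task, and a row of baseline features (proportion of female
members, Big-5 trait averages, social perceptiveness, total communication
amount, and its per-member standard deviation).  Task order is fixed across
teams.  Missing values stay missing through I/O; imputation, where it
happens at all, is a modeling-stage decision.  Score normalization uses
supplied per-task (min, max) ranges when available and the observed range
otherwise (logged), since the theoretical scale of a task is not always
known.  Timestamps parse from raw seconds, `MM:SS` (minutes may exceed 59 —
chat platforms print running minute counters) or `HH:MM:SS`.

## Response detection and the collaboration network

Message *r* is a probable response to *m* iff `m.time < r.time`,
`t1 ≤ r.time − m.time ≤ t2`, and the senders differ.  Equal timestamps are
never responses (strict inequality together with t1 > 0); a message may
answer several antecedents, and no deduplication is applied because the
edge weight sums over pairs.  The shipped default window [1, 17] s comes
from calibration on manually annotated logs of the original study and is
not re-derivable without them; the calibration machinery itself is fully
functional and is exercised against planted annotations.  Calibration
maximizes F_β (β = 2: recall counts four times precision) over a grid with
t1 ∈ {0.5, 1, …, 5} and t2 ∈ {5, 6, …, 30}; ties break toward the
narrowest window (smallest t2, then largest t1), which makes exact recovery
of a planted window well-defined.  All ordered pairs within the largest
grid t2 are candidate pairs.

Edge weights follow the time-decay form with ρ = 0.15 /s; the gap
`q.time − p.time` is non-negative by construction, so the absolute value in
the defining formula is moot.  Zero-weight ordered pairs are absent edges.
Sparsification removes ⌊fraction · |E|⌋ lowest-weight edges — floor, the
conservative integral reading — with the deterministic tie-break
(weight, source, target), which guarantees the nesting
S₇₅ ⊆ S₅₀ ⊆ S₂₅ ⊆ W.

## Features

Network degree statistics use the population (÷n) standard deviation:
they are descriptive summaries of one finite network, not estimates.
Reciprocity of a communicating pair is min(w_ij, w_ji)/max(w_ij, w_ji),
averaged over pairs — the ratio reading; a correlation-style estimator
would be an alternative, but the ratio is elementary and bounded in [0, 1].
Algebraic connectivity is computed on the symmetrized matrix (W + Wᵀ)/2
(the minimal way to apply an undirected spectral concept to a directed
network) as the smallest Laplacian eigenvalue above 1e-9; note that for
disconnected graphs this "smallest positive" quantity is not the Fiedler
value and is not monotone under edge addition — the monotonicity property
is only asserted, and tested, on connected graphs.  Distances, diameter and
clustering of sparse networks are computed on the undirected projection of
the largest weakly connected component; betweenness is directed with the
1/((n−1)(n−2)) normalization.  Chat-log characters count every stored
character including whitespace; a turn is a maximal run of consecutive
messages by one sender; delays are successive gaps over the whole log.

Dynamics features of a score prefix (length ≥ 3; prediction starts at task
4) fix these conventions: sample (n−1) standard deviation and variance,
adjusted Fisher–Pearson skewness, bias-corrected excess kurtosis (both
undefined, hence missing, for constant prefixes); the trend line is least
squares against the task index with `fit_mid` evaluated at the possibly
fractional middle abscissa (1 + len)/2; the slope is reported as atan
(radians); `fit_last_minus_first` is the difference of the *fitted* line
endpoints, i.e. slope · (len − 1) — the raw endpoints are already separate
features; changes exactly equal to the median change (to 1e-9, absorbing
floating-point differencing noise) count as neither above nor below.  Both
variance and standard deviation are emitted even though redundant, matching
the stated feature list.

## Regression and model selection

The elastic-net objective is penalized raw RSS — no 1/(2n) scaling — so the
scikit-learn solver is reparameterized (α = λ₁/2n + λ₂/n,
l1_ratio = (λ₁/2n)/α); the unpenalized limit routes through `lstsq` and the
pure-ridge limit through the closed-form normal equations.  Features are
standardized; the response is centered, so the intercept is the training
mean.  The λ grid crosses mixing ratios λ₁:λ₂ ∈
{100:0, 75:25, 50:50, 25:75, 0:100} with 20 total magnitudes on a log grid
10⁻³…10¹ — the grid must contain the LASSO-dominant 75:25 mix, which tends
to win.  "Weight" in the sparsity rule is |β_j| on standardized features,
the only scale-free reading.  The sparsity filter is judged on the
full-data fit; the score is the RMSE of pooled out-of-fold predictions
under a seed-fixed 10-fold assignment, with standardization statistics
recomputed on each training fold.  When nothing eligible and non-degenerate
survives, the returned model is the all-zero fit predicting the mean score,
with an honest out-of-fold RMSE of the mean predictor.  Screening reports
Pearson correlations that pass both the Benjamini–Hochberg step-up at FDR
10% (jointly across all tested pairs) and a raw p < 0.05 display threshold;
both knobs are exposed because their interplay is a reporting convention,
not a statistical necessity.

Forecasting baselines: the mean-oracle and observed-mean divisors are the
number of averaged tasks (m and t−1); ARMA is fixed at order (1,1) with ML
estimation — the smallest nontrivial choice — falling back to the observed
mean on histories shorter than 4 or any fit failure; least squares needs 2
points; an empty history predicts 0.5.  Forecasts are clipped to [0, 1]
since scores are bounded (clipping is logged at debug level).

## Workload planning

The allocation step maximizes sᵀω − α‖ω‖² over the simplex.  For α > 0 the
problem is strictly concave and solved exactly by support-scan
water-filling, ω_i = max(0, (s_i − μ)/2α) — equivalently the Euclidean
projection of s/2α onto the simplex — rather than a numerical optimizer,
giving bit-stable results; α = 0 degenerates to a linear program whose ties
on the maximal score are split uniformly.  The outlier-control policy clips
estimates into [(1−ε)·mean, (1+ε)·mean] of each team's observed mean
(divisor: number of observed tasks).  Model-based policies train one
elastic-net dynamics model per target task per split on the training teams
and apply it to the managed teams' prefixes, falling back to the observed
mean before task 4; undefined features at prediction time (e.g. skewness of
a constant prefix) impute to the training mean, i.e. zero on the
standardized scale.  Policy evaluation draws seeded random 75/25 splits and
scales mean cumulative payoffs by the mean-oracle policy's.

Problem sizes used by the test suite and the acceptance script: the cheap
policies run the full 100 splits of the 68-team table; ARMA runs 5 and the
model-based policies 10 splits with a reduced LASSO-dominant λ grid (8
magnitudes), since their per-split cost is dominated by per-task model
fits; the planted-signal recovery check uses 50 generator seeds and the
affinity-recovery check one long chat session (~1300 messages).  These are
the package's own evaluation sizes; all knobs (`repeats`, `lambda_grid`,
`session_length`) are plain arguments.

## Synthetic data: what it emulates, what it does not

Scores: s_i(t) = clip(q_i + slope_i (t−1) + noise, 0, 1) with latent
quality q_i ~ U(0.2, 0.8), slope_i = 0.05 (0.5 − q_i) + N(0, 0.005), noise
sd 0.1 — weak teams start low and drift upward, strong teams start high and
stay flat, and the first-task score correlates with the rest of the series,
reproducing the qualitative structure the models exploit.  Defaults are 68
teams × 15 tasks × 4 members, hour-long sessions.

Chat: base messages arrive with an exponential extra gap (mean 10 s) after
a quiet period of one response window; after a base message by member i, at
most one member replies — member j with probability
reply_prob · A_ij / (n−1) — at a lag uniform in the true window.  Two
deliberate departures from real chat make the planted structure
identifiable: the quiet-period pacing guarantees every cross-sender pair
inside the window is a planted reply (real chat is burstier and ambiguous),
and the single-replier rule makes the expected extracted edge weight
exactly proportional to A_ij (independent per-member replies would add
reply-reply coincidence weight between co-responders).  The planted
affinity matrix is a random permutation of evenly spaced values, so the
planted ordering is strict and recoverable from finite logs; clustered
random affinities would be statistically indistinguishable at realistic log
lengths.  Message text is placeholder vocabulary; sentiment is clipped
Gaussian noise.  Consequently, passing tests demonstrate that the pipeline
recovers structure *when the timing assumption holds exactly*; they cannot
certify behavior on real logs where responses blur into ongoing
conversation — there the calibrated F₂ is far below 1 by nature.

Baseline features are r · z_q + √(1−r²) · noise mapped affinely to natural
scales, with default target correlations to quality of 0.4 (social
perceptiveness), 0.35 (proportion female), 0.3 (communication amount),
−0.3 (communication distribution), −0.2 (extraversion, agreeableness) —
inside the correlation ranges reported for such features.  All generators
derive per-team sub-seeds from the master seed via `SeedSequence` spawn
keys, so any single team regenerates in isolation.

## Known limitations

* The calibrated default window and any real-data headline numbers depend
  on the original study's deposited data, which this package does not ship;
  everything data-dependent is exercised on synthetic inputs instead.
* No sentiment classifier is included — sentiment values are consumed as
  input, with a pluggable scorer interface and a neutral stub.
* The reciprocity estimator is the ratio form; results with a
  correlation-style estimator may differ on weighted networks.
* ARMA(1,1) on ≤14 points is fragile by construction; the observed-mean
  fallback fires often and is part of the method's defined behavior.
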