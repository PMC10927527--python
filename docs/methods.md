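# Methods

## Model

The repeated game couples one transmitter to N receivers.  Each round the
transmitter draws the next story's veracity from its rule r_k^j (j the
previous story's veracity, k the number of receivers who engaged with it),
and each receiver draws engagement from q_ij^m (i its own previous
engagement, j the previous story's veracity, m the current story's).  Two
noise rates act on every round: an execution error ε flips the realized
veracity choice and each engagement action independently, and a perception
error η flips the transmitter's memory of the previous story's veracity
before the rule is selected.  Receiver payoffs and all measured accuracy
quantities always use the true veracity.

For N = 1 the pair induces a Markov chain on the four states
(c,t), (c,f), (n,t), (n,f) — previous engagement × previous veracity.  The
transition matrix is assembled exactly from the two rules and the
engagement probabilities with the ε/η flips applied as independent
post-hoc action flips; the stationary distribution is obtained from the
linear system πT = π, Σπ = 1.  At ε = η = 0 the stationary outcome
satisfies the enforced affine constraint identically (machine precision;
the suite checks < 1e-10 over 1000 random pairs).  For ε = 0 a chain can
have two recurrent veracity classes (e.g. α = 1, β = 0); the stationary
solver then raises by default, or returns the Cesàro limit from the
uniform start (tolerance 1e-12, at most 1e6 iterations) when asked.

Polynomial strategies are *viable* when both rules stay inside [0,1] on
the integer grid k = 0..N; for linear feedback this reduces to the two
endpoint rules (k = 0 and k = N) lying in [0,1], which the constructors
enforce.  Uniform sampling of viable linear strategies (α, β ~ U[0,1],
γ ~ U[−α, 1−α], θ ~ U[−β, 1−β]) is identical in law to sampling the four
endpoint rules independently uniform on [0,1]; the co-optimization code
exploits this by exploring endpoint space, where every point is viable.

## Strategy optimization

Optimization is myopic noisy search: propose a change to one strategy
component, evaluate the exact stationary payoff of current and candidate
(N = 1), accept with the Fermi probability 1/(1+exp[σ(w_cur − w_cand)]).
Local proposals perturb one component by U(−s, s) reflected into [0,1]
with default step s = 0.1 (region-probe signs are verified unchanged at
s = 0.05 and 0.2); global proposals resample the component uniformly.
Receivers start from the non-engaging strategy (all behavioral
probabilities zero).  Proposals are restricted to components the
attention weights allow to be expressed (with a1 = 1 the four
memory-conditioned probabilities — matching a four-component behavioral
strategy; with a1 = 0 just the baseline rate p0).

Measured quantities (v_f, v_t, overall engagement, per-story engagement
rates v_fc/v_f and v_tc/v_t) are averages of the current pair's stationary
outcome over the measurement window (default 1e4 update events after 1e4
burn-in).  Ratios are formed from the window-summed components, so slow
receiver drift contributes the covariance between engagement level and
misinformation output that the feedback mechanism creates; this is what
makes per-story engagement rates differ even for veracity-blind receivers.

Co-optimization alternates one receiver update and one transmitter update
per time-step (receiver first); the transmitter perturbs one endpoint rule
per event and uses its own attention σ_T = 100 by default.  Region scans
average the per-story engagement difference v_fc/v_f − v_tc/v_t over
replicates of co-optimizing pairs per (π_f, σ) cell with π_t = −π_f;
replicate initial transmitters are uniform viable strategies and receivers
are blind (a0 = a1 = 0) non-engagers.  Desk-scale defaults (100–150
replicates, 4000–6000 steps against the reference protocol's 1e3
replicates and 1e4 steps on a 100×100 grid) preserve all six probe signs
stably across seeds; the F3/T3 probes have small magnitudes (~1e-3) —
there the transmitter converges to a nearly pure strategy and only
optimization transients differentiate the per-story rates — but their
signs are consistent.

All batched work (ensembles, region replicates) runs through a vectorized
engine that solves the 4×4 stationary systems for the whole batch per
update event, so a 2000-strategy ensemble evaluates in well under a
minute on one CPU.

## Ensemble search and classification

Study conditions for the strategy search: π_t = 1, π_f = −1, ε = 1e-3,
η = 0.3, N = 1, receiver a0 = 0 with memory attention a1 = 1 and payoff
attention σ = 1, local proposals, 1e4/1e4 burn-in/measurement events.
(The receiver's initial strategy is the four-component non-engaging
profile; the utility scale ±1 is the conventional unit choice.)
Successful misinformation strategies satisfy v_f > 0.5 with per-false-story
engagement at or above the 90th percentile of the whole run ("higher"
quantile convention, so ties cannot admit more than the top decile);
accurate strategies symmetrically.

A strategy's enforcement classification derives from the affine constraint
v_f = v_f0 + c_t·v_tc + c_f·v_fc with c_t = −γ/s, c_f = −θ/s, s = 1−α+β:
the sign pattern of (c_t, c_f) gives the direction of the enforced
engagement–misinformation coupling.  The *responsive* conditions
(v_f ≥ v_fc + v_tc for misinformation, 1 − v_f ≥ v_fc + v_tc for accurate
transmitters) are evaluated at the measured equilibrium: a universal
("for every receiver") version of the inequality is satisfiable only on
the boundary families, because a fully engaging receiver forces
v_fc + v_tc = 1.  Those boundary families — α = 1, γ = θ = −β (pins
v_f = v_fc + v_tc identically) and β = 0, γ = θ = 1−α (pins
1 − v_f = v_fc + v_tc) — are the package's operationalization of the
equality-enforcing extortion strategies; a strategy is an extortion
neighbor when its max-norm distance in (α, β, γ, θ) to either family is
at most Δ = 0.05.

Running this pipeline at 2000 strategies yields responsive proportions of
roughly 55–70% for successful misinformation strategies and 65–75% for
successful accurate ones (seed-dependent; the acceptance script computes
them from scratch).  Under these desk-scale conditions the selection is
partly noise-driven — the per-story engagement rates of individual
strategies carry measurement noise comparable to their strategy-driven
spread at σ = 1 — so the proportions carry several percentage points of
seed-to-seed variation and the sharper structure attainable with much
larger ensembles and stronger payoff attention (e.g. unanimity of the
enforcement sign among successful strategies) is not resolved here.

## Experiments

The sigmoid demonstration runs a steep sigmoidal-feedback transmitter
(midpoints 0.5 after true, 0.25 after false) against 100 blind receivers
whose engagement rates adapt by one local Fermi update per round, scoring
candidate rates by engagement × the mean per-engagement utility of the
last 50 stories — a windowed stand-in for the equilibrium payoff, which
has no closed form at population scale.  The hysteresis between the two
midpoints produces the characteristic pattern: truth while engagement is
low, misinformation once it is high, with higher realized engagement per
false than per true story (50 of 50 seeded replicates) and more
misinformation in above-median-engagement rounds.

Story sequences iterate the game at population scale in mean field: the
expected engagement for a story mixes the receiver's engaged/non-engaged
memory rules by the previous story's realized engagement fraction, the
realized count is a binomial draw over the population (1e5 by default)
and drives the transmitter's feedback, and perceived accuracy is a
per-story Bernoulli η-flip of the binary veracity (a deterministic
1−η / η convention is available).  Sequences start from the game's
conventional initial state (previous story true, no engagement).  The
engagement–accuracy slope is the correlation of the two per-story series;
zero-variance sequences return slope 0 with a warning.  The rank
experiment draws 20 + 20 transmitters per replicate from successful
accurate/misinformation pools, sorts the 40 slopes, and averages the slope
and type composition per rank.

## Statistics

Per-site regression standardizes accuracy and log10 engagement within
site, so the slope is the correlation coefficient; rows with zero
engagement enter as log10(engagement+1).  Fisher's combined statistic is
−2Σln p with 2k degrees of freedom.  The random-effects meta-analysis is
DerSimonian–Laird (moment τ² truncated at zero, inverse-variance weights,
two-sided z-test); it is implemented directly and cross-checked in the
suite against an independent library implementation to 1e-10.  Rating-level
regressions z-score outcome and predictor over the table and use the
inclusion–exclusion two-way cluster-robust covariance
V_subject + V_headline − V_{subject×headline} with no small-sample
adjustment by default (a flag enables it); with singleton clusters in one
dimension this collapses exactly to one-way clustering, which the suite
checks algebraically.  No Fisher-z transformation is applied to slopes
before meta-analysis (flag-free default; the slopes in scope are small).

## Synthetic data

The site generator draws headline accuracies from type-specific clipped
normals on the 1–7 scale (mainstream centered at 4.9, misinformation at
3.6, sd 0.9 — overlapping, as in real perceived-accuracy ratings) and sets
log10 engagement to an intercept (3.0) plus a slope times the within-site
z-scored accuracy plus residual noise (sd 0.35), with the slope calibrated
so the population correlation equals the requested true slope (defaults
0.13 / −0.11, mirroring the empirical effect sizes the pipeline is meant
to detect); engagement counts are rounded powers of ten.  The rating
generator produces a full subject × headline crossing with crossed random
intercepts; when the non-accuracy variance components sum to
1 − true_effect², the standardized coefficient equals the requested effect
exactly, up to rare 1–7 clipping.  Accuracy ratings are clipped normals
rather than ordinal draws — the analyses consume means and z-scores, for
which an ordinal mechanism adds nothing.  These generators emulate the
cluster structure and effect scales of real engagement/ratings data but
not its heavy-tailed engagement distributions, item non-response, or
rater drift, so passing recovery tests demonstrate correctness of the
estimators, not robustness to those features.

## Known limitations

* The responsive-proportion reproduction is qualitative at desk scale:
  majority-responsive in both successful groups, with seed variation of
  several percentage points (see the acceptance script's output for exact
  values per seed).
* The rank experiment reproduces negative-to-positive ordered mean slopes,
  but the over-representation of misinformation transmitters at the lowest
  ranks is at the edge of detectability under these receiver dynamics: the
  pool-level slope separation (~0.02) is small against per-sequence noise
  (~0.23 sd at 20 stories with η = 0.3).
* Multi-receiver payoff evaluation during optimization falls back to
  finite-round simulation (1e4 rounds) and is orders of magnitude slower
  than the exact single-receiver path.
* SI-only model variants (perfectly rational receivers, social learning,
  competing transmitters, clickbait payoffs) are out of scope; the
  strategy/receiver abstractions accommodate them as extensions.
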