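# misinfogame

Game-theoretic machinery for studying how news producers shape reader
engagement with misinformation, together with the statistical pipeline used
to test the theory's predictions on engagement/ratings data.

## The problem

Observing that false stories draw more engagement than true ones is often
read as a revealed preference of readers for misinformation.  This package
implements a model in which that inference fails: an asymmetric, infinitely
repeated game between a news **transmitter** (an outlet choosing each round
whether its next story is true or false) and **receivers** (readers choosing
whether to engage with each story).  A transmitter strategy with engagement
feedback,

    r_k^t = α + Σ_l γ_l (k/N)^l        r_k^f = β + Σ_l θ_l (k/N)^l,

gives the probability that the next story is true after a true (t) or false
(f) story that k of N receivers engaged with.  A receiver engages with
probability

    q_ij^m = a0·δ_mt + (1−a0)(1−a1)·p0 + (1−a0)·a1·p_ij,

mixing attention to the current story's veracity (a0), memory of the last
interaction (a1, with behavioral profile p = {p_ct, p_cf, p_nt, p_nf}), and a
baseline rate p0.  For a single receiver the joint process is a four-state
Markov chain whose stationary distribution v = (v_tc, v_tn, v_fc, v_fn)
yields all payoffs.

The central structural result is a constraint the transmitter enforces
**unilaterally** — for any receiver strategy, at stationarity (no errors):

    v_f = (1−α)/(1−α+β) − θ/(1−α+β)·v_fc − γ/(1−α+β)·v_tc ,

the analogue of the linear payoff constraints enforced by zero-determinant
("extortion") strategies in the iterated prisoner's dilemma.  With γ, θ < 0
the outlet guarantees that its misinformation output rises with reader
engagement no matter what the reader does.  Strategy optimization (noisy
myopic search with Fermi acceptance 1/(1+exp[σ(w_i−w_j)])) then shows that
even truth-seeking but inattentive readers can be driven to engage more with
false than true stories.

## What's in the package

| module | contents |
|---|---|
| `misinfogame.game_core` | strategies, the exact 4-state chain, stationary distributions, payoffs, the enforced constraint, multi-receiver round simulation |
| `misinfogame.dynamics` | Fermi rule, receiver optimization, transmitter/receiver co-optimization, the (π_f, σ) engagement-region scan, population-scale adaptation |
| `misinfogame.ensemble` | random search over viable strategies, success selection, responsive/extortion classification |
| `misinfogame.experiments` | sigmoid-feedback demonstration, story sequences, engagement-accuracy regression, rank-ordering experiment |
| `misinfogame.stats` | per-site accuracy/engagement regression, Fisher's combined test, DerSimonian–Laird meta-analysis, two-way cluster-robust rating regression |
| `misinfogame.synthetic_data` | site/rating table generators with known ground truth, canned strategy fixtures |
| `misinfogame.cli` | `misinfogame` command-line interface (simulate / optimize / coopt / regions / ensemble / sigmoid-demo / rank-demo / analyze / synth) |

## Worked example

An equality-enforcing "responsive" strategy (α=1, β=0.4, γ=θ=−0.4) pins the
false-story share to the reader's total engagement, for *any* reader:

```python
from misinfogame import (TransmitterStrategy, ReceiverStrategy, GameConfig,
                         exact_stationary, enforced_constraint_residual)

strategy = TransmitterStrategy.linear(alpha=1.0, beta=0.4, gamma=-0.4, theta=-0.4)
receiver = ReceiverStrategy(a1=1.0, p_ct=0.9, p_cf=0.2, p_nt=0.5, p_nf=0.3)
config   = GameConfig(epsilon=0.0, eta=0.0)

v = exact_stationary(strategy, receiver, config)
print(v.v_f, v.engagement)                     # 0.4993  0.4993  (identical)
print(enforced_constraint_residual(strategy, v))  # 0.0
```

The false-story share (0.4993) equals the reader's overall engagement rate
exactly — engage more, receive more misinformation.  Evaluating the same
strategy under the full ensemble protocol (inattentive receiver, σ=1,
execution error 10⁻³, perception error 0.3, 10⁴ burn-in and 10⁴ measured
update events):

```python
from misinfogame.ensemble import evaluate_strategy
from misinfogame import OptimizationConfig

rec = evaluate_strategy(strategy, opt=OptimizationConfig(seed=1))
print(rec.v_f, rec.engage_per_false, rec.engage_per_true, rec.responsive_misinfo)
# 0.495  0.547  0.434  True
```

the outlet shares false stories about half the time yet draws *more*
engagement per false story (0.547) than per true story (0.434) from a
truth-seeking reader — the signature engagement reversal.

From the shell, the same pipelines run as e.g.

```bash
misinfogame ensemble --n 1000 --seed 0 --out results/ensemble
misinfogame sigmoid-demo --seed 0 --out results/sigmoid_demo
misinfogame synth --kind site --n 20 --seed 1 --out results/synth
misinfogame analyze --input results/synth/site_table.csv --out results/analysis
```

each writing CSV/JSON results plus a reproducibility manifest.

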