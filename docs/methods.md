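# Model and methods

## The repeated enforcement game

A population of `N` agents is split into two occupations. In every
period the agents play an indefinitely repeated stage game: after each
round, a new round begins with probability `δ`, so the realized number
of rounds `T` is geometric with mean `1/(1−δ)`. Period payoffs are
per-round averages `Σ_t π_i(t)/T`.

Each round has three steps.

1. **Production.** Producers pair uniformly at random and play a
   prisoner's dilemma on top of their autarky payoff `w`: cooperation
   gives the partner `b` at own cost `c` (with `c < b`), defection
   gives nothing and costs nothing. An unmatched producer (odd
   headcount) consumes `w` untaxed.
2. **Enforcement.** Each producer pair is assigned to a uniformly
   random enforcer (an enforcer can serve zero or several pairs). The
   enforcer taxes each client a fraction `τ` of the client's pre-tax
   resources `w + (PD payoff)` and may punish any client, costing the
   client `p` and the enforcer `v` per punished client.
3. **Meta-enforcement.** Enforcers pair uniformly at random; each may
   attack the other over the tax revenue `R` collected in step 2. A
   unilateral attacker grabs a fraction `ψ` of the victim's revenue and
   the victim additionally loses `l`; under mutual attack each side
   loses `l` and nothing is transferred. An unmatched enforcer keeps
   `R`.

Every binary choice (cooperate/defect, punish/spare, attack/peace) is
executed correctly with probability `1−μ` and flipped otherwise.

## Reputation

Enforcers carry a score `z ∈ {0, …, κ}` under each active reputation
system; `z = 0` is good standing, `z > 0` is bad standing. The **CE
standard** demands punishing exactly the defecting clients and
attacking the meta coplayer exactly when that coplayer is in bad CE
standing; the **PE standard** judges only the attack decision against
PE standing. Compliance is a single verdict per enforcer per round,
judged on realized actions; a compliant round decrements a positive
score, any violation resets it to `κ`. All enforcers start each period
in good standing and are scored under *every* active system, whether
or not their own strategy consults it; a strategy conditions only on
its own system's standings. Where two systems coexist, each judges all
enforcers by its own standard — the model does not specify any
cross-bookkeeping, and this symmetric convention is the minimal one.

Enforcer strategies are four-bit tables `(a_coop, a_def, a_good,
a_bad)`. A strategy that conditions on nothing (constant punish and
attack actions) acquires no information and pays no fixed cost `f`;
all other enforcer strategies pay `f` every round. A strategy whose
attack action ignores standing (`a_good = a_bad`) is canonicalized to
carry no system tag, so the never-punish/always-attack strategy (DE,
`0011`) is a single object in mixed-system sets.

## Learning dynamic

Between consecutive periods exactly one agent revises. The revision
class is drawn with probabilities `(γ_PE, γ_E, γ_P)`: a producer
revising over producer strategies (`γ_P`), an enforcer over enforcer
strategies (`γ_E`), or any agent over the full set (`γ_PE`). With
probability `ε` the revision is a mistake (uniform over the menu);
otherwise the agent samples a logit best response with imprecision
`η`,

    q(X) = exp(π_X/η) / Σ_Y exp(π_Y/η),

computed with max-subtraction; `η = 0` is the exact best response with
uniform tie-breaking. The payoff input `π_Y` is the realized
per-strategy average payoff of the period just played. Two conventions
the model's verbal description leaves open are fixed as follows:

- *"Current" payoffs* are whole-period per-round averages (payoffs are
  defined as per-round averages, so this is the natural reading).
- *Unused strategies* have no realized payoff; they are scored by an
  analytic expectation (below). An ordinary alternative — giving
  unused strategies zero — would bias revisions in states where
  typical payoffs are far from zero.

The invariant distribution of the resulting ergodic chain is
approximated by time averages of strategy shares over all periods (no
burn-in), across independent runs started from i.i.d.-uniform random
initial conditions, with cross-run standard errors.

## Analytic expected payoffs

`hypothetical_payoff` evaluates a candidate strategy against a
composition in the regime of the closed-form analysis (`μ = 0`,
`δ → 1`, `κ → ∞`): matchings are averaged out and every enforcer sits
at its long-run standing. Long-run standings are computed as a least
fixed point: starting from the all-good period-start configuration,
any present strategy that violates a standard with positive per-round
probability (given the current standing assignment) is marked
permanently bad, until nothing changes. The iteration is monotone, so
it terminates and is order-independent. For the two-enforcer-strategy
set this reproduces the closed forms exactly: complying enforcers stay
good and earn `τ(w+b−c)·n_P/n_E − f` in the cooperative state;
defecting enforcers end up bad and earn `τw·n_P/n_E − l` in the
defection state; the equalizing enforcer fractions are

    α^C = τ(w+b−c)/(w+b+f−c),   α^D = τw/(w+l).

The per-candidate CE-vs-DE payoff gap, `l·(n_CE−1)/(n_E−1) − f` for a
current complier and `l·n_CE/(n_E−1) − f` for a current defector,
yields the basin thresholds used by `classify_basin`: the cooperative
set attracts states with `n_CE > (f/l)(n_E−1)+1`, the defection set
attracts `n_CE < (f/l)(n_E−1)` or `n_E < 2`, and the band in between
can fall either way depending on which enforcer happens to revise
first. The exact best-reply dynamic follows the structured schedule
(all producers one by one, then one enforcer, repeating until all
enforcers have revised, then one whole-population draw) and stops on
entering an absorbing bracket `αN−1 ≤ n ≤ αN`. Bracket detection
presumes the population is large enough that the brackets are
genuinely absorbing (`N ≳ 20` at the default parameters).

The stochastic-stability criterion — cooperation retains the long-run
mass as `ε → 0` iff `l/f − 1/(1+l/w) > 1 + f/(w+b−c)` — is implemented
exactly as printed, under the analytic assumption `v = 0`; the result
carries a flag when evaluated with `v > 0`.

## Default parameters

| symbol | meaning | baseline | alternative |
|---|---|---|---|
| `b`, `c` | PD benefit, cost | 4, 1 | 3, 2 |
| `w` | autarky payoff | 2 | 2 |
| `τ` | tax rate | 0.3 | 0.3 |
| `p`, `v` | punishment loss, cost | 2, 0.1 | 2, 0.3 |
| `f` | per-round information cost | 0.3 | 0.4 |
| `l`, `ψ` | attack loss, grab share | 5, 0.7 | 4, 0.7 |
| `δ`, `κ` | continuation, punishment length | 0.9, 8 | 0.9, 8 |
| `μ`, `η`, `ε` | action, logit, revision noise | 0.005, 0.01, 0.05 | same |
| `(γ_PE, γ_E, γ_P)` | revision classes | (0.1, 0.3, 0.6) | same |
| `N` | population size | 50 | 50 |

The baseline makes enforcer conflict destructive and information
cheap, so cooperation is selected; the alternative raises the costs of
cooperation and information and lowers `l`, flipping the selection.

## Numerical choices

- **Engines.** Every operation has a readable pure-Python
  implementation; long-chain estimation additionally has a compiled
  (numba) kernel with identical semantics, used by default. The two
  are cross-checked exactly on the deterministic analytic payoffs and
  statistically on simulated trajectories. Random streams differ
  between engines; within an engine, results are bit-reproducible from
  the seed.
- **Geometric stop** is drawn round-by-round with no cap (a cap exists
  as a testing aid only).
- **Ties** at `η = 0` break uniformly; basin/bracket inequalities at
  exact equality are labelled `boundary` rather than assigned a side.
- **Degenerate rounds** never crash: missing partners or role classes
  yield vacuous compliance and untaxed autarky production, as listed
  above. The model's own description of unmatched agents is not part
  of the main text, so these conventions are the package's choice.
- **Problem sizes.** The acceptance checks run the basin Monte Carlo
  at 200 random states for `N ∈ {20, 50}`, the two-strategy
  invariant-distribution estimates at 4 runs × 10⁵ periods, and the
  sixteen-strategy reproducibility estimate at the full 7 runs × 10⁶
  periods.

## What the simulations do and do not show

The synthetic populations here *are* the model's study conditions —
there is no external data. Passing tests show that the implementation
reproduces the model's closed forms, its basin geometry, and the
qualitative selection results under the stated parameterizations. They
do not show anything about the behaviour of real enforcement
institutions: the stage game abstracts from partner choice, enforcer
monopolies, counter-punishment, private or noisy reputation
information, and heterogeneous matching, all of which are structural
features of the applications the model is meant to illuminate.

## Known limitations

- The exact invariant distribution is never computed by linear algebra
  (the state space is combinatorially large); all distribution results
  are time-average estimates.
- `hypothetical_payoff` ignores odd-headcount matching corrections;
  at `N = 50` these are `O(1/N)` and irrelevant to the comparisons it
  feeds.
- Bracket detection in the exact best-reply runner can mislabel
  absorbing states for very small populations (`N ≲ 12` at default
  parameters), where the printed brackets stop being fixed points.
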