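# Methods

## Model

Two agents play a single-shot, three-stage game over two goods, apple and
orange. A scenario is the pair `(r(apple), d(apple))`: the buyer's reward
for the apple and the walking distance to it. Rewards, distances and prices
each satisfy the sum constraint `x(apple) + x(orange) = S` (default
`S = 10`), so the orange components are derived accessors — the constraint
cannot be violated by construction. Rewards, distances (at unit cost per
step) and prices share one scalar unit, since the utilities subtract them
directly:

- stage 1 (approach): `U1(i) = r(i) − d(i)`
- stage 3 (purchase): `U3(i) = r(i) − m(i)`; the purchase is forced — there
  is no opt-out
- seller payoff: `m(i3)`, the price of whichever item is bought
- total buyer utility: `U1 + U3`, undiscounted

All agents reason on the uniform lattice `{0, Δ, …, S}` (default
`Δ = 0.5`), and all continuous integrals are realized as probability-mass
sums over that lattice (a discrete uniform prior with mass `1/|grid|` per
point), which keeps every distribution normalized exactly and makes the
KL/MI quantities well defined without density conventions.

### Choice rule

Every binary choice is softmax in the action-value difference,
`P = σ(β (Q_i − Q_j))`, with inverse temperature `β = 0.5` by default.
Under the sum constraint the stage-1 difference is `2(r − d)` and the
stage-3 difference `2(r − m)`. `β` is common knowledge: every agent's model
of any other agent uses the same `β` (a per-level override hook exists,
`TaskConfig.beta_overrides`, but defaults to shared).

### The hierarchy

Levels alternate strictly — buyers odd, sellers even — and level `k` reads
only the tabulated artifact of level `k − 1`:

- **ToM(−1) buyer** treats each stage as an isolated softmax choice.
- **ToM(0) seller** runs Bayesian inverse reinforcement learning: posterior
  over `r` proportional to (ToM(−1) stage-1 likelihood of the observed
  move) × (flat prior), then posts the revenue-maximizing price on the
  lattice. The seller knows `d` and observes the first move, never `r`.
- **ToM(1) buyer** plans through the ToM(0) seller: for each candidate
  first move it looks up the seller's deterministic price response, adds
  the expected purchase-stage utility under its own softmax purchase
  behaviour, and softmaxes the resulting action values. (The expectation
  over the seller is degenerate because pricing is deterministic.)
- **ToM(2) seller** is the same IRL-plus-pricing operation with the ToM(1)
  policy as likelihood.
- **ToM(3) buyer** is the same planning operation against the ToM(2) table.

Because the nesting is strict and the state space finite, the hierarchy is
tabulated bottom-up with memoization — one policy table per buyer level
(`p(apple)` on the `(r, d)` lattice) and one price table per seller level
(`m(apple)` per `(d, observed move)`), mathematically identical to the
nested recursion but linear in depth. The pipeline contains no randomness:
two builds of the same configuration are bit-identical, and sweep outputs
carry a config hash instead of a seed.

### Pricing objective

The seller's payoff is the price of whichever item is bought, so the
default objective (`JOINT`) maximizes
`Σ_r p(r|a₁) [m σ_buy + (S − m)(1 − σ_buy)]` over the price lattice. A
literal single-item alternative (`CHOSEN_ONLY`), maximizing only
`Σ_r p(r|a₁) m σ_buy`, is provided as a configuration switch
(`--pricing-objective chosen-only`); divergences between the two are a
documented diagnostic, not a bug. Argmax ties (within 1e−12) break toward
the price closest to `S/2`, then toward the lower price — deterministic,
and midpoint-pricing for mirror-symmetric revenue landscapes.

## Information-theoretic instruments

All three are conditioned on one apple distance, marginalize the
preference under the uniform prior, and use log base 2 (bits) by default
(`log_base` is configurable; the `0·log 0 = 0` convention applies, though
finite `β` keeps all hierarchy-produced tables strictly interior):

- **Mutual information** `I(r; a₁)`: prior-weighted KL between the
  conditional and marginal action distributions. Bounded by 1 bit for a
  binary action.
- **Belief-update divergence** `D_KL(posterior ‖ prior)`: computed after
  observing the *closer* (likelier) item at each distance, with the
  equidistant tie resolved to the apple (immaterial — the curve is
  mirror-symmetric).
- **Policy discrepancy** `E_r D_KL(actual ‖ assumed)`: the actual policy of
  the ToM(k+1) buyer against the ToM(k−1) policy its ToM(k) seller assumes.

## Numerical conventions

- IRL likelihoods are rescaled by their maximum before multiplication with
  the prior (a pure renormalization that improves conditioning); an
  all-zero evidence vector raises a degenerate-evidence error rather than
  renormalizing silently — with finite `β` this can only arise from
  user-supplied tables.
- KL divergences snap rounding residues in `(−1e−9, 0)` to exactly zero
  (Gibbs' inequality guarantees non-negativity).
- Beliefs validate non-negativity and unit mass to 1e−12 at construction.
- Off-lattice queries raise a configuration error naming the offending
  value; grid membership is tested to 1e−9.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `sum_total` | 10 | reward/money | the game's published sum constraint |
| `grid_step` | 0.5 | reward/money | coarsest lattice that can represent half-unit thresholds; keeps full sweeps sub-second |
| `beta` | 0.5 | 1/reward | the published choice temperature |
| `log_base` | 2 | — | report information in bits |
| `pricing_objective` | joint | — | faithful expectation of the seller's payoff |
| `max_level` | 3 | — | the hierarchy's claims stop at ToM(3) |

## What the sweeps emulate — and what they do not

The sweep enumerates every lattice scenario exhaustively; there is no
sampling error anywhere, so "passing tests" means the deterministic result
surface has the asserted structure, not that any estimator is well
calibrated. The model idealizes away everything a real market would add:
one interaction (no repeated play or learning), deterministic environment,
two items, forced purchase, common knowledge of `β` and of the opponent's
exact level (no belief over levels, no mixed populations). Levels above
ToM(3) are supported by the generic recursion but not exercised by
default.

## Observed behaviour under the defaults

With `S = 10, Δ = 0.5, β = 0.5`, the package's own sweeps show the
expected qualitative arms race: the planning buyer over-selects the close
item (bluff), cutting action–preference mutual information well below the
naive buyer's at short distances; the skeptical seller prices flat at the
midpoint and near-ignores the signal for the most bluffable distances; the
ToM(3) buyer is largely cornered into ToM(1)-like play, and its residual
deception (policy discrepancy vs what the ToM(2) assumes) is an order of
magnitude below the ToM(1)/ToM(0) discrepancy.

Two boundary quantities deserve explicit numbers, both computed by
`scripts/acceptance.py` and the test suite rather than quoted from
anywhere: the planning buyer's apple-selection threshold at `d(apple) = 7`
lands at `r = 9.0` (the naive buyer's is 7.5, i.e. one step past exact
indifference at 7), and the bluff band where the planning buyer picks the
apple for *every* preference extends to `d(apple) = 1.5` (at `d = 2` the
lowest-preference scenarios drop to ≈ 0.35). Correspondingly the skeptical
seller's flat midpoint pricing and ≤ 0.02-bit belief updates hold for
`d ≤ 1.5` and relax at `d = 2`, and the naive seller's price after an
8-step apple walk is 7.0 (two lattice steps, not one, below the distance
walked). These edges move with `β` and `Δ`: sharper choice rules
(`β ≳ 2`) and the chosen-only objective widen the bluff band past `d = 2`
and push the post-walk price to 7.5, but leave the planning threshold at
9.0. The threshold location is robust across every objective/forecast
variant we examined — the stage-3 discount a deceptive first move earns at
`d = 7` is large enough that only strong apple preferences (`r ≥ 9`)
justify an honest far-apple walk.

## Known limitations

- The lattice argmax makes price tables piecewise constant in `d`; metric
  curves inherit small staircase artifacts that shrink with `Δ`.
- Computational cost grows as `O(L · n²)` for `L` levels on an `n`-point
  lattice — trivial at the defaults, but the model family itself is known
  to scale badly in level depth in richer state spaces.
- `CHOSEN_ONLY` pricing maximizes one item's revenue term while the payoff
  actually collected follows the joint expression; it exists for
  comparison, and its tables should be interpreted accordingly.
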