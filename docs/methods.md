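# Methods

## Model

The population is divided into five discrete life stages: infancy (1),
early childhood (2), late childhood (3), adulthood (4) and
post-reproductive life (5). Demography follows an adapted Leslie
matrix: only adults reproduce (`f4`), each stage survives to the next
with probability `s_i`, and post-reproductive survivors remain in
class 5 through a self-loop. Stage sizes are continuous non-negative
reals; there is no density dependence, migration or two-sex structure.

A cultural trait **T** (versus the baseline variant *t*) segregates at
frequency `x_i` in stage `i`. Per run the trait affects *either*
fertility (`b → b + w_f` in carriers) *or* survival
(`s_i → s_i + w_s` in carriers, all stages), selected by a mode flag;
a neutral mode disables both. The stage-average vital rates that enter
the projection matrix are carrier-frequency-weighted means, e.g.
`f4 = (b + w_f) x4 + b (1 − x4)`.

Learning happens every step until the post-reproductive stage:

* **Newborns** make one vertical learning attempt: acquisition
  probability is the fertility-weighted parental trait frequency times
  the vertical fidelity `p_v`.
* **Cohorts entering classes 2–4** keep the trait if they have it;
  the naive fraction makes one mixed attempt, vertical with proportion
  `V_j` (success `p_v` against the parental-pool frequency) and
  horizontal/oblique with proportion `1 − V_j` (success `p_h` against
  the size-weighted trait frequency of stages `j..ω`).
* **Class 5** does not learn; its frequency is the survival-weighted
  mix of maturing adults and surviving elders.

### Update order

Each step is synchronous: (1) all five new frequencies are computed
from the time-τ state; (2) stage proportions are advanced with the
projection matrix built from time-τ frequencies; (3) the current adult
frequency is pushed onto a lag buffer; (4) the time index increments.

### Lag convention

A cohort in class `j` at time τ+1 was born at τ+1−(j−1); its parents
were the adults of time τ+1−j. All parental quantities — the
vertical-learning source frequency and the niche-construction contact
time — therefore use the adult frequency at lag `j − 1` relative to
the time-τ state being consumed (the newborn update uses lag 0, i.e.
the current adults). Lags reaching before the start of a run are
served from a buffer padded with the initial adult frequency; with the
trait introduced near absence everywhere, the padding choice is
numerically negligible.

### Parental weighting

The trait frequency among a cohort's parents differs from the raw
adult frequency at its birth time:

* fertility mode: carriers are over-represented among parents in
  proportion to their fertility,
  `x_parent = (b+w_f) x / [(b+w_f) x + b (1−x)]`;
* survival mode: carriers are over-represented among parents *still
  alive* after `j` steps,
  `x_parent = (s4+w_s)^j x / [(s4+w_s)^j x + s4^j (1−x)]`
  (adult-rate powers throughout, a deliberate simplification — parents
  spend all but one of those steps in class 5);
* neutral mode: `x_parent = x` unchanged.

Survival mode applies `w_s` in exactly two places: the stage-average
survival entries of the projection matrix, and the parental weighting
above. Within-cohort survival selection on the *frequency* recursion
(survivors of a partially-knowledgeable cohort being enriched for
carriers) is deliberately not modelled; an individual-based model
necessarily includes it, which is why the deterministic-versus-agent
equivalence checks run in fertility/neutral mode.

### Horizontal/oblique source pool

The pool for a learner entering class `j` spans stages `j` through
`ω` (default 5), weighted by time-τ stage sizes. The learner's own
cohort (stage `j − 1` at time τ) is not part of its pool. An empty
pool contributes nothing (the library operation raises a "no role
models" error when called directly on an empty pool).

### Niche construction

With the feedback enabled, the fixed `V_j` of classes 2–4 is replaced
by a contact-time norm `v_j = v_b (1 − ε x4,lag)`, evaluated at the
same parental-cohort lag as the vertical source frequency: the norm is
set by the adult generation that reared the cohort. The newborn
vertical round is left unmodified — the feedback is a norm about
post-infancy child rearing, and extending it to infancy is not implied
by the model description we follow. `v_j` is clamped to [0, 1]
(possible only for ε > 1); clamping events are counted and logged.
With ε = 0 the dynamic schedule is *bit-identical* to a fixed schedule
`V_j = v_b` (both run through the same kernel path), which the test
suite asserts over full trajectories.

## Parameters and defaults

| parameter | meaning | default | notes |
|---|---|---|---|
| `b` | offspring per adult per step | 5.0 | baseline spread parameterization |
| `s1..s5` | stage survival probabilities | 0.5, 0.6, 0.6, 0.6, 0.2 | |
| `w_f` | carrier fertility increment | 1.0 | may be negative (`b + w_f ≥ 0`) |
| `w_s` | carrier survival increment | 0.05 | needs `s_i + w_s ≤ 1` in survival mode |
| `p_v`, `p_h` | transmission fidelities | 0.6 | probability of acquisition per contact |
| `V_2..V_4` | vertical learning proportions | scenario | see below |
| `ω` | oldest oblique source stage | 5 | |
| `v_b` | baseline vertical contact time | 0.6 | niche model |
| `ε` | niche-construction strength | 0 (off) / 1 (canonical) | |
| initial size / structure / frequency | | 100, uniform 0.2, 0.005 | a rarer-introduction preset uses 0.001 |
| steps | | 5000 | rescue preset: 50 founders, 2500 steps |

Bundled learning life histories (`V_2, V_3, V_4`): `all_vertical`
(1, 1, 1), `hunter_gatherer` (0.8, 0.8, 0.4), `agriculturalist`
(0.5, 0.25, 0.1), `all_horizontal` (0, 0, 0). The two ethnographic
schedules are stand-ins shaped like published forager/farmer
time-allocation profiles, whose exact per-stage values are reported
only graphically in the literature; both are fully configurable
(explicit `V2..V4` keys override any scenario). The
selected-versus-neutral contrast preset (`fitness_contrast`: b = 4,
s = (0.6, 0.7, 0.7, 0.7, 0.4)) does not pin the effect sizes, so it
carries the baseline `w_f = 1` and `w_s = 0.05`.

## Period-4 demographic cycles and end-state statistics

With a single reproductive stage, the classes-1–4 block of the
projection matrix is cyclic: `L⁴` restricted to that block is exactly
`λ⁴ I`. Consequences:

* Cohort waves excited by the initial age structure **never damp**.
  From the canonical uniform start the stage proportions ride a
  permanent period-4 cycle (which the fertility–frequency coupling can
  amplify substantially), and every instantaneous size-weighted
  statistic oscillates with the same period. End-state statistics
  (sweep cells, contrasts, rescue sizes) are therefore averaged over
  the final maturation cycle (last 4 steps), which is phase-free; the
  instantaneous endpoint remains available as `statistic="final_freq"`.
* A generic age structure does not converge to the dominant
  eigenvector; growth and structure limits are therefore stated
  cycle-aware: the growth factor per 4-step cycle equals `λ⁴` (to
  machine precision after the class-5 transient), and the stable stage
  distribution is the unique structure that reproduces itself each
  step (verified to 1e-6 over 500 steps when started there).
* Several eigenvalues share the spectral radius (λ, ±iλ, −λ), so the
  stable-structure routine selects the real non-negative Perron root
  explicitly rather than trusting a modulus argmax.

## The individual-based oracle

`agecult.oracle` implements the same rules per agent: Bernoulli
survival, Poisson offspring with the parent's fertility (only the mean
matters for the comparison), and one learning draw per learner per
step. It exists to validate the recursion, and doubles as the place
where finite-population effects can be studied.

Design choices that matter for the correspondence:

* **Initialization** rounds expected stage/carrier counts instead of
  drawing them, so replicate variance reflects dynamics only and the
  deterministic twin starts from identical fractions. Founders get an
  ancestry record assigned independently of their own trait at the
  appropriately weighted parental frequency.
* **Vertical role models are sampled from the cohort's parental pool**
  (the recorded parent traits of all same-cohort members), afresh at
  every attempt, not from one fixed recorded parent. The recursion
  multiplies the naive fraction by the *marginal* parental frequency
  every round; a fixed parent would deplete the parental frequency
  among still-naive learners (a naive child of a carrier parent has
  already failed vertical draws) — a correlation the recursion does
  not contain. Pool sampling is the individual-based model whose mean
  field is exactly the recursion; the fixed-parent variant undershoots
  it by large margins.
* In survival mode each recorded parent carries a simulated survival
  chain at the adult rate, with the first draw at the birth step, so a
  cohort entering class `j` has parental survival weighted by
  `(s4 + w_s)^j`; the pool is restricted to surviving parents.

What the oracle shows — and does not. The law-of-large-numbers test
demonstrates that the recursion is the mean-field limit: the maximum
deviation between replicate-mean frequencies and the deterministic
trajectory shrinks roughly as 1/N₀ across N₀ = 100 → 10⁴. At any
finite N₀ a small systematic gap of that order remains (nonlinear maps
of fluctuating frequencies do not average to the map of the mean), so
pointwise standardized comparisons against replicate standard errors
tighten into this bias as replicates accumulate. None of this involves
real data: agreement between the two implementations checks internal
consistency of the rules, not the adequacy of those rules for any
empirical population.

## Numerical choices

* Internal state is stage *proportions* plus log total size; every
  recursion depends on sizes only through ratios, so super-critical
  growth over 5000 steps cannot overflow. `n` vectors are derived
  views.
* Sweeps run all grid cells as one vectorized batch in lock step; a
  scalar reference implementation of the step, composed from the
  documented per-operation functions, is cross-checked against the
  kernel to 1e-12 (and used for single-step work).
* Division guards: an empty horizontal pool contributes 0; an empty
  class-5 inflow reports frequency 0 by convention (logged); a zero
  total growth factor marks the run extinct and freezes the state.
* Trajectories serialize as CSV at 12 significant digits and
  round-trip losslessly at that precision.

## Known limitations

* One-sex, deterministic demography with no density dependence or
  carrying capacity; "collapse" is a reporting threshold (default
  total size 1.0), not an absorbing state.
* The trait affects fertility or survival, not both at once, in any
  canonical run (the types allow both; the experiments do not exercise
  it).
* No environmental change that devalues information, no prestige or
  conformity biases, no one-to-many transmission.
* The survival-mode frequency recursion omits within-cohort survival
  selection (see above), and parental survival uses adult-rate powers
  throughout.
* The ethnographic learning schedules are configurable stand-ins, not
  fitted estimates; conclusions about real forager or farmer
  populations require schedules estimated from data.
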