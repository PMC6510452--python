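"""Stochastic individual-based twin of the deterministic recursion.

Used purely for validation: the deterministic model tracks expected
stage sizes and trait frequencies; this module simulates the same rules
agent by agent (Bernoulli survival, Poisson offspring, one learning
draw per learner per step) so the deterministic trajectory can be
checked against replicate means.

Correspondence notes
--------------------
* Each newborn records whether its parent carries the trait (the
  fertility weighting of the parental frequency arises automatically
  because carrier adults produce more offspring).  The newborn's single
  vertical round consults its own parent's record.
* Vertical learning in later stages samples a role model afresh from
  the *cohort's parental pool* (the recorded parent traits of all
  same-cohort members) at every attempt, rather than re-consulting one
  fixed parent.  The recursion multiplies the naive fraction by the
  marginal parental-cohort frequency at every step; with a fixed parent
  the naive subset's parental frequency would be progressively depleted
  (a naive child of a carrier parent has, by construction, already
  failed vertical draws), which is a correlation the recursion does not
  contain.  Pool sampling is the individual-based model whose mean
  field *is* the recursion.
* Offspring numbers are Poisson with the parent's fertility; only the
  mean matters for the equivalence check.
* In survival mode each recorded parent carries a simulated survival
  chain at the adult survival rate (matching the ``(s4 + w_s)^j``
  weighting of the recursion) and the parental pool is restricted to
  surviving parents.
* The recursion (following its published form) does not apply survival
  selection within a cohort to the *frequency* updates, while an
  individual-based model necessarily does; deterministic-versus-agent
  equivalence is therefore asserted in fertility/neutral mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import N_CLASSES
from .experiments import SimulationConfig, initial_state
from .learning import surviving_parent_frequency

__all__ = ["AgentPopulation", "init_population", "abm_step", "run_abm", "replicate_summary"]


@dataclass
class AgentPopulation:
    """Flat per-agent arrays plus the adult-frequency history buffer."""

    age: np.ndarray  # stage 1..5, int8
    trait: np.ndarray  # carries T
    parent_trait: np.ndarray  # parent carried T at the agent's birth
    parent_alive: np.ndarray  # parent survival chain (survival mode only)
    adult_freq_history: tuple[float, ...] = ()
    tau: int = 0

    def __post_init__(self) -> None:
        n = len(self.age)
        for arr in (self.trait, self.parent_trait, self.parent_alive):
            if len(arr) != n:
                raise ValueError("per-agent arrays must have equal length")

    @property
    def size(self) -> int:
        return len(self.age)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.age, minlength=N_CLASSES + 1)[1:].astype(float)

    def class_frequencies(self) -> np.ndarray:
        """Per-stage trait frequency; NaN for empty stages."""
        counts = self.class_counts()
        carriers = np.bincount(
            self.age, weights=self.trait.astype(float), minlength=N_CLASSES + 1
        )[1:]
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, carriers / np.where(counts > 0, counts, 1), np.nan)

    def lagged_adult_frequency(self, lag: int) -> float:
        if lag == 0:
            counts = self.class_counts()
            freqs = self.class_frequencies()
            return float(freqs[3]) if counts[3] > 0 else 0.0
        return self.adult_freq_history[-lag]


def init_population(
    config: SimulationConfig, n0: int | None = None, rng=None
) -> AgentPopulation:
    """Deterministic initialization by rounding expected stage/carrier counts.

    Rounding (rather than Bernoulli draws) makes replicate variance
    reflect the dynamics only, and lets the deterministic twin start
    from the same exact per-stage frequencies.

    Founding cohorts need an ancestry record for later vertical
    learning.  The recursion serves those lags from a history buffer
    padded with the initial adult frequency, so founders are assigned
    ``parent_trait`` *independently of their own trait* at the
    correspondingly weighted parental frequency (fertility-weighted in
    fertility mode, raw otherwise — in survival mode the weighting
    accrues through the parent-survival chain instead).
    """
    total = int(round(n0 if n0 is not None else config.initial_total))
    state = initial_state(config)
    counts = np.rint(state.a * total).astype(int)
    carriers = np.rint(counts * state.x).astype(int)
    age = np.repeat(np.arange(1, N_CLASSES + 1), counts).astype(np.int8)
    trait = np.zeros(age.size, dtype=bool)
    parent_trait = np.zeros(age.size, dtype=bool)
    x4 = carriers[3] / counts[3] if counts[3] > 0 else 0.0
    if config.mode == "fertility":
        parent_prob = surviving_parent_frequency(
            "fertility", config.demography, float(x4), 1
        )
    else:
        parent_prob = float(x4)
    pos = 0
    for i in range(N_CLASSES):
        trait[pos : pos + carriers[i]] = True
        k = int(round(counts[i] * parent_prob))
        if k > 0:
            # evenly spread, offset by half a stride to stay independent
            # of the carrier block at the start of the stage
            idx = pos + ((np.arange(k) + 0.5) * counts[i] / k).astype(int)
            parent_trait[idx] = True
        pos += counts[i]
    parent_alive = np.ones(age.size, dtype=bool)
    if config.mode == "survival" and rng is not None:
        # a cohort in class k has parents who already survived k steps
        # (the newborn's parent draws its first survival at the birth step)
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        s4, ws = config.demography.s[3], config.demography.w_s
        prob = (s4 + ws * parent_trait) ** age
        parent_alive = rng.random(age.size) < prob
    return AgentPopulation(
        age=age,
        trait=trait,
        parent_trait=parent_trait,
        parent_alive=parent_alive,
        adult_freq_history=(float(x4),) * (N_CLASSES - 1),
    )


def exact_initial_frequencies(config: SimulationConfig, n0: int) -> np.ndarray:
    """Per-stage frequencies actually realized by :func:`init_population`."""
    state = initial_state(config)
    counts = np.rint(state.a * int(round(n0))).astype(int)
    carriers = np.rint(counts * state.x).astype(int)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, carriers / np.maximum(counts, 1), np.nan)


def abm_step(
    pop: AgentPopulation, config: SimulationConfig, rng
) -> AgentPopulation:
    """One synchronous step mirroring the deterministic update order."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if pop.size == 0:
        return AgentPopulation(
            age=pop.age,
            trait=pop.trait,
            parent_trait=pop.parent_trait,
            parent_alive=pop.parent_alive,
            adult_freq_history=(pop.adult_freq_history + (0.0,))[-(N_CLASSES - 1):],
            tau=pop.tau + 1,
        )
    dem, lp, nichep = config.demography, config.learning, config.niche
    mode = config.mode
    s = np.array(dem.s)
    x4_now = pop.lagged_adult_frequency(0)

    # births from current adults (Poisson offspring, fertility by trait)
    adults = pop.age == 4
    rates = np.full(int(adults.sum()), dem.b, dtype=float)
    if mode == "fertility":
        rates += dem.w_f * pop.trait[adults]
    n_off = rng.poisson(rates) if rates.size else np.zeros(0, dtype=int)
    nb_parent_trait = np.repeat(pop.trait[adults], n_off)
    nb_trait = nb_parent_trait & (rng.random(nb_parent_trait.size) < lp.p_v)
    nb_parent_alive = np.ones(nb_parent_trait.size, dtype=bool)
    if mode == "survival":
        # the parent's first survival draw happens at the birth step
        nb_parent_alive = rng.random(nb_parent_trait.size) < (
            s[3] + dem.w_s * nb_parent_trait
        )

    # snapshot of the pre-update population for role-model sampling
    snap_age = pop.age
    snap_trait = pop.trait.copy()

    # survival and maturation
    sprob = s[pop.age - 1]
    if mode == "survival":
        sprob = sprob + dem.w_s * pop.trait
    surv = rng.random(pop.size) < sprob
    new_age = np.minimum(pop.age + 1, N_CLASSES).astype(np.int8)

    parent_alive = pop.parent_alive
    if mode == "survival":
        pprob = s[3] + dem.w_s * pop.parent_trait
        parent_alive = parent_alive & (rng.random(pop.size) < pprob)

    trait = pop.trait.copy()
    for j in (2, 3, 4):
        cohort = surv & (new_age == j)
        learner_idx = np.flatnonzero(cohort & ~trait)
        if learner_idx.size == 0:
            continue
        if nichep.enabled:
            xl = pop.lagged_adult_frequency(j - 1)
            v_eff = min(max(nichep.v_b * (1.0 - nichep.epsilon * xl), 0.0), 1.0)
        else:
            v_eff = lp.V[j - 2]
        vertical = rng.random(learner_idx.size) < v_eff
        v_idx = learner_idx[vertical]
        if v_idx.size:
            # vertical role model drawn afresh from the cohort's parental
            # pool (surviving parents only in survival mode); see module
            # docstring for why this, not a fixed recorded parent, is the
            # stochastic reading of the recursion
            if mode == "survival":
                donors = pop.parent_trait[cohort & parent_alive]
            else:
                donors = pop.parent_trait[cohort]
            if donors.size:
                drawn = donors[rng.integers(0, donors.size, v_idx.size)]
                success = drawn & (rng.random(v_idx.size) < lp.p_v)
                trait[v_idx[success]] = True
        h_idx = learner_idx[~vertical]
        if h_idx.size:
            pool = np.flatnonzero((snap_age >= j) & (snap_age <= lp.omega))
            if pool.size:
                models = pool[rng.integers(0, pool.size, h_idx.size)]
                success = snap_trait[models] & (rng.random(h_idx.size) < lp.p_h)
                trait[h_idx[success]] = True

    keep = surv
    next_pop = AgentPopulation(
        age=np.concatenate([new_age[keep], np.ones(nb_trait.size, dtype=np.int8)]),
        trait=np.concatenate([trait[keep], nb_trait]),
        parent_trait=np.concatenate([pop.parent_trait[keep], nb_parent_trait]),
        parent_alive=np.concatenate([parent_alive[keep], nb_parent_alive]),
        adult_freq_history=(pop.adult_freq_history + (float(x4_now),))[
            -(N_CLASSES - 1):
        ],
        tau=pop.tau + 1,
    )
    return next_pop


def run_abm(
    config: SimulationConfig,
    n0: int,
    n_steps: int,
    seed: int | np.random.Generator,
):
    """One replicate; returns per-step stage frequencies, proportions, sizes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = init_population(config, n0, rng=rng if config.mode == "survival" else None)
    freqs = np.empty((n_steps + 1, N_CLASSES))
    props = np.empty((n_steps + 1, N_CLASSES))
    sizes = np.empty(n_steps + 1)
    for t in range(n_steps + 1):
        counts = pop.class_counts()
        total = counts.sum()
        freqs[t] = pop.class_frequencies()
        props[t] = counts / total if total > 0 else np.nan
        sizes[t] = total
        if t < n_steps:
            pop = abm_step(pop, config, rng)
    return {"freq": freqs, "prop": props, "size": sizes, "final_pop": pop}


def replicate_summary(
    config: SimulationConfig,
    n_replicates: int = 50,
    n0: int = 10_000,
    n_steps: int = 100,
    seed: int = 0,
    seeds=None,
):
    """Mean and standard error across independent seeded replicates.

    Returns per-step, per-stage mean/SE of trait frequencies and stage
    proportions plus mean/SE of total size.  Empty stages contribute
    NaN and are excluded from the moments.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates for a standard error")
    if seeds is None:
        seeds = np.random.SeedSequence(seed).spawn(n_replicates)
    elif len(seeds) != n_replicates:
        raise ValueError("seeds must match n_replicates")
    freq = np.empty((n_replicates, n_steps + 1, N_CLASSES))
    prop = np.empty((n_replicates, n_steps + 1, N_CLASSES))
    size = np.empty((n_replicates, n_steps + 1))
    for r, sd in enumerate(seeds):
        rng = np.random.default_rng(sd)
        out = run_abm(config, n0, n_steps, rng)
        freq[r] = out["freq"]
        prop[r] = out["prop"]
        size[r] = out["size"]

    def _mean_se(arr):
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # stages empty in every replicate yield all-NaN slices by design
            warnings.simplefilter("ignore", RuntimeWarning)
            count = np.sum(~np.isnan(arr), axis=0)
            mean = np.nanmean(arr, axis=0)
            sd_ = np.nanstd(arr, axis=0, ddof=1)
            se = sd_ / np.sqrt(np.maximum(count, 1))
        return mean, se

    freq_mean, freq_se = _mean_se(freq)
    prop_mean, prop_se = _mean_se(prop)
    size_mean, size_se = _mean_se(size)
    return {
        "freq_mean": freq_mean,
        "freq_se": freq_se,
        "prop_mean": prop_mean,
        "prop_se": prop_se,
        "size_mean": size_mean,
        "size_se": size_se,
        "n_replicates": n_replicates,
    }
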