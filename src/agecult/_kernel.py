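"""Vectorized time-stepping kernel.

Runs a *batch* of independent deterministic simulations in lock step
(one row per parameter combination), which is what makes dense
fidelity-grid sweeps over thousands of time steps cheap.  A single run
is a batch of size one.  The scalar reference implementation of one
step lives in :mod:`agecult.experiments` (``step``), composed from the
documented per-operation functions; the two paths are cross-checked in
the test suite.

Update order within a step (synchronous: every right-hand side refers to
the time-``tau`` state):

1. new trait frequencies for all five classes,
2. stage proportions advanced with the projection matrix built from the
   time-``tau`` frequencies; total size advanced in log space,
3. current adult frequency pushed onto the lag buffer,
4. time index incremented.
"""

from __future__ import annotations

import numpy as np

__all__ = ["iterate_batch"]

_LAG_DEPTH = 3  # adult-frequency lags 1..3 serve the class 2..4 updates


def _fertility_weighted(x, b, wf):
    num = (b + wf) * x
    den = num + b * (1.0 - x)
    safe = den > 0
    return np.where(safe, num / np.where(safe, den, 1.0), 0.0)


def _survival_weighted(x, s4, ws, j):
    num = (s4 + ws) ** j * x
    den = num + s4**j * (1.0 - x)
    safe = den > 0
    return np.where(safe, num / np.where(safe, den, 1.0), 0.0)


def iterate_batch(
    a0,
    x0,
    log_n0,
    hist0,
    *,
    b,
    wf,
    ws,
    s,
    pv,
    ph,
    V,
    omega,
    mode,
    niche,
    vb,
    eps,
    n_steps,
    record=False,
):
    """Iterate ``n_steps`` of the coupled recursion for a batch of runs.

    Parameters
    ----------
    a0, x0 : (B, 5) arrays
        Initial stage proportions and trait frequencies.
    log_n0 : (B,) array
        Initial log total sizes.
    hist0 : (B, 3) array
        Adult-frequency lag buffer, column k = adult frequency k+1 steps
        before the initial state (padded with the initial value).
    b, wf, ws, pv, ph, vb, eps : (B,) arrays
        Per-run parameters.
    s : (B, 5) array; V : (B, 3) array
        Survival probabilities and fixed vertical proportions.
    omega : int
        Oldest horizontal/oblique source stage (shared by the batch).
    mode : {"fertility", "survival", "neutral"}
    niche : bool
        Use the frequency-dependent contact-time schedule instead of V.
    record : bool
        Keep the full trajectory (otherwise only the final state).

    Returns
    -------
    dict with final ``a``, ``x``, ``log_n``, ``hist``, ``extinct`` and
    ``clamp_events``; with ``record=True`` also trajectory arrays
    ``traj_a``, ``traj_x``, ``traj_log_n`` of shape (n_steps+1, B, ...).
    """
    a = np.array(a0, dtype=float)
    x = np.array(x0, dtype=float)
    log_n = np.array(log_n0, dtype=float)
    hist = np.array(hist0, dtype=float)
    B = a.shape[0]
    b = np.asarray(b, dtype=float)
    wf = np.asarray(wf, dtype=float)
    ws = np.asarray(ws, dtype=float)
    s = np.asarray(s, dtype=float)
    pv = np.asarray(pv, dtype=float)
    ph = np.asarray(ph, dtype=float)
    V = np.asarray(V, dtype=float)
    vb = np.asarray(vb, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if mode not in ("fertility", "survival", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")

    wf_eff = wf if mode == "fertility" else np.zeros(B)
    ws_eff = ws if mode == "survival" else np.zeros(B)
    extinct = np.zeros(B, dtype=bool)
    clamp_events = 0

    if record:
        traj_a = np.empty((n_steps + 1, B, 5))
        traj_x = np.empty((n_steps + 1, B, 5))
        traj_log_n = np.empty((n_steps + 1, B))
        traj_a[0] = a
        traj_x[0] = x
        traj_log_n[0] = log_n
    # rolling buffer of the final maturation cycle (4 steps + endpoint):
    # with a single reproductive stage the stage structure is generically
    # period-4, so phase-free end-state statistics average over one cycle
    cycle: list[tuple] = [(a.copy(), x.copy(), log_n.copy())]

    new_x = np.empty_like(x)
    for t in range(n_steps):
        x4 = x[:, 3]

        # class 1: newborn vertical round (fertility-weighted parents)
        new_x[:, 0] = pv * _fertility_weighted(x4, b, wf_eff)

        # classes 2..4: retained trait + one mixed learning attempt
        for j in (2, 3, 4):
            xl = hist[:, j - 2]  # adult frequency at the cohort's birth time
            if mode == "survival":
                xp = _survival_weighted(xl, s[:, 3], ws, j)
            elif mode == "fertility":
                xp = _fertility_weighted(xl, b, wf)
            else:
                xp = xl
            if niche:
                raw = vb * (1.0 - eps * xl)
                v_eff = np.clip(raw, 0.0, 1.0)
                clamp_events += int(np.count_nonzero(raw != v_eff))
            else:
                v_eff = V[:, j - 2]
            seg_a = a[:, j - 1 : omega]
            den = seg_a.sum(axis=1)
            safe = den > 0
            pool = np.where(
                safe,
                (seg_a * x[:, j - 1 : omega]).sum(axis=1) / np.where(safe, den, 1.0),
                0.0,
            )
            prev = x[:, j - 2]
            new_x[:, j - 1] = prev + (1.0 - prev) * (
                v_eff * xp * pv + (1.0 - v_eff) * ph * pool
            )

        # class 5: maturing adults pooled with surviving elders, no learning
        m4 = s[:, 3] * a[:, 3]
        m5 = s[:, 4] * a[:, 4]
        den5 = m4 + m5
        safe5 = den5 > 0
        new_x[:, 4] = np.where(
            safe5, (x4 * m4 + x[:, 4] * m5) / np.where(safe5, den5, 1.0), 0.0
        )

        # stage counts: projection with time-tau stage-average vital rates
        f4 = b + wf_eff * x4
        se = s + ws_eff[:, None] * x
        an = np.empty_like(a)
        an[:, 0] = f4 * a[:, 3]
        an[:, 1] = se[:, 0] * a[:, 0]
        an[:, 2] = se[:, 1] * a[:, 1]
        an[:, 3] = se[:, 2] * a[:, 2]
        an[:, 4] = se[:, 3] * a[:, 3] + se[:, 4] * a[:, 4]
        g = an.sum(axis=1)
        alive = g > 0
        extinct |= ~alive
        with np.errstate(divide="ignore"):
            log_n = log_n + np.where(alive, np.log(np.where(alive, g, 1.0)), -np.inf)
        a = np.where(alive[:, None], an / np.where(alive, g, 1.0)[:, None], a)

        hist = np.column_stack([x4, hist[:, 0], hist[:, 1]])
        x, new_x = new_x.copy(), x  # keep recorded rows independent

        if record:
            traj_a[t + 1] = a
            traj_x[t + 1] = x
            traj_log_n[t + 1] = log_n
        cycle.append((a.copy(), x.copy(), log_n.copy()))
        if len(cycle) > 4:
            cycle.pop(0)

    out = {
        "cycle_a": np.stack([c[0] for c in cycle]),
        "cycle_x": np.stack([c[1] for c in cycle]),
        "cycle_log_n": np.stack([c[2] for c in cycle]),
        "a": a,
        "x": x,
        "log_n": log_n,
        "hist": hist,
        "extinct": extinct,
        "clamp_events": clamp_events,
    }
    if record:
        out["traj_a"] = traj_a
        out["traj_x"] = traj_x
        out["traj_log_n"] = traj_log_n
    return out
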