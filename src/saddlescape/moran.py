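"""Exact stochastic simulation of the Moran jump process on a type graph.

The population is a vector of counts summing to a constant N.  Three kinds
of transitions define the continuous-time Markov jump process:

* reproduction–replacement: an individual of type i reproduces and the
  child displaces a uniformly chosen individual of another type j, at total
  rate N f_i x_i x_j per ordered pair (i, j), i != j;
* mutation: an individual of type i turns into an adjacent type j
  (E_ij = 1), at total rate N λ x_i per incident edge.

Same-type replacements (i = j) do not change the state and are excluded
from the event space — an exact thinning.  Types are exchangeable, so the
count vector is a sufficient state and no per-individual bookkeeping is
done.

Two engines implement the same process:

* ``engine="fast"`` — a numba direct-method kernel used for all production
  runs, with recording policies "grid" (snapshots on a fixed time grid),
  "support-changes" (snapshot whenever the set of present types changes),
  "dominance" (a compact log of dominance changes and (1-ε)-threshold
  crossings, exact segmentation input for very long runs), or "none";
* ``engine="reference"`` — a pure-Python full-recompute implementation that
  records every jump event and exists for differential testing and replay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .dynamics import selection_coefficient
from .landscape import TypeGraph

__all__ = [
    "JumpEvent",
    "Trajectory",
    "RateTable",
    "total_rates",
    "simulate",
    "run_to_fixation",
    "estimate_fixation_probability",
    "replay_events",
    "as_counts",
    "child_seeds",
]

# recording policies
_REC_NONE, _REC_GRID, _REC_DOM, _REC_SUPPORT = 0, 1, 2, 3
# stop modes
_STOP_NONE, _STOP_MONO, _STOP_TYPE_ABSORB, _STOP_TYPE_FIX = 0, 1, 2, 3
# stop reasons
_REASONS = {
    0: "t_max",
    1: "absorbed",
    2: "monomorphic",
    3: "type_fixed",
    4: "type_extinct",
    5: "overflow",
}

DEFAULT_MAX_EVENTS = 2_000_000_000


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 31-bit child seeds from a root seed via
    numpy's SeedSequence spawning — the documented replicate-splitting rule."""
    ss = np.random.SeedSequence(seed)
    return np.array(
        [int(c.generate_state(1, np.uint32)[0]) & 0x7FFFFFFF for c in ss.spawn(n)],
        dtype=np.int64,
    )


def as_counts(graph: TypeGraph, initial_state, N: int) -> np.ndarray:
    """Coerce an initial-state spec to a count vector summing to N.

    Accepts a mapping {type_id: count}, the string "uniform" (equal split,
    remainder to the fittest types first), a pair ("monomorphic", type_id),
    or an integer array.
    """
    K = graph.n_types
    if isinstance(initial_state, str):
        if initial_state != "uniform":
            raise ValueError(f"unknown initial state spec {initial_state!r}")
        base = N // K
        counts = np.full(K, base, dtype=np.int64)
        order = np.argsort(graph.fitness)[::-1]
        for i in range(N - base * K):
            counts[order[i % K]] += 1
    elif isinstance(initial_state, tuple) and initial_state[0] == "monomorphic":
        counts = np.zeros(K, dtype=np.int64)
        counts[graph.index(initial_state[1])] = N
    elif isinstance(initial_state, dict):
        counts = np.zeros(K, dtype=np.int64)
        for tid, c in initial_state.items():
            counts[graph.index(tid)] = int(c)
    else:
        counts = np.asarray(initial_state, dtype=np.int64).copy()
        if counts.shape != (K,):
            raise ValueError(f"expected {K} counts, got shape {counts.shape}")
    if np.any(counts < 0) or counts.sum() != N:
        raise ValueError("counts must be nonnegative and sum to N")
    if not np.any(counts > 0):
        raise ValueError("initial support must be nonempty")
    return counts


# ---------------------------------------------------------------------------
# rate table (inspection / small-scale verification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateTable:
    """All instantaneous transition rates out of a state.

    ``reproduction[(i, j)]`` is the rate of (i gains one, j loses one),
    equal to N f_i x_i x_j; ``mutation[(i, j)]`` is the rate of one i
    individual turning into neighbor type j, equal to N λ x_i = λ c_i per
    incident edge.
    """

    reproduction: dict
    mutation: dict
    total: float


def total_rates(state, graph: TypeGraph, lam: float) -> RateTable:
    counts = state if isinstance(state, np.ndarray) else as_counts(
        graph, state, int(sum(state.values()))
    )
    N = int(counts.sum())
    rep: dict = {}
    mut: dict = {}
    for i, ti in enumerate(graph.type_ids):
        if counts[i] == 0:
            continue
        xi = counts[i] / N
        for j, tj in enumerate(graph.type_ids):
            if j != i and counts[j] > 0:
                rep[(ti, tj)] = N * graph.fitness[i] * xi * counts[j] / N
        if lam > 0:
            for tj in graph.neighbors(ti):
                mut[(ti, tj)] = N * lam * xi
    return RateTable(
        reproduction=rep,
        mutation=mut,
        total=float(sum(rep.values()) + sum(mut.values())),
    )


# ---------------------------------------------------------------------------
# fast kernel
# ---------------------------------------------------------------------------

@njit(cache=False)
def _gillespie_kernel(
    counts,
    fitness,
    indptr,
    indices,
    N,
    lam,
    t_max,
    seed,
    rec_mode,
    grid_dt,
    n_ticks,
    eps_count,
    stop_mode,
    stop_type,
    max_events,
    grid_out,
    rec_times,
    rec_dom,
    rec_domcount,
    sup_times,
    sup_out,
    gain_counts,
):
    np.random.seed(seed)
    K = counts.shape[0]
    active = np.empty(K, np.int64)
    pos = np.full(K, -1, np.int64)
    n_active = 0
    for i in range(K):
        if counts[i] > 0:
            active[n_active] = i
            pos[i] = n_active
            n_active += 1
    deg = np.empty(K, np.int64)
    for i in range(K):
        deg[i] = indptr[i + 1] - indptr[i]
    wrep = np.empty(K, np.float64)

    t = 0.0
    next_tick = 0
    n_events = 0
    n_rec = 0
    n_sup = 0
    reason = 0  # t_max

    dom = active[0]
    for a in range(1, n_active):
        if counts[active[a]] > counts[dom]:
            dom = active[a]
    dom_ok = counts[dom] >= eps_count
    if rec_mode == 2:  # dominance
        rec_times[0] = 0.0
        rec_dom[0] = dom
        rec_domcount[0] = counts[dom]
        n_rec = 1
    elif rec_mode == 3:  # support-changes
        sup_times[0] = 0.0
        sup_out[0, :] = counts
        n_sup = 1

    while True:
        R_rep = 0.0
        R_mut = 0.0
        for a in range(n_active):
            i = active[a]
            w = fitness[i] * counts[i] * (N - counts[i]) / N
            wrep[a] = w
            R_rep += w
            if lam > 0.0:
                R_mut += counts[i] * deg[i]
        R_mut *= lam
        R = R_rep + R_mut
        if R <= 0.0:
            if rec_mode == 1:
                while next_tick < n_ticks:
                    grid_out[next_tick, :] = counts
                    next_tick += 1
            reason = 1  # absorbed
            break

        t_new = t - math.log(1.0 - np.random.random()) / R
        if rec_mode == 1:
            while next_tick < n_ticks and next_tick * grid_dt < t_new:
                grid_out[next_tick, :] = counts
                next_tick += 1
        if t_new >= t_max:
            t = t_max
            reason = 0
            break
        t = t_new

        support_changed = False
        u = np.random.random() * R
        if u < R_rep:
            # reproduction: source i ~ wrep, displaced j != i ~ counts[j]
            acc = 0.0
            ai = n_active - 1
            for a in range(n_active):
                acc += wrep[a]
                if u < acc:
                    ai = a
                    break
            i = active[ai]
            v = np.random.random() * (N - counts[i])
            acc2 = 0.0
            j = -1
            for a in range(n_active):
                jj = active[a]
                if jj == i:
                    continue
                acc2 += counts[jj]
                if v < acc2:
                    j = jj
                    break
            if j == -1:
                for a in range(n_active - 1, -1, -1):
                    if active[a] != i:
                        j = active[a]
                        break
            counts[i] += 1
            counts[j] -= 1
            gain_counts[i] += 1
            if counts[j] == 0:
                pj = pos[j]
                last = active[n_active - 1]
                active[pj] = last
                pos[last] = pj
                pos[j] = -1
                n_active -= 1
                support_changed = True
        else:
            # mutation: source i ~ lam*counts[i]*deg[i], neighbor uniform
            u -= R_rep
            acc = 0.0
            i = -1
            for a in range(n_active):
                ii = active[a]
                acc += lam * counts[ii] * deg[ii]
                if u < acc:
                    i = ii
                    break
            if i == -1:
                for a in range(n_active - 1, -1, -1):
                    if deg[active[a]] > 0 and counts[active[a]] > 0:
                        i = active[a]
                        break
            e = int(np.random.random() * deg[i])
            if e >= deg[i]:
                e = deg[i] - 1
            j = indices[indptr[i] + e]
            counts[i] -= 1
            counts[j] += 1
            if counts[j] == 1:
                active[n_active] = j
                pos[j] = n_active
                n_active += 1
                support_changed = True
            if counts[i] == 0:
                pi = pos[i]
                last = active[n_active - 1]
                active[pi] = last
                pos[last] = pi
                pos[i] = -1
                n_active -= 1
                support_changed = True
        n_events += 1

        if rec_mode == 2:
            nd = active[0]
            for a in range(1, n_active):
                if counts[active[a]] > counts[nd]:
                    nd = active[a]
            nok = counts[nd] >= eps_count
            if nok != dom_ok or (nok and nd != dom):
                if n_rec >= rec_times.shape[0]:
                    reason = 5
                    break
                rec_times[n_rec] = t
                rec_dom[n_rec] = nd
                rec_domcount[n_rec] = counts[nd]
                n_rec += 1
            dom = nd
            dom_ok = nok
        elif rec_mode == 3 and support_changed:
            if n_sup >= sup_times.shape[0]:
                reason = 5
                break
            sup_times[n_sup] = t
            sup_out[n_sup, :] = counts
            n_sup += 1

        if stop_mode == 1 and n_active == 1:
            reason = 2
            break
        if stop_mode == 2:
            if counts[stop_type] == N:
                reason = 3
                break
            if counts[stop_type] == 0:
                reason = 4
                break
        if stop_mode == 3 and counts[stop_type] == N:
            reason = 3
            break
        if n_events >= max_events:
            reason = 5
            break

    return t, n_events, reason, next_tick, n_rec, n_sup


# ---------------------------------------------------------------------------
# trajectory containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JumpEvent:
    """One jump of the process.

    For ``kind="reproduction"``, ``source`` gains one individual and
    ``target`` loses one (the child displaces a member of ``target``).  For
    ``kind="mutation"``, one individual of ``source`` becomes ``target``.
    """

    time: float
    kind: str
    source: object
    target: object


@dataclass
class Trajectory:
    """Output of one stochastic run.

    Exactly one of the recording products is populated depending on the
    recording policy: ``events`` (reference engine), ``times``/``counts``
    snapshots (grid or support-changes), or the compact ``dominance`` log.
    """

    type_ids: tuple
    N: int
    lam: float
    initial_counts: np.ndarray
    final_counts: np.ndarray
    t_end: float
    stop_reason: str
    seed: int
    config: dict = field(default_factory=dict)
    times: np.ndarray | None = None
    counts: np.ndarray | None = None
    dominance: pd.DataFrame | None = None
    events: list | None = None
    n_events: int = 0
    gain_counts: np.ndarray | None = None

    def fractions(self) -> np.ndarray:
        if self.counts is None:
            raise ValueError("trajectory has no state snapshots")
        return self.counts / self.N

    def dominance_series(self) -> pd.DataFrame:
        """(time, dominant id, dominant count) rows, from whichever
        recording is present."""
        if self.dominance is not None:
            return self.dominance
        if self.counts is None:
            raise ValueError("trajectory has neither snapshots nor dominance log")
        idx = np.argmax(self.counts, axis=1)
        return pd.DataFrame(
            {
                "time": self.times,
                "dominant": [self.type_ids[i] for i in idx],
                "dominant_count": self.counts[np.arange(len(idx)), idx],
            }
        )


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _simulate_fast(
    graph,
    N,
    lam,
    counts0,
    t_max,
    seed,
    recording,
    grid_dt,
    epsilon,
    stop_mode,
    stop_index,
    max_events,
    record_cap,
):
    rec_mode = {
        "none": _REC_NONE,
        "grid": _REC_GRID,
        "dominance": _REC_DOM,
        "support-changes": _REC_SUPPORT,
    }[recording]
    K = graph.n_types
    indptr, indices = graph.neighbor_csr()

    if rec_mode == _REC_GRID:
        if not np.isfinite(t_max):
            raise ValueError("grid recording needs a finite t_max")
        n_ticks = int(np.floor(t_max / grid_dt)) + 1
        grid_out = np.zeros((n_ticks, K), dtype=np.int64)
    else:
        n_ticks, grid_out = 0, np.zeros((1, K), dtype=np.int64)
    if rec_mode == _REC_DOM:
        rec_times = np.zeros(record_cap)
        rec_dom = np.zeros(record_cap, dtype=np.int64)
        rec_domcount = np.zeros(record_cap, dtype=np.int64)
    else:
        rec_times = np.zeros(1)
        rec_dom = np.zeros(1, dtype=np.int64)
        rec_domcount = np.zeros(1, dtype=np.int64)
    if rec_mode == _REC_SUPPORT:
        sup_times = np.zeros(record_cap)
        sup_out = np.zeros((record_cap, K), dtype=np.int64)
    else:
        sup_times = np.zeros(1)
        sup_out = np.zeros((1, K), dtype=np.int64)

    counts = counts0.copy()
    gain_counts = np.zeros(K, dtype=np.int64)
    eps_count = int(math.ceil((1.0 - epsilon) * N))
    kseed = int(np.random.SeedSequence(seed).generate_state(1, np.uint32)[0]) & 0x7FFFFFFF

    t_end, n_events, reason, n_grid, n_rec, n_sup = _gillespie_kernel(
        counts,
        graph.fitness,
        indptr,
        indices,
        N,
        float(lam),
        float(t_max),
        kseed,
        rec_mode,
        float(grid_dt),
        n_ticks,
        eps_count,
        stop_mode,
        stop_index,
        max_events,
        grid_out,
        rec_times,
        rec_dom,
        rec_domcount,
        sup_times,
        sup_out,
        gain_counts,
    )
    if reason == 5:
        raise RuntimeError(
            "simulation overflow: event or record budget exceeded "
            f"(n_events={n_events}); raise max_events/record_cap or shorten t_max"
        )
    if reason == 1 and np.isfinite(t_max):
        # absorbing state reached: the trajectory is defined (and constant)
        # up to the full observation window
        t_end = t_max

    traj = Trajectory(
        type_ids=graph.type_ids,
        N=N,
        lam=lam,
        initial_counts=counts0,
        final_counts=counts,
        t_end=float(t_end),
        stop_reason=_REASONS[reason],
        seed=seed,
        n_events=int(n_events),
        gain_counts=gain_counts,
    )
    if rec_mode == _REC_GRID:
        traj.times = np.arange(n_grid) * grid_dt
        traj.counts = grid_out[:n_grid]
    elif rec_mode == _REC_DOM:
        traj.dominance = pd.DataFrame(
            {
                "time": rec_times[:n_rec],
                "dominant": [graph.type_ids[i] for i in rec_dom[:n_rec]],
                "dominant_count": rec_domcount[:n_rec],
            }
        )
    elif rec_mode == _REC_SUPPORT:
        traj.times = sup_times[:n_sup].copy()
        traj.counts = sup_out[:n_sup].copy()
    return traj


def _simulate_reference(
    graph,
    N,
    lam,
    counts0,
    t_max,
    seed,
    stop_mode,
    stop_index,
    max_events,
    include_self_replacement,
):
    """Full-recompute direct-method engine recording every jump event."""
    rng = np.random.default_rng(seed)
    K = graph.n_types
    fitness = graph.fitness
    indptr, indices = graph.neighbor_csr()
    deg = np.diff(indptr)
    counts = counts0.astype(np.int64).copy()
    events: list[JumpEvent] = []
    t = 0.0
    reason = "t_max"

    while True:
        x = counts / N
        # ordered-pair reproduction rates N f_i x_i x_j (optionally i = j)
        rep = N * np.outer(fitness * x, x)
        if not include_self_replacement:
            np.fill_diagonal(rep, 0.0)
        mut = lam * counts * deg  # per source type
        R = rep.sum() + mut.sum()
        if R <= 0:
            reason = "absorbed"
            break
        t_new = t + rng.exponential(1.0 / R)
        if t_new >= t_max:
            t = t_max
            break
        t = t_new
        u = rng.random() * R
        if u < rep.sum():
            flat = rep.ravel().cumsum()
            idx = int(np.searchsorted(flat, u, side="right"))
            i, j = divmod(idx, K)
            counts[i] += 1
            counts[j] -= 1
            if i != j:
                events.append(
                    JumpEvent(t, "reproduction", graph.type_ids[i], graph.type_ids[j])
                )
        else:
            u -= rep.sum()
            i = int(np.searchsorted(mut.cumsum(), u, side="right"))
            j = int(indices[indptr[i] + int(rng.random() * deg[i])])
            counts[i] -= 1
            counts[j] += 1
            events.append(
                JumpEvent(t, "mutation", graph.type_ids[i], graph.type_ids[j])
            )
        if stop_mode == _STOP_MONO and np.count_nonzero(counts) == 1:
            reason = "monomorphic"
            break
        if stop_mode == _STOP_TYPE_ABSORB:
            if counts[stop_index] == N:
                reason = "type_fixed"
                break
            if counts[stop_index] == 0:
                reason = "type_extinct"
                break
        if stop_mode == _STOP_TYPE_FIX and counts[stop_index] == N:
            reason = "type_fixed"
            break
        if len(events) >= max_events:
            raise RuntimeError("reference engine exceeded max_events")

    return Trajectory(
        type_ids=graph.type_ids,
        N=N,
        lam=lam,
        initial_counts=counts0,
        final_counts=counts,
        t_end=float(t),
        stop_reason=reason,
        seed=seed,
        events=events,
        n_events=len(events),
    )


def default_grid_dt(graph: TypeGraph, N: int) -> float:
    """Default snapshot spacing ln(N)/(10 s): ten samples per sweep."""
    try:
        s = selection_coefficient(graph)
    except ValueError:
        return 1.0
    return math.log(max(N, 2)) / (10.0 * s)


def simulate(
    graph: TypeGraph,
    N: int,
    lam: float,
    initial_state,
    t_max: float,
    seed: int,
    recording: str = "grid",
    *,
    grid_dt: float | None = None,
    engine: str = "fast",
    stop_when_monomorphic: bool = False,
    stop_on_type=None,
    stop_on_fixation_of=None,
    epsilon: float = 0.05,
    max_events: int = DEFAULT_MAX_EVENTS,
    record_cap: int = 4_000_000,
    include_self_replacement: bool = False,
) -> Trajectory:
    """Run one exact realization of the Moran jump process.

    Parameters
    ----------
    recording : {"grid", "events", "support-changes", "dominance", "none"}
        "events" forces the reference engine.
    stop_when_monomorphic : bool
        Stop at the first monomorphic state (fixation under λ = 0).
    stop_on_type : type id, optional
        Stop when this type fixes or goes extinct (mutant-fate runs).
    stop_on_fixation_of : type id, optional
        Stop only when this type fixes (e.g. arrival at a landscape peak).
    epsilon : float
        Dominance threshold 1-ε used by the "dominance" recording policy.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    counts0 = as_counts(graph, initial_state, N)
    if grid_dt is None:
        grid_dt = default_grid_dt(graph, N)

    stop_mode, stop_index = _STOP_NONE, 0
    if stop_when_monomorphic:
        stop_mode = _STOP_MONO
    if stop_on_type is not None:
        stop_mode, stop_index = _STOP_TYPE_ABSORB, graph.index(stop_on_type)
    if stop_on_fixation_of is not None:
        stop_mode, stop_index = _STOP_TYPE_FIX, graph.index(stop_on_fixation_of)

    if recording == "events" or engine == "reference":
        traj = _simulate_reference(
            graph,
            N,
            lam,
            counts0,
            t_max,
            seed,
            stop_mode,
            stop_index,
            max_events,
            include_self_replacement,
        )
    else:
        traj = _simulate_fast(
            graph,
            N,
            lam,
            counts0,
            t_max,
            seed,
            recording,
            grid_dt,
            epsilon,
            stop_mode,
            stop_index,
            max_events,
            record_cap,
        )
    traj.config = {
        "N": N,
        "lambda": lam,
        "t_max": t_max,
        "seed": seed,
        "recording": recording,
        "engine": "reference" if (recording == "events" or engine == "reference") else "fast",
        "epsilon": epsilon,
        "grid_dt": grid_dt,
    }
    return traj


def replay_events(
    graph: TypeGraph, initial_counts: np.ndarray, events: Sequence[JumpEvent]
) -> np.ndarray:
    """Re-apply an event log to an initial state, asserting population
    conservation at every step; returns the final count vector."""
    counts = np.asarray(initial_counts, dtype=np.int64).copy()
    N = int(counts.sum())
    last_t = -math.inf
    for ev in events:
        if ev.time <= last_t:
            raise ValueError("event times must be strictly increasing")
        last_t = ev.time
        i, j = graph.index(ev.source), graph.index(ev.target)
        if ev.kind == "reproduction":
            if i == j:
                raise ValueError("reproduction events must have source != target")
            counts[i] += 1
            counts[j] -= 1
        elif ev.kind == "mutation":
            if graph.type_ids[j] not in graph.neighbors(ev.source):
                raise ValueError(f"mutation along a non-edge: {ev.source}->{ev.target}")
            counts[i] -= 1
            counts[j] += 1
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
        if counts.min() < 0 or counts.sum() != N:
            raise ValueError("replay violated population conservation")
    return counts


def run_to_fixation(
    graph: TypeGraph, N: int, initial_state, seed: int, *, max_events=DEFAULT_MAX_EVENTS
):
    """Run the mutation-free process until monomorphic; returns
    ``(fixed_type_id, fixation_time)``."""
    counts0 = as_counts(graph, initial_state, N)
    if np.count_nonzero(counts0) < 2:
        return graph.type_ids[int(np.argmax(counts0))], 0.0
    traj = simulate(
        graph,
        N,
        0.0,
        counts0,
        math.inf,
        seed,
        recording="none",
        stop_when_monomorphic=True,
        max_events=max_events,
    )
    winner = graph.type_ids[int(np.argmax(traj.final_counts))]
    return winner, traj.t_end


def estimate_fixation_probability(
    graph: TypeGraph,
    N: int,
    mutant_type,
    initial_copies: int,
    replicates: int,
    seed: int,
    *,
    resident_type=None,
) -> tuple[float, float]:
    """Monte-Carlo fixation frequency of ``mutant_type`` started at
    ``initial_copies`` copies against a monomorphic resident background,
    with a binomial standard error.  Replicates use independent child
    streams derived from ``seed``."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if resident_type is None:
        others = [t for t in graph.type_ids if t != mutant_type]
        if len(others) != 1:
            raise ValueError("resident_type is required for >2-type landscapes")
        resident_type = others[0]
    counts0 = np.zeros(graph.n_types, dtype=np.int64)
    counts0[graph.index(mutant_type)] = initial_copies
    counts0[graph.index(resident_type)] = N - initial_copies

    if initial_copies == N:
        return 1.0, 0.0
    if initial_copies == 0:
        return 0.0, 0.0

    seeds = child_seeds(seed, replicates)
    fixed = 0
    for r in range(replicates):
        traj = simulate(
            graph,
            N,
            0.0,
            counts0,
            math.inf,
            int(seeds[r]),
            recording="none",
            stop_on_type=mutant_type,
        )
        fixed += traj.stop_reason == "type_fixed"
    p = fixed / replicates
    return p, math.sqrt(max(p * (1 - p), 1.0 / replicates) / replicates)
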