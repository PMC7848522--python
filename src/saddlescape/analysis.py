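"""Trajectory phenomenology: discrepancy from the ODE flow, stasis/sweep
segmentation, dwell statistics, clonal interference, and N-scaling
experiments.

This module turns raw stochastic trajectories into the quantities that
exhibit punctuated-equilibrium behavior: the running L1 discrepancy D*(t)
between the finite-N process and its deterministic replicator limit, the
tiling of a run into stasis epochs (one type holding fraction >= 1-ε) and
fast transitions, the dwell/sweep duration statistics those epochs imply,
and counts of clonal-interference events where a second beneficial mutant
establishes before the current sweep completes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import closed_form_solution, selection_coefficient
from .landscape import TypeGraph
from .moran import Trajectory, as_counts, child_seeds, simulate

__all__ = [
    "DiscrepancySeries",
    "discrepancy_series",
    "Segment",
    "SegmentationResult",
    "segment_trajectory",
    "dwell_statistics",
    "detect_clonal_interference",
    "interference_experiment",
    "scaling_experiment",
]


# ---------------------------------------------------------------------------
# discrepancy from the deterministic flow
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscrepancySeries:
    """L1 distance between the stochastic state and the replicator flow
    started from the same initial condition, sampled at snapshot times;
    ``max_values`` is the running supremum D*(t)."""

    times: np.ndarray
    values: np.ndarray
    max_values: np.ndarray
    mode: str
    lam_nonzero: bool

    @property
    def d_star(self) -> float:
        return float(self.max_values[-1]) if len(self.max_values) else 0.0


def discrepancy_series(
    trajectory: Trajectory, graph: TypeGraph, mode: str = "anchored"
) -> DiscrepancySeries:
    """Compute D(t) = ||x(t) - Φ_t x(0)||_1 along a trajectory.

    ``mode="anchored"`` compares against the flow from the trajectory's own
    initial state for all times (the definition used by the mutation-free
    approximation theory).  ``mode="patched"`` re-anchors the flow whenever
    the support of the sampled state changes, mirroring the restart argument
    that patches ODE trajectories together; use it for runs with mutations,
    where new types enter the support.
    """
    if tuple(trajectory.type_ids) != tuple(graph.type_ids):
        raise ValueError("trajectory and landscape have different type sets")
    if trajectory.counts is None:
        raise ValueError("discrepancy needs state snapshots (grid recording)")
    times = np.asarray(trajectory.times, dtype=float)
    fracs = trajectory.fractions()

    if mode == "anchored":
        x0 = trajectory.initial_counts / trajectory.N
        ode = closed_form_solution(x0, graph, times)
        values = np.abs(fracs - ode).sum(axis=1)
    elif mode == "patched":
        values = np.empty(len(times))
        anchor = trajectory.initial_counts / trajectory.N
        t_anchor = 0.0
        support = anchor > 0
        for k in range(len(times)):
            cur_support = fracs[k] > 0
            if not np.array_equal(cur_support, support):
                anchor = fracs[k]
                t_anchor = times[k]
                support = cur_support
            ode = closed_form_solution(anchor, graph, times[k] - t_anchor)
            values[k] = np.abs(fracs[k] - ode).sum()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return DiscrepancySeries(
        times=times,
        values=values,
        max_values=np.maximum.accumulate(values),
        mode=mode,
        lam_nonzero=trajectory.lam > 0,
    )


# ---------------------------------------------------------------------------
# stasis / transition segmentation
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    kind: str  # "stasis" | "transition"
    start: float
    end: float
    dominant: object = None  # stasis only

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class Reign:
    """Maximal run of stasis epochs sharing one dominant type.  A reign may
    be interrupted by failed sweep attempts (a challenger crosses ε and dies
    back); ``stasis_time`` sums only the stasis pieces, ``n_pieces`` counts
    them."""

    dominant: object
    start: float
    end: float
    stasis_time: float
    n_pieces: int


@dataclass
class SegmentationResult:
    """Tiling of [0, T] into stasis and transition epochs.

    ``dwell_times`` are total stasis durations of *completed* reigns (the
    final, censored reign is excluded) — the empirical counterpart of the
    origin–fixation waiting time, which includes failed sweep attempts;
    ``sweep_durations`` are the transition epochs whose flanking stasis
    epochs have *different* dominants (actual sweeps, not failed attempts);
    ``n_transitions`` counts dominant-type changes between consecutive
    reigns.
    """

    segments: list
    epsilon: float
    t_end: float
    reigns: list = field(default_factory=list)
    dwell_times: np.ndarray = field(default=None)
    sweep_durations: np.ndarray = field(default=None)
    n_transitions: int = 0
    interference_events: list | None = None

    @property
    def stasis_fraction(self) -> float:
        stasis = sum(s.duration for s in self.segments if s.kind == "stasis")
        return stasis / self.t_end if self.t_end > 0 else math.nan


def _dominance_rows(trajectory: Trajectory) -> tuple[np.ndarray, list, np.ndarray]:
    df = trajectory.dominance_series()
    return (
        df["time"].to_numpy(dtype=float),
        list(df["dominant"]),
        df["dominant_count"].to_numpy(),
    )


def segment_trajectory(
    trajectory: Trajectory, epsilon: float = 0.05, min_duration: float = 0.0
) -> SegmentationResult:
    """Label maximal epochs with max-type fraction >= 1-ε as stasis (with
    their dominant type) and the complement as transitions.

    The sampled classification is held piecewise-constant from the left
    between records; with the "dominance" recording policy records sit
    exactly at classification changes (for the recording ε), so the tiling
    is exact.  Segments shorter than ``min_duration`` are merged into their
    preceding neighbor (default 0: no merging).
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    times, dominants, dom_counts = _dominance_rows(trajectory)
    if len(times) == 0:
        raise ValueError("empty trajectory")
    t_end = trajectory.t_end
    thresh = math.ceil((1.0 - epsilon) * trajectory.N)

    segments: list[Segment] = []
    for k in range(len(times)):
        is_stasis = dom_counts[k] >= thresh
        kind = "stasis" if is_stasis else "transition"
        dom = dominants[k] if is_stasis else None
        start = times[k]
        end = times[k + 1] if k + 1 < len(times) else t_end
        if end <= start:
            continue
        if segments and segments[-1].kind == kind and segments[-1].dominant == dom:
            segments[-1].end = end
        else:
            segments.append(Segment(kind=kind, start=start, end=end, dominant=dom))

    if min_duration > 0 and len(segments) > 1:
        merged: list[Segment] = []
        for seg in segments:
            if merged and seg.duration < min_duration:
                merged[-1].end = seg.end
            elif (
                merged
                and merged[-1].kind == seg.kind
                and merged[-1].dominant == seg.dominant
            ):
                merged[-1].end = seg.end
            else:
                merged.append(seg)
        segments = merged

    # group stasis epochs into reigns of one dominant type
    reigns: list[Reign] = []
    for s in segments:
        if s.kind != "stasis":
            continue
        if reigns and reigns[-1].dominant == s.dominant:
            reigns[-1].end = s.end
            reigns[-1].stasis_time += s.duration
            reigns[-1].n_pieces += 1
        else:
            reigns.append(
                Reign(
                    dominant=s.dominant,
                    start=s.start,
                    end=s.end,
                    stasis_time=s.duration,
                    n_pieces=1,
                )
            )
    dwell = [r.stasis_time for r in reigns[:-1]]  # final reign is censored

    # sweeps: transitions whose flanking stasis epochs differ in dominant
    sweeps = []
    for k, s in enumerate(segments):
        if s.kind != "transition" or k == 0 or k == len(segments) - 1:
            continue
        prev_dom = segments[k - 1].dominant
        next_dom = segments[k + 1].dominant
        if (
            segments[k - 1].kind == "stasis"
            and segments[k + 1].kind == "stasis"
            and prev_dom != next_dom
        ):
            sweeps.append(s.duration)

    n_transitions = max(len(reigns) - 1, 0)
    return SegmentationResult(
        segments=segments,
        epsilon=epsilon,
        t_end=t_end,
        reigns=reigns,
        dwell_times=np.asarray(dwell),
        sweep_durations=np.asarray(sweeps),
        n_transitions=n_transitions,
    )


def dwell_statistics(segmentation: SegmentationResult) -> dict:
    """Summary table of the punctuated-equilibrium statistics.

    Returns a dict with overall means/medians plus a per-dominant-type
    DataFrame of completed dwell times.
    """
    seg = segmentation
    if not any(s.kind == "stasis" for s in seg.segments):
        raise ValueError("no stasis segment in the segmentation")
    rows = [
        {"dominant": r.dominant, "dwell": r.stasis_time} for r in seg.reigns[:-1]
    ]
    dwell = seg.dwell_times
    if not rows:  # only the (censored) final reign exists: report it as-is
        rows = [{"dominant": r.dominant, "dwell": r.stasis_time} for r in seg.reigns]
        dwell = np.asarray([r.stasis_time for r in seg.reigns])
    per_type = (
        pd.DataFrame(rows).groupby("dominant")["dwell"].agg(["mean", "median", "count"])
        if rows
        else pd.DataFrame(columns=["mean", "median", "count"])
    )
    sweeps = seg.sweep_durations
    return {
        "mean_dwell": float(np.mean(dwell)) if len(dwell) else math.nan,
        "median_dwell": float(np.median(dwell)) if len(dwell) else math.nan,
        "mean_sweep": float(np.mean(sweeps)) if len(sweeps) else math.nan,
        "median_sweep": float(np.median(sweeps)) if len(sweeps) else math.nan,
        "stasis_fraction": seg.stasis_fraction,
        "n_transitions": seg.n_transitions,
        "n_dwells": int(len(dwell)),
        "per_type": per_type,
    }


# ---------------------------------------------------------------------------
# clonal interference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterferenceEvent:
    time: float
    sweeping_type: object
    challenger_type: object


def detect_clonal_interference(
    trajectory: Trajectory,
    graph: TypeGraph,
    epsilon: float = 0.05,
    establish_copies: int | None = None,
) -> list[InterferenceEvent]:
    """Find events where a strictly fitter type establishes while a sweep is
    still in progress.

    At each snapshot the "sweeping type" is the fittest type with fraction
    in [ε, 1-ε).  An interference event is recorded the first time a
    strictly fitter challenger holds at least ``establish_copies`` (default
    ceil(sqrt(N)): copy counts, not fractions, because the vulnerable phase
    is the challenger's establishment) while still below the ε window —
    i.e. an established-but-minor lineage — while such a sweep is underway.
    One event per (sweeper, challenger) pair.

    Interference requires mutational input: a λ = 0 run merely sorts its
    standing variation and reports no events.  The establishment threshold
    must sit below the ε window (sqrt(N) < ε N), else sweeper and challenger
    are indistinguishable at this resolution.
    """
    if trajectory.counts is None:
        raise ValueError("interference detection needs state snapshots")
    if tuple(trajectory.type_ids) != tuple(graph.type_ids):
        raise ValueError("trajectory and landscape have different type sets")
    if trajectory.lam == 0:
        return []
    N = trajectory.N
    thr = establish_copies if establish_copies is not None else math.ceil(math.sqrt(N))
    if thr >= epsilon * N:
        raise ValueError(
            "establishment threshold >= epsilon*N: increase N, epsilon, or "
            "pass a smaller establish_copies"
        )
    lo, hi = epsilon * N, (1.0 - epsilon) * N
    fitness = graph.fitness
    events: list[InterferenceEvent] = []
    seen: set = set()
    counts = trajectory.counts
    times = trajectory.times
    for k in range(len(times)):
        row = counts[k]
        window = np.flatnonzero((row >= lo) & (row < hi))
        if window.size == 0:
            continue
        sweeper = window[np.argmax(fitness[window])]
        challengers = np.flatnonzero(
            (fitness > fitness[sweeper]) & (row >= thr) & (row < lo)
        )
        for ch in challengers:
            key = (int(sweeper), int(ch))
            if key not in seen:
                seen.add(key)
                events.append(
                    InterferenceEvent(
                        time=float(times[k]),
                        sweeping_type=trajectory.type_ids[sweeper],
                        challenger_type=trajectory.type_ids[ch],
                    )
                )
    return events


def interference_experiment(
    graph: TypeGraph,
    N: int,
    lam: float,
    resident,
    sweeper,
    n_sweeps: int,
    seed: int,
    *,
    epsilon: float = 0.05,
    t_max: float | None = None,
    grid_dt: float | None = None,
    max_episodes: int = 100_000,
) -> dict:
    """Per-sweep clonal-interference frequency from repeated sweep episodes.

    Each episode starts with one ``sweeper`` mutant in a monomorphic
    ``resident`` background and runs until the sweeper fixes or dies out
    (mutations on).  Episodes where the sweeper establishes (reaches ε N or
    fixes) count as sweeps; among those, the fraction with at least one
    interference event (a strictly fitter challenger establishing mid-sweep,
    per :func:`detect_clonal_interference`) is returned with its binomial
    standard error.
    """
    s = graph.fitness_of(sweeper) - graph.fitness_of(resident)
    if s <= 0:
        raise ValueError("sweeper must be fitter than resident")
    if t_max is None:
        t_max = 20.0 * math.log(N) / s
    if grid_dt is None:
        grid_dt = math.log(N) / (30.0 * s)
    seeds = child_seeds(seed, max_episodes)
    sweeper_col = graph.index(sweeper)
    establish = epsilon * N
    sweeps = interfered = episodes = 0
    while sweeps < n_sweeps and episodes < max_episodes:
        traj = simulate(
            graph,
            N,
            lam,
            {resident: N - 1, sweeper: 1},
            t_max,
            int(seeds[episodes]),
            recording="grid",
            grid_dt=grid_dt,
            stop_on_type=sweeper,
        )
        episodes += 1
        started = (
            traj.counts[:, sweeper_col].max() >= establish
            or traj.stop_reason == "type_fixed"
        )
        if not started:
            continue
        sweeps += 1
        if detect_clonal_interference(traj, graph, epsilon):
            interfered += 1
    if sweeps == 0:
        raise RuntimeError("no sweep established within the episode budget")
    freq = interfered / sweeps
    se = math.sqrt(max(freq * (1 - freq), 1.0 / sweeps) / sweeps)
    return {
        "frequency_per_sweep": freq,
        "se": se,
        "n_sweeps": sweeps,
        "n_interfered": interfered,
        "n_episodes": episodes,
    }


# ---------------------------------------------------------------------------
# N-scaling of the discrepancy
# ---------------------------------------------------------------------------

def scaling_experiment(
    graph: TypeGraph,
    N_list: list[int],
    replicates: int,
    seed: int,
    *,
    initial_state="uniform",
    n_grid: int = 200,
    s: float | None = None,
) -> pd.DataFrame:
    """Median and 90th percentile of D*(T_N), T_N = ln(N)/s, per population
    size, from mutation-free runs off a shared initial condition.

    The deterministic limit predicts D* -> 0 as N grows; the returned frame
    carries a ``monotone_decreasing`` attribute for the median column and a
    log-log regression slope in ``loglog_slope``.
    """
    if sorted(N_list) != list(N_list):
        raise ValueError("N_list must be increasing")
    if s is None:
        s = selection_coefficient(graph)
    all_seeds = child_seeds(seed, len(N_list) * replicates)
    rows = []
    for which_N, N in enumerate(N_list):
        T = math.log(N) / s
        dt = T / (n_grid - 1)
        counts0 = as_counts(graph, initial_state, N)
        x0 = counts0 / N
        tick_times = np.arange(n_grid) * dt
        ode = closed_form_solution(x0, graph, tick_times)
        seeds = all_seeds[which_N * replicates : (which_N + 1) * replicates]
        dstars = np.empty(replicates)
        for r in range(replicates):
            traj = simulate(
                graph,
                N,
                0.0,
                counts0,
                T + dt / 2,
                int(seeds[r]),
                recording="grid",
                grid_dt=dt,
            )
            m = min(len(traj.times), n_grid)
            dstars[r] = np.abs(traj.fractions()[:m] - ode[:m]).sum(axis=1).max()
        rows.append(
            {
                "N": N,
                "T": T,
                "median_dstar": float(np.median(dstars)),
                "q90_dstar": float(np.quantile(dstars, 0.9)),
                "replicates": replicates,
            }
        )
    table = pd.DataFrame(rows)
    med = table["median_dstar"].to_numpy()
    if len(N_list) > 1:
        table.attrs["monotone_decreasing"] = bool(np.all(np.diff(med) < 0))
        slope = np.polyfit(np.log(table["N"]), np.log(med), 1)[0]
        table.attrs["loglog_slope"] = float(slope)
    return table
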