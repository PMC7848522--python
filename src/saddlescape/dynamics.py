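"""Replicator dynamics on the simplex and its heteroclinic skeleton.

The infinite-population, mutation-free limit of the Moran process is the
competitive-exclusion (replicator) ODE

    dx_i/dt = x_i (f_i - fbar(x)),      fbar(x) = sum_j f_j x_j,

whose solution has the closed form x_i(t) = x_i(0) e^{f_i t} / Z(t).  The
simplex vertices e(k) are hyperbolic critical points; within the face
spanned by the currently present types the linearization at e(k) has
eigenvalues f_i - f_k along the edge directions e(i) - e(k), so every vertex
except the fittest one is a saddle and selective sweeps run along the
heteroclinic edges, where the dynamics reduces to a logistic equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .landscape import TypeGraph

__all__ = [
    "as_fractions",
    "mean_fitness",
    "replicator_rhs",
    "closed_form_solution",
    "integrate_replicator",
    "selection_coefficient",
    "VertexAnalysis",
    "vertex_analysis",
    "logistic_edge_solution",
    "sweep_time",
]

SIMPLEX_ATOL = 1e-9


def as_fractions(graph: TypeGraph, x) -> np.ndarray:
    """Coerce a mapping or array of type fractions to a validated ndarray
    aligned with ``graph.type_ids``."""
    if isinstance(x, dict):
        vec = np.zeros(graph.n_types)
        for tid, v in x.items():
            vec[graph.index(tid)] = v
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != (graph.n_types,):
            raise ValueError(
                f"expected {graph.n_types} fractions, got shape {vec.shape}"
            )
    if np.any(vec < -SIMPLEX_ATOL) or abs(vec.sum() - 1.0) > 1e-6:
        raise ValueError("fractions must be nonnegative and sum to 1")
    return np.clip(vec, 0.0, None)


def mean_fitness(x, graph: TypeGraph) -> float:
    """Population mean fitness fbar(x) = sum_j f_j x_j."""
    return float(np.dot(as_fractions(graph, x), graph.fitness))


def replicator_rhs(x, graph: TypeGraph) -> np.ndarray:
    """Right-hand side b_i(x) = x_i (f_i - fbar(x)); components sum to 0."""
    x = as_fractions(graph, x)
    return x * (graph.fitness - np.dot(graph.fitness, x))


def closed_form_solution(x0, graph: TypeGraph, t) -> np.ndarray:
    """Exact replicator flow x_i(t) = x_i(0) e^{f_i t} / Z(t).

    ``t`` may be a scalar (returns one simplex point) or an array (returns a
    ``(len(t), n_types)`` array).  Evaluated in the log domain — the maximum
    of f_i t over present types is subtracted before exponentiation — so the
    result is overflow-safe and invariant to adding a constant to all
    fitness values.  Types absent from ``x0`` stay identically zero; the
    flow is defined on the face spanned by the initial support.
    """
    x0 = as_fractions(graph, x0)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    active = x0 > 0
    logw0 = np.log(x0[active])
    f_act = graph.fitness[active]

    out = np.zeros((t_arr.size, graph.n_types))
    logw = logw0[None, :] + np.outer(t_arr, f_act)
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    out[:, active] = w / w.sum(axis=1, keepdims=True)
    return out[0] if np.isscalar(t) or np.ndim(t) == 0 else out


def integrate_replicator(
    x0, graph: TypeGraph, t_grid, tolerance: float = 1e-10
) -> np.ndarray:
    """Numerical solution of the replicator ODE on ``t_grid``.

    A cross-check of the closed form, not the primary path.  Uses a
    high-order explicit solver at the requested tolerance and renormalizes
    each output point onto the simplex.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    x0 = as_fractions(graph, x0)
    t_grid = np.asarray(t_grid, dtype=float)
    f = graph.fitness

    def rhs(_t, y):
        return y * (f - np.dot(f, y))

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method="DOP853",
        rtol=tolerance,
        atol=tolerance * 1e-2,
    )
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)
    return y / y.sum(axis=1, keepdims=True)


def selection_coefficient(graph: TypeGraph, active_set=None) -> float:
    """s = f* - f**: gap between the largest and second-largest fitness in
    the active set.  Sets the exponential rate of the sweep toward e(i*)."""
    ids = graph.type_ids if active_set is None else tuple(active_set)
    if len(ids) < 2:
        raise ValueError("selection coefficient needs at least two active types")
    f = np.sort([graph.fitness_of(t) for t in ids])
    return float(f[-1] - f[-2])


@dataclass(frozen=True)
class VertexAnalysis:
    """Within-face linearization of the replicator field at a vertex e(k).

    ``eigenvalues[i] = f_i - f_k`` for each other active type i, along the
    edge direction e(i) - e(k).  The transversal eigenvalue -f_k (direction
    off the simplex) is excluded.  ``saddle_index`` counts the negative
    (stable) directions; the fittest active type is the unique sink of the
    face it spans.
    """

    vertex_type: object
    eigenvalues: dict
    saddle_index: int
    is_sink_in_I: bool


def vertex_analysis(graph: TypeGraph, k, active_set=None) -> VertexAnalysis:
    ids = graph.type_ids if active_set is None else tuple(active_set)
    if k not in ids:
        raise ValueError(f"vertex {k!r} not in the active set")
    fk = graph.fitness_of(k)
    eig = {i: graph.fitness_of(i) - fk for i in ids if i != k}
    saddle_index = sum(1 for v in eig.values() if v < 0)
    return VertexAnalysis(
        vertex_type=k,
        eigenvalues=eig,
        saddle_index=saddle_index,
        is_sink_in_I=all(v < 0 for v in eig.values()),
    )


def logistic_edge_solution(xi0: float, f_i: float, f_k: float, t) -> np.ndarray | float:
    """Logistic orbit along the heteroclinic edge between e(k) and e(i):
    dx/dt = (f_i - f_k) x (1 - x), the closed-form flow restricted to the
    two-type sub-simplex.  Endpoints 0 and 1 are absorbing."""
    if not 0.0 <= xi0 <= 1.0:
        raise ValueError("xi0 must lie in [0, 1]")
    t_arr = np.asarray(t, dtype=float)
    if xi0 in (0.0, 1.0):
        out = np.full_like(t_arr, xi0, dtype=float)
        return float(out) if t_arr.ndim == 0 else out
    # x(t) = 1 / (1 + exp(-(s t + logit(xi0))))
    z = (f_i - f_k) * t_arr + np.log(xi0 / (1 - xi0))
    out = 0.5 * (1.0 + np.tanh(z / 2.0))
    return float(out) if t_arr.ndim == 0 else out


def sweep_time(N: float, s: float) -> float:
    """Deterministic selective-sweep timescale ln(N)/s: the time for the
    fittest type to go from one copy's fraction to dominance."""
    if N < 2:
        raise ValueError("N must be >= 2")
    if s <= 0:
        raise ValueError("s must be > 0")
    return float(np.log(N) / s)
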