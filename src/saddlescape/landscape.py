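"""Fitness landscapes as type graphs.

A landscape is a finite undirected graph whose vertices are coarse-grained
"types" (clusters of genotypes treated as a single state), each carrying a
strictly positive fitness value, with an edge between two types whenever a
single mutational transition connects them.  All downstream machinery — the
replicator ODE, the Moran jump process, the origin–fixation theory — is
parameterised by such a graph.

Fitness values are required to be pairwise distinct: ties would make the
selection coefficient between the tied pair zero and every sweep-timescale
quantity (ln N / s) undefined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TypeGraph",
    "NeighborhoodSummary",
    "build_landscape",
    "staircase_landscape",
    "hypercube_landscape",
    "random_landscape",
    "neighborhood_summary",
    "mutational_neighborhood_size",
    "expected_beneficial_count",
]

#: warn (not reject) when the smallest fitness gap falls below this value;
#: near-ties make s ~ 0 and blow up every ln(N)/s timescale.
DEFAULT_MIN_GAP_WARN = 1e-9


class LandscapeError(ValueError):
    """Raised when a landscape violates its structural invariants."""


@dataclass(frozen=True)
class TypeGraph:
    """Validated fitness landscape.

    Attributes
    ----------
    type_ids : tuple of str
        Opaque labels, in a fixed order that defines the integer indexing
        used by the simulation kernels.
    fitness : ndarray of float
        Strictly positive, pairwise distinct reproduction rates, aligned
        with ``type_ids``.
    graph : networkx.Graph
        Undirected mutation network on ``type_ids`` (no self loops).
    """

    type_ids: tuple
    fitness: np.ndarray
    graph: nx.Graph
    _index: dict = field(repr=False, hash=False, compare=False, default=None)

    # -- basic queries -----------------------------------------------------
    @property
    def n_types(self) -> int:
        return len(self.type_ids)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def max_fitness(self) -> float:
        """F = max_i f_i, the global fitness bound."""
        return float(self.fitness.max())

    def index(self, type_id) -> int:
        try:
            return self._index[type_id]
        except KeyError:
            raise LandscapeError(f"unknown type id: {type_id!r}") from None

    def fitness_of(self, type_id) -> float:
        return float(self.fitness[self.index(type_id)])

    def neighbors(self, type_id) -> list:
        self.index(type_id)
        return list(self.graph.neighbors(type_id))

    def degree(self, type_id) -> int:
        self.index(type_id)
        return self.graph.degree(type_id)

    def fitter_neighbors(self, type_id) -> list:
        f0 = self.fitness_of(type_id)
        return [j for j in self.neighbors(type_id) if self.fitness_of(j) > f0]

    def less_fit_neighbors(self, type_id) -> list:
        f0 = self.fitness_of(type_id)
        return [j for j in self.neighbors(type_id) if self.fitness_of(j) < f0]

    def fittest_type(self):
        """i*, the type of maximal fitness."""
        return self.type_ids[int(np.argmax(self.fitness))]

    def adjacency_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix E_ij in ``type_ids`` order."""
        return nx.to_numpy_array(self.graph, nodelist=self.type_ids, dtype=np.int8)

    def neighbor_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """(indptr, indices) adjacency in integer indexing, for the kernels."""
        indptr = np.zeros(self.n_types + 1, dtype=np.int64)
        blocks = []
        for pos, tid in enumerate(self.type_ids):
            nbrs = sorted(self._index[j] for j in self.graph.neighbors(tid))
            blocks.append(np.asarray(nbrs, dtype=np.int64))
            indptr[pos + 1] = indptr[pos] + len(nbrs)
        indices = (
            np.concatenate(blocks) if blocks and indptr[-1] else np.zeros(0, np.int64)
        )
        return indptr, indices


@dataclass(frozen=True)
class NeighborhoodSummary:
    """Beneficial/deleterious split of one type's mutational neighborhood.

    ``k_beneficial`` counts adjacent types with strictly higher fitness
    (available beneficial mutations), ``L_deleterious`` those with strictly
    lower fitness; distinct fitness values make the split a partition of the
    neighbors.  ``M_bound`` is the maximum ``k`` over a stated reference set
    of types, the uniform bound entering the beneficial-mutation probability
    bound.
    """

    type_id: object
    k_beneficial: int
    L_deleterious: int
    M_bound: int


# ---------------------------------------------------------------------------
# construction & validation
# ---------------------------------------------------------------------------

def build_landscape(
    type_ids: Sequence,
    fitness_map: Mapping,
    edge_list: Iterable = (),
    *,
    min_gap_warn: float = DEFAULT_MIN_GAP_WARN,
) -> TypeGraph:
    """Construct and validate a :class:`TypeGraph`.

    Parameters
    ----------
    type_ids : sequence
        Declared type labels (order fixes integer indexing).
    fitness_map : mapping
        label -> strictly positive fitness; values must be pairwise
        distinct.
    edge_list : iterable of pairs
        Undirected edges between declared labels; duplicates collapse,
        orientation is ignored (the adjacency is symmetrized).

    Raises
    ------
    LandscapeError
        On empty type set, unknown labels, self-edges, non-positive or tied
        fitness values.
    """
    type_ids = tuple(type_ids)
    if not type_ids:
        raise LandscapeError("a landscape needs at least one type")
    if len(set(type_ids)) != len(type_ids):
        raise LandscapeError("duplicate type ids")

    try:
        fitness = np.asarray([float(fitness_map[t]) for t in type_ids])
    except KeyError as exc:
        raise LandscapeError(f"missing fitness for type {exc.args[0]!r}") from None
    if not np.all(np.isfinite(fitness)):
        raise LandscapeError("fitness values must be finite")
    if np.any(fitness <= 0):
        raise LandscapeError("fitness values must be strictly positive")
    if len(np.unique(fitness)) != len(fitness):
        raise LandscapeError("fitness values must be pairwise distinct")
    if len(fitness) > 1:
        gap = float(np.min(np.diff(np.sort(fitness))))
        if gap < min_gap_warn:
            warnings.warn(
                f"minimum fitness gap {gap:.3g} is below {min_gap_warn:.3g}; "
                "selection coefficients this small make ln(N)/s timescales "
                "effectively unresolvable",
                stacklevel=2,
            )

    g = nx.Graph()
    g.add_nodes_from(type_ids)
    declared = set(type_ids)
    for edge in edge_list:
        a, b = edge
        if a not in declared or b not in declared:
            raise LandscapeError(f"edge {edge!r} references an undeclared type")
        if a == b:
            raise LandscapeError(f"self-edge on type {a!r}")
        g.add_edge(a, b)

    index = {t: i for i, t in enumerate(type_ids)}
    return TypeGraph(type_ids=type_ids, fitness=fitness, graph=g, _index=index)


def staircase_landscape(
    n_types: int, base_fitness: float = 1.0, step: float = 0.1
) -> TypeGraph:
    """Path graph 0–1–…–(n−1) with fitness ``base + i*step``.

    The canonical saddle-to-saddle fixture: every interior type has exactly
    one beneficial and one deleterious neighbor, so each stasis epoch has
    k = 1 and L = 1 and the walk to the top is a strict fitness staircase.
    """
    if n_types < 1:
        raise LandscapeError("n_types must be >= 1")
    if step <= 0:
        raise LandscapeError("step must be > 0")
    ids = [str(i) for i in range(n_types)]
    fit = {str(i): base_fitness + i * step for i in range(n_types)}
    edges = [(str(i), str(i + 1)) for i in range(n_types - 1)]
    return build_landscape(ids, fit, edges)


def _default_hypercube_fitness(k0, gain, jitter, seed):
    """Level-multiplicative assignment with a seeded multiplicative jitter.

    f(S) = gain^|S| * (1 + jitter*u_S),  u_S ~ U(-1, 1) i.i.d. per subset.
    Monotone along lattice covers as long as gain*(1-jitter) > 1+jitter, and
    almost surely pairwise distinct.
    """
    if gain * (1 - jitter) <= 1 + jitter:
        raise LandscapeError("gain too small for the requested jitter")
    rng = np.random.default_rng(seed)

    def assign(sites: frozenset) -> float:
        return gain ** len(sites) * (1 + jitter * rng.uniform(-1, 1))

    return assign


def hypercube_landscape(
    k0: int,
    fitness_assignment: Callable[[frozenset], float] | Mapping | None = None,
    seed: int | None = None,
    *,
    gain: float = 1.25,
    jitter: float = 1e-3,
) -> TypeGraph:
    """Boolean-lattice landscape on the 2^k0 subsets of {0..k0-1}.

    Types are bitstring labels over the ``k0`` sites still separating the
    population from the local optimum; flipping a site on moves one level up
    the lattice.  The fitness assignment must be strictly increasing along
    subset inclusion, so the full set is the unique local (and global) peak
    and a type at level m has exactly ``k0 - m`` beneficial neighbors.

    ``fitness_assignment`` maps each ``frozenset`` of switched-on sites to a
    fitness (a mapping keyed by frozensets also works).  The default is
    multiplicative in the level, ``gain**|S|``, with a small seeded jitter
    making values distinct; then the fitness ratio across every beneficial
    edge is ~1/gain, uniform over the lattice.
    """
    if k0 < 1:
        raise LandscapeError("k0 must be >= 1")
    if fitness_assignment is None:
        fitness_assignment = _default_hypercube_fitness(k0, gain, jitter, seed)
    assign = (
        fitness_assignment.__getitem__
        if isinstance(fitness_assignment, Mapping)
        else fitness_assignment
    )

    def label(mask: int) -> str:
        return format(mask, f"0{k0}b")

    def sites(mask: int) -> frozenset:
        return frozenset(b for b in range(k0) if mask >> b & 1)

    masks = range(1 << k0)
    fit = {label(m): float(assign(sites(m))) for m in masks}
    edges = []
    for m in masks:
        for b in range(k0):
            if not m >> b & 1:
                edges.append((label(m), label(m | 1 << b)))

    for a, b in edges:  # covers of the lattice: monotonicity check
        if fit[b] <= fit[a]:
            raise LandscapeError(
                "fitness assignment is not strictly increasing along subset "
                f"inclusion ({a} -> {b})"
            )
    return build_landscape([label(m) for m in masks], fit, edges)


def random_landscape(
    n_types: int,
    seed: int,
    *,
    edge_probability: float = 1.0,
    fitness_low: float = 1.0,
    fitness_high: float = 2.0,
) -> TypeGraph:
    """Random landscape for property tests: i.i.d. uniform fitness values
    (redrawn until pairwise distinct, which they are almost surely) on a
    G(n, p) mutation network, complete by default."""
    if n_types < 1:
        raise LandscapeError("n_types must be >= 1")
    rng = np.random.default_rng(seed)
    while True:
        fit = rng.uniform(fitness_low, fitness_high, size=n_types)
        if len(np.unique(fit)) == n_types:
            break
    ids = [str(i) for i in range(n_types)]
    edges = [
        (a, b)
        for a, b in combinations(ids, 2)
        if edge_probability >= 1.0 or rng.random() < edge_probability
    ]
    return build_landscape(ids, dict(zip(ids, fit)), edges)


# ---------------------------------------------------------------------------
# neighborhood bookkeeping
# ---------------------------------------------------------------------------

def neighborhood_summary(
    graph: TypeGraph, type_id, reference_set: Iterable | None = None
) -> NeighborhoodSummary:
    """Count beneficial (fitter) and deleterious (less fit) neighbors.

    ``M_bound`` is max k over ``reference_set`` (default: all types), the
    uniform bound M on available beneficial mutations.
    """
    k = len(graph.fitter_neighbors(type_id))
    L = len(graph.less_fit_neighbors(type_id))
    ref = graph.type_ids if reference_set is None else tuple(reference_set)
    M = max((len(graph.fitter_neighbors(t)) for t in ref), default=0)
    return NeighborhoodSummary(type_id=type_id, k_beneficial=k, L_deleterious=L, M_bound=M)


def mutational_neighborhood_size(n_sites: int, n_alternatives: int) -> int:
    """Size of the one-step mutational neighborhood in sequence space:
    ``n_sites`` mutable positions times ``n_alternatives`` states per
    position (19 for amino acids)."""
    if n_sites < 1 or n_alternatives < 1:
        raise ValueError("n_sites and n_alternatives must be positive integers")
    return int(n_sites) * int(n_alternatives)


def expected_beneficial_count(
    neighborhood_size: float, deleterious_fraction: float, suppression_factor: float
) -> float:
    """Expected number of available beneficial mutations: the neighborhood
    scaled by the fraction under selection and divided by the suppression
    factor by which beneficial mutations are rarer than deleterious ones."""
    if not 0 < deleterious_fraction <= 1:
        raise ValueError("deleterious_fraction must be in (0, 1]")
    if suppression_factor <= 0:
        raise ValueError("suppression_factor must be > 0")
    return neighborhood_size * deleterious_fraction / suppression_factor
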