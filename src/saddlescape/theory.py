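"""Closed-form origin–fixation theory and regime diagnostics.

Everything here is analytic: the gambler's-ruin fixation probability of the
embedded jump chain, the extinction law of the dominating linear
birth–death process, the waiting/sweep timescales, the dimensionless number
r_N = λ N ln N / s separating punctuated-equilibrium dynamics from clonal
interference, and the deleterious-load condition λ L ln N / s << 1.

The paper-level timescales are order-of-magnitude statements; the functions
report exact formula values and the test-suite checks *scalings* (ratios
under parameter doublings), never prefactors the asymptotics do not pin
down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .landscape import TypeGraph, neighborhood_summary

__all__ = [
    "RegimeReport",
    "regime_numbers",
    "beneficial_mutation_probability_bound",
    "rw_fixation_probability",
    "bd_extinction_probability",
    "simulate_bd_extinction",
    "expected_climb_time",
    "waiting_time",
    "expected_dwell_time",
    "expected_hitting_time",
]


# ---------------------------------------------------------------------------
# fixation / extinction closed forms
# ---------------------------------------------------------------------------

def rw_fixation_probability(
    f_star: float, f_second: float, N: int, start_copies: int
) -> float:
    """Gambler's-ruin fixation probability of the fitter type.

    For two types the jump chain of the fitter type's copy number is an
    asymmetric walk with up/down odds p/(1-p) = f*/f**; absorption at N from
    m copies has probability (1 - rho^m)/(1 - rho^N) with rho = f**/f*.
    As N -> infinity with m = 1 this tends to 1 - rho, independent of N.
    """
    if not f_star > f_second > 0:
        raise ValueError("need f_star > f_second > 0")
    if not 0 <= start_copies <= N:
        raise ValueError("start_copies must be in [0, N]")
    if start_copies == 0:
        return 0.0
    if start_copies == N:
        return 1.0
    rho = f_second / f_star
    # stable form: (1-rho^m)/(1-rho^N) via expm1 of m*log(rho)
    log_rho = math.log(rho)
    return float(math.expm1(start_copies * log_rho) / math.expm1(N * log_rho))


def bd_extinction_probability(k_start: int, A: float, B: float, t: float) -> float:
    """Extinction probability by time t of a linear birth–death process with
    per-capita birth rate A and death rate B > A, started from ``k_start``
    individuals:

        p_k(t) = (1 - (B - A) / (B e^{(B-A)t} - A))^k .

    The subcritical case (A < B) is the one that dominates the loser types
    during a sweep; p_k = p_1^k because lineages are independent.
    """
    if not 0 < A < B:
        raise ValueError("need 0 < A < B (subcritical birth-death)")
    if k_start < 0 or int(k_start) != k_start:
        raise ValueError("k_start must be a nonnegative integer")
    if t < 0:
        raise ValueError("t must be >= 0")
    if k_start == 0:
        return 1.0
    growth = (B - A) * t
    if growth > 700.0:  # e^growth overflows; the formula is 1 to machine precision
        return 1.0
    p1 = 1.0 - (B - A) / (B * math.exp(growth) - A)
    return float(p1 ** k_start)


def simulate_bd_extinction(
    A: float, B: float, k_start: int, t: float, replicates: int, rng
) -> float:
    """Monte-Carlo extinction frequency of the same linear birth–death
    process, by direct Gillespie simulation.  Independent cross-check of
    :func:`bd_extinction_probability` (not used by it)."""
    if A <= 0 or B <= 0:
        raise ValueError("rates must be positive")
    rng = np.random.default_rng(rng)
    p_birth = A / (A + B)
    extinct = 0
    for _ in range(replicates):
        n = k_start
        clock = 0.0
        while n > 0:
            clock += rng.exponential(1.0 / ((A + B) * n))
            if clock > t:
                break
            n += 1 if rng.random() < p_birth else -1
        if n == 0:
            extinct += 1
    return extinct / replicates


# ---------------------------------------------------------------------------
# timescales
# ---------------------------------------------------------------------------

def waiting_time(k: int, lam: float, N: int) -> float:
    """Expected time (k λ N)^-1 to *produce* a beneficial mutant when k
    beneficial mutations are available at total per-individual rate k λ.

    Returns ``inf`` when k = 0 (local fitness peak: the population is
    peak-trapped and the escape time is exponentially large in N, not a
    formula of this theory) or when λ = 0.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if k == 0 or lam == 0.0:
        return math.inf
    return 1.0 / (k * lam * N)


def expected_climb_time(k0: int, lam: float, N: int) -> tuple[float, float]:
    """Leading-order time to climb a k0-step ladder of beneficial mutations
    when the number of available beneficial mutations decreases from k0 to 1:

        sum_{j=1..k0} (j λ N)^-1 = H_{k0} / (λ N)  ~  ln(k0) / (λ N).

    Returns ``(harmonic_sum_time, log_approximation)``.  Production times
    only; fixation thinning and the ln N / s sweeps are lower order and
    handled by :func:`expected_hitting_time`.
    """
    if k0 < 1:
        raise ValueError("k0 must be >= 1")
    if lam <= 0 or N < 1:
        raise ValueError("need lam > 0 and N >= 1")
    harmonic = sum(1.0 / j for j in range(1, k0 + 1)) / (lam * N)
    return harmonic, math.log(k0) / (lam * N)


def expected_dwell_time(graph: TypeGraph, type_id, N: int, lam: float) -> float:
    """Origin–fixation expectation of the stasis (dwell) time at a type:
    successful beneficial mutants arrive as a thinned Poisson stream of rate
    λ N Σ_j π_j over the fitter neighbors j, with π_j the gambler's-ruin
    fixation probability of a single copy; the dwell is the inverse rate.
    Infinite at a local peak or when λ = 0."""
    f0 = graph.fitness_of(type_id)
    rate = 0.0
    for j in graph.fitter_neighbors(type_id):
        rate += lam * N * rw_fixation_probability(graph.fitness_of(j), f0, N, 1)
    return math.inf if rate == 0.0 else 1.0 / rate


def expected_hitting_time(graph: TypeGraph, start, target, N: int, lam: float) -> float:
    """Expected origin–fixation time to first fix ``target`` starting
    monomorphic at ``start``, by dynamic programming over the fitness-ordered
    type DAG: from each type the next fixed type is a fitter neighbor j with
    probability proportional to its single-copy fixation probability π_j,
    after an exponential dwell of mean (λ N Σ π_j)^-1.  Sweep durations are
    not included (they are o(dwell) in the weak-mutation regime)."""
    graph.index(start), graph.index(target)
    order = sorted(graph.type_ids, key=graph.fitness_of, reverse=True)
    expect: dict = {}
    for tid in order:  # descending fitness: successors already solved
        if tid == target:
            expect[tid] = 0.0
            continue
        f0 = graph.fitness_of(tid)
        pis = {
            j: rw_fixation_probability(graph.fitness_of(j), f0, N, 1)
            for j in graph.fitter_neighbors(tid)
        }
        total = sum(pis.values())
        if total == 0.0:
            expect[tid] = math.inf  # peak other than target: never reaches it
            continue
        dwell = 1.0 / (lam * N * total)
        expect[tid] = dwell + sum(
            pi / total * expect[j] for j, pi in pis.items()
        )
    return expect[start]


# ---------------------------------------------------------------------------
# regime diagnostics
# ---------------------------------------------------------------------------

def beneficial_mutation_probability_bound(M: float, r_N: float) -> tuple[float, float]:
    """Probability that any of at most M available beneficial mutations is
    produced during one sweep window of length ln(N)/s:

        exact = 1 - e^{-M r_N}  <=  bound = M r_N.
    """
    if M < 0 or r_N < 0:
        raise ValueError("M and r_N must be >= 0")
    x = M * r_N
    return float(-math.expm1(-x)), float(x)


@dataclass(frozen=True)
class RegimeReport:
    """Dimensionless numbers governing the evolutionary regime at a type.

    s : selection coefficient of the next sweep (minimum fitness gap to a
        fitter neighbor; the conservative choice when several are available).
    r_N : λ N ln N / s — mutation supply per sweep window; << 1 means sweeps
        complete before the next beneficial mutant appears.
    deleterious_load : λ L ln N / s — deleterious mutant production per sweep
        window relative to N; << 1 keeps the dynamic-stasis cloud negligible.
    waiting_time : (k λ N)^-1 production time of the next beneficial mutant.
    sweep_time : ln N / s.
    beneficial_prob_bound : M r_N, the union bound on a beneficial mutation
        arriving during a single sweep.
    verdict : "PE-like", "clonal-interference-prone", or "load-violating".
    """

    type_id: object
    N: int
    lam: float
    k: int
    L: int
    M: int
    s: float
    r_N: float
    deleterious_load: float
    waiting_time: float
    sweep_time: float
    beneficial_prob_bound: float
    peak_trapped: bool
    verdict: str

    def to_dict(self) -> dict:
        return asdict(self)


def regime_numbers(
    graph: TypeGraph,
    active_type,
    N: int,
    lam: float,
    *,
    threshold: float = 0.1,
    M: int | None = None,
) -> RegimeReport:
    """Compute the regime report for a monomorphic population at
    ``active_type``.

    ``threshold`` is the configurable cutoff standing in for "<< 1"
    (default 0.1).  ``M`` defaults to the global bound max_i k_i over the
    whole landscape.  At a local peak (k = 0) the waiting time is infinite
    and the report is flagged ``peak_trapped``; the mutation-supply numbers
    are reported as 0 (no beneficial mutations to supply).
    """
    nb = neighborhood_summary(graph, active_type)
    k, L = nb.k_beneficial, nb.L_deleterious
    M_eff = nb.M_bound if M is None else M
    f0 = graph.fitness_of(active_type)
    fitter = graph.fitter_neighbors(active_type)

    if fitter:
        s = min(graph.fitness_of(j) - f0 for j in fitter)
        logN = math.log(N)
        r_N = lam * N * logN / s
        load = lam * L * logN / s
        sweep = logN / s
        peak = False
    else:
        s = math.nan
        r_N = 0.0
        load = 0.0
        sweep = math.nan
        peak = True

    if load > threshold:
        verdict = "load-violating"
    elif r_N > threshold:
        verdict = "clonal-interference-prone"
    else:
        verdict = "PE-like"

    return RegimeReport(
        type_id=active_type,
        N=N,
        lam=lam,
        k=k,
        L=L,
        M=M_eff,
        s=s,
        r_N=r_N,
        deleterious_load=load,
        waiting_time=waiting_time(k, lam, N),
        sweep_time=sweep,
        beneficial_prob_bound=M_eff * r_N,
        peak_trapped=peak,
        verdict=verdict,
    )
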