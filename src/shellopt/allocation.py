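"""Optimal per-shell volume counts under a fixed total-volume budget.

Minimising SSCV subject to Σ_s n_s = N_total is a classic Lagrange problem.
Because SSCV separates over shells,

    SSCV = σ² Σ_s q_s / n_s   with   q_s = Σ_c (H_sc / ε_c)²,

stationarity gives n_s ∝ sqrt(q_s): each shell receives volumes in
proportion to the square root of its noise-weighted contribution to the
retained components.  The resulting *fractions* are independent of both σ
and N_total — they depend only on the intrinsic structure of the signal.

Integer counts are obtained by largest-remainder rounding of the fractions,
followed by repair to any per-shell minima (e.g. minimum direction counts
from angular-sampling requirements) and a deterministic pairwise-exchange
polish; an exhaustive enumeration oracle is provided for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .sensitivity import NoiseModel

__all__ = [
    "AllocationResult",
    "shell_demand",
    "optimal_fractions",
    "integerise",
    "brute_force_allocation",
    "allocate",
]

_ENUMERATION_GUARD = 1_000_000


@dataclass(frozen=True)
class AllocationResult:
    """Continuous fractions, integer counts and the SSCV they achieve."""

    fractions: np.ndarray
    counts: np.ndarray
    sscv: float


def shell_demand(H: np.ndarray, eps) -> np.ndarray:
    """Per-shell demand q_s = Σ_c (H_sc/ε_c)² over retained components."""
    H = np.asarray(H, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(eps <= 0):
        raise ValueError(
            "zero effect size among retained components; truncate the basis "
            "before allocating"
        )
    return ((H / eps[None, :]) ** 2).sum(axis=1)


def optimal_fractions(H: np.ndarray, eps) -> np.ndarray:
    """Continuous optimal per-shell fractions n_s*/Σ n_s* ∝ sqrt(q_s).

    Independent of σ and of the total volume budget.
    """
    root = np.sqrt(shell_demand(H, eps))
    return root / root.sum()


def _sscv_of_counts(fractions: np.ndarray, counts: np.ndarray) -> float:
    # SSCV up to the (constant) σ² factor; q_s ∝ fractions² by construction
    return float((fractions**2 / counts).sum())


def integerise(fractions, n_total: int, minima=None) -> np.ndarray:
    """Round optimal fractions to integer counts summing to `n_total`.

    Largest-remainder rounding, ties broken towards the lower shell index;
    shells pushed below their minimum (1 by default, or e.g. the minimum
    direction count required for alias-free angular sampling) are topped up
    by taking volumes from the donor shells with the smallest SSCV penalty
    per moved volume.  A final pass moves single volumes between shell pairs
    while that strictly lowers SSCV, so the result cannot be improved by any
    one-volume exchange.
    """
    f = np.asarray(fractions, dtype=float)
    if f.ndim != 1 or f.size == 0 or np.any(f < 0):
        raise ValueError("fractions must be a non-negative vector")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_total = int(n_total)
    k = f.size
    if minima is None:
        minima = np.ones(k, dtype=int)
    else:
        minima = np.asarray(minima, dtype=int)
        minima = np.maximum(minima, 1)
        if minima.size != k:
            raise ValueError("minima length must match number of shells")
    if minima.sum() > n_total:
        raise ValueError(
            f"infeasible minima: require {minima.sum()} volumes but budget "
            f"is {n_total}"
        )

    ideal = f * n_total
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    deficit = n_total - counts.sum()
    # largest remainder first; np.argsort is stable, so equal remainders
    # resolve to the lower shell index
    order = np.argsort(-remainder, kind="stable")
    for i in order[:deficit]:
        counts[i] += 1

    def move_cost(donor):
        # SSCV increase of removing one volume from `donor`
        return f[donor] ** 2 * (1.0 / (counts[donor] - 1) - 1.0 / counts[donor])

    # repair to minima: cheapest donor each time
    while True:
        short = np.nonzero(counts < minima)[0]
        if short.size == 0:
            break
        s = short[0]
        donors = [d for d in range(k) if d != s and counts[d] > minima[d]]
        best = min(donors, key=lambda d: (move_cost(d), d))
        counts[best] -= 1
        counts[s] += 1

    # pairwise polish: apply the best strictly improving one-volume move
    improved = True
    while improved:
        improved = False
        current = _sscv_of_counts(f, counts)
        best_delta, best_move = 0.0, None
        for d in range(k):
            if counts[d] <= minima[d]:
                continue
            for r in range(k):
                if r == d:
                    continue
                trial = counts.copy()
                trial[d] -= 1
                trial[r] += 1
                delta = _sscv_of_counts(f, trial) - current
                if delta < best_delta - 1e-15:
                    best_delta, best_move = delta, (d, r)
        if best_move is not None:
            d, r = best_move
            counts[d] -= 1
            counts[r] += 1
            improved = True
    return counts


def brute_force_allocation(H, eps, noise: NoiseModel, n_total: int,
                           minima=None) -> AllocationResult:
    """Exhaustive search over all positive integer compositions of the budget.

    Validation oracle for the closed-form allocation; guarded to at most
    1e6 compositions.  Ties resolve to the lexicographically smallest counts.
    """
    q = shell_demand(H, eps)
    k = q.size
    n_total = int(n_total)
    if minima is None:
        minima = np.ones(k, dtype=int)
    else:
        minima = np.maximum(np.asarray(minima, dtype=int), 1)
    free = n_total - int(minima.sum())
    if free < 0:
        raise ValueError("infeasible minima for the given budget")
    n_comp = comb(free + k - 1, k - 1)
    if n_comp > _ENUMERATION_GUARD:
        raise ValueError(
            f"{n_comp} compositions exceed the enumeration guard "
            f"({_ENUMERATION_GUARD})"
        )

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    best_counts, best_val = None, np.inf
    for extra in compositions(free, k):
        counts = minima + np.asarray(extra)
        val = noise.sigma**2 * float((q / counts).sum())
        if val < best_val * (1 - 1e-15):
            best_val, best_counts = val, counts
    root = np.sqrt(q)
    return AllocationResult(fractions=root / root.sum(),
                            counts=best_counts, sscv=best_val)


def allocate(H, eps, noise: NoiseModel, n_total: int,
             minima=None) -> AllocationResult:
    """Closed-form fractions → integer counts → achieved SSCV."""
    fractions = optimal_fractions(H, eps)
    counts = integerise(fractions, n_total, minima)
    q = shell_demand(H, eps)
    val = noise.sigma**2 * float((q / counts).sum())
    return AllocationResult(fractions=fractions, counts=counts, sscv=val)
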