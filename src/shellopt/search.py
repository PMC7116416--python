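"""Optimising shell b-values by interpolated resampling + simplex search.

Acquiring data at every candidate b-value is impractical, but the shell-mean
signal varies smoothly with b, so densely measured data can stand in for any
intermediate protocol: per-voxel monotonicity-preserving PCHIP interpolation
over the measured b-values predicts the mean-signal matrix at an arbitrary
candidate set of shells.  For each candidate the full sensitivity pipeline
runs — SVD basis, T2-attenuated effect sizes from the implied echo time,
closed-form optimal per-shell fractions — and the resulting SSCV is the cost
driving a multi-start Nelder–Mead simplex over the nonzero b-values (in
log-b coordinates; b = 0 is always retained as a fixed shell).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from . import allocation as alloc
from . import timing as tm
from .basis import decompose
from .io import MeanSignalMatrix, ShellScheme
from .sensitivity import NoiseModel, sensitivity_report

__all__ = [
    "CandidateProtocol",
    "interpolate_shell_signal",
    "ProtocolCost",
    "protocol_cost",
    "optimise_bvalues",
]

#: Lowest admissible nonzero shell, s/mm² (keeps candidates clear of b = 0).
B_FLOOR = 50.0
#: Candidate shells closer than this are treated as degenerate, s/mm².
B_SEPARATION = 1.0
_PENALTY = 1e12


@dataclass
class CandidateProtocol:
    """An optimised multi-shell protocol and the sensitivity it achieves."""

    bvalues: tuple            # including the fixed b = 0 shell, s/mm²
    fractions: np.ndarray     # per-shell fraction of N_total
    counts: np.ndarray        # integer volumes per shell (sum = n_total)
    sscv: float
    cv: np.ndarray
    cnr: np.ndarray
    effect_sizes: np.ndarray  # T2-attenuated
    te: float                 # ms
    attenuation: float
    n_total: int
    sigma: float
    t2: float
    seed: int | None = None
    search_trace: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "bvalues": [round(float(b), 6) for b in self.bvalues],
            "fractions": self.fractions.tolist(),
            "counts": [int(c) for c in self.counts],
            "sscv": self.sscv,
            "cv": self.cv.tolist(),
            "cnr": self.cnr.tolist(),
            "effect_sizes": self.effect_sizes.tolist(),
            "te_ms": self.te,
            "attenuation": self.attenuation,
            "n_total": self.n_total,
            "sigma": self.sigma,
            "t2_ms": None if math.isinf(self.t2) else self.t2,
            "seed": self.seed,
            "search_trace": self.search_trace,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def interpolate_shell_signal(data: MeanSignalMatrix, target_bvals
                             ) -> MeanSignalMatrix:
    """Resample the mean-signal matrix at new b-values by per-voxel PCHIP.

    Interpolation only — targets must lie within the measured b-range — and
    exact at the measured b-values.  The returned scheme carries placeholder
    counts of 1 per shell (counts are an acquisition property, decided later
    by the allocation step).
    """
    measured = np.asarray(data.scheme.bvalues, dtype=float)
    if measured.size < 3:
        raise ValueError("need at least 3 measured shells to interpolate")
    targets = np.asarray(target_bvals, dtype=float).ravel()
    if np.any(targets < measured[0]) or np.any(targets > measured[-1]):
        raise ValueError(
            f"extrapolation requested: targets must lie in "
            f"[{measured[0]:g}, {measured[-1]:g}] s/mm^2"
        )
    if np.any(np.diff(targets) <= 0):
        raise ValueError("target b-values must be strictly increasing")
    interp = PchipInterpolator(measured, data.D, axis=0, extrapolate=False)
    D = np.clip(interp(targets), 0.0, None)
    scheme = ShellScheme(tuple(targets), tuple([1] * targets.size))
    return MeanSignalMatrix(D=D, scheme=scheme, provenance=list(data.provenance))


class ProtocolCost:
    """Reusable SSCV cost over candidate nonzero b-values.

    Builds the PCHIP interpolant once and caches cost evaluations keyed by
    b-values rounded to 0.1 s/mm².  Degenerate candidates (out of range or
    shells closer than ``B_SEPARATION``) receive a large finite penalty that
    grows with the violation, so the simplex can back out of them.
    """

    def __init__(self, data: MeanSignalMatrix, noise: NoiseModel,
                 timing: tm.TimingModel | None = None, n_total: int = 100,
                 n_components: int | None = None):
        measured = np.asarray(data.scheme.bvalues, dtype=float)
        if measured.size < 3:
            raise ValueError("need at least 3 measured shells")
        if measured[0] != 0.0:
            raise ValueError("measured data must include a b = 0 shell")
        self.data = data
        self.noise = noise
        self.timing = timing or tm.TimingModel()
        self.n_total = int(n_total)
        self.n_components = n_components
        self.b_max_measured = float(measured[-1])
        self._interp = PchipInterpolator(measured, data.D, axis=0,
                                         extrapolate=False)
        self._cache: dict = {}
        self.n_evaluations = 0

    # -- candidate handling ---------------------------------------------
    def _violation(self, b_sorted: np.ndarray) -> float:
        v = 0.0
        v += float(np.clip(B_FLOOR - b_sorted, 0, None).sum())
        v += float(np.clip(b_sorted - self.b_max_measured, 0, None).sum())
        gaps = np.diff(np.concatenate([[0.0], b_sorted]))
        v += float(np.clip(B_SEPARATION - gaps, 0, None).sum())
        return v

    def evaluate(self, nonzero_bvals) -> float:
        """SSCV of the candidate protocol (b = 0 + sorted nonzero shells)."""
        b = np.sort(np.asarray(nonzero_bvals, dtype=float).ravel())
        violation = self._violation(b)
        if violation > 0:
            return _PENALTY * (1.0 + violation)
        key = tuple(np.round(b, 1))
        if key in self._cache:
            return self._cache[key]
        self.n_evaluations += 1

        bvals = np.concatenate([[0.0], b])
        D = np.clip(self._interp(bvals), 0.0, None)
        basis = decompose(D, bvalues=tuple(bvals))
        eps = tm.attenuated_effect_sizes(basis.effect_sizes, bvals[-1],
                                         self.timing)
        H = basis.H
        if self.n_components is not None:
            H = H[:, :self.n_components]
            eps = eps[:self.n_components]
        if np.any(eps <= 1e-12 * max(eps.max(initial=0.0), 1e-300)):
            cost = _PENALTY  # numerically rank-deficient candidate
        else:
            fractions = alloc.optimal_fractions(H, eps)
            q = alloc.shell_demand(H, eps)
            counts = fractions * self.n_total  # continuous allocation
            cost = float(self.noise.sigma**2 * (q / counts).sum())
        self._cache[key] = cost
        return cost

    # -- finalisation ----------------------------------------------------
    def protocol_at(self, nonzero_bvals, minima=None, seed=None,
                    search_trace=None) -> CandidateProtocol:
        """Full protocol report (integer counts, CV/CNR, TE) at given shells."""
        b = np.sort(np.asarray(nonzero_bvals, dtype=float).ravel())
        if self._violation(b) > 0:
            raise ValueError("degenerate candidate b-values")
        bvals = np.concatenate([[0.0], b])
        D = np.clip(self._interp(bvals), 0.0, None)
        basis = decompose(D, bvalues=tuple(bvals))
        te = tm.min_echo_time(bvals[-1], self.timing)
        factor = tm.attenuation(te, self.timing.t2)
        eps = basis.effect_sizes * factor
        H = basis.H
        if self.n_components is not None:
            H = H[:, :self.n_components]
            eps = eps[:self.n_components]
        fractions = alloc.optimal_fractions(H, eps)
        counts = alloc.integerise(fractions, self.n_total, minima)
        scheme = ShellScheme(tuple(bvals), tuple(int(c) for c in counts))
        attenuated = type(basis)(
            H=basis.H, singular_values=basis.singular_values * factor,
            W=basis.W * factor, effect_sizes=basis.effect_sizes * factor,
            n_voxels=basis.n_voxels, bvalues=basis.bvalues,
        )
        report = sensitivity_report(attenuated, self.noise, scheme,
                                    n_components=self.n_components)
        return CandidateProtocol(
            bvalues=tuple(float(v) for v in bvals), fractions=fractions,
            counts=counts, sscv=report.sscv, cv=report.cv, cnr=report.cnr,
            effect_sizes=eps, te=te, attenuation=factor,
            n_total=self.n_total, sigma=self.noise.sigma,
            t2=self.timing.t2, seed=seed, search_trace=search_trace or [],
        )


def protocol_cost(data: MeanSignalMatrix, candidate_bvals, noise: NoiseModel,
                  timing: tm.TimingModel | None = None, n_total: int = 100,
                  n_components: int | None = None) -> float:
    """One-shot SSCV of a candidate protocol (must include b = 0).

    Order of the supplied b-values is irrelevant; shells are sorted before
    evaluation.
    """
    bvals = np.sort(np.asarray(candidate_bvals, dtype=float).ravel())
    if bvals[0] != 0.0:
        raise ValueError("candidate protocol must include b = 0")
    evaluator = ProtocolCost(data, noise, timing, n_total, n_components)
    return evaluator.evaluate(bvals[1:])


def _stratified_starts(n_starts, n_shells, lo, hi, rng):
    """Jittered log-space quantile starts; the first start is unjittered."""
    starts = []
    base = (np.arange(1, n_shells + 1)) / (n_shells + 1.0)
    for j in range(n_starts):
        u = base.copy()
        if j > 0:
            u = u + rng.uniform(-0.45, 0.45, size=n_shells) / (n_shells + 1.0)
        u = np.sort(np.clip(u, 0.02, 0.999))
        starts.append(lo + u * (hi - lo))
    return starts


def optimise_bvalues(data: MeanSignalMatrix, n_shells: int, noise: NoiseModel,
                     timing: tm.TimingModel | None = None, n_total: int = 100,
                     n_components: int | None = None, minima=None,
                     n_starts: int = 8, seed: int = 0, maxiter: int = 500,
                     starts=None) -> CandidateProtocol:
    """Optimise the nonzero shell b-values for a fixed shell count.

    Multi-start Nelder–Mead over log-b coordinates of the `n_shells` nonzero
    shells (b = 0 fixed).  Starts are stratified over the measured b-range
    and jittered with the seeded generator; `starts` overrides them with
    explicit nonzero b-value vectors.  Convergence per start: simplex
    diameter below ~1 s/mm² (log-b tolerance 1e-4) or `maxiter` iterations.

    Returns the best protocol found, with the per-start history in
    ``search_trace``.
    """
    measured = np.asarray(data.scheme.bvalues, dtype=float)
    n_measured = measured.size
    if not 1 <= n_shells <= n_measured - 1:
        raise ValueError(f"n_shells must be in [1, {n_measured - 1}]")
    if n_measured < n_shells + 2:
        raise ValueError(
            f"need at least {n_shells + 2} measured shells for a "
            f"{n_shells}-shell search"
        )
    evaluator = ProtocolCost(data, noise, timing, n_total, n_components)
    lo, hi = np.log(B_FLOOR), np.log(evaluator.b_max_measured)
    rng = np.random.default_rng(seed)
    if starts is None:
        start_list = _stratified_starts(n_starts, n_shells, lo, hi, rng)
    else:
        start_list = [np.log(np.asarray(s, dtype=float).ravel())
                      for s in starts]
        if any(s.size != n_shells for s in start_list):
            raise ValueError("each start must supply n_shells b-values")

    trace, best = [], None
    for x0 in start_list:
        res = minimize(lambda x: evaluator.evaluate(np.exp(x)), x0,
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-12,
                                "maxiter": maxiter, "maxfev": 4 * maxiter})
        entry = {
            "start_bvalues": np.round(np.exp(x0), 3).tolist(),
            "final_bvalues": np.round(np.sort(np.exp(res.x)), 3).tolist(),
            "sscv": float(res.fun),
            "n_iterations": int(res.nit),
            "converged": bool(res.success),
        }
        trace.append(entry)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), np.sort(np.exp(res.x)))
    if best is None or best[0] >= _PENALTY:
        raise RuntimeError(f"all simplex starts failed; trace: {trace}")
    # polish the winning start with a tighter simplex
    res = minimize(lambda x: evaluator.evaluate(np.exp(x)), np.log(best[1]),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 0.0, "maxiter": maxiter})
    if res.fun <= best[0]:
        best = (float(res.fun), np.sort(np.exp(res.x)))
    return evaluator.protocol_at(best[1], minima=minima, seed=seed,
                                 search_trace=trace)
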