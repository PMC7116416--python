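"""Angular-domain analysis: spherical-harmonic content and direction sets.

The diffusion signal on a shell is antipodally symmetric, so only even-order
spherical harmonics contribute.  A signal band-limited at order ``lmax``
has ``(lmax + 1)(lmax + 2) / 2`` free coefficients, which is therefore the
minimum number of distinct gradient directions required to sample that
shell without angular aliasing.  This module provides:

* a real, even-order, orthonormal SH basis and least-squares fitting;
* the rotation-invariant per-order power spectrum and a noise-floor test
  deciding the highest *detectable* order (and hence the minimum direction
  count) at a given noise level;
* electrostatic-repulsion generation of uniform antipodal direction sets;
* selection and realignment of single-fibre voxels, whose profiles carry
  the highest angular frequencies and can be averaged after rotating each
  voxel's principal fibre direction onto a common axis.

SH convention: real basis built from the complex harmonics Y_l^m with the
Condon–Shortley phase, ordered l = 0, 2, 4, ... and m = −l ... l within
each order; orthonormal over the sphere, so a constant signal of value a
fits to c_00 = a·sqrt(4π) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

from .io import DataError, DWIDataset, group_shells

__all__ = [
    "DirectionSet",
    "AngularSpectrum",
    "SingleFibreSelection",
    "n_even_sh_coeffs",
    "real_sh_basis",
    "sh_fit",
    "rotational_power_spectrum",
    "noise_floor",
    "detectable_lmax",
    "angular_spectrum",
    "generate_directions",
    "write_directions",
    "read_directions",
    "select_single_fibre_voxels",
]

#: Relative numerical floor: per-order power below this fraction of the l=0
#: power is never called detectable, even when the noise floor is zero.
RELATIVE_POWER_FLOOR = 1e-10


def n_even_sh_coeffs(lmax: int) -> int:
    """Number of even-order SH coefficients up to `lmax`: (l+1)(l+2)/2.

    Equals the minimum number of directions required to sample a shell whose
    angular content is band-limited at `lmax`.
    """
    lmax = int(lmax)
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError("lmax must be an even non-negative integer")
    return (lmax + 1) * (lmax + 2) // 2


def _even_orders(lmax: int):
    return list(range(0, lmax + 1, 2))


def real_sh_basis(lmax: int, directions) -> np.ndarray:
    """Design matrix of the real even-order SH basis at unit `directions`.

    Returns an (n_directions, n_even_sh_coeffs(lmax)) array.
    """
    n_even_sh_coeffs(lmax)  # validates lmax
    u = np.atleast_2d(np.asarray(directions, dtype=float))
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    cols = []
    for ell in _even_orders(lmax):
        for m in range(-ell, ell + 1):
            y = sph_harm_y(ell, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(math.sqrt(2.0) * (-1.0) ** m * y.real)
            else:
                cols.append(math.sqrt(2.0) * (-1.0) ** m * y.imag)
    return np.stack(cols, axis=1)


def sh_fit(directions, values, lmax: int, regularisation: float = 0.0
           ) -> np.ndarray:
    """Least-squares even-order SH coefficients of shell data.

    Parameters
    ----------
    values : array, (n_directions,) or (n_signals, n_directions)
    regularisation : float
        Optional Laplace–Beltrami penalty λ·l²(l+1)² on the coefficients.
    """
    B = real_sh_basis(lmax, directions)
    n, p = B.shape
    if n < p:
        raise ValueError(
            f"underdetermined SH fit: {n} directions for {p} coefficients "
            f"(order {lmax})"
        )
    y = np.asarray(values, dtype=float)
    single = y.ndim == 1
    y2 = np.atleast_2d(y)
    if y2.shape[1] != n:
        raise ValueError("values do not match the number of directions")
    if regularisation > 0:
        ell = np.concatenate([[l] * (2 * l + 1) for l in _even_orders(lmax)])
        L = np.diag((ell * (ell + 1.0)) ** 2)
        A = B.T @ B + regularisation * L
        coeffs = np.linalg.solve(A, B.T @ y2.T).T
    else:
        coeffs = np.linalg.lstsq(B, y2.T, rcond=None)[0].T
    return coeffs[0] if single else coeffs


def _infer_lmax(n_coeffs: int) -> int:
    lmax = 0
    while n_even_sh_coeffs(lmax) < n_coeffs:
        lmax += 2
    if n_even_sh_coeffs(lmax) != n_coeffs:
        raise ValueError(f"{n_coeffs} is not an even-order SH coefficient count")
    return lmax


def rotational_power_spectrum(coefficients) -> dict:
    """Per-order power Σ_m c_lm², a rotation invariant of the signal.

    Accepts a single coefficient vector or a stack (n_signals, n_coeffs);
    stacks are averaged over signals.  Returns {order: power}.
    """
    c = np.atleast_2d(np.asarray(coefficients, dtype=float))
    lmax = _infer_lmax(c.shape[1])
    power, start = {}, 0
    for ell in _even_orders(lmax):
        width = 2 * ell + 1
        power[ell] = float(np.mean((c[:, start:start + width] ** 2).sum(axis=1)))
        start += width
    return power


def noise_floor(directions, lmax: int, sigma: float, n_voxels: int = 1,
                n_trials: int = 500, percentile: float = 95.0,
                seed: int = 0) -> dict:
    """Per-order power expected from pure noise, by simulation.

    Draws `n_trials` pure-Gaussian-noise shells (σ per measurement, averaged
    over `n_voxels` voxels as the real spectrum would be), fits the SH basis
    and returns the given percentile of each order's power distribution.
    σ = 0 returns an all-zero floor.
    """
    orders = _even_orders(lmax)
    if sigma == 0:
        return {ell: 0.0 for ell in orders}
    B = real_sh_basis(lmax, directions)
    pinv = np.linalg.pinv(B)
    n = B.shape[0]
    rng = np.random.default_rng(seed)
    per_trial = np.zeros((n_trials, len(orders)))
    for t in range(n_trials):
        noise = rng.normal(0.0, sigma, size=(n_voxels, n))
        coeffs = noise @ pinv.T
        start = 0
        for k, ell in enumerate(orders):
            width = 2 * ell + 1
            per_trial[t, k] = np.mean(
                (coeffs[:, start:start + width] ** 2).sum(axis=1))
            start += width
    pct = np.percentile(per_trial, percentile, axis=0)
    return {ell: float(v) for ell, v in zip(orders, pct)}


def detectable_lmax(per_order_power: dict, noise_floor_estimate: dict | None
                    = None):
    """Highest even order whose power rises above the noise floor.

    An order counts as detectable when its power exceeds the floor estimate
    by more than a small fraction (``RELATIVE_POWER_FLOOR``) of the l = 0
    power, which guards against calling float-epsilon residuals detectable
    on noiseless inputs.  Returns ``(lmax, min_directions)`` with
    min_directions = (lmax+1)(lmax+2)/2.
    """
    floor = noise_floor_estimate or {}
    p0 = per_order_power.get(0, 0.0)
    tol = RELATIVE_POWER_FLOOR * p0
    best = 0
    for ell in sorted(per_order_power):
        if ell == 0:
            continue
        if per_order_power[ell] > floor.get(ell, 0.0) + tol:
            best = ell
    return best, n_even_sh_coeffs(best)


@dataclass
class AngularSpectrum:
    """Per-order SH power of a shell with its detectability verdict."""

    per_order_power: dict
    noise_floor: dict
    detectable_lmax: int
    min_directions: int
    sigma: float

    def to_rows(self):
        return [
            {"order": ell, "power": self.per_order_power[ell],
             "noise_floor": self.noise_floor.get(ell, 0.0)}
            for ell in sorted(self.per_order_power)
        ]


def angular_spectrum(directions, values, lmax: int, sigma: float,
                     n_trials: int = 500, seed: int = 0) -> AngularSpectrum:
    """Fit, spectrum, noise floor and detectability for one shell's data.

    `values` may be a stack of per-voxel profiles; the spectrum and the
    simulated floor then both refer to the across-voxel mean power.  The
    assumed σ is recorded in the result.
    """
    coeffs = sh_fit(directions, values, lmax)
    power = rotational_power_spectrum(coeffs)
    n_voxels = 1 if np.asarray(values).ndim == 1 else np.asarray(values).shape[0]
    floor = noise_floor(directions, lmax, sigma, n_voxels=n_voxels,
                        n_trials=n_trials, seed=seed)
    best, min_dirs = detectable_lmax(power, floor)
    return AngularSpectrum(per_order_power=power, noise_floor=floor,
                           detectable_lmax=best, min_directions=min_dirs,
                           sigma=sigma)


# ---------------------------------------------------------------------------
# electrostatic-repulsion direction sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectionSet:
    """Unit gradient directions with antipodal symmetry and their energy."""

    vectors: np.ndarray  # (n, 3)
    energy: float

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        object.__setattr__(self, "vectors", v)
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("directions must be unit vectors")
        if v.shape[0] > 1:
            dots = np.clip(np.abs(v @ v.T), 0.0, 1.0)
            np.fill_diagonal(dots, 0.0)
            if np.degrees(np.arccos(dots.max())) < 0.5:
                raise ValueError(
                    "directions closer than 0.5 degrees (incl. antipodes)"
                )

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def min_angle_deg(self) -> float:
        if self.n < 2:
            return 180.0
        dots = np.clip(np.abs(self.vectors @ self.vectors.T), 0.0, 1.0)
        np.fill_diagonal(dots, 0.0)
        return float(np.degrees(np.arccos(dots.max())))


def _electrostatic_energy_grad(P: np.ndarray):
    n = P.shape[0]
    diff = P[:, None, :] - P[None, :, :]
    summ = P[:, None, :] + P[None, :, :]
    d1 = np.linalg.norm(diff, axis=2)
    d2 = np.linalg.norm(summ, axis=2)
    np.fill_diagonal(d1, np.inf)
    np.fill_diagonal(d2, np.inf)
    energy = 0.5 * float((1.0 / d1 + 1.0 / d2).sum())
    grad = -(diff / d1[:, :, None] ** 3).sum(axis=1) \
        - (summ / d2[:, :, None] ** 3).sum(axis=1)
    return energy, grad


def generate_directions(n: int, seed: int = 0, max_iter: int = 2000,
                        tol: float = 1e-12) -> DirectionSet:
    """Uniform antipodal directions by electrostatic-repulsion descent.

    Minimises Σ_{i<j} 1/‖u_i−u_j‖ + 1/‖u_i+u_j‖ (charges interacting with
    both poles of every axis) by projected gradient descent with
    backtracking, so the energy is non-increasing at every accepted step.
    Deterministic for a given (n, seed).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(n, 3))
    P /= np.linalg.norm(P, axis=1, keepdims=True)
    if n == 1:
        return DirectionSet(vectors=P, energy=0.0)

    energy, grad = _electrostatic_energy_grad(P)
    step = 1e-3
    for _ in range(max_iter):
        tangent = grad - (grad * P).sum(axis=1, keepdims=True) * P
        accepted = False
        for _ in range(60):
            Q = P - step * tangent
            Q /= np.linalg.norm(Q, axis=1, keepdims=True)
            new_energy, new_grad = _electrostatic_energy_grad(Q)
            if new_energy <= energy:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        if energy - new_energy < tol * energy:
            P, energy = Q, new_energy
            break
        P, energy, grad = Q, new_energy, new_grad
        step *= 1.2
    # canonical hemisphere: flip so the largest-|.| component is positive
    for i in range(n):
        j = int(np.argmax(np.abs(P[i])))
        if P[i, j] < 0:
            P[i] = -P[i]
    return DirectionSet(vectors=P, energy=energy)


def write_directions(directions: DirectionSet | np.ndarray, path,
                     style: str = "bvec", bvalue: float = 1000.0) -> None:
    """Write a direction set as text: FSL bvecs (3 rows) or MRtrix
    4-column (x y z b)."""
    v = directions.vectors if isinstance(directions, DirectionSet) \
        else np.atleast_2d(np.asarray(directions, dtype=float))
    if style == "bvec":
        np.savetxt(path, v.T, fmt="%.8f")
    elif style == "mrtrix":
        np.savetxt(path, np.column_stack([v, np.full(len(v), bvalue)]),
                   fmt="%.8f")
    else:
        raise ValueError("style must be 'bvec' or 'mrtrix'")


def read_directions(path, style: str = "auto") -> DirectionSet:
    """Read a direction set from FSL bvecs or MRtrix 4-column text."""
    arr = np.atleast_2d(np.loadtxt(path))
    if style == "auto":
        style = "bvec" if arr.shape[0] == 3 and arr.shape[1] != 4 else "mrtrix"
    if style == "bvec":
        v = arr.T if arr.shape[0] == 3 else arr
    elif style == "mrtrix":
        v = arr[:, :3]
    else:
        raise ValueError("style must be 'bvec', 'mrtrix' or 'auto'")
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    return DirectionSet(vectors=v, energy=_electrostatic_energy_grad(v)[0]
                        if len(v) > 1 else 0.0)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform full-sphere point set (dense evaluation grids)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


# ---------------------------------------------------------------------------
# single-fibre voxel selection and realignment
# ---------------------------------------------------------------------------

@dataclass
class SingleFibreSelection:
    """Voxels consistent with one dominant fibre, plus their mean profile."""

    mask: np.ndarray              # 3-D boolean, within the dataset's mask
    stage_counts: dict            # voxels surviving each filter stage
    mean_profile: np.ndarray      # realigned mean S/S0 at `directions`
    directions: np.ndarray        # common directions (fibre along +z)
    fa: np.ndarray                # FA of all masked voxels (scan order)


def _tensor_design(bvals, bvecs):
    g = bvecs.T
    return np.column_stack([
        np.ones(len(bvals)),
        -bvals * g[:, 0] ** 2,
        -bvals * g[:, 1] ** 2,
        -bvals * g[:, 2] ** 2,
        -2 * bvals * g[:, 0] * g[:, 1],
        -2 * bvals * g[:, 0] * g[:, 2],
        -2 * bvals * g[:, 1] * g[:, 2],
    ])


def _fit_tensors(signals, bvals, bvecs):
    """Weighted least-squares log-linear tensor fit.

    signals: (n_voxels, n_volumes).  Weights are the squared observed
    signals, the standard WLS choice for log-transformed data.
    """
    X = _tensor_design(bvals, bvecs)
    S = np.clip(signals, 1e-10, None)
    logS = np.log(S)
    n_vox = S.shape[0]
    evals = np.empty((n_vox, 3))
    evecs = np.empty((n_vox, 3, 3))
    s0 = np.empty(n_vox)
    for v in range(n_vox):
        w = S[v] ** 2
        Xw = X * w[:, None]
        beta = np.linalg.solve(X.T @ Xw, Xw.T @ logS[v])
        s0[v] = math.exp(beta[0])
        Dt = np.array([[beta[1], beta[4], beta[5]],
                       [beta[4], beta[2], beta[6]],
                       [beta[5], beta[6], beta[3]]])
        vals, vecs = np.linalg.eigh(Dt)
        evals[v] = vals[::-1]          # descending
        evecs[v] = vecs[:, ::-1].T     # rows are eigenvectors
    return s0, evals, evecs


def _fa(evals):
    lam = np.clip(evals, 0.0, None)
    mean = lam.mean(axis=1, keepdims=True)
    num = ((lam - mean) ** 2).sum(axis=1)
    den = (lam**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    return np.where(den > 0, fa, 0.0)


def _rotation_to_z(axis):
    """Rotation matrix R with R @ axis = z."""
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    a = np.cross(axis, helper)
    a /= np.linalg.norm(a)
    b = np.cross(axis, a)
    return np.stack([a, b, axis])


def _sh_peaks(coeffs, grid, neighbours, basis_grid):
    """Local maxima of an SH-represented function on a dense sphere grid.

    Returns peak amplitudes above the grid minimum, deduplicated over
    antipodes and near-coincident directions, sorted descending.
    """
    values = basis_grid @ coeffs
    is_max = np.ones(len(values), dtype=bool)
    for k in range(neighbours.shape[1]):
        is_max &= values >= values[neighbours[:, k]]
    idx = np.nonzero(is_max)[0]
    idx = idx[np.argsort(-values[idx], kind="stable")]
    floor_val = values.min()
    peaks, peak_dirs = [], []
    for i in idx:
        u = grid[i]
        if any(abs(u @ w) > math.cos(math.radians(25.0)) for w in peak_dirs):
            continue
        peaks.append(values[i] - floor_val)
        peak_dirs.append(u)
    return np.asarray(peaks), np.asarray(peak_dirs)


def select_single_fibre_voxels(dataset: DWIDataset, fa_threshold: float = 0.25,
                               peak_ratio_threshold: float = 0.5,
                               b_low_max: float = 1000.0,
                               lmax: int | None = None
                               ) -> SingleFibreSelection:
    """Select voxels whose highest-shell signal shows one dominant fibre.

    Two-stage filter: a tensor fit on the b ≤ `b_low_max` shells must give
    FA above `fa_threshold`, and the angular profile of the highest shell
    (fitted with even-order SH) must have a second ADC peak smaller than
    `peak_ratio_threshold` times the first.  Each surviving voxel's profile
    is rotated so its principal eigenvector lies along +z before averaging.
    """
    scheme, labels = group_shells(dataset.bvals)
    if scheme.n_shells < 2:
        raise DataError("need at least two shells (incl. b = 0)")
    high = scheme.n_shells - 1
    b_high = scheme.bvalues[high]

    flat_mask = dataset.mask.reshape(-1)
    signals = dataset.volumes.reshape(-1, dataset.n_volumes)[flat_mask]
    n_masked = signals.shape[0]

    low = np.nonzero(dataset.bvals <= b_low_max)[0]
    if low.size < 7:
        raise DataError("tensor fit needs at least 7 volumes with b <= b_low_max")
    s0, evals, evecs = _fit_tensors(signals[:, low], dataset.bvals[low],
                                    dataset.bvecs[:, low])
    fa = _fa(evals)
    fa_pass = fa > fa_threshold

    high_cols = np.nonzero(labels == high)[0]
    dirs_high = dataset.bvecs[:, high_cols].T
    if lmax is None:
        lmax = 0
        while lmax + 2 <= 8 and n_even_sh_coeffs(lmax + 2) <= len(high_cols):
            lmax += 2
    # lightly Laplace-Beltrami-regularised fit: damps noise in the peak test
    B = real_sh_basis(lmax, dirs_high)
    ell = np.concatenate([[l] * (2 * l + 1) for l in _even_orders(lmax)])
    L = np.diag((ell * (ell + 1.0)) ** 2)
    basis_high_pinv = np.linalg.solve(B.T @ B + 5e-3 * L, B.T)
    grid = fibonacci_sphere(500)
    basis_grid = real_sh_basis(lmax, grid)
    dots = grid @ grid.T
    np.fill_diagonal(dots, -np.inf)
    neighbours = np.argsort(-dots, axis=1)[:, :6]

    keep = np.zeros(n_masked, dtype=bool)
    candidates = np.nonzero(fa_pass)[0]
    for v in candidates:
        adc = -np.log(np.clip(signals[v, high_cols] / max(s0[v], 1e-10),
                              1e-10, None)) / b_high
        coeffs = basis_high_pinv @ adc
        peaks, _ = _sh_peaks(coeffs, grid, neighbours, basis_grid)
        if peaks.size == 0:
            continue
        ratio = peaks[1] / peaks[0] if peaks.size > 1 and peaks[0] > 0 else 0.0
        keep[v] = ratio < peak_ratio_threshold

    counts = {
        "masked": int(n_masked),
        "fa_pass": int(fa_pass.sum()),
        "peak_pass": int(keep.sum()),
    }
    if not keep.any():
        raise DataError(
            f"no single-fibre voxels found (stage counts: {counts})"
        )

    # realign each voxel's highest-shell profile so e1 -> +z, then average
    sh_pinv = basis_high_pinv
    profiles = []
    for v in np.nonzero(keep)[0]:
        coeffs = sh_pinv @ (signals[v, high_cols] / max(s0[v], 1e-10))
        R = _rotation_to_z(evecs[v, 0])
        rotated_dirs = dirs_high @ R  # = (R.T @ u.T).T for each common u
        profiles.append(real_sh_basis(lmax, rotated_dirs) @ coeffs)
    mean_profile = np.mean(profiles, axis=0)

    mask3d = np.zeros(flat_mask.size, dtype=bool)
    mask3d[np.nonzero(flat_mask)[0][keep]] = True
    return SingleFibreSelection(
        mask=mask3d.reshape(dataset.mask.shape), stage_counts=counts,
        mean_profile=mean_profile, directions=dirs_high, fa=fa,
    )
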