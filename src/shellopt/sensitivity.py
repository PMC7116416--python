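"""Noise propagation: coefficient covariance, CV, CNR and the SSCV objective.

With i.i.d. Gaussian noise of standard deviation σ on every measurement, the
mean signal of a shell acquired with n_s volumes has variance σ²/n_s.  For a
voxel with per-shell mean vector d = H w, error propagation through the
orthonormal basis gives the coefficient covariance

    Σ_w = σ² Hᵀ diag(1/n_s) H.

The coefficient of variation of component c is CV_c = sqrt(Σ_w(c,c)) / ε_c,
the reciprocal of its contrast-to-noise ratio, and the scalar objective used
for protocol design is the sum of squared CVs,

    SSCV = Σ_c CV_c² = σ² Σ_c (1/ε_c²) Σ_s H_sc²/n_s.

SSCV weights the optimisation towards the components that are hardest to
detect without overly penalising the strong ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import ShellScheme

__all__ = [
    "NoiseModel",
    "SensitivityReport",
    "shell_variance",
    "coefficient_covariance",
    "coefficient_cv",
    "sscv",
    "rescale_cnr",
    "sensitivity_report",
]

#: Total-volume and b=0 SNR convention under which listed CNR tables are given.
CNR_REFERENCE_N_TOTAL = 100
CNR_REFERENCE_SNR = 30.0


@dataclass(frozen=True)
class NoiseModel:
    """Per-measurement noise level.

    sigma is the standard deviation of a single DW measurement in signal
    units, assumed identical for all volumes and b-values (echo time is
    constant across shells, so thermal noise is too; T2 losses enter through
    the effect sizes instead).
    """

    sigma: float
    snr_b0: float | None = None

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.snr_b0 is not None and not self.snr_b0 > 0:
            raise ValueError("snr_b0 must be positive")

    @classmethod
    def from_snr(cls, snr_b0: float, b0_signal: float) -> "NoiseModel":
        """Derive σ from the b=0 SNR: σ = S(b=0) / SNR_b0."""
        if not (snr_b0 > 0 and b0_signal > 0):
            raise ValueError("snr_b0 and b0_signal must be positive")
        return cls(sigma=b0_signal / snr_b0, snr_b0=snr_b0)


def _counts(scheme) -> np.ndarray:
    """Per-shell counts from a ShellScheme or array-like (floats allowed)."""
    if isinstance(scheme, ShellScheme):
        n = np.asarray(scheme.counts, dtype=float)
    else:
        n = np.asarray(scheme, dtype=float).ravel()
    if n.size == 0 or np.any(n <= 0):
        raise ValueError("per-shell counts must all be positive")
    return n


def shell_variance(noise: NoiseModel, scheme) -> np.ndarray:
    """Variance of each shell's mean signal: σ²/n_s."""
    return noise.sigma**2 / _counts(scheme)


def coefficient_covariance(H: np.ndarray, noise: NoiseModel, scheme) -> np.ndarray:
    """Covariance of basis coefficients: Σ_w = σ² Hᵀ diag(1/n_s) H."""
    H = np.asarray(H, dtype=float)
    n = _counts(scheme)
    if H.shape[0] != n.size:
        raise ValueError(
            f"basis has {H.shape[0]} shells but scheme has {n.size}"
        )
    sigma_w = noise.sigma**2 * (H.T * (1.0 / n)) @ H
    return 0.5 * (sigma_w + sigma_w.T)  # enforce exact symmetry


def coefficient_cv(sigma_w: np.ndarray, eps) -> np.ndarray:
    """Per-component coefficient of variation sqrt(Σ_w(c,c))/ε_c.

    Components with ε_c = 0 are undetectable: their CV is +inf.  They stay in
    the returned vector; truncate the basis to exclude them from SSCV.
    """
    eps = np.asarray(eps, dtype=float)
    var = np.diag(np.asarray(sigma_w, dtype=float))
    with np.errstate(divide="ignore"):
        cv = np.where(eps > 0, np.sqrt(var) / np.where(eps > 0, eps, 1.0), np.inf)
    return cv


def sscv(H: np.ndarray, eps, noise: NoiseModel, scheme,
         n_components: int | None = None) -> float:
    """Sum of squared coefficients of variation over retained components."""
    eps = np.asarray(eps, dtype=float)
    H = np.asarray(H, dtype=float)
    if n_components is not None:
        H = H[:, :n_components]
        eps = eps[:n_components]
    if np.any(eps <= 0):
        raise ValueError(
            "zero effect size among retained components; truncate the basis"
        )
    n = _counts(scheme)
    # Σ_c (1/ε_c²) Σ_s H_sc²/n_s, evaluated without forming Σ_w
    per_shell = (H**2 / eps[None, :] ** 2).sum(axis=1)
    return float(noise.sigma**2 * (per_shell / n).sum())


def rescale_cnr(cnr_listed, snr_listed: float = CNR_REFERENCE_SNR,
                snr_actual: float = CNR_REFERENCE_SNR,
                n_total_actual: float = CNR_REFERENCE_N_TOTAL):
    """Rescale listed CNR values to other SNR / volume-count conditions.

    CNR tables are conventionally quoted at N_total = 100 volumes and a given
    b=0 SNR; CNR scales linearly with SNR and with the square root of the
    total number of volumes:

        CNR_actual = CNR_listed × (SNR_actual / SNR_listed)
                                × sqrt(N_total_actual / 100).
    """
    cnr_listed = np.asarray(cnr_listed, dtype=float)
    if np.any(cnr_listed <= 0) or snr_listed <= 0 or snr_actual <= 0 \
            or n_total_actual <= 0:
        raise ValueError("all CNR-rescaling arguments must be positive")
    out = cnr_listed * (snr_actual / snr_listed) * np.sqrt(
        n_total_actual / CNR_REFERENCE_N_TOTAL
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class SensitivityReport:
    """Noise-propagation summary for one candidate protocol."""

    sigma_w: np.ndarray
    cv: np.ndarray
    cnr: np.ndarray
    sscv: float
    scheme: ShellScheme
    shell_variances: np.ndarray
    effect_sizes: np.ndarray
    sigma: float
    pooled: bool | None = None  # whether ε came from pooled-subject data
    meta: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "bvalues": list(self.scheme.bvalues),
            "counts": list(self.scheme.counts),
            "sigma": self.sigma,
            "shell_variances": self.shell_variances.tolist(),
            "effect_sizes": self.effect_sizes.tolist(),
            "sigma_w": self.sigma_w.tolist(),
            "cv": [v if np.isfinite(v) else None for v in self.cv],
            "cnr": [v if np.isfinite(v) else None for v in self.cnr],
            "sscv": self.sscv if np.isfinite(self.sscv) else None,
            "pooled": self.pooled,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def sensitivity_report(basis, noise: NoiseModel, scheme,
                       n_components: int | None = None,
                       pooled: bool | None = None) -> SensitivityReport:
    """Full noise-propagation report for a basis under a candidate scheme.

    By default all components of the compact SVD are retained (N_c = N_s);
    pass `n_components` to truncate.
    """
    H = basis.H
    eps = basis.effect_sizes
    if n_components is not None:
        H = H[:, :n_components]
        eps = eps[:n_components]
    sigma_w = coefficient_covariance(H, noise, scheme)
    cv = coefficient_cv(sigma_w, eps)
    with np.errstate(divide="ignore"):
        cnr = np.where(cv > 0, 1.0 / cv, np.inf)
    finite = np.isfinite(cv)
    total = float(np.sum(cv[finite] ** 2)) if finite.any() else np.inf
    sch = scheme if isinstance(scheme, ShellScheme) else ShellScheme(
        tuple(basis.bvalues), tuple(int(c) for c in np.asarray(scheme))
    )
    return SensitivityReport(
        sigma_w=sigma_w, cv=cv, cnr=cnr, sscv=total, scheme=sch,
        shell_variances=shell_variance(noise, sch),
        effect_sizes=np.asarray(eps, dtype=float), sigma=noise.sigma,
        pooled=pooled,
    )
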