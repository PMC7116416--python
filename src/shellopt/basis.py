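"""Data-driven signal basis over b-values via the compact SVD.

The b-value dependence of the shell-mean signal has no natural analytic
basis, so we let the data choose one: the compact singular value
decomposition of the shells × voxels matrix ``D = U S Vᵀ`` yields an
orthonormal basis ``H = U`` over shells and per-voxel weights ``W = S Vᵀ``
with ``D = H W``.  The singular values give the typical per-component effect
size across the brain,

    ε_c = S_c / sqrt(N_v),

equal to the root-mean-square of row *c* of ``W``.  Components come out in
order of decreasing effect size; for brain-like data the first component is
the mean signal decay and higher components are increasingly rapid
oscillations in b.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import MeanSignalMatrix

__all__ = ["SignalBasis", "decompose", "effect_sizes", "truncate"]


@dataclass(frozen=True)
class SignalBasis:
    """Orthonormal shell basis with weights and effect sizes.

    Attributes
    ----------
    H : ndarray, (N_s, N_c)
        Orthonormal basis over shells (columns are components).
    singular_values : ndarray, (N_c,)
        Non-increasing, ≥ 0.
    W : ndarray, (N_c, N_v)
        Per-voxel weights; ``D ≈ H @ W``.
    effect_sizes : ndarray, (N_c,)
        ``singular_values / sqrt(N_v)`` — RMS weight per component.
    n_voxels : int
    bvalues : tuple
        Shell b-values the rows of ``H`` correspond to.
    """

    H: np.ndarray
    singular_values: np.ndarray
    W: np.ndarray
    effect_sizes: np.ndarray
    n_voxels: int
    bvalues: tuple

    @property
    def n_shells(self) -> int:
        return self.H.shape[0]

    @property
    def n_components(self) -> int:
        return self.H.shape[1]

    def reconstruct(self) -> np.ndarray:
        return self.H @ self.W

    def to_csv(self, path, metadata_path=None) -> None:
        """Export the basis as CSV (rows = shells, columns = components),
        with JSON metadata (b-values, N_v, effect sizes, sign convention)."""
        import json

        import pandas as pd

        df = pd.DataFrame(
            self.H, columns=[f"component_{c + 1}"
                             for c in range(self.n_components)])
        df.insert(0, "bvalue", list(self.bvalues))
        df.to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump({
                    "bvalues": list(self.bvalues),
                    "n_voxels": self.n_voxels,
                    "singular_values": self.singular_values.tolist(),
                    "effect_sizes": self.effect_sizes.tolist(),
                    "sign_convention":
                        "largest-magnitude entry of each column positive",
                }, fh, indent=2, sort_keys=True)


def _fix_signs(U: np.ndarray, W: np.ndarray):
    """Resolve the SVD sign ambiguity deterministically.

    Each basis column is flipped so that its largest-magnitude entry is
    positive (first such entry on exact ties); weights flip accordingly.
    """
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            W[j, :] = -W[j, :]
    return U, W


def decompose(data: MeanSignalMatrix | np.ndarray,
              bvalues=None, normalise_b0: bool = False) -> SignalBasis:
    """Compact SVD of the mean-signal matrix.

    Parameters
    ----------
    data : MeanSignalMatrix or ndarray
        Shells × voxels matrix; an ndarray requires `bvalues`.
    normalise_b0 : bool
        Divide each voxel column by its first-shell (b=0) value before
        decomposing.  Off by default: the basis is taken over raw means.

    Returns
    -------
    SignalBasis
    """
    if isinstance(data, MeanSignalMatrix):
        D = data.D
        bvalues = tuple(data.scheme.bvalues)
    else:
        D = np.atleast_2d(np.asarray(data, dtype=float))
        bvalues = tuple(bvalues) if bvalues is not None else tuple(range(D.shape[0]))
    if not np.all(np.isfinite(D)):
        raise ValueError("mean-signal matrix contains non-finite values")
    n_s, n_v = D.shape
    if n_s > n_v:
        raise ValueError(
            f"need at least as many voxels as shells (got {n_s} shells, "
            f"{n_v} voxels)"
        )
    if normalise_b0:
        b0 = D[0]
        if np.any(b0 <= 0):
            raise ValueError("b=0 normalisation requires positive b=0 signal")
        D = D / b0

    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    W = S[:, None] * Vt
    U, W = _fix_signs(U.copy(), W)
    eps = S / np.sqrt(n_v)
    return SignalBasis(H=U, singular_values=S, W=W, effect_sizes=eps,
                       n_voxels=n_v, bvalues=bvalues)


def effect_sizes(basis: SignalBasis) -> np.ndarray:
    """Per-component effect size ε_c = S_c / sqrt(N_v).

    Identical to the RMS of the corresponding weight row, which is asserted
    here as a consistency check of the decomposition.
    """
    eps = basis.singular_values / np.sqrt(basis.n_voxels)
    rms = np.sqrt(np.mean(basis.W**2, axis=1))
    if not np.allclose(eps, rms, rtol=1e-8, atol=1e-12 * max(1.0, eps.max(initial=0.0))):
        raise ValueError("inconsistent basis: effect sizes do not match RMS weights")
    return eps


def truncate(basis: SignalBasis, n_components: int) -> SignalBasis:
    """Keep the leading `n_components` components of a basis.

    The squared Frobenius reconstruction error equals the sum of squared
    discarded singular values (Eckart–Young).
    """
    if not 1 <= n_components <= basis.n_components:
        raise ValueError(
            f"n_components must be in [1, {basis.n_components}], got {n_components}"
        )
    return replace(
        basis,
        H=basis.H[:, :n_components],
        singular_values=basis.singular_values[:n_components],
        W=basis.W[:n_components, :],
        effect_sizes=basis.effect_sizes[:n_components],
    )
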