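"""Reading DWI data, shell grouping, and the per-shell mean-signal matrix.

The quantity everything downstream consumes is the ``N_s × N_v`` matrix ``D``
of orientationally averaged diffusion-weighted signal: one row per b-value
shell, one column per brain voxel.  Provided the angular sampling of each
shell is uniform and dense enough, this shell mean is rotationally invariant
and independent of the local fibre arrangement, which is what makes it a
useful target for b-value-domain protocol optimisation.

Conventions
-----------
* b-values and gradient tables follow the FSL text dialect: one
  whitespace-separated row of b-values, three rows of direction components.
* Masks are NIfTI volumes on the same grid as the data; nonzero = included.
* Voxels enter ``D`` in row-major (C) scan order of the mask, so per-voxel
  results can be re-embedded into the original volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "DWIDataset",
    "ShellScheme",
    "MeanSignalMatrix",
    "read_dwi",
    "group_shells",
    "shell_mean_signal",
    "pool_subjects",
]

DEFAULT_SHELL_TOLERANCE = 50.0  # s/mm²


class DataError(ValueError):
    """Raised for structurally invalid or inconsistent input data."""


@dataclass(frozen=True)
class ShellScheme:
    """A multi-shell scheme: ordered b-values with per-shell volume counts.

    Parameters
    ----------
    bvalues : tuple of float
        Nominal shell b-values in s/mm², strictly increasing.  b = 0 is an
        ordinary shell.
    counts : tuple of int
        Number of volumes (directions) per shell, each ≥ 1.
    """

    bvalues: tuple
    counts: tuple

    def __post_init__(self):
        b = tuple(float(v) for v in self.bvalues)
        n = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "counts", n)
        if len(b) != len(n):
            raise DataError("bvalues and counts must have equal length")
        if len(b) == 0:
            raise DataError("scheme must contain at least one shell")
        if any(v < 0 for v in b):
            raise DataError("b-values must be non-negative")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise DataError("shell b-values must be strictly increasing")
        if any(c < 1 for c in n):
            raise DataError("per-shell counts must be >= 1")

    @property
    def n_shells(self) -> int:
        return len(self.bvalues)

    @property
    def n_total(self) -> int:
        return int(sum(self.counts))


@dataclass
class DWIDataset:
    """A 4-D DWI acquisition with gradient table and brain mask."""

    volumes: np.ndarray  # (x, y, z, n_volumes)
    bvals: np.ndarray  # (n_volumes,), s/mm²
    bvecs: np.ndarray  # (3, n_volumes), unit columns (zero allowed at b=0)
    mask: np.ndarray  # (x, y, z) boolean
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.volumes.ndim != 4:
            raise DataError("volumes must be a 4-D array")
        n = self.volumes.shape[3]
        if self.bvals.shape[0] != n:
            raise DataError(
                f"bval count mismatch: {self.bvals.shape[0]} b-values for "
                f"{n} volumes"
            )
        if self.bvecs.shape != (3, n):
            raise DataError(
                f"bvec count mismatch: expected shape (3, {n}), got "
                f"{self.bvecs.shape}"
            )
        if self.mask.shape != self.volumes.shape[:3]:
            raise DataError("mask grid does not match volume grid")
        if np.any(self.bvals < 0):
            raise DataError("b-values must be non-negative")
        if not np.all(np.isfinite(self.volumes)):
            raise DataError("non-finite voxel values in image data")
        norms = np.linalg.norm(self.bvecs, axis=0)
        nonzero = norms > 1e-8
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-3):
            raise DataError("nonzero gradient directions must have unit norm")

    @property
    def n_volumes(self) -> int:
        return self.volumes.shape[3]


@dataclass
class MeanSignalMatrix:
    """Per-shell, per-voxel mean DW signal ``D`` (shells × voxels)."""

    D: np.ndarray
    scheme: ShellScheme
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.D = np.atleast_2d(np.asarray(self.D, dtype=float))
        if self.D.shape[0] != self.scheme.n_shells:
            raise DataError(
                f"matrix has {self.D.shape[0]} rows but scheme has "
                f"{self.scheme.n_shells} shells"
            )
        if not np.all(np.isfinite(self.D)):
            raise DataError("mean-signal matrix contains non-finite values")
        if np.any(self.D < 0):
            raise DataError("mean-signal matrix contains negative values")
        if not self.provenance:
            self.provenance = [{"subject": "unknown", "n_voxels": self.n_voxels}]

    @property
    def n_shells(self) -> int:
        return self.D.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.D.shape[1]

    @property
    def bvalues(self) -> np.ndarray:
        return np.asarray(self.scheme.bvalues)

    # -- serialisation ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write shells × voxels CSV; first columns are bvalue and count."""
        df = pd.DataFrame(self.D, columns=[f"v{i}" for i in range(self.n_voxels)])
        df.insert(0, "count", list(self.scheme.counts))
        df.insert(0, "bvalue", list(self.scheme.bvalues))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance=None) -> "MeanSignalMatrix":
        df = pd.read_csv(path)
        if "bvalue" not in df.columns or "count" not in df.columns:
            raise DataError(f"{path}: missing 'bvalue'/'count' columns")
        scheme = ShellScheme(tuple(df["bvalue"]), tuple(df["count"].astype(int)))
        D = df.drop(columns=["bvalue", "count"]).to_numpy(dtype=float)
        return cls(D=D, scheme=scheme, provenance=provenance or [])


def read_dwi(image_path, bval_path, bvec_path, mask_path) -> DWIDataset:
    """Load a NIfTI DWI series with FSL-style bvals/bvecs and a brain mask.

    Raises
    ------
    DataError
        If the number of b-values or directions does not match the number of
        volumes, the mask grid differs, or voxel values are non-finite; the
        message names the offending file.
    """
    img = nib.load(str(image_path))
    volumes = np.asarray(img.dataobj, dtype=float)
    if volumes.ndim != 4:
        raise DataError(f"{image_path}: expected a 4-D image")
    n = volumes.shape[3]

    bvals = np.loadtxt(str(bval_path), dtype=float).ravel()
    if bvals.size != n:
        raise DataError(
            f"{bval_path}: bval count mismatch ({bvals.size} b-values for "
            f"{n} volumes)"
        )
    bvecs = np.atleast_2d(np.loadtxt(str(bvec_path), dtype=float))
    if bvecs.shape == (n, 3):  # tolerate transposed tables
        bvecs = bvecs.T
    if bvecs.shape != (3, n):
        raise DataError(
            f"{bvec_path}: bvec count mismatch (expected 3 rows x {n} "
            f"columns, got {bvecs.shape})"
        )

    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != volumes.shape[:3]:
        raise DataError(f"{mask_path}: mask grid does not match image grid")
    if not np.all(np.isfinite(volumes)):
        raise DataError(f"{image_path}: non-finite voxel values")

    return DWIDataset(volumes=volumes, bvals=bvals, bvecs=bvecs, mask=mask,
                      affine=np.asarray(img.affine))


def group_shells(bvals, tolerance: float = DEFAULT_SHELL_TOLERANCE):
    """Cluster per-volume b-values into shells.

    Values within `tolerance` (s/mm²) of each other merge into a shell; the
    shell's nominal b-value is the mean of its members.  The grouping is
    rejected as ambiguous when merging chains values that end up farther than
    `tolerance` apart, or when two shell centres lie closer than
    ``2 × tolerance``.

    Returns
    -------
    scheme : ShellScheme
    shell_index : ndarray of int
        Per-volume shell assignment into ``scheme.bvalues``.
    """
    if tolerance <= 0:
        raise DataError("tolerance must be positive")
    bvals = np.asarray(bvals, dtype=float).ravel()
    if bvals.size == 0:
        raise DataError("no b-values supplied")
    if np.any(bvals < 0):
        raise DataError("b-values must be non-negative")

    order = np.argsort(bvals, kind="stable")
    sorted_b = bvals[order]
    # connected components of the "within tolerance" relation
    breaks = np.nonzero(np.diff(sorted_b) > tolerance)[0]
    bounds = np.concatenate([[0], breaks + 1, [bvals.size]])
    centres, labels = [], np.empty(bvals.size, dtype=int)
    for k in range(len(bounds) - 1):
        members = sorted_b[bounds[k]:bounds[k + 1]]
        if members[-1] - members[0] > tolerance:
            raise DataError(
                "ambiguous shell structure: b-values "
                f"{members[0]:g}..{members[-1]:g} chain together beyond the "
                f"tolerance of {tolerance:g}"
            )
        centres.append(float(members.mean()))
        labels[order[bounds[k]:bounds[k + 1]]] = k
    centres = np.asarray(centres)
    if np.any(np.diff(centres) < 2 * tolerance):
        raise DataError(
            "ambiguous shell structure: shell centres closer than "
            f"2 x tolerance ({2 * tolerance:g} s/mm^2)"
        )
    counts = np.bincount(labels, minlength=len(centres))
    scheme = ShellScheme(tuple(centres), tuple(int(c) for c in counts))
    return scheme, labels


def shell_mean_signal(dataset: DWIDataset, scheme: ShellScheme | None = None,
                      tolerance: float = DEFAULT_SHELL_TOLERANCE
                      ) -> MeanSignalMatrix:
    """Average DW volumes per shell within the brain mask.

    Entry ``(s, v)`` is the arithmetic mean over the volumes of shell *s* at
    masked voxel *v*; voxels are taken in row-major scan order of the mask.
    """
    if scheme is None:
        scheme, labels = group_shells(dataset.bvals, tolerance)
    else:
        centres = np.asarray(scheme.bvalues)
        dist = np.abs(dataset.bvals[:, None] - centres[None, :])
        labels = np.argmin(dist, axis=1)
        if np.any(dist[np.arange(dataset.n_volumes), labels] > tolerance):
            raise DataError("dataset b-values do not match the given scheme")
    flat_mask = dataset.mask.reshape(-1)
    if not flat_mask.any():
        raise DataError("empty brain mask")
    signals = dataset.volumes.reshape(-1, dataset.n_volumes)[flat_mask]
    D = np.empty((scheme.n_shells, signals.shape[0]))
    for s in range(scheme.n_shells):
        D[s] = signals[:, labels == s].mean(axis=1)
    return MeanSignalMatrix(D=np.clip(D, 0.0, None), scheme=scheme,
                            provenance=[{"subject": "subject-0",
                                         "n_voxels": signals.shape[0]}])


def pool_subjects(matrices) -> MeanSignalMatrix:
    """Concatenate per-subject mean-signal matrices along the voxel axis.

    All inputs must share the same shell scheme; provenance records the
    concatenation order so voxel columns remain attributable.
    """
    matrices = list(matrices)
    if not matrices:
        raise DataError("no matrices to pool")
    ref = matrices[0].scheme
    for m in matrices[1:]:
        if m.scheme.bvalues != ref.bvalues or m.scheme.counts != ref.counts:
            raise DataError("mismatched shell schemes across subjects")
    D = np.hstack([m.D for m in matrices])
    provenance = []
    for i, m in enumerate(matrices):
        for entry in m.provenance:
            entry = dict(entry)
            entry.setdefault("subject", f"subject-{i}")
            provenance.append(entry)
    return MeanSignalMatrix(D=D, scheme=ref, provenance=provenance)
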