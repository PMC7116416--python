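"""Synthetic multi-shell phantoms with known ground truth.

Every analysis step in this package can be exercised without any scanner
data: phantoms mix isotropic and axially symmetric tensor compartments with
spatially varying volume fractions, and produce either the shell-mean
matrix directly (for the b-value pipeline) or a direction-resolved 4-D
dataset (for the angular pipeline).  The per-voxel noiseless signal is

    S(b) = Σ_i f_i · φ_i(b),

with φ_i(b) = exp(−b D_i) for an isotropic compartment and the exact
orientation average of exp(−b gᵀ D g) for an axially symmetric tensor.
Noise is added to each of the n_s simulated measurements of a shell before
averaging, so the shell-mean variance σ²/n_s that the sensitivity analysis
assumes holds by construction.  All generators are deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from .angular import generate_directions
from .io import DWIDataset, MeanSignalMatrix, ShellScheme

__all__ = [
    "Compartment",
    "PhantomConfig",
    "make_shell_means",
    "make_dwi",
    "neonatal_like_preset",
    "write_phantom",
]


@dataclass(frozen=True)
class Compartment:
    """One diffusion compartment of the phantom.

    Isotropic: give `diffusivity` (mm²/s).  Anisotropic: give `axial` and
    `radial` diffusivities plus a unit fibre `orientation`.  `fraction_map`
    optionally fixes the per-voxel volume fraction; otherwise a smooth
    random field is generated from the phantom seed.
    """

    name: str
    diffusivity: float | None = None
    axial: float | None = None
    radial: float | None = None
    orientation: tuple | None = None
    fraction_map: np.ndarray | None = None

    def __post_init__(self):
        iso = self.diffusivity is not None
        aniso = self.axial is not None and self.radial is not None
        if iso == aniso:
            raise ValueError(
                f"compartment {self.name!r}: give either diffusivity or "
                f"(axial, radial)"
            )
        for v in (self.diffusivity, self.axial, self.radial):
            if v is not None and v <= 0:
                raise ValueError(
                    f"compartment {self.name!r}: diffusivities must be positive"
                )
        if aniso and self.radial > self.axial:
            raise ValueError(
                f"compartment {self.name!r}: axial must be >= radial"
            )
        if aniso and self.orientation is None:
            object.__setattr__(self, "orientation", (0.0, 0.0, 1.0))

    @property
    def is_anisotropic(self) -> bool:
        return self.axial is not None

    def mean_diffusivity(self) -> float:
        if self.is_anisotropic:
            return (self.axial + 2 * self.radial) / 3.0
        return self.diffusivity

    def sphere_mean_signal(self, bvals) -> np.ndarray:
        """Orientation-averaged signal at the given b-values (S(0) = 1)."""
        b = np.asarray(bvals, dtype=float)
        if not self.is_anisotropic:
            return np.exp(-b * self.diffusivity)
        alpha = b * (self.axial - self.radial)
        out = np.empty_like(b)
        small = np.abs(alpha) < 1e-12
        out[small] = np.exp(-b[small] * self.mean_diffusivity())
        a = alpha[~small]
        out[~small] = np.exp(-b[~small] * self.radial) * \
            (np.sqrt(np.pi) / 2.0) * erf(np.sqrt(a)) / np.sqrt(a)
        return out

    def directional_signal(self, bvals, bvecs) -> np.ndarray:
        """Signal per volume for directions `bvecs` (3 × n)."""
        b = np.asarray(bvals, dtype=float)
        if not self.is_anisotropic:
            return np.exp(-b * self.diffusivity)
        u = np.asarray(self.orientation, dtype=float)
        u = u / np.linalg.norm(u)
        cos2 = (np.asarray(bvecs).T @ u) ** 2
        adc = self.radial + (self.axial - self.radial) * cos2
        return np.exp(-b * adc)


@dataclass
class PhantomConfig:
    """Phantom recipe: grid, compartments, scheme, noise, seed."""

    shape: tuple
    compartments: list
    bvalues: tuple
    counts: tuple
    noise: str | None = "gaussian"  # gaussian | rician | None
    sigma: float = 0.0
    s0: float = 1.0
    seed: int = 0
    smoothness: float = 2.0  # voxels, for generated fraction fields
    sharpness: float = 6.0   # softmax temperature of the regional mixing
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.noise not in ("gaussian", "rician", None):
            raise ValueError("noise must be 'gaussian', 'rician' or None")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if len(self.bvalues) != len(self.counts):
            raise ValueError("bvalues and counts must have equal length")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def scheme(self) -> ShellScheme:
        return ShellScheme(tuple(self.bvalues), tuple(self.counts))


def _fraction_maps(config: PhantomConfig, rng) -> np.ndarray:
    """Per-compartment volume fractions, (k, n_voxels), summing to ≤ 1.

    Explicit fraction maps are honoured; missing ones come from smoothed
    random fields passed through a softmax over the unassigned budget, which
    gives anatomy-like smooth regional structure.
    """
    k = len(config.compartments)
    fractions = np.zeros((k, config.n_voxels))
    explicit = np.zeros(config.n_voxels)
    free = []
    for i, comp in enumerate(config.compartments):
        if comp.fraction_map is not None:
            fm = np.asarray(comp.fraction_map, dtype=float).reshape(-1)
            if fm.size != config.n_voxels:
                raise ValueError(
                    f"compartment {comp.name!r}: fraction map does not "
                    f"match grid"
                )
            if np.any(fm < 0) or np.any(fm > 1):
                raise ValueError("fractions must lie in [0, 1]")
            fractions[i] = fm
            explicit += fm
        else:
            free.append(i)
    if np.any(explicit > 1 + 1e-9):
        raise ValueError("explicit fractions exceed 1 in some voxels")
    if free:
        fields = np.stack([
            gaussian_filter(rng.normal(size=config.shape), config.smoothness)
            for _ in free
        ])
        fields = fields.reshape(len(free), -1)
        z = np.exp(config.sharpness * (fields - fields.max(axis=0, keepdims=True)))
        soft = z / z.sum(axis=0, keepdims=True)
        budget = np.clip(1.0 - explicit, 0.0, 1.0)
        for j, i in enumerate(free):
            fractions[i] = soft[j] * budget
    return fractions


def _effective_rank(config: PhantomConfig, fractions: np.ndarray) -> int:
    sigs = set()
    for comp, f in zip(config.compartments, fractions):
        if f.max() > 0:
            if comp.is_anisotropic:
                sigs.add(("aniso", round(comp.axial, 12), round(comp.radial, 12)))
            else:
                sigs.add(("iso", round(comp.diffusivity, 12)))
    return len(sigs)


def _add_noise_and_average(clean, counts, config: PhantomConfig, rng):
    """Average n_s noisy replicates of each shell's clean signal."""
    D = np.empty_like(clean)
    for s, n_s in enumerate(counts):
        if config.sigma == 0 or config.noise is None:
            D[s] = clean[s]
            continue
        size = (int(n_s),) + clean[s].shape
        if config.noise == "gaussian":
            draws = clean[s] + rng.normal(0.0, config.sigma, size=size)
        else:  # rician: magnitude of a complex Gaussian around the signal
            real = clean[s] + rng.normal(0.0, config.sigma, size=size)
            imag = rng.normal(0.0, config.sigma, size=size)
            draws = np.hypot(real, imag)
        D[s] = draws.mean(axis=0)
    return D


def make_shell_means(config: PhantomConfig):
    """Simulate the shells × voxels mean-signal matrix with ground truth.

    Returns
    -------
    data : MeanSignalMatrix
    truth : dict
        Per-compartment fractions and diffusivities, the noiseless matrix,
        and the effective rank (number of distinct compartment signatures).
    """
    rng = np.random.default_rng(config.seed)
    fractions = _fraction_maps(config, rng)
    b = np.asarray(config.bvalues, dtype=float)
    clean = np.zeros((b.size, config.n_voxels))
    for comp, f in zip(config.compartments, fractions):
        clean += f[None, :] * comp.sphere_mean_signal(b)[:, None]
    clean *= config.s0
    D = np.clip(_add_noise_and_average(clean, config.counts, config, rng),
                0.0, None)
    data = MeanSignalMatrix(D=D, scheme=config.scheme(),
                            provenance=[{"subject": "phantom",
                                         "n_voxels": config.n_voxels,
                                         "seed": config.seed}])
    truth = {
        "fractions": fractions,
        "diffusivities": [
            {"name": c.name,
             "mean_diffusivity": c.mean_diffusivity(),
             "axial": c.axial, "radial": c.radial,
             "isotropic": not c.is_anisotropic}
            for c in config.compartments
        ],
        "noiseless": clean,
        "effective_rank": _effective_rank(config, fractions),
        "sigma": config.sigma,
    }
    return data, truth


def make_dwi(config: PhantomConfig):
    """Simulate a direction-resolved 4-D dataset with single-fibre labels.

    Directions per shell come from the electrostatic-repulsion generator
    (b = 0 shells get zero vectors).  Labels mark voxels whose anisotropic
    signal is carried by a single compartment with fraction ≥ 0.95.
    """
    rng = np.random.default_rng(config.seed)
    fractions = _fraction_maps(config, rng)

    bvals_list, bvecs_list = [], []
    for s, (b, n_s) in enumerate(zip(config.bvalues, config.counts)):
        if b == 0:
            vecs = np.zeros((int(n_s), 3))
        else:
            vecs = generate_directions(int(n_s), seed=config.seed + s).vectors
        bvals_list.append(np.full(int(n_s), float(b)))
        bvecs_list.append(vecs)
    bvals = np.concatenate(bvals_list)
    bvecs = np.vstack(bvecs_list).T

    clean = np.zeros((config.n_voxels, bvals.size))
    for comp, f in zip(config.compartments, fractions):
        clean += f[:, None] * comp.directional_signal(bvals, bvecs)[None, :]
    clean *= config.s0
    if config.sigma > 0 and config.noise is not None:
        if config.noise == "gaussian":
            noisy = clean + rng.normal(0.0, config.sigma, size=clean.shape)
        else:
            noisy = np.hypot(
                clean + rng.normal(0.0, config.sigma, size=clean.shape),
                rng.normal(0.0, config.sigma, size=clean.shape))
        clean = noisy
    volumes = np.clip(clean, 0.0, None).reshape(config.shape + (bvals.size,))

    aniso_fracs = np.stack([
        f for comp, f in zip(config.compartments, fractions)
        if comp.is_anisotropic
    ]) if any(c.is_anisotropic for c in config.compartments) else \
        np.zeros((0, config.n_voxels))
    if aniso_fracs.shape[0]:
        dominant = aniso_fracs.max(axis=0)
        labels = (dominant >= 0.95).reshape(config.shape)
    else:
        labels = np.zeros(config.shape, dtype=bool)

    dataset = DWIDataset(volumes=volumes, bvals=bvals, bvecs=bvecs,
                         mask=np.ones(config.shape, dtype=bool))
    return dataset, {"single_fibre": labels, "fractions": fractions}


def neonatal_like_preset(seed: int = 0) -> PhantomConfig:
    """Phantom emulating neonatal-brain shell-mean data.

    Four isotropic compartments spanning mean diffusivities 1.0–1.8 ×
    10⁻³ mm²/s (neonatal tissue is faster-diffusing and far less
    anisotropic than adult), smooth regional fraction maps, the pilot
    acquisition grid b = 0/500/1000/2000/3000/4000 s/mm² with 5 b = 0 and
    50 directions per shell, and Gaussian noise at b = 0 SNR 30.
    """
    return PhantomConfig(
        shape=(16, 16, 4),
        compartments=[
            Compartment("fast-iso", diffusivity=1.8e-3),
            Compartment("mid-iso-a", diffusivity=1.5e-3),
            Compartment("mid-iso-b", diffusivity=1.25e-3),
            Compartment("slow-iso", diffusivity=1.0e-3),
        ],
        bvalues=(0.0, 500.0, 1000.0, 2000.0, 3000.0, 4000.0),
        counts=(5, 50, 50, 50, 50, 50),
        noise="gaussian",
        sigma=1.0 / 30.0,
        s0=1.0,
        seed=seed,
        meta={"preset": "neonatal-like", "version": 1},
    )


def fibre_phantom_preset(seed: int = 0) -> PhantomConfig:
    """Direction-resolved phantom for angular-content analysis.

    Half the voxels hold a coherent single-fibre tensor population (neonatal
    anisotropy level), the rest isotropic tissue; three shells with enough
    directions to fit order-8 spherical harmonics on the top shell.
    """
    shape = (8, 8, 2)
    nv = int(np.prod(shape))
    f_fibre = np.zeros(nv)
    f_fibre[: nv // 2] = 1.0
    f_iso = 1.0 - f_fibre
    return PhantomConfig(
        shape=shape,
        compartments=[
            Compartment("fibre", axial=1.9e-3, radial=0.7e-3,
                        orientation=(1.0, 0.0, 0.0),
                        fraction_map=f_fibre.reshape(shape)),
            Compartment("iso", diffusivity=1.4e-3,
                        fraction_map=f_iso.reshape(shape)),
        ],
        bvalues=(0.0, 1000.0, 2500.0),
        counts=(5, 50, 50),
        noise="gaussian",
        sigma=1.0 / 60.0,
        s0=1.0,
        seed=seed,
        meta={"preset": "fibre", "version": 1},
    )


def write_phantom(config: PhantomConfig, outdir) -> dict:
    """Write a DWI phantom to disk (NIfTI + bvals/bvecs + mask + truth JSON).

    Returns the paths written.
    """
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    dataset, truth = make_dwi(config)
    paths = {
        "image": os.path.join(outdir, "dwi.nii.gz"),
        "bvals": os.path.join(outdir, "dwi.bval"),
        "bvecs": os.path.join(outdir, "dwi.bvec"),
        "mask": os.path.join(outdir, "mask.nii.gz"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(dataset.volumes.astype(np.float32), affine),
             paths["image"])
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), affine),
             paths["mask"])
    np.savetxt(paths["bvals"], dataset.bvals[None, :], fmt="%.1f")
    np.savetxt(paths["bvecs"], dataset.bvecs, fmt="%.8f")
    with open(paths["truth"], "w") as fh:
        json.dump({
            "single_fibre_fraction": float(truth["single_fibre"].mean()),
            "compartments": [c.name for c in config.compartments],
            "seed": config.seed,
            "sigma": config.sigma,
        }, fh, indent=2, sort_keys=True)
    return paths
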