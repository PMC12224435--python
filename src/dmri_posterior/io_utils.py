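"""File I/O, run configuration, seeding and fixture generation.

Real-data mode reads a 4D NIfTI volume with FSL-style ``bvals``/``bvecs``
text files (and an optional brain mask); per-voxel signals are normalized
by the mean b=0 volume so they enter the pipeline as attenuations.  Outputs
(fiber-count labels, parameter means/stds, measure maps) are written back
as NIfTI volumes with the input geometry.  Synthetic mode generates
labeled voxel datasets from the prior for training, testing and demos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import forward_model as fm
from .forward_model import AcquisitionScheme, PriorSpec, hcp_like_scheme
from .odf_maps import MapRenderer

__all__ = [
    "RunConfig",
    "VoxelDataset",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_dmri",
    "save_maps",
    "make_fixture",
    "spawn_seeds",
]


def spawn_seeds(master_seed: int, count: int) -> list:
    """Derive independent child seeds (< 2³¹) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(count)]


# --------------------------------------------------------------------------
# gradient tables
# --------------------------------------------------------------------------

def read_bvals_bvecs(bval_path, bvec_path) -> tuple:
    """FSL whitespace-separated text: bvals 1×N, bvecs 3×N."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim != 2:
        raise ValueError("bvecs must be a 2D table")
    if bvecs.shape[0] != 3 and bvecs.shape[1] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (3, bvals.size):
        raise ValueError(
            f"bvec columns ({bvecs.shape}) do not match {bvals.size} bvals")
    return bvals, bvecs


def write_bvals_bvecs(scheme: AcquisitionScheme, bval_path, bvec_path) -> None:
    bvals, bvecs = scheme.to_bvals_bvecs()
    np.savetxt(bval_path, bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, bvecs, fmt="%.8f")


# --------------------------------------------------------------------------
# NIfTI ingestion / output
# --------------------------------------------------------------------------

def load_dmri(nifti_path, bval_path, bvec_path, mask_path=None,
              shell_tolerance: float = 100.0) -> dict:
    """Load a 4D dMRI volume into normalized per-voxel signals.

    Returns a dict with the scheme (b=0 entries dropped after
    normalization), an (M, N) signal array for the M in-mask voxels, their
    integer coordinates, and the reference NIfTI image for geometry.
    """
    import nibabel as nib

    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D dMRI volume")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.size != data.shape[3]:
        raise ValueError(
            f"{bvals.size} gradient entries for {data.shape[3]} volumes")
    scheme_full = AcquisitionScheme.from_bvals_bvecs(
        bvals, bvecs, shell_tolerance=shell_tolerance)
    b0_mask = scheme_full.shell_ids < 0
    if not np.any(b0_mask):
        raise ValueError("no b=0 volume found for normalization")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise ValueError("mask geometry does not match the volume")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    coords = np.argwhere(mask)
    vox = data[mask]  # (M, N)
    b0 = vox[:, b0_mask].mean(axis=1)
    valid = b0 > 0
    signals = np.zeros((vox.shape[0], int((~b0_mask).sum())))
    signals[valid] = vox[valid][:, ~b0_mask] / b0[valid, None]
    dwi_scheme = AcquisitionScheme(
        directions=scheme_full.directions[~b0_mask],
        bvalues=scheme_full.bvalues[~b0_mask],
        shell_ids=scheme_full.shell_ids[~b0_mask])
    return {"scheme": dwi_scheme, "signals": signals, "coords": coords,
            "mask": mask, "reference": img, "valid": valid}


def save_maps(values_by_name: dict, coords: np.ndarray, reference,
              out_dir, prefix: str = "") -> list:
    """Write per-voxel scalars as NIfTI volumes (masked-out voxels = NaN).

    ``values_by_name`` maps quantity name → (M,) array aligned with
    ``coords``; geometry (affine, header) is copied from the reference.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shape = reference.shape[:3]
    written = []
    for name, vals in values_by_name.items():
        vals = np.asarray(vals, dtype=np.float32)
        if vals.shape[0] != coords.shape[0]:
            raise ValueError(f"'{name}' length does not match voxel count")
        vol = np.full(shape, np.nan, dtype=np.float32)
        vol[coords[:, 0], coords[:, 1], coords[:, 2]] = vals
        img = nib.Nifti1Image(vol, reference.affine, reference.header)
        path = out_dir / f"{prefix}{name}.nii.gz"
        nib.save(img, str(path))
        written.append(path)
    return written


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Serializable pipeline configuration with one master seed.

    Every stochastic stage receives a child seed spawned from
    ``master_seed``, so a desk-scale run is reproducible end to end.
    """

    mode: str = "simulate"
    scale: str = "desk"  # "desk" or "full"
    master_seed: int = 0
    prior: dict = field(default_factory=dict)  # PriorSpec overrides
    n_dirs_per_shell: int = 90
    shells: tuple = (1000.0, 2000.0, 3000.0)
    sh_order: int = 8
    sh_reg: float = 6e-3
    sharpen: bool = True
    noise_sigma: float = 0.04
    classifier_train_per_class: int = 1000
    classifier_epochs: int = 12
    posterior_train_size: int = 20_000
    posterior_epochs: int = 15
    output_dir: str = "outputs"

    def prior_spec(self) -> PriorSpec:
        return dataclasses.replace(PriorSpec(), **self.prior)

    def scheme(self) -> AcquisitionScheme:
        return hcp_like_scheme(self.n_dirs_per_shell, self.shells)

    def renderer(self) -> MapRenderer:
        return MapRenderer(self.scheme(), self.sh_order, self.sh_reg,
                           sharpen=self.sharpen)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shells"] = list(self.shells)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "shells" in d:
            d["shells"] = tuple(float(b) for b in d["shells"])
        if "prior" in d and d["prior"]:
            prior = dict(d["prior"])
            for key in ("theta_range", "phi_range", "lam_fast_range",
                        "lam_slow_range"):
                if key in prior:
                    prior[key] = tuple(prior[key])
            for key in ("min_angle_deg", "max_angle_deg"):
                if key in prior:
                    prior[key] = {int(k): float(v)
                                  for k, v in prior[key].items()}
            d["prior"] = prior
        return cls(**d)

    def save(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# synthetic fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VoxelDataset:
    """Labeled synthetic voxels with full provenance.

    ``alphas`` is a list (per voxel) because the parameter dimension is 6n.
    The stored prior, scheme settings and seed regenerate the dataset
    bit-identically.
    """

    signals: np.ndarray  # (M, N)
    maps: np.ndarray  # (M, 32, 32, 3)
    labels: np.ndarray  # (M,) fiber counts
    alphas: list  # per-voxel (6n,) arrays
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        m = self.labels.shape[0]
        if not (self.signals.shape[0] == self.maps.shape[0] == m
                == len(self.alphas)):
            raise ValueError("dataset arrays are misaligned")


def make_fixture(prior: PriorSpec, renderer: MapRenderer, counts: dict,
                 seed: int, noise_sigma: float = None) -> VoxelDataset:
    """Balanced labeled dataset: ``counts`` maps fiber count → #voxels."""
    if any(c < 1 for c in counts.values()):
        raise ValueError("per-class counts must be positive")
    sigma = prior.noise_sigma if noise_sigma is None else noise_sigma
    seeds = spawn_seeds(seed, 2 * len(counts))
    sig_parts, map_parts, labels, alphas = [], [], [], []
    for j, (n, count) in enumerate(sorted(counts.items())):
        rng = np.random.default_rng(seeds[2 * j])
        a = fm.sample_prior_alphas(prior, n, count, rng)
        s = fm.simulate_signals(a, prior.w_fast, renderer.scheme)
        if sigma > 0:
            noise_rng = np.random.default_rng(seeds[2 * j + 1])
            s = s + noise_rng.normal(0.0, sigma, s.shape)
        sig_parts.append(s)
        map_parts.append(renderer.render_batch(s))
        labels.append(np.full(count, n, dtype=int))
        alphas.extend(list(a))
    return VoxelDataset(signals=np.vstack(sig_parts),
                        maps=np.concatenate(map_parts),
                        labels=np.concatenate(labels),
                        alphas=alphas, noise_sigma=sigma, seed=int(seed))
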