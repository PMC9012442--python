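"""CT-like volume synthesis and volume file I/O.

Voxelizes spine poses into Hounsfield-unit (HU) volumes the way a bone-window
scan presents them: voxels inside a vertebra take bone HU, voxels inside a
soft-tissue envelope (a dilation of the bone by a configurable margin,
standing in for the musculature) take soft-tissue HU, and everything else is
air.  Partial-volume mixing at bone boundaries comes from supersampled
occupancy fractions, computed by an even-odd column rasterizer: every
triangle's z-crossing toggles the fill state of its (x, y) sample column,
which is exact for watertight meshes.

Volumes are read and written as NIfTI (.nii/.nii.gz) or MetaImage
(.mha/.mhd); the reference label grid travels alongside with a ``_labels``
suffix.  Arrays are indexed ``[x, y, z]`` in the anatomical frame with voxel
centres at ``origin + index * spacing`` (0-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = ["CTVolume", "HUModel", "voxelize", "mesh_occupancy", "read_volume", "write_volume"]


@dataclass
class CTVolume:
    """3D scalar grid of HU values with physical spacing and origin (mm)."""

    hu: np.ndarray  # (nx, ny, nz)
    spacing: np.ndarray  # mm triple
    origin: np.ndarray  # mm triple

    def __post_init__(self):
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise ValueError("hu grid must be 3-dimensional")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("HU grid contains non-finite values")

    @property
    def voxel_diagonal(self) -> float:
        return float(np.linalg.norm(self.spacing))


@dataclass(frozen=True)
class HUModel:
    """Tissue HU statistics of the emulated scan.

    The deterministic part of a voxel is the occupancy-weighted mix of the
    bone mean and its context (soft tissue or air); all stochastic texture
    (tissue SDs and scanner noise) is a single zero-mean Gaussian whose SD is
    the same occupancy-weighted mix plus ``noise_sd``.  With every SD at zero
    the rendering is fully deterministic.
    """

    bone_mean: float = 1500.0
    bone_sd: float = 150.0
    soft_tissue_mean: float = 40.0
    soft_tissue_sd: float = 30.0
    background: float = -1000.0
    noise_sd: float = 20.0
    partial_volume_supersampling: int = 3
    soft_margin: float = 30.0  # mm, dilation of bone standing in for musculature

    def __post_init__(self):
        if not (700.0 <= self.bone_mean <= 3000.0):
            raise ValueError("bone_mean must lie in the bone window +700..+3000 HU")
        if self.soft_tissue_mean >= 700.0:
            raise ValueError("soft_tissue_mean must lie below the +700 HU bone threshold")
        if self.partial_volume_supersampling < 1:
            raise ValueError("supersampling must be >= 1")

    @classmethod
    def noiseless(cls, supersampling: int = 1, **kw) -> "HUModel":
        return cls(bone_sd=0.0, soft_tissue_sd=0.0, noise_sd=0.0,
                   partial_volume_supersampling=supersampling, **kw)


# tiny fixed offset keeps sample columns off triangle edges/vertices
_JITTER = np.array([1.1920929e-6, 2.3841858e-6, 0.7152557e-6])


def mesh_occupancy(
    mesh,
    origin: np.ndarray,
    spacing: np.ndarray,
    shape: tuple,
    supersampling: int = 3,
) -> np.ndarray:
    """Volume-occupancy fraction of a watertight mesh on a voxel grid.

    Even-odd fill along z at ``supersampling^2`` sample columns per voxel
    footprint, with ``supersampling`` z-samples per voxel; the returned array
    is the per-voxel mean occupancy in [0, 1].
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    s = int(supersampling)
    nx, ny, nz = map(int, shape)
    tri = np.asarray(mesh.triangles, dtype=float)
    frac = np.zeros((nx, ny, nz), dtype=np.float32)
    if len(tri) == 0:
        return frac

    lo = tri.reshape(-1, 3).min(axis=0)
    hi = tri.reshape(-1, 3).max(axis=0)
    # coarse-voxel crop around the mesh
    c_lo = np.maximum(np.floor((lo - origin) / spacing - 1).astype(int), 0)
    c_hi = np.minimum(np.ceil((hi - origin) / spacing + 1).astype(int), [nx - 1, ny - 1, nz - 1])
    if np.any(c_hi < c_lo):
        return frac

    jit = _JITTER * spacing

    def fine_coords(axis: int, c0: int, c1: int) -> np.ndarray:
        idx = np.arange((c1 - c0 + 1) * s)
        return origin[axis] + (c0 + (idx + 0.5) / s - 0.5) * spacing[axis] + jit[axis]

    ys = fine_coords(1, c_lo[1], c_hi[1])
    zs = fine_coords(2, c_lo[2], c_hi[2])
    nyf, nzf = len(ys), len(zs)
    dz = spacing[2] / s
    z0 = zs[0]

    # slab the x range so the toggle buffer stays small
    max_cols = max(1, int(16_000_000 // (nzf + 1)))
    slab_cx = max(1, max_cols // max(nyf, 1) // s)
    for cx0 in range(c_lo[0], c_hi[0] + 1, slab_cx):
        cx1 = min(cx0 + slab_cx - 1, c_hi[0])
        xs = fine_coords(0, cx0, cx1)
        nxf = len(xs)
        toggle = np.zeros((nxf * nyf, nzf + 1), dtype=np.uint16)
        x_lo, x_hi = xs[0], xs[-1]
        # rasterize each triangle's z-crossings over its (x, y) footprint
        for (a, b, c) in tri:
            txs = (a[0], b[0], c[0])
            if max(txs) < x_lo or min(txs) > x_hi:
                continue
            i0 = int(np.searchsorted(xs, min(txs), side="left"))
            i1 = int(np.searchsorted(xs, max(txs), side="right"))
            j0 = int(np.searchsorted(ys, min(a[1], b[1], c[1]), side="left"))
            j1 = int(np.searchsorted(ys, max(a[1], b[1], c[1]), side="right"))
            if i0 >= i1 or j0 >= j1:
                continue
            px = xs[i0:i1][:, None]
            py = ys[j0:j1][None, :]
            d = (b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1])
            if abs(d) < 1e-12:
                continue  # projection-degenerate: generic columns miss it
            u = ((b[0] - px) * (c[1] - py) - (c[0] - px) * (b[1] - py)) / d
            v = ((c[0] - px) * (a[1] - py) - (a[0] - px) * (c[1] - py)) / d
            w = 1.0 - u - v
            hit = (u >= 0) & (v >= 0) & (w >= 0)
            if not hit.any():
                continue
            zc = u * a[2] + v * b[2] + w * c[2]
            ii, jj = np.nonzero(hit)
            k = np.clip(np.ceil((zc[ii, jj] - z0) / dz), 0, nzf).astype(int)
            cols = (ii + i0) * nyf + (jj + j0)
            np.add.at(toggle, (cols, k), 1)
        inside = (np.cumsum(toggle[:, :nzf], axis=1) % 2).astype(np.float32)
        inside = inside.reshape(nxf // s, s, nyf // s, s, nzf // s, s)
        frac[cx0 : cx1 + 1, c_lo[1] : c_hi[1] + 1, c_lo[2] : c_hi[2] + 1] = inside.mean(
            axis=(1, 3, 5)
        )
    return frac


def voxelize(
    pose,
    hu_model: HUModel = HUModel(),
    spacing=(0.5, 0.5, 0.5),
    seed: int = 0,
    pad: float | None = None,
) -> tuple:
    """Render a spine pose as a CT volume plus the true per-vertebra label grid.

    Returns ``(CTVolume, labels)`` where ``labels[i,j,k]`` is the 1-based
    index (cranial to caudal) of the vertebra occupying the majority of the
    voxel, 0 elsewhere.  Deterministic for a fixed seed.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    meshes = pose.mesh_list() if hasattr(pose, "mesh_list") else list(pose)
    s = hu_model.partial_volume_supersampling
    if pad is None:
        pad = hu_model.soft_margin + 3 * float(spacing.max())

    if len(meshes) == 0:
        shape = (8, 8, 8)
        hu = np.full(shape, hu_model.background, dtype=np.float32)
        if hu_model.noise_sd > 0:
            rng = np.random.default_rng(seed)
            hu = hu + rng.normal(0.0, hu_model.noise_sd, shape).astype(np.float32)
        return CTVolume(hu, spacing, np.zeros(3)), np.zeros(shape, dtype=np.int16)

    bounds = np.array([m.bounds for m in meshes])
    lo = bounds[:, 0].min(axis=0) - pad
    hi = bounds[:, 1].max(axis=0) + pad
    origin = lo
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)

    bone = np.zeros(shape, dtype=np.float32)
    best = np.zeros(shape, dtype=np.float32)
    labels = np.zeros(shape, dtype=np.int16)
    for idx, mesh in enumerate(meshes, start=1):
        f = mesh_occupancy(mesh, origin, spacing, shape, s)
        if not np.any(f > 0.5):
            raise ValueError(
                f"spacing {tuple(spacing)} too coarse: vertebra {idx} has no interior voxel"
            )
        bone += f
        better = f > best
        labels[better] = idx
        np.maximum(best, f, out=best)
    np.clip(bone, 0.0, 1.0, out=bone)
    labels[best <= 0.5] = 0

    # soft-tissue envelope: every voxel within soft_margin of bone
    dist = ndimage.distance_transform_edt(bone == 0, sampling=spacing)
    soft = dist <= hu_model.soft_margin
    ctx_mean = np.where(soft, hu_model.soft_tissue_mean, hu_model.background).astype(np.float32)
    ctx_sd = np.where(soft, hu_model.soft_tissue_sd, 0.0).astype(np.float32)

    hu = bone * hu_model.bone_mean + (1.0 - bone) * ctx_mean
    sd = bone * hu_model.bone_sd + (1.0 - bone) * ctx_sd + hu_model.noise_sd
    if np.any(sd > 0):
        rng = np.random.default_rng(seed)
        hu = hu + rng.standard_normal(shape).astype(np.float32) * sd
    return CTVolume(hu.astype(np.float32), spacing, origin), labels


# ---------------------------------------------------------------------------
# file I/O

_EXTENSIONS = (".nii.gz", ".nii", ".mha", ".mhd")


def _check_ext(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(e) for e in _EXTENSIONS):
        raise ValueError(
            f"unsupported volume format for {path}; expected one of {_EXTENSIONS}"
        )


def _labels_path(path: Path) -> Path:
    name = path.name
    for e in _EXTENSIONS:
        if name.lower().endswith(e):
            return path.with_name(name[: -len(e)] + "_labels" + e)
    raise ValueError(f"unsupported volume format for {path}")


def write_volume(volume: CTVolume, path, labels: np.ndarray | None = None) -> Path:
    """Write a volume (NIfTI or MetaImage); labels go to a ``_labels`` sibling."""
    path = Path(path)
    _check_ext(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.hu.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(v) for v in volume.spacing))
    img.SetOrigin(tuple(float(v) for v in volume.origin))
    sitk.WriteImage(img, str(path))
    if labels is not None:
        lab = sitk.GetImageFromArray(
            np.ascontiguousarray(labels.astype(np.int16).transpose(2, 1, 0))
        )
        lab.SetSpacing(tuple(float(v) for v in volume.spacing))
        lab.SetOrigin(tuple(float(v) for v in volume.origin))
        sitk.WriteImage(lab, str(_labels_path(path)))
    return path


def read_volume(path) -> CTVolume:
    """Read a NIfTI/MetaImage volume into the anatomical ``[x, y, z]`` layout."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    _check_ext(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as err:
        raise ValueError(f"cannot read volume {path}: {err}") from None
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return CTVolume(arr, np.array(img.GetSpacing()), np.array(img.GetOrigin()))
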