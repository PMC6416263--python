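"""Emulation of the print -> CT -> segmentation chain.

The physical pipeline (3D print, CT acquisition, HU thresholding) is
replaced by deterministic rasterization: a voxel is foreground iff its
center lies inside the closed surface.  Anisotropic spacing emulates the
scanner geometry (0.68 mm in-plane pixels, 0.6 or 2 mm slices).  The module
also implements the grid-resampling, volume-equalization and
volume-rescaling transforms used by the robustness experiments; the latter
two are pure homotheties realized by recomputing the voxel spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy import ndimage

from .geometry import is_watertight

__all__ = [
    "BinaryMask",
    "voxelize",
    "resample_mask",
    "equalize_volumes",
    "rescale_volume",
    "read_mask",
    "write_mask",
]

# fixed sub-voxel offset applied to ray columns so that mesh edges/vertices
# are never hit exactly (generic-position rasterization)
_RAY_EPS = (7.3e-7, 3.1e-7)


@dataclass(frozen=True)
class BinaryMask:
    """0/1 volumetric array with anisotropic voxel spacing.

    The physical center of voxel ``(i, j, k)`` is
    ``origin + (i * sx, j * sy, k * sz)``; axes are (x, y, z) with z the
    slice direction.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.ascontiguousarray(self.values, dtype=np.uint8)
        object.__setattr__(self, "values", values)
        if values.ndim != 3:
            raise ValueError("mask must be a 3D array")
        if not all(s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if values.sum() == 0:
            raise ValueError("mask has no foreground voxels")

    @property
    def voxel_volume(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def count_volume(self) -> float:
        """Foreground voxel count times voxel volume (mm^3)."""
        return float(self.values.sum()) * self.voxel_volume

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of all foreground voxel centers, (n, 3)."""
        idx = np.argwhere(self.values > 0).astype(float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def _largest_component(values: np.ndarray) -> np.ndarray:
    """Reduce foreground to its largest 6-connected component.

    Spiculation tips rasterized at coarse slice spacing detach into small
    islets; stray components would generate spurious isosurfaces.
    """
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(values, structure=structure)
    if n <= 1:
        return values
    sizes = ndimage.sum_labels(values, labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (labels == keep).astype(np.uint8)


def voxelize(
    mesh: trimesh.Trimesh,
    spacing: tuple[float, float, float],
    keep_largest: bool = True,
    blur_sigma: float | None = None,
) -> BinaryMask:
    """Rasterize a watertight mesh: voxel = 1 iff its center is inside.

    Containment is decided by the parity of z-ray crossings through the
    surface, computed by a vectorized scanline sweep.  The grid is padded
    with a one-voxel background border so downstream isosurfaces are closed.

    Parameters
    ----------
    blur_sigma : float, optional
        If given, the binary mask is additionally smoothed with a Gaussian
        of this sigma (mm) and re-thresholded at 0.5, emulating
        partial-volume blur.  Off by default: the default chain is
        deterministic and parameter-free.
    """
    if not is_watertight(mesh):
        raise ValueError("voxelize requires a watertight mesh (inside test undefined)")
    s = np.asarray(spacing, dtype=float)
    if np.any(s <= 0):
        raise ValueError("spacing must be positive")
    v = np.asarray(mesh.vertices, dtype=float)
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    # voxel index 0 centered one full voxel below the mesh minimum
    origin = (np.floor(lo / s) - 1) * s
    shape = np.ceil((hi - origin) / s).astype(int) + 2

    tri = v[np.asarray(mesh.faces, dtype=np.int64)]
    # generic-position offset of the ray grid (equivalently of the mesh)
    ox = origin[0] - _RAY_EPS[0]
    oy = origin[1] - _RAY_EPS[1]

    x = tri[:, :, 0]
    y = tri[:, :, 1]
    ix_lo = np.ceil((x.min(axis=1) - ox) / s[0]).astype(int)
    ix_hi = np.floor((x.max(axis=1) - ox) / s[0]).astype(int)
    iy_lo = np.ceil((y.min(axis=1) - oy) / s[1]).astype(int)
    iy_hi = np.floor((y.max(axis=1) - oy) / s[1]).astype(int)
    nx = np.maximum(ix_hi - ix_lo + 1, 0)
    ny = np.maximum(iy_hi - iy_lo + 1, 0)
    counts = nx * ny
    keep = counts > 0
    if not np.any(keep):
        raise ValueError("mesh produced an empty mask at this spacing")

    tri_k = tri[keep]
    ix_lo_k, nx_k = ix_lo[keep], nx[keep]
    iy_lo_k, ny_k = iy_lo[keep], ny[keep]
    counts_k = counts[keep]

    # expand (triangle, column) candidate pairs
    rep = np.repeat(np.arange(len(tri_k)), counts_k)
    offs = np.arange(counts_k.sum()) - np.repeat(
        np.cumsum(counts_k) - counts_k, counts_k
    )
    ci = ix_lo_k[rep] + offs // ny_k[rep]
    cj = iy_lo_k[rep] + offs % ny_k[rep]
    cx = ox + ci * s[0]
    cy = oy + cj * s[1]

    t = tri_k[rep]
    x0, y0 = t[:, 0, 0], t[:, 0, 1]
    x1, y1 = t[:, 1, 0], t[:, 1, 1]
    x2, y2 = t[:, 2, 0], t[:, 2, 1]
    denom = (y1 - y2) * (x0 - x2) + (x2 - x1) * (y0 - y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        l0 = ((y1 - y2) * (cx - x2) + (x2 - x1) * (cy - y2)) / denom
        l1 = ((y2 - y0) * (cx - x2) + (x0 - x2) * (cy - y2)) / denom
        l2 = 1.0 - l0 - l1
    hit = (denom != 0) & (l0 >= 0) & (l1 >= 0) & (l2 >= 0)

    zc = l0[hit] * t[hit, 0, 2] + l1[hit] * t[hit, 1, 2] + l2[hit] * t[hit, 2, 2]
    col = ci[hit] * shape[1] + cj[hit]

    order = np.lexsort((zc, col))
    col = col[order]
    zc = zc[order]

    values = np.zeros(shape, dtype=np.uint8)
    kz = np.arange(shape[2])
    zgrid = origin[2] + kz * s[2]

    # per column: drop duplicate crossings (edge double-hits), pair up,
    # fill voxels whose center z lies strictly inside each (z_in, z_out)
    starts = np.searchsorted(col, np.unique(col))
    bounds = np.append(starts, len(col))
    uniq = np.unique(col)
    for u, b0, b1 in zip(uniq, bounds[:-1], bounds[1:]):
        zs = zc[b0:b1]
        if len(zs) > 1:
            dup = np.isclose(np.diff(zs), 0.0, atol=1e-9)
            if np.any(dup):
                kill = np.zeros(len(zs), dtype=bool)
                i = 0
                while i < len(zs) - 1:
                    if not kill[i] and abs(zs[i + 1] - zs[i]) <= 1e-9:
                        kill[i] = kill[i + 1] = True
                        i += 2
                    else:
                        i += 1
                zs = zs[~kill]
        if len(zs) % 2 == 1:
            zs = zs[:-1]
        if len(zs) == 0:
            continue
        i0 = np.searchsorted(zgrid, zs[0::2], side="left")
        i1 = np.searchsorted(zgrid, zs[1::2], side="left")
        ii, jj = u // shape[1], u % shape[1]
        for a, b in zip(i0, i1):
            values[ii, jj, a:b] = 1

    if blur_sigma is not None:
        values = (
            ndimage.gaussian_filter(values.astype(float), sigma=blur_sigma / s)
            >= 0.5
        ).astype(np.uint8)
    if keep_largest:
        values = _largest_component(values)
    return BinaryMask(values, tuple(s), tuple(origin))


def resample_mask(
    mask: BinaryMask, new_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> BinaryMask:
    """Trilinear resampling onto a new grid, then binarization at 0.5.

    The new grid shares the mask's origin; values exactly at the 0.5
    threshold map to foreground.
    """
    s_old = np.asarray(mask.spacing, dtype=float)
    s_new = np.asarray(new_spacing, dtype=float)
    if np.any(s_new <= 0):
        raise ValueError("new spacing must be positive")
    shape_new = np.maximum(
        np.ceil((np.asarray(mask.values.shape) - 1) * s_old / s_new).astype(int) + 1,
        1,
    )
    grids = np.meshgrid(
        *[np.arange(n) * s_new[a] / s_old[a] for a, n in enumerate(shape_new)],
        indexing="ij",
    )
    interp = ndimage.map_coordinates(
        mask.values.astype(float), np.stack(grids), order=1, mode="constant", cval=0.0
    )
    values = (interp >= 0.5).astype(np.uint8)
    if values.sum() == 0:
        raise ValueError("resampled mask is empty (object thinner than new grid)")
    values = np.pad(values, 1)
    origin = np.asarray(mask.origin) - s_new
    return BinaryMask(values, tuple(s_new), tuple(origin))


def equalize_volumes(
    masks: list[BinaryMask],
    reference_volume: float,
    measured_volumes: list[float] | None = None,
) -> list[BinaryMask]:
    """Homothetically rescale each mask so its volume equals the reference.

    The voxel arrays are untouched: spacing (and origin) are multiplied by
    ``(reference_volume / V_i)^(1/3)``.  ``measured_volumes`` should be the
    mesh-derived (isosurface) volumes so the post-transform mesh volumes
    land exactly on the reference; voxel-count volumes are the fallback.
    """
    if reference_volume <= 0:
        raise ValueError("reference_volume must be positive")
    if measured_volumes is None:
        measured_volumes = [m.count_volume for m in masks]
    out = []
    for mask, vol in zip(masks, measured_volumes):
        if vol <= 0:
            raise ValueError("measured volume must be positive")
        f = (reference_volume / vol) ** (1.0 / 3.0)
        out.append(
            replace(
                mask,
                spacing=tuple(np.asarray(mask.spacing) * f),
                origin=tuple(np.asarray(mask.origin) * f),
            )
        )
    return out


def rescale_volume(mask: BinaryMask, fraction: float) -> BinaryMask:
    """Scale the enclosed volume by ``fraction`` via pure spacing change."""
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    f = fraction ** (1.0 / 3.0)
    return replace(
        mask,
        spacing=tuple(np.asarray(mask.spacing) * f),
        origin=tuple(np.asarray(mask.origin) * f),
    )


def write_mask(mask: BinaryMask, path) -> None:
    """Write NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha/.mhd), spacing in header."""
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(mask.spacing) + [1.0])
        affine[:3, 3] = mask.origin
        nib.save(nib.Nifti1Image(mask.values.astype(np.uint8), affine), path)
    elif path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        # SimpleITK arrays are indexed (z, y, x)
        img = sitk.GetImageFromArray(np.transpose(mask.values, (2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in mask.spacing))
        img.SetOrigin(tuple(float(o) for o in mask.origin))
        sitk.WriteImage(img, path)
    else:
        raise ValueError(f"unsupported mask format: {path}")


def read_mask(path) -> BinaryMask:
    path = str(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        affine = img.affine
        spacing = tuple(float(x) for x in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(x) for x in affine[:3, 3])
        return BinaryMask(
            (np.asarray(img.dataobj) > 0).astype(np.uint8), spacing, origin
        )
    if path.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        values = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
        return BinaryMask(
            (values > 0).astype(np.uint8),
            tuple(img.GetSpacing()),
            tuple(img.GetOrigin()),
        )
    raise ValueError(f"unsupported mask format: {path}")
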