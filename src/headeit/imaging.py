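"""Voxelization, centre-of-gravity localization and report metrics.

Reconstructed element fields are resampled onto a regular voxel grid (each
voxel takes the value of the element containing its centre; voxels outside
the mesh are zero).  Localization of a conductive inclusion is quantified by
the distance between the true centre and the intensity-weighted centroid
(CoG) of the image, conventionally computed on the positive part of dsigma --
a blood-like inclusion raises conductivity.  The scalp region is removed
before localization so that only intracranial change is scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import HeadMesh


@dataclass
class VoxelImage:
    """Regular 3-D grid of conductivity-change values (S/m)."""

    data: np.ndarray
    resolution: float
    origin: np.ndarray

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = [np.arange(n) for n in self.data.shape]
        return tuple(self.origin[i] + (idx[i] + 0.5) * self.resolution
                     for i in range(3))


@dataclass
class LocalizationReport:
    cog: np.ndarray
    truth: np.ndarray
    error_mm: float


def voxelize(mesh: HeadMesh, field: np.ndarray, resolution: float
             ) -> VoxelImage:
    """Rasterize a per-element field onto a voxel grid of edge ``resolution``.

    Containment is exact: a voxel takes an element's value iff its centre
    lies inside that tetrahedron (barycentric test, rasterized per element).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    field = np.asarray(field, dtype=float)
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    if np.any(resolution > (hi - lo)):
        raise ValueError("voxel resolution exceeds the mesh extent")
    shape = np.ceil((hi - lo) / resolution).astype(int)
    data = np.zeros(shape)
    x = mesh.nodes[mesh.elements]            # (m, 4, 3)
    T = np.transpose(x[:, 1:] - x[:, :1], (0, 2, 1))   # (m, 3, 3)
    Tinv = np.linalg.inv(T)
    for e in range(mesh.n_elements):
        emin = x[e].min(axis=0)
        emax = x[e].max(axis=0)
        i0 = np.floor((emin - lo) / resolution - 0.5).astype(int)
        i1 = np.ceil((emax - lo) / resolution - 0.5).astype(int)
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape - 1)
        if np.any(i1 < i0):
            continue
        gi = [np.arange(i0[k], i1[k] + 1) for k in range(3)]
        gx, gy, gz = np.meshgrid(*gi, indexing="ij")
        centers = lo + (np.stack([gx, gy, gz], axis=-1) + 0.5) * resolution
        bary = np.einsum("ij,...j->...i", Tinv[e], centers - x[e, 0])
        inside = (np.all(bary >= -1e-12, axis=-1)
                  & (bary.sum(axis=-1) <= 1 + 1e-12))
        sel = np.where(inside)
        data[gx[sel], gy[sel], gz[sel]] = field[e]
    return VoxelImage(data, float(resolution), lo.copy())


def center_of_gravity(image: VoxelImage, mask: np.ndarray | None = None,
                      weighting: str = "positive") -> np.ndarray:
    """Intensity-weighted centroid of the image.

    ``weighting="positive"`` uses max(dsigma, 0) as voxel weights (the
    conductive-inclusion convention); ``"absolute"`` uses |dsigma|.
    """
    w = image.data.copy()
    if mask is not None:
        w = np.where(mask, w, 0.0)
    if weighting == "positive":
        w = np.maximum(w, 0.0)
    elif weighting == "absolute":
        w = np.abs(w)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = w.sum()
    if total == 0:
        raise ValueError("all voxel weights are zero")
    cx, cy, cz = image.voxel_centers()
    return np.array([
        (w.sum(axis=(1, 2)) @ cx) / total,
        (w.sum(axis=(0, 2)) @ cy) / total,
        (w.sum(axis=(0, 1)) @ cz) / total,
    ])


def remove_scalp(field: np.ndarray, mesh: HeadMesh) -> np.ndarray:
    """Zero the scalp-labelled elements (display/metrics step only)."""
    out = np.array(field, dtype=float, copy=True)
    out[mesh.tissue_mask("scalp")] = 0.0
    return out


def localization_error(cog, truth) -> float:
    """Euclidean distance between CoG and the true centre, in millimetres."""
    return float(np.linalg.norm(np.asarray(cog, float)
                                - np.asarray(truth, float)) * 1e3)


def save_nifti(image: VoxelImage, path) -> None:
    """Export a voxel image as a NIfTI volume (affine maps voxel indices to
    metres in the head frame)."""
    import nibabel as nib

    affine = np.diag([image.resolution] * 3 + [1.0])
    affine[:3, 3] = image.origin + image.resolution / 2.0
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), affine), path)


def section_2d(image: VoxelImage, point, normal, extent: float,
               step: float) -> np.ndarray:
    """Sample the voxel image on an oblique plane (trilinear interpolation).

    The plane passes through ``point`` with unit ``normal``; the output is a
    square array of half-width ``extent`` sampled every ``step`` metres.
    """
    point = np.asarray(point, float)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ normal) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    a1 = np.cross(normal, helper)
    a1 /= np.linalg.norm(a1)
    a2 = np.cross(normal, a1)
    t = np.arange(-extent, extent + step / 2, step)
    P = (point[None, None, :] + t[:, None, None] * a1[None, None, :]
         + t[None, :, None] * a2[None, None, :])
    lo = image.origin
    hi = image.origin + np.array(image.data.shape) * image.resolution
    if np.all((P < lo) | (P > hi)):
        raise ValueError("plane lies outside the image volume")
    coords = (P - lo[None, None, :]) / image.resolution - 0.5
    return ndimage.map_coordinates(image.data, coords.transpose(2, 0, 1),
                                   order=1, mode="constant", cval=0.0)
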