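"""Imaging data model and voxel-level operations.

Everything downstream of this module works on :class:`Volume` objects: a
single 3-D scalar field together with its voxel-to-mm affine.  The module
provides NIfTI I/O, FWHM-parameterised Gaussian smoothing, construction of
control-referenced abnormality maps, U-threshold/extent binarisation of
lesions, connected-component cluster extraction and the geometric helpers
(centre of mass, Euclidean displacement) used throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtr

#: full-width-half-maximum of a Gaussian = FWHM_TO_SIGMA * sigma
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...

#: roles that carry extra value constraints
_CHECKED_ROLES = ("abnormality", "binary", "label")


@dataclass
class Volume:
    """One 3-D scalar field with voxel-index -> mm geometry.

    Parameters
    ----------
    data : ndarray, shape (i, j, k)
        Voxel values.
    affine : ndarray, shape (4, 4)
        Homogeneous voxel-index to mm transform; its 3x3 block must be
        invertible.
    role : str
        Semantic tag.  ``"abnormality"`` requires values in [0, 1],
        ``"binary"`` values in {0, 1} and ``"label"`` non-negative
        integers; other tags (``"scalar"``, ``"zscore"``, ``"count"``,
        ``"statistic"``, ``"p"``) are unchecked.
    """

    data: np.ndarray
    affine: np.ndarray
    role: str = "scalar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected a 3-D volume, got a {self.data.ndim}-D array"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible (zero voxel volume)")
        if self.role == "abnormality":
            lo, hi = float(np.min(self.data)), float(np.max(self.data))
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"abnormality values must lie in [0, 1]; got [{lo}, {hi}]"
                )
        elif self.role == "binary":
            vals = np.unique(self.data)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("binary volume must contain only {0, 1}")
        elif self.role == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.allclose(self.data, np.round(self.data)):
                    raise ValueError("label volume must hold integers")
                self.data = np.round(self.data).astype(np.int32)
            if np.min(self.data) < 0:
                raise ValueError("label volume must be non-negative")

    # -- geometry -----------------------------------------------------
    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (.., 3) voxel indices to mm coordinates via the affine."""
        arr = np.asarray(ijk, dtype=float)
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if arr.ndim == 1 else out

    def with_data(self, data: np.ndarray, role: str | None = None) -> "Volume":
        """New volume on the same grid."""
        return Volume(data, self.affine.copy(), role if role is not None else self.role)

    def same_grid(self, other: "Volume") -> bool:
        return self.grid_shape == other.grid_shape and np.allclose(
            self.affine, other.affine
        )


@dataclass
class BrainMask:
    """Binary analysis mask; all matrix operations restrict to it."""

    volume: Volume

    def __post_init__(self) -> None:
        if self.volume.role != "binary":
            self.volume = Volume(
                (np.asarray(self.volume.data) > 0).astype(np.uint8),
                self.volume.affine,
                "binary",
            )
        if self.n_voxels == 0:
            raise ValueError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.volume.data))

    @property
    def indices(self) -> np.ndarray:
        """(n_voxels, 3) voxel indices of in-mask voxels (C order)."""
        return np.argwhere(self.volume.data > 0)

    @property
    def boolean(self) -> np.ndarray:
        return np.asarray(self.volume.data) > 0


@dataclass
class LesionIdentificationConfig:
    """Thresholds that turn an abnormality map into a binary lesion.

    ``u_threshold`` is the abnormality cut-off above which a voxel is a
    lesion candidate; candidates must form connected clusters strictly
    larger than ``min_cluster_voxels`` to survive.
    """

    u_threshold: float = 0.5
    min_cluster_voxels: int = 100
    fwhm_mm: float = 8.0
    connectivity: int = 26

    def __post_init__(self) -> None:
        if not 0 < self.u_threshold < 1:
            raise ValueError("u_threshold must lie strictly between 0 and 1")
        if self.min_cluster_voxels < 1:
            raise ValueError("min_cluster_voxels must be >= 1")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be non-negative")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path, role: str = "scalar") -> Volume:
    """Read a single-volume NIfTI-1 image."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D NIfTI volume, got {data.ndim} dimensions"
        )
    return Volume(data, np.asarray(img.affine), role)


def write_volume(volume: Volume, path) -> None:
    """Write a volume as NIfTI-1; round trips bit-exactly for float32/uint8."""
    img = nib.Nifti1Image(volume.data, volume.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Smoothing and abnormality maps
# ---------------------------------------------------------------------------

def gaussian_smooth(volume: Volume, fwhm_mm: float, mode: str = "reflect") -> Volume:
    """Separable Gaussian smoothing with an FWHM given in millimetres.

    The per-axis sigma in voxels is ``(fwhm_mm / 2.3548) / voxel_size``,
    honouring anisotropic voxels through the affine.  The default
    ``reflect`` boundary preserves total mass.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return volume.with_data(np.array(volume.data, dtype=float, copy=True))
    sigma_vox = (fwhm_mm / FWHM_TO_SIGMA) / volume.voxel_sizes
    out = ndimage.gaussian_filter(
        np.asarray(volume.data, dtype=float), sigma=tuple(sigma_vox), mode=mode
    )
    return volume.with_data(out)


def abnormality_from_controls(
    patient_volume: Volume,
    control_volumes: Sequence[Volume],
    sigma_floor_frac: float = 1e-6,
) -> Volume:
    """Control-referenced abnormality likelihood map in [0, 1].

    Per voxel the patient intensity is compared with the control
    distribution: ``abnormality = 2 * Phi(|x - mu| / sd) - 1`` with ``Phi``
    the standard normal CDF and the control SD floored at
    ``sigma_floor_frac`` times the global control intensity range, so the
    map is monotone in the absolute deviation and invariant to adding a
    constant to patient and controls alike.
    """
    if len(control_volumes) < 3:
        raise ValueError(
            f"need at least 3 control volumes, got {len(control_volumes)}"
        )
    for c in control_volumes:
        if not patient_volume.same_grid(c):
            raise ValueError("control volume grid does not match patient grid")
    stack = np.stack([np.asarray(c.data, dtype=float) for c in control_volumes])
    mu = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    rng_ = float(stack.max() - stack.min())
    floor = max(sigma_floor_frac * rng_, 1e-12)
    sd = np.maximum(sd, floor)
    z = np.abs(np.asarray(patient_volume.data, dtype=float) - mu) / sd
    abn = 2.0 * ndtr(z) - 1.0
    return patient_volume.with_data(np.clip(abn, 0.0, 1.0), role="abnormality")


# ---------------------------------------------------------------------------
# Connected components / binarisation
# ---------------------------------------------------------------------------

def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be one of 6, 18, 26")


def binarize_lesion(
    abnormality: Volume, config: LesionIdentificationConfig | None = None
) -> Volume:
    """Binary lesion map: abnormality > U-threshold, extent-filtered.

    Suprathreshold voxels are grouped into connected components under
    ``config.connectivity``; components must contain strictly more than
    ``config.min_cluster_voxels`` voxels to survive.
    """
    config = config or LesionIdentificationConfig()
    if abnormality.role != "abnormality":
        raise TypeError("binarize_lesion expects an abnormality-tagged volume")
    cand = np.asarray(abnormality.data) > config.u_threshold
    labels, n = ndimage.label(cand, structure=_structure(config.connectivity))
    if n:
        counts = np.bincount(labels.ravel())
        keep = counts > config.min_cluster_voxels
        keep[0] = False
        out = keep[labels]
    else:
        out = np.zeros_like(cand)
    return abnormality.with_data(out.astype(np.uint8), role="binary")


def overlap_map(binary_volumes: Sequence[Volume]) -> Volume:
    """Voxel-wise lesion count across patients (lesion overlap profile)."""
    if len(binary_volumes) == 0:
        raise ValueError("need at least one binary volume")
    first = binary_volumes[0]
    total = np.zeros(first.grid_shape, dtype=np.int32)
    for v in binary_volumes:
        if not first.same_grid(v):
            raise ValueError("binary volume grids do not match")
        total += (np.asarray(v.data) > 0).astype(np.int32)
    return first.with_data(total, role="count")


# ---------------------------------------------------------------------------
# Cluster extraction
# ---------------------------------------------------------------------------

CLUSTER_COLUMNS = [
    "id", "n_voxels", "volume_mm3", "peak",
    "peak_x_mm", "peak_y_mm", "peak_z_mm",
    "com_x_mm", "com_y_mm", "com_z_mm",
]


def extract_clusters(
    volume: Volume,
    threshold: float,
    min_cluster_voxels: int = 0,
    connectivity: int = 26,
    two_sided: bool = False,
) -> tuple[Volume, pd.DataFrame]:
    """Threshold a statistic volume and tabulate surviving clusters.

    Voxels with ``value > threshold`` (or ``|value| > threshold`` if
    ``two_sided``) are grouped into connected components; components with
    strictly more than ``min_cluster_voxels`` voxels are kept.  The table is
    sorted by size descending, ids renumbered from 1; the peak is the voxel
    of maximum (absolute) value and the centre of mass weights every
    suprathreshold voxel equally, both reported in mm.
    """
    data = np.asarray(volume.data, dtype=float)
    score = np.abs(data) if two_sided else data
    sup = score > threshold
    labels, n = ndimage.label(sup, structure=_structure(connectivity))
    rows = []
    out = np.zeros(volume.grid_shape, dtype=np.uint8)
    if n:
        counts = np.bincount(labels.ravel())
        order = [
            lab for lab in np.argsort(counts[1:])[::-1] + 1
            if counts[lab] > min_cluster_voxels
        ]
        for new_id, lab in enumerate(order, start=1):
            idx = np.argwhere(labels == lab)
            out[tuple(idx.T)] = 1
            vals = data[tuple(idx.T)]
            peak_pos = idx[np.argmax(np.abs(vals) if two_sided else vals)]
            mm = volume.voxel_to_mm(idx)
            com = mm.mean(axis=0)
            peak_mm = volume.voxel_to_mm(peak_pos)
            rows.append(
                dict(
                    id=new_id,
                    n_voxels=int(counts[lab]),
                    volume_mm3=float(counts[lab] * volume.voxel_volume_mm3),
                    peak=float(vals[np.argmax(np.abs(vals) if two_sided else vals)]),
                    peak_x_mm=float(peak_mm[0]),
                    peak_y_mm=float(peak_mm[1]),
                    peak_z_mm=float(peak_mm[2]),
                    com_x_mm=float(com[0]),
                    com_y_mm=float(com[1]),
                    com_z_mm=float(com[2]),
                )
            )
    table = pd.DataFrame(rows, columns=CLUSTER_COLUMNS)
    return volume.with_data(out, role="binary"), table


def write_cluster_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def centre_of_mass_mm(
    mask: Volume, largest_cluster_only: bool = False, connectivity: int = 26
) -> np.ndarray:
    """Unweighted centre of mass (mm) of the nonzero voxels of a mask.

    With ``largest_cluster_only`` the centre is computed over the single
    largest connected component instead of all nonzero voxels pooled.
    """
    data = np.asarray(mask.data) > 0
    if not data.any():
        raise ValueError("mask has no nonzero voxels")
    if largest_cluster_only:
        labels, n = ndimage.label(data, structure=_structure(connectivity))
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        data = labels == int(np.argmax(counts))
    idx = np.argwhere(data)
    return mask.voxel_to_mm(idx).mean(axis=0)


def euclidean_displacement(point_a_mm, point_b_mm) -> float:
    """L2 distance in mm between two points."""
    a = np.asarray(point_a_mm, dtype=float)
    b = np.asarray(point_b_mm, dtype=float)
    return float(np.linalg.norm(a - b))
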