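"""Voxel-level layer: tumor volume from lesion label maps and the
new-lesion criterion on paired scans.

Only what the response framework itself defines at image level lives here:
summing a segmentation's labeled voxels into total PSMA-positive tumor
volume (PSMA-VOL, mL), and flagging interim lesions as *new* when they are
unmatched by any baseline lesion and their SUVmax exceeds a caller-supplied
reference-region mean SUV. Segmentation is consumed, not produced — label
maps come from external tools or from the synthetic phantoms generated
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class SuvImage:
    """A 3-D SUV grid with voxel spacing (mm) and an optional lesion label map.

    Label 0 is background; positive integers identify lesions.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("SUV grid must be 3-D")
        if (self.data < 0).any():
            raise ValueError("SUV values must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or min(self.spacing) <= 0:
            raise ValueError("need three positive voxel spacings (mm)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.data.shape:
                raise ValueError("label map shape must match SUV grid")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class Lesion:
    """One segmented lesion: volume, peak uptake, and centroid in mm."""

    label: int
    volume_ml: float
    suv_max: float
    centroid_mm: tuple[float, float, float]


def psma_vol(image: SuvImage) -> float:
    """Total PSMA-positive tumor volume in mL: labeled voxels x voxel volume."""
    if image.labels is None:
        raise ValueError("PSMA-VOL requires a lesion label map")
    return float(np.count_nonzero(image.labels)) * image.voxel_volume_ml


def lesion_set(image: SuvImage) -> list[Lesion]:
    """Per-lesion volume, SUVmax and centroid from a labeled SUV image."""
    if image.labels is None:
        raise ValueError("lesion extraction requires a label map")
    ids = np.unique(image.labels)
    ids = ids[ids > 0]
    lesions = []
    if ids.size == 0:
        return lesions
    centroids = ndimage.center_of_mass(
        np.ones_like(image.labels, dtype=float), image.labels, ids
    )
    maxima = ndimage.maximum(image.data, image.labels, ids)
    counts = ndimage.sum_labels(np.ones_like(image.labels, dtype=float), image.labels, ids)
    for lid, com, mx, cnt in zip(ids, np.atleast_2d(centroids), np.atleast_1d(maxima), np.atleast_1d(counts)):
        centroid_mm = tuple(float(c) * s for c, s in zip(com, image.spacing))
        lesions.append(
            Lesion(
                label=int(lid),
                volume_ml=float(cnt) * image.voxel_volume_ml,
                suv_max=float(mx),
                centroid_mm=centroid_mm,
            )
        )
    return lesions


def detect_new_lesions(
    baseline: list[Lesion],
    interim: list[Lesion],
    background_suv_mean: float,
    match_radius: float = 15.0,
) -> tuple[int, list[int]]:
    """Flag interim lesions absent at baseline.

    An interim lesion is *new* iff no baseline lesion centroid lies within
    ``match_radius`` mm of its centroid AND its SUVmax exceeds the
    reference-region mean SUV (``background_suv_mean``). Returns the binary
    any-new-lesion flag and the label ids of the new lesions.
    """
    if match_radius < 0:
        raise ValueError("match_radius must be nonnegative")
    base_centroids = np.array([l.centroid_mm for l in baseline], dtype=float).reshape(-1, 3)
    new_ids = []
    for lesion in interim:
        if lesion.suv_max <= background_suv_mean:
            continue
        if base_centroids.size:
            dists = np.linalg.norm(base_centroids - np.asarray(lesion.centroid_mm), axis=1)
            if float(dists.min()) <= match_radius:
                continue
        new_ids.append(lesion.label)
    return int(bool(new_ids)), new_ids


@dataclass(frozen=True)
class Blob:
    """Spherical Gaussian-profile lesion for phantom images."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    peak_suv: float


def make_phantom(
    blobs: list[Blob],
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
    background: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SuvImage:
    """Synthetic SUV image: Gaussian blobs on a constant background.

    Each blob adds ``peak_suv * exp(-d^2 / (2 (r/2)^2))`` to the background;
    its truth label covers the voxels within ``radius_mm`` of the center,
    with overlaps resolved by nearest center. Noise is seeded Gaussian,
    clipped at zero.
    """
    spacing = tuple(float(s) for s in spacing)
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
    )
    data = np.full(shape, float(background))
    labels = np.zeros(shape, dtype=int)
    best_dist = np.full(shape, np.inf)
    for idx, blob in enumerate(blobs, start=1):
        center = np.asarray(blob.center_mm, dtype=float)
        if ((center < 0) | (center >= np.array(shape) * np.array(spacing))).any():
            raise ValueError(f"blob {idx} center {tuple(center)} outside the grid")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        sigma = blob.radius_mm / 2.0
        data += blob.peak_suv * np.exp(-d2 / (2.0 * sigma**2))
        inside = d2 <= blob.radius_mm**2
        closer = inside & (d2 < best_dist)
        labels[closer] = idx
        best_dist[closer] = d2[closer]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=shape)
    data = np.clip(data, 0.0, None)
    return SuvImage(data=data, spacing=spacing, labels=labels)


def load_nifti(image_path, labels_path=None) -> SuvImage:
    """Load an SUV image (and optional label map) from NIfTI files."""
    import nibabel as nib

    img = nib.load(str(image_path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    data = np.asarray(img.dataobj, dtype=float)
    labels = None
    if labels_path is not None:
        labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(int)
    return SuvImage(data=data, spacing=spacing, labels=labels)
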