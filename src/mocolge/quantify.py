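"""Contrast ratios, FWHM scar mass, and objective image-quality
surrogates for comparing the two reconstructions.

Regions of interest and myocardial contours are voxel-index masks that
are shared (copied verbatim) between the reconstructions being
compared, mirroring the reading procedure in which all ROIs and
contours are drawn once and copied to the exactly corresponding
position in the paired dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom_sim import LABELS

__all__ = [
    "ROISet",
    "MyocardialContours",
    "contrast_ratio",
    "fwhm_mass",
    "edge_sharpness",
    "rmse",
    "truth_rois",
    "truth_contours",
    "boundary_band",
]


@dataclass
class ROISet:
    """Voxel-index masks for signal-intensity measurements: three LGE
    ROIs, three remote-myocardium ROIs, one luminal blood ROI."""

    lge_rois: list
    myo_rois: list
    blood_roi: np.ndarray

    def __post_init__(self):
        masks = [*self.lge_rois, *self.myo_rois, self.blood_roi]
        if any(not m.any() for m in masks):
            raise ValueError("every ROI must be nonempty")
        total = np.zeros_like(self.blood_roi, dtype=int)
        for m in masks:
            total += m.astype(int)
        if total.max() > 1:
            raise ValueError("ROIs must be pairwise disjoint")


@dataclass
class MyocardialContours:
    """Endo/epicardial masks; the shell (epi minus endo) is the
    myocardium searched by the FWHM method."""

    endo_mask: np.ndarray
    epi_mask: np.ndarray
    voxel_volume_ml: float

    def __post_init__(self):
        if (self.endo_mask & ~self.epi_mask).any():
            raise ValueError("endo region must lie inside the epi region")
        if not self.shell.any():
            raise ValueError("myocardial shell is empty")

    @property
    def shell(self) -> np.ndarray:
        return self.epi_mask & ~self.endo_mask


def contrast_ratio(image: np.ndarray, numerator_rois, denominator_rois) -> float:
    """Mean signal intensity over the pooled numerator ROIs divided by
    the mean over the pooled denominator ROIs."""
    img = np.abs(image)
    num_mask = np.zeros(img.shape, bool)
    for m in numerator_rois:
        num_mask |= m
    den_mask = np.zeros(img.shape, bool)
    for m in denominator_rois:
        den_mask |= m
    den = img[den_mask].mean()
    if den <= 0:
        raise ValueError("denominator ROI mean must be positive")
    return float(img[num_mask].mean() / den)


def fwhm_mass(
    image: np.ndarray,
    contours: MyocardialContours,
    density_g_per_ml: float = 1.05,
):
    """Full-width-half-maximum scar quantification.

    Threshold = half of the maximal signal intensity within the scar
    search region (the myocardial shell); scar voxels are shell voxels
    at or above the threshold; mass = voxel count x voxel volume x
    tissue density (1.05 g/mL).  Invariant to global intensity scaling.
    """
    img = np.abs(image)
    shell = contours.shell
    mx = img[shell].max()
    if mx == 0:
        return 0.0, np.zeros_like(shell)
    thr = 0.5 * mx
    scar_mask = shell & (img >= thr)
    mass = float(scar_mask.sum() * contours.voxel_volume_ml * density_g_per_ml)
    return mass, scar_mask


def edge_sharpness(image: np.ndarray, boundary_band_mask: np.ndarray) -> float:
    """Mean gradient magnitude within the band, normalized by the
    image's interior dynamic range (objective surrogate for reader-rated
    border sharpness).  Higher is sharper."""
    if not boundary_band_mask.any():
        raise ValueError("band mask is empty")
    img = np.abs(image)
    dyn = np.percentile(img, 99) - np.percentile(img, 1)
    if dyn <= 0:
        raise ValueError("zero dynamic range")
    grad = np.sqrt(sum(g**2 for g in np.gradient(img)))
    return float(grad[boundary_band_mask].mean() / dyn)


def rmse(image: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Root mean squared magnitude difference over the mask after
    least-squares global intensity matching of the image to the
    reference."""
    a = np.abs(image)
    r = np.abs(reference)
    if a.shape != r.shape:
        raise ValueError("image and reference must be conformal")
    if mask is None:
        mask = np.ones(a.shape, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    a = a[mask]
    r = r[mask]
    denom = float((a * a).sum())
    scale = float((a * r).sum()) / denom if denom > 0 else 1.0
    return float(np.sqrt(np.mean((scale * a - r) ** 2)))


# ---------------------------------------------------------------------------
# truth-derived analysis regions for the digital phantom


def _split_three(mask: np.ndarray):
    """Split a mask into three equal-count chunks ordered along its
    longest axis (equal counts guarantee three nonempty ROIs)."""
    idx = np.nonzero(mask)
    if idx[0].size < 3:
        raise ValueError("mask too small to split into three ROIs")
    ax = int(np.argmax([i.max() - i.min() for i in idx]))
    order = np.argsort(idx[ax], kind="stable")
    out = []
    for chunk in np.array_split(order, 3):
        part = np.zeros_like(mask)
        part[tuple(i[chunk] for i in idx)] = True
        out.append(part)
    return out


def truth_rois(labels: np.ndarray, erode: int = 1) -> ROISet:
    """Build the measurement ROIs from the phantom's truth labels:
    scar split into three chunks, remote myocardium (eroded, away from
    the scar) split into three chunks, and a luminal (eroded) blood
    ROI that contains no non-blood voxels."""
    scar = labels == LABELS["scar"]
    myo = labels == LABELS["myocardium"]
    blood = labels == LABELS["blood"]
    if erode:
        myo_e = ndimage.binary_erosion(myo, iterations=erode)
        blood_e = ndimage.binary_erosion(blood, iterations=erode + 1)
        scar_e = ndimage.binary_erosion(scar, iterations=erode)
        if scar_e.sum() >= 12:
            scar = scar_e
        if myo_e.sum() >= 12:
            myo = myo_e
        if blood_e.sum() >= 12:
            blood = blood_e
    near_scar = ndimage.binary_dilation(scar, iterations=3)
    remote = myo & ~near_scar
    return ROISet(_split_three(scar), _split_three(remote), blood)


def truth_contours(labels: np.ndarray, voxel_mm, endo_margin_vox: int = 0) -> MyocardialContours:
    """Endo/epicardial contours from the truth labels.

    ``endo_margin_vox`` optionally draws the endocardial contour that
    many voxels outside the blood pool (conservative contouring, which
    excludes blood partial volume from the shell at the price of cutting
    into subendocardial scar).  The default keeps the plain label
    boundary.
    """
    blood = labels == LABELS["blood"]
    shell = (labels == LABELS["myocardium"]) | (labels == LABELS["scar"])
    endo = ndimage.binary_dilation(blood, iterations=endo_margin_vox) if endo_margin_vox else blood
    endo &= blood | shell  # keep the contour inside the epicardium
    vox_ml = float(np.prod(voxel_mm)) / 1000.0
    return MyocardialContours(endo_mask=endo, epi_mask=blood | shell, voxel_volume_ml=vox_ml)


def boundary_band(labels: np.ndarray, width: int = 1) -> np.ndarray:
    """Band of voxels straddling the myocardium-blood interface, used by
    the edge-sharpness surrogate."""
    blood = labels == LABELS["blood"]
    myo = (labels == LABELS["myocardium"]) | (labels == LABELS["scar"])
    b = ndimage.binary_dilation(blood, iterations=width) & ndimage.binary_dilation(
        myo, iterations=width
    )
    if not b.any():
        raise ValueError("no myocardium-blood interface found")
    return b
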