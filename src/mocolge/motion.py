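"""Respiratory binning, k-space translational correction, and bin-to-bin
non-rigid motion-field estimation.

The non-rigid pipeline follows the order: sort lines into respiratory
bins by FH navigator position; translationally correct each bin toward
its own center with a k-space linear phase; reconstruct half-resolution
bin images from the opposed-phase echo; histogram-equalize them;
register every bin to the central bin (the average breathing position)
with translation-initialized diffeomorphic demons; interpolate the
fields back to the full grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.stats import rankdata

from .core import (
    AP,
    FH,
    RL,
    DeformationField,
    centered_freqs,
    crop_kspace_center,
    downsample_image_kspace,
)
from .phantom_sim import CoilSensitivities, KSpaceData

__all__ = [
    "BinAssignment",
    "assign_bins",
    "phase_shift_correct",
    "reconstruct_bin_images",
    "histogram_equalize",
    "RegistrationResult",
    "register_nonrigid",
    "upsample_field",
    "estimate_bin_fields",
]


@dataclass
class BinAssignment:
    """Partition of acquired lines into respiratory bins by FH position."""

    n_bins: int
    labels: np.ndarray  # [n_lines] int in 0..n_bins-1
    edges: np.ndarray  # [n_bins + 1] FH thresholds (mm), monotone
    centers: np.ndarray  # per-bin median FH (mm)
    central_bin: int  # bin whose center is nearest the overall FH median

    def lines_of_bin(self, b: int) -> np.ndarray:
        return np.nonzero(self.labels == b)[0]

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_bins)


def assign_bins(fh_per_line: np.ndarray, n_bins: int = 5) -> BinAssignment:
    """Equal-count (quantile) binning of per-line FH positions.

    Quantile bins guarantee comparably conditioned bin reconstructions.
    Degenerate quantile edges (fewer distinct FH values than bins) are
    merged with a warning.  The per-bin center is the median FH of its
    lines; the central bin is the one whose center is nearest the overall
    median (the average breathing position).
    """
    fh = np.asarray(fh_per_line, dtype=np.float64)
    if fh.ndim != 1 or fh.size == 0 or not np.all(np.isfinite(fh)):
        raise ValueError("fh_per_line must be a finite 1-D array")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.quantile(fh, np.linspace(0.0, 1.0, n_bins + 1))
    inner = np.unique(edges[1:-1])
    if inner.size < n_bins - 1:
        warnings.warn("fewer distinct FH values than bins; merging degenerate bins")
    labels = np.searchsorted(inner, fh, side="right")
    occupied = np.unique(labels)
    if occupied.size < labels.max() + 1:
        warnings.warn("empty quantile bin; compressing bin labels")
        labels = np.searchsorted(occupied, labels)
    n_eff = int(labels.max()) + 1
    centers = np.array([np.median(fh[labels == b]) for b in range(n_eff)])
    central = int(np.argmin(np.abs(centers - np.median(fh))))
    edges = np.concatenate([[edges[0]], inner, [edges[-1]]])
    return BinAssignment(n_eff, labels, edges, centers, central)


def phase_shift_correct(
    ksp: KSpaceData,
    fh_mm: np.ndarray,
    rl_mm: np.ndarray,
    target_fh_mm=0.0,
    target_rl_mm=0.0,
) -> KSpaceData:
    """Translational correction by k-space linear phase modulation.

    Each line acquired with the heart displaced by (fh, rl) is modulated
    so its contribution moves to the target position: sample at centered
    frequency f gains ``exp(+2 pi i f * delta)`` per axis, with
    ``delta = (measured - target)`` in voxels.  FH acts along the readout
    axis, RL along kz; AP is not observable from a coronal navigator.
    The modulation is unitary (sample magnitudes unchanged) and purely
    metadata-preserving.
    """
    fh_mm = np.asarray(fh_mm, dtype=np.float64)
    rl_mm = np.asarray(rl_mm, dtype=np.float64)
    if fh_mm.shape != (ksp.n_lines,) or rl_mm.shape != (ksp.n_lines,):
        raise ValueError("need one (fh, rl) shift per line")
    nx, ny, nz = ksp.grid_shape
    dvox = ksp.voxel_mm
    dx = (fh_mm - target_fh_mm) / dvox[FH]
    dz = (rl_mm - target_rl_mm) / dvox[RL]

    fx = centered_freqs(nx)
    fz = centered_freqs(nz)[ksp.kz]
    phase = np.exp(2j * np.pi * (fx[None, :] * dx[:, None] + (fz * dz)[:, None]))
    out = ksp.copy()
    out.data = out.data * phase[None, None, :, :]
    return out


def histogram_equalize(vol: np.ndarray, floor: float | None = None) -> np.ndarray:
    """Rank-based intensity remap of magnitudes to uniform [0, 1].

    Order-preserving (stable average ranks on ties) and invariant to any
    strictly monotone intensity warp of the input.  A constant volume
    maps to zeros.  ``floor`` clamps intensities from below first, which
    ties all background voxels to a single rank: without it the rank map
    would stretch background noise across a wide output range and
    dominate a registration metric.
    """
    mag = np.abs(np.asarray(vol))
    if floor is not None:
        out = np.zeros(mag.shape, dtype=np.float64)
        fg = mag > floor
        if fg.sum() > 1:
            r = rankdata(mag[fg], method="average")
            out[fg] = r / r.max()
        return out
    if mag.max() == mag.min():
        return np.zeros_like(mag, dtype=np.float64)
    ranks = rankdata(mag.ravel(), method="average").reshape(mag.shape)
    return (ranks - ranks.min()) / (ranks.max() - ranks.min())


def reconstruct_bin_images(
    ksp: KSpaceData,
    bins: BinAssignment,
    coils: CoilSensitivities,
    echo: int = 0,
    cg_params=None,
    line_subset=None,
):
    """Half-resolution per-bin reconstructions of one echo.

    Each bin's lines (assumed already translationally corrected toward
    the bin center) are cropped to the central half-size k-space region
    in all three dimensions and reconstructed with iterative SENSE on the
    half grid using decimated coil maps.  Half resolution is implemented
    as a central k-space crop, consistent with Fourier acquisition
    semantics.
    """
    from .recon import CGParams, itsense  # deferred: recon also imports this module

    if cg_params is None:
        cg_params = CGParams()
    nx, ny, nz = ksp.grid_shape
    half = (nx // 2, ny // 2, nz // 2)
    # amplitude-preserving scale for the cropped (orthonormal) spectra
    scale = np.sqrt(np.prod(half) / np.prod(ksp.grid_shape))
    maps_half = np.stack(
        [downsample_image_kspace(m, 2, rescale=True) for m in coils.maps]
    )
    coils_half = CoilSensitivities(maps_half)

    counts = bins.counts()
    if np.any(counts == 0):
        raise ValueError("every bin must contain at least one line")
    if np.any(counts < max(1, ksp.n_lines // 100)):
        warnings.warn("bin with < 1% of lines; expect a poor bin image")

    kx_lo = nx // 2 - half[0] // 2
    images, masks = [], []
    for b in range(bins.n_bins):
        sel = bins.lines_of_bin(b)
        if line_subset is not None:
            sel = sel[np.asarray(line_subset)[sel]]
        keep = sel[
            (np.abs(ksp.ky[sel] - ny // 2 + 0.5) < half[1] / 2)
            & (np.abs(ksp.kz[sel] - nz // 2 + 0.5) < half[2] / 2)
        ]
        gridded, mask = ksp.gridded(echo, keep)
        ksp_half = gridded[:, kx_lo : kx_lo + half[0], :, :]
        ksp_half = crop_kspace_center(ksp_half, half[1:], axes=(2, 3)) * scale
        mask_half = crop_kspace_center(mask, half[1:], axes=(0, 1))
        img, _ = itsense(ksp_half, coils_half, mask_half, cg_params)
        images.append(img)
        masks.append(mask_half)
    return images, masks


@dataclass
class RegistrationResult:
    field: DeformationField  # maps fixed-grid coords into the moving image
    metric_before: float
    metric_after: float
    converged: bool


_DEFAULT_REG = dict(iterations=40, levels=3, demons_stddev=1.5)


def _demons_pyramid(fix, mov, stddev: float, iterations: int, levels: int):
    """Multi-resolution diffeomorphic demons; returns the displacement
    field transform on the fixed grid."""
    field = None
    for lev in range(levels - 1, -1, -1):
        shrink = 2**lev
        if shrink > 1:
            sigma = shrink / 2.0
            fl = sitk.Shrink(sitk.SmoothingRecursiveGaussian(fix, sigma), [shrink] * 3)
            ml = sitk.Shrink(sitk.SmoothingRecursiveGaussian(mov, sigma), [shrink] * 3)
        else:
            fl, ml = fix, mov
        if field is None:
            init = sitk.Image(fl.GetSize(), sitk.sitkVectorFloat64, 3)
            init.CopyInformation(fl)
        else:
            init = sitk.Resample(field, fl)
        dem = sitk.DiffeomorphicDemonsRegistrationFilter()
        dem.SetNumberOfIterations(iterations)
        dem.SetSmoothDisplacementField(True)
        dem.SetStandardDeviations(stddev)
        field = dem.Execute(fl, ml, init)
    return sitk.DisplacementFieldTransform(sitk.Image(field))


def register_nonrigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    settings: dict | None = None,
    init_translation_vox=None,
) -> RegistrationResult:
    """Non-rigid registration: translation pre-alignment followed by
    diffeomorphic demons.

    The translation stage (mean-squares metric, all voxels, LBFGSB)
    captures the bulk shift; when the bulk shift is already known (e.g.
    from navigator-derived bin centers) it can be supplied directly as
    ``init_translation_vox`` (FH, AP, RL voxels) and the stage is
    skipped.  The demons stage models the residual deformation with
    Gaussian regularization of the displacement field
    (``demons_stddev``, voxels).  Returns the displacement field ``u``
    such that resampling the moving image at ``r + u(r)`` matches the
    fixed image: ``u`` maps fixed-grid coordinates into the moving
    image.  All settings are deterministic.  If the metric did not
    improve, the best-so-far field is returned with
    ``converged = False``.
    """
    if moving.shape != fixed.shape:
        raise ValueError("moving / fixed grid mismatch")
    cfg = dict(_DEFAULT_REG)
    if settings:
        cfg.update(settings)

    mov = sitk.GetImageFromArray(np.ascontiguousarray(moving, dtype=np.float64))
    fix = sitk.GetImageFromArray(np.ascontiguousarray(fixed, dtype=np.float64))
    levels = int(cfg["levels"])

    if init_translation_vox is not None:
        off = np.asarray(init_translation_vox, dtype=np.float64)
        t_tx = sitk.TranslationTransform(3, tuple(off[::-1]))  # sitk xyz = axes 2,1,0
    else:
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMeanSquares()
        reg.SetMetricSamplingStrategy(reg.NONE)
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsLBFGSB(gradientConvergenceTolerance=1e-9, numberOfIterations=60)
        reg.SetInitialTransform(sitk.TranslationTransform(3), inPlace=True)
        reg.SetShrinkFactorsPerLevel([2 ** (levels - 1 - i) for i in range(levels)])
        reg.SetSmoothingSigmasPerLevel([float(levels - 1 - i) for i in range(levels)])
        t_tx = reg.Execute(fix, mov)

    mov_pre = sitk.Resample(mov, fix, t_tx, sitk.sitkLinear, 0.0)
    d_tx = _demons_pyramid(
        fix, mov_pre, float(cfg["demons_stddev"]), int(cfg["iterations"]), levels
    )
    out_tx = sitk.CompositeTransform([t_tx, d_tx])

    df = sitk.TransformToDisplacementField(
        out_tx,
        sitk.sitkVectorFloat64,
        fix.GetSize(),
        fix.GetOrigin(),
        fix.GetSpacing(),
        fix.GetDirection(),
    )
    arr = sitk.GetArrayFromImage(df)  # [n0, n1, n2, (x=axis2, y=axis1, z=axis0)]
    disp = np.stack([arr[..., 2 - a] for a in range(3)])

    # the demons stage must beat the translation-aligned baseline
    aligned = sitk.GetArrayFromImage(sitk.Resample(mov, fix, t_tx, sitk.sitkLinear, 0.0))
    warped = sitk.GetArrayFromImage(sitk.Resample(mov, fix, out_tx, sitk.sitkLinear, 0.0))
    before = float(np.mean((aligned - fixed) ** 2))
    after = float(np.mean((warped - fixed) ** 2))
    converged = after <= before
    if not converged:
        warnings.warn("registration metric did not improve; returning best-so-far field")
    fld = DeformationField(disp, resolution_level="half")
    return RegistrationResult(fld, before, after, converged)


def upsample_field(fld: DeformationField, full_shape=None) -> DeformationField:
    """Trilinear interpolation of a half-resolution field to the full
    grid, with displacements scaled by the per-axis grid-size ratio."""
    if fld.resolution_level != "half":
        raise ValueError("expected a half-resolution field")
    half = fld.grid_shape
    if full_shape is None:
        full_shape = tuple(2 * n for n in half)
    ratio = [full_shape[a] / half[a] for a in range(3)]
    disp = np.stack(
        [ndimage.zoom(fld.disp[a], ratio, order=1, mode="nearest") * ratio[a] for a in range(3)]
    )
    return DeformationField(disp, resolution_level="full")


_PIPELINE_REG = dict(iterations=40, levels=1, demons_stddev=1.5, residual_smooth_vox=6.0)


def _interior_fg(eq_a: np.ndarray, eq_b: np.ndarray, trim: int = 4) -> np.ndarray:
    """Joint foreground away from the volume boundary.

    The trim matters: respiratory shifts move content across the FOV
    edge, where the zero-padded simulator/warp and the circular k-space
    phase shifts disagree systematically — nothing estimated there is
    trustworthy.
    """
    valid = (eq_a > 0) & (eq_b > 0)
    t = trim
    valid[:t] = valid[-t:] = False
    valid[:, :t] = valid[:, -t:] = False
    valid[:, :, :t] = valid[:, :, -t:] = False
    return valid


def _equalized(bin_images):
    from skimage.filters import threshold_otsu

    # clamp background (noise / undersampling artifact) below a robust
    # foreground threshold so equalization spreads anatomy, not noise
    return [
        histogram_equalize(im, floor=0.5 * threshold_otsu(np.abs(im))) for im in bin_images
    ]


def _bin_residual(eq_central, eq_b, init, cfg):
    """Register central -> bin and return the (smoothed) residual beyond
    the bulk translation, plus the RegistrationResult."""
    res = register_nonrigid(
        moving=eq_central, fixed=eq_b, settings=cfg, init_translation_vox=init
    )
    t = np.zeros((3, 1, 1, 1))
    if init is not None:
        t = np.asarray(init, dtype=np.float64).reshape(3, 1, 1, 1)
    # a demons stage that failed to improve the metric is not trusted:
    # fall back to the bulk translation for that bin
    if not res.converged:
        return np.zeros_like(res.field.disp), res
    resid = res.field.disp - t
    sig = float(cfg["residual_smooth_vox"])
    if sig > 0:
        # keep only the large-scale part of the residual: genuine
        # respiratory deformation varies over the whole volume, while
        # artifact-chasing components of the demons field are
        # mid-frequency and average away; the smoothing is confined to
        # the joint foreground
        valid = _interior_fg(eq_central, eq_b)
        w = ndimage.gaussian_filter(valid.astype(np.float64), sig)
        resid = np.stack(
            [
                np.where(
                    w > 1e-3,
                    ndimage.gaussian_filter(resid[a] * valid, sig) / np.maximum(w, 1e-3),
                    0.0,
                )
                for a in range(3)
            ]
        )
    return resid, res


def estimate_bin_fields(
    bin_images,
    central_bin: int,
    full_shape=None,
    settings: dict | None = None,
    bin_translations_vox=None,
    include_translation: bool = True,
):
    """Histogram-equalize bin images, register to the central bin, and
    return full-resolution per-bin deformation fields.

    ``bin_translations_vox`` optionally supplies, per bin, the known
    (FH, AP, RL) displacement of the central bin relative to that bin
    in half-grid voxels (available from the navigator-derived bin
    centers); when given, the registration's translation stage is
    initialized with it exactly and demons only estimates the residual
    deformation.  The pipeline default is a single demons level:
    coarse pyramid levels of heavily undersampled bin images inject
    spurious large-scale deformation.

    The returned field of bin b, applied as a pull-back warp, maps the
    central-bin (average breathing position) image onto bin b's anatomy,
    which is the warp the motion-compensated encoding operator needs.
    With ``include_translation=False`` the bulk inter-bin translation is
    left out and only the non-rigid residual is returned — the right
    warp when the final reconstruction's k-space data are beat-wise
    translationally corrected to the central position rather than to
    the per-bin centers.  The central bin's entry is None (identity).
    """
    cfg = dict(_PIPELINE_REG)
    if settings:
        cfg.update(settings)
    eq = _equalized(bin_images)

    fields, reg_info = [], []
    for b, im in enumerate(eq):
        if b == central_bin:
            fields.append(None)
            reg_info.append(None)
            continue
        init = None if bin_translations_vox is None else bin_translations_vox[b]
        t = np.zeros((3, 1, 1, 1))
        if init is not None:
            t = np.asarray(init, dtype=np.float64).reshape(3, 1, 1, 1)
        # u maps bin-b grid coords into the central image; the pull-back
        # warp of the central image with -u produces bin b's anatomy
        resid, res = _bin_residual(eq[central_bin], im, init, cfg)
        u = (t + resid) if include_translation else resid
        half = DeformationField(-u, resolution_level="half")
        fields.append(upsample_field(half, full_shape))
        reg_info.append(res)
    return fields, reg_info
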