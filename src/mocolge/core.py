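"""Shared conventions and numeric primitives.

Coordinate convention (fixed project-wide):
    axis 0 = FH (foot-head, head positive)
    axis 1 = AP (anterior-posterior, anterior positive)
    axis 2 = RL (right-left, right positive)
Voxel indices are 0-based. The k-space DC sample sits at index ``n // 2``
on every axis (centered spectra); FFTs are orthonormal.

Deformation fields are dense per-voxel displacement vectors in voxel
units.  Warping an image ``I`` with a field ``d`` produces
``J(r) = I(r - d(r))``: a positive FH component moves anatomy toward the
head.  The adjoint of the warp is the exact transpose of the linear
interpolation matrix (scatter), not the inverse warp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

FH, AP, RL = 0, 1, 2

__all__ = [
    "FH",
    "AP",
    "RL",
    "fftc",
    "ifftc",
    "centered_freqs",
    "DeformationField",
    "warp_image",
    "warp_matrix",
    "crop_kspace_center",
    "downsample_image_kspace",
]


def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centered orthonormal FFT (DC at n//2 on every transformed axis)."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Inverse of :func:`fftc`."""
    if axes is None:
        axes = tuple(range(x.ndim))
    return np.fft.ifftshift(
        np.fft.ifftn(np.fft.fftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def centered_freqs(n: int) -> np.ndarray:
    """Frequencies (cycles/voxel) of the centered spectrum: (idx - n//2)/n."""
    return (np.arange(n) - n // 2) / n


@dataclass
class DeformationField:
    """Dense displacement field, one 3-vector per voxel, in voxel units.

    ``disp[a]`` is the displacement along axis ``a`` on the field's own
    grid.  ``resolution_level`` distinguishes half-resolution fields
    (estimated on bin images) from full-resolution ones (used in the
    encoding operator).
    """

    disp: np.ndarray  # [3, nx, ny, nz], float
    resolution_level: str = "full"  # {"half", "full"}
    sanity_limit_vox: float = 30.0

    def __post_init__(self):
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[0] != 3:
            raise ValueError("disp must have shape [3, nx, ny, nz]")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("non-finite displacements")
        m = float(np.abs(self.disp).max())
        if m > self.sanity_limit_vox:
            raise ValueError(
                f"max |disp| = {m:.1f} voxels exceeds sanity limit "
                f"{self.sanity_limit_vox}"
            )

    @property
    def grid_shape(self):
        return self.disp.shape[1:]

    def max_abs(self) -> float:
        return float(np.abs(self.disp).max())


def warp_image(img: np.ndarray, fld: DeformationField, order: int = 1) -> np.ndarray:
    """Pull-back warp: out(r) = img(r - disp(r)), linear interpolation.

    Out-of-range samples read as zero.  Complex images are warped by
    real/imag parts.
    """
    if img.shape != fld.grid_shape:
        raise ValueError("image / field grid mismatch")
    coords = np.mgrid[[slice(n) for n in img.shape]].astype(np.float64)
    coords -= fld.disp
    if np.iscomplexobj(img):
        re = ndimage.map_coordinates(img.real, coords, order=order, mode="constant")
        im = ndimage.map_coordinates(img.imag, coords, order=order, mode="constant")
        return re + 1j * im
    return ndimage.map_coordinates(img, coords, order=order, mode="constant")


def _keys_cubic(t: np.ndarray) -> np.ndarray:
    """Catmull-Rom (Keys, a = -1/2) cubic convolution kernel."""
    at = np.abs(t)
    out = np.zeros_like(at)
    m1 = at < 1
    m2 = (at >= 1) & (at < 2)
    out[m1] = 1.5 * at[m1] ** 3 - 2.5 * at[m1] ** 2 + 1.0
    out[m2] = -0.5 * at[m2] ** 3 + 2.5 * at[m2] ** 2 - 4.0 * at[m2] + 2.0
    return out


def warp_matrix(fld: DeformationField, order: int = 1) -> sparse.csr_matrix:
    """Sparse interpolation matrix W with (W x)(r) = x(r - d(r)).

    ``order`` 1 builds trilinear weights (8 neighbours per voxel);
    ``order`` 3 builds Catmull-Rom cubic-convolution weights (64
    neighbours), which attenuate high frequencies far less at
    fractional displacements.  Rows index output voxels, columns input
    voxels (both flattened in C order).  Out-of-range interpolation
    neighbours are dropped (zero boundary), so ``W.T`` is the exact
    adjoint used by the reconstruction.
    """
    if order not in (1, 3):
        raise ValueError("order must be 1 or 3")
    shape = fld.grid_shape
    nvox = int(np.prod(shape))
    coords = np.mgrid[[slice(n) for n in shape]].astype(np.float64)
    coords -= fld.disp
    pts = coords.reshape(3, nvox)

    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    offsets = (0, 1) if order == 1 else (-1, 0, 1, 2)

    # per-axis weights for each offset
    wax = []
    for a in range(3):
        if order == 1:
            wax.append({0: 1.0 - frac[a], 1: frac[a]})
        else:
            wax.append({j: _keys_cubic(frac[a] - j) for j in offsets})

    rows, cols, vals = [], [], []
    row_idx = np.arange(nvox)
    for j0 in offsets:
        w0 = wax[0][j0]
        i0 = base[0] + j0
        for j1 in offsets:
            w01 = w0 * wax[1][j1]
            i1 = base[1] + j1
            for j2 in offsets:
                w = w01 * wax[2][j2]
                i2 = base[2] + j2
                valid = (
                    (np.abs(w) > 1e-12)
                    & (i0 >= 0) & (i0 < shape[0])
                    & (i1 >= 0) & (i1 < shape[1])
                    & (i2 >= 0) & (i2 < shape[2])
                )
                flat = (i0 * shape[1] + i1) * shape[2] + i2
                rows.append(row_idx[valid])
                cols.append(flat[valid])
                vals.append(w[valid])

    W = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nvox, nvox),
    )
    return W.tocsr()


def crop_kspace_center(ksp: np.ndarray, new_shape, axes=None) -> np.ndarray:
    """Central crop of a centered spectrum (DC at n//2 stays at n'//2)."""
    if axes is None:
        axes = tuple(range(-len(new_shape), 0))
    sl = [slice(None)] * ksp.ndim
    for a, m in zip(axes, new_shape):
        n = ksp.shape[a]
        if m > n:
            raise ValueError("crop larger than input")
        lo = n // 2 - m // 2
        sl[a] = slice(lo, lo + m)
    return ksp[tuple(sl)]


def downsample_image_kspace(img: np.ndarray, factor: int = 2, rescale: bool = True) -> np.ndarray:
    """Downsample an image by central k-space cropping (Fourier truncation).

    With ``rescale``, intensities are scaled so that a smooth (band-limited)
    image keeps its amplitude.
    """
    new_shape = tuple(n // factor for n in img.shape)
    out = ifftc(crop_kspace_center(fftc(img), new_shape))
    if rescale:
        out = out * np.sqrt(np.prod(new_shape) / np.prod(img.shape))
    return out
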