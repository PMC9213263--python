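"""Two-point Dixon water-fat separation of the reconstructed
opposed-phase (TE1) and in-phase (TE2) echo images.

Under the exact opposed/in-phase convention the separation is the
closed-form combination W = |IP + OP| / 2, F = |IP - OP| / 2.  An
optional smooth-phasor mode estimates the slowly varying off-resonance
(B0) phase from IP * conj(OP), low-passes it, and demodulates both
echoes before combining, which guards against water-fat swaps caused by
background field variation.  Outputs are magnitude maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EchoPair", "separate"]


@dataclass
class EchoPair:
    op_image: np.ndarray  # complex volume at TE1 (fat opposed to water)
    ip_image: np.ndarray  # complex volume at TE2 (fat in phase)
    te1_ms: float = 2.38
    te2_ms: float = 4.76

    def __post_init__(self):
        if self.op_image.shape != self.ip_image.shape:
            raise ValueError("echo images must share the grid")
        if not (self.te2_ms > self.te1_ms):
            raise ValueError("te2_ms must exceed te1_ms")


def _weighted_poly_phase(z: np.ndarray, order: int) -> np.ndarray:
    """Fit angle(z) with a degree-``order`` polynomial in the voxel
    coordinates, weighted by |z| (voxels without signal carry no phase
    information).  Assumes the phase does not wrap, the regime a
    two-point acquisition can resolve anyway."""
    shape = z.shape
    g = [c.ravel() / max(n - 1, 1) for c, n in zip(np.mgrid[[slice(n) for n in shape]], shape)]
    cols = [np.ones(g[0].size)]
    cols += list(g)
    if order >= 2:
        cols += [gi * gj for i, gi in enumerate(g) for gj in g[i:]]
    A = np.stack(cols, axis=1)
    w = np.abs(z).ravel()
    ph = np.angle(z).ravel()
    Aw = A * w[:, None]
    coef, *_ = np.linalg.lstsq(Aw, ph * w, rcond=None)
    return (A @ coef).reshape(shape)


def separate(pair: EchoPair, phase_correction: str = "none", b0_poly_order: int = 2):
    """Separate water and fat from an in-/opposed-phase echo pair.

    phase_correction:
        "none" — direct magnitude combination (exact under ideal phases).
        "smooth_phasor" — estimate the slowly varying B0 phase from the
        squared echo-product (the squaring removes the sign ambiguity of
        fat-dominant voxels) as a magnitude-weighted low-order polynomial
        field, demodulate both echoes, remove the residual
        echo-independent (receiver) phase the same way, and combine.
        Guards against water-fat swaps caused by background field
        variation.

    Returns (water, fat) magnitude volumes.
    """
    op = np.asarray(pair.op_image, dtype=np.complex128)
    ip = np.asarray(pair.ip_image, dtype=np.complex128)

    if phase_correction == "none":
        water = np.abs(ip + op) / 2.0
        fat = np.abs(ip - op) / 2.0
        return water, fat
    if phase_correction != "smooth_phasor":
        raise ValueError("phase_correction must be 'none' or 'smooth_phasor'")

    dte = pair.te2_ms - pair.te1_ms
    # (ip conj(op))^2 has phase 2 * (B0 phase accrued over dte),
    # independent of whether water or fat dominates the voxel
    phi = 0.5 * _weighted_poly_phase((ip * np.conj(op)) ** 2, b0_poly_order)
    op_c = op * np.exp(-1j * phi * pair.te1_ms / dte)
    ip_c = ip * np.exp(-1j * phi * pair.te2_ms / dte)
    # residual echo-independent phase (coil/receiver), estimated from the
    # in-phase echo whose tissue phasor is non-negative (W + F)
    phi0 = _weighted_poly_phase(ip_c, b0_poly_order)
    op_c = op_c * np.exp(-1j * phi0)
    ip_c = ip_c * np.exp(-1j * phi0)
    water = np.abs(ip_c + op_c) / 2.0
    fat = np.abs(ip_c - op_c) / 2.0
    return water, fat
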