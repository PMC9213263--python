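"""Beat-to-beat translational motion estimation from 2D image navigators.

Each heartbeat's coronal iNAV frame is matched against a template cut
from a fixed reference frame using normalized cross-correlation; the
correlation peak is refined to sub-pixel precision by Fourier-upsampled
phase correlation.  Only the in-plane directions of a coronal
navigator are observable: foot-head (frame axis 0) and right-left
(frame axis 1).  A positive FH estimate means the heart moved toward
the head relative to the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

__all__ = ["INavStack", "track_template"]


@dataclass
class INavStack:
    """Stack of per-beat low-resolution coronal navigator frames.

    frames: real array [beat, u, v] with u = FH, v = RL.
    pixel_mm: pixel size, a scalar or a per-axis (FH, RL) pair (the two
        axes may be downsampled by different factors).
    template_box: (u0, u1, v0, v1) half-open bounds of the tracking
        template within the reference frame.  Defaults to the central
        three quarters of the frame — a template covering the whole
        heart plus surroundings tracks with less scatter than a tight
        crop on these low-resolution frames.
    """

    frames: np.ndarray
    pixel_mm: float | tuple
    template_box: tuple | None = None
    reference_beat: int = 0
    frames_ip: np.ndarray | None = None  # in-phase echo frames (not tracked)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if np.isscalar(self.pixel_mm):
            self.pixel_mm = (float(self.pixel_mm), float(self.pixel_mm))
        else:
            self.pixel_mm = tuple(float(p) for p in self.pixel_mm)
        if self.frames.ndim != 3:
            raise ValueError("frames must be [beat, u, v]")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite navigator frames")
        nu, nv = self.frames.shape[1:]
        if self.template_box is None:
            self.template_box = (nu // 8, nu - nu // 8, nv // 8, nv - nv // 8)
        u0, u1, v0, v1 = self.template_box
        if not (0 <= u0 < u1 <= nu and 0 <= v0 < v1 <= nv):
            raise ValueError("template_box out of frame bounds")
        if not (0 <= self.reference_beat < self.frames.shape[0]):
            raise ValueError("reference_beat out of range")

    @property
    def n_beats(self) -> int:
        return self.frames.shape[0]


def _quadratic_peak_offset(c_m, c_0, c_p):
    denom = c_m - 2.0 * c_0 + c_p
    if abs(denom) < 1e-15:
        return 0.0
    delta = 0.5 * (c_m - c_p) / denom
    return float(np.clip(delta, -0.5, 0.5))


def track_template(stack: INavStack):
    """Track the reference template through all frames.

    Returns ``(fh_mm, rl_mm, reliable)``: per-beat in-plane shifts of the
    heart relative to the reference beat (which maps to exactly 0), and a
    flag that is False where the correlation peak sat on the border of
    the search window (estimate untrustworthy).

    The integer-pixel match from normalized cross-correlation is refined
    to sub-pixel precision by Fourier upsampling of the cross-correlation
    between the template and the matched patch; where the patch would
    leave the frame, separable quadratic peak interpolation is the
    fallback.
    """
    if stack.n_beats < 2:
        raise ValueError("need at least 2 navigator frames")
    u0, u1, v0, v1 = stack.template_box
    template = stack.frames[stack.reference_beat, u0:u1, v0:v1]
    if template.std() == 0:
        raise ValueError("flat (zero-variance) template cannot be tracked")
    th, tw = template.shape

    fh = np.zeros(stack.n_beats)
    rl = np.zeros(stack.n_beats)
    reliable = np.ones(stack.n_beats, dtype=bool)
    for k in range(stack.n_beats):
        if k == stack.reference_beat:
            continue
        frame = stack.frames[k]
        ncc = match_template(frame, template, pad_input=False)
        pu, pv = np.unravel_index(np.argmax(ncc), ncc.shape)
        if pu in (0, ncc.shape[0] - 1) or pv in (0, ncc.shape[1] - 1):
            reliable[k] = False
            du = dv = 0.0
        else:
            patch = frame[pu : pu + th, pv : pv + tw]
            if patch.shape == template.shape:
                shift, _, _ = phase_cross_correlation(
                    template, patch, upsample_factor=20, normalization=None
                )
                du, dv = -shift[0], -shift[1]
            else:
                du = _quadratic_peak_offset(ncc[pu - 1, pv], ncc[pu, pv], ncc[pu + 1, pv])
                dv = _quadratic_peak_offset(ncc[pu, pv - 1], ncc[pu, pv], ncc[pu, pv + 1])
        fh[k] = (pu + du - u0) * stack.pixel_mm[0]
        rl[k] = (pv + dv - v0) * stack.pixel_mm[1]
    return fh, rl, reliable
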