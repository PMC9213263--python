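"""Variable-density golden-step Cartesian trajectory with spiral profile
ordering (VD-CASPR).

Each heartbeat acquires one spiral-like interleaf of Cartesian
phase-encode points (ky, kz), emitted from the k-space center outward
(centric in-out).  Successive beats rotate the interleaf by the golden
step (137.508 deg), and the radial sample density decreases linearly
toward the periphery, so the center of k-space reaches full sampling
long before the edge.  The construction is fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

GOLDEN_STEP_DEG = 137.508

__all__ = [
    "CartesianTrajectory",
    "generate_vdcaspr",
    "sampling_mask",
    "measured_acceleration",
    "paper_trajectory_defaults",
]


@dataclass
class CartesianTrajectory:
    """Ordered list of acquired phase-encode lines on an ny x nz grid."""

    ky: np.ndarray  # [n_lines] int
    kz: np.ndarray  # [n_lines] int
    beat: np.ndarray  # [n_lines] int, non-decreasing
    order_in_beat: np.ndarray  # [n_lines] int, 0..L_b-1 within each beat
    ny: int
    nz: int
    accel_nominal: float = 1.0

    def __post_init__(self):
        for name in ("ky", "kz", "beat", "order_in_beat"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        if np.any(self.ky < 0) or np.any(self.ky >= self.ny):
            raise ValueError("ky out of range")
        if np.any(self.kz < 0) or np.any(self.kz >= self.nz):
            raise ValueError("kz out of range")

    @property
    def n_lines(self) -> int:
        return self.ky.size

    @property
    def n_beats(self) -> int:
        return int(self.beat.max()) + 1 if self.n_lines else 0

    def lines_of_beat(self, b: int) -> np.ndarray:
        return np.nonzero(self.beat == b)[0]


def _arm_cells(ny, nz, theta0, density_p, turns, n_cand=4096):
    """Cells visited by one centric in-out spiral arm, center outward.

    Radial candidate density falls off as (1 - r)^p; the inverse CDF for
    p = 1 is r(u) = 1 - sqrt(1 - u).  The arm's radius is stretched per
    azimuth to the bounding rectangle so grid corners stay reachable.
    Returns flat (ky*nz + kz) indices in first-visit order.
    """
    cy, cz = ny // 2, nz // 2
    u = np.linspace(0.0, 1.0, n_cand)
    if density_p == 1:
        r = 1.0 - np.sqrt(1.0 - u)
    else:
        # inverse CDF of the (1-r)^p density, tabulated numerically
        rr = np.linspace(0.0, 1.0, 4096)
        cdf = np.cumsum((1.0 - rr) ** density_p)
        cdf /= cdf[-1]
        r = np.interp(u, cdf, rr)
    theta = theta0 + turns * 2.0 * np.pi * r
    ct, st = np.cos(theta), np.sin(theta)
    ay, az = (ny - 1) / 2.0, (nz - 1) / 2.0
    # stretch factor taking the unit radius to the rectangle boundary
    with np.errstate(divide="ignore"):
        lim = np.minimum(1.0 / np.maximum(np.abs(ct), 1e-12),
                         1.0 / np.maximum(np.abs(st), 1e-12))
    lim = np.minimum(lim, np.sqrt(2.0))
    ky = np.clip(np.round(cy + r * lim * ay * ct), 0, ny - 1).astype(np.int64)
    kz = np.clip(np.round(cz + r * lim * az * st), 0, nz - 1).astype(np.int64)
    flat = ky * nz + kz
    # keep first visit of each cell, preserving walk order
    _, first = np.unique(flat, return_index=True)
    return flat[np.sort(first)]


def _generate_with_budget(
    ny, nz, n_beats, total_lines, golden_step_deg, density_p, turns, core_radius=0.12
):
    """Emit interleaves under a total line budget.

    Every beat starts at the exact k-space center (centric in-out,
    keeping the center adjacent in time to the beat's navigator) and may
    re-acquire any cell of the low-k core (normalized ellipse radius <=
    ``core_radius``): the repeatedly sampled core is what gives every
    respiratory bin a fully sampled k-space center to reconstruct its
    bin image from.  Outside the core each cell is acquired at most once
    over the whole scan: a cell already taken by a previous beat is
    skipped and the walk continues to the next radial candidate.  A beat
    whose arm is exhausted before its budget falls back to the nearest
    not-yet-acquired cells (sorted by radius, then angular distance to
    the arm), so full coverage is reachable in the accel = 1 limit.
    """
    grid = ny * nz
    center_flat = (ny // 2) * nz + (nz // 2)

    # cell geometry: normalized ellipse radius and azimuth of every cell
    yy, zz = np.divmod(np.arange(grid), nz)
    ay, az = max((ny - 1) / 2.0, 1e-9), max((nz - 1) / 2.0, 1e-9)
    cr = np.hypot((yy - ny // 2) / ay, (zz - nz // 2) / az)
    cang = np.arctan2((zz - nz // 2) / az, (yy - ny // 2) / ay)
    core = cr <= core_radius

    acquired = np.zeros(grid, dtype=bool)
    acquired[center_flat] = True

    base, extra = divmod(total_lines, n_beats)
    ky_all, kz_all, beat_all, order_all = [], [], [], []
    for b in range(n_beats):
        lb = base + (1 if b < extra else 0)
        if lb == 0:
            continue
        theta0 = np.deg2rad((b * golden_step_deg) % 360.0)
        cells = _arm_cells(ny, nz, theta0, density_p, turns)
        cells = cells[cells != center_flat]
        fresh = cells[core[cells] | ~acquired[cells]]
        take = fresh[: lb - 1]
        if take.size < lb - 1 and not acquired.all():
            need = lb - 1 - take.size
            rest = np.nonzero(~acquired)[0]
            rest = np.setdiff1d(rest, take, assume_unique=False)
            if rest.size:
                d = np.abs((cang[rest] - theta0 + np.pi) % (2 * np.pi) - np.pi)
                order = np.lexsort((d, np.round(cr[rest], 6)))
                take = np.concatenate([take, rest[order][:need]])
        flat = np.concatenate([[center_flat], take])
        acquired[take] = True
        ky_all.append(flat // nz)
        kz_all.append(flat % nz)
        beat_all.append(np.full(flat.size, b, dtype=np.int64))
        order_all.append(np.arange(flat.size, dtype=np.int64))
    return (
        np.concatenate(ky_all),
        np.concatenate(kz_all),
        np.concatenate(beat_all),
        np.concatenate(order_all),
    )


def generate_vdcaspr(
    ny: int,
    nz: int,
    accel: float = 1.0,
    n_beats: int = 100,
    lines_per_beat: int | None = None,
    golden_step_deg: float = GOLDEN_STEP_DEG,
    density_p: float = 1.0,
    turns: float = 0.5,
) -> CartesianTrajectory:
    """Generate a VD-CASPR sampling pattern.

    If ``lines_per_beat`` is given, each beat acquires exactly that many
    lines.  Otherwise the per-beat line budget is derived from ``accel``:
    a deterministic bisection picks the total line count whose unique
    (ky, kz) coverage matches the prescribed undersampling factor (this
    is how the sequence budget is planned for a prescribed acceleration:
    golden-step arms overlap, so the total must exceed the unique
    budget).
    """
    if accel < 1:
        raise ValueError("accel must be >= 1")
    grid = ny * nz
    if accel > grid:
        raise ValueError("acceleration exceeds grid capacity")

    if lines_per_beat is not None:
        if lines_per_beat > grid:
            raise ValueError("lines_per_beat exceeds grid capacity")
        total = lines_per_beat * n_beats
        if total < max(16, grid // 100):
            warnings.warn("line budget may not cover the k-space center")
        ky, kz, beat, order = _generate_with_budget(
            ny, nz, n_beats, total, golden_step_deg, density_p, turns
        )
        return CartesianTrajectory(ky, kz, beat, order, ny, nz, accel_nominal=accel)

    target_unique = grid / accel

    def unique_count(total):
        ky, kz, _, _ = _generate_with_budget(
            ny, nz, n_beats, total, golden_step_deg, density_p, turns
        )
        return np.unique(ky * nz + kz).size

    lo, hi = n_beats, grid * 4
    while unique_count(hi) < target_unique and hi < grid * 32:
        hi *= 2
    for _ in range(40):
        if hi - lo <= 1:
            break
        mid = (lo + hi) // 2
        if unique_count(mid) < target_unique:
            lo = mid
        else:
            hi = mid
    # pick the closer of the bracketing budgets
    best = min((lo, hi), key=lambda t: abs(unique_count(t) - target_unique))
    ky, kz, beat, order = _generate_with_budget(
        ny, nz, n_beats, best, golden_step_deg, density_p, turns
    )
    return CartesianTrajectory(ky, kz, beat, order, ny, nz, accel_nominal=accel)


def paper_trajectory_defaults() -> dict:
    """Acquisition-scale trajectory configuration: 240 x 240 encode grid,
    3.3-fold undersampling, and a beat count matching a ~10.5 min scan at
    ~69 bpm."""
    return dict(ny=240, nz=240, accel=3.3, n_beats=722)


def sampling_mask(traj: CartesianTrajectory, line_idx=None) -> np.ndarray:
    """Binary ny x nz map of acquired phase-encode locations.

    ``line_idx`` restricts the mask to a subset of lines (e.g. one
    respiratory bin).
    """
    mask = np.zeros((traj.ny, traj.nz), dtype=bool)
    ky, kz = traj.ky, traj.kz
    if line_idx is not None:
        ky, kz = ky[line_idx], kz[line_idx]
    mask[ky, kz] = True
    return mask


def measured_acceleration(traj: CartesianTrajectory) -> float:
    """ny*nz divided by the number of unique acquired (ky, kz) locations."""
    if traj.n_lines == 0:
        raise ValueError("empty trajectory")
    n_unique = np.unique(traj.ky * traj.nz + traj.kz).size
    return traj.ny * traj.nz / n_unique
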