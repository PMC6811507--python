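"""Velocity-volume preprocessing: aliasing correction and background phase.

Phase-contrast velocities wrap when the true speed exceeds the venc,
producing jumps of ~2 venc between neighboring voxels.  Unwrapping partitions
each velocity component into wrap-consistent regions and shifts whole regions
by one wrap (+/- 2 venc) to match their neighbors across the jump
boundaries; it is idempotent on alias-free data.

Eddy currents leave a spatially smooth spurious phase that biases every
velocity.  It is estimated by a low-order polynomial least-squares fit to
static-tissue voxels and subtracted everywhere, mirroring standard
phase-contrast background-offset correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VelocityVolume

__all__ = [
    "UnwrapResult",
    "BackgroundModel",
    "unwrap_velocity",
    "detect_static_tissue",
    "correct_background_phase",
]



@dataclass
class UnwrapResult:
    volume: VelocityVolume
    n_corrected: int
    n_iterations: int


@dataclass
class BackgroundModel:
    """Fitted per-axis background velocity offset.

    ``coeffs[axis]`` are the polynomial coefficients in velocity units
    (cm/s, cm/s per cm, ...) against the monomial basis returned by
    :func:`_design_matrix`; ``residual_rms[axis]`` is the post-fit RMS over
    the static-tissue mask.
    """

    coeffs: np.ndarray
    order: int
    mask: np.ndarray
    residual_rms: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("background coefficients must be finite")
        if not np.any(self.mask):
            raise ValueError("static-tissue mask is empty")


def _consistent_regions(v: np.ndarray, thr: float):
    """Label maximal face-connected regions without wrap jumps (> thr)."""
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    shape = v.shape
    n = v.size
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a = idx[tuple(sl_a)].ravel()
        b = idx[tuple(sl_b)].ravel()
        ok = np.abs(v.ravel()[a] - v.ravel()[b]) <= thr
        rows.append(a[ok])
        cols.append(b[ok])
    g = sparse.coo_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    n_reg, labels = connected_components(g, directed=False)
    return n_reg, labels.reshape(shape)


def unwrap_velocity(
    vol: VelocityVolume,
    threshold: float | None = None,
    max_iterations: int = 10,  # kept for API stability; correction is direct
) -> UnwrapResult:
    """Correct single-wrap velocity aliasing by region shifting.

    Aliasing produces jumps of ~2 venc between neighboring voxels.  Each
    velocity component is partitioned into maximal face-connected regions
    whose internal differences stay within ``threshold`` (default: venc);
    starting from the largest region, every other region is shifted by
    k * 2 venc (k in {-1, 0, 1}, single wrap) to best match its
    already-anchored neighbors across the jump boundaries.  This handles both
    isolated aliased voxels and extended aliased cores, and is idempotent:
    an alias-free field forms a single region and is returned unchanged.
    """
    thr = vol.venc if threshold is None else threshold
    out = vol.copy()
    total = 0
    iterations = 0
    for axis in range(3):
        for t in range(out.n_phases):
            v = out.velocity[axis, ..., t]
            n_reg, labels = _consistent_regions(v, thr)
            if n_reg <= 1:
                continue
            iterations = max(iterations, 1)
            sizes = np.bincount(labels.ravel())
            order = np.argsort(sizes)[::-1]
            anchored = {int(order[0])}
            # boundary voxel pairs between different regions
            pairs = []
            for ax in range(3):
                sl_a = [slice(None)] * 3
                sl_b = [slice(None)] * 3
                sl_a[ax] = slice(None, -1)
                sl_b[ax] = slice(1, None)
                la = labels[tuple(sl_a)].ravel()
                lb = labels[tuple(sl_b)].ravel()
                va = v[tuple(sl_a)].ravel()
                vb = v[tuple(sl_b)].ravel()
                cross = la != lb
                pairs.append((la[cross], lb[cross], va[cross], vb[cross]))
            la = np.concatenate([p[0] for p in pairs])
            lb = np.concatenate([p[1] for p in pairs])
            va = np.concatenate([p[2] for p in pairs])
            vb = np.concatenate([p[3] for p in pairs])

            remaining = [int(r) for r in order[1:]]
            progressed = True
            while remaining and progressed:
                progressed = False
                for r in list(remaining):
                    sel_a = (la == r) & np.isin(lb, list(anchored))
                    sel_b = (lb == r) & np.isin(la, list(anchored))
                    diffs = np.concatenate(
                        [va[sel_b] - vb[sel_b], vb[sel_a] - va[sel_a]]
                    )
                    if diffs.size == 0:
                        continue
                    k = int(np.clip(np.round(np.median(diffs) / (2.0 * vol.venc)), -1, 1))
                    if k != 0:
                        region = labels == r
                        v[region] += k * 2.0 * vol.venc
                        va[la == r] += k * 2.0 * vol.venc
                        vb[lb == r] += k * 2.0 * vol.venc
                        total += int(region.sum())
                    anchored.add(r)
                    remaining.remove(r)
                    progressed = True
    return UnwrapResult(volume=out, n_corrected=total, n_iterations=iterations)


def detect_static_tissue(
    vol: VelocityVolume,
    magnitude_percentile: float = 25.0,
    velocity_fraction: float = 0.05,
    vessel_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mask of voxels usable for the background-phase fit.

    A voxel qualifies when its time-averaged magnitude is at or above the
    given percentile of the magnitude image AND its speed is below
    ``velocity_fraction * venc``.  Speed is measured after subtracting the
    per-axis global median velocity, so the selection is insensitive to the
    very background offset the mask is used to remove (static tissue
    dominates the volume, so the median tracks the offset, not the flow).
    A vessel mask, when supplied, is excluded.
    """
    mag = vol.tavg_magnitude
    tavg = vol.tavg_velocity
    offset = np.median(tavg, axis=(1, 2, 3))
    speed = np.linalg.norm(tavg - offset[:, None, None, None], axis=0)
    mag_thr = np.percentile(mag, magnitude_percentile)
    mask = (mag >= mag_thr) & (speed < velocity_fraction * vol.venc)
    if vessel_mask is not None:
        mask &= ~vessel_mask.astype(bool)
    if not np.any(mask):
        raise ValueError(
            "static-tissue mask is empty; lower magnitude_percentile or "
            "raise velocity_fraction"
        )
    return mask


def _design_matrix(coords: np.ndarray, order: int) -> np.ndarray:
    """Monomial basis [1, x, y, z (, x^2, y^2, z^2, xy, xz, yz)] in world cm."""
    x, y, z = coords.T
    cols = [np.ones_like(x), x, y, z]
    if order >= 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    return np.column_stack(cols)


def correct_background_phase(
    vol: VelocityVolume,
    mask: np.ndarray,
    order: int = 1,
) -> tuple[VelocityVolume, BackgroundModel]:
    """Fit and subtract a low-order background velocity offset per axis.

    The fit uses the cardiac-phase-averaged velocity within ``mask`` and the
    fitted trend is subtracted from every cardiac phase, matching the
    time-averaged nature of eddy-current offsets.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    mask = mask.astype(bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    h = vol.voxel_size
    coords_mask = np.argwhere(mask) * h
    A = _design_matrix(coords_mask, order)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(
            "background fit is rank-deficient (degenerate static-tissue mask)"
        )

    nx, ny, nz = vol.grid_shape
    grid = np.indices((nx, ny, nz)).reshape(3, -1).T * h
    A_full = _design_matrix(grid, order)

    tavg = vol.tavg_velocity
    coeffs = np.zeros((3, A.shape[1]))
    residual_rms = np.zeros(3)
    out = vol.copy()
    for axis in range(3):
        b = tavg[axis][mask]
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        coeffs[axis] = beta
        residual_rms[axis] = float(np.sqrt(np.mean((b - A @ beta) ** 2)))
        trend = (A_full @ beta).reshape(nx, ny, nz)
        out.velocity[axis] -= trend[..., None]
    model = BackgroundModel(
        coeffs=coeffs, order=order, mask=mask, residual_rms=residual_rms
    )
    return out, model
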