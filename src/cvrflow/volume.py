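"""In-memory containers for velocity-encoded volumes.

Coordinate convention (used everywhere in this package): arrays are indexed
``(x, y, z)`` with 0-based voxel indices, voxel-center alignment, and world
position ``index * voxel_size`` in cm on right-handed axes.  Velocity fields
carry an explicit (possibly singleton) cardiac-phase axis last.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VelocityVolume", "EncodedVolume"]


@dataclass
class VelocityVolume:
    """Three-directional velocity field plus signal magnitude.

    Parameters
    ----------
    velocity : ndarray, shape (3, nx, ny, nz, nt)
        Velocity components along the array axes, cm/s.
    magnitude : ndarray, shape (nx, ny, nz, nt)
        Signal magnitude, arbitrary units.
    voxel_size : float
        Isotropic voxel edge length, cm.
    venc : float
        Velocity-encoding limit, cm/s.  Velocities beyond +/- venc alias
        during phase encoding.
    """

    velocity: np.ndarray
    magnitude: np.ndarray
    voxel_size: float
    venc: float

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.velocity.ndim == 4:  # allow (3, nx, ny, nz)
            self.velocity = self.velocity[..., None]
        if self.magnitude.ndim == 3:
            self.magnitude = self.magnitude[..., None]
        if self.velocity.ndim != 5 or self.velocity.shape[0] != 3:
            raise ValueError("velocity must have shape (3, nx, ny, nz[, nt])")
        if self.magnitude.shape != self.velocity.shape[1:]:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} does not match "
                f"velocity grid {self.velocity.shape[1:]}"
            )
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity contains non-finite values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def n_phases(self) -> int:
        return self.velocity.shape[4]

    @property
    def tavg_velocity(self) -> np.ndarray:
        """Cardiac-phase average, shape (3, nx, ny, nz)."""
        return self.velocity.mean(axis=4)

    @property
    def tavg_magnitude(self) -> np.ndarray:
        return self.magnitude.mean(axis=3)

    def speed(self) -> np.ndarray:
        """Euclidean norm of the time-averaged velocity, shape (nx, ny, nz)."""
        return np.linalg.norm(self.tavg_velocity, axis=0)

    def world_extent(self) -> np.ndarray:
        """World coordinate of the last voxel center per axis, cm."""
        return (np.array(self.grid_shape) - 1) * self.voxel_size

    def copy(self) -> "VelocityVolume":
        return replace(
            self, velocity=self.velocity.copy(), magnitude=self.magnitude.copy()
        )


@dataclass
class EncodedVolume:
    """Complex phase-contrast signal, one channel per velocity axis.

    ``signal[i] = magnitude * exp(1j * pi * v_i / venc)`` before any noise or
    background phase is applied; shape (3, nx, ny, nz, nt).
    """

    signal: np.ndarray
    voxel_size: float
    venc: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        if self.signal.ndim == 4:
            self.signal = self.signal[..., None]
        if self.signal.ndim != 5 or self.signal.shape[0] != 3:
            raise ValueError("signal must have shape (3, nx, ny, nz[, nt])")
        if self.venc <= 0 or self.voxel_size <= 0:
            raise ValueError("venc and voxel_size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:4]

    def copy(self) -> "EncodedVolume":
        return replace(self, signal=self.signal.copy(), meta=dict(self.meta))

    def decode(self) -> VelocityVolume:
        """Recover velocity and magnitude from the complex signal.

        The decoded velocity is ``venc * angle(S) / pi`` and therefore lies in
        ``[-venc, venc)``; true velocities beyond the venc appear aliased.
        The magnitude image is the mean modulus over the three encodings.
        """
        phase = np.angle(self.signal)
        velocity = self.venc * phase / np.pi
        magnitude = np.abs(self.signal).mean(axis=0)
        return VelocityVolume(
            velocity=velocity,
            magnitude=magnitude,
            voxel_size=self.voxel_size,
            venc=self.venc,
        )
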