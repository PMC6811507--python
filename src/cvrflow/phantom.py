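"""Synthetic 4D-flow phantom with analytic ground truth.

Generates velocity-encoded volumes of an intracranial-like vessel layout
(left/right internal carotid arteries, left/right middle cerebral arteries,
basilar artery) carrying steady Poiseuille flow, phase-encoded at a chosen
venc, with optional complex Gaussian noise, spatially smooth background phase
offsets, and velocity aliasing.  A three-condition hypercapnia study
(normocapnia, 4% CO2, 6% CO2) is simulated so that the true cerebrovascular
conductance (CVC = flow/MAP x 100) of every vessel lies exactly on a
programmed line against end-tidal CO2; the slope of that line is the ground
truth that the analysis pipeline must recover.

Everything the downstream stages measure (flow, cross-sectional area, CVR
slope) is recorded analytically in a :class:`PhantomTruth` ledger, so the
whole pipeline is testable without real MRI data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .volume import EncodedVolume, VelocityVolume

__all__ = [
    "VesselSpec",
    "AcquisitionSpec",
    "Condition",
    "StudySpec",
    "PhantomTruth",
    "StudyData",
    "VESSEL_LABELS",
    "FEEDING_VESSELS",
    "samples_per_heartbeat",
    "build_velocity_field",
    "encode_phase",
    "add_noise",
    "add_background_phase",
    "simulate_cvr_study",
    "simulate_cvc_tables",
    "default_acquisition",
    "default_study",
    "default_vessel_layout",
    "straight_tube",
    "y_bifurcation",
]

VESSEL_LABELS = ("ICA_L", "ICA_R", "MCA_L", "MCA_R", "BA")


def samples_per_heartbeat(tr_ms: float, hr_bpm: float = 60.0) -> int:
    """Continuously acquired samples per heartbeat: round(beat length / TR).

    A TR of 7.8 ms at 60 bpm gives round(1000 / 7.8) = 128 samples, the
    sampling density that retrospective gating redistributes into cardiac
    phases.
    """
    if tr_ms <= 0 or hr_bpm <= 0:
        raise ValueError("TR and heart rate must be positive")
    return int(round(60000.0 / hr_bpm / tr_ms))
#: Vessels whose flows sum to global cerebral inflow.
FEEDING_VESSELS = ("ICA_L", "ICA_R", "BA")


@dataclass
class VesselSpec:
    """A single tube: parametric centerline + caliber + mean velocity.

    ``centerline`` is a polyline of 3D control points in world cm;
    ``radius`` in cm; ``mean_velocity`` is the cross-section mean velocity
    v-bar in cm/s, one value per cardiac phase (a scalar means steady flow).
    Poiseuille flow gives the axial profile v(r) = 2 v-bar (1 - (r/R)^2) and
    the analytic volumetric flow Q = v-bar * pi R^2 * 60 mL/min.
    """

    label: str
    centerline: np.ndarray
    radius: float
    mean_velocity: np.ndarray | float

    def __post_init__(self) -> None:
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.mean_velocity = np.atleast_1d(
            np.asarray(self.mean_velocity, dtype=float)
        )
        if self.radius <= 0:
            raise ValueError(f"{self.label}: radius must be positive")
        if self.centerline.shape[0] < 2 or self.centerline.shape[1] != 3:
            raise ValueError(f"{self.label}: centerline needs >= 2 3D points")
        if np.allclose(self.centerline[0], self.centerline[-1]):
            raise ValueError(f"{self.label}: centerline points must be distinct")
        if np.any(self.mean_velocity < 0):
            raise ValueError(f"{self.label}: mean_velocity must be >= 0")

    @property
    def csa(self) -> float:
        """Analytic lumen cross-sectional area, cm^2."""
        return math.pi * self.radius**2

    @property
    def vbar(self) -> float:
        """Cardiac-cycle mean of the mean velocity, cm/s."""
        return float(np.mean(self.mean_velocity))

    @property
    def flow(self) -> float:
        """Analytic time-averaged flow, mL/min."""
        return self.vbar * self.csa * 60.0


@dataclass
class AcquisitionSpec:
    """Image-space acquisition model.

    snr is the magnitude-image signal-to-noise ratio referenced to the
    in-vessel magnitude (1.0); ``np.inf`` means noise-free.
    ``background_phase_coeffs`` has shape (3, 4): per velocity axis a constant
    plus three linear terms (radians, radians/cm) of the spurious
    eddy-current-like phase added at encoding time.
    """

    voxel_size: float = 0.0375
    grid_shape: tuple[int, int, int] = (56, 56, 56)
    venc: float = 80.0
    n_cardiac_phases: int = 1
    snr: float = np.inf
    tissue_magnitude: float = 0.3
    background_phase_coeffs: np.ndarray | None = None
    supersampling: int = 4

    def __post_init__(self) -> None:
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not (self.snr > 0):
            raise ValueError("snr must be positive (np.inf for noise-free)")
        if self.n_cardiac_phases < 1:
            raise ValueError("n_cardiac_phases must be >= 1")
        if self.supersampling < 1:
            raise ValueError("supersampling must be >= 1")
        if self.background_phase_coeffs is not None:
            c = np.asarray(self.background_phase_coeffs, dtype=float)
            if c.shape != (3, 4) or not np.all(np.isfinite(c)):
                raise ValueError("background_phase_coeffs must be finite (3, 4)")
            self.background_phase_coeffs = c


@dataclass
class Condition:
    """One scan condition's physiological state (scan-length means)."""

    label: str
    etco2: float  # mmHg
    map_mmHg: float  # mmHg
    hr: float = 60.0  # bpm
    spo2: float = 98.0  # %

    def __post_init__(self) -> None:
        if self.map_mmHg <= 0 or self.etco2 <= 0:
            raise ValueError("etco2 and map must be positive")


@dataclass
class StudySpec:
    """A hypercapnia study design with programmed CVR ground truth.

    ``vessel_slopes`` maps each vessel to its true CVR slope (CVC units per
    mmHg ETCO2); ``baseline_flows`` gives the flow in mL/min at the first
    condition.  The true global slope is the sum of the feeding-vessel
    (ICA_L, ICA_R, BA) slopes, because global CVC is the sum of their CVCs.
    ``mca_dilation_fraction`` is the relative MCA CSA increase at the
    highest-ETCO2 condition.
    """

    conditions: list[Condition]
    vessel_slopes: dict[str, float]
    baseline_flows: dict[str, float]
    mca_dilation_fraction: float = 0.0435
    subjects: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("need >= 2 conditions")
        etco2 = [c.etco2 for c in self.conditions]
        if len(set(etco2)) < 2:
            raise ValueError("conditions must span distinct ETCO2 values")
        missing = set(VESSEL_LABELS) - set(self.vessel_slopes)
        if missing or set(VESSEL_LABELS) - set(self.baseline_flows):
            raise ValueError(f"slopes/flows required for all of {VESSEL_LABELS}")

    @property
    def true_global_slope(self) -> float:
        return float(sum(self.vessel_slopes[v] for v in FEEDING_VESSELS))

    @property
    def top_condition(self) -> Condition:
        return max(self.conditions, key=lambda c: c.etco2)

    def flow(self, vessel: str, cond: Condition) -> float:
        """Flow (mL/min) placing true CVC exactly on the programmed line."""
        c0 = self.conditions[0]
        cvc0 = self.baseline_flows[vessel] / c0.map_mmHg * 100.0
        cvc = cvc0 + self.vessel_slopes[vessel] * (cond.etco2 - c0.etco2)
        return cvc * cond.map_mmHg / 100.0


@dataclass
class PhantomTruth:
    """Analytic ground-truth ledger for one simulated study."""

    flow: dict[str, dict[str, float]]  # condition -> vessel -> mL/min
    csa: dict[str, dict[str, float]]  # condition -> vessel -> cm^2
    global_flow: dict[str, float]  # condition -> mL/min
    vessel_slopes: dict[str, float]
    global_slope: float
    mca_dilation_fraction: float

    def cvc(self, conditions: list[Condition]) -> dict[str, dict[str, float]]:
        """True CVC per condition, per vessel plus 'global'."""
        out: dict[str, dict[str, float]] = {}
        for c in conditions:
            row = {
                v: self.flow[c.label][v] / c.map_mmHg * 100.0
                for v in self.flow[c.label]
            }
            row["global"] = self.global_flow[c.label] / c.map_mmHg * 100.0
            out[c.label] = row
        return out

    def to_dict(self) -> dict:
        return {
            "flow_ml_min": self.flow,
            "csa_cm2": self.csa,
            "global_flow_ml_min": self.global_flow,
            "vessel_slopes": self.vessel_slopes,
            "global_slope": self.global_slope,
            "mca_dilation_fraction": self.mca_dilation_fraction,
        }


@dataclass
class StudyData:
    """Simulated study: encoded volumes per subject and condition."""

    volumes: dict[int, dict[str, EncodedVolume]]
    conditions: pd.DataFrame
    truth: PhantomTruth
    seeds: dict[str, list[float]]  # vessel label -> world seed point (cm)
    acq: AcquisitionSpec
    study: StudySpec


# ---------------------------------------------------------------------------
# field construction


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at approximately uniform arclength spacing."""
    seg = np.diff(points, axis=0)
    seglen = np.linalg.norm(seg, axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    n = max(int(np.ceil(total / spacing)) + 1, 2)
    t = np.linspace(0.0, total, n)
    return np.column_stack(
        [np.interp(t, arclen, points[:, i]) for i in range(3)]
    )


def _tangents(points: np.ndarray) -> np.ndarray:
    g = np.gradient(points, axis=0)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def build_velocity_field(
    vessels: list[VesselSpec], acq: AcquisitionSpec
) -> VelocityVolume:
    """Rasterize Poiseuille tubes into a velocity + magnitude volume.

    Each voxel is supersampled ``acq.supersampling`` times per axis; sub-voxel
    points inside a tube carry the parabolic profile directed along the local
    centerline tangent, and the voxel value is the sub-sample average
    (partial-volume model).  Magnitude is 1 inside vessels, blending to
    ``acq.tissue_magnitude`` outside via the inside fraction.

    Raises
    ------
    ValueError
        If a vessel (centerline inflated by its radius) leaves the grid, or
        if two vessels with distinct labels overlap away from a shared
        centerline endpoint (a junction).
    """
    nx, ny, nz = acq.grid_shape
    h = acq.voxel_size
    s = acq.supersampling
    hi = (np.array([nx, ny, nz]) - 1) * h

    vel = np.zeros((3, nx, ny, nz))
    frac = np.zeros((nx, ny, nz))
    owner: dict[str, np.ndarray] = {}

    offsets = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets in voxels
    ox, oy, oz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    sub = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()]) * h

    for vs in vessels:
        dense = _resample_polyline(vs.centerline, h / 4.0)
        if np.any(dense - vs.radius < -h / 2) or np.any(dense + vs.radius > hi + h / 2):
            raise ValueError(f"vessel {vs.label} exits the grid")
        tang = _tangents(dense)
        tree = cKDTree(dense)

        lo_idx = np.maximum(
            np.floor((dense.min(axis=0) - vs.radius) / h - 1).astype(int), 0
        )
        hi_idx = np.minimum(
            np.ceil((dense.max(axis=0) + vs.radius) / h + 1).astype(int),
            np.array([nx, ny, nz]) - 1,
        )
        ix, iy, iz = [
            np.arange(lo_idx[d], hi_idx[d] + 1) for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
        centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) * h
        nvox = centers.shape[0]

        # coarse cull: voxels whose center is far from the centerline
        d0, _ = tree.query(centers, workers=-1)
        near = d0 <= vs.radius + h
        if not np.any(near):
            continue
        centers = centers[near]
        pts = (centers[:, None, :] + sub[None, :, :]).reshape(-1, 3)
        d, idx = tree.query(pts, workers=-1)
        inside = d <= vs.radius
        v_here = np.zeros((pts.shape[0], 3))
        if np.any(inside):
            rr = d[inside] / vs.radius
            vmag = 2.0 * vs.vbar * (1.0 - rr**2)
            v_here[inside] = vmag[:, None] * tang[idx[inside]]
        v_vox = v_here.reshape(centers.shape[0], s**3, 3).mean(axis=1)
        f_vox = inside.reshape(centers.shape[0], s**3).mean(axis=1)

        flat = np.zeros((nx, ny, nz))
        vflat = np.zeros((3, nx, ny, nz))
        sel = np.zeros(nvox, dtype=bool)
        sel[near.nonzero()[0]] = True
        ii = (centers / h + 0.5).astype(int)
        flat[ii[:, 0], ii[:, 1], ii[:, 2]] = f_vox
        for d3 in range(3):
            vflat[d3, ii[:, 0], ii[:, 1], ii[:, 2]] = v_vox[:, d3]

        _check_overlap(vs, owner, flat, vessels, h)
        owner[vs.label] = flat > 0
        # where vessels share a junction, the voxel belongs to whichever
        # tube carries more flux through it (no double counting)
        new_wins = flat * np.linalg.norm(vflat, axis=0) > frac * np.linalg.norm(
            vel, axis=0
        )
        both = (flat > 0) & (frac > 0)
        take_new = (flat > 0) & (~both | new_wins)
        for d3 in range(3):
            vel[d3] = np.where(take_new, vflat[d3], vel[d3])
        frac = np.where(take_new, flat, frac)

    frac = np.clip(frac, 0.0, 1.0)
    mag = acq.tissue_magnitude + (1.0 - acq.tissue_magnitude) * frac

    if acq.n_cardiac_phases > 1:
        # optional sinusoidal pulsatility whose cycle mean equals vbar
        t = np.arange(acq.n_cardiac_phases)
        mod = 1.0 + 0.0 * np.sin(2 * np.pi * t / acq.n_cardiac_phases)
        velocity = vel[..., None] * mod
        magnitude = np.repeat(mag[..., None], acq.n_cardiac_phases, axis=3)
    else:
        velocity = vel[..., None]
        magnitude = mag[..., None]
    return VelocityVolume(
        velocity=velocity, magnitude=magnitude, voxel_size=h, venc=acq.venc
    )


def _check_overlap(
    vs: VesselSpec,
    owner: dict[str, np.ndarray],
    flat: np.ndarray,
    vessels: list[VesselSpec],
    h: float,
) -> None:
    """Reject overlap between distinct vessels except around shared junctions."""
    by_label = {v.label: v for v in vessels}
    mine = flat > 0
    for other_label, other_mask in owner.items():
        both = mine & other_mask
        if not np.any(both):
            continue
        other = by_label[other_label]
        shared = [
            p
            for p in (vs.centerline[0], vs.centerline[-1])
            for q in (other.centerline[0], other.centerline[-1])
            if np.linalg.norm(p - q) < h
        ]
        if not shared:
            raise ValueError(
                f"vessels {vs.label} and {other_label} overlap without a "
                "shared junction point"
            )
        coords = np.argwhere(both) * h
        junction = np.asarray(shared[0])
        dist = np.linalg.norm(coords - junction, axis=1)
        allow = 2.0 * (vs.radius + other.radius)
        if np.any(dist > allow):
            raise ValueError(
                f"vessels {vs.label} and {other_label} overlap beyond the "
                "junction neighborhood"
            )


# ---------------------------------------------------------------------------
# encoding model


def encode_phase(vol: VelocityVolume, acq: AcquisitionSpec | None = None) -> EncodedVolume:
    """Phase-encode velocities: per axis, phase = pi * v / venc wrapped to
    [-pi, pi).  Velocities with |v| > venc therefore alias on decode."""
    venc = acq.venc if acq is not None else vol.venc
    phase = np.pi * vol.velocity / venc
    wrapped = np.mod(phase + np.pi, 2 * np.pi) - np.pi
    signal = vol.magnitude[None] * np.exp(1j * wrapped)
    return EncodedVolume(signal=signal, voxel_size=vol.voxel_size, venc=venc)


def add_noise(
    enc: EncodedVolume, snr: float, seed: int | np.random.Generator
) -> EncodedVolume:
    """Add independent complex Gaussian noise to each velocity encoding.

    SNR is defined on the magnitude image relative to the in-vessel signal
    (1.0), so the per-channel noise standard deviation is 1/snr on both the
    real and imaginary parts.  For a voxel of magnitude A the first-order
    decoded-velocity noise is ``sigma_v = venc / (pi * snr * A)`` per axis.
    """
    if not (snr > 0):
        raise ValueError("snr must be positive")
    if np.isinf(snr):
        return enc.copy()
    rng = np.random.default_rng(seed)
    sigma = 1.0 / snr
    noise = rng.normal(0.0, sigma, enc.signal.shape) + 1j * rng.normal(
        0.0, sigma, enc.signal.shape
    )
    out = enc.copy()
    out.signal = out.signal + noise
    return out


def add_background_phase(enc: EncodedVolume, coeffs: np.ndarray) -> EncodedVolume:
    """Add a smooth spurious phase: per axis a0 + a1 x + a2 y + a3 z (world cm).

    Emulates eddy-current background phase offsets; the preprocessing stage
    estimates and removes exactly this class of artifact.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (3, 4) or not np.all(np.isfinite(coeffs)):
        raise ValueError("coeffs must be finite with shape (3, 4)")
    nx, ny, nz = enc.grid_shape
    h = enc.voxel_size
    x = np.arange(nx) * h
    y = np.arange(ny) * h
    z = np.arange(nz) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    out = enc.copy()
    for axis in range(3):
        a0, a1, a2, a3 = coeffs[axis]
        phi = a0 + a1 * X + a2 * Y + a3 * Z
        out.signal[axis] *= np.exp(1j * phi)[..., None]
    return out


# ---------------------------------------------------------------------------
# study simulation


def default_acquisition(**kw) -> AcquisitionSpec:
    """Acquisition defaults mirroring the study protocol (venc 80 cm/s) at a
    desk-scale grid: 56^3 voxels of 0.0375 cm so the MCA spans ~8 voxels per
    diameter."""
    return AcquisitionSpec(**kw)


def default_study(seed: int = 0, **kw) -> StudySpec:
    """Three-condition young-adult study: ETCO2 40/47/49 mmHg and MAP
    94/93/96 mmHg, baseline flows and calibers at MCA/ICA/BA scale, and a
    programmed global CVR slope of 25 CVC-units per mmHg."""
    conditions = [
        Condition("normocapnia", 40.0, 94.0, hr=53.0, spo2=98.0),
        Condition("co2_4pct", 47.0, 93.0, hr=56.0, spo2=98.0),
        Condition("co2_6pct", 49.0, 96.0, hr=58.0, spo2=98.0),
    ]
    kw.setdefault("vessel_slopes", {
        "ICA_L": 9.0, "ICA_R": 9.0, "BA": 7.0, "MCA_L": 3.5, "MCA_R": 3.5,
    })
    kw.setdefault("baseline_flows", {
        "ICA_L": 240.0, "ICA_R": 240.0, "BA": 150.0,
        "MCA_L": 120.0, "MCA_R": 120.0,
    })
    return StudySpec(conditions=conditions, seed=seed, **kw)


#: vessel calibers, cm; MCA radius gives CSA = pi r^2 = 0.069 cm^2
DEFAULT_RADII = {
    "ICA_L": 0.23,
    "ICA_R": 0.23,
    "BA": 0.16,
    "MCA_L": 0.14821,
    "MCA_R": 0.14821,
}


def default_vessel_layout(
    acq: AcquisitionSpec, radii: dict[str, float] | None = None
) -> dict[str, np.ndarray]:
    """Five nearly-parallel slightly tilted tubes spanning the grid along z.

    Returns label -> centerline control points (world cm).  Tubes are spaced
    so that segmentation masks stay disjoint and measurement planes do not
    clip the grid.
    """
    radii = radii or DEFAULT_RADII
    nx, ny, nz = acq.grid_shape
    h = acq.voxel_size
    ext = (np.array([nx, ny, nz]) - 1) * h
    frac_xy = {
        "ICA_L": (0.28, 0.28),
        "ICA_R": (0.72, 0.28),
        "BA": (0.50, 0.52),
        "MCA_L": (0.28, 0.76),
        "MCA_R": (0.72, 0.76),
    }
    tilt = {
        "ICA_L": (0.05, 0.02),
        "ICA_R": (-0.04, 0.03),
        "BA": (0.03, -0.04),
        "MCA_L": (0.02, -0.05),
        "MCA_R": (-0.05, -0.02),
    }
    layout = {}
    for label, (fx, fy) in frac_xy.items():
        x0, y0 = fx * ext[0], fy * ext[1]
        dx, dy = tilt[label]
        # inset by the (dilated) radius so the rounded end caps stay inside
        margin = 1.05 * radii[label] + 3 * h
        z0, z1 = margin, ext[2] - margin
        length = z1 - z0
        layout[label] = np.array(
            [
                [x0 - dx * length / 2, y0 - dy * length / 2, z0],
                [x0 + dx * length / 2, y0 + dy * length / 2, z1],
            ]
        )
    return layout


def _vessels_for_condition(
    study: StudySpec, cond: Condition, layout: dict[str, np.ndarray],
    radii: dict[str, float],
) -> list[VesselSpec]:
    is_top = cond.label == study.top_condition.label
    vessels = []
    for label in VESSEL_LABELS:
        r = radii[label]
        if is_top and label.startswith("MCA"):
            r = r * math.sqrt(1.0 + study.mca_dilation_fraction)
        q = study.flow(label, cond)  # mL/min
        vbar = q / (60.0 * math.pi * r**2)
        vessels.append(
            VesselSpec(label=label, centerline=layout[label], radius=r,
                       mean_velocity=vbar)
        )
    return vessels


def simulate_cvr_study(
    study: StudySpec,
    acq: AcquisitionSpec | None = None,
    layout: dict[str, np.ndarray] | None = None,
    radii: dict[str, float] | None = None,
) -> StudyData:
    """Simulate a hypercapnia study with exact CVC-line ground truth.

    For every condition the per-vessel flow is chosen so that the true CVC
    lies exactly on the programmed line against ETCO2; the MCA radius is
    dilated by ``mca_dilation_fraction`` (in CSA) at the top condition.
    Noise realizations differ per subject and condition but the truth ledger
    is seed-independent.
    """
    acq = acq or default_acquisition()
    radii = radii or DEFAULT_RADII
    layout = layout or default_vessel_layout(acq, radii)

    flow_truth: dict[str, dict[str, float]] = {}
    csa_truth: dict[str, dict[str, float]] = {}
    global_truth: dict[str, float] = {}
    noise_free: dict[str, EncodedVolume] = {}

    for cond in study.conditions:
        vessels = _vessels_for_condition(study, cond, layout, radii)
        for vs in vessels:
            if vs.vbar * 2.0 > acq.venc:
                warnings.warn(
                    f"{vs.label} peak velocity {2 * vs.vbar:.1f} cm/s exceeds "
                    f"venc {acq.venc:.0f}: aliasing will occur", stacklevel=2
                )
        vol = build_velocity_field(vessels, acq)
        enc = encode_phase(vol, acq)
        if acq.background_phase_coeffs is not None:
            enc = add_background_phase(enc, acq.background_phase_coeffs)
        noise_free[cond.label] = enc
        flow_truth[cond.label] = {v.label: v.flow for v in vessels}
        csa_truth[cond.label] = {v.label: v.csa for v in vessels}
        global_truth[cond.label] = sum(
            flow_truth[cond.label][v] for v in FEEDING_VESSELS
        )

    ss = np.random.SeedSequence(study.seed)
    volumes: dict[int, dict[str, EncodedVolume]] = {}
    for subj, child in enumerate(ss.spawn(study.subjects)):
        rngs = [np.random.default_rng(s) for s in child.spawn(len(study.conditions))]
        volumes[subj] = {
            cond.label: add_noise(noise_free[cond.label], acq.snr, rng)
            for cond, rng in zip(study.conditions, rngs)
        }

    conditions = pd.DataFrame(
        [
            {
                "condition": c.label,
                "etco2_mmHg": c.etco2,
                "map_mmHg": c.map_mmHg,
                "hr_bpm": c.hr,
                "spo2_pct": c.spo2,
            }
            for c in study.conditions
        ]
    )
    truth = PhantomTruth(
        flow=flow_truth,
        csa=csa_truth,
        global_flow=global_truth,
        vessel_slopes=dict(study.vessel_slopes),
        global_slope=study.true_global_slope,
        mca_dilation_fraction=study.mca_dilation_fraction,
    )
    # seed points 25% along each vessel, used for centerline labeling
    seeds = {
        label: list(pts[0] + 0.25 * (pts[-1] - pts[0]))
        for label, pts in layout.items()
    }
    return StudyData(
        volumes=volumes, conditions=conditions, truth=truth, seeds=seeds,
        acq=acq, study=study,
    )


# ---------------------------------------------------------------------------
# convenience geometries


def straight_tube(
    radius: float = 0.15,
    vbar: float = 30.0,
    acq: AcquisitionSpec | None = None,
    direction: np.ndarray | None = None,
    label: str = "MCA_L",
) -> tuple[VesselSpec, AcquisitionSpec]:
    """A single straight tube through the grid center, optionally oblique."""
    acq = acq or AcquisitionSpec(grid_shape=(40, 40, 48))
    ext = (np.array(acq.grid_shape) - 1) * acq.voxel_size
    center = ext / 2
    d = np.array([0.0, 0.0, 1.0]) if direction is None else np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    # longest span keeping the inflated tube inside the grid
    margin = radius + 2 * acq.voxel_size
    ts = []
    for axis in range(3):
        if abs(d[axis]) > 1e-12:
            ts.append((ext[axis] - margin - center[axis]) / d[axis])
            ts.append((margin - center[axis]) / d[axis])
    tmax = min(t for t in ts if t > 0)
    tmin = max(t for t in ts if t < 0)
    pts = np.array([center + tmin * d, center + tmax * d])
    return VesselSpec(label=label, centerline=pts, radius=radius,
                      mean_velocity=vbar), acq


def y_bifurcation(
    parent_radius: float = 0.18,
    parent_vbar: float = 30.0,
    split: tuple[float, float] = (0.6, 0.4),
    branch_angle_deg: float = 25.0,
    acq: AcquisitionSpec | None = None,
) -> tuple[list[VesselSpec], AcquisitionSpec, dict[str, float]]:
    """Parent tube bifurcating into two daughters with flows split 60/40.

    Daughter radii are chosen to keep mean velocities comparable to the
    parent; the returned truth dict records the analytic flows, with the
    parent flow equal to the daughter sum by construction.
    """
    acq = acq or AcquisitionSpec(grid_shape=(56, 56, 64))
    ext = (np.array(acq.grid_shape) - 1) * acq.voxel_size
    cx, cy = ext[0] / 2, ext[1] / 2
    zj = 0.5 * ext[2]
    z0 = 0.08 * ext[2]
    z1 = 0.92 * ext[2]
    q_parent = parent_vbar * math.pi * parent_radius**2 * 60.0
    ang = math.radians(branch_angle_deg)
    vessels = [
        VesselSpec("BA", np.array([[cx, cy, z0], [cx, cy, zj]]),
                   parent_radius, parent_vbar)
    ]
    truth = {"BA": q_parent}
    for (fraction, sign, label) in [(split[0], +1, "MCA_L"), (split[1], -1, "MCA_R")]:
        q = fraction * q_parent
        r = parent_radius * math.sqrt(fraction)  # keeps vbar equal to parent
        vbar = q / (60.0 * math.pi * r**2)
        length = z1 - zj
        end = np.array(
            [cx + sign * math.tan(ang) * length, cy, z1]
        )
        vessels.append(
            VesselSpec(label, np.array([[cx, cy, zj], end]), r, vbar)
        )
        truth[label] = q
    return vessels, acq, truth


# ---------------------------------------------------------------------------
# table-level cohort simulation (no imaging)


def simulate_cvc_tables(
    n_subjects: int,
    slope_mean: float,
    slope_sd: float,
    etco2: tuple[float, ...] = (40.0, 47.0, 49.0),
    cvc0_mean: float = 670.0,
    cvc0_sd: float = 60.0,
    noise_sd: float = 15.0,
    seed: int | np.random.Generator = 0,
    group: str = "young",
) -> pd.DataFrame:
    """Per-subject CVC-vs-ETCO2 points with between-subject slope variation.

    Emulates the tabular stage of a cohort (no imaging): each subject has a
    true slope drawn from N(slope_mean, slope_sd); measured CVC adds
    N(0, noise_sd) per condition.  Used for group-statistics scenarios.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        slope = rng.normal(slope_mean, slope_sd)
        cvc0 = rng.normal(cvc0_mean, cvc0_sd)
        for e in etco2:
            cvc = cvc0 + slope * (e - etco2[0]) + rng.normal(0.0, noise_sd)
            rows.append(
                {"subject": f"{group}_{s:02d}", "group": group,
                 "etco2": e, "cvc": cvc, "true_slope": slope}
            )
    return pd.DataFrame(rows)
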