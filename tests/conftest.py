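"""Shared fixtures: phantoms are generated programmatically, never stored."""
from __future__ import annotations

import numpy as np
import pytest

from cvrflow import angio, phantom, preproc, quant
from cvrflow.pipeline import analyze_simulated_study

TUBE_TILT = (0.08, 0.04, 1.0)


def build_tube(radius=0.15, vbar=30.0, direction=TUBE_TILT, voxels_per_radius=4.0,
               snr=np.inf, **acq_kw):
    """Straight-tube phantom scaled to a fixed voxels-per-radius ratio."""
    vox = radius / voxels_per_radius
    side = max(32, int(round(12 * radius / vox)))
    acq = phantom.AcquisitionSpec(
        voxel_size=vox, grid_shape=(side, side, 48), snr=snr, **acq_kw
    )
    vs, acq = phantom.straight_tube(
        radius=radius, vbar=vbar, acq=acq, direction=direction
    )
    return vs, acq


def measure_tube(vs, acq, *, unwrap=True, volume=None, seed=None, **measure_kw):
    """Encode, decode, (optionally) unwrap, segment and measure one tube."""
    vol = volume if volume is not None else phantom.build_velocity_field([vs], acq)
    enc = phantom.encode_phase(vol, acq)
    if np.isfinite(acq.snr):
        enc = phantom.add_noise(enc, acq.snr, seed if seed is not None else 0)
    dec = enc.decode()
    if unwrap:
        dec = preproc.unwrap_velocity(dec).volume
    mask = angio.segment_vessels(angio.compute_pcmra(dec))
    tree = angio.extract_centerlines(mask, acq.voxel_size)
    seed_pt = vs.centerline[0] + 0.3 * (vs.centerline[-1] - vs.centerline[0])
    tree = angio.label_and_trim(tree, {vs.label: seed_pt})
    m = quant.measure_vessel(dec, mask, tree, vs.label, **measure_kw)
    return m, dec, mask, tree


@pytest.fixture(scope="session")
def tube_measurement():
    """Reference tube (R = 0.15 cm, vbar = 30 cm/s) measured end to end."""
    vs, acq = build_tube()
    m, dec, mask, tree = measure_tube(vs, acq)
    return {"spec": vs, "acq": acq, "measurement": m, "volume": dec,
            "mask": mask, "tree": tree}


@pytest.fixture(scope="session")
def study_data():
    """Noise-free default hypercapnia study with analytic truth."""
    return phantom.simulate_cvr_study(
        phantom.default_study(seed=7), phantom.default_acquisition()
    )


@pytest.fixture(scope="session")
def study_result(study_data):
    """Full-pipeline analysis of the noise-free study."""
    return analyze_simulated_study(study_data)
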