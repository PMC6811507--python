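"""File formats: NIfTI velocity datasets, sidecar metadata, trees, tables.

A velocity dataset on disk is one NIfTI per velocity axis plus magnitude
(``<cond>_vx.nii.gz`` ... ``<cond>_mag.nii.gz``) and a sidecar JSON
``<cond>_meta.json`` carrying the venc and voxel size — sidecars rather than
NIfTI header extensions keep the metadata portable across viewers.  Cardiac
phases map onto the NIfTI time axis.
"""
from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .angio import VesselTree
from .phantom import StudyData
from .volume import VelocityVolume

__all__ = [
    "write_velocity_dataset",
    "read_velocity_dataset",
    "write_study",
    "write_tree",
    "read_seeds",
    "measurements_to_frame",
]

AXES = ("vx", "vy", "vz")


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size * 10.0  # cm -> mm
    return aff


def write_velocity_dataset(
    out_dir: str | Path, vol: VelocityVolume, condition: str
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(vol.voxel_size)
    for i, axis in enumerate(AXES):
        data = vol.velocity[i]
        if vol.n_phases == 1:
            data = data[..., 0]
        nib.save(nib.Nifti1Image(data, aff), out_dir / f"{condition}_{axis}.nii.gz")
    mag = vol.magnitude if vol.n_phases > 1 else vol.magnitude[..., 0]
    nib.save(nib.Nifti1Image(mag, aff), out_dir / f"{condition}_mag.nii.gz")
    meta = {
        "venc_cm_s": vol.venc,
        "voxel_size_cm": vol.voxel_size,
        "n_cardiac_phases": vol.n_phases,
    }
    (out_dir / f"{condition}_meta.json").write_text(json.dumps(meta, indent=2))


def read_velocity_dataset(in_dir: str | Path, condition: str) -> VelocityVolume:
    """Assemble a velocity volume from per-axis NIfTI files + sidecar JSON.

    Raises FileNotFoundError naming any missing component, and ValueError on
    shape mismatches or missing venc metadata.
    """
    in_dir = Path(in_dir)
    meta_path = in_dir / f"{condition}_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata {meta_path.name}")
    meta = json.loads(meta_path.read_text())
    if "venc_cm_s" not in meta:
        raise ValueError(f"{meta_path.name} lacks 'venc_cm_s'")
    if "voxel_size_cm" not in meta:
        raise ValueError(f"{meta_path.name} lacks 'voxel_size_cm'")

    arrays = []
    for axis in AXES + ("mag",):
        path = in_dir / f"{condition}_{axis}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(f"missing component {path.name}")
        arrays.append(np.asarray(nib.load(path).dataobj, dtype=float))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"component shapes disagree: {sorted(shapes)}")
    vel = np.stack(arrays[:3], axis=0)
    return VelocityVolume(
        velocity=vel,
        magnitude=arrays[3],
        voxel_size=float(meta["voxel_size_cm"]),
        venc=float(meta["venc_cm_s"]),
    )


def write_study(out_dir: str | Path, study_data: StudyData, subject: int = 0) -> None:
    """Write one subject's decoded volumes, condition table, seeds and truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for cond, enc in study_data.volumes[subject].items():
        write_velocity_dataset(out_dir, enc.decode(), cond)
    study_data.conditions.to_csv(out_dir / "conditions.csv", index=False)
    (out_dir / "seeds.json").write_text(
        json.dumps({k: list(map(float, v)) for k, v in study_data.seeds.items()},
                   indent=2)
    )
    (out_dir / "truth.json").write_text(
        json.dumps(study_data.truth.to_dict(), indent=2)
    )


def write_tree(path: str | Path, tree: VesselTree) -> None:
    nodes = [
        {
            "id": int(n),
            "ijk": [int(v) for v in d["ijk"]],
            "world_cm": [float(v) for v in d["world"]],
            "tangent": [float(v) for v in d["tangent"]],
            "radius_cm": float(d["radius"]),
            "flag": d["flag"],
        }
        for n, d in tree.graph.nodes(data=True)
    ]
    payload = {
        "voxel_size_cm": tree.voxel_size,
        "nodes": nodes,
        "edges": [[int(a), int(b)] for a, b in tree.graph.edges],
        "measurement_nodes": {
            k: [int(n) for n in v] for k, v in tree.measurement_nodes.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_seeds(path: str | Path) -> dict[str, np.ndarray]:
    raw = json.loads(Path(path).read_text())
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()}


def measurements_to_frame(rows) -> pd.DataFrame:
    """Tidy measurements table: vessel, condition, flow, csa, n_sections."""
    return pd.DataFrame(
        [
            {
                "vessel": m.label,
                "condition": m.condition,
                "flow_ml_min": m.flow,
                "csa_cm2": m.csa,
                "n_sections": m.n_sections,
            }
            for m in rows
        ]
    )
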