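"""End-to-end orchestration: decode -> preprocess -> segment -> quantify -> CVR.

``analyze_condition`` runs the per-scan stages on one velocity volume;
``analyze_study`` loops over the conditions of a (simulated or loaded) study
and fits the CVR lines; ``run_pipeline`` is the file-based wrapper used by
the command line.  All analytic parameters live in :class:`RunConfig` and
are serialized next to the outputs so that a run documents its choices.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import angio, cvr, io, preproc, quant
from .phantom import StudyData
from .volume import VelocityVolume

__all__ = ["RunConfig", "analyze_condition", "analyze_study", "run_pipeline"]

log = logging.getLogger(__name__)

VESSELS = ("ICA_L", "ICA_R", "MCA_L", "MCA_R", "BA")


@dataclass
class RunConfig:
    """Every analysis parameter that alters results, in one place."""

    venc: float = 80.0
    unwrap: bool = True
    background_order: int = 1
    magnitude_percentile: float = 25.0
    velocity_fraction: float = 0.05
    threshold_method: str = "hysteresis"
    low_fraction: float = 0.06
    min_component_size: int = 27
    junction_margin: int = 2
    endpoint_margin: int = 3
    fit_mode: str = "all_conditions"
    alpha: float = 0.05
    seed: int = 0
    version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class ConditionResult:
    condition: str
    measurements: dict[str, quant.VesselMeasurement]
    global_flow: float
    tree: angio.VesselTree
    mask: np.ndarray
    unwrap_corrected: int
    background: preproc.BackgroundModel


@dataclass
class StudyResult:
    conditions: list[ConditionResult]
    measurements: pd.DataFrame
    cvr_results: pd.DataFrame

    def slope(self, scope: str) -> float:
        sel = self.cvr_results[self.cvr_results["scope"] == scope]
        return float(sel["slope"].iloc[0])


def analyze_condition(
    vol: VelocityVolume,
    seeds: dict[str, np.ndarray],
    config: RunConfig | None = None,
    condition: str = "scan",
    vessels: tuple[str, ...] | None = None,
) -> ConditionResult:
    """Run preprocessing, segmentation and per-vessel quantification."""
    cfg = config or RunConfig()
    n_corrected = 0
    if cfg.unwrap:
        res = preproc.unwrap_velocity(vol)
        vol = res.volume
        n_corrected = res.n_corrected
        log.info("%s: unwrapped %d voxel components", condition, n_corrected)

    static = preproc.detect_static_tissue(
        vol,
        magnitude_percentile=cfg.magnitude_percentile,
        velocity_fraction=cfg.velocity_fraction,
    )
    vol, bg = preproc.correct_background_phase(
        vol, static, order=cfg.background_order
    )
    log.info(
        "%s: background residual RMS %s cm/s",
        condition, np.round(bg.residual_rms, 3),
    )

    angiogram = angio.compute_pcmra(vol)
    mask = angio.segment_vessels(
        angiogram,
        threshold_method=cfg.threshold_method,
        low_fraction=cfg.low_fraction,
        min_size=cfg.min_component_size,
    )
    tree = angio.extract_centerlines(mask, vol.voxel_size)
    tree = angio.label_and_trim(
        tree,
        {k: seeds[k] for k in (vessels or seeds)},
        junction_margin=cfg.junction_margin,
        endpoint_margin=cfg.endpoint_margin,
    )

    measurements: dict[str, quant.VesselMeasurement] = {}
    for label in tree.measurement_nodes:
        m = quant.measure_vessel(vol, mask, tree, label)
        m.condition = condition
        measurements[label] = m
    gflow = quant.global_flow(measurements) if all(
        v in measurements for v in quant.REQUIRED_FOR_GLOBAL
    ) else float("nan")
    return ConditionResult(
        condition=condition,
        measurements=measurements,
        global_flow=gflow,
        tree=tree,
        mask=mask,
        unwrap_corrected=n_corrected,
        background=bg,
    )


def analyze_study(
    volumes: dict[str, VelocityVolume],
    conditions: pd.DataFrame,
    seeds: dict[str, np.ndarray],
    config: RunConfig | None = None,
    brain_volume: cvr.BrainVolumes | None = None,
) -> StudyResult:
    """Analyze every condition of one subject and fit the CVR lines.

    ``volumes`` maps condition label -> decoded velocity volume;
    ``conditions`` is the physiological table (condition, etco2_mmHg,
    map_mmHg, ...).  Returns per-vessel measurements and a tidy CVR table
    with one row per scope (each vessel, global, and the brain-volume
    corrected global when volumes are given).
    """
    cfg = config or RunConfig()
    cond_meta = conditions.set_index("condition")
    results = []
    for label in conditions["condition"]:
        results.append(
            analyze_condition(volumes[label], seeds, cfg, condition=label)
        )

    meas_frame = io.measurements_to_frame(
        [m for r in results for m in r.measurements.values()]
    )

    cvr_rows = []
    scopes = [
        v for v in VESSELS if all(v in r.measurements for r in results)
    ] + ["global"]
    for scope in scopes:
        pts = []
        for r in results:
            etco2 = float(cond_meta.loc[r.condition, "etco2_mmHg"])
            mapv = float(cond_meta.loc[r.condition, "map_mmHg"])
            flow = (
                r.global_flow if scope == "global"
                else r.measurements[scope].flow
            )
            pts.append((r.condition, etco2, cvr.compute_cvc(flow, mapv)))
        fit = cvr.fit_cvr(pts, mode=cfg.fit_mode, scope=scope)
        cvr_rows.append(fit)
        if scope == "global" and brain_volume is not None:
            pts_bv = [
                (c, e, v / brain_volume.brain_volume) for c, e, v in pts
            ]
            cvr_rows.append(
                cvr.fit_cvr(pts_bv, mode=cfg.fit_mode, scope="global_bv_corrected")
            )

    cvr_frame = pd.DataFrame(
        [
            {
                "scope": f.scope,
                "slope": f.slope,
                "intercept": f.intercept,
                "n_points": f.n_points,
                "mode": f.mode,
            }
            for f in cvr_rows
        ]
    )
    return StudyResult(
        conditions=results, measurements=meas_frame, cvr_results=cvr_frame
    )


def analyze_simulated_study(
    data: StudyData, config: RunConfig | None = None, subject: int = 0
) -> StudyResult:
    """Convenience: decode a simulated subject's volumes and analyze them."""
    volumes = {c: enc.decode() for c, enc in data.volumes[subject].items()}
    seeds = {k: np.asarray(v) for k, v in data.seeds.items()}
    return analyze_study(volumes, data.conditions, seeds, config)


def run_pipeline(
    in_dir: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> StudyResult:
    """File-based pipeline: read a study directory, write all result tables.

    Expects ``conditions.csv``, ``seeds.json`` and per-condition NIfTI
    datasets in ``in_dir``; writes ``measurements.csv``, ``cvr_results.csv``
    and the resolved ``config.json`` into ``out_dir``.
    """
    cfg = config or RunConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    cond_path = in_dir / "conditions.csv"
    if not cond_path.exists():
        raise FileNotFoundError(f"missing {cond_path}")
    conditions = pd.read_csv(cond_path)
    seeds = io.read_seeds(in_dir / "seeds.json")
    volumes = {
        label: io.read_velocity_dataset(in_dir, label)
        for label in conditions["condition"]
    }
    result = analyze_study(volumes, conditions, seeds, cfg)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.measurements.to_csv(out_dir / "measurements.csv", index=False)
    result.cvr_results.to_csv(out_dir / "cvr_results.csv", index=False)
    (out_dir / "config.json").write_text(cfg.to_json())
    return result
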