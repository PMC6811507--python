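"""Cerebrovascular conductance and reactivity statistics.

CVC (cerebrovascular conductance) = flow / MAP x 100, in
(mL/min/mmHg) x 100; it accounts for the perfusion-pressure changes that
accompany hypercapnia.  CVR is the ordinary least-squares slope of CVC
against end-tidal CO2 over the study conditions — either all three
(normocapnia + 4% + 6% CO2, the default) or the hypercapnic conditions only,
in which case with two points the slope is the difference quotient.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CVRResult",
    "BrainVolumes",
    "compute_cvc",
    "fit_cvr",
    "correct_global_flow",
    "csa_change",
    "summarize_condition",
    "NORMOCAPNIA_LABELS",
]

#: condition labels treated as the normocapnic baseline
NORMOCAPNIA_LABELS = frozenset({"normocapnia", "baseline", "room_air"})

FIT_MODES = ("all_conditions", "hypercapnic_only")


@dataclass
class CVRResult:
    """Slope/intercept of CVC vs ETCO2 for one scope (vessel or global)."""

    scope: str
    slope: float  # CVC units per mmHg ETCO2
    intercept: float
    n_points: int
    conditions: tuple[str, ...]
    mode: str = "all_conditions"

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("CVR fit needs >= 2 points")
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


@dataclass
class BrainVolumes:
    """Gray- and white-matter volumes in liters."""

    gm: float
    wm: float

    def __post_init__(self) -> None:
        if self.gm <= 0 or self.wm <= 0:
            raise ValueError("GM and WM volumes must be positive")

    @property
    def brain_volume(self) -> float:
        return self.gm + self.wm


def compute_cvc(flow: float, map_mmHg: float) -> float:
    """Cerebrovascular conductance: flow / MAP x 100."""
    if map_mmHg <= 0:
        raise ValueError("MAP must be positive")
    return flow / map_mmHg * 100.0


def fit_cvr(
    points,
    mode: str = "all_conditions",
    scope: str = "global",
) -> CVRResult:
    """OLS fit of CVC on ETCO2.

    ``points`` is an iterable of ``(condition_label, etco2, cvc)`` triples or
    a DataFrame with columns condition/etco2/cvc.  ``hypercapnic_only`` drops
    the normocapnic baseline before fitting; with exactly two remaining
    points the OLS slope equals the two-point difference quotient.
    """
    if mode not in FIT_MODES:
        raise ValueError(f"mode must be one of {FIT_MODES}")
    if isinstance(points, pd.DataFrame):
        rows = list(points[["condition", "etco2", "cvc"]].itertuples(index=False))
    else:
        rows = list(points)
    if mode == "hypercapnic_only":
        rows = [r for r in rows if r[0] not in NORMOCAPNIA_LABELS]
    if len(rows) < 2:
        raise ValueError("need >= 2 points after condition selection")
    labels = tuple(r[0] for r in rows)
    x = np.array([r[1] for r in rows], dtype=float)
    y = np.array([r[2] for r in rows], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("ETCO2 values are identical; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return CVRResult(
        scope=scope,
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(rows),
        conditions=labels,
        mode=mode,
    )


def correct_global_flow(flow: float, bv: BrainVolumes) -> float:
    """Brain-volume-normalized global flow, mL/min per liter of brain."""
    if bv.brain_volume <= 0:
        raise ValueError("brain volume must be positive")
    return flow / bv.brain_volume


def csa_change(normo: float, hyper: float) -> tuple[float, float]:
    """Absolute (cm^2) and percent CSA change from normocapnia to hypercapnia."""
    if normo <= 0:
        raise ValueError("normocapnic CSA must be positive")
    delta = hyper - normo
    return delta, delta / normo * 100.0


def summarize_condition(
    timeseries: pd.DataFrame,
    window: tuple[float, float],
    label: str,
    time_col: str = "time_s",
):
    """Scan-length means of the physiological channels within a time window.

    ``timeseries`` needs columns ``time_s, etco2, map, hr, spo2``; returns a
    :class:`cvrflow.phantom.Condition` with the channel means.
    """
    from .phantom import Condition

    t0, t1 = window
    sel = timeseries[(timeseries[time_col] >= t0) & (timeseries[time_col] <= t1)]
    if sel.empty:
        raise ValueError(f"no samples in window [{t0}, {t1}]")
    return Condition(
        label=label,
        etco2=float(sel["etco2"].mean()),
        map_mmHg=float(sel["map"].mean()),
        hr=float(sel["hr"].mean()),
        spo2=float(sel["spo2"].mean()),
    )
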