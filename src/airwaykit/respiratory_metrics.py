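"""Rhinomanometric resistance calculus, grid-refinement assessment and CFD
case metadata.

Anterior rhinomanometry measures, per naris, the pressure drop across the
nasal airway (anterior pressure P1 minus posterior pressure P2, the
contralateral naris being plugged and used as a static-pressure tap) and
the corresponding airflow F.  One naris' resistance is R = (P1 - P2) / F;
with both nares measured, the total nasal resistance follows the parallel
(Ohm's law) combination R_L * R_R / (R_L + R_R).

Units follow clinical convention: pressures in Pa, flow in cm^3/s,
resistance in Pa.s/cm^3.  Inhalation values are stored positive; the phase
field carries the direction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ParameterError

#: international anterior-rhinomanometry reference pressure (Pa)
DEFAULT_REFERENCE_DELTA_P = 100.0


@dataclass
class PressureFlowCurve:
    """Measured (delta_p, flow) readings for one naris, phase and timepoint."""

    naris: Literal["left", "right", "total"]
    phase: Literal["inhale", "exhale"]
    timepoint: Literal["pre", "post"]
    points: np.ndarray  # (k, 2): delta_p (Pa), flow (cm^3/s)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(pts) < 1:
            raise ParameterError("a pressure-flow curve needs at least one point")
        order = np.argsort(np.abs(pts[:, 0]))
        self.points = pts[order]


@dataclass
class ResistanceResult:
    """Per-naris and parallel-total resistance at a reference pressure."""

    R_total: float
    reference_delta_p: float
    R_left: float | None = None
    R_right: float | None = None

    def to_dict(self) -> dict:
        return {
            "R_left": self.R_left,
            "R_right": self.R_right,
            "R_total": self.R_total,
            "reference_delta_p": self.reference_delta_p,
        }


@dataclass
class RefinementSeries:
    """(cell count, delta_p, optional y+) triples of a grid-refinement study."""

    points: list[tuple[float, float, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.points) >= 2:
            cells = [p[0] for p in self.points]
            if any(b <= a for a, b in zip(cells, cells[1:])):
                raise ParameterError("cell counts must be strictly increasing")
        if any(p[1] <= 0 for p in self.points):
            raise ParameterError("pressure differences must be positive")


class CfdCaseSpec(BaseModel):
    """Boundary-condition metadata for an external steady-state CFD solve.

    Breathing at rest at ambient conditions: mass flow fixed at the inlet,
    static pressure at the outlet, non-slip adiabatic walls; iterative
    convergence by residual or inlet/outlet mass-flow imbalance; near-wall
    resolution tracked through the y+ range.
    """

    ambient_pressure: float = Field(default=1.013e5, gt=0)
    temperature_c: float = 25.0
    viscosity: float = Field(default=1.822e-5, gt=0)
    inlet_condition: str = "mass-flow-fixed"
    outlet_condition: str = "static-pressure-fixed"
    residual_criterion: float = Field(default=1e-6, gt=0)
    mass_flow_imbalance_criterion: float = Field(default=0.005, gt=0)
    y_plus_range: tuple[float, float] = (2.0, 5.0)

    def model_post_init(self, __context) -> None:
        if not self.y_plus_range[0] < self.y_plus_range[1]:
            raise ParameterError("y_plus_range must be ordered (low, high)")


def naris_resistance(p1: float, p2: float, flow: float) -> float:
    """Single-naris resistance (P1 - P2) / F in Pa.s/cm^3."""
    if flow == 0:
        raise ParameterError(
            "flow is zero: resistance is undefined; measure at a non-zero "
            "airflow or use a different reference pressure"
        )
    r = (p1 - p2) / flow
    if r == 0:
        warnings.warn("zero resistance (P1 == P2) is non-physical", stacklevel=2)
    return r


def total_resistance(r_left: float, r_right: float) -> float:
    """Parallel (Ohm's law) combination of the two nares' resistances."""
    if r_left <= 0 or r_right <= 0:
        raise ParameterError("per-naris resistances must be positive")
    return (r_left * r_right) / (r_left + r_right)


def resistance_from_curve(
    curve: PressureFlowCurve, reference_delta_p: float = DEFAULT_REFERENCE_DELTA_P
) -> float:
    """Resistance read off a pressure-flow curve at a reference pressure.

    Flow is linearly interpolated at the reference delta-p; extrapolation
    outside the measured range is refused.
    """
    dp = curve.points[:, 0]
    flow = curve.points[:, 1]
    if len(dp) == 1:
        if abs(dp[0] - reference_delta_p) > 1e-9:
            raise ParameterError(
                f"single-point curve at {dp[0]:g} Pa cannot be read at "
                f"{reference_delta_p:g} Pa"
            )
        return naris_resistance(dp[0], 0.0, flow[0])
    if not dp.min() <= reference_delta_p <= dp.max():
        raise ParameterError(
            f"reference {reference_delta_p:g} Pa outside the measured range "
            f"[{dp.min():g}, {dp.max():g}] Pa; extrapolation refused"
        )
    f_ref = float(np.interp(reference_delta_p, dp, flow))
    return naris_resistance(reference_delta_p, 0.0, f_ref)


def assess_refinement(
    series: RefinementSeries, relative_tolerance: float = 0.10
) -> tuple[float, list[float]]:
    """Smallest cell count whose delta-p sits within tolerance of the finest.

    Returns ``(recommended_cells, per_point_relative_deviation)`` where the
    deviations are ``|dp_i - dp_finest| / dp_finest``.
    """
    if len(series.points) < 2:
        raise ParameterError("refinement assessment needs at least 2 points")
    if relative_tolerance <= 0:
        raise ParameterError("relative_tolerance must be positive")
    cells = np.array([p[0] for p in series.points], dtype=np.float64)
    dp = np.array([p[1] for p in series.points], dtype=np.float64)
    deviation = np.abs(dp - dp[-1]) / dp[-1]
    within = np.nonzero(deviation <= relative_tolerance)[0]
    return float(cells[within[0]]), deviation.tolist()


def write_cfd_case(spec: CfdCaseSpec, flow_rate: float, path: str | Path) -> Path:
    """Record the case constants plus the requested mass flow as JSON."""
    if flow_rate <= 0:
        raise ParameterError("flow_rate must be positive (cm^3/s)")
    path = Path(path)
    payload = spec.model_dump()
    payload["flow_rate_cm3_s"] = flow_rate
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_cfd_case(path: str | Path) -> tuple[CfdCaseSpec, float]:
    """Round-trip reader for :func:`write_cfd_case`."""
    payload = json.loads(Path(path).read_text())
    flow = payload.pop("flow_rate_cm3_s")
    return CfdCaseSpec(**payload), flow


def read_pressure_flow_csv(path: str | Path) -> list[PressureFlowCurve]:
    """Load curves from CSV columns naris, phase, timepoint, delta_p_pa, flow_cm3_s."""
    df = pd.read_csv(path)
    required = {"naris", "phase", "timepoint", "delta_p_pa", "flow_cm3_s"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"pressure-flow CSV missing columns: {sorted(missing)}")
    curves = []
    for (naris, phase, timepoint), grp in df.groupby(
        ["naris", "phase", "timepoint"], sort=True
    ):
        curves.append(
            PressureFlowCurve(
                naris=naris,
                phase=phase,
                timepoint=timepoint,
                points=grp[["delta_p_pa", "flow_cm3_s"]].to_numpy(),
            )
        )
    return curves


def read_refinement_csv(path: str | Path) -> RefinementSeries:
    """Load a refinement series from CSV columns cells, delta_p_pa[, y_plus]."""
    df = pd.read_csv(path)
    if not {"cells", "delta_p_pa"} <= set(df.columns):
        raise ParameterError("refinement CSV needs columns cells, delta_p_pa")
    has_yp = "y_plus" in df.columns
    pts = [
        (float(r.cells), float(r.delta_p_pa), float(r.y_plus) if has_yp else None)
        for r in df.itertuples()
    ]
    return RefinementSeries(points=pts)
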