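"""Iterative fitting of deformation parameters to postoperative targets.

Given target section widths (or a target area) on the controlled pivotal
planes — typically measured on follow-up imaging — the fitter picks the
``dY``/``dX_half`` parameters whose deformed geometry reproduces them.
Because the displacement field responds linearly, with unit gain, at the
control planes, the width update is an undamped difference step and
converges in a couple of iterations; the area update is a damped
multiplicative step since area responds nonlinearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from pydantic import BaseModel, Field, model_validator

from .cross_section import slice_mesh
from .deformation import DeformationConfig, deform_mesh, resolve_anatomy
from .errors import ParameterError
from .geometry_io import TriangleMesh

#: plane-matching tolerance between a target and a pivotal plane (mm)
PLANE_MATCH_MM = 1e-3

#: damping applied to the multiplicative area step
AREA_DAMPING = 0.5


class FitTarget(BaseModel):
    """A per-plane target: either both widths, or an enclosed area."""

    z: float
    mode: Literal["widths", "area"] = "widths"
    target_width_x: float | None = None
    target_depth_y: float | None = None
    target_area: float | None = None
    tolerance: float = 0.05        # mm, widths mode
    area_tolerance: float = 0.005  # relative, area mode
    max_iterations: int = 50

    @model_validator(mode="after")
    def _check(self) -> "FitTarget":
        if self.mode == "widths":
            if self.target_width_x is None and self.target_depth_y is None:
                raise ParameterError("widths mode needs target_width_x and/or target_depth_y")
            if self.target_area is not None:
                raise ParameterError("widths mode must not carry target_area")
            for v in (self.target_width_x, self.target_depth_y):
                if v is not None and v <= 0:
                    raise ParameterError("width targets must be positive")
        else:
            if self.target_area is None or self.target_area <= 0:
                raise ParameterError("area mode needs a positive target_area")
            if self.target_width_x is not None or self.target_depth_y is not None:
                raise ParameterError("area mode must not carry width targets")
        if self.tolerance <= 0 or self.area_tolerance <= 0 or self.max_iterations < 1:
            raise ParameterError("tolerances must be positive, max_iterations >= 1")
        return self


@dataclass
class FitResult:
    """Outcome of :func:`fit_parameters`."""

    config: DeformationConfig
    iterations_used: int
    residuals: dict[str, float]
    converged: bool
    residual_history: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(),
            "iterations_used": self.iterations_used,
            "residuals": self.residuals,
            "converged": self.converged,
            "residual_history": self.residual_history,
        }


def _match_plane(config: DeformationConfig, z: float) -> str:
    for name in ("middle_plane", "lower_plane"):
        if abs(getattr(config, name).z - z) <= PLANE_MATCH_MM:
            return name
    raise ParameterError(
        f"target plane z={z:g} mm does not coincide with a controlled pivotal "
        f"plane (middle {config.middle_plane.z:g}, lower {config.lower_plane.z:g})"
    )


def fit_parameters(
    mesh: TriangleMesh,
    base_config: DeformationConfig,
    targets: list[FitTarget],
) -> FitResult:
    """Choose per-plane (dY, dX_half) so deformed sections meet the targets.

    Fixed-point iteration: deform, slice at the target planes, then per
    plane update ``dY`` by the depth shortfall and ``dX_half`` by half the
    width shortfall (area mode: a 0.5-damped joint step scaled by
    ``sqrt(target_area / achieved_area)``).  Parameters are clamped at zero
    — the model only enlarges.  Non-convergence is reported in the result,
    not raised.  Deterministic.
    """
    if not targets:
        raise ParameterError("at least one fit target is required")
    z_lo, z_hi = mesh.bounds[:, 2]
    for t in targets:
        if not z_lo <= t.z <= z_hi:
            raise ParameterError(f"target plane z={t.z:g} mm lies outside the mesh")
    config = resolve_anatomy(mesh, base_config)
    plane_of = {id(t): _match_plane(config, t.z) for t in targets}
    if len({plane_of[id(t)] for t in targets}) < len(targets):
        raise ParameterError("at most one target per controlled plane")

    max_iter = max(t.max_iterations for t in targets)
    history: list[float] = []
    iterations = 0
    converged = False
    residuals: dict[str, float] = {}

    for iterations in range(1, max_iter + 1):
        deformed = deform_mesh(mesh, config)
        residuals = {}
        worst = 0.0
        updates: dict[str, dict[str, float]] = {}
        all_ok = True
        for t in targets:
            name = plane_of[id(t)]
            plane = getattr(config, name)
            section = slice_mesh(deformed, t.z)
            if section.is_empty:
                raise ParameterError(f"deformed mesh has no contour at z={t.z:g} mm")
            d_dY, d_dX = 0.0, 0.0
            if t.mode == "widths":
                ok = True
                if t.target_depth_y is not None:
                    r = t.target_depth_y - section.depth_y
                    residuals[f"{name}.depth_y"] = abs(r)
                    worst = max(worst, abs(r))
                    ok &= abs(r) <= t.tolerance
                    d_dY = r
                if t.target_width_x is not None:
                    r = t.target_width_x - section.width_x
                    residuals[f"{name}.width_x"] = abs(r)
                    worst = max(worst, abs(r))
                    ok &= abs(r) <= t.tolerance
                    d_dX = r / 2.0
            else:
                rel = abs(section.area - t.target_area) / t.target_area
                residuals[f"{name}.area"] = rel
                worst = max(worst, rel)
                ok = rel <= t.area_tolerance
                scale = (t.target_area / section.area) ** 0.5
                d_dY = AREA_DAMPING * (scale - 1.0) * section.depth_y
                d_dX = AREA_DAMPING * (scale - 1.0) * section.width_x / 2.0
            all_ok &= ok
            updates[name] = {
                "dY": max(0.0, plane.dY + d_dY),
                "dX_half": max(0.0, plane.dX_half + d_dX),
            }
        history.append(worst)
        if all_ok:
            converged = True
            break
        config = config.model_copy(
            update={
                name: getattr(config, name).model_copy(update=upd)
                for name, upd in updates.items()
            }
        )

    return FitResult(
        config=config,
        iterations_used=iterations,
        residuals=residuals,
        converged=converged,
        residual_history=history,
    )
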