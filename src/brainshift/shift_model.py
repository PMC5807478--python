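"""Staged CSF-drainage protocol driving the reduced column model.

The drainage experiment starts with the skull completely full (100%,
220 ml) and removes fluid in steps down to 180, 150, 120 and 90 ml —
18, 32, 45 and 59% of liquid loss by exact arithmetic (the 18/32/46/60%
figures commonly quoted round two of the steps differently; this module
reports exact percentages).  Each drainage level is simulated with three
sub-steps:

1. 0.1 s — gravity / buoyancy equilibration at the new fluid level;
2. 10 s  — free drainage: pore pressure released (``p = 0``) at emerged
   nodes, matching the time taken to draw the fluid with the syringe;
3. 60 s  — hold, covering the delay before the MRI acquisition starts.

The fluid level maps linearly onto the column height.  Marker
trajectories are reported as displacement vectors (mm) of material
points; in the 1D reduced model the lateral components are zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .constitutive import STANDARD_GRAVITY, MaterialCard
from .poro_solver import (
    ColumnMesh,
    ConsolidationResult,
    DrainageBC,
    Phase,
    _ColumnSolver,
)

__all__ = [
    "DrainageSchedule",
    "MarkerLayout",
    "ShiftStep",
    "ShiftResult",
    "schedule_from_volumes",
    "run_shift",
    "nearest_material_point",
]


@dataclass(frozen=True)
class DrainageSchedule:
    """Sequence of fluid volumes left in the skull and sub-step timing."""

    step_volumes_ml: tuple = (220.0, 180.0, 150.0, 120.0, 90.0)
    total_volume_ml: float = 220.0
    gravity_duration: float = 0.1
    drain_duration: float = 10.0
    wait_duration: float = 60.0

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.step_volumes_ml)
        object.__setattr__(self, "step_volumes_ml", v)
        if not v or v[0] != self.total_volume_ml:
            raise ValueError("first step volume must equal the total volume")
        if any(b > a for a, b in zip(v, v[1:])):
            raise ValueError("drainage volumes must be non-increasing")
        if any(x < 0 for x in v):
            raise ValueError("volumes must be non-negative")

    def levels(self):
        """List of ``(level_fraction, pct_loss)`` per drainage step."""
        return schedule_from_volumes(self.step_volumes_ml, self.total_volume_ml)


def schedule_from_volumes(volumes_ml, total_ml):
    """Map remaining volumes to ``(level fraction, % loss)`` pairs.

    The level fraction ``v/total`` maps linearly to column height;
    percentage loss is ``100 (total - v)/total`` (exact, not rounded).
    """
    volumes = [float(v) for v in volumes_ml]
    total = float(total_ml)
    if any(b > a for a, b in zip(volumes, volumes[1:])):
        raise ValueError("volumes must be non-increasing")
    if any(v > total for v in volumes):
        raise ValueError("volumes cannot exceed the total")
    return [(v / total, 100.0 * (total - v) / total) for v in volumes]


@dataclass(frozen=True)
class MarkerLayout:
    """Labelled marker material positions for the reduced column model.

    ``elevation_fraction`` places each marker along the column height;
    ``marker_class`` is ``superficial`` or ``internal``.
    """

    ids: tuple
    elevation_fraction: tuple
    marker_class: tuple

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.ids)
        ef = tuple(float(x) for x in self.elevation_fraction)
        mc = tuple(str(c) for c in self.marker_class)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "elevation_fraction", ef)
        object.__setattr__(self, "marker_class", mc)
        if len({len(ids), len(ef), len(mc)}) != 1:
            raise ValueError("ids, elevations and classes must align")
        if len(set(ids)) != len(ids):
            raise ValueError("marker ids must be unique")
        if any(not 0.0 <= x <= 1.0 for x in ef):
            raise ValueError("elevation fractions must lie in [0, 1]")
        if any(c not in ("superficial", "internal") for c in mc):
            raise ValueError("marker class must be superficial or internal")

    def __len__(self) -> int:
        return len(self.ids)

    def elevations(self, height: float) -> np.ndarray:
        return np.array(self.elevation_fraction) * height


@dataclass
class ShiftStep:
    """Marker displacements (mm) at the end of one drainage level."""

    pct_loss: float
    fluid_level: float
    t: float
    displacement_mm: np.ndarray   # (n_markers, 3), columns ux, uy, uz


@dataclass
class ShiftResult:
    """Simulated marker trajectories for one material formulation."""

    card_name: str
    layout: MarkerLayout
    steps: list
    column: ConsolidationResult | None = None

    def to_frame(self) -> pd.DataFrame:
        """Trajectory table (step, pct_loss, marker_id, ux/uy/uz in mm)."""
        rows = []
        for si, step in enumerate(self.steps):
            for mi, mid in enumerate(self.layout.ids):
                rows.append({
                    "step": si,
                    "pct_loss": step.pct_loss,
                    "marker_id": mid,
                    "ux_mm": step.displacement_mm[mi, 0],
                    "uy_mm": step.displacement_mm[mi, 1],
                    "uz_mm": step.displacement_mm[mi, 2],
                })
        return pd.DataFrame(rows)

    def displacements(self, step_index: int) -> np.ndarray:
        return self.steps[step_index].displacement_mm


def nearest_material_point(position: float, mesh: ColumnMesh) -> int:
    """Index of the mesh node closest to a marker position.

    Distances are Euclidean (1D: absolute elevation difference); ties are
    broken toward the lowest node index.
    """
    z = mesh.z
    if not (z[0] - 1e-12 <= position <= z[-1] + 1e-12):
        raise ValueError(f"position {position} outside the column")
    d = np.abs(z - position)
    return int(np.argmin(d))  # argmin returns the first (lowest) index on ties


def run_shift(
    card: MaterialCard,
    schedule: DrainageSchedule | None = None,
    layout: MarkerLayout | None = None,
    mesh: ColumnMesh | None = None,
    *,
    height: float = 0.1,
    n_nodes: int = 41,
    gravity: float = 1.0,
    rho_fluid: float = 1000.0,
    g_const: float = STANDARD_GRAVITY,
    dt_gravity: float = 0.025,
    dt_drain: float = 0.5,
    dt_wait: float = 2.0,
    extra_wait: float = 0.0,
    keep_column: bool = True,
) -> ShiftResult:
    """Drive the column solver through the staged drainage protocol.

    Each drainage level runs the three sub-steps described in the module
    docstring, carrying displacement, pressure and viscoelastic state
    between stages.  Marker displacements are linearly interpolated at
    the marker material elevations at the end of each level's final
    sub-step.

    Parameters
    ----------
    card : MaterialCard
        PHVE / PHE cards solve the coupled biphasic problem; an HVE card
        skips the pore-pressure physics entirely.
    gravity : float
        Scale factor on the body force (0 switches gravity off).
    extra_wait : float
        Additional hold time, s, appended to the final drainage level
        (useful to probe the long-time viscoelastic limit).

    Raises
    ------
    ValueError
        If the schedule would raise the fluid level (drainage must be
        monotone).
    """
    from .synthetic_data import gen_default_layout  # circular-free import

    schedule = schedule or DrainageSchedule()
    layout = layout or gen_default_layout()
    if mesh is None:
        mesh = ColumnMesh.uniform(n_nodes, height, confinement="uniaxial_stress")
    levels = schedule.levels()
    fracs = [f for f, _ in levels]
    if any(b > a for a, b in zip(fracs, fracs[1:])):
        raise ValueError("monotone drainage only: fluid level must not rise")

    H = mesh.height
    solver = _ColumnSolver(mesh, card, rho_fluid=rho_fluid, g_const=g_const)
    marker_z = layout.elevations(H)
    steps: list = []
    record: list = []
    drained_sticky: set = set()

    for i, (frac, pct) in enumerate(levels):
        level = frac * H
        # sub-step 1: gravity / buoyancy equilibration at the new level,
        # drainage as left by the previous stage
        bc_prev = DrainageBC(drained_nodes=tuple(sorted(drained_sticky)))
        solver.run_phase(
            Phase(duration=schedule.gravity_duration, dt=dt_gravity,
                  bc=bc_prev, gravity=gravity, fluid_level=level, ramp=True),
            record,
        )
        # sub-steps 2 and 3: free drainage at emerged nodes
        emerged = np.nonzero(mesh.z > level + 1e-12)[0]
        drained_sticky.update(int(j) for j in emerged)
        bc = DrainageBC(drained_nodes=tuple(sorted(drained_sticky)))
        solver.run_phase(
            Phase(duration=schedule.drain_duration, dt=dt_drain,
                  bc=bc, gravity=gravity, fluid_level=level),
            record,
        )
        wait = schedule.wait_duration
        if i == len(levels) - 1:
            wait += extra_wait
        solver.run_phase(
            Phase(duration=wait, dt=dt_wait,
                  bc=bc, gravity=gravity, fluid_level=level),
            record,
        )
        uz_mm = np.interp(marker_z, mesh.z, solver.u) * 1000.0
        disp = np.zeros((len(layout), 3))
        disp[:, 2] = uz_mm
        steps.append(ShiftStep(pct_loss=pct, fluid_level=level,
                               t=solver.t, displacement_mm=disp))

    column = ConsolidationResult(
        mesh=mesh, states=record,
        cumulative_outflow=solver.cum_outflow,
        volume_change=solver.volume_change,
    ) if keep_column else None
    return ShiftResult(card_name=card.name, layout=layout, steps=steps,
                       column=column)
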