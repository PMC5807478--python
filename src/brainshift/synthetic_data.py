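"""Synthetic inputs emulating the compression rig and the MRI marker data.

The raw study data (MRI scans of a hydrogel phantom) are not public, so
every pipeline stage is exercised on generated inputs carrying the
instruments' stated error structure:

* compression rig — 75 uN force resolution, 0.1 um displacement
  resolution (load cell and moving stage of the testing system);
* marker observations — centroids on a 1 mm isotropic voxel grid with
  about 0.5 mm positional uncertainty per axis.  The uncertainty is
  modelled as a uniform perturbation within +/-0.5 mm (reading the
  stated value as a bound); a Gaussian mode with that standard deviation
  is available behind a flag.

All generators are seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .characterization import (
    CompressionProtocol,
    Curve,
    simulate_compression_test,
)
from .constitutive import MaterialCard
from .shift_model import MarkerLayout, ShiftResult

__all__ = [
    "NoiseModel",
    "gen_compression_curve",
    "gen_marker_observations",
    "gen_default_layout",
]


@dataclass(frozen=True)
class NoiseModel:
    """Instrument error model for the synthetic generators."""

    force_resolution: float = 7.5e-5        # N
    displacement_resolution: float = 1.0e-7  # m
    voxel_size: float = 1.0                 # mm
    centroid_uncertainty: float = 0.5       # mm per axis
    gaussian_centroid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("force_resolution", "displacement_resolution",
                     "voxel_size", "centroid_uncertainty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _quantize(x: np.ndarray, step: float) -> np.ndarray:
    if step <= 0:
        return x
    return np.round(x / step) * step


def gen_compression_curve(
    card: MaterialCard,
    proto: CompressionProtocol | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> Curve:
    """Noisy compression-relaxation curve as the rig would record it.

    The noiseless quasi-linear viscoelastic response is perturbed with
    Gaussian force noise at the load-cell resolution scale, then force
    and displacement are quantized to the instrument resolutions.  With
    all noise scales zero the output equals
    :func:`~brainshift.characterization.simulate_compression_test`.
    """
    proto = proto or CompressionProtocol()
    noise = noise or NoiseModel()
    curve = simulate_compression_test(card, proto)
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    force = curve.force.copy()
    if noise.force_resolution > 0:
        force = force + rng.normal(0.0, noise.force_resolution, size=force.shape)
        force = _quantize(force, noise.force_resolution)
    disp = _quantize(curve.displacement, noise.displacement_resolution)
    return Curve(
        t=curve.t,
        displacement=disp,
        force=force,
        sample_height=curve.sample_height,
        sample_area=curve.sample_area,
    )


def gen_default_layout() -> MarkerLayout:
    """The 18-marker arrangement of the phantom, reduced to elevations.

    Eight superficial markers sit near the surface of the column (ids
    1-8); ten internal markers form three rows of three, four and three
    (ids 9-18) spanning the interior.  Elevation fractions place the
    rows proportionally to their depth in the phantom.
    """
    sup_ids = tuple(range(1, 9))
    sup_elev = (0.86, 0.88, 0.90, 0.92, 0.94, 0.96, 0.98, 1.00)
    rows = ((0.70, 3), (0.50, 4), (0.30, 3))
    int_ids = tuple(range(9, 19))
    int_elev = tuple(e for e, cnt in rows for _ in range(cnt))
    return MarkerLayout(
        ids=sup_ids + int_ids,
        elevation_fraction=sup_elev + int_elev,
        marker_class=("superficial",) * 8 + ("internal",) * 10,
    )


def gen_marker_observations(
    truth: ShiftResult,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """MRI-like marker observations of a simulated trajectory.

    Marker positions (material position + displacement, in mm) are
    snapped to the voxel grid and then perturbed per axis within the
    centroid uncertainty.  Returns a trajectory-layout frame with
    observed positions (``x_mm .. z_mm``) and observed displacements
    relative to the first (100% fluid) step (``ux_mm .. uz_mm``).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    layout = truth.layout
    height_mm = truth.column.mesh.height * 1000.0 if truth.column is not None \
        else 100.0
    z0 = np.array(layout.elevation_fraction) * height_mm
    base = np.zeros((len(layout), 3))
    base[:, 2] = z0

    rows = []
    obs_first = None
    for si, step in enumerate(truth.steps):
        pos = base + step.displacement_mm
        obs = _quantize(pos, noise.voxel_size)
        if noise.centroid_uncertainty > 0:
            if noise.gaussian_centroid:
                obs = obs + rng.normal(0.0, noise.centroid_uncertainty,
                                       size=obs.shape)
            else:
                obs = obs + rng.uniform(-noise.centroid_uncertainty,
                                        noise.centroid_uncertainty,
                                        size=obs.shape)
        if obs_first is None:
            obs_first = obs.copy()
        disp = obs - obs_first
        for mi, mid in enumerate(layout.ids):
            rows.append({
                "step": si,
                "pct_loss": step.pct_loss,
                "marker_id": mid,
                "marker_class": layout.marker_class[mi],
                "x_mm": obs[mi, 0],
                "y_mm": obs[mi, 1],
                "z_mm": obs[mi, 2],
                "ux_mm": disp[mi, 0],
                "uy_mm": disp[mi, 1],
                "uz_mm": disp[mi, 2],
            })
    return pd.DataFrame(rows)
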