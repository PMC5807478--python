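"""Plain-text readers and writers: material cards, curves, trajectories.

Material cards are ``key = value`` files using the characterization
vocabulary (``mu0``, ``alpha``, ``D`` or ``nu``, ``g1``/``tau1`` pairs,
``k``, ``e0``, ``gamma_w``, ...).  Curves and marker trajectories are
CSV.  SI units are used internally; marker I/O is in millimetres.  All
writes are atomic (write to a temporary file, then rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .characterization import Curve
from .constitutive import (
    FluidPhase,
    MaterialCard,
    OgdenParams,
    PronySeries,
)

__all__ = [
    "read_material_card",
    "write_material_card",
    "read_curve_csv",
    "write_curve_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "atomic_write_text",
]

_SOLID_KEYS = {"name", "mu0", "alpha", "D", "nu", "rho_solid"}
_FLUID_KEYS = {"k", "e0", "gamma_w", "rho_w", "eta", "g_const"}


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` atomically (temp file + rename)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", prefix=path.name,
                               suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _parse_kv(path) -> dict:
    out = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in out:
            raise ValueError(f"{path}:{ln}: duplicate key {key!r}")
        out[key] = val
    return out


def read_material_card(path) -> MaterialCard:
    """Read and validate a plain-text material card.

    The formulation is inferred from the keys present and cross-checked
    against the declared ``name``: an HVE card must not carry fluid keys,
    a PHE card must not carry Prony keys, and so on.  Unknown keys are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"material card not found: {path}")
    kv = _parse_kv(path)
    if "name" not in kv:
        raise ValueError(f"{path}: missing 'name'")
    name = kv.pop("name").upper()

    prony_keys = {k for k in kv if k.startswith(("g", "tau")) and k[-1].isdigit()}
    unknown = set(kv) - _SOLID_KEYS - _FLUID_KEYS - prony_keys
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")

    def fget(key, default=None):
        if key in kv:
            return float(kv.pop(key))
        return default

    mu0 = fget("mu0")
    alpha = fget("alpha")
    if mu0 is None or alpha is None:
        raise ValueError(f"{path}: mu0 and alpha are required")
    D = fget("D")
    nu = fget("nu")
    if D is not None and nu is not None:
        implied = 3.0 * (1.0 - 2.0 * nu) / (mu0 * (1.0 + nu))
        if abs(D - implied) > 0.05 * max(abs(implied), 1e-30):
            raise ValueError(
                f"{path}: inconsistent D = {D} and nu = {nu} "
                f"(nu implies D = {implied:.3g})"
            )
    if D is None:
        if nu is not None:
            D = 3.0 * (1.0 - 2.0 * nu) / (mu0 * (1.0 + nu))
        elif name == "HVE":
            D = 0.0
        else:
            raise ValueError(f"{path}: D or nu required for {name}")
    ogden = OgdenParams(mu0=mu0, alpha=alpha, D=D)

    # Prony pairs g1/tau1, g2/tau2, ...
    g, tau = [], []
    i = 1
    while f"g{i}" in kv or f"tau{i}" in kv:
        if f"g{i}" not in kv or f"tau{i}" not in kv:
            raise ValueError(f"{path}: g{i}/tau{i} must come as a pair")
        g.append(float(kv.pop(f"g{i}")))
        tau.append(float(kv.pop(f"tau{i}")))
        i += 1
    leftovers = {k for k in kv if k.startswith(("g", "tau")) and k[-1].isdigit()}
    if leftovers - _FLUID_KEYS:
        raise ValueError(f"{path}: non-contiguous Prony keys {sorted(leftovers)}")
    prony = PronySeries(g=tuple(g), tau=tuple(tau))

    fluid_kv = {k: float(kv.pop(k)) for k in list(kv) if k in _FLUID_KEYS}
    rho_solid = fget("rho_solid", 1015.0)

    if name == "HVE" and fluid_kv:
        raise ValueError(f"{path}: HVE card must not carry fluid keys "
                         f"{sorted(fluid_kv)}")
    if name == "PHE" and len(prony):
        raise ValueError(f"{path}: PHE card must not carry Prony keys")
    fluid = None
    if name in ("PHVE", "PHE"):
        if "k" not in fluid_kv:
            raise ValueError(f"{path}: {name} card requires hydraulic "
                             "conductivity 'k'")
        fluid = FluidPhase(**fluid_kv)
    return MaterialCard(name=name, ogden=ogden, prony=prony, fluid=fluid,
                        rho_solid=rho_solid)


def write_material_card(card: MaterialCard, path) -> None:
    """Serialize a material card; round-trips through
    :func:`read_material_card`."""
    lines = [f"name = {card.name}"]
    lines.append(f"mu0 = {card.ogden.mu0!r}")
    lines.append(f"alpha = {card.ogden.alpha!r}")
    lines.append(f"D = {card.ogden.D!r}")
    for i, (g, tau) in enumerate(zip(card.prony.g, card.prony.tau), start=1):
        lines.append(f"g{i} = {g!r}")
        lines.append(f"tau{i} = {tau!r}")
    if card.fluid is not None:
        f = card.fluid
        lines.append(f"k = {f.k!r}")
        lines.append(f"e0 = {f.e0!r}")
        lines.append(f"gamma_w = {f.gamma_w!r}")
        lines.append(f"rho_w = {f.rho_w!r}")
        lines.append(f"eta = {f.eta!r}")
        lines.append(f"g_const = {f.g_const!r}")
    lines.append(f"rho_solid = {card.rho_solid!r}")
    atomic_write_text(path, "\n".join(lines) + "\n")


_CURVE_COLS = ["time_s", "displacement_m", "force_N"]


def read_curve_csv(path, sample_height: float, sample_area: float) -> Curve:
    """Read a compression curve CSV (header ``time_s, displacement_m,
    force_N`` required; derived columns are ignored on input)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _CURVE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return Curve(
        t=df["time_s"].to_numpy(),
        displacement=df["displacement_m"].to_numpy(),
        force=df["force_N"].to_numpy(),
        sample_height=sample_height,
        sample_area=sample_area,
    )


def write_curve_csv(curve: Curve, path) -> None:
    """Write a curve CSV with the derived stress/strain columns."""
    df = pd.DataFrame({
        "time_s": curve.t,
        "displacement_m": curve.displacement,
        "force_N": curve.force,
        "stress_Pa": curve.stress,
        "true_strain": curve.true_strain,
    })
    atomic_write_text(path, df.to_csv(index=False))


_TRAJ_COLS = ["step", "pct_loss", "marker_id", "ux_mm", "uy_mm", "uz_mm"]


def read_trajectory_csv(path) -> pd.DataFrame:
    """Read a marker-trajectory CSV (displacements in mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_trajectory_csv(df: pd.DataFrame, path) -> None:
    """Write a marker-trajectory CSV (atomic)."""
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory frame missing columns {missing}")
    atomic_write_text(path, df.to_csv(index=False))
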