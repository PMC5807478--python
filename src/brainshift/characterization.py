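"""Unconfined compression-relaxation protocol and sequential parameter fits.

The characterization experiment compresses a cylindrical gel sample
(12 mm diameter x 7 mm height by default) at a constant crosshead speed of
8.3 mm/s down to 30% of its height (0.356 true strain) and then holds the
displacement for 500 s while the force relaxes.

Fitting is sequential, replicating the experimental procedure: the Ogden
pair ``(mu0, alpha)`` is fitted on the loading ramp, then a Prony series
is fitted on the normalized relaxation curve.  Because the ramp is three
orders of magnitude shorter than the shortest retardation time, the
viscous stiffening absorbed into the "instantaneous" ``mu0`` is below a
percent for the published parameters.

The simulated stress is quasi-linear viscoelastic: the incompressible
Ogden uniaxial stress (entirely deviatoric) is scaled through the
hereditary integral with the exponential internal-variable update.
Nominal stress (force / undeformed area) versus true strain is the default
measure, standard for unconfined gel tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize

from .constitutive import (
    MaterialCard,
    OgdenParams,
    PronySeries,
    hereditary_convolution,
    ogden_uniaxial_stress,
)

__all__ = [
    "CompressionProtocol",
    "Curve",
    "OgdenFit",
    "PronyFit",
    "true_strain_from_compression",
    "simulate_compression_test",
    "fit_ogden",
    "fit_prony",
]


@dataclass(frozen=True)
class CompressionProtocol:
    """Geometry and loading programme of the compression-relaxation test."""

    sample_diameter: float = 0.012      # m
    sample_height: float = 0.007        # m
    ramp_speed: float = 8.3e-3          # m/s
    target_compression: float = 0.30    # fraction of height
    hold_duration: float = 500.0        # s
    sample_dt: float = 5.0e-3           # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_compression < 1.0:
            raise ValueError("target_compression must lie in [0, 1)")
        if self.ramp_speed <= 0:
            raise ValueError("ramp_speed must be positive")
        if self.hold_duration < 0:
            raise ValueError("hold_duration must be non-negative")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be positive")

    @property
    def area0(self) -> float:
        """Undeformed cross-section, m^2."""
        return np.pi * (self.sample_diameter / 2.0) ** 2

    @property
    def peak_displacement(self) -> float:
        return self.target_compression * self.sample_height

    @property
    def ramp_duration(self) -> float:
        return self.peak_displacement / self.ramp_speed


@dataclass
class Curve:
    """Time-stamped force/displacement record of one compression test.

    ``displacement`` is the compression depth (non-negative, m) and
    ``force`` the compressive force as read by the load cell (non-negative
    for a compressed sample, N).  Derived quantities use the package sign
    convention (compression negative): ``stress = -force/A0`` and
    ``true_strain = ln(1 - displacement/h0)``.
    """

    t: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    sample_height: float
    sample_area: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.t.ndim != 1 or len({len(self.t), len(self.displacement),
                                    len(self.force)}) != 1:
            raise ValueError("t, displacement, force must be 1D, equal length")
        if self.t[0] != 0.0 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing from 0")

    @property
    def stress(self) -> np.ndarray:
        """Nominal stress, Pa, compression negative."""
        return -self.force / self.sample_area

    @property
    def true_strain(self) -> np.ndarray:
        """Logarithmic axial strain, negative in compression."""
        return np.log(1.0 - self.displacement / self.sample_height)

    @property
    def stretch(self) -> np.ndarray:
        return 1.0 - self.displacement / self.sample_height

    def ramp_mask(self) -> np.ndarray:
        """Samples belonging to the loading ramp (before peak displacement)."""
        peak = self.displacement.max()
        idx = int(np.argmax(self.displacement >= peak * (1.0 - 1e-12)))
        mask = np.zeros_like(self.t, dtype=bool)
        mask[: idx + 1] = True
        return mask

    def hold_mask(self) -> np.ndarray:
        """Samples at peak displacement (relaxation hold)."""
        return ~self.ramp_mask() | (np.arange(len(self.t)) == self.ramp_mask().sum() - 1)


def true_strain_from_compression(fraction: float) -> float:
    """True-strain magnitude ``|ln(1 - fraction)|`` of a compression ratio.

    A 30% compression corresponds to 0.357 true strain (printed as 0.356
    in the characterization protocol).
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("compression fraction must lie in [0, 1)")
    return float(abs(np.log(1.0 - fraction)))


def simulate_compression_test(
    card: MaterialCard, proto: CompressionProtocol | None = None
) -> Curve:
    """Simulate the ramp-and-hold test for a material card.

    The unconfined test is assumed fully drained (thin sample, free
    lateral surface), so only the solid phase of the card matters; a fluid
    phase, if present, is ignored.  The deviatoric Ogden stress is scaled
    by the hereditary integral (quasi-linear viscoelasticity), so an empty
    Prony series gives a constant hold-phase stress equal to the elastic
    peak stress.
    """
    proto = proto or CompressionProtocol()
    if len(card.prony) and proto.sample_dt > min(card.prony.tau) / 10.0:
        warnings.warn(
            "sample_dt exceeds min(tau)/10; relaxation may be under-resolved",
            stacklevel=2,
        )
    t_end = proto.ramp_duration + proto.hold_duration
    n = int(np.ceil(t_end / proto.sample_dt)) + 1
    t = np.linspace(0.0, t_end, n)
    # make sure the exact peak instant is sampled
    if proto.ramp_duration not in t:
        t = np.sort(np.append(t, proto.ramp_duration))
    d = np.minimum(proto.ramp_speed * t, proto.peak_displacement)
    lam = 1.0 - d / proto.sample_height
    sigma_e = ogden_uniaxial_stress(lam, card.ogden, measure="nominal")
    sigma = hereditary_convolution(t, sigma_e, card.prony)
    force = -sigma * proto.area0
    return Curve(
        t=t,
        displacement=d,
        force=force,
        sample_height=proto.sample_height,
        sample_area=proto.area0,
    )


@dataclass(frozen=True)
class OgdenFit:
    """Result of the ramp-portion Ogden fit."""

    mu0: float
    alpha: float
    residual_norm: float
    alpha_identifiable: bool
    n_samples: int

    @property
    def params(self) -> OgdenParams:
        return OgdenParams(mu0=self.mu0, alpha=self.alpha, D=0.0)


#: Strain magnitude below which alpha is flagged as unidentifiable
#: (the small-strain response depends on mu0 only).
_ALPHA_ID_STRAIN = 0.05


def fit_ogden(curve: Curve, ramp_mask=None) -> OgdenFit:
    """Least-squares fit of ``(mu0, alpha)`` on the loading ramp.

    Fits the incompressible uniaxial nominal stress against the measured
    nominal stress over a fixed multi-start grid of ``alpha`` values (the
    sign of ``alpha`` is not identifiable from an initial guess alone).
    Deterministic: no randomized starts.
    """
    mask = curve.ramp_mask() if ramp_mask is None else np.asarray(ramp_mask)
    lam = curve.stretch[mask]
    sig = curve.stress[mask]
    if len(lam) < 10:
        raise ValueError(f"need >= 10 ramp samples, got {len(lam)}")
    # small-strain slope gives E ~ 3 mu0 for an incompressible solid
    eps = np.log(lam)
    small = np.abs(eps) < max(0.02, 0.2 * np.abs(eps).max())
    if small.sum() >= 2:
        slope = np.polyfit(eps[small], sig[small], 1)[0]
    else:
        slope = np.polyfit(eps, sig, 1)[0]
    mu0_init = max(abs(slope) / 3.0, 1e-12)
    scale = max(np.abs(sig).max(), 1e-12)

    def resid(theta):
        mu0, alpha = theta
        model = ogden_uniaxial_stress(
            lam, OgdenParams(mu0=mu0, alpha=alpha, D=0.0), measure="nominal"
        )
        return (model - sig) / scale

    best = None
    for alpha0 in (-6.0, -4.0, -2.0, -1.0, 1.0, 2.0, 4.0, 6.0):
        try:
            sol = least_squares(
                resid,
                x0=[mu0_init, alpha0],
                bounds=([1e-12, -50.0], [np.inf, 50.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e-6:
        raise RuntimeError("Ogden fit did not converge from any start")
    mu0, alpha = best.x
    if alpha == 0.0:
        raise RuntimeError("Ogden fit returned alpha = 0")
    return OgdenFit(
        mu0=float(mu0),
        alpha=float(alpha),
        residual_norm=float(np.sqrt(2.0 * best.cost) * scale),
        alpha_identifiable=bool(np.abs(eps).max() >= _ALPHA_ID_STRAIN),
        n_samples=int(len(lam)),
    )


@dataclass(frozen=True)
class PronyFit:
    """Result of the hold-portion Prony fit."""

    series: PronySeries
    residual_norm: float
    ill_conditioned: bool
    n_samples: int


def fit_prony(curve: Curve, n_terms: int = 2, hold_mask=None) -> PronyFit:
    """Fit a Prony series to the normalized relaxation curve.

    The hold-portion stress is divided by the peak stress, removing the
    ``mu0`` coupling, and ``g_R(t)`` is fitted with the constraints
    ``g_i >= 0``, ``sum(g) < 1``, ``tau_i > 0``.  Retardation times are
    returned sorted ascending.  Multi-start over log-spaced ``tau``
    initializations; deterministic.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    mask = curve.hold_mask() if hold_mask is None else np.asarray(hold_mask)
    t = curve.t[mask]
    sig = curve.stress[mask]
    if len(t) < 2 * n_terms + 2:
        raise ValueError("too few hold samples for the requested n_terms")
    t = t - t[0]
    peak = sig[0]
    if peak == 0.0:
        raise ValueError("zero peak stress: nothing to normalize against")
    y = sig / peak
    span = t[-1]
    t_min = max(np.diff(t).min(), 1e-9)
    if span < 4.0 * t_min * 10**n_terms:
        warnings.warn("hold span is short for the requested number of terms",
                      stacklevel=2)

    def unpack(theta):
        g = theta[:n_terms]
        tau = np.exp(theta[n_terms:])
        return g, tau

    def resid(theta):
        g, tau = unpack(theta)
        model = 1.0 - (g[None, :] * (1.0 - np.exp(-t[:, None] / tau[None, :]))).sum(axis=1)
        return model - y

    # amplitude of the observed relaxation seeds the weights
    drop = max(1.0 - y.min(), 1e-3)
    starts = []
    grids = np.log(np.geomspace(max(10 * t_min, span * 1e-3), span, 4))
    if n_terms == 1:
        starts = [[drop * 0.8, lg] for lg in grids]
    else:
        base = np.log(np.geomspace(max(10 * t_min, span * 1e-3), span, n_terms))
        starts.append(list(np.full(n_terms, drop / n_terms)) + list(base))
        for shift in (-1.0, 1.0):
            starts.append(list(np.full(n_terms, drop / n_terms)) + list(base + shift))

    lb = [0.0] * n_terms + [np.log(t_min)] * n_terms
    ub = [1.0] * n_terms + [np.log(span * 10.0)] * n_terms
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lb, ub)
        sol = least_squares(resid, x0=x0, bounds=(lb, ub),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    g, tau = unpack(best.x)

    if g.sum() >= 1.0 - 1e-9:
        # re-solve with the simplex constraint active
        cons = [{"type": "ineq", "fun": lambda th: 1.0 - 1e-6 - th[:n_terms].sum()}]
        bounds = list(zip(lb, ub))
        sol2 = minimize(lambda th: 0.5 * np.sum(resid(th) ** 2), best.x,
                        bounds=bounds, constraints=cons, method="SLSQP")
        g, tau = unpack(sol2.x)
        best_cost = 0.5 * np.sum(resid(sol2.x) ** 2)
    else:
        best_cost = best.cost

    order = np.argsort(tau)
    g, tau = g[order], tau[order]
    ill = bool(tau.max() > span / 2.0 and n_terms > 1 and
               np.min(np.diff(np.log(tau))) < np.log(2.0))
    # weights below resolution are noise, keep but flag via residual
    series = PronySeries(g=tuple(g), tau=tuple(tau))
    return PronyFit(
        series=series,
        residual_norm=float(np.sqrt(2.0 * best_cost)),
        ill_conditioned=ill,
        n_samples=int(len(t)),
    )
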