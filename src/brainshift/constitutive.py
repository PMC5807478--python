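"""Closed-form constitutive relations for the hydrogel brain mimic.

The solid skeleton is a one-term Ogden hyperelastic material

.. math::

    U = \\frac{2\\mu_0}{\\alpha^2}\\left(\\bar\\lambda_1^\\alpha
        + \\bar\\lambda_2^\\alpha + \\bar\\lambda_3^\\alpha - 3\\right)
        + \\frac{1}{D}(J - 1)^2,

with deviatoric principal stretches
:math:`\\bar\\lambda_i = J^{-1/3}\\lambda_i` and volume strain
:math:`J = \\lambda_1\\lambda_2\\lambda_3`.  Stresses follow by partial
differentiation of :math:`U` with respect to the principal stretches.

Rate dependence of the skeleton is expressed through a Prony series for the
shear relaxation modulus,

.. math::

    \\mu(t) = \\mu_0\\, g_R(t), \\qquad
    g_R(t) = 1 - \\sum_i g_i\\left(1 - e^{-t/\\tau_i}\\right),

and the hereditary integral
:math:`\\tau(t) = \\int_0^t \\mu(t - s)\\,\\dot\\gamma(s)\\, ds`, which is
evaluated here with the recursive exponential internal-variable update
(exact for strain histories that are piecewise linear between samples).

The fluid phase obeys Darcy's law,
:math:`n\\mathbf{v} = -(k/\\gamma_w)(\\nabla p - \\rho_w \\mathbf{g})`, and
the total stress in the saturated medium splits as
:math:`\\sigma = \\bar\\sigma^* - p\\,I`.

Sign conventions: tension positive, so uniaxial compression
(:math:`\\lambda < 1`, with :math:`\\alpha < 0` for this gel) yields
negative stress.  All quantities are SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "STANDARD_GRAVITY",
    "OgdenParams",
    "PronySeries",
    "FluidPhase",
    "MaterialCard",
    "KinematicState",
    "strain_energy",
    "ogden_principal_stress",
    "ogden_uniaxial_stress",
    "relaxation_modulus",
    "hereditary_convolution",
    "hereditary_shear_stress",
    "effective_stress_split",
    "D_from_nu",
    "nu_from_D",
    "porosity_from_void_ratio",
    "permeability_from_conductivity",
    "conductivity_from_permeability",
    "table_card",
]

#: Gravitational constant used throughout, m/s^2.
STANDARD_GRAVITY = 9.812


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OgdenParams:
    """One-term Ogden parameters for the rate-independent skeleton.

    Parameters
    ----------
    mu0 : float
        Instantaneous shear modulus, Pa.  Must be positive.
    alpha : float
        Ogden exponent (dimensionless, nonzero).  Negative for the
        hydrogel, which stiffens in compression.
    D : float
        Compressibility parameter, 1/Pa.  ``D = 0`` denotes an
        incompressible solid (``nu = 0.5``).  Related to the bulk modulus
        by ``K = 2/D`` and to the Poisson ratio by
        ``D = 3(1 - 2 nu) / (mu0 (1 + nu))``.
    """

    mu0: float
    alpha: float
    D: float

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise ValueError(f"mu0 must be positive, got {self.mu0}")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if self.D < 0:
            raise ValueError(f"D must be non-negative, got {self.D}")

    @classmethod
    def from_nu(cls, mu0: float, alpha: float, nu: float) -> "OgdenParams":
        """Build parameters from a Poisson ratio instead of ``D``."""
        return cls(mu0=mu0, alpha=alpha, D=D_from_nu(mu0, nu))

    @property
    def nu(self) -> float:
        """Solid-matrix Poisson ratio implied by ``D``."""
        return nu_from_D(self.mu0, self.D)

    @property
    def K(self) -> float:
        """Bulk modulus ``K = 2/D`` (``inf`` when incompressible)."""
        if self.D == 0:
            return np.inf
        return 2.0 / self.D

    @property
    def incompressible(self) -> bool:
        return self.D == 0.0


@dataclass(frozen=True)
class PronySeries:
    """Prony weights ``g_i`` and retardation times ``tau_i`` (seconds).

    An empty series describes a purely hyperelastic (rate-independent)
    solid.  The long-term modulus fraction is ``1 - sum(g)``.
    """

    g: tuple = ()
    tau: tuple = ()

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.g)
        tau = tuple(float(x) for x in self.tau)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "tau", tau)
        if len(g) != len(tau):
            raise ValueError("g and tau must have equal length")
        if any(x < 0 for x in g):
            raise ValueError("Prony weights must be non-negative")
        if sum(g) >= 1.0:
            raise ValueError(f"sum of Prony weights must be < 1, got {sum(g)}")
        if any(x <= 0 for x in tau):
            raise ValueError("retardation times must be positive")

    def __len__(self) -> int:
        return len(self.g)

    @property
    def long_term_fraction(self) -> float:
        """``g_R(inf) = 1 - sum(g_i)``."""
        return 1.0 - sum(self.g)

    def g_R(self, t):
        """Normalized relaxation function ``g_R(t)`` for ``t >= 0``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("t must be non-negative")
        out = np.ones_like(t)
        for gi, ti in zip(self.g, self.tau):
            out = out - gi * (1.0 - np.exp(-t / ti))
        return out


@dataclass(frozen=True)
class FluidPhase:
    """Incompressible pore fluid (water) and its transport properties.

    Parameters
    ----------
    k : float
        Hydraulic conductivity of the medium, m/s.
    gamma_w : float
        Specific weight of the fluid, N/m^3.  Must agree with
        ``rho_w * g_const`` to within 1%.
    rho_w : float
        Fluid density, kg/m^3.
    eta : float
        Dynamic viscosity, Pa s (used only for the permeability
        conversion).
    e0 : float
        Initial void ratio (fluid volume / solid volume).
    g_const : float
        Gravitational acceleration, m/s^2.
    """

    k: float
    gamma_w: float = 9779.0
    rho_w: float = 1000.0
    eta: float = 1.0e-3
    e0: float = 0.2
    g_const: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("hydraulic conductivity k must be positive")
        if not self.e0 > 0:
            raise ValueError("initial void ratio e0 must be positive")
        ref = self.rho_w * self.g_const
        if abs(self.gamma_w - ref) > 0.01 * ref:
            raise ValueError(
                f"gamma_w = {self.gamma_w} inconsistent with rho_w * g = {ref:.1f} "
                "(must agree within 1%)"
            )

    @property
    def n0(self) -> float:
        """Initial porosity ``n = e/(1+e)``."""
        return porosity_from_void_ratio(self.e0)


@dataclass(frozen=True)
class MaterialCard:
    """Full parameter set for one constitutive formulation.

    ``name`` must be one of ``PHVE`` (poro-hyper-viscoelastic), ``PHE``
    (poro-hyperelastic, empty Prony series) or ``HVE``
    (hyper-viscoelastic, incompressible, no fluid phase).
    """

    name: str
    ogden: OgdenParams
    prony: PronySeries = field(default_factory=PronySeries)
    fluid: FluidPhase | None = None
    rho_solid: float = 1015.0

    def __post_init__(self) -> None:
        if self.name not in ("PHVE", "PHE", "HVE"):
            raise ValueError(f"unknown formulation name {self.name!r}")
        if self.rho_solid <= 0:
            raise ValueError("rho_solid must be positive")
        if self.name == "HVE":
            if self.fluid is not None:
                raise ValueError("HVE card must not carry a fluid phase")
            if not self.ogden.incompressible:
                raise ValueError("HVE card requires an incompressible solid (D = 0)")
        else:
            if self.fluid is None:
                raise ValueError(f"{self.name} card requires a fluid phase")
            if self.ogden.incompressible:
                raise ValueError(
                    f"{self.name} card requires a compressible solid matrix (D > 0)"
                )
            if self.name == "PHE" and len(self.prony) > 0:
                raise ValueError("PHE card must have an empty Prony series")
        if self.name in ("PHVE", "HVE") and len(self.prony) == 0:
            raise ValueError(f"{self.name} card requires a non-empty Prony series")

    @property
    def has_fluid(self) -> bool:
        return self.fluid is not None


@dataclass(frozen=True)
class KinematicState:
    """Principal-stretch kinematics of a material point."""

    lam: tuple
    gamma_dot: float = 0.0

    def __post_init__(self) -> None:
        lam = tuple(float(x) for x in self.lam)
        object.__setattr__(self, "lam", lam)
        if len(lam) != 3:
            raise ValueError("three principal stretches required")
        if any(x <= 0 for x in lam):
            raise ValueError("principal stretches must be positive")

    @property
    def J(self) -> float:
        """Volume strain ``lambda_1 lambda_2 lambda_3``."""
        return self.lam[0] * self.lam[1] * self.lam[2]

    @property
    def lam_bar(self) -> tuple:
        """Deviatoric stretches ``J^{-1/3} lambda_i`` (product is 1)."""
        s = self.J ** (-1.0 / 3.0)
        return tuple(s * x for x in self.lam)


# --------------------------------------------------------------------------
# Ogden energy and stresses
# --------------------------------------------------------------------------

def strain_energy(state: KinematicState, p: OgdenParams) -> float:
    """Ogden strain-energy density, Pa.

    ``U = (2 mu0/alpha^2)(lb1^a + lb2^a + lb3^a - 3) + (1/D)(J-1)^2``.
    When ``D = 0`` the volumetric term is dropped and the state must be
    isochoric (``J = 1``).
    """
    J = state.J
    lb = np.array(state.lam_bar)
    dev = 2.0 * p.mu0 / p.alpha**2 * (np.sum(lb**p.alpha) - 3.0)
    if p.D == 0.0:
        if abs(J - 1.0) > 1e-9:
            raise ValueError(
                f"incompressible material requires J = 1, got J = {J}"
            )
        return float(dev)
    return float(dev + (J - 1.0) ** 2 / p.D)


def ogden_principal_stress(lam, p: OgdenParams, split: bool = False):
    """Nominal principal stresses ``P_j = dU/dlambda_j``.

    Parameters
    ----------
    lam : array_like, shape (..., 3)
        Principal stretches.
    p : OgdenParams
    split : bool
        If True return ``(P_dev, P_vol)``, the derivatives of the
        isochoric and volumetric energy terms separately; otherwise their
        sum.  The volumetric part is zero for ``D = 0``.

    Notes
    -----
    The isochoric part evaluates to
    ``P_dev_j = (2 mu0/(alpha lam_j)) (lb_j^alpha - mean(lb^alpha))``
    and the volumetric part to ``(2/D)(J-1) J/lam_j``.
    """
    lam = np.asarray(lam, dtype=float)
    J = np.prod(lam, axis=-1, keepdims=True)
    lb = J ** (-1.0 / 3.0) * lam
    lba = lb**p.alpha
    mean = np.mean(lba, axis=-1, keepdims=True)
    P_dev = 2.0 * p.mu0 / p.alpha * (lba - mean) / lam
    if p.D == 0.0:
        P_vol = np.zeros_like(P_dev)
    else:
        P_vol = (2.0 / p.D) * (J - 1.0) * J / lam
    if split:
        return P_dev, P_vol
    return P_dev + P_vol


def ogden_uniaxial_stress(lam_axial, p: OgdenParams, measure: str = "cauchy"):
    """Axial stress in incompressible uniaxial stress, Pa.

    The lateral stretches are ``lambda^{-1/2}`` and the indeterminate
    pressure is eliminated by the traction-free lateral condition, giving
    the Cauchy stress ``sigma = (2 mu0/alpha)(lam^alpha - lam^{-alpha/2})``.
    The nominal stress (force / reference area) is ``sigma / lam``.
    Compression (``lam < 1`` with ``alpha < 0``) gives negative stress.
    """
    lam = np.asarray(lam_axial, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("stretch must be positive")
    sigma = 2.0 * p.mu0 / p.alpha * (lam**p.alpha - lam ** (-p.alpha / 2.0))
    if measure == "cauchy":
        return sigma
    if measure == "nominal":
        return sigma / lam
    raise ValueError(f"unknown stress measure {measure!r}")


# --------------------------------------------------------------------------
# viscoelasticity
# --------------------------------------------------------------------------

def relaxation_modulus(t, mu0: float, prony: PronySeries):
    """Shear relaxation modulus ``mu(t) = mu0 g_R(t)``, Pa, for ``t >= 0``."""
    return mu0 * prony.g_R(t)


def hereditary_convolution(t, x, prony: PronySeries):
    """Evaluate ``y(t) = int_0^t g_R(t - s) x'(s) ds`` on sampled data.

    A nonzero ``x[0]`` is treated as a step applied at ``t = 0`` (so a
    constant history returns ``g_R(t) * x[0]``).  Uses one exponential
    internal variable per Prony term; the update is exact when ``x`` is
    piecewise linear between samples.

    Parameters
    ----------
    t : array_like
        Strictly increasing sample times starting at 0.
    x : array_like
        Driving history sampled at ``t`` (e.g. shear strain, or an
        elastic stress for quasi-linear viscoelastic scaling).
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    if t.ndim != 1 or t.shape != x.shape:
        raise ValueError("t and x must be 1D arrays of equal length")
    if t[0] != 0.0:
        raise ValueError("time samples must start at 0")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time samples must be strictly increasing")

    g = np.array(prony.g)
    tau = np.array(prony.tau)
    y = np.empty_like(x)
    # internal variables h_i(t) = int_0^t exp(-(t-s)/tau_i) x'(s) ds,
    # initialized to x[0] for the step at t = 0
    h = np.full(len(g), x[0], dtype=float)
    g_inf = 1.0 - g.sum()
    y[0] = x[0]
    for n in range(len(dt)):
        e = np.exp(-dt[n] / tau) if len(tau) else tau
        dx = x[n + 1] - x[n]
        h = e * h + (tau / dt[n]) * (1.0 - e) * dx if len(tau) else h
        y[n + 1] = g_inf * x[n + 1] + np.dot(g, h)
    return y


def hereditary_shear_stress(t, gamma, mu0: float, prony: PronySeries):
    """Viscoelastic shear stress ``tau(t) = int mu(t-s) gamma'(s) ds``, Pa."""
    return mu0 * hereditary_convolution(t, gamma, prony)


# --------------------------------------------------------------------------
# effective stress and conversions
# --------------------------------------------------------------------------

def effective_stress_split(sigma_eff, p_pore: float):
    """Total stress ``sigma = sigma_eff - p I`` in the saturated medium."""
    sigma_eff = np.asarray(sigma_eff, dtype=float)
    if sigma_eff.shape[-1] != sigma_eff.shape[-2]:
        raise ValueError("stress tensor must be square")
    if not np.allclose(sigma_eff, np.swapaxes(sigma_eff, -1, -2)):
        raise ValueError("effective stress tensor must be symmetric")
    return sigma_eff - p_pore * np.eye(sigma_eff.shape[-1])


def D_from_nu(mu0: float, nu: float) -> float:
    """Compressibility parameter ``D = 2/K = 3(1-2 nu)/(mu0 (1+nu))``."""
    if not 0.0 <= nu <= 0.5:
        raise ValueError(f"nu must lie in [0, 0.5], got {nu}")
    if not mu0 > 0:
        raise ValueError("mu0 must be positive")
    return 3.0 * (1.0 - 2.0 * nu) / (mu0 * (1.0 + nu))


def nu_from_D(mu0: float, D: float) -> float:
    """Poisson ratio implied by ``D``; inverse of :func:`D_from_nu`."""
    if D < 0:
        raise ValueError("D must be non-negative")
    if not mu0 > 0:
        raise ValueError("mu0 must be positive")
    x = D * mu0
    return (3.0 - x) / (6.0 + x)


def porosity_from_void_ratio(e) -> float:
    """Porosity ``n = e/(1+e)`` for void ratio ``e >= 0``."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("void ratio must be non-negative")
    out = e / (1.0 + e)
    return float(out) if out.ndim == 0 else out


def permeability_from_conductivity(
    k: float, eta: float = 1.0e-3, rho_w: float = 1000.0,
    g_const: float = STANDARD_GRAVITY,
) -> float:
    """Intrinsic permeability ``Pi = k eta/(rho_w g)`` from conductivity."""
    if min(k, eta, rho_w, g_const) <= 0:
        raise ValueError("all arguments must be positive")
    return k * eta / (rho_w * g_const)


def conductivity_from_permeability(
    Pi: float, eta: float = 1.0e-3, rho_w: float = 1000.0,
    g_const: float = STANDARD_GRAVITY,
) -> float:
    """Inverse of :func:`permeability_from_conductivity`."""
    if min(Pi, eta, rho_w, g_const) <= 0:
        raise ValueError("all arguments must be positive")
    return Pi * rho_w * g_const / eta


# --------------------------------------------------------------------------
# published parameter sets
# --------------------------------------------------------------------------

# Characterized hydrogel parameters (solid phase from the unconfined
# compression-relaxation fit; fluid phase from the soft-tissue literature).
_MU0 = 794.36       # Pa
_ALPHA = -2.8
_D = 0.84e-3        # 1/Pa, from nu = 0.35
_G = (0.13, 0.32)
_TAU = (14.0, 333.0)
_K_HYD = 1.57e-9    # m/s
_E0 = 0.2
_GAMMA_W = 9779.0   # N/m^3


def table_card(name: str) -> MaterialCard:
    """Material card for one of the three published formulations.

    ``PHVE`` carries the full parameter set, ``PHE`` drops the Prony
    series, and ``HVE`` drops the fluid phase and sets ``D = 0``
    (incompressible solid, ``nu = 0.5``).
    """
    if name == "PHVE":
        return MaterialCard(
            name="PHVE",
            ogden=OgdenParams(mu0=_MU0, alpha=_ALPHA, D=_D),
            prony=PronySeries(g=_G, tau=_TAU),
            fluid=FluidPhase(k=_K_HYD, gamma_w=_GAMMA_W, e0=_E0),
        )
    if name == "PHE":
        return MaterialCard(
            name="PHE",
            ogden=OgdenParams(mu0=_MU0, alpha=_ALPHA, D=_D),
            prony=PronySeries(),
            fluid=FluidPhase(k=_K_HYD, gamma_w=_GAMMA_W, e0=_E0),
        )
    if name == "HVE":
        return MaterialCard(
            name="HVE",
            ogden=OgdenParams(mu0=_MU0, alpha=_ALPHA, D=0.0),
            prony=PronySeries(g=_G, tau=_TAU),
            fluid=None,
        )
    raise ValueError(f"unknown formulation name {name!r}")
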