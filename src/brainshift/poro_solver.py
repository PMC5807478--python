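"""One-dimensional coupled consolidation solver for the reduced shift model.

The paper-scale 3D contact problem is replaced by a vertical column of
saturated gel on a rigid, impermeable base.  Unknowns are the nodal
vertical displacement ``u`` and (for biphasic materials) the nodal excess
pore pressure ``p``, discretized with linear finite elements and advanced
with backward Euler.  The solid skeleton is the Ogden material of
:mod:`brainshift.constitutive`, optionally with Prony viscoelasticity on
the deviatoric stress (exponential internal-variable update inside each
global step); the fluid obeys Darcy's law with both constituents
incompressible, so skeleton volume change equals fluid efflux.

Two lateral confinement modes are supported:

``oedometer``
    Lateral stretches fixed at 1.  This is the classical consolidation
    setting validated against the Terzaghi closed form.
``uniaxial_stress``
    Each slice is laterally free: the lateral stretch of every element is
    found from the zero total lateral traction condition
    ``dU/dlam_l = p J/lam_l``.  In the undrained limit this recovers the
    isochoric response (the pore pressure carries the volumetric load);
    with ``p = 0`` it is the drained uniaxial-stress response.  The
    incompressible (HVE) case uses the closed-form lateral stretch
    ``lam^(-1/2)`` and carries no pressure field.

Conventions: ``z`` increases upward from the base (datum), gravity acts
downward, tension positive (compression negative), excess pore pressure
measured relative to the external fluid column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constitutive import STANDARD_GRAVITY, MaterialCard, OgdenParams

__all__ = [
    "ColumnMesh",
    "DrainageBC",
    "Phase",
    "ColumnState",
    "ConsolidationResult",
    "solve_consolidation",
    "terzaghi_pressure",
    "buoyant_body_force",
    "constrained_modulus",
    "consolidation_coefficient",
]


# --------------------------------------------------------------------------
# meshes, boundary conditions, states
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnMesh:
    """Vertical column discretization (node elevations, datum at base)."""

    z: np.ndarray
    confinement: str = "oedometer"

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.ndim != 1 or len(z) < 3:
            raise ValueError("mesh needs at least 3 nodes")
        if np.any(np.diff(z) <= 0):
            raise ValueError("node elevations must be strictly increasing")
        if self.confinement not in ("oedometer", "uniaxial_stress"):
            raise ValueError(f"unknown confinement {self.confinement!r}")

    @classmethod
    def uniform(cls, n_nodes: int, height: float,
                confinement: str = "oedometer") -> "ColumnMesh":
        return cls(z=np.linspace(0.0, height, n_nodes), confinement=confinement)

    @property
    def n_nodes(self) -> int:
        return len(self.z)

    @property
    def height(self) -> float:
        return float(self.z[-1] - self.z[0])


@dataclass(frozen=True)
class DrainageBC:
    """Pore-pressure boundary condition for one loading phase.

    Emerged nodes (reference elevation above ``fluid_level``) are free
    draining (``p = 0``) when ``top_draining`` is set.  ``drained_nodes``
    overrides the emergence rule with an explicit node-index set (used for
    the Terzaghi benchmark, where the top node drains while submerged).
    """

    top_draining: bool = False
    fluid_level: float = np.inf
    drained_nodes: tuple | None = None

    def drained_index(self, mesh: ColumnMesh) -> np.ndarray:
        if self.drained_nodes is not None:
            return np.asarray(self.drained_nodes, dtype=int)
        if not self.top_draining:
            return np.empty(0, dtype=int)
        return np.nonzero(mesh.z > self.fluid_level)[0]


@dataclass(frozen=True)
class Phase:
    """One stage of the loading/drainage programme."""

    duration: float
    dt: float
    bc: DrainageBC = field(default_factory=DrainageBC)
    surface_load: float = 0.0     # total traction on top face, Pa (compression < 0)
    gravity: float = 1.0          # scale factor on the buoyant body force
    fluid_level: float = np.inf   # external fluid level for buoyancy, m
    ramp: bool = False            # ramp loads linearly from the previous phase


@dataclass
class ColumnState:
    """Solution snapshot: displacement, pore pressure, internal variables."""

    t: float
    u: np.ndarray
    p: np.ndarray
    internal: dict


class ConsolidationResult(Sequence):
    """Time series of :class:`ColumnState` with conservation bookkeeping."""

    def __init__(self, mesh: ColumnMesh, states: list,
                 cumulative_outflow: float, volume_change: float):
        self.mesh = mesh
        self.states = states
        #: fluid volume (per unit plan area) expelled through drained nodes, m
        self.cumulative_outflow = cumulative_outflow
        #: column volume change sum((J - 1) h), m (negative in compression)
        self.volume_change = volume_change

    def __len__(self):
        return len(self.states)

    def __getitem__(self, i):
        return self.states[i]

    @property
    def final(self) -> ColumnState:
        return self.states[-1]


# --------------------------------------------------------------------------
# body force
# --------------------------------------------------------------------------

def buoyant_body_force(z, fluid_level, rho_solid, rho_w,
                       g_const: float = STANDARD_GRAVITY):
    """Vertical body-force density, N/m^3, downward positive.

    Submerged material (``z <= fluid_level``) weighs
    ``(rho_solid - rho_w) g``; emerged material weighs its full
    ``rho_solid g`` (buoyancy lost as the fluid level drops).
    """
    if rho_solid <= 0 or rho_w <= 0:
        raise ValueError("densities must be positive")
    z = np.asarray(z, dtype=float)
    submerged = z <= fluid_level
    w = np.where(submerged, (rho_solid - rho_w) * g_const, rho_solid * g_const)
    return float(w) if w.ndim == 0 else w


# --------------------------------------------------------------------------
# element-level response
# --------------------------------------------------------------------------

def _axisym_partials(lam_a, lam_l, p: OgdenParams):
    """Nominal stress partials for stretches ``(lam_a, lam_l, lam_l)``.

    Returns ``(S_dev_a, S_vol_a, S_tot_l, J)`` with
    ``S_x = dU/dlam_x`` split into isochoric/volumetric parts for the
    axial direction and summed for the lateral one.
    """
    J = lam_a * lam_l**2
    Jm13 = J ** (-1.0 / 3.0)
    A = (Jm13 * lam_a) ** p.alpha
    L = (Jm13 * lam_l) ** p.alpha
    mean = (A + 2.0 * L) / 3.0
    c = 2.0 * p.mu0 / p.alpha
    S_dev_a = c * (A - mean) / lam_a
    S_dev_l = c * (L - mean) / lam_l
    if p.D == 0.0:
        S_vol_a = np.zeros_like(S_dev_a)
        S_vol_l = np.zeros_like(S_dev_l)
    else:
        fac = (2.0 / p.D) * (J - 1.0) * J
        S_vol_a = fac / lam_a
        S_vol_l = fac / lam_l
    return S_dev_a, S_vol_a, S_dev_l + S_vol_l, J


def _solve_lateral(lam_a, pbar, p: OgdenParams, guess):
    """Vectorized Newton for the lateral stretch in uniaxial-stress mode.

    Solves ``dU/dlam_l - pbar * lam_a * lam_l = 0`` (zero total lateral
    nominal traction) element-wise.
    """
    x = np.array(guess, dtype=float)
    scale = p.mu0 + np.abs(pbar) + 1.0

    def f(xl):
        _, _, S_l, _ = _axisym_partials(lam_a, xl, p)
        return S_l - pbar * lam_a * xl

    for _ in range(80):
        F = f(x)
        if np.max(np.abs(F)) < 1e-11 * np.max(scale):
            break
        d = 1e-7 * x
        dF = (f(x + d) - f(x - d)) / (2.0 * d)
        dF = np.where(np.abs(dF) < 1e-30, 1e-30, dF)
        dx = -F / dF
        dx = np.clip(dx, -0.2 * x, 0.2 * x)
        x = np.clip(x + dx, 0.05, 20.0)
    else:
        raise _NonConverged("lateral stretch iteration stalled")
    return x


class _NonConverged(RuntimeError):
    pass


# --------------------------------------------------------------------------
# the solver
# --------------------------------------------------------------------------

class _ColumnSolver:
    """Backward-Euler Newton solver; one instance carries all state."""

    newton_tol = 1e-8
    newton_maxit = 30
    max_bisections = 10

    def __init__(self, mesh: ColumnMesh, card: MaterialCard,
                 p_init: float = 0.0, rho_fluid: float = 1000.0,
                 g_const: float = STANDARD_GRAVITY):
        if card.has_fluid:
            if mesh.confinement not in ("oedometer", "uniaxial_stress"):
                raise ValueError("bad confinement")
        else:
            if mesh.confinement != "uniaxial_stress":
                raise ValueError(
                    "a card without fluid phase (incompressible solid) is "
                    "only meaningful in uniaxial_stress confinement"
                )
        self.mesh = mesh
        self.card = card
        self.poro = card.has_fluid
        self.g_const = g_const
        self.rho_fluid = card.fluid.rho_w if card.has_fluid else rho_fluid
        n = mesh.n_nodes
        self.h = np.diff(mesh.z)
        m = n - 1
        self.u = np.zeros(n)
        self.p = np.full(n, float(p_init)) if self.poro else np.zeros(n)
        nt = len(card.prony)
        self.g = np.array(card.prony.g, dtype=float)
        self.tau = np.array(card.prony.tau, dtype=float)
        self.g_inf = 1.0 - self.g.sum()
        self.hvisc = np.zeros((nt, m))
        self.S_dev = np.zeros(m)
        self.lam_l = np.ones(m)
        self.t = 0.0
        self.J_prev = np.ones(m)
        self.cum_outflow = 0.0
        self._w_prev = np.zeros(m)       # element body force at last phase end
        self._q_prev = 0.0               # surface load at last phase end

    # ---- element response ------------------------------------------------

    def _elements(self, u, p, dt, hv_prev, S_prev, lam_l_guess):
        """Element stress/volume response for a trial nodal state."""
        lam = 1.0 + np.diff(u) / self.h
        if np.any(lam < 0.05) or np.any(lam > 20.0):
            raise _NonConverged("element inverted or over-stretched")
        og = self.card.ogden
        if self.mesh.confinement == "oedometer":
            lam_l = np.ones_like(lam)
            S_dev, S_vol, _, J = _axisym_partials(lam, lam_l, og)
        elif og.D == 0.0:
            # incompressible uniaxial stress: lateral condition eliminated
            lam_l = lam ** -0.5
            S_dev = 2.0 * og.mu0 / og.alpha * (
                lam ** (og.alpha - 1.0) - lam ** (-og.alpha / 2.0 - 1.0))
            S_vol = np.zeros_like(S_dev)
            J = np.ones_like(lam)
        else:
            pbar = 0.5 * (p[:-1] + p[1:])
            lam_l = _solve_lateral(lam, pbar, og, lam_l_guess)
            S_dev, S_vol, _, J = _axisym_partials(lam, lam_l, og)
        # quasi-linear viscoelastic update on the deviatoric stress
        if len(self.tau):
            e = np.exp(-dt / self.tau)
            hv = e[:, None] * hv_prev + \
                ((self.tau / dt) * (1.0 - e))[:, None] * (S_dev - S_prev)[None, :]
            S_ve = self.g_inf * S_dev + np.einsum("i,ij->j", self.g, hv)
        else:
            hv = hv_prev
            S_ve = self.g_inf * S_dev + 0.0
        P_eff = S_ve + S_vol
        pbar = 0.5 * (p[:-1] + p[1:]) if self.poro else np.zeros_like(lam)
        P_tot = P_eff - pbar * lam_l**2
        return P_tot, J, S_dev, lam_l, hv

    # ---- residual --------------------------------------------------------

    def _residual(self, u, p, dt, w_elem, t_z, drained):
        P, J, S_dev, lam_l, hv = self._elements(
            u, p, dt, self.hvisc, self.S_dev, self.lam_l)
        n = self.mesh.n_nodes
        F_int = np.zeros(n)
        F_int[:-1] -= P
        F_int[1:] += P
        F_ext = np.zeros(n)
        b = -w_elem * self.h / 2.0
        F_ext[:-1] += b
        F_ext[1:] += b
        F_ext[-1] += t_z
        R_u = F_int - F_ext
        ref_u = max(np.max(np.abs(P)), np.max(np.abs(b)), abs(t_z),
                    1e-9 * self.card.ogden.mu0)
        tol_u = self.newton_tol * ref_u + 1e3 * np.finfo(float).eps * ref_u
        if not self.poro:
            return R_u, None, None, J, S_dev, lam_l, hv, tol_u, np.inf
        c = self.card.fluid.k / self.card.fluid.gamma_w
        stor = (J - self.J_prev) / dt * self.h / 2.0
        R_p = np.zeros(n)
        R_p[:-1] += stor
        R_p[1:] += stor
        dp = np.diff(p)
        flux = c * dp / self.h
        R_p[:-1] -= flux
        R_p[1:] += flux
        # the storage term (J - J_prev)/dt cannot be evaluated below the
        # roundoff of J ~ O(1); that floor enters the threshold additively
        eps_floor = 1e3 * np.finfo(float).eps * np.max(self.h) / (2.0 * dt) \
            * max(np.max(np.abs(J)), 1.0)
        ref_p = max(np.max(np.abs(stor)) if len(stor) else 0.0,
                    np.max(np.abs(flux)) if len(flux) else 0.0,
                    c / np.mean(self.h) * 1e-6, 1e-30)
        tol_p = self.newton_tol * ref_p + eps_floor
        reaction = R_p[drained].sum() if len(drained) else 0.0
        return R_u, R_p, reaction, J, S_dev, lam_l, hv, tol_u, tol_p

    # ---- one implicit step ----------------------------------------------

    def _newton(self, dt, w_elem, t_z, drained):
        n = self.mesh.n_nodes
        m = n - 1
        u = self.u.copy()
        p = self.p.copy()
        if len(drained):
            p[drained] = 0.0
        ndof = 2 * n if self.poro else n
        for it in range(self.newton_maxit):
            (R_u, R_p, reaction, J, S_dev, lam_l, hv,
             tol_u, tol_p) = self._residual(u, p, dt, w_elem, t_z, drained)
            conv_u = np.max(np.abs(R_u[1:])) <= tol_u
            if self.poro:
                free_p = np.setdiff1d(np.arange(n), drained)
                conv_p = (len(free_p) == 0 or
                          np.max(np.abs(R_p[free_p])) <= tol_p)
            else:
                conv_p = True
            if conv_u and conv_p and it > 0:
                return u, p, J, S_dev, lam_l, hv, reaction
            # --- element tangents by central differences -----------------
            lam = 1.0 + np.diff(u) / self.h
            dl = 1e-7
            Pp, Jp = self._elem_PJ_lam(lam + dl, p, dt)
            Pm, Jm = self._elem_PJ_lam(lam - dl, p, dt)
            dP_dlam = (Pp - Pm) / (2.0 * dl)
            dJ_dlam = (Jp - Jm) / (2.0 * dl)
            if self.poro:
                dpp = max(1e-6 * self.card.ogden.mu0, 1e-3)
                Pp2, Jp2 = self._elem_PJ_lam(lam, p, dt, dpbar=dpp)
                Pm2, Jm2 = self._elem_PJ_lam(lam, p, dt, dpbar=-dpp)
                dP_dp = (Pp2 - Pm2) / (2.0 * dpp)
                dJ_dp = (Jp2 - Jm2) / (2.0 * dpp)
            # --- assemble dense Jacobian ---------------------------------
            A = np.zeros((ndof, ndof))
            R = np.zeros(ndof)
            R[:n] = R_u
            ku = dP_dlam / self.h
            a = np.arange(m)
            A[a, a] += ku
            A[a, a + 1] -= ku
            A[a + 1, a] -= ku
            A[a + 1, a + 1] += ku
            if self.poro:
                R[n:] = R_p
                # coupling of axial stress to nodal pressures
                # (row a carries -P_e, row a+1 carries +P_e)
                A[a, n + a] -= dP_dp / 2.0
                A[a, n + a + 1] -= dP_dp / 2.0
                A[a + 1, n + a] += dP_dp / 2.0
                A[a + 1, n + a + 1] += dP_dp / 2.0
                # storage wrt u
                s_u = dJ_dlam / (2.0 * dt)
                A[n + a, a] -= s_u
                A[n + a, a + 1] += s_u
                A[n + a + 1, a] -= s_u
                A[n + a + 1, a + 1] += s_u
                # storage wrt p
                s_p = dJ_dp * self.h / (4.0 * dt)
                for (ra, ca) in ((a, a), (a, a + 1), (a + 1, a), (a + 1, a + 1)):
                    A[n + ra, n + ca] += s_p
                # Darcy stiffness
                c = self.card.fluid.k / self.card.fluid.gamma_w
                kp = c / self.h
                A[n + a, n + a] += kp
                A[n + a, n + a + 1] -= kp
                A[n + a + 1, n + a] -= kp
                A[n + a + 1, n + a + 1] += kp
                # Dirichlet pressure rows
                for i in drained:
                    A[n + i, :] = 0.0
                    A[n + i, n + i] = 1.0
                    R[n + i] = p[i]
            # fixed base
            A[0, :] = 0.0
            A[0, 0] = 1.0
            R[0] = u[0]
            try:
                dx = np.linalg.solve(A, -R)
            except np.linalg.LinAlgError as exc:
                raise _NonConverged(str(exc)) from exc
            u = u + dx[:n]
            if self.poro:
                p = p + dx[n:]
        raise _NonConverged(f"Newton stalled after {self.newton_maxit} iterations")

    def _elem_PJ_lam(self, lam, p, dt, dpbar: float = 0.0):
        """Element response for perturbed stretches / pressures."""
        og = self.card.ogden
        if np.any(lam < 0.04):
            raise _NonConverged("element inverted during tangent evaluation")
        if self.mesh.confinement == "oedometer":
            lam_l = np.ones_like(lam)
            S_dev, S_vol, _, J = _axisym_partials(lam, lam_l, og)
        elif og.D == 0.0:
            lam_l = lam ** -0.5
            S_dev = 2.0 * og.mu0 / og.alpha * (
                lam ** (og.alpha - 1.0) - lam ** (-og.alpha / 2.0 - 1.0))
            S_vol = np.zeros_like(S_dev)
            J = np.ones_like(lam)
        else:
            pbar = 0.5 * (p[:-1] + p[1:]) + dpbar
            lam_l = _solve_lateral(lam, pbar, og, self.lam_l)
            S_dev, S_vol, _, J = _axisym_partials(lam, lam_l, og)
        if len(self.tau):
            e = np.exp(-dt / self.tau)
            hv = e[:, None] * self.hvisc + \
                ((self.tau / dt) * (1.0 - e))[:, None] * (S_dev - self.S_dev)[None, :]
            S_ve = self.g_inf * S_dev + np.einsum("i,ij->j", self.g, hv)
        else:
            S_ve = self.g_inf * S_dev + 0.0
        P_eff = S_ve + S_vol
        pbar = (0.5 * (p[:-1] + p[1:]) + dpbar) if self.poro else np.zeros_like(lam)
        P_tot = P_eff - pbar * lam_l**2
        return P_tot, J

    def _advance(self, dt, w_elem, t_z, drained, depth: int = 0):
        try:
            u, p, J, S_dev, lam_l, hv, reaction = self._newton(
                dt, w_elem, t_z, drained)
        except _NonConverged:
            if depth >= self.max_bisections:
                raise RuntimeError(
                    f"consolidation step failed after {depth} bisections "
                    f"(t = {self.t:.4g} s, dt = {dt:.3g} s)"
                )
            self._advance(dt / 2.0, w_elem, t_z, drained, depth + 1)
            self._advance(dt / 2.0, w_elem, t_z, drained, depth + 1)
            return
        if self.poro:
            self.cum_outflow += -reaction * dt
        self.u, self.p = u, p
        self.J_prev = J
        self.S_dev = S_dev
        self.lam_l = lam_l
        self.hvisc = hv
        self.t += dt

    # ---- phase driver ----------------------------------------------------

    def run_phase(self, phase: Phase, record: list) -> None:
        n_steps = max(1, int(round(phase.duration / phase.dt)))
        dt = phase.duration / n_steps
        drained = phase.bc.drained_index(self.mesh)
        # body force uses current-configuration element midpoints,
        # evaluated once per phase (explicit emergence)
        z_cur = self.mesh.z + self.u
        z_mid = 0.5 * (z_cur[:-1] + z_cur[1:])
        w_target = phase.gravity * buoyant_body_force(
            z_mid, phase.fluid_level, self.card.rho_solid, self.rho_fluid,
            self.g_const)
        w_target = np.broadcast_to(np.asarray(w_target, dtype=float),
                                   z_mid.shape).copy()
        q_target = phase.surface_load
        for i in range(n_steps):
            if phase.ramp:
                f = (i + 1) / n_steps
                w = self._w_prev + f * (w_target - self._w_prev)
                q = self._q_prev + f * (q_target - self._q_prev)
            else:
                w, q = w_target, q_target
            self._advance(dt, w, q, drained)
            record.append(self.snapshot())
        self._w_prev = w_target
        self._q_prev = q_target

    def snapshot(self) -> ColumnState:
        return ColumnState(
            t=self.t,
            u=self.u.copy(),
            p=self.p.copy(),
            internal={
                "hvisc": self.hvisc.copy(),
                "S_dev": self.S_dev.copy(),
                "lam_l": self.lam_l.copy(),
                "J": self.J_prev.copy(),
            },
        )

    @property
    def volume_change(self) -> float:
        return float(np.sum((self.J_prev - 1.0) * self.h))


def solve_consolidation(
    mesh: ColumnMesh,
    card: MaterialCard,
    phases: Sequence[Phase],
    *,
    p_init: float = 0.0,
    rho_fluid: float = 1000.0,
    g_const: float = STANDARD_GRAVITY,
    solver: _ColumnSolver | None = None,
) -> ConsolidationResult:
    """Run the column through a schedule of loading/drainage phases.

    Parameters
    ----------
    mesh : ColumnMesh
    card : MaterialCard
        ``PHVE``/``PHE`` cards carry a pressure field; an ``HVE`` card is
        solved as a monophasic (visco)elastic column.
    phases : sequence of Phase
        Executed in order; loads may ramp linearly from the previous
        phase (``ramp=True``).
    p_init : float
        Initial uniform excess pore pressure, Pa (undrained
        initialization for the Terzaghi benchmark).
    rho_fluid : float
        External fluid density for buoyancy when the card has no fluid
        phase (HVE); biphasic cards use their own ``rho_w``.

    Returns
    -------
    ConsolidationResult
        Sequence of per-step :class:`ColumnState` snapshots, plus the
        cumulative drained outflow and skeleton volume change for
        conservation checks.
    """
    s = solver or _ColumnSolver(mesh, card, p_init=p_init,
                                rho_fluid=rho_fluid, g_const=g_const)
    record: list = [s.snapshot()]
    for phase in phases:
        s.run_phase(phase, record)
    return ConsolidationResult(
        mesh=mesh,
        states=record,
        cumulative_outflow=s.cum_outflow,
        volume_change=s.volume_change,
    )


# --------------------------------------------------------------------------
# linear-theory oracles and helpers
# --------------------------------------------------------------------------

def constrained_modulus(ogden: OgdenParams) -> float:
    """Small-strain constrained (oedometric) modulus of the skeleton, Pa.

    Evaluated as the numerical derivative of the confined axial stress at
    the reference state; equals ``K + 4 mu0 / 3`` in the linear limit.
    """
    d = 1e-7
    lam = np.array([1.0 - d, 1.0 + d])
    one = np.ones(2)
    S_dev, S_vol, _, _ = _axisym_partials(lam, one, ogden)
    S = S_dev + S_vol
    return float((S[1] - S[0]) / (2.0 * d))


def consolidation_coefficient(card: MaterialCard) -> float:
    """Terzaghi coefficient ``c_v = k M / gamma_w``, m^2/s (oedometer)."""
    if not card.has_fluid:
        raise ValueError("consolidation coefficient requires a fluid phase")
    M = constrained_modulus(card.ogden)
    return card.fluid.k * M / card.fluid.gamma_w


def terzaghi_pressure(z, t, c_v: float, H: float, p0: float,
                      tol: float = 1e-12):
    """Closed-form excess pore pressure in single-drained consolidation.

    Column of height ``H`` drained at the top (``z = H``), impermeable at
    the base, uniform initial excess pressure ``p0``:

    ``p(z, t) = sum_n  4 p0 (-1)^n / ((2n+1) pi) * cos(k_n z) *
    exp(-c_v k_n^2 t)`` with ``k_n = (2n+1) pi / (2H)``.  The series is
    truncated once the term bound drops below ``tol * p0``.
    """
    if c_v <= 0 or H <= 0:
        raise ValueError("c_v and H must be positive")
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > H * (1 + 1e-12)):
        raise ValueError("z must lie in [0, H]")
    if t < 0:
        raise ValueError("t must be non-negative")
    if t == 0.0:
        out = np.where(z < H, p0, 0.0)
        return float(out) if out.ndim == 0 else out
    out = np.zeros_like(z, dtype=float)
    n = 0
    while True:
        kn = (2 * n + 1) * np.pi / (2.0 * H)
        amp = 4.0 * p0 * (-1.0) ** n / ((2 * n + 1) * np.pi)
        decay = np.exp(-c_v * kn**2 * t)
        if abs(amp) * decay < tol * abs(p0) and n > 0:
            break
        out = out + amp * np.cos(kn * z) * decay
        n += 1
        if n > 200000:  # pragma: no cover - safety stop
            break
    return float(out) if out.ndim == 0 else out
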