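"""Validate the coupled column solver against Terzaghi consolidation.

A laterally confined (oedometer) gel column is loaded with a small
surface stress under undrained initial conditions, then drained through
its top face.  In this linear limit the excess pore pressure obeys the
classical diffusion solution with c_v = k M / gamma_w, where M is the
constrained modulus of the linearized Ogden skeleton.
"""

import numpy as np

from brainshift import poro_solver as ps
from brainshift.constitutive import (
    D_from_nu,
    FluidPhase,
    MaterialCard,
    OgdenParams,
    PronySeries,
)

# gel skeleton; permeability raised so consolidation finishes in minutes
# of simulated time instead of months (k as published: 1.57e-9 m/s)
card = MaterialCard(
    name="PHE",
    ogden=OgdenParams(mu0=794.36, alpha=-2.8, D=D_from_nu(794.36, 0.35)),
    prony=PronySeries(),
    fluid=FluidPhase(k=1e-6, gamma_w=9779.0),
)
M = ps.constrained_modulus(card.ogden)
c_v = ps.consolidation_coefficient(card)
print(f"constrained modulus M = {M:.0f} Pa, c_v = {c_v:.3e} m^2/s")

H, n, q = 0.02, 100, 0.5
mesh = ps.ColumnMesh.uniform(n, H, confinement="oedometer")
t_char = H**2 / c_v
phase = ps.Phase(duration=0.5 * t_char, dt=0.5 * t_char / 500,
                 bc=ps.DrainageBC(drained_nodes=(n - 1,)),
                 surface_load=-q, gravity=0.0)
res = ps.solve_consolidation(mesh, card, [phase], p_init=q)

print(f"column: {n} nodes, H = {H * 100:.0f} cm, load {q} Pa, "
      f"characteristic time {t_char:.0f} s")
print("T (dimensionless)   max |p_num - p_Terzaghi| / p0")
for T in (0.05, 0.1, 0.2, 0.5):
    t = T * t_char
    st = min(res.states, key=lambda s: abs(s.t - t))
    ana = ps.terzaghi_pressure(mesh.z, st.t, c_v, H, q)
    print(f"   {T:4.2f}                 {np.max(np.abs(st.p - ana)) / q:.5f}")

print(f"final settlement {res.final.u[-1] * 1e6:.2f} um; fully drained "
      f"elastic value -qH/M = {-q * H / M * 1e6:.2f} um")
print(f"expelled fluid volume {res.cumulative_outflow * 1e6:.3f} um "
      f"(per unit area) vs column volume change "
      f"{-res.volume_change * 1e6:.3f} um")
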