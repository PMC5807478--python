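"""Characterize the hydrogel from a simulated compression-relaxation test.

Reproduces the bench protocol: a 12 mm x 7 mm gel cylinder is compressed
at 8.3 mm/s to 30% of its height (0.356 true strain) and held for 500 s.
The Ogden pair (mu0, alpha) is fitted on the loading ramp and a two-term
Prony series on the normalized relaxation curve, then the fitted card is
written to a plain-text config file.
"""

import tempfile
from pathlib import Path

from brainshift import characterization as ch
from brainshift import io as bio
from brainshift.constitutive import (
    D_from_nu,
    FluidPhase,
    MaterialCard,
    OgdenParams,
    table_card,
)

card = table_card("PHVE")
proto = ch.CompressionProtocol()
print(f"ramp: {proto.ramp_speed * 1e3:.1f} mm/s for "
      f"{proto.ramp_duration:.3f} s -> "
      f"{ch.true_strain_from_compression(proto.target_compression):.3f} "
      f"true strain, then {proto.hold_duration:.0f} s hold")

curve = ch.simulate_compression_test(card, proto)
print(f"peak nominal stress: {curve.stress.min():.1f} Pa "
      f"({curve.force.max() * 1e3:.2f} mN on the load cell)")

ogden = ch.fit_ogden(curve)
prony = ch.fit_prony(curve, n_terms=2)
print(f"fitted mu0   = {ogden.mu0:.2f} Pa    (generating card: 794.36)")
print(f"fitted alpha = {ogden.alpha:.3f}      (generating card: -2.8)")
print(f"fitted Prony g   = {tuple(round(g, 3) for g in prony.series.g)}")
print(f"fitted Prony tau = {tuple(round(t, 1) for t in prony.series.tau)} s")
print(f"long-term modulus fraction 1 - sum(g) = "
      f"{prony.series.long_term_fraction:.3f} (0.55 for the gel)")

# assemble a full biphasic card from the fit and the literature fluid
# phase, and round-trip it through the plain-text format
fitted = MaterialCard(
    name="PHVE",
    ogden=OgdenParams(mu0=ogden.mu0, alpha=ogden.alpha,
                      D=D_from_nu(ogden.mu0, 0.35)),
    prony=prony.series,
    fluid=FluidPhase(k=1.57e-9, gamma_w=9779.0, e0=0.2),
)
out = Path(tempfile.gettempdir()) / "fitted_phve.cfg"
bio.write_material_card(fitted, out)
print(f"material card written to {out}; re-reads identically: "
      f"{bio.read_material_card(out) == fitted}")
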