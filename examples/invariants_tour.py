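"""Scattering invariants of two particles of equal mass but different shape.

Builds a noise-free solid sphere and a 4:1 prolate ellipsoid of the same
66 kDa mass, then prints the quantities every mass estimator is built from:
the Guinier parameters (Rg, I(0)), the Porod volume V_p, the volume of
correlation V_c with its correlation length l_c, and the dimensionless
apparent-volume triplet V'(3, 4, 5) that encodes shape independently of
size.
"""

import numpy as np

from saxsmm import auto_guinier, compute_invariants, ideal_profile, particle_from_mm

MM_KDA = 66.0

for shape in ("compact", "extended"):
    spec = particle_from_mm(shape, MM_KDA)
    profile = ideal_profile(spec)
    g = auto_guinier(profile)
    inv = compute_invariants(profile, g)
    print(f"\n{shape} particle, true mass {MM_KDA} kDa, "
          f"true volume {spec.volume:,.0f} A^3")
    print(f"  Rg        {g.rg:8.2f} A      (Guinier fit, window quality {g.quality:.4f})")
    print(f"  V_p       {inv.vp:10,.0f} A^3  (Porod volume; mass ~ V_p/1.37 = "
          f"{inv.vp / 1.37 / 1000:.1f} kDa)")
    print(f"  V_c       {inv.vc:8.1f} A^2    l_c {inv.lc:6.1f} A")
    print(f"  V'(3,4,5) {inv.vprime_3:6.2f} {inv.vprime_4:6.2f} {inv.vprime_5:6.2f}"
          "   (shape fingerprint, size-independent)")

print(
    "\nThe sphere's V_p matches its true volume closely; the elongated particle"
    "\nof the same mass has a larger Rg and a different V' triplet — that shape"
    "\nsignature is what the nearest-neighbour mass estimator exploits."
)
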