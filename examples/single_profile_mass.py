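"""Consensus molecular mass of one SAXS profile, end to end.

Trains the pipeline on a small synthetic corpus (database-mirroring class
weights, 1000 particles), then estimates the mass of a held-out 66 kDa globular
particle at moderate noise (SNR = 4): the four individual estimates, the
Bayesian MAP mass with its probability score, and the 90% credibility
interval.  Takes about half a minute.
"""

import numpy as np

from saxsmm import (
    MMPipeline,
    NoiseSpec,
    add_noise,
    build_corpus,
    ideal_profile,
    particle_from_mm,
    records_from_corpus,
)

print("training on a small synthetic corpus ...")
train, _ = build_corpus(n_per_class=50, split=0.7, seed=11)
rng = np.random.default_rng(42)
bin_masses = np.exp(rng.uniform(np.log(7.0), np.log(300.0), 2000))
pipe = MMPipeline().fit(records_from_corpus(train), bin_masses=bin_masses)

spec = particle_from_mm("compact", 66.0)
profile = add_noise(ideal_profile(spec), NoiseSpec(target_snr=4.0, seed=7))

evidence = pipe.evidence(profile)
result = pipe.predict(profile)

print(f"\ntrue mass: {spec.mm:.1f} kDa (globular particle, SNR = 4)")
for name, key in (("MM_Qp", "mm_qp"), ("MoW", "mm_mow"),
                  ("V_c", "mm_vc"), ("Size&Shape", "mm_ss")):
    value = getattr(evidence, key)
    shown = f"{value:8.1f} kDa" if np.isfinite(value) else "   absent"
    print(f"  {name:<11} {shown}")
print(f"  {'Bayesian':<11} {result.map_mm:8.1f} kDa  "
      f"(P = {result.map_probability:.3f}, "
      f"90% interval {result.ci_low:.1f} - {result.ci_high:.1f} kDa)")
print(
    "\nThe consensus estimate combines the four methods through their learned"
    "\nerror distributions; the interval width reflects how much they agree."
)
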