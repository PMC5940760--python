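"""Prior forwarding across a series of noisy exposures (SEC-SAXS style).

Simulates five successive frames of the same 40 kDa ring-shaped particle at
the worst noise level (SNR = 1) and compares two analyses: each frame on
its own (uniform prior) versus forwarding each frame's posterior as the
next frame's prior.  Accumulating evidence across frames stabilizes the
estimate and narrows the credibility interval.  Takes about half a minute.
"""

import numpy as np

from saxsmm import (
    MMPipeline,
    NoiseSpec,
    add_noise,
    build_corpus,
    forward_prior,
    ideal_profile,
    particle_from_mm,
    records_from_corpus,
)

print("training on a small synthetic corpus ...")
train, _ = build_corpus(n_per_class=50, split=0.7, seed=11)
rng = np.random.default_rng(42)
bin_masses = np.exp(rng.uniform(np.log(7.0), np.log(300.0), 2000))
pipe = MMPipeline().fit(records_from_corpus(train), bin_masses=bin_masses)

spec = particle_from_mm("ring", 40.0)
ideal = ideal_profile(spec)

print(f"\ntrue mass {spec.mm:.1f} kDa (ring-shaped), five frames at SNR = 1:")
print(f"{'frame':>5}{'single MAP':>12}{'width':>8}{'forwarded MAP':>15}{'width':>8}")
prior = None
for frame in range(5):
    noisy = add_noise(ideal, NoiseSpec(target_snr=1.0, seed=100 + frame))
    single = pipe.predict(noisy)
    chained = pipe.predict(noisy, prior=prior)
    prior = forward_prior(chained)
    print(f"{frame + 1:>5}{single.map_mm:>12.1f}{single.ci_high - single.ci_low:>8.1f}"
          f"{chained.map_mm:>15.1f}{chained.ci_high - chained.ci_low:>8.1f}")

print(
    "\nEach frame alone gives a wobbly estimate with a wide 90% interval;"
    "\nforwarding the posterior pins the mass down after the second frame."
)
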