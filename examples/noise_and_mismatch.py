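"""How each estimator responds to counting noise and buffer mismatch.

Takes one 50 kDa globular particle and re-estimates its mass (i) at the
five simulated noise levels and (ii) with the profile over- and
under-subtracted by 40% of its mean high-angle intensity.  Uses a quickly
trained pipeline; prints one row per condition.  Takes about half a minute.
"""

import numpy as np

from saxsmm import (
    MMPipeline,
    NoiseSpec,
    add_noise,
    build_corpus,
    ideal_profile,
    mismatch,
    particle_from_mm,
    records_from_corpus,
)
from saxsmm.synthetic import TEST_SNRS

print("training on a small synthetic corpus ...")
train, _ = build_corpus(n_per_class=50, split=0.7, seed=11)
rng = np.random.default_rng(42)
bin_masses = np.exp(rng.uniform(np.log(7.0), np.log(300.0), 2000))
pipe = MMPipeline().fit(records_from_corpus(train), bin_masses=bin_masses)

spec = particle_from_mm("compact", 50.0)
ideal = ideal_profile(spec)

conditions = [("ideal", ideal)]
for snr in TEST_SNRS:
    conditions.append((f"SNR {snr:g}", add_noise(ideal, NoiseSpec(snr, seed=int(snr)))))
snr4 = add_noise(ideal, NoiseSpec(4.0, seed=4))
conditions.append(("over-subtracted 0.4", mismatch(snr4, 0.4, "over")))
conditions.append(("under-subtracted 0.4", mismatch(snr4, 0.4, "under")))

print(f"\ntrue mass {spec.mm:.1f} kDa; estimates in kDa:")
print(f"{'condition':<22}{'MM_Qp':>8}{'MoW':>8}{'V_c':>8}{'S&S':>8}{'Bayes':>8}")
for label, profile in conditions:
    ev = pipe.evidence(profile)
    res = pipe.predict(profile)
    cells = "".join(
        f"{getattr(ev, m):8.1f}" if np.isfinite(getattr(ev, m)) else f"{'--':>8}"
        for m in ("mm_qp", "mm_mow", "mm_vc", "mm_ss")
    )
    print(f"{label:<22}{cells}{res.map_mm:8.1f}")

print(
    "\nMM_Qp sits low on clean data (its fixed volume-to-mass divisor assumes"
    "\nhydrated reference volumes) yet the consensus corrects for that learned"
    "\nbias; the individual estimates drift with noise while the Bayesian"
    "\ncombination stays close to the truth."
)
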