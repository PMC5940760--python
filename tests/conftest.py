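"""Shared fixtures: analytic reference profiles and a small trained pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from saxsmm.estimators import PROTEIN_DENSITY
from saxsmm.pipeline import MMPipeline, records_from_corpus
from saxsmm.synthetic import SHAPE_CLASSES, build_corpus, ideal_profile, particle_from_mm

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

SPHERE_RADIUS = 30.0
SPHERE_RG = np.sqrt(3.0 / 5.0) * SPHERE_RADIUS  # 23.238 A
SPHERE_VOLUME = 4.0 / 3.0 * np.pi * SPHERE_RADIUS**3  # 113 097 A^3

UNIFORM_WEIGHTS = {c: 1.0 for c in SHAPE_CLASSES}


def sphere_spec(radius: float):
    """ParticleSpec of a solid sphere of the given radius."""
    mm = PROTEIN_DENSITY * 4.0 / 3.0 * np.pi * radius**3 / 1000.0
    return particle_from_mm("compact", mm)


@pytest.fixture(scope="session")
def sphere_profile():
    """Noise-free solid sphere, R = 30 A, on the standard 1001-point grid."""
    return ideal_profile(sphere_spec(SPHERE_RADIUS))


@pytest.fixture(scope="session")
def mini_corpus():
    """Small uniform-weight corpus for integration tests (50 particles/class)."""
    return build_corpus(n_per_class=50, split=0.7, seed=11, class_weights=UNIFORM_WEIGHTS)


@pytest.fixture(scope="session")
def mini_pipeline(mini_corpus):
    """Pipeline trained on the mini corpus (bins from an auxiliary mass sample)."""
    train, _ = mini_corpus
    rng = np.random.default_rng(42)
    bin_masses = np.exp(rng.uniform(np.log(7.0), np.log(300.0), 2000))
    return MMPipeline().fit(records_from_corpus(train), bin_masses=bin_masses)
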