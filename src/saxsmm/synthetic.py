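"""Synthetic scattering profiles with known mass and shape class.

This is the training/validation corpus generator: in place of spherical-
harmonics scattering from atomic coordinates it uses analytic, orientationally
averaged form factors for seven shape classes (the classes a shape classifier
distinguishes for proteins):

* ``compact``        — solid sphere
* ``extended``       — prolate ellipsoid of revolution
* ``flat``           — oblate ellipsoid of revolution
* ``ring``           — torus (circular cross-section)
* ``compact-hollow`` — concentric two-density shell, half-density core
* ``hollow-sphere``  — spherical shell (empty core)
* ``random-chain``   — Gaussian chain (Debye function)

Solid-shape masses follow ``MM = 0.83 Da/A^3 x (density-weighted) volume``;
chain masses are set directly and mapped to a radius of gyration through a
Flory-type law calibrated for disordered proteins (Rg = 2.54 N^0.522 A with
N = MM/110 Da residues), so chain sizes overlap the solid-shape range.

Corruption models reproduce experimental conditions: Gaussian counting-like
noise with a high-angle noise floor at target median-SNR levels
(32, 11, 4, 2, 1) and constant-offset buffer over/under-subtraction at
fractions of the mean high-angle intensity (0.1, 0.2, 0.4, 0.6, 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .exceptions import SaxsmmError
from .estimators import PROTEIN_DENSITY
from .profile_io import ScatteringProfile

__all__ = [
    "SHAPE_CLASSES",
    "TRAIN_SNRS",
    "TEST_SNRS",
    "MISMATCH_FRACTIONS",
    "ParticleSpec",
    "NoiseSpec",
    "CorpusEntry",
    "particle_from_mm",
    "analytic_rg",
    "ideal_profile",
    "add_noise",
    "mismatch",
    "build_corpus",
]

SHAPE_CLASSES = (
    "compact",
    "extended",
    "flat",
    "ring",
    "compact-hollow",
    "hollow-sphere",
    "random-chain",
)

#: Noise levels used for training (the highest noise level is omitted).
TRAIN_SNRS = (32.0, 11.0, 4.0, 2.0)
#: Noise levels in the test conditions.
TEST_SNRS = (32.0, 11.0, 4.0, 2.0, 1.0)
#: Buffer-mismatch offsets as fractions of the mean intensity over 0.4-0.6 1/A.
MISMATCH_FRACTIONS = (0.1, 0.2, 0.4, 0.6, 0.9)

#: Flory law for disordered chains: Rg [A] = RG_CHAIN_PREF * N^RG_CHAIN_EXP.
RG_CHAIN_PREF = 2.54
RG_CHAIN_EXP = 0.522
#: Average residue mass, Da.
RESIDUE_MASS_DA = 110.0

#: Relative density of the compact-hollow core (hollow-sphere core is empty).
COMPACT_HOLLOW_CORE_DENSITY = 0.5

#: Default per-class sampling weights, mirroring the composition of protein
#: structure databases: compact globular folds dominate, moderately
#: anisotropic particles and disordered chains are minorities, rings and
#: hollow shells are rare.  Multiplied by ``n_per_class`` in build_corpus.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "compact": 12.0,
    "extended": 2.0,
    "flat": 2.0,
    "ring": 1.0,
    "compact-hollow": 1.0,
    "hollow-sphere": 1.0,
    "random-chain": 1.0,
}


@dataclass(frozen=True)
class ParticleSpec:
    """Geometry, volume and mass of one synthetic particle.

    ``geometry`` holds shape-specific lengths in Angstrom; ``volume`` is the
    density-weighted protein volume in A^3 (NaN for chains, which have no
    meaningful uniform-density volume); ``mm`` is the true mass in kDa.
    """

    shape_class: str
    geometry: dict[str, float]
    volume: float
    mm: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise SaxsmmError(f"unknown shape class {self.shape_class!r}")
        if not self.mm > 0:
            raise SaxsmmError("particle mass must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Target median signal-to-noise ratio and the random seed realizing it."""

    target_snr: float
    seed: int

    def __post_init__(self) -> None:
        if not self.target_snr > 0:
            raise SaxsmmError("target SNR must be > 0")


@dataclass(frozen=True)
class CorpusEntry:
    """One corpus profile with its ground truth and generation condition."""

    profile: ScatteringProfile
    mm: float
    shape_class: str
    condition: str  # "ideal", "snr32", ..., "over0.4", "under0.9"
    particle_id: str
    snr: float | None = None
    mismatch_fraction: float | None = None
    mismatch_direction: str | None = None


# ---------------------------------------------------------------------------
# particle construction


def _solid_volume(mm_kda: float) -> float:
    return mm_kda * 1000.0 / PROTEIN_DENSITY


def particle_from_mm(
    shape_class: str,
    mm_kda: float,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> ParticleSpec:
    """Construct a particle of the requested class and mass.

    Free aspect parameters (ellipsoid axial ratios, torus tube ratio, shell
    cavity ratio) are drawn from realistic ranges using ``rng``; without an
    rng, mid-range defaults are used.
    """
    u = (lambda lo, hi: float(rng.uniform(lo, hi))) if rng is not None else (
        lambda lo, hi: 0.5 * (lo + hi)
    )
    if shape_class == "random-chain":
        n_res = mm_kda * 1000.0 / RESIDUE_MASS_DA
        rg = RG_CHAIN_PREF * n_res**RG_CHAIN_EXP
        return ParticleSpec(shape_class, {"rg": rg}, float("nan"), mm_kda, label)

    v = _solid_volume(mm_kda)
    if shape_class == "compact":
        r = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
        return ParticleSpec(shape_class, {"radius": r}, v, mm_kda, label)
    if shape_class == "extended":
        ratio = u(3.0, 6.0)  # c/a > 1: prolate
        a = (3.0 * v / (4.0 * np.pi * ratio)) ** (1.0 / 3.0)
        return ParticleSpec(shape_class, {"a": a, "c": a * ratio}, v, mm_kda, label)
    if shape_class == "flat":
        ratio = u(3.0, 6.0)  # a/c > 1: oblate
        a = (3.0 * v * ratio / (4.0 * np.pi)) ** (1.0 / 3.0)
        return ParticleSpec(shape_class, {"a": a, "c": a / ratio}, v, mm_kda, label)
    if shape_class == "ring":
        ratio = u(0.15, 0.35)  # tube radius / ring radius
        big_r = (v / (2.0 * np.pi**2 * ratio**2)) ** (1.0 / 3.0)
        return ParticleSpec(
            shape_class, {"ring_radius": big_r, "tube_radius": big_r * ratio}, v, mm_kda, label
        )
    if shape_class in ("compact-hollow", "hollow-sphere"):
        if shape_class == "compact-hollow":
            ratio, rho_core = u(0.40, 0.60), COMPACT_HOLLOW_CORE_DENSITY
        else:
            ratio, rho_core = u(0.65, 0.85), 0.0
        # density-weighted volume: rho_core*V1 + (V2 - V1) = v
        # with V1 = (4/3) pi (ratio*r2)^3, V2 = (4/3) pi r2^3
        geom_factor = 1.0 - (1.0 - rho_core) * ratio**3
        r2 = (3.0 * v / (4.0 * np.pi * geom_factor)) ** (1.0 / 3.0)
        return ParticleSpec(
            shape_class,
            {"r_inner": r2 * ratio, "r_outer": r2, "core_density": rho_core},
            v,
            mm_kda,
            label,
        )
    raise SaxsmmError(f"unsupported geometry for shape class {shape_class!r}")


def analytic_rg(spec: ParticleSpec) -> float:
    """Closed-form radius of gyration of a particle spec, Angstrom."""
    g = spec.geometry
    if spec.shape_class == "compact":
        return float(np.sqrt(3.0 / 5.0) * g["radius"])
    if spec.shape_class in ("extended", "flat"):
        return float(np.sqrt((2.0 * g["a"] ** 2 + g["c"] ** 2) / 5.0))
    if spec.shape_class == "ring":
        # second moment of a uniform torus: Rg^2 = R^2 + a^2
        return float(np.sqrt(g["ring_radius"] ** 2 + g["tube_radius"] ** 2))
    if spec.shape_class in ("compact-hollow", "hollow-sphere"):
        r1, r2, rho = g["r_inner"], g["r_outer"], g["core_density"]
        num = rho * r1**5 + (r2**5 - r1**5)
        den = rho * r1**3 + (r2**3 - r1**3)
        return float(np.sqrt(0.6 * num / den))
    if spec.shape_class == "random-chain":
        return float(g["rg"])
    raise SaxsmmError(f"no analytic Rg for {spec.shape_class!r}")


# ---------------------------------------------------------------------------
# form factors (orientationally averaged, I(0) normalized to 1)


def _sphere_amp(x: np.ndarray) -> np.ndarray:
    """Normalized sphere amplitude 3(sin x - x cos x)/x^3 with a stable x->0 limit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def _sphere_intensity(q: np.ndarray, radius: float) -> np.ndarray:
    return _sphere_amp(q * radius) ** 2


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(128)
_GL_U = 0.5 * (_GL_NODES + 1.0)  # nodes mapped to [0, 1]
_GL_W = 0.5 * _GL_WEIGHTS


def _ellipsoid_intensity(q: np.ndarray, a: float, c: float) -> np.ndarray:
    """Ellipsoid of revolution, semi-axes (a, a, c), averaged over orientations."""
    r_eff = np.sqrt(a * a * (1.0 - _GL_U**2) + c * c * _GL_U**2)  # (nodes,)
    amp2 = _sphere_amp(np.outer(q, r_eff)) ** 2  # (nq, nodes)
    return amp2 @ _GL_W


def _shell_intensity(
    q: np.ndarray, r_inner: float, r_outer: float, core_density: float
) -> np.ndarray:
    """Concentric two-density shell: core at ``core_density``, shell at 1."""
    v1 = r_inner**3
    v2 = r_outer**3  # common 4pi/3 factor cancels
    amp = (
        core_density * v1 * _sphere_amp(q * r_inner)
        + (v2 * _sphere_amp(q * r_outer) - v1 * _sphere_amp(q * r_inner))
    ) / (core_density * v1 + v2 - v1)
    return amp**2


_TORUS_N_POINTS = 1200
_TORUS_N_BINS = 600
_TORUS_SEED = 20180508  # fixed: the sampled cloud is part of the model definition


def _torus_points(ratio: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a torus of ring radius 1 and tube radius ``ratio``."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        m = 2 * (n - got)
        rho = ratio * np.sqrt(rng.random(m))
        phi = rng.uniform(0.0, 2.0 * np.pi, m)
        # radial density in the tube cross-section is proportional to (1 + rho cos phi)
        keep = rng.random(m) * (1.0 + ratio) < (1.0 + rho * np.cos(phi))
        rho, phi = rho[keep], phi[keep]
        theta = rng.uniform(0.0, 2.0 * np.pi, rho.size)
        take = min(rho.size, n - got)
        rr = 1.0 + rho[:take] * np.cos(phi[:take])
        pts[got : got + take, 0] = rr * np.cos(theta[:take])
        pts[got : got + take, 1] = rr * np.sin(theta[:take])
        pts[got : got + take, 2] = rho[:take] * np.sin(phi[:take])
        got += take
    return pts


def _torus_intensity(q: np.ndarray, ring_radius: float, tube_radius: float) -> np.ndarray:
    """Torus via a Debye sum over a pair-distance histogram of sampled points."""
    rng = np.random.default_rng(_TORUS_SEED)
    pts = _torus_points(tube_radius / ring_radius, _TORUS_N_POINTS, rng) * ring_radius
    dists = pdist(pts)
    hist, edges = np.histogram(dists, bins=_TORUS_N_BINS)
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    n = _TORUS_N_POINTS
    qr = np.outer(q, r_mid)
    sinc = np.sinc(qr / np.pi)  # sin(qr)/(qr)
    return (n + 2.0 * sinc @ hist) / (n * n)


def _debye_intensity(q: np.ndarray, rg: float) -> np.ndarray:
    """Debye function for a Gaussian chain, I(0) = 1."""
    u = (q * rg) ** 2
    out = np.empty_like(u)
    small = u < 1e-6
    out[small] = 1.0 - u[small] / 3.0
    ul = u[~small]
    out[~small] = 2.0 * (np.exp(-ul) - 1.0 + ul) / (ul * ul)
    return out


def _intensity(spec: ParticleSpec, q: np.ndarray) -> np.ndarray:
    g = spec.geometry
    if spec.shape_class == "compact":
        return _sphere_intensity(q, g["radius"])
    if spec.shape_class in ("extended", "flat"):
        return _ellipsoid_intensity(q, g["a"], g["c"])
    if spec.shape_class == "ring":
        return _torus_intensity(q, g["ring_radius"], g["tube_radius"])
    if spec.shape_class in ("compact-hollow", "hollow-sphere"):
        return _shell_intensity(q, g["r_inner"], g["r_outer"], g["core_density"])
    if spec.shape_class == "random-chain":
        return _debye_intensity(q, g["rg"])
    raise SaxsmmError(f"unsupported geometry for shape class {spec.shape_class!r}")


# Gauss-Hermite nodes for the size-polydispersity average.
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(9)


def ideal_profile(
    spec: ParticleSpec,
    s_max: float = 0.6,
    n_points: int = 1001,
    polydispersity: float = 0.0,
) -> ScatteringProfile:
    """Noise-free profile on a uniform grid (default: 1001 points to 0.6 1/A).

    With ``polydispersity > 0`` the curve is the intensity-weighted average
    over a narrow Gaussian distribution of particle size (fractional standard
    deviation ``polydispersity``), which fills in the exact form-factor zeros
    that would otherwise make ``ln I`` undefined.  Scaling every length by t
    scales the amplitude by the volume (t^3) and the momentum transfer by t,
    so the average is taken over ``I(t q)`` with weights ``w t^6``.
    """
    q = np.linspace(s_max / n_points, s_max, n_points)
    if polydispersity <= 0 or spec.shape_class == "random-chain":
        intensity = _intensity(spec, q)
    else:
        t_all = 1.0 + np.sqrt(2.0) * polydispersity * _GH_NODES
        keep = t_all > 0.1
        t = t_all[keep]
        wv = _GH_WEIGHTS[keep] * t**6
        wv /= wv.sum()
        intensity = np.zeros_like(q)
        for ti, wi in zip(t, wv):
            intensity += wi * _intensity(spec, ti * q)
    return ScatteringProfile(s=q, intensity=intensity, sigma=None, label=spec.label)


# ---------------------------------------------------------------------------
# corruption models


#: High-angle noise floor as a fraction of the forward scattering.
NOISE_FLOOR = 1e-3


def add_noise(profile: ScatteringProfile, noise: NoiseSpec) -> ScatteringProfile:
    """Perturb a profile with Gaussian counting-like noise at a target SNR.

    The error template is ``sigma(s) = a sqrt(I(s) + 1e-3 I(0))`` — Poisson-
    like growth of the *relative* error toward high angles plus a constant
    floor — with ``a`` chosen so that ``median(I)/median(sigma)`` equals the
    target SNR exactly.  The template is deterministic given the profile;
    only the intensity perturbation depends on the seed.  The template is
    written into the sigma column.
    """
    i = profile.intensity
    i0_proxy = float(np.max(i))
    template = np.sqrt(np.clip(i, 0.0, None) + NOISE_FLOOR * i0_proxy)
    scale = float(np.median(i)) / (noise.target_snr * float(np.median(template)))
    sigma = scale * template
    rng = np.random.default_rng(noise.seed)
    noisy = i + rng.normal(0.0, 1.0, i.size) * sigma
    return profile.with_intensity(noisy, sigma=sigma)


def mismatch(
    profile: ScatteringProfile, fraction: float, direction: str
) -> ScatteringProfile:
    """Constant-offset buffer mismatch.

    The intensity over s in [0.4, 0.6] 1/A is averaged (``I_average``);
    over-subtraction removes ``fraction * I_average`` at every s,
    under-subtraction adds it.  The sigma column is unchanged.
    """
    if direction not in ("over", "under"):
        raise SaxsmmError(f"direction must be 'over' or 'under', got {direction!r}")
    if profile.s[-1] < 0.6 * (1.0 - 1e-9):
        raise SaxsmmError(
            f"profile ends at s = {profile.s[-1]:g}; mismatch needs data to 0.6 1/A"
        )
    window = (profile.s >= 0.4) & (profile.s <= 0.6)
    i_average = float(np.mean(profile.intensity[window]))
    offset = fraction * i_average
    shifted = profile.intensity + (offset if direction == "under" else -offset)
    return profile.with_intensity(shifted)


# ---------------------------------------------------------------------------
# corpus


def build_corpus(
    n_per_class: int = 150,
    mm_range: tuple[float, float] = (7.0, 300.0),
    split: float = 0.75,
    seed: int = 0,
    class_weights: dict[str, float] | None = None,
    s_max: float = 0.6,
    n_points: int = 1001,
    polydispersity: float = 0.03,
) -> tuple[list[CorpusEntry], list[CorpusEntry]]:
    """Generate a training/test corpus of condition-variant profiles.

    Per shape class, ``n_per_class`` particles scaled by the class weight
    (``DEFAULT_CLASS_WEIGHTS`` unless overridden: compact-skewed, mirroring
    structure databases) are sampled with log-uniform mass over ``mm_range``.
    Particles
    are randomly split into a training fraction ``split`` and a test rest.
    Training particles contribute the ideal profile plus noise variants at
    SNR 32, 11, 4 and 2 (the noisiest level is withheld from training); test
    particles contribute 16 variants each: ideal, the five SNR levels, and
    the ten constant-offset mismatch variants (applied to the SNR = 4
    profile, where solvent mismatch is emulated).  Everything is reproducible
    from ``seed``.
    """
    if n_per_class < 50:
        raise SaxsmmError("n_per_class must be at least 50")
    lo, hi = mm_range
    if not (0 < lo < hi):
        raise SaxsmmError(f"degenerate mass range {mm_range}")
    weights = DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights
    rng = np.random.default_rng(seed)
    specs: list[ParticleSpec] = []
    for cls in SHAPE_CLASSES:
        n_cls = int(round(n_per_class * weights.get(cls, 1.0)))
        for i in range(n_cls):
            mm = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            specs.append(particle_from_mm(cls, mm, rng=rng, label=f"{cls}-{i:04d}"))
    order = rng.permutation(len(specs))
    n_train = int(round(split * len(specs)))
    train_ids = set(order[:n_train].tolist())

    train: list[CorpusEntry] = []
    test: list[CorpusEntry] = []
    for j, spec in enumerate(specs):
        is_train = j in train_ids
        ideal = ideal_profile(
            spec, s_max=s_max, n_points=n_points, polydispersity=polydispersity
        )
        entries = train if is_train else test

        def add(profile: ScatteringProfile, condition: str, **kw) -> None:
            entries.append(
                CorpusEntry(
                    profile=profile,
                    mm=spec.mm,
                    shape_class=spec.shape_class,
                    condition=condition,
                    particle_id=spec.label,
                    **kw,
                )
            )

        add(ideal, "ideal")
        snrs = TRAIN_SNRS if is_train else TEST_SNRS
        snr4_profile = None
        for snr in snrs:
            noise_seed = int(rng.integers(0, 2**31 - 1))
            noisy = add_noise(ideal, NoiseSpec(target_snr=snr, seed=noise_seed))
            add(noisy, f"snr{snr:g}", snr=snr)
            if snr == 4.0:
                snr4_profile = noisy
        if not is_train:
            for direction in ("over", "under"):
                for frac in MISMATCH_FRACTIONS:
                    add(
                        mismatch(snr4_profile, frac, direction),
                        f"{direction}{frac:g}",
                        snr=4.0,
                        mismatch_fraction=frac,
                        mismatch_direction=direction,
                    )
    return train, test
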