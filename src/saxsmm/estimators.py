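"""The four concentration-independent molecular-mass estimators.

* ``MM_Qp``   — Porod volume divided by 1.37 (Da per A^3 of excluded volume).
* ``MoW``     — apparent volume at fixed s_max, empirically corrected to the
  true volume by a log-log affine law, times the protein mass density
  0.83 Da/A^3.
* ``V_c``     — power law between the size-normalised invariant
  ``Q_R = V_c^2 / Rg`` and the mass, fitted on training data.
* ``Size&Shape`` — inverse-distance-weighted k-nearest-neighbour lookup in the
  four-dimensional space ``(V'_3, V'_4, V'_5, Rg)`` populated from training
  particles of known mass.

MoW's correction law, the V_c power law and the Size&Shape index are
empirical and must be fitted on a training corpus before use; MM_Qp needs no
training.  All four estimators are invariant to an overall intensity
rescaling of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EstimatorError, NotTrainedError
from .guinier import GuinierResult, auto_guinier
from .invariants import InvariantSet, apparent_volume_dimensional
from .profile_io import ScatteringProfile

__all__ = [
    "PROTEIN_DENSITY",
    "QP_MASS_DIVISOR",
    "MMEvidence",
    "MowCorrection",
    "VcPowerLaw",
    "ShapeSpaceIndex",
    "estimate_mm_qp",
    "estimate_mm_mow",
    "fit_mow_correction",
    "fit_mow_correction_from_volumes",
    "estimate_mm_vc",
    "fit_vc_powerlaw",
    "estimate_mm_ss",
]

#: Average mass density of an unmodified protein, Da per A^3.
PROTEIN_DENSITY = 0.83
#: Divisor converting a Porod volume (A^3) to mass (Da) for the MM_Qp method.
QP_MASS_DIVISOR = 1.37

METHODS = ("mm_qp", "mm_mow", "mm_vc", "mm_ss")


@dataclass
class MMEvidence:
    """Per-method mass estimates for one profile, in kDa; NaN means absent.

    ``flags`` records per-method failure reasons for absent values.
    """

    mm_qp: float = np.nan
    mm_mow: float = np.nan
    mm_vc: float = np.nan
    mm_ss: float = np.nan
    flags: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METHODS}

    @property
    def n_present(self) -> int:
        return int(sum(np.isfinite(v) for v in self.as_dict().values()))


# ---------------------------------------------------------------------------
# MM_Qp


def estimate_mm_qp(inv: InvariantSet) -> float:
    """Mass from the Porod volume: ``MM [Da] = V_p [A^3] / 1.37``; kDa returned."""
    if not np.isfinite(inv.vp) or inv.vp <= 0:
        raise EstimatorError("Porod volume absent or non-positive")
    return inv.vp / QP_MASS_DIVISOR / 1000.0


# ---------------------------------------------------------------------------
# MoW


@dataclass(frozen=True)
class MowCorrection:
    """Log-log affine correction ``log10 V = a log10 V' + b`` at a fixed s_max."""

    a: float
    b: float
    s_max: float = 0.3

    def correct(self, vprime: float) -> float:
        return float(10.0 ** (self.a * np.log10(vprime) + self.b))


def fit_mow_correction_from_volumes(
    vprimes: np.ndarray, masses_kda: np.ndarray, s_max: float = 0.3
) -> MowCorrection:
    """Fit the MoW correction from apparent volumes (A^3) and true masses (kDa).

    True volumes are taken as ``MM / rho`` with rho = 0.83 Da/A^3.
    """
    vprimes = np.asarray(vprimes, dtype=float)
    masses = np.asarray(masses_kda, dtype=float)
    ok = np.isfinite(vprimes) & np.isfinite(masses) & (vprimes > 0) & (masses > 0)
    vprimes, masses = vprimes[ok], masses[ok]
    if vprimes.size < 200:
        raise EstimatorError(
            f"{vprimes.size} usable training profiles; at least 200 required"
        )
    if masses.max() / masses.min() < 10.0:
        raise EstimatorError("training masses span less than a decade; fit degenerate")
    v_true = masses * 1000.0 / PROTEIN_DENSITY
    lx = np.log10(vprimes)
    if np.ptp(lx) < 1e-6:
        raise EstimatorError("degenerate spread in apparent volumes")
    a, b = np.polyfit(lx, np.log10(v_true), 1)
    return MowCorrection(a=float(a), b=float(b), s_max=s_max)


def fit_mow_correction(
    training: list[tuple[ScatteringProfile, float]], s_max: float = 0.3
) -> MowCorrection:
    """Fit the MoW correction from (profile, true mass in kDa) pairs.

    Runs the automatic Guinier fit and the apparent-volume integral per
    profile; pairs whose analysis fails are skipped.
    """
    vprimes, masses = [], []
    for profile, mm in training:
        try:
            g = auto_guinier(profile)
            vprimes.append(apparent_volume_dimensional(profile, g, s_max=s_max))
        except Exception:
            continue
        masses.append(mm)
    return fit_mow_correction_from_volumes(
        np.array(vprimes), np.array(masses), s_max=s_max
    )


def estimate_mm_mow(
    profile: ScatteringProfile, g: GuinierResult, coeffs: MowCorrection
) -> float:
    """MoW mass estimate in kDa at the correction model's s_max."""
    if coeffs is None:
        raise NotTrainedError("MoW correction coefficients not fitted")
    if coeffs.s_max < 3.0 / g.rg:
        raise EstimatorError(
            f"range: s_max = {coeffs.s_max:g} below 3/Rg = {3.0 / g.rg:g}"
        )
    vprime = apparent_volume_dimensional(profile, g, s_max=coeffs.s_max)
    volume = coeffs.correct(vprime)
    return PROTEIN_DENSITY * volume / 1000.0


# ---------------------------------------------------------------------------
# V_c


@dataclass(frozen=True)
class VcPowerLaw:
    """``MM = (Q_R / c) ** k`` with ``Q_R = V_c^2 / Rg`` (the mass power law)."""

    c: float
    k: float


def fit_vc_powerlaw(qr: np.ndarray, masses_kda: np.ndarray) -> VcPowerLaw:
    """Fit the V_c power law on ``Q_R = V_c^2/Rg`` vs true mass, log-log."""
    qr = np.asarray(qr, dtype=float)
    masses = np.asarray(masses_kda, dtype=float)
    ok = np.isfinite(qr) & np.isfinite(masses) & (qr > 0) & (masses > 0)
    qr, masses = qr[ok], masses[ok]
    if qr.size < 2 or np.ptp(np.log10(qr)) < 1e-6:
        raise EstimatorError("degenerate spread in Q_R; power law unfit")
    k, beta = np.polyfit(np.log10(qr), np.log10(masses), 1)
    c = 10.0 ** (-beta / k)
    return VcPowerLaw(c=float(c), k=float(k))


def estimate_mm_vc(
    inv: InvariantSet, g: GuinierResult, powerlaw: VcPowerLaw
) -> float:
    """V_c-based mass estimate in kDa."""
    if powerlaw is None:
        raise NotTrainedError("V_c power-law constants not fitted")
    if not np.isfinite(inv.vc) or inv.vc <= 0 or not np.isfinite(g.rg) or g.rg <= 0:
        raise EstimatorError("V_c or Rg absent")
    q_r = inv.vc**2 / g.rg
    return float((q_r / powerlaw.c) ** powerlaw.k)


# ---------------------------------------------------------------------------
# Size & Shape


@dataclass
class ShapeSpaceIndex:
    """k-NN index over the standardized 4-D size-and-shape space.

    Coordinates are ``(V'_3, V'_4, V'_5, log Rg)``, z-scored per coordinate
    (the log transform of Rg and the standardization make the Euclidean
    metric meaningful across incommensurate scales).
    """

    points: np.ndarray  # (n, 4) standardized
    masses: np.ndarray  # (n,) kDa
    mean: np.ndarray
    std: np.ndarray
    k: int = 5
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @classmethod
    def build(
        cls,
        vprime_triplets: np.ndarray,
        rgs: np.ndarray,
        masses_kda: np.ndarray,
        k: int = 5,
    ) -> "ShapeSpaceIndex":
        """Build the index from raw triplets (n, 3), Rg values and masses."""
        feats = np.column_stack(
            [np.asarray(vprime_triplets, dtype=float), np.log(np.asarray(rgs, dtype=float))]
        )
        masses = np.asarray(masses_kda, dtype=float)
        ok = np.all(np.isfinite(feats), axis=1) & np.isfinite(masses) & (masses > 0)
        feats, masses = feats[ok], masses[ok]
        if feats.shape[0] == 0:
            raise EstimatorError("empty size-and-shape training set")
        mean = feats.mean(axis=0)
        std = feats.std(axis=0)
        std[std <= 0] = 1.0
        return cls(points=(feats - mean) / std, masses=masses, mean=mean, std=std, k=k)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def query_point(self, vprime_triplet: np.ndarray, rg: float) -> np.ndarray:
        feat = np.append(np.asarray(vprime_triplet, dtype=float), np.log(rg))
        return (feat - self.mean) / self.std


def estimate_mm_ss(
    inv: InvariantSet,
    g: GuinierResult,
    index: ShapeSpaceIndex,
    exclude_self: bool = False,
) -> float:
    """Size&Shape k-NN mass estimate in kDa.

    Inverse-distance-weighted mean of the masses of the ``k`` nearest
    training points; with ``exclude_self`` the single nearest neighbour is
    skipped (ranks 2..k+1), the cross-validation variant that prevents a
    training particle acting as its own neighbour.  An exact match
    (zero distance) short-circuits to that point's mass.
    """
    if index is None:
        raise NotTrainedError("size-and-shape index not built")
    triplet = np.array([inv.vprime_3, inv.vprime_4, inv.vprime_5])
    if not np.all(np.isfinite(triplet)) or not np.isfinite(g.rg):
        raise EstimatorError("V' triplet or Rg absent")
    q = index.query_point(triplet, g.rg)
    n_needed = index.k + (1 if exclude_self else 0)
    if index.masses.size < n_needed:
        raise EstimatorError(
            f"only {index.masses.size} training points; {n_needed} needed"
        )
    dist, idx = index.tree.query(q, k=n_needed)
    dist, idx = np.atleast_1d(dist), np.atleast_1d(idx)
    if exclude_self:
        dist, idx = dist[1:], idx[1:]
    if dist[0] < 1e-12:
        return float(index.masses[idx[0]])
    w = 1.0 / (dist + 1e-9)
    return float(np.sum(w * index.masses[idx]) / np.sum(w))
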