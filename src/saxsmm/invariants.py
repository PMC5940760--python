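"""Scattering invariants: Porod invariant/volume, volume of correlation,
and normalized-Kratky apparent volumes.

All quantities are built from integrals of the measured curve plus two
analytic pieces that the data cannot supply directly:

* a low-angle head from 0 to the first tabulated point, integrated in closed
  form on the fitted Guinier model ``I(s) = I(0) exp(-s^2 Rg^2 / 3)``;
* for the Porod invariant only, a high-angle Porod tail
  ``I(s) ~ K / s^4`` beyond the cutoff ``s_cut`` (where ``s_cut * Rg = 8``),
  contributing ``K / s_cut`` to the integral of ``s^2 I``.

Every invariant is invariant under an overall intensity rescaling, which is
what makes the downstream mass estimators concentration independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .exceptions import InvariantError
from .guinier import GuinierResult
from .profile_io import ScatteringProfile

__all__ = [
    "InvariantSet",
    "porod_invariant",
    "volume_of_correlation",
    "apparent_volumes",
    "apparent_volume_dimensional",
    "compute_invariants",
]

#: Upper integration bound for the Porod invariant, in units of s * Rg.
POROD_SRG_CUT = 8.0
#: Fraction of the integration range used to estimate the Porod constant.
TAIL_WINDOW_FRACTION = 0.6


@dataclass(frozen=True)
class InvariantSet:
    """The invariants one profile yields.

    qp: Porod invariant (intensity * A^-3); vp: Porod (excluded) volume, A^3;
    vc: volume of correlation, A^2; lc = vp / (2 pi vc): correlation length, A;
    vprime_3/4/5: dimensionless apparent volumes at s*Rg = 3, 4, 5;
    s_upper_used: upper end of the Porod integration, 1/A;
    truncated: True when the profile ended before s*Rg = 8.
    """

    qp: float
    vp: float
    vc: float
    lc: float
    vprime_3: float
    vprime_4: float
    vprime_5: float
    s_upper_used: float
    truncated: bool = False


def _guinier_head_s2(i0: float, rg: float, s1: float) -> float:
    """integral_0^s1 of s^2 * i0 * exp(-a s^2) ds with a = rg^2/3 (closed form)."""
    a = rg * rg / 3.0
    ra = np.sqrt(a)
    return float(
        i0 * (np.sqrt(np.pi) * erf(ra * s1) / (4.0 * a * ra) - s1 * np.exp(-a * s1 * s1) / (2.0 * a))
    )


def _guinier_head_s1(i0: float, rg: float, s1: float) -> float:
    """integral_0^s1 of s * i0 * exp(-a s^2) ds with a = rg^2/3 (closed form)."""
    a = rg * rg / 3.0
    return float(i0 * (1.0 - np.exp(-a * s1 * s1)) / (2.0 * a))


def _cut_grid(
    s: np.ndarray, i: np.ndarray, s_upper: float
) -> tuple[np.ndarray, np.ndarray]:
    """Grid restricted to s <= s_upper, with the endpoint interpolated exactly."""
    k = int(np.searchsorted(s, s_upper, side="right"))
    if k == 0:
        raise InvariantError(f"profile starts beyond s_upper = {s_upper:g}")
    if k >= s.size:
        return s, i
    s_cut = np.append(s[:k], s_upper)
    i_cut = np.append(i[:k], np.interp(s_upper, s, i))
    return s_cut, i_cut


def porod_invariant(
    profile: ScatteringProfile,
    g: GuinierResult,
    allow_truncated: bool = True,
    tail: bool = True,
) -> tuple[float, float, bool]:
    """Porod invariant Q_p and excluded volume V_p = 2 pi^2 I(0) / Q_p.

    ``Q_p = integral of s^2 I(s)`` assembled from the analytic Guinier head,
    the trapezoidal integral of the data up to ``s_cut`` (``s_cut * Rg = 8``),
    and an analytic ``K / s_cut`` Porod tail.  The Porod constant ``K`` is a
    triangular-window weighted mean of ``s^4 I(s)`` over the last 60% of the
    integration range: for sharp-interface particles ``s^4 I`` oscillates
    around its asymptote, and the taper suppresses the leakage of a partial
    oscillation period into the average far better than a plain mean or
    median does (validated against the closed-form sphere volume).

    Returns ``(qp, vp, truncated)``; ``truncated`` flags profiles that end
    before ``s * Rg = 8`` (integration then stops at the last point, the tail
    still being attached there).
    """
    s_target = POROD_SRG_CUT / g.rg
    truncated = bool(profile.s[-1] < s_target)
    if truncated and not allow_truncated:
        raise InvariantError(
            f"profile ends at s = {profile.s[-1]:g} < {s_target:g} (s*Rg = 8)"
        )
    s_cut, i_cut = _cut_grid(profile.s, profile.intensity, min(s_target, profile.s[-1]))
    qp = _guinier_head_s2(g.i0, g.rg, float(s_cut[0]))
    qp += float(np.trapezoid(s_cut * s_cut * i_cut, s_cut))
    if tail:
        win = s_cut >= (1.0 - TAIL_WINDOW_FRACTION) * s_cut[-1]
        sw = s_cut[win]
        vw = sw**4 * i_cut[win]
        u = (sw - sw[0]) / max(sw[-1] - sw[0], 1e-300)
        wt = 1.0 - np.abs(2.0 * u - 1.0)
        k_const = float(np.sum(wt * vw) / np.sum(wt))
        qp += k_const / float(s_cut[-1])
    if qp <= 0:
        raise InvariantError("Porod invariant <= 0 (pathological over-subtraction)")
    vp = 2.0 * np.pi**2 * g.i0 / qp
    return float(qp), float(vp), truncated


def volume_of_correlation(
    profile: ScatteringProfile,
    g: GuinierResult,
    s_upper: float | None = 0.3,
) -> float:
    """Volume of correlation ``V_c = I(0) / integral_0^{s_upper} s I(s) ds`` (A^2).

    The integrand converges on its own (no tail model); ``s_upper = None``
    integrates to the end of the profile.
    """
    if s_upper is None:
        s_upper = float(profile.s[-1])
    if profile.s[-1] < s_upper * (1.0 - 1e-9):
        raise InvariantError(
            f"profile ends at s = {profile.s[-1]:g}, below s_upper = {s_upper:g}"
        )
    s_cut, i_cut = _cut_grid(profile.s, profile.intensity, s_upper)
    denom = _guinier_head_s1(g.i0, g.rg, float(s_cut[0]))
    denom += float(np.trapezoid(s_cut * i_cut, s_cut))
    if denom <= 0:
        raise InvariantError("integral of s*I(s) <= 0; V_c undefined")
    return float(g.i0 / denom)


def _q_prime_dimensionless(
    x: np.ndarray, y: np.ndarray, x_max: float
) -> float:
    """Q'(x_max) = integral_0^{x_max} x^2 I(x)/I(0) dx on the s*Rg axis."""
    x_cut, y_cut = _cut_grid(x, y, x_max)
    head = _guinier_head_s2(1.0, 1.0, float(x_cut[0]))  # Rg = 1 on the x = s*Rg axis
    return head + float(np.trapezoid(x_cut * x_cut * y_cut, x_cut))


def apparent_volumes(
    profile: ScatteringProfile, g: GuinierResult
) -> tuple[float, float, float]:
    """Dimensionless apparent volumes ``V' = 2 pi^2 / Q'`` at s*Rg = 3, 4, 5.

    Computed on the normalized Kratky axis ``x = s * Rg`` with intensities
    scaled to ``I(0) = 1``, so the triplet depends on shape only: identical
    particles at different sizes give identical triplets.
    """
    x = profile.s * g.rg
    if x[-1] < 5.0:
        raise InvariantError(
            f"profile reaches s*Rg = {x[-1]:.2f} < 5; apparent volumes unavailable"
        )
    y = profile.intensity / g.i0
    out = tuple(2.0 * np.pi**2 / _q_prime_dimensionless(x, y, xm) for xm in (3.0, 4.0, 5.0))
    return out  # type: ignore[return-value]


def apparent_volume_dimensional(
    profile: ScatteringProfile, g: GuinierResult, s_max: float = 0.3
) -> float:
    """Apparent volume ``V' = 2 pi^2 / Q'`` (A^3) at a fixed ``s_max`` in 1/A.

    ``Q' = integral_0^{s_max} s^2 I(s)/I(0) ds`` — the quantity the SAXSMoW
    family of estimators corrects into a true volume.
    """
    if profile.s[-1] < s_max * (1.0 - 1e-9):
        raise InvariantError(
            f"profile ends at s = {profile.s[-1]:g}, below s_max = {s_max:g}"
        )
    s_cut, i_cut = _cut_grid(profile.s, profile.intensity, s_max)
    q = _guinier_head_s2(1.0, g.rg, float(s_cut[0]))
    q += float(np.trapezoid(s_cut * s_cut * i_cut / g.i0, s_cut))
    if q <= 0:
        raise InvariantError("apparent Kratky integral <= 0")
    return float(2.0 * np.pi**2 / q)


def compute_invariants(
    profile: ScatteringProfile,
    g: GuinierResult,
    s_upper_vc: float | None = 0.3,
) -> InvariantSet:
    """All invariants of one profile in a single :class:`InvariantSet`."""
    qp, vp, truncated = porod_invariant(profile, g)
    vc = volume_of_correlation(profile, g, s_upper=s_upper_vc)
    v3, v4, v5 = apparent_volumes(profile, g)
    lc = vp / (2.0 * np.pi * vc)
    s_upper_used = min(POROD_SRG_CUT / g.rg, float(profile.s[-1]))
    return InvariantSet(
        qp=qp,
        vp=vp,
        vc=vc,
        lc=lc,
        vprime_3=v3,
        vprime_4=v4,
        vprime_5=v5,
        s_upper_used=s_upper_used,
        truncated=truncated,
    )
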