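"""Guinier analysis: radius of gyration and forward scattering.

At small angles the scattering of a monodisperse particle follows
``ln I(s) = ln I(0) - s^2 Rg^2 / 3``, classically trusted up to
``s * Rg <= 1.3`` for globular particles.  :func:`guinier_fit` performs the
weighted least-squares line through ``(s^2, ln I)`` over a caller-chosen
window; :func:`auto_guinier` searches for the best window automatically,
which is what noisy data requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GuinierError
from .profile_io import ScatteringProfile

__all__ = ["GuinierResult", "guinier_fit", "auto_guinier", "SRG_LIMIT"]

#: Classical Guinier validity bound on s * Rg at the end of the fit window.
SRG_LIMIT = 1.3


@dataclass(frozen=True)
class GuinierResult:
    """Result of a Guinier fit.

    Attributes
    ----------
    rg : float
        Radius of gyration, Angstrom.
    i0 : float
        Forward scattering I(0), intensity units.
    fit_first, fit_last : int
        Inclusive indices (into the original profile) of the fitted window.
    quality : float
        R^2 of the (weighted) fit, clamped to [0, 1].
    """

    rg: float
    i0: float
    fit_first: int
    fit_last: int
    quality: float


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted least squares y = slope*x + intercept; returns (slope, intercept, r2)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    dx = x - mx
    dy = y - my
    sxx = (w * dx * dx).sum()
    sxy = (w * dx * dy).sum()
    syy = (w * dy * dy).sum()
    if sxx <= 0:
        raise GuinierError("degenerate window: no spread in s^2")
    slope = sxy / sxx
    intercept = my - slope * mx
    if syy <= 0:
        r2 = 1.0
    else:
        r2 = (sxy * sxy) / (sxx * syy)
    return slope, intercept, float(min(max(r2, 0.0), 1.0))


def guinier_fit(
    profile: ScatteringProfile, window: tuple[int, int]
) -> GuinierResult:
    """Guinier fit over an explicit inclusive index window.

    The line is fitted through ``(s^2, ln I)``; when the profile carries
    per-point errors the points are weighted by ``(I / sigma)^2``, the
    propagated inverse variance of ``ln I``.

    Raises
    ------
    GuinierError
        If the window is shorter than 5 points, contains non-positive
        intensities, or yields a non-negative slope (no Guinier decay).
    """
    first, last = int(window[0]), int(window[1])
    if last < first or last >= len(profile) or first < 0:
        raise GuinierError(f"invalid window ({first}, {last})")
    n = last - first + 1
    if n < 5:
        raise GuinierError(f"window of {n} points; at least 5 required")
    s = profile.s[first : last + 1]
    inten = profile.intensity[first : last + 1]
    if np.any(inten <= 0):
        raise GuinierError("window contains non-positive intensities")
    x = s * s
    y = np.log(inten)
    if profile.sigma is not None:
        sig = profile.sigma[first : last + 1]
        w = (inten / sig) ** 2
    else:
        w = np.ones_like(x)
    slope, intercept, r2 = _weighted_line(x, y, w)
    if slope >= 0:
        raise GuinierError("no Guinier decay: non-negative slope")
    rg = float(np.sqrt(-3.0 * slope))
    i0 = float(np.exp(intercept))
    return GuinierResult(rg=rg, i0=i0, fit_first=first, fit_last=last, quality=r2)


def auto_guinier(
    profile: ScatteringProfile,
    min_window: int = 10,
    max_start: int = 60,
    max_points: int = 500,
) -> GuinierResult:
    """Automatic Guinier-range search.

    Candidate windows of at least ``min_window`` consecutive positive-intensity
    points (at least 5 when fewer are available) are fitted over the low-angle
    region; windows whose own fitted Rg violates ``s_end * Rg <= 1.3`` or whose
    slope is non-negative are discarded.  Windows are scored by the fit R^2
    with a mild shortness penalty; ties favour the longer, lower-angle window.

    Raises
    ------
    GuinierError
        If no acceptable window exists (the caller typically records the
        estimate as absent).
    """
    pos = np.flatnonzero(profile.intensity > 0)
    if pos.size >= 2:
        # restrict to the low-angle portion to bound the search
        pos = pos[:max_points]
    if pos.size < 5:
        raise GuinierError("fewer than 5 positive-intensity points")
    min_len = min_window if pos.size >= min_window else 5

    s = profile.s[pos]
    x = s * s
    y = np.log(profile.intensity[pos])
    if profile.sigma is not None:
        w = (profile.intensity[pos] / profile.sigma[pos]) ** 2
    else:
        w = np.ones_like(x)

    # prefix sums for O(1) weighted line fits over any contiguous window
    def pref(a: np.ndarray) -> np.ndarray:
        out = np.empty(a.size + 1)
        out[0] = 0.0
        np.cumsum(a, out=out[1:])
        return out

    Pw, Pwx, Pwy = pref(w), pref(w * x), pref(w * y)
    Pwxx, Pwxy, Pwyy = pref(w * x * x), pref(w * x * y), pref(w * y * y)

    n = pos.size
    best: tuple[float, int, int, int] | None = None  # (score, length, -start, end)
    for a in range(0, min(max_start, n - min_len + 1)):
        ends = np.arange(a + min_len - 1, n)
        sw = Pw[ends + 1] - Pw[a]
        swx = Pwx[ends + 1] - Pwx[a]
        swy = Pwy[ends + 1] - Pwy[a]
        swxx = Pwxx[ends + 1] - Pwxx[a]
        swxy = Pwxy[ends + 1] - Pwxy[a]
        swyy = Pwyy[ends + 1] - Pwyy[a]
        sxx = swxx - swx * swx / sw
        sxy = swxy - swx * swy / sw
        syy = swyy - swy * swy / sw
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(sxx > 0, sxy / sxx, 0.0)
            r2 = np.where((sxx > 0) & (syy > 0), sxy * sxy / (sxx * syy), 1.0)
        valid = (sxx > 0) & (slope < 0)
        if not np.any(valid):
            continue
        rg = np.sqrt(np.where(valid, -3.0 * slope, np.nan))
        valid &= s[ends] * rg <= SRG_LIMIT
        if not np.any(valid):
            continue
        lengths = ends - a + 1
        score = np.clip(r2, 0.0, 1.0) - 0.5 / lengths
        score = np.where(valid, score, -np.inf)
        j = int(np.argmax(score + 1e-9 * lengths))  # ties -> longer window
        cand = (float(score[j]), int(lengths[j]), -a, int(ends[j]))
        if best is None or cand > best:
            best = cand
    if best is None:
        raise GuinierError("no Guinier window found (no low-angle decay)")
    a = -best[2]
    end = best[3]
    # refit on the positive-point subset (the original-index window may
    # contain interleaved non-positive points on noisy data)
    sl = slice(a, end + 1)
    slope, intercept, r2 = _weighted_line(x[sl], y[sl], w[sl])
    if slope >= 0:  # pragma: no cover - excluded by the search
        raise GuinierError("no Guinier decay: non-negative slope")
    return GuinierResult(
        rg=float(np.sqrt(-3.0 * slope)),
        i0=float(np.exp(intercept)),
        fit_first=int(pos[a]),
        fit_last=int(pos[end]),
        quality=r2,
    )
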