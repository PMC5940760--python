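"""Reading, validating and writing 1-D SAXS profiles, plus model persistence.

The on-disk dialect is the de-facto ``.dat`` convention: whitespace-delimited
ASCII with columns ``s  I(s)  [sigma]``, where ``s = 4*pi*sin(theta)/lambda``
is the momentum transfer in 1/Angstrom and the intensity is on an arbitrary
scale.  Comment/header lines (leading ``#`` or a non-numeric first token) are
skipped; columns beyond the third are ignored.

Trained pipeline state (bin edges, estimator coefficients, likelihood tables)
is persisted as a JSON archive tagged with ``MODEL_SCHEMA`` so a saved model
can be validated before use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .exceptions import ProfileFormatError

__all__ = [
    "ScatteringProfile",
    "read_profile",
    "write_profile",
    "save_model",
    "load_model",
    "MODEL_SCHEMA",
]

logger = logging.getLogger(__name__)

#: Minimum number of tabulated points for invariant integration to make sense.
MIN_POINTS = 50
#: Minimum dynamic range s_max/s_min of the momentum-transfer grid.
MIN_SPAN = 10.0

MODEL_SCHEMA = "saxsmm-model/1"


@dataclass(frozen=True)
class ScatteringProfile:
    """A background-subtracted 1-D scattering curve.

    Parameters
    ----------
    s : array
        Momentum transfer grid in 1/Angstrom; strictly increasing, all > 0
        (``s = 0`` is never tabulated — the forward scattering ``I(0)`` comes
        from Guinier extrapolation).
    intensity : array
        ``I(s)`` on an arbitrary scale.  Negative values are legitimate after
        background subtraction and are kept.
    sigma : array, optional
        Per-point standard error, same units as the intensity, all > 0.
    label : str
        Free-text identifier.
    """

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "intensity", i)
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", sig)
        if s.ndim != 1 or i.shape != s.shape:
            raise ProfileFormatError("s and intensity must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != s.shape:
            raise ProfileFormatError("sigma must match s in length")
        if s.size < MIN_POINTS:
            raise ProfileFormatError(
                f"profile has {s.size} points; at least {MIN_POINTS} required"
            )
        if not np.all(np.isfinite(s)) or not np.all(np.isfinite(i)):
            raise ProfileFormatError("non-finite values in s or intensity")
        if s[0] <= 0.0:
            raise ProfileFormatError("s values must all be > 0")
        ds = np.diff(s)
        if np.any(ds <= 0):
            k = int(np.argmax(ds <= 0))
            raise ProfileFormatError(f"s not strictly increasing at index {k + 1}")
        if s[-1] / s[0] < MIN_SPAN:
            raise ProfileFormatError(
                f"s range too narrow: s_max/s_min = {s[-1] / s[0]:.2f} < {MIN_SPAN}"
            )
        if self.sigma is not None:
            if not np.all(np.isfinite(self.sigma)) or np.any(self.sigma <= 0):
                raise ProfileFormatError("sigma must be finite and > 0 everywhere")

    def __len__(self) -> int:
        return int(self.s.size)

    def with_intensity(
        self, intensity: np.ndarray, sigma: np.ndarray | None = None, label: str | None = None
    ) -> "ScatteringProfile":
        """Copy of this profile with replaced intensity (and optionally sigma)."""
        return ScatteringProfile(
            s=self.s.copy(),
            intensity=np.asarray(intensity, dtype=float),
            sigma=self.sigma.copy() if sigma is None and self.sigma is not None else sigma,
            label=self.label if label is None else label,
        )


def _parse_rows(path: Path) -> tuple[list[list[float]], int]:
    rows: list[list[float]] = []
    n_cols = 0
    n_dropped = 0
    first_bad: tuple[int, str] | None = None
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            try:
                values = [float(t) for t in tokens[:3]]
            except ValueError:
                # header / comment line with a non-numeric leading token
                continue
            if len(values) < 2:
                if first_bad is None:
                    first_bad = (lineno, stripped)
                continue
            if not all(np.isfinite(v) for v in values) or (
                len(values) >= 3 and values[2] <= 0
            ):
                n_dropped += 1
                continue
            rows.append(values)
            n_cols = max(n_cols, len(values))
    if n_dropped:
        logger.info("%s: dropped %d rows (non-finite values or sigma <= 0)", path, n_dropped)
    if not rows and first_bad is not None:
        raise ProfileFormatError(
            f"{path}: no parseable data rows (first offending line {first_bad[0]}: "
            f"{first_bad[1]!r})"
        )
    return rows, n_cols


def read_profile(path: str | Path) -> ScatteringProfile:
    """Read a ``.dat`` profile from disk.

    Two-column files yield ``sigma = None``; in three-column files a sigma is
    only taken for rows that actually carry one.  Rows with non-finite values
    or non-positive sigma are dropped with a logged count.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"no such profile file: {path}")
    rows, n_cols = _parse_rows(path)
    if len(rows) < MIN_POINTS:
        raise ProfileFormatError(
            f"{path}: only {len(rows)} valid data rows; at least {MIN_POINTS} required"
        )
    have_sigma = n_cols >= 3 and all(len(r) >= 3 for r in rows)
    arr = np.array([r[:3] if have_sigma else r[:2] for r in rows], dtype=float)
    s, i = arr[:, 0], arr[:, 1]
    ds = np.diff(s)
    if np.any(ds <= 0):
        k = int(np.argmax(ds <= 0)) + 1
        raise ProfileFormatError(f"{path}: s not strictly increasing at data row {k + 1}")
    sigma = arr[:, 2] if have_sigma else None
    return ScatteringProfile(s=s, intensity=i, sigma=sigma, label=path.stem)


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile as 2- or 3-column ASCII with a one-line ``#`` header.

    ``read_profile(write_profile(p))`` reproduces s, I and sigma to better
    than 6 significant digits (values are written with 9).
    """
    path = Path(path)
    cols = [profile.s, profile.intensity]
    header = "s(1/A) I(s)"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    data = np.column_stack(cols)
    try:
        np.savetxt(
            path,
            data,
            fmt="%.9e",
            header=f"{profile.label or 'scattering profile'} | {header}",
        )
    except OSError as exc:
        raise IOError(f"cannot write profile to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# trained-model persistence


def save_model(state: dict[str, Any], path: str | Path) -> None:
    """Persist a trained-model state dictionary as a schema-tagged JSON file."""
    payload = dict(state)
    payload["schema"] = MODEL_SCHEMA
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> dict[str, Any]:
    """Load a model archive written by :func:`save_model`; verifies the schema tag."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("schema") != MODEL_SCHEMA:
        raise ProfileFormatError(
            f"{path}: not a {MODEL_SCHEMA} archive (schema = {payload.get('schema')!r})"
        )
    return payload
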