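"""Bayesian combination of the four mass estimates.

The mass axis is discretized into bins (hypotheses H).  For each estimator a
likelihood table ``P(E | H)`` is learned from training pairs of (estimated
mass, true mass): the row for an evidence bin is the Laplace-smoothed,
normalized histogram of true-mass bins observed with that evidence.  For a
new profile the posterior over hypothesis bins is

    P(H | E) ∝ P(E_qp | H) * P(E_vc | H) * P(E_mow | H) * P(E_ss | H) * P(H)

with absent estimates simply contributing nothing.  The products are
accumulated in log space.  The point estimate is the MAP bin center and the
uncertainty a 90% highest-posterior-density credibility interval, reported
as the contiguous envelope of the greedily accumulated bin set.

The bin scheme follows the empirical mass distribution: the central 90% of
the (log) training masses is split into equal-count quantile bins — narrow
where proteins are common — while the extreme 5% tails get equal-width
linear bins; masses below 0.7 kDa or above 1300 kDa clamp to the first/last
bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import NoEvidenceError, SaxsmmError
from .estimators import METHODS, MMEvidence

__all__ = [
    "BinScheme",
    "LikelihoodTable",
    "PosteriorResult",
    "build_bins",
    "fit_likelihood",
    "posterior",
    "credible_interval",
    "forward_prior",
    "CLAMP_LOW_KDA",
    "CLAMP_HIGH_KDA",
]

#: Masses below/above these clamp to the first/last bin (kDa).
CLAMP_LOW_KDA = 0.7
CLAMP_HIGH_KDA = 1300.0


@dataclass(frozen=True)
class BinScheme:
    """Discretized mass axis: ``edges`` (n+1, kDa) and ``centers`` (n, kDa)."""

    edges: np.ndarray
    centers: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        c = np.asarray(self.centers, dtype=float)
        object.__setattr__(self, "edges", e)
        object.__setattr__(self, "centers", c)
        if np.any(np.diff(e) <= 0):
            raise SaxsmmError("bin edges must be strictly increasing")
        if c.size != e.size - 1:
            raise SaxsmmError("need exactly one center per bin")

    @property
    def n_bins(self) -> int:
        return int(self.centers.size)

    def index_of(self, mm: float | np.ndarray) -> np.ndarray | int:
        """Bin index of a mass in kDa; out-of-range clamps to the first/last bin."""
        idx = np.searchsorted(self.edges, mm, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)


def build_bins(
    training_masses: np.ndarray,
    n_bins: int = 100,
    tail_fraction: float = 0.05,
) -> BinScheme:
    """Adaptive mass bins from an empirical mass sample (kDa).

    The central ``1 - 2*tail_fraction`` of the log-mass distribution is
    partitioned into equal-count quantile bins (uniform structure count per
    bin); each tail gets ``tail_fraction * n_bins`` equal-width bins spanning
    the empirical tail (5th percentile down to the smallest mass, 95th up to
    the largest).  Where the data stop short of the 0.7 kDa / 1300 kDa
    clamps, a single catch-all bin covers the data-free zone out to the
    clamp, so that tail resolution is spent where masses actually occur.
    Bin centers are geometric means of the edges.
    """
    masses = np.asarray(training_masses, dtype=float)
    masses = masses[np.isfinite(masses) & (masses > 0)]
    if masses.size < 1000:
        raise SaxsmmError(
            f"{masses.size} masses supplied; at least 1000 required for stable bins"
        )
    masses = np.clip(masses, CLAMP_LOW_KDA, CLAMP_HIGH_KDA)
    n_tail = max(int(round(tail_fraction * n_bins)), 1)
    n_central = n_bins - 2 * n_tail
    if n_central < 1:
        raise SaxsmmError("n_bins too small for the tail layout")
    log_m = np.log(masses)
    qs = np.linspace(tail_fraction, 1.0 - tail_fraction, n_central + 1)
    central = np.exp(np.quantile(log_m, qs))
    m_min, m_max = float(masses.min()), float(masses.max())
    if m_min > CLAMP_LOW_KDA * 1.001:
        low = np.concatenate([[CLAMP_LOW_KDA], np.linspace(m_min, central[0], n_tail)[:-1]])
    else:
        low = np.linspace(CLAMP_LOW_KDA, central[0], n_tail + 1)[:-1]
    if m_max < CLAMP_HIGH_KDA * 0.999:
        high = np.concatenate([np.linspace(central[-1], m_max, n_tail)[1:], [CLAMP_HIGH_KDA]])
    else:
        high = np.linspace(central[-1], CLAMP_HIGH_KDA, n_tail + 1)[1:]
    edges = np.concatenate([low, central, high])
    # enforce strict monotonicity against duplicated quantiles
    min_step = 1e-9
    for i in range(1, edges.size):
        if edges[i] <= edges[i - 1]:
            edges[i] = edges[i - 1] * (1.0 + min_step)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return BinScheme(edges=edges, centers=centers)


@dataclass(frozen=True)
class LikelihoodTable:
    """``P(truth bin | evidence bin)`` for one method.

    ``table[e, h]`` is the probability of hypothesis bin ``h`` given the
    method produced an estimate in evidence bin ``e``; every row sums to 1
    and, thanks to the Laplace pseudo-count, has no zero entries.
    """

    method: str
    table: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", t)
        if t.ndim != 2:
            raise SaxsmmError("likelihood table must be 2-D")
        if np.any(t <= 0):
            raise SaxsmmError("likelihood table has non-positive entries")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise SaxsmmError("likelihood rows must sum to 1")


def fit_likelihood(
    method: str,
    pairs: list[tuple[float, float]] | np.ndarray,
    bins: BinScheme,
) -> LikelihoodTable:
    """Learn ``P(truth | evidence)`` from (estimated, true) mass pairs (kDa).

    Pairs with an absent (NaN) estimate are skipped.  Counts get a Laplace
    pseudo-count of one in every cell before row normalization, so evidence
    bins never observed in training yield a uniform row.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise SaxsmmError("no training pairs")
    est, truth = arr[:, 0], arr[:, 1]
    ok = np.isfinite(est) & np.isfinite(truth) & (truth > 0)
    est, truth = est[ok], truth[ok]
    n = bins.n_bins
    counts = np.ones((n, n), dtype=float)  # Laplace pseudo-count everywhere
    if est.size:
        e_idx = np.asarray(bins.index_of(est))
        t_idx = np.asarray(bins.index_of(truth))
        np.add.at(counts, (e_idx, t_idx), 1.0)
    table = counts / counts.sum(axis=1, keepdims=True)
    return LikelihoodTable(method=method, table=table)


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior over mass bins with its MAP summary.

    map_mm: center of the highest-posterior bin (kDa); map_probability: that
    bin's posterior mass; (ci_low, ci_high): contiguous envelope of the 90%
    highest-density bin set, kDa.
    """

    posterior: np.ndarray
    map_mm: float
    map_probability: float
    ci_low: float
    ci_high: float
    ci_mass: float = 0.90


def credible_interval(
    post: np.ndarray, bins: BinScheme, mass: float = 0.90
) -> tuple[float, float]:
    """Envelope of the greedy highest-posterior-density set accumulating ``mass``.

    Bins are accumulated in decreasing posterior order (stable ties) until the
    requested probability mass is reached; the interval is the contiguous
    range from the smallest accumulated lower edge to the largest upper edge.
    """
    post = np.asarray(post, dtype=float)
    order = np.argsort(-post, kind="stable")
    csum = np.cumsum(post[order])
    n_take = int(np.searchsorted(csum, mass - 1e-12)) + 1
    taken = order[:n_take]
    return float(bins.edges[taken.min()]), float(bins.edges[taken.max() + 1])


def posterior(
    evidence: MMEvidence,
    tables: dict[str, LikelihoodTable],
    bins: BinScheme,
    prior: np.ndarray | None = None,
    ci_mass: float = 0.90,
) -> PosteriorResult:
    """Combine the available evidence into a posterior over mass bins.

    Absent (NaN) estimates contribute nothing; if all four are absent a
    :class:`NoEvidenceError` is raised.  The per-bin products are accumulated
    in log space to avoid underflow, then normalized.
    """
    n = bins.n_bins
    if prior is None:
        log_post = np.full(n, -np.log(n))
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.size != n or not np.isclose(prior.sum(), 1.0, atol=1e-6):
            raise SaxsmmError("prior must be a probability vector over the bins")
        with np.errstate(divide="ignore"):
            log_post = np.log(prior)
    n_used = 0
    for method in METHODS:
        value = getattr(evidence, method)
        if not np.isfinite(value):
            continue
        table = tables.get(method)
        if table is None:
            continue
        e_idx = int(bins.index_of(float(value)))
        log_post = log_post + np.log(table.table[e_idx])
        n_used += 1
    if n_used == 0:
        raise NoEvidenceError("no evidence: all mass estimates absent")
    log_post -= logsumexp(log_post)
    post = np.exp(log_post)
    post /= post.sum()
    map_idx = int(np.argmax(post))  # ties resolve to the lowest-mass bin
    ci_low, ci_high = credible_interval(post, bins, mass=ci_mass)
    return PosteriorResult(
        posterior=post,
        map_mm=float(bins.centers[map_idx]),
        map_probability=float(post[map_idx]),
        ci_low=ci_low,
        ci_high=ci_high,
        ci_mass=ci_mass,
    )


def forward_prior(previous: PosteriorResult, floor: float = 0.01) -> np.ndarray:
    """Turn a frame's posterior into the next frame's prior.

    For sequences of statistically independent frames (SEC-SAXS, successive
    short exposures) the posterior of frame n-1 primes frame n.  A small
    uniform admixture (``floor``) keeps every bin reachable so one bad frame
    cannot permanently zero out the true mass.
    """
    post = np.asarray(previous.posterior, dtype=float)
    n = post.size
    out = (1.0 - floor) * post + floor / n
    return out / out.sum()
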