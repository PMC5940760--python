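"""Binning, likelihood tables and the Bayesian combination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from saxsmm.bayes import (
    CLAMP_HIGH_KDA,
    CLAMP_LOW_KDA,
    BinScheme,
    LikelihoodTable,
    build_bins,
    credible_interval,
    fit_likelihood,
    forward_prior,
    posterior,
)
from saxsmm.estimators import MMEvidence
from saxsmm.exceptions import NoEvidenceError, SaxsmmError


@pytest.fixture(scope="module")
def lognormal_bins():
    rng = np.random.default_rng(0)
    masses = np.exp(rng.normal(np.log(40.0), 0.9, 5000))
    return build_bins(masses, n_bins=100), masses


def test_bins_tile_the_clamp_range(lognormal_bins):
    bins, _ = lognormal_bins
    assert bins.edges[0] == CLAMP_LOW_KDA
    assert bins.edges[-1] == CLAMP_HIGH_KDA
    assert np.all(np.diff(bins.edges) > 0)
    assert np.all((bins.centers > bins.edges[:-1]) & (bins.centers < bins.edges[1:]))


def test_central_bins_have_equal_counts(lognormal_bins):
    """Quantile binning puts an equal number of training masses in each central bin."""
    bins, masses = lognormal_bins
    idx = np.asarray(bins.index_of(masses))
    counts = np.bincount(idx, minlength=bins.n_bins)
    central = counts[5:95]
    assert central.max() - central.min() <= 2  # +-1 around the quantile count


def test_clamp_rule(lognormal_bins):
    """Masses below 0.7 kDa / above 1300 kDa fall in the first/last bin."""
    bins, _ = lognormal_bins
    assert bins.index_of(0.5) == 0
    assert bins.index_of(2000.0) == bins.n_bins - 1
    assert bins.index_of(CLAMP_LOW_KDA / 2) == 0


def test_bins_require_enough_masses():
    with pytest.raises(SaxsmmError):
        build_bins(np.full(100, 40.0))


def test_likelihood_identity_evidence_is_diagonal(lognormal_bins):
    bins, masses = lognormal_bins
    pairs = np.column_stack([masses[:2000], masses[:2000]])
    table = fit_likelihood("mm_ss", pairs, bins)
    idx = np.asarray(bins.index_of(masses[:2000]))
    for e_bin in np.unique(idx):
        assert np.argmax(table.table[e_bin]) == e_bin


def test_likelihood_unseen_evidence_bin_is_uniform(lognormal_bins):
    """A row fed only by pseudo-counts is exactly uniform."""
    bins, _ = lognormal_bins
    pairs = np.array([[40.0, 40.0]] * 1200)
    table = fit_likelihood("mm_qp", pairs, bins)
    empty_row = table.table[0]  # 40 kDa evidence never lands in bin 0
    np.testing.assert_allclose(empty_row, 1.0 / bins.n_bins, rtol=1e-12)


def test_likelihood_rows_normalized_and_positive(lognormal_bins):
    bins, masses = lognormal_bins
    rng = np.random.default_rng(1)
    pairs = np.column_stack([masses * rng.lognormal(0, 0.2, masses.size), masses])
    pairs[::17, 0] = np.nan  # absent estimates are skipped
    table = fit_likelihood("mm_vc", pairs, bins)
    np.testing.assert_allclose(table.table.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(table.table > 0)


def test_likelihood_empty_pairs_fail(lognormal_bins):
    bins, _ = lognormal_bins
    with pytest.raises(SaxsmmError):
        fit_likelihood("mm_qp", np.empty((0, 2)), bins)


# ---------------------------------------------------------------------------
# posterior


def toy_scheme():
    edges = np.array([0.7, 10.0, 20.0, 40.0, 80.0, 1300.0])
    return BinScheme(edges=edges, centers=np.sqrt(edges[:-1] * edges[1:]))


def near_one_hot(n, j, floor=1e-6):
    row = np.full(n, floor)
    row[j] = 1.0 - floor * (n - 1)
    return row


def test_uniform_tables_give_uniform_posterior():
    bins = toy_scheme()
    n = bins.n_bins
    tables = {
        m: LikelihoodTable(method=m, table=np.full((n, n), 1.0 / n))
        for m in ("mm_qp", "mm_mow", "mm_vc", "mm_ss")
    }
    ev = MMEvidence(mm_qp=30.0, mm_mow=30.0, mm_vc=30.0, mm_ss=30.0)
    res = posterior(ev, tables, bins)
    np.testing.assert_allclose(res.posterior, 1.0 / n, rtol=1e-12)
    assert res.map_mm == bins.centers[0]  # tie -> lowest-mass bin
    # uniform posterior must take at least ceil(0.9 n) bins
    taken = np.sum((bins.edges[:-1] >= res.ci_low) & (bins.edges[1:] <= res.ci_high))
    assert taken >= int(np.ceil(0.9 * n))


def test_point_mass_evidence_dominates():
    bins = toy_scheme()
    n = bins.n_bins
    table = np.vstack([near_one_hot(n, 2)] * n)
    tables = {"mm_ss": LikelihoodTable(method="mm_ss", table=table)}
    ev = MMEvidence(mm_ss=15.0)
    res = posterior(ev, tables, bins)
    assert res.map_mm == bins.centers[2]
    assert res.map_probability > 0.999
    assert (res.ci_low, res.ci_high) == (bins.edges[2], bins.edges[3])


def test_absent_methods_do_not_contribute():
    """NaN estimates are skipped; a lone method defines the posterior."""
    bins = toy_scheme()
    n = bins.n_bins
    rng = np.random.default_rng(5)
    raw = rng.random((n, n)) + 0.1
    tables = {
        "mm_qp": LikelihoodTable("mm_qp", raw / raw.sum(axis=1, keepdims=True)),
        "mm_ss": LikelihoodTable("mm_ss", np.full((n, n), 1.0 / n)),
    }
    only_qp = posterior(MMEvidence(mm_qp=30.0), tables, bins)
    qp_and_flat = posterior(MMEvidence(mm_qp=30.0, mm_ss=30.0), tables, bins)
    np.testing.assert_allclose(only_qp.posterior, qp_and_flat.posterior, atol=1e-12)
    with pytest.raises(NoEvidenceError):
        posterior(MMEvidence(), tables, bins)


def test_posterior_matches_brute_force_enumeration():
    """5-bin hand-built example: log-space result equals the direct product to 1e-12."""
    bins = toy_scheme()
    n = bins.n_bins
    rng = np.random.default_rng(7)
    tables = {}
    for m in ("mm_qp", "mm_mow", "mm_vc", "mm_ss"):
        raw = rng.random((n, n)) + 0.05
        tables[m] = LikelihoodTable(m, raw / raw.sum(axis=1, keepdims=True))
    prior = rng.random(n)
    prior /= prior.sum()
    ev = MMEvidence(mm_qp=12.0, mm_mow=25.0, mm_vc=55.0, mm_ss=33.0)
    res = posterior(ev, tables, bins, prior=prior)

    # independent oracle: plain-product enumeration over hypothesis bins
    expected = prior.copy()
    for m, value in (("mm_qp", 12.0), ("mm_mow", 25.0), ("mm_vc", 55.0), ("mm_ss", 33.0)):
        e_bin = int(bins.index_of(value))
        expected *= tables[m].table[e_bin]
    expected /= expected.sum()
    np.testing.assert_allclose(res.posterior, expected, atol=1e-12)
    assert res.map_mm == bins.centers[int(np.argmax(expected))]


def test_posterior_order_invariance():
    """The combination is a product: method order cannot matter."""
    bins = toy_scheme()
    n = bins.n_bins
    rng = np.random.default_rng(9)
    raws = {m: rng.random((n, n)) + 0.1 for m in ("mm_qp", "mm_mow", "mm_vc", "mm_ss")}
    tables_fwd = {m: LikelihoodTable(m, r / r.sum(axis=1, keepdims=True)) for m, r in raws.items()}
    tables_rev = dict(reversed(list(tables_fwd.items())))
    ev = MMEvidence(mm_qp=12.0, mm_mow=25.0, mm_vc=55.0, mm_ss=33.0)
    a = posterior(ev, tables_fwd, bins)
    b = posterior(ev, tables_rev, bins)
    np.testing.assert_allclose(a.posterior, b.posterior, atol=1e-15)


@given(seed=st.integers(min_value=0, max_value=10_000))
def test_posterior_always_normalized(seed):
    bins = toy_scheme()
    n = bins.n_bins
    rng = np.random.default_rng(seed)
    tables = {}
    for m in ("mm_qp", "mm_vc"):
        raw = rng.random((n, n)) + 1e-6
        tables[m] = LikelihoodTable(m, raw / raw.sum(axis=1, keepdims=True))
    ev = MMEvidence(mm_qp=float(rng.uniform(1, 1000)), mm_vc=float(rng.uniform(1, 1000)))
    res = posterior(ev, tables, bins)
    assert res.posterior.sum() == pytest.approx(1.0, abs=1e-9)
    assert res.ci_low <= res.map_mm <= res.ci_high


# ---------------------------------------------------------------------------
# credibility interval


def test_interval_uniform_posterior_covers_90_percent_of_bins():
    rng = np.random.default_rng(0)
    masses = np.exp(rng.normal(np.log(40.0), 0.9, 5000))
    bins = build_bins(masses, n_bins=100)
    lo, hi = credible_interval(np.full(100, 0.01), bins)
    taken = np.sum((bins.edges[:-1] >= lo) & (bins.edges[1:] <= hi))
    assert taken >= 90


def test_interval_contains_map_for_unimodal_posterior():
    bins = toy_scheme()
    post = np.array([0.05, 0.1, 0.5, 0.3, 0.05])
    lo, hi = credible_interval(post, bins)
    assert lo <= bins.centers[2] <= hi
    # greedy HPD: bins 2 and 3 already hold 0.8; adding bin 1 reaches 0.9
    assert (lo, hi) == (bins.edges[1], bins.edges[4])


# ---------------------------------------------------------------------------
# prior forwarding


def test_forwarding_uniform_posterior_is_identity():
    bins = toy_scheme()
    res = posterior(
        MMEvidence(mm_ss=30.0),
        {"mm_ss": LikelihoodTable("mm_ss", np.full((5, 5), 0.2))},
        bins,
    )
    np.testing.assert_allclose(forward_prior(res), 0.2, rtol=1e-12)


def test_forwarding_consistent_evidence_concentrates():
    """Re-feeding the same evidence with forwarded priors never loses MAP mass."""
    bins = toy_scheme()
    n = bins.n_bins
    table = np.vstack([np.array([0.05, 0.1, 0.6, 0.2, 0.05])] * n)
    tables = {"mm_ss": LikelihoodTable("mm_ss", table)}
    ev = MMEvidence(mm_ss=30.0)
    prior = None
    last_mass = 0.0
    for _ in range(5):
        res = posterior(ev, tables, bins, prior=prior)
        assert res.posterior[2] >= last_mass - 1e-12
        last_mass = res.posterior[2]
        prior = forward_prior(res)
    assert last_mass > 0.9
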