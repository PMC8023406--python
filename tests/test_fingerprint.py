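import numpy as np
import pytest
from scipy.stats import binomtest, kendalltau

from cytomon import (
    compute_fingerprint,
    diversity_timeseries,
    diversity_with_bootstrap,
    hill_diversity,
    rescale_channels,
    transform_events,
)
from cytomon.fcs_io import MeasurementSeries
from cytomon.fingerprint import LOG_FULL_SCALE, InsufficientEventsError

from conftest import cluster_table, make_table

PROK_A = (4.3, 3.9, 4.9, 1.8)
PROK_B = (4.1, 3.7, 4.5, 2.4)
PROK_C = (4.5, 4.1, 5.2, 2.1)


def log_table(rng, n=500):
    return transform_events(make_table(rng.uniform(1, 1e6, (n, 5))))


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

def test_rescale_endpoints(rng):
    events = np.zeros((2, 5))
    events[1] = LOG_FULL_SCALE
    table = make_table(np.ones((2, 5))).with_events(events, log_transformed=True)
    mat = rescale_channels(table)
    np.testing.assert_allclose(mat[0], 0.0)
    np.testing.assert_allclose(mat[1], 1.0)


def test_rescale_round_trip(rng):
    table = log_table(rng)
    mat = rescale_channels(table, ["FL1-A", "FL3-A", "FSC-A", "SSC-A"])
    back = mat * LOG_FULL_SCALE
    for j, c in enumerate(["FL1-A", "FL3-A", "FSC-A", "SSC-A"]):
        np.testing.assert_allclose(back[:, j], table.channel(c), atol=1e-12)


def test_rescale_requires_log_space(rng):
    with pytest.raises(ValueError, match="log-transformed"):
        rescale_channels(make_table(rng.uniform(1, 10, (5, 5))))


# ---------------------------------------------------------------------------
# fingerprint contract
# ---------------------------------------------------------------------------

def test_fingerprint_normalization_and_length(rng):
    fp = compute_fingerprint(log_table(rng), nbin=32)
    assert fp.values.size == 6 * 32**2
    assert fp.values.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(fp.values >= 0)


def test_fingerprint_per_pair_normalization(rng):
    fp = compute_fingerprint(log_table(rng), nbin=32, normalize="per_pair")
    per_grid = fp.values.reshape(6, -1).sum(axis=1)
    np.testing.assert_allclose(per_grid, 1 / 6, atol=1e-12)


def test_fingerprint_deterministic_under_seed(rng):
    table = log_table(rng, n=800)
    a = compute_fingerprint(table, nbin=32, subsample_n=400, seed=7)
    b = compute_fingerprint(table, nbin=32, subsample_n=400, seed=7)
    np.testing.assert_array_equal(a.values, b.values)


def test_fingerprint_delta_input_concentrates_mass():
    # all events at one point: each of the 6 pair grids holds ~1/6 of the
    # mass in the cells around that point
    events = np.full((50, 5), 3.6)  # log10 units
    table = make_table(np.ones((50, 5))).with_events(events, log_transformed=True)
    fp = compute_fingerprint(table, nbin=32, bandwidth=0.01)
    grids = fp.values.reshape(6, 32, 32)
    per_grid = grids.sum(axis=(1, 2))
    np.testing.assert_allclose(per_grid, 1 / 6, atol=1e-3)
    for g in grids:
        peak = np.unravel_index(np.argmax(g), g.shape)
        window = g[
            max(peak[0] - 3, 0) : peak[0] + 4, max(peak[1] - 3, 0) : peak[1] + 4
        ]
        assert window.sum() >= 0.95 / 6


def test_fingerprint_insufficient_events(rng):
    table = log_table(rng, n=1)
    with pytest.raises(InsufficientEventsError):
        compute_fingerprint(table, nbin=16)


# ---------------------------------------------------------------------------
# Hill diversity
# ---------------------------------------------------------------------------

def brute_force_hill(p, q):
    p = np.asarray(p, float)
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def test_hill_identities():
    point = np.zeros(100)
    point[0] = 1.0
    assert hill_diversity(point, q=2) == pytest.approx(1.0)
    uniform = np.full(128**2, 1.0 / 128**2)
    assert hill_diversity(uniform, q=2) == pytest.approx(16_384.0)
    assert hill_diversity(np.array([0.5, 0.25, 0.25]), q=2) == pytest.approx(
        1 / 0.375, abs=1e-9
    )


def test_hill_matches_brute_force_on_random_vectors(rng):
    for _ in range(200):
        n = rng.integers(2, 10_000)
        p = rng.dirichlet(np.full(min(n, 200), rng.uniform(0.2, 3.0)))
        for q in (0.0, 0.5, 2.0, 3.0):
            assert hill_diversity(p, q=q) == pytest.approx(
                brute_force_hill(p, q), rel=1e-9
            )


def test_hill_q1_limit_equals_exp_shannon(rng):
    for _ in range(50):
        p = rng.dirichlet(np.ones(64))
        exact = hill_diversity(p, q=1.0)
        assert exact == pytest.approx(np.exp(-np.sum(p * np.log(p))), rel=1e-9)
        # numeric limit from both sides
        assert hill_diversity(p, q=1 + 1e-7) == pytest.approx(exact, rel=1e-4)
        assert hill_diversity(p, q=1 - 1e-7) == pytest.approx(exact, rel=1e-4)


def test_hill_permutation_invariance_and_bounds(rng):
    p = rng.dirichlet(np.ones(50))
    d = hill_diversity(p, q=2)
    assert hill_diversity(rng.permutation(p), q=2) == pytest.approx(d, rel=1e-12)
    assert 1.0 <= d <= np.count_nonzero(p)


def test_hill_schur_concavity_spot_checks(rng):
    # moving mass from a poorer to a richer cell must decrease D2
    for _ in range(50):
        p = rng.dirichlet(np.ones(rng.integers(3, 11)))
        i, j = np.argmin(p), np.argmax(p)
        eps = p[i] * 0.5
        q = p.copy()
        q[i] -= eps
        q[j] += eps
        assert hill_diversity(q, q=2) < hill_diversity(p, q=2)


def test_hill_rejects_unnormalized_input():
    with pytest.raises(ValueError, match="normalized"):
        hill_diversity(np.array([0.5, 0.6]), q=2)


# ---------------------------------------------------------------------------
# bootstrap diversity
# ---------------------------------------------------------------------------

def test_bootstrap_single_resample_has_zero_sd(rng):
    table = log_table(rng)
    res = diversity_with_bootstrap(table, n_boot=1, nbin=32, seed=3)
    assert res.d2_sd == 0.0
    assert res.n_boot == 1


def test_bootstrap_deterministic_under_seed(rng):
    table = log_table(rng)
    a = diversity_with_bootstrap(table, n_boot=3, nbin=32, seed=11)
    b = diversity_with_bootstrap(table, n_boot=3, nbin=32, seed=11)
    assert (a.d2_mean, a.d2_sd) == (b.d2_mean, b.d2_sd)
    c = diversity_with_bootstrap(table, n_boot=3, nbin=32, seed=12)
    assert abs(c.d2_mean - a.d2_mean) < 5 * max(a.d2_sd, 1.0)


def test_even_community_more_diverse_than_skewed():
    # 50:50 two-cluster community vs 95:5 of the same clusters,
    # 20 seeded replicate pairs, one-sided sign test
    wins = 0
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        even = transform_events(cluster_table(rng, [PROK_A, PROK_B], [0.5, 0.5]))
        skew = transform_events(cluster_table(rng, [PROK_A, PROK_B], [0.95, 0.05]))
        d_even = diversity_with_bootstrap(even, nbin=64, seed=rep).d2_mean
        d_skew = diversity_with_bootstrap(skew, nbin=64, seed=rep).d2_mean
        wins += d_even > d_skew
    assert binomtest(wins, 20, 0.5, alternative="greater").pvalue < 0.05


def test_diversity_timeseries_flat_and_succession():
    rng = np.random.default_rng(77)
    t0 = __import__("datetime").datetime(2024, 1, 1)

    def tab(weights, minutes):
        t = cluster_table(rng, [PROK_A, PROK_B, PROK_C], weights)
        t.timestamp = t0 + __import__("datetime").timedelta(minutes=minutes)
        return t

    flat = MeasurementSeries(
        samples=[tab([1, 1, 1], 25 * i) for i in range(10)], t0=t0
    )
    res = diversity_timeseries(flat, gate=None, nbin=64, seed=5, transform=transform_events)
    d2 = np.array([r.d2_mean for r in res])
    spread = np.mean([r.d2_sd for r in res])
    assert d2.std() < 4 * max(spread, 1.0)  # flat within bootstrap error

    weights = np.linspace([0.9, 0.05, 0.05], [1 / 3, 1 / 3, 1 / 3], 10)
    succession = MeasurementSeries(
        samples=[tab(w, 25 * i) for i, w in enumerate(weights)], t0=t0
    )
    res = diversity_timeseries(
        succession, gate=None, nbin=64, seed=5, transform=transform_events
    )
    tau, p = kendalltau(np.arange(10), [r.d2_mean for r in res])
    assert tau > 0 and p < 0.05
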