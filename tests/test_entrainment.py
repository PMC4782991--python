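"""Transfer-entropy estimators, cross-entropy distance, and dyad patterns."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import simpson as scipy_simpson

from emotrain.entrainment import (
    TEConfig, InsufficientDataError, transfer_entropy, etr, simpson_estimate,
    cross_entropy_distance, estimate_distribution, mean_pairwise_ce, en_dis,
    classify_dyad, build_network, DUAL, SINGLE, NONE,
)
from emotrain.experiments import brute_force_transfer_entropy
from emotrain.series import EmotionSeries


class TestTransferEntropy:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_matches_bruteforce_on_random_pairs(self, rng, order):
        """Vectorized plug-in TE equals explicit count-table computation."""
        cfg = TEConfig(order_m=order, order_n=order, min_samples=1)
        for _ in range(40):
            length = int(rng.integers(8 * order, 51))
            x = rng.integers(-1, 2, size=length).astype(float)
            y = rng.integers(-1, 2, size=length).astype(float)
            assert transfer_entropy(x, y, cfg) == pytest.approx(
                max(brute_force_transfer_entropy(x, y, order, order), 0.0), abs=1e-12
            )

    def test_missing_bins_are_excluded_not_imputed(self, rng):
        """NaN bins drop the affected windows only, matching the reference."""
        cfg = TEConfig(order_m=2, order_n=2, min_samples=1)
        x = rng.integers(-1, 2, size=60).astype(float)
        y = rng.integers(-1, 2, size=60).astype(float)
        x[[5, 17, 40]] = np.nan
        y[[6, 30]] = np.nan
        assert transfer_entropy(x, y, cfg) == pytest.approx(
            max(brute_force_transfer_entropy(x, y, 2, 2), 0.0), abs=1e-12
        )

    def test_lag1_copy_of_uniform_source_gives_log2_3(self, rng):
        """Deterministic lag-1 copying of an iid uniform ternary source
        carries log2(3) bits at orders m = n = 1."""
        n = 50_000
        src = rng.integers(-1, 2, size=n).astype(float)
        tgt = np.concatenate([[0.0], src[:-1]])
        te = transfer_entropy(tgt, src, TEConfig(order_m=1, order_n=1))
        assert te == pytest.approx(np.log2(3), abs=0.02)

    def test_alphabet_permutation_invariance(self, rng):
        """Relabeling the state alphabet by a bijection leaves TE unchanged."""
        cfg = TEConfig(min_samples=1)
        x = rng.integers(-1, 2, size=200).astype(float)
        y = rng.integers(-1, 2, size=200).astype(float)
        base = transfer_entropy(x, y, cfg)
        perm = {-1.0: 1.0, 0.0: -1.0, 1.0: 0.0}
        xp = np.vectorize(perm.get)(x)
        yp = np.vectorize(perm.get)(y)
        assert transfer_entropy(xp, yp, cfg) == pytest.approx(base, abs=1e-12)

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            transfer_entropy(np.zeros(10), np.zeros(10), TEConfig(min_samples=30))

    def test_alphabet_violation_raises(self):
        with pytest.raises(ValueError):
            transfer_entropy(np.array([0.0, 2.0, 1.0] * 20), np.zeros(60),
                             TEConfig(min_samples=1))

    def test_etr_direction_convention(self, coupled_dyad):
        """Etr(i -> j) = TE(j -> i): the follower of a planted coupling shows
        the larger adopter-side strength."""
        source, follower = coupled_dyad.series[0], coupled_dyad.series[1]
        assert etr(follower, source) > etr(source, follower)
        assert etr(follower, source) == pytest.approx(
            transfer_entropy(follower.states, source.states), abs=1e-15
        )

    def test_simpson_estimator_close_to_plugin(self, coupled_dyad):
        """The quadrature-smoothed estimator tracks the plug-in estimate."""
        follower, source = coupled_dyad.series[1], coupled_dyad.series[0]
        plug = transfer_entropy(follower, source, TEConfig())
        smooth = transfer_entropy(follower, source,
                                  TEConfig(estimator="simpson", simpson_grid_n=512))
        assert smooth >= 0.0
        assert smooth == pytest.approx(plug, rel=0.05)


class TestSimpsonQuadrature:
    def test_constant_integrand(self):
        assert simpson_estimate(np.full(11, 3.25), (0, 1), 10) == pytest.approx(3.25)

    @pytest.mark.parametrize("grid_n", [2, 4, 6, 10, 20, 50])
    def test_exact_for_cubics(self, grid_n):
        """Composite Simpson integrates x^3 on [0, 2] to exactly 4."""
        xs = np.linspace(0.0, 2.0, grid_n + 1)
        assert simpson_estimate(xs**3, (0.0, 2.0), grid_n) == pytest.approx(4.0, abs=1e-12)

    def test_exp_meets_classical_error_bound(self):
        """|estimate - (e - 1)| <= (b-a) h^4 / 180 * max|f''''| for e^x."""
        grid_n = 10
        xs = np.linspace(0.0, 1.0, grid_n + 1)
        est = simpson_estimate(np.exp(xs), (0.0, 1.0), grid_n)
        bound = 1.0 * (1.0 / grid_n) ** 4 / 180.0 * np.e
        assert abs(est - (np.e - 1.0)) <= bound

    @given(st.integers(2, 40).map(lambda k: 2 * k),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_agrees_with_scipy_on_polynomials(self, grid_n, coeffs):
        """Matches scipy's composite Simpson on arbitrary quartics."""
        xs = np.linspace(-1.0, 2.0, grid_n + 1)
        ys = np.polyval(coeffs, xs)
        ours = simpson_estimate(ys, (-1.0, 2.0), grid_n)
        ref = scipy_simpson(ys, x=xs)
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-9)

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError):
            simpson_estimate(np.zeros(4), (0, 1), 3)


class TestCrossEntropy:
    def test_identity_is_entropy(self):
        """CE(p, p) = H(p); log2(3) bits for the uniform distribution."""
        u = np.full(3, 1 / 3)
        assert cross_entropy_distance(u, u) == pytest.approx(np.log2(3))

    def test_hand_value(self):
        assert cross_entropy_distance((1, 0, 0), (0.5, 0.25, 0.25)) == pytest.approx(1.0)

    @given(st.lists(st.floats(0.01, 1), min_size=3, max_size=3),
           st.lists(st.floats(0.01, 1), min_size=3, max_size=3))
    def test_gibbs_inequality(self, a, b):
        """CE(p, q) >= H(p), equality iff p = q."""
        p = np.array(a) / np.sum(a)
        q = np.array(b) / np.sum(b)
        assert cross_entropy_distance(p, q) >= cross_entropy_distance(p, p) - 1e-12

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_distance((0.5, 0.5, 0.5), (1, 0, 0))

    def test_mean_pairwise_ce_matches_hand_computation(self):
        """Three users with hand-set windows: average over the 6 ordered
        pairs divided by N^2."""
        series = {
            "a": EmotionSeries("a", [1, 1, 1, 0]),
            "b": EmotionSeries("b", [-1, -1, 0, 0]),
            "c": EmotionSeries("c", [1, 0, -1, 0]),
        }
        dists = {u: estimate_distribution(s) for u, s in series.items()}
        expected = sum(
            cross_entropy_distance(dists[i], dists[j])
            for i in series for j in series if i != j
        ) / 9.0
        assert mean_pairwise_ce(series) == pytest.approx(expected, abs=1e-12)

    def test_homogeneous_community_value(self):
        """Identical users: <CE>_t = H(p) (N^2 - N) / N^2 under the printed
        normalizer."""
        s = EmotionSeries("u", [1, 0, -1] * 40)
        series = {k: s for k in range(4)}
        p = estimate_distribution(s)
        h = cross_entropy_distance(p, p)
        assert mean_pairwise_ce(series) == pytest.approx(h * 12 / 16, abs=1e-12)


class TestDyadPatterns:
    def test_en_dis_examples(self):
        assert en_dis(0.4, 0.4) == 0.0
        assert en_dis(0.0, 0.7) == 1.0
        assert en_dis(0.3, 0.1) == pytest.approx(2 / 3, abs=1e-4)
        assert np.isnan(en_dis(0.0, 0.0))

    @given(st.floats(0, 5), st.floats(0, 5))
    def test_en_dis_bounds_and_symmetry(self, a, b):
        if max(a, b) == 0:
            return
        d = en_dis(a, b)
        assert 0.0 <= d <= 1.0
        assert d == en_dis(b, a)

    def test_classification_boundary_inclusive(self):
        """Strengths exactly at theta count as entrained (>= as printed)."""
        theta = 0.2
        assert classify_dyad(theta, theta, theta) == DUAL
        # numpy scalars must classify identically to python floats
        assert classify_dyad(np.float64(theta), np.float64(theta),
                             np.float64(theta)) == DUAL
        assert classify_dyad(theta, theta - 1e-9, theta) == SINGLE
        assert classify_dyad(theta - 1e-9, theta - 1e-9, theta) == NONE

    def test_two_user_network(self, coupled_dyad):
        """Smallest network: two directed edges, theta is their mean."""
        net = build_network(coupled_dyad.series)
        assert len(net.strengths) == 2
        assert net.theta_t == pytest.approx(np.mean(list(net.strengths.values())))
        dyad = net.dyads[frozenset((0, 1))]
        assert dyad.pattern in (DUAL, SINGLE, NONE)
        assert dyad.etr_ij >= 0 and dyad.etr_ji >= 0

    def test_network_counts_all_ordered_pairs(self, small_community):
        net = build_network(small_community.series)
        n = len(small_community.series)
        assert len(net.strengths) + len(net.excluded) == n * (n - 1)
        assert len(net.dyads) <= n * (n - 1) // 2

    def test_insufficient_pairs_reported_not_dropped(self):
        """A user that is mostly missing shows up in `excluded`."""
        rng = np.random.default_rng(0)
        full_a = EmotionSeries(0, rng.integers(-1, 2, 200).astype(float))
        full_b = EmotionSeries(1, rng.integers(-1, 2, 200).astype(float))
        sparse_states = np.full(200, np.nan)
        sparse_states[:10] = rng.integers(-1, 2, 10)
        sparse = EmotionSeries(2, sparse_states)
        net = build_network({0: full_a, 1: full_b, 2: sparse})
        assert len(net.strengths) == 2  # only the full-full pair survives
        assert len(net.excluded) == 4  # every direction touching the sparse user
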