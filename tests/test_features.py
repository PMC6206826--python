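import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimod import (
    LogisticParams,
    UsageError,
    compute_features,
    connection_strength,
    logistic_transform,
    normalize_layers,
    participation_coefficient,
)
from conftest import make_mn


def edge_mn(weights):
    """M layers over 3 nodes with a single edge (0,1) carrying the given weights."""
    layers = []
    for w in weights:
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = w
        layers.append(m)
    return make_mn(layers)


class TestConnectionStrength:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((0.2, 0.4), 0.3),           # arithmetic mean
            ((0.0, 0.0), 0.0),           # absent everywhere
            ((1.0, 1.0, 1.0), 1.0),      # upper bound
        ],
    )
    def test_average_weight(self, weights, expected):
        s = connection_strength(edge_mn(weights))
        assert s[0, 1] == pytest.approx(expected, abs=1e-15)
        assert s[1, 0] == s[0, 1]
        assert np.all(np.diag(s) == 0)


class TestParticipationCoefficient:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            ((0.01,) * 30, 1.0),          # uniform across all layers
            ((0.0, 0.0), 0.0),            # in no layer
            ((0.5, 0.0), 0.0),            # confined to one layer
            ((0.3, 0.3), 1.0),            # perfectly uniform, M=2
        ],
    )
    def test_printed_cases(self, weights, expected):
        p = participation_coefficient(edge_mn(weights))
        assert p[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_single_layer_rejected(self):
        mn = edge_mn((0.5, 0.5))
        mn.layers = mn.layers[:1]
        mn.layer_names = mn.layer_names[:1]
        with pytest.raises(UsageError):
            participation_coefficient(mn)

    def test_unweighted_closed_form(self):
        """For 0/1 layers, participation depends only on the number m of
        layers carrying the edge: (M/(M-1)) * (1 - 1/m)."""
        M = 7
        for m in range(1, M + 1):
            weights = [1.0] * m + [0.0] * (M - m)
            p = participation_coefficient(edge_mn(weights))
            assert p[0, 1] == pytest.approx(M / (M - 1) * (1 - 1 / m), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.one_of(st.just(0.0), st.floats(0.01, 1.0)), min_size=2, max_size=10))
    def test_extremes_iff_uniform_or_confined(self, weights):
        """p = 1 iff identical positive weight everywhere; p = 0 iff the edge
        is in at most one layer (brute force over random weight vectors)."""
        p = participation_coefficient(edge_mn(weights))[0, 1]
        positive = [w for w in weights if w > 0]
        M = len(weights)
        if positive and len(set(positive)) == 1 and len(positive) == M:
            assert p == pytest.approx(1.0, abs=1e-9)
        elif len(positive) <= 1:
            assert p == pytest.approx(0.0, abs=1e-12)
        else:
            assert 0 < p < 1 + 1e-12

    def test_matches_scalar_oracle(self, rng):
        """Vectorized features match a double-loop scalar evaluation."""
        layers = []
        for _ in range(4):
            a = rng.random((5, 5)) * (rng.random((5, 5)) < 0.6)
            layers.append(np.triu(a, 1) + np.triu(a, 1).T)
        mn = make_mn(layers)
        p = participation_coefficient(mn)
        s = connection_strength(mn)
        M = len(layers)
        for i in range(5):
            for j in range(5):
                o = sum(w[i, j] for w in layers)
                assert s[i, j] == pytest.approx(o / M, abs=1e-10)
                if o == 0:
                    expected = 0.0
                else:
                    expected = M / (M - 1) * (1 - sum((w[i, j] / o) ** 2 for w in layers))
                assert p[i, j] == pytest.approx(expected, abs=1e-10)

    def test_permutation_equivariance(self, rng):
        layers = []
        for _ in range(3):
            a = rng.random((6, 6))
            layers.append(np.triu(a, 1) + np.triu(a, 1).T)
        mn = make_mn(layers)
        perm = rng.permutation(6)
        mn_p = make_mn([w[np.ix_(perm, perm)] for w in layers])
        for fn in (connection_strength, participation_coefficient):
            np.testing.assert_allclose(fn(mn)[np.ix_(perm, perm)], fn(mn_p), atol=1e-12)


class TestLogisticTransform:
    def test_calibration_at_zero(self):
        """L(0) = 0.0001 exactly with d = log(9999), c = -2 log(9999)."""
        params = LogisticParams()
        assert params(0.0) == pytest.approx(1e-4, abs=1e-12)
        assert params.d == pytest.approx(math.log(9999.0))
        assert params.c == pytest.approx(-2 * math.log(9999.0))

    def test_midpoint_and_upper_end(self):
        params = LogisticParams()
        assert params(0.5) == pytest.approx(0.5, abs=1e-12)
        assert params(1.0) == pytest.approx(1 / (1 + 1 / 9999), abs=1e-12)

    def test_inconsistent_params_rejected(self):
        with pytest.raises(UsageError):
            LogisticParams(c=-1.0, d=0.0, zero_value=1e-4)
        with pytest.raises(UsageError):
            LogisticParams(c=1.0)  # decreasing logistic

    def test_structural_zeros_stay_zero(self):
        mn = edge_mn((0.5, 0.0))
        out = logistic_transform(mn)
        assert out.layers[0][0, 1] == pytest.approx(0.5)
        assert out.layers[1][0, 1] == 0.0          # absent edge not densified
        assert out.layers[0][0, 2] == 0.0

    def test_low_weights_squash_near_zero(self):
        # the lower logistic arm: weights in [0, 0.3] map close to 0
        params = LogisticParams()
        assert 1e-4 <= params(0.05) < 3e-4
        assert params(0.3) < 0.03
        # truncation below L(0) keeps the transform anchored: exactly L(0) at 0
        mn = edge_mn((0.05, 0.05))
        out = logistic_transform(mn)
        assert 0 < out.layers[0][0, 1] < 3e-4


class TestComputeFeatures:
    def test_unweighted_two_layer_hand_case(self, two_layer_shared_edge):
        """Shared edge: strength 1, participation 1; layer-1-only edge:
        strength 0.5, participation 0."""
        fp = compute_features(two_layer_shared_edge)
        assert fp.strength[0, 1] == 1.0
        assert fp.participation[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert fp.strength[2, 3] == 0.5
        assert fp.participation[2, 3] == 0.0

    def test_all_zero_layers(self):
        mn = make_mn([np.zeros((4, 4)), np.zeros((4, 4))])
        fp = compute_features(mn)
        assert np.all(fp.strength == 0) and np.all(fp.participation == 0)

    def test_near_binary_weighted_strength_tracks_presence(self, rng):
        """Present weights >= 0.95 of the max squash to ~1, so the logistic
        strength approximates the presence fraction; and L(w) > 0.97 for
        w >= 0.7."""
        params = LogisticParams()
        assert params(0.7) > 0.97
        M, n = 6, 8
        layers = []
        for _ in range(M):
            present = rng.random((n, n)) < 0.5
            w = np.where(present, rng.uniform(0.95, 1.0, (n, n)), 0.0)
            layers.append(np.triu(w, 1) + np.triu(w, 1).T)
        mn = make_mn(layers)
        fp = compute_features(mn, apply_logistic=True)
        presence_frac = np.mean([w > 0 for w in layers], axis=0)
        np.testing.assert_allclose(fp.strength, presence_frac, atol=0.01)

    def test_weighted_autodetect_applies_logistic(self):
        # in layer 0 the edge (0,1) carries 0.05 of the layer max, which
        # squashes below the cutoff -> only layer 1 contributes to that edge
        l0 = np.zeros((3, 3))
        l0[0, 1] = l0[1, 0] = 0.05
        l0[0, 2] = l0[2, 0] = 1.0
        l1 = np.zeros((3, 3))
        l1[0, 1] = l1[1, 0] = 1.0
        l1[0, 2] = l1[2, 0] = 1.0
        fp = compute_features(make_mn([l0, l1]))
        # near-zero (the weak edge contributes ~2.5e-4 weight vs ~1 in layer 1)
        assert fp.participation[0, 1] < 0.01
        assert fp.participation[0, 2] == pytest.approx(1.0, abs=1e-12)

    def test_global_normalization_option(self):
        layers = []
        for w in (0.5, 1.0):
            m = np.zeros((3, 3))
            m[0, 1] = m[1, 0] = w
            layers.append(m)
        mn = make_mn(layers)
        per_layer = compute_features(mn, apply_logistic=True, per_layer_norm=True)
        global_ = compute_features(mn, apply_logistic=True, per_layer_norm=False)
        # per-layer: both layers normalize to weight 1 -> identical; global: differ
        assert per_layer.participation[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert global_.participation[0, 1] < 1.0


def test_normalize_layers_preserves_zeros_and_order(rng):
    a = rng.random((5, 5)) * 3
    w = np.triu(a, 1) + np.triu(a, 1).T
    mn = make_mn([w, 2 * w])
    out = normalize_layers(mn)
    for layer in out.layers:
        assert layer.max() == pytest.approx(1.0)
        assert np.all((layer == 0) == (w == 0))
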