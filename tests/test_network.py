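"""Structure, constraints and forward-pass semantics of the network."""

import math

import numpy as np
import pytest

from tfnn import fuzzy_core as fc
from tfnn import network as net


def naive_forward(X, state):
    """Independent per-sample loop over the documented closed forms."""
    w = net.constrain_weights(state)
    A, M, W = w["A"], w["M"], w["W"]
    bp = w["breakpoints"]
    e_enc, e_rule, e_inf = w["eps"]
    H, D, K = A.shape
    C = W.shape[1]

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    def mem(x, i, d):
        s = fc.TAU * e_enc
        if d == 0:
            return min(1.0, sig((bp[i, 0] - x) / s) / sig(bp[i, 0] / s))
        if d == D - 1:
            return min(1.0, sig((x - bp[i, -1]) / s) / sig((1 - bp[i, -1]) / s))
        half = (bp[i, d] - bp[i, d - 1]) / 2
        peak = sig(half / s) ** 2
        return min(1.0, sig((x - bp[i, d - 1]) / s) * sig((bp[i, d] - x) / s) / peak)

    def co(values, weights, eps):
        terms = [(wi * vi) ** (1 / eps) for wi, vi in zip(weights, values) if wi * vi > 0]
        return sum(terms) ** eps if terms else 0.0

    def tn(values, weights, eps):
        if not any(wi > 0 for wi in weights):
            return 1.0
        s = sum(wi * (-math.log(max(vi, 1e-12)) + 1e-12) ** (1 / eps)
                for wi, vi in zip(weights, values))
        return math.exp(-(s ** eps))

    out = np.zeros((X.shape[0], C))
    for n_i, row in enumerate(X):
        a = np.zeros((H, K))
        for i in range(H):
            mus = [mem(row[i], i, d) for d in range(D)]
            for k in range(K):
                a[i, k] = min(1.0, co(mus, A[i, :, k], e_enc))
        r = [tn(a[:, k], M[:, k], e_rule) for k in range(K)]
        for c in range(C):
            out[n_i, c] = co(r, W[:, c], e_inf)
    return out


class TestInit:
    def test_same_seed_bit_identical(self):
        a = net.init_model(5, 3, 4, 2, seed=3)
        b = net.init_model(5, 3, 4, 2, seed=3)
        for k, v in a.parameter_blocks().items():
            assert np.array_equal(v, b.parameter_blocks()[k])

    @pytest.mark.parametrize("H,D,K,C", [(18, 3, 30, 2), (4, 2, 5, 3)])
    def test_shapes(self, H, D, K, C):
        s = net.init_model(H, D, K, C, seed=0)
        assert s.raw_attention.shape == (H, D, K)
        assert s.raw_connection.shape == (H, K)
        assert s.raw_inference.shape == (K, C)
        assert s.raw_gaps.shape == (H, D)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            net.init_model(0, 3, 2, 2, seed=0)
        with pytest.raises(ValueError):
            net.init_model(3, 1, 2, 2, seed=0)

    def test_initial_constrained_weights_not_dead(self, small_state):
        w = net.constrain_weights(small_state)
        assert w["A"].min() > 0.05 and w["A"].max() < 0.6
        assert w["M"].min() > 0.05


class TestConstraints:
    def test_tanh_mapping(self):
        s = net.init_model(2, 3, 2, 2, seed=0)
        s.raw_attention[:] = 0.0
        s.raw_attention[0, 0, 0] = 0.5
        s.raw_attention[0, 1, 0] = -40.0
        w = net.constrain_weights(s)
        assert w["A"][0, 0, 0] == pytest.approx(abs(np.tanh(0.5)), abs=1e-12)
        assert w["A"][0, 1, 0] == pytest.approx(1.0, abs=1e-12)
        assert w["A"][1, 0, 0] == 0.0

    def test_ranges_on_random_states(self, rng):
        for seed in range(5):
            s = net.init_model(4, 3, 3, 2, seed=seed)
            s.raw_attention += rng.normal(0, 3, s.raw_attention.shape)
            w = net.constrain_weights(s)
            assert (w["A"] >= 0).all() and (w["A"] < 1).all()
            assert (w["M"] >= 0).all() and (w["M"] < 1).all()
            assert (w["W"] >= 0).all()
            bp = w["breakpoints"]
            assert (bp > 0).all() and (bp < 1).all()
            assert (np.diff(bp, axis=1) > 0).all()
            assert ((fc.EPS_MIN < w["eps"]) & (w["eps"] <= 1)).all()


class TestForward:
    def test_activation_ranges(self, rng):
        s = net.init_model(6, 3, 5, 2, seed=1)
        X = rng.uniform(0, 1, (50, 6))
        t = net.forward(X, s)
        assert (t.encoding >= 0).all() and (t.encoding <= 1).all()
        assert (t.concept_activation >= 0).all() and (t.concept_activation <= 1).all()
        assert (t.rule_activation > 0).all() and (t.rule_activation <= 1).all()
        assert (t.class_score >= 0).all()
        assert np.allclose(t.probabilities.sum(axis=1), 1.0)

    def test_matches_naive_loop(self, rng):
        for seed in range(3):
            s = net.init_model(3, 3, 2, 2, seed=seed)
            X = rng.uniform(0, 1, (7, 3))
            got = net.forward(X, s).class_score
            ref = naive_forward(X, s)
            assert np.allclose(got, ref, atol=1e-10)

    def test_empty_rule_gives_identity_activation(self, rng):
        s = net.init_model(3, 3, 2, 2, seed=0)
        s.raw_connection[:, 1] = 0.0  # rule 1 has no connected variables
        t = net.forward(rng.uniform(0, 1, (4, 3)), s)
        assert np.allclose(t.rule_activation[:, 1], 1.0)

    def test_hand_set_single_rule_model(self):
        """K=1, one variable, attention only on 'high', full connection:
        o_1 must equal the high membership; o_2 = 0."""
        s = net.init_model(1, 3, 1, 2, seed=0)
        s.raw_eps[:] = fc.raw_from_eps(1.0)
        s.raw_attention[0, :, 0] = [0.0, 0.0, 40.0]   # |tanh| -> (0,0,~1)
        s.raw_connection[0, 0] = 40.0
        s.raw_inference[0] = [20.0, -40.0]            # softplus -> (20, ~0)
        x = np.array([[0.8]])
        t = net.forward(x, s)
        mu_high = net.forward(x, s).encoding[0, 0, 2]
        # o_1 = W * r = 20 * mu_high with eps=1 (sum/product regime)
        assert t.class_score[0, 0] == pytest.approx(20 * mu_high, rel=1e-6)
        assert t.class_score[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_tropical_inference_is_max_of_rules(self, rng):
        s = net.init_model(3, 3, 2, 2, seed=2)
        s.raw_eps[2] = fc.raw_from_eps(fc.EPS_MIN + 1e-9)
        s.raw_inference[:, 0] = np.log(np.e - 1)  # softplus -> exactly 1
        t = net.forward(rng.uniform(0, 1, (10, 3)), s)
        assert np.allclose(t.class_score[:, 0], t.rule_activation.max(axis=1), atol=1e-3)

    def test_rule_permutation_equivariance(self, rng):
        s = net.init_model(4, 3, 3, 2, seed=5)
        X = rng.uniform(0, 1, (6, 4))
        base = net.forward(X, s).class_score
        perm = [2, 0, 1]
        s2 = net.init_model(4, 3, 3, 2, seed=5)
        s2.raw_attention = s.raw_attention[:, :, perm]
        s2.raw_connection = s.raw_connection[:, perm]
        s2.raw_inference = s.raw_inference[perm, :]
        assert np.allclose(net.forward(X, s2).class_score, base, atol=1e-12)

    def test_shape_mismatch_raises(self, small_state, rng):
        with pytest.raises(ValueError, match="encoding layer"):
            net.forward(rng.uniform(0, 1, (4, 5)), small_state)


class TestNormalizeAndSerialize:
    def test_normalize_uses_stored_stats_and_clamps(self):
        s = net.init_model(2, 3, 2, 2, seed=0,
                           feature_min=np.array([0.0, 10.0]),
                           feature_max=np.array([10.0, 20.0]))
        Z = net.normalize(np.array([[5.0, 25.0]]), s)
        assert np.allclose(Z, [[0.5, 1.0]])

    def test_roundtrip_bit_identical(self, tmp_path, small_state):
        p = tmp_path / "model.json"
        net.save_model(small_state, p)
        back = net.load_model(p)
        for k, v in small_state.parameter_blocks().items():
            assert np.array_equal(v, back.parameter_blocks()[k])
        wa = net.constrain_weights(small_state)
        wb = net.constrain_weights(back)
        for k in ("A", "M", "W", "breakpoints", "eps"):
            assert np.array_equal(wa[k], wb[k])

    def test_membership_curve_samples(self, small_state):
        frame = net.membership_curve_samples(small_state, 1, n_points=51)
        assert list(frame.columns) == ["x1", "low", "medium", "high"]
        assert len(frame) == 51
        mu = frame[["low", "medium", "high"]].to_numpy()
        assert (mu >= 0).all() and (mu <= 1).all()
        assert mu.max(axis=0).min() > 0.99  # every concept peaks near 1

    def test_schema_version_checked(self, tmp_path, small_state):
        p = tmp_path / "model.json"
        net.save_model(small_state, p)
        import json

        payload = json.loads(p.read_text())
        payload["schema_version"] = 99
        p.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="schema"):
            net.load_model(p)
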