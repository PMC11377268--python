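import numpy as np
import pytest

from gaitxai.data import GaitDataset
from gaitxai.graph import LayerGraph, TrainedModel, TrainingConfig, build_architecture
from gaitxai.layers import (
    AvgPool, BatchNorm, Conv2D, Dense, Dropout, Flatten, Input, MaxPool, Softmax,
)
from gaitxai.lrp import (
    AlphaBetaRule, EpsilonRule, FlatRule, RuleAssignment, ZBoxRule, explain_batch,
    fold_batchnorm, make_ruleset, rule_alphabeta, rule_epsilon, rule_flat,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles (plain loops over the defining formulas)

def brute_epsilon(a, w, b, R, eps):
    J, K = w.shape
    out = np.zeros(J)
    for k in range(K):
        z = sum(a[j] * w[j, k] for j in range(J)) + b[k]
        denom = z + eps * (1.0 if z >= 0 else -1.0)
        for j in range(J):
            out[j] += (a[j] * w[j, k] / denom) * R[k] if denom != 0 else 0.0
    return out


def brute_alphabeta(a, w, b, R, alpha, beta):
    J, K = w.shape
    out = np.zeros(J)
    for k in range(K):
        zp = sum(max(a[j] * w[j, k], 0.0) for j in range(J)) + max(b[k], 0.0)
        zn = sum(min(a[j] * w[j, k], 0.0) for j in range(J)) + min(b[k], 0.0)
        for j in range(J):
            p = max(a[j] * w[j, k], 0.0)
            n = min(a[j] * w[j, k], 0.0)
            if zp != 0:
                out[j] += alpha * p / zp * R[k]
            if zn != 0:
                out[j] -= beta * n / zn * R[k]
    return out


def brute_zbox(a, w, b, R, lo, hi):
    J, K = w.shape
    out = np.zeros(J)
    for k in range(K):
        z = b[k]
        for j in range(J):
            z += a[j] * w[j, k] - lo * max(w[j, k], 0) - hi * min(w[j, k], 0)
        if z == 0:
            continue
        for j in range(J):
            num = a[j] * w[j, k] - lo * max(w[j, k], 0) - hi * min(w[j, k], 0)
            out[j] += num / z * R[k]
    return out


@pytest.fixture()
def random_layer(rng):
    a = rng.standard_normal(5)
    w = rng.standard_normal((5, 4))
    b = rng.standard_normal(4)
    R = rng.standard_normal(4)
    return a, w, b, R


class TestDenseRuleOracles:
    def test_epsilon_matches_brute_force(self, rng):
        for _ in range(10):
            a = rng.standard_normal(5)
            w = rng.standard_normal((5, 4))
            b = rng.standard_normal(4)
            R = rng.standard_normal(4)
            got = rule_epsilon(a[None], w, b, R[None], 0.01)[0]
            np.testing.assert_allclose(got, brute_epsilon(a, w, b, R, 0.01), atol=1e-10)

    @pytest.mark.parametrize("alpha,beta", [(1.0, 0.0), (2.0, 1.0)])
    def test_alphabeta_matches_brute_force(self, rng, alpha, beta):
        for _ in range(10):
            a = rng.standard_normal(5)
            w = rng.standard_normal((5, 4))
            b = rng.standard_normal(4)
            R = rng.standard_normal(4)
            got = rule_alphabeta(a[None], w, b, R[None], alpha, beta)[0]
            np.testing.assert_allclose(got, brute_alphabeta(a, w, b, R, alpha, beta),
                                       atol=1e-10)

    def test_zbox_matches_brute_force(self, rng, random_layer):
        a, w, b, R = random_layer
        d = Dense(4, "linear")
        d.infer_shape([(5,)])
        d.params = {"w": w, "b": b}
        from gaitxai.lrp import _dense_lrp

        got = _dense_lrp(d, a[None], R[None], ZBoxRule(-2.0, 2.0))[0]
        np.testing.assert_allclose(got, brute_zbox(a, w, b, R, -2.0, 2.0), atol=1e-10)

    def test_alphabeta_constraint_enforced(self):
        with pytest.raises(ValueError):
            AlphaBetaRule(1.5, 0.0)
        with pytest.raises(ValueError):
            AlphaBetaRule(0.5, -0.5)

    def test_epsilon_stabilizes_zero_denominator(self):
        a = np.array([[1.0, -1.0]])
        w = np.ones((2, 1))
        R = np.array([[3.0]])
        out = rule_epsilon(a, w, np.zeros(1), R, 0.01)
        assert np.all(np.isfinite(out))

    def test_epsilon_hand_examples(self):
        # weights [1,1], input [2,3]: f=5, proportional R=[2,3]
        out = rule_epsilon(np.array([[2.0, 3.0]]), np.array([[1.0], [1.0]]),
                           np.zeros(1), np.array([[5.0]]), 0.0)
        np.testing.assert_allclose(out, [[2.0, 3.0]])
        # weights [2,-1], input [1,1]: R=[2,-1], conserved sum 1
        out = rule_epsilon(np.array([[1.0, 1.0]]), np.array([[2.0], [-1.0]]),
                           np.zeros(1), np.array([[1.0]]), 0.0)
        np.testing.assert_allclose(out, [[2.0, -1.0]])

    def test_alphabeta_10_equals_epsilon0_on_positive_layer(self, rng):
        a = rng.uniform(0.1, 1, 5)
        w = rng.uniform(0.1, 1, (5, 3))
        R = rng.uniform(0, 1, 3)
        ab = rule_alphabeta(a[None], w, np.zeros(3), R[None], 1.0, 0.0)
        ep = rule_epsilon(a[None], w, np.zeros(3), R[None], 0.0)
        np.testing.assert_allclose(ab, ep, atol=1e-12)

    def test_alphabeta_10_nonnegative_for_nonnegative_relevance(self, rng):
        a = rng.standard_normal(6)
        w = rng.standard_normal((6, 4))
        R = rng.uniform(0, 1, 4)
        out = rule_alphabeta(a[None], w, np.zeros(4), R[None], 1.0, 0.0)
        assert np.all(out >= -1e-12)

    def test_flat_spreads_uniformly(self):
        out = rule_flat(3, np.array([[6.0]]))
        np.testing.assert_allclose(out, [[2.0, 2.0, 2.0]])


class TestConvRulesAgainstDenseEquivalent:
    """A convolution is a structured dense layer; rules must agree."""

    def _conv_and_dense(self, rng, rule):
        conv = Conv2D(2, (2, 2), padding="valid", activation="linear")
        conv.infer_shape([(3, 3, 1)])
        conv.init_params(rng)
        x = rng.standard_normal((1, 3, 3, 1))
        # build the equivalent dense weight matrix column by column
        z = conv.forward([x])
        K = z.size
        W = np.zeros((9, K))
        for j in range(9):
            e = np.zeros((1, 3, 3, 1))
            e.ravel()[j] = 1.0
            W[j] = (conv.forward([e]) - conv.forward([np.zeros_like(e)])).ravel()
        b_dense = np.repeat(conv.params["b"], K // 2) * 0 + np.tile(conv.params["b"], K // 2)
        # per-position bias equals the filter bias
        b_dense = conv.forward([np.zeros_like(x)]).ravel()
        conv.forward([x])  # restore cache
        R = rng.standard_normal(z.shape)
        from gaitxai.lrp import _conv_lrp

        got = _conv_lrp(conv, x, R, rule).ravel()
        d = Dense(K, "linear")
        d.infer_shape([(9,)])
        d.params = {"w": W, "b": b_dense}
        from gaitxai.lrp import _dense_lrp

        want = _dense_lrp(d, x.reshape(1, 9), R.reshape(1, K), rule).ravel()
        return got, want

    @pytest.mark.parametrize("rule", [EpsilonRule(0.05), AlphaBetaRule(1, 0),
                                      AlphaBetaRule(2, 1), ZBoxRule(-1.5, 1.5)])
    def test_conv_rule_equals_dense_oracle(self, rng, rule):
        got, want = self._conv_and_dense(rng, rule)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestPoolRules:
    def test_maxpool_winner_take_all(self):
        p = MaxPool((1, 2))
        p.infer_shape([(1, 2, 1)])
        x = np.array([1.0, 3.0]).reshape(1, 1, 2, 1)
        p.forward([x])
        from gaitxai.lrp import _maxpool_lrp

        out = _maxpool_lrp(p, np.array(4.0).reshape(1, 1, 1, 1))
        np.testing.assert_allclose(out.ravel(), [0.0, 4.0])

    def test_maxpool_tie_to_first_index(self):
        p = MaxPool((1, 2))
        p.infer_shape([(1, 2, 1)])
        x = np.array([2.0, 2.0]).reshape(1, 1, 2, 1)
        p.forward([x])
        from gaitxai.lrp import _maxpool_lrp

        out = _maxpool_lrp(p, np.array(4.0).reshape(1, 1, 1, 1))
        np.testing.assert_allclose(out.ravel(), [4.0, 0.0])

    def test_avgpool_proportional_under_epsilon0(self):
        p = AvgPool((1, 2))
        p.infer_shape([(1, 2, 1)])
        x = np.array([1.0, 3.0]).reshape(1, 1, 2, 1)
        p.forward([x])
        from gaitxai.lrp import _avgpool_lrp

        out = _avgpool_lrp(p, x, np.array(4.0).reshape(1, 1, 1, 1), EpsilonRule(0.0))
        np.testing.assert_allclose(out.ravel(), [1.0, 3.0])

    def test_avgpool_flat_spreads_uniformly(self):
        p = AvgPool((1, 2))
        p.infer_shape([(1, 2, 1)])
        x = np.array([1.0, 3.0]).reshape(1, 1, 2, 1)
        p.forward([x])
        from gaitxai.lrp import _avgpool_lrp

        out = _avgpool_lrp(p, x, np.array(4.0).reshape(1, 1, 1, 1), FlatRule())
        np.testing.assert_allclose(out.ravel(), [2.0, 2.0])


def _toy_model(arch="single", n_classes=3, zero_bias=False, seed=0, hw=(48, 18)):
    g = build_architecture(arch, hw, n_classes, {"scale": 0.25, "dense_width": 8})
    g.init_params(np.random.default_rng(seed))
    if zero_bias:
        for l in g.layers.values():
            if "b" in l.params:
                l.params["b"][:] = 0
            if "beta" in l.params:
                l.params["beta"][:] = 0
            if isinstance(l, BatchNorm):
                l.running_mean[:] = 0.0
    # a non-negative head keeps every explained logit positive, avoiding
    # the degenerate z+ = 0 case of the alpha1-beta0 rule (in which a
    # negative score has no positive contributions to flow through)
    head = g.layers["logits"]
    head.params["w"] = np.abs(head.params["w"])
    return TrainedModel(graph=g, config=TrainingConfig(), classes=list(range(n_classes)))


class TestConservation:
    @pytest.mark.parametrize("arch", ["single", "parallel", "quadruplet"])
    def test_alphabeta_zero_bias_conserves_through_architecture(self, arch, rng):
        m = _toy_model(arch, zero_bias=True)
        X = rng.standard_normal((3, 48, 18))
        rules = RuleAssignment("ab", dense=AlphaBetaRule(1, 0), conv=AlphaBetaRule(1, 0))
        rmap = explain_batch(m, X, 1, rules)
        assert np.max(np.atleast_1d(rmap.conservation_residual)) < 1e-6

    @pytest.mark.parametrize("arch", ["single", "parallel", "quadruplet"])
    def test_flat_rule_conserves_exactly(self, arch, rng):
        m = _toy_model(arch, zero_bias=True)
        X = rng.standard_normal((2, 48, 18))
        rmap = explain_batch(m, X, 0, "flat")
        assert np.max(np.atleast_1d(rmap.conservation_residual)) < 1e-6

    def test_epsilon_residual_grows_with_epsilon(self, rng):
        m = _toy_model("single", zero_bias=True)
        X = rng.standard_normal((1, 48, 18))
        residuals = []
        for eps in (0.01, 0.1, 1.0):
            rules = RuleAssignment("eps", dense=EpsilonRule(eps), conv=EpsilonRule(eps))
            residuals.append(float(np.max(np.atleast_1d(
                explain_batch(m, X, 0, rules).conservation_residual))))
        assert residuals[0] <= residuals[1] <= residuals[2]


class TestComposites:
    def test_lrp_spf_uses_flat_first_layer(self):
        rs = make_ruleset("lrp_spf")
        assert isinstance(rs.first_layer, FlatRule)
        assert isinstance(rs.dense, EpsilonRule)
        assert isinstance(rs.conv, AlphaBetaRule)

    def test_unknown_ruleset_raises(self):
        with pytest.raises(ValueError):
            make_ruleset("shap")

    def test_deep_taylor_bounded_gives_finite_scores(self, rng):
        m = _toy_model("single")
        X = rng.standard_normal((2, 48, 18))
        rs = make_ruleset("deep_taylor_bounded", input_bounds=(X.min(), X.max()))
        rmap = explain_batch(m, X, 1, rs)
        assert np.all(np.isfinite(rmap.scores))

    def test_guided_backprop_equals_gradient_on_positive_chain(self):
        # all-positive weights and inputs: no gating anywhere
        g = LayerGraph("chain")
        g.add("input", Input((4,) + (3, 1)))
        g.add("conv", Conv2D(2, (1, 1), activation="relu"), ["input"])
        g.add("flat", Flatten(), ["conv"])
        g.add("fc", Dense(3, "relu"), ["flat"])
        g.add("logits", Dense(2, "linear"), ["fc"])
        g.add("softmax", Softmax(), ["logits"])
        rng = np.random.default_rng(0)
        for l in g.layers.values():
            l.init_params(rng)
            if "w" in l.params:
                l.params["w"] = np.abs(l.params["w"]) + 0.1
        m = TrainedModel(graph=g, config=TrainingConfig(), classes=[0, 1])
        X = np.abs(rng.standard_normal((2, 4, 3))) + 0.1
        guided = explain_batch(m, X, 1, "guided_backprop").scores
        # plain gradient via the training backward pass
        logits, _, _ = g.forward(X[..., None])
        seed = np.zeros_like(logits)
        seed[:, 1] = 1.0
        grad = g.backward(seed, relu_mode="grad")[..., 0]
        np.testing.assert_allclose(guided, grad, atol=1e-10)

    def test_scale_covariance_of_explained_logit(self, rng):
        m = _toy_model("single", zero_bias=True)
        X = rng.standard_normal((1, 48, 18))
        rules = RuleAssignment("ab", dense=AlphaBetaRule(1, 0), conv=AlphaBetaRule(1, 0))
        r1 = explain_batch(m, X, 1, rules)
        head = m.graph.layers["logits"]
        head.params["w"] = head.params["w"].copy()
        head.params["w"][:, 1] *= 3.0
        r2 = explain_batch(m, X, 1, rules)
        np.testing.assert_allclose(r2.scores, 3.0 * r1.scores, rtol=1e-8)


class TestPassthroughAndFolding:
    def test_batchnorm_folding_matches_manual_fold(self, rng):
        g = LayerGraph("bn")
        g.add("input", Input((6,) + (4, 1)))
        g.add("flatten", Flatten(), ["input"])
        g.add("bn", BatchNorm(), ["flatten"])
        g.add("drop", Dropout(0.3), ["bn"])
        g.add("fc", Dense(5, "relu"), ["drop"])
        g.add("logits", Dense(3, "linear"), ["fc"])
        g.add("softmax", Softmax(), ["logits"])
        g.init_params(rng)
        bn = g.layers["bn"]
        bn.running_mean = rng.standard_normal(24)
        bn.running_var = rng.uniform(0.5, 2.0, 24)
        bn.params["gamma"] = rng.uniform(0.5, 1.5, 24)
        bn.params["beta"] = rng.standard_normal(24)
        m = TrainedModel(graph=g, config=TrainingConfig(), classes=[0, 1, 2])
        X = rng.standard_normal((2, 6, 4))

        # manually folded reference network
        g2 = LayerGraph("manual")
        g2.add("input", Input((6, 4, 1)))
        g2.add("flatten", Flatten(), ["input"])
        g2.add("fc", Dense(5, "relu"), ["flatten"])
        g2.add("logits", Dense(3, "linear"), ["fc"])
        g2.add("softmax", Softmax(), ["logits"])
        scale, shift = bn.effective_affine()
        w, b = g.layers["fc"].params["w"], g.layers["fc"].params["b"]
        g2.layers["fc"].params = {"w": w * scale[:, None], "b": b + shift @ w}
        g2.layers["logits"].params = {k: v.copy() for k, v in g.layers["logits"].params.items()}
        m2 = TrainedModel(graph=g2, config=TrainingConfig(), classes=[0, 1, 2])

        for rules in ("lrp_spf", "flat"):
            ra = explain_batch(m, X, 2, rules)
            rb = explain_batch(m2, X, 2, rules)
            np.testing.assert_allclose(ra.scores, rb.scores, atol=1e-8)
            np.testing.assert_allclose(np.atleast_1d(ra.f_c), np.atleast_1d(rb.f_c),
                                       atol=1e-8)

    def test_flatten_concat_preserve_relevance_totals(self, rng):
        m = _toy_model("quadruplet", zero_bias=True)
        X = rng.standard_normal((2, 48, 18))
        rules = RuleAssignment("ab", dense=AlphaBetaRule(1, 0), conv=AlphaBetaRule(1, 0))
        rmap = explain_batch(m, X, 0, rules)
        total = rmap.scores.reshape(2, -1).sum(axis=1)
        np.testing.assert_allclose(total, np.atleast_1d(rmap.f_c), rtol=1e-6, atol=1e-9)


class TestTargetSelection:
    def test_unknown_class_raises(self, tiny_model, tiny_pd_dataset):
        with pytest.raises(ValueError, match="unknown target class"):
            explain_batch(tiny_model, tiny_pd_dataset.values[:1], "no-such", "flat")

    def test_single_sample_returns_2d_scores(self, tiny_model, tiny_pd_dataset):
        rmap = explain_batch(tiny_model, tiny_pd_dataset.values[0], 2, "flat")
        assert rmap.scores.shape == tiny_pd_dataset.values[0].shape
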