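"""Meta-learner algebra: closed-form toys, Kronecker preconditioning,
learner-equivalence reductions and the ANIL body-freeze contract."""

from collections import OrderedDict

import numpy as np
import pytest

from echolandmarks.backbone import BackboneConfig, HeatmapNet, ModelParams
from echolandmarks.meta import (InnerConfig, create_meta_state, inner_adapt,
                                load_meta_state, mc_precondition,
                                meta_iteration, outer_update,
                                save_meta_state)


class QuadraticToy:
    """Scalar model with loss L(theta) = 0.5 * theta^2 (batch ignored)."""

    def loss_and_grad(self, params, batch):
        th = params["head.w"]
        return float(0.5 * np.sum(th * th)), OrderedDict(
            [("head.w", th.copy())])


class SlopeToy:
    """Linear loss: batch = (support_slope, query_slope); gradient is the
    slope, so inner and query gradients can be set independently."""

    def loss_and_grad(self, params, batch):
        slope = float(batch)
        return slope * float(params["head.w"][0]), OrderedDict(
            [("head.w", np.array([slope]))])


def scalar_state(theta0=1.0, learner="fomaml", beta=1.0, inner_lr=0.1):
    p = ModelParams(head=OrderedDict([("head.w", np.array([theta0]))]))
    return create_meta_state(p, learner, outer_lr=beta,
                             outer_optimizer="sgd", inner_lr_init=inner_lr)


class TestScalarClosedForms:
    def test_single_inner_step(self):
        r = inner_adapt(QuadraticToy(), scalar_state(), None,
                        InnerConfig(0.1, 1))
        assert r.params["head.w"][0] == pytest.approx(0.9)

    def test_three_inner_steps(self):
        r = inner_adapt(QuadraticToy(), scalar_state(), None,
                        InnerConfig(0.1, 3))
        assert r.params["head.w"][0] == pytest.approx(0.9**3)

    def test_fomaml_outer_step(self):
        """Query gradient at theta_1 = 0.9 with beta = 1 moves the
        initialisation from 1 to 0.1."""
        model, state = QuadraticToy(), scalar_state()
        cfg = InnerConfig(0.1, 1)
        adapt = inner_adapt(model, state, None, cfg)
        new, _ = outer_update(model, state, adapt, None, cfg)
        assert new.theta["head.w"][0] == pytest.approx(0.1)
        assert state.theta["head.w"][0] == pytest.approx(1.0)  # untouched

    def test_zero_outer_rate_is_identity(self):
        model = QuadraticToy()
        state = scalar_state(beta=0.0)
        cfg = InnerConfig(0.1, 1)
        adapt = inner_adapt(model, state, None, cfg)
        new, _ = outer_update(model, state, adapt, None, cfg)
        assert new.theta["head.w"][0] == state.theta["head.w"][0]

    def test_zero_inner_steps_returns_initialisation(self):
        r = inner_adapt(QuadraticToy(), scalar_state(), None,
                        InnerConfig(0.1, 0))
        assert r.params["head.w"][0] == pytest.approx(1.0)


class TestMetaSGD:
    def test_alpha_gradient_cancels_on_symmetric_task_pair(self):
        """Tasks with equal support slope but opposite query slopes leave
        alpha unchanged while the initialisation still moves."""
        model = SlopeToy()
        state = scalar_state(learner="meta_sgd")
        cfg = InnerConfig(0.1, 1)
        batch = [((1.0), (1.0)), ((-1.0), (1.0))]
        new, _ = meta_iteration(model, state, batch, cfg)
        assert np.allclose(new.alpha["head.w"], state.alpha["head.w"])
        assert new.theta["head.w"][0] != state.theta["head.w"][0]

    def test_constant_alpha_reproduces_fomaml_trajectory(self):
        net = HeatmapNet(BackboneConfig(width=2, image_size=8))
        rng = np.random.default_rng(0)
        batch = (rng.uniform(0, 255, (2, 1, 8, 8)),
                 rng.uniform(0, 1, (2, 4, 8, 8)))
        theta = net.init_params(1)
        cfg = InnerConfig(0.03, 3)
        fo = inner_adapt(net, create_meta_state(theta, "fomaml"), batch, cfg)
        ms = inner_adapt(net, create_meta_state(theta, "meta_sgd",
                                                inner_lr_init=0.03),
                         batch, cfg, record_grads=True)
        assert all(np.array_equal(fo.params[k], ms.params[k])
                   for k in theta.names())

    def test_alpha_allocated_only_for_meta_sgd(self):
        theta = ModelParams(head=OrderedDict([("head.w", np.ones(2))]))
        assert create_meta_state(theta, "fomaml").alpha is None
        assert create_meta_state(theta, "fomaml").curvature is None
        assert create_meta_state(theta, "meta_sgd").alpha is not None


class TestMetaCurvature:
    def test_factored_matches_dense_kronecker_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=(2, 3, 2, 2))   # C_out=2, C_in=3, d=4
        mo = rng.normal(size=(2, 2))
        mi = rng.normal(size=(3, 3))
        mf = rng.normal(size=(4, 4))
        dense = (np.kron(mo, np.kron(np.eye(3), np.eye(4)))
                 @ np.kron(np.eye(2), np.kron(mi, np.eye(4)))
                 @ np.kron(np.eye(2), np.kron(np.eye(3), mf)))
        oracle = (dense @ g.reshape(2, 3, 4).ravel()).reshape(g.shape)
        assert np.allclose(mc_precondition(g, (mo, mi, mf)), oracle,
                           atol=1e-12)

    def test_identity_factors_are_the_identity_map(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=(2, 3, 2, 2))
        out = mc_precondition(g, (np.eye(2), np.eye(3), np.eye(4)))
        assert np.array_equal(out, g)

    def test_zero_gradient_maps_to_zero(self):
        rng = np.random.default_rng(2)
        factors = (rng.normal(size=(2, 2)), rng.normal(size=(3, 3)),
                   rng.normal(size=(4, 4)))
        assert np.all(mc_precondition(np.zeros((2, 3, 2, 2)), factors) == 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mc_precondition(np.zeros((2, 3, 2, 2)),
                            (np.eye(3), np.eye(3), np.eye(4)))

    def test_identity_factors_reproduce_fomaml_trajectory(self):
        net = HeatmapNet(BackboneConfig(width=2, image_size=8))
        rng = np.random.default_rng(3)
        batch = (rng.uniform(0, 255, (2, 1, 8, 8)),
                 rng.uniform(0, 1, (2, 4, 8, 8)))
        theta = net.init_params(4)
        cfg = InnerConfig(0.03, 3)
        fo = inner_adapt(net, create_meta_state(theta, "fomaml"), batch, cfg)
        mc = inner_adapt(net, create_meta_state(theta, "meta_curvature"),
                         batch, cfg, record_grads=True)
        assert all(np.array_equal(fo.params[k], mc.params[k])
                   for k in theta.names())


class TestANIL:
    def test_body_bit_identical_through_inner_loop(self):
        net = HeatmapNet(BackboneConfig(width=2, image_size=8))
        rng = np.random.default_rng(5)
        batch = (rng.uniform(0, 255, (2, 1, 8, 8)),
                 rng.uniform(0, 1, (2, 4, 8, 8)))
        state = create_meta_state(net.init_params(6), "anil")
        adapted = inner_adapt(net, state, batch, InnerConfig(0.05, 5)).params
        for k in state.theta.body:
            assert adapted.body[k] is state.theta.body[k]  # bit-identical
        assert any(not np.array_equal(adapted.head[k], state.theta.head[k])
                   for k in state.theta.head)

    def test_outer_update_moves_the_body(self):
        net = HeatmapNet(BackboneConfig(width=2, image_size=8))
        rng = np.random.default_rng(7)
        batch = (rng.uniform(0, 255, (2, 1, 8, 8)),
                 rng.uniform(0, 1, (2, 4, 8, 8)))
        state = create_meta_state(net.init_params(8), "anil", outer_lr=0.1,
                                  outer_optimizer="sgd")
        cfg = InnerConfig(0.05, 2)
        adapt = inner_adapt(net, state, batch, cfg)
        new, _ = outer_update(net, state, adapt, batch, cfg)
        assert any(not np.array_equal(new.theta.body[k], state.theta.body[k])
                   for k in state.theta.body)


class TestMetaIteration:
    def test_first_order_meta_gradient_equals_query_gradient_at_adapted(self):
        """The FOMAML meta-gradient is exactly the query-set gradient
        evaluated at the adapted parameters (no inner-trajectory terms)."""
        net = HeatmapNet(BackboneConfig(width=2, image_size=8))
        rng = np.random.default_rng(9)
        sup = (rng.uniform(0, 255, (2, 1, 8, 8)),
               rng.uniform(0, 1, (2, 4, 8, 8)))
        qry = (rng.uniform(0, 255, (2, 1, 8, 8)),
               rng.uniform(0, 1, (2, 4, 8, 8)))
        state = create_meta_state(net.init_params(10), "fomaml",
                                  outer_lr=1.0, outer_optimizer="sgd")
        cfg = InnerConfig(0.03, 2)
        adapt = inner_adapt(net, state, sup, cfg)
        new, _ = outer_update(net, state, adapt, qry, cfg)
        _, g_q = net.loss_and_grad(adapt.params, qry)
        for k in state.theta.names():
            expected = state.theta[k] - 1.0 * g_q[k]
            assert np.allclose(new.theta[k], expected, atol=1e-7)

    def test_sum_aggregation_doubles_for_identical_episodes(self):
        model = QuadraticToy()
        cfg = InnerConfig(0.1, 1)
        one, _ = meta_iteration(model, scalar_state(), [(None, None)], cfg)
        two, _ = meta_iteration(model, scalar_state(),
                                [(None, None), (None, None)], cfg)
        d1 = 1.0 - one.theta["head.w"][0]
        d2 = 1.0 - two.theta["head.w"][0]
        assert d2 == pytest.approx(2 * d1)

    def test_singleton_batch_equals_outer_update(self):
        model = QuadraticToy()
        cfg = InnerConfig(0.1, 1)
        st = scalar_state()
        via_batch, _ = meta_iteration(model, st, [(None, None)], cfg)
        adapt = inner_adapt(model, st, None, cfg)
        via_single, _ = outer_update(model, st, adapt, None, cfg)
        assert via_batch.theta["head.w"][0] == pytest.approx(
            via_single.theta["head.w"][0])

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            meta_iteration(QuadraticToy(), scalar_state(), [],
                           InnerConfig(0.1, 1))


class OffsetToy:
    """Vector model: prediction = body + head; loss = 0.5*||body+head-c||^2.

    The task parameter c plays the role of a task-specific optimum, giving
    a family of quadratic losses with task-varying minima.
    """

    def loss_and_grad(self, params, batch):
        c = np.asarray(batch, dtype=np.float64)
        f = params["body.w"] + params["head.w"]
        r = f - c
        g = OrderedDict([("body.w", r.copy()), ("head.w", r.copy())])
        return float(0.5 * np.sum(r * r)), g


@pytest.mark.parametrize("learner",
                         ["fomaml", "meta_sgd", "meta_curvature", "anil"])
def test_meta_training_beats_no_meta_training_on_quadratic_family(learner):
    """50 meta-iterations reduce post-adaptation query loss below the
    untrained-initialisation baseline for every learner."""
    model = OffsetToy()
    rng = np.random.default_rng(0)
    centre = np.array([3.0, -2.0])

    def episode():
        c = centre + rng.normal(0, 0.3, 2)
        return (c, c)  # support and query share the task optimum

    theta0 = ModelParams(body=OrderedDict([("body.w", np.zeros(2))]),
                         head=OrderedDict([("head.w", np.zeros(2))]))
    cfg = InnerConfig(0.1, 3)
    state = create_meta_state(theta0, learner, outer_lr=0.05,
                              outer_optimizer="adam")
    for _ in range(50):
        state, _ = meta_iteration(model, state, [episode(), episode()], cfg)

    def post_adapt_loss(st):
        losses = []
        for _ in range(10):
            sup, qry = episode()
            adapted = inner_adapt(model, st, sup, cfg).params
            loss, _ = model.loss_and_grad(adapted, qry)
            losses.append(loss)
        return float(np.mean(losses))

    baseline = create_meta_state(theta0, learner)
    assert post_adapt_loss(state) < post_adapt_loss(baseline)


def test_meta_state_roundtrips_through_checkpoint(tmp_path):
    net = HeatmapNet(BackboneConfig(width=2, image_size=8))
    for learner in ("fomaml", "meta_sgd", "meta_curvature"):
        st = create_meta_state(net.init_params(0), learner, outer_lr=0.01)
        path = tmp_path / f"{learner}.npz"
        save_meta_state(st, path)
        back = load_meta_state(path)
        assert back.learner == learner
        assert back.theta.allclose(st.theta)
        if learner == "meta_sgd":
            assert all(np.array_equal(back.alpha[k], st.alpha[k])
                       for k in st.alpha)
        if learner == "meta_curvature":
            assert all(
                np.array_equal(a, b)
                for k in st.curvature
                for a, b in zip(back.curvature[k], st.curvature[k]))
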