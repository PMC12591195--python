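"""The five cognitive operators and the dual-input/dual-output block."""

import numpy as np
import pytest

from vcogm.autograd import Tensor
from vcogm.vcnu import (
    Analyze,
    Attend,
    Perceive,
    Recall,
    UpdateMemory,
    VcnuBlock,
    VcnuConfig,
    pbm_wrap,
)

import oracles


def _mk(seed):
    return np.random.default_rng(seed)


class TestPerceive:
    def test_zero_weights_give_zero(self):
        p = Perceive(VcnuConfig(D=4, j=2, n=2), _mk(0))
        for k in p.kernels:
            k.data[:] = 0
        p.bias.data[:] = 0
        out = p.forward(Tensor(np.ones((1, 4, 5, 5))))
        assert np.all(out.data == 0)

    def test_linearity_with_zero_bias(self, rng):
        p = Perceive(VcnuConfig(D=4, j=2, n=2), _mk(1))
        p.bias.data[:] = 0
        x = rng.normal(size=(1, 4, 5, 5))
        one = p.forward(Tensor(x)).data
        three = p.forward(Tensor(3.0 * x)).data
        np.testing.assert_allclose(three, 3.0 * one, atol=1e-12)

    def test_single_branch_matches_loop_oracle(self, rng):
        p = Perceive(VcnuConfig(D=1, j=1, n=0, enable_m=True), _mk(2))
        x = rng.normal(size=(1, 4, 4))
        got = p.forward(Tensor(x[None])).data[0]
        want = oracles.perceive_oracle(x, [p.kernels[0].data], p.bias.data)
        np.testing.assert_allclose(got, want, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_multibranch_matches_oracle(self, seed):
        rng = _mk(seed)
        p = Perceive(VcnuConfig(D=4, j=2, n=2), rng)
        x = rng.normal(size=(2, 4, 5, 5))
        got = p.forward(Tensor(x)).data
        want = np.stack([
            oracles.perceive_oracle(xb, [k.data for k in p.kernels], p.bias.data)
            for xb in x
        ])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            VcnuConfig(D=5, j=2, n=2)


class TestRecall:
    def test_zero_weights(self):
        m = Recall(5, 3, _mk(0))
        m.W_m.data[:] = 0
        m.bias.data[:] = 0
        out = m.forward(Tensor(np.ones((1, 3, 4))))
        assert np.all(out.data == 0)

    def test_stacked_identity_copies_memory_rows(self, rng):
        m = Recall(5, 3, _mk(0))
        m.W_m.data[:] = 0
        m.W_m.data[:3, :3] = np.eye(3)
        m.bias.data[:] = 0
        ltm = rng.normal(size=(1, 3, 4))
        out = m.forward(Tensor(ltm)).data
        np.testing.assert_allclose(out[0, :3], ltm[0], atol=1e-15)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_matmul_oracle(self, seed):
        rng = _mk(seed)
        m = Recall(5, 3, rng)
        ltm = rng.normal(size=(3, 4))
        got = m.forward(Tensor(ltm[None])).data[0]
        want = oracles.recall_oracle(ltm, m.W_m.data, m.bias.data)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestAttend:
    def test_zero_weight_gives_bias_everywhere(self, rng):
        a = Attend(4, _mk(0))
        a.W_a.data[:] = 0
        a.bias.data[:] = rng.normal(size=(4, 1))
        out = a.forward(Tensor(rng.normal(size=(2, 4, 6))),
                        Tensor(rng.normal(size=(2, 4, 6)))).data
        np.testing.assert_allclose(out, np.broadcast_to(a.bias.data, (2, 4, 6)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepwise_oracle(self, seed):
        rng = _mk(seed)
        a = Attend(4, rng)
        wm = rng.normal(size=(2, 4, 6))
        mp = rng.normal(size=(2, 4, 6))
        got = a.forward(Tensor(wm), Tensor(mp)).data
        want = oracles.attend_oracle(
            wm, mp, a.W_a.data, a.bias.data,
            a.norm.gamma.data.ravel(), a.norm.beta.data.ravel(),
        )
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_inference_without_running_stats_raises(self, rng):
        a = Attend(4, _mk(0))
        a.eval()
        with pytest.raises(RuntimeError, match="running statistics"):
            a.forward(Tensor(rng.normal(size=(2, 4, 6))),
                      Tensor(rng.normal(size=(2, 4, 6))))


class TestUpdateMemory:
    def test_zero_weight_is_gelu_of_state(self, rng):
        u = UpdateMemory(4, 2, _mk(0))
        u.W_u.data[:] = 0
        ltm = rng.normal(size=(1, 2, 3))
        out = u.forward(Tensor(np.zeros((1, 4, 3))), Tensor(ltm)).data
        np.testing.assert_allclose(out, oracles.gelu_oracle(ltm), atol=1e-12)

    def test_zero_state_zero_weight_fixed_point(self):
        u = UpdateMemory(4, 2, _mk(0))
        u.W_u.data[:] = 0
        state = Tensor(np.zeros((1, 2, 3)))
        for _ in range(5):
            state = u.forward(Tensor(np.ones((1, 4, 3))), state)
        assert np.all(state.data == 0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle(self, seed):
        rng = _mk(seed)
        u = UpdateMemory(4, 2, rng)
        attn = rng.normal(size=(2, 4, 3))
        ltm = rng.normal(size=(2, 2, 3))
        got = u.forward(Tensor(attn), Tensor(ltm)).data
        np.testing.assert_allclose(got, oracles.update_oracle(attn, ltm, u.W_u.data),
                                   atol=1e-10)


class TestAnalyze:
    def test_zero_weights_give_zero(self, rng):
        n = Analyze(4, 4.0, _mk(0))
        for p in (n.W1, n.b1, n.W2, n.b2):
            p.data[:] = 0
        out = n.forward(Tensor(rng.normal(size=(1, 4, 5)))).data
        assert np.all(out == 0)

    def test_identity_weights_recover_positive_input(self):
        # in the far-positive linear region GeLU is near-identity
        n = Analyze(4, 1.0, _mk(0))
        n.W1.data = np.eye(4)
        n.b1.data[:] = 0
        n.W2.data = np.eye(4)
        n.b2.data[:] = 0
        x = np.full((1, 4, 5), 8.0)
        out = n.forward(Tensor(x)).data
        np.testing.assert_allclose(out, x, atol=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_two_matmul_oracle(self, seed):
        rng = _mk(seed)
        n = Analyze(4, 4.0, rng)
        attn = rng.normal(size=(2, 4, 5))
        got = n.forward(Tensor(attn)).data
        want = oracles.analyze_oracle(attn, n.W1.data, n.b1.data, n.W2.data, n.b2.data)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestVcnuBlock:
    def test_output_shapes(self, rng):
        block = VcnuBlock(VcnuConfig(D=4, j=2, n=2), _mk(0))
        y, ltm = block.forward(Tensor(rng.normal(size=(3, 4, 4, 4))),
                               Tensor(rng.normal(size=(3, 2, 16))))
        assert y.shape == (3, 4, 4, 4)
        assert ltm.shape == (3, 2, 16)

    def test_bit_identical_across_runs(self, rng):
        x = rng.normal(size=(2, 4, 4, 4))
        ltm = rng.normal(size=(2, 2, 16))
        outs = []
        for _ in range(2):
            block = VcnuBlock(VcnuConfig(D=4, j=2, n=2), _mk(3))
            y, lt = block.forward(Tensor(x), Tensor(ltm))
            outs.append((y.data.copy(), lt.data.copy()))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_composed_oracles(self, seed):
        rng = _mk(seed)
        block = VcnuBlock(VcnuConfig(D=4, j=2, n=2), rng)
        x = rng.normal(size=(2, 4, 4, 4))
        ltm = rng.normal(size=(2, 2, 16))
        y, ltm_next = block.forward(Tensor(x), Tensor(ltm))

        mp = np.stack([
            oracles.perceive_oracle(xb, [k.data for k in block.perceive.kernels],
                                    block.perceive.bias.data)
            for xb in x
        ]).reshape(2, 4, 16)
        wm = np.stack([
            oracles.recall_oracle(lb, block.recall.W_m.data, block.recall.bias.data)
            for lb in ltm
        ])
        attn = oracles.attend_oracle(
            wm, mp, block.attend.W_a.data, block.attend.bias.data,
            block.attend.norm.gamma.data.ravel(), block.attend.norm.beta.data.ravel(),
        )
        want_ltm = oracles.update_oracle(attn, ltm, block.update.W_u.data)
        want_y = oracles.analyze_oracle(
            attn, block.analyze.W1.data, block.analyze.b1.data,
            block.analyze.W2.data, block.analyze.b2.data,
        ).reshape(2, 4, 4, 4)
        np.testing.assert_allclose(y.data, want_y, atol=1e-8)
        np.testing.assert_allclose(ltm_next.data, want_ltm, atol=1e-8)

    def test_zero_update_weights_give_gelu_iterates(self, rng):
        """With W_u = 0 the memory trajectory is the GeLU iteration of LTM_0."""
        block = VcnuBlock(VcnuConfig(D=4, j=2, n=2), _mk(0))
        block.update.W_u.data[:] = 0
        ltm0 = rng.normal(size=(1, 2, 16))
        state = Tensor(ltm0)
        closed_form = ltm0.copy()
        for _ in range(4):
            _, state = block.forward(Tensor(rng.normal(size=(1, 4, 4, 4))), state)
            closed_form = oracles.gelu_oracle(closed_form)
            np.testing.assert_allclose(state.data, closed_form, atol=1e-12)


class TestPbmWrapper:
    def test_identity_base_matches_component_oracles(self, rng):
        cfg = VcnuConfig(D=4, j=2, n=2)
        w = pbm_wrap(lambda t: t, cfg, _mk(0))
        x = rng.normal(size=(2, 4, 3, 3))
        ltm = rng.normal(size=(2, 2, 9))
        y, ltm_next = w.forward(Tensor(x), Tensor(ltm))
        mp = x.reshape(2, 4, 9)
        wm = np.stack([
            oracles.recall_oracle(lb, w.recall.W_m.data, w.recall.bias.data) for lb in ltm
        ])
        attn = oracles.attend_oracle(
            wm, mp, w.attend.W_a.data, w.attend.bias.data,
            w.attend.norm.gamma.data.ravel(), w.attend.norm.beta.data.ravel(),
        )
        np.testing.assert_allclose(
            ltm_next.data, oracles.update_oracle(attn, ltm, w.update.W_u.data), atol=1e-8
        )
        want_y = oracles.analyze_oracle(
            attn, w.analyze.W1.data, w.analyze.b1.data, w.analyze.W2.data, w.analyze.b2.data
        ).reshape(2, 4, 3, 3)
        np.testing.assert_allclose(y.data, want_y, atol=1e-8)

    def test_parameter_groups_exposed(self):
        w = pbm_wrap(lambda t: t, VcnuConfig(D=4, j=2, n=2), _mk(0))
        names = {n.split(".")[0] for n, _ in w.named_parameters()}
        assert names == {"recall", "attend", "update", "analyze"}
        assert w.num_parameters() > 0

    def test_wrapping_strictly_increases_parameter_count(self):
        base = Perceive(VcnuConfig(D=4, j=2, n=2), _mk(0))
        wrapped = pbm_wrap(base, VcnuConfig(D=4, j=2, n=2), _mk(1))
        assert wrapped.num_parameters() > base.num_parameters()

    def test_disabling_update_freezes_memory_exactly(self, rng):
        cfg = VcnuConfig(D=4, j=2, n=2, enable_u=False)
        w = pbm_wrap(lambda t: t, cfg, _mk(0))
        ltm = Tensor(rng.normal(size=(1, 2, 9)))
        _, ltm_next = w.forward(Tensor(rng.normal(size=(1, 4, 3, 3))), ltm)
        assert ltm_next is ltm

    def test_channel_mismatch_rejected(self, rng):
        cfg = VcnuConfig(D=4, j=2, n=2)
        w = pbm_wrap(lambda t: t[:, :2], cfg, _mk(0))
        with pytest.raises(ValueError, match="channels"):
            w.forward(Tensor(rng.normal(size=(1, 4, 3, 3))),
                      Tensor(rng.normal(size=(1, 2, 9))))

    def test_preserves_spatial_and_channel_dims(self, rng):
        w = pbm_wrap(lambda t: t, VcnuConfig(D=6, j=2, n=3), _mk(0))
        y, _ = w.forward(Tensor(rng.normal(size=(2, 6, 5, 4))),
                         Tensor(rng.normal(size=(2, 3, 20))))
        assert y.shape == (2, 6, 5, 4)
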