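"""Baseline aggregation strategies under the common plug-in contract."""

import numpy as np
import pytest

from fedgh.baselines import (
    BaselineConfig,
    FedDyn,
    fedavg_aggregate,
    fedaw_aggregate,
    fedbn_aggregate,
    feddyn_local_loss,
    fedprox_local_loss,
    make_aggregator,
)
from fedgh.params import ClientUpdate, ParamVector


def _update(values, n, cid=0, val_loss=None):
    return ClientUpdate(cid, ParamVector.from_arrays({"w": np.asarray(values, float)}),
                        n, val_loss)


class TestFedAvg:
    def test_single_client_identity(self):
        out = fedavg_aggregate([_update([1.0, 2.0], 5)])
        np.testing.assert_array_equal(out.values, [1.0, 2.0])

    def test_opposed_params_cancel(self):
        out = fedavg_aggregate([_update([1.0, -2.0], 3), _update([-1.0, 2.0], 3)])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_sample_size_weighting(self):
        out = fedavg_aggregate([_update([4.0], 3), _update([0.0], 1)])
        np.testing.assert_allclose(out.values, [3.0])

    def test_zero_total_samples_rejected(self):
        with pytest.raises(ValueError):
            fedavg_aggregate([_update([1.0], 0)])


class TestFedProx:
    def test_mu_zero_and_no_drift_leave_loss(self):
        w = np.array([1.0, 2.0])
        assert fedprox_local_loss(0.7, w, w + 1, mu=0.0) == 0.7
        assert fedprox_local_loss(0.7, w, w, mu=5.0) == 0.7

    def test_quadratic_penalty_arithmetic(self):
        w_g = np.zeros(9)
        w_l = np.ones(9)  # ‖Δ‖² = 9
        assert fedprox_local_loss(1.5, w_l, w_g, mu=2.0) == pytest.approx(1.5 + 9.0)


class TestFedBN:
    def _mixed_updates(self):
        a = ParamVector.from_arrays({"conv.w": np.array([2.0, 4.0]),
                                     "norm.gamma": np.array([1.0])})
        b = ParamVector.from_arrays({"conv.w": np.array([0.0, 0.0]),
                                     "norm.gamma": np.array([3.0])})
        g = ParamVector.from_arrays({"conv.w": np.array([9.0, 9.0]),
                                     "norm.gamma": np.array([7.0])})
        return [ClientUpdate(0, a, 1), ClientUpdate(1, b, 1)], g

    def test_mixed_layout_slicewise(self):
        updates, global_params = self._mixed_updates()
        out = fedbn_aggregate(updates, global_params, ["norm*"])
        arrays = out.to_arrays()
        np.testing.assert_allclose(arrays["conv.w"], [1.0, 2.0])  # FedAvg slice
        np.testing.assert_allclose(arrays["norm.gamma"], [7.0])   # frozen slice

    def test_no_norm_layers_degenerates_to_fedavg(self):
        updates, global_params = self._mixed_updates()
        with pytest.warns(UserWarning):
            out = fedbn_aggregate(updates, global_params, ["nothing_matches*"])
        np.testing.assert_allclose(out.values,
                                   fedavg_aggregate(updates).values)

    def test_norm_only_layout_frozen(self):
        g = ParamVector.from_arrays({"norm.gamma": np.array([7.0, 8.0])})
        ups = [ClientUpdate(0, ParamVector.from_arrays(
            {"norm.gamma": np.array([1.0, 1.0])}), 1)]
        out = fedbn_aggregate(ups, g, ["norm*"])
        np.testing.assert_array_equal(out.values, g.values)


class TestFedDyn:
    def test_neutral_settings_reduce_to_plain(self):
        w = np.array([0.5, 0.5])
        assert feddyn_local_loss(1.0, w, w, np.zeros(2), alpha=0.0) == 1.0
        assert feddyn_local_loss(1.0, w, w, np.zeros(2), alpha=3.0) == 1.0

    def test_scalar_trace_matches_hand_stepped_recursion(self):
        """One round on a scalar model, stepped by hand.

        Local objective f(w) = (w−2)² with global w_g = 0, h = 0, α = 1:
        augmented loss = (w−2)² + ½·w².  One gradient step from w = 0 with
        lr 0.1: grad = 2(w−2) + w = −4 → w₁ = 0.4.  Then
        h ← h − α(w₁ − w_g) = −0.4.
        """
        alpha, lr = 1.0, 0.1
        w_g = 0.0
        agg = FedDyn(BaselineConfig(dyn_alpha=alpha))
        pen = agg.local_penalty(0, np.array([w_g]))
        w = 0.0
        grad = 2 * (w - 2.0) + pen(np.array([w]))[0]
        w1 = w - lr * grad
        assert w1 == pytest.approx(0.4)
        update = _update([w1], 1, cid=0)
        agg.after_local_training(update, _update([w_g], 1).params)
        np.testing.assert_allclose(agg._h[0], [-0.4])
        # loss value at w1 matches the closed form
        expected = (w1 - 2.0) ** 2 + 0.5 * alpha * w1 ** 2
        assert feddyn_local_loss((w1 - 2.0) ** 2, np.array([w1]),
                                 np.array([w_g]), np.zeros(1), alpha) \
            == pytest.approx(expected)

    def test_server_correction_vanishes_on_round_one(self):
        agg = FedDyn(BaselineConfig(dyn_alpha=0.5))
        ups = [_update([2.0], 1, cid=0), _update([4.0], 1, cid=1)]
        g = _update([0.0], 1).params
        out, _ = agg.aggregate(ups, g, np.random.default_rng(0))
        np.testing.assert_allclose(out.values, [3.0])  # plain average, h̄ was 0
        # second round: accumulated state now shifts the average
        out2, _ = agg.aggregate(ups, g, np.random.default_rng(0))
        assert out2.values[0] != pytest.approx(3.0)


class TestFedAW:
    def test_equal_quality_equals_fedavg(self):
        ups = [_update([2.0], 2), _update([6.0], 2)]
        out = fedaw_aggregate(ups, [1.0, 1.0])
        np.testing.assert_allclose(out.values,
                                   fedavg_aggregate(ups).values)

    def test_zero_quality_excludes_client(self):
        ups = [_update([2.0], 1), _update([6.0], 1)]
        out = fedaw_aggregate(ups, [1.0, 0.0])
        np.testing.assert_allclose(out.values, [2.0])

    def test_hand_worked_weights(self):
        ups = [_update([1.0], 1), _update([0.0], 1)]
        out = fedaw_aggregate(ups, [3.0, 1.0])
        np.testing.assert_allclose(out.values, [0.75])

    def test_all_zero_scores_fall_back_with_warning(self):
        ups = [_update([2.0], 1), _update([6.0], 1)]
        with pytest.warns(UserWarning):
            out = fedaw_aggregate(ups, [0.0, 0.0])
        np.testing.assert_allclose(out.values, [4.0])


class TestContract:
    def test_symmetry_collapse_across_all_strategies(self):
        """Identical updates from cloned clients: every strategy returns the
        same global model."""
        rng = np.random.default_rng(0)
        vals = rng.normal(size=40)
        global_params = ParamVector.from_arrays({"w": np.zeros(40)})
        ups = [ClientUpdate(cid, ParamVector.from_arrays({"w": vals.copy()}), 7,
                            val_loss=0.5)
               for cid in range(10)]
        outs = {}
        for name in ("fedavg", "fedprox", "fedbn", "feddyn", "fedaw", "fedgh"):
            agg = make_aggregator(name, eta=1e-3)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out, report = agg.aggregate(ups, global_params,
                                            np.random.default_rng(1))
            assert report.objective == pytest.approx(0.0)
            outs[name] = out.values
        for name, v in outs.items():
            np.testing.assert_allclose(v, vals, rtol=1e-9,
                                       err_msg=f"{name} broke symmetry")

    def test_weights_finite_outputs(self):
        rng = np.random.default_rng(5)
        global_params = ParamVector.from_arrays({"w": rng.normal(size=20)})
        ups = [ClientUpdate(c, ParamVector.from_arrays(
            {"w": rng.normal(size=20)}), int(rng.integers(1, 30)),
            val_loss=float(rng.random())) for c in range(6)]
        for name in ("fedavg", "fedprox", "feddyn", "fedaw", "fedgh"):
            agg = make_aggregator(name, eta=1e-3)
            out, _ = agg.aggregate(ups, global_params, np.random.default_rng(2))
            assert np.all(np.isfinite(out.values))
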