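"""Hebbian successor/predecessor learning against its closed forms."""

import numpy as np
import pytest

import laplacemem as lm
from laplacemem.assoc_memory import (RhoGrid, init_memory, predict_future_init,
                                     steady_state_oracle,
                                     update_on_presentation)
from laplacemem.core_manifold import AntiTrace, PastState
from laplacemem.schedules import LagSpec
from laplacemem import demos


def play_trial(mem, grid, events, reset=True, iti=1000.0,
               past=None, anti=None):
    """Hand-drive one trial: events is a list of (symbol, time)."""
    symbols = mem.symbols
    if past is None:
        past = PastState(grid, symbols)
        anti = AntiTrace(grid, symbols)
    if reset:
        past.reset()
        anti.reset()
    t0 = past.clock
    for sym, t in events:
        dt = (t0 + t) - past.clock
        lm.evolve_past(past, dt)
        anti.evolve(dt)
        update_on_presentation(mem, past, anti, sym)
        lm.encode_present(past, sym)
        anti.encode(sym)
    lm.evolve_past(past, iti)
    anti.evolve(iti)
    return past, anti


class TestInit:
    def test_shapes(self):
        g = lm.make_s_grid(0.01, 10, 4)
        mem = init_memory(("x", "y"), g, RhoGrid(np.array([0.5, 0.9, 0.99])))
        assert mem.M.shape == (3, 4, 2, 2)
        assert mem.Mbar.shape == (3, 8, 2, 2)  # 2N signed entries
        assert mem.successor_row(0, "y", "x").sum() == 0.0
        assert mem.successor_at_zero(2, "y", "x") == 0.0

    def test_signed_axis(self):
        g = lm.make_s_grid(0.01, 10, 4)
        mem = init_memory(("x",), g, RhoGrid.single(0.5))
        np.testing.assert_array_equal(mem.signed_s_values,
                                      np.concatenate([g.s_values, -g.s_values]))

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            init_memory((), lm.make_s_grid(0.01, 10, 4), RhoGrid.single(0.5))


class TestUpdate:
    def test_single_pairing_hand_values(self, grid64, s1_index):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.5))
        play_trial(mem, grid64, [("x", 0.0), ("y", 2.0)])
        row = mem.successor_row(0, "y", "x")
        np.testing.assert_allclose(row, 0.5 * np.exp(-2 * grid64.s_values),
                                   rtol=1e-12)
        assert mem.successor_at_zero(0, "y", "x") == pytest.approx(0.5)
        assert row[s1_index] == pytest.approx(0.067668, abs=1e-6)

    def test_predecessor_mirrored_values(self, grid64, s1_index):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.5))
        play_trial(mem, grid64, [("x", 0.0), ("y", 2.0)])
        plus = mem.predecessor_row(0, "x", "y")
        minus = mem.predecessor_row(0, "x", "y", mirrored=True)
        assert plus[s1_index] == pytest.approx(0.5 * np.exp(-2.0), rel=1e-12)
        assert minus[s1_index] == pytest.approx(3.694528, abs=1e-6)

    def test_source_presentation_decays(self, grid64, s1_index):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.5))
        past, anti = play_trial(mem, grid64, [("x", 0.0), ("y", 2.0)])
        play_trial(mem, grid64, [("x", 0.0)], past=past, anti=anti)
        assert mem.successor_row(0, "y", "x")[s1_index] == pytest.approx(
            0.25 * np.exp(-2.0), rel=1e-12)

    def test_growing_trace_masked_beyond_cap(self, grid64):
        """Entries whose mirrored exponent overflows the cap are NaN."""
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.5))
        play_trial(mem, grid64, [("x", 0.0), ("y", 8.0)])  # smax*8 = 80 > 30
        minus = mem.predecessor_row(0, "x", "y", mirrored=True)
        assert np.isnan(minus[0])            # s = 10
        assert np.isfinite(minus[-1])        # s = 0.01

    def test_weights_bounded_by_one(self, grid64, trainer):
        res = trainer(demos.deterministic_pairing(200, seed=3), 0.5)
        assert np.nanmax(res.memory.M) <= 1.0 + 1e-12


class TestClosedForms:
    def test_deterministic_finite_n_geometric_sum(self, grid64, trainer):
        """After n deterministic pairings, M_yx = (1 - rho^n) e^{-s tau}."""
        rho, n, tau = 0.9, 40, 3.0
        res = trainer(demos.deterministic_pairing(n, lag=tau, seed=0), rho)
        expected = (1 - rho ** n) * np.exp(-grid64.s_values * tau)
        np.testing.assert_allclose(res.memory.successor_row(0, "y", "x"),
                                   expected, rtol=1e-9)
        assert res.memory.successor_at_zero(0, "y", "x") == pytest.approx(
            1 - rho ** n, abs=1e-12)

    def test_transpose_like_duality(self, grid64, trainer):
        """With one source and one target, Mbar_xy(+s) equals M_yx(+s)."""
        res = trainer(demos.deterministic_pairing(25, seed=2), 0.8)
        np.testing.assert_array_equal(
            res.memory.predecessor_row(0, "x", "y"),
            res.memory.successor_row(0, "y", "x"))

    def test_probability_recovered_as_rho_to_one(self, trainer):
        """The s=0 weight converges to P(y|x) as rho -> 1 over seeds.

        0.05 is 1.76 SD of the exponentially weighted mean at rho = 0.99
        (true per-seed rate ~0.92), so the battery asserts the binomially
        consistent count plus a tight bound on the median error.
        """
        errs = []
        for seed in range(20):
            res = trainer(demos.probabilistic_pairing(0.8, 2000, seed=seed),
                          0.99)
            errs.append(abs(res.memory.successor_at_zero(0, "y", "x") - 0.8))
        assert sum(e <= 0.05 for e in errs) >= 14
        assert np.median(errs) <= 0.05

    def test_smaller_learning_rate_tightens_estimate(self, trainer):
        """Error shrinks as rho -> 1 (averaged over a small seed battery)."""
        def mean_err(rho):
            return np.mean([
                abs(trainer(demos.probabilistic_pairing(0.8, 2000, seed=s),
                            rho).memory.successor_at_zero(0, "y", "x") - 0.8)
                for s in range(6)])
        assert mean_err(0.99) < mean_err(0.9) < mean_err(0.5)

    def test_gamma_mgf_curve_recovered(self, grid64, trainer):
        """Normalized weights trace (1+s)^-2 for gamma(2,1) lags."""
        res = trainer(demos.gamma_lag_pairing(5000, seed=1), 0.995)
        mem = res.memory
        curve = mem.successor_row(0, "y", "x") / mem.successor_at_zero(0, "y", "x")
        expected = (1.0 + grid64.s_values) ** -2.0
        assert np.max(np.abs(curve - expected)) <= 0.03


class TestSteadyStateOracle:
    def test_fixed_lag(self):
        assert steady_state_oracle(0.8, LagSpec.fixed(3.0), 1.0) == \
            pytest.approx(0.039829, abs=1e-6)

    def test_zero_s_gives_probability(self):
        for lag in (LagSpec.fixed(3.0), LagSpec.uniform((1, 2, 5)),
                    LagSpec.gamma(2, 1)):
            assert steady_state_oracle(0.8, lag, 0.0) == pytest.approx(0.8)

    def test_gamma_mgf(self):
        assert steady_state_oracle(0.8, LagSpec.gamma(2.0, 1.0), 1.0) == \
            pytest.approx(0.2)

    def test_divergent_mgf_rejected(self):
        with pytest.raises(ValueError):
            steady_state_oracle(0.8, LagSpec.gamma(2.0, 1.0), -1.5)


class TestPredictFutureInit:
    def test_exact_exponential_row(self, grid64):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.9))
        mem.M[0, :, 1, 0] = 0.8 * np.exp(-3.0 * grid64.s_values)
        mem.M0[0, 1, 0] = 0.8
        pred = predict_future_init(mem, "x", 0)
        (src,) = pred.sources
        assert (src.symbol, src.weight) == ("y", 0.8)
        assert src.tau_rem == pytest.approx(3.0, abs=1e-9)
        assert not pred.multimodal

    def test_zero_memory_no_sources(self, grid64):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.9))
        assert predict_future_init(mem, "x", 0).sources == []

    def test_two_targets_decoded_independently(self, grid64):
        mem = init_memory(("x", "y", "z"), grid64, RhoGrid.single(0.9))
        mem.M[0, :, 1, 0] = 0.5 * np.exp(-2.0 * grid64.s_values)
        mem.M[0, :, 2, 0] = 0.5 * np.exp(-7.0 * grid64.s_values)
        srcs = {s.symbol: s for s in predict_future_init(mem, "x", 0).sources}
        assert srcs["y"].tau_rem == pytest.approx(2.0, abs=1e-9)
        assert srcs["z"].tau_rem == pytest.approx(7.0, abs=1e-9)
        assert srcs["y"].weight == pytest.approx(0.5, abs=1e-9)

    def test_bimodal_row_flagged(self, grid64):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.9))
        mem.M[0, :, 1, 0] = 0.5 * (np.exp(-1.0 * grid64.s_values)
                                   + np.exp(-9.0 * grid64.s_values))
        pred = predict_future_init(mem, "x", 0)
        assert "y" in pred.multimodal
        sampled = predict_future_init(mem, "x", 0, mode="sample",
                                      rng=np.random.default_rng(0))
        assert sampled.sources[0].tau_rem > 0

    def test_unknown_symbol(self, grid64):
        mem = init_memory(("x", "y"), grid64, RhoGrid.single(0.9))
        with pytest.raises(ValueError):
            predict_future_init(mem, "q", 0)


class TestPersistence:
    def test_save_load_bit_exact(self, grid64, trainer, tmp_path):
        res = trainer(demos.dependent_chain(30, seed=5), RhoGrid.default())
        path = tmp_path / "mem.npz"
        res.memory.save(path)
        loaded = lm.AssocMemory.load(path)
        np.testing.assert_array_equal(loaded.M, res.memory.M)
        np.testing.assert_array_equal(loaded.Mbar, res.memory.Mbar)
        np.testing.assert_array_equal(loaded.M0, res.memory.M0)
        assert loaded.symbols == res.memory.symbols

    def test_tidy_frame_layout(self, grid64):
        mem = init_memory(("x", "y"), lm.make_s_grid(0.1, 10, 3),
                          RhoGrid.single(0.5))
        df = mem.to_frame()
        assert list(df.columns) == ["rho", "s", "target", "source", "value"]
        assert len(df) == 1 * 3 * 2 * 2
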