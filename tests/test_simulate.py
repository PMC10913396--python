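"""Steady-state simulator: closed forms, fixed points, subsampling, dropout."""

import numpy as np
import pytest
from scipy import optimize

from spred.grn import GrnConfig, GrnSpec, RegEdge, sample_grn, sample_interaction_params
from spred.simulate import (
    ConditionPanel,
    ExpressionMatrix,
    SimParams,
    deterministic_steady_state,
    inject_dropout,
    read_expression_tsv,
    read_master_rates_file,
    sample_mr_rates,
    simulate_steady_state,
    subsample_conditions,
    write_expression_tsv,
    write_master_rates_file,
)

FAST = SimParams(burn_in=2000, n_steps=500)


def _panel(rates):
    rates = np.asarray(rates, dtype=float)
    return ConditionPanel(rates=rates, low_range=(rates.min(), rates.min()),
                          high_range=(rates.max(), rates.max()))


class TestMrRates:
    def test_panel_shape_and_ranges(self):
        panel = sample_mr_rates(5, 100, seed=0)
        assert panel.rates.shape == (5, 100)
        lo, hi = panel.low_range, panel.high_range
        in_low = (panel.rates >= lo[0]) & (panel.rates <= lo[1])
        in_high = (panel.rates >= hi[0]) & (panel.rates <= hi[1])
        assert np.all(in_low | in_high)
        assert np.all(panel.rates > 0)

    def test_point_intervals_give_two_valued_rates(self):
        pool = [((0.5, 0.5), (2.0, 2.0))]
        panel = sample_mr_rates(4, 50, range_pool=pool, seed=1)
        assert set(np.round(panel.rates, 12).ravel()) <= {0.5, 2.0}

    def test_high_interval_chosen_half_the_time(self):
        pool = [((0.5, 0.5), (2.0, 2.0))]
        panel = sample_mr_rates(10, 1000, range_pool=pool, seed=2)
        frac_high = (panel.rates == 2.0).mean()
        n = panel.rates.size
        assert abs(frac_high - 0.5) < 4 * np.sqrt(0.25 / n)

    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            sample_mr_rates(2, 10, range_pool=[((0.0, 0.5), (1.0, 2.0))])
        with pytest.raises(ValueError):
            sample_mr_rates(2, 10, range_pool=[((0.5, 1.5), (1.0, 2.0))])


class TestDeterministicLimit:
    def test_isolated_mr_reaches_rate_over_decay(self):
        grn = GrnSpec(n_mr=1, n_tf=0, n_gene=0)
        panel = _panel([[2.0, 0.5, 1.0]])
        params = SimParams(noise_scale=0.0)
        expr = simulate_steady_state(grn, panel, params, seed=0)
        np.testing.assert_allclose(expr.values[0], np.array([2.0, 0.5, 1.0]) / params.decay,
                                   rtol=1e-6)

    def test_saturating_activator_approaches_k_over_decay(self):
        """Parent far above its half-response drives the child to |k|/decay."""
        grn = GrnSpec(
            n_mr=1, n_tf=1, n_gene=0,
            edges=[RegEdge(parent=0, child=1, k=3.0, hill_n=2)],
        )
        # widely spread rates: in the high-rate condition x_parent >> h
        panel = _panel([[0.01] * 9 + [100.0]])
        params = SimParams(noise_scale=0.0)
        expr = simulate_steady_state(grn, panel, params, seed=0)
        assert expr.values[1, -1] == pytest.approx(3.0 / params.decay, rel=0.01)

    def test_noise_free_simulation_matches_independent_fixed_point(self):
        """Euler-integrated noise-free output equals the Hill-ODE fixed point
        found by an independent root solver, on a 10-node random GRN."""
        cfg = GrnConfig(n_mr=2, n_tf=4, n_gene=4, d_mr_tf=2, d_tf_gene_range=(1, 3))
        grn = sample_interaction_params(sample_grn(cfg, 3), 4)
        panel = sample_mr_rates(2, 5, seed=5)
        params = SimParams(noise_scale=0.0)
        expr = simulate_steady_state(grn, panel, params, seed=0)
        _, h = deterministic_steady_state(grn, panel, params)
        for c in range(panel.n_celltype):
            def residual(x):
                prod = np.zeros(grn.n_nodes)
                prod[: grn.n_mr] = panel.rates[:, c]
                for e in grn.edges:
                    xp, hp, n = x[e.parent], h[e.parent], e.hill_n
                    hill = xp**n / (hp**n + xp**n) if e.k > 0 else hp**n / (hp**n + xp**n)
                    prod[e.child] += abs(e.k) * hill
                return prod - params.decay * x
            sol = optimize.root(residual, np.full(grn.n_nodes, 0.5), method="hybr")
            assert sol.success
            np.testing.assert_allclose(expr.values[:, c], sol.x, rtol=1e-3, atol=1e-6)

    def test_activating_child_is_monotone_in_parent_rate(self):
        """Raising the MR production rate never lowers the deterministic
        steady state of an activated child (grid over a 2-node system)."""
        grn = GrnSpec(n_mr=1, n_tf=1, n_gene=0,
                      edges=[RegEdge(parent=0, child=1, k=2.0, hill_n=2)])
        params = SimParams(noise_scale=0.0)
        rates = np.linspace(0.2, 3.0, 15)
        panel = _panel(rates[None, :])
        det, _ = deterministic_steady_state(grn, panel, params)
        child = det[1]
        assert np.all(np.diff(child) >= -1e-12)


class TestStochastic:
    def test_values_stay_nonnegative(self, tiny_grn):
        panel = sample_mr_rates(tiny_grn.n_mr, 20, seed=1)
        expr = simulate_steady_state(tiny_grn, panel, SimParams(noise_scale=2.0), seed=2)
        assert np.all(expr.values >= 0)

    def test_same_seed_reproduces_bit_identical_matrix(self, tiny_grn):
        panel = sample_mr_rates(tiny_grn.n_mr, 10, seed=1)
        params = SimParams(burn_in=300, n_steps=50)
        a = simulate_steady_state(tiny_grn, panel, params, seed=3)
        b = simulate_steady_state(tiny_grn, panel, params, seed=3)
        assert np.array_equal(a.values, b.values)
        c = simulate_steady_state(tiny_grn, panel, params, seed=4)
        assert not np.array_equal(a.values, c.values)

    def test_row_blocks_follow_grn_layers(self, tiny_grn, tiny_expression):
        roles = tiny_expression.row_roles
        assert list(roles) == ["MR"] * 2 + ["TF"] * 5 + ["GENE"] * 6


class TestSubsampleAndDropout:
    def test_full_subsample_is_identity(self, tiny_expression):
        out = subsample_conditions(tiny_expression, tiny_expression.n_conditions, seed=0)
        assert np.array_equal(out.values, tiny_expression.values)
        assert out.condition_ids == tiny_expression.condition_ids

    def test_subsample_preserves_order_and_membership(self, tiny_expression):
        out = subsample_conditions(tiny_expression, 10, seed=1)
        assert out.values.shape[1] == 10
        positions = [tiny_expression.condition_ids.index(c) for c in out.condition_ids]
        assert positions == sorted(positions)
        for j, pos in enumerate(positions):
            assert np.array_equal(out.values[:, j], tiny_expression.values[:, pos])

    def test_subsample_varies_with_seed(self, tiny_expression):
        a = subsample_conditions(tiny_expression, 5, seed=1)
        b = subsample_conditions(tiny_expression, 5, seed=2)
        assert a.condition_ids != b.condition_ids

    def test_subsample_too_many_raises(self, tiny_expression):
        with pytest.raises(ValueError):
            subsample_conditions(tiny_expression, tiny_expression.n_conditions + 1)

    def test_dropout_zero_and_one(self, tiny_expression):
        same = inject_dropout(tiny_expression, 0.0, seed=0)
        assert np.array_equal(same.values, tiny_expression.values)
        gone = inject_dropout(tiny_expression, 1.0, seed=0)
        assert np.all(gone.values == 0)

    def test_dropout_zeroes_exact_count(self, rng):
        values = rng.uniform(1, 2, size=(10, 10))
        expr = ExpressionMatrix(values, np.array(["GENE"] * 10), [f"c{i}" for i in range(10)])
        out = inject_dropout(expr, 0.5, seed=7)
        changed = (out.values == 0) & (expr.values != 0)
        assert changed.sum() == 50
        untouched = out.values != 0
        assert np.array_equal(out.values[untouched], expr.values[untouched])


class TestFileFormats:
    def test_expression_tsv_round_trip(self, tiny_expression, tmp_path):
        path = tmp_path / "expr.tsv"
        write_expression_tsv(tiny_expression, path)
        back = read_expression_tsv(path)
        np.testing.assert_allclose(back.values, tiny_expression.values, rtol=1e-12)
        assert list(back.row_roles) == list(tiny_expression.row_roles)
        assert back.condition_ids == tiny_expression.condition_ids

    def test_master_rates_round_trip(self, tmp_path):
        panel = sample_mr_rates(3, 10, seed=5)
        path = tmp_path / "mrs.csv"
        write_master_rates_file(panel, path)
        back = read_master_rates_file(path)
        np.testing.assert_array_equal(back.rates, panel.rates)


def test_unstable_integration_params_rejected():
    with pytest.raises(ValueError):
        SimParams(decay=2.0, dt=0.6)
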