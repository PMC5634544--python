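"""Tests for parameter sweeps, multi-day runs, and debt-shape diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sleepenergy as se


class TestSweepMai:
    def test_zero_target_reduces_to_mr_strategy(self, mai_sweep_table):
        row0 = mai_sweep_table.iloc[0]
        assert row0["mai_target"] == 0.0
        assert row0["ES_MAI"] == 0.0  # identical to the MR-reduction match

    def test_clamp_caps_achievable_mai(self, mai_sweep_table):
        tab = mai_sweep_table
        assert tab["mai_achieved"].max() == pytest.approx(0.71, abs=0.02)
        # achieved tracks the target until the clamp, then saturates
        low = tab[tab["mai_target"] <= 0.5]
        assert np.allclose(low["mai_achieved"], low["mai_target"], atol=1e-6)

    def test_savings_rederivable_from_stored_rates(self, mai_sweep_table):
        """Every row's ES values must reproduce exactly from its stored
        mean metabolic rates (pure arithmetic, no integration)."""
        for _, row in mai_sweep_table[mai_sweep_table["has_cycle"]].iterrows():
            es = se.energy_savings(row["m_MR1"], row["m_MR2"], row["m_MR3"])
            assert row["ES_total"] == pytest.approx(es.ES_total, abs=1e-12)
            assert row["ES_rho"] == pytest.approx(es.ES_rho, abs=1e-12)
            p = se.ModelParameters(TST_h=row["TST_h"]).with_rates(
                row["r_Ww"], row["r_Bw"], row["r_Ws"], row["r_Bs"]
            )
            assert se.mean_MR(p) == pytest.approx(row["m_MR3"], abs=1e-12)

    def test_determinism(self, standard, mai_sweep_table):
        again = se.sweep_mai([0.0, 0.4], 0.3, 8.0, standard)
        sub = mai_sweep_table[mai_sweep_table["mai_target"].isin([0.0, 0.4])]
        for col in ("ES_total", "r_Bw", "m_BD"):
            assert np.array_equal(sub[col].to_numpy(), again[col].to_numpy())


class TestSweepTst:
    def test_partitioning_dominates_at_all_quotas(self, tst_sweep_table):
        ok = tst_sweep_table[tst_sweep_table["has_cycle"]]
        assert (ok["ES_MAI"] >= ok["ES_rho"]).all()

    def test_marginal_gains_cross_over(self, tst_sweep_table):
        """Short quotas: extra sleep buys mostly partitioning savings; past
        ~14 h the per-hour gains come mostly from rate reduction."""
        t = tst_sweep_table.set_index("TST_h")
        d_mai = t["ES_MAI"].diff()
        d_rho = t["ES_rho"].diff()
        assert d_mai[5.0] > d_rho[5.0]
        assert d_rho[16.0] > d_mai[16.0]

    def test_long_quota_total_savings(self, tst_sweep_table):
        assert tst_sweep_table["ES_total"].max() > 50.0

    def test_zero_quota_equals_baseline(self, standard):
        tab = se.sweep_tst([0.0], 0.4, 0.3, standard)
        assert tab.iloc[0]["ES_total"] == pytest.approx(0.0, abs=0.05)


@pytest.fixture(scope="module")
def rho_sweep_table(standard):
    return se.sweep_rho([0.0, 0.3, 0.9], 0.7, 8.0, standard)


@pytest.fixture(scope="module")
def circadian_sweep_table(standard):
    return se.sweep_circadian([0.0, 0.6], [0.0, 2.5], 0.3, 8.0, standard)


@pytest.fixture(scope="module")
def restriction_rates(mp_04):
    """Fixed-rate convention for sleep-restriction runs: the rates matched
    at TST = 8, MAI target 0.4, rho = 0.3."""
    return (mp_04.r_Ww, mp_04.r_Bw, mp_04.r_Ws, mp_04.r_Bs)


class TestSweepRho:
    def test_no_reduction_means_no_rho_savings(self, rho_sweep_table):
        table = rho_sweep_table
        assert table.iloc[0]["ES_rho"] == pytest.approx(0.0, abs=0.05)
        assert table.iloc[0]["ES_total"] == pytest.approx(35.6, abs=0.5)

    def test_deep_reduction_constrains_partitioning(self, rho_sweep_table):
        t = rho_sweep_table.set_index("rho")
        assert t.loc[0.9, "ES_MAI"] < t.loc[0.3, "ES_MAI"]
        assert t.loc[0.9, "mai_achieved"] < t.loc[0.3, "mai_achieved"]


class TestSweepCircadian:
    def test_amplitude_hurts_without_partitioning(self, circadian_sweep_table):
        t = circadian_sweep_table.set_index(["mai_target", "A"])
        assert t.loc[(0.0, 2.5), "ES_total"] < t.loc[(0.0, 0.0), "ES_total"]

    def test_amplitude_helps_with_partitioning(self, circadian_sweep_table):
        t = circadian_sweep_table.set_index(["mai_target", "A"])
        assert t.loc[(0.6, 2.5), "ES_total"] > t.loc[(0.6, 0.0), "ES_total"]

    def test_zero_amplitude_column_matches_mai_sweep(
        self, circadian_sweep_table, standard
    ):
        direct = se.sweep_mai([0.0, 0.6], 0.3, 8.0, standard.with_(A=0.0))
        t = circadian_sweep_table.set_index(["mai_target", "A"])
        for mai in (0.0, 0.6):
            assert t.loc[(mai, 0.0), "ES_total"] == pytest.approx(
                direct.set_index("mai_target").loc[mai, "ES_total"], abs=1e-9
            )


class TestSensitivity:
    def test_small_grid_flags_missing_and_is_deterministic(self, standard):
        tab = se.sensitivity_grid(
            [0.0, 1.3], [0.0, 0.7], [5.0], standard, TST_h=8.0, rho=0.3,
            mai_target=0.4,
        )
        assert len(tab) == 4
        # the (p_W=0, p_B1=0) corner has no limit cycle but stays in the table
        corner = tab[(tab["p_W"] == 0.0) & (tab["p_B1"] == 0.0)].iloc[0]
        assert not corner["has_cycle"]
        # duplicate evaluation is bit-identical
        again = se.sensitivity_grid(
            [0.0, 1.3], [0.0, 0.7], [5.0], standard, TST_h=8.0, rho=0.3,
            mai_target=0.4,
        )
        assert tab.equals(again)
        s = se.summarize_sensitivity(tab)
        assert s["n_points"] == 4 and s["n_with_cycle"] < 4


class TestMultiday:
    def test_full_quota_reaches_steady_state(self, standard, mp_04, restriction_rates):
        p = standard.with_rates(*restriction_rates)
        run = se.multiday_run(6, p, mp_04.cycle.BD0)
        assert run.steady_state and not run.escalation
        means = run.days["mean_BD"].to_numpy()
        assert np.allclose(means, means[0], rtol=1e-4)

    def test_restriction_below_4h_breaks_homeostasis(
        self, standard, mp_04, restriction_rates
    ):
        for tst in (2.0, 3.0):
            p = standard.with_(TST_h=tst).with_rates(*restriction_rates)
            run = se.multiday_run(12, p, mp_04.cycle.BD0)
            assert not run.steady_state

    def test_severe_restriction_escalates(self, standard, mp_04, restriction_rates):
        p = standard.with_(TST_h=1.0).with_rates(*restriction_rates)
        run = se.multiday_run(12, p, mp_04.cycle.BD0)
        assert run.escalation and not run.steady_state

    def test_mild_restriction_stabilizes_at_elevated_debt(
        self, standard, mp_04, restriction_rates
    ):
        p = standard.with_(TST_h=6.0).with_rates(*restriction_rates)
        run = se.multiday_run(12, p, mp_04.cycle.BD0)
        assert run.steady_state
        assert run.days["mean_BD"].iloc[-1] > mp_04.m_BD  # elevated level

    def test_debt_continuous_across_reset(self, standard, mp_04, restriction_rates):
        p = standard.with_rates(*restriction_rates)
        run = se.multiday_run(3, p, 1.0)
        day_len = len(run.BD) // 3
        for d in (1, 2):
            before = run.BD[d * day_len - 1]
            after = run.BD[d * day_len]
            assert after == pytest.approx(before, rel=1e-9)

    def test_zero_rates_trivially_steady(self, standard):
        p = standard.with_rates(0, 0, 0, 0)
        run = se.multiday_run(3, p, 0.7)
        assert run.steady_state and not run.escalation
        assert np.allclose(run.BD, 0.7, atol=1e-10)


class TestShapeMetrics:
    def test_flat_line_without_circadian_or_partitioning(self):
        p0 = se.ModelParameters(A=0.0)
        w0 = se.solve_strategy_wake(p0)
        mr0 = se.match_mean_BD(w0.m_BD, 0.3, 0.0, p0)
        m = se.bd_shape_metrics(mr0.cycle.trajectory)
        assert m["bd_range"] < 1e-6

    def test_sinusoid_like_with_circadian_only(self, mr_reduction):
        m = se.bd_shape_metrics(mr_reduction.cycle.trajectory)
        assert m["bd_range"] > 0.01
        assert m["n_local_max"] == 1 and m["n_local_min"] == 1

    def test_homeostat_shape_with_partitioning(self, mp_04):
        """Partitioning turns the debt curve into the homeostat pattern:
        rising through wake, falling through sleep."""
        m = se.bd_shape_metrics(mp_04.cycle.trajectory)
        assert m["wake_increasing_frac"] > 0.9
        assert m["sleep_decreasing_frac"] > 0.9
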