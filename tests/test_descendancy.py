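"""Salient-change calling, adaptive FDR, peak retest, CDMs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ctxcausal.rppa_io import Context
from ctxcausal.descendancy import (
    adaptive_fdr,
    build_descendancy_matrix,
    call_salient_changes,
    context_difference_stats,
    detect_peak_window,
    paired_mean_test,
    pooled_replicate_sd,
)
from ctxcausal.synthetic_data import simulate_change_panel
from conftest import make_dataset


class TestPairedMeanTest:
    def test_identical_series_is_null(self):
        r = paired_mean_test([1, 2, 3], [1, 2, 3])
        assert (r.t, r.p, r.effect) == (0.0, 1.0, 0.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=7), rng.normal(size=7)
        r1, r2 = paired_mean_test(a, b), paired_mean_test(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.effect == pytest.approx(-r2.effect)
        assert r1.p == pytest.approx(r2.p)

    def test_worked_example_frozen_values(self):
        """d = 1..7: t = 4/(2.1602/sqrt(7)) = 4.8990, p = 0.0027137 (df 6)."""
        r = paired_mean_test(np.arange(1.0, 8.0), np.zeros(7))
        assert r.t == pytest.approx(4.898979, abs=1e-5)
        assert r.p == pytest.approx(0.0027137, abs=1e-6)
        assert r.effect == 4.0

    def test_agrees_with_scipy_on_random_series(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=7), rng.normal(size=7)
            ours = paired_mean_test(a, b)
            ref = sps.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic)
            assert ours.p == pytest.approx(ref.pvalue)

    def test_degenerate_cases(self):
        shifted = paired_mean_test([1.0, 2.0], [0.0, 1.0])
        assert shifted.p == 0.0 and shifted.degenerate
        equal = paired_mean_test([1.0, 2.0], [1.0, 2.0])
        assert equal.p == 1.0 and equal.degenerate


class TestPeakWindow:
    def test_monotone_series_has_no_window(self):
        assert detect_peak_window(np.arange(7.0), 0.5) is None

    def test_worked_example_window(self):
        """{0,3,5,4,2,1,0}: half height 2.5, run of intermediate indices
        above it is {1,2,3}."""
        w = detect_peak_window(np.array([0, 3, 5, 4, 2, 1, 0.0]), 0.5)
        np.testing.assert_array_equal(w, [1, 2, 3])

    def test_flat_series_has_no_window(self):
        assert detect_peak_window(np.ones(7), 0.5) is None

    def test_exceedance_must_clear_both_endpoints(self):
        y = np.array([0.0, 0.4, 0.5, 0.4, 0.3, 0.2, 0.1])
        assert detect_peak_window(y, rep_sd=1.0) is None  # 0.5 < 1.0 over endpoint
        assert detect_peak_window(y, rep_sd=0.1) is not None

    def test_window_narrower_than_two_rejected(self):
        y = np.array([0.0, 0.1, 5.0, 0.1, 0.0, 0.0, 0.0])
        assert detect_peak_window(y, rep_sd=0.5) is None


def _two_stage_oracle(p, q):
    """Literal transcription of the two-stage adaptive step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    q1 = q / (1 + q)

    def step_up(p, level):
        order = np.argsort(p)
        reject_upto = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= level * k / m:
                reject_upto = k
        flags = np.zeros(m, bool)
        flags[order[:reject_upto]] = True
        return flags

    s1 = step_up(p, q1)
    r1 = s1.sum()
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return step_up(p, q1 * m / (m - r1))


class TestAdaptiveFdr:
    def test_all_ones_rejects_nothing(self):
        flags, _ = adaptive_fdr(np.ones(35))
        assert not flags.any()

    def test_all_tiny_rejects_everything(self):
        flags, _ = adaptive_fdr(np.full(35, 1e-12))
        assert flags.all()

    def test_worked_example_matches_stepwise_definition(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.09, 0.7])
        flags, adj = adaptive_fdr(p, q=0.05)
        np.testing.assert_array_equal(flags, _two_stage_oracle(p, 0.05))
        np.testing.assert_array_equal(flags, [True, True, True, True, False, False])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_and_statsmodels_on_random_panels(self, seed):
        rng = np.random.default_rng(seed)
        p = np.concatenate([rng.uniform(size=25), rng.uniform(0, 0.01, size=10)])
        flags, adj = adaptive_fdr(p, q=0.05)
        np.testing.assert_array_equal(flags, _two_stage_oracle(p, 0.05))
        ref_flags, ref_adj, *_ = multipletests(p, alpha=0.05, method="fdr_tsbky")
        np.testing.assert_array_equal(flags, ref_flags)
        # statsmodels scales its adjusted values by (1+q); rejections agree
        np.testing.assert_allclose(adj * 1.05, ref_adj, atol=1e-12)

    def test_rejections_monotone_in_q(self, rng):
        p = rng.uniform(size=35) ** 2
        prev = np.zeros(35, bool)
        for q in [0.01, 0.02, 0.05, 0.1, 0.2, 0.5]:
            flags, _ = adaptive_fdr(p, q=q)
            assert (flags | prev).sum() == flags.sum()  # superset of previous
            prev = flags

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adaptive_fdr(np.array([0.5, 1.5]))


class TestPooledReplicateSd:
    def test_identical_replicates_give_zero(self):
        sd, fb = pooled_replicate_sd([np.array([2.0, 2.0])], [np.array([3.0, 3.0])])
        assert sd == 0.0 and not fb

    def test_hand_pooled_variance(self):
        """DMSO {0,2} and inhibitor {1,3} each have variance 2 with 1 df,
        so the pooled SD is sqrt(2)."""
        sd, _ = pooled_replicate_sd([np.array([0.0, 2.0])], [np.array([1.0, 3.0])])
        assert sd == pytest.approx(np.sqrt(2))

    def test_mean_over_time_points(self):
        t1 = [np.array([0.0, 2.0])]  # pooled SD sqrt(2)... construct SDs 1 and 3
        a = [np.array([0.0, 2.0]) / np.sqrt(2)]  # SD 1
        b = [np.array([0.0, 6.0]) / np.sqrt(2)]  # SD 3
        sd, _ = pooled_replicate_sd(a + b, [np.empty(0), np.empty(0)])
        assert sd == pytest.approx(2.0)

    def test_fallback_when_no_replication(self):
        sd, fb = pooled_replicate_sd([np.array([1.0])], [np.array([2.0])], fallback=0.3)
        assert sd == 0.3 and fb


class TestCallSalientChanges:
    def test_strong_halving_effect_called_with_negative_sign(self, ctx):
        effects = np.zeros(10)
        effects[4] = 1.0  # inhibitor halves this protein (1 log2 unit)
        panel = simulate_change_panel(10, effects, noise_sd=0.05, seed=1)
        calls = call_salient_changes(panel, "INH", ctx)
        by_prot = {c.phosphoprotein: c for c in calls}
        hit = by_prot[panel.antibody_names[4]]
        assert hit.salient and hit.sign == -1
        assert all(
            not c.salient for c in calls if c.phosphoprotein != panel.antibody_names[4]
        )

    def test_identical_arms_yield_no_calls(self, ctx):
        panel = simulate_change_panel(10, np.zeros(10), noise_sd=0.05, seed=2)
        calls = call_salient_changes(panel, "INH", ctx)
        assert calls and not any(c.salient for c in calls)

    def test_increase_under_inhibition_has_positive_sign(self, ctx):
        effects = np.zeros(6)
        effects[0] = -0.8  # abundance rises under the inhibitor
        panel = simulate_change_panel(6, effects, noise_sd=0.03, seed=3)
        calls = call_salient_changes(panel, "INH", ctx)
        assert {c.sign for c in calls if c.salient} == {1}

    def test_missing_arm_warns_and_skips(self, ctx):
        panel = simulate_change_panel(4, seed=4)
        with pytest.warns(UserWarning, match="missing arm"):
            calls = call_salient_changes(panel, "NOT_A_REGIME", ctx)
        assert calls == []

    def test_peak_only_effect_needs_retest(self, ctx, rng):
        """An effect confined to a 3-point peak window washes out over all
        7 points but is recovered by the peak retest."""
        times = (0.0, 5.0, 15.0, 30.0, 60.0, 120.0, 240.0)
        n_prot, noise = 8, 0.02
        peak_shape = np.array([0.0, 2.0, 3.0, 2.0, 0.0, 0.0, 0.0])
        rows, vals = [], []
        rng2 = np.random.default_rng(7)
        for reg in ("DMSO", "INH"):
            for k, t in enumerate(times):
                n_rep = 8 if k == 0 else 2
                for rep in range(1, n_rep + 1):
                    base = np.full(n_prot, 10.0) + peak_shape[k]
                    if reg == "INH" and peak_shape[k] > 0:
                        base[0] -= 0.8  # flat effect confined to the peak window
                    rows.append(["MCF7", "EGF", reg, t, rep, "B1"])
                    vals.append(base + rng2.normal(0, noise, n_prot))
        data = make_dataset(
            np.array(vals),
            cell_line=[r[0] for r in rows],
            stimulus=[r[1] for r in rows],
            inhibitor=[r[2] for r in rows],
            times=[r[3] for r in rows],
            replicate=[r[4] for r in rows],
        )
        with_retest = call_salient_changes(data, "INH", ctx, peak_retest=True)
        without = call_salient_changes(data, "INH", ctx, peak_retest=False)
        target = data.antibody_names[0]
        p_with = {c.phosphoprotein: c.p_final for c in with_retest}[target]
        p_without = {c.phosphoprotein: c.p_final for c in without}[target]
        assert p_with < p_without
        assert {c.phosphoprotein: c.salient for c in with_retest}[target]


class TestDescendancyMatrix:
    def _call(self, prot, ctx, sign, regime="INH"):
        from ctxcausal.descendancy import ChangeCall

        return ChangeCall(
            phosphoprotein=prot,
            context=ctx,
            regime_id=regime,
            p_full=0.01,
            p_peak=None,
            p_final=0.01,
            q_fdr=0.01,
            effect=-float(sign),
            rep_sd=0.1,
            salient=sign != 0,
            sign=sign,
        )

    def test_single_decrease_entry(self):
        ctx = Context("MCF7", "EGF")
        cdm = build_descendancy_matrix([self._call("P1", ctx, -1)])
        assert cdm.entries.loc["P1", str(ctx)] == -1

    def test_no_salient_calls_gives_zero_matrix(self):
        ctx = Context("MCF7", "EGF")
        cdm = build_descendancy_matrix(
            [self._call("P1", ctx, 0), self._call("P2", ctx, 0)]
        )
        assert (cdm.entries.to_numpy() == 0).all()

    def test_unfilled_cells_are_missing_not_zero(self):
        c1, c2 = Context("MCF7", "EGF"), Context("BT20", "EGF")
        cdm = build_descendancy_matrix(
            [self._call("P1", c1, 1)], proteins=["P1", "P2"], contexts=[c1, c2]
        )
        assert np.isnan(cdm.entries.loc["P2", str(c2)])

    def test_matrix_agrees_with_call_list(self, rng):
        contexts = [Context(f"CL{i}", "S") for i in range(3)]
        prots = [f"P{i}" for i in range(5)]
        calls = [
            self._call(p, c, int(rng.integers(-1, 2)))
            for p in prots
            for c in contexts
        ]
        cdm = build_descendancy_matrix(calls, proteins=prots, contexts=contexts)
        for call in calls:
            assert cdm.entries.loc[call.phosphoprotein, str(call.context)] == call.sign

    def test_mixed_regimes_rejected(self):
        ctx = Context("MCF7", "EGF")
        with pytest.raises(ValueError):
            build_descendancy_matrix(
                [self._call("P1", ctx, 1), self._call("P1", ctx, 1, regime="OTHER")]
            )


class TestContextDifferenceStats:
    def _cdm(self, mat, contexts):
        return pd.DataFrame(
            mat, index=[f"P{i}" for i in range(len(mat))], columns=contexts
        )

    def test_identical_columns_give_zero(self):
        cols = ["CL1__S1", "CL2__S1"]
        cdms = {"INH": self._cdm([[1, 1], [0, 0], [-1, -1]], cols)}
        stats = context_difference_stats(cdms)
        assert stats["grand_mean"] == 0.0

    def test_presence_absence_definition(self):
        # A salient only in c1; B in both; C in neither -> one difference
        cols = ["CL1__S1", "CL2__S1"]
        cdms = {"INH": self._cdm([[1, 0], [-1, 1], [0, 0]], cols)}
        stats = context_difference_stats(cdms)
        assert stats["grand_mean"] == 1.0
        assert stats["cell_line_pairs_mean"] == 1.0
        assert np.isnan(stats["stimulus_pairs_mean"])

    def test_grand_mean_matches_nested_loop_oracle(self, rng):
        contexts = [f"CL{i}__S{j}" for i in range(3) for j in range(2)]
        cdms = {
            reg: self._cdm(rng.integers(-1, 2, size=(6, len(contexts))), contexts)
            for reg in ("R1", "R2")
        }
        got = context_difference_stats(cdms)["grand_mean"]
        counts = []
        for reg, cdm in cdms.items():
            for a, b in itertools.combinations(cdm.columns, 2):
                n = 0
                for prot in cdm.index:
                    if (cdm.loc[prot, a] != 0) != (cdm.loc[prot, b] != 0):
                        n += 1
                counts.append(n)
        assert got == pytest.approx(np.mean(counts))
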