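"""Loading normalization, batch normalization, QC, panel selection, imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctxcausal.rppa_io import AntibodyInfo, RppaDataset
from ctxcausal.preprocess import (
    average_replicates,
    batch_normalize,
    compute_snr,
    impute_series,
    impute_time_course,
    median_center_loading,
    qc_flag_samples,
    select_phospho_panel,
)
from conftest import make_dataset


class TestMedianCenterLoading:
    def test_all_zero_matrix_is_fixed_point(self):
        data = make_dataset(np.zeros((3, 3)))
        out, cf = median_center_loading(data)
        np.testing.assert_array_equal(out.values.to_numpy(), 0.0)
        np.testing.assert_array_equal(cf.cf_log2.to_numpy(), 0.0)
        np.testing.assert_array_equal(cf.cf_linear.to_numpy(), 1.0)

    def test_worked_three_by_three_matrix(self):
        """Rows {0,1,2},{1,2,3},{2,3,4}: antibody medians are {1,2,3}, so
        the per-sample CFs are {-1,0,1} and all normalized rows equal {1,2,3}."""
        data = make_dataset([[0, 1, 2], [1, 2, 3], [2, 3, 4]])
        out, cf = median_center_loading(data)
        np.testing.assert_allclose(cf.cf_log2.to_numpy(), [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out.values.to_numpy(), [[1, 2, 3]] * 3)

    def test_loading_multiplier_absorbed_into_cf(self, rng):
        """Multiplying one sample's linear values by 8 (log2 + 3) raises its
        linear CF 8-fold and leaves its normalized values unchanged."""
        base = rng.normal(10, 1, size=(5, 7))
        data = make_dataset(base)
        out0, cf0 = median_center_loading(data)
        shifted = base.copy()
        shifted[2] += 3.0  # x8 on the linear scale
        out1, cf1 = median_center_loading(make_dataset(shifted))
        assert cf1.cf_linear.iloc[2] == pytest.approx(8 * cf0.cf_linear.iloc[2])
        np.testing.assert_allclose(
            out1.values.iloc[2].to_numpy(), out0.values.iloc[2].to_numpy(), atol=1e-10
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        arrays(
            float,
            (5, 9),
            elements=st.floats(min_value=-20, max_value=20, allow_nan=False),
        )
    )
    def test_per_sample_median_invariant(self, mat):
        """After normalization, the median across antibodies of the
        antibody-centered output is zero for every sample."""
        data = make_dataset(mat)
        out, _ = median_center_loading(data)
        centered = out.values - data.values.median(axis=0)
        np.testing.assert_allclose(centered.median(axis=1).to_numpy(), 0.0, atol=1e-10)

    def test_idempotent_on_loading_artifacts(self, rng):
        """For data whose sample-to-sample variation is loading (a per-sample
        offset) plus small noise, a second normalization pass is a near
        no-op: its CFs shrink to the noise scale."""
        base = rng.normal(10, 1, size=7)
        loads = rng.uniform(-3, 3, size=6)
        noise = rng.normal(0, 0.01, size=(6, 7))
        data = make_dataset(base[None, :] + loads[:, None] + noise)
        once, cf1 = median_center_loading(data)
        twice, cf2 = median_center_loading(once)
        assert cf1.cf_log2.abs().max() > 1.0
        assert cf2.cf_log2.abs().max() < 0.05
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=0.05
        )


def _two_batch_data(rng, shift=1.0, scale=1.5):
    """UACC812-style pair of batches with a planted affine batch effect."""

    def batch(batch_id, inhibitors, transform=False, rep_offset=0):
        times = [0.0, 0.0, 0.0, 5.0, 15.0]  # 3 reps at t=0, singles later
        reps = [r + rep_offset for r in [1, 2, 3, 1, 1]]
        meta_rows, vals = [], []
        for inhib in inhibitors:
            for t, r in zip(times, reps):
                if inhib != "DMSO" and r > 1:
                    continue
                meta_rows.append(["UACC812", "EGF", inhib, t, r, batch_id])
                v = rng.normal(10, 1, size=4)
                if transform:
                    v = shift + scale * v
                vals.append(v)
        return make_dataset(
            np.array(vals),
            cell_line=[m[0] for m in meta_rows],
            stimulus=[m[1] for m in meta_rows],
            inhibitor=[m[2] for m in meta_rows],
            times=[m[3] for m in meta_rows],
            replicate=[m[4] for m in meta_rows],
            batch=batch_id,
        )

    b1 = batch("B1", ["DMSO", "AZD8055"])
    b2 = batch("B2", ["DMSO", "BEZ235"], transform=True, rep_offset=10)
    return b1, b2


class TestBatchNormalize:
    def test_printed_formula_value(self):
        # x = 5, mu1 = 0, sigma1 = 1, mu2 = 4, sigma2 = 2 -> 0.5
        assert 0.0 + 1.0 * (5.0 - 4.0) / 2.0 == 0.5

    def test_identity_when_stats_agree(self, rng):
        b1, _ = _two_batch_data(rng)
        b2 = b1.copy()
        b2.meta["batch"] = "B2"
        b2.meta["inhibitor"] = b2.meta["inhibitor"].replace("AZD8055", "BEZ235")
        b2.meta["replicate"] += 10
        combined, stats = batch_normalize(b1, b2)
        n1 = b1.n_samples
        np.testing.assert_allclose(
            combined.values.iloc[n1:].to_numpy(), b2.values.to_numpy(), atol=1e-10
        )

    def test_batch2_dmso_stats_match_batch1_after_transform(self, rng):
        b1, b2 = _two_batch_data(rng)
        combined, stats = batch_normalize(b1, b2)
        from ctxcausal.preprocess import _dmso_stats

        sub2 = combined.subset((combined.meta["batch"] == "B2").to_numpy())
        mu, sd = _dmso_stats(sub2, combined.antibody_names)
        np.testing.assert_allclose(mu.to_numpy(), stats.table["mu1"].to_numpy(), atol=1e-10)
        np.testing.assert_allclose(sd.to_numpy(), stats.table["sigma1"].to_numpy(), atol=1e-10)

    def test_each_value_matches_independent_formula(self, rng):
        """Every individual batch-2 value equals mu1 + sigma1 (x - mu2) / sigma2
        recomputed independently per antibody."""
        b1, b2 = _two_batch_data(rng)
        combined, stats = batch_normalize(b1, b2)
        n1 = b1.n_samples
        for ab in combined.antibody_names:
            row = stats.table.loc[ab]
            expect = row.mu1 + row.sigma1 * (b2.values[ab] - row.mu2) / row.sigma2
            np.testing.assert_allclose(
                combined.values[ab].iloc[n1:].to_numpy(), expect.to_numpy(), atol=1e-12
            )

    def test_sigma2_zero_falls_back_to_centering(self, rng):
        b1, b2 = _two_batch_data(rng)
        b2.values["AB0"] = 7.0  # constant -> sigma2 = 0
        with pytest.warns(UserWarning, match="sigma2"):
            combined, stats = batch_normalize(b1, b2)
        assert bool(stats.table.loc["AB0", "sigma2_zero"])
        n1 = b1.n_samples
        expect = 7.0 - stats.table.loc["AB0", "mu2"] + stats.table.loc["AB0", "mu1"]
        np.testing.assert_allclose(combined.values["AB0"].iloc[n1:], expect)


class TestSnr:
    def test_two_replicates(self):
        data = make_dataset([[2.0], [4.0]], scale="linear")
        table, _ = compute_snr(data)
        assert table.snr.iloc[0] == pytest.approx(3 / np.sqrt(2))

    def test_zero_sd_flagged_infinite(self):
        data = make_dataset([[3.0], [3.0], [3.0]], scale="linear")
        table, _ = compute_snr(data)
        assert np.isinf(table.snr.iloc[0]) and bool(table.sd_zero.iloc[0])

    def test_single_replicate_skipped_with_warning(self):
        data = make_dataset([[3.0]], scale="linear")
        with pytest.warns(UserWarning, match="single replicate"):
            table, _ = compute_snr(data)
        assert table.empty

    def test_grand_mean_tracks_inverse_cv(self, rng):
        """With lognormal replicate noise of known CV, the grand mean SNR
        approaches 1/CV (Monte Carlo over 1,000 groups)."""
        from scipy.special import gammaln

        cv = 0.1
        sigma = np.sqrt(np.log(1 + cv**2))
        n_groups, n_rep = 1000, 8
        vals = np.exp(rng.normal(np.log(100.0), sigma, size=(n_rep, n_groups)))
        data = make_dataset(vals, scale="linear")
        table, summary = compute_snr(data)
        snrs = table.snr.to_numpy()
        se = snrs.std(ddof=1) / np.sqrt(len(snrs))
        # finite-sample bias of 1/s (normal theory): E[m/s] = (mu/sigma) * c_n
        c_n = np.sqrt((n_rep - 1) / 2) * np.exp(
            gammaln((n_rep - 2) / 2) - gammaln((n_rep - 1) / 2)
        )
        assert abs(summary["grand_mean"] - c_n / cv) <= 3 * se + 0.01 / cv


class TestQcFlags:
    def _cf(self, linear_values):
        from ctxcausal.preprocess import LoadingCorrection

        t = pd.DataFrame(
            {"cf_log2": np.log2(linear_values), "cf_linear": linear_values}
        )
        return LoadingCorrection(t)

    def test_cf_boundary_is_strict(self, rng):
        data = make_dataset(rng.normal(10, 1, (3, 4)))
        report = qc_flag_samples(data, self._cf([2.5, 2.51, 0.25]))
        assert report.excluded == {1: "cf_bounds"}

    def test_variance_threshold(self, rng):
        vals = rng.normal(10, 0.5, (2, 50))
        vals[1] = rng.normal(10, np.sqrt(41), 50)
        while vals[1].var(ddof=1) <= 40:
            vals[1] = vals[1] * 1.05
        data = make_dataset(vals)
        report = qc_flag_samples(data, self._cf([1.0, 1.0]))
        assert report.excluded == {1: "variance"}

    def test_snr_flags_groups_not_samples(self, rng):
        data = make_dataset(rng.normal(10, 0.1, (3, 2)))
        snr = pd.DataFrame(
            {
                "cell_line": ["MCF7", "MCF7"],
                "antibody": ["AB0", "AB1"],
                "inhibitor": ["DMSO", "DMSO"],
                "snr": [100.0, 0.5],
                "n_rep": [3, 3],
                "sd_zero": [False, False],
            }
        )
        report = qc_flag_samples(data, self._cf([1.0, 1.0, 1.0]), snr)
        assert report.snr_flagged_groups == [("MCF7", "AB1", "DMSO")]
        assert not report.excluded

    def test_planted_loading_outliers_all_caught(self, rng):
        """8x loading multipliers always push the linear CF past the bound."""
        base = rng.normal(10, 0.5, size=(20, 30))
        outliers = [3, 11]
        for i in outliers:
            base[i] += 3.0
        data = make_dataset(base)
        _, cf = median_center_loading(data)
        report = qc_flag_samples(data, cf)
        assert set(report.excluded) == set(outliers)
        assert all(v == "cf_bounds" for v in report.excluded.values())


class TestPanelSelection:
    def _dataset(self, rng, r_high_everywhere=True):
        lines = ["MCF7", "UACC812", "BT20", "BT549"]
        rows, vals = [], []
        for cl in lines:
            for t in [0.0, 5.0, 15.0]:
                rows.append(cl)
                vals.append(rng.normal(10, 1, size=3))
        vals = np.array(vals)
        vals[:, 1] = vals[:, 0] + 0.001 * rng.normal(size=len(vals))
        if not r_high_everywhere:  # decorrelate within the last cell line
            vals[-3:, 1] = rng.normal(10, 1, size=3)
        abs_ = {
            "AKT_pS473": AntibodyInfo("AKT_pS473", "AKT", ("S473",)),
            "AKT_pT308": AntibodyInfo("AKT_pT308", "AKT", ("T308",)),
            "MEK_pS217": AntibodyInfo("MEK_pS217", "MEK", ("S217",)),
        }
        data = make_dataset(
            vals,
            cell_line=rows,
            times=[0.0, 5.0, 15.0] * 4,
            antibodies=list(abs_),
        )
        data.antibodies.update(abs_)
        return data

    def test_identical_pair_collapsed(self, rng):
        data = self._dataset(rng)
        out, dropped = select_phospho_panel(data)
        assert dropped == [("AKT_pS473", "AKT_pT308")]
        assert out.antibody_names == ["AKT_pS473", "MEK_pS217"]

    def test_pair_kept_unless_high_in_every_cell_line(self, rng):
        data = self._dataset(rng, r_high_everywhere=False)
        out, dropped = select_phospho_panel(data)
        assert dropped == []
        assert len(out.antibody_names) == 3

    def test_independent_columns_rarely_dropped(self, rng):
        drops = 0
        for trial in range(100):
            lines = ["CL1", "CL2"]
            rows = [cl for cl in lines for _ in range(6)]
            vals = np.random.default_rng(trial).normal(10, 1, size=(12, 2))
            abs_ = {
                "A_pS1": AntibodyInfo("A_pS1", "A", ("S1",)),
                "A_pS2": AntibodyInfo("A_pS2", "A", ("S2",)),
            }
            data = make_dataset(
                vals, cell_line=rows, times=list(range(6)) * 2, antibodies=list(abs_)
            )
            data.antibodies.update(abs_)
            _, dropped = select_phospho_panel(data)
            drops += len(dropped)
        assert drops <= 2


class TestAveragingAndImputation:
    def test_single_replicate_is_identity(self):
        data = make_dataset([[1.0, 2.0]], times=[0.0])
        avg, counts = average_replicates(data)
        np.testing.assert_array_equal(avg.values.to_numpy(), [[1.0, 2.0]])
        np.testing.assert_array_equal(counts.to_numpy(), [[1, 1]])

    def test_mean_of_two_replicates(self):
        data = make_dataset([[1.0], [3.0]], times=[0.0, 0.0], replicate=[1, 2])
        avg, _ = average_replicates(data)
        assert avg.values.iloc[0, 0] == 2.0

    def test_missing_values_averaged_over_available(self):
        vals = np.array([[1.0, 5.0], [3.0, np.nan], [np.nan, np.nan], [5.0, 7.0]])
        data = make_dataset(vals, times=[0.0] * 4, replicate=[1, 2, 3, 4])
        avg, counts = average_replicates(data)
        assert avg.values.iloc[0, 0] == pytest.approx((1 + 3 + 5) / 3)
        assert avg.values.iloc[0, 1] == pytest.approx(6.0)
        np.testing.assert_array_equal(counts.to_numpy(), [[3, 2]])

    def test_interior_interpolation_linear_in_minutes(self):
        filled, mask = impute_series(
            np.array([0.0, 5.0, 15.0]), np.array([1.0, np.nan, 3.0])
        )
        assert filled[1] == pytest.approx(1 + 2 * (5 / 15))
        np.testing.assert_array_equal(mask, [False, True, False])

    def test_boundary_missing_uses_nearest(self):
        filled, mask = impute_series(
            np.array([0.0, 5.0, 15.0]), np.array([np.nan, 2.0, 4.0])
        )
        assert filled[0] == 2.0 and mask[0]

    def test_complete_series_untouched(self):
        y = np.array([1.0, 2.0, 3.0])
        filled, mask = impute_series(np.array([0.0, 5.0, 15.0]), y)
        np.testing.assert_array_equal(filled, y)
        assert not mask.any()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            impute_series(np.array([0.0, 5.0]), np.array([np.nan, 2.0]))

    def test_dataset_imputation_flags_entries(self):
        times = [0.0, 5.0, 15.0, 30.0, 60.0, 120.0, 240.0]
        vals = np.arange(7.0).reshape(-1, 1)
        vals[3] = np.nan
        data = make_dataset(vals, times=times, replicate=[1] * 7)
        completed, flags = impute_time_course(data)
        assert len(flags) == 1
        assert flags.time_min.iloc[0] == 30.0
        assert completed.values.iloc[3, 0] == pytest.approx(
            2.0 + (4.0 - 2.0) * (30 - 15) / (60 - 15)
        )
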