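"""Joint statistics: axis metric, axial mean, summaries, GPD, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from histodti import valstats
from histodti.valstats import (
    axis_angle_diff,
    build_voxel_table,
    fit_gpd,
    max_mean_axis_deviation,
    mean_axis,
    regression_r2,
    sectionwise_correlations,
    summarize_differences,
)


def random_records(seed: int, n_sections: int = 5, n_per: int = 60) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sections):
        for _ in range(n_per):
            rows.append(
                {
                    "section_id": s,
                    "tissue": rng.choice(["WM", "GM"]),
                    "diff": rng.uniform(0, 90),
                    "fa": rng.uniform(0, 1),
                    "md": rng.normal(1e-3, 2e-4),
                    "rd": rng.normal(8e-4, 2e-4),
                    "stain": rng.uniform(0, 1),
                    "ampl1": rng.uniform(0, 0.1),
                    "width1": rng.uniform(0, 1),
                    "ampl2": rng.uniform(0, 0.05),
                    "width2": rng.uniform(0, 1),
                    "ampl3": rng.uniform(0, 0.02),
                    "width3": rng.uniform(0, 1),
                }
            )
    return pd.DataFrame(rows)


class TestAxisAngleDiff:
    @pytest.mark.parametrize(
        "a, b, expected", [(10.0, 170.0, 20.0), (0.0, 90.0, 90.0), (42.0, 42.0, 0.0)]
    )
    def test_values(self, a, b, expected):
        assert axis_angle_diff(a, b) == expected

    def test_out_of_range_normalized_with_warning(self):
        with pytest.warns(UserWarning):
            assert axis_angle_diff(185.0, 0.0) == 5.0

    def test_metric_on_degree_grid(self):
        """d is symmetric, zero iff equal, and satisfies the triangle
        inequality — exhaustively on the 1-degree axis grid."""
        grid = np.arange(180.0)
        d = np.abs(grid[:, None] - grid[None, :])
        d = np.minimum(d, 180.0 - d)
        assert np.allclose(d, d.T)
        assert (np.diag(d) == 0).all()
        assert ((d == 0) == np.eye(180, dtype=bool)).all()
        # triangle inequality via min-plus matrix product
        via = (d[:, :, None] + d[None, :, :].transpose(1, 0, 2)).min(axis=1)
        assert (d <= via + 1e-12).all()
        assert np.allclose(d, valstats.axis_angle_diff(grid[:, None], grid[None, :]))


class TestMeanAxis:
    def test_symmetric_mean(self):
        assert mean_axis(10.0, 30.0) == pytest.approx(20.0, abs=1e-9)

    def test_orthogonal_tie_undefined(self):
        assert np.isnan(mean_axis(0.0, 90.0))

    def test_wraparound_mean(self):
        assert mean_axis(170.0, 10.0) == pytest.approx(0.0, abs=1e-9)

    def test_weighted_mean_pulls_toward_heavier_axis(self):
        m = mean_axis(0.0, 60.0, 3.0, 1.0)
        assert 0.0 < m < 30.0

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            mean_axis(0.0, 10.0, 0.0, 0.0)

    def test_crossing_average_bound_is_45_degrees(self):
        """The equal-weight mean of two axes deviates from either member by
        at most 45 degrees, approached as the pair nears orthogonality."""
        assert max_mean_axis_deviation(step_deg=1.0) == pytest.approx(45.0, abs=1e-9)


class TestSummaries:
    def test_truncated_mean(self):
        df = pd.DataFrame({"diff": [10.0, 60.0], "tissue": ["WM", "WM"],
                           "section_id": [0, 0]})
        out = summarize_differences(df, truncation_deg=50.0, min_bin_n=1)
        assert out["mean"].iloc[0] == 10.0

    def test_constant_diffs_zero_se(self):
        df = pd.DataFrame({"diff": [5.0] * 8, "tissue": ["GM"] * 8})
        out = summarize_differences(df, min_bin_n=1)
        assert out["se"].iloc[0] == 0.0
        assert out["mean"].iloc[0] == out["median"].iloc[0] == 5.0

    def test_small_bins_suppressed(self):
        df = random_records(0)
        out = summarize_differences(df, fa_bins=True, fa_bin_width=0.05, min_bin_n=100)
        assert out.loc[out["n"] < 100, "suppressed"].all()

    def test_brute_force_groupby_oracle(self):
        """Grouped summaries equal a naive loop implementation to 1e-12."""
        df = random_records(3)
        out = summarize_differences(df, by=("tissue",), min_bin_n=1)
        for _, row in out.iterrows():
            vals = [
                r["diff"] for _, r in df.iterrows() if r["tissue"] == row["tissue"]
            ]
            assert row["n"] == len(vals)
            assert row["mean"] == pytest.approx(float(np.mean(vals)), abs=1e-12)
            assert row["median"] == pytest.approx(float(np.median(vals)), abs=1e-12)
            se = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
            assert row["ci95"] == pytest.approx(1.96 * se, abs=1e-12)


class TestGPD:
    def test_parameter_recovery(self):
        """MLE recovers shape 0.3 / scale 8 from 50,000 samples.

        Recovery is checked on untruncated draws: discarding even the
        0.7% of mass beyond 90 degrees shifts the fitted shape by ~0.1,
        a truncation effect of the model rather than an estimator error.
        """
        rng = np.random.default_rng(12)
        x = stats.genpareto.rvs(0.3, loc=0.0, scale=8.0, size=50_000, random_state=rng)
        fit = fit_gpd(x)
        assert fit["shape"] == pytest.approx(0.3, abs=0.05)
        assert fit["scale"] == pytest.approx(8.0, abs=0.5)
        assert fit["r2"] > 0.99

    def test_self_fit_r2_near_one(self):
        rng = np.random.default_rng(4)
        x = stats.genpareto.rvs(0.2, loc=0.0, scale=6.0, size=200_000, random_state=rng)
        x = x[x <= 90.0]
        assert fit_gpd(x)["r2"] >= 0.999

    def test_uniform_fits_worse_than_exponential_like(self):
        rng = np.random.default_rng(5)
        uniform = rng.uniform(0, 90, 20_000)
        peaked = stats.genpareto.rvs(0.3, scale=8.0, size=20_000, random_state=rng)
        peaked = peaked[peaked <= 90]
        assert fit_gpd(uniform)["r2"] < fit_gpd(peaked)["r2"]

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_gpd(np.full(500, 10.0))


class TestSectionwiseCorrelations:
    VARS = ["fa", "md", "stain"]

    def test_single_section_equals_plain_pearson(self):
        df = random_records(6, n_sections=1, n_per=80)
        mat, _ = sectionwise_correlations(df, self.VARS)
        for p in self.VARS:
            for q in self.VARS:
                r = stats.pearsonr(df[p], df[q]).statistic
                assert mat.loc[p, q] == pytest.approx(r, abs=1e-12)

    def test_two_equal_sections_arithmetic_mean(self):
        df = random_records(7, n_sections=2, n_per=50)
        mat, _ = sectionwise_correlations(df, self.VARS)
        r0 = stats.pearsonr(*(df[df.section_id == 0][v] for v in ("fa", "md"))).statistic
        r1 = stats.pearsonr(*(df[df.section_id == 1][v] for v in ("fa", "md"))).statistic
        assert mat.loc["fa", "md"] == pytest.approx((r0 + r1) / 2, abs=1e-12)

    def test_brute_force_oracle_five_sections(self):
        """Weighted sectionwise matrix equals a naive loop to 1e-12."""
        rng = np.random.default_rng(13)
        frames = []
        for s in range(5):
            n = int(rng.integers(20, 80))
            frames.append(
                pd.DataFrame(
                    {
                        "section_id": s,
                        "fa": rng.normal(size=n),
                        "md": rng.normal(size=n),
                        "stain": rng.normal(size=n),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        mat, _ = sectionwise_correlations(df, self.VARS)
        for p in self.VARS:
            for q in self.VARS:
                num = den = 0.0
                for s in range(5):
                    sec = df[df.section_id == s]
                    r = stats.pearsonr(sec[p], sec[q]).statistic
                    num += len(sec) * r
                    den += len(sec)
                assert mat.loc[p, q] == pytest.approx(num / den, abs=1e-12)
        assert np.allclose(mat.to_numpy(), mat.to_numpy().T)
        assert np.allclose(np.diag(mat.to_numpy()), 1.0)

    def test_constant_variable_sections_skipped(self):
        df = random_records(8, n_sections=2, n_per=30)
        df.loc[df.section_id == 0, "stain"] = 0.5
        mat, skipped = sectionwise_correlations(df, self.VARS)
        assert skipped.loc["fa", "stain"] == 1
        assert np.isfinite(mat.loc["fa", "stain"])


class TestRegressionR2:
    def test_exact_linear_combination(self):
        df = random_records(9)
        df["fa"] = 0.2 + 0.5 * df["stain"] - 0.3 * df["ampl1"] + 0.1 * df["width2"]
        r2, skipped = regression_r2(df, "fa")
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert skipped == 0

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(14)
        df = random_records(15, n_sections=1, n_per=10_000)
        df["fa"] = rng.normal(size=len(df))
        r2, _ = regression_r2(df, "fa")
        assert r2 < 0.05

    def test_brute_force_weighted_oracle(self):
        df = random_records(16)
        r2, _ = regression_r2(df, "md")
        preds = valstats.HISTOLOGY_VARIABLES
        num = den = 0.0
        for s in sorted(df.section_id.unique()):
            sec = df[df.section_id == s]
            X = np.column_stack([np.ones(len(sec)), sec[preds].to_numpy()])
            y = sec["md"].to_numpy()
            beta = np.linalg.pinv(X) @ y
            res = y - X @ beta
            r2_s = 1 - (res**2).sum() / ((y - y.mean()) ** 2).sum()
            num += len(sec) * r2_s
            den += len(sec)
        assert r2 == pytest.approx(num / den, abs=1e-12)

    def test_too_few_voxels_section_skipped(self):
        df = random_records(17, n_sections=2, n_per=60)
        df = df[(df.section_id == 1) | (df.index < 5)]
        _, skipped = regression_r2(df, "fa")
        assert skipped == 1


class TestBuildVoxelTable:
    @staticmethod
    def tables(n=8):
        fod = pd.DataFrame(
            {
                "i": range(n),
                "j": 0,
                "k": 0,
                "section_id": 0,
                "stain": 0.5,
                "valid_fraction": 1.0,
                "theta1": 30.0,
                "ampl1": 0.05,
                "width1": 0.2,
            }
        )
        dti = pd.DataFrame(
            {
                "i": range(n),
                "j": 0,
                "k": 0,
                "tissue": "WM",
                "phi_dt": 40.0,
                "out_of_plane": [0.0, 10, 20, 30, 40, 45, 50, 60][:n],
                "fa": 0.5,
                "md": 1e-3,
                "rd": 8e-4,
                "projection_length": 1.0,
            }
        )
        return fod, dti

    def test_out_of_plane_threshold_semantics(self):
        fod, dti = self.tables()
        records, ledger = build_voxel_table(fod, dti)
        assert len(records) == 6  # angles <= 45 retained, inclusive
        assert ledger.n_out_of_plane == 2
        assert (records["diff"] == 10.0).all()

    def test_clean_join_no_exclusions(self):
        fod, dti = self.tables()
        dti["out_of_plane"] = 0.0
        records, ledger = build_voxel_table(fod, dti)
        led = ledger.as_dict()
        assert led["frac_damage"] == 0.0
        assert led["frac_unstained"] == 0.0
        assert led["frac_within_out_of_plane"] == 1.0
        assert len(records) == 8

    def test_damage_filter_fraction(self):
        fod, dti = self.tables()
        dti["out_of_plane"] = 0.0
        fod.loc[fod.index[:2], "valid_fraction"] = 0.01  # 25% damaged
        _, ledger = build_voxel_table(fod, dti)
        assert ledger.n_damage == 2
        assert ledger.as_dict()["frac_damage"] == pytest.approx(0.25)

    def test_empty_join_raises(self):
        fod, dti = self.tables()
        dti["k"] = 5
        with pytest.raises(ValueError):
            build_voxel_table(fod, dti)
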