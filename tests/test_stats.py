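"""Per-participant maps, slopes, variable error and group statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from boardmap import (
    analyze_group,
    analyze_participant,
    axis_slopes,
    build_map,
    exclude_outside,
    one_sample_t,
    one_sample_t_from_summary,
    paired_t,
    pearson_r,
    variable_error,
)
from boardmap.errors import (
    DegenerateDataError,
    InsufficientRepetitionsError,
    MissingLocationError,
)
from boardmap.stats import ParticipantStats  # noqa: F401  (re-exported surface)


def make_trials(grid, judged, participant="P01", condition="none"):
    """Trial table with one row per (repetition, location); judged has shape (reps, 36, 2)."""
    judged = np.asarray(judged, dtype=float)
    reps = judged.shape[0]
    coords = grid.bookstein_points.coords
    rows = np.repeat(np.arange(1, grid.rows + 1), grid.cols)
    cols = np.tile(np.arange(1, grid.cols + 1), grid.rows)
    frames = []
    for r in range(reps):
        frames.append(pd.DataFrame({
            "participant": participant,
            "experiment": "test",
            "condition": condition,
            "block": r + 1,
            "trial_index": np.arange(r * 36 + 1, r * 36 + 37),
            "loc_row": rows,
            "loc_col": cols,
            "actual_x": coords[:, 0],
            "actual_y": coords[:, 1],
            "judged_x": judged[r, :, 0],
            "judged_y": judged[r, :, 1],
        }))
    return pd.concat(frames, ignore_index=True)


def gaussian_trials(grid, reps, sd_x, sd_y, rng, slope=(1.0, 1.0), center=(0.5, 0.5)):
    actual = grid.bookstein_points.coords
    mean = np.asarray(center) + np.array(slope) * (actual - np.asarray(center))
    noise = rng.normal(0.0, [sd_x, sd_y], size=(reps, 36, 2))
    return make_trials(grid, mean + noise)


class TestExclusion:
    def test_counts_strictly_outside_clicks(self, grid):
        judged = np.full((1, 36, 2), 0.5)
        trials = make_trials(grid, judged)
        big = pd.concat([trials] * 28, ignore_index=True).head(1000).copy()
        big.loc[3, "judged_x"] = -0.01
        big.loc[500, "judged_y"] = 1.2
        kept, rate = exclude_outside(big)
        assert len(kept) == 998
        assert rate == pytest.approx(0.002)

    def test_boundary_clicks_kept(self, grid):
        judged = np.full((1, 36, 2), 0.5)
        trials = make_trials(grid, judged)
        trials.loc[0, ["judged_x", "judged_y"]] = [1.0, 0.0]
        kept, rate = exclude_outside(trials)
        assert len(kept) == 36
        assert rate == 0.0

    def test_idempotent_and_order_independent(self, grid, rng):
        judged = rng.uniform(-0.2, 1.2, size=(2, 36, 2))
        trials = make_trials(grid, judged)
        kept1, _ = exclude_outside(trials)
        kept2, rate2 = exclude_outside(kept1)
        assert rate2 == 0.0
        pd.testing.assert_frame_equal(kept1, kept2)
        shuffled = trials.sample(frac=1.0, random_state=0)
        kept3, _ = exclude_outside(shuffled)
        assert sorted(kept3["trial_index"]) == sorted(kept1["trial_index"])

    def test_empty_input(self, grid):
        trials = make_trials(grid, np.full((1, 36, 2), 0.5)).iloc[0:0]
        kept, rate = exclude_outside(trials)
        assert len(kept) == 0 and rate == 0.0


class TestBuildMap:
    def test_veridical_judgments_reproduce_grid(self, grid):
        actual = grid.bookstein_points.coords
        trials = make_trials(grid, np.broadcast_to(actual, (3, 36, 2)))
        pmap = build_map(trials, grid)
        np.testing.assert_allclose(pmap.means.coords, actual, atol=1e-12)
        assert pmap.means.labels == grid.labels
        np.testing.assert_array_equal(pmap.n_valid, 3)

    def test_symmetric_pair_averages_to_center(self, grid):
        actual = grid.bookstein_points.coords
        delta = np.full((36, 2), [0.01, -0.02])
        trials = make_trials(grid, np.stack([actual + delta, actual - delta]))
        pmap = build_map(trials, grid)
        np.testing.assert_allclose(pmap.means.coords, actual, atol=1e-12)

    def test_missing_location_rejected(self, grid):
        trials = make_trials(grid, np.full((2, 36, 2), 0.5))
        partial = trials[~((trials.loc_row == 3) & (trials.loc_col == 4))]
        with pytest.raises(MissingLocationError, match="r3c4"):
            build_map(partial, grid)

    def test_per_location_mean_sd_follows_clt(self, grid, rng):
        # with 8 reps of sd-0.1 noise the location means scatter with sd 0.1/sqrt(8)
        means = []
        for _ in range(200):
            trials = gaussian_trials(grid, reps=8, sd_x=0.1, sd_y=0.1, rng=rng)
            means.append(build_map(trials, grid).means.coords[0, 0])
        sd = np.std(means, ddof=1)
        assert sd == pytest.approx(0.1 / np.sqrt(8), rel=0.15)


class TestAxisSlopes:
    def test_veridical_gives_unit_slopes(self, grid):
        actual = grid.bookstein_points.coords
        trials = make_trials(grid, np.broadcast_to(actual, (2, 36, 2)))
        reg_x, reg_y = axis_slopes(trials)
        assert (reg_x.slope, reg_y.slope) == (pytest.approx(1.0), pytest.approx(1.0))
        assert reg_x.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg_x.axis == "mediolateral" and reg_y.axis == "proximodistal"

    def test_constant_judgment_gives_zero_slope(self, grid):
        trials = make_trials(grid, np.full((2, 36, 2), 0.37))
        reg_x, reg_y = axis_slopes(trials)
        assert reg_x.slope == pytest.approx(0.0, abs=1e-12)
        assert reg_x.intercept == pytest.approx(0.37)
        assert reg_y.slope == pytest.approx(0.0, abs=1e-12)

    def test_recovers_generating_slope_within_3_se(self, grid, rng):
        trials = gaussian_trials(
            grid, reps=8, sd_x=0.12, sd_y=0.12, rng=rng, slope=(0.84, 0.84)
        )
        reg_x, _ = axis_slopes(trials)
        sd_actual = grid.bookstein_points.coords[:, 0].std()
        se = 0.12 / (np.sqrt(288) * sd_actual)
        assert abs(reg_x.slope - 0.84) < 3 * se

    def test_location_mean_variant_matches_trial_level_for_balanced_data(self, grid, rng):
        # balanced design, identical per-location counts: both conventions coincide
        actual = grid.bookstein_points.coords
        offset = rng.normal(0, 0.05, size=(36, 2))
        judged = np.stack([actual + offset, actual + offset])
        trials = make_trials(grid, judged)
        trial_fit = axis_slopes(trials)
        mean_fit = axis_slopes(trials, on_location_means=True)
        assert trial_fit[0].slope == pytest.approx(mean_fit[0].slope)
        assert trial_fit[1].slope == pytest.approx(mean_fit[1].slope)

    def test_zero_variance_actual_rejected(self, grid):
        trials = make_trials(grid, np.full((2, 36, 2), 0.5))
        degenerate = trials[trials.loc_col == 2].copy()
        with pytest.raises(DegenerateDataError):
            axis_slopes(degenerate)


class TestVariableError:
    def test_zero_noise_gives_zero_sds(self, grid):
        actual = grid.bookstein_points.coords
        trials = make_trials(grid, np.broadcast_to(actual, (4, 36, 2)))
        ve_x, ve_y = variable_error(trials, grid)
        np.testing.assert_allclose(ve_x.per_location_sd, 0.0, atol=1e-12)
        assert ve_x.mean_sd == 0.0 and ve_y.mean_sd == 0.0

    def test_recovers_generating_noise_at_200_reps(self, grid, rng):
        trials = gaussian_trials(grid, reps=200, sd_x=0.121, sd_y=0.137, rng=rng)
        ve_x, ve_y = variable_error(trials, grid)
        assert ve_x.mean_sd == pytest.approx(0.121, rel=0.05)
        assert ve_y.mean_sd == pytest.approx(0.137, rel=0.05)
        assert ve_x.mean_sd == pytest.approx(float(ve_x.per_location_sd.mean()))

    def test_doubling_deviations_doubles_mean_sd(self, grid, rng):
        trials = gaussian_trials(grid, reps=8, sd_x=0.05, sd_y=0.05, rng=rng)
        ve_x, _ = variable_error(trials, grid)
        means = trials.groupby(["loc_row", "loc_col"])[["judged_x", "judged_y"]].transform("mean")
        doubled = trials.copy()
        doubled[["judged_x", "judged_y"]] = means + 2.0 * (
            trials[["judged_x", "judged_y"]] - means
        )
        ve_x2, _ = variable_error(doubled, grid)
        assert ve_x2.mean_sd == pytest.approx(2.0 * ve_x.mean_sd)

    def test_single_trial_location_rejected(self, grid):
        trials = make_trials(grid, np.full((2, 36, 2), 0.5))
        butchered = trials.drop(trials[(trials.loc_row == 1) & (trials.loc_col == 1)].index[:1])
        with pytest.raises(InsufficientRepetitionsError, match="r1c1"):
            variable_error(butchered, grid)


class TestGroupTests:
    def test_one_sample_t_matches_textbook_hand_calculation(self):
        # values 2,4,4,4,6 vs mu0=3: mean 4, sd sqrt(2); t = 1/(sqrt(2)/sqrt(5))
        res = one_sample_t([2, 4, 4, 4, 6], mu0=3.0)
        assert res.statistic == pytest.approx(np.sqrt(5.0 / 2.0), rel=1e-12)
        assert res.df == 4
        assert res.effect == pytest.approx(1.0 / np.sqrt(2.0), rel=1e-12)
        assert res.p == pytest.approx(0.189, abs=0.001)

    def test_summary_and_raw_paths_agree(self, rng):
        x = rng.normal(0.4, 0.2, size=20)
        raw = one_sample_t(x, 0.0)
        summ = one_sample_t_from_summary(float(x.mean()), float(x.std(ddof=1)), 20, 0.0)
        assert raw.statistic == pytest.approx(summ.statistic, rel=1e-12)
        assert raw.p == pytest.approx(summ.p, rel=1e-12)
        assert raw.effect == pytest.approx(summ.effect, rel=1e-12)
        scipy_t = scipy.stats.ttest_1samp(x, 0.0)
        assert raw.statistic == pytest.approx(scipy_t.statistic, rel=1e-12)
        assert raw.p == pytest.approx(scipy_t.pvalue, rel=1e-12)

    def test_mean_equal_to_mu0_gives_zero(self):
        res = one_sample_t([1.0, 2.0, 3.0], mu0=2.0)
        assert res.statistic == 0.0 and res.effect == 0.0

    def test_zero_sd_rejected(self):
        with pytest.raises(DegenerateDataError):
            one_sample_t([1.0, 1.0, 1.0], 0.0)

    def test_paired_t_antisymmetric(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        assert paired_t(a, b).statistic == pytest.approx(-paired_t(b, a).statistic)
        assert paired_t(a, b).effect_kind == "dz"

    def test_paired_t_identical_samples_rejected(self):
        a = [1.0, 2.0, 3.0]
        with pytest.raises(DegenerateDataError):
            paired_t(a, a)

    def test_paired_t_recovers_dz_of_3(self, rng):
        b = rng.normal(0.0, 1.0, size=20)
        a = b + rng.normal(0.3, 0.1, size=20)
        dz = paired_t(a, b).effect
        se_dz = np.sqrt(1 / 20 + 3.0**2 / 40)  # approximate sampling SE of dz
        assert abs(dz - 3.0) < 3 * se_dz

    def test_pearson_r_exact_cases(self):
        a = np.array([0.1, 0.4, 0.5, 0.9])
        assert pearson_r(a, 2 * a + 1).statistic == pytest.approx(1.0)
        assert pearson_r(a, -a).statistic == pytest.approx(-1.0)
        assert pearson_r(a, -a).df == 2

    def test_pearson_r_recovers_rho(self, rng):
        rho = 0.77
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=20)
        r = pearson_r(xy[:, 0], xy[:, 1]).statistic
        z_se = 1 / np.sqrt(20 - 3)
        lo, hi = np.tanh(np.arctanh(rho) + np.array([-3, 3]) * z_se)
        assert lo < r < hi

    def test_pearson_r_constant_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


class TestParticipantAndGroup:
    def _perfect_participant(self, grid, pid="P01"):
        actual = grid.bookstein_points.coords
        return make_trials(grid, np.broadcast_to(actual, (8, 36, 2)), participant=pid)

    def test_perfect_participant(self, grid, null_10k):
        stats = analyze_participant(self._perfect_participant(grid), grid, null_10k)
        assert stats.procrustes_distance == pytest.approx(0.0, abs=1e-10)
        assert stats.procrustes_p == 0.0
        assert stats.slope_x.slope == pytest.approx(1.0)
        assert stats.slope_y.slope == pytest.approx(1.0)
        assert stats.exclusion_rate == 0.0

    def test_identical_participants_surface_degenerate_stats(self, grid, null_10k):
        per = [
            analyze_participant(self._perfect_participant(grid, f"P{i}"), grid, null_10k,
                                participant=f"P{i}")
            for i in range(3)
        ]
        report = analyze_group(per)
        assert "error" in report["slope_axis_correlation"]
        assert "error" in report["slope_anisotropy_paired"]
        assert report["procrustes"]["n_below_p05"] == 3

    def test_group_report_structure(self, grid, null_10k, rng):
        per = []
        for i in range(4):
            trials = gaussian_trials(
                grid, reps=8, sd_x=0.1, sd_y=0.13, rng=rng,
                slope=(0.8 + 0.05 * i, 0.4 + 0.05 * i),
            )
            trials["participant"] = f"P{i:02d}"
            per.append(analyze_participant(trials, grid, null_10k, participant=f"P{i:02d}"))
        report = analyze_group(per)
        assert report["n_participants"] == 4
        test = report["slope_mediolateral"]["test"]
        assert test["df"] == 3 and 0 <= test["p"] <= 1
        assert report["exclusion"]["n_trials"] == 4 * 288
        assert report["slope_anisotropy_paired"]["effect_kind"] == "dz"
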