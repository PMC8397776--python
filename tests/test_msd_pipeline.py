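"""Windowed-MSD statistic, fits, normalization, and distribution comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from colonydrift.msd_pipeline import (
    BeadTrajectory,
    MSDCurve,
    PowerLawFit,
    aggregate_msd,
    combine_weighted,
    compare_distributions,
    fit_power_law,
    flag_diverging_trajectories,
    msd_at_reference,
    normalize_to_wildtype,
    summarize_strain,
    windowed_msd,
)

from conftest import naive_windowed_msd, random_walk_trajectory


class TestWindowedMSD:
    def test_three_point_hand_oracle(self):
        # TLS principal axis of (0,0),(1,1),(2,0) is horizontal through the
        # centroid; mean squared perpendicular deviation is 2/9
        tr = BeadTrajectory("c", "b", [0, 1, 2], [[0, 0], [1, 1], [2, 0]])
        m, _, n = windowed_msd(tr, L=tr.total_arclength_um)
        assert n == 1
        assert m == pytest.approx(2.0 / 9.0, rel=1e-12)

    def test_ols_mode_three_point(self):
        # regression of y on x has zero slope here, so vertical deviations
        # coincide with perpendicular ones
        tr = BeadTrajectory("c", "b", [0, 1, 2], [[0, 0], [1, 1], [2, 0]])
        m, _, _ = windowed_msd(tr, L=tr.total_arclength_um, mode="ols")
        assert m == pytest.approx(2.0 / 9.0, rel=1e-12)

    def test_collinear_is_zero_everywhere(self):
        x = np.arange(50.0)
        tr = BeadTrajectory("c", "b", x, np.column_stack([x * 3, 2 * x * 3 + 1]))
        for L in [5.0, 20.0, 100.0]:
            m, _, n = windowed_msd(tr, L)
            if n:
                assert m == pytest.approx(0.0, abs=1e-18)

    def test_matches_bruteforce(self, rng):
        for i in range(5):
            tr = random_walk_trajectory(rng, n=int(rng.integers(30, 120)))
            for L in [6.0, 25.0, 0.4 * tr.total_arclength_um]:
                m, s, n = windowed_msd(tr, L)
                m2, s2, n2 = naive_windowed_msd(tr, L)
                assert n == n2
                if n:
                    assert m == pytest.approx(m2, rel=1e-9)
                    if n > 1:
                        assert s == pytest.approx(s2, rel=1e-9)

    def test_ols_matches_bruteforce(self, rng):
        tr = random_walk_trajectory(rng, n=80)
        m, _, n = windowed_msd(tr, 30.0, mode="ols")
        m2, _, n2 = naive_windowed_msd(tr, 30.0, mode="ols")
        assert n == n2 and m == pytest.approx(m2, rel=1e-9)

    def test_scaling_covariance(self, rng):
        # coordinates × c map MSD(L) -> c²·MSD(cL)
        c = 3.0
        tr = random_walk_trajectory(rng, n=120)
        scaled = BeadTrajectory("c", "b", tr.t_min, tr.xy_um * c)
        for L in [10.0, 40.0]:
            m, _, n = windowed_msd(tr, L)
            ms, _, ns = windowed_msd(scaled, c * L)
            assert n == ns
            assert ms == pytest.approx(c * c * m, rel=1e-9)

    @settings(deadline=None, max_examples=20)
    @given(theta=st.floats(-np.pi, np.pi), tx=st.floats(-50, 50), ty=st.floats(-50, 50))
    def test_rigid_motion_invariance(self, theta, tx, ty):
        rng = np.random.default_rng(7)
        tr = random_walk_trajectory(rng, n=60)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = BeadTrajectory("c", "b", tr.t_min, tr.xy_um @ R.T + [tx, ty])
        m, _, n = windowed_msd(tr, 25.0)
        m2, _, n2 = windowed_msd(moved, 25.0)
        assert n == n2
        assert m2 == pytest.approx(m, rel=1e-7, abs=1e-12)

    def test_no_window_marker(self):
        tr = BeadTrajectory("c", "b", [0, 1], [[0, 0], [1, 0]])
        m, s, n = windowed_msd(tr, 50.0)
        assert n == 0 and np.isnan(m)


class TestAggregate:
    def test_identical_trajectories_pass_through(self, rng):
        tr = random_walk_trajectory(rng, n=80)
        copies = [
            BeadTrajectory("c", f"b{i}", tr.t_min, tr.xy_um.copy()) for i in range(6)
        ]
        curve = aggregate_msd(copies, window_grid=[20.0])
        m, _, _ = windowed_msd(tr, 20.0)
        assert curve.msd_um2[0] == pytest.approx(m, rel=1e-12)

    def test_min_trajectory_drop_rule(self, rng):
        # 4 long + 2 short trajectories: long-only window lengths must drop
        long = [random_walk_trajectory(rng, n=120, bead=f"l{i}") for i in range(4)]
        short = [random_walk_trajectory(rng, n=15, bead=f"s{i}") for i in range(2)]
        L_long = 0.5 * min(tr.total_arclength_um for tr in long)
        L_short = 0.5 * min(tr.total_arclength_um for tr in short)
        curve = aggregate_msd(long + short, window_grid=[L_short, L_long])
        assert L_short in curve.L_um
        assert L_long not in curve.L_um  # only 4 trajectories reach it

    @pytest.mark.parametrize("weighting", ["fixed", "random-effects"])
    def test_weighted_mean_matches_resummation(self, rng, weighting):
        m = rng.uniform(1.0, 5.0, 8)
        s = rng.uniform(0.1, 0.5, 8)
        got, err = combine_weighted(m, s, weighting)
        w = 1.0 / s**2
        mfe = np.sum(w * m) / np.sum(w)
        if weighting == "fixed":
            assert got == pytest.approx(mfe, rel=1e-12)
            assert err == pytest.approx(np.sum(w) ** -0.5, rel=1e-12)
        else:
            q = np.sum(w * (m - mfe) ** 2)
            tau2 = max(0.0, (q - 7) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
            wr = 1.0 / (s**2 + tau2)
            assert got == pytest.approx(np.sum(wr * m) / np.sum(wr), rel=1e-12)

    def test_empty_input(self):
        curve = aggregate_msd([], window_grid=[10.0])
        assert len(curve) == 0


class TestPowerLawFit:
    def test_exact_power_law(self):
        L = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        curve = MSDCurve(L, 2.0 * L, np.full(5, 0.1), np.full(5, 10))
        fit = fit_power_law(curve)
        assert fit.amplitude == pytest.approx(2.0, rel=1e-9)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_too_few_windows(self):
        L = np.array([10.0, 20.0, 40.0, 80.0])
        curve = MSDCurve(L, 2.0 * L, np.full(4, 0.1), np.full(4, 10))
        fit = fit_power_law(curve)
        assert fit.failed and fit.failure_reason == "too_few_windows"

    def test_nonpositive_rows_excluded_with_warning(self):
        L = np.array([10.0, 20.0, 40.0, 80.0, 160.0, 320.0])
        m = 2.0 * L
        m[2] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            fit = fit_power_law(MSDCurve(L, m, np.full(6, 0.1), np.full(6, 10)))
        assert not fit.failed
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_noisy_exponent_unbiased(self, rng):
        # 5% multiplicative noise: the fitted exponent has no systematic bias
        L = np.linspace(6, 1152, 50)
        betas = []
        for _ in range(200):
            m = 0.5 * L**1.2 * (1 + rng.normal(0, 0.05, len(L)))
            curve = MSDCurve(L, m, 0.05 * m, np.full(len(L), 10))
            betas.append(fit_power_law(curve).exponent)
        assert np.mean(betas) == pytest.approx(1.2, abs=0.05)


class TestReferenceValue:
    def _fit(self, A=2.0, beta=1.0, sla=0.0, sb=0.0):
        return PowerLawFit(A, beta, A * sla, sb, np.log(A), sla)

    def test_reference_arithmetic(self):
        out = msd_at_reference(self._fit())
        assert out.msd50_um2 == pytest.approx(100.0)
        assert out.msd50_err_um2 == 0.0 and out.qc_pass

    def test_error_matches_two_point_oracle(self, rng):
        for _ in range(20):
            A = float(rng.uniform(0.5, 5))
            beta = float(rng.uniform(0.5, 1.5))
            sla, sb = float(rng.uniform(0, 0.3)), float(rng.uniform(0, 0.2))
            out = msd_at_reference(self._fit(A, beta, sla, sb))
            hi = np.exp((np.log(A) + sla) + (beta + sb) * np.log(50.0))
            lo = np.exp((np.log(A) - sla) + (beta - sb) * np.log(50.0))
            assert out.msd50_err_um2 == pytest.approx(abs(hi - lo) / 2, rel=1e-12)

    def test_qc_rule(self):
        noisy = msd_at_reference(self._fit(sla=1.0, sb=1.0))
        assert not noisy.qc_pass  # error exceeds half the value

    def test_envelope_mode_at_least_joint(self):
        f = self._fit(sla=0.2, sb=0.1)
        joint = msd_at_reference(f, bound_method="joint")
        env = msd_at_reference(f, bound_method="envelope")
        assert env.msd50_err_um2 >= joint.msd50_err_um2 - 1e-12

    def test_failed_fit_propagates(self):
        failed = PowerLawFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            failed=True, failure_reason="too_few_windows",
        )
        assert msd_at_reference(failed).failed


class TestSectorFlag:
    def _pair(self, sep_t):
        t = np.arange(len(sep_t), dtype=float)
        a = BeadTrajectory("c", "a", t, np.column_stack([t, np.zeros_like(t)]))
        b = BeadTrajectory("c", "b", t, np.column_stack([t, sep_t]))
        return [a, b]

    def test_parallel_not_flagged(self):
        assert not flag_diverging_trajectories(self._pair(np.full(20, 10.0)))

    def test_planted_divergence_flagged(self):
        sep = np.linspace(10, 50, 20)  # 5× monotone growth
        assert flag_diverging_trajectories(self._pair(sep), separation_gain=3.0)

    def test_threshold_respected(self):
        sep = np.linspace(10, 50, 20)
        assert not flag_diverging_trajectories(self._pair(sep), separation_gain=10.0)


class TestNormalization:
    def _table(self, rng, n_plates=3, n_strains=10):
        rows = []
        cid = 0
        for p in range(n_plates):
            for i in range(8):
                rows.append(("WT", f"p{p}", 1.0 + 0.05 * rng.normal(), 0.05))
            for i in range(n_strains):
                rows.append((f"ko{i}", f"p{p}", 0.9 + 0.1 * rng.normal(), 0.05))
        return pd.DataFrame(
            [
                {
                    "colony_id": f"c{j}",
                    "strain_id": s,
                    "plate_id": p,
                    "msd50": v,
                    "msd50_err": e,
                }
                for j, (s, p, v, e) in enumerate(rows)
            ]
        )

    def test_wildtype_weighted_mean_is_one(self, rng):
        # weights are those used in the normalization (measurement errors)
        out = normalize_to_wildtype(self._table(rng))
        for _, grp in out[out["is_wt"]].groupby("plate_id"):
            w = 1 / grp["msd50_err"] ** 2
            assert np.sum(w * grp["relative_msd"]) / np.sum(w) == pytest.approx(1.0, rel=1e-12)

    def test_plate_scale_invariance(self, rng):
        tab = self._table(rng)
        out1 = normalize_to_wildtype(tab)
        tab2 = tab.copy()
        mask = tab2["plate_id"] == "p1"
        tab2.loc[mask, ["msd50", "msd50_err"]] *= 7.0
        out2 = normalize_to_wildtype(tab2)
        np.testing.assert_allclose(out1["relative_msd"], out2["relative_msd"], rtol=1e-12)

    def test_ratio_error_matches_monte_carlo(self, rng):
        tab = self._table(rng)
        out = normalize_to_wildtype(tab)
        row = out[~out["is_wt"]].iloc[0]
        wt = tab[(tab.strain_id == "WT") & (tab.plate_id == row.plate_id)]
        draws = 10**5
        m = rng.normal(row.msd50, tab.loc[row.name, "msd50_err"], draws)
        w_weights = 1 / wt["msd50_err"].to_numpy() ** 2
        wt_draws = np.sum(
            w_weights * rng.normal(
                wt["msd50"].to_numpy(), wt["msd50_err"].to_numpy(), (draws, len(wt))
            ),
            axis=1,
        ) / np.sum(w_weights)
        mc_sd = np.std(m / wt_draws)
        assert row.relative_msd_err == pytest.approx(mc_sd, rel=0.10)

    def test_plate_without_wildtype_excluded(self, rng):
        tab = self._table(rng)
        tab = tab[~((tab.plate_id == "p2") & (tab.strain_id == "WT"))]
        with pytest.warns(UserWarning, match="no passing wild-type"):
            out = normalize_to_wildtype(tab)
        assert (out.loc[out.plate_id == "p2", "exclusion_reason"] == "no_wt").all()


class TestStrainSummary:
    def _tab(self, strains, vals, errs):
        return pd.DataFrame(
            {
                "strain_id": strains,
                "relative_msd": vals,
                "relative_msd_err": errs,
                "exclusion_reason": "",
            }
        )

    def test_equal_errors_give_plain_mean(self):
        out = summarize_strain(self._tab(["a"] * 3, [1.0, 1.2, 0.8], [0.1] * 3))
        assert out.loc[0, "relative_msd"] == pytest.approx(1.0)

    def test_huge_error_replicate_has_no_weight(self):
        out = summarize_strain(self._tab(["a"] * 3, [1.0, 1.0, 50.0], [0.1, 0.1, 1e6]))
        assert out.loc[0, "relative_msd"] == pytest.approx(1.0, abs=1e-6)

    def test_weighted_mean_matches_resummation(self, rng):
        vals = rng.uniform(0.5, 1.5, 5)
        errs = rng.uniform(0.05, 0.3, 5)
        out = summarize_strain(self._tab(["a"] * 5, vals, errs))
        w = 1 / errs**2
        assert out.loc[0, "relative_msd"] == pytest.approx(
            np.sum(w * vals) / np.sum(w), rel=1e-12
        )
        assert out.loc[0, "sem"] == pytest.approx(np.std(vals, ddof=1) / np.sqrt(5))

    def test_min_replicates_drop(self):
        out = summarize_strain(
            self._tab(["a", "a", "b"], [1.0, 1.1, 0.9], [0.1, 0.1, 0.1]),
            min_replicates=2,
        )
        assert list(out["strain_id"]) == ["a"]


class TestCompareDistributions:
    def test_identical_samples(self, rng):
        v = rng.normal(1, 0.1, 30)
        res = compare_distributions(v, v.copy(), n_bootstrap=200, seed=0)
        assert res["ks_statistic"] == 0.0
        assert res["median_shift"] == 0.0

    def test_shifted_scaled_sample_detected(self, rng):
        wt = rng.normal(1.0, 0.07, 45)
        ko = rng.normal(0.9, 0.14, 191)
        res = compare_distributions(ko, wt, n_bootstrap=500, seed=1)
        assert res["ks_p"] < 0.01
        assert res["var_ko"] > res["var_wt"]

    def test_needs_two_per_group(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [1.0, 2.0])

    def test_bootstrap_is_seeded(self, rng):
        wt = rng.normal(1.0, 0.07, 40)
        ko = rng.normal(0.95, 0.1, 60)
        a = compare_distributions(ko, wt, n_bootstrap=500, seed=5)
        b = compare_distributions(ko, wt, n_bootstrap=500, seed=5)
        assert a["median_shift_ci"] == b["median_shift_ci"]
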