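import itertools

import numpy as np
import pandas as pd
import pytest

import plasmatrace as pt
from plasmatrace import synthetic_data as sd
from plasmatrace.sec_complexome import (
    Calibrant,
    ElutionProfile,
    FractionTable,
    SecCalibrationError,
    coelution_score,
    detect_coelution_groups,
    estimate_apparent_mw,
    fit_mw_calibration,
    flag_complex_bound,
)


def gaussian_profile(center, sigma=1.5, n=66, amplitude=1.0):
    f = np.arange(1, n + 1)
    return pd.Series(amplitude * np.exp(-0.5 * ((f - center) / sigma) ** 2), index=f)


class TestFitMwCalibration:
    def test_two_point_fit_passes_through_both(self):
        cal = fit_mw_calibration(
            [Calibrant("big", 1000.0, 10.0), Calibrant("small", 10.0, 40.0)]
        )
        assert cal.mw_at(10.0) == pytest.approx(1000.0, rel=1e-12)
        assert cal.mw_at(40.0) == pytest.approx(10.0, rel=1e-12)

    def test_exact_log_linear_standards_have_zero_residuals(self, p2_sec_run):
        table, _ = p2_sec_run
        cal = fit_mw_calibration(table.calibrants)
        assert max(abs(r) for r in cal.residuals.values()) < 1e-12

    def test_increasing_mw_with_fraction_is_an_error(self):
        with pytest.raises(SecCalibrationError, match="orientation"):
            fit_mw_calibration(
                [Calibrant("a", 10.0, 10.0), Calibrant("b", 1000.0, 40.0)]
            )

    def test_single_calibrant_rejected(self):
        with pytest.raises(SecCalibrationError, match=">= 2"):
            fit_mw_calibration([Calibrant("a", 10.0, 10.0)])

    def test_non_monotone_order_warns_with_residuals(self):
        cals = [
            Calibrant("a", 1000.0, 10.0),
            Calibrant("b", 20.0, 25.0),  # out of order
            Calibrant("c", 100.0, 30.0),
            Calibrant("d", 10.0, 45.0),
        ]
        with pytest.warns(UserWarning, match="not strictly decreasing"):
            cal = fit_mw_calibration(cals)
        assert set(cal.residuals) == {"a", "b", "c", "d"}


class TestEstimateApparentMw:
    @pytest.fixture
    def calibration(self, p2_mw_calibration):
        return p2_mw_calibration

    def test_single_nonzero_fraction_maps_directly(self, calibration):
        prof = pd.Series(0.0, index=range(1, 67))
        prof[30] = 5.0
        mw, window, _ = estimate_apparent_mw(prof, calibration)
        assert window == (30,)
        assert mw == pytest.approx(calibration.mw_at(30.0), rel=1e-12)

    def test_symmetric_gaussian_centroid_recovers_center(self, calibration):
        prof = gaussian_profile(30.0)
        mw, _, _ = estimate_apparent_mw(prof, calibration)
        centroid = calibration.fraction_at(mw)
        assert centroid == pytest.approx(30.0, abs=0.01)

    def test_all_zero_profile_is_undefined(self, calibration):
        with pytest.raises(ValueError, match="all-zero"):
            estimate_apparent_mw(pd.Series(0.0, index=range(1, 67)), calibration)

    def test_secondary_peaks_reported_but_do_not_set_apparent_mw(self, calibration):
        prof = gaussian_profile(20.0, amplitude=1.0) + gaussian_profile(
            50.0, amplitude=0.5
        )
        mw, window, secondary = estimate_apparent_mw(prof, calibration)
        assert calibration.fraction_at(mw) == pytest.approx(20.0, abs=0.05)
        assert len(secondary) == 1
        assert calibration.fraction_at(secondary[0]) == pytest.approx(50.0, abs=0.05)

    def test_mode_estimator_uses_argmax_fraction(self, calibration):
        prof = gaussian_profile(30.4)
        mw, _, _ = estimate_apparent_mw(prof, calibration, estimator="mode")
        assert mw == pytest.approx(calibration.mw_at(30.0), rel=1e-12)

    def test_round_trip_recovery_within_one_fraction_width(self, calibration):
        """Species placed anywhere in 10..3000 kDa recover their MW within
        one fraction-width under the calibration."""
        design_mws = [10.5, 24, 66, 150, 375, 720, 1500, 2900]
        width_factor = 10.0 ** abs(calibration.slope)  # one fraction in MW
        for true_mw in design_mws:
            design = sd.StudyDesign(
                name="toy",
                proteins=(sd.ProteinSpec("X", true_mw, 10.0),),
                complexes=(),
                donors=(sd.DonorDesign("D", 3, "healthy"),),
            )
            table, _ = sd.generate_sec_run(design, timepoint=0, seed=0)
            mw, _, _ = estimate_apparent_mw(table.profile("X"), calibration)
            assert mw / true_mw < width_factor
            assert true_mw / mw < width_factor


class TestExcludedFractions:
    def test_excluded_fractions_carry_no_data_after_drop(self):
        table, _ = sd.generate_sec_run(
            "p2_apr", timepoint=2, seed=0,
            excluded_fractions=sd.DEFAULT_EXCLUDED_FRACTIONS, drop_excluded=True,
        )
        assert set(sd.DEFAULT_EXCLUDED_FRACTIONS).isdisjoint(
            table.fraction_indices
        )

    def test_excluded_fractions_never_contribute_to_centroids(
        self, p2_mw_calibration
    ):
        prof = gaussian_profile(30.0)
        full = pd.Series(prof, index=range(1, 67))
        spiked = full.copy()
        spiked[31] = 100.0  # corrupt an excluded fraction
        retained = [f for f in range(1, 67) if f not in {31, 32}]
        mw_clean, _, _ = estimate_apparent_mw(
            full[retained], p2_mw_calibration
        )
        mw_spiked, _, _ = estimate_apparent_mw(
            spiked[retained], p2_mw_calibration
        )
        assert mw_spiked == mw_clean

    def test_profile_accessor_skips_excluded(self):
        table, _ = sd.generate_sec_run(
            "p2_apr", timepoint=2, seed=0,
            excluded_fractions=sd.DEFAULT_EXCLUDED_FRACTIONS,
        )
        prof = table.profile("CRP")
        assert set(sd.DEFAULT_EXCLUDED_FRACTIONS).isdisjoint(prof.index)


class TestCoelutionScore:
    def test_identical_profiles_score_one(self):
        p = gaussian_profile(30.0)
        assert coelution_score(p, p) == pytest.approx(1.0)

    def test_disjoint_single_fraction_peaks_score_nonpositive(self):
        a = pd.Series(0.0, index=range(1, 11))
        b = a.copy()
        a[3] = 1.0
        b[8] = 1.0
        assert coelution_score(a, b) <= 0.0

    def test_same_complex_members_score_one_noise_free(self, p2_sec_run):
        table, _ = p2_sec_run
        score = coelution_score(table.profile("SAA1"), table.profile("SAA2"))
        assert score == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_overlap_is_undefined(self):
        a = pd.Series([1.0, 2.0, 3.0], index=[1, 2, 3])
        b = pd.Series([1.0, 2.0, 3.0], index=[3, 4, 5])
        with pytest.raises(ValueError, match="shared fractions"):
            coelution_score(a, b)


class TestCoelutionGroups:
    def make_profiles(self, centers: dict[str, float]) -> dict[str, ElutionProfile]:
        cal = fit_mw_calibration(
            [Calibrant("hi", 3000.0, 1.0), Calibrant("lo", 10.0, 66.0)]
        )
        out = {}
        for pid, center in centers.items():
            prof = gaussian_profile(center)
            mw, window, _ = estimate_apparent_mw(prof, cal)
            out[pid] = ElutionProfile(pid, prof, mw, window)
        return out

    def test_two_monomers_at_distant_mws_stay_singletons(self):
        groups = detect_coelution_groups(self.make_profiles({"A": 15.0, "B": 50.0}))
        assert [g.members for g in groups] == [("A",), ("B",)]

    def test_coeluting_trio_forms_one_group(self):
        groups = detect_coelution_groups(
            self.make_profiles({"A": 30.0, "B": 30.0, "C": 30.0, "D": 55.0})
        )
        assert ("A", "B", "C") in [g.members for g in groups]

    def test_agreement_with_brute_force_connected_components(self):
        """Grouping equals brute-force components on small inputs."""
        from plasmatrace.sec_complexome import (
            DEFAULT_COELUTION_THRESHOLD,
            DEFAULT_MW_TOLERANCE,
        )

        rng = np.random.default_rng(0)
        for trial in range(6):
            centers = {
                f"P{i}": float(rng.uniform(10, 60))
                for i in range(int(rng.integers(3, 9)))
            }
            profiles = self.make_profiles(centers)
            groups = detect_coelution_groups(profiles)
            # brute force: adjacency + transitive closure
            pids = sorted(profiles)
            linked = {
                (p, q)
                for p, q in itertools.combinations(pids, 2)
                if abs(profiles[p].apparent_mw - profiles[q].apparent_mw)
                / max(profiles[p].apparent_mw, profiles[q].apparent_mw)
                <= DEFAULT_MW_TOLERANCE
                and coelution_score(
                    profiles[p].intensities, profiles[q].intensities
                )
                >= DEFAULT_COELUTION_THRESHOLD
            }
            comp = {p: {p} for p in pids}
            changed = True
            while changed:
                changed = False
                for p, q in linked:
                    union = comp[p] | comp[q]
                    if union != comp[p] or union != comp[q]:
                        for m in union:
                            comp[m] = union
                        changed = True
            expected = {frozenset(c) for c in comp.values()}
            assert {frozenset(g.members) for g in groups} == expected

    def test_iai_trio_groups_at_225_kda(self):
        design = sd.subset_design(
            sd.preset("p2_apr"), ["ITIH1", "ITIH2", "AMBP"]
        )
        table, truth = sd.generate_sec_run(design, timepoint=2, seed=0)
        cal = fit_mw_calibration(table.calibrants)
        profiles = pt.build_elution_profiles(table, cal, truth.monomer_mw)
        (group,) = [g for g in detect_coelution_groups(profiles)
                    if len(g.members) > 1]
        assert group.members == ("AMBP", "ITIH1", "ITIH2")
        assert group.group_mw == pytest.approx(225.0, rel=0.1)

    def test_fibrinogen_trio_single_group(self, p2_sec_run, p2_mw_calibration):
        table, truth = p2_sec_run
        profiles = pt.build_elution_profiles(
            table, p2_mw_calibration, truth.monomer_mw
        )
        groups = detect_coelution_groups(profiles)
        fg_group = next(g for g in groups if "FGA" in g.members)
        assert {"FGA", "FGB", "FGG"} <= set(fg_group.members)


class TestFlagComplexBound:
    def test_monomer_at_own_mw_not_flagged(self, p2_mw_calibration):
        design = sd.StudyDesign(
            name="toy",
            proteins=(sd.ProteinSpec("X", 66.0, 10.0),),
            complexes=(),
            donors=(sd.DonorDesign("D", 3, "healthy"),),
        )
        table, truth = sd.generate_sec_run(design, timepoint=0, seed=0)
        profiles = pt.build_elution_profiles(
            table, p2_mw_calibration, truth.monomer_mw
        )
        flagged, ratio = flag_complex_bound(profiles["X"])
        assert not flagged
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_inflamed_hdl_saa1_ratio_at_least_20(self, p2_sec_run, p2_mw_calibration):
        table, truth = p2_sec_run
        profiles = pt.build_elution_profiles(
            table, p2_mw_calibration, truth.monomer_mw
        )
        flagged, ratio = flag_complex_bound(profiles["SAA1"])
        assert flagged
        assert ratio >= 20.0

    def test_calprotectin_heterodimer_near_24_kda(self):
        design = sd.subset_design(sd.preset("p2_apr"), ["S100A8", "S100A9"])
        table, truth = sd.generate_sec_run(design, timepoint=2, seed=0)
        cal = fit_mw_calibration(table.calibrants)
        profiles = pt.build_elution_profiles(table, cal, truth.monomer_mw)
        for pid in ("S100A8", "S100A9"):
            assert profiles[pid].apparent_mw == pytest.approx(24.0, rel=0.15)

    def test_unknown_monomer_mw_raises(self, p2_mw_calibration):
        prof = ElutionProfile("X", gaussian_profile(30.0), 100.0, (30,))
        with pytest.raises(ValueError, match="monomer"):
            flag_complex_bound(prof)


class TestFractionTableIO:
    def test_tsv_round_trip(self, tmp_path, p2_sec_run):
        table, _ = p2_sec_run
        path = tmp_path / "fractions.tsv"
        table.write(path)
        back = FractionTable.read(path, excluded_fractions=table.excluded_fractions)
        assert back.fraction_indices == table.fraction_indices
        np.testing.assert_allclose(
            back.intensities.values, table.intensities.values, rtol=1e-9
        )

    def test_negative_intensities_rejected(self):
        df = pd.DataFrame([[-1.0, 2.0]], index=["X"], columns=[1, 2])
        with pytest.raises(ValueError, match=">= 0"):
            FractionTable(intensities=df)
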