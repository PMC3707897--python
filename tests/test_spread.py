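import numpy as np
import pandas as pd
import pytest

from cortexdecorr import GenerationConfig, StudyGeometry, generate_study
from cortexdecorr.geometry import cortical_position, ring_midpoints
from cortexdecorr.spread import (
    CrossingEstimate,
    profile,
    resampling_error,
    select_voi,
    spread_mm,
    zero_crossing,
)


def _table_from_ring_values(values_by_subject, geometry, area="V1", condition="C"):
    """Small table with one voxel per ring at the ring midpoint."""
    mids = ring_midpoints(geometry)
    rows = []
    for subj, vals in enumerate(values_by_subject, start=1):
        for ring, (ecc, v) in enumerate(zip(mids, vals), start=1):
            rows.append({
                "subject": subj, "hemisphere": "R", "area": area, "ring": ring,
                "eccentricity_deg": ecc, "C": v, "S_N": v, "S_F": v,
                "m_C_SN": v, "m_C_SF": v,
            })
    return pd.DataFrame(rows)


class TestProfile:
    def test_constant_values_give_flat_profile_with_zero_se(self, geometry):
        table = _table_from_ring_values([[2.0] * 5, [2.0] * 5], geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        assert prof.means == pytest.approx([2.0] * 5)
        assert prof.ses == pytest.approx([0.0] * 5)

    def test_group_profile_is_mean_of_subject_profiles(self, clean_cd_study, geometry):
        table, _ = clean_cd_study
        group = profile(table, "V1", "C", level="group", geometry=geometry)
        subj_profiles = [
            profile(table, "V1", "C", level="subject", subject=s, geometry=geometry).means
            for s in sorted(table["subject"].unique())
        ]
        assert group.means == pytest.approx(np.mean(subj_profiles, axis=0))

    def test_empty_ring_errors_with_ring_name(self, geometry):
        table = _table_from_ring_values([[1.0] * 5], geometry)
        broken = table[table["ring"] != 3]
        with pytest.raises(ValueError, match="ring 3"):
            profile(broken, "V1", "C", level="subject", subject=1, geometry=geometry)


class TestZeroCrossing:
    def test_linear_profile_crossing_recovered(self, geometry):
        # profile = 7 - ecc crosses zero at exactly 7 degrees
        mids = ring_midpoints(geometry)
        vals = 7.0 - mids
        table = _table_from_ring_values([vals, vals], geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        est = zero_crossing(prof, "peripheral", 2.3, n_boot=50, seed=0)
        assert est.crossing == pytest.approx(7.0, abs=1e-8)
        assert not est.censored

    def test_analytic_parabola_root_matches_quadratic_formula(self, geometry):
        mids = ring_midpoints(geometry)
        a, b, c = -0.05, 0.3, 0.4
        vals = a * mids**2 + b * mids + c
        table = _table_from_ring_values([vals, vals], geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        est = zero_crossing(prof, "peripheral", 2.3, n_boot=0, seed=0)
        expected = (-b - np.sqrt(b**2 - 4 * a * c)) / (2 * a)
        assert est.crossing == pytest.approx(expected, abs=1e-9)

    def test_all_positive_profile_censored_beyond_periphery(self, geometry):
        table = _table_from_ring_values([[1.0, 0.9, 0.8, 0.75, 0.7]] * 2, geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        est = zero_crossing(prof, "peripheral", 2.3, n_boot=20, seed=0)
        assert est.censored
        assert est.format_degrees().startswith(">12")

    def test_censoring_symmetric_under_direction_reversal(self, geometry):
        mids = ring_midpoints(geometry)
        rising = mids - 0.5  # crosses below ring 1: censored "<1" in central travel
        table = _table_from_ring_values([rising, rising], geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        est = zero_crossing(prof, "central", 8.7, n_boot=0, seed=0)
        assert est.crossing < 1.0 or est.crossing == -np.inf
        assert est.format_degrees().startswith("<1")

    def test_bootstrap_ci_brackets_the_estimate(self, geometry):
        rng = np.random.default_rng(5)
        mids = ring_midpoints(geometry)
        subjects = [7.0 - mids + rng.normal(0, 0.3, 5) for _ in range(10)]
        table = _table_from_ring_values(subjects, geometry)
        prof = profile(table, "V1", "C", level="group", geometry=geometry)
        est = zero_crossing(prof, "peripheral", 2.3, n_boot=200, seed=1)
        assert est.ci[0] <= est.crossing <= est.ci[1]


class TestSpreadMm:
    def test_crossing_at_reference_edge_is_zero(self, geometry):
        est = CrossingEstimate("peripheral", 2.3, 2.3, (np.nan, np.nan))
        assert spread_mm(2.3, est, geometry).mm == 0.0

    def test_censored_central_crossing_gives_documented_lower_bound(self, geometry):
        est = CrossingEstimate("central", 8.7, -np.inf, (np.nan, np.nan))
        sp = spread_mm(8.7, est, geometry)
        assert sp.is_lower_bound
        assert sp.mm == pytest.approx(17 * np.log(9.7 / 2.0))

    def test_spread_linear_in_magnification_k(self, geometry):
        est = CrossingEstimate("peripheral", 2.3, 7.7, (np.nan, np.nan))
        doubled = StudyGeometry(magnification_k=34.0)
        assert spread_mm(2.3, est, doubled).mm == pytest.approx(
            2 * spread_mm(2.3, est, geometry).mm
        )


class TestSelectVoi:
    def test_zero_threshold_ava_returns_everything(self, clean_cd_study):
        table, _ = clean_cd_study
        assert len(select_voi(table, "VOI_AVA", theta=0.0)) == len(table)

    def test_ring_vois_partition_the_table_at_zero_threshold(self, clean_cd_study):
        table, _ = clean_cd_study
        sizes = [len(select_voi(table, f"VOI_RING{i}", theta=0.0)) for i in range(1, 6)]
        assert sum(sizes) == len(table)

    def test_raising_threshold_never_grows_a_voi(self, noisy_cd_study):
        table, _ = noisy_cd_study
        for voi in ("VOI_C", "VOI_SN", "VOI_V1", "VOI_RING2"):
            sizes = [len(select_voi(table, voi, theta=t)) for t in (0.0, 0.2, 0.5, 1.0)]
            assert sizes == sorted(sizes, reverse=True)

    def test_unknown_rule_lists_valid_names(self, clean_cd_study):
        table, _ = clean_cd_study
        with pytest.raises(ValueError, match="VOI_AVA"):
            select_voi(table, "VOI_BOGUS")


class TestResamplingError:
    def test_zero_noise_cd_data_have_vanishing_error(self):
        # with the decorrelating interaction strength and no noise, every
        # repeat's mean d_M equals d_true exactly; the residual error is only
        # the finite-sample gap between the subsample's d_T and the pooled
        # d_T, which shrinks as the resample grows
        cfg = GenerationConfig(
            n_subjects=1, voxels_per_ring_per_area=30, noise_sd=0.0, d_true="auto",
            seed=6,
        )
        table, truth = generate_study(cfg)
        one_subject = table[table["subject"] == 1]
        err_small = resampling_error(one_subject, "VOI_C", n_voxels=20, n_repeats=20, seed=0)
        err_large = resampling_error(one_subject, "VOI_C", n_voxels=150, n_repeats=20, seed=0)
        assert err_small < 1e-2
        assert err_large < err_small
        # the measured side of the gap is exact
        from cortexdecorr.core import measured_d

        d, _ = measured_d(one_subject["C"], one_subject["S_N"], one_subject["m_C_SN"])
        assert np.nanmax(np.abs(d - truth.d_true["1"]["near"])) < 1e-10

    def test_same_seed_reproduces_error(self, noisy_cd_study):
        table, _ = noisy_cd_study
        e1 = resampling_error(table, "VOI_C", n_repeats=30, seed=9)
        e2 = resampling_error(table, "VOI_C", n_repeats=30, seed=9)
        assert e1 == e2

    def test_error_decreases_with_measurement_noise(self):
        # noise decorrelates the measured patterns, pulling the subsample d_T
        # toward the (noise-robust) mean d_M; the d_M-vs-d_T gap shrinks
        errors = []
        for noise in (0.02, 0.1, 0.3):
            cfg = GenerationConfig(
                n_subjects=2, voxels_per_ring_per_area=40, noise_sd=noise,
                d_true=0.3, seed=8,
            )
            table, _ = generate_study(cfg)
            errors.append(
                resampling_error(table, "VOI_RING1", n_repeats=50, seed=2)
            )
        assert errors[0] > errors[1] > errors[2]

    def test_fixed_size_errors_comparable_across_ring_vois(self):
        # on rings with identical generative distributions, the fixed
        # selection size leaves no room for VOI-size effects: errors agree
        # within a factor of two
        from cortexdecorr.core import theoretical_d

        rng = np.random.default_rng(10)
        rows = []
        for ring in range(1, 6):
            n = 300
            C = rng.normal(1.0, 0.3, n)
            S = 0.4 * C + rng.normal(0.3, 0.25, n)
            d_ring = theoretical_d(C, S).d_T  # each ring sits on its own CD manifold
            m = (1 - d_ring) * (C + S) + rng.normal(0, 0.05, n)
            ecc = np.full(n, [1.5, 3.0, 5.0, 7.0, 10.0][ring - 1])
            for i in range(n):
                rows.append({
                    "subject": 1, "hemisphere": "R", "area": "V1", "ring": ring,
                    "eccentricity_deg": ecc[i] + i * 1e-4, "C": C[i], "S_N": S[i],
                    "S_F": S[i], "m_C_SN": m[i], "m_C_SF": m[i],
                })
        table = pd.DataFrame(rows)
        errs = [
            resampling_error(table, f"VOI_RING{i}", n_repeats=100, seed=3, theta=0.1)
            for i in range(1, 6)
        ]
        assert max(errs) / min(errs) < 2.0

    def test_too_small_voi_reports_count(self, clean_cd_study):
        table, _ = clean_cd_study
        with pytest.raises(ValueError, match="voxels"):
            resampling_error(table.head(10), "VOI_AVA", n_voxels=20)
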