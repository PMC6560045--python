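import math

import numpy as np
import pytest

from vlmalign import (
    AlignmentModel,
    DetectionParams,
    MzInterval,
    SpectraSet,
    Spectrum,
    audit_vlms,
    bin_spectrum,
    correct_set,
    detect_alignment_points,
    detect_vlms,
    loo_theta,
    represent,
    represent_set,
    run_pipeline,
    select_theta,
)
from vlmalign.synthetic import SyntheticConfig, generate

from conftest import make_set, make_spectrum


class TestSelectTheta:
    def test_95th_of_twenty_is_19th_order_statistic(self):
        thetas = np.arange(1.0, 21.0)  # 1..20
        assert select_theta(thetas, 95.0) == 19.0

    def test_all_equal_values(self):
        assert select_theta([2.5, 2.5, 2.5], 37.0) == 2.5

    def test_z_100_returns_maximum(self):
        assert select_theta([3.0, 1.0, 2.0], 100.0) == 3.0

    def test_empty_or_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            select_theta([], 95.0)
        with pytest.raises(ValueError):
            select_theta([1.0], 0.0)


class TestLooTheta:
    def test_prealigned_spectra_give_zero_deviations(self):
        ss = make_set([[100.0, 200.0, 300.0, 400.0]] * 3)
        vlms = detect_vlms(ss, DetectionParams.from_ppm(40.0))
        thetas = loo_theta(ss, vlms)
        assert thetas.shape == (2,)
        np.testing.assert_array_equal(thetas, 0.0)

    def test_hand_computed_middle_deviation(self):
        # leaving out the middle lock mass, the bridge between exact outer
        # anchors is the identity, so the corrected middle peak stays at
        # 199.99 and theta_2 = 0.01/200 = 5e-5
        others = [[100.0, 200.0, 300.0]] * 2
        off = [[100.0, 199.99, 300.0]]
        ss = make_set(others + off)
        vlms = detect_vlms(ss, DetectionParams.from_ppm(300.0))
        assert len(vlms) == 3
        thetas = loo_theta(ss, vlms)
        v2 = vlms.mzs[1]
        expected = abs(199.99 - v2) / v2 + 0.01 / 200 * 0  # dominated by off spectrum
        # the exact value: bridge is identity for every spectrum, so the
        # worst deviation is |199.99 - v2|/v2 with v2 the group mean
        assert thetas[0] == pytest.approx(expected, rel=1e-12)

    def test_fewer_than_three_vlms_rejected(self):
        ss = make_set([[100.0, 200.0]] * 2)
        vlms = detect_vlms(ss, DetectionParams.from_ppm(40.0))
        with pytest.raises(ValueError, match="at least 3"):
            loo_theta(ss, vlms)

    def test_deviations_bounded_by_twice_jitter(self):
        # pure multiplicative drift is removed exactly by interpolation, so
        # leave-one-out deviations are controlled by the per-peak jitter
        jitter = 2e-6
        spectra, _ = generate(
            SyntheticConfig(m=25, jitter_scale=jitter, k_noise_per_spectrum=0, seed=13)
        )
        vlms = detect_vlms(spectra, DetectionParams.from_ppm(40.0))
        thetas = loo_theta(spectra, vlms)
        assert thetas.max() <= 3.0 * jitter  # own jitter + bridge-anchor jitter


class TestAlignmentPoints:
    def test_shared_and_private_peaks(self):
        ss = SpectraSet(
            (
                make_spectrum("a", [100.0, 200.0, 300.0]),
                make_spectrum("b", [100.00001, 200.00001]),
                make_spectrum("c", [99.99999, 199.99999]),
            )
        )
        points = detect_alignment_points(ss, theta=5e-6)
        sizes = sorted(v.size for v in points)
        assert sizes == [1, 3, 3]
        audit_vlms(points, ss)

    def test_tiny_theta_isolates_every_peak(self, rng):
        mzs = np.sort(rng.uniform(100, 900, size=50))
        ss = SpectraSet(
            (
                make_spectrum("a", mzs * (1 + 1e-7)),
                make_spectrum("b", mzs * (1 - 1e-7)),
            )
        )
        points = detect_alignment_points(ss, theta=1e-9)
        assert len(points) == ss.n
        assert all(v.size == 1 for v in points)

    def test_noise_floor_suppresses_background(self):
        ss = SpectraSet(
            (
                Spectrum("a", np.array([100.0, 150.0]), np.array([5000.0, 50.0])),
                Spectrum("b", np.array([100.00001]), np.array([5000.0])),
            )
        )
        points = detect_alignment_points(ss, theta=5e-6, noise_floor=1000.0)
        assert len(points) == 1 and points[0].size == 2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            detect_alignment_points(SpectraSet(()), theta=1e-5)


class TestRepresent:
    def _model(self, point_mzs, theta=4e-5):
        ss = SpectraSet(tuple(make_spectrum(f"s{i}", point_mzs) for i in range(2)))
        points = detect_alignment_points(ss, theta=theta)
        return AlignmentModel(
            theta=theta, thetas_i=np.empty(0), percentile_z=95.0, points=points
        )

    def test_feature_values_and_zero_fill(self):
        model = self._model([100.0, 200.0])
        s = Spectrum("x", np.array([100.0001, 150.0]), np.array([5000.0, 300.0]))
        np.testing.assert_array_equal(represent(s, model), [5000.0, 0.0])

    def test_empty_spectrum_gives_zero_vector(self):
        model = self._model([100.0, 200.0])
        s = Spectrum("x", np.empty(0), np.empty(0))
        np.testing.assert_array_equal(represent(s, model), [0.0, 0.0])

    def test_closest_peak_wins_in_shared_window(self):
        theta = 4e-5
        model = self._model([100.0, 200.0], theta)
        near = 100.0 * (1 + 0.2 * theta)
        far = 100.0 * (1 + 0.6 * theta)
        s = Spectrum("x", np.array([near, far]), np.array([111.0, 999.0]))
        assert represent(s, model)[0] == 111.0

    def test_represent_set_columns_are_point_masses(self, default_dataset, default_params):
        spectra, _ = default_dataset
        vlms = detect_vlms(spectra, default_params)
        corrected, _ = correct_set(spectra, vlms)
        model = AlignmentModel.fit(spectra, corrected, vlms, noise_floor=1000.0)
        feats = represent_set(corrected, model)
        assert feats.shape == (spectra.m, len(model.points))
        np.testing.assert_allclose(feats.columns, np.round(model.point_mzs, 6))

    def test_training_member_intensity_reproduced(self, default_dataset, default_params):
        spectra, _ = default_dataset
        vlms = detect_vlms(spectra, default_params)
        corrected, _ = correct_set(spectra, vlms)
        model = AlignmentModel.fit(spectra, corrected, vlms, noise_floor=1000.0)
        feats = represent_set(corrected, model)
        # every lock mass is also an alignment point; at it, each training
        # spectrum's feature is exactly its member-peak intensity
        point_idx = {round(float(mz), 6): k for k, mz in enumerate(model.point_mzs)}
        for v in vlms:
            k = point_idx[round(v.mz, 6)]
            for p in v.members:
                sid = spectra.ids[p.spectrum_index]
                assert feats.loc[sid].iloc[k] == p.intensity


class TestBinning:
    def test_sum_within_single_bin(self):
        s = make_spectrum("x", [100.2, 100.4], [10.0, 5.0])
        values, centers = bin_spectrum(s, 1.0, MzInterval(100.0, 101.0))
        assert values.tolist() == [15.0]
        assert centers.tolist() == [100.5]

    def test_empty_bins_are_zero(self):
        s = make_spectrum("x", [100.2], [10.0])
        values, _ = bin_spectrum(s, 1.0, MzInterval(100.0, 103.0))
        assert values.tolist() == [10.0, 0.0, 0.0]

    def test_edge_peak_falls_in_right_bin(self):
        s = make_spectrum("x", [101.0], [7.0])
        values, _ = bin_spectrum(s, 1.0, MzInterval(100.0, 102.0))
        assert values.tolist() == [0.0, 7.0]

    def test_max_aggregation(self):
        s = make_spectrum("x", [100.2, 100.4], [10.0, 5.0])
        values, _ = bin_spectrum(s, 1.0, MzInterval(100.0, 101.0), agg="max")
        assert values.tolist() == [10.0]

    def test_relative_bins_form_geometric_ladder(self):
        s = make_spectrum("x", [100.0], [1.0])
        _, centers = bin_spectrum(s, 1e-3, MzInterval(100.0, 110.0), relative=True)
        ratios = centers[1:] / centers[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_bad_inputs_rejected(self):
        s = make_spectrum("x", [100.0], [1.0])
        with pytest.raises(ValueError):
            bin_spectrum(s, 1.0, MzInterval(100.0, 100.0))
        with pytest.raises(ValueError):
            bin_spectrum(s, 0.0, MzInterval(100.0, 101.0))


class TestSupportMatchesPresence:
    def test_constructed_corrected_data(self, rng):
        # corrected-like data built directly: per-compound spread s, compound
        # separation far above 4s, theta chosen above the spread
        masses = np.arange(100.0, 400.0, 10.0)
        spread = 2e-6
        m = 6
        present = rng.random((masses.size, m)) < 0.6
        present[:, 0] = True  # keep spectra non-empty
        spectra = []
        for sigma in range(m):
            mask = present[:, sigma]
            mz = masses[mask] * (1 + rng.uniform(-spread, spread, size=mask.sum()))
            order = np.argsort(mz)
            spectra.append(
                Spectrum(
                    f"s{sigma}",
                    mz[order],
                    rng.uniform(2000, 9000, size=mask.sum())[order],
                )
            )
        ss = SpectraSet(tuple(spectra))
        points = detect_alignment_points(ss, theta=2 * spread)
        assert len(points) == masses.size
        model = AlignmentModel(
            theta=2 * spread, thetas_i=np.empty(0), percentile_z=95.0, points=points
        )
        feats = represent_set(ss, model)
        comp = np.array([int(np.argmin(np.abs(masses - p))) for p in model.point_mzs])
        for sigma in range(m):
            support = feats.iloc[sigma].values > 0
            np.testing.assert_array_equal(support, present[comp, sigma])


class TestPipeline:
    def test_transductive_without_test_equals_plain_fit(self, default_dataset):
        spectra, _ = default_dataset
        small = spectra.subset(range(12))
        res = run_pipeline(small, None, DetectionParams.from_ppm(40.0))
        assert res.features_test is None
        vlms = detect_vlms(small, DetectionParams.from_ppm(40.0))
        np.testing.assert_array_equal(res.vlms.mzs, vlms.mzs)
        assert res.features_train.shape[0] == small.m

    def test_inductive_model_frozen_before_test(self, default_dataset):
        spectra, _ = default_dataset
        train, test = spectra.subset(range(35)), spectra.subset(range(35, 50))
        res = run_pipeline(
            train, test, DetectionParams.from_ppm(40.0), mode="inductive",
            noise_floor=1000.0,
        )
        train_only = run_pipeline(
            train, None, DetectionParams.from_ppm(40.0), mode="inductive",
            noise_floor=1000.0,
        )
        # detection, theta and points must be identical with or without test data
        np.testing.assert_array_equal(res.vlms.mzs, train_only.vlms.mzs)
        assert res.alignment.theta == train_only.alignment.theta
        np.testing.assert_array_equal(
            res.alignment.point_mzs, train_only.alignment.point_mzs
        )
        assert res.features_test.shape == (test.m, len(res.alignment.points))

    def test_intensities_pass_through_untouched(self, default_dataset):
        spectra, _ = default_dataset
        train, test = spectra.subset(range(35)), spectra.subset(range(35, 50))
        res = run_pipeline(
            train, test, DetectionParams.from_ppm(40.0), mode="inductive",
            noise_floor=1000.0,
        )
        original = {
            s.id: set(s.intensity.tolist()) for s in test
        }
        for sid, row in res.features_test.iterrows():
            nonzero = set(v for v in row.values if v > 0)
            assert nonzero <= original[sid]

    def test_unknown_mode_rejected(self, default_dataset):
        spectra, _ = default_dataset
        with pytest.raises(ValueError, match="mode"):
            run_pipeline(spectra, None, mode="semisupervised")
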