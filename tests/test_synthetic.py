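"""Synthetic study generator: kinetics, labels, cubes, planted designs."""

import numpy as np
import pytest

from salmonhsi import synthetic as syn
from salmonhsi.evaluation import index_correlation, r2_score
from salmonhsi.hypercube import radiometric_calibrate
from salmonhsi.models import mlr_fit, mlr_predict
from salmonhsi.segmentation import (
    SpoilageLabels, mean_grayscale, morphological_open, threshold_segment,
)
from salmonhsi.selection import spa_select


class TestKinetics:
    def test_endpoint_anchors_hit_within_one_percent(self, kinetics):
        for key, (a0, a11) in syn.DEFAULT_ANCHORS.items():
            p = kinetics.series[key]
            assert p(0) == pytest.approx(a0, rel=0.01)
            assert p(11) == pytest.approx(a11, rel=0.01)

    def test_every_threshold_crossing_reproduced(self, kinetics):
        for key, crossings in syn.DEFAULT_CROSSINGS.items():
            for limit, day in crossings:
                assert syn.first_crossing_day(kinetics.series[key], limit) == day

    def test_noise_free_trajectories_nondecreasing(self, kinetics):
        t = np.linspace(0, 11, 200)
        for p in kinetics.series.values():
            assert np.all(np.diff(p(t)) >= 0)

    def test_infeasible_constraints_rejected(self):
        anchors = {("tvbn", 4): (1.0, 50.0)}
        crossings = {("tvbn", 4): [(25.0, 2), (25.0, 9)]}  # contradictory
        with pytest.raises(RuntimeError, match="infeasible"):
            syn.calibrate_kinetics(anchors, crossings)

    def test_logistic_parameter_validation(self):
        with pytest.raises(ValueError):
            syn.LogisticParams(5.0, 4.0, 1.0, 3.0)        # vmax < v0


class TestLabels:
    def test_zero_noise_equals_means(self, kinetics):
        design = syn.StudyDesign(replicates=2)
        df = syn.sample_labels(design, kinetics, tvbn_cv=0.0, tvc_cv=0.0, seed=0)
        for row in df.itertuples():
            assert row.tvbn == pytest.approx(
                kinetics.trajectory("tvbn", row.temperature_c, row.day))
            assert row.tvc == pytest.approx(
                kinetics.trajectory("tvc", row.temperature_c, row.day))

    def test_default_noise_cohort_coevolution(self, kinetics):
        df = syn.sample_labels(syn.StudyDesign(), kinetics, seed=5)
        out = index_correlation(df)
        assert len(df) == 480
        assert out[4] >= 0.90 and out[8] >= 0.90

    def test_deterministic_given_seed(self, kinetics):
        design = syn.StudyDesign(replicates=3)
        a = syn.sample_labels(design, kinetics, seed=9)
        b = syn.sample_labels(design, kinetics, seed=9)
        assert a.equals(b)

    def test_rho_bounds(self, kinetics):
        with pytest.raises(ValueError, match="rho"):
            syn.sample_labels(syn.StudyDesign(), kinetics, rho=1.0)


class TestDesignArithmetic:
    def test_full_factorial_counts(self):
        bundle = syn.generate_experiment(syn.StudyDesign(), seed=0)
        assert bundle.n_samples == 480
        assert bundle.n_cubes == 960

    def test_reduced_design_counts(self):
        bundle = syn.generate_experiment(syn.StudyDesign(replicates=3), seed=0)
        assert bundle.n_samples == 48
        assert bundle.n_cubes == 96

    def test_entry_seeds_deterministic(self):
        a = syn.generate_experiment(syn.StudyDesign(replicates=2), seed=3)
        b = syn.generate_experiment(syn.StudyDesign(replicates=2), seed=3)
        assert [e[3] for e in a.entries] == [e[3] for e in b.entries]
        assert a.labels.equals(b.labels)


@pytest.fixture(scope="module")
def fresh_cube(kinetics):
    lab = SpoilageLabels(1.29, 2.16, 4, 0)
    return syn.generate_fillet_cube(lab, kinetics=kinetics, seed=7,
                                    sample_id="F", side="dorsal")


class TestFilletCubes:

    def test_nir_exceeds_visible_for_fresh_sample(self, fresh_cube):
        raw, refs, gt = fresh_cube
        cube = radiometric_calibrate(raw, refs)
        lam = cube.wavelengths_nm
        spec = cube.data[gt.mask].mean(axis=0)
        assert spec[lam >= 780].mean() > spec[(lam >= 400) & (lam < 700)].mean()

    def test_peak_reflectance_below_50_percent(self, fresh_cube):
        raw, refs, _ = fresh_cube
        assert radiometric_calibrate(raw, refs).data.max() < 50.0

    def test_monotone_decline_with_spoilage(self, kinetics):
        lab0 = SpoilageLabels(1.29, 2.16, 4, 0)
        lab11 = SpoilageLabels(55.67, 6.91, 4, 11)
        raw0, refs, _ = syn.generate_fillet_cube(lab0, kinetics=kinetics,
                                                 seed=1, noise=False)
        raw11, _, _ = syn.generate_fillet_cube(lab11, kinetics=kinetics,
                                               seed=1, noise=False)
        c0 = radiometric_calibrate(raw0, refs)
        c11 = radiometric_calibrate(raw11, refs)
        assert np.all(c11.data <= c0.data + 1e-9)

    def test_segmentation_recovers_ground_truth(self, fresh_cube):
        raw, refs, gt = fresh_cube
        cube = radiometric_calibrate(raw, refs)
        mask = morphological_open(
            threshold_segment(mean_grayscale(cube), 10.0)).mask
        iou = (mask & gt.mask).sum() / (mask | gt.mask).sum()
        assert iou >= 0.95

    def test_references_invert_exactly(self, kinetics):
        lab = SpoilageLabels(10.0, 4.0, 4, 3)
        raw, refs, gt = syn.generate_fillet_cube(lab, kinetics=kinetics,
                                                 seed=2, noise=False)
        cube = radiometric_calibrate(raw, refs)
        s = syn.spoilage_index(lab, kinetics)
        expected = syn.SpectralForwardParams().spectrum(cube.wavelengths_nm, s)
        inside = cube.data[gt.mask]
        assert np.allclose(inside, expected, atol=1e-6)

    def test_out_of_range_parameters_flagged(self, kinetics):
        bad = syn.SpectralForwardParams(trough_depth=40.0, beta=30.0)
        lab = SpoilageLabels(55.67, 6.91, 4, 11)
        with pytest.raises(syn.ForwardModelRangeError):
            syn.generate_fillet_cube(lab, params=bad, kinetics=kinetics, seed=0)

    def test_bundle_write_layout(self, kinetics, tmp_path):
        design = syn.StudyDesign(temperatures=(4,), days=(0,), replicates=1,
                                 image_shape=(80, 96))
        bundle = syn.generate_experiment(design, seed=0)
        bundle.write(tmp_path)
        assert (tmp_path / "labels.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        assert len(list((tmp_path / "cubes").glob("*.hdr"))) == 2


class TestPlantedSignal:
    def test_deterministic(self):
        a = syn.planted_signal_dataset(seed=4)
        b = syn.planted_signal_dataset(seed=4)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_noiseless_identifiability(self):
        X, y, truth = syn.planted_signal_dataset(n_samples=150, snr=1e6, seed=0)
        planted = truth["planted_bands"]
        model = mlr_fit(X[:, planted], y)
        assert r2_score(y, mlr_predict(model, X[:, planted])) > 0.9

    def test_permuted_response_breaks_lasso_recovery(self):
        """Shuffling y drops a response-driven selector to chance.

        (SPA chains are variance-driven, so the permutation null is probed
        with the L1 selector, whose support is a pure function of the
        X-y relationship.)
        """
        from salmonhsi.selection import lasso_select
        true_hits, null_hits = [], []
        for seed in range(6):
            X, y, truth = syn.planted_signal_dataset(seed=seed)
            planted = set(truth["planted_bands"].tolist())
            rng = np.random.default_rng(seed)
            sub = lasso_select(X, y, seed=seed)
            true_hits.append(len(set(sub.band_indices) & planted))
            try:
                sub0 = lasso_select(X, rng.permutation(y), seed=seed)
                null_hits.append(len(set(sub0.band_indices) & planted))
            except ValueError:            # full shrinkage: empty support
                null_hits.append(0)
        assert np.median(true_hits) >= 4
        assert np.median(null_hits) <= 2

    def test_validates_band_indices(self):
        with pytest.raises(ValueError, match="inside"):
            syn.planted_signal_dataset(n_bands=10, planted_bands=(12,))


def test_spoilage_index_bounds(kinetics):
    fresh = SpoilageLabels(1.29, 2.16, 4, 0)
    gone = SpoilageLabels(80.0, 9.0, 8, 11)
    assert 0.0 <= syn.spoilage_index(fresh, kinetics) < 0.1
    assert syn.spoilage_index(gone, kinetics) == pytest.approx(1.0)
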