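"""Validation metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from volgan.metrics import (REALISM_CAP, FeatureSet, RandomConvVolumeExtractor,
                            RandomProjectionSliceExtractor, evaluate,
                            extract_slice_features, extract_volume_features,
                            fid, filter_vgs, precision_recall, realism_scores,
                            train_vgs_classifier)
from volgan.phantoms import GradedVolume, PhantomSpec, generate_cohort, generate_phantom
from volgan.volume import Volume


def _gauss(n, d, seed, mean=0.0, scale=1.0):
    rng = np.random.default_rng(seed)
    return FeatureSet(mean + scale * rng.standard_normal((n, d)))


class TestFid:
    def test_identical_sets_score_zero(self):
        a = _gauss(300, 16, 0)
        b = FeatureSet(a.features.copy())
        assert abs(fid(a, b)) < 1e-6

    def test_symmetry(self):
        a, b = _gauss(200, 8, 1), _gauss(200, 8, 2, mean=0.5)
        assert fid(a, b) == pytest.approx(fid(b, a), abs=1e-8)

    def test_mean_shift_closed_form(self):
        d, n = 8, 5000
        mu = np.full(d, 0.8)
        a = _gauss(n, d, 3)
        b = _gauss(n, d, 4, mean=mu)
        # population FID for equal covariances: ||mu||^2
        assert fid(a, b) == pytest.approx(float(mu @ mu), abs=0.35)

    def test_commuting_covariance_closed_form(self):
        d, n = 6, 8000
        a = _gauss(n, d, 5, scale=2.0)   # N(0, 4I)
        b = _gauss(n, d, 6, scale=1.0)   # N(0, I)
        # d * (4 + 1 - 2*2) = d
        assert fid(a, b) == pytest.approx(d, rel=0.1)

    @given(st.integers(0, 50))
    def test_nonnegative_on_random_sets(self, seed):
        a = _gauss(30, 4, seed)
        b = _gauss(25, 4, seed + 1000, mean=0.3)
        assert fid(a, b) >= -1e-9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fid(_gauss(10, 4, 7), _gauss(10, 5, 8))


def brute_precision_recall(xr, xg, k):
    def radius(x, i):
        d = np.sort([np.linalg.norm(x[i] - x[j]) for j in range(len(x)) if j != i])
        return d[k - 1]
    rr = [radius(xr, i) for i in range(len(xr))]
    rg = [radius(xg, i) for i in range(len(xg))]
    prec = np.mean([any(np.linalg.norm(g - xr[i]) <= rr[i]
                        for i in range(len(xr))) for g in xg])
    rec = np.mean([any(np.linalg.norm(r - xg[i]) <= rg[i]
                       for i in range(len(xg))) for r in xr])
    return float(prec), float(rec)


class TestPrecisionRecall:
    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(9)
        xr = rng.standard_normal((60, 5))
        xg = rng.standard_normal((50, 5)) + 0.5
        got = precision_recall(FeatureSet(xr), FeatureSet(xg), k=3)
        assert got == brute_precision_recall(xr, xg, 3)

    def test_identical_sets_give_perfect_scores(self):
        x = np.random.default_rng(10).standard_normal((40, 4))
        p, r = precision_recall(FeatureSet(x), FeatureSet(x.copy()), k=3)
        assert (p, r) == (1.0, 1.0)

    def test_far_separated_clusters_give_zero(self):
        rng = np.random.default_rng(11)
        a = rng.standard_normal((30, 3))
        b = rng.standard_normal((30, 3)) + 100.0
        assert precision_recall(FeatureSet(a), FeatureSet(b), k=3) == (0.0, 0.0)

    def test_mode_dropping_lowers_recall_not_precision(self):
        rng = np.random.default_rng(12)
        mode = rng.standard_normal((40, 3)) * 0.1
        distant = rng.standard_normal((10, 3)) * 0.1 + 50.0
        real = FeatureSet(np.vstack([mode, distant]))
        gen = FeatureSet(mode[:30] + rng.standard_normal((30, 3)) * 0.01)
        p, r = precision_recall(real, gen, k=3)
        assert p == 1.0
        assert r < 1.0

    def test_excessive_k_rejected(self):
        x = FeatureSet(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            precision_recall(x, x, k=5)


class TestRealism:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        xr = rng.standard_normal((30, 4))
        xg = rng.standard_normal((20, 4))
        got = realism_scores(FeatureSet(xr), FeatureSet(xg), k=3)
        # loop oracle
        def radius(i):
            d = np.sort([np.linalg.norm(xr[i] - xr[j])
                         for j in range(len(xr)) if j != i])
            return d[2]
        for gi, g in enumerate(xg):
            expect = max(radius(i) / np.linalg.norm(g - xr[i])
                         for i in range(len(xr)))
            assert got[gi] == pytest.approx(expect, rel=1e-12)

    def test_coincident_point_hits_cap(self):
        xr = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        xg = xr[:1].copy()
        s = realism_scores(FeatureSet(xr), FeatureSet(xg), k=2)
        assert s[0] == REALISM_CAP

    def test_scores_decay_radially_from_cluster(self):
        rng = np.random.default_rng(14)
        xr = rng.standard_normal((50, 3))
        direction = np.array([1.0, 0.0, 0.0])
        scores = [realism_scores(FeatureSet(xr),
                                 FeatureSet((t * direction)[None]), k=3)[0]
                  for t in (2.0, 4.0, 8.0, 16.0, 32.0)]
        assert all(b <= a for a, b in zip(scores, scores[1:]))
        assert scores[-1] < 0.5  # far away: not realistic


class TestExtractors:
    def _vols(self, n=4, seed=0):
        rng = np.random.default_rng(seed)
        return [Volume(rng.random((6, 12, 10), dtype=np.float32)) for _ in range(n)]

    def test_two_slices_per_volume(self):
        ex = RandomProjectionSliceExtractor(feature_dim=16, seed=0)
        fs = extract_slice_features(self._vols(5), ex, np.random.default_rng(1))
        assert len(fs) == 10
        assert fs.features.shape[1] == 16

    def test_slice_picks_reproducible(self):
        ex = RandomProjectionSliceExtractor(feature_dim=8, seed=0)
        a = extract_slice_features(self._vols(3), ex, np.random.default_rng(2))
        b = extract_slice_features(self._vols(3), ex, np.random.default_rng(2))
        assert np.array_equal(a.features, b.features)

    def test_constant_volumes_give_identical_features(self):
        ex = RandomProjectionSliceExtractor(feature_dim=8, seed=0)
        vols = [Volume(np.full((4, 8, 8), 0.5, dtype=np.float32))] * 3
        fs = extract_slice_features(vols, ex, np.random.default_rng(3))
        assert np.allclose(fs.features, fs.features[0])

    def test_volume_extractor_contract(self):
        ex = RandomConvVolumeExtractor(feature_dim=12, seed=0)
        fs = extract_volume_features(self._vols(3, seed=4), ex)
        assert fs.features.shape == (3, 12)
        fs2 = extract_volume_features(self._vols(3, seed=4), ex)
        assert np.array_equal(fs.features, fs2.features)

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_volume_features(self._vols(2),
                                    RandomProjectionSliceExtractor())
        with pytest.raises(ValueError):
            extract_slice_features(self._vols(2), RandomConvVolumeExtractor(),
                                   np.random.default_rng(0))


class TestVgsFilter:
    def _graded(self, grades):
        v = Volume(np.zeros((2, 4, 4), dtype=np.float32))
        return [GradedVolume(v, g) for g in grades]

    def test_keeps_exactly_grades_up_to_three(self):
        kept = filter_vgs(self._graded([1, 2, 3, 4, 5]))
        assert [g.vgs for g in kept] == [1, 2, 3]

    def test_all_good_identity_all_bad_empty(self):
        assert len(filter_vgs(self._graded([1, 1, 2]))) == 3
        assert filter_vgs(self._graded([5, 5])) == []

    def test_filtered_fraction_near_cohort_artifact_rate(self):
        from volgan.phantoms import CohortRanges
        ranges = CohortRanges(vertical=(24, 32), horizontal=(24, 32), axial_slices=6)
        cohort = generate_cohort(100, ranges, seed=3, artifact_fraction=0.17)
        kept = filter_vgs(cohort)
        assert 100 - len(kept) == sum(g.vgs >= 4 for g in cohort)


@pytest.fixture(scope="module")
def cohort():
    from volgan.phantoms import CohortRanges
    ranges = CohortRanges(vertical=(32, 32), horizontal=(32, 32),
                          axial_slices=16, cortical_thickness=(2.0, 5.0))
    return generate_cohort(60, ranges, seed=21, artifact_fraction=0.3)


class TestVgsClassifier:
    def test_beats_majority_class_on_held_out_grades(self, cohort):
        train_set, test_set = cohort[:45], cohort[45:]
        clf = train_vgs_classifier(train_set, np.random.default_rng(0))
        vols = np.stack([g.volume.data for g in test_set])
        pred = clf.predict(vols)
        truth = np.array([g.vgs for g in test_set])
        acc = (pred == truth).mean()
        counts = np.bincount([g.vgs for g in train_set], minlength=6)
        majority = counts.max() / counts.sum()
        assert acc > majority

    def test_feature_width_and_determinism(self, cohort):
        clf = train_vgs_classifier(cohort[:12], np.random.default_rng(1),
                                   steps=5, batch=4, feature_dim=24)
        vols = np.stack([g.volume.data for g in cohort[:3]])
        f = clf.apply_volumes(vols)
        assert f.shape == (3, 24)
        clf2 = train_vgs_classifier(cohort[:12], np.random.default_rng(1),
                                    steps=5, batch=4, feature_dim=24)
        assert np.array_equal(f, clf2.apply_volumes(vols))

    def test_single_class_rejected(self):
        v = Volume(np.zeros((4, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError):
            train_vgs_classifier([GradedVolume(v, 2)] * 4)


def test_evaluate_report_schema():
    real = _gauss(30, 6, 30)
    gen = _gauss(25, 6, 31, mean=0.2)
    rep = evaluate(real, gen, k=3)
    assert rep.n_real == 30 and rep.n_gen == 25
    assert 0.0 <= rep.precision <= 1.0
    assert 0.0 <= rep.recall <= 1.0
    assert rep.realism.shape == (25,)
    assert rep.fid >= 0.0
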