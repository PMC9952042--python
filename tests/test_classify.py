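"""Mass segmentation stand-in, shape/texture features, feature selection
and the weighted k-NN cross-validation."""

import numpy as np
import pandas as pd
import pytest
from skimage import measure

from sbbdem.classify import (
    FEATURE_NAMES,
    KNNConfig,
    chi_square_filter,
    circularity,
    extract_features,
    knn_cv,
    pca_reduce,
    segment_in_box,
)
from sbbdem.metrics import BoundingBox, mask_eval, roc_auc
from sbbdem.phantom import PhantomSpec, generate_phantom


def disc_mask(size, radius):
    rr, cc = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    return (rr - c) ** 2 + (cc - c) ** 2 <= radius**2


class TestSegmentInBox:
    def test_recovers_phantom_masses(self):
        ious = []
        for i in range(10):
            ph = generate_phantom(PhantomSpec(seed=300 + i, acr_level=1 + i % 4, mass_kinds=("benign",)))
            seg = segment_in_box(ph.image, ph.boxes[0])
            ious.append(mask_eval(seg, ph.mass_masks[0]).iou_mass)
        assert np.mean(ious) >= 0.85

    def test_flat_background_errors(self):
        img = np.full((64, 64), 0.4)
        with pytest.raises(ValueError):
            segment_in_box(img, BoundingBox(10, 10, 20, 20))

    def test_filled_rectangle_exact(self):
        img = np.full((64, 64), 0.3)
        img[20:30, 15:35] = 0.6
        seg = segment_in_box(img, BoundingBox(15, 20, 20, 10))
        want = np.zeros((64, 64), dtype=bool)
        want[20:30, 15:35] = True
        np.testing.assert_array_equal(seg, want)

    def test_box_outside_image_errors(self):
        with pytest.raises(ValueError):
            segment_in_box(np.zeros((32, 32)), BoundingBox(20, 20, 20, 20))


class TestCircularity:
    def test_disc_close_to_one(self):
        mask = disc_mask(80, 30)
        assert 0.95 <= circularity(mask) <= 1.08
        # dual route: the raw-contour variant must equal the explicit
        # marching-squares polygon-length computation
        contour = max(measure.find_contours(np.pad(mask.astype(float), 1), 0.5), key=len)
        per = np.sum(np.linalg.norm(np.diff(contour, axis=0), axis=1))
        assert circularity(mask, perimeter="contour-raw") == pytest.approx(4 * np.pi * mask.sum() / per**2)

    def test_smoothed_contour_matches_independent_computation(self):
        from scipy.ndimage import uniform_filter1d

        mask = disc_mask(60, 20)
        contour = max(measure.find_contours(np.pad(mask.astype(float), 1), 0.5), key=len)
        closed = contour[:-1]
        sm = np.column_stack([uniform_filter1d(closed[:, i], 7, mode="wrap") for i in (0, 1)])
        per = np.sum(np.linalg.norm(np.diff(np.vstack([sm, sm[:1]]), axis=0), axis=1))
        assert circularity(mask) == pytest.approx(4 * np.pi * mask.sum() / per**2)

    def test_one_pixel_mask_errors(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(ValueError):
            circularity(mask)

    def test_multi_component_errors(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:6, 2:6] = True
        mask[12:16, 12:16] = True
        with pytest.raises(ValueError):
            circularity(mask)

    def test_disc_beats_star_of_similar_area(self):
        ben = generate_phantom(PhantomSpec(seed=21, mass_kinds=("benign",)))
        mal = generate_phantom(PhantomSpec(seed=22, mass_kinds=("malignant",)))
        assert circularity(ben.mass_masks[0]) > circularity(mal.mass_masks[0])

    def test_rotation_invariant_for_discs(self):
        from sbbdem.phantom import apply_geometric
        from sbbdem.metrics import tight_box

        mask = disc_mask(80, 25)
        base = circularity(mask)
        for angle in (30.0, 115.0, 260.0):
            _, masks, _ = apply_geometric(np.zeros((80, 80)), [mask], [tight_box(mask)], angle, False, 1.0)
            assert circularity(masks[0]) == pytest.approx(base, rel=0.02)

    def test_printed_variant_constant_placement(self):
        mask = disc_mask(60, 20)
        std = circularity(mask)
        alt = circularity(mask, printed_variant=True)
        assert alt == pytest.approx(std / np.pi**2, rel=1e-9)


class TestExtractFeatures:
    def test_constant_disc(self):
        img = np.full((64, 64), 0.2)
        mask = disc_mask(64, 15)
        img[mask] = 0.7
        f = extract_features(img, mask)
        assert tuple(f) == FEATURE_NAMES
        assert f["contrast"] == 0.0
        assert f["energy"] == 1.0
        assert f["mean_intensity"] == pytest.approx(0.7)
        assert 0.9 <= f["circularity"] <= 1.08
        assert np.isnan(f["correlation"])  # uniform mass: undefined

    def test_circularity_separates_phantom_classes(self):
        scores, labels = [], []
        for i in range(40):
            kind = "benign" if i % 2 == 0 else "malignant"
            ph = generate_phantom(PhantomSpec(seed=600 + i, acr_level=1 + i % 4, mass_kinds=(kind,)))
            f = extract_features(ph.image, ph.mass_masks[0])
            scores.append(f["circularity"])
            labels.append(int(kind == "benign"))
        assert roc_auc(scores, labels) >= 0.9

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            extract_features(np.zeros((8, 8)), np.zeros((8, 8), dtype=bool))


class TestChiSquareFilter:
    def chi2_oracle(self, binned, labels):
        table = pd.crosstab(binned, labels).to_numpy().astype(float)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        return ((table - expected) ** 2 / expected).sum()

    def test_informative_kept_flat_removed(self):
        rng = np.random.default_rng(0)
        n = 120
        labels = np.array([0, 1] * (n // 2))
        flat = np.empty(n)
        vals = rng.random(n // 2)
        flat[labels == 0] = vals  # identical values in both classes
        flat[labels == 1] = vals
        informative = labels * 2.0 + rng.normal(0, 0.05, n)
        df = pd.DataFrame({"flat": flat, "good": informative})
        kept = chi_square_filter(df, labels)
        assert kept == ["good"]

    def test_label_indicator_feature_kept(self):
        labels = np.array([0] * 30 + [1] * 30)
        df = pd.DataFrame({"ind": labels.astype(float)})
        assert chi_square_filter(df, labels) == ["ind"]

    def test_matches_contingency_oracle_selection(self):
        rng = np.random.default_rng(5)
        n = 200
        labels = rng.integers(0, 2, n)
        data = {
            "info1": labels + rng.normal(0, 0.1, n),
            "info2": -labels + rng.normal(0, 0.1, n),
        }
        # class-balanced nuisance features: both classes draw the same values
        for k in range(4):
            v = np.empty(n)
            vals = rng.random(max((labels == 0).sum(), (labels == 1).sum()))
            v[labels == 0] = vals[: (labels == 0).sum()]
            v[labels == 1] = vals[: (labels == 1).sum()]
            data[f"noise{k}"] = v
        df = pd.DataFrame(data)
        kept = chi_square_filter(df, labels, chi2_min=1.0)
        # oracle: recompute every score with an explicit contingency table
        for name in df.columns:
            binned = pd.qcut(df[name].to_numpy(), q=4, duplicates="drop", labels=False)
            score = self.chi2_oracle(binned, labels)
            assert (name in kept) == (score >= 1.0)
        assert set(kept) >= {"info1", "info2"}

    def test_single_class_errors(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            chi_square_filter(df, np.array([1, 1]))

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        labels = np.array([0, 1] * 40)
        df = pd.DataFrame({
            "a": labels + rng.normal(0, 0.2, 80),
            "b": rng.normal(0, 1, 80),
            "c": 2 * labels + rng.normal(0, 0.2, 80),
        })
        k1 = set(chi_square_filter(df, labels))
        k2 = set(chi_square_filter(df[["c", "b", "a"]], labels))
        assert k1 == k2


class TestPCA:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((50, 4)), columns=list("abcd"))
        Z, loadings, evr = pca_reduce(df, 4)
        assert evr.sum() == pytest.approx(1.0)
        # project back: standardized data recovered
        from sklearn.preprocessing import StandardScaler

        X = StandardScaler().fit_transform(df.to_numpy())
        np.testing.assert_allclose(Z.to_numpy() @ loadings, X, atol=1e-8)

    def test_rank_one_data_first_component_dominates(self):
        rng = np.random.default_rng(2)
        direction = np.array([1.0, -2.0, 0.5])
        t = rng.normal(0, 1, 100)
        df = pd.DataFrame(np.outer(t, direction) + rng.normal(0, 1e-4, (100, 3)))
        df.columns = ["x", "y", "z"]
        _, _, evr = pca_reduce(df, 3)
        assert evr[0] >= 0.99

    def test_sign_convention(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((30, 3)), columns=list("xyz"))
        _, loadings, _ = pca_reduce(df, 3)
        for row in loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_bad_component_counts(self):
        df = pd.DataFrame(np.random.default_rng(0).random((10, 3)))
        df.columns = list("abc")
        with pytest.raises(ValueError):
            pca_reduce(df, 0)
        with pytest.raises(ValueError):
            pca_reduce(df, 4)


class TestKNN:
    def test_separable_classes_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.01, (30, 3)), rng.normal(5, 0.01, (30, 3))])
        y = np.array([0] * 30 + [1] * 30)
        rep = knn_cv(pd.DataFrame(X, columns=list("abc")), y, KNNConfig(), seed=0)
        assert rep.mean_accuracy == 1.0
        assert rep.auc == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.random((120, 4)), columns=list("abcd"))
        accs = []
        for s in range(10):
            y = np.random.default_rng(s).permutation([0, 1] * 60)
            accs.append(knn_cv(X, y, KNNConfig(), seed=s).mean_accuracy)
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_manual_inverse_distance_vote(self):
        # 10 hand-placed neighbors in 1-D, one far query point; compare the
        # k-NN probability with the explicit 1/d weighted vote
        train_x = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 2.0, 2.1, 2.2, 2.3, 2.4])
        train_y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        query = 1.3
        from sklearn.neighbors import KNeighborsClassifier

        clf = KNeighborsClassifier(n_neighbors=10, weights="distance", metric="euclidean")
        clf.fit(train_x[:, None], train_y)
        proba = clf.predict_proba([[query]])[0]
        w = 1.0 / np.abs(train_x - query)
        want = np.array([w[train_y == 0].sum(), w[train_y == 1].sum()])
        want /= want.sum()
        np.testing.assert_allclose(proba, want, atol=1e-12)
        assert clf.predict([[query]])[0] == int(want[1] > want[0])

    def test_k_too_large_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).random((12, 2)), columns=list("ab"))
        y = np.array([0, 1] * 6)
        with pytest.raises(ValueError):
            knn_cv(X, y, KNNConfig(k=50), seed=0)

    def test_too_few_per_class_errors(self):
        X = pd.DataFrame(np.random.default_rng(0).random((6, 2)), columns=list("ab"))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError):
            knn_cv(X, y, KNNConfig(), seed=0)
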