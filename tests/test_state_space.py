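import numpy as np
import pandas as pd
import pytest

import statemi as sm
from conftest import random_annotation


def as_norm(matrix: np.ndarray, centered=True) -> sm.NormalizedMatrix:
    m = np.asarray(matrix, dtype=float)
    if centered:
        m = m - m.mean(axis=1, keepdims=True)
    df = pd.DataFrame(
        m,
        index=[f"g{i}" for i in range(m.shape[0])],
        columns=[f"s{j}" for j in range(m.shape[1])],
    )
    return sm.NormalizedMatrix(
        values=df,
        centered=centered,
        size_factors=pd.Series(1.0, index=df.columns),
        pseudocount=1.0,
    )


def brute_force_coords(m: np.ndarray) -> np.ndarray:
    """Sample coordinates via eigendecomposition of the sample-sample
    covariance M^T M — an oracle independent of the SVD route."""
    w, v = np.linalg.eigh(m.T @ m)
    order = np.argsort(w)[::-1]
    w, v = np.clip(w[order], 0, None), v[:, order]
    return v * np.sqrt(w)


class TestFitStateSpace:
    def test_rank_one_input_has_single_singular_value(self):
        rng = np.random.default_rng(0)
        m = np.outer(rng.normal(size=30), rng.normal(size=6))
        model = sm.fit_state_space(as_norm(m))  # row-centering preserves rank 1
        assert np.sum(model.singular_values > 1e-10) == 1

    def test_energy_conservation(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(40, 12))
        norm = as_norm(m)
        model = sm.fit_state_space(norm)
        fro2 = np.sum(norm.values.to_numpy() ** 2)
        assert np.sum(model.singular_values**2) == pytest.approx(fro2, rel=1e-6)

    def test_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = rng.normal(size=(50, 20))
            norm = as_norm(m)
            model = sm.fit_state_space(norm)
            oracle = brute_force_coords(norm.values.to_numpy())
            coords = model.sample_coords.to_numpy()
            s = model.singular_values
            for k in range(coords.shape[1]):
                if s[k] <= 1e-8 * s[0]:
                    continue  # null direction: coordinates are pure noise
                a, b = coords[:, k], oracle[:, k]
                if np.dot(a, b) < 0:
                    b = -b
                assert np.allclose(a, b, atol=1e-8)

    def test_loading_columns_orthonormal(self):
        model = sm.fit_state_space(as_norm(np.random.default_rng(3).normal(size=(30, 8))))
        u = model.gene_loadings.to_numpy()
        assert np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8)

    def test_sign_convention_is_deterministic(self):
        m = np.random.default_rng(4).normal(size=(25, 7))
        a = sm.fit_state_space(as_norm(m))
        b = sm.fit_state_space(as_norm(m))
        pd.testing.assert_frame_equal(a.sample_coords, b.sample_coords)
        for k in range(a.n_components):
            col = a.gene_loadings.iloc[:, k].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_universe_subsetting_and_disjoint_error(self, small_norm):
        genes = list(small_norm.genes[:50])
        model = sm.fit_state_space(small_norm, universe=genes)
        assert model.universe == genes
        with pytest.raises(ValueError, match="disjoint"):
            sm.fit_state_space(small_norm, universe=["nope1", "nope2"])

    def test_uncentered_matrix_rejected(self, small_dataset):
        norm = sm.normalize_log(small_dataset.counts)
        with pytest.raises(ValueError, match="centered"):
            sm.fit_state_space(norm)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            sm.fit_state_space(as_norm(np.ones((10, 2)) + np.arange(2)))


class TestScreeElbow:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 6, 3.5, 2.0, 1.9, 1.8, 1.7, 1.6], 4),
            ([10, 1, 1, 1, 1], 2),
            ([5, 4, 3, 2, 1], 2),  # linear decay: smallest interior tie
        ],
    )
    def test_elbow_examples(self, values, expected):
        assert sm.find_scree_elbow(np.array(values, dtype=float)) == expected

    def test_increasing_sequence_rejected(self):
        with pytest.raises(ValueError, match="nonincreasing"):
            sm.find_scree_elbow(np.array([1.0, 2.0, 3.0]))

    def test_elbow_matches_geometry_oracle(self):
        """Independent point-to-chord distance computation on random screes."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = np.sort(rng.exponential(1.0, size=10))[::-1]
            n = len(s)
            p1, p2 = np.array([1.0, s[0]]), np.array([float(n), s[-1]])
            dists = []
            for i in range(2, n):  # interior, 1-based
                p = np.array([float(i), s[i - 1]])
                u, v = p2 - p1, p - p1
                d = np.abs(u[0] * v[1] - u[1] * v[0]) / np.linalg.norm(u)
                dists.append(d)
            expected = int(np.argmax(np.array(dists) > max(dists) - 1e-12)) + 2
            assert sm.find_scree_elbow(s) == expected


class TestAxisSeparation:
    def make_model(self, coords: np.ndarray) -> sm.StateSpaceModel:
        n = coords.shape[0]
        samples = [f"s{j}" for j in range(n)]
        return sm.StateSpaceModel(
            singular_values=np.ones(coords.shape[1]),
            sample_coords=pd.DataFrame(
                coords, index=samples,
                columns=[f"PC{k+1}" for k in range(coords.shape[1])],
            ),
            gene_loadings=pd.DataFrame(),
            elbow_index=1,
            universe=[],
        )

    def annotation_for(self, labels):
        leuk = ["CML" if l == "B" else "non-CML" for l in labels]
        return pd.DataFrame(
            {
                "leukemic": leuk,
                "genotype": ["wt"] * len(labels),
                "condition": labels,
            },
            index=[f"s{j}" for j in range(len(labels))],
        )

    def test_perfect_separation_scores_one(self):
        model = self.make_model(np.array([[-1.0], [-1.0], [1.0], [1.0]]))
        ann = self.annotation_for(["A", "A", "B", "B"])
        scores = sm.score_axis_separation(model, ann, "leukemic")
        assert scores[0] == pytest.approx(1.0)

    def test_equal_group_means_score_zero(self):
        model = self.make_model(np.array([[1.0], [-1.0], [1.0], [-1.0]]))
        ann = self.annotation_for(["A", "A", "B", "B"])
        scores = sm.score_axis_separation(model, ann, "leukemic")
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_level_factor_rejected(self):
        model = self.make_model(np.ones((4, 1)))
        ann = self.annotation_for(["A", "A", "A", "A"])
        with pytest.raises(ValueError, match="single level"):
            sm.score_axis_separation(model, ann, "leukemic")

    def test_null_expectation_matches_brute_force_oracle(self):
        """Random coords: per-draw agreement with a loop-based BSS/TSS
        oracle, and mean score near 1/(n-1) over 1000 draws."""
        rng = np.random.default_rng(6)
        n = 20
        labels = ["A"] * 10 + ["B"] * 10
        ann = self.annotation_for(labels)
        scores = []
        for i in range(1000):
            c = rng.normal(size=(n, 1))
            model = self.make_model(c)
            score = sm.score_axis_separation(model, ann, "leukemic")[0]
            # independent oracle
            grand = c[:, 0].mean()
            bss = sum(
                (c[np.array(labels) == lev, 0].mean() - grand) ** 2
                * np.sum(np.array(labels) == lev)
                for lev in ("A", "B")
            )
            tss = np.sum((c[:, 0] - grand) ** 2)
            assert score == pytest.approx(bss / tss, abs=1e-12)
            scores.append(score)
        assert abs(np.mean(scores) - 1 / (n - 1)) < 0.01


class TestRotation:
    def plane_model(self, xy, extra_cols=0):
        coords = np.hstack([xy, np.zeros((len(xy), extra_cols))])
        model = TestAxisSeparation().make_model(coords)
        model.selected_axes = (1, 2)
        return model

    def test_quarter_turn(self):
        model = self.plane_model(np.array([[1.0, 0.0]]))
        rotated = sm.rotate_plane(model, angle_deg=90.0)
        assert np.allclose(rotated.sample_coords.iloc[0, :2], [0.0, 1.0], atol=1e-12)

    def test_auto_angle_from_centroids(self):
        xy = np.array([[0.1, -0.1], [-0.1, 0.1], [1.1, 0.9], [0.9, 1.1]])
        model = self.plane_model(xy)
        ann = TestAxisSeparation().annotation_for(["A", "A", "B", "B"])
        rotated = sm.rotate_plane(model, annotation=ann)
        assert rotated.rotation_angle_deg == pytest.approx(-45.0, abs=1e-9)
        c = rotated.sample_coords.to_numpy()
        centroid_diff = c[2:, :2].mean(axis=0) - c[:2, :2].mean(axis=0)
        assert abs(centroid_diff[1]) < 1e-9  # aligned with +x

    def test_rotation_inverse_restores_coordinates(self):
        rng = np.random.default_rng(7)
        model = self.plane_model(rng.normal(size=(8, 2)))
        there = sm.rotate_plane(model, angle_deg=33.3)
        back = sm.rotate_plane(there, angle_deg=-33.3)
        assert np.allclose(
            back.sample_coords.to_numpy(), model.sample_coords.to_numpy(), atol=1e-10
        )

    def test_rotation_is_plane_isometry(self):
        rng = np.random.default_rng(8)
        model = self.plane_model(rng.normal(size=(10, 2)), extra_cols=2)
        rotated = sm.rotate_plane(model, angle_deg=-34.4)
        before = model.sample_coords.to_numpy()[:, :2]
        after = rotated.sample_coords.to_numpy()[:, :2]
        d0 = np.linalg.norm(before[:, None] - before[None, :], axis=-1)
        d1 = np.linalg.norm(after[:, None] - after[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-10)
        # components outside the plane untouched
        assert np.allclose(
            rotated.sample_coords.to_numpy()[:, 2:],
            model.sample_coords.to_numpy()[:, 2:],
        )

    def test_coincident_centroids_rejected(self):
        xy = np.array([[1.0, 1.0], [-1.0, -1.0], [1.0, 1.0], [-1.0, -1.0]])
        model = self.plane_model(xy)
        ann = TestAxisSeparation().annotation_for(["A", "B", "B", "A"])
        with pytest.raises(ValueError, match="centroid"):
            sm.rotate_plane(model, annotation=ann)

    def test_auto_rotation_does_not_reduce_disease_separation(self, default_dataset):
        """After centroid alignment, separation along x is at least the
        pre-rotation separation along the selected disease axis."""
        norm = sm.mean_center(sm.normalize_log(default_dataset.counts))
        model = sm.fit_state_space(norm)
        sm.select_axes(model, default_dataset.annotation)
        pre = model.separation_scores["leukemic"][model.selected_axes[0] - 1]
        rotated = sm.rotate_plane(model, annotation=default_dataset.annotation)
        post_scores = sm.score_axis_separation(
            rotated, default_dataset.annotation, "leukemic"
        )
        assert post_scores[rotated.selected_axes[0] - 1] >= pre - 1e-9


class TestCompareStateSpaces:
    def frame(self, arr):
        return pd.DataFrame(
            arr, index=[f"s{j}" for j in range(len(arr))], columns=["PC1", "PC2"]
        )

    def test_identical_coordinates_r2_one(self):
        a = self.frame(np.random.default_rng(9).normal(size=(10, 2)))
        comp = sm.compare_state_spaces(a, a.copy())
        assert comp.r_squared_axis1 == pytest.approx(1.0)
        assert comp.r_squared_axis2 == pytest.approx(1.0)

    def test_sign_and_scale_invariance(self):
        a = self.frame(np.random.default_rng(10).normal(size=(10, 2)))
        comp = sm.compare_state_spaces(a, a * -3.0)
        assert comp.r_squared_axis1 == pytest.approx(1.0)

    def test_mismatched_samples_rejected(self):
        a = self.frame(np.zeros((4, 2)))
        b = a.copy()
        b.index = ["x0", "x1", "x2", "x3"]
        with pytest.raises(ValueError, match="same samples"):
            sm.compare_state_spaces(a, b)

    def test_zero_variance_axis_flagged(self):
        a = self.frame(np.random.default_rng(11).normal(size=(6, 2)))
        b = a.copy()
        b["PC1"] = 1.0
        comp = sm.compare_state_spaces(a, b)
        assert np.isnan(comp.r_squared_axis1)
        assert comp.degenerate_axes == ["PC1"]

    def test_null_r2_expectation(self):
        """Independent N(0,1) vectors, n=20: E[r^2] = 1/(n-1) ~ 0.0526."""
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(2000):
            a = self.frame(rng.normal(size=(20, 2)))
            b = self.frame(rng.normal(size=(20, 2)))
            comp = sm.compare_state_spaces(a, b)
            vals.append(comp.r_squared_axis1)
        assert 0.045 <= np.mean(vals) <= 0.061


def test_disease_axis_is_first_component_on_default_design(default_dataset):
    """Dominant leukemic variation maps to PC1, genotype to a later axis."""
    norm = sm.mean_center(sm.normalize_log(default_dataset.counts))
    model = sm.fit_state_space(norm)
    axes = sm.select_axes(model, default_dataset.annotation)
    assert axes[0] == 1
    assert axes[1] != 1
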