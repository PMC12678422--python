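import numpy as np
import pytest

from lthrm.cluster import (
    change_filter,
    change_image,
    make_features,
    mean_intra_cluster_distance,
    representatives,
    select_k,
    two_stage_cluster,
)


def brute_change_filter(window, k_len=10):
    """Direct double-loop convolution with [-1, 0, ..., 0, 1], squared."""
    rows, width = window.shape
    out = np.zeros((rows, width - k_len + 1))
    kernel = np.zeros(k_len)
    kernel[0], kernel[-1] = -1.0, 1.0
    for i in range(rows):
        for j in range(width - k_len + 1):
            acc = 0.0
            for l in range(k_len):
                acc += kernel[l] * window[i, j + l]
            out[i, j] = acc**2
    return out


class TestChangeFilter:
    def test_constant_window_zero_response(self):
        assert not change_filter(np.full((36, 500), 42.0)).any()

    def test_step_response(self):
        row = np.zeros((1, 500))
        row[0, 250:] = 10.0
        out = change_filter(row)
        assert (out == 100.0).sum() == 9  # kernel straddles the step 9 ways
        assert out[out != 100.0].sum() == 0

    def test_ramp_closed_form(self):
        m = 3.0
        ramp = (np.arange(500) * m)[None, :]
        np.testing.assert_allclose(change_filter(ramp), (9 * m) ** 2)

    def test_output_width(self, rng):
        out = change_filter(rng.normal(size=(36, 500)))
        assert out.shape == (36, 491)

    def test_too_narrow_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            change_filter(rng.normal(size=(36, 5)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(3):
            w = rng.normal(size=(6, 40))
            np.testing.assert_allclose(
                change_filter(w), brute_change_filter(w), atol=1e-9
            )


class TestMakeFeatures:
    def test_identical_images_identical_features(self, rng):
        win = rng.normal(50, 20, size=(36, 500))
        feats, _ = make_features([win] * 5, n_components=3)
        X = np.stack([f.feature for f in feats])
        assert np.allclose(np.linalg.norm(X[0] - X[1:], axis=1), 0, atol=1e-8)

    def test_two_groups_separated_by_pc1(self, rng):
        a = rng.normal(0, 1, size=(36, 500))
        b = a + 100.0 * np.sin(np.arange(500) / 10)[None, :]
        feats, _ = make_features([a, a, b, b], n_components=1)
        pc1 = np.array([f.feature[0] for f in feats])
        assert np.sign(pc1[0]) == np.sign(pc1[1]) != np.sign(pc1[2])

    def test_feature_length_30(self, rng):
        wins = [rng.normal(size=(36, 500)) for _ in range(40)]
        feats, pca = make_features(wins)
        assert all(len(f.feature) == 30 for f in feats)
        assert pca.n_components_ == 30

    def test_change_image_nonnegative_50x50(self, rng):
        img = change_image(rng.normal(size=(36, 500)))
        assert img.shape == (50, 50)
        assert img.min() >= -1e-9

    def test_fewer_samples_reduce_components_with_warning(self, rng):
        wins = [rng.normal(size=(36, 500)) for _ in range(5)]
        with pytest.warns(UserWarning, match="reducing"):
            feats, _ = make_features(wins)
        assert len(feats[0].feature) == 4

    def test_too_few_samples_error(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            make_features([rng.normal(size=(36, 500))])


class TestSelectK:
    def test_five_zero_variance_blobs_tie_resolves_to_five(self, rng):
        pts = np.repeat(rng.normal(size=(5, 30)) * 10, 10, axis=0)
        assert select_k(pts) == 5

    def test_all_identical_points_return_smallest_k(self, rng):
        pts = np.tile(rng.normal(size=30), (20, 1))
        assert select_k(pts) == 4

    def test_literal_rule_prefers_large_k_with_spread(self, rng):
        blobs = np.vstack(
            [rng.normal(0, 1, (30, 8)), rng.normal(50, 1, (30, 8))]
        )
        assert select_k(blobs, strategy="intra") == 10  # documented bias

    def test_knee_recovers_interior_cluster_count(self, rng):
        centers = rng.normal(0, 60, size=(6, 8))
        pts = np.vstack([c + rng.normal(0, 0.5, (15, 8)) for c in centers])
        assert select_k(pts, strategy="knee") == 6

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            select_k(rng.normal(size=(8, 5)))

    def test_intra_score_zero_for_perfect_partition(self, rng):
        X = np.repeat(rng.normal(size=(4, 6)) * 10, 5, axis=0)
        labels = np.repeat(np.arange(4), 5)
        assert mean_intra_cluster_distance(X, labels) == pytest.approx(0.0, abs=1e-12)


class TestTwoStageCluster:
    def test_equal_blobs_all_main_no_stage2(self, rng):
        X = np.vstack(
            [rng.normal(30 * i, 0.1, (25, 5)) for i in range(4)]
        )
        rep = two_stage_cluster(X, k_range=[4], strategy="intra")
        mains = [c for c in rep.clusters if c.stage == 1]
        assert len(mains) == 4  # each blob holds 25% >= 15%: all main
        assert all(c.frequency == 25 for c in mains)
        assert not [c for c in rep.clusters if c.stage == 2]
        assert sum(c.frequency for c in rep.clusters) == 100

    def test_minority_blobs_pooled_into_stage2(self, rng):
        X = np.vstack(
            [
                rng.normal(0, 0.01, (85, 5)),
                rng.normal(20, 0.01, (5, 5)),
                rng.normal(40, 0.01, (5, 5)),
                rng.normal(60, 0.01, (5, 5)),
            ]
        )
        rep = two_stage_cluster(X, k_range=[4], strategy="intra")
        mains = [c for c in rep.clusters if c.stage == 1]
        assert len(mains) == 1 and mains[0].frequency == 85
        assert sum(c.frequency for c in rep.clusters if c.stage == 2) == 15

    def test_stage2_k_capped_by_pool_size(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.01, (93, 5)), rng.normal(40, 3.0, (7, 5))]
        )
        rep = two_stage_cluster(X, k_range=[4], strategy="intra", special_k=10)
        stage2 = [c for c in rep.clusters if c.stage == 2]
        assert 0 < len(stage2) <= 7

    def test_every_sample_assigned_exactly_once(self, rng):
        X = rng.normal(size=(60, 10))
        rep = two_stage_cluster(X)
        assert np.all(rep.final_labels >= 0)
        counted = sum(c.frequency for c in rep.clusters)
        assert counted == 60
        for c in rep.clusters:
            assert np.all(rep.final_labels[c.member_indices] == c.cluster_id)

    def test_report_serializes_to_json(self, rng, tmp_path):
        X = rng.normal(size=(30, 5))
        rep = two_stage_cluster(X, k_range=[4])
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["stage1_k"] == 4
        assert len(payload["final_labels"]) == 30


class TestRepresentatives:
    def test_small_cluster_returns_all_members(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (3, 4)), rng.normal(9, 0.1, (27, 4))])
        rep = two_stage_cluster(X, k_range=[4], strategy="intra", main_share=0.05)
        reps = representatives(rep, X, n=5)
        sizes = {c.cluster_id: c.frequency for c in rep.clusters}
        for cid, r in reps.items():
            assert len(r["closest"]) == min(5, sizes[cid])

    def test_planted_outlier_is_most_distant(self, rng):
        X = rng.normal(0, 0.1, size=(20, 4))
        X[7] += 30.0
        X2 = np.vstack([X, rng.normal(60, 0.1, size=(20, 4))])
        rep = two_stage_cluster(X2, k_range=[4], strategy="intra")
        cid = rep.final_labels[7]
        cluster = next(c for c in rep.clusters if c.cluster_id == cid)
        assert cluster.most_distant[0] == 7

    def test_tied_members_ordered_by_index(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [3.0, 0.0], [-3.0, 0.0]])
        from lthrm.cluster import _cluster_info

        info = _cluster_info(X, np.arange(4), 0, stage=1, n_repr=2)
        assert list(info.closest) == [0, 1]  # same distance, lower index first
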