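"""Recruitment score: overlap oracle, pooling algebra, condition statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pictquant as pq
from pictquant.segmentation import LabeledSpots


def make_spots(labels):
    labels = np.asarray(labels, dtype=int)
    rows = [{"label": int(l), "area_px2": int((labels == l).sum())}
            for l in np.unique(labels) if l > 0]
    return LabeledSpots(labels, pd.DataFrame(rows, columns=["label", "area_px2"]))


def random_label_pair(rng, shape=(16, 16)):
    prey = np.zeros(shape, dtype=int)
    anchors = np.zeros(shape, dtype=int)
    for lab in (1, 2, 3):
        r, c = rng.integers(0, shape[0] - 4, 2)
        prey[r:r + rng.integers(2, 5), c:c + rng.integers(2, 5)] = lab
    for lab in (1, 2):
        r, c = rng.integers(0, shape[0] - 5, 2)
        anchors[r:r + rng.integers(2, 6), c:c + rng.integers(2, 6)] = lab
    return make_spots(prey), make_spots(anchors)


class TestOverlap:
    def test_disjoint_masks_have_zero_overlap(self):
        prey = np.zeros((8, 8), dtype=int); prey[0:2, 0:2] = 1
        anch = np.zeros((8, 8), dtype=int); anch[5:7, 5:7] = 1
        ov = pq.overlap_regions(make_spots(prey), make_spots(anch))
        assert ov.yellow_area == 0 and ov.pairs == []

    def test_nested_prey_overlap_equals_prey_area(self):
        prey = np.zeros((10, 10), dtype=int); prey[4:6, 4:6] = 1
        anch = np.zeros((10, 10), dtype=int); anch[2:8, 2:8] = 1
        ov = pq.overlap_regions(make_spots(prey), make_spots(anch))
        assert ov.yellow_area == 4 and ov.pairs == [(1, 1)]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            prey, anch = random_label_pair(rng)
            ov = pq.overlap_regions(prey, anch)
            # oracle: per-pixel loop
            area = 0; pairs = set()
            for i in range(16):
                for j in range(16):
                    if prey.labels[i, j] > 0 and anch.labels[i, j] > 0:
                        area += 1
                        pairs.add((prey.labels[i, j], anch.labels[i, j]))
            assert ov.yellow_area == area
            assert set(ov.pairs) == pairs

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pq.overlap_regions(make_spots(np.zeros((4, 4), dtype=int)),
                               make_spots(np.zeros((5, 5), dtype=int)))


class TestRecruitmentScore:
    def test_no_overlap_scores_zero(self):
        green = np.full((8, 8), 50.0)
        prey = np.zeros((8, 8), dtype=int); prey[0, 0:2] = 1
        anch = np.zeros((8, 8), dtype=int); anch[6:8, 6:8] = 1
        res = pq.recruitment_score(green, make_spots(prey), make_spots(anch))
        assert res.score == 0.0 and res.yellow_area == 0

    def test_fully_covered_anchor_scores_mean_intensity(self):
        green = np.zeros((12, 12)); green[3:7, 3:7] = 80.0
        anch = np.zeros((12, 12), dtype=int); anch[3:7, 3:7] = 1
        prey = np.zeros((12, 12), dtype=int); prey[2:8, 2:8] = 1
        res = pq.recruitment_score(green, make_spots(prey), make_spots(anch))
        assert res.score == pytest.approx(80.0)

    def test_matches_bruteforce_sum_over_yellow(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            prey, anch = random_label_pair(rng, (8, 8))
            if anch.total_area == 0:
                continue
            green = rng.integers(0, 100, (8, 8)).astype(float)
            res = pq.recruitment_score(green, prey, anch)
            total = sum(green[i, j]
                        for i in range(8) for j in range(8)
                        if prey.labels[i, j] > 0 and anch.labels[i, j] > 0)
            assert res.score * res.red_area == pytest.approx(total)
            assert res.score == pytest.approx(total / anch.total_area)

    def test_no_anchor_field_is_excluded(self):
        green = np.full((8, 8), 5.0)
        prey = np.zeros((8, 8), dtype=int); prey[1:3, 1:3] = 1
        res = pq.recruitment_score(green, make_spots(prey),
                                   make_spots(np.zeros((8, 8), dtype=int)))
        assert res is None

    def test_scaling_green_scales_score(self):
        rng = np.random.default_rng(17)
        prey, anch = random_label_pair(rng, (12, 12))
        green = rng.uniform(0, 50, (12, 12))
        r1 = pq.recruitment_score(green, prey, anch)
        r2 = pq.recruitment_score(3.0 * green, prey, anch)
        assert r2.score == pytest.approx(3.0 * r1.score)

    def test_prey_spots_off_anchor_contribute_nothing(self):
        # false-positive prey spots count only if they overlap an anchor
        green = np.full((16, 16), 10.0)
        anch = np.zeros((16, 16), dtype=int); anch[2:5, 2:5] = 1
        prey_on = np.zeros((16, 16), dtype=int); prey_on[2:5, 2:5] = 1
        prey_extra = prey_on.copy(); prey_extra[10:14, 10:14] = 2
        r_on = pq.recruitment_score(green, make_spots(prey_on), make_spots(anch))
        r_extra = pq.recruitment_score(green, make_spots(prey_extra),
                                       make_spots(anch))
        assert r_extra.score == pytest.approx(r_on.score)

    def test_whole_spot_mode_counts_spot_pixels_past_anchor(self):
        green = np.full((12, 12), 10.0)
        anch = np.zeros((12, 12), dtype=int); anch[4:6, 4:6] = 1
        prey = np.zeros((12, 12), dtype=int); prey[4:8, 4:6] = 1
        overlap = pq.recruitment_score(green, make_spots(prey), make_spots(anch),
                                       area_mode="overlap")
        whole = pq.recruitment_score(green, make_spots(prey), make_spots(anch),
                                     area_mode="whole_spot")
        assert overlap.yellow_area == 4 and whole.yellow_area == 8
        assert whole.score == pytest.approx(2 * overlap.score)


class TestPooling:
    def test_single_field_pool_is_identity(self):
        r = pq.RecruitmentResult(10, 500.0, 50)
        pooled = pq.pool_replicate([r])
        assert pooled.score == pytest.approx(r.score)

    def test_equal_red_area_pool_is_mean_of_scores(self):
        r1 = pq.RecruitmentResult(10, 400.0, 50)
        r2 = pq.RecruitmentResult(20, 800.0, 50)
        pooled = pq.pool_replicate([r1, r2])
        assert pooled.score == pytest.approx(0.5 * (r1.score + r2.score))

    def test_pool_matches_global_enumeration(self):
        rng = np.random.default_rng(19)
        fields = []
        tot_green, tot_red = 0.0, 0
        for _ in range(3):
            prey, anch = random_label_pair(rng, (8, 8))
            if anch.total_area == 0:
                continue
            green = rng.uniform(0, 20, (8, 8))
            fields.append(pq.recruitment_score(green, prey, anch))
            yellow = prey.mask & anch.mask
            tot_green += green[yellow].sum()
            tot_red += anch.total_area
        pooled = pq.pool_replicate(fields)
        assert pooled.score == pytest.approx(tot_green / tot_red)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pq.pool_replicate([])

    @given(st.lists(st.tuples(st.integers(0, 30),
                              st.floats(0, 1000),
                              st.integers(1, 100)), min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_score_red_area_identity_always_holds(self, triples):
        results = [pq.RecruitmentResult(y, g if y else 0.0, r)
                   for y, g, r in triples]
        pooled = pq.pool_replicate(results)
        assert pooled.score * pooled.red_area == pytest.approx(
            pooled.sum_green_in_yellow)


class TestConditionSummary:
    def test_self_reference_normalizes_to_one(self):
        s = pq.summarize_condition("wt", [1.0, 1.2, 0.8])
        s2 = pq.summarize_condition("wt", [1.0, 1.2, 0.8], reference=s)
        assert s2.normalized_mean == pytest.approx(1.0)

    def test_identical_replicates_give_p_of_one(self):
        a = pq.summarize_condition("a", [2.0, 2.0, 2.0])
        b = pq.summarize_condition("b", [2.0, 2.0, 2.0],
                                   comparison=a)
        assert b.p_value == pytest.approx(1.0)

    def test_mean_and_sample_sd(self):
        s = pq.summarize_condition("wt", [1.0, 1.2, 0.8])
        assert s.mean == pytest.approx(1.0)
        assert s.sd == pytest.approx(0.2)

    def test_welch_matches_scipy(self):
        from scipy import stats
        a = [1.0, 1.3, 0.9]
        b = [2.0, 2.4, 1.8]
        sa = pq.summarize_condition("a", a)
        sb = pq.summarize_condition("b", b, comparison=sa)
        assert sb.p_value == pytest.approx(
            stats.ttest_ind(b, a, equal_var=False).pvalue)

    def test_test_requires_two_replicates(self):
        a = pq.summarize_condition("a", [1.0, 2.0])
        with pytest.raises(ValueError):
            pq.summarize_condition("b", [1.0], comparison=a)
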