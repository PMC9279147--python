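import numpy as np
import pytest
from scipy import stats as sps

from loopferret.loops import (
    CONVERGENT_ONLY,
    LOOP_CATEGORIES,
    NO_CTCF,
    NONCONVERGENT,
    Loop,
    aggregate_loops,
    bh_adjust,
    bidirectional_stats,
    call_loops_simple,
    chi2_test,
    classify_anchors,
    classify_loops,
    corner_association,
    loop_strength,
    read_loops_bedpe,
    write_loops_bedpe,
)
from loopferret.motifs import CBSAnnotation

from oracles import (
    brute_force_classification,
    chi2_textbook,
    random_toy_loop_set,
)

RES = 10_000


def loop(i, j, loop_id):
    return Loop(
        chrom="t",
        anchor1_start=i * RES,
        anchor1_end=(i + 1) * RES,
        anchor2_start=j * RES,
        anchor2_end=(j + 1) * RES,
        resolution_bp=RES,
        loop_id=loop_id,
    )


def site(bin_, orientation):
    start = bin_ * RES + 100
    return CBSAnnotation(chrom="t", start=start, end=start + 19,
                         orientation=orientation)


class TestAnchorClassification:
    def test_forward_cbs_with_rightward_loop_is_convergent_only(self):
        anchors = classify_anchors([loop(0, 10, "L0")], [site(0, "forward")])
        a = next(a for a in anchors if a.rightward_loops)
        assert a.category == CONVERGENT_ONLY
        assert not a.bidirectional

    def test_anchor_without_cbs_is_no_ctcf(self):
        anchors = classify_anchors([loop(0, 10, "L0")], [])
        assert all(a.category == NO_CTCF for a in anchors)

    def test_two_loop_toy_set(self):
        # A(fwd) --L0--> B(rev); B --L1--> C(rev): B loops rightward with
        # only reverse CBSs -> nonconvergent and bidirectional
        loops = [loop(0, 10, "L0"), loop(10, 20, "L1")]
        cbs = [site(0, "forward"), site(10, "reverse"), site(20, "reverse")]
        anchors = classify_anchors(loops, cbs)
        by_start = {a.start // RES: a for a in anchors}
        assert by_start[0].category == CONVERGENT_ONLY
        assert by_start[10].category == NONCONVERGENT
        assert by_start[10].bidirectional
        assert by_start[20].category == CONVERGENT_ONLY

    def test_nearby_anchors_merge_into_one_record(self):
        loops = [loop(0, 10, "L0"), loop(11, 30, "L1")]
        anchors = classify_anchors(loops, [])
        # anchors at bins 10 and 11 overlap after one-bin padding
        assert len(anchors) == 3


class TestLoopClassification:
    def test_isolated_convergent_loop_is_single_sided(self):
        loops = [loop(0, 10, "L0")]
        cbs = [site(0, "forward"), site(10, "reverse")]
        records = classify_loops(loops, classify_anchors(loops, cbs))
        assert records[0].convergent
        assert records[0].category == "single_sided_convergent"

    def test_interference_pair_is_associated(self):
        loops = [loop(0, 10, "L0"), loop(10, 20, "L1")]
        cbs = [site(0, "forward"), site(10, "reverse"), site(20, "reverse")]
        records = {r.loop_id: r for r in
                   classify_loops(loops, classify_anchors(loops, cbs))}
        assert records["L0"].category == "convergent_associated"
        assert records["L1"].category == "nonconvergent_associated"

    def test_shared_divergent_anchor_gives_double_sided(self):
        # convergent loops on both sides of a middle anchor carrying both
        # orientations
        loops = [loop(0, 10, "L0"), loop(10, 20, "L1")]
        cbs = [site(0, "forward"), site(10, "reverse"), site(10, "forward"),
               site(20, "reverse")]
        records = {r.loop_id: r for r in
                   classify_loops(loops, classify_anchors(loops, cbs))}
        assert records["L0"].category == "double_sided_convergent"
        assert records["L1"].category == "double_sided_convergent"

    def test_categories_partition_the_loop_set(self, rng):
        for _ in range(50):
            loops, cbs, slot_bins, slot_cbs = random_toy_loop_set(rng)
            records = classify_loops(loops, classify_anchors(loops, cbs))
            assert len(records) == len(loops)
            assert all(r.category in LOOP_CATEGORIES for r in records)

    def test_matches_brute_force_evaluator(self, rng):
        for _ in range(100):
            loops, cbs, slot_bins, slot_cbs = random_toy_loop_set(rng)
            anchors = classify_anchors(loops, cbs)
            records = classify_loops(loops, anchors)
            anchor_info, loop_cats = brute_force_classification(
                loops, slot_bins, slot_cbs
            )
            by_start = {a.start // RES: a for a in anchors}
            for k, b in enumerate(slot_bins):
                if anchor_info[k]["n_loops"] == 0:
                    continue  # loopless slots produce no anchor record
                got = by_start[int(b)]
                assert got.category == anchor_info[k]["category"]
                assert got.bidirectional == anchor_info[k]["bidirectional"]
            for r in records:
                assert r.category == loop_cats[r.loop_id]

    def test_mirror_symmetry_preserves_category_counts(self, rng):
        from collections import Counter

        for _ in range(25):
            loops, cbs, _, _ = random_toy_loop_set(rng)
            records = classify_loops(loops, classify_anchors(loops, cbs))
            counts = Counter(r.category for r in records)

            hi = max(l.anchor2_end for l in loops) + RES
            m_loops = [
                Loop(chrom="t",
                     anchor1_start=hi - l.anchor2_end,
                     anchor1_end=hi - l.anchor2_start,
                     anchor2_start=hi - l.anchor1_end,
                     anchor2_end=hi - l.anchor1_start,
                     resolution_bp=RES, loop_id=l.loop_id)
                for l in loops
            ]
            m_cbs = [
                CBSAnnotation(chrom="t", start=hi - c.end, end=hi - c.start,
                              orientation=("forward" if c.orientation == "reverse"
                                           else "reverse"))
                for c in cbs
            ]
            m_records = classify_loops(m_loops, classify_anchors(m_loops, m_cbs))
            assert Counter(r.category for r in m_records) == counts


class TestStats:
    def test_all_unidirectional_gives_zero_fractions_and_zero_chi2(self):
        loops = [loop(0, 10, "L0"), loop(20, 30, "L1"), loop(40, 50, "L2")]
        cbs = [site(0, "forward"), site(10, "reverse"), site(20, "forward"),
               site(30, "reverse")]  # L2 anchors carry no CBS
        anchors = classify_anchors(loops, cbs)
        with pytest.warns(UserWarning):
            out = bidirectional_stats(anchors)
        assert all(f == 0.0 for f in out["fractions"].values())
        assert out["omnibus_chi2"] == 0.0

    def test_2x2_chi2_matches_textbook_formula(self):
        table = [[45, 55], [5, 95]]
        stat, p, df = chi2_test(table)
        expected_stat, expected_df = chi2_textbook(table)
        assert stat == pytest.approx(expected_stat)
        assert df == expected_df
        assert p == pytest.approx(sps.chi2.sf(expected_stat, expected_df))

    def test_single_category_is_an_error(self):
        loops = [loop(0, 10, "L0")]
        cbs = [site(0, "forward"), site(10, "reverse")]
        anchors = classify_anchors(loops, cbs)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                bidirectional_stats(anchors)

    def test_bh_adjustment_monotone_and_bounded(self):
        raw = [0.01, 0.04, 0.03]
        adj = bh_adjust(raw)
        assert all(0 <= q <= 1 for q in adj)
        assert all(q >= p for q, p in zip(adj, raw))


class TestStrength:
    def test_flat_obs_exp_has_zero_strength(self):
        oe = np.ones((100, 100))
        assert loop_strength(loop(40, 60, "L"), oe) == pytest.approx(0.0)

    def test_center_four_corner_one_is_two(self):
        oe = np.ones((100, 100))
        i, j = 45, 65
        oe[i - 1 : i + 2, j - 1 : j + 2] = 4.0
        assert loop_strength(loop(i, j, "L"), oe) == pytest.approx(2.0)

    def test_window_beyond_edge_is_an_error(self):
        oe = np.ones((30, 30))
        with pytest.raises(ValueError):
            loop_strength(loop(3, 25, "L"), oe, window_bins=10)

    def test_fully_masked_center_returns_none(self):
        oe = np.full((100, 100), np.nan)
        assert loop_strength(loop(40, 60, "L"), oe) is None


class TestAggregate:
    def test_single_loop_aggregate_is_its_own_window(self):
        rng = np.random.default_rng(0)
        oe = rng.uniform(0.5, 2.0, size=(100, 100))
        agg, n = aggregate_loops([loop(40, 60, "L")], oe, window_bins=5)
        np.testing.assert_array_equal(agg, oe[35:46, 55:66])
        assert n == 1

    def test_two_loops_aggregate_is_their_mean(self):
        rng = np.random.default_rng(1)
        oe = rng.uniform(0.5, 2.0, size=(100, 100))
        loops = [loop(30, 50, "a"), loop(40, 70, "b")]
        agg, n = aggregate_loops(loops, oe, window_bins=4)
        w1 = oe[26:35, 46:55]
        w2 = oe[36:45, 66:75]
        np.testing.assert_allclose(agg, (w1 + w2) / 2)
        assert n == 2

    def test_no_usable_loops_is_an_error(self):
        oe = np.ones((20, 20))
        with pytest.raises(ValueError):
            aggregate_loops([loop(1, 18, "L")], oe, window_bins=10)


class TestCornerAssociation:
    def test_loops_at_boundaries_have_corner_fraction_one(self):
        loops = [loop(10, 30, "L0"), loop(30, 50, "L1")]
        cbs = [site(10, "forward"), site(30, "reverse"), site(30, "forward"),
               site(50, "reverse")]
        records = classify_loops(loops, classify_anchors(loops, cbs))
        out = corner_association(records, loops, boundary_bins=[10, 30, 50],
                                 bin_size=RES, zone_radius_bins=2)
        for frac in out["corner_fractions"].values():
            assert frac == 1.0
        assert all(r.at_tad_corner for r in records)

    def test_identical_distances_give_flat_kruskal(self):
        loops = [loop(0, 10, "a"), loop(20, 30, "b")]
        cbs = [site(0, "forward"), site(10, "reverse"),
               site(20, "forward"), site(30, "reverse")]
        records = classify_loops(loops, classify_anchors(loops, cbs))
        out = corner_association(records, loops, boundary_bins=[],
                                 bin_size=RES)
        assert out["kruskal_p"] in (None, 1.0)
        assert out["posthoc"] == []

    def test_no_boundaries_still_computes_distances(self):
        loops = [loop(0, 10, "a")]
        cbs = [site(0, "forward"), site(10, "reverse")]
        records = classify_loops(loops, classify_anchors(loops, cbs))
        out = corner_association(records, loops, boundary_bins=[], bin_size=RES)
        assert out["corner_fractions"] == {}
        assert out["distances"]["single_sided_convergent"] == [10 * RES]


class TestSimpleCaller:
    def test_flat_obs_exp_yields_no_loops(self):
        assert call_loops_simple(np.ones((60, 60)), RES, threshold=3.0) == []

    def test_single_planted_peak_recovered(self):
        oe = np.ones((200, 200))
        oe[50, 150] = oe[150, 50] = 5.0
        called = call_loops_simple(oe, RES, threshold=3.0)
        assert len(called) == 1
        assert called[0].pixel() == (50, 150)

    def test_nonmax_suppression_keeps_the_larger_peak(self):
        oe = np.ones((200, 200))
        oe[50, 150] = oe[150, 50] = 5.0
        oe[50, 151] = oe[151, 50] = 7.0
        called = call_loops_simple(oe, RES, threshold=3.0)
        assert len(called) == 1
        assert called[0].pixel() == (50, 151)

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            call_loops_simple(np.ones((30, 30)), RES, threshold=0.5)


class TestBedpeIO:
    def test_round_trip_with_categories(self, tmp_path):
        loops = [loop(0, 10, "L0"), loop(10, 20, "L1")]
        cbs = [site(0, "forward"), site(10, "reverse"), site(20, "reverse")]
        records = classify_loops(loops, classify_anchors(loops, cbs))
        path = tmp_path / "loops.bedpe"
        write_loops_bedpe(loops, path, records)
        back = read_loops_bedpe(path, RES)
        assert [(l.loop_id, l.pixel()) for l in back] == [
            ("L0", (0, 10)), ("L1", (10, 20)),
        ]
        line = path.read_text().splitlines()[0].split("\t")
        assert line[7] == "convergent_associated"
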