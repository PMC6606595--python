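"""Train/test splitting, score binning, and precision-recall machinery."""

import numpy as np
import pytest

import conshmm as ch
from conshmm.intervals import from_mask, intersect, total_bases

from conftest import segmentation_from_labels


def track(values, defined=None, chrom="chr1"):
    values = np.asarray(values, dtype=np.float64)
    defined = np.ones(len(values), dtype=bool) if defined is None else np.asarray(defined, dtype=bool)
    return ch.ScoreTrack(values={chrom: values}, defined={chrom: defined})


def ivmap(*triples):
    out = {}
    for chrom, s, e in triples:
        out.setdefault(chrom, []).append([s, e])
    return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}


class TestSplit:
    def test_even_split(self):
        part = ch.GenomePartition((("chr1", 800),), slice_length=200)
        train, test = ch.split_train_test(part, seed=0)
        assert len(train) == 2 and len(test) == 2
        assert sorted(train + test) == sorted(part.slices)

    def test_odd_split_sizes_differ_by_one(self):
        part = ch.GenomePartition((("chr1", 1000),), slice_length=200)
        train, test = ch.split_train_test(part, seed=3)
        assert {len(train), len(test)} == {3, 2}
        assert not set(train) & set(test)

    def test_seed_determinism(self):
        part = ch.GenomePartition((("chr1", 1000),), slice_length=100)
        assert ch.split_train_test(part, 7) == ch.split_train_test(part, 7)
        assert ch.split_train_test(part, 7) != ch.split_train_test(part, 8)


def manual_pr(labels, target_mask, train_mask, test_mask, n_states):
    """Exhaustive counting oracle for state-ranked precision-recall."""
    folds = []
    for k in range(1, n_states + 1):
        state_train = (labels == k) & train_mask
        tp = ((labels == k) & target_mask & train_mask).sum()
        ann = (target_mask & train_mask).sum()
        if state_train.sum() == 0:
            folds.append(-np.inf)
        else:
            folds.append((tp / ann) / (state_train.sum() / train_mask.sum()))
    order = sorted(range(n_states), key=lambda k: (-folds[k], k))
    pts = []
    cum = np.zeros(len(labels), dtype=bool)
    for k in order:
        cum |= (labels == k + 1) & test_mask
        tp = (cum & target_mask).sum()
        pts.append((tp / cum.sum() if cum.sum() else np.nan,
                    tp / (target_mask & test_mask).sum()))
    return order, pts


class TestPrByStates:
    def test_single_state_reaches_full_recall(self):
        labels = np.ones(40, dtype=np.int32)
        seg = segmentation_from_labels(labels, 1)
        target = ch.AnnotationSet.from_tuples("t", [("chr1", 5, 15)])
        train, test = ivmap(("chr1", 0, 20)), ivmap(("chr1", 20, 40))
        # target must intersect both splits
        target2 = ch.AnnotationSet.from_tuples("t", [("chr1", 5, 15), ("chr1", 25, 30)])
        curve = ch.pr_by_states(seg, target2, train, test).points
        assert len(curve) == 1
        assert curve["recall"].iloc[0] == 1.0
        assert curve["precision"].iloc[0] == pytest.approx(5 / 20)  # target density in test

    def test_target_whole_genome_gives_precision_one(self, rng):
        labels = rng.integers(1, 4, size=60).astype(np.int32)
        seg = segmentation_from_labels(labels, 3)
        target = ch.AnnotationSet.from_tuples("t", [("chr1", 0, 60)])
        train, test = ivmap(("chr1", 0, 30)), ivmap(("chr1", 30, 60))
        curve = ch.pr_by_states(seg, target, train, test).points
        assert np.allclose(curve["precision"].dropna(), 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_counting(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(1, 4, size=30).astype(np.int32)
        seg = segmentation_from_labels(labels, 3)
        tmask = rng.random(30) < 0.4
        train_mask = np.zeros(30, dtype=bool)
        train_mask[:15] = True
        test_mask = ~train_mask
        if not (tmask & train_mask).any() or not (tmask & test_mask).any():
            pytest.skip("degenerate target draw")
        target = ch.AnnotationSet.from_tuples(
            "t", [("chr1", int(s), int(e)) for s, e in from_mask(tmask)])
        train, test = ivmap(("chr1", 0, 15)), ivmap(("chr1", 15, 30))
        curve = ch.pr_by_states(seg, target, train, test).points
        order, pts = manual_pr(labels, tmask, train_mask, test_mask, 3)
        assert list(curve["unit"]) == [k + 1 for k in order]
        for (p, r), row in zip(pts, curve.itertuples()):
            if not np.isnan(p):
                assert row.precision == pytest.approx(p)
            assert row.recall == pytest.approx(r)

    def test_recall_is_nondecreasing(self, rng):
        labels = rng.integers(1, 6, size=200).astype(np.int32)
        seg = segmentation_from_labels(labels, 5)
        target = ch.AnnotationSet.from_tuples("t", [("chr1", 20, 90), ("chr1", 140, 170)])
        train, test = ivmap(("chr1", 0, 100)), ivmap(("chr1", 100, 200))
        curve = ch.pr_by_states(seg, target, train, test).points
        assert (np.diff(curve["recall"]) >= 0).all()


class TestBinScore:
    def test_distinct_scores_one_base_per_bin(self):
        t = track(np.arange(399, dtype=float))
        binned = ch.bin_score(t, n_bins=400, seed=0)
        counts = binned.bin_base_counts()
        assert counts[0] == 0
        assert np.all(counts[1:] == 1)
        # highest score lands in bin 1
        assert binned.labels["chr1"][398] == 1

    def test_all_tied_scores_split_evenly(self):
        t = track(np.full(1000, 3.14))
        binned = ch.bin_score(t, n_bins=11, seed=1)
        counts = binned.bin_base_counts()[1:]
        assert counts.sum() == 1000
        assert counts.max() - counts.min() <= 1

    def test_undefined_bases_go_to_bin_zero(self):
        defined = np.array([True, False, True, False])
        t = track([1.0, 0.0, 2.0, 0.0], defined)
        binned = ch.bin_score(t, n_bins=3, seed=0)
        lab = binned.labels["chr1"]
        assert lab[1] == 0 and lab[3] == 0
        assert lab[2] == 1 and lab[0] == 2  # descending score

    def test_conserves_bases_exactly(self, rng):
        defined = rng.random(777) < 0.8
        t = track(rng.random(777), defined)
        binned = ch.bin_score(t, n_bins=40, seed=2)
        assert binned.bin_base_counts().sum() == 777

    def test_plateau_split_matches_rank_allocation_oracle(self):
        """A 300-base tied plateau is split across bins proportionally to the
        overlap of its rank interval with each bin's rank interval."""
        values = np.concatenate([
            np.linspace(10, 9, 350),      # ranks 0..349
            np.full(300, 5.0),            # ranks 350..649
            np.linspace(4, 3, 350),       # ranks 650..999
        ])
        t = track(values)
        B = 4  # bins of 250 bases: plateau covers rank intervals [350,500) and [500,650)
        binned = ch.bin_score(t, n_bins=B + 1, seed=0)
        lab = binned.labels["chr1"]
        plateau_bins = lab[350:650]
        assert np.bincount(plateau_bins, minlength=B + 1)[2] == 150
        assert np.bincount(plateau_bins, minlength=B + 1)[3] == 150
        counts = binned.bin_base_counts()
        assert np.all(counts[1:] == 250)

    def test_binning_is_seed_deterministic(self, rng):
        t = track(np.repeat(rng.random(10), 37))
        a = ch.bin_score(t, n_bins=5, seed=9)
        b = ch.bin_score(t, n_bins=5, seed=9)
        assert all(np.array_equal(a.labels[c], b.labels[c]) for c in a.labels)


class TestOtherPrModes:
    def test_bins_as_states_match_counting(self, rng):
        values = rng.random(30)
        t = track(values)
        binned = ch.bin_score(t, n_bins=4, seed=0)
        labels = binned.labels["chr1"] + 1
        tmask = values > 0.5
        if not (tmask[:15]).any() or not (tmask[15:]).any():
            pytest.skip("degenerate")
        target = ch.AnnotationSet.from_tuples(
            "t", [("chr1", int(s), int(e)) for s, e in from_mask(tmask)])
        train, test = ivmap(("chr1", 0, 15)), ivmap(("chr1", 15, 30))
        curve = ch.pr_by_bins(binned, target, train, test).points
        _, pts = manual_pr(labels, tmask, np.arange(30) < 15, np.arange(30) >= 15, 4)
        assert [r for _, r in pts] == pytest.approx(list(curve["recall"]))

    def test_raw_score_thresholds(self):
        values = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        t = track(values)
        tmask = np.array([True, True, False, False, True, False])
        target = ch.AnnotationSet.from_tuples(
            "t", [("chr1", int(s), int(e)) for s, e in from_mask(tmask)])
        test = ivmap(("chr1", 0, 6))
        curve = ch.pr_by_raw_score(t, target, test).points
        assert list(curve["precision"]) == pytest.approx([1, 1, 2 / 3, 1 / 2, 3 / 5, 3 / 6])
        assert list(curve["recall"]) == pytest.approx([1 / 3, 2 / 3, 2 / 3, 2 / 3, 1, 1])

    def test_element_point_identities(self):
        target = ch.AnnotationSet.from_tuples("t", [("chr1", 0, 10)])
        test = ivmap(("chr1", 0, 20))
        assert ch.pr_point_elements(target, target, test) == (1.0, 1.0)
        disjoint = ch.AnnotationSet.from_tuples("e", [("chr1", 15, 20)])
        assert ch.pr_point_elements(disjoint, target, test) == (0.0, 0.0)

    def test_element_point_manual(self):
        elements = ch.AnnotationSet.from_tuples("e", [("chr1", 0, 8)])
        target = ch.AnnotationSet.from_tuples("t", [("chr1", 4, 12)])
        test = ivmap(("chr1", 0, 16))
        p, r = ch.pr_point_elements(elements, target, test)
        assert p == pytest.approx(4 / 8)
        assert r == pytest.approx(4 / 8)


class TestConcatenation:
    def test_single_sample_is_identity_up_to_renaming(self, rng):
        labels = rng.integers(1, 3, size=40).astype(np.int32)
        seg = segmentation_from_labels(labels, 2)
        cseg = ch.concat_segmentation(seg, ["s1"])
        assert [(c, s, e, st) for c, s, e, st in cseg.runs] == \
            [(f"{c}#s1", s, e, st) for c, s, e, st in seg.runs]

    def test_two_identical_samples_reproduce_single_sample_pr(self, rng):
        labels = rng.integers(1, 4, size=60).astype(np.int32)
        seg = segmentation_from_labels(labels, 3)
        tmask = rng.random(60) < 0.3
        tmask[:5] = True
        tmask[30:35] = True
        tuples = [("chr1", int(s), int(e)) for s, e in from_mask(tmask)]
        t1 = ch.AnnotationSet.from_tuples("s1", tuples)
        t2 = ch.AnnotationSet.from_tuples("s2", tuples)
        train, test = ivmap(("chr1", 0, 30)), ivmap(("chr1", 30, 60))
        # the single-sample curve uses the same pseudo-chromosome naming
        single = ch.pr_by_states(ch.concat_segmentation(seg, ["s1"]),
                                 ch.concat_targets([t1]),
                                 ch.concat_intervals(train, ["s1"]),
                                 ch.concat_intervals(test, ["s1"])).points
        double = ch.pr_by_states(ch.concat_segmentation(seg, ["s1", "s2"]),
                                 ch.concat_targets([t1, t2]),
                                 ch.concat_intervals(train, ["s1", "s2"]),
                                 ch.concat_intervals(test, ["s1", "s2"])).points
        assert list(single["unit"]) == list(double["unit"])
        assert list(single["precision"]) == pytest.approx(list(double["precision"]))
        assert list(single["recall"]) == pytest.approx(list(double["recall"]))

    def test_two_different_samples_match_pooled_counting(self, rng):
        labels = rng.integers(1, 3, size=20).astype(np.int32)
        seg = segmentation_from_labels(labels, 2)
        m1 = rng.random(20) < 0.5
        m2 = rng.random(20) < 0.5
        m1[:3] = m1[10:12] = True
        m2[:2] = m2[15:17] = True
        t1 = ch.AnnotationSet.from_tuples("a", [("chr1", int(s), int(e)) for s, e in from_mask(m1)])
        t2 = ch.AnnotationSet.from_tuples("b", [("chr1", int(s), int(e)) for s, e in from_mask(m2)])
        train, test = ivmap(("chr1", 0, 10)), ivmap(("chr1", 10, 20))
        curve = ch.pr_by_states(ch.concat_segmentation(seg, ["a", "b"]),
                                ch.concat_targets([t1, t2]),
                                ch.concat_intervals(train, ["a", "b"]),
                                ch.concat_intervals(test, ["a", "b"])).points
        # pooled oracle: duplicate the genome, concatenate masks
        lab2 = np.concatenate([labels, labels])
        tm = np.concatenate([m1, m2])
        trm = np.concatenate([np.arange(20) < 10] * 2)
        _, pts = manual_pr(lab2, tm, trm, ~trm, 2)
        assert [r for _, r in pts] == pytest.approx(list(curve["recall"]))
        assert [p for p, _ in pts] == pytest.approx(list(curve["precision"]))


class TestTopFractionSet:
    def test_distinct_scores_exact_fraction(self):
        t = track(np.arange(100, dtype=float))
        uni = ivmap(("chr1", 0, 100))
        top = ch.top_fraction_set(t, 0.10, uni)
        assert top.n_bases == 10
        assert top.intervals["chr1"].tolist() == [[90, 100]]

    def test_all_tied_chooses_closer_of_all_or_none(self):
        t = track(np.full(100, 1.0))
        uni = ivmap(("chr1", 0, 100))
        assert ch.top_fraction_set(t, 0.6, uni).n_bases == 100
        assert ch.top_fraction_set(t, 0.4, uni).n_bases == 0

    def test_plateau_matches_exhaustive_threshold_search(self):
        values = np.concatenate([np.full(30, 5.0), np.full(50, 3.0), np.full(20, 1.0)])
        t = track(values)
        uni = ivmap(("chr1", 0, 100))
        # candidates: 30 (>=5), 80 (>=3), 100 (>=1); fraction .5 -> closest is 30? |30-50|=20, |80-50|=30
        assert ch.top_fraction_set(t, 0.5, uni).n_bases == 30
        assert ch.top_fraction_set(t, 0.7, uni).n_bases == 80

    def test_undefined_count_toward_universe_but_rank_lowest(self):
        defined = np.concatenate([np.ones(50, dtype=bool), np.zeros(50, dtype=bool)])
        t = track(np.concatenate([np.arange(50, dtype=float), np.zeros(50)]), defined)
        uni = ivmap(("chr1", 0, 100))
        top = ch.top_fraction_set(t, 0.10, uni)  # 10% of 100 = 10 bases
        assert top.n_bases == 10
        assert top.intervals["chr1"].tolist() == [[40, 50]]

    def test_monotone_nesting(self, rng):
        vals = np.round(rng.random(200), 2)
        t = track(vals)
        uni = ivmap(("chr1", 0, 200))
        prev = None
        for frac in (0.01, 0.05, 0.10, 0.25, 0.5):
            cur = ch.top_fraction_set(t, frac, uni).intervals
            if prev is not None:
                assert total_bases(intersect(prev, cur)) == total_bases(prev)
            prev = cur


class TestWiggleInput:
    def test_fixed_step_track_round_trip(self, tmp_path):
        text = "fixedStep chrom=chr1 start=3 step=1\n0.5\n0.75\n1.0\n"
        path = tmp_path / "track.wig"
        path.write_text(text)
        t = ch.ScoreTrack.from_wiggle(str(path), {"chr1": 10})
        assert t.defined["chr1"].tolist() == [False, False, True, True, True] + [False] * 5
        assert t.values["chr1"][2:5].tolist() == [0.5, 0.75, 1.0]
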