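"""Precision-recall recovery of target annotations and score-set machinery.

States (or score bins) are ranked by their fold enrichment for the target
among training-split bases, then added cumulatively while precision and
recall are measured on the test split only.  Raw scores are thresholded at
every distinct value; element sets contribute a single point.  Score tracks
can be partitioned into 400 near-equal bins (one extra bin holding the bases
where the score is undefined) so that score-based and state-based rankings
are compared at matched resolution.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .alignment_io import GenomePartition
from .enrichment import AnnotationSet
from .segmentation import Segmentation


@dataclass
class ScoreTrack:
    """Per-base float values over the genome with a defined-base mask."""

    values: dict[str, np.ndarray]   # chrom -> (L,) float array
    defined: dict[str, np.ndarray]  # chrom -> (L,) bool array

    def __post_init__(self) -> None:
        for chrom, v in self.values.items():
            d = self.defined[chrom]
            if v.shape != d.shape:
                raise ValueError(f"{chrom}: values/defined shape mismatch")
            if not np.all(np.isfinite(v[d])):
                raise ValueError(f"{chrom}: non-finite score among defined bases")

    @classmethod
    def from_intervals(
        cls,
        records: Sequence[tuple[str, int, int, float]],
        chrom_lengths: Mapping[str, int],
    ) -> "ScoreTrack":
        values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
        defined = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        for chrom, start, end, value in records:
            values[chrom][start:end] = value
            defined[chrom][start:end] = True
        return cls(values=values, defined=defined)

    @classmethod
    def from_wiggle(cls, path: str, chrom_lengths: Mapping[str, int]) -> "ScoreTrack":
        """Read a fixedStep wiggle-like text track (1-based starts)."""
        opener = gzip.open if path.endswith(".gz") else open
        values = {c: np.zeros(n) for c, n in chrom_lengths.items()}
        defined = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        chrom, pos, step, span = None, 0, 1, 1
        with opener(path, "rt") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                    continue
                if chrom is None:
                    raise ValueError("value line before any fixedStep declaration")
                values[chrom][pos:pos + span] = float(line)
                defined[chrom][pos:pos + span] = True
                pos += step
        return cls(values=values, defined=defined)

    @classmethod
    def from_tsv(cls, path: str, chrom_lengths: Mapping[str, int]) -> "ScoreTrack":
        opener = gzip.open if path.endswith(".gz") else open
        records = []
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                chrom, start, end, value = line.split()[:4]
                records.append((chrom, int(start), int(end), float(value)))
        return cls.from_intervals(records, chrom_lengths)


@dataclass
class PRCurve:
    """Ordered precision-recall points with the contributing unit per point."""

    points: pd.DataFrame  # columns: unit, n_bases, precision, recall

    def __post_init__(self) -> None:
        rec = self.points["recall"].to_numpy()
        if np.any(np.diff(rec) < -1e-12):
            raise ValueError("recall must be non-decreasing along the curve")


def split_train_test(partition: GenomePartition, seed: int) -> tuple[list, list]:
    """Randomly halve the genome slices into train and test sets.

    Disjoint, union = all slices, sizes differing by at most one;
    deterministic for a given seed.
    """
    slices = list(partition.slices)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(slices))
    n_train = (len(slices) + 1) // 2
    train = [slices[i] for i in sorted(order[:n_train])]
    test = [slices[i] for i in sorted(order[n_train:])]
    return train, test


def slices_to_intervals(slices: Sequence[tuple[str, int, int]]) -> iv.IntervalMap:
    return iv.merge_records(slices)


def _as_ivmap(x) -> iv.IntervalMap:
    if isinstance(x, AnnotationSet):
        return x.intervals
    if isinstance(x, dict):
        return x
    return slices_to_intervals(x)


def _ranked_pr(
    seg: Segmentation,
    target_iv: iv.IntervalMap,
    train_iv: iv.IntervalMap,
    test_iv: iv.IntervalMap,
) -> pd.DataFrame:
    tp_train = seg.overlap_counts(iv.intersect(target_iv, train_iv)).astype(float)
    st_train = seg.overlap_counts(train_iv).astype(float)
    ann_train = iv.total_bases(iv.intersect(target_iv, train_iv))
    train_total = iv.total_bases(train_iv)
    if ann_train == 0:
        raise ValueError("target has no bases in the training split")
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = (tp_train / ann_train) / (st_train / train_total)
    fold = np.where(st_train > 0, fold, -np.inf)
    order = sorted(range(seg.n_states), key=lambda k: (-fold[k], k))

    tp_test = seg.overlap_counts(iv.intersect(target_iv, test_iv)).astype(float)
    st_test = seg.overlap_counts(test_iv).astype(float)
    ann_test = iv.total_bases(iv.intersect(target_iv, test_iv))
    if ann_test == 0:
        raise ValueError("target has no bases in the test split")
    cum_tp = np.cumsum(tp_test[order])
    cum_n = np.cumsum(st_test[order])
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(cum_n > 0, cum_tp / cum_n, np.nan)
    recall = cum_tp / ann_test
    return pd.DataFrame(
        {
            "unit": [k + 1 for k in order],
            "n_bases": cum_n.astype(np.int64),
            "precision": precision,
            "recall": recall,
        }
    )


def pr_by_states(seg: Segmentation, target, train, test) -> PRCurve:
    """PR curve from cumulatively adding states ranked by train enrichment."""
    return PRCurve(_ranked_pr(seg, _as_ivmap(target), _as_ivmap(train), _as_ivmap(test)))


# ---------------------------------------------------------------------------
# Score binning
# ---------------------------------------------------------------------------


@dataclass
class BinnedScore:
    """Per-base bin labels: bin 0 = score undefined, bins 1..n_bins-1 by
    descending score, equalised to within one base."""

    labels: dict[str, np.ndarray]  # chrom -> (L,) int array in 0..n_bins-1
    n_bins: int

    def to_segmentation(self) -> Segmentation:
        """Bins as states (state = bin + 1) for the shared PR machinery."""
        runs = []
        for chrom in sorted(self.labels):
            lab = self.labels[chrom]
            change = np.flatnonzero(np.diff(lab)) + 1
            bounds = np.concatenate([[0], change, [len(lab)]])
            for s, e in zip(bounds[:-1], bounds[1:]):
                runs.append((chrom, int(s), int(e), int(lab[s]) + 1))
        return Segmentation(runs=runs, n_states=self.n_bins)

    def bin_base_counts(self) -> np.ndarray:
        counts = np.zeros(self.n_bins, dtype=np.int64)
        for lab in self.labels.values():
            counts += np.bincount(lab, minlength=self.n_bins)
        return counts


def bin_score(score: ScoreTrack, n_bins: int = 400, seed: int = 0) -> BinnedScore:
    """Partition the genome into score bins of near-equal size.

    Undefined bases go to bin 0; defined bases are ranked by descending
    score and cut into ``n_bins - 1`` contiguous rank intervals whose sizes
    differ by at most one base.  A tied score increment straddling a bin
    boundary is split across those bins proportionally to the overlap of its
    rank interval with each bin; which of its bases land in which bin is a
    seeded uniform choice.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    chroms = sorted(score.values)
    labels = {c: np.zeros(score.values[c].shape, dtype=np.int32) for c in chroms}
    vals, locs = [], []
    for c in chroms:
        d = score.defined[c]
        idx = np.flatnonzero(d)
        vals.append(score.values[c][idx])
        locs.append((c, idx))
    if not vals:
        return BinnedScore(labels=labels, n_bins=n_bins)
    flat = np.concatenate(vals)
    D = flat.shape[0]
    B = n_bins - 1
    rng = np.random.default_rng(seed)
    # random permutation first, then stable sort by descending value: ties
    # end up in seeded-uniform order, so proportional boundary splits are
    # unbiased within each tied increment
    perm = rng.permutation(D)
    order = perm[np.argsort(-flat[perm], kind="stable")]
    ranks = np.empty(D, dtype=np.int64)
    ranks[order] = np.arange(D)
    bounds = np.floor(np.arange(1, B + 1) * D / B + 0.5).astype(np.int64)
    bins = np.searchsorted(bounds, ranks, side="right") + 1  # 1..B
    offset = 0
    for (c, idx), v in zip(locs, vals):
        labels[c][idx] = bins[offset:offset + v.shape[0]]
        offset += v.shape[0]
    return BinnedScore(labels=labels, n_bins=n_bins)


def pr_by_bins(binned: BinnedScore, target, train, test) -> PRCurve:
    """PR curve treating score bins as states."""
    return PRCurve(_ranked_pr(binned.to_segmentation(), _as_ivmap(target), _as_ivmap(train), _as_ivmap(test)))


def pr_by_raw_score(score: ScoreTrack, target, test) -> PRCurve:
    """PR curve thresholding the raw score at every distinct value.

    Bases with undefined scores rank below every defined value and are added
    as one final block, so recall reaches 1.
    """
    target_iv = _as_ivmap(target)
    test_iv = _as_ivmap(test)
    vals, is_tp = [], []
    for chrom, arr in score.values.items():
        mask = iv.mask_from(test_iv, chrom, arr.shape[0])
        tmask = iv.mask_from(target_iv, chrom, arr.shape[0])
        sel = np.flatnonzero(mask)
        v = np.where(score.defined[chrom][sel], arr[sel], -np.inf)
        vals.append(v)
        is_tp.append(tmask[sel])
    flat = np.concatenate(vals)
    tp = np.concatenate(is_tp).astype(np.int64)
    if tp.sum() == 0:
        raise ValueError("target has no bases in the test split")
    order = np.argsort(-flat, kind="stable")
    flat, tp = flat[order], tp[order]
    # last index of each distinct value block
    block_end = np.flatnonzero(np.concatenate([flat[1:] != flat[:-1], [True]]))
    cum_tp = np.cumsum(tp)[block_end]
    cum_n = block_end + 1
    thresholds = flat[block_end]
    return PRCurve(pd.DataFrame({
        "unit": thresholds,
        "n_bases": cum_n.astype(np.int64),
        "precision": cum_tp / cum_n,
        "recall": cum_tp / tp.sum(),
    }))


def pr_point_elements(elements: AnnotationSet, target, test) -> tuple[float, float]:
    """Single (precision, recall) point for an element set on the test split."""
    target_iv = _as_ivmap(target)
    test_iv = _as_ivmap(test)
    elem_test = iv.intersect(elements.intervals, test_iv)
    n_elem = iv.total_bases(elem_test)
    n_target = iv.total_bases(iv.intersect(target_iv, test_iv))
    tp = iv.total_bases(iv.intersect(elem_test, target_iv))
    precision = tp / n_elem if n_elem else 0.0
    recall = tp / n_target if n_target else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# Concatenated multi-sample targets
# ---------------------------------------------------------------------------


def _pseudo(chrom: str, sample: str) -> str:
    return f"{chrom}#{sample}"


def concat_targets(targets: Sequence[AnnotationSet], name: str = "concatenated") -> AnnotationSet:
    """Pool per-sample targets on a concatenated pseudo-genome.

    Each (chromosome, sample) pair becomes pseudo-chromosome
    ``chrom#sample``; downstream PR machinery works unchanged on the result
    once the segmentation and splits are replicated with the same sample
    names (:func:`concat_segmentation`, :func:`concat_intervals`).
    """
    from .enrichment import Record as _Record

    recs = [
        _Record(_pseudo(r.chrom, t.name), r.start, r.end, r.name, r.strand)
        for t in targets
        for r in t.records
    ]
    return AnnotationSet(name=name, records=recs)


def concat_segmentation(seg: Segmentation, sample_names: Sequence[str]) -> Segmentation:
    """Replicate a segmentation across samples of a concatenated genome."""
    runs = [
        (_pseudo(chrom, s), start, end, state)
        for s in sample_names
        for chrom, start, end, state in seg.runs
    ]
    runs.sort(key=lambda r: (r[0], r[1]))
    return Segmentation(runs=runs, n_states=seg.n_states)


def concat_intervals(ivmap: iv.IntervalMap, sample_names: Sequence[str]) -> iv.IntervalMap:
    return {_pseudo(c, s): arr.copy() for s in sample_names for c, arr in ivmap.items()}


def concat_binned(binned: BinnedScore, sample_names: Sequence[str]) -> BinnedScore:
    labels = {_pseudo(c, s): lab.copy() for s in sample_names for c, lab in binned.labels.items()}
    return BinnedScore(labels=labels, n_bins=binned.n_bins)


# ---------------------------------------------------------------------------
# Top-percent score sets
# ---------------------------------------------------------------------------


def top_fraction_set(score: ScoreTrack, fraction: float, universe, name: str | None = None) -> AnnotationSet:
    """Bases above the score threshold whose set size is closest to
    ``fraction`` of the universe.

    Thresholds are searched over distinct defined score values within the
    universe; undefined bases rank below every value but count toward the
    universe size.  When two candidate sizes are equally close the smaller
    set wins, which makes the sets nested across fractions.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    uni = _as_ivmap(universe)
    per_chrom = {}
    vals = []
    for chrom, arr in score.values.items():
        mask = iv.mask_from(uni, chrom, arr.shape[0])
        sel = np.flatnonzero(mask)
        v = np.where(score.defined[chrom][sel], arr[sel], -np.inf)
        per_chrom[chrom] = (sel, v)
        vals.append(v)
    flat = np.concatenate(vals) if vals else np.empty(0)
    n_universe = flat.shape[0]
    target = fraction * n_universe
    distinct = np.unique(flat[np.isfinite(flat)])[::-1]  # descending
    best_thr, best_size, best_err = None, 0, abs(0 - target)
    for thr in distinct:
        size = int((flat >= thr).sum())
        err = abs(size - target)
        if err < best_err:  # ties keep the earlier (smaller) set
            best_thr, best_size, best_err = thr, size, err
    recs = []
    if best_thr is not None:
        from .enrichment import Record as _Record
        for chrom, (sel, v) in per_chrom.items():
            chosen = sel[v >= best_thr]
            mask = np.zeros(score.values[chrom].shape[0], dtype=bool)
            mask[chosen] = True
            for s, e in iv.from_mask(mask):
                recs.append(_Record(chrom, int(s), int(e)))
    return AnnotationSet(name=name or f"top_{fraction:g}", records=recs)
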