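"""Base-resolution fold enrichments of states for external annotations.

The fold enrichment of a state for an annotation is

    (% of annotation bases falling in the state)
    -------------------------------------------
    (% of the background universe falling in the state)

computed at single-base resolution with a uniform background.  The universe
defaults to the whole segmented genome; restricting it implements
background-relative analyses (motif backgrounds, non-coding or non-exonic
backgrounds).  Positional (neighborhood) enrichments evaluate the same ratio
at every signed offset around a set of anchor points, mirroring offsets for
minus-strand anchors so positive offsets are downstream in the direction of
transcription.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .segmentation import Segmentation

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Record:
    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None


@dataclass
class AnnotationSet:
    """A named set of genomic intervals; base counting merges overlaps."""

    name: str
    records: list[Record]

    @classmethod
    def from_tuples(cls, name: str, tuples: Iterable[Sequence]) -> "AnnotationSet":
        recs = []
        for t in tuples:
            chrom, start, end = t[0], int(t[1]), int(t[2])
            nm = t[3] if len(t) > 3 else None
            strand = t[5] if len(t) > 5 else (t[4] if len(t) > 4 and t[4] in "+-" else None)
            recs.append(Record(chrom, start, end, nm, strand))
        return cls(name=name, records=recs)

    @classmethod
    def from_bed(cls, path: str, name: str | None = None) -> "AnnotationSet":
        opener = gzip.open if path.endswith(".gz") else open
        tuples = []
        with opener(path, "rt") as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.rstrip("\n").split("\t")
                tuples.append(parts)
        return cls.from_tuples(name or path, tuples)

    @property
    def intervals(self) -> iv.IntervalMap:
        """Merged interval map (a base counts once)."""
        cached = getattr(self, "_merged", None)
        if cached is None:
            cached = iv.merge_records((r.chrom, r.start, r.end) for r in self.records)
            self._merged = cached
        return cached

    @property
    def n_bases(self) -> int:
        return iv.total_bases(self.intervals)

    def restricted_to(self, universe: iv.IntervalMap) -> iv.IntervalMap:
        clipped = iv.intersect(self.intervals, universe)
        lost = self.n_bases - iv.total_bases(clipped)
        if lost:
            log.warning("%s: %d base(s) outside the universe were clipped", self.name, lost)
        return clipped


@dataclass
class EnrichmentTable:
    """States x annotations fold enrichments with the marginal fractions."""

    folds: pd.DataFrame                 # index: state 1..K, columns: annotation names
    genome_fraction: pd.Series          # per state, of the universe
    annotation_fraction: pd.Series      # per annotation, of the universe


def _genome_universe(seg: Segmentation) -> iv.IntervalMap:
    return iv.merge_records((c, s, e) for c, s, e, _ in seg.runs)


def overlap_enrichment(
    seg: Segmentation,
    ann: AnnotationSet,
    universe: AnnotationSet | iv.IntervalMap | None = None,
) -> pd.Series:
    """Fold enrichment of every state for one annotation.

    Returns a Series indexed by state (1..K); NaN throughout if the
    annotation is empty within the universe, and NaN for states with no
    bases in the universe.
    """
    if universe is None:
        uni = _genome_universe(seg)
    elif isinstance(universe, AnnotationSet):
        uni = universe.intervals
    else:
        uni = universe
    ann_iv = ann.restricted_to(uni)
    ann_total = iv.total_bases(ann_iv)
    state_in_uni = seg.overlap_counts(uni).astype(np.float64)
    uni_total = iv.total_bases(uni)
    idx = pd.RangeIndex(1, seg.n_states + 1, name="state")
    if ann_total == 0:
        return pd.Series(np.nan, index=idx, name=ann.name)
    ann_in_state = seg.overlap_counts(ann_iv).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        fold = (ann_in_state / ann_total) / (state_in_uni / uni_total)
    fold[state_in_uni == 0] = np.nan
    return pd.Series(fold, index=idx, name=ann.name)


def enrichment_table(
    seg: Segmentation,
    annotations: Sequence[AnnotationSet],
    universe: AnnotationSet | iv.IntervalMap | None = None,
) -> EnrichmentTable:
    if universe is None:
        uni = _genome_universe(seg)
    elif isinstance(universe, AnnotationSet):
        uni = universe.intervals
    else:
        uni = universe
    uni_total = iv.total_bases(uni)
    folds = pd.DataFrame({a.name: overlap_enrichment(seg, a, uni) for a in annotations})
    genome_fraction = pd.Series(
        seg.overlap_counts(uni) / uni_total, index=folds.index, name="genome_fraction"
    )
    ann_fraction = pd.Series(
        {a.name: iv.total_bases(a.restricted_to(uni)) / uni_total for a in annotations},
        name="annotation_fraction",
    )
    return EnrichmentTable(folds=folds, genome_fraction=genome_fraction, annotation_fraction=ann_fraction)


def relative_enrichment(fold_foreground: pd.Series, fold_background: pd.Series) -> pd.Series:
    """Elementwise ratio of two fold-enrichment columns; 0 background -> NaN."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = fold_foreground / fold_background
    return ratio.where(fold_background != 0)


def neighborhood_enrichment(
    seg: Segmentation,
    anchors: AnnotationSet,
    left: int,
    right: int,
) -> pd.DataFrame:
    """Positional fold enrichment at 1 bp spacing around anchor points.

    Each anchor record contributes its start position; a '-' strand mirrors
    the offsets so positive offsets are downstream in the 5'->3' direction.
    At each offset the fraction of contributing anchors in a state is divided
    by the state's genome fraction; anchors whose offset position leaves the
    segmented extent are skipped at that offset.
    """
    positions, signs = [], []
    covered = set(seg.chromosomes)
    dropped = 0
    for rec in anchors.records:
        if rec.chrom not in covered:
            dropped += 1
            continue
        positions.append((rec.chrom, rec.start))
        signs.append(-1 if rec.strand == "-" else 1)
    if dropped:
        log.warning("%s: %d anchor(s) on unannotated chromosomes dropped", anchors.name, dropped)
    if not positions:
        raise ValueError("no usable anchor points")
    uni = _genome_universe(seg)
    genome_frac = seg.overlap_counts(uni) / iv.total_bases(uni)
    offsets = np.arange(-left, right + 1)
    folds = np.full((len(offsets), seg.n_states), np.nan)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for (chrom, pos), sign in zip(positions, signs):
        by_chrom.setdefault(chrom, []).append((pos, sign))
    extents = {c: seg.chrom_extent(c) for c in seg.chromosomes}
    for di, d in enumerate(offsets):
        counts = np.zeros(seg.n_states, dtype=np.int64)
        n_valid = 0
        for chrom, pts in by_chrom.items():
            lo, hi = extents[chrom]
            pos = np.array([p + s * d for p, s in pts], dtype=np.int64)
            ok = (pos >= lo) & (pos < hi)
            if not ok.any():
                continue
            states = seg.states_at(chrom, pos[ok])
            n_valid += int(ok.sum())
            np.add.at(counts, states[states > 0] - 1, 1)
        if n_valid:
            with np.errstate(invalid="ignore", divide="ignore"):
                folds[di] = (counts / n_valid) / genome_frac
    return pd.DataFrame(folds, index=pd.Index(offsets, name="offset"),
                        columns=pd.RangeIndex(1, seg.n_states + 1, name="state"))


def rank_genes_by_state(
    seg: Segmentation,
    genes: AnnotationSet,
    window: int = 2000,
    top_fraction: float = 0.05,
) -> dict[int, tuple[list[str], list[str]]]:
    """Rank genes per state by promoter-proximal state coverage.

    For each gene (one TSS per gene, the record start), counts the bases of
    the state within +/- ``window`` of the TSS (a closed symmetric window of
    2*window+1 bases, clipped to the segmented extent).  Genes are sorted by
    descending count with lexicographic gene-id tie-breaks; the top set holds
    the first ``floor(top_fraction * n_genes)`` genes.

    Returns ``{state: (ranked_gene_ids, top_gene_ids)}``.
    """
    ids, windows = [], []
    extents = {c: seg.chrom_extent(c) for c in seg.chromosomes}
    for rec in genes.records:
        if rec.name is None:
            raise ValueError("gene records need ids in the name field")
        if rec.chrom not in extents:
            continue
        lo, hi = extents[rec.chrom]
        s = max(rec.start - window, lo)
        e = min(rec.start + window + 1, hi)
        ids.append(rec.name)
        windows.append((rec.chrom, s, e))
    n_top = int(top_fraction * len(ids))
    out: dict[int, tuple[list[str], list[str]]] = {}
    counts = np.zeros((len(ids), seg.n_states), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(windows):
        counts[i] = seg.overlap_counts({chrom: np.array([[s, e]], dtype=np.int64)})
    for k in range(1, seg.n_states + 1):
        order = sorted(range(len(ids)), key=lambda i: (-counts[i, k - 1], ids[i]))
        ranked = [ids[i] for i in order]
        out[k] = (ranked, ranked[:n_top])
    return out
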