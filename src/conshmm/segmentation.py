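"""Posterior decoding and genome-wide segmentations.

A segmentation is the run-length representation of the per-base maximum
posterior state labels: sorted, non-overlapping, maximal runs tiling every
annotated chromosome, written as BED4 with the 1-based state label in the
name column.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .alignment_io import GenomePartition, ObservationMatrix
from .hmm import ConsHMMModel, StatePath, forward_backward
from .intervals import IntervalMap


@dataclass
class Segmentation:
    """Maximal same-state runs tiling the annotated genome.

    ``runs`` holds (chrom, start, end, state) with 0-based half-open
    intervals and 1-based state labels; adjacent runs on a chromosome carry
    different states.
    """

    runs: list[tuple[str, int, int, int]]
    n_states: int

    def __post_init__(self) -> None:
        prev: tuple[str, int, int, int] | None = None
        for run in self.runs:
            chrom, start, end, state = run
            if end <= start:
                raise ValueError(f"empty run {run}")
            if not 1 <= state <= self.n_states:
                raise ValueError(f"state {state} outside 1..{self.n_states}")
            if prev is not None and prev[0] == chrom:
                if start != prev[2]:
                    raise ValueError(f"runs not contiguous at {chrom}:{prev[2]} vs {start}")
                if state == prev[3]:
                    raise ValueError(f"adjacent runs share state {state} at {chrom}:{start}")
            prev = run

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for chrom, *_ in self.runs:
            seen.setdefault(chrom)
        return list(seen)

    def chrom_extent(self, chrom: str) -> tuple[int, int]:
        runs = [r for r in self.runs if r[0] == chrom]
        return runs[0][1], runs[-1][2]

    @property
    def total_bases(self) -> int:
        return sum(end - start for _, start, end, _ in self.runs)

    def state_base_counts(self) -> np.ndarray:
        """Number of bases per state, shape (K,), index = state - 1."""
        counts = np.zeros(self.n_states, dtype=np.int64)
        for _, start, end, state in self.runs:
            counts[state - 1] += end - start
        return counts

    def state_intervals(self, state: int) -> IntervalMap:
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, st in self.runs:
            if st == state:
                out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def _per_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        cache = getattr(self, "_chrom_cache", None)
        if cache is None:
            cache = {}
            for chrom in self.chromosomes:
                runs = [(s, e, st) for c, s, e, st in self.runs if c == chrom]
                arr = np.asarray(runs, dtype=np.int64)
                cache[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2])
            self._chrom_cache = cache
        return cache

    def states_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """State labels at the given positions; 0 where uncovered."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros(positions.shape, dtype=np.int64)
        per = self._per_chrom().get(chrom)
        if per is None:
            return out
        starts, ends, states = per
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
        out[ok] = states[idx[ok]]
        return out

    def overlap_counts(self, ivmap: Mapping[str, np.ndarray]) -> np.ndarray:
        """Bases of each state overlapped by an interval map, shape (K,)."""
        counts = np.zeros(self.n_states, dtype=np.int64)
        per = self._per_chrom()
        for chrom, ivs in ivmap.items():
            if chrom not in per:
                continue
            starts, ends, states = per[chrom]
            for s, e in ivs:
                i = max(int(np.searchsorted(starts, s, side="right")) - 1, 0)
                while i < len(starts) and starts[i] < e:
                    lo, hi = max(starts[i], s), min(ends[i], e)
                    if lo < hi:
                        counts[states[i] - 1] += hi - lo
                    i += 1
        return counts

    def labels(self, chrom: str) -> np.ndarray:
        """Dense per-base label array for one chromosome (1-based states)."""
        start, end = self.chrom_extent(chrom)
        out = np.zeros(end - start, dtype=np.int32)
        for c, s, e, st in self.runs:
            if c == chrom:
                out[s - start:e - start] = st
        return out


def decode(model: ConsHMMModel, obs: ObservationMatrix) -> StatePath:
    """Maximum-posterior state labels; ties go to the lowest state index."""
    post = forward_backward(model, obs)
    states = np.argmax(post.values, axis=1).astype(np.int32) + 1
    return StatePath(chrom=obs.chrom, start=obs.start, end=obs.end, states=states)


def path_to_runs(path: StatePath) -> list[tuple[str, int, int, int]]:
    states = path.states
    change = np.flatnonzero(np.diff(states)) + 1
    bounds = np.concatenate([[0], change, [len(states)]])
    return [
        (path.chrom, path.start + int(s), path.start + int(e), int(states[s]))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def merge_segmentation(paths: Iterable[StatePath], partition: GenomePartition, n_states: int) -> Segmentation:
    """Stitch per-slice state paths into one maximal-run segmentation.

    Runs spanning slice boundaries are merged into single intervals.  Every
    slice of the partition must be covered exactly once.
    """
    by_slice = {(p.chrom, p.start, p.end): p for p in paths}
    missing = [s for s in partition.slices if s not in by_slice]
    if missing:
        raise ValueError(f"missing state paths for slices: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    runs: list[tuple[str, int, int, int]] = []
    for chrom, length in partition.chromosomes:
        for sl in partition.slices:
            if sl[0] != chrom:
                continue
            for run in path_to_runs(by_slice[sl]):
                if runs and runs[-1][0] == chrom and runs[-1][2] == run[1] and runs[-1][3] == run[3]:
                    runs[-1] = (chrom, runs[-1][1], run[2], run[3])
                else:
                    runs.append(run)
    return Segmentation(runs=runs, n_states=n_states)


def uniform_transition_model(model: ConsHMMModel, p_uniform: float | None = None) -> ConsHMMModel:
    """Copy of the model with every transition probability set to 1/K.

    Removing the transition information isolates the emission signal; with
    K=100 states the uniform probability is 0.01.  ``p_uniform``, if given,
    must equal 1/K.
    """
    K = model.n_states
    if p_uniform is not None and abs(p_uniform * K - 1.0) > 1e-9:
        raise ValueError(f"p_uniform must be 1/K = {1.0 / K}")
    b = np.full((K, K), 1.0 / K)
    return ConsHMMModel(species=model.species, a=model.a.copy(), b=b, f=model.f.copy(), g=model.g.copy())


def annotation_agreement(original: Segmentation, other: Segmentation) -> np.ndarray:
    """Per-state fraction of originally assigned bases kept by ``other``.

    Entry k-1 is |bases in state k in both| / |bases in state k in original|;
    NaN for states absent from the original segmentation.
    """
    if original.n_states != other.n_states:
        raise ValueError("segmentations have different state counts")
    orig_counts = original.state_base_counts().astype(np.float64)
    both = np.zeros(original.n_states, dtype=np.int64)
    for k in range(1, original.n_states + 1):
        ivs = original.state_intervals(k)
        if ivs:
            both[k - 1] = other.overlap_counts(ivs)[k - 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = both / orig_counts
    frac[orig_counts == 0] = np.nan
    return frac


def count_segments(seg: Segmentation) -> int:
    """Number of maximal same-state runs."""
    return len(seg.runs)


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------


def write_bed(seg: Segmentation, path: str, mnemonics: Mapping[int, str] | None = None) -> None:
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "wt") as fh:
        for chrom, start, end, state in seg.runs:
            name = mnemonics[state] if mnemonics else str(state)
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed_segmentation(path: str, n_states: int | None = None) -> Segmentation:
    opener = gzip.open if path.endswith(".gz") else open
    runs: list[tuple[str, int, int, int]] = []
    with opener(path, "rt") as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            runs.append((chrom, int(start), int(end), int(name)))
    if n_states is None:
        n_states = max(r[3] for r in runs)
    return Segmentation(runs=runs, n_states=n_states)
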