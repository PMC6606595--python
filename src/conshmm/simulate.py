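"""Synthetic alignments from a known generative model.

The simulator draws hidden state paths from the model's Markov chain, emits
per-species align/match observations from the state's (f, g) parameters, and
can render the result as MAF text whose re-encoding reproduces the simulated
observations bit-exactly.  A deterministic "clade" preset builds states that
mimic the broad families of conservation states seen in vertebrate
alignments: alignment through all species, through progressively closer
clades only, alignment without matching, and an artifact-like pattern where
distal species align but intermediate ones do not.

No phylogenetic tree or substitution model is involved: the simulator's
generative assumptions are exactly the annotator's model assumptions, which
is what makes it a ground-truth fixture for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .alignment_io import MISSING, GenomePartition, ObservationMatrix, SpeciesSet
from .hmm import ConsHMMModel, StatePath

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticTruth:
    """A simulated dataset with its generating model and true state paths."""

    model: ConsHMMModel
    partition: GenomePartition
    paths: list[StatePath]
    obs: list[ObservationMatrix]
    seed: int
    maf: str | None = None


def simulate(model: ConsHMMModel, partition: GenomePartition, seed: int) -> SyntheticTruth:
    """Sample state paths and observations for every slice of a partition.

    Each slice is an independent chain started from the initial
    distribution ``a``; per base, each species aligns with probability
    ``f[state]`` and, if aligned, matches with probability ``g[state]``.
    """
    rng = np.random.default_rng(seed)
    K, J = model.n_states, model.n_others
    b_cum = np.cumsum(model.b, axis=1)
    a_cum = np.cumsum(model.a)
    paths, obs_list = [], []
    for chrom, start, end in partition.slices:
        T = end - start
        states = np.empty(T, dtype=np.int32)
        u = rng.random(T)
        states[0] = np.searchsorted(a_cum, u[0], side="right")
        for t in range(1, T):
            states[t] = np.searchsorted(b_cum[states[t - 1]], u[t], side="right")
        states = np.minimum(states, K - 1)
        y = (rng.random((T, J)) < model.f[states]).astype(np.uint8)
        matched = rng.random((T, J)) < model.g[states]
        z = np.where(y == 1, matched.astype(np.uint8), np.uint8(MISSING))
        paths.append(StatePath(chrom=chrom, start=start, end=end, states=states + 1))
        obs_list.append(ObservationMatrix(chrom=chrom, start=start, end=end, y=y, z=z))
    return SyntheticTruth(model=model, partition=partition, paths=paths, obs=obs_list, seed=seed)


def emit_maf(truth: SyntheticTruth, nucleotide_seed: int, max_block: int = 10_000) -> str:
    """Render simulated observations as MAF text.

    Reference bases are uniform over {A, C, G, T}; matching species copy the
    reference base, mismatching species draw uniformly from the other three,
    unaligned species appear as gaps (or their row is omitted when they
    contribute nothing to a block).  Blocks break at runs where no species
    aligns and every ``max_block`` bases.  Re-encoding the text reproduces
    ``truth.obs`` exactly.
    """
    rng = np.random.default_rng(nucleotide_seed)
    species = truth.model.species
    J = species.n_others
    lines = ["##maf version=1"]
    aligned_sofar = {sp: 0 for sp in species.others}
    total_aligned = {sp: 0 for sp in species.others}
    per_slice = []
    for obs in truth.obs:
        T = obs.n_positions
        ref_idx = rng.integers(0, 4, size=T)
        offsets = rng.integers(1, 4, size=(T, J))
        per_slice.append((ref_idx, offsets))
        for j, sp in enumerate(species.others):
            total_aligned[sp] += int((obs.y[:, j] == 1).sum())
    chrom_lengths = dict(truth.partition.chromosomes)

    for obs, (ref_idx, offsets) in zip(truth.obs, per_slice):
        T = obs.n_positions
        any_align = obs.y.any(axis=1)
        # maximal aligned runs, capped at max_block
        t = 0
        while t < T:
            if not any_align[t]:
                t += 1
                continue
            s = t
            while t < T and any_align[t] and t - s < max_block:
                t += 1
            e = t
            ref_chars = _BASES[ref_idx[s:e]]
            sp_idx = (ref_idx[s:e, None] + offsets[s:e]) % 4  # mismatch characters
            lines.append("a")
            lines.append(
                "s\t{src}\t{start}\t{size}\t+\t{srcsize}\t{text}".format(
                    src=f"{species.reference}.{obs.chrom}",
                    start=obs.start + s,
                    size=e - s,
                    srcsize=chrom_lengths[obs.chrom],
                    text=ref_chars.tobytes().decode("ascii"),
                )
            )
            for j, sp in enumerate(species.others):
                yj = obs.y[s:e, j]
                if not yj.any():
                    continue
                zj = obs.z[s:e, j]
                chars = np.full(e - s, b"-", dtype="S1")
                match = (yj == 1) & (zj == 1)
                mism = (yj == 1) & (zj == 0)
                chars[match] = ref_chars[match]
                chars[mism] = _BASES[sp_idx[mism, j]]
                size = int(yj.sum())
                lines.append(
                    f"s\t{sp}.chr\t{aligned_sofar[sp]}\t{size}\t+\t{total_aligned[sp]}\t"
                    + chars.tobytes().decode("ascii")
                )
                aligned_sofar[sp] += size
            lines.append("")
    truth.maf = "\n".join(lines) + "\n"
    return truth.maf


def preset_clade_model(
    n_species: int,
    n_states: int,
    self_transition: float = 0.99,
    reference: str = "ref",
) -> ConsHMMModel:
    """Deterministic model with clade-structured emission patterns.

    Species are ordered by divergence from the reference (closest first).
    Most states align a prefix of the species list whose length shrinks with
    the state index (deep conservation through to reference-proximal only);
    with four or more states, state K-1 is an align-without-match pattern,
    and with five or more, state K is an artifact-like pattern aligning the
    closest and the most distal species but not the middle of the tree.
    Transitions are sticky (``self_transition`` on the diagonal) and the
    initial distribution is uniform.
    """
    if n_species < 2:
        raise ValueError("need at least two species (reference + one other)")
    if n_states < 1:
        raise ValueError("need at least one state")
    J, K = n_species - 1, n_states
    species = SpeciesSet(reference=reference, others=tuple(f"sp{j + 1}" for j in range(J)))
    f = np.full((K, J), 0.05)
    g = np.full((K, J), 0.5)
    for k in range(K):
        prefix = max(1, round(J * (K - k) / K)) if K > 1 else J
        f[k, :prefix] = 0.95
        g[k, :prefix] = 0.9
    if K >= 4:
        k = K - 2  # align-without-match analog
        prefix = max(2, round(0.75 * J))
        f[k] = 0.05
        f[k, :prefix] = 0.95
        g[k] = 0.1
    if K >= 5:
        k = K - 1  # artifact-like: proximal and most-distal align, middle does not
        wing = max(1, int(np.ceil(J / 4)))
        f[k] = 0.05
        f[k, :wing] = 0.95
        f[k, J - wing:] = 0.95
        g[k] = 0.5
        g[k, :wing] = 0.9
        g[k, J - wing:] = 0.9
    a = np.full(K, 1.0 / K)
    if K == 1:
        b = np.ones((1, 1))
    else:
        b = np.full((K, K), (1.0 - self_transition) / (K - 1))
        np.fill_diagonal(b, self_transition)
    return ConsHMMModel(species=species, a=a, b=b, f=f, g=g)


# ---------------------------------------------------------------------------
# State matching for recovery tests
# ---------------------------------------------------------------------------


def match_states(truth: ConsHMMModel, learned: ConsHMMModel) -> np.ndarray:
    """Optimal assignment of learned states to true states.

    EM state labels are not identifiable, so recovery is judged after a
    minimum-cost bipartite matching on the L1 distance between multinomial
    emission vectors.  Returns ``perm`` with ``perm[k]`` the learned state
    (0-based) matched to true state ``k``.
    """
    pt = truth.p.reshape(truth.n_states, -1)
    pl = learned.p.reshape(learned.n_states, -1)
    cost = np.abs(pt[:, None, :] - pl[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(truth.n_states, dtype=np.int64)
    perm[rows] = cols
    return perm


def recovery_errors(truth: ConsHMMModel, learned: ConsHMMModel) -> dict[str, float]:
    """Max-abs parameter errors after optimal state matching."""
    perm = match_states(truth, learned)
    err_f = float(np.abs(truth.f - learned.f[perm]).max())
    err_g = float(np.abs(truth.g - learned.g[perm]).max())
    err_b = float(np.abs(truth.b - learned.b[perm][:, perm]).max())
    err_a = float(np.abs(truth.a - learned.a[perm]).max())
    return {"f": err_f, "g": err_g, "b": err_b, "a": err_a}


def emission_l1_separation(model: ConsHMMModel) -> float:
    """Minimum pairwise L1 distance between state emission vectors."""
    p = model.p.reshape(model.n_states, -1)
    K = model.n_states
    dists = [np.abs(p[i] - p[j]).sum() for i in range(K) for j in range(i + 1, K)]
    return float(min(dists)) if dists else np.inf
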