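"""Multivariate hidden Markov model over per-species align/match observations.

Each of the K hidden states emits, independently for every non-reference
species j, a three-way multinomial observation with probabilities

    p[k,j,1] = f[k,j] * g[k,j]        aligned and matching
    p[k,j,2] = f[k,j] * (1 - g[k,j])  aligned, not matching
    p[k,j,3] = 1 - f[k,j]             not aligned

where f is the align probability and g the match probability conditioned on
aligning.  The two-Bernoulli (f, g) factorisation is exactly equivalent to
the multinomial; the match flag is treated as missing data when the species
does not align, so g is estimated only from aligned positions.

Forward-backward uses per-position scaling with per-position log-emission
offsets, which keeps products of ~100 species emission factors from
underflowing.  The per-position recursions are compiled with numba.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Callable, Iterable, Sequence

import numpy as np
from numba import njit

from .alignment_io import MISSING, ObservationMatrix, SpeciesSet

PROB_FLOOR = 1e-10
PROB_CEIL = 1.0 - 1e-10


@dataclass
class ConsHMMModel:
    """Parameters of a K-state conservation-state HMM.

    a : (K,) initial state probabilities, applied at the first base of each
        independently modelled sequence (a slice during training/decoding).
    b : (K, K) transition matrix, rows sum to 1.
    f : (K, N-1) per-state, per-species align probabilities.
    g : (K, N-1) per-state, per-species match probabilities given aligned.
    """

    species: SpeciesSet
    a: np.ndarray
    b: np.ndarray
    f: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        self.f = np.atleast_2d(np.asarray(self.f, dtype=np.float64))
        self.g = np.atleast_2d(np.asarray(self.g, dtype=np.float64))
        K = self.a.shape[0]
        J = self.species.n_others
        if self.b.shape != (K, K) or self.f.shape != (K, J) or self.g.shape != (K, J):
            raise ValueError("inconsistent parameter shapes")
        self.validate()

    @property
    def n_states(self) -> int:
        return self.a.shape[0]

    @property
    def n_others(self) -> int:
        return self.f.shape[1]

    def validate(self, atol: float = 1e-8) -> None:
        for name, arr in (("a", self.a), ("b", self.b), ("f", self.f), ("g", self.g)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} has entries outside [0, 1]")
        if not math.isclose(self.a.sum(), 1.0, abs_tol=atol):
            raise ValueError("initial probabilities must sum to 1")
        if not np.allclose(self.b.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")

    @property
    def p(self) -> np.ndarray:
        """Equivalent multinomial emissions, shape (K, N-1, 3).

        The last axis orders the outcomes (align+match, align+mismatch,
        not aligned).  The residual construction below makes each (k, j)
        triple sum to exactly 1.0 in float64, not just up to rounding:
        p2 = f - p1 and p3 = 1 - (p1 + p2) differ from f*(1-g) and 1-f by
        at most one ulp each.
        """
        p1 = self.f * self.g
        p2 = self.f - p1
        p3 = 1.0 - (p1 + p2)
        return np.stack([p1, p2, p3], axis=-1)

    def n_free_parameters(self) -> int:
        K, J = self.n_states, self.n_others
        return (K - 1) + K * (K - 1) + 2 * K * J


@dataclass
class PosteriorMatrix:
    """Marginal state posteriors for one slice, plus its log-likelihood."""

    chrom: str
    start: int
    end: int
    values: np.ndarray  # (T, K)
    loglik: float


@dataclass
class StatePath:
    """Per-base state labels (1-based) for one slice."""

    chrom: str
    start: int
    end: int
    states: np.ndarray  # (T,), int values in 1..K

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int32)
        if self.states.shape != (self.end - self.start,):
            raise ValueError("state path length must equal slice length")


# ---------------------------------------------------------------------------
# Emissions
# ---------------------------------------------------------------------------


def emission_prob(model: ConsHMMModel, state: int, y: np.ndarray, z: np.ndarray) -> float:
    """Probability of one position's observation vector under state ``state``.

    ``state`` is 1-based.  Computed in the two-Bernoulli form, with the match
    Bernoulli dropped wherever the species does not align -- identical to the
    product of multinomial probabilities.
    """
    y = np.asarray(y)
    z = np.asarray(z)
    if np.any((z == MISSING) != (y == 0)):
        raise ValueError("z must be MISSING exactly where y == 0")
    k = state - 1
    f, g = model.f[k], model.g[k]
    prob = 1.0
    for j in range(model.n_others):
        if y[j]:
            prob *= f[j] * (g[j] if z[j] == 1 else 1.0 - g[j])
        else:
            prob *= 1.0 - f[j]
    return prob


def log_emission_matrix(model: ConsHMMModel, obs: ObservationMatrix) -> np.ndarray:
    """(T, K) matrix of log emission probabilities, accumulated in log space."""
    if obs.n_others != model.n_others:
        raise ValueError("observation/species dimension mismatch")
    with np.errstate(divide="ignore"):
        lfg = np.log(model.f * model.g)          # (K, J)
        lfng = np.log(model.f * (1.0 - model.g))
        l1f = np.log(1.0 - model.f)
    # boundary parameters (f or g exactly 0/1) make some outcomes impossible;
    # a huge finite penalty keeps 0 * log(0) products well-defined
    lfg = np.maximum(lfg, -1e30)
    lfng = np.maximum(lfng, -1e30)
    l1f = np.maximum(l1f, -1e30)
    y1z1 = ((obs.y == 1) & (obs.z == 1)).astype(np.float64)
    y1z0 = ((obs.y == 1) & (obs.z == 0)).astype(np.float64)
    y0 = (obs.y == 0).astype(np.float64)
    return y1z1 @ lfg.T + y1z0 @ lfng.T + y0 @ l1f.T


# ---------------------------------------------------------------------------
# Scaled forward-backward (numba kernels)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _forward(a, b, Bs):  # pragma: no cover - exercised via forward_backward
    T, K = Bs.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    row = a * Bs[0]
    c[0] = row.sum()
    alpha[0] = row / c[0]
    for t in range(1, T):
        row = (alpha[t - 1] @ b) * Bs[t]
        c[t] = row.sum()
        alpha[t] = row / c[t]
    return alpha, c


@njit(cache=True)
def _backward(b, Bs, c):  # pragma: no cover
    T, K = Bs.shape
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (b @ (Bs[t + 1] * beta[t + 1])) / c[t + 1]
    return beta


@njit(cache=True)
def _transition_counts(alpha, beta, b, Bs, c):  # pragma: no cover
    T, K = Bs.shape
    num = np.zeros((K, K))
    for t in range(T - 1):
        w = Bs[t + 1] * beta[t + 1] / c[t + 1]
        for i in range(K):
            num[i] += alpha[t, i] * b[i] * w
    return num


def _scaled_fb(model: ConsHMMModel, obs: ObservationMatrix):
    logB = log_emission_matrix(model, obs)
    m = logB.max(axis=1)
    Bs = np.exp(logB - m[:, None])
    alpha, c = _forward(model.a, model.b, Bs)
    if not np.all(np.isfinite(c)) or np.any(c <= 0):
        raise FloatingPointError("forward recursion underflowed; model parameters too extreme")
    beta = _backward(model.b, Bs, c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + m.sum())
    return gamma, loglik, alpha, beta, Bs, c


def forward_backward(model: ConsHMMModel, obs: ObservationMatrix) -> PosteriorMatrix:
    """Exact marginal state posteriors and log-likelihood of one slice.

    The slice is treated as an independent sequence: the initial distribution
    ``a`` applies at its first base.
    """
    gamma, loglik, *_ = _scaled_fb(model, obs)
    return PosteriorMatrix(chrom=obs.chrom, start=obs.start, end=obs.end, values=gamma, loglik=loglik)


def log_likelihood(model: ConsHMMModel, obs_collection: Iterable[ObservationMatrix]) -> float:
    """Total log-likelihood of a collection of independently modelled slices."""
    return sum(forward_backward(model, obs).loglik for obs in obs_collection)


def bic(model: ConsHMMModel, obs_collection: Sequence[ObservationMatrix]) -> float:
    """Bayesian Information Criterion: -2 log L + P log T.

    P counts the free parameters, (K-1) initial + K(K-1) transition +
    2K(N-1) emission; T is the total number of scored positions.
    """
    obs_collection = list(obs_collection)
    total = sum(o.n_positions for o in obs_collection)
    ll = log_likelihood(model, obs_collection)
    return -2.0 * ll + model.n_free_parameters() * math.log(total)


# ---------------------------------------------------------------------------
# Baum-Welch with per-iteration slice subsampling
# ---------------------------------------------------------------------------


def random_init(species: SpeciesSet, n_states: int, seed: int) -> ConsHMMModel:
    """Seeded random initialisation.

    f and g are Uniform(0.2, 0.8) to break symmetry while staying away from
    the boundaries; a is uniform; b has 0.9 on the diagonal with the
    remaining mass spread uniformly.
    """
    rng = np.random.default_rng(seed)
    K, J = n_states, species.n_others
    a = np.full(K, 1.0 / K)
    if K == 1:
        b = np.ones((1, 1))
    else:
        b = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(b, 0.9)
    f = rng.uniform(0.2, 0.8, size=(K, J))
    g = rng.uniform(0.2, 0.8, size=(K, J))
    return ConsHMMModel(species=species, a=a, b=b, f=f, g=g)


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, PROB_FLOOR, PROB_CEIL)


ObsSource = Sequence[ObservationMatrix] | Sequence[Callable[[], ObservationMatrix]]


def _materialise(item) -> ObservationMatrix:
    return item() if callable(item) else item


def baum_welch(
    init: ConsHMMModel,
    obs_source: ObsSource,
    n_iterations: int = 200,
    segments_per_iteration: int | None = 150,
    seed: int = 0,
    callback: Callable[[int, float, ConsHMMModel], None] | None = None,
) -> ConsHMMModel:
    """EM parameter estimation with per-iteration random slice subsampling.

    Runs exactly ``n_iterations`` iterations with no likelihood-based
    stopping rule: when a different random subset of slices is scored each
    iteration the likelihood is expected to move both up and down, so a
    change-based criterion is meaningless.  Each iteration draws
    ``min(segments_per_iteration, n_slices)`` slices uniformly without
    replacement from the seeded generator; ``segments_per_iteration=None``
    uses all slices every iteration (full-data EM, monotone in likelihood).

    ``obs_source`` may hold observation matrices or zero-argument callables
    returning them, so large datasets can stay on disk between iterations.
    ``callback(iteration, loglik, model)`` receives, after each iteration,
    the log-likelihood of the sampled slices under the pre-update model and
    the updated model.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be at least 1")
    if len(obs_source) == 0:
        raise ValueError("at least one slice is required")
    rng = np.random.default_rng(seed)
    model = init
    n = len(obs_source)
    K, J = model.n_states, model.n_others

    for it in range(n_iterations):
        if segments_per_iteration is None or segments_per_iteration >= n:
            idx = np.arange(n)
        else:
            idx = np.sort(rng.choice(n, size=segments_per_iteration, replace=False))
        a_num = np.zeros(K)
        b_num = np.zeros((K, K))
        occ = np.zeros(K)             # expected state occupancy
        f_num = np.zeros((K, J))      # expected aligned counts
        m_num = np.zeros((K, J))      # expected aligned-and-matching counts
        total_ll = 0.0
        for i in idx:
            obs = _materialise(obs_source[i])
            gamma, ll, alpha, beta, Bs, c = _scaled_fb(model, obs)
            total_ll += ll
            a_num += gamma[0]
            if obs.n_positions > 1:
                b_num += _transition_counts(alpha, beta, model.b, Bs, c)
            occ += gamma.sum(axis=0)
            y1 = (obs.y == 1).astype(np.float64)
            z1 = ((obs.z == 1)).astype(np.float64)
            f_num += gamma.T @ y1
            m_num += gamma.T @ (y1 * z1)
        a = _clamp(a_num / a_num.sum())
        a /= a.sum()
        row = b_num.sum(axis=1, keepdims=True)
        b = np.where(row > 0, b_num / np.where(row > 0, row, 1.0), model.b)
        b = _clamp(b)
        b /= b.sum(axis=1, keepdims=True)
        f = _clamp(f_num / np.maximum(occ[:, None], PROB_FLOOR))
        g = _clamp(m_num / np.maximum(f_num, PROB_FLOOR))
        model = ConsHMMModel(species=model.species, a=a, b=b, f=f, g=g)
        if callback is not None:
            callback(it, total_ll, model)
    return model


# ---------------------------------------------------------------------------
# Model file I/O (TSV, round-trips at 17 significant digits)
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_model(model: ConsHMMModel, handle: IO[str] | None = None) -> str:
    lines = ["#conshmm model"]
    lines.append(f"K\t{model.n_states}")
    lines.append(f"reference\t{model.species.reference}")
    lines.append("species\t" + "\t".join(model.species.others))
    lines.append("initial\t" + "\t".join(_fmt(v) for v in model.a))
    for t in range(model.n_states):
        lines.append(f"transition\t{t + 1}\t" + "\t".join(_fmt(v) for v in model.b[t]))
    for k in range(model.n_states):
        for j, sp in enumerate(model.species.others):
            lines.append(f"emission\t{k + 1}\t{sp}\t{_fmt(model.f[k, j])}\t{_fmt(model.g[k, j])}")
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


def read_model(text: str | IO[str]) -> ConsHMMModel:
    if hasattr(text, "read"):
        text = text.read()  # type: ignore[union-attr]
    fields: dict[str, list[list[str]]] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        fields.setdefault(parts[0], []).append(parts[1:])
    K = int(fields["K"][0][0])
    reference = fields["reference"][0][0]
    others = tuple(fields["species"][0])
    species = SpeciesSet(reference=reference, others=others)
    a = np.array([float(v) for v in fields["initial"][0]])
    b = np.zeros((K, K))
    for row in fields["transition"]:
        b[int(row[0]) - 1] = [float(v) for v in row[1:]]
    f = np.zeros((K, len(others)))
    g = np.zeros((K, len(others)))
    for row in fields["emission"]:
        k, sp = int(row[0]) - 1, row[1]
        j = species.index_of(sp)
        f[k, j], g[k, j] = float(row[2]), float(row[3])
    return ConsHMMModel(species=species, a=a, b=b, f=f, g=g)
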