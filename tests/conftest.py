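import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conshmm as ch

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_model(n_states: int, n_others: int, rng: np.random.Generator) -> ch.ConsHMMModel:
    """A valid random model with parameters away from the boundaries."""
    species = ch.SpeciesSet("ref", tuple(f"sp{j + 1}" for j in range(n_others)))
    a = rng.dirichlet(np.ones(n_states))
    b = rng.dirichlet(np.ones(n_states), size=n_states)
    f = rng.uniform(0.05, 0.95, (n_states, n_others))
    g = rng.uniform(0.05, 0.95, (n_states, n_others))
    return ch.ConsHMMModel(species=species, a=a, b=b, f=f, g=g)


def random_obs(n_positions: int, n_others: int, rng: np.random.Generator,
               chrom: str = "chr1", start: int = 0) -> ch.ObservationMatrix:
    y = (rng.random((n_positions, n_others)) < 0.6).astype(np.uint8)
    z = np.where(y == 1, (rng.random((n_positions, n_others)) < 0.5).astype(np.uint8),
                 np.uint8(ch.MISSING))
    return ch.ObservationMatrix(chrom=chrom, start=start, end=start + n_positions, y=y, z=z)


def brute_force_posteriors(model: ch.ConsHMMModel, obs: ch.ObservationMatrix):
    """Sum-over-paths oracle: enumerates all K^T state paths.

    Uses the multinomial emission form directly, independent of the
    two-Bernoulli implementation it checks.
    """
    import itertools

    K, T = model.n_states, obs.n_positions
    p = model.p
    total = 0.0
    post = np.zeros((T, K))
    for path in itertools.product(range(K), repeat=T):
        pr = model.a[path[0]]
        for t in range(1, T):
            pr *= model.b[path[t - 1], path[t]]
        for t in range(T):
            for j in range(model.n_others):
                if obs.y[t, j] == 1:
                    m = 0 if obs.z[t, j] == 1 else 1
                else:
                    m = 2
                pr *= p[path[t], j, m]
        total += pr
        for t in range(T):
            post[t, path[t]] += pr
    return float(np.log(total)), post / total


def segmentation_from_labels(labels: np.ndarray, n_states: int,
                             chrom: str = "chr1") -> ch.Segmentation:
    """Build a segmentation from a dense 1-based label array."""
    labels = np.asarray(labels)
    change = np.flatnonzero(np.diff(labels)) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    runs = [(chrom, int(s), int(e), int(labels[s])) for s, e in zip(bounds[:-1], bounds[1:])]
    return ch.Segmentation(runs=runs, n_states=n_states)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
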