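import numpy as np
import pytest

from ingestphase import syngen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def infusion_session():
    """One seeded 200-neuron water-infusion imaging session with ground truth."""
    design = syngen.SessionDesign(seed=11, duration_min=70)
    traces, events, truth = syngen.gen_session(design, n_neurons=200)
    return design, traces, events, truth


def random_lick_train(rng, n_max=60, t_max=120.0):
    """Unstructured lick times for oracle comparisons: a mix of tight runs and
    stray licks so bout boundaries are non-trivial."""
    n = int(rng.integers(0, n_max))
    times = []
    t = 0.0
    for _ in range(n):
        if rng.random() < 0.7:
            t += rng.uniform(0.05, 2.0)  # can be exactly at/below the gap limit
        else:
            t += rng.uniform(2.01, 8.0)
        times.append(t)
        if t > t_max:
            break
    return np.array(times)


def exhaustive_otsu_variances(x, nbins=256):
    """Between-class variance of every possible histogram split, computed
    longhand: list of (threshold = last lower-class bin center, variance)."""
    counts, edges = np.histogram(x, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    out = []
    for k in range(1, nbins):
        w0, w1 = counts[:k].sum(), counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        out.append((centers[k - 1], w0 * w1 * (m0 - m1) ** 2))
    return out


def brute_force_bouts(times, min_duration=10.0, max_gap=2.0):
    """Independent O(n^2)-style bout oracle: grow maximal runs lick by lick."""
    times = sorted(float(t) for t in times)
    bouts = []
    i = 0
    while i < len(times):
        j = i
        while j + 1 < len(times) and times[j + 1] - times[j] <= max_gap:
            j += 1
        if times[j] - times[i] >= min_duration:
            bouts.append((times[i], times[j], j - i + 1))
        i = j + 1
    return bouts
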