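"""Independent brute-force oracles shared by the test modules."""

from itertools import combinations

import numpy as np


def brute_force_otsu(counts: np.ndarray, n_classes: int) -> tuple[int, ...]:
    """Exhaustive enumeration of all threshold tuples.

    Returns the lexicographically smallest maximizer of the between-class
    variance (equivalently of sum S_k^2 / W_k).
    """
    n = len(counts)
    cw = np.concatenate(([0.0], np.cumsum(counts.astype(float))))
    vals = np.arange(n, dtype=float)
    cs = np.concatenate(([0.0], np.cumsum(counts * vals)))

    def term(a, b):
        w = cw[b] - cw[a]
        return (cs[b] - cs[a]) ** 2 / w if w > 0 else 0.0

    best, best_v = None, -1.0
    for ths in combinations(range(n - 1), n_classes - 1):
        bounds = (0,) + tuple(t + 1 for t in ths) + (n,)
        v = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            v += term(a, b)
        if v > best_v:
            best_v, best = v, ths
    return best


def random_histogram(rng, n_bins=64, min_nonempty=5):
    counts = rng.integers(0, 50, size=n_bins)
    while (counts > 0).sum() < min_nonempty:
        counts = rng.integers(0, 50, size=n_bins)
    return counts
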