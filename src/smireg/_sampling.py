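"""Alias-method sampler for discrete distributions (Vose's algorithm).

Used for weighted edge sampling in the proximity-embedding SGD and for
unigram^{3/4} noise sampling in both skip-gram trainers. O(n) setup,
O(1) per draw, exact.
"""

from __future__ import annotations

import numpy as np


class AliasSampler:
    def __init__(self, weights: np.ndarray):
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must not all be zero")
        n = w.size
        prob = w * n / total
        self.n = n
        self.accept = np.ones(n)
        self.alias = np.arange(n)
        small = [i for i in range(n) if prob[i] < 1.0]
        large = [i for i in range(n) if prob[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            self.accept[s] = prob[s]
            self.alias[s] = l
            prob[l] = prob[l] - (1.0 - prob[s])
            (small if prob[l] < 1.0 else large).append(l)
        for i in small + large:
            self.accept[i] = 1.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        idx = rng.integers(0, self.n, size=size)
        u = rng.random(size)
        return np.where(u < self.accept[idx], idx, self.alias[idx])
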