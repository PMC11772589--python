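"""Shared numerics: RNG sub-streams, link functions, convergence diagnostics."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent RNG stream from a run seed and a hashable key path.

    Sub-streams are derived by stable hashing of the key path (stage name,
    feature id, replicate index, ...), so the stream a feature receives does
    not depend on execution order.
    """
    hashed = [zlib.crc32(repr(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *hashed]))


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat potential scale reduction for a (n_chains, n_draws) array."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("expected (n_chains, n_draws)")
    n = chains.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    w = halves.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else np.inf
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))
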