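"""Synthetic fixtures: block-structured similarity matrices with planted clans.

These emulate the small weighted acoustic networks the analysis stack
consumes, with modules planted by construction, and are used both in tests
and as quick sanity inputs for :func:`codaclans.networks.detect_clans`.
"""

from __future__ import annotations

import numpy as np

from .similarity import SimilarityMatrix

__all__ = ["make_fixture_network", "planted_membership"]


def make_fixture_network(
    n_blocks: int,
    block_size: int,
    w_in: float,
    w_out: float,
    rng: np.random.Generator | None = None,
    jitter: float = 0.0,
) -> SimilarityMatrix:
    """Similarity matrix with ``n_blocks`` planted modules of equal size.

    Within-block similarities are ``w_in``, between-block ``w_out`` (both in
    [0, 1]); optional symmetric uniform jitter breaks ties while staying in
    [0, 1]. Unit ids are 0..n-1 in block order.
    """
    if not (0.0 <= w_out <= 1.0 and 0.0 <= w_in <= 1.0):
        raise ValueError("w_in and w_out must lie in [0, 1]")
    if n_blocks < 1 or block_size < 1:
        raise ValueError("need at least one block of at least one unit")
    n = n_blocks * block_size
    labels = planted_membership(n_blocks, block_size)
    values = np.where(labels[:, None] == labels[None, :], w_in, w_out).astype(float)
    if jitter > 0:
        rng = np.random.default_rng() if rng is None else rng
        noise = rng.uniform(-jitter, jitter, size=(n, n))
        values = np.clip(values + np.triu(noise, 1) + np.triu(noise, 1).T, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(unit_ids=list(range(n)), values=values)


def planted_membership(n_blocks: int, block_size: int) -> np.ndarray:
    """Ground-truth block label per unit, matching make_fixture_network."""
    return np.repeat(np.arange(n_blocks), block_size)
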