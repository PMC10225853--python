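"""Habitat suitability index from categorical land-cover maps.

Suitability of a 1-km landscape cell is the count of habitat-classified
fine-scale (100 m) cells it contains, an integer ``h`` in 0..100.  A cell is
suitable for settlement iff ``h > 0``; ``h`` further modulates the strength
of density-dependent fecundity (see :mod:`dcrange.dcr`).
"""

from __future__ import annotations

import warnings

import numpy as np


def classify_landcover(
    landcover: np.ndarray,
    preferred: set[int] | frozenset[int],
    known_classes: set[int] | None = None,
) -> np.ndarray:
    """Binary habitat map: 1 where the land-cover class is preferred, else 0.

    Codes outside ``known_classes`` (when given) are treated as non-habitat
    with a warning.
    """
    lc = np.asarray(landcover)
    if known_classes is not None:
        unknown = set(np.unique(lc).tolist()) - set(known_classes)
        if unknown:
            warnings.warn(f"unknown land-cover codes treated as non-habitat: {sorted(unknown)}")
    return np.isin(lc, list(preferred)).astype(np.uint8)


def aggregate_suitability(binary: np.ndarray, factor: int = 10) -> np.ndarray:
    """Count habitat cells inside each ``factor x factor`` block.

    With the default factor of 10 (100 m cells into 1-km cells) the result is
    the 0..100 suitability index.  Dimensions not divisible by ``factor`` are
    zero-padded at the bottom/right edge (logged via a warning).
    """
    b = np.asarray(binary)
    if b.ndim != 2:
        raise ValueError("binary habitat map must be 2-d")
    r, c = b.shape
    pr, pc = (-r) % factor, (-c) % factor
    if pr or pc:
        warnings.warn(f"padding habitat map by ({pr}, {pc}) zero cells to a multiple of {factor}")
        b = np.pad(b, ((0, pr), (0, pc)))
        r, c = b.shape
    blocks = b.reshape(r // factor, factor, c // factor, factor)
    return blocks.sum(axis=(1, 3)).astype(np.int64)


def suitable_mask(h: np.ndarray) -> np.ndarray:
    """Boolean mask of cells an individual may occupy (``h > 0``)."""
    return np.asarray(h) > 0


def core_mask(shape: tuple[int, int], buffer_cells: int) -> np.ndarray:
    """Mask of cells outside the boundary buffer ring.

    The buffer (the analogue of a band around the national border) is kept
    in-domain for the dynamics but excluded from likelihood aggregation and
    evaluation metrics.
    """
    mask = np.zeros(shape, dtype=bool)
    b = int(buffer_cells)
    if b < 0:
        raise ValueError("buffer_cells must be >= 0")
    if 2 * b >= shape[0] or 2 * b >= shape[1]:
        return mask
    mask[b : shape[0] - b, b : shape[1] - b] = True
    return mask
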