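"""Binary hypervectors and the three HDC primitives.

A hypervector is a dense binary vector of dimension ``D`` (typically
10,000), represented throughout as a 1-D :class:`numpy.ndarray` of dtype
``uint8`` holding only 0s and 1s.  Random pairs of such vectors are nearly
orthogonal — their normalized Hamming distance concentrates tightly around
0.5 — which is the property every encoding step in this package relies on.

Three operations act on hypervectors:

* **binding** — componentwise XOR; the result is pseudo-orthogonal to both
  inputs, and binding is its own inverse,
* **bundling** — componentwise majority vote over a set of vectors; the
  superposition operation,
* **permutation** — 1-bit cyclic shift; encodes sequence position.

Similarity is measured by Hamming distance (XOR then popcount).
"""

from __future__ import annotations

from typing import Sequence, Union

import numpy as np

__all__ = [
    "Hypervector",
    "random_hypervector",
    "bind",
    "bundle",
    "permute",
    "hamming",
    "normalized_hamming",
]

#: Type alias: a hypervector is a 1-D uint8 array of 0/1 values.
Hypervector = np.ndarray

TieRule = Union[np.ndarray, str, None]


def _as_hv(a: np.ndarray) -> Hypervector:
    arr = np.asarray(a, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError(f"hypervector must be 1-D, got shape {arr.shape}")
    return arr


def _check_dims(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape[-1] != b.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {a.shape[-1]} vs {b.shape[-1]}"
        )


def random_hypervector(dim: int, rng: np.random.Generator) -> Hypervector:
    """Draw a hypervector with i.i.d. uniform {0,1} components.

    Parameters
    ----------
    dim : int
        Dimensionality ``D``; must be at least 2.
    rng : numpy.random.Generator
        Source of randomness.  Identical generator states yield identical
        vectors in identical order, which is the reproducibility contract
        every provisioning strategy builds on.
    """
    if dim < 2:
        raise ValueError(f"hypervector dimension must be >= 2, got {dim}")
    return rng.integers(0, 2, size=dim, dtype=np.uint8)


def bind(a: Hypervector, b: Hypervector) -> Hypervector:
    """Bind two hypervectors: componentwise XOR.

    The result is pseudo-orthogonal to both inputs; ``bind`` is associative,
    commutative and self-inverse (``bind(bind(a, b), b) == a``).
    """
    a = _as_hv(a)
    b = _as_hv(b)
    _check_dims(a, b)
    return np.bitwise_xor(a, b)


def majority(counts: np.ndarray, n: int, tie_breaker: TieRule = None) -> np.ndarray:
    """Binarize per-position 1-counts over ``n`` vectors by strict majority.

    ``counts[i] > n/2`` maps to 1. When ``n`` is even an exact half can
    occur; the tie is resolved by appending one extra vote from
    ``tie_breaker`` (augmented majority): an explicit hypervector, or the
    rules ``"zeros"`` / ``"ones"``. An even ``n`` without a tie rule is an
    error — silent bias is worse than a loud one.
    """
    counts = np.asarray(counts)
    out = (2 * counts > n)
    if n % 2 == 0:
        tie = counts * 2 == n
        if np.any(tie):
            if tie_breaker is None:
                raise ValueError(
                    "even-count bundle produced ties but no tie_breaker given"
                )
            if isinstance(tie_breaker, str):
                if tie_breaker == "zeros":
                    tie_bits = np.zeros(counts.shape[-1], dtype=bool)
                elif tie_breaker == "ones":
                    tie_bits = np.ones(counts.shape[-1], dtype=bool)
                else:
                    raise ValueError(f"unknown tie rule {tie_breaker!r}")
            else:
                tie_bits = _as_hv(tie_breaker).astype(bool)
                if tie_bits.shape[-1] != counts.shape[-1]:
                    raise ValueError("tie_breaker dimension mismatch")
            out = out | (tie & tie_bits)
    return out.astype(np.uint8)


def bundle(vectors: Sequence[Hypervector], tie_breaker: TieRule = None) -> Hypervector:
    """Bundle hypervectors: componentwise majority vote.

    Position ``i`` of the result is 1 iff more than half of the inputs have
    a 1 there.  For an even number of inputs exact ties are resolved by the
    ``tie_breaker`` (see :func:`majority`); a single tie-breaker vector drawn
    once per run keeps the rule unbiased yet deterministic given the seed.
    """
    if len(vectors) == 0:
        raise ValueError("cannot bundle an empty list of hypervectors")
    stack = np.stack([_as_hv(v) for v in vectors])
    if not np.all(stack.shape[1] == np.array([v.shape[-1] for v in vectors])):
        raise ValueError("all bundled hypervectors must share one dimension")
    counts = stack.sum(axis=0, dtype=np.int64)
    return majority(counts, len(vectors), tie_breaker)


def permute(a: Hypervector, k: int = 1) -> Hypervector:
    """Cyclically shift a hypervector by ``k`` positions.

    Positive ``k`` rotates toward higher indices (``rho^{+1}`` is a one-step
    right rotation); negative ``k`` inverts it, so
    ``permute(permute(a, k), -k) == a``.
    """
    a = _as_hv(a)
    return np.roll(a, k)


def hamming(a: Hypervector, b: Hypervector) -> int:
    """Hamming distance: the number of positions where ``a`` and ``b`` differ.

    For binary vectors this is XOR followed by popcount.
    """
    a = _as_hv(a)
    b = _as_hv(b)
    _check_dims(a, b)
    return int(np.count_nonzero(a != b))


def normalized_hamming(a: Hypervector, b: Hypervector) -> float:
    """Hamming distance divided by the dimension; 0.5 for random pairs."""
    return hamming(a, b) / a.shape[-1]
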