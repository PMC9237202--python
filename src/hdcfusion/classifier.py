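"""Associative memory: prototype training and nearest-prototype inference.

Training bundles all encoded vectors of a class into a single prototype.
The bundle is kept as per-position integer accumulators so that the
prototype is the exact majority over every training example — making
training order-independent and incrementally updatable — and binarized on
demand.  Inference XORs a query against each class prototype and popcounts;
the class at minimum Hamming distance is the inferred label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .hv_core import Hypervector, majority

__all__ = ["AssociativeMemory", "train", "infer", "evaluate"]

TieRule = Union[np.ndarray, str, None]


class AssociativeMemory:
    """Per-class bundling accumulators and binarized class prototypes.

    Parameters
    ----------
    dim : int
        Hypervector dimension.
    tie_breaker : array, "zeros", "ones", or None
        Resolves exact-half majorities when a class has an even number of
        training vectors (see :func:`hdcfusion.hv_core.majority`).
    classes : sequence, optional
        Declared class order; also the inference tie-break order.  Classes
        not declared up front are appended in first-seen order.
    """

    def __init__(
        self,
        dim: int,
        tie_breaker: TieRule = None,
        classes: Optional[Sequence] = None,
    ):
        self.dim = dim
        self.tie_breaker = tie_breaker
        self.classes: List = list(classes) if classes is not None else []
        self._acc: Dict[object, np.ndarray] = {
            c: np.zeros(dim, dtype=np.int64) for c in self.classes
        }
        self._counts: Dict[object, int] = {c: 0 for c in self.classes}

    # -- training ----------------------------------------------------------

    def add(self, vector: Hypervector, label) -> None:
        vector = np.asarray(vector, dtype=np.uint8)
        if vector.shape[-1] != self.dim:
            raise ValueError(
                f"vector dimension {vector.shape[-1]} != memory dimension {self.dim}"
            )
        if label not in self._acc:
            self.classes.append(label)
            self._acc[label] = np.zeros(self.dim, dtype=np.int64)
            self._counts[label] = 0
        self._acc[label] += vector
        self._counts[label] += 1

    def add_batch(self, vectors: np.ndarray, labels: np.ndarray) -> None:
        vectors = np.atleast_2d(np.asarray(vectors, dtype=np.uint8))
        labels = np.asarray(labels)
        if vectors.shape[-1] != self.dim:
            raise ValueError(
                f"vector dimension {vectors.shape[-1]} != memory dimension {self.dim}"
            )
        for label in np.unique(labels):
            key = label.item() if hasattr(label, "item") else label
            sel = vectors[labels == label]
            if key not in self._acc:
                self.classes.append(key)
                self._acc[key] = np.zeros(self.dim, dtype=np.int64)
                self._counts[key] = 0
            self._acc[key] += sel.sum(axis=0, dtype=np.int64)
            self._counts[key] += len(sel)

    @property
    def class_counts(self) -> Dict[object, int]:
        return dict(self._counts)

    def prototype(self, label) -> Hypervector:
        """Binarized class prototype: strict majority over the accumulator."""
        n = self._counts[label]
        if n == 0:
            raise ValueError(f"class {label!r} has no training vectors")
        return majority(self._acc[label], n, self.tie_breaker)

    @property
    def prototypes(self) -> Dict[object, Hypervector]:
        return {c: self.prototype(c) for c in self.classes}

    # -- inference ---------------------------------------------------------

    def distances(self, query: Hypervector) -> Dict[object, int]:
        query = np.asarray(query, dtype=np.uint8)
        if query.shape[-1] != self.dim:
            raise ValueError(
                f"query dimension {query.shape[-1]} != memory dimension {self.dim}"
            )
        return {
            c: int(np.count_nonzero(self.prototype(c) != query))
            for c in self.classes
        }

    def infer(self, query: Hypervector) -> Tuple[object, Dict[object, int]]:
        """Label of the closest prototype; ties go to the earliest class."""
        d = self.distances(query)
        best = min(self.classes, key=lambda c: d[c])  # stable: class order
        return best, d

    def infer_batch(self, queries: np.ndarray) -> np.ndarray:
        """Labels for a (W, D) query matrix, chunked to bound memory."""
        queries = np.atleast_2d(np.asarray(queries, dtype=np.uint8))
        protos = np.stack([self.prototype(c) for c in self.classes])
        out = np.empty(len(queries), dtype=object)
        for start in range(0, len(queries), 2048):
            chunk = queries[start: start + 2048]
            d = (chunk[:, None, :] != protos[None, :, :]).sum(axis=2)
            out[start: start + len(chunk)] = [
                self.classes[i] for i in d.argmin(axis=1)
            ]
        return out


def train(
    encoded: Iterable[Tuple[Hypervector, object]],
    dim: Optional[int] = None,
    tie_breaker: TieRule = None,
    classes: Optional[Sequence] = None,
) -> AssociativeMemory:
    """Build an associative memory from (vector, label) pairs."""
    encoded = list(encoded)
    if not encoded:
        raise ValueError("cannot train on an empty list of encoded vectors")
    if dim is None:
        dim = np.asarray(encoded[0][0]).shape[-1]
    am = AssociativeMemory(dim, tie_breaker, classes)
    for vec, label in encoded:
        am.add(vec, label)
    return am


def infer(am: AssociativeMemory, query: Hypervector) -> Tuple[object, Dict[object, int]]:
    """Nearest-prototype inference; returns (label, per-class distances)."""
    return am.infer(query)


@dataclass
class EvaluationReport:
    """Per-window accuracy with per-class breakdown and confusion counts."""

    accuracy: float
    n_windows: int
    per_class_accuracy: Dict[object, float]
    confusion: Dict[Tuple[object, object], int]

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_windows": self.n_windows,
            "per_class_accuracy": {str(k): v for k, v in self.per_class_accuracy.items()},
            "confusion": {f"{t}->{p}": n for (t, p), n in self.confusion.items()},
        }


def evaluate(
    am: AssociativeMemory,
    encoded_test: Sequence[Tuple[Hypervector, object]],
) -> EvaluationReport:
    """Classify every test vector and tally accuracies and confusions."""
    encoded_test = list(encoded_test)
    if not encoded_test:
        raise ValueError("cannot evaluate on an empty test list")
    vectors = np.stack([np.asarray(v, dtype=np.uint8) for v, _ in encoded_test])
    truth = [l for _, l in encoded_test]
    pred = am.infer_batch(vectors)
    confusion: Dict[Tuple[object, object], int] = {}
    correct_by: Dict[object, int] = {}
    total_by: Dict[object, int] = {}
    n_correct = 0
    for t, p in zip(truth, pred):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
        total_by[t] = total_by.get(t, 0) + 1
        if t == p:
            correct_by[t] = correct_by.get(t, 0) + 1
            n_correct += 1
    return EvaluationReport(
        accuracy=n_correct / len(truth),
        n_windows=len(truth),
        per_class_accuracy={
            c: correct_by.get(c, 0) / total_by[c] for c in total_by
        },
        confusion=confusion,
    )
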