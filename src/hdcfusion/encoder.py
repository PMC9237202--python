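"""Spatial, fusion and temporal encoding of feature streams.

The datapath has three stages:

1. **Map into hyperdimensional space** — each channel's feature value
   selects, by its sign, one of two pre-provisioned projection vectors,
   which is bound (XOR) to the channel's item-memory vector:
   ``SE_{i,j} = iM_i ^ FP_{i,j}``.  Magnitude is deliberately not encoded;
   the sign-multiplexer scheme keeps projections pseudo-orthogonal without
   multipliers.
2. **Spatial encoder with early fusion** — the per-channel vectors of one
   modality are bundled (majority), and the per-modality vectors are then
   bundled again into a single fused vector per sample, so every modality
   is weighted equally rather than by channel count.
3. **Temporal encoder** — an n-gram over N consecutive samples:
   ``TE_j = SE_j ^ rho(SE_{j-1}) ^ ... ^ rho^{N-1}(SE_{j-N+1})``, where
   ``rho`` is the 1-bit cyclic shift tracking how far in the past a sample
   lies.

A late-fusion variant (one temporal encoder per modality, bundled after) is
provided as a comparison baseline.

Windows whose samples carry more than one class label ("transitionary"
n-grams) straddle a class boundary and can be excluded from training and
testing; windows never cross trial boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .hv_core import Hypervector, bind, bundle, majority, permute
from .provisioning import DatasetLayout, ModalityConfig, ChannelVectorSet, ProvisionedMemory
from .stream import FeatureStream

__all__ = [
    "FeatureSample",
    "NgramWindow",
    "EncodedWindows",
    "project_feature",
    "encode_modality",
    "encode_sample",
    "temporal_encode",
    "stream_encode",
    "stream_encode_late_fusion",
    "spatial_encode_batch",
    "temporal_encode_batch",
]

TieRule = Union[np.ndarray, str, None]


@dataclass(frozen=True)
class FeatureSample:
    """One time sample: per-channel values in [-1, +1] plus identifiers."""

    values: np.ndarray
    sample_index: int = 0
    label: Optional[int] = None
    subject_id: object = None
    trial_id: object = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if np.any(np.abs(self.values) > 1.0):
            raise ValueError("feature values must lie in [-1, +1]")


@dataclass(frozen=True)
class NgramWindow:
    """N consecutive samples of one trial, oldest first."""

    samples: Tuple[FeatureSample, ...]

    def __init__(self, samples: Sequence[FeatureSample]):
        object.__setattr__(self, "samples", tuple(samples))
        if not self.samples:
            raise ValueError("window must contain at least one sample")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def labels(self) -> List[Optional[int]]:
        return [s.label for s in self.samples]

    @property
    def is_transitionary(self) -> bool:
        return len(set(self.labels)) > 1


@dataclass
class EncodedWindows:
    """Temporal-encoded windows with labels and provenance, one row each."""

    vectors: np.ndarray  # (W, D) uint8
    labels: np.ndarray  # (W,) int; -1 marks a transitionary window
    subjects: np.ndarray
    trials: np.ndarray

    def __len__(self) -> int:
        return len(self.vectors)

    def drop_transitionary(self) -> "EncodedWindows":
        keep = self.labels >= 0
        return EncodedWindows(
            self.vectors[keep], self.labels[keep],
            self.subjects[keep], self.trials[keep],
        )

    def as_pairs(self) -> List[Tuple[Hypervector, int]]:
        return [(v, int(l)) for v, l in zip(self.vectors, self.labels)]


# ---------------------------------------------------------------------------
# Single-sample operations
# ---------------------------------------------------------------------------

def project_feature(value: float, cvs: ChannelVectorSet) -> Hypervector:
    """Map one channel value into hyperspace by its sign.

    Non-negative values (zero included) select the positive projection,
    negative values the negative one; the chosen projection is bound to the
    channel's item-memory vector.
    """
    if abs(value) > 1.0:
        raise ValueError(f"feature value {value} outside [-1, +1]")
    fp = cvs.PFP if value >= 0 else cvs.NFP
    return bind(cvs.iM, fp)


def _modality_slice(layout: DatasetLayout, modality: ModalityConfig) -> slice:
    for mod, sl in zip(layout.modalities, layout.channel_slices()):
        if mod == modality or mod.name == getattr(modality, "name", None):
            return sl
    raise ValueError(f"modality {modality!r} not in layout")


def encode_modality(
    sample: FeatureSample,
    modality: ModalityConfig,
    memory: ProvisionedMemory,
    tie_breaker: TieRule = None,
) -> Hypervector:
    """Bundle the per-channel projections of one modality for one sample."""
    sl = _modality_slice(memory.layout, modality)
    vals = sample.values
    if len(vals) != memory.layout.total_channels:
        raise ValueError(
            f"sample has {len(vals)} values, layout expects "
            f"{memory.layout.total_channels}"
        )
    projections = [
        project_feature(vals[i], memory.channel_set(i))
        for i in range(sl.start, sl.stop)
    ]
    return bundle(projections, tie_breaker)


def encode_sample(
    sample: FeatureSample,
    layout: DatasetLayout,
    memory: ProvisionedMemory,
    tie_breaker: TieRule = None,
) -> Hypervector:
    """Early fusion: bundle the per-modality spatial vectors of one sample."""
    per_mod = [
        encode_modality(sample, mod, memory, tie_breaker)
        for mod in layout.modalities
    ]
    if len(per_mod) == 1:
        return per_mod[0]
    return bundle(per_mod, tie_breaker)


def temporal_encode(
    window: NgramWindow,
    layout: DatasetLayout,
    memory: ProvisionedMemory,
    tie_breaker: TieRule = None,
) -> Hypervector:
    """n-gram encode one window: XOR of successively permuted spatial vectors.

    The most recent sample enters unpermuted; a sample ``k`` steps in the
    past is rotated by ``k`` before binding.
    """
    ses = [encode_sample(s, layout, memory, tie_breaker) for s in window.samples]
    te = ses[-1]
    for k in range(1, window.n):
        te = bind(te, permute(ses[-1 - k], k))
    return te


# ---------------------------------------------------------------------------
# Vectorized batch encoding (same math, whole trials at once)
# ---------------------------------------------------------------------------

def spatial_encode_batch(
    values: np.ndarray,
    memory: ProvisionedMemory,
    tie_breaker: TieRule = None,
) -> np.ndarray:
    """Early-fusion spatial encoding of a (S, C) value matrix -> (S, D) bits.

    Row ``j`` equals ``encode_sample`` of sample ``j``; channels enter via
    per-channel majority counts computed with two matrix products against the
    stacked positive/negative projection matrices.
    """
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    layout = memory.layout
    if values.shape[1] != layout.total_channels:
        raise ValueError(
            f"value matrix has {values.shape[1]} channels, layout expects "
            f"{layout.total_channels}"
        )
    if np.any(np.abs(values) > 1.0):
        raise ValueError("feature values must lie in [-1, +1]")
    pos, neg = memory.projection_matrices()
    # float32 is exact here: per-position counts never exceed the channel
    # count, far below the 2**24 integer limit.
    pos_f = pos.astype(np.float32)
    neg_f = neg.astype(np.float32)
    mod_bits = []
    for mod, sl in zip(layout.modalities, layout.channel_slices()):
        sel = (values[:, sl] >= 0).astype(np.float32)
        counts = sel @ pos_f[sl] + (1.0 - sel) @ neg_f[sl]
        counts = np.rint(counts).astype(np.int64)
        mod_bits.append(majority(counts, mod.n_channels, tie_breaker))
    if len(mod_bits) == 1:
        return mod_bits[0]
    counts = np.sum(np.stack(mod_bits, axis=0, dtype=np.int64), axis=0)
    return majority(counts, len(mod_bits), tie_breaker)


def temporal_encode_batch(se: np.ndarray, n: int) -> np.ndarray:
    """All n-gram vectors of a trial's (S, D) spatial encodings.

    Returns (S - n + 1, D); row ``w`` is the temporal encoding of the window
    ending at sample ``w + n - 1``.
    """
    se = np.atleast_2d(np.asarray(se, dtype=np.uint8))
    s = se.shape[0]
    if n < 1:
        raise ValueError("n-gram size must be >= 1")
    if s < n:
        return np.empty((0, se.shape[1]), dtype=np.uint8)
    te = se[n - 1:].copy()
    for k in range(1, n):
        te ^= np.roll(se[n - 1 - k: s - k], k, axis=1)
    return te


# ---------------------------------------------------------------------------
# Stream-level encoding
# ---------------------------------------------------------------------------

def _window_labels(labels: np.ndarray, n: int) -> np.ndarray:
    """Per-window label; -1 where the window mixes labels (transitionary)."""
    s = len(labels)
    if s < n:
        return np.empty(0, dtype=np.int64)
    wins = np.stack([labels[k: s - n + 1 + k] for k in range(n)])
    uniform = np.all(wins == wins[0], axis=0)
    return np.where(uniform, wins[0], -1).astype(np.int64)


def _coerce_stream(stream) -> FeatureStream:
    if isinstance(stream, FeatureStream):
        return stream
    # A plain sequence of FeatureSample: wrap into a single-target table.
    import pandas as pd

    from .stream import META_COLUMNS, channel_columns

    samples = list(stream)
    values = np.stack([s.values for s in samples])
    frame = pd.DataFrame(
        {
            "subject": [s.subject_id if s.subject_id is not None else 0 for s in samples],
            "trial": [s.trial_id if s.trial_id is not None else 0 for s in samples],
            "sample": [s.sample_index for s in samples],
            "label_valence": [s.label if s.label is not None else 0 for s in samples],
            "label_arousal": [s.label if s.label is not None else 0 for s in samples],
        }
    )
    n_ch = values.shape[1]
    frame = pd.concat(
        [frame, pd.DataFrame(values, columns=channel_columns(n_ch))], axis=1
    )
    layout = DatasetLayout([ModalityConfig("all", n_ch)])
    return FeatureStream(layout, frame[META_COLUMNS + channel_columns(n_ch)])


def encode_stream(
    stream,
    n: int,
    memory: ProvisionedMemory,
    target: str = "valence",
    tie_breaker: TieRule = None,
    exclude_transitionary: bool = True,
    fusion: str = "early",
) -> EncodedWindows:
    """Temporal-encode every within-trial window of a feature stream.

    Windows never span trial boundaries (an n-gram mixing two recordings is
    meaningless).  With ``exclude_transitionary`` set, windows whose samples
    carry more than one label of the chosen target are dropped; otherwise
    they are kept with label -1.
    """
    fs = _coerce_stream(stream)
    if fusion not in ("early", "late"):
        raise ValueError(f"fusion must be 'early' or 'late', got {fusion!r}")
    layout = memory.layout
    vecs, labs, subjs, trials = [], [], [], []
    for subj, trial, grp in fs.iter_trials():
        values = grp.iloc[:, 5:].to_numpy(dtype=np.float64)
        labels = grp[f"label_{target}"].to_numpy(dtype=np.int64)
        if len(values) < n:
            continue
        if fusion == "early":
            se = spatial_encode_batch(values, memory, tie_breaker)
            te = temporal_encode_batch(se, n)
        else:
            per_mod = []
            for mod, sl in zip(layout.modalities, layout.channel_slices()):
                sub_mem = _ModalityView(memory, sl, mod)
                se_m = spatial_encode_batch(values[:, sl], sub_mem, tie_breaker)
                per_mod.append(temporal_encode_batch(se_m, n))
            if len(per_mod) == 1:
                te = per_mod[0]
            else:
                counts = np.sum(np.stack(per_mod, axis=0, dtype=np.int64), axis=0)
                te = majority(counts, len(per_mod), tie_breaker)
        wl = _window_labels(labels, n)
        vecs.append(te)
        labs.append(wl)
        subjs.extend([subj] * len(wl))
        trials.extend([trial] * len(wl))
    if not vecs:
        dim = memory.dim
        out = EncodedWindows(
            np.empty((0, dim), dtype=np.uint8),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=object),
            np.empty(0, dtype=object),
        )
    else:
        out = EncodedWindows(
            np.concatenate(vecs),
            np.concatenate(labs),
            np.asarray(subjs, dtype=object),
            np.asarray(trials, dtype=object),
        )
    return out.drop_transitionary() if exclude_transitionary else out


class _ModalityView:
    """Single-modality view of a provisioned memory, for late fusion."""

    def __init__(self, memory: ProvisionedMemory, sl: slice, mod: ModalityConfig):
        self._memory = memory
        self._slice = sl
        self.layout = DatasetLayout([mod])
        self.dim = memory.dim

    def projection_matrices(self):
        pos, neg = self._memory.projection_matrices()
        return pos[self._slice], neg[self._slice]


def stream_encode(
    stream,
    n: int,
    layout: DatasetLayout,
    memory: ProvisionedMemory,
    exclude_transitionary: bool = True,
    target: str = "valence",
    tie_breaker: TieRule = None,
) -> List[Tuple[Hypervector, int]]:
    """Early-fusion stream encoding as (vector, label) pairs."""
    del layout  # carried by the memory; kept in the signature for symmetry
    return encode_stream(
        stream, n, memory, target, tie_breaker, exclude_transitionary, "early"
    ).as_pairs()


def stream_encode_late_fusion(
    stream,
    n: int,
    layout: DatasetLayout,
    memory: ProvisionedMemory,
    exclude_transitionary: bool = True,
    target: str = "valence",
    tie_breaker: TieRule = None,
) -> List[Tuple[Hypervector, int]]:
    """Late-fusion baseline: per-modality temporal encoders, bundled after."""
    del layout
    return encode_stream(
        stream, n, memory, target, tie_breaker, exclude_transitionary, "late"
    ).as_pairs()
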