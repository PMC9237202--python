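"""Synthetic multimodal feature streams with controllable class structure.

Real affect datasets provide, after feature extraction, a table of
per-sample channel values scaled to [-1, +1] with binary valence/arousal
labels per trial.  Since the encoder uses only the *sign* of each value,
the generator plants class signal exactly there: each joint class (one of
the four valence x arousal combinations) owns a fixed random sign prototype
over the channels, and every sample matches its class prototype's sign per
channel independently with probability ``p`` (the separability).  ``p=1``
gives perfectly separable classes; ``p=0.5`` gives pure noise.  Magnitudes
are uniform in (0, 1] and carry no information, mirroring what the
sign-multiplexer encoding can and cannot use.

Labels are assigned per trial by default, balanced across the four joint
classes.  An optional block scheme splits each trial into two label blocks
to create genuine transitionary windows for exercising the exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .provisioning import DatasetLayout, ModalityConfig
from .stream import FeatureStream, META_COLUMNS, channel_columns

__all__ = ["SynthSpec", "make_layout", "generate", "write_stream"]

#: Channel counts of the bundled layout presets.
PRESETS = {
    "amigos_like": [("GSR", 32), ("ECG", 77), ("EEG", 105)],
    "deap_like": [("EMG", 10), ("EEG", 192), ("GSR", 7), ("BVP", 17), ("Respiration", 12)],
}


def make_layout(preset: str = "amigos_like", channels=None) -> DatasetLayout:
    """A named dataset layout.

    ``amigos_like``: 3 modalities (GSR 32, ECG 77, EEG 105), 214 channels.
    ``deap_like``: 5 modalities (EMG 10, EEG 192, GSR 7, BVP 17,
    Respiration 12), 238 channels.  ``custom`` builds from ``channels``, a
    sequence of (name, n_channels) pairs or plain channel counts.
    """
    if preset in PRESETS:
        return DatasetLayout([ModalityConfig(n, k) for n, k in PRESETS[preset]])
    if preset == "custom":
        if not channels:
            raise ValueError("custom layout needs a channels sequence")
        mods = []
        for i, entry in enumerate(channels):
            if isinstance(entry, (tuple, list)):
                mods.append(ModalityConfig(str(entry[0]), int(entry[1])))
            else:
                mods.append(ModalityConfig(f"mod{i + 1}", int(entry)))
        return DatasetLayout(mods)
    raise ValueError(
        f"unknown preset {preset!r}; expected 'amigos_like', 'deap_like' or 'custom'"
    )


@dataclass
class SynthSpec:
    """Recipe for one synthetic stream.

    ``separability`` is the per-channel probability that a sample's sign
    matches its class prototype; it must lie in [0.5, 1.0] (0.5 = chance).
    ``label_scheme`` is ``"per_trial"`` (one label pair per trial) or
    ``"blocks"`` (two consecutive label blocks within each trial, creating
    transitionary windows).
    """

    layout: DatasetLayout
    n_subjects: int = 4
    n_trials_per_subject: int = 8
    samples_per_trial: int = 30
    separability: float = 0.9
    label_scheme: str = "per_trial"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 <= self.separability <= 1.0):
            raise ValueError("separability must lie in [0.5, 1.0]")
        for name in ("n_subjects", "n_trials_per_subject", "samples_per_trial"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.label_scheme not in ("per_trial", "blocks"):
            raise ValueError("label_scheme must be 'per_trial' or 'blocks'")


# The four joint classes, cycled for balance: (valence, arousal).
_JOINT = [(0, 0), (0, 1), (1, 0), (1, 1)]


def generate(spec: SynthSpec) -> FeatureStream:
    """Draw a feature stream according to a :class:`SynthSpec`.

    Deterministic given ``spec.seed``; all values lie in [-1, +1] and are
    nonzero, so sign information is never ambiguous.
    """
    rng = np.random.default_rng(spec.seed)
    C = spec.layout.total_channels
    # One sign prototype in {-1, +1}^C per joint class, fixed for the run.
    prototypes = {
        jc: rng.choice(np.array([-1.0, 1.0]), size=C) for jc in _JOINT
    }
    rows_meta = []
    blocks_values = []
    for s in range(spec.n_subjects):
        # Balanced assignment of joint classes to trials, order shuffled.
        trial_classes = [
            _JOINT[t % 4] for t in range(spec.n_trials_per_subject)
        ]
        rng.shuffle(trial_classes)
        for t, jc in enumerate(trial_classes):
            S = spec.samples_per_trial
            if spec.label_scheme == "blocks":
                # Second half of the trial flips to the complementary class.
                cut = S // 2
                jc2 = (1 - jc[0], 1 - jc[1])
                sample_classes = [jc] * cut + [jc2] * (S - cut)
            else:
                sample_classes = [jc] * S
            proto = np.stack([prototypes[c] for c in sample_classes])
            match = rng.random((S, C)) < spec.separability
            signs = np.where(match, proto, -proto)
            mags = 1.0 - rng.random((S, C))  # uniform in (0, 1]
            blocks_values.append(signs * mags)
            for j, c in enumerate(sample_classes):
                rows_meta.append((s, t, j, c[0], c[1]))
    meta = pd.DataFrame(rows_meta, columns=META_COLUMNS)
    values = pd.DataFrame(np.concatenate(blocks_values), columns=channel_columns(C))
    return FeatureStream(spec.layout, pd.concat([meta, values], axis=1))


def write_stream(stream: FeatureStream, table_path, layout_path) -> None:
    """Write a stream in the pipeline's external format (CSV + JSON layout)."""
    stream.write(table_path, layout_path)
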