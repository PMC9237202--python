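"""Feature-stream container shared by the generator, encoder and pipeline.

A :class:`FeatureStream` is a table of pre-extracted per-sample feature
values, one row per time sample, with subject / trial / sample identifiers
and the two binary affect labels (valence, arousal).  Feature values are
scaled to [-1, +1] upstream; only the sign is used by the encoder, but the
full value is carried so real feature tables can be ingested unchanged.

External format: CSV with header
``subject,trial,sample,label_valence,label_arousal,ch_0001,...`` plus a
JSON layout descriptor (ordered list of ``{name, n_channels}``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Tuple

import numpy as np
import pandas as pd

from .provisioning import DatasetLayout

__all__ = ["FeatureStream", "META_COLUMNS", "channel_columns"]

META_COLUMNS = ["subject", "trial", "sample", "label_valence", "label_arousal"]
TARGETS = ("valence", "arousal")


def channel_columns(n_channels: int) -> list:
    return [f"ch_{i:04d}" for i in range(1, n_channels + 1)]


@dataclass
class FeatureStream:
    """Per-sample channel values in [-1, +1] with labels and identifiers."""

    layout: DatasetLayout
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        expected = META_COLUMNS + channel_columns(self.layout.total_channels)
        got = list(self.frame.columns)
        if got != expected:
            n_ch = len([c for c in got if c.startswith("ch_")])
            raise ValueError(
                f"feature table has {n_ch} channel columns but the layout "
                f"declares {self.layout.total_channels} channels"
            )
        vals = self.values
        bad = np.argwhere(np.abs(vals) > 1.0)
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"feature value {vals[r, c]:g} out of range [-1, +1] at "
                f"row {r} (subject {self.frame['subject'].iat[r]}, "
                f"trial {self.frame['trial'].iat[r]}), channel ch_{c + 1:04d}"
            )

    # -- views -------------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        """Channel values as a float array of shape (n_samples, C)."""
        return self.frame.iloc[:, len(META_COLUMNS):].to_numpy(dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].unique()

    def labels(self, target: str) -> np.ndarray:
        if target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {target!r}")
        return self.frame[f"label_{target}"].to_numpy(dtype=np.int64)

    def iter_trials(self) -> Iterator[Tuple[object, object, pd.DataFrame]]:
        """Yield (subject, trial, sorted rows) for each trial, in table order."""
        for (subj, trial), grp in self.frame.groupby(
            ["subject", "trial"], sort=False
        ):
            yield subj, trial, grp.sort_values("sample")

    def subset_trials(self, keys) -> "FeatureStream":
        """Rows of the listed (subject, trial) pairs, original order kept."""
        keyset = set(map(tuple, keys))
        idx = [
            tuple(t) in keyset
            for t in self.frame[["subject", "trial"]].itertuples(index=False)
        ]
        return FeatureStream(self.layout, self.frame.loc[idx].reset_index(drop=True))

    def subset_subjects(self, subjects) -> "FeatureStream":
        mask = self.frame["subject"].isin(list(subjects))
        return FeatureStream(self.layout, self.frame.loc[mask].reset_index(drop=True))

    def trial_keys(self) -> list:
        return list(
            self.frame[["subject", "trial"]].drop_duplicates().itertuples(index=False, name=None)
        )

    # -- I/O ----------------------------------------------------------------

    def write(self, table_path, layout_path) -> None:
        """Write the CSV feature table and the JSON layout descriptor."""
        self.frame.to_csv(table_path, index=False)
        Path(layout_path).write_text(json.dumps(self.layout.to_dict(), indent=1))

    @classmethod
    def read(cls, table_path, layout_path) -> "FeatureStream":
        layout = DatasetLayout.from_dict(json.loads(Path(layout_path).read_text()))
        frame = pd.read_csv(table_path)
        if list(frame.columns[: len(META_COLUMNS)]) != META_COLUMNS:
            raise ValueError(
                f"malformed header in {table_path}: expected leading columns "
                f"{META_COLUMNS}, got {list(frame.columns[:len(META_COLUMNS)])}"
            )
        return cls(layout, frame)

    def equals(self, other: "FeatureStream") -> bool:
        return self.layout == other.layout and np.allclose(
            self.values, other.values
        ) and self.frame[META_COLUMNS].equals(other.frame[META_COLUMNS])
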