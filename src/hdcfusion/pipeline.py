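"""Evaluation protocols, provisioning reports and model persistence.

Protocols follow affect-recognition practice: leave-one-subject-out
(train on all subjects but one, test on the held-out one) and a per-subject
trial split (train and test within each subject, 80/20 by whole trials).
Trials — never individual samples — are the split unit, so no temporal
n-gram window can straddle the train/test boundary.

Valence and arousal are trained as two independent binary classifiers over
the same encoded windows.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .classifier import AssociativeMemory
from .encoder import EncodedWindows, encode_stream, _window_labels
from .hv_core import Hypervector, random_hypervector
from .provisioning import (
    DatasetLayout,
    ProvisionedMemory,
    STRATEGIES,
    provision,
    request_rate,
    storage_count,
)
from .stream import FeatureStream

__all__ = [
    "RunConfig",
    "read_stream",
    "run_loso",
    "run_split",
    "sweep_dimension",
    "provision_report",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class RunConfig:
    """Everything that determines one training/evaluation run."""

    dim: int = 10_000
    ngram: int = 3
    strategy: str = "unoptimized"
    bank_size: Optional[int] = None
    fusion: str = "early"
    target: str = "both"  # valence | arousal | both
    protocol: str = "loso"  # loso | per_subject_split
    split_fraction: float = 0.8
    seed: int = 0
    exclude_transitionary: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.dim < 100:
            raise ValueError("dimension below 100 is statistically meaningless here")
        if self.dim < 1000:
            warnings.warn(
                f"dimension {self.dim} is small; hypervector pseudo-orthogonality "
                "degrades below ~1000 bits",
                stacklevel=2,
            )
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.fusion not in ("early", "late"):
            raise ValueError("fusion must be 'early' or 'late'")
        if self.target not in ("valence", "arousal", "both"):
            raise ValueError("target must be 'valence', 'arousal' or 'both'")
        if self.protocol not in ("loso", "per_subject_split"):
            raise ValueError("protocol must be 'loso' or 'per_subject_split'")
        if self.ngram < 1:
            raise ValueError("ngram must be >= 1")

    @property
    def targets(self) -> List[str]:
        return ["valence", "arousal"] if self.target == "both" else [self.target]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def read_stream(table_path, layout_path) -> FeatureStream:
    """Read and validate a feature table plus its layout descriptor.

    Rejects out-of-range values and channel-count mismatches with the
    offending row and channel named in the error.
    """
    return FeatureStream.read(table_path, layout_path)


# ---------------------------------------------------------------------------
# Shared encoding machinery
# ---------------------------------------------------------------------------

def _tie_vector(config: RunConfig) -> Hypervector:
    # One fixed tie-breaker per run, from a stream independent of the
    # provisioning draws so neither perturbs the other.
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E]))
    return random_hypervector(config.dim, rng)


def _encode_both_targets(
    stream: FeatureStream,
    config: RunConfig,
    memory: ProvisionedMemory,
    tie: Hypervector,
) -> Dict[str, EncodedWindows]:
    """Encode once, label per target; exclusion applied per target."""
    base = encode_stream(
        stream,
        config.ngram,
        memory,
        target="valence",
        tie_breaker=tie,
        exclude_transitionary=False,
        fusion=config.fusion,
    )
    out: Dict[str, EncodedWindows] = {}
    for target in config.targets:
        if target == "valence":
            labels = base.labels
        else:
            parts = [
                _window_labels(
                    grp[f"label_{target}"].to_numpy(dtype=np.int64), config.ngram
                )
                for _, _, grp in stream.iter_trials()
            ]
            labels = (
                np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
            )
        win = EncodedWindows(base.vectors, labels, base.subjects, base.trials)
        out[target] = (
            win.drop_transitionary() if config.exclude_transitionary else win
        )
    return out


def _fit_eval(
    train_win: EncodedWindows,
    test_win: EncodedWindows,
    config: RunConfig,
    tie: Hypervector,
) -> dict:
    classes = sorted(set(np.unique(train_win.labels).tolist()))
    am = AssociativeMemory(config.dim, tie_breaker=tie, classes=classes)
    am.add_batch(train_win.vectors, train_win.labels)
    pred = am.infer_batch(test_win.vectors)
    correct = pred == test_win.labels
    # Optional per-trial aggregation: majority vote over a trial's windows.
    trial_votes: Dict[Tuple, List[bool]] = {}
    for s, t, lab, p in zip(
        test_win.subjects, test_win.trials, test_win.labels, pred
    ):
        trial_votes.setdefault((s, t), []).append((p, lab))
    trial_hits = []
    for votes in trial_votes.values():
        labs = [l for _, l in votes]
        preds = [p for p, _ in votes]
        maj = max(sorted(set(preds)), key=preds.count)
        trial_hits.append(maj == max(sorted(set(labs)), key=labs.count))
    return {
        "accuracy": float(np.mean(correct)),
        "n_windows": int(len(test_win)),
        "trial_accuracy": float(np.mean(trial_hits)) if trial_hits else float("nan"),
        "n_trials": len(trial_votes),
    }


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def run_loso(stream: FeatureStream, config: RunConfig) -> dict:
    """Leave-one-subject-out evaluation.

    One fold per subject: train on every other subject's windows, test on
    the held-out subject.  The provisioned vectors are identical across
    folds (they depend only on the seed), so folds differ purely in the
    data split.
    """
    subjects = list(stream.subjects)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    memory = provision(
        config.strategy, stream.layout, config.dim, config.seed, config.bank_size
    )
    tie = _tie_vector(config)
    per_target = _encode_both_targets(stream, config, memory, tie)
    report: dict = {"protocol": "loso", "config": config.to_dict(), "targets": {}}
    for target, win in per_target.items():
        folds = []
        for held_out in subjects:
            test_mask = win.subjects == held_out
            train_win = EncodedWindows(
                win.vectors[~test_mask], win.labels[~test_mask],
                win.subjects[~test_mask], win.trials[~test_mask],
            )
            test_win = EncodedWindows(
                win.vectors[test_mask], win.labels[test_mask],
                win.subjects[test_mask], win.trials[test_mask],
            )
            if len(test_win) == 0 or len(train_win) == 0:
                continue
            fold = _fit_eval(train_win, test_win, config, tie)
            fold["subject"] = held_out
            folds.append(fold)
        report["targets"][target] = {
            "folds": folds,
            "mean_accuracy": float(np.mean([f["accuracy"] for f in folds])),
        }
    return report


def run_split(stream: FeatureStream, config: RunConfig) -> dict:
    """Per-subject train/test split by whole trials (default 80/20)."""
    memory = provision(
        config.strategy, stream.layout, config.dim, config.seed, config.bank_size
    )
    tie = _tie_vector(config)
    per_target = _encode_both_targets(stream, config, memory, tie)
    split_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5B]))
    subjects = list(stream.subjects)
    # Choose test trials once per subject; shared by both targets.
    test_keys = set()
    for subj in subjects:
        trials = sorted(
            {t for s, t in stream.trial_keys() if s == subj}
        )
        if len(trials) < 5:
            raise ValueError(
                f"subject {subj!r} has {len(trials)} trials; need >= 5 for a "
                "meaningful train/test split"
            )
        n_test = int(np.clip(round(len(trials) * (1 - config.split_fraction)), 1, len(trials) - 1))
        chosen = split_rng.choice(len(trials), size=n_test, replace=False)
        test_keys.update((subj, trials[i]) for i in chosen)
    report: dict = {
        "protocol": "per_subject_split",
        "config": config.to_dict(),
        "targets": {},
    }
    for target, win in per_target.items():
        key_arr = np.array(
            [(s, t) in test_keys for s, t in zip(win.subjects, win.trials)]
        )
        per_subject = []
        for subj in subjects:
            subj_mask = win.subjects == subj
            train_mask = subj_mask & ~key_arr
            test_mask = subj_mask & key_arr
            if not train_mask.any() or not test_mask.any():
                continue
            train_win = EncodedWindows(
                win.vectors[train_mask], win.labels[train_mask],
                win.subjects[train_mask], win.trials[train_mask],
            )
            test_win = EncodedWindows(
                win.vectors[test_mask], win.labels[test_mask],
                win.subjects[test_mask], win.trials[test_mask],
            )
            entry = _fit_eval(train_win, test_win, config, tie)
            entry["subject"] = subj
            per_subject.append(entry)
        report["targets"][target] = {
            "subjects": per_subject,
            "mean_accuracy": float(
                np.mean([e["accuracy"] for e in per_subject])
            ),
        }
    return report


def run_protocol(stream: FeatureStream, config: RunConfig) -> dict:
    return (
        run_loso(stream, config)
        if config.protocol == "loso"
        else run_split(stream, config)
    )


def mean_accuracy(report: dict) -> float:
    """Grand mean over the report's targets."""
    return float(
        np.mean([t["mean_accuracy"] for t in report["targets"].values()])
    )


def sweep_dimension(
    stream: FeatureStream,
    config: RunConfig,
    dims: Sequence[int],
    strategies: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Repeat the configured protocol per (dimension, strategy).

    Returns one row per combination with the mean accuracy per target.
    Shorter hypervectors shrink the whole datapath but hold less of the
    bundled channel information, so accuracy degrades as dimension falls.
    """
    for d in dims:
        if d < 100:
            raise ValueError("swept dimensions must be >= 100")
    strategies = list(strategies) if strategies is not None else [config.strategy]
    rows = []
    for dim in dims:
        for strat in strategies:
            cfg = RunConfig(**{**config.to_dict(), "dim": dim, "strategy": strat})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                report = run_protocol(stream, cfg)
            row = {"dim": dim, "strategy": strat}
            for target, t in report["targets"].items():
                row[f"accuracy_{target}"] = t["mean_accuracy"]
            row["mean_accuracy"] = mean_accuracy(report)
            rows.append(row)
    return pd.DataFrame(rows)


def provision_report(
    layout: DatasetLayout,
    bank_sizes: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Stored-vector counts and request rates for every strategy.

    Percentage reductions are reported against the unoptimized storage and
    against the pure rule-90 request rate of 1 vector per channel.
    """
    baseline = storage_count("unoptimized", layout)
    rows = []
    for strat in STRATEGIES:
        sizes = (
            list(bank_sizes)
            if strat == "hybrid" and bank_sizes
            else [None]
        )
        for b in sizes:
            stored = storage_count(strat, layout, b)
            rate = request_rate(strat, b if b else 2 * layout.n_modalities + 1) \
                if strat == "hybrid" else request_rate(strat)
            rows.append(
                {
                    "strategy": strat,
                    "bank_size": b if b is not None else (
                        2 * layout.n_modalities + 1 if strat == "hybrid" else pd.NA
                    ),
                    "stored_vectors": stored,
                    "storage_reduction_pct": round(100.0 * (1 - stored / baseline), 2),
                    "request_rate": rate,
                    "request_reduction_pct": (
                        round(100.0 * (1 - rate), 2) if rate > 0 else pd.NA
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def _hv_to_hex(hv: np.ndarray) -> str:
    return np.packbits(np.asarray(hv, dtype=np.uint8)).tobytes().hex()


def _hv_from_hex(s: str, dim: int) -> np.ndarray:
    return np.unpackbits(
        np.frombuffer(bytes.fromhex(s), dtype=np.uint8), count=dim
    ).astype(np.uint8)


def save_model(
    am: AssociativeMemory,
    memory: ProvisionedMemory,
    config: RunConfig,
    path,
) -> None:
    """Persist a trained model: metadata JSON plus hex-encoded prototypes.

    The provisioning seed (and the rule-90 seed vector where one exists) is
    recorded so the channel vectors can be regenerated bit-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": config.to_dict(),
        "dim": am.dim,
        "strategy": memory.strategy,
        "provision_seed": memory.seed,
        "bank_size": memory.bank_size,
        "layout": memory.layout.to_dict(),
        "classes": [int(c) for c in am.classes],
        "tie_breaker": _hv_to_hex(np.asarray(am.tie_breaker, dtype=np.uint8))
        if isinstance(am.tie_breaker, np.ndarray)
        else am.tie_breaker,
        "rule90_seed_vector": (
            _hv_to_hex(memory.rule90_seed_vector)
            if memory.rule90_seed_vector is not None
            else None
        ),
    }
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    protos = {str(c): _hv_to_hex(am.prototype(c)) for c in am.classes}
    (path / "prototypes.json").write_text(json.dumps(protos, indent=1, sort_keys=True))


def load_model(path) -> Tuple[AssociativeMemory, ProvisionedMemory, RunConfig]:
    """Load a persisted model; inferences are bit-identical to pre-save."""
    path = Path(path)
    meta = json.loads((path / "metadata.json").read_text())
    if meta.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"incompatible model format version {meta.get('format_version')!r}; "
            f"expected {MODEL_FORMAT_VERSION}"
        )
    config = RunConfig.from_dict(meta["config"])
    dim = meta["dim"]
    if config.dim != dim:
        raise ValueError(
            f"model dimension {dim} does not match its config dimension {config.dim}"
        )
    protos = json.loads((path / "prototypes.json").read_text())
    tie = meta["tie_breaker"]
    if isinstance(tie, str) and set(tie) <= set("0123456789abcdef") and len(tie) > 8:
        tie = _hv_from_hex(tie, dim)
    am = AssociativeMemory(dim, tie_breaker=tie, classes=meta["classes"])
    for c in meta["classes"]:
        hv = _hv_from_hex(protos[str(c)], dim)
        if hv.shape[-1] != dim:
            raise ValueError("prototype length does not match model dimension")
        am.add(hv, c)
    layout = DatasetLayout.from_dict(meta["layout"])
    memory = provision(
        meta["strategy"], layout, dim, meta["provision_seed"], meta["bank_size"]
    )
    return am, memory, config
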