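"""Shared in-memory containers for the workload-estimation pipeline.

The pipeline moves data through three representations:

``Recording``
    A continuous multichannel EEG/EOG signal (microvolts) plus the event
    schedule of the n-back protocol (letter onsets, target flags, block,
    workload level, affective context).

``EpochSet``
    Letter-locked trials (trials x channels x samples) with per-trial
    labels.  All feature branches consume this.

``FeatureMatrix``
    Trials x features with per-feature provenance (which branch, band,
    spatial filter or time sample each column came from) and the trial
    labels carried along.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "Recording",
    "EpochSet",
    "FeatureMatrix",
    "EVENT_COLUMNS",
]


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented contract."""


#: canonical column order of the event table / TSV sidecar
EVENT_COLUMNS = ["onset_sample", "letter", "is_target", "block", "workload", "context"]

WORKLOAD_LEVELS = ("low", "high")
CONTEXTS = ("relax", "stress")


@dataclass
class Recording:
    """Continuous multichannel recording in microvolts with an event table.

    Parameters
    ----------
    signal
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channel_labels
        One label per channel.
    channel_roles
        Per-channel role, ``"EEG"`` or ``"EOG"``.
    sampling_rate
        Sampling rate in Hz.
    events
        DataFrame with columns ``onset_sample, letter, is_target, block,
        workload, context`` -- one row per presented letter.
    """

    signal: np.ndarray
    channel_labels: list[str]
    channel_roles: list[str]
    sampling_rate: float
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        n_ch = self.signal.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_roles) != n_ch:
            raise ValueError("channel_labels/channel_roles length mismatch")
        bad = set(self.channel_roles) - {"EEG", "EOG"}
        if bad:
            raise ValueError(f"unknown channel roles: {sorted(bad)}")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"events table missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EEG" for r in self.channel_roles])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EOG" for r in self.channel_roles])

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            sampling_rate=self.sampling_rate,
            events=self.events.copy(),
        )


@dataclass
class EpochSet:
    """Letter-locked trials with per-trial labels (EEG channels only).

    ``data`` has shape ``(n_trials, n_channels, n_samples)``; every label
    array has length ``n_trials``.  ``half`` marks whether a trial's block
    lies in the first or second six-block half of its affective context.
    """

    data: np.ndarray
    sampling_rate: float
    workload: np.ndarray
    context: np.ndarray
    block: np.ndarray
    half: np.ndarray
    is_target: np.ndarray
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        n = self.data.shape[0]
        for name in ("workload", "context", "block", "half", "is_target"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"label '{name}' must have length {n}")
            setattr(self, name, arr)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, index: np.ndarray) -> "EpochSet":
        """Return the sub-set of trials given by boolean mask or indices."""
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            sampling_rate=self.sampling_rate,
            workload=self.workload[index],
            context=self.context[index],
            block=self.block[index],
            half=self.half[index],
            is_target=self.is_target[index],
            channel_labels=list(self.channel_labels),
        )

    def with_data(self, data: np.ndarray, sampling_rate: float | None = None) -> "EpochSet":
        """Same labels, new signal content (used by filtering steps)."""
        return EpochSet(
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            workload=self.workload,
            context=self.context,
            block=self.block,
            half=self.half,
            is_target=self.is_target,
            channel_labels=list(self.channel_labels),
        )

    # -- serialization: binary container (npz) with a JSON label header ----
    def save(self, path: str | Path) -> None:
        header = {
            "sampling_rate": self.sampling_rate,
            "channel_labels": list(self.channel_labels),
        }
        np.savez_compressed(
            path,
            data=self.data,
            workload=self.workload.astype(str),
            context=self.context.astype(str),
            block=self.block.astype(int),
            half=self.half.astype(int),
            is_target=self.is_target.astype(bool),
            header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EpochSet":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(bytes(z["header"]).decode())
            return cls(
                data=z["data"],
                sampling_rate=header["sampling_rate"],
                workload=z["workload"],
                context=z["context"],
                block=z["block"],
                half=z["half"],
                is_target=z["is_target"],
                channel_labels=header["channel_labels"],
            )


@dataclass
class FeatureMatrix:
    """Trials x features with per-feature provenance and trial labels.

    ``provenance`` holds one record per column, e.g.
    ``{"branch": "fb", "band": "alpha", "filter": 3}`` for the oscillatory
    branch or ``{"branch": "erp", "filter": 1, "sample": 17}`` for the ERP
    branch.
    """

    values: np.ndarray
    provenance: list[dict]
    workload: np.ndarray
    context: np.ndarray
    block: np.ndarray
    half: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (trials x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.provenance) != self.values.shape[1]:
            raise ValueError("provenance length must equal feature count")
        n = self.values.shape[0]
        for name in ("workload", "context", "block", "half"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"label '{name}' must have length {n}")
            setattr(self, name, arr)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_trials(self, index: np.ndarray) -> "FeatureMatrix":
        index = np.asarray(index)
        return FeatureMatrix(
            values=self.values[index],
            provenance=list(self.provenance),
            workload=self.workload[index],
            context=self.context[index],
            block=self.block[index],
            half=self.half[index],
        )

    def select_columns(self, columns: np.ndarray) -> "FeatureMatrix":
        columns = np.asarray(columns)
        return FeatureMatrix(
            values=self.values[:, columns],
            provenance=[self.provenance[int(c)] for c in columns],
            workload=self.workload,
            context=self.context,
            block=self.block,
            half=self.half,
        )

    def to_csv(self, path: str | Path) -> None:
        """Write features to CSV with provenance header columns.

        Columns carry a three-level header ``(branch, band-or-filter,
        filter-or-sample)``; trial labels are written as leading columns.
        """
        keys = ("branch", "band", "filter", "sample")
        cols = []
        for p in self.provenance:
            cols.append(tuple(str(p.get(k, "")) for k in keys))
        frame = pd.DataFrame(self.values, columns=pd.MultiIndex.from_tuples(cols, names=keys))
        labels = pd.DataFrame(
            {
                ("workload", "", "", ""): self.workload,
                ("context", "", "", ""): self.context,
                ("block", "", "", ""): self.block,
                ("half", "", "", ""): self.half,
            }
        )
        pd.concat([labels, frame], axis=1).to_csv(path, index=False)


def concat_features(first: FeatureMatrix, second: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation; trial labels must agree."""
    if first.n_trials != second.n_trials:
        raise ValueError(
            f"trial-count mismatch: {first.n_trials} vs {second.n_trials}"
        )
    if not (np.array_equal(first.workload, second.workload)
            and np.array_equal(first.block, second.block)):
        raise ValueError("trial labels of the two feature blocks disagree")
    return FeatureMatrix(
        values=np.hstack([first.values, second.values]),
        provenance=list(first.provenance) + list(second.provenance),
        workload=first.workload,
        context=first.context,
        block=first.block,
        half=first.half,
    )
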