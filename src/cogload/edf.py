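"""Minimal EDF writing and reading for simulated recordings.

Signals are stored as plain 16-bit EDF (one-second data records, physical
units microvolts); the event schedule travels in a TSV sidecar with columns
``onset_s letter is_target block workload context`` (onsets in seconds,
sample-aligned, 0-based).  MNE reads the EDF files produced here.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EVENT_COLUMNS, Recording

__all__ = ["write_recording", "read_recording", "events_to_tsv", "events_from_tsv"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("ascii", errors="replace")[:width]
    return raw + b" " * (width - len(raw))


def write_edf(path: str | Path, signal: np.ndarray, labels: list[str],
              sampling_rate: int, physical_dim: str = "uV") -> None:
    """Write ``signal`` (channels x samples, microvolts) as 16-bit EDF."""
    sampling_rate = int(sampling_rate)
    n_ch, n_samp = signal.shape
    n_records = int(np.ceil(n_samp / sampling_rate))
    padded = np.zeros((n_ch, n_records * sampling_rate))
    padded[:, :n_samp] = signal

    # symmetric physical range per channel so that 0 uV maps to digital 0
    phys_max = np.maximum(np.abs(padded).max(axis=1), 1.0) * 1.0001
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))                       # version
        fh.write(_pad("X X X X", 80))                # patient id (anonymous)
        fh.write(_pad("Startdate X X X X", 80))      # recording id
        fh.write(_pad("01.01.00", 8))                # start date
        fh.write(_pad("00.00.00", 8))                # start time
        fh.write(_pad(str(256 * (n_ch + 1)), 8))     # header byte count
        fh.write(_pad("", 44))                       # reserved
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))                       # record duration (s)
        fh.write(_pad(str(n_ch), 4))
        for lab in labels:
            fh.write(_pad(lab, 16))
        fh.write(b" " * 80 * n_ch)                   # transducer
        for _ in range(n_ch):
            fh.write(_pad(physical_dim, 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(_DIG_MAX), 8))
        fh.write(b" " * 80 * n_ch)                   # prefiltering
        for _ in range(n_ch):
            fh.write(_pad(str(sampling_rate), 8))
        fh.write(b" " * 32 * n_ch)                   # reserved
        # data records: per record, all samples of ch 0, then ch 1, ...
        rec = digital.reshape(n_ch, n_records, sampling_rate)
        np.ascontiguousarray(rec.transpose(1, 0, 2)).tofile(fh)


def events_to_tsv(events: pd.DataFrame, path: str | Path, sampling_rate: float) -> None:
    out = pd.DataFrame(
        {
            "onset_s": events["onset_sample"] / sampling_rate,
            "letter": events["letter"],
            "is_target": events["is_target"].astype(int),
            "block": events["block"],
            "workload": events["workload"],
            "context": events["context"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def events_from_tsv(path: str | Path, sampling_rate: float) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    events = pd.DataFrame(
        {
            "onset_sample": np.round(table["onset_s"] * sampling_rate).astype(int),
            "letter": table["letter"],
            "is_target": table["is_target"].astype(bool),
            "block": table["block"].astype(int),
            "workload": table["workload"],
            "context": table["context"],
        }
    )
    return events[EVENT_COLUMNS]


def write_recording(recording: Recording, directory: str | Path, stem: str = "session") -> tuple[Path, Path]:
    """Write one recording as ``<stem>.edf`` + ``<stem>_events.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    edf_path = directory / f"{stem}.edf"
    tsv_path = directory / f"{stem}_events.tsv"
    write_edf(edf_path, recording.signal, recording.channel_labels,
              int(recording.sampling_rate))
    events_to_tsv(recording.events, tsv_path, recording.sampling_rate)
    return edf_path, tsv_path


def read_recording(edf_path: str | Path, tsv_path: str | Path | None = None) -> Recording:
    """Read an EDF + TSV sidecar pair back into a :class:`Recording`.

    Channel roles are inferred from labels: channels named ``EOG*`` are
    ocular, everything else is EEG.
    """
    import mne

    edf_path = Path(edf_path)
    if tsv_path is None:
        tsv_path = edf_path.with_name(edf_path.stem + "_events.tsv")
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE returns volts; containers use uV
    labels = list(raw.ch_names)
    roles = ["EOG" if lab.upper().startswith("EOG") else "EEG" for lab in labels]
    rate = float(raw.info["sfreq"])
    events = events_from_tsv(tsv_path, rate)
    return Recording(
        signal=signal,
        channel_labels=labels,
        channel_roles=roles,
        sampling_rate=rate,
        events=events,
    )
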