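"""EOG cleaning, letter-locked epoching, and target-trial exclusion.

The cleaning step removes ocular contamination by regressing every EEG
channel on all EOG channels (coefficients from the channel cross-covariances
over the full recording) and subtracting the fitted combination.  Epoching
cuts one 2-s trial per presented letter, starting at letter onset, keeping
EEG channels only.  Trials on target letters are discarded downstream so
that target-evoked potentials (P300) cannot confound workload decoding.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import EpochSet, Recording

logger = logging.getLogger(__name__)

__all__ = ["remove_eog", "segment_epochs", "discard_targets"]


def remove_eog(recording: Recording) -> Recording:
    """Subtract the least-squares EOG combination from every EEG channel.

    Coefficients ``B = C_eeg,eog @ C_eog,eog^-1`` are estimated once from
    the mean-centered cross-covariances over the full recording.  EOG
    channels are retained unmodified; shapes are unchanged.
    """
    eeg_idx = recording.eeg_indices
    eog_idx = recording.eog_indices
    if eog_idx.size == 0:
        raise ValueError("recording has no EOG channels to regress out")
    if eeg_idx.size == 0:
        raise ValueError("recording has no EEG channels to clean")

    eeg = recording.signal[eeg_idx]
    eog = recording.signal[eog_idx]
    eog_c = eog - eog.mean(axis=1, keepdims=True)
    eeg_c = eeg - eeg.mean(axis=1, keepdims=True)
    n = eog.shape[1]
    c_oo = eog_c @ eog_c.T / n
    c_eo = eeg_c @ eog_c.T / n

    eigvals = np.linalg.eigvalsh(c_oo)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        degenerate = _degenerate_channels(c_oo, [recording.channel_labels[i] for i in eog_idx])
        raise ValueError(
            "EOG covariance is rank deficient; degenerate channels: "
            + ", ".join(degenerate)
        )
    coeffs = np.linalg.solve(c_oo, c_eo.T).T  # (n_eeg, n_eog)
    logger.debug("EOG regression coefficient range: [%.3g, %.3g]",
                 coeffs.min(), coeffs.max())

    cleaned = recording.copy()
    cleaned.signal[eeg_idx] = eeg - coeffs @ eog_c
    return cleaned


def _degenerate_channels(cov: np.ndarray, labels: list[str]) -> list[str]:
    """Name channels responsible for a rank-deficient covariance: zero
    variance, or perfectly correlated with an earlier channel."""
    bad = []
    var = np.diag(cov)
    for i, v in enumerate(var):
        if v <= 1e-12 * max(var.max(), 1.0):
            bad.append(labels[i])
    good = [i for i in range(len(labels)) if labels[i] not in bad]
    for pos, i in enumerate(good):
        for j in good[:pos]:
            r = cov[i, j] / np.sqrt(var[i] * var[j])
            if abs(r) > 1.0 - 1e-10:
                bad.append(labels[i])
                break
    return bad or list(labels)


def _half_labels(events_block: np.ndarray, events_context: np.ndarray) -> np.ndarray:
    """Half = 1 for a context's first half of blocks (first six in the full
    protocol), 2 for the rest, assigned per trial from its block."""
    half = np.zeros(len(events_block), dtype=int)
    for context in np.unique(events_context):
        mask = events_context == context
        blocks = np.unique(events_block[mask])
        first = set(blocks[: int(np.ceil(blocks.size / 2))])
        half[mask] = [1 if b in first else 2 for b in events_block[mask]]
    return half


def segment_epochs(recording: Recording, duration_s: float = 2.0) -> EpochSet:
    """Cut one trial per event: ``[onset, onset + duration)``, EEG only."""
    fs = recording.sampling_rate
    n_samp = int(round(duration_s * fs))
    eeg_idx = recording.eeg_indices
    onsets = recording.events["onset_sample"].to_numpy()
    ends = onsets + n_samp
    too_long = np.flatnonzero(ends > recording.n_samples)
    if too_long.size:
        i = int(too_long[0])
        raise ValueError(
            f"event {i} (onset sample {onsets[i]}) is truncated: needs "
            f"{ends[i]} samples but the recording has {recording.n_samples}"
        )
    data = np.stack([recording.signal[eeg_idx, s:s + n_samp] for s in onsets])
    ev = recording.events
    return EpochSet(
        data=data,
        sampling_rate=fs,
        workload=ev["workload"].to_numpy(),
        context=ev["context"].to_numpy(),
        block=ev["block"].to_numpy(),
        half=_half_labels(ev["block"].to_numpy(), ev["context"].to_numpy()),
        is_target=ev["is_target"].to_numpy(),
        channel_labels=[recording.channel_labels[i] for i in eeg_idx],
    )


def discard_targets(epochs: EpochSet) -> EpochSet:
    """Drop target-letter trials (order otherwise preserved)."""
    keep = ~epochs.is_target.astype(bool)
    if keep.all():
        return epochs
    return epochs.select(np.flatnonzero(keep))
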