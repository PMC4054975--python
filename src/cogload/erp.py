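"""ERP branch: low-frequency filtering, 36 Hz resampling, Fisher spatial
filters, and sample-level features.

Trials are band-pass filtered 0.5-16 Hz (zero phase), resampled to 36 Hz by
polyphase rational resampling (the 16 Hz low-pass doubling as the
anti-alias filter), and truncated to the first second after letter onset:
36 samples per channel.  Regularized Fisher Spatial Filters then maximize
the Fisher criterion of the per-sample class means: every time sample of
every trial is treated as a channel-space observation labeled with the
trial's workload class; the between-class scatter sums the outer products
of the per-sample class-mean differences and the within-class scatter sums
the residual outer products.  The within-class scatter is regularized as

    (1 - lambda) * S_w + lambda * (trace(S_w) / n_channels) * I,

with lambda = 0.4 by default.  The six leading generalized eigenvectors
give 6 spatially filtered 36-sample time courses per trial: 216 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import linalg, signal as sps

from .containers import ConfigError, EpochSet, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["FsfModel", "preprocess_erp", "fit_fsf", "extract_erp_features"]

ERP_BAND = (0.5, 16.0)   # Hz
ERP_RATE = 36            # Hz after resampling
ERP_WINDOW_S = 1.0       # analysis window after letter onset


@dataclass
class FsfModel:
    """Fisher spatial filters: ``filters`` is ``(n_filters, n_channels)``
    with rows ordered by descending Fisher criterion, unit-norm and
    sign-canonicalized; ``lam`` is the shrinkage weight used."""

    filters: np.ndarray
    lam: float
    fisher_values: np.ndarray

    def to_dict(self) -> dict:
        return {
            "filters": self.filters.tolist(),
            "lambda": self.lam,
            "fisher_values": self.fisher_values.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FsfModel":
        return cls(
            filters=np.asarray(d["filters"], dtype=float),
            lam=float(d["lambda"]),
            fisher_values=np.asarray(d["fisher_values"], dtype=float),
        )


def preprocess_erp(epochs: EpochSet) -> EpochSet:
    """Filter 0.5-16 Hz, resample to 36 Hz, keep the first second."""
    fs = epochs.sampling_rate
    if fs < 2 * ERP_BAND[1] * 2.25:  # need headroom for 16 Hz content at 36 Hz
        raise ConfigError(
            f"sampling rate {fs} Hz is too low for the ERP branch (need >= 72 Hz)"
        )
    sos = sps.butter(4, list(ERP_BAND), btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, epochs.data, axis=-1)
    ratio = Fraction(ERP_RATE, int(round(fs))).limit_denominator(10000)
    resampled = sps.resample_poly(filtered, ratio.numerator, ratio.denominator,
                                  axis=-1)
    n_keep = int(round(ERP_RATE * ERP_WINDOW_S))
    return epochs.with_data(resampled[..., :n_keep], sampling_rate=float(ERP_RATE))


def _scatter_matrices(data: np.ndarray, workload: np.ndarray):
    """Between/within-class scatter over channel-space sample observations."""
    classes = np.unique(workload)
    if classes.size != 2:
        raise ValueError("FSF needs exactly two workload classes present")
    means = {c: data[workload == c].mean(axis=0) for c in classes}  # (C, S)
    diff = means[classes[1]] - means[classes[0]]
    s_b = diff @ diff.T
    s_w = np.zeros((data.shape[1], data.shape[1]))
    for c in classes:
        resid = data[workload == c] - means[c]
        s_w += np.einsum("ncs,nds->cd", resid, resid)
    return s_b, s_w


def _canonicalize(vectors: np.ndarray) -> np.ndarray:
    rows = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    flip = np.take_along_axis(
        rows, np.abs(rows).argmax(axis=1, keepdims=True), axis=1
    ) < 0
    rows[flip[:, 0]] *= -1.0
    return rows


def fit_fsf(erp_epochs: EpochSet, lam: float = 0.4, n_filters: int = 6) -> FsfModel:
    """Fit regularized Fisher spatial filters on 36-sample epochs."""
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(f"lambda must lie in [0, 1], got {lam}")
    classes, counts = np.unique(erp_epochs.workload, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("FSF needs >= 2 trials in each workload class")
    s_b, s_w = _scatter_matrices(erp_epochs.data, erp_epochs.workload)
    n_channels = s_w.shape[0]
    s_reg = (1.0 - lam) * s_w + lam * (np.trace(s_w) / n_channels) * np.eye(n_channels)
    try:
        linalg.cholesky(s_reg)
    except linalg.LinAlgError as exc:
        raise ValueError(
            "regularized within-class scatter is singular; use lambda > 0"
        ) from exc
    eigvals, eigvecs = linalg.eigh(s_b, s_reg)
    order = np.argsort(eigvals)[::-1][:n_filters]
    filters = _canonicalize(eigvecs[:, order].T)
    return FsfModel(filters=filters, lam=lam,
                    fisher_values=np.maximum(eigvals[order], 0.0))


def extract_erp_features(erp_epochs: EpochSet, model: FsfModel) -> FeatureMatrix:
    """Concatenated spatially filtered time courses (filter-major,
    sample-minor) with ``(branch='erp', filter, sample)`` provenance."""
    if model.filters.shape[1] != erp_epochs.n_channels:
        raise ValueError(
            f"model expects {model.filters.shape[1]} channels, epochs have "
            f"{erp_epochs.n_channels}"
        )
    projected = np.einsum("fc,ncs->nfs", model.filters, erp_epochs.data)
    n_trials = erp_epochs.n_trials
    n_filters, n_samples = model.filters.shape[0], erp_epochs.n_samples
    values = projected.reshape(n_trials, n_filters * n_samples)
    provenance = [
        {"branch": "erp", "filter": f, "sample": s}
        for f in range(n_filters)
        for s in range(n_samples)
    ]
    return FeatureMatrix(
        values=values,
        provenance=provenance,
        workload=erp_epochs.workload,
        context=erp_epochs.context,
        block=erp_epochs.block,
        half=erp_epochs.half,
    )
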