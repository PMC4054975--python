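"""Oscillatory branch: filter bank, CSP spatial filters, log-power features.

Each trial is band-pass filtered into the six classical rhythms
(delta 1-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-47, high gamma
53-90 Hz).  Per band, Common Spatial Patterns maximize the variance ratio
between the two workload classes: with class-average trial covariances
``C_low`` and ``C_high`` (each trial covariance trace-normalized first),
the filters solve the generalized eigenproblem

    C_high w = lambda (C_high + C_low) w,   lambda in [0, 1],

and the six filters with the largest plus the six with the smallest
eigenvalues are kept (6 pairs = 12 filters per band).  Features are the
log-variance of each spatially filtered trial: 6 bands x 12 filters = 72
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal as sps

from .containers import ConfigError, EpochSet, FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "CspModel",
    "default_filter_bank",
    "apply_filter_bank",
    "fit_csp",
    "extract_fbcsp_features",
]

_DEFAULT_BANK = [
    ("delta", 1.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 12.0),
    ("beta", 12.0, 30.0),
    ("gamma", 30.0, 47.0),
    ("gamma2", 53.0, 90.0),
]

_FILTER_ORDER = 4  # Butterworth, applied forward-backward (zero phase)


@dataclass(frozen=True)
class BandSpec:
    """One band of the filter bank."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not self.low_hz < self.high_hz:
            raise ConfigError(f"band {self.name}: low_hz must be < high_hz")


def default_filter_bank() -> list[BandSpec]:
    """The six classical rhythm bands."""
    return [BandSpec(name, lo, hi) for name, lo, hi in _DEFAULT_BANK]


@dataclass
class CspModel:
    """Fitted CSP filters for one band.

    ``filters`` has shape ``(2 * n_pairs, n_channels)``: the ``n_pairs``
    largest-eigenvalue filters (descending) followed by the ``n_pairs``
    smallest (ascending).  Rows are unit-norm with the largest-magnitude
    coefficient positive.  ``eigenvalues`` holds the matching discriminability
    values in [0, 1] (share of high-workload variance captured).
    """

    band: BandSpec
    filters: np.ndarray
    eigenvalues: np.ndarray
    n_pairs: int = 6

    def to_dict(self) -> dict:
        return {
            "band": {"name": self.band.name, "low_hz": self.band.low_hz,
                     "high_hz": self.band.high_hz},
            "filters": self.filters.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "n_pairs": self.n_pairs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CspModel":
        return cls(
            band=BandSpec(**d["band"]),
            filters=np.asarray(d["filters"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            n_pairs=int(d["n_pairs"]),
        )


def bandpass_sos(low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    nyquist = fs / 2.0
    if high_hz >= nyquist:
        raise ConfigError(
            f"band edge {high_hz} Hz is at or above Nyquist ({nyquist} Hz)"
        )
    return sps.butter(_FILTER_ORDER, [low_hz, high_hz], btype="bandpass",
                      fs=fs, output="sos")


def apply_filter_bank(
    epochs: EpochSet, bands: list[BandSpec] | None = None
) -> dict[str, EpochSet]:
    """Zero-phase band-pass filter the epochs into every band of the bank."""
    if bands is None:
        bands = default_filter_bank()
    out: dict[str, EpochSet] = {}
    for band in bands:
        sos = bandpass_sos(band.low_hz, band.high_hz, epochs.sampling_rate)
        out[band.name] = epochs.with_data(sps.sosfiltfilt(sos, epochs.data, axis=-1))
    return out


# ---------------------------------------------------------------------------
# CSP fitting
# ---------------------------------------------------------------------------

def trial_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial channel covariance, mean-subtracted, normalized by the
    sample count: shape ``(n_trials, n_channels, n_channels)``."""
    centered = data - data.mean(axis=-1, keepdims=True)
    return np.einsum("ncs,nds->ncd", centered, centered) / data.shape[-1]


def _canonicalize(vectors: np.ndarray) -> np.ndarray:
    """Rows scaled to unit norm with the largest-magnitude entry positive."""
    rows = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    flip = np.take_along_axis(
        rows, np.abs(rows).argmax(axis=1, keepdims=True), axis=1
    ) < 0
    rows[flip[:, 0]] *= -1.0
    return rows


def _class_mean_covs(covs: np.ndarray, workload: np.ndarray, normalize: str):
    classes = np.unique(workload)
    if classes.size < 2:
        raise ValueError("CSP needs trials from both workload classes")
    if normalize == "trace":
        traces = np.trace(covs, axis1=1, axis2=2)
        covs = covs / traces[:, None, None]
    elif normalize != "none":
        raise ConfigError(f"unknown covariance normalization {normalize!r}")
    c_low = covs[workload == "low"].mean(axis=0)
    c_high = covs[workload == "high"].mean(axis=0)
    return c_low, c_high


def fit_csp(
    band_epochs: EpochSet | None,
    n_pairs: int = 6,
    band: BandSpec | None = None,
    *,
    trial_covs: np.ndarray | None = None,
    workload: np.ndarray | None = None,
    normalize: str = "trace",
) -> CspModel:
    """Fit CSP filters on one band's epochs.

    ``trial_covs``/``workload`` allow fitting from precomputed per-trial
    covariances (identical result, used by the evaluation loop to avoid
    recomputing covariances per fold).  ``normalize='trace'`` (default)
    trace-normalizes every trial covariance before class averaging so that
    high-amplitude trials cannot dominate; ``'none'`` skips it, which makes
    the eigenvalues exactly invariant under any invertible channel mixing
    (with trace normalization this holds only for orthogonal mixings, which
    preserve traces).
    """
    if trial_covs is None:
        if band_epochs is None:
            raise ValueError("either band_epochs or trial_covs is required")
        trial_covs = trial_covariances(band_epochs.data)
        workload = band_epochs.workload
    if workload is None:
        raise ValueError("workload labels are required with trial_covs")
    classes, counts = np.unique(workload, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("CSP needs >= 2 trials in each workload class")
    n_channels = trial_covs.shape[1]
    if n_channels < 2 * n_pairs:
        raise ValueError(
            f"{n_channels} channels cannot supply {n_pairs} CSP pairs"
        )
    c_low, c_high = _class_mean_covs(trial_covs, np.asarray(workload), normalize)
    pooled = c_low + c_high
    pooled_eigs = linalg.eigvalsh(pooled)
    if pooled_eigs[0] <= 1e-10 * max(pooled_eigs[-1], np.finfo(float).tiny):
        raise ValueError(
            "pooled class covariance is singular; consider regularizing the "
            "covariance estimates or reducing the channel count"
        )
    eigvals, eigvecs = linalg.eigh(c_high, pooled)  # ascending in [0, 1]
    top = eigvecs[:, -n_pairs:][:, ::-1].T      # largest, descending
    bottom = eigvecs[:, :n_pairs].T             # smallest, ascending
    filters = _canonicalize(np.vstack([top, bottom]))
    eigenvalues = np.concatenate([eigvals[-n_pairs:][::-1], eigvals[:n_pairs]])
    if band is None:
        band = BandSpec("unspecified", 0.0, 0.5)
    return CspModel(band=band, filters=filters, eigenvalues=eigenvalues,
                    n_pairs=n_pairs)


def log_variance_features(filters: np.ndarray, *, data: np.ndarray | None = None,
                          trial_covs: np.ndarray | None = None) -> np.ndarray:
    """Log-variance of the spatially filtered trials, from raw epochs or the
    equivalent quadratic form on precomputed trial covariances."""
    if trial_covs is not None:
        var = np.einsum("fc,ncd,fd->nf", filters, trial_covs, filters)
    elif data is not None:
        projected = np.einsum("fc,ncs->nfs", filters, data)
        var = projected.var(axis=-1)
    else:
        raise ValueError("either data or trial_covs is required")
    return np.log(np.maximum(var, np.finfo(float).tiny))


def extract_fbcsp_features(
    band_epochs: dict[str, EpochSet], models: dict[str, CspModel]
) -> FeatureMatrix:
    """Log-power features, ordered band-major / filter-minor, with
    ``(branch='fb', band, filter)`` provenance per column."""
    if set(band_epochs) != set(models):
        raise ValueError(
            f"band/model mismatch: epochs have {sorted(band_epochs)}, "
            f"models have {sorted(models)}"
        )
    blocks, provenance = [], []
    reference = None
    for name in band_epochs:
        ep = band_epochs[name]
        reference = reference or ep
        model = models[name]
        if model.filters.shape[1] != ep.n_channels:
            raise ValueError(f"band {name}: model channel count mismatch")
        blocks.append(log_variance_features(model.filters, data=ep.data))
        provenance += [{"branch": "fb", "band": name, "filter": j}
                       for j in range(model.filters.shape[0])]
    values = np.hstack(blocks)
    return FeatureMatrix(
        values=values,
        provenance=provenance,
        workload=reference.workload,
        context=reference.context,
        block=reference.block,
        half=reference.half,
    )
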