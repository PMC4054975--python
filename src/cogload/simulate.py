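"""Synthetic n-back EEG study generator.

Emulates the event structure of a two-context workload protocol: in each
affective context (relaxation vs. psychosocial stress) the subject performs
12 alternating two-minute n-back blocks (six 0-back = low workload, six
2-back = high workload).  Each block presents 60 letters for 500 ms at a
2-s pitch (1500 ms inter-stimulus interval); 25% of letters are targets.

The signal model is deliberately simple and fully controllable:

* one stationary band-limited Gaussian source per classical EEG rhythm
  (delta, theta, alpha, beta, gamma, high gamma), obtained by band-pass
  filtering white noise and spatially mixed through a seeded random
  orthonormal forward matrix;
* workload scales the source variances via ``band_power_effects`` (power
  ratio high/low) and the affective context scales them via
  ``context_shift`` (power ratio stress/relax), planting a class effect and
  a class-independent nonstationarity respectively;
* an event-locked biphasic ERP waveform (positive deflection around 300 ms
  after letter onset) on a fixed centro-parietal channel subset, whose
  amplitude differs between workload levels by ``erp_amplitude_effect``;
* EOG channels carrying blink-like transients that leak into frontal EEG
  channels with fixed known coefficients, plus white sensor noise.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .containers import ConfigError, Recording

logger = logging.getLogger(__name__)

__all__ = ["SynthConfig", "generate_session", "generate_study"]

#: 10/20-style montage of 28 EEG channels (no T7/T8/Fp1/Fp2) + 4 EOG
EEG_LABELS_28 = [
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "C3", "Cz", "C4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4",
    "O1", "O2",
]
EOG_LABELS_4 = ["EOG1", "EOG2", "EOG3", "EOG4"]

#: classical rhythm band edges in Hz, shared with the oscillatory branch
BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 47.0),
    "gamma2": (53.0, 90.0),
}

#: resting amplitude (uV RMS at the source) of each band-limited source
_BASE_SOURCE_SD = {
    "delta": 6.0,
    "theta": 5.0,
    "alpha": 8.0,
    "beta": 4.0,
    "gamma": 2.0,
    "gamma2": 1.5,
}

#: fixed ERP topography: channel label -> relative weight
_ERP_TOPOGRAPHY = {
    "Cz": 1.0, "CPz": 0.9, "Pz": 0.8,
    "C3": 0.5, "C4": 0.5, "CP3": 0.6, "CP4": 0.6, "P3": 0.5, "P4": 0.5,
}

#: fixed EOG blink leakage into frontal EEG channels (label -> coefficient)
EOG_LEAKAGE = {
    "F7": 0.28, "F3": 0.32, "Fz": 0.35, "F4": 0.32, "F8": 0.28,
    "FT7": 0.12, "FC3": 0.15, "FCz": 0.18, "FC4": 0.15, "FT8": 0.12,
}

#: relative blink amplitude on the four EOG electrodes
_EOG_WEIGHTS = np.array([1.0, 0.9, -0.7, -0.6])

_SCENARIOS = [
    ("relax-first", "low-first"),
    ("relax-first", "high-first"),
    ("stress-first", "low-first"),
    ("stress-first", "high-first"),
]

_ALPHABET = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWYZ"]  # 'X' reserved for 0-back


def _default_band_effects() -> dict:
    # workload power ratios high/low: low bands up under load, alpha down
    return {"delta": 1.2, "theta": 1.3, "alpha": 0.7,
            "beta": 1.0, "gamma": 1.0, "gamma2": 1.0}


def _default_context_shift() -> dict:
    # stress/relax power ratios, applied regardless of workload: the
    # nonstationarity is concentrated in the low bands
    return {"delta": 1.25, "theta": 1.25, "alpha": 0.8,
            "beta": 1.0, "gamma": 1.0, "gamma2": 1.0}


@dataclass
class SynthConfig:
    """Configuration of one simulated subject/session.

    The defaults reproduce the protocol geometry of the emulated study
    (28 EEG + 4 EOG channels, 2 contexts x 12 two-minute blocks, 60 letters
    per block at 500 ms + 1500 ms ISI, 25% targets) with moderate planted
    effects.
    """

    seed: int = 0
    n_eeg_channels: int = 28
    n_eog_channels: int = 4
    sampling_rate: int = 256
    n_blocks_per_context_per_level: int = 6
    letters_per_block: int = 60
    letter_duration: float = 500.0   # ms
    isi: float = 1500.0              # ms
    target_fraction: float = 0.25
    band_power_effects: dict = field(default_factory=_default_band_effects)
    erp_amplitude_effect: float = 1.0   # uV, high minus low workload
    context_shift: dict = field(default_factory=_default_context_shift)
    eog_artifact_rate: float = 6.0      # blink events per minute
    noise_sd: float = 2.0               # uV white sensor noise
    context_order: str = "relax-first"
    workload_order: str = "low-first"
    erp_base_amplitude: float = 2.0     # uV at the template peak, low workload

    def validate(self) -> None:
        if not 0.0 < self.target_fraction < 1.0:
            raise ConfigError("target_fraction must lie in (0, 1)")
        for name, value in [
            ("n_eeg_channels", self.n_eeg_channels),
            ("n_eog_channels", self.n_eog_channels),
            ("sampling_rate", self.sampling_rate),
            ("n_blocks_per_context_per_level", self.n_blocks_per_context_per_level),
            ("letters_per_block", self.letters_per_block),
        ]:
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        top_edge = max(high for _, high in BAND_EDGES.values())
        if self.sampling_rate < 2 * top_edge:
            raise ConfigError(
                f"sampling_rate {self.sampling_rate} Hz cannot represent the "
                f"{top_edge} Hz band edge (need >= {2 * top_edge} Hz)"
            )
        for mapping, name in [(self.band_power_effects, "band_power_effects"),
                              (self.context_shift, "context_shift")]:
            for band, ratio in mapping.items():
                if band not in BAND_EDGES:
                    raise ConfigError(f"{name}: unknown band '{band}'")
                if ratio <= 0:
                    raise ConfigError(f"{name}[{band}] must be > 0")
        if self.context_order not in ("relax-first", "stress-first"):
            raise ConfigError("context_order must be 'relax-first' or 'stress-first'")
        if self.workload_order not in ("low-first", "high-first"):
            raise ConfigError("workload_order must be 'low-first' or 'high-first'")

    # -- derived protocol geometry ----------------------------------------
    @property
    def letter_pitch_s(self) -> float:
        """Onset-to-onset interval in seconds (letter + ISI)."""
        return (self.letter_duration + self.isi) / 1000.0

    @property
    def block_duration_s(self) -> float:
        return self.letters_per_block * self.letter_pitch_s

    @property
    def n_blocks(self) -> int:
        return 4 * self.n_blocks_per_context_per_level  # 2 contexts x 2 levels

    @property
    def n_targets_per_block(self) -> int:
        return int(round(self.target_fraction * self.letters_per_block))


def _block_schedule(config: SynthConfig) -> list[tuple[int, str, str]]:
    """Return (block_index, context, workload) in presentation order."""
    contexts = ["relax", "stress"]
    if config.context_order == "stress-first":
        contexts.reverse()
    levels = ["low", "high"]
    if config.workload_order == "high-first":
        levels.reverse()
    schedule = []
    b = 0
    for context in contexts:
        for k in range(2 * config.n_blocks_per_context_per_level):
            schedule.append((b, context, levels[k % 2]))
            b += 1
    return schedule


def _block_letters(rng: np.random.Generator, config: SynthConfig, workload: str):
    """Letters and target flags of one block, honoring n-back semantics.

    0-back blocks: the target letter is 'X'.  2-back blocks: a target is a
    letter equal to the one two positions earlier.  Exactly
    ``round(target_fraction * letters_per_block)`` targets per block.
    """
    n = config.letters_per_block
    n_targets = config.n_targets_per_block
    is_target = np.zeros(n, dtype=bool)
    letters = [""] * n
    if workload == "low":  # 0-back
        target_pos = rng.choice(n, size=n_targets, replace=False)
        is_target[target_pos] = True
        for i in range(n):
            letters[i] = "X" if is_target[i] else str(rng.choice(_ALPHABET))
    else:  # 2-back
        target_pos = rng.choice(np.arange(2, n), size=n_targets, replace=False)
        is_target[target_pos] = True
        for i in range(n):
            if is_target[i]:
                letters[i] = letters[i - 2]
            else:
                pool = [c for c in _ALPHABET if i < 2 or c != letters[i - 2]]
                letters[i] = str(rng.choice(pool))
    return letters, is_target


def _erp_template(config: SynthConfig) -> np.ndarray:
    """Biphasic waveform: small negativity ~170 ms, positive peak ~300 ms
    (~400 ms wide), confined to the first second after letter onset."""
    fs = config.sampling_rate
    t = np.arange(int(round(fs * 1.0))) / fs
    wave = (-0.4 * np.exp(-0.5 * ((t - 0.170) / 0.045) ** 2)
            + 1.0 * np.exp(-0.5 * ((t - 0.300) / 0.085) ** 2))
    wave[t > 0.85] *= np.clip((1.0 - t[t > 0.85]) / 0.15, 0.0, 1.0)
    return wave


def _blink_template(config: SynthConfig) -> np.ndarray:
    fs = config.sampling_rate
    t = np.arange(int(round(fs * 0.4))) / fs
    return np.exp(-0.5 * ((t - 0.2) / 0.06) ** 2)


def _band_source(rng: np.random.Generator, band: str, n_samples: int, fs: int) -> np.ndarray:
    low, high = BAND_EDGES[band]
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_session(config: SynthConfig) -> Recording:
    """Generate one subject's full two-context recording.

    Returns a :class:`Recording` with ``2 x 2 x n_blocks_per_context_per_level``
    blocks of ``letters_per_block`` events each, scheduled at the letter
    pitch, and a signal composed of spatially mixed band-limited sources,
    an event-locked ERP, EOG artifacts with frontal leakage, and white
    sensor noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    block_samples = int(round(config.block_duration_s * fs))
    n_blocks = config.n_blocks
    pad_samples = 2 * fs  # tail so the last trial (+2 s) always fits
    n_samples = n_blocks * block_samples + pad_samples
    n_eeg, n_eog = config.n_eeg_channels, config.n_eog_channels

    labels = list(EEG_LABELS_28[:n_eeg])
    labels += [f"EEG{i}" for i in range(len(labels), n_eeg)]
    eog_labels = list(EOG_LABELS_4[:n_eog])
    eog_labels += [f"EOG{i + 1}" for i in range(len(eog_labels), n_eog)]

    schedule = _block_schedule(config)

    # -- event table -------------------------------------------------------
    rows = []
    pitch = int(round(config.letter_pitch_s * fs))
    for block, context, workload in schedule:
        letters, is_target = _block_letters(rng, config, workload)
        start = block * block_samples
        for j in range(config.letters_per_block):
            rows.append((start + j * pitch, letters[j], bool(is_target[j]),
                         block, workload, context))
    events = pd.DataFrame(rows, columns=["onset_sample", "letter", "is_target",
                                         "block", "workload", "context"])

    # -- oscillatory sources through a random orthonormal forward model ----
    bands = list(BAND_EDGES)
    forward = np.linalg.qr(rng.standard_normal((n_eeg, len(bands))))[0]
    eeg = np.zeros((n_eeg, n_samples))
    gain = np.ones(n_samples)
    for bi, band in enumerate(bands):
        source = _band_source(rng, band, n_samples, fs)
        gain[:] = _BASE_SOURCE_SD[band]
        wl_ratio = config.band_power_effects.get(band, 1.0)
        cx_ratio = config.context_shift.get(band, 1.0)
        for block, context, workload in schedule:
            g = _BASE_SOURCE_SD[band]
            if workload == "high":
                g *= np.sqrt(wl_ratio)
            if context == "stress":
                g *= np.sqrt(cx_ratio)
            gain[block * block_samples:(block + 1) * block_samples] = g
        eeg += np.outer(forward[:, bi], gain * source)

    # -- event-locked ERP on the centro-parietal subset ---------------------
    template = _erp_template(config)
    topo = np.zeros(n_eeg)
    for lab, w in _ERP_TOPOGRAPHY.items():
        if lab in labels:
            topo[labels.index(lab)] = w
    if not topo.any():  # non-standard montage: put the ERP on mid channels
        topo[n_eeg // 2] = 1.0
    patch = np.outer(topo, template)
    for onset, workload in zip(events["onset_sample"], events["workload"]):
        amp = config.erp_base_amplitude
        if workload == "high":
            amp += config.erp_amplitude_effect
        eeg[:, onset:onset + template.size] += amp * patch

    # -- EOG blinks with fixed frontal leakage ------------------------------
    blink = _blink_template(config)
    n_blinks = rng.poisson(config.eog_artifact_rate * n_samples / fs / 60.0)
    blink_trace = np.zeros(n_samples)
    if n_blinks > 0:
        onsets = rng.integers(0, n_samples - blink.size, size=n_blinks)
        amps = rng.uniform(60.0, 120.0, size=n_blinks)
        for onset, amp in zip(onsets, amps):
            blink_trace[onset:onset + blink.size] += amp * blink
    eog = np.outer(_EOG_WEIGHTS[:n_eog], blink_trace)
    eog += 1.0 * rng.standard_normal((n_eog, n_samples))  # sensor noise on EOG
    leak = np.zeros(n_eeg)
    for lab, coef in EOG_LEAKAGE.items():
        if lab in labels:
            leak[labels.index(lab)] = coef
    eeg += np.outer(leak, blink_trace)

    # -- sensor noise -------------------------------------------------------
    if config.noise_sd > 0:
        eeg += config.noise_sd * rng.standard_normal((n_eeg, n_samples))

    return Recording(
        signal=np.vstack([eeg, eog]),
        channel_labels=labels + eog_labels,
        channel_roles=["EEG"] * n_eeg + ["EOG"] * n_eog,
        sampling_rate=float(fs),
        events=events,
    )


def subject_configs(config: SynthConfig, n_subjects: int) -> list[SynthConfig]:
    """Derive per-subject configurations: independent deterministic seeds
    and context/workload orders counterbalanced over the four scenarios
    (cycling when ``n_subjects`` is not divisible by four, starting from the
    base configuration's own order)."""
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    start = _SCENARIOS.index((config.context_order, config.workload_order))
    configs = []
    for i in range(n_subjects):
        child = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        derived = int(child.generate_state(1)[0] % (2 ** 31))
        context_order, workload_order = _SCENARIOS[(start + i) % 4]
        configs.append(replace(config, seed=derived,
                               context_order=context_order,
                               workload_order=workload_order))
    return configs


def generate_study(config: SynthConfig, n_subjects: int) -> list[Recording]:
    """Generate ``n_subjects`` independent sessions (counterbalanced orders,
    per-subject seeds derived deterministically from ``config.seed``)."""
    out = []
    for i, cfg in enumerate(subject_configs(config, n_subjects)):
        logger.info("generating subject %d/%d (scenario %s/%s)",
                    i + 1, n_subjects, cfg.context_order, cfg.workload_order)
        out.append(generate_session(cfg))
    return out
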