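"""Cross-validation schemes on block-structured data, decision fusion, and
chance-level computation.

Folds always partition whole blocks (a two-minute n-back task) so that no
block is split between training and testing, and they balance workload
levels (and, where applicable, contexts) per fold.  Five schemes probe
robustness to the affective context:

``general``
    Sixfold over all 24 blocks: 20 train / 4 test blocks, workload and
    context balanced.
``within``
    Sixfold over one context's 12 blocks: 10 train / 2 test.
``across``
    Train exactly as ``within`` on one context, test on two-block folds of
    the other context.
``combined``
    Per fold, six randomly drawn blocks per context train the model; all
    trials of four of them plus every other trial of the remaining two (per
    context) are used so the training-set size matches ``within``.  Testing
    uses two held-out blocks of a single context.  Repeated six times.
``halves_within`` / ``halves_across``
    Threefold over one six-block half of a context (4 train / 2 test
    blocks), tested on the same or the other half; folds run for both
    halves of both contexts and are averaged, isolating the effect of time
    passing from the effect of the context change.

Per fold, spatial filters (CSP and/or FSF), mRMR and the LDA are fitted on
training trials only.  Block-level decisions fuse the per-trial labels of a
test block by majority vote.  The chance level for n test trials is the
two-sided binomial significance bound around 50%.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfigError, EpochSet
from .erp import extract_erp_features, fit_fsf, preprocess_erp
from .model import (
    CLASS_ORDER,
    DEFAULT_K,
    assemble_variety,
    mrmr_select,
    predict,
    train_lda,
)
from .oscillatory import (
    BandSpec,
    default_filter_bank,
    bandpass_sos,
    fit_csp,
    log_variance_features,
    trial_covariances,
)
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SchemeSpec",
    "SchemeResult",
    "BehavioralCounts",
    "Fold",
    "make_folds",
    "run_scheme",
    "majority_vote",
    "chance_level",
    "nback_performance",
    "FeatureCache",
    "evaluate_study",
]

SCHEME_NAMES = ("general", "within", "across", "combined",
                "halves_within", "halves_across")


@dataclass(frozen=True)
class SchemeSpec:
    """One evaluation scheme: name, contexts, feature variety, folds, seed."""

    name: str
    train_context: str | None = None
    test_context: str | None = None
    feature_variety: str = "fb"
    n_folds: int = 6
    seed: int = 0
    bands: tuple = ()       # empty = default six-band bank
    k_select: int = DEFAULT_K

    def __post_init__(self) -> None:
        if self.name not in SCHEME_NAMES:
            raise ConfigError(f"unknown scheme {self.name!r}")
        if self.feature_variety not in ("fb", "erp", "both"):
            raise ConfigError(f"unknown feature variety {self.feature_variety!r}")


@dataclass(frozen=True)
class Fold:
    """Block sets plus the explicit trial indices they induce (the
    ``combined`` scheme subsamples every other trial in two blocks)."""

    train_blocks: tuple
    test_blocks: tuple
    train_index: np.ndarray
    test_index: np.ndarray


@dataclass
class SchemeResult:
    scheme: SchemeSpec
    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    per_block_fused_label: dict
    n_train_trials: list[int]
    n_test_trials: list[int]

    def to_dict(self) -> dict:
        return {
            "scheme": {
                "name": self.scheme.name,
                "train_context": self.scheme.train_context,
                "test_context": self.scheme.test_context,
                "feature_variety": self.scheme.feature_variety,
                "n_folds": self.scheme.n_folds,
                "seed": self.scheme.seed,
            },
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean_accuracy": float(self.mean_accuracy),
            "per_block_fused_label": {str(k): v for k, v in
                                      self.per_block_fused_label.items()},
            "n_train_trials": self.n_train_trials,
            "n_test_trials": self.n_test_trials,
        }


@dataclass
class BehavioralCounts:
    """Button-press outcome counts of one n-back block."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

def _blocks_by_cell(epochs: EpochSet, context: str | None = None,
                    half: int | None = None) -> dict[str, np.ndarray]:
    """Blocks per workload level within an optional context/half slice."""
    mask = np.ones(epochs.n_trials, dtype=bool)
    if context is not None:
        mask &= epochs.context == context
    if half is not None:
        mask &= epochs.half == half
    cells = {}
    for level in CLASS_ORDER:
        cells[level] = np.unique(epochs.block[mask & (epochs.workload == level)])
    return cells


def _indices_for_blocks(epochs: EpochSet, blocks) -> np.ndarray:
    return np.flatnonzero(np.isin(epochs.block, list(blocks)))


def _fold_count(spec_folds: int, *cell_sizes: int) -> int:
    n = min(cell_sizes)
    if n < spec_folds:
        warnings.warn(
            f"only {n} complete blocks per cell: falling back to {n}-fold "
            f"cross-validation", stacklevel=3)
    return min(spec_folds, n)


def _partition(rng: np.random.Generator, blocks: np.ndarray, n_folds: int):
    """Shuffle blocks and deal them into n_folds test groups."""
    blocks = rng.permutation(blocks)
    return [blocks[i::n_folds] for i in range(n_folds)]


def make_folds(epochs: EpochSet, spec: SchemeSpec) -> list[Fold]:
    """Construct the block-wise folds of one scheme (see module docstring)."""
    rng = np.random.default_rng(spec.seed)
    folds: list[Fold] = []

    if spec.name == "general":
        cells = {}
        for context in np.unique(epochs.context):
            for level, blocks in _blocks_by_cell(epochs, context).items():
                cells[(context, level)] = blocks
        n_folds = _fold_count(spec.n_folds, *(len(b) for b in cells.values()))
        parts = {key: _partition(rng, blocks, n_folds)
                 for key, blocks in cells.items()}
        for f in range(n_folds):
            test = np.concatenate([parts[key][f] for key in sorted(parts)])
            train = np.setdiff1d(np.unique(epochs.block), test)
            folds.append(Fold(tuple(train), tuple(test),
                              _indices_for_blocks(epochs, train),
                              _indices_for_blocks(epochs, test)))
        return folds

    if spec.name in ("within", "across"):
        if spec.train_context is None:
            raise ConfigError(f"scheme {spec.name!r} needs train_context")
        train_cells = _blocks_by_cell(epochs, spec.train_context)
        if spec.name == "within":
            test_context = spec.train_context
            test_cells = train_cells
        else:
            test_context = spec.test_context or _other_context(epochs, spec.train_context)
            test_cells = _blocks_by_cell(epochs, test_context)
        n_folds = _fold_count(spec.n_folds,
                              *(len(b) for b in train_cells.values()),
                              *(len(b) for b in test_cells.values()))
        train_parts = {lv: _partition(rng, blocks, n_folds)
                       for lv, blocks in train_cells.items()}
        if spec.name == "within":
            test_parts = train_parts
        else:
            test_parts = {lv: _partition(rng, blocks, n_folds)
                          for lv, blocks in test_cells.items()}
        all_train_blocks = np.concatenate(list(train_cells.values()))
        for f in range(n_folds):
            test = np.concatenate([test_parts[lv][f] for lv in CLASS_ORDER])
            if spec.name == "within":
                train = np.setdiff1d(all_train_blocks, test)
            else:
                train = np.setdiff1d(
                    all_train_blocks,
                    np.concatenate([train_parts[lv][f] for lv in CLASS_ORDER]),
                )
            folds.append(Fold(tuple(train), tuple(test),
                              _indices_for_blocks(epochs, train),
                              _indices_for_blocks(epochs, test)))
        return folds

    if spec.name == "combined":
        if spec.test_context is None:
            raise ConfigError("scheme 'combined' needs test_context")
        contexts = list(np.unique(epochs.context))
        if spec.test_context not in contexts:
            raise ConfigError(f"no blocks in test context {spec.test_context!r}")
        for _ in range(spec.n_folds):
            train_blocks: list[int] = []
            train_index_parts: list[np.ndarray] = []
            test_blocks: list[int] = []
            for context in contexts:
                cells = _blocks_by_cell(epochs, context)
                if min(len(b) for b in cells.values()) < 4:
                    raise ConfigError(
                        "combined scheme needs >= 4 blocks per level per context")
                halved_parity = 0
                held_out: dict[str, np.ndarray] = {}
                for level in CLASS_ORDER:
                    chosen = rng.choice(cells[level], size=3, replace=False)
                    held_out[level] = np.setdiff1d(cells[level], chosen)
                    # one of the three blocks contributes every other trial
                    halved = chosen[0]
                    for b in chosen[1:]:
                        train_index_parts.append(_indices_for_blocks(epochs, [b]))
                    idx = _indices_for_blocks(epochs, [halved])
                    train_index_parts.append(idx[halved_parity::2])
                    halved_parity ^= 1  # alternate starting parity
                    train_blocks.extend(int(b) for b in chosen)
                if context == spec.test_context:
                    for level in CLASS_ORDER:
                        test_blocks.append(int(rng.choice(held_out[level])))
            train_index = np.sort(np.concatenate(train_index_parts))
            folds.append(Fold(tuple(sorted(train_blocks)), tuple(sorted(test_blocks)),
                              train_index,
                              _indices_for_blocks(epochs, test_blocks)))
        return folds

    if spec.name in ("halves_within", "halves_across"):
        n_sub = 3  # threefold inside a six-block half
        for context in np.unique(epochs.context):
            for train_half in (1, 2):
                test_half = train_half if spec.name == "halves_within" else 3 - train_half
                train_cells = _blocks_by_cell(epochs, context, train_half)
                test_cells = _blocks_by_cell(epochs, context, test_half)
                n_folds = _fold_count(n_sub,
                                      *(len(b) for b in train_cells.values()),
                                      *(len(b) for b in test_cells.values()))
                train_parts = {lv: _partition(rng, b, n_folds)
                               for lv, b in train_cells.items()}
                test_parts = (train_parts if spec.name == "halves_within"
                              else {lv: _partition(rng, b, n_folds)
                                    for lv, b in test_cells.items()})
                all_train = np.concatenate(list(train_cells.values()))
                for f in range(n_folds):
                    test = np.concatenate([test_parts[lv][f] for lv in CLASS_ORDER])
                    drop = np.concatenate([train_parts[lv][f] for lv in CLASS_ORDER])
                    train = np.setdiff1d(all_train, drop)
                    folds.append(Fold(tuple(train), tuple(test),
                                      _indices_for_blocks(epochs, train),
                                      _indices_for_blocks(epochs, test)))
        return folds

    raise ConfigError(f"unknown scheme {spec.name!r}")


def _other_context(epochs: EpochSet, context: str) -> str:
    others = [c for c in np.unique(epochs.context) if c != context]
    if len(others) != 1:
        raise ConfigError(f"cannot infer the context opposite to {context!r}")
    return others[0]


# ---------------------------------------------------------------------------
# feature cache: unsupervised per-subject computations shared across folds
# ---------------------------------------------------------------------------

@dataclass
class FeatureCache:
    """Label-free per-subject precomputations: per-band trial covariances
    for the oscillatory branch and 36 Hz epochs for the ERP branch.  Safe
    to share across folds because no class information enters."""

    epochs: EpochSet
    bands: list[BandSpec]
    band_covs: dict[str, np.ndarray] = field(default_factory=dict)
    erp_epochs: EpochSet | None = None

    @classmethod
    def build(cls, epochs: EpochSet, bands: list[BandSpec] | None = None,
              variety: str = "both") -> "FeatureCache":
        bands = list(bands) if bands else default_filter_bank()
        cache = cls(epochs=epochs, bands=bands)
        if variety in ("fb", "both"):
            for band in bands:
                sos = bandpass_sos(band.low_hz, band.high_hz, epochs.sampling_rate)
                filtered = sps.sosfiltfilt(sos, epochs.data, axis=-1)
                cache.band_covs[band.name] = trial_covariances(filtered)
        if variety in ("erp", "both"):
            cache.erp_epochs = preprocess_erp(epochs)
        return cache


def _fb_fold_features(cache: FeatureCache, train_index, test_index, k, rng_unused=None):
    """Fit per-band CSP on the training trials and return selected
    (train, test) feature arrays plus fitted models."""
    from .containers import FeatureMatrix

    ep = cache.epochs
    train_blocks, test_blocks = [], []
    provenance = []
    models = {}
    for band in cache.bands:
        covs = cache.band_covs[band.name]
        model = fit_csp(None, band=band,
                        trial_covs=covs[train_index],
                        workload=ep.workload[train_index])
        models[band.name] = model
        train_blocks.append(log_variance_features(model.filters,
                                                  trial_covs=covs[train_index]))
        test_blocks.append(log_variance_features(model.filters,
                                                 trial_covs=covs[test_index]))
        provenance += [{"branch": "fb", "band": band.name, "filter": j}
                       for j in range(model.filters.shape[0])]

    def matrix(values, index):
        return FeatureMatrix(values=values, provenance=provenance,
                             workload=ep.workload[index],
                             context=ep.context[index],
                             block=ep.block[index], half=ep.half[index])

    train_fm = matrix(np.hstack(train_blocks), train_index)
    test_fm = matrix(np.hstack(test_blocks), test_index)
    selection = mrmr_select(train_fm, k=k)
    return (train_fm.select_columns(selection.selected_indices),
            test_fm.select_columns(selection.selected_indices),
            models, selection)


def _erp_fold_features(cache: FeatureCache, train_index, test_index, k):
    erp = cache.erp_epochs
    model = fit_fsf(erp.select(train_index))
    train_fm = extract_erp_features(erp.select(train_index), model)
    test_fm = extract_erp_features(erp.select(test_index), model)
    selection = mrmr_select(train_fm, k=k)
    return (train_fm.select_columns(selection.selected_indices),
            test_fm.select_columns(selection.selected_indices),
            model, selection)


def run_scheme(epochs: EpochSet, spec: SchemeSpec,
               cache: FeatureCache | None = None) -> SchemeResult:
    """Run one evaluation scheme end to end on one subject's epochs.

    Per fold, spatial models, mRMR and the LDA are fitted on the training
    trials only; accuracy is the fraction of correctly labeled test trials.
    ``cache`` may carry the label-free per-subject precomputations (band
    covariances, ERP epochs) to share across schemes.
    """
    bands = list(spec.bands) if spec.bands else default_filter_bank()
    if cache is not None:
        cached_names = [b.name for b in cache.bands]
        needs_fb = spec.feature_variety in ("fb", "both")
        needs_erp = spec.feature_variety in ("erp", "both")
        if ((needs_fb and ([b.name for b in bands] != cached_names
                           or not cache.band_covs))
                or (needs_erp and cache.erp_epochs is None)):
            cache = None  # cache does not cover this spec; rebuild
    if cache is None:
        cache = FeatureCache.build(epochs, bands, variety=spec.feature_variety)
    folds = make_folds(epochs, spec)
    accuracies, n_train, n_test = [], [], []
    fused: dict = {}
    for fold in folds:
        fb_train = fb_test = erp_train = erp_test = None
        if spec.feature_variety in ("fb", "both"):
            fb_train, fb_test, _, _ = _fb_fold_features(
                cache, fold.train_index, fold.test_index, spec.k_select)
        if spec.feature_variety in ("erp", "both"):
            erp_train, erp_test, _, _ = _erp_fold_features(
                cache, fold.train_index, fold.test_index, spec.k_select)
        train_fm = assemble_variety(fb_train, erp_train, spec.feature_variety)
        test_fm = assemble_variety(fb_test, erp_test, spec.feature_variety)
        lda = train_lda(train_fm)
        labels, scores = predict(lda, test_fm)
        truth = epochs.workload[fold.test_index]
        accuracies.append(float(np.mean(labels == truth)))
        n_train.append(int(fold.train_index.size))
        n_test.append(int(fold.test_index.size))
        for b in fold.test_blocks:
            in_block = epochs.block[fold.test_index] == b
            fused[int(b)] = majority_vote(labels[in_block], scores[in_block])
    return SchemeResult(
        scheme=spec,
        per_fold_accuracy=np.asarray(accuracies),
        mean_accuracy=float(np.mean(accuracies)),
        per_block_fused_label=fused,
        n_train_trials=n_train,
        n_test_trials=n_test,
    )


# ---------------------------------------------------------------------------
# decision fusion, chance level, behavioral statistic
# ---------------------------------------------------------------------------

def majority_vote(labels: np.ndarray, scores: np.ndarray | None = None) -> str:
    """Most frequent label of one block's trials.

    With an odd trial count (45 relevant trials per block) a tie cannot
    occur; for even counts a tie resolves to the class with the higher mean
    signed score, i.e. ``class_order[1]`` ('high') when the mean score is
    non-negative.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("majority_vote needs at least one label")
    n_high = int(np.sum(labels == CLASS_ORDER[1]))
    n_low = labels.size - n_high
    if n_high > n_low:
        return CLASS_ORDER[1]
    if n_low > n_high:
        return CLASS_ORDER[0]
    if scores is not None and float(np.mean(scores)) < 0:
        return CLASS_ORDER[0]
    return CLASS_ORDER[1]


def chance_level(n_trials: int, alpha: float = 0.05,
                 method: str = "normal") -> float:
    """Two-class chance-level accuracy threshold, in percent (one decimal).

    ``method='normal'`` (default) uses the two-sided normal approximation
    to the binomial: the smallest correct-count ``k = ceil(n/2 + z *
    sqrt(n/4))`` with ``z`` the (1 - alpha) two-sided normal quantile, and
    returns ``100 k / n``.  ``method='binomial'`` uses the exact binomial
    quantile instead.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if method == "normal":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        k = math.ceil(n_trials / 2.0 + z * math.sqrt(n_trials / 4.0))
    elif method == "binomial":
        k = int(stats.binom.ppf(1.0 - alpha / 2.0, n_trials, 0.5)) + 1
    else:
        raise ConfigError(f"unknown chance-level method {method!r}")
    k = min(k, n_trials)
    return round(100.0 * k / n_trials, 1)


def nback_performance(counts: BehavioralCounts) -> float:
    """Block-level behavioral accuracy (TP + TN) / (TP + TN + FP + FN)."""
    total = counts.TP + counts.TN + counts.FP + counts.FN
    if total <= 0:
        raise ValueError("performance undefined for all-zero counts")
    return (counts.TP + counts.TN) / total


# ---------------------------------------------------------------------------
# study-level runner
# ---------------------------------------------------------------------------

def scheme_grid(varieties=("fb", "erp", "both"), seed: int = 0,
                schemes=SCHEME_NAMES) -> list[SchemeSpec]:
    """All (scheme, variety, context) combinations of the evaluation plan."""
    specs = []
    for variety in varieties:
        for name in schemes:
            if name == "general" or name.startswith("halves"):
                specs.append(SchemeSpec(name, feature_variety=variety, seed=seed))
            elif name in ("within", "across"):
                for context in ("relax", "stress"):
                    specs.append(SchemeSpec(name, train_context=context,
                                            feature_variety=variety, seed=seed))
            elif name == "combined":
                for context in ("relax", "stress"):
                    specs.append(SchemeSpec(name, test_context=context,
                                            feature_variety=variety, seed=seed))
    return specs


def evaluate_study(epoch_sets: list[EpochSet], specs: list[SchemeSpec]) -> pd.DataFrame:
    """Run every scheme spec on every subject's epochs.

    Returns a tidy table with columns ``subject, scheme, train_context,
    test_context, variety, fold, accuracy, n_train, n_test`` (one row per
    fold), suitable for any external stats tool.
    """
    varieties = {s.feature_variety for s in specs}
    cache_variety = "both" if varieties - {"fb"} and varieties - {"erp"} else varieties.pop()
    rows = []
    for subject, epochs in enumerate(epoch_sets):
        cache = FeatureCache.build(epochs, None, variety=cache_variety)
        for spec in specs:
            result = run_scheme(epochs, spec, cache=cache)
            for f, acc in enumerate(result.per_fold_accuracy):
                rows.append({
                    "subject": subject,
                    "scheme": spec.name,
                    "train_context": spec.train_context or "",
                    "test_context": spec.test_context or "",
                    "variety": spec.feature_variety,
                    "fold": f,
                    "accuracy": acc,
                    "n_train": result.n_train_trials[f],
                    "n_test": result.n_test_trials[f],
                })
        logger.info("subject %d done (%d scheme runs)", subject, len(specs))
    return pd.DataFrame(rows)
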