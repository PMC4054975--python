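"""Feature selection and classification.

mRMR (minimum-redundancy maximum-relevance) greedily picks features that
maximize the mutual information with the workload class minus the mean
mutual information with the already-picked features (the difference, "MID",
scheme).  Mutual information is estimated after equal-frequency
discretization of each feature into 8 bins.  Per branch, 18 of the
candidate features are kept; for the combined variety the two 18-feature
blocks are concatenated (36 features).

Classification uses shrinkage LDA: the pooled within-class covariance is
convexly blended with a scaled identity, ``(1-gamma) S + gamma (tr S / d) I``,
with the shrinkage intensity ``gamma`` computed analytically from the
training data (Ledoit-Wolf estimator).  The weight vector is the shrunk-
covariance-whitened class-mean difference and the bias places the boundary
at the midpoint of the projected class means.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.covariance import ledoit_wolf

from .containers import ConfigError, FeatureMatrix, concat_features

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionModel",
    "LdaModel",
    "mrmr_select",
    "assemble_variety",
    "train_lda",
    "predict",
    "save_model_bundle",
    "load_model_bundle",
]

DEFAULT_K = 18
DEFAULT_BINS = 8
CLASS_ORDER = ("low", "high")


@dataclass
class SelectionModel:
    """Ordered mRMR picks with their incremental scores."""

    selected_indices: np.ndarray
    scores: np.ndarray
    k: int
    discretization_bins: int

    def to_dict(self) -> dict:
        return {
            "selected_indices": [int(i) for i in self.selected_indices],
            "scores": [float(s) for s in self.scores],
            "k": self.k,
            "discretization_bins": self.discretization_bins,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionModel":
        return cls(
            selected_indices=np.asarray(d["selected_indices"], dtype=int),
            scores=np.asarray(d["scores"], dtype=float),
            k=int(d["k"]),
            discretization_bins=int(d["discretization_bins"]),
        )


@dataclass
class LdaModel:
    """Shrinkage LDA: ``score = weights . x + bias``; positive scores map
    to ``class_order[1]`` ('high'), including exact ties at 0."""

    weights: np.ndarray
    bias: float
    gamma: float
    class_order: tuple[str, str] = CLASS_ORDER

    def to_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "gamma": float(self.gamma),
            "class_order": list(self.class_order),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LdaModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            gamma=float(d["gamma"]),
            class_order=tuple(d["class_order"]),
        )


# ---------------------------------------------------------------------------
# mRMR
# ---------------------------------------------------------------------------

def discretize_equal_frequency(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin codes; a constant column collapses to one bin."""
    edges = np.unique(np.quantile(column, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, column, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Mutual information (nats) of two discrete code vectors, from their
    contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    cont = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    n = cont.sum()
    joint = cont / n
    outer = joint.sum(axis=1, keepdims=True) @ joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def _mutual_information_many(codes: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Mutual information of every row of ``codes`` with ``b`` in one pass
    (flattened contingency tables via bincount)."""
    p, n = codes.shape
    na = int(codes.max()) + 1
    nb = int(b.max()) + 1
    flat = (np.arange(p)[:, None] * (na * nb) + codes * nb + b[None, :]).ravel()
    cont = np.bincount(flat, minlength=p * na * nb).reshape(p, na, nb).astype(float)
    joint = cont / n
    outer = joint.sum(axis=2, keepdims=True) * joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / outer)
    return np.nansum(terms, axis=(1, 2))


def mrmr_select(features: FeatureMatrix, k: int = DEFAULT_K,
                n_bins: int = DEFAULT_BINS) -> SelectionModel:
    """Greedy forward mRMR selection (difference scheme, deterministic
    lowest-index tie-break)."""
    n_features = features.n_features
    if k > n_features:
        raise ValueError(f"cannot select k={k} from {n_features} features")
    classes = np.unique(features.workload)
    if classes.size < 2:
        raise ValueError("mRMR needs both workload classes present")
    y = np.searchsorted(classes, features.workload)
    codes = np.stack(
        [discretize_equal_frequency(features.values[:, j], n_bins)
         for j in range(n_features)]
    )
    relevance = _mutual_information_many(codes, y)

    selected: list[int] = []
    scores: list[float] = []
    redundancy = np.zeros((n_features, 0))
    available = np.ones(n_features, dtype=bool)
    for _ in range(k):
        if selected:
            mean_red = redundancy.mean(axis=1)
        else:
            mean_red = np.zeros(n_features)
        crit = np.where(available, relevance - mean_red, -np.inf)
        pick = int(np.argmax(crit))  # argmax takes the lowest index on ties
        selected.append(pick)
        scores.append(float(crit[pick]))
        available[pick] = False
        new_red = _mutual_information_many(codes, codes[pick])
        redundancy = np.column_stack([redundancy, new_red])
    return SelectionModel(
        selected_indices=np.asarray(selected, dtype=int),
        scores=np.asarray(scores, dtype=float),
        k=k,
        discretization_bins=n_bins,
    )


def assemble_variety(fb: FeatureMatrix | None, erp: FeatureMatrix | None,
                     variety: str) -> FeatureMatrix:
    """Combine the branch feature blocks: ``fb``, ``erp``, or ``both``
    (fb block first)."""
    if variety == "fb":
        if fb is None:
            raise ValueError("variety 'fb' requires the oscillatory block")
        return fb
    if variety == "erp":
        if erp is None:
            raise ValueError("variety 'erp' requires the ERP block")
        return erp
    if variety == "both":
        if fb is None or erp is None:
            raise ValueError("variety 'both' requires both branches")
        return concat_features(fb, erp)
    raise ConfigError(f"unknown feature variety: {variety!r}")


# ---------------------------------------------------------------------------
# shrinkage LDA
# ---------------------------------------------------------------------------

def train_lda(features: FeatureMatrix, gamma: float | None = None) -> LdaModel:
    """Train shrinkage LDA on a feature matrix.

    ``gamma=None`` computes the Ledoit-Wolf shrinkage intensity from the
    class-centered training data; passing a value in [0, 1] forces it.
    """
    x = features.values
    y = features.workload
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("LDA needs both workload classes present")
    for c in CLASS_ORDER:
        if np.sum(y == c) < 2:
            raise ValueError(f"LDA needs >= 2 trials of class '{c}'")
    mu_low = x[y == CLASS_ORDER[0]].mean(axis=0)
    mu_high = x[y == CLASS_ORDER[1]].mean(axis=0)
    centered = np.vstack([
        x[y == CLASS_ORDER[0]] - mu_low,
        x[y == CLASS_ORDER[1]] - mu_high,
    ])
    d = x.shape[1]
    if gamma is None:
        shrunk, gamma = ledoit_wolf(centered, assume_centered=True)
    else:
        if not 0.0 <= gamma <= 1.0:
            raise ConfigError("gamma must lie in [0, 1]")
        s = centered.T @ centered / centered.shape[0]
        shrunk = (1.0 - gamma) * s + gamma * (np.trace(s) / d) * np.eye(d)
    weights = np.linalg.solve(shrunk, mu_high - mu_low)
    bias = -float(weights @ (mu_high + mu_low) / 2.0)
    logger.debug("LDA trained: d=%d, gamma=%.4f", d, gamma)
    return LdaModel(weights=weights, bias=bias, gamma=float(gamma))


def predict(model: LdaModel, features: FeatureMatrix):
    """Per-trial labels and signed scores.

    Positive (and exactly zero) scores map to ``class_order[1]``.
    """
    x = features.values
    if x.shape[1] != model.weights.size:
        raise ValueError(
            f"feature dimension {x.shape[1]} does not match model "
            f"dimension {model.weights.size}"
        )
    scores = x @ model.weights + model.bias
    labels = np.where(scores >= 0, model.class_order[1], model.class_order[0])
    return labels, scores


# ---------------------------------------------------------------------------
# model bundle serialization
# ---------------------------------------------------------------------------

def save_model_bundle(path: str | Path, *, lda: LdaModel,
                      selections: dict | None = None,
                      csp_models: dict | None = None,
                      fsf_model=None, variety: str = "fb") -> None:
    """Write spatial + selection + LDA models to one JSON file."""
    bundle: dict = {"variety": variety, "lda": lda.to_dict()}
    if selections:
        bundle["selections"] = {k: v.to_dict() for k, v in selections.items()}
    if csp_models:
        bundle["csp"] = {k: m.to_dict() for k, m in csp_models.items()}
    if fsf_model is not None:
        bundle["fsf"] = fsf_model.to_dict()
    Path(path).write_text(json.dumps(bundle, indent=1))


def load_model_bundle(path: str | Path) -> dict:
    from .erp import FsfModel
    from .oscillatory import CspModel

    bundle = json.loads(Path(path).read_text())
    out: dict = {"variety": bundle["variety"],
                 "lda": LdaModel.from_dict(bundle["lda"])}
    if "selections" in bundle:
        out["selections"] = {k: SelectionModel.from_dict(v)
                             for k, v in bundle["selections"].items()}
    if "csp" in bundle:
        out["csp"] = {k: CspModel.from_dict(v) for k, v in bundle["csp"].items()}
    if "fsf" in bundle:
        out["fsf"] = FsfModel.from_dict(bundle["fsf"])
    return out
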