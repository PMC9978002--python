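"""One-vs-All non-linear logistic regression for grasp stiffness recognition.

Each of the three stiffness classes (0 void, 1 rigid, 2 soft) gets a binary
logistic model: membership probability

    P(1 | x, w) = g(w·phi(x) + b),        g(z) = 1 / (1 + exp(-z)),

where ``phi`` is a polynomial feature expansion of the z-scored raw triple
(motor current, reference angle, encoder angle).  The "non-linear" part is
the expansion: degree 1 recovers plain logistic regression, degree 2 (the
default) adds squares and pairwise products, which lets a single sigmoid
carve the curved current/position boundary between soft steady-state grasps
and rigid transients.

Weights minimize the cross-entropy J by full-batch gradient descent from a
zero initialization.  Each binary model then gets its own decision
threshold TH, chosen on the validation split to maximize that class's
binary F1.  The multi-class decision compares every class probability with
its threshold: among classes that fire (p_k >= TH_k) the largest margin
p_k − TH_k wins; if none fires, the largest probability wins.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .dataset import LabeledDataset, Normalization
from .errors import (
    InsufficientData,
    InvalidLabel,
    LearningRateTooHigh,
    ModelInputMismatch,
    TraceTooShort,
)
from .simulator import GraspTrace

CLASSES = (0, 1, 2)

#: Per-closure decision window (s): terminal samples capture the
#: steady-state grasp regime the training protocol emphasizes.
DECISION_WINDOW_S = 0.5

#: Tie preference for the per-closure vote, most-current-consistent first
#: (a rigid grasp implies the highest steady current, void the lowest).
_VOTE_TIE_ORDER = (1, 2, 0)


def sigmoid(z):
    """Numerically stable logistic function, elementwise."""
    z = np.asarray(z, float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def expand_features(X: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial expansion (no constant term) of degrees 1..``degree``.

    For a 3-vector and degree 2 this yields 9 columns: the 3 linear terms,
    3 squares, and 3 pairwise products.
    """
    if degree < 1:
        raise ValueError("feature_degree must be a positive integer")
    X = np.atleast_2d(np.asarray(X, float))
    cols = []
    for d in range(1, degree + 1):
        for combo in itertools.combinations_with_replacement(range(X.shape[1]), d):
            col = np.ones(X.shape[0])
            for j in combo:
                col = col * X[:, j]
            cols.append(col)
    return np.column_stack(cols)


def n_expanded_features(n_raw: int, degree: int) -> int:
    return sum(
        len(list(itertools.combinations_with_replacement(range(n_raw), d)))
        for d in range(1, degree + 1)
    )


@dataclass
class TrainConfig:
    """Optimizer and threshold-search hyperparameters (not printed anywhere
    upstream; these are the package defaults)."""

    learning_rate: float = 0.1
    max_iterations: int = 5000
    convergence_tol: float = 1e-8
    l2_penalty: float = 0.0
    threshold_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.05, 0.9501, 0.01), 4)
    )
    feature_degree: int = 2
    shared_threshold: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        grid = np.asarray(self.threshold_grid, float)
        if grid.size and (np.any(grid <= 0) or np.any(grid >= 1) or np.any(np.diff(grid) < 0)):
            raise ValueError("threshold_grid must be sorted and inside (0, 1)")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be >= 0")


@dataclass
class BinaryNLR:
    """One binary membership model of the One-vs-All ensemble."""

    weights: np.ndarray
    bias: float
    threshold: float = 0.5
    feature_degree: int = 2
    positive_class: int = 1
    normalization: Optional[Normalization] = None
    j_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """w·phi(normalize(x)) + b for raw feature rows."""
        X = np.atleast_2d(np.asarray(X, float))
        if self.normalization is not None:
            X = self.normalization.apply(X)
        Xe = expand_features(X, self.feature_degree)
        if Xe.shape[1] != self.weights.size:
            raise ModelInputMismatch(
                f"expanded dimension {Xe.shape[1]} != weight dimension {self.weights.size}"
            )
        return Xe @ self.weights + self.bias


def predict_proba(model: BinaryNLR, x) -> float | np.ndarray:
    """Class-membership probability P(1 | x) for raw feature row(s)."""
    x = np.asarray(x, float)
    p = sigmoid(model.decision_values(x))
    return float(p[0]) if x.ndim == 1 else p


def cross_entropy(
    model: BinaryNLR, X: np.ndarray, y: np.ndarray, l2_penalty: float = 0.0
) -> float:
    """Mean cross-entropy J of the model on raw rows ``X`` with binary ``y``."""
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise InvalidLabel("binary labels must be in {0, 1}")
    p = sigmoid(model.decision_values(X))
    return _cost(p, y.astype(float), model.weights, l2_penalty)


_EPS = 1e-12


def _cost(p: np.ndarray, y: np.ndarray, w: np.ndarray, l2: float) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    m = y.size
    J = -(y @ np.log(p) + (1.0 - y) @ np.log(1.0 - p)) / m
    if l2:
        J += l2 * (w @ w) / (2.0 * m)
    return float(J)


def _grad(Xe: np.ndarray, p: np.ndarray, y: np.ndarray, w: np.ndarray, l2: float):
    m = y.size
    r = p - y
    gw = Xe.T @ r / m
    if l2:
        gw = gw + (l2 / m) * w
    return gw, float(r.sum() / m)


def fit_binary(
    X: np.ndarray,
    y_binary: np.ndarray,
    config: TrainConfig,
    normalization: Optional[Normalization] = None,
    positive_class: int = 1,
) -> BinaryNLR:
    """Fit one binary model by full-batch gradient descent from zero init.

    ``X`` holds raw feature rows; if ``normalization`` is omitted it is
    fitted on ``X``.  Training stops at ``max_iterations`` or when the
    relative decrease of J falls below ``convergence_tol``; the J trajectory
    is stored on the model.  A tenfold growth of J over its initial value
    raises :class:`LearningRateTooHigh`.
    """
    y = np.asarray(y_binary, float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise InvalidLabel("binary labels must be in {0, 1}")
    if y.min() == y.max():
        raise InsufficientData("both classes must be present to fit")
    X = np.atleast_2d(np.asarray(X, float))
    if normalization is None:
        normalization = Normalization.fit(X)
    Xe = expand_features(normalization.apply(X), config.feature_degree)
    w = np.zeros(Xe.shape[1])
    b = 0.0
    lr, l2 = config.learning_rate, config.l2_penalty
    history = np.empty(config.max_iterations + 1)
    p = sigmoid(Xe @ w + b)
    J = _cost(p, y, w, l2)
    history[0] = J
    J0 = J
    n_done = 0
    for it in range(1, config.max_iterations + 1):
        gw, gb = _grad(Xe, p, y, w, l2)
        w -= lr * gw
        b -= lr * gb
        p = sigmoid(Xe @ w + b)
        J_new = _cost(p, y, w, l2)
        history[it] = J_new
        n_done = it
        if J_new > 10.0 * J0:
            raise LearningRateTooHigh(
                f"cross-entropy grew from {J0:.4g} to {J_new:.4g}; lower learning_rate"
            )
        if J > 0 and abs(J - J_new) / max(J, _EPS) < config.convergence_tol:
            J = J_new
            break
        J = J_new
    return BinaryNLR(
        weights=w,
        bias=float(b),
        threshold=0.5,
        feature_degree=config.feature_degree,
        positive_class=positive_class,
        normalization=normalization,
        j_history=history[: n_done + 1].copy(),
    )


def _binary_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def optimize_threshold(
    model: BinaryNLR, X_val: np.ndarray, y_val: np.ndarray, grid: Sequence[float]
) -> float:
    """Grid-search TH maximizing the positive-class F1 on the validation set.

    Ties are broken toward the grid value closest to 0.5 (then toward the
    smaller value), so a flat objective returns the most neutral threshold.
    """
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    y_val = np.asarray(y_val, int)
    if y_val.min() == y_val.max():
        raise InsufficientData("validation set must contain both classes")
    p = sigmoid(model.decision_values(X_val))
    best_th, best_key = None, None
    for th in grid:
        f1 = _binary_f1(y_val, (p >= th).astype(int))
        key = (-f1, abs(th - 0.5), th)
        if best_key is None or key < best_key:
            best_key, best_th = key, float(th)
    return best_th


@dataclass
class OvAClassifier:
    """Three binary models (one per stiffness class) sharing one
    normalization and feature degree."""

    binaries: Dict[int, BinaryNLR]
    normalization: Normalization
    feature_degree: int = 2
    classes: tuple = CLASSES
    metadata: dict = field(default_factory=dict)

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """(m, 3) membership probabilities for raw feature rows."""
        X = np.atleast_2d(np.asarray(X, float))
        return np.column_stack(
            [sigmoid(self.binaries[c].decision_values(X)) for c in self.classes]
        )

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([self.binaries[c].threshold for c in self.classes])

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "feature_degree": self.feature_degree,
            "normalization": self.normalization.to_dict(),
            "metadata": self.metadata,
            "binaries": {
                str(c): {
                    "weights": m.weights.tolist(),
                    "bias": m.bias,
                    "threshold": m.threshold,
                    "positive_class": m.positive_class,
                }
                for c, m in self.binaries.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "OvAClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        norm = Normalization.from_dict(payload["normalization"])
        degree = int(payload["feature_degree"])
        binaries = {}
        for key, spec in payload["binaries"].items():
            binaries[int(key)] = BinaryNLR(
                weights=np.asarray(spec["weights"], float),
                bias=float(spec["bias"]),
                threshold=float(spec["threshold"]),
                feature_degree=degree,
                positive_class=int(spec["positive_class"]),
                normalization=norm,
            )
        return cls(
            binaries=binaries,
            normalization=norm,
            feature_degree=degree,
            classes=tuple(payload["classes"]),
            metadata=payload.get("metadata", {}),
        )


def decide(p: np.ndarray, thresholds: np.ndarray) -> int:
    """Multi-class resolution for one probability row.

    Classes whose probability reaches their threshold are candidates; the
    candidate with the largest margin p_k − TH_k wins.  With no candidate,
    the largest probability wins.  Exact ties go to the lower class index.
    """
    p = np.asarray(p, float)
    margins = p - thresholds
    fired = margins >= 0.0
    if fired.any():
        masked = np.where(fired, margins, -np.inf)
        return int(np.argmax(masked))
    return int(np.argmax(p))


def predict_sample(model: OvAClassifier, x):
    """Predicted class for one raw feature triple, or an array for rows."""
    x = np.asarray(x, float)
    P = model.probabilities(x)
    th = model.thresholds
    margins = P - th
    fired = margins >= 0.0
    masked = np.where(fired, margins, -np.inf)
    out = np.where(fired.any(axis=1), np.argmax(masked, axis=1), np.argmax(P, axis=1))
    return int(out[0]) if x.ndim == 1 else out.astype(int)


def predict_closure(
    model: OvAClassifier, trace: GraspTrace, window_s: float = DECISION_WINDOW_S
) -> int:
    """Per-closure decision: majority vote over the final ``window_s`` of
    the trace; vote ties prefer the class consistent with higher grasp
    current (rigid > soft > void)."""
    n_win = int(round(window_s * trace.sample_rate))
    if len(trace) < n_win or n_win < 1:
        raise TraceTooShort(
            f"trace has {len(trace)} samples; decision window needs {n_win}"
        )
    X = np.column_stack(
        [trace.current[-n_win:], trace.theta_ref[-n_win:], trace.theta_out[-n_win:]]
    )
    votes = predict_sample(model, X)
    counts = np.bincount(votes, minlength=3)
    best = counts.max()
    for c in _VOTE_TIE_ORDER:
        if counts[c] == best:
            return int(c)
    raise AssertionError("unreachable")


def fit_ova(ds: LabeledDataset, config: Optional[TrainConfig] = None) -> OvAClassifier:
    """Train the One-vs-All ensemble on a split dataset.

    One binary model per class is fitted on the training rows (class k vs
    rest); each threshold is then optimized on the validation rows.  With
    ``config.shared_threshold`` the mean of the three optimal thresholds is
    applied to every binary.
    """
    config = config or TrainConfig()
    X_tr, y_tr = ds.features("train"), ds.labels("train")
    X_val, y_val = ds.features("validation"), ds.labels("validation")
    if X_tr.size == 0 or X_val.size == 0:
        raise InsufficientData("dataset must carry train and validation splits")
    for split_name, y in (("train", y_tr), ("validation", y_val)):
        missing = set(CLASSES) - set(np.unique(y))
        if missing:
            raise InsufficientData(f"classes {sorted(missing)} absent from {split_name} split")
    norm = ds.normalization or Normalization.fit(X_tr)
    binaries: Dict[int, BinaryNLR] = {}
    for c in CLASSES:
        model = fit_binary(
            X_tr, (y_tr == c).astype(int), config, normalization=norm, positive_class=c
        )
        model.threshold = optimize_threshold(
            model, X_val, (y_val == c).astype(int), config.threshold_grid
        )
        binaries[c] = model
    if config.shared_threshold:
        th = float(np.mean([binaries[c].threshold for c in CLASSES]))
        for c in CLASSES:
            binaries[c].threshold = th
    return OvAClassifier(
        binaries=binaries,
        normalization=norm,
        feature_degree=config.feature_degree,
        metadata={
            "seed": config.seed,
            "learning_rate": config.learning_rate,
            "max_iterations": config.max_iterations,
            "l2_penalty": config.l2_penalty,
            "shared_threshold": config.shared_threshold,
            "provenance": {k: v for k, v in ds.provenance.items() if not isinstance(v, np.ndarray)},
        },
    )
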