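"""Confidence scoring for predicted interactions.

Alignment features of the two partners (sequence score, secondary-structure
score, length — supplied by the upstream threading stage), the interface size
Y_i and the two tree log-likelihoods L+ and L- enter a logistic model

    log p/(1-p) = alpha + beta1'X1 + beta2'X2 + beta_y*Y_i
                  + beta_plus*L+ + beta_minus*L-

whose output p in (0, 1) is the confidence that the pair interacts.  L+ and
L- are scalars (one tree each); any length-dependence of the raw
log-likelihoods is absorbed by the fitted weights.  Pairs with p at or above
the confidence cutoff (default 0.6) are called high-confidence.

Fitting is L2-penalized maximum likelihood on standardized features
(scikit-learn's lbfgs solver); a small penalty is always applied because L+
and L- can be nearly collinear.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .interface import InterfaceAssignment
from .tree import InterfaceProfilePair, score_interface

FEATURE_COLUMNS = (
    "seq_score_a",
    "ss_score_a",
    "len_a",
    "seq_score_b",
    "ss_score_b",
    "len_b",
    "interface_size",
    "l_plus",
    "l_minus",
)

DEFAULT_CUTOFF = 0.6


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentFeatures:
    """Per-protein features from the threading/alignment stage."""

    seq_score: float
    ss_score: float
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be positive")
        for name in ("seq_score", "ss_score"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"alignment feature {name!r} is not finite")


@dataclass(frozen=True)
class FeatureVector:
    """One row of the classifier design: alignment + interface features."""

    x1: AlignmentFeatures
    x2: AlignmentFeatures
    yi: int
    l_plus: float
    l_minus: float

    def __post_init__(self) -> None:
        if self.yi < 0:
            raise ValueError("interface size must be non-negative")
        if not (math.isfinite(self.l_plus) and math.isfinite(self.l_minus)):
            raise ValueError("tree log-likelihoods must be finite")

    def to_array(self) -> np.ndarray:
        return np.array(
            [
                self.x1.seq_score,
                self.x1.ss_score,
                self.x1.length,
                self.x2.seq_score,
                self.x2.ss_score,
                self.x2.length,
                self.yi,
                self.l_plus,
                self.l_minus,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class QueryRecord:
    """A query pair's alignment features as delivered by the threading stage."""

    pair_id: str
    features_a: AlignmentFeatures
    features_b: AlignmentFeatures

    @classmethod
    def from_mapping(cls, d: Mapping) -> "QueryRecord":
        for key in ("pair_id", "seq_score_a", "ss_score_a", "len_a",
                    "seq_score_b", "ss_score_b", "len_b"):
            if key not in d or (isinstance(d[key], float) and math.isnan(d[key])):
                raise ValueError(f"missing alignment feature {key!r}")
        return cls(
            pair_id=str(d["pair_id"]),
            features_a=AlignmentFeatures(
                float(d["seq_score_a"]), float(d["ss_score_a"]), int(d["len_a"])
            ),
            features_b=AlignmentFeatures(
                float(d["seq_score_b"]), float(d["ss_score_b"]), int(d["len_b"])
            ),
        )


def extract_features(
    query_record: QueryRecord,
    assignment: InterfaceAssignment,
    profile_pair: InterfaceProfilePair,
) -> FeatureVector:
    """Assemble the classifier features for one query pair.

    Y_i is the interface node count of the family profile; L+ and L- are the
    assignment's log-likelihoods under the positive and negative trees.
    """
    nodes = profile_pair.positive.nodes
    if len(nodes) == 0:
        raise ValueError("no interface model: the family profile has zero interface nodes")
    l_plus, l_minus = score_interface(assignment, profile_pair)
    return FeatureVector(
        x1=query_record.features_a,
        x2=query_record.features_b,
        yi=len(nodes),
        l_plus=l_plus,
        l_minus=l_minus,
    )


# ---------------------------------------------------------------------------
# labeled datasets
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Pairs with binary interaction labels and classifier features."""

    frame: pd.DataFrame  # columns: pair_id, label, *FEATURE_COLUMNS

    def __post_init__(self) -> None:
        required = ["pair_id", "label", *FEATURE_COLUMNS]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if self.frame["pair_id"].duplicated().any():
            dup = self.frame.loc[self.frame["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise ValueError(f"duplicate pair id {dup!r}")
        if not set(self.frame["label"].unique()) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        feats = self.frame[list(FEATURE_COLUMNS)].to_numpy(float)
        if not np.all(np.isfinite(feats)):
            raise ValueError("non-finite feature value in dataset")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def features(self) -> np.ndarray:
        return self.frame[list(FEATURE_COLUMNS)].to_numpy(float)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(int)

    @property
    def pair_ids(self) -> list[str]:
        return self.frame["pair_id"].astype(str).tolist()

    @classmethod
    def from_rows(
        cls,
        pair_ids: Sequence[str],
        feature_vectors: Sequence[FeatureVector],
        labels: Sequence[int],
    ) -> "LabeledDataset":
        rows = np.stack([fv.to_array() for fv in feature_vectors]) if feature_vectors else np.empty((0, 9))
        frame = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
        frame.insert(0, "label", list(labels))
        frame.insert(0, "pair_id", list(pair_ids))
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LabeledDataset":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------
# the logistic model
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    """Fitted logistic model with its standardization, self-contained for prediction.

    Coefficients are stored in standardized feature space; ``coefficients()``
    maps them back to the original units.
    """

    alpha: float
    beta: np.ndarray  # (9,) on standardized features, FEATURE_COLUMNS order
    mean: np.ndarray
    scale: np.ndarray
    regularization: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.mean = np.asarray(self.mean, float)
        self.scale = np.asarray(self.scale, float)
        k = len(FEATURE_COLUMNS)
        if self.beta.shape != (k,) or self.mean.shape != (k,) or self.scale.shape != (k,):
            raise ValueError(f"coefficient/standardization vectors must have length {k}")

    # named views onto the coefficient vector (standardized space)
    @property
    def beta1(self) -> np.ndarray:
        return self.beta[0:3]

    @property
    def beta2(self) -> np.ndarray:
        return self.beta[3:6]

    @property
    def beta_y(self) -> float:
        return float(self.beta[6])

    @property
    def beta_plus(self) -> float:
        return float(self.beta[7])

    @property
    def beta_minus(self) -> float:
        return float(self.beta[8])

    def coefficients(self) -> tuple[float, np.ndarray]:
        """(alpha, beta) on the original (unstandardized) feature scale."""
        beta_orig = self.beta / self.scale
        alpha_orig = self.alpha - float(np.sum(self.beta * self.mean / self.scale))
        return alpha_orig, beta_orig

    def decision(self, x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x) - self.mean) / self.scale
        return self.alpha + z @ self.beta

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision(x)))

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta.tolist(),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "regularization": self.regularization,
            "feature_columns": list(FEATURE_COLUMNS),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticModel":
        return cls(
            alpha=float(d["alpha"]),
            beta=np.asarray(d["beta"], float),
            mean=np.asarray(d["mean"], float),
            scale=np.asarray(d["scale"], float),
            regularization=float(d["regularization"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def train_logistic(
    dataset: LabeledDataset,
    regularization: float = 1.0,
    rng_seed: int = 0,
) -> LogisticModel:
    """Fit the logistic model by L2-penalized maximum likelihood.

    Features are standardized to zero mean / unit variance first (constants
    are left unscaled); the intercept is unpenalized.  Deterministic given the
    data: lbfgs from a fixed start, gradient tolerance 1e-10.
    """
    if len(dataset) < 2:
        raise ValueError("need at least two rows")
    y = dataset.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    if regularization < 0:
        raise ValueError("regularization must be non-negative")
    x = dataset.features
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - mean) / scale
    c = 1.0 / regularization if regularization > 0 else 1e12
    clf = LogisticRegression(
        C=c,
        solver="lbfgs",
        tol=1e-10,
        max_iter=20000,
        random_state=rng_seed,
    )
    clf.fit(z, y)
    return LogisticModel(
        alpha=float(clf.intercept_[0]),
        beta=clf.coef_[0].copy(),
        mean=mean,
        scale=scale,
        regularization=regularization,
    )


def predict_confidence(model: LogisticModel, feature_vector: FeatureVector) -> float:
    """Confidence p in (0, 1) that the pair interacts."""
    p = float(model.predict(feature_vector.to_array())[0])
    # clamp away exact 0/1 from floating underflow
    return min(max(p, np.finfo(float).tiny), 1.0 - np.finfo(float).epsneg)


def classify_high_confidence(p: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """High-confidence iff p >= cutoff (boundary inclusive)."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must be in [0, 1]")
    return p >= cutoff


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    """Sensitivity/specificity swept over all distinct score thresholds."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def sensitivity_at_specificity(self, target: float) -> float:
        """Highest sensitivity achievable at specificity >= target."""
        ok = self.specificity >= target
        return float(self.sensitivity[ok].max()) if ok.any() else 0.0


def roc_curve(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC by sweeping every distinct score as an inclusive positive threshold.

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP); tied scores
    collapse to one threshold; AUC by the trapezoidal rule.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.nonzero(np.diff(s))[0]  # last index of each tied block
    block_ends = np.concatenate([distinct, [len(s) - 1]])
    tp_cum = np.cumsum(y == 1)
    fp_cum = np.cumsum(y == 0)
    tp = tp_cum[block_ends].astype(float)
    fp = fp_cum[block_ends].astype(float)
    thresholds = s[block_ends]

    sens = np.concatenate([[0.0], tp / n_pos])
    spec = np.concatenate([[1.0], 1.0 - fp / n_neg])
    thresholds = np.concatenate([[np.inf], thresholds])
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(thresholds, sens, spec, auc)


@dataclass
class CVResult:
    """Stratified k-fold (optionally repeated) cross-validation summary."""

    fold_aucs: np.ndarray  # (n_repeats, k)
    specificity_grid: tuple[float, ...]
    sensitivity_mean: np.ndarray  # per grid point
    sensitivity_sd: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(self.fold_aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.fold_aucs.std(ddof=1)) if self.fold_aucs.size > 1 else 0.0


def cross_validate(
    dataset: LabeledDataset,
    k: int = 5,
    n_repeats: int = 1,
    rng_seed: int = 0,
    regularization: float = 1.0,
    specificity_grid: Sequence[float] = (0.5, 0.8, 0.9, 0.95),
) -> CVResult:
    """Stratified k-fold CV of the logistic model, deterministic given the seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = dataset.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows; cannot stratify into {k} folds"
        )
    fold_aucs = np.empty((n_repeats, k))
    sens_grid: list[list[float]] = [[] for _ in specificity_grid]
    frame = dataset.frame
    for rep in range(n_repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed + rep)
        for fold, (train_idx, test_idx) in enumerate(splitter.split(frame, y)):
            train = LabeledDataset(frame.iloc[train_idx].reset_index(drop=True))
            model = train_logistic(train, regularization, rng_seed)
            p = model.predict(dataset.features[test_idx])
            curve = roc_curve(p, y[test_idx])
            fold_aucs[rep, fold] = curve.auc
            for g, target in enumerate(specificity_grid):
                sens_grid[g].append(curve.sensitivity_at_specificity(target))
    sens = np.array([np.mean(v) for v in sens_grid])
    sens_sd = np.array([np.std(v, ddof=1) if len(v) > 1 else 0.0 for v in sens_grid])
    return CVResult(fold_aucs, tuple(specificity_grid), sens, sens_sd)


def association_test(
    predicted_labels: Sequence[int], reference_labels: Sequence[int]
) -> tuple[float, float]:
    """2x2 association between predicted and reference binary labels.

    Returns (odds_ratio, two-sided Fisher exact p-value); the odds ratio uses
    the Haldane 0.5 correction when any cell is empty.
    """
    pred = np.asarray(predicted_labels, int)
    ref = np.asarray(reference_labels, int)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("label vectors must be the same non-zero length")
    if not (set(pred.tolist()) <= {0, 1} and set(ref.tolist()) <= {0, 1}):
        raise ValueError("labels must be binary")
    table = np.array(
        [
            [int(np.sum((pred == 1) & (ref == 1))), int(np.sum((pred == 1) & (ref == 0)))],
            [int(np.sum((pred == 0) & (ref == 1))), int(np.sum((pred == 0) & (ref == 0)))],
        ]
    )
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds_ratio), float(p_value)
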