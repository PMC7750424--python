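"""Three-class production-rate predictor over amino-acid count features.

Antibody variant production is normalized to a reference construct (100%),
categorized as low (< 20%), medium (20–70%, boundaries inclusive) or high
(> 70%), and predicted from the 20 amino-acid counts of the variant with a
one-vs-rest L2-regularized logistic model:

    P(y_k | x) = 1 / (1 + exp(-(b0_k + beta_k . x)))

one sigmoid per class, NOT a softmax; the predicted label is the class
with the highest score (ties toward the lower class index).  The
regularization strength is tuned by 20-fold cross-validation (95%/5%
train/validation per cycle) maximizing weighted precision, samples are
weighted by inverse class frequency to counter class imbalance, and the
whole train/test protocol runs in triplicate from a base seed.

Evaluation uses the mean pairwise (one-vs-one) ROC AUC, weighted F1 and
weighted precision, against a stratified dummy baseline.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata

from .amino_acids import ALPHABET

logger = logging.getLogger(__name__)

#: Fixed feature order: the 20 one-letter codes, alphabetical.
FEATURE_ORDER: tuple[str, ...] = tuple(ALPHABET)

CLASS_NAMES = {0: "low", 1: "medium", 2: "high"}


# ---------------------------------------------------------------------------
# labels


@dataclass(frozen=True)
class LabelScheme:
    """Production-rate cuts, in % of the reference construct."""

    low_cut: float = 20.0
    high_cut: float = 70.0

    def __post_init__(self) -> None:
        if not (0 < self.low_cut < self.high_cut):
            raise ValueError("require 0 < low_cut < high_cut")


DEFAULT_SCHEME = LabelScheme()


def normalize_rate(raw_quantity: float, reference_quantity: float) -> float:
    """Production rate as % of the reference construct; may exceed 100."""
    if not reference_quantity > 0:
        raise ValueError(f"reference quantity must be positive, got {reference_quantity}")
    return 100.0 * raw_quantity / reference_quantity


def categorize(rate: float, scheme: LabelScheme = DEFAULT_SCHEME) -> int:
    """Map a % rate to 0 (low), 1 (medium) or 2 (high).

    Low is strictly below ``low_cut`` and high strictly above ``high_cut``;
    both boundary values are medium.
    """
    if not math.isfinite(rate) or rate < 0:
        raise ValueError(f"rate must be finite and non-negative, got {rate}")
    if rate < scheme.low_cut:
        return 0
    if rate > scheme.high_cut:
        return 2
    return 1


@dataclass(frozen=True)
class VariantRecord:
    """A variant's amino-acid count features and its production rate."""

    id: str
    features: np.ndarray  # counts in FEATURE_ORDER
    production_rate: float
    label: int = field(init=False)
    scheme: LabelScheme = field(default=DEFAULT_SCHEME, repr=False, compare=False)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(feats)) or np.any(feats < 0):
            raise ValueError(f"{self.id}: features must be finite and non-negative")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "label", categorize(self.production_rate, self.scheme))


def records_to_xy(records: Sequence[VariantRecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([r.features for r in records])
    y = np.array([r.label for r in records], dtype=int)
    return X, y


def load_dataset(path, scheme: LabelScheme = DEFAULT_SCHEME) -> list[VariantRecord]:
    """Read the dataset CSV: id, the 20 count columns A..Y, production_rate.

    Labels are derived from the rate under ``scheme``, never stored.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("id", "production_rate", *FEATURE_ORDER) if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV missing columns: {missing}")
    return [
        VariantRecord(
            id=str(row["id"]),
            features=row[list(FEATURE_ORDER)].to_numpy(dtype=float),
            production_rate=float(row["production_rate"]),
            scheme=scheme,
        )
        for _, row in df.iterrows()
    ]


def save_dataset(records: Sequence[VariantRecord], path) -> None:
    rows = [
        {"id": r.id, **dict(zip(FEATURE_ORDER, r.features)), "production_rate": r.production_rate}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# the logistic model


@dataclass(frozen=True)
class LogisticModel:
    """One-vs-rest logistic predictor with per-feature standardization.

    ``intercepts[k]`` and ``coefficients[k]`` parametrize the class-k
    sigmoid on standardized features ``(x - mu) / sd``; ``mu``/``sd``
    default to the identity transform.
    """

    intercepts: np.ndarray  # (k,)
    coefficients: np.ndarray  # (k, d)
    lam: float = 0.0
    mu: np.ndarray | None = None
    sd: np.ndarray | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b0 = np.asarray(self.intercepts, dtype=float)
        B = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        if b0.shape[0] != B.shape[0]:
            raise ValueError("one intercept per coefficient vector required")
        if not (np.all(np.isfinite(b0)) and np.all(np.isfinite(B))):
            raise ValueError("model parameters must be finite")
        object.__setattr__(self, "intercepts", b0)
        object.__setattr__(self, "coefficients", B)

    @property
    def n_classes(self) -> int:
        return self.intercepts.shape[0]

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[1]

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.mu is None or self.sd is None:
            return X
        return (X - self.mu) / self.sd

    def class_probability(self, x: np.ndarray) -> np.ndarray:
        """Per-class sigmoid scores of the affine model, each in [0, 1].

        One-vs-rest: the scores need not sum to 1; use
        :meth:`normalized_scores` where a probability simplex is needed.
        """
        X = np.atleast_2d(np.asarray(x, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match model ({self.n_features})"
            )
        Z = self._standardize(X)
        scores = expit(self.intercepts + Z @ self.coefficients.T)
        return scores[0] if np.ndim(x) == 1 else scores

    def normalized_scores(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid scores divided by their sum (view for ranking metrics)."""
        p = np.atleast_2d(self.class_probability(x))
        total = p.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        out = p / total
        return out[0] if np.ndim(x) == 1 else out

    def predict(self, x: np.ndarray) -> np.ndarray | int:
        """Label with the highest class score; ties toward the lower index."""
        p = np.atleast_2d(self.class_probability(x))
        labels = np.argmax(p, axis=1)  # argmax takes the first maximum
        return int(labels[0]) if np.ndim(x) == 1 else labels

    def to_dict(self) -> dict:
        return {
            "classes": list(range(self.n_classes)),
            "intercepts": self.intercepts.tolist(),
            "coefficients": self.coefficients.tolist(),
            "lambda": self.lam,
            "mu": None if self.mu is None else np.asarray(self.mu).tolist(),
            "sd": None if self.sd is None else np.asarray(self.sd).tolist(),
            "metadata": dict(self.metadata),
        }

    def to_json(self, handle) -> None:
        json.dump(self.to_dict(), handle, indent=2)
        handle.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "LogisticModel":
        return cls(
            intercepts=np.asarray(d["intercepts"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            lam=float(d.get("lambda", 0.0)),
            mu=None if d.get("mu") is None else np.asarray(d["mu"], dtype=float),
            sd=None if d.get("sd") is None else np.asarray(d["sd"], dtype=float),
            metadata=dict(d.get("metadata", {})),
        )


def class_probability(model: LogisticModel, x: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`LogisticModel.class_probability`."""
    return model.class_probability(x)


def predict(model: LogisticModel, x: np.ndarray):
    """Functional alias for :meth:`LogisticModel.predict`."""
    return model.predict(x)


# ---------------------------------------------------------------------------
# penalized binary fits


def fit_penalized_logistic(
    X: np.ndarray,
    y01: np.ndarray,
    lam: float,
    sample_weight: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray, list[float]]:
    """Minimize the weighted, L2-penalized binary negative log-likelihood.

    Objective: -sum_i w_i [y_i log s_i + (1-y_i) log(1-s_i)] + (lam/2)||beta||^2,
    with the intercept unpenalized.  Quasi-Newton (L-BFGS-B) with analytic
    gradient, stopping at projected-gradient norm <= ``tol`` or ``max_iter``
    iterations.  Returns (intercept, coefficients, objective trajectory).
    """
    n, d = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)

    def objective(theta):
        b0, beta = theta[0], theta[1:]
        s = b0 + X @ beta
        # log(1+exp(s)) - y*s, numerically stable via logaddexp
        nll = np.sum(w * (np.logaddexp(0.0, s) - y01 * s))
        return nll + 0.5 * lam * beta @ beta

    def gradient(theta):
        b0, beta = theta[0], theta[1:]
        p = expit(b0 + X @ beta)
        r = w * (p - y01)
        return np.concatenate(([r.sum()], X.T @ r + lam * beta))

    trajectory: list[float] = []

    res = minimize(
        objective,
        np.zeros(d + 1),
        jac=gradient,
        method="L-BFGS-B",
        callback=lambda theta: trajectory.append(float(objective(theta))),
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-14},
    )
    return float(res.x[0]), res.x[1:].copy(), trajectory


def _class_weights(y: np.ndarray, mode) -> np.ndarray:
    """Per-sample weights; ``'balanced'`` = inverse class frequency."""
    if mode is None:
        return np.ones(len(y))
    if mode == "balanced":
        classes, counts = np.unique(y, return_counts=True)
        per_class = {c: len(y) / (len(classes) * n) for c, n in zip(classes, counts)}
    elif isinstance(mode, Mapping):
        per_class = dict(mode)
    else:
        raise ValueError(f"unsupported class_weight {mode!r}")
    return np.array([per_class[c] for c in y], dtype=float)


def _fit_ovr(X, y, classes, lam, class_weight, max_iter, tol=1e-6):
    w = _class_weights(y, class_weight)
    intercepts, coefs = [], []
    for k in classes:
        b0, beta, _ = fit_penalized_logistic(
            X, (y == k).astype(float), lam, sample_weight=w, max_iter=max_iter, tol=tol
        )
        intercepts.append(b0)
        coefs.append(beta)
    return np.array(intercepts), np.vstack(coefs)


DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-4, 4, 10))


def fit(
    records: Sequence[VariantRecord],
    lambda_grid: Iterable[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 20,
    max_iter: int = 1000,
    class_weight="balanced",
    seed: int = 0,
) -> LogisticModel:
    """Cross-validated one-vs-rest fit on a model set.

    For each candidate regularization strength, a ``folds``-fold CV over a
    seeded permutation of the records scores the held-out weighted
    precision (folds whose training part misses a class are skipped with a
    warning); the strength with the best mean validation score (ties to
    the smaller, i.e. less-penalized toward zero coefficients last) is
    refit on all records.  Features are z-scored on the training portion
    of each fold and on the full set for the final model.
    """
    X, y = records_to_xy(records)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("fit requires at least two classes present")
    grid = sorted(set(float(l) for l in lambda_grid))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    chunks = np.array_split(order, folds)

    def standardize_params(Xp):
        mu = Xp.mean(axis=0)
        sd = Xp.std(axis=0)
        sd[sd == 0] = 1.0
        return mu, sd

    cv_scores: dict[float, float] = {}
    cv_detail: dict[float, list[float]] = {}
    for lam in grid:
        scores = []
        for i, val_idx in enumerate(chunks):
            if val_idx.size == 0:
                continue
            train_idx = np.setdiff1d(order, val_idx)
            ytr = y[train_idx]
            if np.unique(ytr).size < classes.size:
                logger.warning("fold %d skipped: a class is absent from training", i)
                continue
            mu, sd = standardize_params(X[train_idx])
            Ztr = (X[train_idx] - mu) / sd
            b0, B = _fit_ovr(Ztr, ytr, classes, lam, class_weight, max_iter)
            m = LogisticModel(intercepts=b0, coefficients=B)
            pred = m.predict((X[val_idx] - mu) / sd)
            scores.append(weighted_precision(y[val_idx], pred))
        if not scores:
            raise ValueError("all cross-validation folds were skipped")
        cv_scores[lam] = float(np.mean(scores))
        cv_detail[lam] = scores
        logger.debug("lambda=%.3g mean weighted precision=%.4f", lam, cv_scores[lam])
    best_lam = min(grid, key=lambda l: (-cv_scores[l], l))

    mu, sd = standardize_params(X)
    b0, B = _fit_ovr((X - mu) / sd, y, classes, best_lam, class_weight, max_iter)
    return LogisticModel(
        intercepts=b0,
        coefficients=B,
        lam=best_lam,
        mu=mu,
        sd=sd,
        metadata={
            "folds": folds,
            "max_iter": max_iter,
            "seed": seed,
            "cv_weighted_precision": cv_scores,
            "n_train": len(records),
        },
    )


# ---------------------------------------------------------------------------
# metrics


def _per_class_counts(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    classes = np.unique(y_true)
    stats = {}
    for k in classes:
        tp = np.sum((y_pred == k) & (y_true == k))
        fp = np.sum((y_pred == k) & (y_true != k))
        fn = np.sum((y_pred != k) & (y_true == k))
        stats[int(k)] = (int(tp), int(fp), int(fn), int(np.sum(y_true == k)))
    return stats, y_true.size


def per_class_precision_recall(y_true, y_pred) -> dict[int, dict[str, float]]:
    stats, _ = _per_class_counts(y_true, y_pred)
    out = {}
    for k, (tp, fp, fn, _) in stats.items():
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        out[k] = {"precision": precision, "recall": recall}
    return out


def weighted_precision(y_true, y_pred) -> float:
    """Support-weighted mean of per-class precision.

    A class present in the truth but never predicted contributes
    precision 0 (logged), so models that ignore a class are penalized.
    """
    stats, n = _per_class_counts(y_true, y_pred)
    total = 0.0
    for k, (tp, fp, fn, support) in stats.items():
        if tp + fp == 0:
            logger.debug("class %d never predicted; precision counted as 0", k)
            precision = 0.0
        else:
            precision = tp / (tp + fp)
        total += (support / n) * precision
    return total


def weighted_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class F1 (0 where undefined)."""
    stats, n = _per_class_counts(y_true, y_pred)
    total = 0.0
    for k, (tp, fp, fn, support) in stats.items():
        precision = tp / (tp + fp) if tp + fp > 0 else 0.0
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        total += (support / n) * f1
    return total


def _binary_auc(pos_mask: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for the positive class; ties count 0.5."""
    n_pos = int(pos_mask.sum())
    n_neg = int((~pos_mask).sum())
    ranks = rankdata(scores)
    return (ranks[pos_mask].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pairwise_auc(y_true, class_scores) -> float:
    """Mean one-vs-one ROC AUC over all unordered class pairs.

    For a pair (j, k) the samples of the two classes are isolated, the AUC
    of the class-k score column (k positive) and of the class-j column (j
    positive) are averaged; the final score is the mean over pairs.  Pairs
    with an absent class are skipped with a log message.
    """
    y_true = np.asarray(y_true)
    S = np.atleast_2d(np.asarray(class_scores, dtype=float))
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValueError("pairwise AUC requires at least two classes in y_true")
    vals = []
    n_classes = S.shape[1]
    for j in range(n_classes):
        for k in range(j + 1, n_classes):
            mask = (y_true == j) | (y_true == k)
            if not (np.any(y_true == j) and np.any(y_true == k)):
                logger.debug("pair (%d, %d) skipped: a class is absent", j, k)
                continue
            yk = y_true[mask] == k
            auc_k = _binary_auc(yk, S[mask, k])
            auc_j = _binary_auc(~yk, S[mask, j])
            vals.append((auc_j + auc_k) / 2)
    if not vals:
        raise ValueError("no class pair had both classes present")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# protocol: split / baseline / replicates


@dataclass(frozen=True)
class SplitPlan:
    """Partition sizes for model set M and test sets T_a, T_b."""

    sizes: tuple[int, int, int] = (118, 30, 20)
    seed: int = 0
    replicate: int = 0

    @classmethod
    def proportional(cls, n: int, seed: int = 0, replicate: int = 0) -> "SplitPlan":
        """Scale the 118:30:20 reference sizes to ``n`` (largest remainder)."""
        if n < 3:
            raise ValueError("need at least 3 records to split")
        ref = np.array([118, 30, 20], dtype=float)
        exact = ref / ref.sum() * n
        sizes = np.floor(exact).astype(int)
        remainder = exact - sizes
        for i in np.argsort(-remainder)[: n - sizes.sum()]:
            sizes[i] += 1
        return cls(sizes=tuple(int(s) for s in sizes), seed=seed, replicate=replicate)


def split(
    records: Sequence[VariantRecord], plan: SplitPlan
) -> tuple[list[VariantRecord], list[VariantRecord], list[VariantRecord]]:
    """Uniform random disjoint partition into (M, T_a, T_b).

    Reproducible from the plan's seed; the replicate index advances the
    stream deterministically.
    """
    if sum(plan.sizes) != len(records):
        raise ValueError(
            f"plan sizes {plan.sizes} sum to {sum(plan.sizes)}, dataset has {len(records)}"
        )
    rng = np.random.default_rng(plan.seed + plan.replicate)
    order = rng.permutation(len(records))
    n_m, n_a, _ = plan.sizes
    idx_m = order[:n_m]
    idx_a = order[n_m : n_m + n_a]
    idx_b = order[n_m + n_a :]
    take = lambda idx: [records[i] for i in idx]
    return take(idx_m), take(idx_a), take(idx_b)


@dataclass(frozen=True)
class DummyBaseline:
    """Chance-level control: class scores are the training priors.

    ``stratified`` predicts by sampling labels from the priors;
    ``most_frequent`` always predicts the modal class.
    """

    classes: np.ndarray
    priors: np.ndarray
    strategy: str = "stratified"
    seed: int = 0

    def class_scores(self, X: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(X).shape[0]
        return np.tile(self.priors, (n, 1))

    def predict(self, X: np.ndarray) -> np.ndarray:
        n = np.atleast_2d(X).shape[0]
        if self.strategy == "most_frequent":
            return np.full(n, self.classes[int(np.argmax(self.priors))])
        rng = np.random.default_rng(self.seed)
        return rng.choice(self.classes, size=n, p=self.priors)


def dummy_baseline(
    records: Sequence[VariantRecord], seed: int = 0, strategy: str = "stratified"
) -> DummyBaseline:
    if not records:
        raise ValueError("dummy baseline requires at least one training record")
    if strategy not in ("stratified", "most_frequent"):
        raise ValueError(f"unknown strategy {strategy!r}")
    _, y = records_to_xy(records)
    classes, counts = np.unique(y, return_counts=True)
    return DummyBaseline(
        classes=classes, priors=counts / counts.sum(), strategy=strategy, seed=seed
    )


@dataclass(frozen=True)
class EvalReport:
    """Scores of one predictor on one test set of one replicate."""

    kind: str  # "model" | "dummy"
    replicate: int
    test_set: str  # "T_a" | "T_b"
    seed: int
    pairwise_auc: float
    weighted_f1: float
    weighted_precision: float
    per_class: Mapping[int, Mapping[str, float]]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "replicate": self.replicate,
            "test_set": self.test_set,
            "seed": self.seed,
            "pairwise_auc": self.pairwise_auc,
            "weighted_f1": self.weighted_f1,
            "weighted_precision": self.weighted_precision,
            "per_class": {CLASS_NAMES.get(k, str(k)): dict(v) for k, v in self.per_class.items()},
        }


def _evaluate(kind, predictor, test_records, replicate, test_set, seed) -> EvalReport:
    X, y = records_to_xy(test_records)
    if kind == "model":
        scores = predictor.normalized_scores(X)
    else:
        scores = predictor.class_scores(X)
    pred = predictor.predict(X)
    return EvalReport(
        kind=kind,
        replicate=replicate,
        test_set=test_set,
        seed=seed,
        pairwise_auc=pairwise_auc(y, scores),
        weighted_f1=weighted_f1(y, pred),
        weighted_precision=weighted_precision(y, pred),
        per_class=per_class_precision_recall(y, pred),
    )


def run_replicates(
    records: Sequence[VariantRecord],
    n_replicates: int = 3,
    base_seed: int = 0,
    lambda_grid: Iterable[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 20,
    max_iter: int = 1000,
    class_weight="balanced",
) -> list[EvalReport]:
    """Full protocol: split, fit, evaluate on T_a and T_b, with a baseline.

    Returns one report per (replicate, test set, predictor): 6 model and 6
    dummy reports for the default 3 replicates.  All randomness derives
    from ``base_seed``; reruns are bit-identical.
    """
    reports: list[EvalReport] = []
    for r in range(n_replicates):
        plan = SplitPlan.proportional(len(records), seed=base_seed, replicate=r)
        model_set, test_a, test_b = split(records, plan)
        fit_seed = base_seed + 1000 + r
        model = fit(
            model_set,
            lambda_grid=lambda_grid,
            folds=folds,
            max_iter=max_iter,
            class_weight=class_weight,
            seed=fit_seed,
        )
        dummy = dummy_baseline(model_set, seed=base_seed + 2000 + r)
        for name, subset in (("T_a", test_a), ("T_b", test_b)):
            reports.append(_evaluate("model", model, subset, r, name, fit_seed))
            reports.append(_evaluate("dummy", dummy, subset, r, name, dummy.seed))
    return reports


def reports_to_json(reports: Sequence[EvalReport], handle) -> None:
    """Serialize replicate reports with per-kind aggregate means."""
    payload: dict = {"reports": [r.to_dict() for r in reports], "aggregate": {}}
    for kind in ("model", "dummy"):
        sub = [r for r in reports if r.kind == kind]
        if sub:
            payload["aggregate"][kind] = {
                "mean_pairwise_auc": float(np.mean([r.pairwise_auc for r in sub])),
                "mean_weighted_f1": float(np.mean([r.weighted_f1 for r in sub])),
                "mean_weighted_precision": float(
                    np.mean([r.weighted_precision for r in sub])
                ),
            }
    json.dump(payload, handle, indent=2)
    handle.write("\n")
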