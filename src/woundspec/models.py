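"""Outcome classifiers: univariate threshold, PCA, PLSDA, and the sequential
two-stage wound classifier, plus stratified splitting and permutation tests.

PLSDA here is PLS1 regression (NIPALS) of a 0/1 class dummy on autoscaled
predictors, thresholded at 0.5. The two-stage ("hierarchical") classifier
first separates delayed-healing wounds from the rest, then discriminates
healed from dehisced among the not-delayed; wounds routed to "delayed" are
reported as healed, so the final label space is {healed, dehisced}.

Permutation tests estimate the probability that a label-shuffled model
matches the observed cross-validated accuracy (the model's "probability of
insignificance"): small p indicates the fitted model is not explained by
overfitting alone.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MODEL_PREDICTORS

__all__ = [
    "LabeledDataset",
    "PLSDAModel",
    "HierarchicalWoundClassifier",
    "SplitSpec",
    "PermutationResult",
    "threshold_classify",
    "stratified_indices",
    "stratified_split",
    "pca_fit",
    "plsda_fit",
    "plsda_predict",
    "fit_hierarchical",
    "predict_hierarchical",
    "permutation_test",
    "cross_val_accuracy",
    "plsda_recipe",
    "hierarchical_recipe",
    "collapse_to_binary",
]

POSITIVE = "dehisced"


def collapse_to_binary(y3) -> np.ndarray:
    """Map the three-class outcome to the binary one: healed and delayed
    wounds are both 'healed'; dehisced stays 'dehisced'."""
    y3 = np.asarray(y3, dtype=object)
    return np.where(y3 == POSITIVE, POSITIVE, "healed").astype(object)


@dataclass(frozen=True)
class LabeledDataset:
    """Predictor matrix (canonical 17-column order) with three-class labels."""

    X: np.ndarray
    y3: np.ndarray
    ids: np.ndarray
    predictor_names: tuple = MODEL_PREDICTORS

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y3 = np.asarray(self.y3, dtype=object)
        ids = np.asarray(self.ids)
        if X.shape[0] != y3.shape[0] or X.shape[0] != ids.shape[0]:
            raise ValueError("X, y3 and ids must have matching lengths")
        if np.isnan(X).any():
            raise ValueError("dataset contains missing predictors; drop rows first")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y3", y3)
        object.__setattr__(self, "ids", ids)

    @property
    def y2(self) -> np.ndarray:
        return collapse_to_binary(self.y3)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y3[idx], self.ids[idx],
                              self.predictor_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, predictors=MODEL_PREDICTORS,
                   id_col: str = "image_id", outcome_col: str = "outcome",
                   log=None) -> "LabeledDataset":
        """Build from a feature table, dropping rows with missing predictors
        (the number dropped is reported through ``log`` when given)."""
        cols = list(predictors)
        complete = df[cols].notna().all(axis=1)
        dropped = int((~complete).sum())
        if dropped and log is not None:
            log(f"dropped {dropped} rows with missing predictor values")
        sub = df.loc[complete]
        return cls(sub[cols].to_numpy(float), sub[outcome_col].to_numpy(object),
                   sub[id_col].to_numpy(), tuple(predictors))


def threshold_classify(values, cutoff: float = 1.00) -> np.ndarray:
    """Univariate threshold rule on (R-B)/(R^2+B^2): values at or above the
    cutoff are called dehisced, below it healed; missing values are left
    'unclassified'."""
    v = np.asarray(values, dtype=float)
    out = np.empty(v.shape, dtype=object)
    out[:] = "unclassified"
    finite = np.isfinite(v)
    out[finite & (v >= cutoff)] = POSITIVE
    out[finite & (v < cutoff)] = "healed"
    return out


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_indices(y, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified partition indices preserving class prevalence.

    Within each class the rows are shuffled and the first
    round(train_fraction * n_class) go to training, so per-class prevalence
    in each side differs from the full data by at most one sample.
    """
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in sorted(set(y)):
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot stratify")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)  # both sides non-empty
        train_idx.extend(perm[:n_train])
        val_idx.extend(perm[n_train:])
    return np.sort(train_idx), np.sort(val_idx)


def stratified_split(ds: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Deterministic stratified train/validation partition of a dataset."""
    train_idx, val_idx = stratified_indices(ds.y3, spec.train_fraction, spec.seed)
    return ds.subset(train_idx), ds.subset(val_idx)


# ---------------------------------------------------------------------------
# PCA (visualization)
# ---------------------------------------------------------------------------

def _autoscale(X: np.ndarray, drop_constant: bool = False):
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
    constant = sd == 0
    if constant.any():
        if drop_constant:
            warnings.warn(f"dropping {int(constant.sum())} constant column(s)")
        sd = np.where(constant, 1.0, sd)
    return (X - mu) / sd, mu, sd, ~constant


def pca_fit(X, k: int):
    """PCA of the autoscaled matrix via SVD.

    Returns (scores, loadings, explained_variance_ratio); constant columns
    are dropped with a warning. Scores are left singular vectors scaled by
    the singular values; loadings rows follow the retained column order.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 observations")
    Xs, _, _, keep = _autoscale(X, drop_constant=True)
    Xs = Xs[:, keep]
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    k = min(k, s.size)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    total = (s**2).sum()
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return scores, loadings, evr


# ---------------------------------------------------------------------------
# PLSDA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSDAModel:
    """A fitted PLS1 discriminant model (autoscaled X, centered 0/1 y)."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    W: np.ndarray          # p x A weight vectors
    P: np.ndarray          # p x A X-loadings
    q: np.ndarray          # A response loadings
    b: np.ndarray          # p regression vector (scaled space)
    n_components: int
    threshold: float = 0.5
    classes: tuple = ("healed", POSITIVE)  # (negative, positive)

    def to_json_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "n_components": self.n_components,
            "threshold": self.threshold,
            "classes": list(self.classes),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "PLSDAModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], float),
            x_sd=np.asarray(d["x_sd"], float),
            y_mean=float(d["y_mean"]),
            W=np.asarray(d["W"], float),
            P=np.asarray(d["P"], float),
            q=np.asarray(d["q"], float),
            b=np.asarray(d["b"], float),
            n_components=int(d["n_components"]),
            threshold=float(d["threshold"]),
            classes=tuple(d["classes"]),
        )


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, A: int):
    """PLS1 NIPALS on autoscaled X and centered y; returns W, P, q, scores."""
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy()
    Ws, Ps, qs, Ts = [], [], [], []
    for _ in range(A):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        if norm < 1e-12:
            break  # remaining X carries no covariance with y: truncate
        w = cov / norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-24:
            break
        pvec = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X = X - np.outer(t, pvec)
        y = y - qa * t
        Ws.append(w)
        Ps.append(pvec)
        qs.append(qa)
        Ts.append(t)
    if not Ws:
        raise ValueError("no PLS component could be extracted (y uncorrelated with X)")
    return (np.column_stack(Ws), np.column_stack(Ps), np.asarray(qs),
            np.column_stack(Ts))


def _fit_fixed(Xs: np.ndarray, yc: np.ndarray, A: int):
    W, P, q, T = _nipals_pls1(Xs, yc, A)
    # regression vector reproducing the deflation-based predictions
    b = W @ np.linalg.solve(P.T @ W, q)
    return W, P, q, T, b


def _stratified_folds(y, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded stratified k-fold assignment (round-robin within each class)."""
    assignment = np.empty(len(y), dtype=int)
    y = np.asarray(y, dtype=object)
    for cls in sorted(set(y)):
        members = rng.permutation(np.flatnonzero(y == cls))
        assignment[members] = np.arange(members.size) % k
    return [np.flatnonzero(assignment == f) for f in range(k)]


def plsda_fit(X, y, A="auto", cv: int = 10, seed: int = 0,
              threshold: float = 0.5, max_components: int = 10,
              classes: tuple = ("healed", POSITIVE)) -> PLSDAModel:
    """Fit a PLS1 discriminant model of a binary outcome.

    ``y`` may be 0/1 integers or labels matching ``classes`` (negative,
    positive). X is autoscaled and y centered internally. With ``A="auto"``
    the component count minimizing stratified ``cv``-fold misclassification
    is chosen (ties break toward fewer components, capped at
    ``max_components``); requested counts beyond what NIPALS can extract are
    truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y01 = _as_dummy(y, classes)
    if X.shape[0] < 4:
        raise ValueError("PLSDA needs at least 4 observations")
    if len(set(y01)) < 2:
        raise ValueError("both classes must be present in y")

    Xs, mu, sd, _ = _autoscale(X)
    y_mean = float(y01.mean())
    yc = y01 - y_mean

    a_cap = int(min(max_components, X.shape[0] - 1, X.shape[1]))
    if A == "auto":
        A_sel = _select_components(X, y01, a_cap, cv, seed, threshold, classes)
    else:
        A_sel = int(A)
        if A_sel < 1:
            raise ValueError("number of components must be >= 1")
        if A_sel > a_cap:
            warnings.warn(f"requested {A_sel} components truncated to {a_cap}")
            A_sel = a_cap

    W, P, q, T, b = _fit_fixed(Xs, yc, A_sel)
    if W.shape[1] < A_sel:
        warnings.warn(
            f"rank limited: extracted {W.shape[1]} of {A_sel} requested components"
        )
    return PLSDAModel(x_mean=mu, x_sd=sd, y_mean=y_mean, W=W, P=P, q=q, b=b,
                      n_components=W.shape[1], threshold=threshold,
                      classes=tuple(classes))


def _as_dummy(y, classes) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "ifub":
        vals = np.unique(y)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("numeric y must be coded 0/1")
        return y.astype(float)
    neg, pos = classes
    unknown = set(y) - {neg, pos}
    if unknown:
        raise ValueError(f"labels {unknown} not in classes {classes}")
    return (y == pos).astype(float)


def _select_components(X, y01, a_cap, cv, seed, threshold, classes) -> int:
    rng = np.random.default_rng(seed)
    counts = np.bincount(y01.astype(int))
    k = int(min(cv, counts[counts > 0].min()))
    if k < 2:
        return 1
    folds = _stratified_folds(y01, k, rng)
    errors = np.zeros(a_cap)
    for fold in folds:
        mask = np.ones(len(y01), dtype=bool)
        mask[fold] = False
        Xs, mu, sd, _ = _autoscale(X[mask])
        yc = y01[mask] - y01[mask].mean()
        try:
            W, P, q, T = _nipals_pls1(Xs, yc, a_cap)
        except ValueError:
            errors += len(fold)  # degenerate fold penalizes every A equally
            continue
        Xv = (X[fold] - mu) / sd
        y_mean = y01[mask].mean()
        n_comp = W.shape[1]
        fold_err = np.empty(a_cap)
        for a in range(1, n_comp + 1):
            b = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            yhat = y_mean + Xv @ b
            fold_err[a - 1] = np.sum((yhat >= threshold) != (y01[fold] == 1))
        # folds that ran out of rank reuse their largest extractable model
        fold_err[n_comp:] = fold_err[n_comp - 1]
        errors += fold_err
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest A) tie


def plsda_predict(model: PLSDAModel, X_new) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores (predicted class dummy) and thresholded labels."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"expected {model.x_mean.size} predictor columns, got {X_new.shape[1]}"
        )
    Xs = (X_new - model.x_mean) / model.x_sd
    scores = model.y_mean + Xs @ model.b
    neg, pos = model.classes
    labels = np.where(scores >= model.threshold, pos, neg).astype(object)
    return scores, labels


# ---------------------------------------------------------------------------
# Sequential two-stage classifier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HierarchicalWoundClassifier:
    """Stage 1 routes delayed-healing wounds; stage 2 discriminates healed
    from dehisced among the rest. Predicted-delayed wounds are reported as
    healed, so stage-2 never sees them and the final label space is
    {healed, dehisced}."""

    stage1: PLSDAModel  # delayed (positive) vs not-delayed
    stage2: PLSDAModel  # dehisced (positive) vs healed
    route_by: str = "truth"

    def to_json_dict(self) -> dict:
        return {
            "stage1": self.stage1.to_json_dict(),
            "stage2": self.stage2.to_json_dict(),
            "route_by": self.route_by,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "HierarchicalWoundClassifier":
        return cls(PLSDAModel.from_json_dict(d["stage1"]),
                   PLSDAModel.from_json_dict(d["stage2"]),
                   d.get("route_by", "truth"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "HierarchicalWoundClassifier":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def fit_hierarchical(ds_train: LabeledDataset, A="auto", cv: int = 10,
                     seed: int = 0, threshold: float = 0.5,
                     route_by: str = "truth") -> HierarchicalWoundClassifier:
    """Fit the sequential two-stage classifier on three-class training data.

    Stage 1 is fit on all rows (delayed vs not-delayed); stage 2 on the
    remaining data — by default the rows whose *true* class is not delayed
    (``route_by="truth"``), or the rows stage 1 predicts as not-delayed
    (``route_by="prediction"``).
    """
    present = set(ds_train.y3)
    missing = {"healed", "delayed", POSITIVE} - present
    if missing:
        raise ValueError(f"training data lacks outcome class(es): {sorted(missing)}")
    if route_by not in ("truth", "prediction"):
        raise ValueError("route_by must be 'truth' or 'prediction'")

    y_delayed = (ds_train.y3 == "delayed").astype(float)
    stage1 = plsda_fit(ds_train.X, y_delayed, A=A, cv=cv, seed=seed,
                       threshold=threshold, classes=("not_delayed", "delayed"))
    if route_by == "truth":
        keep = ds_train.y3 != "delayed"
    else:
        _, s1_labels = plsda_predict(stage1, ds_train.X)
        keep = s1_labels != "delayed"
    X2 = ds_train.X[keep]
    y2 = collapse_to_binary(ds_train.y3[keep])
    if len(set(y2)) < 2:
        raise ValueError("stage-2 training data lacks one of healed/dehisced")
    stage2 = plsda_fit(X2, y2, A=A, cv=cv, seed=seed + 1, threshold=threshold)
    return HierarchicalWoundClassifier(stage1=stage1, stage2=stage2, route_by=route_by)


def predict_hierarchical(h: HierarchicalWoundClassifier, X_new) -> np.ndarray:
    """Final binary labels: stage-1 'delayed' becomes healed; everything else
    takes stage 2's healed/dehisced call."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    _, s1 = plsda_predict(h.stage1, X_new)
    out = np.empty(X_new.shape[0], dtype=object)
    routed_delayed = s1 == "delayed"
    out[routed_delayed] = "healed"
    rest = ~routed_delayed
    if rest.any():
        _, s2 = plsda_predict(h.stage2, X_new[rest])
        out[rest] = s2
    return out


# ---------------------------------------------------------------------------
# Model recipes and permutation tests
# ---------------------------------------------------------------------------

def plsda_recipe(A=2, threshold: float = 0.5, classes=("healed", POSITIVE)):
    """A fit function usable by cross-validation/permutation machinery:
    recipe(X_train, y_train) -> predict(X) -> labels."""

    def fit(X_tr, y_tr):
        model = plsda_fit(X_tr, y_tr, A=A, threshold=threshold, classes=classes)

        def predict(Xq):
            return plsda_predict(model, Xq)[1]

        return predict

    return fit


def hierarchical_recipe(A=2, threshold: float = 0.5, route_by: str = "truth"):
    """Recipe over three-class labels; predictions are binary."""

    def fit(X_tr, y_tr):
        ds = LabeledDataset(X_tr, y_tr, np.arange(len(y_tr)))
        h = fit_hierarchical(ds, A=A, threshold=threshold, route_by=route_by)

        def predict(Xq):
            return predict_hierarchical(h, Xq)

        return predict

    return fit


def cross_val_accuracy(X, y, recipe, cv: int = 5, seed: int = 0,
                       score_transform=None) -> float:
    """Stratified cross-validated accuracy of a recipe.

    ``score_transform`` maps true labels before comparison with predictions
    (e.g. collapsing a three-class truth to the binary label space).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    counts = pd.Series(y).value_counts()
    k = int(min(cv, counts.min()))
    if k < 2:
        raise ValueError("cross-validation needs every class in >= 2 rows")
    folds = _stratified_folds(y, k, rng)
    correct = 0
    for fold in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[fold] = False
        predict = recipe(X[mask], y[mask])
        pred = np.asarray(predict(X[fold]), dtype=object)
        truth = y[fold]
        if score_transform is not None:
            truth = np.asarray(score_transform(truth), dtype=object)
        correct += int((pred == truth).sum())
    return correct / len(y)


@dataclass(frozen=True)
class PermutationResult:
    n_permutations: int
    observed: float
    permuted: np.ndarray
    p_insignificance: float


def permutation_test(X, y, recipe, n_perm: int = 200, cv: int = 5,
                     seed: int = 0, score_transform=None) -> PermutationResult:
    """Label-shuffling overfitting control for a model recipe.

    The observed score is the stratified cross-validated accuracy on the true
    labels; each permutation shuffles the labels (seeded) and re-runs the
    identical recipe. p = (1 + #{permuted >= observed}) / (1 + n_perm), the
    probability of insignificance — a small value means a random model rarely
    matches the fitted one. Failing permutations are retried with a fresh
    shuffle (max 3) and counted as >= observed if they keep failing.
    """
    if n_perm < 19:
        raise ValueError("need at least 19 permutations for a meaningful p")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    rng = np.random.default_rng(seed)
    observed = cross_val_accuracy(X, y, recipe, cv=cv, seed=seed,
                                  score_transform=score_transform)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        score = None
        for _attempt in range(3):
            y_shuf = rng.permutation(y)
            try:
                score = cross_val_accuracy(X, y_shuf, recipe, cv=cv, seed=seed,
                                           score_transform=score_transform)
                break
            except Exception:
                continue
        permuted[i] = observed if score is None else score  # conservative
    p = (1 + int((permuted >= observed).sum())) / (1 + n_perm)
    return PermutationResult(n_permutations=n_perm, observed=observed,
                             permuted=permuted, p_insignificance=p)
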