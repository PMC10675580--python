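"""Sparse PLS discriminant analysis (NIPALS) with keepX variable selection.

PLS-DA regresses an auto-scaled predictor matrix X on the centered one-hot
class indicator Y, extracting latent components that maximize the covariance
between X-scores and the response.  The sparse variant soft-thresholds each
X-weight vector so that exactly keepX variables survive per component — the
threshold is the (keepX+1)-th largest absolute weight — and renormalizes.
X is deflated by regression on its scores; Y deflation is omitted because
prediction uses the accumulated regression coefficients, which it leaves
unchanged (the deflated X is orthogonal to all earlier scores).

Class prediction supports three distance rules:

* ``max``          — argmax of the predicted dummy response;
* ``centroid``     — nearest training-class centroid in latent-score space;
* ``mahalanobis``  — nearest centroid under the pooled within-class score
  covariance.

Model tuning follows repeated stratified cross-validation on the overall
(OER) and balanced (BER) error rates over an (ncomp, keepX, distance) grid,
with scaling and selection refitted inside every training fold.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISTANCES = ("max", "centroid", "mahalanobis")

_TOL = 1e-12
_MAX_ITER = 10000


# ---------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------
@dataclass
class PLSDAModel:
    classes_: np.ndarray               # sorted unique labels (K,)
    ncomp: int
    keepx: tuple[int, ...]             # per-component budget
    x_weights_: np.ndarray             # (p, H) unit-norm, sparse
    x_loadings_: np.ndarray            # (p, H)
    x_scores_: np.ndarray              # (n, H) mutually orthogonal
    y_weights_: np.ndarray             # (K, H) dummy regression weights
    x_mean_: np.ndarray
    x_std_: np.ndarray
    y_mean_: np.ndarray                # class priors (K,)
    y_train_: np.ndarray               # training labels (n,)
    feature_names: list[str]

    def __post_init__(self) -> None:
        # contract checks: sparsity bounds and orthogonality
        for h, kx in enumerate(self.keepx):
            nz = int(np.count_nonzero(self.x_weights_[:, h]))
            if nz > kx:
                raise AssertionError(
                    f"component {h + 1} keeps {nz} variables, budget {kx}"
                )
        norms = np.linalg.norm(self.x_weights_, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise AssertionError("x_weights columns must be unit-norm")
        G = self.x_scores_.T @ self.x_scores_
        off = G - np.diag(np.diag(G))
        if np.abs(off).max() > 1e-6 * max(1.0, np.abs(np.diag(G)).max()):
            raise AssertionError("score vectors must be mutually orthogonal")

    # -- derived quantities -------------------------------------------
    def rotation(self, ncomp: int | None = None) -> np.ndarray:
        """R = W (PᵀW)⁻¹ mapping scaled X to scores."""
        h = self.ncomp if ncomp is None else ncomp
        W = self.x_weights_[:, :h]
        P = self.x_loadings_[:, :h]
        return W @ np.linalg.inv(P.T @ W)

    def selected(self, component: int | None = None) -> list[str]:
        """Variables with nonzero weight (on one component or overall)."""
        if component is not None:
            idx = np.flatnonzero(self.x_weights_[:, component])
        else:
            idx = np.flatnonzero(np.any(self.x_weights_ != 0, axis=1))
        return [self.feature_names[j] for j in idx]

    def centroids(self, ncomp: int | None = None) -> np.ndarray:
        h = self.ncomp if ncomp is None else ncomp
        T = self.x_scores_[:, :h]
        return np.vstack(
            [T[self.y_train_ == c].mean(axis=0) for c in self.classes_]
        )

    def within_cov(self, ncomp: int | None = None) -> np.ndarray:
        """Pooled within-class covariance of the training scores."""
        h = self.ncomp if ncomp is None else ncomp
        T = self.x_scores_[:, :h]
        K = len(self.classes_)
        S = np.zeros((h, h))
        for c in self.classes_:
            Tc = T[self.y_train_ == c]
            D = Tc - Tc.mean(axis=0)
            S += D.T @ D
        S /= max(len(T) - K, 1)
        # ridge for numerically singular folds
        S += 1e-10 * np.eye(h) * max(np.trace(S) / h, 1.0)
        return S


@dataclass
class CVResult:
    """Cross-validated error grid and the chosen configuration.

    grid: mean OER/BER per (ncomp, keepx, distance); raw: per-repeat rates;
    best: dict with ncomp, keepx, distance attaining the minimum mean BER
    (ties broken toward fewer components, then smaller keepX, then the
    distance order max/centroid/mahalanobis).
    """

    grid: pd.DataFrame
    raw: pd.DataFrame
    best: dict

    def __post_init__(self) -> None:
        if not ((self.grid[["oer", "ber"]] >= 0).all().all()
                and (self.grid[["oer", "ber"]] <= 1).all().all()):
            raise ValueError("error rates must lie in [0, 1]")
        if not np.isclose(
            self.grid["ber"].min(),
            self.grid.loc[
                (self.grid["ncomp"] == self.best["ncomp"])
                & (self.grid["keepx"] == self.best["keepx"])
                & (self.grid["distance"] == self.best["distance"]), "ber",
            ].iloc[0],
        ):
            raise ValueError("chosen configuration must attain the minimum BER")


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = truth) with accuracy/sensitivity/specificity.

    For two classes, sensitivity is the recall of the first class and
    specificity the recall of the second; for more classes both are
    macro-averaged (mean per-class recall, mean per-class true-negative
    rate).
    """

    confusion: pd.DataFrame
    accuracy: float
    sensitivity: float
    specificity: float
    per_class: pd.DataFrame

    def __post_init__(self) -> None:
        cm = self.confusion.to_numpy()
        if not np.isclose(self.accuracy, np.trace(cm) / cm.sum()):
            raise ValueError("accuracy must equal trace/total")


# ---------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------
def soft_threshold_weights(w: np.ndarray, keepx: int) -> np.ndarray:
    """Keep the keepx largest |w|, shrink by the (keepx+1)-th, renormalize."""
    w = np.asarray(w, float)
    p = w.size
    if keepx >= p:
        out = w.copy()
    else:
        thr = np.sort(np.abs(w))[::-1][keepx]  # (keepx+1)-th largest
        out = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
    nrm = np.linalg.norm(out)
    if nrm == 0:
        raise ValueError("soft threshold removed every variable")
    return out / nrm


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def plsda_fit(
    X,
    y: Sequence,
    ncomp: int = 2,
    keepx: int | Sequence[int] | None = None,
) -> PLSDAModel:
    """Fit sparse PLS-DA by NIPALS on auto-scaled X vs centered dummy Y.

    ``keepx`` is a per-component variable budget (a scalar is broadcast);
    None keeps every variable, which reduces to ordinary PLS2-DA.
    """
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    names = [str(c) for c in Xf.columns]
    Xv = Xf.to_numpy(float)
    y = np.asarray(y)
    n, p = Xv.shape
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if not 1 <= ncomp <= min(n - 1, p):
        raise ValueError(f"ncomp must be in [1, {min(n - 1, p)}], got {ncomp}")
    if keepx is None:
        keepx_t = (p,) * ncomp
    elif np.isscalar(keepx):
        keepx_t = (int(keepx),) * ncomp
    else:
        keepx_t = tuple(int(k) for k in keepx)
        if len(keepx_t) != ncomp:
            raise ValueError("keepx must give one budget per component")
    if any(not 1 <= k <= p for k in keepx_t):
        raise ValueError(f"keepX entries must be in [1, {p}]")

    x_mean = Xv.mean(axis=0)
    x_std = Xv.std(axis=0, ddof=1)
    x_std = np.where(x_std == 0, 1.0, x_std)  # constant fold columns
    Xc = (Xv - x_mean) / x_std

    Y = _one_hot(y, classes)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W = np.zeros((p, ncomp))
    P = np.zeros((p, ncomp))
    T = np.zeros((n, ncomp))
    C = np.zeros((len(classes), ncomp))

    Xd = Xc.copy()
    for h in range(ncomp):
        # init u from the dominant covariance direction of the residual
        # cross-product (SVD of Xdᵀ Yc), as in standard sPLS practice
        _, _, vt = np.linalg.svd(Xd.T @ Yc, full_matrices=False)
        u = Yc @ vt[0]
        w = np.zeros(p)
        for _ in range(_MAX_ITER):
            w_raw = Xd.T @ u
            nrm = np.linalg.norm(w_raw)
            if nrm == 0:
                raise ValueError(f"no residual covariance at component {h + 1}")
            w_new = soft_threshold_weights(w_raw / nrm, keepx_t[h])
            t = Xd @ w_new
            c = Yc.T @ t / (t @ t)
            u_new = Yc @ c / (c @ c)
            if np.linalg.norm(w_new - w) < _TOL:
                w = w_new
                break
            w, u = w_new, u_new
        t = Xd @ w
        pl = Xd.T @ t / (t @ t)
        c = Yc.T @ t / (t @ t)
        Xd = Xd - np.outer(t, pl)
        W[:, h], P[:, h], T[:, h], C[:, h] = w, pl, t, c

    return PLSDAModel(
        classes_=classes, ncomp=ncomp, keepx=keepx_t,
        x_weights_=W, x_loadings_=P, x_scores_=T, y_weights_=C,
        x_mean_=x_mean, x_std_=x_std, y_mean_=y_mean,
        y_train_=y, feature_names=names,
    )


# ---------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------
def transform(model: PLSDAModel, Xnew, ncomp: int | None = None) -> np.ndarray:
    """Project new samples onto the latent scores."""
    h = model.ncomp if ncomp is None else ncomp
    Xf = (
        Xnew if isinstance(Xnew, pd.DataFrame)
        else pd.DataFrame(np.asarray(Xnew, float), columns=model.feature_names)
    )
    cols = [str(c) for c in Xf.columns]
    if cols != model.feature_names:
        missing = [c for c in model.feature_names if c not in cols]
        extra = [c for c in cols if c not in model.feature_names]
        raise ValueError(
            f"columns do not match training variables; "
            f"missing={missing}, extra={extra}"
        )
    Xs = (Xf.to_numpy(float) - model.x_mean_) / model.x_std_
    return Xs @ model.rotation(h)


def plsda_predict(
    model: PLSDAModel,
    Xnew,
    distance: str = "max",
    ncomp: int | None = None,
    return_scores: bool = False,
):
    """Predict class labels with one of the three distance rules.

    Ties are broken toward the first class in sorted class order, with a
    warning.  ``ncomp`` evaluates a truncated sub-model.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}, got {distance!r}")
    h = model.ncomp if ncomp is None else ncomp
    Tnew = transform(model, Xnew, ncomp=h)

    if distance == "max":
        Yhat = Tnew @ model.y_weights_[:, :h].T + model.y_mean_
        crit = -Yhat  # smaller is better
    else:
        cent = model.centroids(h)
        diff = Tnew[:, None, :] - cent[None, :, :]
        if distance == "centroid":
            crit = np.einsum("nkh,nkh->nk", diff, diff)
        else:
            Sinv = np.linalg.inv(model.within_cov(h))
            crit = np.einsum("nkh,hj,nkj->nk", diff, Sinv, diff)

    best = crit.argmin(axis=1)
    # tie detection at machine-noise resolution
    sorted_crit = np.sort(crit, axis=1)
    span = np.maximum(np.abs(sorted_crit[:, -1]), 1.0)
    ties = (sorted_crit[:, 1] - sorted_crit[:, 0]) <= 1e-12 * span
    if ties.any():
        warnings.warn(
            f"{int(ties.sum())} tied prediction(s); "
            "broken toward the first class in sorted order",
            stacklevel=2,
        )
    labels = model.classes_[best]
    if return_scores:
        return labels, Tnew
    return labels


# ---------------------------------------------------------------------
# error rates, splits, cross-validation
# ---------------------------------------------------------------------
def error_rates(
    y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray
) -> tuple[float, float]:
    """(OER, BER): overall error and unweighted mean per-class error."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    oer = float(np.mean(y_true != y_pred))
    per_class = [
        float(np.mean(y_pred[y_true == c] != c))
        for c in classes
        if (y_true == c).any()
    ]
    return oer, float(np.mean(per_class))


def stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin after shuffle)."""
    y = np.asarray(y)
    assign = np.empty(len(y), int)
    start = 0
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < folds:
            raise ValueError(
                f"class {c!r} has {len(idx)} samples < {folds} folds; "
                "use fewer folds"
            )
        rng.shuffle(idx)
        assign[idx] = (np.arange(len(idx)) + start) % folds
        start += len(idx)  # stagger so small folds even out
    return [np.flatnonzero(assign == f) for f in range(folds)]


def stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffled stratified train/test split; every class in both sides."""
    y = np.asarray(y)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def cross_validate(
    X,
    y: Sequence,
    ncomp_grid: Sequence[int] = (1, 2, 3),
    keepx_grid: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 17, 20, 30, 50),
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    distances: Sequence[str] = DISTANCES,
) -> CVResult:
    """Repeated stratified CV of OER/BER over the (ncomp, keepX, distance) grid.

    Scaling and variable selection are refitted inside every training fold.
    For each keepX, one model is fitted per fold at max(ncomp_grid) and its
    truncations are evaluated, which is exact because components are nested.
    """
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    y = np.asarray(y)
    classes = np.unique(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    p = Xf.shape[1]
    keepx_grid = sorted({min(int(k), p) for k in keepx_grid})
    ncomp_grid = sorted(set(int(h) for h in ncomp_grid))
    hmax = max(ncomp_grid)

    rng = np.random.default_rng(seed)
    records = []
    for rep in range(repeats):
        fold_idx = stratified_folds(y, folds, rng)
        # predictions pooled over folds within the repeat
        preds: dict[tuple[int, int, str], np.ndarray] = {
            (h, kx, d): np.empty(len(y), object)
            for h in ncomp_grid for kx in keepx_grid for d in distances
        }
        for test in fold_idx:
            train = np.setdiff1d(np.arange(len(y)), test)
            Xtr, Xte = Xf.iloc[train], Xf.iloc[test]
            ytr = y[train]
            for kx in keepx_grid:
                model = plsda_fit(Xtr, ytr, ncomp=hmax, keepx=kx)
                for h in ncomp_grid:
                    for d in distances:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            yhat = plsda_predict(model, Xte, distance=d, ncomp=h)
                        preds[(h, kx, d)][test] = yhat
        for (h, kx, d), yhat in preds.items():
            oer, ber = error_rates(y, yhat.astype(y.dtype), classes)
            records.append(
                {"repeat": rep, "ncomp": h, "keepx": kx, "distance": d,
                 "oer": oer, "ber": ber}
            )

    raw = pd.DataFrame(records)
    grid = (
        raw.groupby(["ncomp", "keepx", "distance"], sort=True)[["oer", "ber"]]
        .mean()
        .reset_index()
    )
    # parsimony tie-break: fewer components, then smaller keepX, then
    # the declared distance order
    dist_rank = {d: i for i, d in enumerate(DISTANCES)}
    order = grid.assign(_d=grid["distance"].map(dist_rank)).sort_values(
        ["ber", "ncomp", "keepx", "_d"], kind="mergesort"
    )
    top = order.iloc[0]
    best = {
        "ncomp": int(top["ncomp"]),
        "keepx": int(top["keepx"]),
        "distance": str(top["distance"]),
        "ber": float(top["ber"]),
        "oer": float(top["oer"]),
    }
    logger.info("cross_validate: best config %s", best)
    return CVResult(grid=grid, raw=raw, best=best)


# ---------------------------------------------------------------------
# held-out evaluation
# ---------------------------------------------------------------------
def classification_report(
    y_true, y_pred, classes: np.ndarray | None = None
) -> ClassificationReport:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    K = len(classes)
    cm = np.zeros((K, K), int)
    pos = {c: i for i, c in enumerate(classes)}
    for t, p_ in zip(y_true, y_pred):
        cm[pos[t], pos[p_]] += 1
    confusion = pd.DataFrame(cm, index=classes, columns=classes)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total)
    recalls, specs = [], []
    for i in range(K):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        recalls.append(tp / (tp + fn) if (tp + fn) else np.nan)
        specs.append(tn / (tn + fp) if (tn + fp) else np.nan)
    per_class = pd.DataFrame(
        {"class": classes, "recall": recalls, "specificity": specs}
    )
    if K == 2:
        sensitivity = float(recalls[0])
        specificity = float(recalls[1])
    else:
        sensitivity = float(np.nanmean(recalls))
        specificity = float(np.nanmean(specs))
    return ClassificationReport(
        confusion=confusion, accuracy=accuracy,
        sensitivity=sensitivity, specificity=specificity,
        per_class=per_class,
    )


def evaluate_holdout(
    X,
    y: Sequence,
    ncomp: int = 2,
    keepx: int | Sequence[int] | None = None,
    distance: str = "max",
    train_frac: float = 0.7,
    seed: int = 0,
) -> tuple[ClassificationReport, PLSDAModel]:
    """Fit on a stratified training fraction, report on the held-out rest."""
    Xf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, test = stratified_split(y, train_frac, rng)
    if len(np.unique(y[train])) < len(np.unique(y)) or len(test) == 0:
        raise ValueError("every class must appear in both splits")
    model = plsda_fit(Xf.iloc[train], y[train], ncomp=ncomp, keepx=keepx)
    yhat = plsda_predict(model, Xf.iloc[test], distance=distance)
    report = classification_report(y[test], yhat, classes=model.classes_)
    return report, model
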