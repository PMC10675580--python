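"""PCA exploration of the element matrix with score-space outlier flagging.

The decomposition is computed by SVD of the centered (and by default
unit-variance scaled) matrix — the standard chemometric auto-scaling for
element data spanning five orders of magnitude.  Outliers are flagged by the
Mahalanobis distance of the first few score dimensions against a chi-square
cutoff, an automatic stand-in for visual score-plot trimming.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PCAModel:
    """Fitted PCA: eigenvalues, scores, unit-norm loadings and derived views.

    var_explained is in % and sums to 100 over all retained dimensions when
    the full rank is kept; contributions (% per variable per dimension) sum
    to 100 within each dimension; var_coords are variable–dimension
    correlations when the input was standardized.
    """

    eigenvalues: np.ndarray            # (k,) score variances
    scores: pd.DataFrame               # samples × k
    loadings: pd.DataFrame             # variables × k, unit norm
    var_explained: np.ndarray          # (k,) percent of total variance
    contributions: pd.DataFrame        # variables × k, percent
    var_coords: pd.DataFrame           # variables × k
    mean_: np.ndarray
    scale_: np.ndarray
    center: bool
    scale: bool

    @property
    def ncomp(self) -> int:
        return len(self.eigenvalues)


@dataclass
class OutlierReport:
    """Samples flagged by the score-space Mahalanobis rule."""

    flagged: list[str]
    distances: pd.Series     # squared Mahalanobis distance per sample
    cutoff: float
    dims: int
    quantile: float

    def __post_init__(self) -> None:
        if (self.distances < 0).any():
            raise ValueError("squared distances must be >= 0")
        if not set(self.flagged) <= set(self.distances.index):
            raise ValueError("flagged ids must be a subset of the samples")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, float)
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"v{j}" for j in range(X.shape[1])],
    )


def pca_fit(
    X, center: bool = True, scale: bool = True, ncomp: int | None = None
) -> PCAModel:
    """Fit PCA by SVD of the centered/scaled matrix.

    Eigenvalues are score variances (ddof=1).  The sign of each component is
    fixed by forcing its largest-magnitude loading positive, so outputs are
    deterministic.  A zero-variance column with scale=True is an error.
    """
    Xf = _as_frame(X)
    n, p = Xf.shape
    if n < 2 or p < 2:
        raise ValueError(f"need at least 2 samples and 2 variables, got {n}x{p}")
    vals = Xf.to_numpy(float)
    if np.isnan(vals).any():
        raise ValueError("matrix contains missing values; substitute non-detects first")

    mean_ = vals.mean(axis=0) if center else np.zeros(p)
    Xc = vals - mean_
    if scale:
        sd = vals.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [Xf.columns[j] for j in zero]
            raise ValueError(f"zero-variance columns cannot be scaled: {names}")
        scale_ = sd
    else:
        scale_ = np.ones(p)
    Xc = Xc / scale_

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = min(n - 1, p) if center else min(n, p)
    k = rank if ncomp is None else min(ncomp, rank)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]

    # deterministic sign: largest |loading| per component positive
    for j in range(rank):
        piv = np.argmax(np.abs(Vt[j]))
        if Vt[j, piv] < 0:
            Vt[j] *= -1
            U[:, j] *= -1

    eig = s**2 / (n - 1)
    total = eig.sum()
    var_exp = 100.0 * eig / total
    dims = [f"PC{j + 1}" for j in range(rank)]
    loadings = pd.DataFrame(Vt.T, index=Xf.columns, columns=dims)
    scores = pd.DataFrame(U * s, index=Xf.index, columns=dims)
    coords = loadings * np.sqrt(eig)
    contrib = 100.0 * loadings**2  # unit-norm loadings: squares sum to 1

    model = PCAModel(
        eigenvalues=eig[:k],
        scores=scores.iloc[:, :k],
        loadings=loadings.iloc[:, :k],
        var_explained=var_exp[:k],
        contributions=contrib.iloc[:, :k],
        var_coords=coords.iloc[:, :k],
        mean_=mean_,
        scale_=scale_,
        center=center,
        scale=scale,
    )
    return model


def variable_contributions(
    model: PCAModel, top: int | None = None
) -> pd.DataFrame:
    """Per-dimension variable contributions (%) with the 100/p reference.

    Returns a long frame (dimension, variable, contribution, reference)
    sorted by contribution within each dimension; ``top`` keeps the N
    strongest per dimension.
    """
    p = model.loadings.shape[0]
    ref = 100.0 / p
    rows = []
    for dim in model.contributions.columns:
        col = model.contributions[dim].sort_values(ascending=False)
        if top is not None:
            col = col.iloc[:top]
        for var, val in col.items():
            rows.append(
                {"dimension": dim, "variable": var,
                 "contribution": float(val), "reference": ref}
            )
    return pd.DataFrame(rows)


def flag_outliers(
    model: PCAModel, dims: int = 2, quantile: float = 0.999
) -> OutlierReport:
    """Flag samples whose score Mahalanobis distance exceeds chi-square.

    On the first ``dims`` score dimensions the covariance is diagonal with
    the eigenvalues, so d² = Σ t²/λ; the cutoff is the chi-square(dims)
    ``quantile``.  Deterministic given the fitted model.
    """
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    if dims > model.ncomp:
        raise ValueError(f"dims={dims} exceeds fitted components {model.ncomp}")
    T = model.scores.iloc[:, :dims].to_numpy()
    lam = model.eigenvalues[:dims]
    d2 = (T**2 / lam).sum(axis=1)
    cutoff = float(stats.chi2.ppf(quantile, df=dims))
    distances = pd.Series(d2, index=model.scores.index, name="mahalanobis_sq")
    flagged = [str(i) for i in distances.index[d2 > cutoff]]
    return OutlierReport(
        flagged=flagged, distances=distances, cutoff=cutoff,
        dims=dims, quantile=quantile,
    )
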