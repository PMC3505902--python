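"""PCA-based applicability-domain assessment.

The domain of a QSAR model is estimated from the training compounds in the
space of the model's selected descriptors: a principal component analysis
of the (normalized) training matrix defines score axes, and a query
compound is in-domain when its scores fall inside the training bounding
box on every retained component (optionally expanded by a margin).  A
leverage criterion (h* = 3p/n) is available as an alternative rule.

Inputs are assumed to carry the TRAINING normalization — external
compounds must be transformed with the training mean/sd, never their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ADModel:
    feature_names: list[str]
    means: np.ndarray           # centering applied before projection
    sds: np.ndarray             # per-feature scale (ones if input pre-scaled)
    loadings: np.ndarray        # (p, n_components), orthonormal columns
    explained_variance: np.ndarray
    score_ranges: np.ndarray    # (n_components, 2): training min/max scores
    n_components: int
    train_leverage_threshold: float  # h* = 3p/n
    _train_gram_inv: np.ndarray | None = None

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = self._standardize(X)
        return Z @ self.loadings

    def _standardize(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {missing}")
        Xv = X[self.feature_names].to_numpy(dtype=float)
        return (Xv - self.means) / self.sds


def fit_ad(
    X_train: pd.DataFrame, n_components: int = 2, standardize: bool = False
) -> ADModel:
    """Fit the applicability-domain model on training descriptors.

    ``X_train`` is normally already z-scored with the training parameters,
    so only centering is applied by default; set ``standardize=True`` to
    also divide by the per-column population sd.  Components are the
    leading eigenvectors of the training covariance; at least 2 must be
    retained and the training set must have at least 3 compounds.
    """
    if n_components < 2:
        raise ValueError("retain at least 2 components")
    n, p = X_train.shape
    if n < 3:
        raise ValueError("need at least 3 training compounds")
    if n_components > min(n, p):
        raise ValueError(
            f"cannot retain {n_components} components from {n} x {p} data"
        )
    Xv = X_train.to_numpy(dtype=float)
    means = Xv.mean(axis=0)
    if standardize:
        sds = Xv.std(axis=0, ddof=0)
        sds = np.where(sds > 1e-12, sds, 1.0)
    else:
        sds = np.ones(p)
    Z = (Xv - means) / sds
    # covariance eigendecomposition via SVD (stable, deterministic)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt[:n_components].T
    # sign convention: largest-magnitude loading positive
    for j in range(n_components):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    scores = Z @ loadings
    ranges = np.stack([scores.min(axis=0), scores.max(axis=0)], axis=1)
    explained = (s[:n_components] ** 2) / max(n - 1, 1)
    gram = Z.T @ Z
    gram_inv = np.linalg.pinv(gram)
    return ADModel(
        feature_names=list(X_train.columns),
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance=explained,
        score_ranges=ranges,
        n_components=n_components,
        train_leverage_threshold=3.0 * p / n,
        _train_gram_inv=gram_inv,
    )


def check_domain(
    ad: ADModel,
    X_query: pd.DataFrame,
    margin: float = 0.0,
    criterion: str = "bbox",
) -> pd.DataFrame:
    """Per-compound in-domain decision.

    ``bbox``: in-domain iff every retained-component score lies inside the
    training score range expanded symmetrically by ``margin`` (margin 1.0
    doubles each accepted range).  ``leverage``: in-domain iff the leverage
    h = x (X'X)^-1 x' is at most h* = 3p/n (margin scales h*).  The
    in-domain set can only grow as the margin grows.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    scores = ad.transform(X_query)
    if criterion == "bbox":
        lo, hi = ad.score_ranges[:, 0], ad.score_ranges[:, 1]
        center = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        half_exp = half * (1.0 + margin)
        inside = np.all(
            (scores >= center - half_exp) & (scores <= center + half_exp), axis=1
        )
    elif criterion == "leverage":
        Z = ad._standardize(X_query)
        h = np.einsum("ij,jk,ik->i", Z, ad._train_gram_inv, Z)
        inside = h <= ad.train_leverage_threshold * (1.0 + margin)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    out = pd.DataFrame(
        scores,
        index=X_query.index,
        columns=[f"PC{j + 1}" for j in range(ad.n_components)],
    )
    out.insert(0, "in_domain", inside)
    return out


def plot_ad(ad: ADModel, X_train: pd.DataFrame, X_query: pd.DataFrame | None = None,
            ax=None):
    """Score plot of the first two components with the domain box."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    tr = ad.transform(X_train)
    ax.scatter(tr[:, 0], tr[:, 1], s=12, alpha=0.5, label="training")
    if X_query is not None:
        q = ad.transform(X_query)
        ax.scatter(q[:, 0], q[:, 1], s=30, marker="^", color="crimson",
                   label="query")
    (x0, x1), (y0, y1) = ad.score_ranges[0], ad.score_ranges[1]
    ax.add_patch(Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False,
                           edgecolor="black", linestyle="--"))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    return ax
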