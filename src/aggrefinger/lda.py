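"""Disease-signature extraction by linear discriminant analysis.

Donor x region profiles (15 features) are standardized and classified into
combined region-cohort classes (cerebellum-CRL, cerebellum-MND_SOD, ...).
The discriminants solve the generalized eigenproblem S_b v = lambda S_w v
for the between- and within-class scatter matrices, with a small ridge on
S_w when it is singular (few donors, many features). Explained-variance
ratios are the normalized eigenvalues; the eigenvectors ("pseudo-eigens")
rank each feature's contribution to the separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .subpopulations import LDA_FEATURES

logger = logging.getLogger(__name__)


@dataclass
class LDAResult:
    projection: np.ndarray          # (n_obs, n_discriminants)
    explained_variance_ratio: np.ndarray
    coefficients: pd.DataFrame      # features x discriminants ("pseudo-eigens")
    labels: np.ndarray
    feature_names: list[str]

    @property
    def n_discriminants(self) -> int:
        return self.projection.shape[1]


def build_feature_matrix(profiles: pd.DataFrame,
                         features: list[str] | None = None
                         ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardized feature matrix and region-cohort labels from donor profiles.

    Features are z-scored (zero mean, unit variance) because they mix nm,
    counts and proportions; zero-variance features are dropped with a
    warning, missing ones raise by name.
    """
    features = list(features or LDA_FEATURES)
    missing = [f for f in features if f not in profiles.columns]
    if missing:
        raise ValueError(f"profiles are missing features: {missing}")
    x = profiles[features].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        logger.warning("dropping zero-variance features: %s", dropped)
        features = [f for f, k in zip(features, keep) if k]
        x, sd = x[:, keep], sd[keep]
    x = (x - x.mean(axis=0)) / sd
    labels = (profiles["region"].astype(str) + "-" +
              profiles["cohort"].astype(str)).to_numpy()
    return x, labels, features


def fit_lda(x: np.ndarray, labels: np.ndarray,
            feature_names: list[str] | None = None,
            ridge: float = 1e-6) -> LDAResult:
    """Fisher discriminants of ``x`` under ``labels``.

    Solves S_b v = lambda (S_w + ridge * tr(S_w)/p * I) v and keeps the
    (n_classes - 1) leading discriminants. The explained-variance ratio of
    each discriminant is its eigenvalue over the eigenvalue sum.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if x.shape[0] <= classes.size:
        raise ValueError("need more observations than classes")
    n, p = x.shape
    feature_names = list(feature_names or [f"f{i}" for i in range(p)])

    grand = x.mean(axis=0)
    sw = np.zeros((p, p))
    sb = np.zeros((p, p))
    for c in classes:
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        dev = xc - mc
        sw += dev.T @ dev
        diff = (mc - grand)[:, None]
        sb += xc.shape[0] * (diff @ diff.T)

    reg = ridge * (np.trace(sw) / p if np.trace(sw) > 0 else 1.0)
    evals, evecs = linalg.eigh(sb, sw + reg * np.eye(p))
    order = np.argsort(evals)[::-1]
    k = classes.size - 1
    evals = np.clip(evals[order][:k], 0.0, None)
    evecs = evecs[:, order][:, :k]

    # deterministic sign: largest-|loading| coefficient positive
    for j in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] *= -1

    total = evals.sum()
    evr = evals / total if total > 0 else np.zeros_like(evals)
    coeffs = pd.DataFrame(evecs, index=feature_names,
                          columns=[f"LD{j + 1}" for j in range(k)])
    return LDAResult(projection=x @ evecs, explained_variance_ratio=evr,
                     coefficients=coeffs, labels=labels,
                     feature_names=feature_names)


def rank_contributions(result: LDAResult, discriminant: str = "LD1"
                       ) -> pd.DataFrame:
    """Features ordered by |coefficient| on one discriminant (ties by name)."""
    col = result.coefficients[discriminant]
    order = sorted(col.index, key=lambda f: (-abs(col[f]), f))
    return pd.DataFrame({"feature": order,
                         "coefficient": [col[f] for f in order],
                         "abs_coefficient": [abs(col[f]) for f in order]})


def loo_nearest_centroid_accuracy(x: np.ndarray, labels: np.ndarray,
                                  group_by: np.ndarray | None = None,
                                  n_dims: int = 2) -> float:
    """Leave-one-out nearest-centroid accuracy in the fitted 2-D projection.

    ``group_by`` (e.g. cohort only) lets accuracy be scored on a coarser
    label than the one used for fitting.
    """
    labels = np.asarray(labels)
    score_labels = labels if group_by is None else np.asarray(group_by)
    correct = 0
    for i in range(len(labels)):
        keep = np.ones(len(labels), dtype=bool)
        keep[i] = False
        res = fit_lda(x[keep], labels[keep])
        # project both training and held-out rows with the training fit
        w = res.coefficients.to_numpy()[:, :min(n_dims, res.n_discriminants)]
        train_proj = x[keep] @ w
        test_proj = x[i] @ w
        best, best_d = None, np.inf
        for c in np.unique(score_labels[keep]):
            centroid = train_proj[score_labels[keep] == c].mean(axis=0)
            d = float(np.sum((test_proj - centroid) ** 2))
            if d < best_d:
                best, best_d = c, d
        correct += best == score_labels[i]
    return correct / len(labels)
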