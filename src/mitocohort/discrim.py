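"""Canonical discriminant analysis with MANOVA group tests.

The canonical axes solve the generalized eigenproblem H v = λ E v, where H is
the between-group and E the pooled within-group SSCP matrix.  Axes are scaled
so canonical scores have unit pooled within-group variance, which makes the
95% confidence circle around a group mean a plain chi-square quantity:
radius = sqrt(χ²₂(0.95) / n_g).

Group separation is tested with Wilks' Λ = det(E)/det(E+H) via Rao's F
approximation, and with Roy's greatest root via its (conservative upper-bound)
F statistic; pairwise two-group Wilks tests are Bonferroni-adjusted over all
g(g−1)/2 pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

log = logging.getLogger(__name__)


@dataclass
class DiscriminantModel:
    groups: list
    group_means: pd.DataFrame           # group x parameter means (original space)
    pooled_within_cov: np.ndarray
    coefficients: np.ndarray            # parameters x axes, unit within-variance scaling
    eigenvalues: np.ndarray             # non-increasing, >= 0
    variance_fraction: np.ndarray
    scores: pd.DataFrame                # observation scores with 'group' column
    center: np.ndarray                  # grand mean subtracted before projection
    ridged: bool = False


@dataclass
class GroupComparison:
    wilks_lambda: float
    rao_F: float
    df1: float
    df2: float
    p_value: float
    roys_root: float
    roy_F: float
    roy_df1: float
    roy_df2: float
    roy_p: float
    pairwise_p: pd.DataFrame
    pairwise_significant: pd.DataFrame
    n_pairs: int


@dataclass
class ConfidenceCircle:
    group: str
    center: tuple[float, float]
    radius: float
    n: int


def _sscp(X: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    """Between (H) and within (E) sums-of-squares-and-cross-products matrices."""
    labels = list(pd.unique(groups))
    grand = X.mean(axis=0)
    p = X.shape[1]
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for gname in labels:
        Xg = X[groups == gname]
        mg = Xg.mean(axis=0)
        d = (mg - grand)[:, None]
        H += len(Xg) * (d @ d.T)
        R = Xg - mg
        E += R.T @ R
    return H, E, labels


def fit_cda(X, groups, ridge: bool = True) -> DiscriminantModel:
    """Fit canonical discriminant axes.

    Parameters
    ----------
    X : (n, p) array or DataFrame of observations.
    groups : length-n labels; >= 2 groups with >= 2 observations each.
    ridge : when the pooled within covariance is singular, add a small ridge
        (1e-8 x trace) with a logged warning instead of failing.
    """
    Xdf = pd.DataFrame(X)
    Xa = Xdf.to_numpy(dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two observations")
    n, p = Xa.shape
    g = len(labels)
    H, E, order = _sscp(Xa, groups)
    W = E / (n - g)
    ridged = False
    if np.linalg.matrix_rank(E) < p:
        if not ridge:
            raise np.linalg.LinAlgError("singular within-group covariance")
        bump = 1e-8 * np.trace(E) * np.eye(p)
        E = E + bump
        W = E / (n - g)
        ridged = True
        log.warning("singular within-group SSCP: applied ridge 1e-8 x trace")
    # generalized symmetric eigenproblem H v = lambda E v
    eigval, eigvec = linalg.eigh(H, E)
    idx = np.argsort(eigval)[::-1]
    n_axes = min(p, g - 1)
    eigval = np.clip(eigval[idx][:n_axes], 0.0, None)
    V = eigvec[:, idx][:, :n_axes]
    # eigh normalizes v' E v = 1; rescale to unit pooled within-group variance
    V = V * np.sqrt(n - g)
    total = eigval.sum()
    varfrac = eigval / total if total > 0 else np.full(n_axes, 1.0 / n_axes)
    center = Xa.mean(axis=0)
    scores = (Xa - center) @ V
    scores_df = pd.DataFrame(scores, columns=[f"can{i+1}" for i in range(n_axes)],
                             index=Xdf.index)
    scores_df["group"] = groups
    means = pd.DataFrame(
        [Xa[groups == gname].mean(axis=0) for gname in order],
        index=order, columns=Xdf.columns,
    )
    return DiscriminantModel(
        groups=list(order), group_means=means, pooled_within_cov=W,
        coefficients=V, eigenvalues=eigval, variance_fraction=varfrac,
        scores=scores_df, center=center, ridged=ridged,
    )


def _wilks(X: np.ndarray, groups: np.ndarray) -> tuple[float, float, float, float, float]:
    """Wilks' Λ with Rao's F approximation: (lambda, F, df1, df2, p)."""
    H, E, _ = _sscp(X, groups)
    n, p = X.shape
    g = len(pd.unique(groups))
    lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    lam = min(max(lam, np.finfo(float).tiny), 1.0)
    q = g - 1
    m = n - 1 - (p + q + 1) / 2.0
    denom = p**2 + q**2 - 5
    s = np.sqrt((p**2 * q**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1
    lam_s = lam ** (1.0 / s)
    F = (1 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(F, df1, df2))
    return lam, float(F), float(df1), float(df2), pval


def test_groups(model: DiscriminantModel, X, groups) -> GroupComparison:
    """Omnibus Wilks/Rao and Roy tests plus Bonferroni pairwise Wilks tests."""
    Xa = pd.DataFrame(X).to_numpy(dtype=float)
    groups = np.asarray(groups)
    n, p = Xa.shape
    g = len(model.groups)
    lam, F, df1, df2, pval = _wilks(Xa, groups)
    # Roy's greatest root, upper-bound F (SAS convention)
    lam1 = float(model.eigenvalues[0]) if len(model.eigenvalues) else 0.0
    q = g - 1
    r = max(p, q)
    roy_df1 = r
    roy_df2 = n - g - r + q
    roy_F = lam1 * roy_df2 / roy_df1
    roy_p = float(stats.f.sf(roy_F, roy_df1, roy_df2)) if roy_df2 > 0 else float("nan")
    labels = model.groups
    pair_p = pd.DataFrame(np.eye(len(labels)) * np.nan, index=labels, columns=labels)
    n_pairs = len(labels) * (len(labels) - 1) // 2
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            sel = (groups == a) | (groups == b)
            _, _, _, _, p_raw = _wilks(Xa[sel], groups[sel])
            p_adj = min(1.0, p_raw * n_pairs)
            pair_p.loc[a, b] = pair_p.loc[b, a] = p_adj
    sig = pair_p < 0.05
    return GroupComparison(
        wilks_lambda=lam, rao_F=F, df1=df1, df2=df2, p_value=pval,
        roys_root=lam1, roy_F=float(roy_F), roy_df1=float(roy_df1),
        roy_df2=float(roy_df2), roy_p=roy_p,
        pairwise_p=pair_p, pairwise_significant=sig, n_pairs=n_pairs,
    )


def confidence_circles(model: DiscriminantModel, level: float = 0.95) -> list[ConfidenceCircle]:
    """95% confidence circles for group means on the first two canonical axes.

    Scores have unit pooled within-group variance per axis, so the standard
    error of a group mean is n_g^{-1/2} per axis and the circle radius is
    sqrt(χ²₂(level) / n_g).  Groups with a single observation are flagged
    (radius undefined) rather than silently given a circle.
    """
    axes = [c for c in model.scores.columns if c.startswith("can")][:2]
    if not axes:
        raise ValueError("model has no canonical axes")
    chi2 = stats.chi2.ppf(level, df=min(2, len(axes)))
    out = []
    for gname, sub in model.scores.groupby("group", sort=False):
        n_g = len(sub)
        cx = float(sub[axes[0]].mean())
        cy = float(sub[axes[1]].mean()) if len(axes) > 1 else 0.0
        if n_g < 2:
            log.warning("group %s has n=1: confidence circle undefined", gname)
            out.append(ConfidenceCircle(str(gname), (cx, cy), float("nan"), n_g))
            continue
        out.append(ConfidenceCircle(str(gname), (cx, cy), float(np.sqrt(chi2 / n_g)), n_g))
    return out
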