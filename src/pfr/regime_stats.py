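"""Regime-level analyses over pooled (PRx, Mx) index clouds.

Covers the joint-density view of the index plane, a two-sample 2-D
Kolmogorov-Smirnov comparison (Fasano-Franceschini quadrant statistic with a
permutation p-value), the one-parameter linear discriminant
``Mx = c * (1 - PRx)`` separating pressure-passive dynamics from the rest,
per-variable distribution comparisons across regime groups, and an
automatic-relevance-determination (ARD) ranking of which monitored signals
best predict a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.linear_model import LassoCV, RidgeCV

from .classify import LABELS


@dataclass
class IndexPointCloud:
    """Pooled per-window (PRx, Mx) pairs with a regime label per point."""

    points: np.ndarray            # (n, 2) columns (prx, mx)
    group: np.ndarray             # regime label per point
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.group = np.asarray(self.group)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2)")
        if len(self.group) != len(self.points):
            raise ValueError("one group label per point required")
        bad = set(np.unique(self.group)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown group labels {bad}")

    def subset(self, label: str) -> np.ndarray:
        return self.points[self.group == label]


@dataclass
class Discriminant:
    """Boundary family ``Mx = c * (1 - PRx)``; passes through (1, 0)."""

    c: float
    objective: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")


def joint_density(cloud: IndexPointCloud, grid: int = 101,
                  bw_method=None) -> dict:
    """Kernel-smoothed per-group densities on a common [-1, 1]^2 grid.

    Each density integrates to 1 (clipped to the index support and
    renormalized); the difference surface pPFR minus pooled non-pPFR is
    returned under ``"difference"``.  Scott's-rule bandwidth by default.
    """
    axes = np.linspace(-1.0, 1.0, grid)
    gx, gy = np.meshgrid(axes, axes, indexing="ij")
    pts = np.vstack([gx.ravel(), gy.ravel()])
    cell = (axes[1] - axes[0]) ** 2
    out = {"grid": axes}
    dens = {}
    for label in LABELS:
        if len(cloud.subset(label)) == 0:
            raise ValueError(f"empty group {label!r}")
    for label in LABELS:
        sub = cloud.subset(label)
        kde = stats.gaussian_kde(sub.T, bw_method=bw_method)
        d = kde(pts).reshape(grid, grid)
        d /= d.sum() * cell
        dens[label] = d
    out.update(dens)
    non = cloud.points[cloud.group != "pPFR"]
    kde = stats.gaussian_kde(non.T, bw_method=bw_method)
    d_non = kde(pts).reshape(grid, grid)
    d_non /= d_non.sum() * cell
    out["non_pPFR"] = d_non
    out["difference"] = dens["pPFR"] - d_non
    return out


def _quadrant_matrices(xy: np.ndarray):
    """Boolean origin-vs-point quadrant membership, ties excluded.

    Returns four (n_points, n_origins) float32 matrices for the open
    quadrants around every pooled point taken as origin.
    """
    x, y = xy[:, 0], xy[:, 1]
    gx = x[:, None] > x[None, :]
    lx = x[:, None] < x[None, :]
    gy = y[:, None] > y[None, :]
    ly = y[:, None] < y[None, :]
    return [(gx & gy).astype(np.float32), (lx & gy).astype(np.float32),
            (lx & ly).astype(np.float32), (gx & ly).astype(np.float32)]


def ks2d_two_sample(a, b, n_perm: int = 999, seed: int | None = None,
                    method: str = "permutation"):
    """Two-sample 2-D Kolmogorov-Smirnov test (Fasano-Franceschini form).

    ``D`` is the maximum, over the four open quadrant orientations anchored
    at every point of both samples, of the absolute difference in empirical
    quadrant probabilities.  The p-value comes from ``n_perm`` label
    permutations (seeded), or from the asymptotic 1-D approximation with the
    effective sample size when ``method="asymptotic"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2 or b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("samples must be (n, 2) point arrays")
    if len(a) < 20 or len(b) < 20:
        raise ValueError("need >= 20 points per sample")
    na, nb = len(a), len(b)
    pooled = np.vstack([a, b])
    quads = _quadrant_matrices(pooled)
    lab = np.zeros(na + nb, dtype=np.float64)
    lab[:na] = 1.0
    # observed statistic in float64 (exact counts); float32 suffices for the
    # permutation distribution
    D = max(
        float(np.abs(lab @ Q.astype(np.float64) / na
                     - (1.0 - lab) @ Q.astype(np.float64) / nb).max())
        for Q in quads)

    if method == "asymptotic":
        n_eff = na * nb / (na + nb)
        p = float(stats.kstwobign.sf(D * (np.sqrt(n_eff) + 0.12
                                          + 0.11 / np.sqrt(n_eff))))
        return D, min(max(p, 0.0), 1.0)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable p-value")

    rng = np.random.default_rng(seed)
    # all permutation label vectors at once -> quadrant counts by matmul
    perm_labels = np.empty((n_perm, na + nb), dtype=np.float32)
    base = lab.copy()
    for i in range(n_perm):
        perm_labels[i] = rng.permutation(base)
    d_perm = np.zeros(n_perm, dtype=np.float32)
    for Q in quads:
        ca = perm_labels @ Q / na
        cb = (1.0 - perm_labels) @ Q / nb
        np.maximum(d_perm, np.abs(ca - cb).max(axis=1), out=d_perm)
    p = (1.0 + np.sum(d_perm >= D - 1e-12)) / (n_perm + 1.0)
    return D, float(p)


def ca_impaired(prx_value: float, mx_value: float, c: float = 0.43):
    """Joint-index reading of impaired autoregulation:
    ``Mx > c * (1 - PRx)``.  With c=0 this reduces to ``Mx > 0``; at PRx=0
    to ``Mx > c``."""
    prx_value = np.asarray(prx_value, dtype=float)
    mx_value = np.asarray(mx_value, dtype=float)
    out = mx_value > c * (1.0 - prx_value)
    return bool(out) if out.ndim == 0 else out


def _balanced_accuracy(is_ppfr: np.ndarray, pred: np.ndarray) -> float:
    tpr = pred[is_ppfr].mean() if is_ppfr.any() else np.nan
    tnr = (~pred[~is_ppfr]).mean() if (~is_ppfr).any() else np.nan
    return 0.5 * (tpr + tnr)


def fit_discriminant(cloud: IndexPointCloud, step: float = 0.01,
                     method: str = "balanced_accuracy") -> Discriminant:
    """Best boundary ``Mx = c * (1 - PRx)`` separating pPFR from the rest.

    Grid search over c in [0, 1] maximizing the balanced accuracy of the
    rule ``pPFR <=> Mx > c * (1 - PRx)``; ties break toward smaller c.
    ``method="density_contour"`` instead picks the c whose boundary best
    follows the zero contour of the pPFR-minus-rest density difference.
    """
    is_ppfr = cloud.group == "pPFR"
    if not is_ppfr.any() or is_ppfr.all():
        raise ValueError("need both pPFR and non-pPFR points")
    cs = np.arange(0.0, 1.0 + step / 2, step)
    prx_v, mx_v = cloud.points[:, 0], cloud.points[:, 1]
    if method == "density_contour":
        dens = joint_density(cloud)
        diff, axes = dens["difference"], dens["grid"]
        best_c, best_obj = 0.0, -np.inf
        for c in cs:
            # mean signed agreement between the rule's halfplane and the
            # density difference sign over the grid
            gx, gy = np.meshgrid(axes, axes, indexing="ij")
            side = np.where(gy > c * (1.0 - gx), 1.0, -1.0)
            obj = float((side * diff).mean())
            if obj > best_obj + 1e-12:
                best_c, best_obj = float(c), obj
        return Discriminant(c=best_c, objective=best_obj)
    best_c, best_obj = 0.0, -np.inf
    for c in cs:
        pred = mx_v > c * (1.0 - prx_v)
        obj = _balanced_accuracy(is_ppfr, pred)
        if obj > best_obj + 1e-12:
            best_c, best_obj = float(c), obj
    return Discriminant(c=best_c, objective=best_obj)


class BoundaryDiscriminant:
    """Scikit-learn-style estimator for the ``Mx = c(1-PRx)`` boundary."""

    def __init__(self, step: float = 0.01, method: str = "balanced_accuracy"):
        self.step = step
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"step": self.step, "method": self.method}

    def set_params(self, **params) -> "BoundaryDiscriminant":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "BoundaryDiscriminant":
        """X: (n, 2) (PRx, Mx) points; y: regime labels."""
        cloud = IndexPointCloud(np.asarray(X, dtype=float), np.asarray(y))
        d = fit_discriminant(cloud, step=self.step, method=self.method)
        self.c_ = d.c
        self.score_ = d.objective
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "c_"):
            raise ValueError("estimator is not fitted")
        X = np.asarray(X, dtype=float)
        return ca_impaired(X[:, 0], X[:, 1], c=self.c_)


def group_compare(variables: dict, ks_alpha: float = 0.005,
                  t_alpha: float = 0.05, bonferroni: bool = False) -> pd.DataFrame:
    """Pairwise distribution comparisons of 1-min variables across regimes.

    ``variables`` maps variable name -> {group label -> 1-D values}.  For
    every variable and group pair the table carries the 1-D two-sample KS
    statistic and p, the two-sample t-test p, group medians/quartiles, and
    significance flags at the stated thresholds (optionally
    Bonferroni-corrected across pairs within a variable).
    """
    rows = []
    for var, groups in variables.items():
        labels = [g for g in groups if len(np.asarray(groups[g])) > 0]
        skipped = set(groups) - set(labels)
        if skipped:
            warnings.warn(f"{var}: empty group(s) {sorted(skipped)} omitted")
        if len(labels) < 2:
            warnings.warn(f"{var}: fewer than 2 non-empty groups, skipped")
            continue
        pairs = [(g1, g2) for i, g1 in enumerate(labels)
                 for g2 in labels[i + 1 :]]
        corr = len(pairs) if bonferroni else 1
        for g1, g2 in pairs:
            a = np.asarray(groups[g1], dtype=float)
            b = np.asarray(groups[g2], dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            ks = stats.ks_2samp(a, b)
            tt = stats.ttest_ind(a, b, equal_var=False)
            qa, qb = np.percentile(a, [25, 50, 75]), np.percentile(b, [25, 50, 75])
            rows.append({
                "variable": var, "group_a": g1, "group_b": g2,
                "n_a": len(a), "n_b": len(b),
                "ks_D": float(ks.statistic), "ks_p": float(ks.pvalue),
                "t_p": float(tt.pvalue),
                "median_a": qa[1], "q1_a": qa[0], "q3_a": qa[2],
                "median_b": qb[1], "q1_b": qb[0], "q3_b": qb[2],
                "ks_significant": bool(ks.pvalue * corr < ks_alpha),
                "t_significant": bool(tt.pvalue * corr < t_alpha),
            })
    return pd.DataFrame(rows)


def rank_predictors(target, predictors: dict, method: str = "ard",
                    seed: int | None = None,
                    max_gp_samples: int = 400) -> pd.DataFrame:
    """Rank monitored signals by their influence on a target signal.

    ``ard``: Gaussian-process regression with an anisotropic
    squared-exponential kernel; marginal-likelihood optimization learns one
    length scale per predictor and importance is the reciprocal scale.
    ``lasso``/``ridge``: absolute standardized coefficient at the
    cross-validated penalty.  Constant predictors get minimal importance
    with a warning.  Inputs are aligned 1-D arrays; at least 10x more
    samples than predictors are required.
    """
    names = list(predictors)
    X = np.column_stack([np.asarray(predictors[k], dtype=float) for k in names])
    y = np.asarray(target, dtype=float)
    if len(y) != len(X):
        raise ValueError("target and predictors must be aligned")
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    X, y = X[ok], y[ok]
    n, p = X.shape
    if n < 10 * p:
        raise ValueError(f"{n} samples for {p} predictors; need >= {10 * p}")

    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant predictor(s) {[names[i] for i in np.nonzero(const)[0]]}"
            " assigned minimal importance")
    live = ~const
    Xs = np.zeros_like(X)
    Xs[:, live] = (X[:, live] - X[:, live].mean(axis=0)) / sd[live]
    ys = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)

    scores = np.zeros(p)
    if method == "ard":
        rng = np.random.default_rng(seed)
        idx = (rng.choice(n, size=max_gp_samples, replace=False)
               if n > max_gp_samples else np.arange(n))
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(np.ones(int(live.sum())), (1e-2, 1e4))
                  + WhiteKernel(0.1, (1e-6, 1e2)))
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      n_restarts_optimizer=0,
                                      random_state=seed)
        with warnings.catch_warnings():
            # irrelevant predictors legitimately push their length scale to
            # the upper bound (infinite scale = no influence)
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(Xs[np.ix_(idx, np.nonzero(live)[0])], ys[idx])
        ls = gp.kernel_.k1.k2.length_scale
        scores[live] = 1.0 / np.atleast_1d(ls)
    elif method in ("lasso", "ridge"):
        if method == "lasso":
            est = LassoCV(cv=5, random_state=seed).fit(Xs[:, live], ys)
        else:
            est = RidgeCV(alphas=np.logspace(-3, 3, 25)).fit(Xs[:, live], ys)
        scores[live] = np.abs(est.coef_)
    else:
        raise ValueError(f"unknown method {method!r}")

    df = pd.DataFrame({"predictor": names, "importance": scores,
                       "method": method})
    df = df.sort_values("importance", ascending=False,
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, p + 1)
    return df
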