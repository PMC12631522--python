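"""Weighted Bernoulli boosted regression trees with CV tree selection.

The occurrence of each parasitic functional type is modelled as a Bernoulli
response over environmental predictors with stagewise gradient boosting of
shallow regression trees ("boosted regression trees" in the ecological
literature).  Plot-level weights encode abundance: a plot without the focal
type gets raw weight 1, an occupied plot gets the type's relative cover, and
raw weights are min-max scaled to [1, 101]:

    scaled = (w - min(w)) / (max(w) - min(w)) * 100 + 1

The number of trees is chosen by k-fold cross-validation: the model is grown
once to ``max_trees`` per fold, staged held-out Bernoulli deviance is
evaluated every ``step_size`` trees, and the tree count minimising the mean
weighted held-out deviance is selected; the final model is refit on all data
at that size.  Per-predictor relative influence (squared-error reduction
importances) is normalised to sum to 100.

Residual spatial structure is checked with a Moran's I correlogram over
equal-width distance classes, the class count set by Sturges's rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class BrtConfig:
    learning_rate: float = 0.001
    tree_complexity: int = 5
    bag_fraction: float = 0.5
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.tree_complexity < 1:
            raise ValueError("tree_complexity must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class BrtFit:
    n_trees_selected: int
    cv_deviance_curve: list[tuple[int, float]]
    relative_influence: dict[str, float]
    partial_dependence: dict[str, tuple[list[float], list[float]]] = field(default_factory=dict)


def presence_weights(type_relative: np.ndarray) -> np.ndarray:
    """Raw plot weights for one functional type: relative cover where the
    type occurs, 1 where it does not."""
    rel = np.asarray(type_relative, dtype=float)
    return np.where(rel > 0, rel, 1.0)


def scale_weights(raw: np.ndarray) -> np.ndarray:
    """Min-max scale raw weights onto [1, 101]."""
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)) or np.any(raw < 0):
        raise ValueError("raw weights must be finite and >= 0")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        logger.warning("all raw weights equal; scaled weights set to 1")
        return np.ones_like(raw)
    return (raw - lo) / (hi - lo) * 100.0 + 1.0


def bernoulli_deviance(y: np.ndarray, p: np.ndarray, w: np.ndarray | None = None) -> float:
    """Weighted mean Bernoulli deviance -2*mean_w[y log p + (1-y) log(1-p)]."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = y * np.log(p) + (1.0 - y) * np.log1p(-p)
    if w is None:
        return float(-2.0 * np.mean(ll))
    w = np.asarray(w, dtype=float)
    return float(-2.0 * np.sum(w * ll) / np.sum(w))


class WeightedBoostedTrees(BaseEstimator, ClassifierMixin):
    """Bernoulli boosted regression trees with CV-selected tree count.

    Parameters mirror the ecological BRT convention: ``tree_complexity`` is
    the interaction depth of each tree, ``bag_fraction`` the stochastic
    subsample used for each tree, ``learning_rate`` the shrinkage.

    Fitted attributes
    -----------------
    n_trees_ : int
        Tree count minimising the mean weighted held-out deviance.
    cv_deviance_curve_ : list of (n_trees, deviance)
    relative_influence_ : dict predictor -> percent (sums to 100)
    estimator_ : the final model refit on all data at ``n_trees_``.
    """

    def __init__(self, learning_rate: float = 0.001, tree_complexity: int = 5,
                 bag_fraction: float = 0.5, n_folds: int = 10, step_size: int = 50,
                 max_trees: int = 1000, random_state: int = 0):
        self.learning_rate = learning_rate
        self.tree_complexity = tree_complexity
        self.bag_fraction = bag_fraction
        self.n_folds = n_folds
        self.step_size = step_size
        self.max_trees = max_trees
        self.random_state = random_state

    def _make_gbm(self, n_estimators: int, seed: int) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            loss="log_loss", learning_rate=self.learning_rate,
            n_estimators=n_estimators, max_depth=self.tree_complexity,
            subsample=self.bag_fraction, random_state=seed)

    def fit(self, X, y, sample_weight=None):
        cfg = BrtConfig(self.learning_rate, self.tree_complexity, self.bag_fraction,
                        self.n_folds, self.step_size, self.max_trees, self.random_state)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{i}" for i in range(Xa.shape[1])], dtype=object)
        ya = np.asarray(y, dtype=int)
        classes = np.unique(ya)
        if len(classes) < 2:
            raise ValueError("response has a single class; cannot fit a Bernoulli model")
        w = np.ones(len(ya)) if sample_weight is None else np.asarray(sample_weight, float)

        steps = np.arange(cfg.step_size, cfg.max_trees + 1, cfg.step_size)
        cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        dev = np.zeros((cfg.n_folds, len(steps)))
        for f, (tr, te) in enumerate(cv.split(Xa, ya)):
            gbm = self._make_gbm(cfg.max_trees, cfg.seed + 1 + f)
            gbm.fit(Xa[tr], ya[tr], sample_weight=w[tr])
            staged = gbm.staged_predict_proba(Xa[te])
            for k, proba in enumerate(staged, start=1):
                j = k // cfg.step_size - 1
                if k % cfg.step_size == 0:
                    dev[f, j] = bernoulli_deviance(ya[te], proba[:, 1], w[te])
        mean_dev = dev.mean(axis=0)
        best = int(np.argmin(mean_dev))
        self.n_trees_ = int(steps[best])
        self.cv_deviance_curve_ = [(int(s), float(d)) for s, d in zip(steps, mean_dev)]
        if best == len(steps) - 1 and len(steps) > 1 and mean_dev[-1] < mean_dev[-2]:
            warnings.warn("CV deviance still decreasing at max_trees; "
                          "consider raising max_trees", stacklevel=2)

        self.estimator_ = self._make_gbm(self.n_trees_, cfg.seed)
        self.estimator_.fit(Xa, ya, sample_weight=w)
        imp = self.estimator_.feature_importances_
        total = imp.sum()
        imp = imp / total * 100.0 if total > 0 else np.full_like(imp, 100.0 / len(imp))
        self.relative_influence_ = {
            str(name): float(v) for name, v in zip(self.feature_names_in_, imp)}
        self.classes_ = classes
        self.X_ = Xa
        return self

    def predict_proba(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.estimator_.predict_proba(Xa)

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X):
        Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.estimator_.decision_function(Xa)

    def partial_dependence(self, predictor: str | int, grid_size: int = 100):
        """Clamp-and-average partial dependence on the logit scale.

        For each grid value spanning the predictor's observed range, the
        predictor is clamped to that value over all training rows and the
        mean decision function recorded.
        """
        names = list(self.feature_names_in_)
        if isinstance(predictor, str):
            if predictor not in names:
                raise ValueError(f"unknown predictor {predictor!r}")
            j = names.index(predictor)
        else:
            j = int(predictor)
        col = self.X_[:, j]
        grid = np.linspace(col.min(), col.max(), grid_size)
        curve = np.empty(grid_size)
        Xc = self.X_.copy()
        for g, value in enumerate(grid):
            Xc[:, j] = value
            curve[g] = float(np.mean(self.estimator_.decision_function(Xc)))
        return grid, curve


def fit_brt(X, y, w=None, cfg: BrtConfig | None = None,
            pd_predictors: Sequence[str] | None = None,
            pd_grid_size: int = 100) -> BrtFit:
    """Functional wrapper returning a serialisable :class:`BrtFit`."""
    cfg = cfg or BrtConfig()
    model = WeightedBoostedTrees(
        learning_rate=cfg.learning_rate, tree_complexity=cfg.tree_complexity,
        bag_fraction=cfg.bag_fraction, n_folds=cfg.n_folds,
        step_size=cfg.step_size, max_trees=cfg.max_trees, random_state=cfg.seed)
    model.fit(X, y, sample_weight=w)
    pdep: dict[str, tuple[list[float], list[float]]] = {}
    for name in (pd_predictors or []):
        grid, curve = model.partial_dependence(name, pd_grid_size)
        pdep[name] = (grid.tolist(), curve.tolist())
    return BrtFit(n_trees_selected=model.n_trees_,
                  cv_deviance_curve=model.cv_deviance_curve_,
                  relative_influence=model.relative_influence_,
                  partial_dependence=pdep)


def relative_influence(fit: BrtFit | WeightedBoostedTrees) -> dict[str, float]:
    if isinstance(fit, WeightedBoostedTrees):
        return dict(fit.relative_influence_)
    return dict(fit.relative_influence)


# ---------------------------------------------------------------------------
# Moran's I correlogram
# ---------------------------------------------------------------------------

@dataclass
class MoranClass:
    d_lower: float
    d_upper: float
    n_pairs: int
    i: float | None
    expected: float
    p: float | None


def sturges_classes(n: int) -> int:
    """Number of distance classes by Sturges's rule: ceil(1 + log2 n)."""
    return int(np.ceil(1.0 + np.log2(n)))


def morans_i_correlogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_perm: int = 199,
    seed: int = 0,
    n_classes: int | None = None,
    binning: str = "equal_width",
) -> list[MoranClass]:
    """Moran's I per distance class with permutation p-values.

    Distance classes are equal-width bins over (0, max pairwise distance]
    (``binning="equal_count"`` uses pair-count quantile edges instead), with
    the class count from Sturges's rule.  Within-class spatial weights are
    binary.  P-values are two-sided permutation tests on I - E[I], where the
    null expectation is -1/(n-1).
    """
    z = np.asarray(residuals, dtype=float)
    xy = np.asarray(coords, dtype=float)
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 observations")
    if binning not in ("equal_width", "equal_count"):
        raise ValueError(f"unknown binning {binning!r}")
    k = n_classes or sturges_classes(n)
    d = pdist(xy)
    dmax = d.max()
    if binning == "equal_width":
        edges = np.linspace(0.0, dmax, k + 1)
    else:
        edges = np.quantile(d, np.linspace(0.0, 1.0, k + 1))
        edges[0] = 0.0
    # upper-inclusive bins over (0, dmax]
    cls = np.clip(np.searchsorted(edges, d, side="left") - 1, 0, k - 1)
    iu, ju = np.triu_indices(n, k=1)

    zc = z - z.mean()
    denom = float(np.sum(zc ** 2))
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)

    cross = zc[iu] * zc[ju]
    obs_sums = np.bincount(cls, weights=cross, minlength=k)
    pair_counts = np.bincount(cls, minlength=k)

    perm_sums = np.empty((n_perm, k))
    for b in range(n_perm):
        zp = rng.permutation(zc)
        perm_sums[b] = np.bincount(cls, weights=zp[iu] * zp[ju], minlength=k)

    out = []
    for c in range(k):
        npairs = int(pair_counts[c])
        if npairs < 2 or denom == 0.0:
            out.append(MoranClass(float(edges[c]), float(edges[c + 1]), npairs,
                                  None, expected, None))
            continue
        s0 = 2.0 * npairs  # symmetric binary weights
        i_obs = (n / s0) * (2.0 * obs_sums[c]) / denom
        i_perm = (n / s0) * (2.0 * perm_sums[:, c]) / denom
        p = float(np.mean(np.abs(i_perm - expected) >= abs(i_obs - expected)))
        out.append(MoranClass(float(edges[c]), float(edges[c + 1]), npairs,
                              float(i_obs), expected, p))
    return out
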