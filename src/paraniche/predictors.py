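"""Predictor preparation and RDA-style forward selection of climate variables.

Climate predictor sets (bioclim variables, evapotranspiration) are strongly
intercorrelated.  Dimensionality is reduced by sequential forward selection:
at each step the candidate that, together with the already-selected set, best
explains the variability of the remaining (unselected) climate columns is
added.  "Explains" is the trace R-squared of the multivariate linear
regression of the remaining columns on the selected set; the cumulative
criterion is the adjusted R-squared (Ezekiel) of regressing the full climate
table on the selected set, and selection stops once it reaches a target
(default 0.95) or no candidate adds variance.

Ties within tolerance are broken by a user-supplied priority list, emulating
the ecological preference for growing-season variables (e.g. bio10 over
annual means); otherwise the first column in order wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .data import Dataset, ENV_PREDICTORS


@dataclass
class PredictorMatrix:
    frame: pd.DataFrame  # plot_id-indexed
    transforms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frame.columns.duplicated().any():
            raise ValueError("duplicate predictor columns")
        if self.frame.isna().any().any():
            raise ValueError("PredictorMatrix contains missing values")


_TRANSFORMS = ("none", "log", "sqrt")


def prepare_predictors(
    dataset: Dataset,
    transforms: Mapping[str, str] | None = None,
    include_plot_size: bool = True,
    include_descriptors: bool = True,
) -> PredictorMatrix:
    """Assemble the plot-level predictor matrix with transformations applied.

    Plot size is square-root transformed; plots lacking a plot size get the
    median imputed plus a binary ``plot_size_missing`` indicator column.
    """
    transforms = dict(transforms or {})
    headers = dataset.headers_frame().set_index("plot_id")
    cols: dict[str, pd.Series] = {}
    for name in ENV_PREDICTORS:
        if headers[name].isna().any():
            missing = headers.index[headers[name].isna()][0]
            raise ValueError(f"predictor {name} missing for plot {missing}")
        cols[name] = _apply_transform(headers[name], transforms.get(name, "none"), name)
    if include_descriptors:
        for name in ("open", "wet", "saline"):
            cols[name] = headers[name].astype(float)
    applied = {name: transforms.get(name, "none") for name in ENV_PREDICTORS}
    if include_plot_size:
        size = headers["plot_size_m2"].astype(float)
        miss = size.isna()
        if miss.all():
            raise ValueError("all plot sizes missing; cannot impute")
        size = size.fillna(size.median())
        tf = transforms.get("plot_size_m2", "sqrt")
        cols["plot_size"] = _apply_transform(size, tf, "plot_size_m2")
        applied["plot_size_m2"] = tf
        if miss.any():
            cols["plot_size_missing"] = miss.astype(float)
    return PredictorMatrix(frame=pd.DataFrame(cols, index=headers.index), transforms=applied)


def _apply_transform(series: pd.Series, transform: str, name: str) -> pd.Series:
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r} for {name}")
    if transform == "none":
        return series.astype(float)
    values = series.astype(float)
    if transform == "log":
        bad = values[values <= 0]
        if len(bad):
            raise ValueError(f"log transform of nonpositive {name} in plot {bad.index[0]}")
        return np.log(values)
    bad = values[values < 0]
    if len(bad):
        raise ValueError(f"sqrt transform of negative {name} in plot {bad.index[0]}")
    return np.sqrt(values)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted_r2 requires n > p + 1 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _trace_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Trace R^2 of the multivariate regression of Y (centred) on X."""
    if X.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ beta
    ss_tot = float(np.sum(Y ** 2))
    if ss_tot == 0.0:
        return 1.0
    return float(np.sum(fitted ** 2) / ss_tot)


@dataclass
class ForwardSelection:
    order: list[str]
    cumulative_r2: list[float]
    cumulative_r2adj: list[float]


def rda_forward_select(
    climate: pd.DataFrame | PredictorMatrix,
    stop_r2adj: float = 0.95,
    priority: Sequence[str] | None = None,
    tol: float = 1e-9,
) -> ForwardSelection:
    """Sequential forward selection of climate predictors.

    Columns are standardised to zero mean and unit variance; constant columns
    are dropped with a warning.  At each step the candidate maximising the
    trace R^2 of the remaining (unselected) columns regressed on the
    selected-so-far set plus the candidate is added; the cumulative criterion
    is the adjusted R^2 of the full climate table on the selected set.
    """
    frame = climate.frame if isinstance(climate, PredictorMatrix) else climate
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 climate columns")
    sd = frame.std(ddof=1)
    constant = list(sd.index[sd == 0])
    if constant:
        warnings.warn(f"dropping constant column(s) {constant}", stacklevel=2)
        frame = frame.drop(columns=constant)
    Z = (frame - frame.mean()) / frame.std(ddof=1)
    names = list(Z.columns)
    n = len(Z)
    data = Z.to_numpy()
    prio = {name: i for i, name in enumerate(priority)} if priority else {}

    selected: list[str] = []
    cum_r2: list[float] = []
    cum_r2adj: list[float] = []
    while len(selected) < len(names):
        remaining = [c for c in names if c not in selected]
        X_sel = data[:, [names.index(c) for c in selected]]
        base = _trace_r2(data[:, [names.index(c) for c in remaining]], X_sel)
        scores: dict[str, float] = {}
        for cand in remaining:
            others = [c for c in remaining if c != cand]
            X = data[:, [names.index(c) for c in selected + [cand]]]
            if others:
                scores[cand] = _trace_r2(data[:, [names.index(c) for c in others]], X)
            else:  # last candidate: it explains itself fully
                scores[cand] = 1.0
        best_score = max(scores.values())
        if best_score <= base + tol and selected:
            break  # no candidate adds variance to the remaining columns
        tied = [c for c in remaining if scores[c] >= best_score - tol]
        tied.sort(key=lambda c: (prio.get(c, math.inf), names.index(c)))
        selected.append(tied[0])
        X_sel = data[:, [names.index(c) for c in selected]]
        r2_full = _trace_r2(data, X_sel)
        cum_r2.append(r2_full)
        cum_r2adj.append(adjusted_r2(r2_full, n, len(selected)))
        if cum_r2adj[-1] >= stop_r2adj:
            break
    return ForwardSelection(order=selected, cumulative_r2=cum_r2,
                            cumulative_r2adj=cum_r2adj)


class ForwardRdaSelector(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer wrapping :func:`rda_forward_select`.

    Parameters
    ----------
    stop_r2adj : float
        Stop once the selected set explains this adjusted R^2 of the full
        climate table.
    priority : sequence of str, optional
        Tie-break preference order (growing-season variables first).
    tol : float
        Tie tolerance on the selection statistic.
    """

    def __init__(self, stop_r2adj: float = 0.95,
                 priority: Sequence[str] | None = None, tol: float = 1e-9):
        self.stop_r2adj = stop_r2adj
        self.priority = priority
        self.tol = tol

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        result = rda_forward_select(X, self.stop_r2adj, self.priority, self.tol)
        self.selected_ = list(result.order)
        self.cumulative_r2_ = list(result.cumulative_r2)
        self.cumulative_r2adj_ = list(result.cumulative_r2adj)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "selected_"):
            raise RuntimeError("ForwardRdaSelector is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        return X[self.selected_]
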