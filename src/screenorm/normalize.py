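"""Piecewise-linear, core-restricted quantile normalization (rscreenorm).

Per replicate the procedure is:

1. standardize readouts into lethality scores against the control medians
   (skipped when the input already lives on that scale);
2. select a core set of score values (percentile or control-distance rule);
3. summarize each core by a fixed grid of empirical quantiles and average
   the grids across replicates;
4. regress the mean grid on the replicate's own grid — the fitted intercept
   a_k and slope b_k re-express the quantile normalization as a linear map
   valid on the whole core;
5. extend the map beyond the core bounds as a pure shift, so values outside
   the core move by the same amount as the nearest core value and tail
   heaviness is preserved.

The result is a continuous piecewise-linear transform per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

try:  # estimator API; degrades gracefully to plain classes
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

    class TransformerMixin:  # type: ignore[no-redef]
        pass

from .core_set import (
    DEFAULT_N_QUANTILES,
    ReplicateCore,
    normalize_grids,
    quantile_grid,
    select_core_distance,
    select_core_percentile,
)
from .lethality import LethalityScores, compute_lethality_scores, scores_from_values
from .study import ScreenStudy, TransformSpec, transform_readout

TAIL_MODES = ("shift", "literal_reflect")


@dataclass
class PiecewiseLinearMap:
    """Fitted per-replicate normalization transform.

    Inside the core bounds the map is ``a + b * z``.  Above the upper bound
    it is a shift by the same amount as the bound itself:
    ``a + (b - 1) * z_max + z``.  Below the lower bound, ``tail_mode="shift"``
    (default) applies the analogous order-preserving shift; the alternative
    ``"literal_reflect"`` form ``a + (b + 1) * z_min - z`` reflects the lower
    tail (slope -1) and is kept for strict reproduction of the published
    lower-tail formula.  Both modes are continuous at the bounds.
    """

    intercept: float
    slope: float
    z_min: float
    z_max: float
    tail_mode: str = "shift"

    def __post_init__(self) -> None:
        if self.tail_mode not in TAIL_MODES:
            raise ValueError(f"tail_mode must be one of {TAIL_MODES}")
        if not self.z_min <= self.z_max:
            raise ValueError("z_min must not exceed z_max")

    def __call__(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        a, b = self.intercept, self.slope
        out = a + b * z
        hi = z > self.z_max
        out = np.where(hi, a + (b - 1) * self.z_max + z, out)
        lo = z < self.z_min
        if self.tail_mode == "shift":
            out = np.where(lo, a + (b - 1) * self.z_min + z, out)
        else:
            out = np.where(lo, a + (b + 1) * self.z_min - z, out)
        return out if out.ndim else float(out)


def fit_linear_map(
    grid_k: np.ndarray,
    mean_grid: np.ndarray,
    core: ReplicateCore,
    tail_mode: str = "shift",
) -> PiecewiseLinearMap:
    """Least-squares fit of the mean grid on one replicate's grid.

    A zero-variance grid (e.g. a degenerate core of identical values) cannot
    identify a slope; the fit then falls back to pure centering (slope 1,
    intercept = difference of grid means) with a warning.
    """
    grid_k = np.asarray(grid_k, dtype=float)
    mean_grid = np.asarray(mean_grid, dtype=float)
    if grid_k.shape != mean_grid.shape:
        raise ValueError("grids must have equal length")
    constant = bool(np.all(grid_k == grid_k[0]))
    if constant:
        warnings.warn(
            "zero-variance quantile grid; falling back to pure centering (slope 1)",
            RuntimeWarning,
            stacklevel=2,
        )
        b = 1.0
        a = float(mean_grid.mean() - grid_k.mean())
    else:
        var = float(np.var(grid_k))
        b = float(np.cov(grid_k, mean_grid, bias=True)[0, 1] / var)
        a = float(mean_grid.mean() - b * grid_k.mean())
    return PiecewiseLinearMap(
        intercept=a, slope=b, z_min=core.z_min, z_max=core.z_max, tail_mode=tail_mode
    )


def apply_map(pwl_map: PiecewiseLinearMap, scores: np.ndarray) -> np.ndarray:
    """Apply a fitted piecewise-linear map to a score vector."""
    return pwl_map(np.asarray(scores, dtype=float))


class RScreenNorm(BaseEstimator, TransformerMixin):
    """Control-anchored piecewise-linear quantile normalizer.

    Parameters
    ----------
    readout_transform
        Elementwise readout transform applied first: ``"identity"``,
        ``"log2_pseudocount"``, ``"asinh"`` or ``"negate"``.
    pseudocount
        Offset for the log2 transform.
    scope
        ``"replicate"`` or ``"plate"``: where control medians are taken when
        computing lethality scores.  Plate scope cancels additive plate
        effects.
    readouts_are_scores
        Set True when the input readouts already are lethality scores (e.g.
        simulated data); the standardization step is then skipped.
    core_method
        ``"percentile"`` (default) or ``"distance"``.
    alpha_high, alpha_low
        Percentile-core parameters; floats or mappings keyed by replicate or
        cell line.  The default 0.95 keeps the lowest 95% of score values.
    gamma
        Distance-core parameter: keep values with
        ``|v - m_neg| <= gamma * |v - m_pos|``.
    tail_mode
        ``"shift"`` (order-preserving, default) or ``"literal_reflect"`` for
        the reflecting lower-tail form.
    n_quantiles
        Length of the per-replicate quantile grids.

    Attributes
    ----------
    scores_ : LethalityScores
        Scores of the training study (controls included).
    core_sets_ : CoreSet
    grids_ : dict[str, numpy.ndarray]
    mean_grid_ : numpy.ndarray
    maps_ : dict[str, PiecewiseLinearMap]
    params_table_ : pandas.DataFrame
        One row per replicate: intercept, slope, core bounds, selection
        parameters and core size.
    """

    def __init__(
        self,
        readout_transform: str = "identity",
        pseudocount: float = 0.0,
        scope: str = "replicate",
        readouts_are_scores: bool = False,
        core_method: str = "percentile",
        alpha_high: float | Mapping[str, float] = 0.95,
        alpha_low: float | Mapping[str, float] = 0.0,
        gamma: float = 1.0,
        tail_mode: str = "shift",
        n_quantiles: int = DEFAULT_N_QUANTILES,
    ) -> None:
        self.readout_transform = readout_transform
        self.pseudocount = pseudocount
        self.scope = scope
        self.readouts_are_scores = readouts_are_scores
        self.core_method = core_method
        self.alpha_high = alpha_high
        self.alpha_low = alpha_low
        self.gamma = gamma
        self.tail_mode = tail_mode
        self.n_quantiles = n_quantiles

    # -- internals ----------------------------------------------------------
    def _scores(self, X: ScreenStudy) -> LethalityScores:
        if self.readouts_are_scores:
            return scores_from_values(X)
        study = transform_readout(
            X, TransformSpec(kind=self.readout_transform, pseudocount=self.pseudocount)
        )
        return compute_lethality_scores(study, scope=self.scope)

    # -- estimator API ------------------------------------------------------
    def fit(self, X: ScreenStudy, y=None) -> "RScreenNorm":
        if self.core_method not in ("percentile", "distance"):
            raise ValueError("core_method must be 'percentile' or 'distance'")
        scores = self._scores(X)
        if self.core_method == "percentile":
            core_sets = select_core_percentile(scores, self.alpha_high, self.alpha_low)
        else:
            core_sets = select_core_distance(scores, self.gamma)

        grids = {
            rep: quantile_grid(core_sets[rep], self.n_quantiles)
            for rep in core_sets.replicates
        }
        mean_grid = normalize_grids(list(grids.values()))
        maps = {
            rep: fit_linear_map(grids[rep], mean_grid, core_sets[rep], self.tail_mode)
            for rep in core_sets.replicates
        }

        rows = []
        for rep in core_sets.replicates:
            core = core_sets[rep]
            m = maps[rep]
            rows.append(
                {
                    "replicate": rep,
                    "a": m.intercept,
                    "b": m.slope,
                    "z_min": m.z_min,
                    "z_max": m.z_max,
                    "alpha_high": core.params.get("alpha_high", np.nan),
                    "alpha_low_or_gamma": core.params.get(
                        "alpha_low", core.params.get("gamma", np.nan)
                    ),
                    "core_size": core.size,
                }
            )

        self.scores_ = scores
        self.core_sets_ = core_sets
        self.grids_ = grids
        self.mean_grid_ = mean_grid
        self.maps_ = maps
        self.params_table_ = pd.DataFrame(rows)
        return self

    def transform(self, X: ScreenStudy) -> pd.DataFrame:
        """Normalize a study with the fitted per-replicate maps.

        Returns a DataFrame with the study annotations plus
        ``lethality_score``, ``rscreenorm_score`` and ``in_core`` columns.
        Controls are transformed with the same map as library features.
        """
        if not hasattr(self, "maps_"):
            raise RuntimeError("RScreenNorm is not fitted")
        scores = self._scores(X)
        df = scores.data.copy()
        unseen = sorted(set(df["replicate"]) - set(self.maps_))
        if unseen:
            raise ValueError(f"replicates not seen during fit: {unseen}")

        normed = np.empty(len(df), dtype=float)
        in_core = np.zeros(len(df), dtype=bool)
        for rep, sub in df.groupby("replicate", sort=False):
            m = self.maps_[rep]
            z = sub["score"].to_numpy(dtype=float)
            normed[sub.index] = m(z)
            in_core[sub.index] = (z >= m.z_min) & (z <= m.z_max)

        df = df.rename(columns={"score": "lethality_score"})
        df["rscreenorm_score"] = normed
        df["in_core"] = in_core
        return df.drop(columns=["readout"])

    def fit_transform(self, X: ScreenStudy, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def rscreenorm(study: ScreenStudy, **params) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-shot functional interface: normalize a study.

    Returns ``(result, fitted_params)`` where ``result`` has per-row
    ``lethality_score``, ``rscreenorm_score`` and ``in_core`` columns and
    ``fitted_params`` is the per-replicate parameter table.
    """
    est = RScreenNorm(**params)
    out = est.fit_transform(study)
    return out, est.params_table_
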