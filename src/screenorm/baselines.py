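"""Comparator normalizations: robust z-scores, median-centering, classic QN.

All three ignore the assay controls when fitting: centers, scales and the
reference distribution are estimated from library features only, and
controls are then pushed through the same per-replicate transform.  They
share the estimator API of :class:`~screenorm.normalize.RScreenNorm` and
accept either a :class:`~screenorm.study.ScreenStudy` (readouts used as the
score), a :class:`~screenorm.lethality.LethalityScores`, or a long DataFrame
with a ``score`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

    class TransformerMixin:  # type: ignore[no-redef]
        pass

from .lethality import LethalityScores
from .study import WELL_LIBRARY, ScreenStudy

MAD_SCALE = 1.4826  # consistency factor for the normal distribution


def _score_frame(X) -> pd.DataFrame:
    if isinstance(X, ScreenStudy):
        df = X.data.copy()
        df["score"] = df["readout"].astype(float)
        return df.reset_index(drop=True)
    if isinstance(X, LethalityScores):
        return X.data.copy().reset_index(drop=True)
    if isinstance(X, pd.DataFrame):
        if "score" not in X.columns:
            raise ValueError("DataFrame input needs a 'score' column")
        return X.copy().reset_index(drop=True)
    raise TypeError(f"unsupported input type {type(X).__name__}")


class _PerReplicateBaseline(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for per-replicate location/scale maps."""

    def _fit_replicate(self, x: np.ndarray, rep: str) -> tuple[float, float]:
        raise NotImplementedError

    def fit(self, X, y=None):
        df = _score_frame(X)
        params: dict[str, tuple[float, float]] = {}
        for rep, sub in df.groupby("replicate", sort=False):
            lib = sub.loc[sub["well_type"] == WELL_LIBRARY, "score"].to_numpy(float)
            if lib.size == 0:
                raise ValueError(f"replicate {rep}: no library features")
            params[rep] = self._fit_replicate(lib, str(rep))
        self.params_ = params
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "params_"):
            raise RuntimeError(f"{type(self).__name__} is not fitted")
        df = _score_frame(X)
        unseen = sorted(set(df["replicate"]) - set(self.params_))
        if unseen:
            raise ValueError(f"replicates not seen during fit: {unseen}")
        out = np.empty(len(df), dtype=float)
        for rep, sub in df.groupby("replicate", sort=False):
            center, scale = self.params_[rep]
            out[sub.index] = (sub["score"].to_numpy(float) - center) / scale
        df["normalized_score"] = out
        return df

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


class RobustZScore(_PerReplicateBaseline):
    """Per-replicate robust z-scores: (x - median) / (1.4826 * MAD).

    ``scale_mad=False`` divides by the raw MAD instead.  Errors out on
    zero-MAD replicates (a constant vector has no scale).
    """

    def __init__(self, scale_mad: bool = True) -> None:
        self.scale_mad = scale_mad

    def _fit_replicate(self, x: np.ndarray, rep: str) -> tuple[float, float]:
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        if mad == 0.0:
            raise ValueError(f"replicate {rep}: MAD is zero")
        return med, mad * MAD_SCALE if self.scale_mad else mad


class MedianCenter(_PerReplicateBaseline):
    """Per-replicate median subtraction (library features define the median)."""

    def _fit_replicate(self, x: np.ndarray, rep: str) -> tuple[float, float]:
        return float(np.median(x)), 1.0


class ClassicQuantileNormalizer(BaseEstimator, TransformerMixin):
    """Full-range quantile normalization across replicates.

    Fit on a complete features x replicates matrix of library scores: the
    reference distribution is the row-wise mean of the sorted columns.
    Transform replaces each replicate's values by the reference value at
    their rank; tied values receive the mean of their tied positions'
    reference values.  This equalizes every replicate's empirical
    distribution exactly — including the tails, which is precisely what the
    core-restricted method avoids.
    """

    def fit(self, X, y=None):
        matrix = self._matrix(X)
        self.n_features_ = matrix.shape[0]
        self.reference_ = np.sort(matrix, axis=0).mean(axis=1)
        return self

    @staticmethod
    def _matrix(X) -> np.ndarray:
        if isinstance(X, np.ndarray):
            if X.ndim != 2:
                raise ValueError("expected a 2-D features x replicates matrix")
            return np.asarray(X, dtype=float)
        df = _score_frame(X)
        lib = df[df["well_type"] == WELL_LIBRARY]
        pivot = lib.pivot_table(
            index="feature_id", columns="replicate", values="score", sort=False
        )
        if pivot.isna().any().any():
            raise ValueError("incomplete matrix: every feature needs a value "
                             "in every replicate")
        return pivot.to_numpy(dtype=float)

    def _normalize_column(self, x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="stable")
        out = np.empty_like(x)
        out[order] = self.reference_
        # ties: average the reference values assigned to equal inputs
        s = pd.Series(out)
        return s.groupby(pd.Series(x)).transform("mean").to_numpy()

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise RuntimeError("ClassicQuantileNormalizer is not fitted")
        if isinstance(X, np.ndarray):
            if X.shape[0] != self.n_features_:
                raise ValueError("matrix height differs from the fitted one")
            return np.column_stack(
                [self._normalize_column(X[:, j]) for j in range(X.shape[1])]
            )
        df = _score_frame(X)
        out = df["score"].to_numpy(dtype=float).copy()
        lib_mask = df["well_type"] == WELL_LIBRARY
        for _, sub in df[lib_mask].groupby("replicate", sort=False):
            if len(sub) != self.n_features_:
                raise ValueError("incomplete matrix: replicate size differs "
                                 "from the fitted feature count")
            out[sub.index] = self._normalize_column(sub["score"].to_numpy(float))
        # controls: mapped through the empirical reference by interpolation
        for rep, sub in df[~lib_mask].groupby("replicate", sort=False):
            lib = df[lib_mask & (df["replicate"] == rep)]
            src = np.sort(lib["score"].to_numpy(float))
            out[sub.index] = np.interp(sub["score"].to_numpy(float), src, self.reference_)
        df["normalized_score"] = out
        return df

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


# -- functional wrappers ----------------------------------------------------

def robust_z(X, scale_mad: bool = True) -> pd.DataFrame:
    """Fit-and-apply robust z-scores; see :class:`RobustZScore`."""
    return RobustZScore(scale_mad=scale_mad).fit_transform(X)


def median_center(X) -> pd.DataFrame:
    """Fit-and-apply per-replicate median-centering; see :class:`MedianCenter`."""
    return MedianCenter().fit_transform(X)


def classic_quantile_normalize(X):
    """Fit-and-apply classic quantile normalization on a complete matrix."""
    return ClassicQuantileNormalizer().fit_transform(X)
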