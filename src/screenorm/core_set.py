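"""Core-set selection and core-restricted quantile grids.

The core set of a replicate is the multiset of lethality-score *values*
assumed to represent phenotypes common to all screens; upper (and optionally
lower) tails are excluded so that genuinely different proportions of extreme
phenotypes survive normalization.  Each core is summarized by a fixed-length
grid of empirical quantiles so that cores of different sizes can be averaged
across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .lethality import LethalityScores

DEFAULT_N_QUANTILES = 1000


class EmptyCoreError(ValueError):
    """A selection rule produced an empty core set."""


@dataclass
class ReplicateCore:
    """Selected score values of one replicate with their bounds."""

    values: np.ndarray
    z_min: float
    z_max: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise EmptyCoreError("core set is empty")

    @property
    def size(self) -> int:
        return int(self.values.size)


@dataclass
class CoreSet:
    """Per-replicate core selections, keyed by replicate id."""

    by_replicate: dict[str, ReplicateCore]
    method: str

    def __getitem__(self, replicate: str) -> ReplicateCore:
        return self.by_replicate[replicate]

    @property
    def replicates(self) -> list[str]:
        return list(self.by_replicate)


def _resolve_alpha(
    alpha, replicate: str, cell_line: str, default: float
) -> float:
    """Per-replicate overrides: mapping keyed by replicate, then cell line."""
    if isinstance(alpha, Mapping):
        if replicate in alpha:
            return float(alpha[replicate])
        if cell_line in alpha:
            return float(alpha[cell_line])
        return float(default)
    return float(alpha)


def select_core_percentile(
    scores: LethalityScores,
    alpha_high: float | Mapping[str, float] = 0.95,
    alpha_low: float | Mapping[str, float] = 0.0,
) -> CoreSet:
    """Select core values between per-replicate empirical quantiles.

    One-sided by default: values at or below the ``alpha_high`` quantile of
    the replicate's library scores (``alpha_high=1`` keeps everything).  A
    nonzero ``alpha_low`` additionally trims the lower tail, for screens
    where increased proliferation is a real phenotype.  Quantiles use linear
    interpolation between order statistics (position ``(m-1)p + 1``); values
    tied with a boundary quantile are all included — the core is a multiset
    of values, not of features.  Both alphas accept a mapping keyed by
    replicate (or cell line) for per-condition choices.
    """
    cores: dict[str, ReplicateCore] = {}
    for rep in scores.replicates:
        line = scores.data.loc[scores.data["replicate"] == rep, "cell_line"].iloc[0]
        a_hi = _resolve_alpha(alpha_high, rep, line, 0.95)
        a_lo = _resolve_alpha(alpha_low, rep, line, 0.0)
        if not 0 < a_hi <= 1:
            raise ValueError(f"alpha_high must be in (0, 1], got {a_hi}")
        if not 0 <= a_lo < a_hi:
            raise ValueError("alpha_low must satisfy 0 <= alpha_low < alpha_high")
        x = scores.library_scores(rep)
        hi = float(np.quantile(x, a_hi))
        keep = x <= hi
        if a_lo > 0:
            lo = float(np.quantile(x, a_lo))
            keep &= x >= lo
        values = x[keep]
        if values.size == 0:
            raise EmptyCoreError(f"replicate {rep}: empty core set")
        cores[rep] = ReplicateCore(
            values=values,
            z_min=float(values.min()),
            z_max=float(values.max()),
            params={"alpha_high": a_hi, "alpha_low": a_lo},
        )
    return CoreSet(cores, method="percentile")


def select_core_distance(scores: LethalityScores, gamma: float = 1.0) -> CoreSet:
    """Select core values by proximity to the negative-control anchor.

    A value v enters the core when ``|v - m_N| <= gamma * |v - m_P|`` with
    m_N, m_P the replicate's scored control medians (0 and 1 when scored in
    that scope); ``gamma = 1`` keeps scores closer to the negative than to
    the positive controls.  Ties are included.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    cores: dict[str, ReplicateCore] = {}
    for rep in scores.replicates:
        m_n, m_p = scores.control_medians(rep)
        x = scores.library_scores(rep)
        keep = np.abs(x - m_n) <= gamma * np.abs(x - m_p)
        values = x[keep]
        if values.size == 0:
            raise EmptyCoreError(f"replicate {rep}: empty core set")
        cores[rep] = ReplicateCore(
            values=values,
            z_min=float(values.min()),
            z_max=float(values.max()),
            params={"gamma": float(gamma), "m_neg": m_n, "m_pos": m_p},
        )
    return CoreSet(cores, method="distance")


def quantile_grid(core: ReplicateCore, n_quantiles: int = DEFAULT_N_QUANTILES) -> np.ndarray:
    """Empirical quantiles of the core at probabilities j/n, j = 1..n.

    Linear interpolation between order statistics; the last grid point is the
    core maximum.  The grid is nondecreasing by construction.
    """
    probs = np.arange(1, n_quantiles + 1) / n_quantiles
    return np.quantile(core.values, probs, method="linear")


def normalize_grids(grids: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Target grid: elementwise mean of the per-replicate quantile grids."""
    grids = np.asarray(grids, dtype=float)
    if grids.ndim != 2:
        raise ValueError("expected a list of equal-length 1-D grids")
    return grids.mean(axis=0)
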