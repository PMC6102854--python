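"""Per-feature hypothesis testing, FDR correction and concordance metrics.

Each library feature is tested for a group effect by ordinary least squares
of its (normalized) scores on a replicate-level design — an intercept, a
two-level group factor, and optional covariates — followed by a two-sided
Student's t-test on the group coefficient and Benjamini-Hochberg correction
across features.  An optional pooled variance moderation shrinks each
feature's residual variance toward the across-feature mean, a lightweight
stand-in for empirical-Bayes moderation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .study import WELL_LIBRARY


def make_design(
    replicate_groups: dict[str, str] | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build a replicate-level design table.

    ``replicate_groups`` maps replicate id -> group label (exactly two
    levels).  Optional ``covariates`` (indexed by replicate) are appended as
    numeric columns.
    """
    design = pd.Series(replicate_groups, name="group").to_frame()
    if covariates is not None:
        design = design.join(covariates, how="left")
    levels = sorted(design["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    return design


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    levels = sorted(design["group"].unique())
    g = (design["group"] == levels[1]).to_numpy(dtype=float)
    cols = [np.ones(len(design)), g]
    names = ["intercept", f"group[{levels[1]}]"]
    for c in design.columns:
        if c == "group":
            continue
        cols.append(design[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _score_matrix(scores, score_col: str | None = None) -> pd.DataFrame:
    """Features x replicates matrix of library scores from long input."""
    if isinstance(scores, pd.DataFrame):
        df = scores
    else:  # LethalityScores or similar wrapper
        df = scores.data
    if score_col is None:
        for cand in ("rscreenorm_score", "normalized_score", "score", "readout"):
            if cand in df.columns:
                score_col = cand
                break
        else:
            raise ValueError("no score column found")
    lib = df[df["well_type"] == WELL_LIBRARY]
    mat = lib.pivot_table(
        index="feature_id", columns="replicate", values=score_col, sort=False
    )
    if mat.isna().any().any():
        raise ValueError("every library feature needs a score in every replicate")
    return mat


def per_feature_test(
    scores,
    design: pd.DataFrame,
    moderation: str = "none",
    d0: float = 4.0,
    score_col: str | None = None,
) -> pd.DataFrame:
    """OLS group-effect test per library feature.

    Parameters
    ----------
    scores
        Long DataFrame (or scores object) with ``feature_id``, ``well_type``,
        ``replicate`` and a score column, or the output of a normalizer.
    design
        Replicate-indexed table with a two-level ``group`` column and
        optional numeric covariates; see :func:`make_design`.
    moderation
        ``"none"`` for the plain residual variance, ``"pooled"`` to shrink it
        toward the across-feature mean with weight ``df / (df + d0)`` and
        test on ``df + d0`` degrees of freedom.

    Returns
    -------
    DataFrame indexed by feature with columns ``estimate``, ``se``, ``t``,
    ``df``, ``pvalue`` and ``degenerate`` (True where the residual variance
    is zero and no moderation rescues the test; ``pvalue`` is NaN there).
    """
    if moderation not in ("none", "pooled"):
        raise ValueError("moderation must be 'none' or 'pooled'")
    mat = _score_matrix(scores, score_col)
    missing = [r for r in mat.columns if r not in design.index]
    if missing:
        raise ValueError(f"replicates missing from design: {missing}")
    design = design.loc[list(mat.columns)]
    X, _names = _design_matrix(design)
    Y = mat.to_numpy(dtype=float).T  # replicates x features

    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("fewer replicates than design parameters + 1")
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y
    resid = Y - X @ B
    s2 = (resid**2).sum(axis=0) / df_resid

    if moderation == "pooled":
        s2_used = (df_resid * s2 + d0 * s2.mean()) / (df_resid + d0)
        df_used = df_resid + d0
    else:
        s2_used = s2
        df_used = df_resid

    est = B[1]
    degenerate = s2_used == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_used * XtX_inv[1, 1])
        t = est / se
    pvalue = 2 * stats.t.sf(np.abs(t), df_used)
    pvalue[degenerate] = np.nan

    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "t": t,
            "df": float(df_used),
            "pvalue": pvalue,
            "degenerate": degenerate,
        },
        index=mat.index,
    )


def bh_adjust(pvalues, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted, significant)``.  NaN p-values are excluded from the
    correction and come back as NaN / not significant.
    """
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adjusted = np.full_like(p, np.nan, dtype=float)
    flags = np.zeros_like(p, dtype=bool)
    if ok.any():
        rej, adj, _, _ = multipletests(p[ok], alpha=level, method="fdr_bh")
        adjusted[ok] = adj
        flags[ok] = adj <= level
    return adjusted, flags


def call_hits(
    scores,
    design: pd.DataFrame,
    level: float = 0.05,
    moderation: str = "none",
    d0: float = 4.0,
    score_col: str | None = None,
) -> pd.DataFrame:
    """Full hit table: per-feature test + BH adjustment + significance flag."""
    table = per_feature_test(scores, design, moderation=moderation, d0=d0,
                             score_col=score_col)
    adjusted, flags = bh_adjust(table["pvalue"].to_numpy(), level=level)
    table["padj"] = adjusted
    table["significant"] = flags
    return table


def false_discovery_proportion(flags, truth) -> float:
    """Share of discoveries that are false; 0 when nothing is discovered."""
    flags = np.asarray(flags, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if flags.shape != truth.shape:
        raise ValueError("flags and truth must have equal length")
    n_disc = int(flags.sum())
    if n_disc == 0:
        return 0.0
    return float((flags & ~truth).sum() / n_disc)


@dataclass
class ConcordanceSummary:
    """Cross-tabulation of significance calls between two hit tables.

    Table A plays the role of the primary analysis; confirmation fractions
    are computed relative to A's calls.  ``ns_overlap_union`` is the Jaccard
    overlap of the two not-significant sets; ``ns_overlap_total`` divides by
    the common feature count instead — both conventions are reported.
    """

    n_total: int
    n_sig_both: int
    n_sig_a_only: int
    n_sig_b_only: int
    n_ns_both: int

    @property
    def agreement(self) -> float:
        return (self.n_sig_both + self.n_ns_both) / self.n_total

    @property
    def discordance(self) -> float:
        return (self.n_sig_a_only + self.n_sig_b_only) / self.n_total

    @property
    def hit_confirmation(self) -> float:
        n_sig_a = self.n_sig_both + self.n_sig_a_only
        return self.n_sig_both / n_sig_a if n_sig_a else float("nan")

    @property
    def ns_confirmation(self) -> float:
        n_ns_a = self.n_ns_both + self.n_sig_b_only
        return self.n_ns_both / n_ns_a if n_ns_a else float("nan")

    @property
    def ns_overlap_union(self) -> float:
        union = self.n_total - self.n_sig_both
        return self.n_ns_both / union if union else float("nan")

    @property
    def ns_overlap_total(self) -> float:
        return self.n_ns_both / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_sig_both": self.n_sig_both,
            "n_sig_a_only": self.n_sig_a_only,
            "n_sig_b_only": self.n_sig_b_only,
            "n_ns_both": self.n_ns_both,
            "agreement": self.agreement,
            "discordance": self.discordance,
            "hit_confirmation": self.hit_confirmation,
            "ns_confirmation": self.ns_confirmation,
            "ns_overlap_union": self.ns_overlap_union,
            "ns_overlap_total": self.ns_overlap_total,
        }


def concordance(table_a: pd.DataFrame, table_b: pd.DataFrame) -> ConcordanceSummary:
    """Compare significance calls of two hit tables on their common features.

    Both tables need a boolean ``significant`` column indexed by feature.
    The intersection of feature sets is used; an empty intersection is an
    error.
    """
    common = table_a.index.intersection(table_b.index)
    if len(common) == 0:
        raise ValueError("hit tables share no features")
    a = table_a.loc[common, "significant"].to_numpy(dtype=bool)
    b = table_b.loc[common, "significant"].to_numpy(dtype=bool)
    return ConcordanceSummary(
        n_total=len(common),
        n_sig_both=int((a & b).sum()),
        n_sig_a_only=int((a & ~b).sum()),
        n_sig_b_only=int((~a & b).sum()),
        n_ns_both=int((~a & ~b).sum()),
    )
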