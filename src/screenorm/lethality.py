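"""Control-anchored lethality scores.

For each observation the lethality score expresses its readout relative to
the assay controls of its scoring scope (replicate, or plate within
replicate)::

    score = (readout - median(negative controls))
            / (median(positive controls) - median(negative controls))

so that the negative-control median of the scope maps exactly to 0 (normal
viability) and the positive-control median exactly to 1 (lethal).  Scoring
per plate uses plate-local control medians and thereby cancels additive
plate effects.  The formula is orientation-free: flipping the readout sign
flips both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import WELL_NEG, WELL_POS, ScreenStudy

DENOMINATOR_TOL = 1e-8


class DegenerateControlsError(ValueError):
    """Controls of a scope do not span a usable functional range."""


@dataclass
class LethalityScores:
    """Per-observation lethality scores with annotations carried through.

    ``data`` has the study columns plus a ``score`` column; library and
    control rows are both scored (controls are kept so that downstream steps
    can locate the anchors on the score scale).
    """

    data: pd.DataFrame
    scope: str = "replicate"

    @property
    def replicates(self) -> list[str]:
        return list(dict.fromkeys(self.data["replicate"]))

    def library_scores(self, replicate: str) -> np.ndarray:
        df = self.data
        sel = (df["replicate"] == replicate) & (df["well_type"] == "lib")
        return df.loc[sel, "score"].to_numpy(dtype=float)

    def control_medians(self, replicate: str) -> tuple[float, float]:
        """(negative, positive) control score medians of a replicate."""
        df = self.data[self.data["replicate"] == replicate]
        m_n = float(df.loc[df["well_type"] == WELL_NEG, "score"].median())
        m_p = float(df.loc[df["well_type"] == WELL_POS, "score"].median())
        return m_n, m_p


def _score_block(sub: pd.DataFrame, scope_name: str, tol: float) -> pd.Series:
    neg = sub.loc[sub["well_type"] == WELL_NEG, "readout"]
    pos = sub.loc[sub["well_type"] == WELL_POS, "readout"]
    if neg.empty or pos.empty:
        raise DegenerateControlsError(
            f"scope {scope_name}: missing "
            f"{'negative' if neg.empty else 'positive'} controls"
        )
    m_n = float(neg.median())
    m_p = float(pos.median())
    denom = m_p - m_n
    if abs(denom) <= tol:
        raise DegenerateControlsError(
            f"scope {scope_name}: control medians too close "
            f"(|{m_p:g} - {m_n:g}| <= {tol:g})"
        )
    return (sub["readout"] - m_n) / denom


def compute_lethality_scores(
    study: ScreenStudy,
    scope: str = "replicate",
    tol: float = DENOMINATOR_TOL,
) -> LethalityScores:
    """Standardize readouts against control medians per replicate or plate.

    With ``scope="plate"`` every plate of every replicate must carry both
    control types; plate-local medians then absorb additive plate effects.
    """
    if scope not in ("replicate", "plate"):
        raise ValueError("scope must be 'replicate' or 'plate'")
    df = study.data
    if scope == "plate" and not study.has_plates:
        raise ValueError("scope='plate' requires plate annotations")

    keys = ["replicate"] if scope == "replicate" else ["replicate", "plate"]
    score = pd.Series(np.nan, index=df.index, dtype=float)
    for key, sub in df.groupby(keys, sort=False):
        name = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        score.loc[sub.index] = _score_block(sub, name, tol)

    out = df.copy()
    out["score"] = score
    return LethalityScores(out, scope=scope)


def scores_from_values(study: ScreenStudy) -> LethalityScores:
    """Wrap readouts that already live on the lethality-score scale.

    Used for data simulated (or precomputed) directly as lethality scores;
    no control standardization is applied.
    """
    out = study.data.copy()
    out["score"] = out["readout"].astype(float)
    return LethalityScores(out, scope="precomputed")
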