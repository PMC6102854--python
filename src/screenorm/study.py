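"""Data model for arrayed and pooled genetic-screen measurements.

A :class:`ScreenStudy` holds long-format well/guide measurements: one row per
(feature, replicate) observation, annotated with well type (library feature,
negative control anchoring normal viability, positive control anchoring a
lethal phenotype), cell line, replicate and optionally plate.  All downstream
normalization is keyed on the replicate identifier, which must be globally
unique (a replicate belongs to exactly one cell line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WELL_LIBRARY = "lib"
WELL_NEG = "neg"
WELL_POS = "pos"
WELL_TYPES = (WELL_LIBRARY, WELL_NEG, WELL_POS)

#: canonical column order of the long format
COLUMNS = ["feature_id", "well_type", "cell_line", "replicate", "plate", "readout"]


class ScreenValidationError(ValueError):
    """Raised when a study violates a structural invariant."""


def _as_object_na(series: pd.Series) -> pd.Series:
    return series.astype(object).where(pd.notna(series), None)


@dataclass
class ScreenStudy:
    """Validated long-format screen measurements.

    Parameters
    ----------
    data
        DataFrame with at least the columns in :data:`COLUMNS`.  ``plate`` may
        be entirely missing (``None``/NaN) for pooled screens.  Extra columns
        are carried through untouched.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ScreenValidationError(f"missing required columns: {missing}")
        df = self.data.copy()
        df["readout"] = pd.to_numeric(df["readout"], errors="raise")
        df["plate"] = _as_object_na(df["plate"])
        self.data = df.reset_index(drop=True)
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        df = self.data
        bad_types = set(df["well_type"].unique()) - set(WELL_TYPES)
        if bad_types:
            raise ScreenValidationError(
                f"unknown well types {sorted(bad_types)}; expected one of {WELL_TYPES}"
            )
        if not np.isfinite(df["readout"].to_numpy(dtype=float)).all():
            raise ScreenValidationError("non-finite readouts present")

        # a replicate id belongs to exactly one cell line
        lines_per_rep = df.groupby("replicate")["cell_line"].nunique()
        clashing = lines_per_rep[lines_per_rep > 1].index.tolist()
        if clashing:
            raise ScreenValidationError(
                f"replicates assigned to more than one cell line: {clashing}"
            )

        # every replicate needs both control types
        counts = (
            df.groupby(["replicate", "well_type"]).size().unstack(fill_value=0)
        )
        for ctrl in (WELL_NEG, WELL_POS):
            have = counts[ctrl] if ctrl in counts else pd.Series(0, index=counts.index)
            lacking = have[have == 0].index.tolist()
            if lacking:
                raise ScreenValidationError(
                    f"replicates without any '{ctrl}' controls: {lacking}"
                )

        # plate annotation is all-or-none within a replicate
        has_plate = df["plate"].notna()
        frac = has_plate.groupby(df["replicate"]).mean()
        partial = frac[(frac > 0) & (frac < 1)].index.tolist()
        if partial:
            raise ScreenValidationError(
                f"replicates with plate ids on only some rows: {partial}"
            )

    # -- accessors ----------------------------------------------------------
    @property
    def replicates(self) -> list[str]:
        """Replicate ids in order of first appearance."""
        return list(dict.fromkeys(self.data["replicate"]))

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.data["cell_line"]))

    @property
    def has_plates(self) -> bool:
        return bool(self.data["plate"].notna().any())

    def library(self) -> pd.DataFrame:
        return self.data[self.data["well_type"] == WELL_LIBRARY]

    def controls(self, kind: str) -> pd.DataFrame:
        return self.data[self.data["well_type"] == kind]

    def cell_line_of(self, replicate: str) -> str:
        sub = self.data.loc[self.data["replicate"] == replicate, "cell_line"]
        return sub.iloc[0]

    def with_readout(self, values: np.ndarray | pd.Series) -> "ScreenStudy":
        """Return a copy with ``readout`` replaced elementwise."""
        df = self.data.copy()
        df["readout"] = np.asarray(values, dtype=float)
        return ScreenStudy(df)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readout transforms
# ---------------------------------------------------------------------------

TRANSFORM_KINDS = ("identity", "log2_pseudocount", "asinh", "negate")


@dataclass(frozen=True)
class TransformSpec:
    """Elementwise readout transform applied before scoring.

    ``log2_pseudocount`` computes ``log2(x + pseudocount)`` and is the usual
    choice for intensity readouts; ``asinh`` suits count readouts containing
    zeros; ``negate`` flips orientation (e.g. so that lower = more viable).
    """

    kind: str = "identity"
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")


def transform_readout(study: ScreenStudy, spec: TransformSpec) -> ScreenStudy:
    """Apply an elementwise transform to the readout column.

    Annotations are untouched.  ``log2_pseudocount`` requires every
    ``readout + pseudocount`` to be strictly positive.
    """
    x = study.data["readout"].to_numpy(dtype=float)
    if spec.kind == "identity":
        return study
    if spec.kind == "negate":
        return study.with_readout(-x)
    if spec.kind == "asinh":
        return study.with_readout(np.arcsinh(x))
    # log2 with pseudocount
    shifted = x + spec.pseudocount
    if np.any(shifted <= 0):
        bad = int(np.sum(shifted <= 0))
        raise ValueError(
            f"log2 transform undefined for {bad} nonpositive readout(s); "
            "increase the pseudocount"
        )
    return study.with_readout(np.log2(shifted))


# ---------------------------------------------------------------------------
# control design checks
# ---------------------------------------------------------------------------

# Practical control-count guidance: pooled replicates want ~20 of each control
# type; arrayed plates want 4 of each, with an absolute minimum of 2.
POOLED_MIN_CONTROLS = 20
ARRAYED_WARN_CONTROLS = 4
ARRAYED_MIN_CONTROLS = 2


@dataclass
class ControlReport:
    """Structured result of :func:`validate_controls`; report-only."""

    design: str
    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def add(self, level: str, scope: str, message: str) -> None:
        self.entries.append((level, scope, message))

    @property
    def errors(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "ERROR"]

    @property
    def warnings(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "WARNING"]

    @property
    def flags(self) -> list[tuple[str, str, str]]:
        return [e for e in self.entries if e[0] == "FLAG"]

    @property
    def ok(self) -> bool:
        return not self.entries


def validate_controls(study: ScreenStudy, design: str = "arrayed") -> ControlReport:
    """Check control counts against practical design guidance.

    Pure: never mutates the study.  Pooled replicates with fewer than 20 of
    either control type get a WARNING; arrayed plates with fewer than 4 a
    WARNING and fewer than 2 an ERROR flag.  Positive-control sets with zero
    variability (all readouts identical, e.g. all-zero counts) are flagged.
    """
    if design not in ("arrayed", "pooled"):
        raise ValueError("design must be 'arrayed' or 'pooled'")
    report = ControlReport(design=design)
    df = study.data

    if design == "pooled":
        for rep, sub in df.groupby("replicate", sort=False):
            for ctrl in (WELL_NEG, WELL_POS):
                n = int((sub["well_type"] == ctrl).sum())
                if n < POOLED_MIN_CONTROLS:
                    report.add(
                        "WARNING",
                        str(rep),
                        f"replicate has {n} '{ctrl}' controls (< {POOLED_MIN_CONTROLS})",
                    )
    else:
        if study.has_plates:
            groups = df.groupby(["replicate", "plate"], sort=False)
        else:
            groups = df.groupby(["replicate"], sort=False)
        for key, sub in groups:
            scope = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
            for ctrl in (WELL_NEG, WELL_POS):
                n = int((sub["well_type"] == ctrl).sum())
                if n < ARRAYED_MIN_CONTROLS:
                    report.add(
                        "ERROR", scope,
                        f"only {n} '{ctrl}' controls (< absolute minimum "
                        f"{ARRAYED_MIN_CONTROLS})",
                    )
                elif n < ARRAYED_WARN_CONTROLS:
                    report.add(
                        "WARNING", scope,
                        f"{n} '{ctrl}' controls (< recommended {ARRAYED_WARN_CONTROLS})",
                    )

    for rep, sub in df.groupby("replicate", sort=False):
        pos = sub.loc[sub["well_type"] == WELL_POS, "readout"]
        if len(pos) > 0 and float(pos.max() - pos.min()) == 0.0:
            report.add(
                "FLAG", str(rep),
                "positive controls have zero variability "
                f"(all readouts = {pos.iloc[0]:g})",
            )
    return report


# ---------------------------------------------------------------------------
# positive-control reliability filter
# ---------------------------------------------------------------------------

def filter_reference_controls(
    study: ScreenStudy,
    min_lethal_replicates: int,
    lethal_rule: float = 0.10,
    lethal_direction: str = "low",
) -> ScreenStudy:
    """Demote unreliable positive controls to library features.

    Suggested positive controls do not always yield a lethal phenotype; only
    those that do so consistently should anchor the normalization.  A control
    counts as "lethal in replicate k" when its readout falls beyond the
    ``lethal_rule`` quantile of that replicate's library readouts, on the
    lethal side given by ``lethal_direction`` (``"low"``: lower readout = more
    lethal, the usual orientation for counts and viability; ``"high"`` for
    negated/inverted readouts).  Controls lethal in fewer than
    ``min_lethal_replicates`` replicates are relabeled as library features.
    """
    if not 0 < lethal_rule < 1:
        raise ValueError("lethal_rule must be in (0, 1)")
    if lethal_direction not in ("low", "high"):
        raise ValueError("lethal_direction must be 'low' or 'high'")

    df = study.data
    q = lethal_rule if lethal_direction == "low" else 1 - lethal_rule
    thresholds = (
        df[df["well_type"] == WELL_LIBRARY]
        .groupby("replicate")["readout"]
        .quantile(q)
    )

    pos = df[df["well_type"] == WELL_POS]
    lethal_counts: dict[str, int] = {}
    for (feat, rep), sub in pos.groupby(["feature_id", "replicate"], sort=False):
        thr = thresholds.get(rep)
        if thr is None:
            continue
        val = float(sub["readout"].median())
        hit = val <= thr if lethal_direction == "low" else val >= thr
        if hit:
            lethal_counts[feat] = lethal_counts.get(feat, 0) + 1

    demote = [
        feat
        for feat in pos["feature_id"].unique()
        if lethal_counts.get(feat, 0) < min_lethal_replicates
    ]
    if len(demote) == pos["feature_id"].nunique():
        raise ScreenValidationError(
            "all candidate positive controls failed the lethality rule; "
            "no positive controls remain"
        )
    if demote:
        logger.info("relabeling %d unreliable positive controls as library", len(demote))
    out = df.copy()
    mask = (out["well_type"] == WELL_POS) & out["feature_id"].isin(demote)
    out.loc[mask, "well_type"] = WELL_LIBRARY
    return ScreenStudy(out)
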