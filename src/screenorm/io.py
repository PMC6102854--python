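"""Readers and writers for arrayed long-format tables and pooled count matrices."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .study import (
    COLUMNS,
    WELL_LIBRARY,
    WELL_NEG,
    WELL_POS,
    ScreenStudy,
    ScreenValidationError,
)

logger = logging.getLogger(__name__)

# accepted spellings for the three well types in arrayed tables
DEFAULT_WELL_ALIASES: dict[str, str] = {
    "lib": WELL_LIBRARY,
    "library": WELL_LIBRARY,
    "sample": WELL_LIBRARY,
    "neg": WELL_NEG,
    "negative": WELL_NEG,
    "neg_control": WELL_NEG,
    "negctrl": WELL_NEG,
    "pos": WELL_POS,
    "positive": WELL_POS,
    "pos_control": WELL_POS,
    "posctrl": WELL_POS,
}


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_arrayed_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    well_type_aliases: Mapping[str, str] | None = None,
) -> ScreenStudy:
    """Read a long-format arrayed-screen table (TSV, or CSV by extension).

    ``column_map`` maps canonical names (``feature_id``, ``well_type``,
    ``cell_line``, ``replicate``, ``plate``, ``readout``) onto the file's
    column names.  Rows with an empty readout are dropped with a logged
    count; a non-numeric readout raises naming the row.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in COLUMNS if column_map.get(c, c) in df.columns}
    df = df.rename(columns=rename)

    required = [c for c in COLUMNS if c != "plate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"{path}: missing required column(s) {missing}")
    if "plate" not in df.columns:
        df["plate"] = None

    aliases = {k.lower(): v for k, v in (well_type_aliases or DEFAULT_WELL_ALIASES).items()}
    raw_types = df["well_type"].astype(str).str.strip().str.lower()
    unknown = sorted(set(raw_types) - set(aliases))
    if unknown:
        raise ScreenValidationError(
            f"{path}: unmappable well_type value(s) {unknown}"
        )
    df["well_type"] = raw_types.map(aliases)

    n_missing = int(df["readout"].isna().sum())
    if n_missing:
        logger.warning("%s: dropping %d rows with missing readout", path, n_missing)
        df = df[df["readout"].notna()]
    readout = pd.to_numeric(df["readout"], errors="coerce")
    bad = readout.isna() & df["readout"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ScreenValidationError(
            f"{path}: non-numeric readout {df['readout'].iloc[row]!r} at data row "
            f"{df.index[row]}"
        )
    df["readout"] = readout
    extra = [c for c in df.columns if c not in COLUMNS]
    return ScreenStudy(df[COLUMNS + extra])


# ---------------------------------------------------------------------------
# pooled count matrices
# ---------------------------------------------------------------------------

def read_control_list(path: str | Path) -> dict[str, str]:
    """Read a two-column guide-control list: ``guide_id<TAB>neg|pos``."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2 or parts[1] not in (WELL_NEG, WELL_POS):
            raise ScreenValidationError(
                f"{path}: expected 'guide_id neg|pos', got {line!r}"
            )
        out[parts[0]] = parts[1]
    return out


def read_sample_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read ``sample<TAB>cell_line<TAB>replicate`` assignments."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"sample", "cell_line", "replicate"}
    if not need.issubset(df.columns):
        raise ScreenValidationError(f"{path}: needs columns {sorted(need)}")
    return {r["sample"]: (r["cell_line"], r["replicate"]) for _, r in df.iterrows()}


def _split_sample_name(sample: str) -> tuple[str, str]:
    # "cellline_rep" convention: cell line is everything before the last "_"
    if "_" not in sample:
        raise ScreenValidationError(
            f"sample {sample!r} not in the mapping and not of the form "
            "'cellline_replicate'"
        )
    line, _, _rep = sample.rpartition("_")
    return line, sample


def read_count_matrix(
    path: str | Path,
    controls: Mapping[str, str] | str | Path,
    sample_map: Mapping[str, tuple[str, str]] | str | Path | None = None,
) -> ScreenStudy:
    """Read a pooled-screen count table: ``sgRNA, gene, <sample...>`` (TSV).

    ``controls`` marks guide ids as ``neg``/``pos`` assay controls (a mapping,
    or the path of a two-column list); unlisted guides are library features.
    ``sample_map`` assigns each sample column to (cell line, replicate);
    without one, column names must follow the ``cellline_replicate``
    convention.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if df.shape[1] < 3:
        raise ScreenValidationError(
            f"{path}: need guide, gene and at least one sample column"
        )
    guide_col, gene_col = df.columns[:2]
    samples = list(df.columns[2:])

    dup = df[guide_col][df[guide_col].duplicated()].unique().tolist()
    if dup:
        raise ScreenValidationError(f"{path}: duplicate guide ids {dup}")

    if isinstance(controls, (str, Path)):
        controls = read_control_list(controls)
    controls = dict(controls)
    if not controls:
        raise ScreenValidationError(f"{path}: no control guides provided")
    unknown_ctrl = sorted(set(controls) - set(df[guide_col]))
    if unknown_ctrl:
        raise ScreenValidationError(
            f"{path}: control guides not present in table: {unknown_ctrl}"
        )

    if isinstance(sample_map, (str, Path)):
        sample_map = read_sample_map(sample_map)

    counts = df[samples].to_numpy()
    counts_num = df[samples].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(counts_num).any():
        i, j = map(int, np.argwhere(np.isnan(counts_num))[0])
        raise ScreenValidationError(
            f"{path}: non-numeric count {counts[i, j]!r} for guide "
            f"{df[guide_col].iloc[i]!r}, sample {samples[j]!r}"
        )
    if (counts_num < 0).any():
        i, j = map(int, np.argwhere(counts_num < 0)[0])
        raise ScreenValidationError(
            f"{path}: negative count {counts_num[i, j]:g} for guide "
            f"{df[guide_col].iloc[i]!r}, sample {samples[j]!r}"
        )

    well_type = df[guide_col].map(lambda g: controls.get(g, WELL_LIBRARY))
    frames = []
    for j, sample in enumerate(samples):
        if sample_map is not None:
            if sample not in sample_map:
                raise ScreenValidationError(
                    f"{path}: sample {sample!r} not in the sample map"
                )
            line, rep = sample_map[sample]
        else:
            line, rep = _split_sample_name(sample)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": df[guide_col],
                    "well_type": well_type,
                    "cell_line": line,
                    "replicate": rep,
                    "plate": None,
                    "readout": counts_num[:, j],
                    "gene": df[gene_col],
                }
            )
        )
    return ScreenStudy(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    """Write a TSV with a header comment recording version and config hash."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# screenorm {__version__} config={config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)
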