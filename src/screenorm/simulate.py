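"""Synthetic multi-cell-line screen data and the FDR/power evaluation harness.

The generator emulates a study of 6 cell lines screened in triplicate,
simulated directly on the lethality-score scale: per replicate, negative
controls ~ Normal(0, 0.1), positive controls ~ Normal(1, 0.1), and library
features ~ Normal(mu_i, 0.2) with feature means mu_i ~ Beta(2, 6) (expected
value 0.25 — most features yield little lethality).  A stretch/contraction
effect multiplies the *means* of library features and positive controls by a
per-cell-line factor (0.7 / 1 / 1.4, balanced across the two comparison
groups so it is orthogonal to the group effect); negative-control means stay
at 0.  In the "with effect" mode the first 20% of features get mean 0.5 in
cell lines 4-6 before stretching, defining the ground-truth hit mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .baselines import ClassicQuantileNormalizer, MedianCenter, RobustZScore
from .hits import bh_adjust, false_discovery_proportion, make_design
from .normalize import RScreenNorm
from .study import WELL_LIBRARY, WELL_NEG, WELL_POS, ScreenStudy

MODES = ("no_effect", "with_effect")
EXPERIMENT_METHODS = ("none", "rscreenorm", "classic_qn", "robust_z", "median_center")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the reference simulation design: 6 cell lines in
    triplicate, 1000 library features, 200 controls of each type, control sd
    0.1, feature sd 0.2, Beta(2, 6) feature means, stretch factors
    0.7/1/1.4 mirrored across the two groups, and a group effect (mean 0.5)
    on 20% of features in cell lines 4-6.
    """

    n_cell_lines: int = 6
    reps_per_line: int = 3
    n_features: int = 1000
    n_neg: int = 200
    n_pos: int = 200
    ctrl_sd: float = 0.1
    feature_sd: float = 0.2
    beta_shape: tuple[float, float] = (2.0, 6.0)
    stretch_factors: tuple[float, ...] = (0.7, 1.0, 1.4, 0.7, 1.0, 1.4)
    effect_fraction: float = 0.2
    effect_mean: float = 0.5
    effect_lines: tuple[int, ...] = (4, 5, 6)  # 1-based cell-line indices
    pos_bias: tuple[float, ...] = (0.0,) * 6
    mu_per_replicate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.effect_fraction <= 1:
            raise ValueError("effect_fraction must be in [0, 1]")
        if min(self.ctrl_sd, self.feature_sd) <= 0:
            raise ValueError("standard deviations must be > 0")
        if min(self.beta_shape) <= 0:
            raise ValueError("beta shape parameters must be > 0")
        for name in ("stretch_factors", "pos_bias"):
            if len(getattr(self, name)) != self.n_cell_lines:
                raise ValueError(f"{name} must have length n_cell_lines")
        if any(not 1 <= l <= self.n_cell_lines for l in self.effect_lines):
            raise ValueError("effect_lines must be 1-based cell-line indices")

    @property
    def n_replicates(self) -> int:
        return self.n_cell_lines * self.reps_per_line

    @property
    def n_effect_features(self) -> int:
        return round(self.effect_fraction * self.n_features)


@dataclass
class SimulatedStudy:
    """One simulated dataset plus its ground truth.

    ``lib`` / ``neg`` / ``pos`` hold the raw score matrices (replicates x
    features); ``truth`` marks the features carrying a group effect and
    ``mu`` the realized feature means before stretching.
    """

    config: SimulationConfig
    mode: str
    lib: np.ndarray
    neg: np.ndarray
    pos: np.ndarray
    mu: np.ndarray
    truth: np.ndarray
    replicate_ids: list[str]
    cell_line_ids: list[str]
    feature_ids: list[str] = field(repr=False, default_factory=list)
    _study_cache: ScreenStudy | None = field(default=None, repr=False, compare=False)

    def to_study(self) -> ScreenStudy:
        """Long-format view with score values in the readout column (cached)."""
        if self._study_cache is not None:
            return self._study_cache
        cfg = self.config
        neg_ids = [f"negctrl{i:03d}" for i in range(cfg.n_neg)]
        pos_ids = [f"posctrl{i:03d}" for i in range(cfg.n_pos)]
        frames = []
        for k, rep in enumerate(self.replicate_ids):
            frames.append(
                pd.DataFrame(
                    {
                        "feature_id": self.feature_ids + neg_ids + pos_ids,
                        "well_type": [WELL_LIBRARY] * cfg.n_features
                        + [WELL_NEG] * cfg.n_neg
                        + [WELL_POS] * cfg.n_pos,
                        "cell_line": self.cell_line_ids[k],
                        "replicate": rep,
                        "plate": None,
                        "readout": np.concatenate(
                            [self.lib[k], self.neg[k], self.pos[k]]
                        ),
                    }
                )
            )
        self._study_cache = ScreenStudy(pd.concat(frames, ignore_index=True))
        return self._study_cache

    def design(self) -> pd.DataFrame:
        """Two-group design: effect cell lines vs the rest."""
        cfg = self.config
        groups = {}
        for rep, line in zip(self.replicate_ids, self.cell_line_ids):
            idx = int(line.removeprefix("line"))
            groups[rep] = "effect" if idx in cfg.effect_lines else "reference"
        return make_design(groups)


def simulate_study(
    config: SimulationConfig,
    mode: str = "no_effect",
    seed: int | np.random.Generator | None = None,
) -> SimulatedStudy:
    """Draw one synthetic dataset under the configured study conditions.

    The stretch multiplies the sampling *means* of library features and
    positive controls by the cell line's factor before the normal draw;
    ``pos_bias`` is added to positive-control means afterwards.  Identical
    seed and config give bit-identical output.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cfg = config
    K = cfg.n_replicates
    line_of_rep = np.repeat(np.arange(cfg.n_cell_lines), cfg.reps_per_line)
    stretch = np.asarray(cfg.stretch_factors)[line_of_rep]
    bias = np.asarray(cfg.pos_bias)[line_of_rep]

    a, b = cfg.beta_shape
    if cfg.mu_per_replicate:
        mu = rng.beta(a, b, size=(K, cfg.n_features))
    else:
        mu = np.tile(rng.beta(a, b, size=cfg.n_features), (K, 1))

    truth = np.zeros(cfg.n_features, dtype=bool)
    means = mu.copy()
    if mode == "with_effect":
        truth[: cfg.n_effect_features] = True
        effect_lines0 = {l - 1 for l in cfg.effect_lines}
        for k in range(K):
            if line_of_rep[k] in effect_lines0:
                means[k, truth] = cfg.effect_mean
    means = means * stretch[:, None]

    lib = rng.normal(means, cfg.feature_sd)
    neg = rng.normal(0.0, cfg.ctrl_sd, size=(K, cfg.n_neg))
    pos = rng.normal(
        (1.0 * stretch + bias)[:, None], cfg.ctrl_sd, size=(K, cfg.n_pos)
    )

    cell_line_ids = [f"line{c + 1}" for c in line_of_rep]
    replicate_ids = [
        f"line{c + 1}_r{r + 1}"
        for c in range(cfg.n_cell_lines)
        for r in range(cfg.reps_per_line)
    ]
    feature_ids = [f"f{i:04d}" for i in range(cfg.n_features)]
    return SimulatedStudy(
        config=cfg,
        mode=mode,
        lib=lib,
        neg=neg,
        pos=pos,
        mu=mu,
        truth=truth,
        replicate_ids=replicate_ids,
        cell_line_ids=cell_line_ids,
        feature_ids=feature_ids,
    )


def _pivot_library(out: pd.DataFrame, sim: SimulatedStudy, value: str) -> np.ndarray:
    mat = out[out["well_type"] == WELL_LIBRARY].pivot_table(
        index="feature_id", columns="replicate", values=value, sort=False
    )
    return mat.loc[sim.feature_ids, sim.replicate_ids].to_numpy(dtype=float)


def _normalized_matrix(sim: SimulatedStudy, method: str) -> np.ndarray:
    """Features x replicates matrix of normalized library scores."""
    if method == "none":
        return sim.lib.T
    if method == "rscreenorm":
        out = RScreenNorm(readouts_are_scores=True).fit_transform(sim.to_study())
        return _pivot_library(out, sim, "rscreenorm_score")
    if method == "classic_qn":
        return ClassicQuantileNormalizer().fit_transform(sim.lib.T)
    if method == "robust_z":
        return _pivot_library(
            RobustZScore().fit_transform(sim.to_study()), sim, "normalized_score"
        )
    if method == "median_center":
        return _pivot_library(
            MedianCenter().fit_transform(sim.to_study()), sim, "normalized_score"
        )
    raise ValueError(f"unknown method {method!r}")


def _group_test_pvalues(mat: np.ndarray, group: np.ndarray,
                        moderation: str = "none", d0: float = 4.0) -> np.ndarray:
    """Vectorized group-coefficient t-test on a features x replicates matrix."""
    from scipy import stats

    X = np.column_stack([np.ones(len(group)), group.astype(float)])
    XtX_inv = np.linalg.inv(X.T @ X)
    Y = mat.T
    B = XtX_inv @ X.T @ Y
    df = len(group) - 2
    s2 = ((Y - X @ B) ** 2).sum(axis=0) / df
    if moderation == "pooled":
        s2 = (df * s2 + d0 * s2.mean()) / (df + d0)
        df = df + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[1] / np.sqrt(s2 * XtX_inv[1, 1])
    return 2 * stats.t.sf(np.abs(t), df)


def run_fdr_experiment(
    n_datasets: int,
    config: SimulationConfig | None = None,
    mode: str = "no_effect",
    methods: tuple[str, ...] = ("none", "rscreenorm"),
    level: float = 0.05,
    seed: int | None = None,
    moderation: str = "none",
) -> pd.DataFrame:
    """Simulate datasets, normalize, test for the group effect, score errors.

    Per dataset and method: normalize the library scores, run the
    per-feature group t-test (effect cell lines vs the rest), adjust with
    Benjamini-Hochberg at ``level``, and record the false-discovery
    proportion plus (in with-effect mode) the true-positive proportion.

    Returns the per-dataset long table; aggregate with
    :func:`summarize_experiment`.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    unknown = set(methods) - set(EXPERIMENT_METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    line_of_rep = np.repeat(np.arange(cfg.n_cell_lines), cfg.reps_per_line)
    group = np.isin(line_of_rep + 1, cfg.effect_lines)

    rows = []
    for d in range(n_datasets):
        sim = simulate_study(cfg, mode=mode, seed=rng)
        for method in methods:
            mat = _normalized_matrix(sim, method)
            p = _group_test_pvalues(mat, group, moderation=moderation)
            _, flags = bh_adjust(p, level=level)
            fdp = false_discovery_proportion(flags, sim.truth)
            tpp = (
                float(flags[sim.truth].mean()) if sim.truth.any() else float("nan")
            )
            rows.append(
                {
                    "dataset": d,
                    "method": method,
                    "n_discoveries": int(flags.sum()),
                    "fdp": fdp,
                    "tpp": tpp,
                }
            )
    return pd.DataFrame(rows)


def summarize_experiment(per_dataset: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and Monte-Carlo standard error of FDP/TPP per method."""
    out = []
    for method, sub in per_dataset.groupby("method", sort=False):
        n = len(sub)
        row = {"method": method, "n_datasets": n}
        for col in ("fdp", "tpp"):
            vals = sub[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                row[f"{col}_mean"] = row[f"{col}_sd"] = row[f"{col}_mcse"] = float("nan")
                continue
            row[f"{col}_mean"] = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            row[f"{col}_sd"] = sd
            row[f"{col}_mcse"] = sd / np.sqrt(vals.size) if vals.size > 1 else float("nan")
        out.append(row)
    return pd.DataFrame(out)


def simulate_arrayed_plates(
    n_plates: int,
    n_lib_per_plate: int = 10,
    n_ctrl_per_plate: int = 4,
    plate_offsets: tuple[float, ...] | None = None,
    neg_mean: float = 10.0,
    pos_mean: float = 2.0,
    lib_means: tuple[float, ...] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ScreenStudy:
    """Arrayed single-replicate fixture with additive per-plate offsets.

    Every well of plate p receives the offset ``plate_offsets[p]`` on top of
    its phenotype mean; the same library phenotype vector is laid out on
    every plate, so plate-scoped standardization should reproduce identical
    scores across plates.  ``noise_sd=0`` (default) gives a deterministic
    study for exact cancellation checks.
    """
    if n_ctrl_per_plate < 2:
        raise ValueError("each plate needs at least 2 controls of each type")
    offsets = plate_offsets if plate_offsets is not None else (0.0,) * n_plates
    if len(offsets) != n_plates:
        raise ValueError("plate_offsets must have length n_plates")
    if lib_means is None:
        lib_means = tuple(
            np.linspace(pos_mean, neg_mean, n_lib_per_plate).tolist()
        )
    if len(lib_means) != n_lib_per_plate:
        raise ValueError("lib_means must have length n_lib_per_plate")
    rng = np.random.default_rng(seed)

    frames = []
    for p in range(n_plates):
        delta = offsets[p]
        means = np.concatenate(
            [
                np.asarray(lib_means),
                np.full(n_ctrl_per_plate, neg_mean),
                np.full(n_ctrl_per_plate, pos_mean),
            ]
        )
        values = means + delta
        if noise_sd > 0:
            values = rng.normal(values, noise_sd)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": [f"p{p + 1}_f{i}" for i in range(n_lib_per_plate)]
                    + [f"p{p + 1}_neg{i}" for i in range(n_ctrl_per_plate)]
                    + [f"p{p + 1}_pos{i}" for i in range(n_ctrl_per_plate)],
                    "well_type": [WELL_LIBRARY] * n_lib_per_plate
                    + [WELL_NEG] * n_ctrl_per_plate
                    + [WELL_POS] * n_ctrl_per_plate,
                    "cell_line": "lineA",
                    "replicate": "lineA_r1",
                    "plate": f"plate{p + 1}",
                    "readout": values,
                }
            )
        )
    return ScreenStudy(pd.concat(frames, ignore_index=True))
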