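"""Data model, readers, readout transforms and control checks."""

import numpy as np
import pandas as pd
import pytest

from screenorm import (
    ScreenStudy,
    ScreenValidationError,
    TransformSpec,
    filter_reference_controls,
    read_arrayed_table,
    read_count_matrix,
    transform_readout,
    validate_controls,
)
from screenorm.io import write_table

from conftest import make_study


class TestScreenStudy:
    def test_replicate_needs_both_control_types(self):
        df = make_study(pos=())
        with pytest.raises(ScreenValidationError, match="pos"):
            ScreenStudy(df)

    def test_replicate_belongs_to_one_cell_line(self):
        df = pd.concat(
            [make_study(cell_line="A"), make_study(cell_line="B")],
            ignore_index=True,
        )
        with pytest.raises(ScreenValidationError, match="more than one cell line"):
            ScreenStudy(df)

    def test_partial_plate_annotation_rejected(self):
        df = make_study(plate="p1")
        df.loc[df.index[:3], "plate"] = None
        with pytest.raises(ScreenValidationError, match="plate"):
            ScreenStudy(df)

    def test_non_finite_readouts_rejected(self):
        df = make_study()
        df.loc[0, "readout"] = np.inf
        with pytest.raises(ScreenValidationError, match="finite"):
            ScreenStudy(df)


class TestArrayedIO:
    def test_round_trip_preserves_readouts(self, tmp_path):
        df = make_study()
        path = tmp_path / "study.tsv"
        write_table(df, path)
        study = read_arrayed_table(path)
        assert len(study) == 9
        assert study.replicates == ["r1"]
        np.testing.assert_array_equal(
            study.data["readout"].to_numpy(), df["readout"].to_numpy()
        )
        # write -> read again is bit-identical
        path2 = tmp_path / "again.tsv"
        write_table(study.data, path2)
        study2 = read_arrayed_table(path2)
        pd.testing.assert_frame_equal(study.data, study2.data)

    def test_well_type_aliases_mapped(self, tmp_path):
        df = make_study()
        df["well_type"] = df["well_type"].map(
            {"lib": "Library", "neg": "NEGATIVE", "pos": "pos_control"}
        )
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        study = read_arrayed_table(path)
        assert sorted(study.data["well_type"].unique()) == ["lib", "neg", "pos"]

    def test_unmappable_well_type_errors(self, tmp_path):
        df = make_study()
        df.loc[0, "well_type"] = "mystery"
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ScreenValidationError, match="mystery"):
            read_arrayed_table(path)

    def test_non_numeric_readout_names_row(self, tmp_path):
        df = make_study().astype({"readout": object})
        df.loc[2, "readout"] = "oops"
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ScreenValidationError, match="oops"):
            read_arrayed_table(path)

    def test_missing_column_errors(self, tmp_path):
        df = make_study().drop(columns=["cell_line"])
        path = tmp_path / "s.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ScreenValidationError, match="cell_line"):
            read_arrayed_table(path)


def _count_table(tmp_path, n_guides=10, samples=("A_1", "A_2"), bad_cell=None):
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"sgRNA": [f"g{i}" for i in range(n_guides)],
                       "gene": [f"G{i // 2}" for i in range(n_guides)]})
    for s in samples:
        df[s] = rng.integers(0, 500, size=n_guides)
    if bad_cell is not None:
        df.loc[bad_cell[0], samples[bad_cell[1]]] = bad_cell[2]
    path = tmp_path / "counts.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


class TestCountMatrix:
    def test_counts_with_controls(self, tmp_path):
        path = _count_table(tmp_path)
        controls = {"g0": "neg", "g1": "neg", "g2": "pos", "g3": "pos"}
        study = read_count_matrix(path, controls=controls)
        assert len(study) == 20
        assert len(study.replicates) == 2
        assert study.cell_lines == ["A"]
        assert (study.data["well_type"] == "pos").sum() == 4

    def test_no_controls_is_an_error(self, tmp_path):
        path = _count_table(tmp_path, n_guides=3)
        with pytest.raises(ScreenValidationError, match="no control"):
            read_count_matrix(path, controls={})

    def test_negative_count_names_cell(self, tmp_path):
        path = _count_table(tmp_path, bad_cell=(4, 1, -5))
        with pytest.raises(ScreenValidationError, match=r"g4.*A_2"):
            read_count_matrix(path, controls={"g0": "neg", "g1": "pos"})

    def test_duplicate_guides_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"sgRNA": ["g0", "g0"], "gene": ["G", "G"], "A_1": [1, 2]}
        )
        path = tmp_path / "c.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ScreenValidationError, match="duplicate"):
            read_count_matrix(path, controls={"g0": "neg"})

    def test_sample_map_file(self, tmp_path):
        path = _count_table(tmp_path, samples=("s1", "s2"))
        mp = tmp_path / "map.tsv"
        mp.write_text("sample\tcell_line\treplicate\ns1\tHT29\tHT29_a\ns2\tHT29\tHT29_b\n")
        study = read_count_matrix(
            path, controls={"g0": "neg", "g1": "pos"}, sample_map=mp
        )
        assert study.replicates == ["HT29_a", "HT29_b"]


class TestTransforms:
    def test_identity_is_a_fixed_point(self, simple_study):
        out = transform_readout(simple_study, TransformSpec("identity"))
        pd.testing.assert_frame_equal(out.data, simple_study.data)

    def test_log2_pseudocount_on_counts(self, tmp_path):
        df = make_study(lib=(7.0, 1.0), neg=(3.0,), pos=(0.0,))
        study = ScreenStudy(df)
        out = transform_readout(study, TransformSpec("log2_pseudocount", pseudocount=1))
        assert out.data["readout"].iloc[0] == pytest.approx(3.0)  # log2(8)

    def test_log2_rejects_nonpositive(self, simple_study):
        df = make_study(lib=(-2.0, 1.0))
        with pytest.raises(ValueError, match="pseudocount"):
            transform_readout(ScreenStudy(df), TransformSpec("log2_pseudocount"))

    def test_asinh_fixes_zero(self):
        study = ScreenStudy(make_study(lib=(0.0, 5.0)))
        out = transform_readout(study, TransformSpec("asinh"))
        assert out.data["readout"].iloc[0] == 0.0

    def test_negate_flips_sign(self, simple_study):
        out = transform_readout(simple_study, TransformSpec("negate"))
        np.testing.assert_allclose(
            out.data["readout"], -simple_study.data["readout"]
        )


class TestValidateControls:
    def test_four_of_each_per_plate_is_clean(self):
        study = ScreenStudy(
            make_study(neg=(0.0,) * 3 + (0.1,), pos=(1.0, 1.1, 0.9, 1.2), plate="p1")
        )
        report = validate_controls(study, design="arrayed")
        assert report.ok

    def test_single_positive_control_is_an_error(self):
        study = ScreenStudy(make_study(neg=(0.0, 0.1), pos=(1.0,), plate="p1"))
        report = validate_controls(study, design="arrayed")
        assert report.errors and "pos" in report.errors[0][2]

    def test_pooled_warns_below_twenty(self):
        study = ScreenStudy(make_study())
        report = validate_controls(study, design="pooled")
        assert len(report.warnings) == 2

    def test_zero_variability_positives_flagged(self):
        study = ScreenStudy(make_study(pos=(0.0, 0.0, 0.0)))
        report = validate_controls(study, design="pooled")
        assert report.flags

    def test_pure_never_mutates(self, simple_study):
        before = simple_study.data.copy()
        validate_controls(simple_study, design="pooled")
        pd.testing.assert_frame_equal(simple_study.data, before)


class TestReferenceControlFilter:
    @staticmethod
    def _multi_rep_study(pos_values_by_rep):
        """57-style reliability setup scaled down: lib spread 0..1 per replicate."""
        frames = []
        for rep, pos_vals in pos_values_by_rep.items():
            lib = tuple(np.linspace(0, 1, 21))
            frames.append(
                make_study(lib=lib, neg=(0.9, 0.95), pos=pos_vals, replicate=rep)
            )
        df = pd.concat(frames, ignore_index=True)
        return ScreenStudy(df)

    def test_consistently_lethal_control_is_kept(self):
        study = self._multi_rep_study({f"r{k}": (0.0, 0.5) for k in range(5)})
        # pos0 sits at the lethal extreme (0.0) everywhere, pos1 does not
        out = filter_reference_controls(study, min_lethal_replicates=5)
        kept = out.data[out.data["well_type"] == "pos"]["feature_id"].unique()
        assert list(kept) == ["pos0"]

    def test_never_lethal_control_is_demoted(self):
        study = self._multi_rep_study({f"r{k}": (0.0, 0.5) for k in range(5)})
        out = filter_reference_controls(study, min_lethal_replicates=1)
        demoted = out.data[
            (out.data["feature_id"] == "pos1") & (out.data["well_type"] == "lib")
        ]
        assert len(demoted) == 5

    def test_boundary_just_below_threshold_is_demoted(self):
        # lethal in 4 of 5 replicates, threshold 5 -> demoted
        reps = {f"r{k}": (0.0, 0.5) for k in range(4)}
        reps["r4"] = (0.5, 0.5)  # pos0 not lethal here
        study = self._multi_rep_study(reps)
        with pytest.raises(ScreenValidationError, match="no positive controls"):
            filter_reference_controls(study, min_lethal_replicates=5)
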