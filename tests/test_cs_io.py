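"""Parsing, pooling, subsampling and assignment intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shiftstate import cs_io
from shiftstate.cs_io import (
    NucleusKey,
    ToleranceConfig,
    intersect_assigned,
    pool_subunits,
    read_experimental_table,
    read_prediction_table,
    subsample,
    write_generic_long,
)

from conftest import make_pred_frame


class TestNucleusKey:
    def test_label(self):
        assert NucleusKey(96, "M", "CA").label == "M96CA"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(residue_number=0, residue_type="A", atom="CA"),
            dict(residue_number=5, residue_type="A", atom="HA"),
            dict(residue_number=5, residue_type="GLY", atom="CB"),
        ],
    )
    def test_invariants(self, kwargs):
        with pytest.raises(ValueError):
            NucleusKey(**kwargs)


class TestToleranceConfig:
    def test_per_isotope_lookup(self, tol):
        assert tol.for_atom("N") == 0.5
        for atom in ("C", "CA", "CB"):
            assert tol.for_atom(atom) == 0.2

    def test_rejects_bad_mass(self):
        with pytest.raises(ValueError):
            ToleranceConfig(ci_mass=1.0)


class TestReadPredictionTable:
    def test_generic_long_direct_parse(self, tmp_path):
        df = make_pred_frame(
            [("PO", "SPARTA+", "A", f, 96, "MET", "CA", 55.0 + f) for f in range(3)]
        )
        path = tmp_path / "pred.tsv"
        write_generic_long(df, path)
        out = read_prediction_table(path, "generic_long")
        assert len(out) == 3
        assert set(out["state"]) == {"PO"}
        assert set(out["residue_type"]) == {"M"}  # normalised to one-letter

    def test_sparta_unsupported_atom_dropped(self, tmp_path):
        path = tmp_path / "pred.tab"
        path.write_text(
            "RESID RESNAME ATOMNAME SHIFT FRAME\n"
            "96 MET CA 55.0 0\n"
            "96 MET HA 4.2 0\n"
        )
        out = read_prediction_table(path, "sparta_plus", state="PO", method="SPARTA+")
        assert len(out) == 1
        assert out["atom"].iloc[0] == "CA"

    def test_shiftx2_tetramer_count(self, tmp_path):
        # 4 chains x 10 frames x 4 atoms x 1 residue = 160 records
        lines = ["NUM,RES,ATOMNAME,SHIFT,CHAIN,FRAME"]
        for chain in "ABCD":
            for frame in range(10):
                for atom, shift in (("N", 119.0), ("C", 175.0), ("CA", 55.0), ("CB", 32.0)):
                    lines.append(f"96,M,{atom},{shift},{chain},{frame}")
        path = tmp_path / "pred.csv"
        path.write_text("\n".join(lines))
        out = read_prediction_table(path, "shiftx2", state="FO", method="SHIFTX2")
        assert len(out) == 160

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("a\n")
        with pytest.raises(ValueError, match="dialect"):
            read_prediction_table(path, "magic", state="PO", method="m")

    def test_unparseable_file_names_path(self, tmp_path):
        path = tmp_path / "broken.tsv"
        path.write_text("state\tmethod\n")  # missing required columns
        with pytest.raises(ValueError, match="broken.tsv"):
            read_prediction_table(path, "generic_long")

    def test_glycine_cb_dropped(self, tmp_path):
        df = make_pred_frame(
            [
                ("PO", "m", "A", 0, 56, "GLY", "CA", 45.0),
                ("PO", "m", "A", 0, 56, "GLY", "CB", 30.0),
            ]
        )
        path = tmp_path / "pred.tsv"
        write_generic_long(df, path)
        out = read_prediction_table(path, "generic_long")
        assert list(out["atom"]) == ["CA"]

    def test_round_trip_exact(self, tmp_path, rng):
        df = make_pred_frame(
            [
                ("PO", "SPARTA+", "A", f, 96, "M", "CA", float(v))
                for f, v in enumerate(rng.normal(55, 0.8, size=50))
            ]
        )
        path = tmp_path / "rt.tsv"
        write_generic_long(df, path)
        out = read_prediction_table(path, "generic_long")
        pd.testing.assert_frame_equal(out, df)


class TestPoolSubunits:
    def test_four_subunits_pool_to_quadruple_sample(self):
        df = make_pred_frame(
            [
                ("PO", "m", su, f, 96, "M", "CA", 55.0 + f * 0.01)
                for su in "ABCD"
                for f in range(250)
            ]
        )
        out = pool_subunits(df)
        assert len(out) == 1000
        assert set(out["subunit"]) == {"pooled"}
        # frames re-enumerated uniquely within the nucleus
        assert sorted(out["frame"]) == list(range(1000))

    def test_single_subunit_identity_up_to_label(self):
        df = make_pred_frame(
            [("PO", "m", "A", f, 96, "M", "CA", 55.0 + f) for f in range(5)]
        )
        out = pool_subunits(df)
        assert list(out["shift_ppm"]) == list(df["shift_ppm"])
        assert list(out["frame"]) == list(df["frame"])

    def test_empty_input(self):
        out = pool_subunits(make_pred_frame([]))
        assert out.empty

    def test_multiset_preserved_through_subsample_all(self, rng):
        df = make_pred_frame(
            [
                ("PO", "m", su, f, 96, "M", "CA", float(v))
                for su, vs in zip("ABCD", rng.normal(55, 1, (4, 30)))
                for f, v in enumerate(vs)
            ]
        )
        out = subsample(pool_subunits(df), n=10**6, seed=0)
        assert sorted(out["shift_ppm"]) == sorted(df["shift_ppm"])


class TestSubsample:
    def _big(self, n=5000):
        return make_pred_frame(
            [("PO", "m", "pooled", f, 96, "M", "CA", float(f)) for f in range(n)]
        )

    def test_exact_count(self):
        assert len(subsample(self._big(), 2000, seed=1)) == 2000

    def test_fewer_available_keeps_all(self):
        assert len(subsample(self._big(800), 2000, seed=1)) == 800

    def test_seed_determinism(self):
        a = subsample(self._big(), 2000, seed=7)
        b = subsample(self._big(), 2000, seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = subsample(self._big(), 2000, seed=8)
        assert not a["shift_ppm"].equals(c["shift_ppm"])

    def test_without_replacement(self):
        out = subsample(self._big(), 2000, seed=1)
        assert out["frame"].is_unique


def _exp_frame(rows):
    return pd.DataFrame(rows, columns=cs_io.EXP_COLUMNS)


class TestExperimentalTable:
    def test_two_conditions(self, tmp_path):
        path = tmp_path / "exp.tsv"
        _exp_frame(
            [(75, "T", "CA", "activated", 62.1), (75, "T", "CA", "deactivated", 62.4)]
        ).to_csv(path, sep="\t", index=False)
        out = read_experimental_table(path)
        assert len(out) == 2

    def test_duplicate_assignment_is_error(self, tmp_path):
        path = tmp_path / "exp.tsv"
        _exp_frame(
            [(75, "T", "CA", "activated", 62.1), (75, "T", "CA", "activated", 62.2)]
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="T75CA"):
            read_experimental_table(path)

    def test_missing_shift_skipped(self, tmp_path):
        path = tmp_path / "exp.tsv"
        _exp_frame(
            [(75, "T", "CA", "activated", 62.1), (76, "A", "CA", "deactivated", None)]
        ).to_csv(path, sep="\t", index=False)
        assert len(read_experimental_table(path)) == 1

    def test_single_condition_loads(self, tmp_path):
        path = tmp_path / "exp.tsv"
        _exp_frame([(75, "T", "CA", "activated", 62.1)]).to_csv(path, sep="\t", index=False)
        assert len(read_experimental_table(path)) == 1


class TestIntersectAssigned:
    def _pred(self):
        return make_pred_frame(
            [
                (state, "m", "A", 0, 75, "T", "CA", 62.0)
                for state in ("C", "PO", "FO")
            ]
            + [("C", "m", "A", 0, 76, "A", "CA", 52.0)]  # 76 missing PO/FO
        )

    def test_fully_covered_key_included(self):
        exp = _exp_frame(
            [(75, "T", "CA", "activated", 62.1), (75, "T", "CA", "deactivated", 62.4)]
        )
        keys = intersect_assigned(self._pred(), exp)
        assert keys == [NucleusKey(75, "T", "CA")]

    def test_missing_deactivated_excluded(self):
        exp = _exp_frame([(75, "T", "CA", "activated", 62.1)])
        assert intersect_assigned(self._pred(), exp) == []

    def test_empty_experiment(self):
        assert intersect_assigned(self._pred(), _exp_frame([])) == []

    def test_monotone_under_row_removal(self):
        exp = _exp_frame(
            [
                (75, "T", "CA", "activated", 62.1),
                (75, "T", "CA", "deactivated", 62.4),
                (76, "A", "CA", "activated", 52.0),
                (76, "A", "CA", "deactivated", 52.1),
            ]
        )
        pred = make_pred_frame(
            [
                (state, "m", "A", 0, rn, rt, "CA", 55.0)
                for state in ("C", "PO", "FO")
                for rn, rt in ((75, "T"), (76, "A"))
            ]
        )
        full = set(intersect_assigned(pred, exp))
        for i in range(len(exp)):
            reduced = set(intersect_assigned(pred, exp.drop(index=i)))
            assert reduced <= full


@settings(max_examples=25, deadline=None)
@given(
    n_sub=st.integers(1, 4),
    n_frames=st.integers(1, 30),
    n=st.integers(1, 50),
    seed=st.integers(0, 2**20),
)
def test_pool_then_subsample_counts(n_sub, n_frames, n, seed):
    """Pooling preserves counts; subsampling never exceeds min(n, available)."""
    df = make_pred_frame(
        [
            ("PO", "m", "ABCD"[s], f, 96, "M", "CA", float(s * 1000 + f))
            for s in range(n_sub)
            for f in range(n_frames)
        ]
    )
    pooled = pool_subunits(df)
    assert len(pooled) == n_sub * n_frames
    out = subsample(pooled, n, seed)
    assert len(out) == min(n, n_sub * n_frames)
    assert set(out["shift_ppm"]) <= set(df["shift_ppm"])
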