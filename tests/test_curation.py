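import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoprof.curation import (
    ActivityRecord,
    MeasurementType,
    Rejection,
    TableFormatError,
    deduplicate_pairs,
    parse_activity_table,
    read_table,
    strict_split,
    to_bioactivity,
    write_table,
)


class TestToBioactivity:
    @pytest.mark.parametrize(
        "value,unit,expected",
        [
            (1, "uM", 3.0),
            (1, "nM", 0.0),
            (50, "nM", math.log10(50)),
            (1, "µM", 3.0),
            (2, "mM", math.log10(2e6)),
            (1, "M", 9.0),
            (1, "UM", 3.0),  # case-insensitive
        ],
    )
    def test_conversion(self, value, unit, expected):
        assert to_bioactivity(value, unit) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError):
            to_bioactivity(0, "nM")
        with pytest.raises(ValueError):
            to_bioactivity(-1, "uM")

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            to_bioactivity(1, "pM")


class TestActivityRecord:
    def test_bioactivity_must_match_value(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ActivityRecord("K", "CCO", MeasurementType.IC50, 1000.0, 2.5)

    def test_from_bioactivity_round_trip(self):
        rec = ActivityRecord.from_bioactivity("K", "CCO", 3.0)
        assert rec.value_nM == pytest.approx(1000.0)


TABLE = """kinase_id,smiles,measurement_type,value,unit
ABL1,CCO,IC50,1,uM
ABL1,CCO,Kd,5,nM
,CCO,IC50,1,nM
ABL1,,IC50,1,nM
ABL1,CCO,Ki,,nM
ABL1,OCC,ic50,50,nM
ABL1,CCO,IC50,1,furlongs
ABL1,C(,IC50,1,nM
ABL1,CCO,IC50,-3,nM
"""


class TestParseActivityTable:
    def test_accept_reject_accounting(self):
        records, rejections = parse_activity_table(io.StringIO(TABLE), source="demo")
        assert len(records) + len(rejections) == 9
        assert len(records) == 2
        reasons = [r.reason for r in rejections]
        assert reasons.count("measurement type") == 1
        assert "missing kinase" in reasons
        assert "missing smiles" in reasons
        assert "missing bioactivity" in reasons
        assert "unit" in reasons
        assert "invalid smiles" in reasons
        assert "nonpositive value" in reasons

    def test_micromolar_anchor(self):
        records, _ = parse_activity_table(io.StringIO(TABLE))
        rec = records[0]
        assert rec.value_nM == pytest.approx(1000.0)
        assert rec.bioactivity == pytest.approx(3.0)

    def test_smiles_canonicalized(self):
        records, _ = parse_activity_table(io.StringIO(TABLE))
        # OCC and CCO canonicalize identically
        assert records[0].compound_smiles == records[1].compound_smiles

    def test_bad_header_is_format_error(self):
        with pytest.raises(TableFormatError):
            parse_activity_table(io.StringIO("a,b\n1,2\n"))

    def test_column_map_remaps_roles(self):
        text = "target\tstructure\tkind\tval\tu\nABL1\tCCO\tKi\t10\tnM\n"
        records, rejections = parse_activity_table(
            io.StringIO(text),
            column_map={"kinase": "target", "smiles": "structure", "type": "kind",
                        "value": "val", "unit": "u"},
        )
        assert not rejections
        assert records[0].measurement_type is MeasurementType.KI
        assert records[0].bioactivity == pytest.approx(1.0)


class TestDeduplicate:
    def test_mean_on_log_scale(self):
        recs = [
            ActivityRecord.from_bioactivity("A", "CCO", 2.0),
            ActivityRecord.from_bioactivity("A", "CCO", 4.0),
        ]
        out = deduplicate_pairs(recs)
        assert len(out) == 1
        assert out[0].bioactivity == pytest.approx(3.0)
        assert out[0].n_merged == 2

    def test_single_record_unchanged(self):
        recs = [ActivityRecord.from_bioactivity("A", "CCO", 1.5)]
        assert deduplicate_pairs(recs) == recs

    def test_distinct_kinases_kept(self):
        recs = [
            ActivityRecord.from_bioactivity("A", "CCO", 1.0),
            ActivityRecord.from_bioactivity("B", "CCO", 5.0),
        ]
        assert len(deduplicate_pairs(recs)) == 2

    def test_idempotent(self):
        recs = [
            ActivityRecord.from_bioactivity("A", "CCO", 2.0),
            ActivityRecord.from_bioactivity("A", "CCO", 4.0),
            ActivityRecord.from_bioactivity("B", "CC", 1.0),
        ]
        once = deduplicate_pairs(recs)
        assert deduplicate_pairs(once) == once

    @settings(deadline=None, max_examples=30)
    @given(st.permutations(list(range(6))))
    def test_order_invariance(self, order):
        base = [
            ActivityRecord.from_bioactivity("A", "CCO", b)
            for b in (1.0, 2.0, 3.0)
        ] + [
            ActivityRecord.from_bioactivity("B", "CC", b) for b in (0.5, 1.5, 4.5)
        ]
        shuffled = [base[i] for i in order]
        assert deduplicate_pairs(shuffled) == deduplicate_pairs(base)


class TestStrictSplit:
    @staticmethod
    def _records():
        return [
            ActivityRecord.from_bioactivity(f"K{i % 5}", f"{'C' * (1 + i % 4)}", float(i))
            for i in range(10)
        ]

    def test_kinase_holdout_partitions(self):
        recs = self._records()
        split = strict_split(recs, holdout_kinases={"K0"})
        assert len(split.train) + len(split.test) == len(recs)
        assert all(r.kinase_id == "K0" for r in split.test)
        assert all(r.kinase_id != "K0" for r in split.train)

    def test_exhaustive_scan_on_synthetic_data(self, small_sim):
        _, _, _, data = small_sim
        kin_ids = sorted({r.kinase_id for r in data.records})[:3]
        split = strict_split(data.records, holdout_kinases=set(kin_ids))
        assert {r.kinase_id for r in split.train} & set(kin_ids) == set()
        assert {r.kinase_id for r in split.test} == set(kin_ids)
        split_c = strict_split(data.records, holdout_compounds={data.records[0].compound_smiles})
        shared = {r.compound_smiles for r in split_c.train} & {
            r.compound_smiles for r in split_c.test
        }
        assert shared == set()

    def test_holdout_of_everything_raises(self):
        recs = self._records()
        with pytest.raises(ValueError, match="empty training"):
            strict_split(recs, holdout_kinases={r.kinase_id for r in recs})

    def test_absent_holdout_warns(self):
        with pytest.warns(UserWarning, match="absent"):
            strict_split(self._records(), holdout_kinases={"K0", "NOPE"})

    def test_exactly_one_holdout_kind(self):
        with pytest.raises(ValueError):
            strict_split(self._records())


def test_table_round_trip(tmp_path):
    recs = deduplicate_pairs(
        [
            ActivityRecord.from_bioactivity("A", "CCO", 2.25, source="x"),
            ActivityRecord.from_bioactivity("B", "CC", 0.5, source="x"),
        ]
    )
    path = tmp_path / "table.tsv"
    write_table(recs, path)
    back = read_table(path)
    assert [(r.kinase_id, r.compound_smiles) for r in back] == [
        (r.kinase_id, r.compound_smiles) for r in recs
    ]
    assert back[0].bioactivity == pytest.approx(recs[0].bioactivity)
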