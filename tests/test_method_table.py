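"""Acquisition-table parsing, round-trips and cross-talk screening."""

import itertools

import pytest

from mrlvalidate.errors import DuplicateTransitionError, SchemaError
from mrlvalidate.method_table import (
    Matrix,
    MethodTable,
    Role,
    TransitionRecord,
    estimate_crosstalk_bias,
    parse_method_table,
    screen_interferences,
)


def _record(analyte, rt, prec, prod, rank="quantifier", **kw):
    return TransitionRecord(
        analyte=analyte,
        role=kw.get("role", Role.target),
        matrices=frozenset({Matrix.muscle, Matrix.milk}),
        retention_time=rt,
        adduct="[M + H]+",
        precursor_mz=prec,
        product_mz=prod,
        collision_energy=20.0,
        rank=rank,
    )


class TestParsing:
    def test_bundled_table_has_64_targets_with_two_transitions(self, method_table):
        assert len(method_table.target_analytes) == 64
        for name in method_table.target_analytes:
            assert len(method_table.transitions_for(name)) == 2

    def test_bundled_table_has_eight_internal_standards(self, method_table):
        assert len(method_table.internal_standards) == 8
        for name in method_table.internal_standards:
            assert len(method_table.transitions_for(name)) in (1, 2)

    def test_milk_only_quinolones(self, method_table):
        for analyte in ("norfloxacin", "nalidixic acid"):
            rec = method_table.transitions_for(analyte)[0]
            assert rec.matrices == frozenset({Matrix.milk})
        assert "norfloxacin" not in method_table.analytes_in("muscle")
        assert "norfloxacin" in method_table.analytes_in("milk")

    def test_header_only_file_yields_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "analyte,role,matrices,rt_min,adduct,precursor_mz,product_mz,ce_ev,rank\n"
        )
        assert len(parse_method_table(path)) == 0

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("analyte,role\nx,target\n")
        with pytest.raises(SchemaError, match="missing columns"):
            parse_method_table(path)

    def test_non_numeric_mz_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "analyte,role,matrices,rt_min,adduct,precursor_mz,product_mz,ce_ev,rank\n"
            "x,target,muscle,1.0,[M + H]+,abc,100.0,20,quantifier\n"
        )
        with pytest.raises(SchemaError):
            parse_method_table(path)

    def test_duplicate_transition_rejected(self):
        recs = (
            _record("a", 1.0, 300.1, 100.0),
            _record("a", 1.0, 300.1, 100.0, rank="qualifier"),
        )
        with pytest.raises(DuplicateTransitionError):
            MethodTable(records=recs)

    def test_target_must_have_exactly_two_transitions(self):
        with pytest.raises(ValueError, match="expected 2"):
            MethodTable(records=(_record("a", 1.0, 300.1, 100.0),))

    def test_bicharged_precursor_below_product_is_legal(self, method_table):
        # spiramycin: doubly charged 422.3 fragments to singly charged 702.4
        spira = method_table.transitions_for("spiramycin")
        assert any(r.product_mz > r.precursor_mz for r in spira)

    def test_roundtrip_is_identity(self, method_table, tmp_path):
        out = tmp_path / "roundtrip.csv"
        method_table.to_csv(out)
        again = parse_method_table(out)
        assert again == method_table

    def test_tsv_dialect_roundtrip(self, method_table, tmp_path):
        out = tmp_path / "roundtrip.tsv"
        method_table.to_csv(out, dialect="tsv")
        assert parse_method_table(out, dialect="tsv") == method_table


class TestInterferenceScreening:
    def test_flags_coeluting_nominal_mass_collision(self, method_table):
        pairs = screen_interferences(method_table, rt_window=0.3, mz_tol=0.5)
        names = {frozenset((p.analyte_a, p.analyte_b)) for p in pairs}
        assert frozenset(("sulfamerazine", "cefquinome")) in names

    def test_separated_isobars_not_flagged(self, method_table):
        # oxolinic acid and flumequine share precursor 262.1 but elute 2.2 min apart
        pairs = screen_interferences(method_table, rt_window=0.3, mz_tol=0.5)
        names = {frozenset((p.analyte_a, p.analyte_b)) for p in pairs}
        assert frozenset(("oxolinic acid", "flumequine")) not in names

    def test_single_analyte_table_has_no_pairs(self):
        table = MethodTable(
            records=(
                _record("a", 1.0, 300.1, 100.0),
                _record("a", 1.0, 300.1, 150.0, rank="qualifier"),
            )
        )
        assert screen_interferences(table) == []

    def test_matches_brute_force_oracle(self, method_table):
        rt_window, mz_tol = 0.3, 0.5
        expected = set()
        targets = method_table.target_analytes
        for a, b in itertools.combinations(targets, 2):
            ta = method_table.transitions_for(a)
            tb = method_table.transitions_for(b)
            if abs(ta[0].retention_time - tb[0].retention_time) > rt_window:
                continue
            if any(
                abs(x.precursor_mz - y.precursor_mz) <= mz_tol
                for x in ta
                for y in tb
            ):
                expected.add(frozenset((a, b)))
        got = {
            frozenset((p.analyte_a, p.analyte_b))
            for p in screen_interferences(method_table, rt_window, mz_tol)
        }
        assert got == expected

    @pytest.mark.parametrize("wider", [(0.5, 0.5), (0.3, 1.0), (1.0, 1.0)])
    def test_enlarging_windows_never_removes_pairs(self, method_table, wider):
        base = {
            frozenset((p.analyte_a, p.analyte_b))
            for p in screen_interferences(method_table, 0.3, 0.5)
        }
        larger = {
            frozenset((p.analyte_a, p.analyte_b))
            for p in screen_interferences(method_table, *wider)
        }
        assert base <= larger

    def test_sorted_by_delta_rt(self, method_table):
        pairs = screen_interferences(method_table, rt_window=1.0, mz_tol=0.5)
        deltas = [p.delta_rt for p in pairs]
        assert deltas == sorted(deltas)


class TestCrosstalkBias:
    def test_reported_cefquinome_overestimation(self):
        # quantifier 1.1e6 with a 4.9e6 co-eluting bleed-through
        factor = estimate_crosstalk_bias(1.1e6, 4.9e6, shared=True)
        assert factor == pytest.approx((1.1 + 4.9) / 1.1)
        assert factor == pytest.approx(5.4545, abs=1e-3)

    def test_no_shared_transition_means_no_bias(self):
        assert estimate_crosstalk_bias(123.0, 4.5e6, shared=False) == 1.0

    def test_equal_areas_double(self):
        assert estimate_crosstalk_bias(5.0, 5.0, shared=True) == pytest.approx(2.0)

    def test_zero_quantifier_area_raises(self):
        with pytest.raises(ZeroDivisionError):
            estimate_crosstalk_bias(0.0, 1.0, shared=True)
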