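"""Stage-1 compilation: loading, priority merge, gap-filling, provenance."""

import numpy as np
import pytest

from nutridbk.fct import (
    CompiledFCT,
    FCTValidationError,
    FoodItem,
    Source,
    SourceTag,
    compile_fct,
    gap_fill,
    load_fct,
    merge_fcts,
    normalize_name,
    provenance_summary,
    read_compiled,
    source_rank,
    write_compiled,
)
from nutridbk.nutrients import NutrientVector


def _item(code, source=Source.IFCT2017, name=None, **nutrients):
    return FoodItem(
        food_code=code,
        name=name or f"food {code}",
        source=source,
        nutrients=NutrientVector(**nutrients),
    )


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadFct:
    def test_fills_missing_energy_representation_from_declared_unit(self, tmp_path):
        p = _write(tmp_path, "a.csv", "food_code,name,energy_kcal,protein_g\nF1,rice,100,7\n")
        (item,) = load_fct(p, Source.IFCT2004, "kcal")
        assert item.nutrients["energy_kj"] == pytest.approx(418.4)
        p2 = _write(tmp_path, "b.csv", "food_code,name,energy_kj\nF2,dal,418.4\n")
        (item2,) = load_fct(p2, Source.IFCT2017, "kJ")
        assert item2.nutrients["energy_kcal"] == pytest.approx(418.4 * 0.239)

    def test_empty_file_yields_empty_collection(self, tmp_path):
        p = _write(tmp_path, "empty.csv", "")
        assert load_fct(p, Source.IFCT2017, "kJ") == []
        p2 = _write(tmp_path, "header_only.csv", "food_code,name,energy_kj\n")
        assert load_fct(p2, Source.IFCT2017, "kJ") == []

    def test_negative_nutrient_is_a_row_addressed_error(self, tmp_path):
        p = _write(
            tmp_path, "neg.csv",
            "food_code,name,energy_kj,potassium_mg\nF1,ok,100,50\nF2,bad,100,-3\n",
        )
        with pytest.raises(FCTValidationError, match="F2.*potassium_mg"):
            load_fct(p, Source.IFCT2017, "kJ")

    def test_duplicate_food_code_rejected(self, tmp_path):
        p = _write(tmp_path, "dup.csv", "food_code,name,energy_kj\nF1,a,1\nF1,b,2\n")
        with pytest.raises(FCTValidationError, match="duplicate"):
            load_fct(p, Source.IFCT2017, "kJ")

    def test_unknown_columns_warn_and_are_ignored(self, tmp_path):
        p = _write(tmp_path, "u.csv", "food_code,name,energy_kj,astrology\nF1,a,10,x\n")
        with pytest.warns(UserWarning, match="astrology"):
            (item,) = load_fct(p, Source.IFCT2017, "kJ")
        assert item.nutrients["energy_kj"] == 10

    def test_provenance_defaults_to_the_loading_source(self, tmp_path):
        p = _write(tmp_path, "s.csv", "food_code,name,energy_kj,iron_mg\nF1,a,10,2\n")
        (item,) = load_fct(p, Source.UKFCT, "kJ")
        assert item.provenance["iron_mg"] is Source.UKFCT


class TestMerge:
    def test_newer_edition_wins_on_duplicate(self):
        new = [_item("rice", Source.IFCT2017, iron_mg=5)]
        old = [_item("rice", Source.IFCT2004, iron_mg=9), _item("bajra", Source.IFCT2004)]
        out, report = merge_fcts(new, old)
        by_code = {it.food_code: it for it in out}
        assert by_code["rice"].source is Source.IFCT2017
        assert by_code["rice"].nutrients["iron_mg"] == 5  # kept whole, no mixing
        assert report.n_dropped == 1 and report.dropped[0][0] == "rice"

    def test_empty_older_collection_is_identity(self):
        new = [_item("a"), _item("b")]
        out, report = merge_fcts(new, [])
        assert out == new and report.n_dropped == 0

    def test_disjoint_collections_union(self):
        out, _ = merge_fcts([_item(c) for c in "abc"], [_item(c, Source.IFCT2004) for c in "de"])
        assert len(out) == 5

    def test_normalized_name_matching(self):
        a = [_item("X1", name="Kidney Beans, raw")]
        b = [_item("Y1", Source.IFCT2004, name="kidney beans raw")]
        out, report = merge_fcts(a, b, match_key="normalized_name")
        assert len(out) == 1 and report.n_dropped == 1
        assert normalize_name("  Kidney--Beans,  RAW ") == "kidney beans raw"

    def test_priority_property_on_random_overlapping_collections(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            codes_a = rng.choice(50, size=rng.integers(1, 20), replace=False)
            codes_b = rng.choice(50, size=rng.integers(1, 20), replace=False)
            a = [_item(f"C{c}", Source.IFCT2017, iron_mg=1.0) for c in codes_a]
            b = [_item(f"C{c}", Source.IFCT2004, iron_mg=2.0) for c in codes_b]
            out, report = merge_fcts(a, b)
            by_code = {it.food_code: it for it in out}
            overlap = set(f"C{c}" for c in codes_a) & set(f"C{c}" for c in codes_b)
            assert {k for k, _, _ in report.dropped} == overlap
            for k in overlap:
                assert by_code[k].nutrients["iron_mg"] == 1.0
            assert len(out) == len(set(by_code) | set(f"C{c}" for c in codes_b))


class TestGapFill:
    def test_copies_value_and_sets_fallback_provenance(self):
        egg = _item("egg", iron_mg=2)  # carb_g missing
        uk_egg = _item("uk_egg", Source.UKFCT, carb_g=0.3)
        filled, records = gap_fill(egg, {"uk_egg": uk_egg}, {"carb_g"}, {"egg": "uk_egg"})
        assert filled.nutrients["carb_g"] == 0.3
        assert filled.provenance["carb_g"] is Source.UKFCT
        assert filled.provenance["iron_mg"] is Source.IFCT2017
        assert records[0].action == "filled"

    def test_item_without_gaps_is_returned_unchanged(self):
        full = _item("x", carb_g=1, fibre_g=2, biotin_ug=3)
        out, records = gap_fill(full, {}, {"carb_g", "fibre_g", "biotin_ug"}, {})
        assert out is full and records == []

    def test_null_on_both_sides_stays_null_and_is_reported_unresolved(self):
        item = _item("x", iron_mg=1)
        fb = _item("y", Source.UKFCT, iron_mg=2)  # carb also null on fallback
        out, records = gap_fill(item, {"y": fb}, {"carb_g"}, {"x": "y"})
        assert out.nutrients["carb_g"] is None
        assert records[0].action == "unresolved"

    def test_missing_mapping_leaves_item_unchanged_with_no_match_record(self):
        item = _item("x")
        out, records = gap_fill(item, {}, {"carb_g"}, {})
        assert out is item
        assert all(r.action == "no_match" for r in records)

    def test_never_overwrites_non_null_values(self):
        item = _item("x", carb_g=9)
        fb = _item("y", Source.UKFCT, carb_g=1, fibre_g=4)
        out, _ = gap_fill(item, {"y": fb}, {"carb_g", "fibre_g"}, {"x": "y"})
        assert out.nutrients["carb_g"] == 9
        assert out.nutrients["fibre_g"] == 4


class TestCompiledFCT:
    def test_provenance_summary_counts_by_item_source(self):
        items = [_item(f"a{i}") for i in range(5)] + [
            _item(f"b{i}", Source.UKFCT) for i in range(3)
        ]
        counts, total = provenance_summary(CompiledFCT.from_items(items))
        assert counts == {Source.IFCT2017: 5, Source.UKFCT: 3}
        assert total == 8

    def test_empty_databank_summary(self):
        counts, total = provenance_summary(CompiledFCT())
        assert counts == {} and total == 0

    def test_source_counts_are_recomputed_not_stale(self):
        fct = CompiledFCT.from_items([_item("a")])
        assert fct.source_counts == {Source.IFCT2017: 1}
        fct.items["b"] = _item("b", Source.USDA)
        assert fct.source_counts == {Source.IFCT2017: 1, Source.USDA: 1}

    def test_round_trip_through_csv_is_lossless(self, tmp_path):
        egg = _item("egg", energy_kj=100, iron_mg=2)
        filled, _ = gap_fill(
            egg, {"uk": _item("uk", Source.UKFCT, carb_g=0.3)}, {"carb_g"}, {"egg": "uk"}
        )
        fct = CompiledFCT.from_items([filled, _item("z", Source.USDA, zinc_mg=1.5)])
        write_compiled(fct, tmp_path)
        back = read_compiled(tmp_path)
        assert set(back.items) == set(fct.items)
        for code, item in fct.items.items():
            assert back[code].nutrients == item.nutrients
            assert back[code].provenance == dict(item.provenance)
            assert back[code].source is item.source


def test_compile_chain_keeps_counts_additive_and_gap_fills():
    t2017 = [_item("a", Source.IFCT2017, iron_mg=1)]  # carb missing
    t2004 = [_item("a", Source.IFCT2004, iron_mg=9), _item("b", Source.IFCT2004)]
    uk = [_item("u", Source.UKFCT, carb_g=12.0)]
    fct, reports, records = compile_fct(
        [(Source.IFCT2017, t2017), (Source.IFCT2004, t2004), (Source.UKFCT, uk)],
        gapfill_mapping={"a": (Source.UKFCT, "u")},
        fill_fields={"carb_g"},
    )
    assert provenance_summary(fct)[0] == {
        Source.IFCT2017: 1,
        Source.IFCT2004: 1,
        Source.UKFCT: 1,
    }
    assert fct["a"].nutrients["iron_mg"] == 1
    assert fct["a"].nutrients["carb_g"] == 12.0
    assert fct["a"].provenance["carb_g"] is Source.UKFCT
    assert sum(r.n_dropped for r in reports) == 1
    assert any(r.action == "filled" for r in records)


def test_source_tag_ranks_follow_default_priority():
    assert [source_rank(s) for s in (Source.IFCT2017, Source.IFCT2004, Source.UKFCT, Source.USDA)] == [1, 2, 3, 4]
    tag = SourceTag.of(Source.UKFCT)
    assert tag.priority_rank == 3 and tag.code is Source.UKFCT
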