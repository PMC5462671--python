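"""Config expansion, descriptor names, table computation, output, projects, batch."""

import math
import random

import numpy as np
import pytest

import algomd as am
from algomd.engine import (
    DescriptorConfig,
    DescriptorSpec,
    encode_name,
    expand_config,
    parse_name,
)
from algomd.matrices import KEEP_ALL, CutoffSpec


def small_config(**kw):
    base = dict(
        forms=["bilinear"],
        schemes=["NS", "SS"],
        powers=[0, 1, 2],
        cutoffs=[KEEP_ALL],
        scopes=["T"],
        property_pairs=[("E", "P")],
        operators=["TS", "EU"],
        diag_mode="lone_pairs",
    )
    base.update(kw)
    return DescriptorConfig(**base)


class TestExpansion:
    def test_product_count(self):
        cfg = small_config(schemes=["NS"], powers=[1, 2], operators=["TS", "EU", "MX"])
        assert len(expand_config(cfg)) == 6

    def test_duplicate_operator_deduplicated(self):
        cfg = small_config(schemes=["NS"], powers=[1], operators=["TS", "TS"])
        assert len(expand_config(cfg)) == 1

    def test_quadratic_with_mismatched_pair_rejected(self):
        cfg = small_config(forms=["quadratic"], property_pairs=[("E", "P")])
        with pytest.raises(ValueError, match="quadratic"):
            expand_config(cfg)

    def test_linear_requires_unit_first(self):
        cfg = small_config(forms=["linear"], property_pairs=[("E", "P")])
        with pytest.raises(ValueError, match="linear"):
            expand_config(cfg)

    def test_mixed_forms_filter_pairs_per_form(self):
        cfg = small_config(
            forms=["bilinear", "quadratic", "linear"],
            schemes=["NS"], powers=[1], operators=["TS"],
            property_pairs=[("E", "P"), ("M", "M"), ("U", "E")],
        )
        specs = expand_config(cfg)
        by_form = {f: [s for s in specs if s.form == f] for f in ("bilinear", "quadratic", "linear")}
        assert [len(v) for v in by_form.values()] == [2, 1, 1]

    def test_empty_expansion_is_an_error(self):
        with pytest.raises(ValueError):
            expand_config(small_config(operators=[]))


def random_spec(rng):
    cut = rng.choice(
        [KEEP_ALL, CutoffSpec("SRW"), CutoffSpec("NSRW"), CutoffSpec("LAG", 2, 5)]
    )
    return DescriptorSpec(
        operator=rng.choice(list(am.OPERATORS)),
        form=rng.choice(["linear", "quadratic", "bilinear"]),
        k=rng.randint(0, 15),
        scheme=rng.choice(["NS", "SS", "DS", "MP"]),
        cutoff=cut,
        scope=rng.choice(["T", "A", "C", "D", "G", "M", "P", "X"]),
        level=rng.choice(["atom", "bond"]),
        h_policy=rng.choice(["suppressed", "explicit"]),
        diag_mode=rng.choice(["none", "aromatic", "lone_pairs", "aromatic+lone_pairs"]),
        x_code=rng.choice(["M", "E", "PSA", "U"]),
        y_code=rng.choice(["M", "E", "PSA"]),
        chirality=rng.choice([None, 0.25, -1.5]),
    )


class TestNames:
    def test_round_trip_identity_on_random_specs(self):
        rng = random.Random(5)
        for _ in range(1000):
            spec = random_spec(rng)
            assert parse_name(encode_name(spec)) == spec

    def test_distinct_specs_get_distinct_names(self):
        rng = random.Random(9)
        specs = {random_spec(rng) for _ in range(500)}
        names = {encode_name(s) for s in specs}
        assert len(names) == len(specs)

    def test_documented_example_decodes(self):
        spec = parse_name("EU_q3_MP_LAG2-5_X_AB_nh-nlp_m-m")
        assert spec.operator == "EU"
        assert spec.form == "quadratic" and spec.k == 3
        assert spec.scheme == "MP"
        assert spec.cutoff == CutoffSpec("LAG", 2, 5)
        assert spec.scope == "X" and spec.level == "atom"
        assert spec.h_policy == "suppressed" and spec.diag_mode == "none"
        assert (spec.x_code, spec.y_code) == ("M", "M")

    @pytest.mark.parametrize(
        "bad", ["", "TS", "ZZ_b2_SS_KA_T_AB_nh-lp_e-p", "TS_x2_SS_KA_T_AB_nh-lp_e-p",
                "TS_b2_QQ_KA_T_AB_nh-lp_e-p", "TS_b2_SS_KA_T_AB_nh-lp_e-p_junk"]
    )
    def test_malformed_names_report_position(self, bad):
        with pytest.raises(ValueError, match="malformed|token"):
            parse_name(bad)


class TestComputeTable:
    def test_shape_and_row_order(self, fixture_set):
        mols = fixture_set[:3]
        cfg = small_config(schemes=["NS"], powers=[1, 2], operators=["TS", "EU", "MX"])
        t = am.compute_table(cfg, mols)
        assert t.values.shape == (3, 6)
        assert t.ids == [g.source_id for g in mols]

    def test_worker_count_does_not_change_values(self, fixture_set):
        cfg = small_config()
        t1 = am.compute_table(cfg, fixture_set, workers=1)
        t2 = am.compute_table(cfg, fixture_set, workers=4)
        assert t1.ids == t2.ids
        assert np.array_equal(t1.values, t2.values, equal_nan=True)

    def test_bondless_molecule_yields_na_row(self):
        mols = am.generate_fixtures("methane") + am.generate_fixtures("ethane")
        cfg = small_config(level="bond", schemes=["NS"])
        t = am.compute_table(cfg, mols)
        assert np.all(np.isnan(t.values[0]))
        assert np.all(np.isfinite(t.values[1]))

    def test_empty_molecule_list_rejected(self):
        with pytest.raises(ValueError):
            am.compute_table(small_config(), [])


@pytest.fixture(scope="module")
def table(fixture_set):
    cfg = small_config(level="bond")
    mols = [g for g in fixture_set if g.n_bonds][:4]
    return am.compute_table(cfg, mols)


class TestOutput:

    @pytest.mark.parametrize("fmt", ["csv", "tsv", "ssv", "arff"])
    def test_round_trip(self, table, tmp_path, fmt):
        p = tmp_path / f"t.{fmt}"
        am.write_table(table, p, fmt, float_digits=17)
        back = am.read_table(p, fmt)
        assert back.ids == table.ids and back.names == table.names
        assert np.allclose(back.values, table.values, atol=1e-12, equal_nan=True)

    def test_na_cells_csv_empty_arff_question(self, tmp_path):
        t = am.ResultTable(["m1"], ["d1", "d2"], np.array([[1.5, np.nan]]))
        am.write_table(t, tmp_path / "t.csv", "csv")
        assert tmp_path.joinpath("t.csv").read_text().splitlines()[1] == "m1,1.5,"
        am.write_table(t, tmp_path / "t.arff", "arff")
        arff = tmp_path.joinpath("t.arff").read_text()
        assert "m1,1.5,?" in arff

    def test_arff_declares_numeric_attributes(self, table, tmp_path):
        am.write_table(table, tmp_path / "t.arff", "arff")
        lines = tmp_path.joinpath("t.arff").read_text().splitlines()
        attrs = [ln for ln in lines if ln.startswith("@ATTRIBUTE")]
        assert attrs[0] == "@ATTRIBUTE id STRING"
        assert len(attrs) == len(table.names) + 1
        assert all(a.endswith("NUMERIC") for a in attrs[1:])

    def test_repeated_writes_are_byte_identical(self, table, tmp_path):
        am.write_table(table, tmp_path / "a.csv", "csv")
        am.write_table(table, tmp_path / "b.csv", "csv")
        assert tmp_path.joinpath("a.csv").read_bytes() == tmp_path.joinpath("b.csv").read_bytes()


class TestProjects:
    def test_round_trip_identity(self, tmp_path):
        cfg = small_config(
            forms=["bilinear", "linear"],
            property_pairs=[("E", "P"), ("U", "M")],
            cutoffs=[KEEP_ALL, CutoffSpec("LAG", 1, 4)],
            chirality=0.5,
            normalize_then_power=True,
        )
        p = tmp_path / "p.xml"
        am.save_project(cfg, p)
        assert am.load_project(p) == cfg

    def test_out_of_range_power_rejected_on_load(self, tmp_path):
        cfg = small_config()
        p = tmp_path / "p.xml"
        am.save_project(cfg, p)
        text = p.read_text().replace("<power>2</power>", "<power>16</power>")
        p.write_text(text)
        with pytest.raises(ValueError, match="power"):
            am.load_project(p)

    def test_missing_chirality_defaults_to_none(self, tmp_path):
        p = tmp_path / "p.xml"
        am.save_project(small_config(), p)
        assert am.load_project(p).chirality is None

    def test_malformed_xml_rejected(self, tmp_path):
        p = tmp_path / "broken.xml"
        p.write_text("<descriptor-project version='1'><forms>")
        with pytest.raises(ValueError, match="well-formed"):
            am.load_project(p)


class TestBatch:
    @pytest.fixture()
    def assets(self, tmp_path, fixture_set):
        from rdkit import Chem

        ds = tmp_path / "mols.sdf"
        with Chem.SDWriter(str(ds)) as w:
            for g in fixture_set[:3]:
                if g.rdmol is not None and g.n_bonds:
                    w.write(g.rdmol)
        p1, p2 = tmp_path / "p1.xml", tmp_path / "p2.xml"
        am.save_project(small_config(schemes=["NS"]), p1)
        am.save_project(small_config(schemes=["SS"]), p2)
        return ds, p1, p2

    def test_two_tasks_two_projects_give_four_outputs(self, assets):
        ds, p1, p2 = assets
        results, report = am.run_batch([([ds], [p1, p2]), ([ds], [p1, p2])])
        assert len(results) == 4
        assert all("ok" in line for line in report)

    def test_more_than_eight_tasks_rejected(self, assets):
        ds, p1, _ = assets
        with pytest.raises(ValueError, match="8"):
            am.run_batch([([ds], [p1])] * 9)

    def test_failing_task_does_not_abort_others(self, assets, tmp_path):
        ds, p1, _ = assets
        missing = tmp_path / "missing.sdf"
        results, report = am.run_batch([([missing], [p1]), ([ds], [p1])])
        assert len(results) == 1
        assert any("FAILED" in line for line in report)
        assert any("ok" in line for line in report)
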