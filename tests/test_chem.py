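"""Molecule/table IO: SDF round-trips, radius assignment, error contracts."""
import numpy as np
import pytest

from herbnet.chem import (
    Atom,
    DescriptorRecord,
    FormulaTable,
    Molecule,
    read_descriptor_table,
    read_formula_table,
    read_sdf,
    vdw_radius,
    write_descriptor_table,
    write_formula_table,
    write_sdf,
)
from herbnet.errors import FormatError, IntegrityError, SchemaError


def _mol(mol_id, coords, elements=None):
    coords = np.asarray(coords, dtype=float)
    elements = elements or ["C"] * len(coords)
    return Molecule(mol_id, [Atom(e, c, vdw_radius(e)) for e, c in zip(elements, coords)])


class TestSdf:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        assert read_sdf(p) == []

    def test_round_trip_preserves_geometry(self, tmp_path, rng):
        mols = [
            _mol("A1", rng.normal(size=(5, 3)), ["C", "N", "O", "S", "C"]),
            _mol("B2", rng.normal(size=(8, 3))),
        ]
        path = tmp_path / "mols.sdf"
        write_sdf(mols, path)
        back = read_sdf(path)
        # independent check of the counts lines by plain text parsing
        counts = [int(l[:3]) for l in path.read_text().splitlines() if l.endswith("V2000")]
        assert counts == [5, 8]
        assert [len(m) for m in back] == [5, 8]
        for orig, rt in zip(mols, back):
            assert rt.id == orig.id
            assert rt.elements == orig.elements
            np.testing.assert_allclose(rt.coords, orig.coords, atol=1e-4)

    def test_rdkit_agrees_on_round_trip(self, tmp_path, rng):
        """Cross-check our V2000 writer/reader against an independent parser."""
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem

        mols = [_mol("X", rng.normal(size=(6, 3)), ["C", "N", "O", "C", "S", "C"])]
        path = tmp_path / "x.sdf"
        write_sdf(mols, path)
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        rd = next(iter(supplier))
        conf = rd.GetConformer()
        coords = np.array([list(conf.GetAtomPosition(i)) for i in range(rd.GetNumAtoms())])
        np.testing.assert_allclose(coords, mols[0].coords, atol=1e-4)
        assert [a.GetSymbol() for a in rd.GetAtoms()] == mols[0].elements

    def test_hydrogens_suppressed_by_default(self, tmp_path):
        mols = [_mol("HX", [[0, 0, 0], [1, 0, 0], [0, 1, 0]], ["C", "H", "H"])]
        path = tmp_path / "h.sdf"
        write_sdf(mols, path)
        assert len(read_sdf(path)[0]) == 1
        assert len(read_sdf(path, suppress_hydrogens=False)[0]) == 3

    def test_all_hydrogen_record_skipped_with_others_kept(self, tmp_path, caplog):
        mols = [_mol("ONLYH", [[0, 0, 0]], ["H"]), _mol("OK", [[0, 0, 0]])]
        path = tmp_path / "h2.sdf"
        write_sdf(mols, path)
        with caplog.at_level("WARNING"):
            back = read_sdf(path)
        assert [m.id for m in back] == ["OK"]
        assert any("zero heavy atoms" in r.message for r in caplog.records)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        mols = [_mol("BAD", [[0, 0, 0], [1, 1, 1]])]
        path = tmp_path / "bad.sdf"
        write_sdf(mols, path)
        text = path.read_text().replace("    1.0000", "    oops  ", 1)
        path.write_text(text)
        with pytest.raises(FormatError, match=r"line \d+"):
            read_sdf(path)

    def test_malformed_counts_line_names_record(self, tmp_path):
        path = tmp_path / "cnt.sdf"
        path.write_text("m\n\n\nxx zz broken\n$$$$\n")
        with pytest.raises(FormatError, match="record 0"):
            read_sdf(path)

    def test_v3000_rejected(self, tmp_path):
        path = tmp_path / "v3.sdf"
        path.write_text("m\n\n\n  0  0  0     0  0            999 V3000\n$$$$\n")
        with pytest.raises(FormatError, match="V3000"):
            read_sdf(path)

    def test_radius_fallback_is_total(self):
        # every element gets a positive radius, known or not
        for el in ["C", "N", "O", "S", "P", "Cl", "Br", "Xx", "Si"]:
            assert vdw_radius(el) > 0


class TestDescriptorTable:
    def test_header_only_gives_empty(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("compound_id\tsolubility_level\tbbb_level\tcyp2d6\tabsorption_level\n")
        assert read_descriptor_table(p) == []

    def test_typed_parse(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "compound_id\tsolubility_level\tbbb_level\tcyp2d6\tabsorption_level\n"
            "NZ088\t-4.1\t2\tFALSE\t1\n"
            "SC001\t-9.0\t3\ttrue\t3\n"
        )
        recs = read_descriptor_table(p)
        assert recs[0] == DescriptorRecord("NZ088", -4.1, 2, False, 1)
        assert recs[1].cyp2d6 is True  # case-insensitive

    def test_missing_column_schema_error(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("compound_id\tsolubility_level\n")
        with pytest.raises(SchemaError, match="bbb_level"):
            read_descriptor_table(p)

    def test_bad_cell_names_row(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(
            "compound_id\tsolubility_level\tbbb_level\tcyp2d6\tabsorption_level\n"
            "A\t-4.0\t1\tmaybe\t1\n"
        )
        with pytest.raises(FormatError, match="row 2"):
            read_descriptor_table(p)

    def test_round_trip_with_missing_values(self, tmp_path):
        recs = [DescriptorRecord("A", None, 1, False, 2), DescriptorRecord("B", -3.5, None, None, None)]
        p = tmp_path / "d.tsv"
        write_descriptor_table(recs, p)
        back = read_descriptor_table(p)
        assert back[0].solubility_level is None
        assert back[1].bbb_level is None and back[1].cyp2d6 is None


class TestFormulaTable:
    def test_six_herbs(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "herb_code\tcompound_id\n" + "".join(f"{h}\t{h}001\n" for h in
                                                 ["SC", "RS", "SW", "MD", "NZ", "GQ"])
        )
        ft = read_formula_table(p)
        assert len(ft.herb_codes) == 6 and len(ft) == 6
        assert ft.herb_of("NZ001") == "NZ"

    def test_duplicate_compound_rejected(self):
        with pytest.raises(IntegrityError, match="X1"):
            FormulaTable({"SC": ["X1"], "RS": ["X1"]})

    def test_published_per_herb_counts_total(self, tmp_path):
        # per-herb candidate counts as printed: SC 88, RS 98, SW 7, MD 15, NZ 54, GQ 67
        counts = {"SC": 88, "RS": 98, "SW": 7, "MD": 15, "NZ": 54, "GQ": 67}
        herbs = {h: [f"{h}{i:03d}" for i in range(n)] for h, n in counts.items()}
        ft = FormulaTable(herbs)
        p = tmp_path / "f.tsv"
        write_formula_table(ft, p)
        back = read_formula_table(p)
        assert len(back) == 329
        assert {h: len(c) for h, c in back.herbs.items()} == counts
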