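"""Synthetic-data generators: determinism, geometry, planted ground truth."""
import numpy as np
import pytest

from herbnet.admet import apply_admet_rules
from herbnet.chem import read_descriptor_table, read_formula_table, read_sdf
from herbnet.enrichment import cluster_terms, hypergeom_enrich
from herbnet.errors import ValidationError
from herbnet.fishing import LigandLibrary, map_to_disease
from herbnet.synthetic import (
    SyntheticSpec,
    generate_annotation_db,
    generate_descriptor_table,
    generate_ligand_library,
    generate_screen_set,
    make_admet_count_fixture,
    make_bipartite_pairs,
    make_ct_count_fixture,
    make_margin_sets,
    simulate,
)


class TestLigandLibrary:
    def test_byte_identical_across_runs(self, tmp_path):
        spec = SyntheticSpec(seed=42, n_targets=5, ligands_per_target=1)
        for d in ("a", "b"):
            simulate(spec, tmp_path / d)
        for name in ("library.sdf", "compounds.sdf", "descriptors.tsv",
                     "annotations.gmt", "disease.txt", "groundtruth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_zero_targets_rejected(self):
        with pytest.raises(ValidationError):
            generate_ligand_library(SyntheticSpec(n_targets=0))

    def test_bond_scale_spacing(self):
        """Nearest-neighbour distance stays above 1.2 A over many seeds."""
        worst = np.inf
        for seed in range(100):
            spec = SyntheticSpec(seed=seed, n_targets=1, ligands_per_target=1)
            lib, _ = generate_ligand_library(spec)
            coords = lib.entries[0][0].coords
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            worst = min(worst, d.min())
        assert worst >= 1.2

    def test_emitted_files_parse_cleanly(self, tmp_path):
        simulate(SyntheticSpec(seed=3), tmp_path)
        lib = LigandLibrary.from_files(tmp_path / "library.sdf", tmp_path / "library_annot.tsv")
        assert len(lib) == 10
        assert len(read_sdf(tmp_path / "compounds.sdf")) == 40
        assert len(read_descriptor_table(tmp_path / "descriptors.tsv")) == 40
        assert len(read_formula_table(tmp_path / "formula.tsv")) == 40


class TestScreenSet:
    def test_zero_jitter_actives_are_rigid_copies(self):
        from herbnet.shape import shape_tanimoto

        spec = SyntheticSpec(seed=5, jitter_sd=0.0, n_actives=3, n_decoys=0)
        lib, _ = generate_ligand_library(spec)
        mols, _, gt = generate_screen_set(spec, lib)
        templates = {t: m for m, t in lib.entries[::-1]}
        for cid, tid in gt.planted_edges:
            mol = next(m for m in mols if m.id == cid)
            best = max(
                shape_tanimoto(mol, lig).tanimoto for lig, t in lib.entries if t == tid
            )
            assert best >= 0.999

    def test_no_actives_means_only_decoys(self):
        spec = SyntheticSpec(seed=5, n_actives=0, n_decoys=4)
        lib, _ = generate_ligand_library(spec)
        mols, _, gt = generate_screen_set(spec, lib)
        assert gt.planted_edges == set()
        assert {m.id for m in mols} == gt.decoy_ids

    def test_round_robin_herb_assignment(self):
        spec = SyntheticSpec(seed=5, n_actives=6, n_decoys=0, n_herbs=3)
        lib, _ = generate_ligand_library(spec)
        _, formula, _ = generate_screen_set(spec, lib)
        assert {h: len(c) for h, c in formula.herbs.items()} == {"SC": 2, "RS": 2, "SW": 2}


class TestDescriptorGenerator:
    def test_zero_rates_retain_everything(self):
        spec = SyntheticSpec(seed=1, solubility_rate=0, bbb_rate=0, cyp2d6_rate=0,
                             absorption_rate=0)
        records, gt = generate_descriptor_table(spec, [f"C{i}" for i in range(50)])
        assert apply_admet_rules(records).removed == []
        assert gt.violator_union == set()

    def test_rate_one_removes_everything_with_code(self):
        spec = SyntheticSpec(seed=1, solubility_rate=1.0, bbb_rate=0, cyp2d6_rate=0,
                             absorption_rate=0)
        records, _ = generate_descriptor_table(spec, [f"C{i}" for i in range(20)])
        result = apply_admet_rules(records)
        assert result.retained == []
        assert all(codes == ["SOLUBILITY"] for _, codes in result.removed)

    def test_filter_recovers_ground_truth_exactly(self):
        spec = SyntheticSpec(seed=7, solubility_rate=0.2, bbb_rate=0.2, cyp2d6_rate=0.2,
                             absorption_rate=0.2)
        ids = [f"C{i:03d}" for i in range(500)]
        records, gt = generate_descriptor_table(spec, ids)
        result = apply_admet_rules(records)
        assert set(result.removed_ids) == gt.violator_union
        for cid, codes in result.removed:
            expected = {code for code, members in gt.rule_violators.items() if cid in members}
            assert set(codes) == expected


class TestAnnotationGenerator:
    def test_single_block_single_module(self):
        spec = SyntheticSpec(seed=2, module_blocks=1, n_terms=4, disease_fraction=1.0)
        universe = [f"T{i:02d}" for i in range(30)]
        db, disease, gt = generate_annotation_db(spec, universe)
        results = hypergeom_enrich(gt.query_pool, db)
        modules = cluster_terms(results, db)
        assert len(modules) == 1

    def test_planted_blocks_recovered(self):
        spec = SyntheticSpec(seed=2, module_blocks=8, n_terms=24, term_size=(8, 12),
                             disease_fraction=0.6)
        universe = [f"T{i:03d}" for i in range(100)]
        db, disease, gt = generate_annotation_db(spec, universe)
        results = hypergeom_enrich(gt.query_pool, db)
        assert {r.term_id for r in results} == gt.enriched_terms
        modules = cluster_terms(results, db)
        assert len(modules) == 8
        assert {frozenset(m.terms) for m in modules} == {frozenset(b) for b in gt.module_blocks}

    def test_full_disease_fraction_keeps_every_association(self):
        from herbnet.fishing import CompoundTargetMap

        spec = SyntheticSpec(seed=2, disease_fraction=1.0)
        universe = [f"T{i:02d}" for i in range(10)]
        _, disease, _ = generate_annotation_db(spec, universe)
        ctmap = CompoundTargetMap([(f"C{i}", t, 0.9) for i, t in enumerate(universe)])
        restricted, pct = map_to_disease(ctmap, disease)
        assert pct == 100.0 and len(restricted.associations) == 10


class TestCountFixtures:
    def test_margin_sets_realize_published_overlap(self):
        sizes = {"SC": 149, "RS": 146, "SW": 120, "NZ": 146, "GQ": 142}
        sets = make_margin_sets(sizes, union_size=156, common_size=116)
        assert {h: len(s) for h, s in sets.items()} == sizes
        assert len(set().union(*sets.values())) == 156
        assert len(set.intersection(*sets.values())) == 116

    def test_margin_sets_infeasible_rejected(self):
        with pytest.raises(ValidationError):
            make_margin_sets({"A": 5, "B": 5}, union_size=20, common_size=0)

    def test_bipartite_pairs_exact_count_and_coverage(self):
        pairs = make_bipartite_pairs(276, 156, 13914)
        assert len(pairs) == len(set(pairs)) == 13914
        assert {i for i, _ in pairs} == set(range(276))
        assert {j for _, j in pairs} == set(range(156))

    def test_ct_count_fixture_shapes(self):
        formula, ctmap = make_ct_count_fixture(6, 276, 156, 13914)
        assert len(formula) == 276
        assert len(ctmap.associations) == 13914

    def test_admet_count_fixture_reproduces_counts(self):
        retained = {"SC": 88, "RS": 98, "SW": 7, "MD": 15, "NZ": 54, "GQ": 67}
        records, formula = make_admet_count_fixture(retained, n_total=688)
        assert len(records) == 688
        from herbnet.admet import filter_summary

        df = filter_summary(apply_admet_rules(records), formula)
        assert df.loc["TOTAL", "n_retained"] == 329
        assert {h: int(df.loc[h, "n_retained"]) for h in retained} == retained
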