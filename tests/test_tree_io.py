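"""Tree / landmark / module-map I/O and taxon reconciliation."""

import numpy as np
import pytest

import phylomorph as pm
from phylomorph.io import ModuleMap, normalize_taxon
from phylomorph.tree import Phylogeny


class TestNewick:
    def test_two_tip_cherry(self):
        t = Phylogeny.from_newick("(A:1,B:1);")
        assert sorted(t.tip_labels) == ["A", "B"]
        assert t.is_ultrametric()

    def test_depths(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        d = t.depths()
        assert all(abs(d[i] - 2.0) < 1e-12 for i in t.tip_indices)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            Phylogeny.from_newick("(A:-1,B:1);")

    def test_duplicate_tip_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            Phylogeny.from_newick("(A:1,A:1);")

    def test_roundtrip_fixed_point(self, tmp_path):
        t = Phylogeny.from_newick("((A:0.3,B:0.3):0.7,((C:0.5,D:0.5):0.2,E:0.7):0.3);")
        p = tmp_path / "t.nwk"
        t.write(p)
        t2 = pm.read_tree(p)
        assert t2.to_newick() == t.to_newick()
        assert np.allclose(sorted(t2.depths()), sorted(t.depths()))

    def test_prune_merges_branches(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        sub = t.prune(["A", "C"])
        assert sorted(sub.tip_labels) == ["A", "C"]
        d = sub.depths()
        assert all(abs(d[i] - 2.0) < 1e-12 for i in sub.tip_indices)


class TestVcv:
    def test_cherry(self):
        C = Phylogeny.from_newick("(A:1,B:1);").vcv()
        assert np.allclose(C, np.eye(2))

    def test_three_tip(self):
        t = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        pc = pm.phylo_vcv(t)
        i = {lab: j for j, lab in enumerate(pc.taxa)}
        assert pc.C[i["A"], i["B"]] == pytest.approx(1.0)
        assert pc.C[i["A"], i["C"]] == pytest.approx(0.0)
        assert np.allclose(np.diag(pc.C), 2.0)

    def test_random_tree_matches_path_enumeration(self):
        """Independent oracle: explicit shared-path enumeration per tip pair."""
        t = pm.simulate_pure_birth_tree(12, seed=5)
        C = t.vcv()
        depths = t.depths()
        labels = t.tip_labels
        for a, la in enumerate(t.tip_indices):
            for b, lb in enumerate(t.tip_indices):
                pa = set(t.ancestor_path(la))
                pb = set(t.ancestor_path(lb))
                shared = pa & pb
                oracle = max(depths[i] for i in shared)
                assert C[a, b] == pytest.approx(oracle, abs=1e-12), (labels[a], labels[b])


class TestTps:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "one.tps"
        p.write_text("LM=3\n0 0\n1 0\n0 1\nID=Genus_species_1\n")
        sets = pm.read_landmarks(p)
        assert len(sets) == 1
        assert sets[0].k == 3 and sets[0].d == 2
        assert sets[0].species == "Genus_species"

    def test_roundtrip_bit_for_bit(self, tmp_path, small_sim):
        p = tmp_path / "rt.tps"
        pm.write_landmarks(small_sim.specimens, p)
        back = pm.read_landmarks(p)
        assert len(back) == len(small_sim.specimens)
        for orig, new in zip(small_sim.specimens, back):
            assert np.array_equal(orig.coords, new.coords)
            assert orig.specimen_id == new.specimen_id

    def test_inconsistent_landmark_count_names_specimen(self, tmp_path):
        p = tmp_path / "bad.tps"
        p.write_text("LM=3\n0 0\n1 0\n0 1\nID=sp_1\n"
                     "LM=4\n0 0\n1 0\n0 1\n1 1\nID=sp_2\n")
        with pytest.raises(ValueError, match="sp_2"):
            pm.read_landmarks(p)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        p = tmp_path / "bad.tps"
        p.write_text("LM=3\n0 0\n1 xx\n0 1\nID=sp_1\n")
        with pytest.raises(ValueError, match=":3"):
            pm.read_landmarks(p)

    def test_scale_lines_ignored(self, tmp_path):
        p = tmp_path / "s.tps"
        p.write_text("LM=3\n0 0\n1 0\n0 1\nIMAGE=x.jpg\nID=sp_1\nSCALE=0.01\n")
        assert len(pm.read_landmarks(p)) == 1

    def test_table_roundtrip(self, tmp_path, small_sim):
        p = tmp_path / "lm.csv"
        pm.write_landmarks(small_sim.specimens, p, format="table")
        back = pm.read_landmarks(p, format="table")
        for orig, new in zip(small_sim.specimens, back):
            assert np.array_equal(orig.coords, new.coords)
            assert orig.species == new.species


class TestModuleMap:
    def test_roundtrip_csv_and_yaml(self, tmp_path):
        mm = pm.seven_region_map()
        for name in ("m.csv", "m.yaml"):
            p = tmp_path / name
            pm.write_module_map(mm, p)
            back = pm.read_module_map(p)
            assert back.assignment == mm.assignment
            assert back.module_names == mm.module_names

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ModuleMap(["a", "a", "a"], ["a", "b"])

    def test_columns_for_3d(self):
        mm = ModuleMap(["a", "b", "a"])
        assert mm.columns("a", 3).tolist() == [0, 1, 2, 6, 7, 8]


class TestMatchTaxa:
    def _means(self, species):
        n, k, d = len(species), 4, 2
        rng = np.random.default_rng(0)
        return pm.AlignedShapes(
            coords=rng.normal(size=(n, k, d)), centroid_size=np.ones(n),
            consensus=np.zeros((k, d)), specimen_ids=list(species),
            species=list(species))

    def test_intersection(self):
        shapes = self._means(["A", "B", "C"])
        tree = Phylogeny.from_newick("((A:1,B:1):1,D:2);")
        sub, ptree, rep = pm.match_taxa(shapes, tree)
        assert sorted(sub.species) == ["A", "B"] == sorted(ptree.tip_labels)
        assert sub.species == ptree.tip_labels
        assert rep.dropped_from_shapes == ["C"]
        assert rep.dropped_from_tree == ["D"]

    def test_identity_and_idempotence(self):
        shapes = self._means(["A", "B", "C"])
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        sub, ptree, rep = pm.match_taxa(shapes, tree)
        assert rep.empty
        sub2, ptree2, rep2 = pm.match_taxa(sub, ptree)
        assert rep2.empty
        assert sub2.species == sub.species
        assert np.array_equal(sub2.coords, sub.coords)
        assert ptree2.to_newick() == ptree.to_newick()

    def test_disjoint_errors(self):
        shapes = self._means(["X", "Y"])
        tree = Phylogeny.from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="no species shared"):
            pm.match_taxa(shapes, tree)

    def test_normalization(self):
        assert normalize_taxon(" Genus species ") == "Genus_species"
        assert normalize_taxon("Genus_species") == "Genus_species"
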