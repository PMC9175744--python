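import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import pathsim_bruteforce

from netpharm.graph_io import DrugProfile, GeneSet, Interactome
from netpharm.similarity import (
    SimilarityMatrix,
    cluster_similarity,
    fingerprint_tanimoto,
    pathsim_matrix,
    sab_separation,
    structure_similarity_matrix,
)

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"
CAFFEINE = "Cn1cnc2c1c(=O)n(C)c(=O)n2C"
IBUPROFEN = "CC(C)Cc1ccc(cc1)C(C)C(=O)O"

# canonical SMILES of two depside natural products that differ only in
# stereochemistry, which the canonical strings omit — so they must compare
# as identical molecules
SALVIANOLIC_B = (
    "C1=CC(=C(C=C1CC(C(=O)O)OC(=O)C=CC2=C3C(C(OC3=C(C=C2)O)C4=CC(=C(C=C4)O)O)"
    "C(=O)OC(CC5=CC(=C(C=C5)O)O)C(=O)O)O)O"
)
SALVIANOLIC_Y = SALVIANOLIC_B


class TestTanimoto:
    def test_identical_smiles(self):
        assert fingerprint_tanimoto(ASPIRIN, ASPIRIN) == 1.0

    def test_stereo_free_isomers_identical(self):
        assert fingerprint_tanimoto(SALVIANOLIC_B, SALVIANOLIC_Y) == 1.0

    def test_methane_vs_water_zero(self):
        assert fingerprint_tanimoto("C", "O") == 0.0

    def test_unparseable_smiles_named_in_error(self):
        with pytest.raises(ValueError, match="not-a-smiles"):
            fingerprint_tanimoto("not-a-smiles", ASPIRIN)

    def test_structure_matrix_invariants(self):
        drugs = [
            DrugProfile("a", ASPIRIN),
            DrugProfile("b", CAFFEINE),
            DrugProfile("c", IBUPROFEN),
            DrugProfile("d", SALVIANOLIC_B),
            DrugProfile("e", SALVIANOLIC_Y),
        ]
        m = structure_similarity_matrix(drugs)
        assert m.values.shape == (5, 5)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert ((m.values >= 0) & (m.values <= 1)).all()
        assert m.loc("d", "e") == 1.0

    def test_duplicate_molecule_rows(self):
        m = structure_similarity_matrix(
            [DrugProfile("x", ASPIRIN), DrugProfile("y", ASPIRIN)]
        )
        assert np.allclose(m.values, 1.0)

    def test_missing_smiles_excluded_with_warning(self):
        drugs = [DrugProfile("a", ASPIRIN), DrugProfile("b", CAFFEINE),
                 DrugProfile("c", None)]
        with pytest.warns(UserWarning, match="without SMILES"):
            m = structure_similarity_matrix(drugs)
        assert m.drug_ids == ["a", "b"]

    def test_too_few_usable_drugs_rejected(self):
        with pytest.raises(ValueError):
            structure_similarity_matrix([DrugProfile("a", ASPIRIN)])


def path_interactome(n=5):
    names = [chr(ord("A") + i) for i in range(n)]
    return Interactome.from_edges(
        [(names[i], names[i + 1]) for i in range(n - 1)]
    )


class TestSabSeparation:
    def test_path_graph_endpoints(self):
        inter = path_interactome(5)
        r = sab_separation(inter, GeneSet("a", ["A"]), GeneSet("b", ["E"]))
        assert (r.d_ab, r.d_aa, r.d_bb, r.s_ab) == (4.0, 0.0, 0.0, 4.0)

    def test_identical_singletons(self):
        inter = path_interactome(3)
        r = sab_separation(inter, GeneSet("a", ["A"]), GeneSet("b", ["A"]))
        assert r.d_ab == 0.0 and r.s_ab == 0.0

    def test_triangle_overlapping_modules(self):
        # closest-distance enumeration on triangle A-B-C with {A,B},{B,C}:
        # d_AB terms: A->1, B->0, B->0, C->1 (mean 0.5); d_AA = d_BB = 1
        inter = Interactome.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
        r = sab_separation(inter, GeneSet("x", ["A", "B"]),
                           GeneSet("y", ["B", "C"]))
        assert r.d_ab == pytest.approx(0.5)
        assert r.d_aa == pytest.approx(1.0) and r.d_bb == pytest.approx(1.0)
        assert r.s_ab == pytest.approx(-0.5)
        assert r.s_ab < 0  # overlap

    def test_empty_after_intersection_rejected(self):
        with pytest.raises(ValueError):
            sab_separation(path_interactome(3), GeneSet("a", ["Z"]),
                           GeneSet("b", ["A"]))

    def test_disconnected_modules_rejected(self):
        inter = Interactome.from_edges([("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            sab_separation(inter, GeneSet("a", ["A"]), GeneSet("b", ["C"]))

    @settings(max_examples=40, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_symmetry_and_self_separation_nonpositive(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        # random connected graph: random tree plus extra edges
        edges = {(f"n{i}", f"n{int(rng.integers(i))}") for i in range(1, n)}
        for _ in range(n):
            i, j = rng.integers(n, size=2)
            if i != j:
                edges.add(tuple(sorted((f"n{i}", f"n{j}"))))
        edges = {tuple(sorted(e)) for e in edges if e[0] != e[1]}
        inter = Interactome.from_edges(sorted(edges))
        names = sorted(inter.nodes)
        a = GeneSet("a", rng.choice(names, size=min(3, n), replace=False))
        b = GeneSet("b", rng.choice(names, size=min(4, n), replace=False))
        r_ab = sab_separation(inter, a, b)
        r_ba = sab_separation(inter, b, a)
        assert r_ab.s_ab == pytest.approx(r_ba.s_ab, abs=1e-12)
        if len(a) >= 2:
            assert sab_separation(inter, a, a).s_ab <= 0


class TestPathSim:
    def test_worked_example(self):
        # c1->{t1}, c2->{t1,t2}, t1->{f1}, t2->{f1}:
        # M11=1, M22=4, M12=2 -> 2*2/(1+4) = 0.8
        drugs = [
            DrugProfile("c1", None, {"t1": -1}),
            DrugProfile("c2", None, {"t1": -1, "t2": -1}),
        ]
        ann = {"t1": {"f1"}, "t2": {"f1"}}
        m = pathsim_matrix(drugs, ann)
        assert m.loc("c1", "c2") == pytest.approx(0.8)
        assert m.loc("c1", "c1") == 1.0

    def test_disjoint_function_terms_zero(self):
        drugs = [
            DrugProfile("c1", None, {"t1": -1}),
            DrugProfile("c2", None, {"t2": -1}),
        ]
        ann = {"t1": {"f1"}, "t2": {"f2"}}
        m = pathsim_matrix(drugs, ann)
        assert m.loc("c1", "c2") == 0.0

    def test_unannotated_drug_excluded_with_warning(self):
        drugs = [
            DrugProfile("c1", None, {"t1": -1}),
            DrugProfile("c2", None, {"t9": -1}),
            DrugProfile("c3", None, {"t1": -1, "t2": -1}),
        ]
        ann = {"t1": {"f1"}, "t2": {"f2"}}
        with pytest.warns(UserWarning, match="excluded"):
            m = pathsim_matrix(drugs, ann)
        assert m.drug_ids == ["c1", "c3"]

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(10):
            n_drugs = int(rng.integers(2, 8))
            n_targets = int(rng.integers(2, 7))
            n_terms = int(rng.integers(1, 5))
            targets = {
                f"c{i}": {
                    f"t{j}" for j in rng.choice(
                        n_targets, size=int(rng.integers(1, n_targets + 1)),
                        replace=False)
                }
                for i in range(n_drugs)
            }
            ann = {
                f"t{j}": {
                    f"f{k}" for k in rng.choice(
                        n_terms, size=int(rng.integers(0, n_terms + 1)),
                        replace=False)
                }
                for j in range(n_targets)
            }
            drugs = [
                DrugProfile(c, None, {t: -1 for t in ts})
                for c, ts in targets.items()
            ]
            usable = [
                d for d in drugs
                if any(ann.get(t) for t in d.targets)
            ]
            if len(usable) < 2:
                continue
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                m = pathsim_matrix(drugs, ann)
            for a in m.drug_ids:
                for b in m.drug_ids:
                    expected = pathsim_bruteforce(targets, ann, a, b)
                    assert m.loc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_range_symmetry_unit_diagonal(self, rng):
        drugs = [
            DrugProfile(f"c{i}", None,
                        {f"t{j}": -1 for j in rng.choice(6, size=3,
                                                         replace=False)})
            for i in range(6)
        ]
        ann = {f"t{j}": {f"f{j % 3}", f"f{(j + 1) % 3}"} for j in range(6)}
        m = pathsim_matrix(drugs, ann)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert ((m.values >= 0) & (m.values <= 1)).all()


class TestClustering:
    def _block_matrix(self):
        ids = ["a", "b", "c", "x", "y"]
        v = np.zeros((5, 5))
        v[:3, :3] = 1.0
        v[3:, 3:] = 1.0
        return SimilarityMatrix(ids, v)

    def test_perfect_blocks_recovered(self):
        m = self._block_matrix()
        for linkage in ("complete", "single", "average"):
            labels = cluster_similarity(m, 2, linkage).labels
            assert labels["a"] == labels["b"] == labels["c"]
            assert labels["x"] == labels["y"]
            assert labels["a"] != labels["x"]

    def test_n_clusters_equals_n_gives_singletons(self):
        m = self._block_matrix()
        labels = cluster_similarity(m, 5).labels
        assert sorted(labels.values()) == [1, 2, 3, 4, 5]

    def test_labels_contiguous_from_one(self):
        labels = cluster_similarity(self._block_matrix(), 3).labels
        assert set(labels.values()) == {1, 2, 3}

    def test_permutation_invariance(self, rng):
        # a tie-free similarity matrix clusters identically under any
        # input ordering (up to label renaming, fixed by the contract)
        n = 6
        base = rng.random((n, n))
        sym = (base + base.T) / 2
        np.fill_diagonal(sym, 1.0)
        ids = [f"d{i}" for i in range(n)]
        m1 = SimilarityMatrix(ids, sym)
        perm = rng.permutation(n)
        m2 = SimilarityMatrix([ids[i] for i in perm], sym[np.ix_(perm, perm)])
        l1 = cluster_similarity(m1, 3).labels
        l2 = cluster_similarity(m2, 3).labels
        assert l1 == l2

    def test_agrees_with_scipy_on_tie_free_input(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        n = 7
        base = rng.random((n, n))
        sym = (base + base.T) / 2
        np.fill_diagonal(sym, 1.0)
        ids = [f"d{i}" for i in range(n)]
        m = SimilarityMatrix(ids, sym)
        ours = cluster_similarity(m, 3, "complete").labels
        z = scipy_linkage(squareform(1.0 - sym, checks=False), "complete")
        flat = fcluster(z, 3, criterion="maxclust")
        # compare partitions up to relabeling
        ours_part = {}
        scipy_part = {}
        for i, d in enumerate(ids):
            ours_part.setdefault(ours[d], set()).add(d)
            scipy_part.setdefault(int(flat[i]), set()).add(d)
        assert set(map(frozenset, ours_part.values())) == set(
            map(frozenset, scipy_part.values())
        )

    def test_invalid_n_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_similarity(self._block_matrix(), 6)
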