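"""Species delineation: distances, UPGMA vs brute force, pan-genomes."""

import itertools

import numpy as np
import pytest

from strainscope.io import SequenceRecord
from strainscope.species_db import (
    DistanceMatrix,
    MarkerGeneSet,
    aggregate_families,
    average_linkage_cluster,
    average_marker_distance,
    build_pangenome,
    consensus_name,
    evaluate_against_ani,
    family_distance_matrix,
    marker_percent_identity,
    percent_identity_to_distance,
    select_representative,
)


def _dm(ids, pairs, default_defined=True):
    """Build a DistanceMatrix from {(a, b): distance}; missing -> masked."""
    n = len(ids)
    idx = {g: i for i, g in enumerate(ids)}
    values = np.zeros((n, n))
    defined = np.eye(n, dtype=bool)
    for (a, b), d in pairs.items():
        i, j = idx[a], idx[b]
        values[i, j] = values[j, i] = d
        defined[i, j] = defined[j, i] = True
    return DistanceMatrix(list(ids), values, defined)


def brute_force_upgma(dm: DistanceMatrix, cutoff: float) -> list[frozenset]:
    """Exhaustive agglomeration oracle: merge the closest cluster pair by
    unweighted average distance until the minimum exceeds the cutoff."""
    full = np.where(dm.defined, dm.values, 1.0)
    idx = {g: i for i, g in enumerate(dm.ids)}
    clusters = [frozenset([g]) for g in dm.ids]
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([full[idx[x], idx[y]] for x in a for y in b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        if d > cutoff:
            break
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return sorted(clusters, key=min)


def _partition(assignment):
    return sorted(frozenset(m) for m in assignment.species.values())


class TestDistances:
    @pytest.mark.parametrize(
        "pid,expected", [(96.5, 0.035), (100.0, 0.0), (0.0, 1.0), (98.0, 0.02)]
    )
    def test_identity_to_distance(self, pid, expected):
        assert percent_identity_to_distance(pid) == pytest.approx(expected)

    def test_out_of_range_identity(self):
        with pytest.raises(ValueError):
            percent_identity_to_distance(101.0)

    def test_average_over_families(self):
        m1 = _dm(["a", "b"], {("a", "b"): 0.02})
        m2 = _dm(["a", "b"], {("a", "b"): 0.04})
        avg = average_marker_distance([m1, m2])
        assert avg.values[0, 1] == pytest.approx(0.03)

    def test_masked_family_excluded_from_mean(self):
        m1 = _dm(["a", "b"], {("a", "b"): 0.05})
        m2 = _dm(["a", "b"], {})  # masked
        avg = average_marker_distance([m1, m2])
        assert avg.values[0, 1] == pytest.approx(0.05)
        assert avg.defined[0, 1]

    def test_all_families_masked_stays_masked(self):
        avg = average_marker_distance([_dm(["a", "b"], {}), _dm(["a", "b"], {})])
        assert not avg.defined[0, 1]

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            average_marker_distance([])

    def test_family_matrix_from_marker_sets(self, rng):
        base = "".join(rng.choice(list("ACGT"), 400))
        near = base[:4] + ("C" if base[4] != "C" else "G") + base[5:]
        sets = [
            MarkerGeneSet("g1", {"fam01": base}),
            MarkerGeneSet("g2", {"fam01": near}),
            MarkerGeneSet("g3", {}),  # family missing
        ]
        dm = family_distance_matrix(sets, "fam01")
        assert dm.values[0, 1] == pytest.approx(1 / 400)
        assert not dm.defined[0, 2] and not dm.defined[1, 2]


class TestClustering:
    def test_three_genome_example(self):
        dm = _dm("ABC", {("A", "B"): 0.01, ("A", "C"): 0.05, ("B", "C"): 0.05})
        assignment = average_linkage_cluster(dm, 0.035)
        assert _partition(assignment) == [frozenset("AB"), frozenset("C")]

    def test_all_far_apart_singletons(self):
        dm = _dm("ABC", {("A", "B"): 0.5, ("A", "C"): 0.5, ("B", "C"): 0.5})
        assert average_linkage_cluster(dm, 0.035).n_species() == 3

    def test_all_identical_one_species(self):
        dm = _dm("ABC", {("A", "B"): 0.0, ("A", "C"): 0.0, ("B", "C"): 0.0})
        assert average_linkage_cluster(dm, 0.035).n_species() == 1

    def test_no_genomes_rejected(self):
        with pytest.raises(ValueError):
            average_linkage_cluster(DistanceMatrix([], np.zeros((0, 0)), np.zeros((0, 0), bool)), 0.1)

    def test_masked_pairs_never_merge_alone(self):
        dm = _dm("AB", {})  # distance unknown -> treated as 1.0
        assert average_linkage_cluster(dm, 0.5).n_species() == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_brute_force_agglomeration(self, seed, n):
        local = np.random.default_rng(seed)
        vals = local.uniform(0, 0.08, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"g{i}" for i in range(n)]
        dm = DistanceMatrix(ids, vals, np.ones((n, n), bool))
        got = _partition(average_linkage_cluster(dm, 0.035))
        expected = brute_force_upgma(dm, 0.035)
        assert got == expected

    def test_invariant_to_input_order(self, rng):
        n = 7
        vals = rng.uniform(0, 0.08, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        ids = [f"g{i}" for i in range(n)]
        dm = DistanceMatrix(ids, vals, np.ones((n, n), bool))
        base = average_linkage_cluster(dm, 0.04).genome_to_species
        perm = rng.permutation(n)
        dm2 = DistanceMatrix(
            [ids[i] for i in perm], vals[np.ix_(perm, perm)], np.ones((n, n), bool)
        )
        assert average_linkage_cluster(dm2, 0.04).genome_to_species == base

    def test_raising_cutoff_never_adds_species(self, rng):
        n = 8
        vals = rng.uniform(0, 0.1, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dm = DistanceMatrix([f"g{i}" for i in range(n)], vals, np.ones((n, n), bool))
        counts = [
            average_linkage_cluster(dm, c).n_species() for c in (0.01, 0.03, 0.05, 0.08, 0.2)
        ]
        assert counts == sorted(counts, reverse=True)


class TestAniValidation:
    def test_perfect_agreement(self):
        dm = _dm("ABCD", {("A", "B"): 0.01, ("C", "D"): 0.01})
        assignment = average_linkage_cluster(dm, 0.035)
        labels = [("A", "B", 99.0), ("C", "D", 98.0), ("A", "C", 80.0), ("B", "D", 80.0)]
        m = evaluate_against_ani(assignment, labels)
        assert (m["TPR"], m["PPV"], m["F1"]) == (1.0, 1.0, 1.0)

    def test_formula_tp8_fp2(self):
        # single cluster of 5 genomes -> C(5,2) = 10 clustered pairs
        dm = _dm("ABCDE", {p: 0.0 for p in itertools.combinations("ABCDE", 2)})
        assignment = average_linkage_cluster(dm, 0.035)
        pairs = list(itertools.combinations("ABCDE", 2))
        labels = [(a, b, 99.0) for a, b in pairs[:8]] + [(a, b, 90.0) for a, b in pairs[8:]]
        m = evaluate_against_ani(assignment, labels)
        assert (m["TP"], m["FP"], m["FN"]) == (8, 2, 0)
        assert m["TPR"] == 1.0 and m["PPV"] == pytest.approx(0.8)
        assert m["F1"] == pytest.approx(2 * 1.0 * 0.8 / 1.8)

    def test_all_split_all_positive(self):
        dm = _dm("AB", {("A", "B"): 0.9})
        assignment = average_linkage_cluster(dm, 0.035)
        m = evaluate_against_ani(assignment, [("A", "B", 99.0)])
        assert m["TPR"] == 0.0 and m["F1"] == 0.0

    def test_no_labels_rejected(self):
        dm = _dm("AB", {("A", "B"): 0.9})
        with pytest.raises(ValueError):
            evaluate_against_ani(average_linkage_cluster(dm, 0.035), [])


class TestRepresentativeAndNaming:
    def test_singleton_is_itself(self):
        dm = _dm(["A"], {})
        assert select_representative(["A"], dm) == "A"

    def test_argmax_mean_identity(self):
        dm = _dm(
            "ABC",
            {("A", "B"): 0.010, ("B", "C"): 0.010, ("A", "C"): 0.030},
        )
        # B has the smallest mean distance (0.010) to the others
        assert select_representative(["A", "B", "C"], dm) == "B"

    def test_tie_breaks_lexicographically(self):
        dm = _dm("AB", {("A", "B"): 0.02})
        assert select_representative(["B", "A"], dm) == "A"

    def test_consensus_name_mode(self):
        assert consensus_name(["X", "X", "Y"], "s1") == "X"

    def test_consensus_name_all_empty(self):
        assert consensus_name(["", ""], "s1") == "unnamed_s1"

    def test_consensus_name_tie_lexicographic(self):
        assert consensus_name(["Y", "X"], "s1") == "X"


class TestPanGenome:
    def test_identical_genes_one_cluster(self):
        genes = [("g1|a", "g1", "ACGT" * 50), ("g2|a", "g2", "ACGT" * 50)]
        pg = build_pangenome(genes, "s1")
        assert len(pg.clusters) == 1 and sorted(pg.clusters[0].members) == ["g1|a", "g2|a"]

    def test_diverged_genes_split(self, rng):
        a = "".join(rng.choice(list("ACGT"), 300))
        b = list(a)
        for pos in rng.choice(300, 15, replace=False):  # 95% identity
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        pg = build_pangenome([("g1|a", "g1", a), ("g2|a", "g2", "".join(b))], "s1")
        assert len(pg.clusters) == 2

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            build_pangenome([], "s1")

    def test_recovers_original_gene_count(self, rng):
        """Genes simulated from 10 originals at <=0.5% mutation cluster
        back into exactly 10 clusters at 99% identity."""
        originals = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(10)]
        genes = []
        for i in range(100):
            src = i % 10
            seq = list(originals[src])
            for pos in rng.choice(400, rng.integers(0, 3), replace=False):  # <=0.5%
                seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            genes.append((f"g{i:03d}", f"genome{i % 7}", "".join(seq)))
        pg = build_pangenome(genes, "s1")
        assert len(pg.clusters) == 10
        assert sum(len(c.members) for c in pg.clusters) == 100

    def test_every_gene_in_exactly_one_cluster(self, small_species_set):
        sp = small_species_set.species[0]
        pg = small_species_set.pangenome(sp)
        members = [m for c in pg.clusters for m in c.members]
        assert len(members) == len(set(members))
        n_genes = sum(len(st.gene_indices) for st in sp.strains)
        assert len(members) == n_genes

    def test_uscg_clusters_flagged(self, small_species_set):
        sp = small_species_set.species[0]
        pg = small_species_set.pangenome(sp)
        assert set(pg.uscg_families.values()) == set(
            small_species_set.marker_family_ids[: len(sp.abundance_indices)]
        )


class TestAggregation:
    def test_invalid_level_rejected(self, small_species_set):
        pg = small_species_set.pangenome(small_species_set.species[0])
        with pytest.raises(ValueError):
            aggregate_families(pg, 88)

    def test_coarse_families_are_unions_of_fine(self, small_species_set):
        pg = small_species_set.pangenome(small_species_set.species[0])
        fine = aggregate_families(pg, 95)
        coarse = aggregate_families(pg, 75)
        # clusters sharing a 95% family must share the 75% family
        by_fine: dict[str, set[str]] = {}
        for cid, fam in fine.items():
            by_fine.setdefault(fam, set()).add(coarse[cid])
        assert all(len(v) == 1 for v in by_fine.values())

    def test_every_cluster_mapped(self, small_species_set):
        pg = small_species_set.pangenome(small_species_set.species[0])
        mapping = aggregate_families(pg, 90)
        assert set(mapping) == set(pg.cluster_ids)
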