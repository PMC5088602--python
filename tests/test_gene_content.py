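"""Gene content: coverage, USCG normalizer, copy number, presence, merge."""

import numpy as np
import pandas as pd
import pytest

from strainscope.gene_content import (
    aggregate_coverage,
    centroid_records,
    copy_number,
    gene_coverage,
    jaccard_distance,
    jaccard_matrix,
    merge_gene_content,
    presence_absence,
    profile_gene_content,
    uscg_normalizer,
)
from strainscope.simulate import simulate_reads
from strainscope.species_db import aggregate_families


@pytest.fixture(scope="module")
def species_and_pg(small_species_set):
    sp = small_species_set.species[0]
    return sp, small_species_set.pangenome(sp)


@pytest.fixture(scope="module")
def profiled(species_and_pg):
    """Strain 0 sequenced at 10x, 1% error, profiled against its pan-genome."""
    sp, pg = species_and_pg
    reads, _ = simulate_reads(
        [(sp.strains[0].genome, 1.0)], total_coverage=10.0, error_rate=0.01, seed=8
    )
    return profile_gene_content(reads, pg)


class TestNormalizer:
    def test_median_of_equal_families(self, species_and_pg):
        _, pg = species_and_pg
        fams = sorted(set(pg.uscg_families.values()))
        cov = pd.Series(0.0, index=pg.cluster_ids)
        for cid, fam in pg.uscg_families.items():
            cov[cid] = 0.0
        # put 8x on exactly one cluster of each family
        seen = set()
        for cid, fam in sorted(pg.uscg_families.items()):
            if fam not in seen:
                cov[cid] = 8.0
                seen.add(fam)
        assert uscg_normalizer(cov, pg) == pytest.approx(8.0)

    def test_mostly_absent_families_zero_median(self, species_and_pg):
        _, pg = species_and_pg
        cov = pd.Series(0.0, index=pg.cluster_ids)
        one_cluster = sorted(pg.uscg_families)[0]
        cov[one_cluster] = 8.0  # 1 family at 8x, 14 at 0
        assert uscg_normalizer(cov, pg) == 0.0

    def test_middle_order_statistic(self, species_and_pg):
        _, pg = species_and_pg
        fams = sorted(set(pg.uscg_families.values()))
        values = {fam: 6.0 + i for i, fam in enumerate(fams)}  # 6..20
        cov = pd.Series(0.0, index=pg.cluster_ids)
        seen = set()
        for cid, fam in sorted(pg.uscg_families.items()):
            if fam not in seen:
                cov[cid] = values[fam]
                seen.add(fam)
        assert uscg_normalizer(cov, pg) == sorted(values.values())[len(fams) // 2]


class TestCopyNumberAndPresence:
    def test_ratio(self):
        cn = copy_number(pd.Series({"g": 4.0}), 8.0)
        assert cn["g"] == pytest.approx(0.5)

    def test_zero_coverage(self):
        assert copy_number(pd.Series({"g": 0.0}), 8.0)["g"] == 0.0

    @pytest.mark.parametrize("cn,present", [(0.34, False), (0.35, True), (0.0, False)])
    def test_presence_boundary(self, cn, present):
        assert presence_absence(pd.Series({"g": cn}))["g"] == present

    def test_uscg_copy_number_near_one(self, small_species_set):
        """Against an unfragmented (single-genome) pan-genome, every USCG
        family of a single-strain species at 40x estimates ~1 copy/cell
        (at lower depth, positional sampling noise on 500-bp genes
        exceeds the 0.2 band)."""
        sp = small_species_set.species[1]
        st = sp.strains[0]
        fam_of = dict(
            zip(sp.abundance_indices,
                small_species_set.marker_family_ids[: len(sp.abundance_indices)])
        )
        genes, marker_families = [], {}
        for idx in st.gene_indices:
            gid = f"{st.genome_id}|g{idx:03d}"
            genes.append((gid, st.genome_id, st.gene_seqs[idx]))
            if idx in fam_of:
                marker_families[gid] = fam_of[idx]
        from strainscope.species_db import build_pangenome

        pg = build_pangenome(genes, sp.species_id, marker_families=marker_families)
        assert len(pg.clusters) == len(st.gene_indices)  # no 99% splits
        reads, _ = simulate_reads([(st.genome, 1.0)], total_coverage=40.0, seed=31)
        result = profile_gene_content(reads, pg)
        cn = result.table.loc[sorted(pg.uscg_families), "copy_number"]
        assert np.all(np.abs(cn.values - 1.0) <= 0.2)

    def test_uscg_family_copy_number_multi_strain(self, profiled, species_and_pg):
        """With a multi-strain pan-genome, tie discards between a family's
        split 99% clusters spread the per-family estimates, but the median
        family stays exactly 1 (it defines the normalizer)."""
        _, pg = species_and_pg
        fam_cn: dict[str, float] = {}
        for cid, fam in pg.uscg_families.items():
            fam_cn[fam] = fam_cn.get(fam, 0.0) + profiled.table.loc[cid, "copy_number"]
        values = np.array(list(fam_cn.values()))
        assert np.median(values) == pytest.approx(1.0)
        assert np.all(np.abs(values - 1.0) <= 0.5)

    def test_gene_coverage_arithmetic(self, species_and_pg):
        """One 100-bp read fully aligned on a centroid contributes
        100 / centroid_length fold coverage."""
        sp, pg = species_and_pg
        from strainscope.mapper import map_reads
        from strainscope.io import ReadRecord

        cl = pg.clusters[0]
        read = ReadRecord("r", cl.centroid_seq[:100], np.full(100, 38, dtype=np.int16))
        alns = map_reads([read], centroid_records(pg), mode="local")
        kept = [a for a in alns if a.target_id == cl.cluster_id]
        cov = gene_coverage(kept, pg)
        assert cov[cl.cluster_id] == pytest.approx(100 / cl.length)
        assert (cov.drop(cl.cluster_id) == 0).all()

    def test_true_coverage_recovered(self, species_and_pg):
        """Strain genes at a true 5x come out near 5x."""
        sp, pg = species_and_pg
        reads, _ = simulate_reads(
            [(sp.strains[0].genome, 1.0)], total_coverage=5.0, error_rate=0.0, seed=12
        )
        result = profile_gene_content(reads, pg)
        # compare summed coverage over each USCG family (robust to cluster splits)
        fam_cov: dict[str, float] = {}
        for cid, fam in pg.uscg_families.items():
            fam_cov[fam] = fam_cov.get(fam, 0.0) + result.table.loc[cid, "coverage"]
        med = np.median(list(fam_cov.values()))
        assert med == pytest.approx(5.0, rel=0.25)


class TestAggregation:
    def test_sum_of_members(self):
        cov = pd.Series({"c1": 2.0, "c2": 3.0})
        agg = aggregate_coverage(cov, {"c1": "f1", "c2": "f1"})
        assert agg["f1"] == pytest.approx(5.0)

    def test_singleton_family_unchanged(self):
        agg = aggregate_coverage(pd.Series({"c1": 1.5}), {"c1": "f1"})
        assert agg["f1"] == 1.5

    def test_total_coverage_conserved(self, profiled, species_and_pg):
        _, pg = species_and_pg
        for level in (75, 95):
            fam_map = aggregate_families(pg, level)
            agg = aggregate_coverage(profiled.table["coverage"], fam_map)
            assert agg.sum() == pytest.approx(profiled.table["coverage"].sum())

    def test_unmapped_cluster_rejected(self):
        with pytest.raises(ValueError):
            aggregate_coverage(pd.Series({"c1": 1.0, "c2": 1.0}), {"c1": "f1"})


class TestMergeAndJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 0.0),
            ({"x"}, {"y"}, 1.0),
            (set("abcdefgh"), set("abcdefgh") | {"i", "j"}, 0.2),
        ],
    )
    def test_jaccard_values(self, a, b, expected):
        assert jaccard_distance(a, b) == pytest.approx(expected)

    def test_jaccard_both_empty_undefined(self):
        assert jaccard_distance(set(), set()) is None

    def test_merge_two_samples(self, species_and_pg):
        sp, pg = species_and_pg
        results = {}
        for i, seed in enumerate((21, 22)):
            reads, _ = simulate_reads(
                [(sp.strains[0].genome, 1.0)], total_coverage=8.0, seed=seed
            )
            results[f"s{i}"] = profile_gene_content(reads, pg)
        m = merge_gene_content(results)
        assert list(m.presence.columns) == ["s0", "s1"]
        assert m.coverage.shape == (len(pg.clusters), 2)
        jm = jaccard_matrix(m)
        assert jm.loc["s0", "s0"] == 0.0
        # same strain twice: near-identical presence sets
        assert jm.loc["s0", "s1"] < 0.05

    def test_merge_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_gene_content({})
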