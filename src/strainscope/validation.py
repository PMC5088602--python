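"""End-to-end benchmark experiments on synthetic mock metagenomes.

Each experiment regenerates its inputs from a seed, runs the relevant
pipeline stage, and scores the output against the simulator's ground
truth: species-abundance recovery (pooled r^2), gene presence/absence
(balanced accuracy at the 0.35 copy-number cutoff, plus a cutoff sweep),
species delineation (pairwise F1 at distance cutoff 0.035), consensus
SNP calling (TPR / FDR), and transmission classification on technical-
replicate and unrelated-pair controls (sensitivity / specificity at the
5% sharing cutoff).

Problem sizes default to desk scale: tens of kilobase genomes and a few
dozen genomes per experiment, chosen so the full benchmark suite runs in
minutes on one core while preserving the coverage regimes (exponential
abundances from 50x down to fractions of 1x) that drive the published
validation figures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import profile_species
from .config import RunConfig
from .gene_content import centroid_records, copy_number, gene_coverage, uscg_normalizer
from .mapper import ReferenceIndex, filter_alignments, map_reads
from .metrics import MetricsReport, classification_metrics, pair_f1, r_squared
from .simulate import exponential_abundances, simulate_reads, simulate_species_set
from .snps import consensus_snp_calls, pileup_sample
from .species_db import average_linkage_cluster, average_marker_distance, family_distance_matrix
from .transmission import (
    SharingResult,
    allele_sharing,
    classify_transmission,
    detect_alleles,
    find_marker_alleles,
)

COPYNUM_SWEEP = tuple(round(0.05 * k, 2) for k in range(1, 20))  # 0.05 .. 0.95


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-component integer seeds below 2^31."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# species abundance recovery (mock-community benchmark)


@dataclass
class AbundanceBenchmark:
    r2: float
    pairs: pd.DataFrame          # community, species, truth, estimate
    r2_coverage: float


def abundance_recovery_experiment(
    seed: int,
    n_communities: int = 20,
    n_species: int = 20,
    total_coverage: float = 100.0,
    error_rate: float = 0.01,
) -> AbundanceBenchmark:
    """Profile mock communities with exponentially decreasing abundances
    and pool (true, estimated) relative abundances across communities."""
    seeds = _child_seeds(seed, n_communities + 1)
    sset = simulate_species_set(seeds[0], n_species=n_species, n_strains_per_species=1)
    db = sset.marker_db(strain_index=0)
    index = ReferenceIndex(db.genes)
    genomes = {sp.species_id: sp.strains[0].genome for sp in sset.species}
    species_ids = sorted(genomes)
    rows = []
    for c in range(n_communities):
        rng = np.random.default_rng(seeds[c + 1])
        order = list(rng.permutation(species_ids))
        abund = exponential_abundances(n_species)
        members = [(genomes[sp], float(a)) for sp, a in zip(order, abund)]
        reads, _ = simulate_reads(
            members,
            total_coverage=total_coverage,
            error_rate=error_rate,
            seed=seeds[c + 1],
            id_prefix=f"c{c:02d}",
        )
        profile = profile_species(reads, db, index=index)
        truth = dict(zip(order, abund))
        for sp in species_ids:
            rows.append(
                {
                    "community": f"c{c:02d}",
                    "species_id": sp,
                    "true_abundance": truth[sp],
                    "est_abundance": float(profile.table.loc[sp, "relative_abundance"]),
                    "true_coverage": total_coverage * truth[sp],
                    "est_coverage": float(profile.table.loc[sp, "coverage"]),
                }
            )
    pairs = pd.DataFrame(rows)
    return AbundanceBenchmark(
        r2=r_squared(pairs["true_abundance"].values, pairs["est_abundance"].values),
        pairs=pairs,
        r2_coverage=r_squared(pairs["true_coverage"].values, pairs["est_coverage"].values),
    )


# ---------------------------------------------------------------------------
# gene presence/absence (strain vs pan-genome benchmark)


@dataclass
class GeneContentBenchmark:
    balanced_accuracy: float
    report: MetricsReport
    sweep: dict[float, float]            # cutoff -> pooled balanced accuracy (>3x species)
    per_species: pd.DataFrame


def gene_content_experiment(
    seed: int,
    n_communities: int = 3,
    n_species: int = 8,
    n_strains_per_species: int = 3,
    total_coverage: float = 100.0,
    error_rate: float = 0.01,
    min_true_coverage: float = 3.0,
    config: RunConfig | None = None,
) -> GeneContentBenchmark:
    """Predict strain gene content against species pan-genomes.

    Exponential abundances spread the species over coverage tiers from
    ~50x down to well below 1x; accuracy is scored for species whose true
    coverage exceeds ``min_true_coverage`` and the copy-number cutoff is
    swept to verify the 0.35 default sits on the optimum plateau.
    """
    cfg = config or RunConfig()
    seeds = _child_seeds(seed, n_communities + 1)
    sset = simulate_species_set(
        seeds[0], n_species=n_species, n_strains_per_species=n_strains_per_species
    )
    pangenomes = {sp.species_id: sset.pangenome(sp) for sp in sset.species}
    all_centroids = [rec for pg in pangenomes.values() for rec in centroid_records(pg)]
    index = ReferenceIndex(all_centroids)
    cluster_species = {
        c.cluster_id: sid for sid, pg in pangenomes.items() for c in pg.clusters
    }
    species_ids = sorted(pangenomes)
    counts: dict[float, np.ndarray] = {c: np.zeros(4, dtype=int) for c in COPYNUM_SWEEP}
    default_counts = np.zeros(4, dtype=int)  # tp, fp, fn, tn at the configured cutoff
    per_species_rows = []
    for c in range(n_communities):
        rng = np.random.default_rng(seeds[c + 1])
        order = list(rng.permutation(species_ids))
        abund = exponential_abundances(n_species)
        truth_cov = dict(zip(order, total_coverage * abund))
        members = [
            (sset.species[species_ids.index(sp)].strains[0].genome, float(a))
            for sp, a in zip(order, abund)
        ]
        reads, _ = simulate_reads(
            members, total_coverage, error_rate=error_rate, seed=seeds[c + 1],
            id_prefix=f"g{c}",
        )
        alignments = map_reads(reads, index, mode="local")
        kept = filter_alignments(
            alignments, cfg.map_pid, cfg.aln_cov, cfg.mapq_min, cfg.read_qual_min
        )
        by_species: dict[str, list] = {sid: [] for sid in species_ids}
        for a in kept:
            by_species[cluster_species[a.target_id]].append(a)
        for sp in species_ids:
            if truth_cov[sp] <= min_true_coverage:
                continue
            pg = pangenomes[sp]
            cov = gene_coverage(by_species[sp], pg)
            norm = uscg_normalizer(cov, pg)
            if norm <= 0:
                continue
            cn = copy_number(cov, norm)
            strain_id = sset.species[species_ids.index(sp)].strains[0].genome_id
            truth = sset.true_gene_presence(pg, strain_id)
            universe = set(pg.cluster_ids)
            for cutoff in COPYNUM_SWEEP:
                rep = classification_metrics(
                    set(cn.index[cn >= cutoff]), truth, universe
                )
                counts[cutoff] += (rep.tp, rep.fp, rep.fn, rep.tn)
            rep = classification_metrics(
                set(cn.index[cn >= cfg.copynum_cutoff]), truth, universe
            )
            default_counts += (rep.tp, rep.fp, rep.fn, rep.tn)
            per_species_rows.append(
                {
                    "community": f"g{c}",
                    "species_id": sp,
                    "true_coverage": truth_cov[sp],
                    "normalizer": norm,
                    "balanced_accuracy": rep.balanced_accuracy,
                }
            )
    pooled = MetricsReport(*map(int, default_counts))
    sweep = {
        cutoff: MetricsReport(*map(int, v)).balanced_accuracy for cutoff, v in counts.items()
    }
    return GeneContentBenchmark(
        balanced_accuracy=pooled.balanced_accuracy,
        report=pooled,
        sweep=sweep,
        per_species=pd.DataFrame(per_species_rows),
    )


# ---------------------------------------------------------------------------
# species delineation (marker-distance clustering benchmark)


@dataclass
class ClusteringBenchmark:
    f1: float
    report: MetricsReport
    n_species_found: int


def clustering_experiment(
    seed: int,
    n_species: int = 25,
    n_strains_per_species: int = 8,
    cutoff: float = 0.035,
    n_families: int = 30,
) -> ClusteringBenchmark:
    """Cluster synthetic genomes on averaged marker distances and score
    clustered/split pairs against the generating partition."""
    sset = simulate_species_set(
        seed, n_species=n_species, n_strains_per_species=n_strains_per_species
    )
    marker_sets = sset.marker_gene_sets()
    families = sset.marker_family_ids[:n_families]
    matrices = [family_distance_matrix(marker_sets, fam) for fam in families]
    avg = average_marker_distance(matrices)
    assignment = average_linkage_cluster(avg, cutoff)
    report = pair_f1(assignment.genome_to_species, sset.true_partition())
    return ClusteringBenchmark(report.f1, report, assignment.n_species())


# ---------------------------------------------------------------------------
# consensus SNP calling benchmark


@dataclass
class SnpBenchmark:
    tpr: float
    fdr: float
    report: MetricsReport


def snp_calling_experiment(
    seed: int,
    coverage: float = 20.0,
    error_rate: float = 0.005,
    config: RunConfig | None = None,
) -> SnpBenchmark:
    """Call consensus SNPs for one strain against its species
    representative and score against the true substitution set."""
    cfg = config or RunConfig()
    sset = simulate_species_set(seed, n_species=1, n_strains_per_species=2)
    sp = sset.species[0]
    rep, strain = sp.strains[0], sp.strains[1]
    reads, _ = simulate_reads(
        [(strain.genome, 1.0)], total_coverage=coverage, error_rate=error_rate,
        seed=_child_seeds(seed, 1)[0], id_prefix="snp",
    )
    pile = pileup_sample(reads, rep.genome, species_id=sp.species_id, config=cfg)
    calls = consensus_snp_calls(pile)
    truth = sset.true_snps(sp, strain.genome_id, rep.genome_id)
    universe = {(rep.genome_id, p, b) for p in range(len(rep.genome)) for b in "ACGT"}
    rep_metrics = classification_metrics(calls, truth, universe)
    return SnpBenchmark(rep_metrics.sensitivity, rep_metrics.fdr, rep_metrics)


# ---------------------------------------------------------------------------
# transmission controls (replicate / unrelated pairs benchmark)


@dataclass
class TransmissionBenchmark:
    sensitivity: float
    specificity: float
    n_replicate_pairs: int
    n_unrelated_pairs: int
    replicate_results: list[SharingResult] = field(default_factory=list)
    unrelated_results: list[SharingResult] = field(default_factory=list)


def transmission_experiment(
    seed: int,
    n_units: int = 30,
    coverage: float = 20.0,
    error_rate: float = 0.01,
    config: RunConfig | None = None,
) -> TransmissionBenchmark:
    """Technical-replicate and unrelated-pair controls for the marker-
    allele transmission classifier.

    A cohort of ``n_units`` units each carries a distinct strain of one
    species; every unit is sequenced twice (independent read samplings at
    ``coverage`` fold). Marker alleles are discovered cohort-wide, then
    replicate pairs (positives) and all unrelated unit pairs (negatives)
    are classified at the 5% sharing cutoff.
    """
    cfg = config or RunConfig()
    sset = simulate_species_set(
        seed, n_species=1, n_strains_per_species=n_units + 1
    )
    sp = sset.species[0]
    rep = sp.strains[n_units]          # representative held out of the cohort
    index = ReferenceIndex([rep.genome])
    seeds = _child_seeds(seed, 2 * n_units)
    presence = {}
    unit_map = {}
    for u in range(n_units):
        strain = sp.strains[u]
        for r in (1, 2):
            sample_id = f"u{u:02d}_r{r}"
            reads, _ = simulate_reads(
                [(strain.genome, 1.0)],
                total_coverage=coverage,
                error_rate=error_rate,
                seed=seeds[2 * u + r - 1],
                id_prefix=sample_id,
            )
            pile = pileup_sample(reads, rep.genome, species_id=sp.species_id, config=cfg, index=index)
            presence[sample_id] = detect_alleles(
                pile, sample_id, cfg.allele_min_reads, cfg.allele_min_freq
            )
            unit_map[sample_id] = f"u{u:02d}"
    markers = find_marker_alleles(presence, unit_map, sp.species_id)

    replicate_results, unrelated_results = [], []
    tp = fn = 0
    for u in range(n_units):
        res = allele_sharing(
            markers[f"u{u:02d}"], presence[f"u{u:02d}_r2"], cfg.marker_min_count
        )
        replicate_results.append(res)
        if not res.excluded:
            if classify_transmission(res, cfg.transmission_cutoff):
                tp += 1
            else:
                fn += 1
    tn = fp = 0
    for u in range(n_units):
        for v in range(u + 1, n_units):
            res = allele_sharing(
                markers[f"u{u:02d}"], presence[f"u{v:02d}_r1"], cfg.marker_min_count
            )
            unrelated_results.append(res)
            if not res.excluded:
                if classify_transmission(res, cfg.transmission_cutoff):
                    fp += 1
                else:
                    tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return TransmissionBenchmark(
        sens, spec, tp + fn, tn + fp, replicate_results, unrelated_results
    )
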