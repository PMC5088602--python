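"""Synthetic species databases, strain genomes, and mock metagenomes.

The generator emulates the benchmark design used to validate the
pipeline: mock communities of 20 organisms with exponentially decreasing
relative abundance (50%, 25%, 12.5%, 6.25%, ...), sequenced as 100-bp
reads at 100x total genome coverage with ~1% substitution error.

Each synthetic species descends from a shared base gene pool so that
between-species marker divergence is controlled (default 5% per-species
mutation, ~10% pairwise); strains within a species carry point mutations
bounded so that pairwise within-species divergence stays at or below 2%.
A strain genome is the concatenation of its genes: all core genes (the
first 30 of which are the clustering marker panel, the first 15 the
single-copy abundance panel) plus a random subset of the species'
accessory pool (30% of the gene pool by default). Substitution-only
mutation keeps every strain colinear with its species mates gene by
gene, which makes gene-content and SNP ground truth exact.

All randomness flows through numpy Generators seeded from a single
integer, so a fixed seed reproduces every sequence byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import MarkerDb
from .io import ReadRecord, SequenceRecord
from .species_db import MarkerGeneSet, PanGenome, build_pangenome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}


def exponential_abundances(n: int = 20) -> np.ndarray:
    """Relative abundances proportional to 2^-i, normalized to sum to 1
    (50%, 25%, 12.5%, 6.25%, ... for n = 20)."""
    if n < 1:
        raise ValueError("need at least one community member")
    a = 0.5 ** np.arange(1, n + 1)
    return a / a.sum()


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _decode(codes: np.ndarray) -> str:
    return codes.tobytes().decode()


def _random_gene(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a
    different base). Returns a new array."""
    out = codes.copy()
    hits = np.flatnonzero(rng.random(len(codes)) < rate)
    if len(hits):
        cur = np.searchsorted(_BASES, out[hits])  # codes are sorted ACGT bytes
        shift = rng.integers(1, 4, len(hits))
        out[hits] = _BASES[(cur + shift) % 4]
    return out


@dataclass
class QualityModel:
    """Phred qualities: correct bases high, errored bases biased low so
    that both the mean-quality (20) and per-base (30) filters have bite."""

    correct_lo: int = 30
    correct_hi: int = 40
    error_lo: int = 2
    error_hi: int = 35


@dataclass
class SyntheticStrain:
    genome_id: str
    species_id: str
    divergence: float                     # per-base mutation rate vs species ancestor
    gene_indices: list[int]               # pool indices present, in genome order
    gene_seqs: dict[int, str]             # pool index -> this strain's gene sequence
    gene_coords: dict[int, tuple[int, int]]  # pool index -> genome span

    @property
    def genome(self) -> SequenceRecord:
        seq = "".join(self.gene_seqs[i] for i in self.gene_indices)
        return SequenceRecord(self.genome_id, seq)


@dataclass
class SyntheticSpecies:
    species_id: str
    pool: list[str]                       # ancestral gene sequences
    core_indices: list[int]
    accessory_indices: list[int]
    marker_indices: list[int]             # clustering markers (subset of core)
    abundance_indices: list[int]          # abundance USCG panel (subset of markers)
    strains: list[SyntheticStrain]

    def strain(self, genome_id: str) -> SyntheticStrain:
        for s in self.strains:
            if s.genome_id == genome_id:
                return s
        raise KeyError(genome_id)


@dataclass
class SpeciesSet:
    """A synthetic reference universe with complete ground truth."""

    species: list[SyntheticSpecies]
    seed: int
    marker_family_ids: list[str]

    # ---- truth views -----------------------------------------------------
    def true_partition(self) -> dict[str, str]:
        return {s.genome_id: sp.species_id for sp in self.species for s in sp.strains}

    def marker_gene_sets(self) -> list[MarkerGeneSet]:
        """Per-genome clustering-marker sequences (family -> sequence)."""
        out = []
        for sp in self.species:
            for st in sp.strains:
                genes = {
                    fam: st.gene_seqs[idx]
                    for fam, idx in zip(self.marker_family_ids, sp.marker_indices)
                }
                out.append(MarkerGeneSet(st.genome_id, genes))
        return out

    # ---- database views --------------------------------------------------
    def marker_db(self, strain_index: int = 0, default_cutoff: float = 95.0) -> MarkerDb:
        """Abundance-panel marker database built from one strain per species."""
        records = []
        n_abund = len(self.species[0].abundance_indices)
        for sp in self.species:
            st = sp.strains[strain_index]
            for fam, idx in zip(self.marker_family_ids[:n_abund], sp.abundance_indices):
                records.append(SequenceRecord(f"{sp.species_id}|{fam}", st.gene_seqs[idx]))
        return MarkerDb.from_records(records, default_cutoff=default_cutoff)

    def pangenome(self, species: SyntheticSpecies, identity: float = 99.0) -> PanGenome:
        """99%-identity pan-genome over all member strains' genes, with
        abundance-panel clusters flagged as USCGs."""
        genes = []
        marker_families: dict[str, str] = {}
        n_abund = len(species.abundance_indices)
        fam_of = dict(zip(species.abundance_indices, self.marker_family_ids[:n_abund]))
        for st in species.strains:
            for idx in st.gene_indices:
                gid = f"{st.genome_id}|g{idx:03d}"
                genes.append((gid, st.genome_id, st.gene_seqs[idx]))
                if idx in fam_of:
                    marker_families[gid] = fam_of[idx]
        return build_pangenome(genes, species.species_id, identity, marker_families)

    def true_gene_presence(self, pangenome: PanGenome, genome_id: str) -> set[str]:
        """Cluster ids holding at least one gene of the given strain."""
        return {
            cl.cluster_id
            for cl in pangenome.clusters
            if any(pangenome.gene_origin[m] == genome_id for m in cl.members)
        }

    def true_snps(
        self, species: SyntheticSpecies, strain_id: str, reference_id: str
    ) -> set[tuple[str, int, str]]:
        """Strain-vs-reference substitutions, in reference coordinates,
        over genes present in both genomes."""
        st = species.strain(strain_id)
        ref = species.strain(reference_id)
        snps: set[tuple[str, int, str]] = set()
        for idx in st.gene_indices:
            if idx not in ref.gene_seqs:
                continue
            a = _encode(st.gene_seqs[idx])
            b = _encode(ref.gene_seqs[idx])
            start, _end = ref.gene_coords[idx]
            for off in np.flatnonzero(a != b):
                snps.add((reference_id, start + int(off), chr(a[off])))
        return snps


def simulate_species_set(
    seed: int,
    n_species: int = 20,
    n_strains_per_species: int = 3,
    n_core_genes: int = 42,
    n_accessory_genes: int = 18,
    gene_len: int = 500,
    n_clustering_markers: int = 30,
    n_abundance_markers: int = 15,
    within_divergence: float = 0.02,
    between_divergence: float = 0.05,
    accessory_retention: float = 0.5,
) -> SpeciesSet:
    """Generate a synthetic reference universe with ground truth.

    ``within_divergence`` bounds the pairwise divergence between strains
    of one species (each strain mutates at up to half of it);
    ``between_divergence`` is the per-species mutation rate away from the
    shared base pool, giving roughly twice that divergence between any
    two species. The bands must not overlap.
    """
    if between_divergence <= within_divergence:
        raise ValueError(
            f"divergence bands overlap: between {between_divergence} "
            f"must exceed within {within_divergence}"
        )
    if n_clustering_markers > n_core_genes:
        raise ValueError("marker panel cannot exceed the core gene count")
    if n_abundance_markers > n_clustering_markers:
        raise ValueError("abundance panel must be a subset of the clustering panel")
    rng = np.random.default_rng(seed)
    n_pool = n_core_genes + n_accessory_genes
    base_pool = [_random_gene(rng, gene_len) for _ in range(n_pool)]
    marker_families = [f"fam{k:02d}" for k in range(1, n_clustering_markers + 1)]
    species_list = []
    sp_width = len(str(n_species))
    for si in range(n_species):
        sid = f"S{si + 1:0{sp_width}d}"
        pool = [_mutate(g, between_divergence, rng) for g in base_pool]
        core = list(range(n_core_genes))
        accessory = list(range(n_core_genes, n_pool))
        strains = []
        for sj in range(n_strains_per_species):
            gid = f"{sid}.t{sj + 1:02d}"
            div = float(rng.uniform(0.0, within_divergence / 2.0))
            present = core + [
                i for i in accessory if rng.random() < accessory_retention
            ]
            gene_seqs, gene_coords = {}, {}
            offset = 0
            for idx in present:
                g = _decode(_mutate(pool[idx], div, rng))
                gene_seqs[idx] = g
                gene_coords[idx] = (offset, offset + len(g))
                offset += len(g)
            strains.append(SyntheticStrain(gid, sid, div, present, gene_seqs, gene_coords))
        species_list.append(
            SyntheticSpecies(
                sid,
                [_decode(g) for g in pool],
                core,
                accessory,
                core[:n_clustering_markers],
                core[:n_abundance_markers],
                strains,
            )
        )
    return SpeciesSet(species_list, seed, marker_families)


def simulate_reads(
    members: list[tuple[SequenceRecord, float]],
    total_coverage: float = 100.0,
    read_len: int = 100,
    error_rate: float = 0.01,
    quality: QualityModel | None = None,
    seed: int = 0,
    id_prefix: str = "r",
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate single-end reads from a community.

    Each genome receives fold coverage ``total_coverage x abundance``;
    read counts are Poisson around coverage x length / read length, start
    positions uniform, strands random, substitution errors i.i.d. at
    ``error_rate`` with qualities drawn from the quality model. Returns
    the reads plus a per-read origin table (genome, position, strand,
    errors).
    """
    qm = quality or QualityModel()
    rng = np.random.default_rng(seed)
    abundances = np.array([a for _, a in members], dtype=float)
    if len(members) and abs(abundances.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances sum to {abundances.sum():.6f}, not 1")
    reads: list[ReadRecord] = []
    origin_rows = []
    for genome, abundance in members:
        cov = total_coverage * abundance
        L = len(genome)
        if L < read_len:
            raise ValueError(f"genome {genome.id} shorter than the read length")
        n_reads = int(rng.poisson(cov * L / read_len)) if cov > 0 else 0
        if n_reads == 0:
            continue
        codes = _encode(genome.sequence)
        starts = rng.integers(0, L - read_len + 1, n_reads)
        mat = codes[starts[:, None] + np.arange(read_len)]
        strands = rng.random(n_reads) < 0.5
        # reverse-complement half the reads (complement = 3 - code index)
        idx = np.searchsorted(_BASES, mat)
        idx[strands] = 3 - idx[strands, ::-1]
        err = rng.random((n_reads, read_len)) < error_rate
        shift = rng.integers(1, 4, err.sum())
        idx[err] = (idx[err] + shift) % 4
        mat = _BASES[idx]
        quals = rng.integers(qm.correct_lo, qm.correct_hi + 1, (n_reads, read_len))
        quals[err] = rng.integers(qm.error_lo, qm.error_hi + 1, err.sum())
        n_err = err.sum(axis=1)
        for i in range(n_reads):
            rid = f"{id_prefix}:{genome.id}:{i}"
            reads.append(ReadRecord(rid, _decode(mat[i]), quals[i].astype(np.int16)))
            origin_rows.append(
                {
                    "read_id": rid,
                    "genome_id": genome.id,
                    "position": int(starts[i]),
                    "strand": "-" if strands[i] else "+",
                    "n_errors": int(n_err[i]),
                }
            )
    origins = pd.DataFrame(
        origin_rows, columns=["read_id", "genome_id", "position", "strand", "n_errors"]
    )
    return reads, origins


@dataclass
class MockCommunity:
    """One mock metagenome with its ground truth."""

    community_id: str
    members: list[tuple[str, float]]      # (genome_id, relative abundance)
    total_coverage: float
    reads: list[ReadRecord]
    origins: pd.DataFrame

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genome_id": g,
                    "abundance": a,
                    "coverage": self.total_coverage * a,
                }
                for g, a in self.members
            ]
        )


def simulate_community(
    genomes: list[SequenceRecord],
    community_id: str,
    total_coverage: float = 100.0,
    read_len: int = 100,
    error_rate: float = 0.01,
    seed: int = 0,
    abundances: np.ndarray | None = None,
) -> MockCommunity:
    """Exponential-abundance mock metagenome over the given genomes."""
    a = exponential_abundances(len(genomes)) if abundances is None else abundances
    members = list(zip(genomes, a))
    reads, origins = simulate_reads(
        members, total_coverage, read_len, error_rate, seed=seed, id_prefix=community_id
    )
    return MockCommunity(
        community_id,
        [(g.id, float(x)) for g, x in members],
        total_coverage,
        reads,
        origins,
    )
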