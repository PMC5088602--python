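"""Core-genome SNP profiling from pileups against representative genomes.

Reads are globally mapped to a species' representative genome, filtered
at 94/70/20/20, and piled up per reference position counting only bases
with quality >= 30 (N bases never count; indels are ignored — variation
is modelled as substitutions only). The core genome is defined from the
data as the sites with depth strictly greater than 10x in at least 95% of
samples. Cross-sample merging defines cohort-wide major/minor alleles
from pooled counts and emits minor-allele-frequency and depth matrices;
consensus SNP calls flag sites whose most-frequent allele differs from
the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ReadRecord, SequenceRecord
from .mapper import Alignment, ReferenceIndex, filter_alignments, map_reads

BASES = np.array(["A", "C", "G", "T"])
MISSING = -1.0  # sentinel for "no coverage" in SNP matrices (distinct from 0)


@dataclass
class Pileup:
    """Quality-filtered base counts along one reference contig."""

    species_id: str
    contig: str
    ref_seq: str
    counts: np.ndarray  # (L, 4) int, columns A,C,G,T

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def site(self, pos: int) -> "SiteSummary":
        return SiteSummary(self.species_id, self.contig, pos, self.ref_seq[pos], self.counts[pos].copy())


@dataclass
class SiteSummary:
    """Allele counts, depth, frequencies and consensus at one site."""

    species_id: str
    contig: str
    position: int  # 0-based
    ref_allele: str
    counts: np.ndarray  # length-4, A,C,G,T

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        d = self.depth
        return self.counts / d if d > 0 else np.zeros(4)

    @property
    def consensus(self) -> str | None:
        """Argmax-count allele; None on a tie (conservative no-call)."""
        if self.depth == 0:
            return None
        top = self.counts.max()
        winners = np.flatnonzero(self.counts == top)
        return str(BASES[winners[0]]) if len(winners) == 1 else None


@dataclass
class CoreGenome:
    """Data-defined core sites of one species."""

    species_id: str
    sites: list[tuple[str, int]]  # ordered (contig, 0-based position)
    min_depth: int
    sample_fraction: float


def pileup(
    alignments: list[Alignment],
    genome: SequenceRecord,
    species_id: str = "",
    base_qual_min: int = 30,
    prefiltered: bool = False,
    config: RunConfig | None = None,
) -> Pileup:
    """Accumulate quality->=30 base counts over a reference contig.

    Alignments are expected from global-mode mapping; unless
    ``prefiltered``, the standard 94/70/20/20 read filters are applied
    here first.
    """
    cfg = config or RunConfig()
    if not prefiltered:
        alignments = filter_alignments(
            alignments, cfg.map_pid, cfg.aln_cov, cfg.mapq_min, cfg.read_qual_min
        )
    counts = np.zeros((len(genome), 4), dtype=np.int32)
    for a in alignments:
        if a.target_id != genome.id:
            continue
        pos, codes, quals = a.aligned_columns()
        keep = quals >= base_qual_min
        if keep.any():
            np.add.at(counts, (pos[keep], codes[keep]), 1)
    return Pileup(species_id, genome.id, genome.sequence, counts)


def pileup_sample(
    reads: list[ReadRecord],
    genome: SequenceRecord,
    species_id: str = "",
    config: RunConfig | None = None,
    index: ReferenceIndex | None = None,
) -> Pileup:
    """Map one sample's reads globally to a representative genome and pile up."""
    cfg = config or RunConfig()
    if index is None:
        index = ReferenceIndex([genome])
    alignments = map_reads(reads, index, mode="global")
    return pileup(alignments, genome, species_id, cfg.base_qual_min, config=cfg)


def identify_core(
    depths: dict[str, dict[str, np.ndarray]],
    min_depth: int = 10,
    sample_fraction: float = 0.95,
    species_id: str = "",
) -> CoreGenome:
    """Sites with depth strictly greater than ``min_depth`` in at least
    ``sample_fraction`` of samples. ``depths`` maps sample -> contig ->
    per-position depth vector."""
    if not depths:
        raise ValueError("no samples supplied")
    samples = sorted(depths)
    contigs = sorted({c for per in depths.values() for c in per})
    n = len(samples)
    sites: list[tuple[str, int]] = []
    for contig in contigs:
        stacked = np.stack(
            [np.asarray(depths[s].get(contig, np.zeros(0))) for s in samples]
        )
        frac = (stacked > min_depth).sum(axis=0) / n
        for pos in np.flatnonzero(frac >= sample_fraction):
            sites.append((contig, int(pos)))
    return CoreGenome(species_id, sites, min_depth, sample_fraction)


@dataclass
class SnpMatrix:
    """Sites x samples minor-allele-frequency and depth matrices.

    Major/minor alleles are cohort-wide (pooled counts); frequency is NaN
    at sites a sample does not cover (depth 0), distinct from frequency 0.
    """

    species_id: str
    sites: pd.DataFrame        # index "contig:pos1"; columns contig, position, ref, major, minor
    freq: pd.DataFrame         # minor-allele frequency per sample
    depth: pd.DataFrame


def merge_snps(
    pileups: dict[str, Pileup],
    core: CoreGenome | None = None,
    all_sites: bool = False,
) -> SnpMatrix:
    """Merge per-sample pileups into cohort SNP matrices.

    Restricted to core sites unless ``all_sites`` (every position covered
    in at least one sample). Sites uncovered in every sample are excluded.
    """
    if not pileups:
        raise ValueError("no samples to merge")
    samples = sorted(pileups)
    first = pileups[samples[0]]
    if all_sites or core is None:
        pooled_depth = sum(pileups[s].depth for s in samples)
        site_list = [(first.contig, int(p)) for p in np.flatnonzero(pooled_depth > 0)]
    else:
        site_list = core.sites
    rows, freq_rows, depth_rows = [], [], []
    for contig, pos in site_list:
        pooled = sum(pileups[s].counts[pos] for s in samples)
        if pooled.sum() == 0:
            continue
        order = np.lexsort((np.arange(4), -pooled))  # count desc, base order on ties
        major_i, minor_i = int(order[0]), int(order[1])
        freqs, depths_ = [], []
        for s in samples:
            c = pileups[s].counts[pos]
            d = int(c.sum())
            depths_.append(d)
            freqs.append(c[minor_i] / d if d > 0 else np.nan)
        rows.append(
            {
                "site": f"{contig}:{pos + 1}",
                "contig": contig,
                "position": pos + 1,  # 1-based in exported tables
                "ref": first.ref_seq[pos],
                "major": str(BASES[major_i]),
                "minor": str(BASES[minor_i]),
            }
        )
        freq_rows.append(freqs)
        depth_rows.append(depths_)
    sites = pd.DataFrame(rows).set_index("site") if rows else pd.DataFrame(
        columns=["contig", "position", "ref", "major", "minor"]
    )
    freq = pd.DataFrame(freq_rows, index=sites.index, columns=samples)
    depth = pd.DataFrame(depth_rows, index=sites.index, columns=samples)
    return SnpMatrix(first.species_id, sites, freq, depth)


def consensus_snp_calls(pile: Pileup) -> set[tuple[str, int, str]]:
    """Sites where the consensus allele differs from the reference:
    (contig, 0-based position, consensus allele). Ties give no call."""
    depth = pile.depth
    covered = np.flatnonzero(depth > 0)
    calls: set[tuple[str, int, str]] = set()
    counts = pile.counts
    top = counts.max(axis=1)
    n_top = (counts == top[:, None]).sum(axis=1)
    argmax = counts.argmax(axis=1)
    ref_codes = np.frombuffer(pile.ref_seq.encode(), dtype=np.uint8)
    base_codes = np.full(128, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        base_codes[ord(b)] = i
    ref_idx = base_codes[ref_codes]
    for pos in covered:
        if n_top[pos] == 1 and argmax[pos] != ref_idx[pos]:
            calls.add((pile.contig, int(pos), str(BASES[argmax[pos]])))
    return calls


def site_table(pile: Pileup, covered_only: bool = True) -> pd.DataFrame:
    """Per-site TSV-ready table: contig, 1-based position, ref, A, C, G, T, depth."""
    depth = pile.depth
    pos = np.flatnonzero(depth > 0) if covered_only else np.arange(len(depth))
    return pd.DataFrame(
        {
            "contig": pile.contig,
            "pos_1based": pos + 1,
            "ref": [pile.ref_seq[p] for p in pos],
            "A": pile.counts[pos, 0],
            "C": pile.counts[pos, 1],
            "G": pile.counts[pos, 2],
            "T": pile.counts[pos, 3],
            "depth": depth[pos],
        }
    )


def write_vcf(pile: Pileup, sample_id: str, path: str | Path) -> None:
    """Minimal VCF 4.2 export of consensus variant sites for one sample."""
    calls = sorted(consensus_snp_calls(pile))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={pile.contig},length={len(pile.ref_seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Quality-filtered depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}\n")
        for contig, pos, alt in calls:
            ref = pile.ref_seq[pos]
            dp = int(pile.depth[pos])
            fh.write(f"{contig}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\tDP={dp}\tGT\t1\n")
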