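"""Pan-genome profiling: gene coverage, copy number, presence/absence.

Reads are locally mapped against the 99%-identity gene-cluster centroids
of each selected species and filtered at 94% identity / 70% read coverage
/ MAPQ 20 / mean quality 20. Cluster coverage is aligned base pairs over
centroid length. Copy number normalizes each coverage by the median
coverage of the species' 15 universal single-copy gene (USCG) families —
an estimate of the per-cell coverage — and presence is called at copy
number >= 0.35 (values below 0.35 are absent). Coverages can be
aggregated onto coarser 75-95% families, and per-sample results merge
into genes x samples matrices with Jaccard distances on presence sets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ReadRecord, SequenceRecord
from .mapper import Alignment, ReferenceIndex, filter_alignments, map_reads
from .species_db import PanGenome


@dataclass
class GeneContentResult:
    """Per-sample gene content for one species."""

    species_id: str
    table: pd.DataFrame      # index cluster_id; columns coverage, copy_number, presence
    normalizer: float        # median USCG family coverage (fold)
    usable: bool             # False when the normalizer is 0

    @property
    def presence_set(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["presence"]])


@dataclass
class GeneContentMatrix:
    """Genes x samples matrices for one species across a cohort."""

    species_id: str
    coverage: pd.DataFrame
    copy_number: pd.DataFrame
    presence: pd.DataFrame   # boolean


def centroid_records(pangenome: PanGenome) -> list[SequenceRecord]:
    return [SequenceRecord(c.cluster_id, c.centroid_seq) for c in pangenome.clusters]


def gene_coverage(alignments: list[Alignment], pangenome: PanGenome) -> pd.Series:
    """Fold coverage per 99% cluster: aligned read bp / centroid length.

    Alignments must already be filtered (94/70/20/20); the MAPQ filter has
    removed ties, so each read contributes to exactly one cluster."""
    bases: dict[str, float] = defaultdict(float)
    for a in alignments:
        bases[a.target_id] += a.read_end - a.read_start
    lengths = {c.cluster_id: c.length for c in pangenome.clusters}
    return pd.Series(
        {cid: bases.get(cid, 0.0) / lengths[cid] for cid in sorted(lengths)},
        name="coverage",
    )


def uscg_normalizer(coverages: pd.Series, pangenome: PanGenome) -> float:
    """Median of the per-family USCG coverages; families with no mapped
    reads count as 0. A family split over several clusters sums their
    coverages (the member copies share one underlying gene)."""
    fam_cov: dict[str, float] = defaultdict(float)
    for cid, fam in pangenome.uscg_families.items():
        fam_cov[fam] += float(coverages.get(cid, 0.0))
    if not fam_cov:
        raise ValueError(f"pan-genome {pangenome.species_id} has no USCG-flagged clusters")
    return float(np.median(list(fam_cov.values())))


def copy_number(coverages: pd.Series, normalizer: float) -> pd.Series:
    """Coverage / normalizer = estimated copies per cell; all-zero (and the
    species flagged unusable) when the normalizer is 0."""
    if normalizer <= 0:
        return pd.Series(0.0, index=coverages.index, name="copy_number")
    return (coverages / normalizer).rename("copy_number")


def presence_absence(copy_numbers: pd.Series, cutoff: float = 0.35) -> pd.Series:
    """Present iff copy number >= cutoff (below 0.35 is absent)."""
    return (copy_numbers >= cutoff).rename("presence")


def profile_gene_content(
    reads: list[ReadRecord],
    pangenome: PanGenome,
    config: RunConfig | None = None,
    index: ReferenceIndex | None = None,
    alignments: list[Alignment] | None = None,
) -> GeneContentResult:
    """Map reads to a species pan-genome and call gene content."""
    cfg = config or RunConfig()
    if alignments is None:
        if index is None:
            index = ReferenceIndex(centroid_records(pangenome))
        alignments = map_reads(reads, index, mode="local")
    kept = filter_alignments(
        alignments, cfg.map_pid, cfg.aln_cov, cfg.mapq_min, cfg.read_qual_min
    )
    cov = gene_coverage(kept, pangenome)
    norm = uscg_normalizer(cov, pangenome)
    if norm > 0:
        cn = copy_number(cov, norm)
        usable = True
    else:
        cn = pd.Series(0.0, index=cov.index, name="copy_number")
        usable = False
    pres = presence_absence(cn, cfg.copynum_cutoff) if usable else pd.Series(
        False, index=cov.index, name="presence"
    )
    table = pd.concat([cov, cn, pres], axis=1)
    table.index.name = "gene_id"
    return GeneContentResult(pangenome.species_id, table, norm, usable)


def aggregate_coverage(coverages: pd.Series, family_map: dict[str, str]) -> pd.Series:
    """Sum member-cluster coverages into coarse-family coverages."""
    unmapped = sorted(set(coverages.index) - set(family_map))
    if unmapped:
        raise ValueError(f"clusters missing from family map: {unmapped[:5]}")
    fam = coverages.groupby(coverages.index.map(family_map)).sum()
    return fam.rename("coverage").sort_index()


def merge_gene_content(results: dict[str, GeneContentResult]) -> GeneContentMatrix:
    """Combine per-sample results for one species into matrices."""
    if not results:
        raise ValueError("no samples to merge")
    species = {r.species_id for r in results.values()}
    if len(species) != 1:
        raise ValueError(f"cannot merge across species: {sorted(species)}")
    samples = sorted(results)
    cov = pd.DataFrame({s: results[s].table["coverage"] for s in samples}).sort_index()
    cn = pd.DataFrame({s: results[s].table["copy_number"] for s in samples}).sort_index()
    pres = pd.DataFrame({s: results[s].table["presence"] for s in samples}).sort_index()
    return GeneContentMatrix(species.pop(), cov, cn, pres)


def jaccard_distance(presence_a: frozenset[str] | set[str], presence_b: frozenset[str] | set[str]) -> float | None:
    """1 - |A n B| / |A u B| on presence sets; undefined for two empty sets."""
    union = len(set(presence_a) | set(presence_b))
    if union == 0:
        return None
    inter = len(set(presence_a) & set(presence_b))
    return 1.0 - inter / union


def jaccard_matrix(matrix: GeneContentMatrix) -> pd.DataFrame:
    """Pairwise sample Jaccard distances on presence sets (NaN where both
    samples have empty presence sets)."""
    samples = list(matrix.presence.columns)
    sets = {s: frozenset(matrix.presence.index[matrix.presence[s]]) for s in samples}
    out = pd.DataFrame(0.0, index=samples, columns=samples)
    for i, a in enumerate(samples):
        for b in samples[i:]:
            d = jaccard_distance(sets[a], sets[b])
            out.loc[a, b] = out.loc[b, a] = np.nan if d is None else d
    return out
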