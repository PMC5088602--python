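"""Species abundance estimation from universal single-copy genes (USCGs).

Reads are locally mapped against a database holding, per species, one
sequence for each of 15 universal single-copy gene families. Alignments
covering <70% of the read, or below the family-specific species-level
percent-identity cutoff (tuned cutoffs range 94.5-98%; 95% default for
untuned families), are discarded. Uniquely mapped reads are assigned to
their best-hit species; reads tying across species are redistributed
fractionally in proportion to each tied species' uniquely-mapped read
counts. Species coverage is total aligned read base pairs over total
marker length, and relative abundance is each species' share of summed
coverage.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import ReadRecord, SequenceRecord
from .mapper import ReferenceIndex, map_reads


@dataclass
class MarkerDb:
    """Per-species USCG sequences plus per-family identity cutoffs."""

    genes: list[SequenceRecord]                 # id convention "<species>|<family>"
    gene_species: dict[str, str]                # gene id -> species id
    gene_family: dict[str, str]                 # gene id -> family id
    family_cutoffs: dict[str, float] = field(default_factory=dict)
    default_cutoff: float = 95.0

    def __post_init__(self) -> None:
        for fam, cut in self.family_cutoffs.items():
            if not 90.0 <= cut <= 100.0:
                raise ValueError(f"family {fam}: cutoff {cut} outside [90, 100]")
        seen = set()
        for g in self.genes:
            key = (self.gene_species[g.id], self.gene_family[g.id])
            if key in seen:
                raise ValueError(f"species {key[0]} has multiple {key[1]} genes")
            seen.add(key)

    @property
    def species_ids(self) -> list[str]:
        return sorted(set(self.gene_species.values()))

    def cutoff(self, family: str) -> float:
        return self.family_cutoffs.get(family, self.default_cutoff)

    def species_marker_length(self) -> dict[str, int]:
        out: dict[str, int] = defaultdict(int)
        for g in self.genes:
            out[self.gene_species[g.id]] += len(g)
        return dict(out)

    @classmethod
    def from_records(
        cls,
        genes: list[SequenceRecord],
        family_cutoffs: dict[str, float] | None = None,
        default_cutoff: float = 95.0,
    ) -> "MarkerDb":
        """Build from records whose ids follow ``species|family``."""
        species, family = {}, {}
        for g in genes:
            try:
                sp, fam = g.id.rsplit("|", 1)
            except ValueError:
                raise ValueError(f"marker id {g.id!r} not of the form species|family")
            species[g.id], family[g.id] = sp, fam
        return cls(genes, species, family, family_cutoffs or {}, default_cutoff)


@dataclass
class SpeciesProfile:
    """Per-sample species coverage / relative abundance / read counts."""

    table: pd.DataFrame  # index species_id; columns coverage, relative_abundance, count_reads
    no_species_detected: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def coverages(self) -> pd.Series:
        return self.table["coverage"]

    def total_species_coverage(self) -> float:
        return float(self.table["coverage"].sum())


def _empty_profile(species_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        0.0,
        index=pd.Index(sorted(species_ids), name="species_id"),
        columns=["coverage", "relative_abundance", "count_reads"],
    )


def profile_species(
    reads: list[ReadRecord],
    db: MarkerDb,
    config: RunConfig | None = None,
    index: ReferenceIndex | None = None,
    pid_override: float | None = None,
) -> SpeciesProfile:
    """Estimate species coverage and relative abundance from marker hits.

    ``pid_override`` replaces every family cutoff (used by the lenient
    re-mapping strategy of the database-coverage estimator).
    """
    cfg = config or RunConfig()
    if index is None:
        index = ReferenceIndex(db.genes)
    alignments = map_reads(reads, index, mode="local")

    # marker-stage filters: read coverage and family identity cutoff only
    kept = []
    for a in alignments:
        fam = db.gene_family[a.target_id]
        cut = pid_override if pid_override is not None else db.cutoff(fam)
        if a.read_coverage >= cfg.marker_aln_cov and a.percent_identity >= cut:
            kept.append(a)

    unique_reads: dict[str, float] = defaultdict(float)
    unique_bases: dict[str, float] = defaultdict(float)
    ties: list[tuple[list[str], float]] = []  # (tied species, aligned bases)
    for a in kept:
        species = sorted({db.gene_species.get(t, t.rsplit("|", 1)[0]) for t in a.tied_targets})
        bases = float(a.read_end - a.read_start)
        if len(species) <= 1:
            sp = db.gene_species[a.target_id]
            unique_reads[sp] += 1.0
            unique_bases[sp] += bases
        else:
            ties.append((species, bases))

    reads_count = dict(unique_reads)
    bases_count = dict(unique_bases)
    for species, bases in ties:
        weights = np.array([unique_reads.get(sp, 0.0) for sp in species])
        if weights.sum() == 0:
            weights = np.ones(len(species))
        weights = weights / weights.sum()
        for sp, w in zip(species, weights):
            reads_count[sp] = reads_count.get(sp, 0.0) + float(w)
            bases_count[sp] = bases_count.get(sp, 0.0) + float(w) * bases

    table = _empty_profile(db.species_ids)
    marker_len = db.species_marker_length()
    for sp in table.index:
        if sp in bases_count:
            table.loc[sp, "coverage"] = bases_count[sp] / marker_len[sp]
            table.loc[sp, "count_reads"] = reads_count[sp]
    total = table["coverage"].sum()
    notes = []
    if total > 0:
        table["relative_abundance"] = table["coverage"] / total
    else:
        notes.append("no species detected")
    return SpeciesProfile(table, no_species_detected=total == 0, notes=notes)


def select_species(profile: SpeciesProfile, min_coverage: float) -> list[str]:
    """Species with coverage strictly greater than ``min_coverage``,
    sorted by descending coverage (ties by species id)."""
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    cov = profile.table["coverage"]
    picked = cov[cov > min_coverage]
    return list(picked.sort_values(ascending=False, kind="stable").index)


def estimate_total_coverage(
    reads: list[ReadRecord],
    db: MarkerDb,
    strategy: str = "lenient_markers",
    average_genome_size: float | None = None,
    config: RunConfig | None = None,
    index: ReferenceIndex | None = None,
) -> tuple[float, list[str]]:
    """Fold coverage of all cellular genomes in the sample.

    ``lenient_markers``: re-map reads with every family cutoff relaxed to
    75% identity and take the median over families of aligned bp divided by
    the family's mean gene length — species absent from the database can
    still recruit reads to conserved markers. ``known_ags``: total read bp
    divided by a supplied average genome size.

    Both are simplified single-pass estimators; the note returned with the
    value flags this.
    """
    notes = ["total-coverage estimate uses a simplified marker-based estimator"]
    if strategy == "known_ags":
        if not average_genome_size:
            raise ValueError("known_ags strategy requires average_genome_size")
        total_bp = float(sum(len(r) for r in reads))
        return total_bp / average_genome_size, notes
    if strategy != "lenient_markers":
        raise ValueError(f"unknown strategy {strategy!r}")

    cfg = config or RunConfig()
    if index is None:
        index = ReferenceIndex(db.genes)
    alignments = map_reads(reads, index, mode="local")
    fam_bases: dict[str, float] = defaultdict(float)
    for a in alignments:
        if a.read_coverage >= cfg.marker_aln_cov and a.percent_identity >= 75.0:
            fam_bases[db.gene_family[a.target_id]] += a.read_end - a.read_start
    fam_lengths: dict[str, list[int]] = defaultdict(list)
    for g in db.genes:
        fam_lengths[db.gene_family[g.id]].append(len(g))
    per_family = [
        fam_bases.get(fam, 0.0) / float(np.mean(lens)) for fam, lens in sorted(fam_lengths.items())
    ]
    if not any(per_family):
        notes.append("no marker hits under lenient mapping")
        return 0.0, notes
    return float(np.median(per_family)), notes


def database_coverage(profile: SpeciesProfile, total_coverage: float) -> float | None:
    """Percentage of community genome coverage captured by database
    species: 100 x (sum of species coverages) / total, capped at 100.
    Undefined (None) when the total is zero."""
    if total_coverage < 0:
        raise ValueError("total_coverage must be >= 0")
    if total_coverage == 0:
        return None
    return min(100.0, 100.0 * profile.total_species_coverage() / total_coverage)
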