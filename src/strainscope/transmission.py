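"""Strain tracking between hosts via rare "marker" alleles.

An allele is present in a sample when supported by >= 3 reads and >= 10%
of the reads at its site (quality-filtered pileup counts). Restricting to
sites with exactly two alleles present cohort-wide, a marker allele for a
unit (an individual, or a mother-infant pair during discovery) is an
allele found in at least one of that unit's samples and in no sample of
any other unit — a fingerprint of the unit's strain. Sharing between a
donor and a recipient sample is the percentage of the donor's marker
alleles also present in the recipient; units with fewer than 10 markers
for a species are excluded, and sharing strictly greater than 5% defines
a transmission event.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snps import Pileup, BASES

Site = tuple[str, int]          # (contig, 0-based position)
SiteAllele = tuple[str, int, str]


@dataclass
class AllelePresence:
    """Alleles present in one sample, with supporting counts and depths."""

    sample_id: str
    species_id: str
    # (contig, pos) -> {allele: count}; only alleles passing both thresholds
    present: dict[Site, dict[str, int]]
    depth: dict[Site, int]

    def has(self, site: Site, allele: str) -> bool:
        return allele in self.present.get(site, {})


@dataclass
class MarkerAlleleSet:
    """Marker alleles private to one unit for one species."""

    species_id: str
    unit_id: str
    alleles: frozenset[SiteAllele]

    @property
    def size(self) -> int:
        return len(self.alleles)


@dataclass
class SharingResult:
    species_id: str
    donor_unit: str
    recipient_sample: str
    n_markers: int
    n_shared: int
    sharing_percent: float | None  # None when excluded
    excluded: bool
    transmitted: bool | None = None


def detect_alleles(
    pile: Pileup,
    sample_id: str,
    allele_min_reads: int = 3,
    allele_min_freq: float = 0.10,
) -> AllelePresence:
    """Alleles supported by >= allele_min_reads reads and
    >= allele_min_freq of the site depth."""
    counts = pile.counts
    depth = counts.sum(axis=1)
    present: dict[Site, dict[str, int]] = {}
    depths: dict[Site, int] = {}
    # a site can qualify only if some allele reaches the read minimum
    for pos in np.flatnonzero(counts.max(axis=1) >= allele_min_reads):
        d = int(depth[pos])
        site_alleles = {
            str(BASES[i]): int(c)
            for i, c in enumerate(counts[pos])
            if c >= allele_min_reads and c / d >= allele_min_freq
        }
        if site_alleles:
            site = (pile.contig, int(pos))
            present[site] = site_alleles
            depths[site] = d
    return AllelePresence(sample_id, pile.species_id, present, depths)


def find_marker_alleles(
    cohort: dict[str, AllelePresence],
    unit_map: dict[str, str],
    species_id: str = "",
) -> dict[str, MarkerAlleleSet]:
    """Marker alleles per unit: biallelic sites only (exactly two distinct
    alleles present cohort-wide), allele present in >= 1 sample of the
    unit and in no sample outside it."""
    units = {unit_map[s] for s in cohort}
    if len(units) < 2:
        raise ValueError("marker-allele privacy is undefined with fewer than 2 units")
    site_alleles: dict[Site, set[str]] = defaultdict(set)
    allele_units: dict[tuple[Site, str], set[str]] = defaultdict(set)
    for sample, pres in cohort.items():
        unit = unit_map[sample]
        for site, alleles in pres.present.items():
            for allele in alleles:
                site_alleles[site].add(allele)
                allele_units[(site, allele)].add(unit)
    out: dict[str, set[SiteAllele]] = {u: set() for u in units}
    for site, alleles in site_alleles.items():
        if len(alleles) != 2:  # biallelic sites only
            continue
        for allele in alleles:
            owners = allele_units[(site, allele)]
            if len(owners) == 1:
                (unit,) = owners
                out[unit].add((site[0], site[1], allele))
    return {
        u: MarkerAlleleSet(species_id, u, frozenset(marks))
        for u, marks in out.items()
    }


def allele_sharing(
    markers: MarkerAlleleSet,
    recipient: AllelePresence,
    marker_min_count: int = 10,
) -> SharingResult:
    """Percentage of the donor unit's marker alleles present in the
    recipient sample; excluded when the donor has < marker_min_count
    markers. The denominator is all donor markers (the >10x species
    coverage gate on both samples makes uncovered marker sites rare)."""
    n = markers.size
    if n < marker_min_count:
        return SharingResult(
            markers.species_id, markers.unit_id, recipient.sample_id, n, 0, None, True
        )
    shared = sum(
        1 for contig, pos, allele in markers.alleles if recipient.has((contig, pos), allele)
    )
    return SharingResult(
        markers.species_id,
        markers.unit_id,
        recipient.sample_id,
        n,
        shared,
        100.0 * shared / n,
        False,
    )


def classify_transmission(result: SharingResult, transmission_cutoff: float = 5.0) -> bool:
    """Transmission iff sharing is strictly greater than the cutoff (5%)."""
    if result.excluded or result.sharing_percent is None:
        raise ValueError("cannot classify an excluded sharing result")
    transmitted = result.sharing_percent > transmission_cutoff
    result.transmitted = transmitted
    return transmitted


def cohort_transmission_summary(results: list[SharingResult]) -> pd.DataFrame:
    """Per-species and pooled transmission rates over evaluable pairs."""
    rows = []
    by_species: dict[str, list[SharingResult]] = defaultdict(list)
    for r in results:
        by_species[r.species_id].append(r)
    for sp in sorted(by_species):
        rs = by_species[sp]
        evaluable = [r for r in rs if not r.excluded and r.transmitted is not None]
        transmitted = sum(r.transmitted for r in evaluable)
        rows.append(
            {
                "species_id": sp,
                "n_pairs": len(rs),
                "n_evaluable": len(evaluable),
                "n_transmitted": transmitted,
                "rate": transmitted / len(evaluable) if evaluable else np.nan,
            }
        )
    pooled_eval = [r for r in results if not r.excluded and r.transmitted is not None]
    pooled_trans = sum(r.transmitted for r in pooled_eval)
    rows.append(
        {
            "species_id": "_all_",
            "n_pairs": len(results),
            "n_evaluable": len(pooled_eval),
            "n_transmitted": pooled_trans,
            "rate": pooled_trans / len(pooled_eval) if pooled_eval else np.nan,
        }
    )
    return pd.DataFrame(rows)


def sharing_table(results: list[SharingResult]) -> pd.DataFrame:
    """TSV-ready table of sharing results."""
    return pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "donor": r.donor_unit,
                "recipient": r.recipient_sample,
                "n_markers": r.n_markers,
                "n_shared": r.n_shared,
                "sharing_percent": np.nan if r.sharing_percent is None else r.sharing_percent,
                "transmitted": r.transmitted,
                "excluded": r.excluded,
            }
            for r in results
        ]
    )
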