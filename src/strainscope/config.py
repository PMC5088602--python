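"""Run configuration: every filter threshold used across the pipeline.

Defaults follow the published profiling protocol: read-mapping filters of
94% identity / 70% alignment coverage / MAPQ 20 / mean base quality 20,
per-base quality 30 for pileups, a copy-number cutoff of 0.35 for gene
presence, a core genome defined as sites with >10x depth in >=95% of
samples, allele presence at >=3 reads and >=10% frequency, a 10-marker
minimum per unit, and a 5% allele-sharing cutoff for transmission.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a threshold is outside its documented range."""


_RANGES = {
    "map_pid": (0.0, 100.0),
    "aln_cov": (0.0, 1.0),
    "mapq_min": (0, 60),
    "read_qual_min": (0.0, 60.0),
    "base_qual_min": (0, 60),
    "species_cov_min": (0.0, None),
    "snp_cov_min": (0.0, None),
    "copynum_cutoff": (0.0, None),
    "core_depth": (0, None),
    "core_fraction": (0.0, 1.0),
    "allele_min_reads": (1, None),
    "allele_min_freq": (0.0, 1.0),
    "marker_min_count": (1, None),
    "transmission_cutoff": (0.0, 100.0),
    "cluster_cutoff": (0.0, 1.0),
    "marker_aln_cov": (0.0, 1.0),
    "marker_default_pid": (90.0, 100.0),
    "seed": (0, None),
}


@dataclass
class RunConfig:
    """Thresholds for every pipeline filter, with published defaults."""

    # pan-genome / genome read-mapping filters
    map_pid: float = 94.0          # minimum mapping percent identity
    aln_cov: float = 0.70          # minimum fraction of the read aligned
    mapq_min: int = 20             # discards non-unique best hits
    read_qual_min: float = 20.0    # minimum mean base quality of the read

    # pileup
    base_qual_min: int = 30        # per-base quality for SNP counting

    # species selection gates
    species_cov_min: float = 1.0   # marker coverage to profile gene content
    snp_cov_min: float = 10.0      # marker coverage to profile SNPs

    # gene content
    copynum_cutoff: float = 0.35   # copy number below this => gene absent

    # core genome
    core_depth: int = 10           # site depth must exceed this (strict >)
    core_fraction: float = 0.95    # ...in at least this fraction of samples

    # strain tracking
    allele_min_reads: int = 3
    allele_min_freq: float = 0.10
    marker_min_count: int = 10
    transmission_cutoff: float = 5.0   # percent sharing, strict >

    # species delineation / marker mapping
    cluster_cutoff: float = 0.035      # distance = (100 - 96.5) / 100
    marker_aln_cov: float = 0.70       # read coverage at the marker stage
    marker_default_pid: float = 95.0   # family cutoff when none is tuned

    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = _RANGES[f.name]
            v = getattr(self, f.name)
            if lo is not None and v < lo:
                raise ConfigError(f"{f.name}={v} below allowed minimum {lo}")
            if hi is not None and v > hi:
                raise ConfigError(f"{f.name}={v} above allowed maximum {hi}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a plain-text ``key = value`` config; overrides win."""
        values: dict = {}
        field_types = {f.name: f.type for f in fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in field_types:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            caster = int if field_types[key] in ("int", int) else float
            values[key] = caster(val)
        values.update(overrides)
        return cls(**values)
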