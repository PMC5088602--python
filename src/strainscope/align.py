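"""Thin wrappers around edlib for percent-identity computations.

edlib performs banded edit-distance alignment in C and reports an extended
CIGAR ('=', 'X', 'I', 'D'; 'I' consumes query only, 'D' target only) plus
the target span of the best hit. Infix (HW) mode aligns the whole query
against the best-matching substring of the target, which is the alignment
style used throughout: reads against genes/genomes, and near-full-length
marker homologs against each other.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XID])")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


@dataclass
class InfixHit:
    """Best placement of a whole query inside a target."""

    edit_distance: int
    target_start: int  # 0-based
    target_end: int    # half-open
    cigar: str
    matches: int
    columns: int

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.columns


def _cigar_counts(cigar: str) -> tuple[int, int]:
    matches = columns = 0
    for n, op in parse_cigar(cigar):
        columns += n
        if op == "=":
            matches += n
    return matches, columns


def align_infix(query: str, target: str, max_distance: int = -1) -> InfixHit | None:
    """Align the full query against the best substring of the target.

    Returns None when edlib finds no alignment within max_distance
    (max_distance < 0 searches unbounded).
    """
    if not query or not target:
        raise ValueError("empty sequence in alignment")
    res = edlib.align(query, target, mode="HW", task="path", k=max_distance)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end_incl = res["locations"][0]
    matches, columns = _cigar_counts(res["cigar"])
    return InfixHit(res["editDistance"], start, end_incl + 1, res["cigar"], matches, columns)


def percent_identity(
    seq_a: str,
    seq_b: str,
    min_coverage: float = 0.70,
) -> float | None:
    """Percent identity between two sequences over their best alignment.

    The shorter sequence is aligned infix-style against the longer; identity
    is matches / alignment columns x 100. Returns None (undefined) when the
    alignment covers less than ``min_coverage`` of either sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence in percent_identity")
    query, target = (seq_a, seq_b) if len(seq_a) <= len(seq_b) else (seq_b, seq_a)
    hit = align_infix(query, target)
    if hit is None:
        return None
    span = hit.target_end - hit.target_start
    # whole query is always consumed in infix mode
    if len(query) < min_coverage * len(target) or span < min_coverage * len(target):
        return None
    if span < min_coverage * len(query):  # degenerate, span shorter than query
        return None
    return hit.percent_identity
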