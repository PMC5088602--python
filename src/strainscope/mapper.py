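"""Self-contained seed-and-extend read mapper.

Reads are mapped to small reference sets (marker genes, pan-genome
centroids, representative genomes) by exact k-mer seeding followed by
banded edit-distance extension with edlib. Each read is reported a single
time according to its best hit; ties are recorded so downstream profilers
can either discard them (MAPQ rule) or redistribute them fractionally
across species.

Scoring is +1 per match, -2 per mismatch or gap column, so one extra
mismatch costs 3 score units. MAPQ is two-valued by contract: 60 when the
best hit beats the runner-up target by at least one mismatch (>= 3 score
units), else 3 — the default MAPQ >= 20 filter therefore implements
"discard non-unique best hits" exactly.

In ``local`` mode (genes) read ends hanging off a target are soft-clipped
for free; in ``global`` mode (genomes) only placements covering the full
read are candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .align import align_infix, parse_cigar, reverse_complement
from .io import ReadRecord, SequenceRecord

MATCH_SCORE = 1
ERROR_PENALTY = 2            # per mismatch or gap column
UNIQUE_MARGIN = MATCH_SCORE + ERROR_PENALTY  # score gap of one mismatch

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_MAP = np.full(128, -1, dtype=np.int8)
for _b, _c in _BASE_CODE.items():
    _CODE_MAP[ord(_b)] = _c


@dataclass
class Alignment:
    """Best placement of one read on one target."""

    read_id: str
    target_id: str
    target_start: int          # 0-based half-open target span
    target_end: int
    read_start: int            # aligned span in original read coordinates
    read_end: int
    strand: str                # '+' or '-'
    matches: int
    alignment_columns: int
    score: int
    mapq: int
    mean_read_quality: float
    read_length: int
    cigar: str
    aligned_seq: str           # aligned read bases, target sense
    aligned_quals: np.ndarray  # qualities matching aligned_seq
    tied_targets: list[str] = field(default_factory=list)

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.alignment_columns

    @property
    def read_coverage(self) -> float:
        return (self.read_end - self.read_start) / self.read_length

    @property
    def is_tie(self) -> bool:
        return len(self.tied_targets) > 1

    def aligned_columns(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-base (target_position, base_code, quality) arrays for match
        and mismatch columns. N bases are dropped (they never count)."""
        ops = parse_cigar(self.cigar)
        if all(op in "=X" for _, op in ops):  # no indels: contiguous span
            pos = np.arange(self.target_start, self.target_end)
            codes = np.frombuffer(self.aligned_seq.encode(), dtype=np.uint8)
            quals = self.aligned_quals
        else:
            positions, bases, qlist = [], [], []
            t, q = self.target_start, 0
            for n, op in ops:
                if op in "=X":
                    positions.extend(range(t, t + n))
                    bases.append(self.aligned_seq[q : q + n])
                    qlist.append(self.aligned_quals[q : q + n])
                    t += n
                    q += n
                elif op == "I":
                    q += n
                else:  # D
                    t += n
            pos = np.array(positions, dtype=np.int64)
            codes = np.frombuffer("".join(bases).encode(), dtype=np.uint8)
            quals = np.concatenate(qlist) if qlist else np.empty(0, dtype=np.int16)
        out_codes = _CODE_MAP[codes]
        keep = out_codes >= 0
        return pos[keep], out_codes[keep], quals[keep]


class ReferenceIndex:
    """Exact k-mer index over a set of reference sequences."""

    def __init__(self, targets: Sequence[SequenceRecord], k: int = 15):
        if not targets:
            raise ValueError("empty target set")
        self.targets = list(targets)
        self.k = k
        self.lengths = [len(t) for t in self.targets]
        index: dict[str, list[tuple[int, int]]] = {}
        for ti, rec in enumerate(self.targets):
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ti, pos))
        self._index = index

    def seed_hits(self, seq: str, stride: int) -> dict[tuple[int, int], int]:
        """Vote count per (target, diagonal) over sampled exact seeds."""
        k = self.k
        last = len(seq) - k
        if last < 0:
            return {}
        positions = list(range(0, last, stride)) + [last]
        votes: dict[tuple[int, int], int] = {}
        index = self._index
        for qpos in positions:
            hits = index.get(seq[qpos : qpos + k])
            if not hits:
                continue
            for ti, tpos in hits:
                key = (ti, tpos - qpos)
                votes[key] = votes.get(key, 0) + 1
        return votes


def _mismatch_positions(a: str, b: str) -> np.ndarray:
    return np.flatnonzero(
        np.frombuffer(a.encode(), dtype=np.uint8) != np.frombuffer(b.encode(), dtype=np.uint8)
    )


def _gapless_cigar(length: int, mismatches: np.ndarray) -> str:
    if len(mismatches) == 0:
        return f"{length}="
    parts = []
    prev = 0
    for pos in mismatches:
        if pos > prev:
            parts.append(f"{pos - prev}=")
        parts.append("1X")
        prev = pos + 1
    if prev < length:
        parts.append(f"{length - prev}=")
    return "".join(parts)


def _evaluate_candidate(
    seq: str,
    quals: np.ndarray,
    target: str,
    diag: int,
    mode: str,
    pad: int,
) -> tuple | None:
    """Extend one (target, diagonal) candidate; returns alignment pieces.

    A gapless placement on the seeded diagonal is preferred unless a
    gapped alignment saves at least two errors: substitutions, not
    spurious indel pairs, should explain point differences, and the
    pileup coordinates stay exact for substitution-only variation.
    """
    rl, tl = len(seq), len(target)
    if mode == "global":
        if diag < 0 or diag + rl > tl:
            return None
        qstart, qend = 0, rl
    else:
        qstart = max(0, -diag)
        qend = min(rl, tl - diag)
        if qend - qstart < pad + 1:
            return None
    segment = seq[qstart:qend]
    L = len(segment)
    tstart = diag + qstart
    gapless = None
    if 0 <= tstart and tstart + L <= tl:
        mism = _mismatch_positions(segment, target[tstart : tstart + L])
        gapless = (len(mism), mism)
        if len(mism) <= 2:  # a gapped alignment cannot save 2 errors here
            h, mism = gapless
            score = MATCH_SCORE * (L - h) - ERROR_PENALTY * h
            return (score, L - h, L, tstart, tstart + L, qstart, qend,
                    _gapless_cigar(L, mism), segment, quals[qstart:qend])
    wstart = max(0, diag + qstart - pad)
    wend = min(tl, diag + qend + pad)
    hit = align_infix(segment, target[wstart:wend])
    if hit is None and gapless is None:
        return None
    if gapless is not None and (hit is None or gapless[0] <= hit.edit_distance + 1):
        h, mism = gapless
        score = MATCH_SCORE * (L - h) - ERROR_PENALTY * h
        return (score, L - h, L, tstart, tstart + L, qstart, qend,
                _gapless_cigar(L, mism), segment, quals[qstart:qend])
    matches, columns = hit.matches, hit.columns
    score = MATCH_SCORE * matches - ERROR_PENALTY * (columns - matches)
    return (
        score,
        matches,
        columns,
        wstart + hit.target_start,
        wstart + hit.target_end,
        qstart,
        qend,
        hit.cigar,
        segment,
        quals[qstart:qend],
    )


def map_reads(
    reads: Iterable[ReadRecord],
    targets: Sequence[SequenceRecord] | ReferenceIndex,
    mode: Literal["local", "global"] = "local",
    k: int = 15,
    seed_stride: int = 10,
    pad: int = 8,
    max_targets: int = 8,
) -> list[Alignment]:
    """Best alignment per read against the target set (empty reads input
    gives an empty result). At most one alignment is reported per read;
    score ties across targets set ``tied_targets`` and MAPQ 3."""
    index = targets if isinstance(targets, ReferenceIndex) else ReferenceIndex(targets, k)
    out: list[Alignment] = []
    for read in reads:
        mean_q = read.mean_quality
        best = None  # (score, strand_rank, target_id) -> alignment pieces
        per_target: dict[int, tuple] = {}
        for strand in "+-":
            if strand == "+":
                seq, quals = read.sequence, read.qualities
            else:
                seq = reverse_complement(read.sequence)
                quals = read.qualities[::-1]
            votes = index.seed_hits(seq, seed_stride)
            if not votes:
                continue
            # best-voted diagonal per target, strongest targets first
            by_target: dict[int, tuple[int, int]] = {}
            for (ti, diag), v in votes.items():
                if ti not in by_target or v > by_target[ti][0]:
                    by_target[ti] = (v, diag)
            ranked = sorted(by_target.items(), key=lambda kv: -kv[1][0])[:max_targets]
            for ti, (_v, diag) in ranked:
                res = _evaluate_candidate(seq, quals, index.targets[ti].sequence, diag, mode, pad)
                if res is None:
                    continue
                prev = per_target.get(ti)
                if prev is None or res[0] > prev[1][0]:
                    per_target[ti] = (strand, res)
        if not per_target:
            continue
        scored = sorted(
            per_target.items(),
            key=lambda kv: (-kv[1][1][0], kv[1][0] != "+", index.targets[kv[0]].id),
        )
        best_ti, (strand, res) = scored[0]
        best_score = res[0]
        tied = [index.targets[ti].id for ti, (_s, r) in scored if r[0] == best_score]
        runner_up = scored[1][1][1][0] if len(scored) > 1 else None
        mapq = 60 if runner_up is None or best_score - runner_up >= UNIQUE_MARGIN else 3
        (score, matches, columns, tstart, tend, qstart, qend, cigar, seg, segq) = res
        rl = len(read)
        if strand == "-":  # report aligned span in original read coordinates
            read_start, read_end = rl - qend, rl - qstart
        else:
            read_start, read_end = qstart, qend
        out.append(
            Alignment(
                read_id=read.id,
                target_id=index.targets[best_ti].id,
                target_start=tstart,
                target_end=tend,
                read_start=read_start,
                read_end=read_end,
                strand=strand,
                matches=matches,
                alignment_columns=columns,
                score=score,
                mapq=mapq,
                mean_read_quality=mean_q,
                read_length=rl,
                cigar=cigar,
                aligned_seq=seg,
                aligned_quals=np.asarray(segq),
                tied_targets=sorted(tied),
            )
        )
    return out


def filter_alignments(
    alignments: Iterable[Alignment],
    map_pid: float = 94.0,
    aln_cov: float = 0.70,
    mapq_min: int = 20,
    read_qual_min: float = 20.0,
) -> list[Alignment]:
    """Keep alignments passing all four read-level filters: mapping percent
    identity, alignment coverage of the read, mapping quality, and mean
    sequence quality."""
    return [
        a
        for a in alignments
        if a.percent_identity >= map_pid
        and a.read_coverage >= aln_cov
        and a.mapq >= mapq_min
        and a.mean_read_quality >= read_qual_min
    ]
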