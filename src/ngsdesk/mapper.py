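"""Minimal deterministic seed-and-extend read mapper.

Exact k-mer seeding, ungapped extension, best-identity placement with
fixed (ref_id, position) tie-breaking.  Reverse-complement search is
deliberately unsupported; externally produced SAM is the escape hatch
for anything richer.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from ngsdesk.types import AlignmentRecord, Read, RefSeq

_ACGT = frozenset("ACGT")


@dataclass
class MapParams:
    k: int = 11
    min_identity: float = 0.8
    max_candidates: int = 50

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")


@dataclass
class MapSummary:
    n_reads: int = 0
    n_mapped: int = 0

    @property
    def n_unmapped(self) -> int:
        return self.n_reads - self.n_mapped


class KmerIndex:
    """Exact k-mer -> list of (ref_id, position); k-mers containing N skipped."""

    def __init__(self, refs: Sequence[RefSeq], k: int):
        if not refs:
            raise ValueError("need at least one reference")
        shortest = min(len(r.seq) for r in refs)
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest reference length {shortest}")
        self.k = k
        self.entries: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for ref in refs:
            seq = ref.seq
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.entries[kmer].append((ref.id, pos))

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.entries.get(kmer, [])


def build_index(refs: Sequence[RefSeq], k: int) -> KmerIndex:
    return KmerIndex(refs, k)


def _score_candidate(
    read_seq: str, ref_seq: str, start: int
) -> tuple[float, int, int]:
    """Ungapped identity of the read placed at ``start`` (may be negative).

    Returns (identity, overlap_read_lo, overlap_read_hi) where the overlap
    is the half-open read-offset range lying on the reference.
    """
    lo = max(0, -start)
    hi = min(len(read_seq), len(ref_seq) - start)
    if hi <= lo:
        return 0.0, 0, 0
    matches = comparable = 0
    for i in range(lo, hi):
        a, b = read_seq[i], ref_seq[start + i]
        if a not in _ACGT or b not in _ACGT:
            continue
        comparable += 1
        if a == b:
            matches += 1
    identity = matches / comparable if comparable else 0.0
    return identity, lo, hi


def map_read(
    read: Read,
    index: KmerIndex,
    refs: Sequence[RefSeq],
    params: MapParams,
) -> Optional[AlignmentRecord]:
    """Place one read; ``None`` when the best identity is below threshold.

    Candidate starts come from seed hits (read k-mer at offset o hitting
    reference position p gives candidate start p - o); candidates are
    ranked by seed-hit count, capped at ``max_candidates``, scored by
    ungapped identity over the overlap, ties broken by (ref_id, position).
    """
    k = index.k
    if len(read.seq) < k:
        return None
    ref_by_id = {r.id: r for r in refs}
    votes: Counter = Counter()
    for offset in range(len(read.seq) - k + 1):
        kmer = read.seq[offset : offset + k]
        if "N" in kmer:
            continue
        for ref_id, pos in index.hits(kmer):
            votes[(ref_id, pos - offset)] += 1
    if not votes:
        return None
    # Most seed support first; (ref_id, position) ascending on ties.
    candidates = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    candidates = candidates[: params.max_candidates]

    best = None  # (identity, ref_id, start, lo, hi)
    for (ref_id, start), _ in candidates:
        ref_seq = ref_by_id[ref_id].seq
        identity, lo, hi = _score_candidate(read.seq, ref_seq, start)
        if hi - lo < k:
            continue
        key = (-identity, ref_id, start)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (identity, ref_id, start, lo, hi)
    if best is None or best[0] < params.min_identity:
        return None
    identity, ref_id, start, lo, hi = best
    pairs = [(i, start + i) for i in range(lo, hi)]
    return AlignmentRecord(
        read_id=read.id,
        ref_id=ref_id,
        ref_start=start + lo,
        pairs=pairs,
        strand="+",
        identity=identity,
    )


def map_all(
    reads: Sequence[Read],
    refs: Sequence[RefSeq],
    params: Optional[MapParams] = None,
) -> tuple[list[AlignmentRecord], MapSummary]:
    """Map every read, preserving input order; unmapped reads are counted."""
    params = params or MapParams()
    index = build_index(refs, params.k)
    summary = MapSummary(n_reads=len(reads))
    alignments = []
    for read in reads:
        aln = map_read(read, index, refs, params)
        if aln is not None:
            alignments.append(aln)
            summary.n_mapped += 1
    return alignments, summary
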