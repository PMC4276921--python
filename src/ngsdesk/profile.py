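"""Pileup-based SNV profiler.

Per-position base counts against a reference, SNV calling with
depth/frequency thresholds, consensus extraction, and conversion to the
sparse SNV-frequency profiles consumed by the clustering tool.

Deletions count toward depth but never toward allele frequencies or
calls; read N bases are ignored entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ngsdesk import core_io
from ngsdesk.types import AlignmentRecord, Read, RefSeq

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
DEL = 4  # column index for deletions

DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_FREQ = 0.05


@dataclass
class PositionProfile:
    """Counts of A/C/G/T/del per 0-based reference position."""

    ref_id: str
    counts: np.ndarray  # shape (ref_length, 5), dtype int64

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class SNVCall:
    ref_id: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.alt_base == self.ref_base:
            raise ValueError("alt_base must differ from ref_base")
        if not 0 < self.alt_count <= self.depth:
            raise ValueError("need 0 < alt_count <= depth")

    @property
    def alt_freq(self) -> float:
        return self.alt_count / self.depth


@dataclass
class SNVProfile:
    """Sparse non-reference frequencies plus the per-position depth map.

    ``freqs`` maps positions carrying non-reference bases to their total
    non-reference frequency; ``depths`` maps every covered position
    (depth >= 1) to its depth so that downstream comparisons can
    distinguish "covered, no variant" from "not covered".
    """

    ref_id: str
    freqs: dict[int, float] = field(default_factory=dict)
    depths: dict[int, int] = field(default_factory=dict)


def pileup(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[Read] | dict,
    ref: RefSeq,
) -> PositionProfile:
    """Tally aligned read bases per reference position.

    Each aligned read base increments exactly one base counter; a
    reference offset with no read base increments the deletion counter;
    N bases are skipped.
    """
    read_by_id = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    counts = np.zeros((len(ref.seq), 5), dtype=np.int64)
    for aln in alignments:
        if aln.ref_id != ref.id:
            raise ValueError(
                f"alignment of {aln.read_id!r} targets {aln.ref_id!r}, "
                f"expected {ref.id!r}"
            )
        if aln.ref_end > len(ref.seq):
            raise ValueError(f"alignment of {aln.read_id!r} past reference end")
        seq = read_by_id[aln.read_id].seq
        for i, j in aln.pairs:
            if j is None:
                continue  # insertion: no reference position
            if i is None:
                counts[j, DEL] += 1
                continue
            base = seq[i]
            if base == "N":
                continue
            counts[j, _BASE_INDEX[base]] += 1
    return PositionProfile(ref_id=ref.id, counts=counts)


def call_snvs(
    profile: PositionProfile,
    ref: RefSeq,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_freq: float = DEFAULT_MIN_FREQ,
) -> list[SNVCall]:
    """Call non-reference bases passing depth and frequency thresholds."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not 0.0 < min_freq <= 1.0:
        raise ValueError("min_freq must be in (0, 1]")
    depth = profile.depth
    calls = []
    for pos in np.nonzero(depth >= min_depth)[0]:
        ref_base = ref.seq[pos]
        d = int(depth[pos])
        for base in BASES:
            if base == ref_base:
                continue
            count = int(profile.counts[pos, _BASE_INDEX[base]])
            if count > 0 and count / d >= min_freq:
                calls.append(
                    SNVCall(
                        ref_id=profile.ref_id,
                        pos=int(pos),
                        ref_base=ref_base,
                        alt_base=base,
                        depth=d,
                        alt_count=count,
                    )
                )
    return calls


def consensus(
    profile: PositionProfile, ref: RefSeq, min_depth: int = 1
) -> RefSeq:
    """Majority-base consensus; reference base wherever evidence is thin.

    Ties break toward the reference base, then alphabetically.  Deletions
    never shorten the output.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    out = list(ref.seq)
    depth = profile.depth
    for pos in range(len(ref.seq)):
        if depth[pos] < min_depth:
            continue
        base_counts = profile.counts[pos, :4]
        if base_counts.sum() == 0:
            continue
        best = int(base_counts.max())
        winners = [BASES[i] for i in range(4) if base_counts[i] == best]
        if ref.seq[pos] in winners:
            out[pos] = ref.seq[pos]
        else:
            out[pos] = min(winners)
    return RefSeq(id=f"{ref.id}_consensus", seq="".join(out))


def to_snv_profile(
    profile: PositionProfile, ref: RefSeq, min_depth: int = 1
) -> SNVProfile:
    """Collapse a pileup into sparse non-reference frequencies.

    The frequency denominator is A+C+G+T (deletions excluded), keeping
    frequencies comparable across samples with different deletion rates.
    Positions with no non-reference base are omitted from ``freqs`` but
    retained in ``depths``.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    depth = profile.depth
    snv = SNVProfile(ref_id=profile.ref_id)
    for pos in np.nonzero(depth >= 1)[0]:
        snv.depths[int(pos)] = int(depth[pos])
    for pos in np.nonzero(depth >= min_depth)[0]:
        base_total = int(profile.counts[pos, :4].sum())
        if base_total == 0:
            continue
        ref_count = int(profile.counts[pos, _BASE_INDEX[ref.seq[pos]]])
        non_ref = base_total - ref_count
        if non_ref > 0:
            snv.freqs[int(pos)] = non_ref / base_total
    return snv


# ---------------------------------------------------------------------------
# TSV export/import
# ---------------------------------------------------------------------------

PROFILE_HEADER = ["ref_id", "pos_1based", "ref_base", "A", "C", "G", "T", "del", "depth"]
SNV_HEADER = ["ref_id", "pos_1based", "ref_base", "alt_base", "depth", "alt_count", "alt_freq"]


def write_profile_table(profile: PositionProfile, ref: RefSeq, path) -> None:
    depth = profile.depth
    rows = (
        [
            profile.ref_id,
            pos + 1,
            ref.seq[pos],
            *(int(profile.counts[pos, i]) for i in range(5)),
            int(depth[pos]),
        ]
        for pos in range(len(ref.seq))
    )
    core_io.write_tsv(path, PROFILE_HEADER, rows)


def read_profile_table(path) -> tuple[PositionProfile, str]:
    """Read a profile TSV back; returns the profile and its reference bases."""
    _, rows = read_rows_checked(path, PROFILE_HEADER)
    counts = np.zeros((len(rows), 5), dtype=np.int64)
    ref_bases = []
    ref_id = rows[0][0] if rows else ""
    for row in rows:
        pos = int(row[1]) - 1
        ref_bases.append(row[2])
        counts[pos] = [int(v) for v in row[3:8]]
    return PositionProfile(ref_id=ref_id, counts=counts), "".join(ref_bases)


def read_rows_checked(path, expected_header):
    header, rows = core_io.read_tsv(path)
    if header != list(expected_header):
        raise ValueError(f"{path}: unexpected header {header}")
    return header, rows


def write_snv_table(calls: Sequence[SNVCall], path) -> None:
    rows = (
        [
            c.ref_id,
            c.pos + 1,
            c.ref_base,
            c.alt_base,
            c.depth,
            c.alt_count,
            f"{c.alt_freq:.6g}",
        ]
        for c in calls
    )
    core_io.write_tsv(path, SNV_HEADER, rows)


def read_snv_table(path) -> list[SNVCall]:
    _, rows = read_rows_checked(path, SNV_HEADER)
    return [
        SNVCall(
            ref_id=row[0],
            pos=int(row[1]) - 1,
            ref_base=row[2],
            alt_base=row[3],
            depth=int(row[4]),
            alt_count=int(row[5]),
        )
        for row in rows
    ]
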