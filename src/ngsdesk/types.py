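"""Shared domain types.

All internal coordinates are 0-based, half-open.  Conversion to the 1-based
conventions of SAM and the TSV exports happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")
IUPAC_EXTRA = frozenset("RYSWKMBDHV")  # accepted on input, rejected per policy


@dataclass
class Read:
    """A sequencing read; ``truth_source`` is set only by the simulator."""

    id: str
    seq: str
    qual: Optional[str] = None
    truth_source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class RefSeq:
    """A reference sequence with an optional taxon label."""

    id: str
    seq: str
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"reference {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


#: Sentinel for the missing side of an aligned pair (insertion/deletion).
GAP = None


@dataclass
class AlignmentRecord:
    """A CIGAR-free alignment layout.

    ``pairs`` is a list of ``(read_offset, ref_offset)`` tuples, either side
    possibly ``None`` (GAP): ``(i, None)`` is an inserted read base,
    ``(None, j)`` is a deleted reference base.  Aligned ref offsets are
    strictly increasing.
    """

    read_id: str
    ref_id: str
    ref_start: int
    pairs: list = field(default_factory=list)
    strand: str = "+"
    identity: float = 0.0

    def __post_init__(self) -> None:
        if self.ref_start < 0:
            raise ValueError("ref_start must be >= 0")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        last = -1
        for _, j in self.pairs:
            if j is not None:
                if j <= last:
                    raise ValueError("aligned ref offsets must be strictly increasing")
                last = j

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        ref_offsets = [j for _, j in self.pairs if j is not None]
        return (max(ref_offsets) + 1) if ref_offsets else self.ref_start


def validate_dna(seq: str, record_id: str, allow_n: bool = True) -> str:
    """Uppercase ``seq`` and reject characters outside {A,C,G,T,N}."""
    up = seq.upper()
    allowed = DNA_ALPHABET if allow_n else DNA_ALPHABET - {"N"}
    bad = set(up) - allowed
    if bad:
        raise ValueError(
            f"record {record_id!r}: characters outside the DNA alphabet: "
            f"{sorted(bad)}"
        )
    return up
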