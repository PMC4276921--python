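"""Synthetic data generation with recorded ground truth.

Every operation is deterministic under its seed.  Reads are single-end,
fixed-length, forward-strand, substitution-errors-only; each read records
its source genome in ``truth_source``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ngsdesk.types import Read, RefSeq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_INDEX = {base: i for i, base in enumerate("ACGT")}


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 10_000
    snv_rate: float = 0.01
    mixture_weights: list[float] = field(default_factory=lambda: [1.0])
    n_reads: int = 1000
    read_length: int = 100
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        weights = np.asarray(self.mixture_weights, dtype=float)
        if (weights < 0).any():
            raise ValueError("mixture weights must be non-negative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length > self.genome_length:
            raise ValueError("read_length must not exceed genome_length")


@dataclass
class TruthSet:
    """Ground truth recorded by the simulator.

    ``snvs`` maps genome id -> list of (0-based position, ref_base,
    alt_base); ``read_sources`` maps read id -> (genome id, 0-based start).
    """

    snvs: dict[str, list[tuple[int, str, str]]] = field(default_factory=dict)
    read_sources: dict[str, tuple[str, int]] = field(default_factory=dict)


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def _array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def make_genome(
    length: int, gc_content: float = 0.5, seed: int = 0, id: str = "genome"
) -> RefSeq:
    """I.i.d. random genome with P(G)+P(C) = ``gc_content`` split equally."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return RefSeq(id=id, seq=_array_to_seq(_BASES[idx]))


def mutate(
    genome: RefSeq,
    snv_rate: Optional[float] = None,
    n_snvs: Optional[int] = None,
    seed: int = 0,
    id: Optional[str] = None,
) -> tuple[RefSeq, list[tuple[int, str, str]]]:
    """Plant SNVs at positions sampled uniformly without replacement.

    The alternate base is uniform over the three non-reference bases.
    Returns the mutant and its truth list of (position, ref, alt).
    """
    length = len(genome.seq)
    rng = np.random.default_rng(seed)
    if n_snvs is None:
        if snv_rate is None:
            raise ValueError("provide snv_rate or n_snvs")
        if not 0.0 <= snv_rate < 1.0:
            raise ValueError("snv_rate must be in [0, 1)")
        n_snvs = int(rng.binomial(length, snv_rate))
    if n_snvs > length:
        raise ValueError(f"n_snvs={n_snvs} exceeds genome length {length}")
    positions = np.sort(rng.choice(length, size=n_snvs, replace=False))
    arr = _seq_to_array(genome.seq)
    truth: list[tuple[int, str, str]] = []
    for pos in positions:
        ref_base = chr(arr[pos])
        choices = [b for b in "ACGT" if b != ref_base]
        alt_base = choices[rng.integers(3)]
        arr[pos] = ord(alt_base)
        truth.append((int(pos), ref_base, alt_base))
    mutant_id = id if id is not None else f"{genome.id}_mut"
    return RefSeq(id=mutant_id, seq=_array_to_seq(arr)), truth


def recombine(
    parents: Sequence[RefSeq],
    breakpoints: Sequence[int],
    id: str = "recombinant",
) -> tuple[RefSeq, list[tuple[str, int, int]]]:
    """Splice equal-length parents at the given breakpoints.

    Segment i (between breakpoints i-1 and i) comes from
    ``parents[i % len(parents)]``.  Returns the recombinant and its
    segment map of (parent_id, start, end) half-open intervals.
    """
    if not parents:
        raise ValueError("need at least one parent")
    length = len(parents[0].seq)
    if any(len(p.seq) != length for p in parents):
        raise ValueError("all parents must have equal length (pre-aligned)")
    bps = list(breakpoints)
    if bps != sorted(set(bps)) or any(not 0 < b < length for b in bps):
        raise ValueError("breakpoints must be strictly increasing within (0, length)")
    bounds = [0] + bps + [length]
    pieces = []
    segment_map = []
    for i in range(len(bounds) - 1):
        start, end = bounds[i], bounds[i + 1]
        parent = parents[i % len(parents)]
        pieces.append(parent.seq[start:end])
        segment_map.append((parent.id, start, end))
    return RefSeq(id=id, seq="".join(pieces)), segment_map


def make_reads(
    genomes: Sequence[RefSeq],
    weights: Sequence[float],
    n_reads: int,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Read], TruthSet]:
    """Draw error-bearing fixed-length forward-strand reads from a mixture.

    Source genome per read follows ``weights``; the start is uniform over
    valid starts; each base is flipped to a uniform other base with
    probability ``error_rate``.
    """
    weights_arr = np.asarray(weights, dtype=float)
    if len(weights_arr) != len(genomes):
        raise ValueError("one weight per genome required")
    if (weights_arr < 0).any() or abs(weights_arr.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    for genome in genomes:
        if read_length > len(genome.seq):
            raise ValueError("read_length exceeds a genome length")

    rng = np.random.default_rng(seed)
    arrays = [_seq_to_array(g.seq) for g in genomes]
    sources = rng.choice(len(genomes), size=n_reads, p=weights_arr)
    pad = len(str(max(n_reads - 1, 1)))
    reads: list[Read] = []
    truth = TruthSet()
    for i in range(n_reads):
        src = int(sources[i])
        genome = genomes[src]
        start = int(rng.integers(len(genome.seq) - read_length + 1))
        arr = arrays[src][start : start + read_length].copy()
        if error_rate > 0:
            flips = np.nonzero(rng.random(read_length) < error_rate)[0]
            for pos in flips:
                current = chr(arr[pos])
                others = [b for b in "ACGT" if b != current]
                arr[pos] = ord(others[rng.integers(3)])
        read_id = f"r{i:0{pad}d}"
        reads.append(
            Read(
                id=read_id,
                seq=_array_to_seq(arr),
                qual="I" * read_length,
                truth_source=genome.id,
            )
        )
        truth.read_sources[read_id] = (genome.id, start)
    return reads, truth
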