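"""Readers and writers for every external format the toolkit touches.

Formats: FASTA, FASTQ (4-line records), a minimal SAM dialect
(mandatory columns, CIGAR ops M/=/X/I/D/S), Newick, and '#'-headed TSV
tables.  Internally everything is 0-based half-open; SAM POS and the
``pos_1based`` TSV columns are converted at this boundary only.
"""

from __future__ import annotations

import os
import tempfile
from contextlib import contextmanager
from typing import Iterable, Optional, Sequence, Union

import pysam
from Bio import SeqIO

from ngsdesk.tree import TreeNode
from ngsdesk.types import AlignmentRecord, Read, RefSeq, validate_dna

# pysam CIGAR op codes
_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_S = 0, 1, 2, 4
_CIGAR_EQ, _CIGAR_X = 7, 8
_SUPPORTED_OPS = {_CIGAR_M, _CIGAR_I, _CIGAR_D, _CIGAR_S, _CIGAR_EQ, _CIGAR_X}
_ACGT = frozenset("ACGT")


@contextmanager
def atomic_write(path: Union[str, os.PathLike], mode: str = "w"):
    """Write to a temp file in the destination directory, then rename."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp.")
    try:
        with os.fdopen(fd, mode) as handle:
            yield handle
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path, as_reads: bool = False) -> list:
    """Read a FASTA file into :class:`RefSeq` (or :class:`Read`) records.

    Sequences are uppercased; N is preserved; characters outside
    {A,C,G,T,N} raise :class:`ValueError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = validate_dna(str(rec.seq), rec.id)
        if as_reads:
            records.append(Read(id=rec.id, seq=seq))
        else:
            records.append(RefSeq(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return records


def write_fasta(records: Iterable[Union[RefSeq, Read]], path, width: int = 70) -> None:
    with atomic_write(path) as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[Read]:
    """Read 4-line-per-record FASTQ; qualities kept verbatim."""
    reads = []
    try:
        for rec in SeqIO.parse(os.fspath(path), "fastq"):
            seq = validate_dna(str(rec.seq), rec.id)
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(Read(id=rec.id, seq=seq, qual=qual))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed FASTQ: {exc}") from exc
    if not reads:
        raise ValueError(f"{path}: empty or not FASTQ")
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    with atomic_write(path) as handle:
        for read in reads:
            qual = read.qual if read.qual is not None else "I" * len(read.seq)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM (minimal dialect)
# ---------------------------------------------------------------------------

def _identity(pairs, read_seq: str, ref_seq: str) -> float:
    """Match fraction over aligned pairs; N on either side is excluded."""
    matches = comparable = 0
    for i, j in pairs:
        if i is None or j is None:
            continue
        a, b = read_seq[i], ref_seq[j]
        if a not in _ACGT or b not in _ACGT:
            continue
        comparable += 1
        if a == b:
            matches += 1
    return matches / comparable if comparable else 0.0


def _sam_header(refs: Sequence[RefSeq]) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.id, "LN": len(r.seq)} for r in refs],
    }


def _cigar_from_pairs(pairs, read_length: int):
    """Build CIGAR tuples (leading/trailing soft clips, M/I/D core)."""
    read_offsets = [i for i, _ in pairs if i is not None]
    lead = min(read_offsets) if read_offsets else 0
    trail = read_length - 1 - max(read_offsets) if read_offsets else read_length
    ops = []

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    for i, j in pairs:
        if i is not None and j is not None:
            push(_CIGAR_M)
        elif i is not None:
            push(_CIGAR_I)
        else:
            push(_CIGAR_D)
    cigar = []
    if lead:
        cigar.append((_CIGAR_S, lead))
    cigar.extend((op, n) for op, n in ops)
    if trail:
        cigar.append((_CIGAR_S, trail))
    return cigar


def write_sam(
    alignments: Sequence[AlignmentRecord],
    reads: Union[Sequence[Read], dict],
    refs: Sequence[RefSeq],
    path,
) -> None:
    """Serialize alignments to SAM text (flag 0, forward strand only)."""
    read_by_id = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    ref_index = {r.id: i for i, r in enumerate(refs)}
    header = pysam.AlignmentHeader.from_dict(_sam_header(refs))
    path = os.fspath(path)
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for aln in alignments:
            read = read_by_id[aln.read_id]
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.flag = 0
            seg.reference_id = ref_index[aln.ref_id]
            seg.reference_start = aln.ref_start
            seg.mapping_quality = 255
            seg.cigartuples = _cigar_from_pairs(aln.pairs, len(read.seq))
            seg.query_sequence = read.seq
            if read.qual is not None:
                seg.query_qualities = pysam.qualitystring_to_array(read.qual)
            out.write(seg)


def read_sam(path, refs: Sequence[RefSeq]) -> list[AlignmentRecord]:
    """Parse a SAM file back into alignment records.

    Unmapped records (flag 4) are skipped.  RNAMEs absent from ``refs`` and
    CIGAR ops outside M/=/X/I/D/S are errors.  Identity is recomputed from
    the stored sequence against the reference (N-excluded).
    """
    ref_by_id = {r.id: r for r in refs}
    records = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            ref_name = seg.reference_name
            if ref_name not in ref_by_id:
                raise ValueError(f"{path}: RNAME {ref_name!r} not in references")
            bad = [op for op, _ in seg.cigartuples if op not in _SUPPORTED_OPS]
            if bad:
                raise ValueError(
                    f"{path}: record {seg.query_name!r}: unsupported CIGAR op "
                    f"code(s) {sorted(set(bad))}"
                )
            pairs = []
            qpos, rpos = 0, seg.reference_start
            for op, length in seg.cigartuples:
                if op == _CIGAR_S:
                    qpos += length
                elif op in (_CIGAR_M, _CIGAR_EQ, _CIGAR_X):
                    for _ in range(length):
                        pairs.append((qpos, rpos))
                        qpos += 1
                        rpos += 1
                elif op == _CIGAR_I:
                    for _ in range(length):
                        pairs.append((qpos, None))
                        qpos += 1
                elif op == _CIGAR_D:
                    for _ in range(length):
                        pairs.append((None, rpos))
                        rpos += 1
            ref_seq = ref_by_id[ref_name].seq
            identity = _identity(pairs, seg.query_sequence, ref_seq)
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=ref_name,
                    ref_start=seg.reference_start,
                    pairs=pairs,
                    strand="-" if seg.is_reverse else "+",
                    identity=identity,
                )
            )
    return records


def sam_reads(path) -> list[Read]:
    """Recover read records (id/seq/qual) from a SAM file, mapped ones only."""
    reads = []
    seen = set()
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.query_name in seen:
                continue
            seen.add(seg.query_name)
            qual = None
            if seg.query_qualities is not None:
                qual = pysam.qualities_to_qualitystring(seg.query_qualities)
            reads.append(Read(id=seg.query_name, seq=seg.query_sequence, qual=qual))
    return reads


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

_NEWICK_META = set(" ()[]':;,")


def _quote_label(label: str) -> str:
    if set(label) & _NEWICK_META:
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: TreeNode) -> str:
    """Serialize a rooted tree (with branch lengths) to a Newick string."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{_quote_label(node.label)}:{node.length}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}):{node.length}"

    if tree.is_leaf:
        return f"{_quote_label(tree.label)}:{tree.length};"
    inner = ",".join(fmt(c) for c in tree.children)
    return f"({inner});"


def write_newick_file(tree: TreeNode, path) -> None:
    with atomic_write(path) as handle:
        handle.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# TSV tables ('#'-prefixed header line, tab-separated)
# ---------------------------------------------------------------------------

def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with atomic_write(path) as handle:
        handle.write("#" + "\t".join(header) + "\n")
        for row in rows:
            handle.write("\t".join(str(v) for v in row) + "\n")


def read_tsv(path) -> tuple[list[str], list[list[str]]]:
    header: Optional[list[str]] = None
    rows: list[list[str]] = []
    with open(os.fspath(path)) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    header = line[1:].split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: missing '#'-prefixed header line")
    return header, rows


def read_taxon_map(path) -> dict[str, str]:
    """TSV of (ref_id, taxon) -> dict."""
    _, rows = read_tsv(path)
    return {row[0]: row[1] for row in rows}


def write_taxon_map(taxon_map: dict[str, str], path) -> None:
    write_tsv(path, ["ref_id", "taxon"], sorted(taxon_map.items()))
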