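"""SNV-based phylogenetics with shrunk-genome concatenation.

Builds a binary sample-by-variant presence matrix (variant key =
(position, alt_base)), trees from row Hamming distances, and the
"shrunk genome" concatenation of merged flanking windows around the
union of SNV positions with per-sample alleles substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ngsdesk import core_io
from ngsdesk.cluster import DistanceMatrix, hierarchical_cluster
from ngsdesk.profile import SNVCall
from ngsdesk.tree import TreeNode
from ngsdesk.types import RefSeq

DEFAULT_FLANK = 10

VariantKey = tuple[int, str]  # (0-based position, alt_base)


@dataclass
class SnvMatrix:
    sample_labels: list[str]
    variant_keys: list[VariantKey]  # sorted by (pos, alt)
    presence: np.ndarray  # shape (n_samples, n_variants), dtype bool


@dataclass
class WindowSet:
    """Sorted, pairwise-disjoint half-open intervals on the reference."""

    intervals: list[tuple[int, int]]

    @property
    def total_length(self) -> int:
        return sum(e - s for s, e in self.intervals)


def _keys(snvs: Sequence[SNVCall]) -> set[VariantKey]:
    return {(c.pos, c.alt_base) for c in snvs}


def build_snv_matrix(
    per_sample_snv_lists: dict[str, Sequence[SNVCall]]
    | Sequence[tuple[str, Sequence[SNVCall]]],
) -> SnvMatrix:
    """Union all samples' (pos, alt) keys into a binary presence matrix."""
    items = (
        list(per_sample_snv_lists.items())
        if isinstance(per_sample_snv_lists, dict)
        else list(per_sample_snv_lists)
    )
    if len(items) < 2:
        raise ValueError("need at least 2 samples")
    labels = [label for label, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sample labels")
    all_keys = sorted(set().union(*(_keys(snvs) for _, snvs in items)))
    key_index = {k: i for i, k in enumerate(all_keys)}
    presence = np.zeros((len(items), len(all_keys)), dtype=bool)
    for row, (_, snvs) in enumerate(items):
        for key in _keys(snvs):
            presence[row, key_index[key]] = True
    return SnvMatrix(sample_labels=labels, variant_keys=all_keys, presence=presence)


def snv_tree(
    matrix: SnvMatrix, linkage: str = "average", add_reference_outgroup: bool = False
) -> TreeNode:
    """Tree from pairwise Hamming distances between binary presence rows."""
    labels = list(matrix.sample_labels)
    presence = matrix.presence
    if add_reference_outgroup:
        labels = labels + ["reference"]
        presence = np.vstack([presence, np.zeros(presence.shape[1], dtype=bool)])
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.count_nonzero(presence[i] != presence[j]))
            values[i, j] = values[j, i] = d
    return hierarchical_cluster(DistanceMatrix(labels=labels, values=values), linkage)


def shrink_windows(
    snv_positions: Sequence[int], flank: int, ref_length: int
) -> WindowSet:
    """Merged flanking windows [p-flank, p+flank+1) clipped to the reference."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    for pos in snv_positions:
        if not 0 <= pos < ref_length:
            raise ValueError(f"position {pos} outside reference of length {ref_length}")
    raw = sorted(
        (max(0, p - flank), min(ref_length, p + flank + 1))
        for p in set(snv_positions)
    )
    merged: list[tuple[int, int]] = []
    for start, end in raw:
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return WindowSet(intervals=merged)


@dataclass
class AlignedSeq:
    """One row of the shrunk-genome alignment; may be empty (no SNVs)."""

    id: str
    seq: str


def shrunk_genomes(
    ref: RefSeq,
    per_sample_snvs: dict[str, Sequence[SNVCall]]
    | Sequence[tuple[str, Sequence[SNVCall]]],
    flank: int = DEFAULT_FLANK,
) -> list[AlignedSeq]:
    """Concatenated reference windows with sample alleles substituted.

    Windows are computed on the union of all samples' SNV positions, so
    every output sequence (including the leading reference row) has the
    same length — a drop-in alignment for external tree tools.  With no
    SNVs anywhere all rows are empty.
    """
    items = (
        list(per_sample_snvs.items())
        if isinstance(per_sample_snvs, dict)
        else list(per_sample_snvs)
    )
    union_positions = sorted({c.pos for _, snvs in items for c in snvs})
    windows = shrink_windows(union_positions, flank, len(ref.seq))
    ref_concat = "".join(ref.seq[s:e] for s, e in windows.intervals)
    records = [AlignedSeq(id="reference", seq=ref_concat)]
    for label, snvs in items:
        seq = list(ref.seq)
        for call in snvs:
            seq[call.pos] = call.alt_base
        records.append(
            AlignedSeq(
                id=label,
                seq="".join("".join(seq[s:e]) for s, e in windows.intervals),
            )
        )
    return records


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

def write_snv_matrix(matrix: SnvMatrix, path) -> None:
    header = ["sample"] + [f"{pos + 1}{alt}" for pos, alt in matrix.variant_keys]
    rows = (
        [label] + [int(v) for v in matrix.presence[i]]
        for i, label in enumerate(matrix.sample_labels)
    )
    core_io.write_tsv(path, header, rows)
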