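"""Recombination detection across mutually aligned references.

Reads are attributed to their best-hit reference; per-reference coverage
along the shared (identity) column map is windowed, each window's
dominant reference is gated by coverage and dominance-ratio thresholds,
runs of same-dominant windows become segments, and adjacent segments
with different dominant references yield candidate breakpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ngsdesk import core_io
from ngsdesk.mapper import MapParams, build_index, map_read
from ngsdesk.types import AlignmentRecord, Read, RefSeq

DEFAULT_WINDOW = 200
DEFAULT_MIN_RATIO = 2.0
DEFAULT_MIN_COV = 5


@dataclass
class CoverageMatrix:
    ref_ids: list[str]
    values: np.ndarray  # shape (n_refs, n_columns), non-negative ints

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class Segment:
    start: int  # 0-based half-open columns
    end: int
    dominant_ref: str
    mean_dominant_coverage: float
    dominance_ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")


def coverage_matrix(
    alignments: Sequence[AlignmentRecord], refs: Sequence[RefSeq]
) -> CoverageMatrix:
    """Per-reference read coverage over shared columns.

    References must be equal length (identity mutual alignment); for real
    unequal genomes, supply externally aligned gap-columned FASTA.  Entry
    (r, c) counts best-hit-to-r reads whose alignment covers column c.
    """
    lengths = {len(r.seq) for r in refs}
    if len(lengths) != 1:
        raise ValueError(
            "references have unequal lengths; supply a pre-computed mutual "
            "alignment (equal-length, gap-columned FASTA)"
        )
    n_cols = lengths.pop()
    row = {r.id: i for i, r in enumerate(refs)}
    values = np.zeros((len(refs), n_cols), dtype=np.int64)
    for aln in alignments:
        if aln.ref_id not in row:
            raise ValueError(f"alignment references unknown ref {aln.ref_id!r}")
        cols = sorted({j for _, j in aln.pairs if j is not None})
        for c in cols:
            values[row[aln.ref_id], c] += 1
    return CoverageMatrix(ref_ids=[r.id for r in refs], values=values)


def per_reference_coverage(
    reads: Sequence[Read],
    refs: Sequence[RefSeq],
    params: MapParams = None,
) -> CoverageMatrix:
    """Coverage matrix from mapping each read against every reference.

    Each read is placed independently on each reference; it contributes
    coverage to every reference achieving its best identity.  Equal-best
    ties therefore cover all tied rows — identical references yield
    identical rows and no window can show confident dominance, so the
    detector cannot hallucinate recombination without divergence signal.
    """
    params = params or MapParams()
    lengths = {len(r.seq) for r in refs}
    if len(lengths) != 1:
        raise ValueError(
            "references have unequal lengths; supply a pre-computed mutual "
            "alignment (equal-length, gap-columned FASTA)"
        )
    n_cols = lengths.pop()
    indexes = [build_index([r], params.k) for r in refs]
    values = np.zeros((len(refs), n_cols), dtype=np.int64)
    for read in reads:
        placements = []
        for row, (ref, index) in enumerate(zip(refs, indexes)):
            aln = map_read(read, index, [ref], params)
            if aln is not None:
                placements.append((row, aln))
        if not placements:
            continue
        best = max(aln.identity for _, aln in placements)
        for row, aln in placements:
            if aln.identity == best:
                for _, j in aln.pairs:
                    if j is not None:
                        values[row, j] += 1
    return CoverageMatrix(ref_ids=[r.id for r in refs], values=values)


def dominant_segments(
    matrix: CoverageMatrix,
    window: int = DEFAULT_WINDOW,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_cov: float = DEFAULT_MIN_COV,
) -> list[Segment]:
    """Merge windows sharing a confidently dominant reference.

    Per non-overlapping window the dominant reference is the argmax of
    window-mean coverage, valid only when that mean is >= ``min_cov`` and
    at least ``min_ratio`` times the runner-up mean; ambiguous windows
    join no segment.  A segment's dominance_ratio is the weakest of its
    windows' ratios.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if min_ratio <= 1.0:
        raise ValueError("min_ratio must be > 1")
    if min_cov < 0:
        raise ValueError("min_cov must be >= 0")
    n_refs, n_cols = matrix.values.shape
    segments: list[Segment] = []
    current = None  # [start, end, ref_index, min_ratio_seen]
    for w_start in range(0, n_cols, window):
        w_end = min(w_start + window, n_cols)
        means = matrix.values[:, w_start:w_end].mean(axis=1)
        order = np.argsort(means, kind="stable")
        top = int(order[-1])
        top_mean = float(means[top])
        runner_mean = float(means[order[-2]]) if n_refs > 1 else 0.0
        ratio = top_mean / runner_mean if runner_mean > 0 else math.inf
        valid = top_mean >= min_cov and top_mean > 0 and ratio >= min_ratio
        if valid and current is not None and current[2] == top and current[1] == w_start:
            current[1] = w_end
            current[3] = min(current[3], ratio)
            continue
        if current is not None:
            segments.append(_finish_segment(matrix, current))
            current = None
        if valid:
            current = [w_start, w_end, top, ratio]
    if current is not None:
        segments.append(_finish_segment(matrix, current))
    return segments


def _finish_segment(matrix: CoverageMatrix, state) -> Segment:
    start, end, ref_idx, worst_ratio = state
    mean_cov = float(matrix.values[ref_idx, start:end].mean())
    return Segment(
        start=start,
        end=end,
        dominant_ref=matrix.ref_ids[ref_idx],
        mean_dominant_coverage=mean_cov,
        dominance_ratio=worst_ratio,
    )


def breakpoints(
    segments: Sequence[Segment],
) -> list[tuple[int, str, str]]:
    """(column, ref_from, ref_to) per adjacent segment pair changing reference.

    The column is the midpoint of the inter-segment gap (the shared
    boundary when segments touch).
    """
    out = []
    for a, b in zip(segments, segments[1:]):
        if a.dominant_ref == b.dominant_ref:
            continue
        column = (a.end + b.start) // 2
        out.append((column, a.dominant_ref, b.dominant_ref))
    return out


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

SEGMENT_HEADER = [
    "start_1based", "end_1based", "dominant_ref",
    "mean_dominant_coverage", "dominance_ratio",
]
BREAKPOINT_HEADER = ["column_1based", "ref_from", "ref_to"]


def write_coverage_matrix(matrix: CoverageMatrix, path) -> None:
    header = ["ref_id"] + [str(c + 1) for c in range(matrix.n_columns)]
    rows = (
        [ref_id] + [int(v) for v in matrix.values[i]]
        for i, ref_id in enumerate(matrix.ref_ids)
    )
    core_io.write_tsv(path, header, rows)


def write_segments(segments: Sequence[Segment], path) -> None:
    rows = (
        [
            s.start + 1,
            s.end,
            s.dominant_ref,
            f"{s.mean_dominant_coverage:.6g}",
            "inf" if math.isinf(s.dominance_ratio) else f"{s.dominance_ratio:.6g}",
        ]
        for s in segments
    )
    core_io.write_tsv(path, SEGMENT_HEADER, rows)


def write_breakpoints(bps: Sequence[tuple[int, str, str]], path) -> None:
    rows = ([col + 1, a, b] for col, a, b in bps)
    core_io.write_tsv(path, BREAKPOINT_HEADER, rows)
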