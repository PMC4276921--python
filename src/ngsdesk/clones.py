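"""Quasispecies clone discovery via mutation co-occurrence in reads.

Pairs of called SNVs co-covered by reads are scored by the fraction of
alt-carrying reads that carry both alts (Jaccard on alt-carrying reads,
n11/(n11+n10+n01)), variants are linked into clones by connected
components over sufficiently supported pairs, and each clone gets a
consensus sequence and a frequency estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ngsdesk import core_io
from ngsdesk.profile import SNVCall
from ngsdesk.types import AlignmentRecord, Read, RefSeq

DEFAULT_MAX_SPAN = 500
DEFAULT_MIN_SUPPORT = 0.8
DEFAULT_MIN_READS = 5


@dataclass
class LinkStats:
    """Co-occurrence counts for one SNV pair at positions p < q."""

    pos_a: int
    pos_b: int
    alt_a: str
    alt_b: str
    n11: int = 0
    n10: int = 0
    n01: int = 0
    n00: int = 0

    @property
    def support(self) -> float:
        denom = self.n11 + self.n10 + self.n01
        return self.n11 / denom if denom else 0.0


@dataclass
class Clone:
    id: str
    variants: set[tuple[int, str]]  # (pos, alt); empty only for the reference clone
    consensus: str
    freq_estimate: float
    mean_support_depth: float = 0.0


def _read_bases_at(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[Read] | dict,
    positions: set[int],
) -> dict[str, dict[int, str]]:
    """Per read id: reference position -> read base, for SNV positions only."""
    read_by_id = reads if isinstance(reads, dict) else {r.id: r for r in reads}
    out: dict[str, dict[int, str]] = {}
    for aln in alignments:
        seq = read_by_id[aln.read_id].seq
        bases: dict[int, str] = {}
        for i, j in aln.pairs:
            if j in positions and i is not None:
                base = seq[i]
                if base != "N":
                    bases[j] = base
        if bases:
            out.setdefault(aln.read_id, {}).update(bases)
    return out


def link_stats(
    alignments: Sequence[AlignmentRecord],
    reads: Sequence[Read] | dict,
    snv_calls: Sequence[SNVCall],
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[LinkStats]:
    """Count alt/ref co-occurrence for SNV pairs within ``max_span``.

    A read contributes to a pair only when it covers both positions with
    an unambiguous base equal to either the reference or the called alt;
    pairs never co-covered are absent from the output.
    """
    if max_span < 1:
        raise ValueError("max_span must be >= 1")
    calls = sorted(snv_calls, key=lambda c: (c.pos, c.alt_base))
    positions = {c.pos for c in calls}
    per_read = _read_bases_at(alignments, reads, positions)
    stats: dict[tuple[int, str, int, str], LinkStats] = {}
    for ai, a in enumerate(calls):
        for b in calls[ai + 1 :]:
            if b.pos == a.pos:
                continue
            if b.pos - a.pos > max_span:
                break
            key = (a.pos, a.alt_base, b.pos, b.alt_base)
            for bases in per_read.values():
                ba, bb = bases.get(a.pos), bases.get(b.pos)
                if ba is None or bb is None:
                    continue
                a_alt = ba == a.alt_base
                b_alt = bb == b.alt_base
                a_ref = ba == a.ref_base
                b_ref = bb == b.ref_base
                if not (a_alt or a_ref) or not (b_alt or b_ref):
                    continue
                stat = stats.get(key)
                if stat is None:
                    stat = stats[key] = LinkStats(
                        pos_a=a.pos, pos_b=b.pos, alt_a=a.alt_base, alt_b=b.alt_base
                    )
                if a_alt and b_alt:
                    stat.n11 += 1
                elif a_alt:
                    stat.n10 += 1
                elif b_alt:
                    stat.n01 += 1
                else:
                    stat.n00 += 1
    return [stats[k] for k in sorted(stats)]


def build_clones(
    snv_calls: Sequence[SNVCall],
    links: Sequence[LinkStats],
    min_support: float = DEFAULT_MIN_SUPPORT,
    min_reads: int = DEFAULT_MIN_READS,
    ref: RefSeq = None,
) -> list[Clone]:
    """Link variants into clones by connected components.

    An edge joins two variants when ``support >= min_support`` and
    ``n11 >= min_reads``.  Singleton variants form their own clones.  A
    reference clone (no variants) is always appended with frequency
    1 - sum(clone frequencies), floored at 0.
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must be in (0, 1]")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    variants = sorted({(c.pos, c.alt_base) for c in snv_calls})
    freq_by_variant = {
        (c.pos, c.alt_base): c.alt_freq for c in snv_calls
    }
    parent = {v: v for v in variants}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    edge_depths: dict[tuple[int, str], list[int]] = {v: [] for v in variants}
    for link in links:
        va, vb = (link.pos_a, link.alt_a), (link.pos_b, link.alt_b)
        if va not in parent or vb not in parent:
            continue
        if link.support >= min_support and link.n11 >= min_reads:
            ra, rb = find(va), find(vb)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
            edge_depths[va].append(link.n11)
            edge_depths[vb].append(link.n11)

    components: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for v in variants:
        components.setdefault(find(v), []).append(v)

    clones: list[Clone] = []
    total_freq = 0.0
    for idx, root in enumerate(sorted(components), start=1):
        members = sorted(components[root])
        seq = None
        if ref is not None:
            arr = list(ref.seq)
            for pos, alt in members:
                arr[pos] = alt
            seq = "".join(arr)
        freq = sum(freq_by_variant[v] for v in members) / len(members)
        depths = [d for v in members for d in edge_depths[v]]
        clones.append(
            Clone(
                id=f"clone{idx}",
                variants=set(members),
                consensus=seq or "",
                freq_estimate=min(freq, 1.0),
                mean_support_depth=sum(depths) / len(depths) if depths else 0.0,
            )
        )
        total_freq += min(freq, 1.0)
    clones.append(
        Clone(
            id="reference",
            variants=set(),
            consensus=ref.seq if ref is not None else "",
            freq_estimate=max(0.0, 1.0 - total_freq),
        )
    )
    return clones


def sankey_table(
    clones: Sequence[Clone], links: Sequence[LinkStats]
) -> list[tuple[str, int, int, int, float]]:
    """Rows of (clone_id, pos_from, pos_to, n11, support) for adjacent
    intra-clone variant pairs, sorted by clone then position."""
    link_by_pair = {
        ((l.pos_a, l.alt_a), (l.pos_b, l.alt_b)): l for l in links
    }
    rows = []
    for clone in sorted(clones, key=lambda c: c.id):
        members = sorted(clone.variants)
        for a, b in zip(members, members[1:]):
            link = link_by_pair.get((a, b))
            n11 = link.n11 if link else 0
            support = link.support if link else 0.0
            rows.append((clone.id, a[0], b[0], n11, support))
    return rows


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

CLONE_HEADER = ["clone_id", "n_variants", "freq_estimate", "mean_support_depth"]
SANKEY_HEADER = ["clone_id", "pos_from_1based", "pos_to_1based", "n11", "support"]


def write_clone_table(clones: Sequence[Clone], path) -> None:
    rows = (
        [c.id, len(c.variants), f"{c.freq_estimate:.6g}", f"{c.mean_support_depth:.6g}"]
        for c in clones
    )
    core_io.write_tsv(path, CLONE_HEADER, rows)


def write_sankey_table(rows: Sequence[tuple], path) -> None:
    out_rows = (
        [cid, pa + 1, pb + 1, n11, f"{support:.6g}"]
        for cid, pa, pb, n11, support in rows
    )
    core_io.write_tsv(path, SANKEY_HEADER, out_rows)
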