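"""Subsampling-based taxonomic census.

Repeatedly draws small random samples of reads, classifies each sampled
read against a reference panel via the minimal mapper's best-hit rule,
and aggregates per-taxon proportions across iterations with percentile
confidence intervals.  An "unaligned" pseudo-taxon absorbs reads with no
acceptable hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ngsdesk import core_io
from ngsdesk.mapper import KmerIndex, MapParams, build_index, map_read
from ngsdesk.types import Read, RefSeq

UNALIGNED = "unaligned"


@dataclass
class CensusParams:
    n_per_iteration: int = 250
    n_iterations: int = 20
    seed: int = 0
    map_params: MapParams = field(default_factory=MapParams)

    def __post_init__(self) -> None:
        if self.n_per_iteration < 1:
            raise ValueError("n_per_iteration must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class TaxonStats:
    mean_proportion: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass
class CensusResult:
    taxa: list[str]  # observed taxa, UNALIGNED last
    stats: dict[str, TaxonStats]
    per_iteration: np.ndarray  # shape (n_iterations, len(taxa)), proportions


def random_pick(reads: Sequence[Read], n: int, seed: int) -> list[Read]:
    """Uniform sample of min(n, len(reads)) reads without replacement."""
    if not reads:
        raise ValueError("cannot sample from an empty read set")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    take = min(n, len(reads))
    idx = rng.choice(len(reads), size=take, replace=False)
    return [reads[int(i)] for i in idx]


def classify_sample(
    sample: Sequence[Read],
    refs: Sequence[RefSeq],
    taxon_map: dict[str, str],
    map_params: MapParams,
    index: KmerIndex = None,
) -> dict[str, int]:
    """Best-hit taxon counts for one sample; UNALIGNED catches the rest."""
    missing = [r.id for r in refs if r.id not in taxon_map]
    if missing:
        raise ValueError(f"references without a taxon entry: {missing}")
    if index is None:
        index = build_index(refs, map_params.k)
    counts: dict[str, int] = {UNALIGNED: 0}
    for read in sample:
        aln = map_read(read, index, refs, map_params)
        if aln is None:
            counts[UNALIGNED] += 1
        else:
            taxon = taxon_map[aln.ref_id]
            counts[taxon] = counts.get(taxon, 0) + 1
    return counts


def run_census(
    reads: Sequence[Read],
    refs: Sequence[RefSeq],
    taxon_map: dict[str, str],
    params: CensusParams,
) -> CensusResult:
    """Iterated random-pick + classify passes with cross-iteration stats.

    Iteration i samples with seed ``params.seed + i``.  Taxa never
    observed in any iteration are absent from the output.  The CI is the
    2.5/97.5 percentile interval across iteration proportions.
    """
    index = build_index(refs, params.map_params.k)
    iteration_counts: list[dict[str, int]] = []
    for i in range(params.n_iterations):
        sample = random_pick(reads, params.n_per_iteration, params.seed + i)
        iteration_counts.append(
            classify_sample(sample, refs, taxon_map, params.map_params, index=index)
        )

    observed = sorted(
        {t for counts in iteration_counts for t, c in counts.items() if c > 0}
        - {UNALIGNED}
    )
    taxa = observed + [UNALIGNED]
    matrix = np.zeros((params.n_iterations, len(taxa)))
    for i, counts in enumerate(iteration_counts):
        total = sum(counts.values())
        for j, taxon in enumerate(taxa):
            matrix[i, j] = counts.get(taxon, 0) / total

    stats = {}
    for j, taxon in enumerate(taxa):
        col = matrix[:, j]
        if np.all(col == col[0]):
            # identical iterations (e.g. exhaustive sampling): exact stats
            stats[taxon] = TaxonStats(
                mean_proportion=float(col[0]), sd=0.0,
                ci_low=float(col[0]), ci_high=float(col[0]),
            )
            continue
        stats[taxon] = TaxonStats(
            mean_proportion=float(col.mean()),
            sd=float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            ci_low=float(np.percentile(col, 2.5)),
            ci_high=float(np.percentile(col, 97.5)),
        )
    return CensusResult(taxa=taxa, stats=stats, per_iteration=matrix)


# ---------------------------------------------------------------------------
# TSV export
# ---------------------------------------------------------------------------

CENSUS_HEADER = ["taxon", "mean_proportion", "sd", "ci_low", "ci_high"]


def write_census_table(result: CensusResult, path) -> None:
    rows = (
        [
            taxon,
            f"{result.stats[taxon].mean_proportion:.6g}",
            f"{result.stats[taxon].sd:.6g}",
            f"{result.stats[taxon].ci_low:.6g}",
            f"{result.stats[taxon].ci_high:.6g}",
        ]
        for taxon in result.taxa
    )
    core_io.write_tsv(path, CENSUS_HEADER, rows)


def write_iteration_matrix(result: CensusResult, path) -> None:
    header = ["iteration"] + list(result.taxa)
    rows = (
        [i] + [f"{v:.6g}" for v in result.per_iteration[i]]
        for i in range(result.per_iteration.shape[0])
    )
    core_io.write_tsv(path, header, rows)
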