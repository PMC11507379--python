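"""Numt presence-absence polymorphism in a genotyped SV call set.

Deletion SVs are matched to reference Numt loci by 90% reciprocal
overlap.  Insertion SVs — whose sequence may be fully assembled or only
partially assembled from each edge — are scanned against the doubled
mitochondrial reference; any retained HSP classifies the insertion as a
Numt (no coverage floor is applied at this stage).  Per-sample Numt
counts are tabulated from genotypes and summarized by canine category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import (
    DeletionSV,
    GenomicInterval,
    InsertionSV,
    SequenceRecord,
)
from .hsp_discovery import AlignmentParams, discover_hsps_multi, double_reference, shift_and_wrap
from .numt_annotation import MergedNumt, NumtHSP

logger = logging.getLogger(__name__)

CATEGORIES = ("Breed Dog", "Mixed/Other", "Village Dog", "Wolf")


@dataclass(frozen=True)
class PopulationParams:
    reciprocal_overlap: float = 0.90
    partial_join_n: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.reciprocal_overlap <= 1):
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        if self.partial_join_n < 0:
            raise ValueError("partial_join_n must be >= 0")


@dataclass(frozen=True)
class SampleNumtCount:
    sample: str
    category: str
    n_numts: int


def reciprocal_overlap_deletions(
    loci: Sequence[MergedNumt],
    dels: Sequence[DeletionSV],
    params: PopulationParams | None = None,
) -> list[tuple[MergedNumt, DeletionSV]]:
    """Match deletions to Numt loci requiring 90% overlap in both directions."""
    params = params or PopulationParams()
    r = params.reciprocal_overlap
    pairs = []
    for locus in loci:
        a = locus.nuclear_span
        for d in dels:
            b = d.span
            ov = a.overlap_bp(b)
            if ov >= r * len(a) and ov >= r * len(b):
                pairs.append((locus, d))
    return pairs


def assemble_insertion_query(
    ins: InsertionSV, params: PopulationParams | None = None
) -> SequenceRecord:
    """Build the searchable sequence for one insertion variant.

    Fully assembled insertions are used as-is; partial insertions are
    joined as left + N*10 + right (a missing side is treated as empty).
    The record is named ``chromosome:position`` (1-based position).
    """
    params = params or PopulationParams()
    name = f"{ins.position.seq_name}:{ins.position.start + 1}"
    if ins.seq_full is not None:
        return SequenceRecord(name, ins.seq_full)
    left = ins.seq_left or ""
    right = ins.seq_right or ""
    seq = left + "N" * params.partial_join_n + right
    if not seq.strip("N"):
        raise ValueError(f"insertion {ins.id} carries no sequence")
    return SequenceRecord(name, seq)


@dataclass
class InsertionScanResult:
    query_id: str
    hsps: list[NumtHSP]
    partial: bool


def _n_blocks(seq: str, min_run: int) -> list[tuple[int, int]]:
    blocks = []
    i = 0
    while i < len(seq):
        if seq[i] == "N":
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            if j - i >= min_run:
                blocks.append((i, j))
            i = j
        else:
            i += 1
    return blocks


def scan_insertions_for_numts(
    queries: Sequence[SequenceRecord],
    mito: SequenceRecord,
    align_params: AlignmentParams | None = None,
    params: PopulationParams | None = None,
) -> list[InsertionScanResult]:
    """Scan insertion queries against the doubled mitochondrial reference.

    A query with at least one retained HSP (e <= cutoff) is a Numt
    insertion.  Partial queries are split at their N-join before search
    and coordinates mapped back, guaranteeing that no reported HSP spans
    the join.  The partial flag marks queries built from edge fragments.
    """
    params = params or PopulationParams()
    min_run = max(1, params.partial_join_n)
    doubled = double_reference(mito)
    L = len(mito.sequence)

    # split each query into N-free pieces; remember (query, piece offset)
    pieces: list[SequenceRecord] = []
    origin: dict[str, tuple[str, int]] = {}
    partial_flags: dict[str, bool] = {}
    for q in queries:
        blocks = _n_blocks(q.sequence, min_run)
        partial_flags[q.name] = bool(blocks)
        bounds = [0] + [b for blk in blocks for b in blk] + [len(q.sequence)]
        idx = 0
        for s, e in zip(bounds[::2], bounds[1::2]):
            if e - s == 0:
                continue
            pid = f"{q.name}|piece{idx}"
            pieces.append(SequenceRecord(pid, q.sequence[s:e]))
            origin[pid] = (q.name, s)
            idx += 1

    hits = discover_hsps_multi(pieces, doubled, align_params) if pieces else {}
    by_query: dict[str, list[NumtHSP]] = {q.name: [] for q in queries}
    for piece in pieces:
        qname, offset = origin[piece.name]
        for raw, circ in shift_and_wrap(hits.get(piece.name, []), L):
            shifted = GenomicInterval(
                qname,
                offset + raw.nuclear.start,
                offset + raw.nuclear.end,
                raw.strand,
            )
            by_query[qname].append(
                NumtHSP(shifted, circ, raw.strand, raw.percent_identity, raw.aligned_mito_bp)
            )
    return [
        InsertionScanResult(q.name, sorted(by_query[q.name], key=lambda h: h.nuclear.start), partial_flags[q.name])
        for q in queries
    ]


def per_sample_counts(
    numt_variants: Sequence[InsertionSV],
    categories: Mapping[str, str],
) -> list[SampleNumtCount]:
    """Count Numt insertion variants carried by each sample.

    A variant counts as present when the sample's alt-allele count is >= 1;
    missing genotypes never count.  Samples without a category fall back to
    Mixed/Other (warned).
    """
    samples: set[str] = set()
    for v in numt_variants:
        samples.update(v.genotypes)
    samples.update(categories)
    out = []
    for s in sorted(samples):
        cat = categories.get(s)
        if cat is None:
            logger.warning("sample %s has no category; using Mixed/Other", s)
            cat = "Mixed/Other"
        n = sum(
            1
            for v in numt_variants
            if (v.genotypes.get(s) or 0) >= 1
        )
        out.append(SampleNumtCount(s, cat, n))
    return out


def summarize_by_category(counts: Sequence[SampleNumtCount]) -> pd.DataFrame:
    """Per-category sample count, median Numts per sample, and min-max range."""
    df = pd.DataFrame(
        [{"sample": c.sample, "category": c.category, "n_numts": c.n_numts} for c in counts]
    )
    if df.empty:
        return pd.DataFrame(columns=["category", "n_samples", "median", "min", "max"])
    summary = (
        df.groupby("category")["n_numts"]
        .agg(n_samples="size", median="median", min="min", max="max")
        .reset_index()
    )
    return summary
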