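"""Flank-anchored test for Numt presence at the orthologous position of an
outgroup assembly.

Each reference locus is extracted with 10 kbp of flanking sequence on
each side and searched against the outgroup.  Hits are filtered to those
anchored by at least 2000 aligned bp in each flank and covering at least
80% of the Numt interval; the best candidate region is then re-queried
against the mitochondrial reference to confirm that the orthologous
sequence really is mitochondrial in origin.  Flanks that align while the
Numt fails confirmation indicate the insertion post-dates the split from
the outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io_formats import GenomicInterval, SequenceRecord
from .hsp_discovery import AlignmentParams, discover_hsps_multi
from .numt_annotation import MergedNumt

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OutgroupParams:
    flank_bp: int = 10_000
    min_flank_alignment: int = 2000
    min_numt_coverage: float = 0.80
    chain_max_gap: int = 15_000  # max gap when chaining HSPs into one hit

    def __post_init__(self) -> None:
        if self.min_flank_alignment > self.flank_bp:
            raise ValueError("min_flank_alignment cannot exceed flank_bp")
        if not (0 < self.min_numt_coverage <= 1):
            raise ValueError("min_numt_coverage must be in (0, 1]")


@dataclass
class FlankedLocus:
    """A locus sequence with flanks, and where the Numt sits inside it."""

    record: SequenceRecord
    source_span: GenomicInterval  # coordinates of the extract on the assembly
    numt_start: int  # Numt interval within the extract
    numt_end: int
    left_clipped: bool = False
    right_clipped: bool = False


@dataclass
class OutgroupHit:
    """One chained alignment of the flanked extract to the outgroup.

    ``blocks`` are aligned intervals in extract (query) coordinates;
    ``target`` is the spanned interval on the outgroup assembly.
    """

    blocks: list[tuple[int, int]]
    target: GenomicInterval
    strand: str

    @property
    def total_aligned(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class OrthologyCall:
    locus_id: str
    outgroup: str
    status: str  # present / absent / unresolved
    candidate: GenomicInterval | None = None
    n_confirmation_hsps: int = 0


def extract_locus_with_flanks(
    assembly: Mapping[str, SequenceRecord],
    locus: MergedNumt,
    params: OutgroupParams | None = None,
) -> FlankedLocus:
    """Extract a locus plus up to ``flank_bp`` of sequence on each side.

    Flanks are clipped at contig bounds (and flagged, since a clipped
    flank may not reach the 2000 bp anchoring requirement).
    """
    params = params or OutgroupParams()
    span = locus.nuclear_span
    rec = assembly.get(span.seq_name)
    if rec is None:
        raise ValueError(f"locus {locus.id}: sequence {span.seq_name!r} not in assembly")
    start = max(0, span.start - params.flank_bp)
    end = min(len(rec.sequence), span.end + params.flank_bp)
    return FlankedLocus(
        record=SequenceRecord(f"{locus.id}_flanked", rec.sequence[start:end]),
        source_span=GenomicInterval(span.seq_name, start, end),
        numt_start=span.start - start,
        numt_end=span.end - start,
        left_clipped=span.start - start < params.flank_bp,
        right_clipped=end - span.end < params.flank_bp,
    )


def _aligned_bp_in(blocks: Sequence[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in blocks)


def filter_outgroup_hits(
    hits: Sequence[OutgroupHit],
    numt_start: int,
    numt_end: int,
    query_len: int,
    params: OutgroupParams | None = None,
) -> list[OutgroupHit]:
    """Keep hits anchored in both flanks and covering enough of the Numt.

    Requires >= ``min_flank_alignment`` aligned bases within the left flank
    region [0, numt_start) and within the right flank [numt_end, query_len),
    and an aligned fraction of the Numt interval >= ``min_numt_coverage``
    (all thresholds inclusive).  Returned best-first by total aligned bases.
    """
    params = params or OutgroupParams()
    numt_len = numt_end - numt_start
    kept = []
    for hit in hits:
        left = _aligned_bp_in(hit.blocks, 0, numt_start)
        right = _aligned_bp_in(hit.blocks, numt_end, query_len)
        numt_cov = _aligned_bp_in(hit.blocks, numt_start, numt_end) / numt_len
        if (
            left >= params.min_flank_alignment
            and right >= params.min_flank_alignment
            and numt_cov >= params.min_numt_coverage
        ):
            kept.append(hit)
    kept.sort(key=lambda h: -h.total_aligned)
    return kept


def chain_hits(raw_hsps, params: OutgroupParams | None = None) -> list[OutgroupHit]:
    """Chain co-linear HSPs on the same target sequence and strand into
    candidate hits (gaps up to ``chain_max_gap`` in either coordinate)."""
    params = params or OutgroupParams()
    by_key: dict[tuple[str, str], list] = {}
    for h in raw_hsps:
        by_key.setdefault((h.nuclear.seq_name, h.strand), []).append(h)
    hits = []
    for (seq_name, strand), group in by_key.items():
        # query coords are (mito_start, mito_end) of the generic HSP record
        group.sort(key=lambda h: h.mito_start)
        chains: list[list] = []
        for h in group:
            placed = False
            for chain in chains:
                last = chain[-1]
                q_gap = h.mito_start - last.mito_end
                if strand == "+":
                    t_gap = h.nuclear.start - last.nuclear.end
                else:
                    t_gap = last.nuclear.start - h.nuclear.end
                if -200 <= q_gap <= params.chain_max_gap and -200 <= t_gap <= params.chain_max_gap:
                    chain.append(h)
                    placed = True
                    break
            if not placed:
                chains.append([h])
        for chain in chains:
            blocks = sorted((h.mito_start, h.mito_end) for h in chain)
            t_start = min(h.nuclear.start for h in chain)
            t_end = max(h.nuclear.end for h in chain)
            hits.append(
                OutgroupHit(blocks, GenomicInterval(seq_name, t_start, t_end, strand), strand)
            )
    return hits


def confirm_candidate(
    candidate_seq: SequenceRecord,
    mito: SequenceRecord,
    align_params: AlignmentParams | None = None,
) -> int:
    """Number of mitochondrial HSPs found in the candidate region."""
    from .hsp_discovery import double_reference

    doubled = double_reference(mito)
    return len(discover_hsps_multi([candidate_seq], doubled, align_params)[candidate_seq.name])


def call_locus_presence(
    reference: Mapping[str, SequenceRecord],
    outgroup: Mapping[str, SequenceRecord],
    locus: MergedNumt,
    mito: SequenceRecord,
    outgroup_label: str = "outgroup",
    params: OutgroupParams | None = None,
    align_params: AlignmentParams | None = None,
) -> OrthologyCall:
    """Full flank-anchored presence test for one locus against one outgroup.

    present    — a hit passes the flank + Numt-coverage filters and the
                 candidate region contains >= 1 mitochondrial HSP;
    absent     — the flanks anchor the orthologous position (>= 2000
                 aligned bp on each side) but either the Numt interval is
                 not covered there, or the candidate has no mitochondrial
                 hit: the insertion post-dates the split;
    unresolved — no alignment anchors both flanks.
    """
    params = params or OutgroupParams()
    flanked = extract_locus_with_flanks(reference, locus, params)
    out_records = list(outgroup.values())
    raw = discover_hsps_multi(out_records, flanked.record, align_params)
    all_hsps = [h for rec in out_records for h in raw[rec.name]]
    hits = chain_hits(all_hsps, params)
    qlen = len(flanked.record.sequence)
    candidates = filter_outgroup_hits(
        hits, flanked.numt_start, flanked.numt_end, qlen, params
    )
    if candidates:
        best = candidates[0]
        target = best.target
        cand_seq = SequenceRecord(
            f"{locus.id}_candidate",
            outgroup[target.seq_name].sequence[target.start : target.end],
        )
        n_hsps = confirm_candidate(cand_seq, mito, align_params)
        status = "present" if n_hsps >= 1 else "absent"
        return OrthologyCall(locus.id, outgroup_label, status, target, n_hsps)
    # no candidate covered the Numt; flank-anchored hits alone mean the
    # orthologous position exists with the Numt missing from it
    anchored = [
        h
        for h in hits
        if _aligned_bp_in(h.blocks, 0, flanked.numt_start) >= params.min_flank_alignment
        and _aligned_bp_in(h.blocks, flanked.numt_end, qlen) >= params.min_flank_alignment
    ]
    if anchored:
        anchored.sort(key=lambda h: -h.total_aligned)
        return OrthologyCall(locus.id, outgroup_label, "absent", anchored[0].target, 0)
    return OrthologyCall(locus.id, outgroup_label, "unresolved")
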