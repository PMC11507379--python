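"""Merging HSPs into Numt loci and summarizing them.

A Numt locus is an ordered group of HSPs lying within 2000 bp of each
other in both nuclear and mitochondrial coordinates with consistent
orientation — the unit counted as one insertion event even when a later
transposon insertion has split the alignment into fragments.  Loci are
refined by re-searching their extracted sequence against the doubled
mitochondrial reference, which recovers origin-spanning alignments as
single HSPs.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GenomicInterval, SequenceRecord, SeqRole
from .hsp_discovery import (
    AlignmentParams,
    CircularInterval,
    RawHSP,
    discover_hsps_multi,
    double_reference,
    shift_and_wrap,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MergeParams:
    """Dual-coordinate merge rule: nearest-end gaps of at most 2000 bp in
    the nucleus and (circular distance) in the mitochondria, same strand."""

    max_gap_nuclear: int = 2000
    max_gap_mito: int = 2000
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.max_gap_nuclear < 0 or self.max_gap_mito < 0:
            raise ValueError("gaps must be non-negative")


@dataclass(frozen=True)
class NumtHSP:
    nuclear: GenomicInterval
    mito: CircularInterval
    strand: str
    percent_identity: float
    aligned_mito_bp: int

    @classmethod
    def from_raw(cls, raw: RawHSP, circ: CircularInterval) -> "NumtHSP":
        return cls(
            nuclear=raw.nuclear,
            mito=circ,
            strand=raw.strand,
            percent_identity=raw.percent_identity,
            aligned_mito_bp=raw.aligned_mito_bp,
        )


@dataclass
class MergedNumt:
    """A merged Numt locus: ordered member HSPs plus aggregate statistics."""

    id: str
    nuclear_span: GenomicInterval
    members: list[NumtHSP]
    strand: str
    unconfirmed: bool = False

    @property
    def total_aligned_bp(self) -> int:
        return sum(m.aligned_mito_bp for m in self.members)

    @property
    def mean_identity(self) -> float:
        """Aligned-length-weighted mean of member identities."""
        total = self.total_aligned_bp
        if total == 0:
            return 0.0
        return sum(m.percent_identity * m.aligned_mito_bp for m in self.members) / total


def _circular_directed_gap(a_end: int, b_start: int, L: int) -> int:
    """Base-pairs walked forward on the circle from position a_end to b_start."""
    return (b_start - a_end) % L


def _mergeable(a: NumtHSP, b: NumtHSP, params: MergeParams) -> bool:
    if a.nuclear.seq_name != b.nuclear.seq_name:
        return False
    if params.require_same_strand and a.strand != b.strand:
        return False
    nuc_gap = max(
        0,
        max(a.nuclear.start, b.nuclear.start) - min(a.nuclear.end, b.nuclear.end),
    )
    if nuc_gap > params.max_gap_nuclear:
        return False
    if a.mito.overlaps(b.mito):
        return True
    first, second = (a, b) if a.nuclear.start <= b.nuclear.start else (b, a)
    L = a.mito.L
    # Orientation consistency: walking along the nucleus must advance along
    # the circle in the direction the strand implies, within the gap budget.
    if a.strand == "-":
        gap = _circular_directed_gap(second.mito.arc_end, first.mito.arc_start, L)
    else:
        gap = _circular_directed_gap(first.mito.arc_end, second.mito.arc_start, L)
    return gap <= params.max_gap_mito


def merge_hsps(
    hsps: Sequence[NumtHSP], params: MergeParams | None = None
) -> list[MergedNumt]:
    """Group HSPs into Numt loci by transitive closure of the merge relation.

    Output is sorted by nuclear span; every input HSP appears in exactly
    one locus.
    """
    params = params or MergeParams()
    n = len(hsps)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(hsps[i], hsps[j], params):
                parent[find(i)] = find(j)

    groups: dict[int, list[NumtHSP]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hsps[i])

    loci = []
    for members in groups.values():
        members.sort(key=lambda h: (h.nuclear.start, h.nuclear.end))
        span = GenomicInterval(
            members[0].nuclear.seq_name,
            min(m.nuclear.start for m in members),
            max(m.nuclear.end for m in members),
        )
        loci.append(MergedNumt("", span, members, members[0].strand))
    loci.sort(key=lambda l: (l.nuclear_span.seq_name, l.nuclear_span.start))
    for i, locus in enumerate(loci, 1):
        locus.id = f"numt_{i:04d}"
    return loci


def refine_locus(
    locus_seq: SequenceRecord,
    mito: SequenceRecord,
    params: AlignmentParams | None = None,
) -> list[NumtHSP]:
    """Re-search an extracted locus sequence with the doubled reference.

    Returns final HSPs with circular mitochondrial coordinates (an empty
    list means the locus failed confirmation).  Nuclear coordinates are
    relative to ``locus_seq``.
    """
    doubled = double_reference(mito)
    raw = discover_hsps_multi([locus_seq], doubled, params)[locus_seq.name]
    L = len(mito.sequence)
    return [NumtHSP.from_raw(h, c) for h, c in shift_and_wrap(raw, L)]


@dataclass
class AssemblySummary:
    """Per-stratum Numt statistics (chromosome vs unplaced)."""

    strata: dict[SeqRole, dict[str, float]]

    def row(self, role: SeqRole) -> dict[str, float]:
        return self.strata.get(
            role,
            {
                "hsp_count": 0,
                "total_size_bp": 0,
                "max_length_bp": 0,
                "median_length_bp": 0.0,
                "merged_locus_count": 0,
            },
        )


def summarize_assembly(
    numts: Sequence[MergedNumt], roles: Mapping[str, SeqRole]
) -> AssemblySummary:
    """Tabulate HSP count, total/max/median aligned mito bp and locus count,
    stratified by chromosome vs unplaced assignment."""
    strata: dict[SeqRole, dict[str, float]] = {}
    for role in (SeqRole.chromosome, SeqRole.unplaced):
        loci = [
            l
            for l in numts
            if roles.get(l.nuclear_span.seq_name, SeqRole.unplaced) == role
            and not l.unconfirmed
        ]
        lengths = [m.aligned_mito_bp for l in loci for m in l.members]
        strata[role] = {
            "hsp_count": len(lengths),
            "total_size_bp": int(sum(lengths)),
            "max_length_bp": max(lengths) if lengths else 0,
            "median_length_bp": float(statistics.median(lengths)) if lengths else 0.0,
            "merged_locus_count": len(loci),
        }
    return AssemblySummary(strata)


def coverage_profile(hsps: Iterable[NumtHSP], L: int) -> np.ndarray:
    """Per-position count of HSPs covering each mitochondrial base.

    The profile total equals the summed aligned segment lengths exactly.
    """
    cov = np.zeros(L, dtype=np.int64)
    for h in hsps:
        for s, e in h.mito.segments:
            cov[s:e] += 1
    return cov


@dataclass
class UnifiedRegion:
    seq_name: str
    start: int
    end: int
    sources: set[str]


def unify_numt_lists(
    sources: Mapping[str, Sequence],
    tolerance: int = 10,
) -> list[UnifiedRegion]:
    """Collapse loci from multiple call sets into unified regions.

    Loci whose start AND end coordinates each differ by at most
    ``tolerance`` bp are treated as the same Numt (transitive closure);
    each region records which sources contributed.  All inputs must be on
    the same reference coordinate system; loci carrying a ``reference``
    attribute are cross-checked.
    """
    entries = []  # (source, seq_name, start, end)
    references = set()
    for src, loci in sources.items():
        for locus in loci:
            iv = getattr(locus, "nuclear_span", locus)
            ref = getattr(locus, "reference", None)
            if ref is not None:
                references.add(ref)
            entries.append((src, iv.seq_name, iv.start, iv.end))
    if len(references) > 1:
        raise ValueError(f"loci come from mismatched references: {sorted(references)}")

    n = len(entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: (entries[i][1], entries[i][2]))
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if entries[j][1] != entries[i][1]:
                break
            if entries[j][2] - entries[i][2] > tolerance:
                break
            if abs(entries[i][3] - entries[j][3]) <= tolerance:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    regions = [
        UnifiedRegion(
            seq_name=entries[idxs[0]][1],
            start=min(entries[i][2] for i in idxs),
            end=max(entries[i][3] for i in idxs),
            sources={entries[i][0] for i in idxs},
        )
        for idxs in groups.values()
    ]
    regions.sort(key=lambda r: (r.seq_name, r.start))
    return regions


@dataclass
class ContextLabel:
    region: GenomicInterval
    label: str  # intergenic / intronic / exonic
    cpg_flag: bool


def _build_trees(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.seq_name, IntervalTree()).addi(iv.start, iv.end)
    return trees


def classify_genomic_context(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
    cpg_islands: Sequence[GenomicInterval] = (),
) -> list[ContextLabel]:
    """Label each region exonic (overlaps an exon), intronic (inside a gene
    body but no exon) or intergenic; flag any CpG-island overlap (>= 1 bp)."""
    gene_trees = _build_trees(genes)
    exon_trees = _build_trees(exons)
    cpg_trees = _build_trees(cpg_islands)
    out = []
    for region in regions:
        if exon_trees.get(region.seq_name, IntervalTree()).overlap(region.start, region.end):
            label = "exonic"
        elif gene_trees.get(region.seq_name, IntervalTree()).overlap(region.start, region.end):
            label = "intronic"
        else:
            label = "intergenic"
        cpg = bool(
            cpg_trees.get(region.seq_name, IntervalTree()).overlap(region.start, region.end)
        )
        out.append(ContextLabel(region, label, cpg))
    return out


def plot_coverage(cov: np.ndarray, out_path: str, dloop: tuple[int, int] | None = None):
    """Simple per-base mitochondrial coverage figure (optionally shading a
    control-region interval, which is typically depleted in Numts)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.fill_between(np.arange(len(cov)), cov, step="mid", color="steelblue")
    if dloop is not None:
        ax.axvspan(dloop[0], dloop[1], color="pink", alpha=0.4)
    ax.set_xlabel("mitochondrial position (bp)")
    ax.set_ylabel("Numt HSP coverage")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def annotate_assembly(
    records: Sequence[SequenceRecord],
    mito: SequenceRecord,
    align_params: AlignmentParams | None = None,
    merge_params: MergeParams | None = None,
) -> list[MergedNumt]:
    """Full annotation pipeline for one assembly.

    1. Search the mitochondrial reference against every assembly sequence.
    2. Map hits onto the circle and merge them into loci (2000 bp rule).
    3. Refine each locus by re-searching its extracted sequence with the
       doubled reference; final HSPs replace the members.  Loci with no
       confirming HSP are flagged ``unconfirmed`` (excluded from summaries).
    """
    align_params = align_params or AlignmentParams()
    merge_params = merge_params or MergeParams()
    L = len(mito.sequence)

    hits_by_seq = discover_hsps_multi(records, mito, align_params)
    hsps = [
        NumtHSP.from_raw(h, c)
        for rec in records
        for h, c in shift_and_wrap(hits_by_seq[rec.name], L)
    ]
    loci = merge_hsps(hsps, merge_params)

    seq_by_name = {rec.name: rec for rec in records}
    locus_records = []
    for locus in loci:
        span = locus.nuclear_span
        locus_records.append(
            SequenceRecord(
                locus.id, seq_by_name[span.seq_name].sequence[span.start : span.end]
            )
        )
    doubled = double_reference(mito)
    refined_hits = discover_hsps_multi(locus_records, doubled, align_params)

    for locus in loci:
        span = locus.nuclear_span
        refined = []
        for raw, circ in shift_and_wrap(refined_hits[locus.id], L):
            shifted = GenomicInterval(
                span.seq_name,
                span.start + raw.nuclear.start,
                span.start + raw.nuclear.end,
                raw.strand,
            )
            refined.append(
                NumtHSP(shifted, circ, raw.strand, raw.percent_identity, raw.aligned_mito_bp)
            )
        refined.sort(key=lambda h: (h.nuclear.start, h.nuclear.end))
        if refined:
            locus.members = refined
            locus.nuclear_span = GenomicInterval(
                span.seq_name,
                min(h.nuclear.start for h in refined),
                max(h.nuclear.end for h in refined),
            )
            locus.strand = refined[0].strand
        else:
            locus.members = []
            locus.unconfirmed = True
            logger.warning("locus %s unconfirmed on refinement", locus.id)
    return loci


def loci_to_table(loci: Sequence[MergedNumt]):
    """Locus report as a DataFrame (1-based inclusive printed coordinates)."""
    import pandas as pd

    rows = []
    for l in loci:
        rows.append(
            {
                "locus_id": l.id,
                "chrom": l.nuclear_span.seq_name,
                "start1": l.nuclear_span.start + 1,
                "end1": l.nuclear_span.end,
                "strand": l.strand,
                "n_hsps": len(l.members),
                "total_aligned_bp": l.total_aligned_bp,
                "mean_identity": round(l.mean_identity, 2),
                "mito_intervals": ";".join(m.mito.render() for m in l.members),
                "unconfirmed": l.unconfirmed,
            }
        )
    return pd.DataFrame(rows)
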