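"""Presence-absence dimorphism of reference Numts across genome assemblies.

Inter-assembly insertion/deletion variants (from whole-assembly alignment,
ingested as BED-like records — this module never re-runs the aligner) are
intersected with Numt HSPs: a deletion covering at least 90% of an HSP
marks the Numt absent in the other assembly.  Variants much longer than
the HSP (> 1000 bp excess) are classified separately as large structural
variants, since the event removing the Numt also removed flanking
sequence.  Identity distributions of fixed vs dimorphic Numts are
compared with Welch's unequal-variances t-test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import GenomicInterval, SequenceRecord
from .hsp_discovery import AlignmentParams, discover_hsps_multi, double_reference
from .numt_annotation import NumtHSP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DimorphismParams:
    min_hsp_overlap_fraction: float = 0.90
    large_sv_margin: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.min_hsp_overlap_fraction <= 1):
            raise ValueError("overlap fraction must be in (0, 1]")
        if self.large_sv_margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass(frozen=True)
class IndelVariant:
    """An insertion or deletion between the reference and another assembly."""

    kind: str  # "insertion" | "deletion"
    reference_interval: GenomicInterval
    length_bp: int
    other_assembly: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if self.length_bp < 1:
            raise ValueError("length_bp must be >= 1")


@dataclass
class DimorphismCall:
    subject_id: str
    status: str  # fixed / absent_clean / absent_large_sv / inserted_clean / inserted_large_sv
    supporting: list[tuple[str, IndelVariant]] = field(default_factory=list)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of interval ``a`` covered by ``b`` (asymmetric)."""
    return a.overlap_bp(b) / len(a)


def call_absence(
    hsps: Sequence[NumtHSP],
    indels: Sequence[IndelVariant],
    params: DimorphismParams | None = None,
    ids: Sequence[str] | None = None,
) -> list[DimorphismCall]:
    """Classify each HSP as fixed, cleanly absent, or removed by a large SV.

    A deletion variant qualifies when it covers at least 90% of the HSP.
    Among qualifying variants the one with maximal overlap fraction (ties:
    smallest length difference) sets the class: ``absent_large_sv`` when
    the variant exceeds the HSP length by more than 1000 bp, otherwise
    ``absent_clean``.  All qualifying variants are kept as support, so a
    Numt absent from several assemblies yields one call listing them all.
    """
    params = params or DimorphismParams()
    dels = [v for v in indels if v.kind == "deletion"]
    calls = []
    for i, hsp in enumerate(hsps):
        sid = ids[i] if ids is not None else f"hsp_{i+1:04d}"
        qualifying = []
        for var in dels:
            frac = overlap_fraction(hsp.nuclear, var.reference_interval)
            if frac >= params.min_hsp_overlap_fraction:
                qualifying.append((frac, -abs(var.length_bp - len(hsp.nuclear)), var))
        if not qualifying:
            calls.append(DimorphismCall(sid, "fixed"))
            continue
        qualifying.sort(key=lambda t: (t[0], t[1]), reverse=True)
        best = qualifying[0][2]
        status = (
            "absent_large_sv"
            if best.length_bp > len(hsp.nuclear) + params.large_sv_margin
            else "absent_clean"
        )
        calls.append(
            DimorphismCall(
                sid, status, [(v.other_assembly, v) for _, _, v in qualifying]
            )
        )
    return calls


def call_novel_insertions(
    insertions: Sequence[IndelVariant],
    mito: SequenceRecord,
    align_params: AlignmentParams | None = None,
    params: DimorphismParams | None = None,
) -> list[DimorphismCall]:
    """Find Numts present in another assembly but absent from the reference.

    Each insertion sequence is scanned against the doubled mitochondrial
    reference.  Coverage >= 90% of the insertion by mitochondrial HSPs →
    ``inserted_clean``; a hit embedded in an insertion more than 1000 bp
    longer than the aligned span → ``inserted_large_sv``; insertions with
    no hit (or no sequence) are dropped.
    """
    params = params or DimorphismParams()
    with_seq = [v for v in insertions if v.sequence]
    n_dropped = len(insertions) - len(with_seq)
    if n_dropped:
        logger.warning("call_novel_insertions: %d insertions lack sequence", n_dropped)
    if not with_seq:
        return []
    doubled = double_reference(mito)
    subjects = [
        SequenceRecord(f"ins_{i+1:04d}", v.sequence) for i, v in enumerate(with_seq)
    ]
    hits = discover_hsps_multi(subjects, doubled, align_params)
    calls = []
    for rec, var in zip(subjects, with_seq):
        hsps = hits[rec.name]
        if not hsps:
            continue
        covered = np.zeros(len(rec.sequence), dtype=bool)
        for h in hsps:
            covered[h.nuclear.start : h.nuclear.end] = True
        frac = covered.mean()
        span = max(h.nuclear.end for h in hsps) - min(h.nuclear.start for h in hsps)
        if frac >= params.min_hsp_overlap_fraction:
            status = "inserted_clean"
        elif len(rec.sequence) > span + params.large_sv_margin:
            status = "inserted_large_sv"
        else:
            status = "inserted_clean"
        calls.append(DimorphismCall(rec.name, status, [(var.other_assembly, var)]))
    return calls


@dataclass(frozen=True)
class WelchResult:
    group_a: str
    group_b: str
    t: float
    df: float
    p: float
    stars: str


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_identity_groups(
    groups: Mapping[str, Sequence[float]]
) -> list[WelchResult]:
    """Pairwise Welch's unequal-variances t-tests between identity groups.

    Groups with fewer than two observations are excluded (warned).  Returns
    the t statistic, Welch-Satterthwaite degrees of freedom, two-sided p,
    and a significance label (**** p<0.0001, *** p<0.001, ** p<0.01,
    * p<0.05, ns otherwise).
    """
    usable = {}
    for name, values in groups.items():
        if len(values) < 2:
            logger.warning("group %s has n=%d < 2; excluded", name, len(values))
            continue
        usable[name] = np.asarray(values, dtype=float)
    results = []
    for a, b in itertools.combinations(sorted(usable), 2):
        res = stats.ttest_ind(usable[a], usable[b], equal_var=False)
        t = float(res.statistic)
        p = float(res.pvalue)
        df = float(res.df)
        if np.isnan(t):  # identical zero-variance groups
            t, p = 0.0, 1.0
        results.append(WelchResult(a, b, t, df, p, _stars(p)))
    return results
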