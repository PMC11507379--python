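"""Local-alignment discovery between nuclear sequence and the circular
mitochondrial reference.

The mitochondrial genome is circular, so an insertion may derive from a
segment spanning the sequence origin.  Searching with the reference
*concatenated twice* makes any such segment contiguous; hits are then
mapped back onto the circle (``wrap_interval``), with origin-spanning
intervals rendered as comma-separated coordinate pairs.

Two search backends implement the same contract:

* ``external_blastn`` shells out to NCBI ``blastn`` in pairwise
  (subject/query) mode with the scoring scheme +2 match, -3 mismatch,
  -5 gap open, -2 gap extend, retaining HSPs at e < 0.001.
* ``builtin`` is a seed-and-extend aligner (exact k-mer seeds, banded
  Smith-Waterman extension under the same scoring) with a
  Karlin-Altschul-style e-value computed from the pairwise search space.
  Its e-values are approximate; the external engine defines parity.

A missing external binary raises — there is never a silent fallback.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .io_formats import SequenceRecord, GenomicInterval, revcomp

DOUBLED_SUFFIX = "_x2"


class BackendUnavailableError(RuntimeError):
    """The requested alignment backend cannot run (missing executable)."""


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and filtering parameters for HSP discovery.

    The scoring function (+2/-3/-5/-2) and the e < 0.001 cutoff are the
    pipeline defaults for nuclear-vs-mitochondrial search.  ``word_size``
    controls seed sensitivity: 7 recovers short insertions diverged up to
    ~15% from the reference; the external engine's own default (11) misses
    a fraction of those.
    """

    match_score: int = 2
    mismatch_score: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    evalue_max: float = 0.001
    word_size: int = 7
    backend: str = "external_blastn"
    blastn_exe: str = "blastn"

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.backend not in ("external_blastn", "builtin"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass(frozen=True)
class RawHSP:
    """One local-alignment hit in linear (possibly doubled-reference) coords.

    ``nuclear`` is the subject interval; ``mito_start``/``mito_end`` are
    0-based half-open on the query as searched (single or doubled).
    """

    nuclear: GenomicInterval
    mito_start: int
    mito_end: int
    strand: str
    percent_identity: float
    aligned_mito_bp: int
    evalue: float
    score: float


@dataclass(frozen=True)
class CircularInterval:
    """An interval on a circular sequence of length L.

    Stored as one segment ``[s, e)`` with ``0 <= s < e <= L``, or as two
    segments ``[s, L) + [0, e')`` when the interval spans the origin.
    """

    L: int
    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (1 <= len(self.segments) <= 2):
            raise ValueError("CircularInterval needs 1 or 2 segments")
        for s, e in self.segments:
            if not (0 <= s < e <= self.L):
                raise ValueError(f"segment [{s},{e}) outside [0,{self.L})")
        if len(self.segments) == 2 and self.segments[0][1] != self.L:
            raise ValueError("two-segment form requires the first to end at L")
        if len(self.segments) == 2 and self.segments[1][0] != 0:
            raise ValueError("two-segment form requires the second to start at 0")

    def __len__(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def spans_origin(self) -> bool:
        return len(self.segments) == 2

    @property
    def arc_start(self) -> int:
        return self.segments[0][0]

    @property
    def arc_end(self) -> int:
        """End of the arc walking forward on the circle (may be < arc_start)."""
        return self.segments[-1][1]

    def covers(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.segments)

    def overlaps(self, other: "CircularInterval") -> bool:
        for s1, e1 in self.segments:
            for s2, e2 in other.segments:
                if max(s1, s2) < min(e1, e2):
                    return True
        return False

    def render(self) -> str:
        return ",".join(f"{s}-{e}" for s, e in self.segments)


def wrap_interval(start: int, end: int, L: int) -> CircularInterval:
    """Map a doubled-reference interval ``[start, end)`` back to the circle.

    Coordinates are reduced mod L; an interval crossing the origin becomes
    the two-segment comma-pair form.  Total length is preserved.
    """
    if not (0 <= start < end <= 2 * L):
        raise ValueError(f"interval [{start},{end}) outside doubled reference [0,{2*L})")
    if end - start > L:
        raise ValueError(f"interval length {end - start} exceeds circle length {L}")
    if start >= L:
        start, end = start - L, end - L
    if end <= L:
        return CircularInterval(L, ((start, end),))
    return CircularInterval(L, ((start, L), (0, end - L)))


def double_reference(mito: SequenceRecord) -> SequenceRecord:
    """Concatenate the circular reference with itself (name suffixed _x2)."""
    if mito.name.endswith(DOUBLED_SUFFIX):
        raise ValueError(f"{mito.name!r} is already a doubled reference")
    return SequenceRecord(mito.name + DOUBLED_SUFFIX, mito.sequence * 2, mito.role)


# ---------------------------------------------------------------------------
# external blastn backend


def _run_blastn(
    subjects: Sequence[SequenceRecord],
    query: SequenceRecord,
    params: AlignmentParams,
) -> dict[str, list[RawHSP]]:
    if shutil.which(params.blastn_exe) is None:
        raise BackendUnavailableError(
            f"alignment backend 'external_blastn' requires the {params.blastn_exe!r} "
            "executable on PATH"
        )
    with tempfile.TemporaryDirectory(prefix="numtkit_blast_") as tmp:
        tmp = Path(tmp)
        subj_fa = tmp / "subject.fa"
        query_fa = tmp / "query.fa"
        with open(subj_fa, "w") as fh:
            for rec in subjects:
                fh.write(f">{rec.name}\n{rec.sequence}\n")
        query_fa.write_text(f">{query.name}\n{query.sequence}\n")
        cmd = [
            params.blastn_exe,
            "-task", "blastn",
            "-subject", str(subj_fa),
            "-query", str(query_fa),
            "-reward", str(params.match_score),
            "-penalty", str(params.mismatch_score),
            "-gapopen", str(abs(params.gap_open)),
            "-gapextend", str(abs(params.gap_extend)),
            "-word_size", str(params.word_size),
            "-evalue", str(params.evalue_max),
            "-dust", "no",
            "-outfmt", "6 sseqid qstart qend sstart send pident length evalue score",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
        hits: dict[str, list[RawHSP]] = {rec.name: [] for rec in subjects}
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            sseqid, qstart, qend, sstart, send, pident, length, evalue, score = (
                line.split("\t")
            )
            qstart, qend = int(qstart), int(qend)
            sstart, send = int(sstart), int(send)
            strand = "+" if sstart <= send else "-"
            lo, hi = (sstart, send) if strand == "+" else (send, sstart)
            hits[sseqid].append(
                RawHSP(
                    nuclear=GenomicInterval(sseqid, lo - 1, hi, strand),
                    mito_start=qstart - 1,
                    mito_end=qend,
                    strand=strand,
                    percent_identity=float(pident),
                    aligned_mito_bp=qend - qstart + 1,
                    evalue=float(evalue),
                    score=float(score),
                )
            )
        return hits


# ---------------------------------------------------------------------------
# builtin seed-and-extend backend

# Ungapped Karlin-Altschul lambda for +2/-3 scoring at uniform base
# composition: solves 0.25 e^{2L} + 0.75 e^{-3L} = 1.  K is a rough
# constant; builtin e-values are approximate by design.
_KA_LAMBDA = brentq(
    lambda lam: 0.25 * math.exp(2 * lam) + 0.75 * math.exp(-3 * lam) - 1, 0.01, 2.0
)
_KA_K = 0.21


def _builtin_evalue(score: float, m: int, n: int) -> float:
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


def _seed_clusters(subject: str, query: str, k: int) -> list[tuple[int, int, int, int]]:
    """Chain exact k-mer seed hits into candidate extension windows.

    Seeds join an existing cluster when the query gap is <= 400 bp and the
    diagonal (s - q) stays within a +/-60 band of the cluster's diagonal
    range (allowing indel drift).  Returns (q_lo, q_hi, s_lo, s_hi) windows.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        kmer = subject[j : j + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)
    hits = []  # (qpos, spos)
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        if "N" in kmer:
            continue
        for j in index.get(kmer, ()):
            hits.append((i, j))
    hits.sort()
    # sweep in query order; a seed joins a cluster when the query gap is
    # small and its diagonal stays within a fixed band of the cluster's
    # first seed (bounding indel drift and window width).  Spurious
    # clusters rarely collect the minimum seed count.
    min_seeds = 3
    max_q_gap = 200
    step_drift = 20  # successive seeds: diag moves only at indels
    total_drift = 100
    # [qlo, qhi, slo, shi, dlo, dhi, n, anchor_diag, last_diag]
    open_clusters: list[list[int]] = []
    closed: list[list[int]] = []
    for q, s in hits:
        diag = s - q
        still_open = []
        for reg in open_clusters:
            if q - reg[1] > max_q_gap:
                closed.append(reg)
            else:
                still_open.append(reg)
        open_clusters = still_open
        for reg in open_clusters:
            if abs(diag - reg[8]) <= step_drift and abs(diag - reg[7]) <= total_drift:
                reg[0] = min(reg[0], q)
                reg[1] = max(reg[1], q + k)
                reg[2] = min(reg[2], s)
                reg[3] = max(reg[3], s + k)
                reg[4] = min(reg[4], diag)
                reg[5] = max(reg[5], diag)
                reg[6] += 1
                reg[8] = diag
                break
        else:
            open_clusters.append([q, q + k, s, s + k, diag, diag, 1, diag, diag])
    closed.extend(open_clusters)
    return [(r[0], r[1], r[2], r[3], r[4], r[5]) for r in closed if r[6] >= min_seeds]


_NEG = np.int32(-(10**8))


def _encode(seq: str) -> np.ndarray:
    # A,C,G,T -> 0..3, anything else (N) -> 4, which never matches
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        table[ord(b)] = i
    return table[np.frombuffer(seq.encode(), dtype=np.uint8)]


_BANDED_SW_CORE = None


def _get_banded_sw_core():
    """Compile (once) the exact banded Gotoh DP with traceback."""
    global _BANDED_SW_CORE
    if _BANDED_SW_CORE is not None:
        return _BANDED_SW_CORE
    from numba import njit

    @njit(cache=False)
    def core(s, q, dlo, W, match, mismatch, go, ge):  # pragma: no cover - jitted
        n = s.shape[0]
        m = q.shape[0]
        NEG = -(10**8)
        H = np.zeros((n + 1, W), np.int32)
        E = np.full((n + 1, W), NEG, np.int32)
        F = np.full((n + 1, W), NEG, np.int32)
        best = 0
        bi = 0
        bk = 0
        for i in range(1, n + 1):
            for k in range(W):
                j = i + dlo + k
                if j < 1 or j > m:
                    H[i, k] = 0
                    E[i, k] = NEG
                    F[i, k] = NEG
                    continue
                e = NEG
                if k + 1 < W:  # vertical gap: consumes subject base i
                    a = H[i - 1, k + 1] + go
                    b = E[i - 1, k + 1] + ge
                    e = a if a > b else b
                f = NEG
                if k - 1 >= 0:  # horizontal gap: consumes query base j
                    a = H[i, k - 1] + go
                    b = F[i, k - 1] + ge
                    f = a if a > b else b
                sc = match if (s[i - 1] == q[j - 1] and s[i - 1] != 4) else mismatch
                h = H[i - 1, k] + sc
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                H[i, k] = h
                E[i, k] = e
                F[i, k] = f
                if h > best:
                    best = h
                    bi = i
                    bk = k
        if best <= 0:
            return (0, 0, 0, 0, 0, 0, 0)
        i = bi
        k = bk
        s_end = i
        q_end = i + dlo + k
        matches = 0
        columns = 0
        state = 0  # 0=H, 1=E, 2=F
        while i > 0:
            j = i + dlo + k
            if state == 0:
                h = H[i, k]
                if h == 0:
                    break
                eq = s[i - 1] == q[j - 1] and s[i - 1] != 4
                sc = match if eq else mismatch
                if h == H[i - 1, k] + sc:
                    if eq:
                        matches += 1
                    columns += 1
                    i -= 1
                elif h == E[i, k]:
                    state = 1
                elif h == F[i, k]:
                    state = 2
                else:
                    break
            elif state == 1:
                columns += 1
                ext = k + 1 < W and E[i, k] == E[i - 1, k + 1] + ge
                i -= 1
                k += 1
                if not ext:
                    state = 0
            else:
                columns += 1
                ext = k - 1 >= 0 and F[i, k] == F[i, k - 1] + ge
                k -= 1
                if not ext:
                    state = 0
        return (best, i, s_end, i + dlo + k, q_end, matches, columns)

    _BANDED_SW_CORE = core
    return core


def _banded_sw(
    s: np.ndarray,
    q: np.ndarray,
    dlo: int,
    dhi: int,
    params: AlignmentParams,
):
    """Banded affine-gap local alignment (exact Gotoh within the band).

    The band restricts subject-minus-query diagonals to [dlo, dhi].
    Returns (score, s_start, s_end, q_start, q_end, matches, columns) for
    the best local alignment inside the band, or None.
    """
    core = _get_banded_sw_core()
    res = core(
        s,
        q,
        dlo,
        dhi - dlo + 1,
        params.match_score,
        params.mismatch_score,
        params.gap_open + params.gap_extend,
        params.gap_extend,
    )
    if res[0] <= 0:
        return None
    return res


def _builtin_one_strand(
    subject: SequenceRecord,
    query_seq: str,
    strand: str,
    params: AlignmentParams,
    search_m: int,
    search_n: int,
) -> list[RawHSP]:
    margin = 80
    band_pad = 50
    s_enc_full = _encode(subject.sequence)
    q_enc_full = _encode(query_seq)
    out = []
    for q_lo, q_hi, s_lo, s_hi, diag_lo, diag_hi in _seed_clusters(
        subject.sequence, query_seq, params.word_size
    ):
        s0 = max(0, s_lo - margin)
        s1 = min(len(subject.sequence), s_hi + margin)
        q0 = max(0, q_lo - margin)
        q1 = min(len(query_seq), q_hi + margin)
        # diagonal band around the seeded diagonals, in window coordinates
        dlo = diag_lo - (s0 - q0) - band_pad
        dhi = diag_hi - (s0 - q0) + band_pad
        res = _banded_sw(s_enc_full[s0:s1], q_enc_full[q0:q1], dlo, dhi, params)
        if res is None:
            continue
        score, ws_start, ws_end, wq_start, wq_end, matches, columns = res
        evalue = _builtin_evalue(score, search_m, search_n)
        if evalue > params.evalue_max:
            continue
        s_start, s_end = s0 + ws_start, s0 + ws_end
        q_start, q_end = q0 + wq_start, q0 + wq_end
        if strand == "-":
            q_start, q_end = len(query_seq) - q_end, len(query_seq) - q_start
        if s_end <= s_start or q_end <= q_start:
            continue
        out.append(
            RawHSP(
                nuclear=GenomicInterval(subject.name, s_start, s_end, strand),
                mito_start=q_start,
                mito_end=q_end,
                strand=strand,
                percent_identity=100.0 * matches / columns if columns else 0.0,
                aligned_mito_bp=q_end - q_start,
                evalue=evalue,
                score=float(score),
            )
        )
    return out


def _dedup_contained(hsps: list[RawHSP]) -> list[RawHSP]:
    """Drop HSPs whose nuclear+query footprint lies inside a higher-scoring one."""
    kept: list[RawHSP] = []
    for h in sorted(hsps, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if (
                h.strand == k.strand
                and h.nuclear.start >= k.nuclear.start
                and h.nuclear.end <= k.nuclear.end
                and h.mito_start >= k.mito_start
                and h.mito_end <= k.mito_end
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def _run_builtin(
    subjects: Sequence[SequenceRecord],
    query: SequenceRecord,
    params: AlignmentParams,
) -> dict[str, list[RawHSP]]:
    hits: dict[str, list[RawHSP]] = {}
    n = len(query.sequence)
    for rec in subjects:
        m = len(rec.sequence)
        fwd = _builtin_one_strand(rec, query.sequence, "+", params, m, n)
        rev = _builtin_one_strand(rec, revcomp(query.sequence), "-", params, m, n)
        hits[rec.name] = _dedup_contained(fwd + rev)
    return hits


# ---------------------------------------------------------------------------
# public entry points


def discover_hsps_multi(
    subjects: Sequence[SequenceRecord],
    query: SequenceRecord,
    params: AlignmentParams | None = None,
) -> dict[str, list[RawHSP]]:
    """Search one query against many subjects; one engine invocation.

    Returns a dict keyed by subject name (every subject present, possibly
    with an empty list).  All returned HSPs satisfy e <= ``evalue_max``.
    """
    params = params or AlignmentParams()
    if not subjects or not query.sequence:
        return {rec.name: [] for rec in subjects}
    if params.backend == "external_blastn":
        return _run_blastn(subjects, query, params)
    return _run_builtin(subjects, query, params)


def discover_hsps(
    subject: SequenceRecord,
    mito: SequenceRecord,
    params: AlignmentParams | None = None,
) -> list[RawHSP]:
    """Find high-scoring local alignments of ``mito`` (the query) in ``subject``."""
    return discover_hsps_multi([subject], mito, params)[subject.name]


def shift_and_wrap(hsps: Iterable[RawHSP], L: int) -> list[tuple[RawHSP, CircularInterval]]:
    """Map doubled-reference HSPs onto the circle and drop mirror duplicates.

    A hit wholly inside the second copy of the doubled reference repeats a
    first-copy hit shifted by +L; shifting by -L before wrapping collapses
    the pair.  An origin-spanning alignment additionally spawns partial
    hits of its two halves at other doubled-reference offsets; any hit
    whose nuclear and circular footprint lies inside a higher-scoring one
    is dropped.  Alignments slightly longer than the full circle (tandem
    or gap-inflated) are clipped to one turn.
    """
    seen = set()
    wrapped: list[tuple[RawHSP, CircularInterval]] = []
    for h in hsps:
        start, end = h.mito_start, h.mito_end
        if end - start > L:
            end = start + L
        if start >= L:
            start, end = start - L, end - L
        circ = wrap_interval(start, end, L)
        key = (h.nuclear.seq_name, h.nuclear.start, h.nuclear.end, h.strand, circ.segments)
        if key in seen:
            continue
        seen.add(key)
        wrapped.append((h, circ))

    def _circ_contained(inner: CircularInterval, outer: CircularInterval) -> bool:
        return all(
            any(os <= s and e <= oe for os, oe in outer.segments)
            for s, e in inner.segments
        )

    wrapped.sort(key=lambda hc: -hc[0].score)
    out: list[tuple[RawHSP, CircularInterval]] = []
    for h, circ in wrapped:
        redundant = any(
            h.strand == k.strand
            and h.nuclear.seq_name == k.nuclear.seq_name
            and h.nuclear.start >= k.nuclear.start
            and h.nuclear.end <= k.nuclear.end
            and _circ_contained(circ, kc)
            for k, kc in out
        )
        if not redundant:
            out.append((h, circ))
    out.sort(key=lambda hc: (hc[0].nuclear.seq_name, hc[0].nuclear.start))
    return out
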