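"""Readers and writers for the formats the Numt pipeline consumes and emits.

Internal coordinates are 0-based half-open everywhere (BED convention).
Human-readable reports print 1-based inclusive coordinates; helpers for
both conventions live here so no other module does its own arithmetic.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

# Missing genotype sentinel: per-sample alt-allele counts are int or MISSING.
MISSING = None

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NORMALIZE = str.maketrans(
    "".join(chr(c) for c in range(256)),
    "".join(
        chr(c) if chr(c) in "ACGTN" else "N" for c in range(256)
    ),
)


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending line."""


class SeqRole(str, Enum):
    chromosome = "chromosome"
    unplaced = "unplaced"


def normalize_sequence(seq: str) -> str:
    """Uppercase and map any non-ACGTN character (IUPAC codes etc.) to N."""
    return seq.upper().translate(_NORMALIZE)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Canonical dog chromosome names: chr1..chr38 and chrX.
CANONICAL_CHROM_RE = r"^chr([1-9]|[12][0-9]|3[0-8]|X)$"

# Names matching any of these are unplaced regardless of the canonical form.
DEFAULT_UNPLACED_PATTERNS = (r"^chrUn", r"scaffold")


def classify_role(
    name: str,
    unplaced_patterns: Sequence[str] = DEFAULT_UNPLACED_PATTERNS,
    canonical_pattern: str = CANONICAL_CHROM_RE,
) -> SeqRole:
    """Assign a sequence name to the chromosome or unplaced stratum.

    A name is *unplaced* when it matches any of ``unplaced_patterns`` or
    when it lacks the canonical chromosome form (``chr1``-``chr38``/``chrX``
    by default).  Both pattern sets are configurable because assemblies use
    different naming dialects for unassigned contigs.
    """
    for pat in unplaced_patterns:
        if re.search(pat, name):
            return SeqRole.unplaced
    if re.match(canonical_pattern, name):
        return SeqRole.chromosome
    return SeqRole.unplaced


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence with its assembly stratum.

    The sequence is stored normalized: uppercase, alphabet {A,C,G,T,N}.
    """

    name: str
    sequence: str
    role: SeqRole = SeqRole.chromosome

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.name!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.name, revcomp(self.sequence), self.role)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named (linear) sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.seq_name != other.seq_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def report_str(self) -> str:
        """1-based inclusive rendering used in human-readable reports."""
        return f"{self.seq_name}:{self.start + 1}-{self.end}"


@dataclass
class InsertionSV:
    """Insertion structural variant, fully or partially assembled.

    Exactly one of two states holds: the full inserted sequence is known
    (``seq_full``), or only sequence extending into the variant from each
    edge is known (``seq_left``/``seq_right``), as happens when the variant
    is larger than what short reads can assemble across.
    """

    id: str
    position: GenomicInterval
    seq_full: str | None = None
    seq_left: str | None = None
    seq_right: str | None = None
    genotypes: dict[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_full = self.seq_full is not None
        has_partial = self.seq_left is not None or self.seq_right is not None
        if has_full == has_partial:
            raise ValueError(
                f"insertion {self.id}: need full sequence XOR partial sequences"
            )

    @property
    def is_partial(self) -> bool:
        return self.seq_full is None


@dataclass
class DeletionSV:
    id: str
    span: GenomicInterval
    genotypes: dict[str, int | None] = field(default_factory=dict)


class SVReadResult(NamedTuple):
    insertions: list[InsertionSV]
    deletions: list[DeletionSV]
    samples: list[str]
    n_skipped: int


def _open_text(path: str | Path):
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(
    path: str | Path,
    unplaced_patterns: Sequence[str] = DEFAULT_UNPLACED_PATTERNS,
) -> list[SequenceRecord]:
    """Read a plain or gzip FASTA into normalized records, order preserved."""
    with _open_text(path) as fh:
        # SeqIO silently skips leading junk; enforce the header contract here.
        pos = fh.tell()
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: line {lineno} is not a FASTA header: {line.strip()!r}"
                    )
                break
        fh.seek(pos)
        records = [
            SequenceRecord(
                name=rec.id,
                sequence=normalize_sequence(str(rec.seq)),
                role=classify_role(rec.id, unplaced_patterns),
            )
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_numt_bed(numts, path: str | Path, seq_lengths: Mapping[str, int] | None = None) -> None:
    """Write merged Numt loci as BED6.

    Name field is the mitochondrial interval in circle coordinates, rendered
    as a comma pair when the source segment spans the origin; multiple member
    segments are joined with ``;``.  Score is ``round(10 x identity)`` capped
    at 1000 (so 100% identity maps to the BED maximum).
    """
    lines = []
    bad = []
    for locus in numts:
        span = locus.nuclear_span
        if seq_lengths is not None:
            limit = seq_lengths.get(span.seq_name)
            if limit is None or span.end > limit:
                bad.append(locus.id)
                continue
        name = ";".join(m.mito.render() for m in locus.members) or "unconfirmed"
        score = min(1000, round(10 * locus.mean_identity))
        lines.append(
            f"{span.seq_name}\t{span.start}\t{span.end}\t{name}\t{score}\t{locus.strand}"
        )
    if bad:
        raise ValueError(f"unresolvable coordinates for loci: {', '.join(bad)}")
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (strand kept when present)."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED fields")
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def _decode_genotype(gt) -> int | None:
    if gt is None:
        return MISSING
    alleles = [a for a in gt if a is not None]
    if len(alleles) < len(gt) or not alleles:
        return MISSING
    return sum(1 for a in alleles if a > 0)


_SEQ_ALT_RE = re.compile(r"^[ACGTNacgtn]+$")


def read_sv_vcf(
    path: str | Path,
    lseq_key: str = "LSEQ",
    rseq_key: str = "RSEQ",
) -> SVReadResult:
    """Read a structural-variant VCF into insertion and deletion calls.

    Variants are partitioned on the SVTYPE INFO tag; records without it are
    skipped (counted).  Insertion sequence comes from the ALT allele when it
    is literal sequence, otherwise from the ``lseq_key``/``rseq_key`` INFO
    fields holding the partially assembled left/right edges.  Genotypes are
    decoded to alt-allele counts; any unresolvable genotype becomes missing.
    """
    import pysam

    ins: list[InsertionSV] = []
    dels: list[DeletionSV] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                n_skipped += 1
                continue
            genotypes = {
                s: _decode_genotype(rec.samples[s].get("GT")) for s in samples
            }
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            if svtype == "DEL":
                start = rec.start
                stop = rec.stop if rec.stop > start else start + 1
                dels.append(
                    DeletionSV(vid, GenomicInterval(rec.chrom, start, stop), genotypes)
                )
            elif svtype == "INS":
                pos_iv = GenomicInterval(rec.chrom, rec.start, rec.start + 1)
                alt = rec.alts[0] if rec.alts else ""
                seq_full = seq_left = seq_right = None
                if alt and _SEQ_ALT_RE.match(alt):
                    seq = normalize_sequence(alt)
                    if seq.startswith(normalize_sequence(rec.ref)):
                        seq = seq[len(rec.ref):]
                    seq_full = seq or None
                if seq_full is None:
                    left = rec.info.get(lseq_key)
                    right = rec.info.get(rseq_key)
                    seq_left = normalize_sequence(left) if left else None
                    seq_right = normalize_sequence(right) if right else None
                if seq_full is None and seq_left is None and seq_right is None:
                    n_skipped += 1
                    logger.warning("insertion %s has no sequence; skipped", vid)
                    continue
                ins.append(
                    InsertionSV(vid, pos_iv, seq_full, seq_left, seq_right, genotypes)
                )
            else:
                n_skipped += 1
    if n_skipped:
        logger.warning("read_sv_vcf: skipped %d records", n_skipped)
    return SVReadResult(ins, dels, samples, n_skipped)
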