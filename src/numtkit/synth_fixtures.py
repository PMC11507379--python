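"""Seeded generators for every input the Numt pipeline consumes.

The generators emulate the structure of the real inputs — a circular
mitochondrial genome, nuclear scaffolds carrying planted Numts of known
origin/divergence/orientation (including origin-spanning copies and
copies fragmented by a later transposon-like insertion), assembly pairs
differing by Numt presence, and a genotyped SV VCF — together with
machine-readable ground truth, so the whole pipeline is testable without
any downloads.  Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    SequenceRecord,
    classify_role,
    revcomp,
)
from .hsp_discovery import CircularInterval, wrap_interval
from .dimorphism_assemblies import IndelVariant

BASES = np.array(list("ACGT"))

DEFAULT_SCAFFOLDS = (
    ("chr1", 200_000),
    ("chr2", 200_000),
    ("chr3", 200_000),
    ("chr4", 200_000),
    ("chr5", 200_000),
    ("chrUn_test", 50_000),
)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_dna(n: int, rng) -> str:
    return "".join(BASES[_rng(rng).integers(0, 4, size=n)])


def make_mito(L: int = 16_727, seed=0) -> SequenceRecord:
    """Uniform-random circular mitochondrial reference (default sized to the
    ~16.7 kb canine mitochondrial genome)."""
    if L < 1000:
        raise ValueError("mitochondrial reference must be at least 1000 bp")
    return SequenceRecord("mito_synth", random_dna(L, _rng(seed)))


def mutate(seq: str, sub_rate: float, indel_rate: float, seed) -> str:
    """Diverge a sequence by per-site substitutions and short indels.

    Substitutions replace a base with one of the other three uniformly;
    indels occur at ``indel_rate`` per site with geometric lengths of mean
    3 bp, split evenly between insertions and deletions.  Deterministic
    for a given seed.
    """
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = _rng(seed)
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(1 / 3))
            if rng.random() < 0.5:
                out.append(random_dna(length, rng))
                # insertion: current base still to be processed
                continue
            i += length  # deletion of `length` bases
            continue
        base = seq[i]
        if sub_rate > 0 and rng.random() < sub_rate and base in "ACGT":
            choices = [b for b in "ACGT" if b != base]
            base = choices[rng.integers(0, 3)]
        out.append(base)
        i += 1
    return "".join(out)


@dataclass(frozen=True)
class PlantSpec:
    """Conditions for planting synthetic Numts into nuclear scaffolds."""

    n_numts: int = 50
    length_range: tuple[int, int] = (100, 5000)
    sub_rate_range: tuple[float, float] = (0.0, 0.15)
    indel_rate: float = 0.002
    minus_strand_fraction: float = 0.5
    origin_spanning_fraction: float = 0.2
    fragmented_fraction: float = 0.1
    disruptor_length: int = 500
    min_separation: int = 3000  # keeps distinct plants from merging
    scaffolds: tuple[tuple[str, int], ...] = DEFAULT_SCAFFOLDS
    seed: int = 42

    def __post_init__(self) -> None:
        if self.length_range[0] < 50:
            raise ValueError("planted Numts must be at least 50 bp")
        for rate in (*self.sub_rate_range, self.indel_rate):
            if not (0 <= rate < 1):
                raise ValueError("rates must be in [0, 1)")


@dataclass
class PlantedNumt:
    numt_id: str
    scaffold: str
    start: int  # nuclear interval of the full inserted sequence
    end: int
    source: CircularInterval
    strand: str
    sub_rate: float
    fragmented: bool
    sequence: str
    present_in: dict[str, bool] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    numts: list[PlantedNumt]

    def __iter__(self):
        return iter(self.numts)

    def __len__(self):
        return len(self.numts)

    def by_id(self) -> dict[str, PlantedNumt]:
        return {n.numt_id: n for n in self.numts}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "numt_id": n.numt_id,
                    "scaffold": n.scaffold,
                    "start": n.start,
                    "end": n.end,
                    "mito_interval": n.source.render(),
                    "strand": n.strand,
                    "sub_rate": round(n.sub_rate, 4),
                    "fragmented": n.fragmented,
                }
                for n in self.numts
            ]
        )


def build_assembly(
    spec: PlantSpec, mito: SequenceRecord, assembly_name: str = "ref"
) -> tuple[list[SequenceRecord], PlantedTruth]:
    """Plant Numts into random scaffolds and emit the ground truth.

    Each Numt is a mutated copy of a mitochondrial segment (origin-spanning
    segments wrap around the circle; fragmented Numts carry a random
    disruptor insertion at their midpoint, emulating a transposon that
    jumped in after Numt integration).  Plants are separated by at least
    ``min_separation`` bp so distinct insertions never co-merge.
    """
    rng = _rng(spec.seed)
    L = len(mito.sequence)
    doubled_seq = mito.sequence * 2

    n = spec.n_numts
    n_origin = round(spec.origin_spanning_fraction * n)
    n_frag = round(spec.fragmented_fraction * n)
    origin_ids = set(rng.choice(n, size=n_origin, replace=False).tolist())
    frag_ids = set(rng.choice(n, size=n_frag, replace=False).tolist())

    plants = []
    for i in range(n):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        length = min(length, L - 1)
        if i in origin_ids:
            m_start = int(rng.integers(max(L - length + 1, 1), L))
        else:
            m_start = int(rng.integers(0, L - length + 1))
        source = wrap_interval(m_start, m_start + length, L)
        sub_rate = float(rng.uniform(*spec.sub_rate_range))
        seq = mutate(
            doubled_seq[m_start : m_start + length],
            sub_rate,
            spec.indel_rate,
            rng,
        )
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        if strand == "-":
            seq = revcomp(seq)
        fragmented = i in frag_ids
        if fragmented:
            mid = len(seq) // 2
            seq = seq[:mid] + random_dna(spec.disruptor_length, rng) + seq[mid:]
        plants.append((f"numt{i+1:03d}", source, strand, sub_rate, fragmented, seq))

    # assign plants to scaffolds proportionally to length, then place them
    # with guaranteed separation using the uniform-spacing construction
    weights = np.array([l for _, l in spec.scaffolds], dtype=float)
    weights /= weights.sum()
    assignment = rng.choice(len(spec.scaffolds), size=n, p=weights)

    records = []
    truth = []
    for s_idx, (name, s_len) in enumerate(spec.scaffolds):
        mine = [plants[i] for i in range(n) if assignment[i] == s_idx]
        background = random_dna(s_len, rng)
        k = len(mine)
        if k == 0:
            records.append(SequenceRecord(name, background, classify_role(name)))
            continue
        usable = s_len - (k + 1) * spec.min_separation
        if usable <= 0:
            raise ValueError(f"scaffold {name} too small for {k} planted Numts")
        offsets = np.sort(rng.choice(usable, size=k, replace=False))
        positions = [int(o + (j + 1) * spec.min_separation) for j, o in enumerate(offsets)]
        parts = []
        cursor = 0
        shift = 0
        rng_order = sorted(zip(positions, mine))
        for pos, (nid, source, strand, sub_rate, fragmented, seq) in rng_order:
            parts.append(background[cursor:pos])
            parts.append(seq)
            truth.append(
                PlantedNumt(
                    numt_id=nid,
                    scaffold=name,
                    start=pos + shift,
                    end=pos + shift + len(seq),
                    source=source,
                    strand=strand,
                    sub_rate=sub_rate,
                    fragmented=fragmented,
                    sequence=seq,
                    present_in={assembly_name: True},
                )
            )
            shift += len(seq)
            cursor = pos
        parts.append(background[cursor:])
        records.append(SequenceRecord(name, "".join(parts), classify_role(name)))

    truth.sort(key=lambda t: t.numt_id)
    return records, PlantedTruth(truth)


def derive_dimorphic_pair(
    records: Sequence[SequenceRecord],
    truth: PlantedTruth,
    absent_ids: set[str],
    large_sv_ids: set[str],
    extra_bp: int = 2000,
    label: str = "alt_assembly",
) -> tuple[list[SequenceRecord], list[IndelVariant]]:
    """Build a second assembly lacking a known subset of the planted Numts.

    Numts in ``absent_ids`` are excised exactly; those in ``large_sv_ids``
    are excised together with ``extra_bp`` of flanking sequence on each
    side, so the corresponding deletion exceeds the Numt by more than the
    1000 bp large-SV margin.  Returns the new assembly plus the exact
    deletion variants an assembly-alignment caller would report (deletions
    in the second assembly relative to the reference).
    """
    by_id = truth.by_id()
    unknown = (absent_ids | large_sv_ids) - set(by_id)
    if unknown:
        raise ValueError(f"unknown Numt ids: {sorted(unknown)}")
    if absent_ids & large_sv_ids:
        raise ValueError("a Numt cannot be both cleanly absent and a large SV")

    cuts: dict[str, list[tuple[int, int]]] = {}
    variants = []
    for nid in sorted(absent_ids | large_sv_ids):
        t = by_id[nid]
        if nid in large_sv_ids:
            start, end = t.start - extra_bp, t.end + extra_bp
        else:
            start, end = t.start, t.end
        start = max(0, start)
        cuts.setdefault(t.scaffold, []).append((start, end))
        variants.append(
            IndelVariant(
                kind="deletion",
                reference_interval=GenomicInterval(t.scaffold, start, end),
                length_bp=end - start,
                other_assembly=label,
            )
        )
        t.present_in[label] = False
    for nid in set(by_id) - absent_ids - large_sv_ids:
        by_id[nid].present_in[label] = True

    for scaffold, spans in cuts.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping excisions on {scaffold}")

    out_records = []
    for rec in records:
        seq = rec.sequence
        for start, end in sorted(cuts.get(rec.name, []), reverse=True):
            seq = seq[:start] + seq[end:]
        out_records.append(SequenceRecord(rec.name, seq, rec.role))
    return out_records, variants


@dataclass
class PopulationFixture:
    vcf_text: str
    categories: pd.DataFrame  # columns: sample, category
    expected_counts: dict[str, int]
    numt_variant_ids: list[str]
    decoy_variant_ids: list[str]

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        vcf_path = out_dir / "population.vcf"
        cat_path = out_dir / "categories.tsv"
        vcf_path.write_text(self.vcf_text)
        self.categories.to_csv(cat_path, sep="\t", index=False)
        return vcf_path, cat_path


DEFAULT_CATEGORY_MIX = {
    "Breed Dog": 0.70,
    "Village Dog": 0.20,
    "Wolf": 0.08,
    "Mixed/Other": 0.02,
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={chrom},length={chrom_len}>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=LSEQ,Number=1,Type=String,Description="Left partial insertion sequence">
##INFO=<ID=RSEQ,Number=1,Type=String,Description="Right partial insertion sequence">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def make_population_vcf(
    truth: PlantedTruth,
    n_samples: int = 100,
    allele_freq_range: tuple[float, float] = (0.1, 0.9),
    partial_fraction: float = 0.5,
    category_mix: Mapping[str, float] = None,
    seed: int = 0,
    n_numt_variants: int | None = 20,
    n_decoys: int = 10,
    partial_edge_bp: int = 150,
    missing_rate: float = 0.02,
    chrom: str = "chr1",
    chrom_len: int = 10_000_000,
) -> PopulationFixture:
    """Emit a genotyped SV VCF whose insertion alleles are planted Numts.

    The first ``n_numt_variants`` planted Numt sequences become INS records
    (a ``partial_fraction`` subset carries only 150 bp edge sequences in
    LSEQ/RSEQ, mimicking insertions too large to assemble from short
    reads); ``n_decoys`` random-sequence insertions are interleaved as
    negative controls.  Genotypes are binomial draws at per-variant allele
    frequencies; the expected per-sample Numt count is tabulated from the
    drawn genotypes (missing counts as absent).
    """
    rng = _rng(seed)
    category_mix = dict(category_mix or DEFAULT_CATEGORY_MIX)
    numts = list(truth)[: n_numt_variants or len(truth.numts)]

    samples = [f"sample{i+1:04d}" for i in range(n_samples)]
    cats = list(category_mix)
    probs = np.array([category_mix[c] for c in cats], dtype=float)
    probs /= probs.sum()
    sample_cat = {s: cats[i] for s, i in zip(samples, rng.choice(len(cats), n_samples, p=probs))}

    variants = []  # (pos, vid, is_numt, seq, partial)
    pos = 50_000
    n_partial = round(partial_fraction * len(numts))
    partial_set = set(rng.choice(len(numts), size=n_partial, replace=False).tolist())
    for i, t in enumerate(numts):
        variants.append((pos, f"numt_ins_{i+1:03d}", True, t.sequence, i in partial_set))
        pos += 10_000
    for j in range(n_decoys):
        dec_len = int(rng.integers(400, 2001))
        variants.append((pos, f"decoy_ins_{j+1:03d}", False, random_dna(dec_len, rng), False))
        pos += 10_000

    lines = [_VCF_HEADER.format(chrom=chrom, chrom_len=chrom_len)]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    expected = {s: 0 for s in samples}
    numt_ids, decoy_ids = [], []
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    for pos, vid, is_numt, seq, partial in variants:
        freq = float(rng.uniform(*allele_freq_range))
        acs = rng.binomial(2, freq, size=n_samples)
        missing = rng.random(n_samples) < missing_rate
        gts = []
        for s, ac, miss in zip(samples, acs, missing):
            if miss:
                gts.append("./.")
            else:
                gts.append(gt_strings[int(ac)])
                if is_numt and ac >= 1:
                    expected[s] += 1
        if partial:
            info = (
                f"SVTYPE=INS;SVLEN={len(seq)};"
                f"LSEQ={seq[:partial_edge_bp]};RSEQ={seq[-partial_edge_bp:]}"
            )
            ref, alt = "A", "<INS>"
        else:
            info = f"SVTYPE=INS;SVLEN={len(seq)}"
            ref, alt = "A", "A" + seq
        (numt_ids if is_numt else decoy_ids).append(vid)
        lines.append(
            f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts)
        )
    categories = pd.DataFrame(
        {"sample": samples, "category": [sample_cat[s] for s in samples]}
    )
    return PopulationFixture(
        vcf_text="\n".join(lines) + "\n",
        categories=categories,
        expected_counts=expected,
        numt_variant_ids=numt_ids,
        decoy_variant_ids=decoy_ids,
    )


# ---------------------------------------------------------------------------
# presets


@dataclass
class BasicFixture:
    mito: SequenceRecord
    records: list[SequenceRecord]
    truth: PlantedTruth


def preset_basic(seed: int = 42, spec: PlantSpec | None = None) -> BasicFixture:
    """Default planted-Numt fixture: 50 Numts of 100-5000 bp at 0-15%
    divergence, 20% origin-spanning, 10% fragmented."""
    spec = spec or PlantSpec(seed=seed)
    mito = make_mito(seed=seed + 1)
    records, truth = build_assembly(spec, mito)
    return BasicFixture(mito, records, truth)


@dataclass
class DimorphFixture:
    mito: SequenceRecord
    reference: list[SequenceRecord]
    other: list[SequenceRecord]
    truth: PlantedTruth
    variants: list[IndelVariant]
    absent_ids: set[str]
    large_sv_ids: set[str]


def preset_dimorph(seed: int = 42) -> DimorphFixture:
    """Assembly pair differing by 10 clean excisions and 5 large-SV
    excisions out of 50 planted Numts (35 remain fixed).

    Plants use moderate divergence without indels or fragmentation so each
    planted Numt is annotated as a single HSP, making the class partition
    of the calls directly comparable to the planted truth.
    """
    spec = PlantSpec(
        n_numts=50,
        sub_rate_range=(0.0, 0.10),
        indel_rate=0.0,
        fragmented_fraction=0.0,
        seed=seed,
    )
    mito = make_mito(seed=seed + 1)
    records, truth = build_assembly(spec, mito)
    rng = _rng(seed + 2)
    ids = [t.numt_id for t in truth]
    picked = rng.choice(len(ids), size=15, replace=False)
    absent_ids = {ids[i] for i in picked[:10]}
    large_sv_ids = {ids[i] for i in picked[10:]}
    other, variants = derive_dimorphic_pair(records, truth, absent_ids, large_sv_ids)
    return DimorphFixture(mito, records, other, truth, variants, absent_ids, large_sv_ids)


@dataclass
class PopulationPreset:
    mito: SequenceRecord
    truth: PlantedTruth
    fixture: PopulationFixture


def preset_population(seed: int = 42) -> PopulationPreset:
    """100 genotyped samples over 20 Numt insertions (50% partially
    assembled) plus 10 random-sequence decoy insertions."""
    spec = PlantSpec(
        n_numts=20,
        length_range=(400, 2000),
        sub_rate_range=(0.0, 0.10),
        indel_rate=0.001,
        fragmented_fraction=0.0,
        seed=seed,
    )
    mito = make_mito(seed=seed + 1)
    _, truth = build_assembly(spec, mito)
    fixture = make_population_vcf(truth, n_samples=100, partial_fraction=0.5, seed=seed + 2)
    return PopulationPreset(mito, truth, fixture)


@dataclass
class OutgroupFixture:
    mito: SequenceRecord
    reference: list[SequenceRecord]
    outgroup: list[SequenceRecord]
    truth: PlantedTruth
    excised_ids: set[str]


def preset_outgroup(seed: int = 42, n_numts: int = 12, n_excised: int = 5) -> OutgroupFixture:
    """Reference plus a synthetic 'outgroup' copy with a Numt subset excised.

    The outgroup is the reference with ``n_excised`` Numts cleanly removed
    and 3% substitution divergence applied genome-wide, so flanks still
    anchor while retained Numts remain confirmable.
    """
    spec = PlantSpec(
        n_numts=n_numts,
        length_range=(300, 3000),
        sub_rate_range=(0.0, 0.10),
        indel_rate=0.0,
        fragmented_fraction=0.0,
        min_separation=25_000,
        scaffolds=(("chr1", 400_000), ("chr2", 400_000)),
        seed=seed,
    )
    mito = make_mito(seed=seed + 1)
    records, truth = build_assembly(spec, mito)
    rng = _rng(seed + 2)
    ids = [t.numt_id for t in truth]
    excised = {ids[i] for i in rng.choice(len(ids), size=n_excised, replace=False)}
    outgroup, _ = derive_dimorphic_pair(records, truth, excised, set(), label="outgroup")
    outgroup = [
        SequenceRecord(r.name, mutate(r.sequence, 0.03, 0.0, rng), r.role)
        for r in outgroup
    ]
    return OutgroupFixture(mito, records, outgroup, truth, excised)
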