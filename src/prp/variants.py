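"""SNV parsing and coding-consequence calling against canonical transcripts.

Coordinates are 1-based inclusive throughout (VCF and GFF3 conventions).
On the minus strand, alleles are reverse-complemented when projected into
CDS space; the genomic ref/alt stored on the variant are never mutated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONSEQUENCES = (
    "missense",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "synonymous",
    "non_coding",
)

#: The nonsynonymous consequence classes retained by curation.
NSSNV_CONSEQUENCES = frozenset(
    {"missense", "start_lost", "stop_gained", "stop_lost"}
)


class ReferenceMismatchError(ValueError):
    """The genome base at the variant position does not match variant.ref."""


class TranscriptModelError(ValueError):
    """The transcript's CDS structure is invalid (e.g. length not /3)."""


class VCFParseError(ValueError):
    """A VCF record could not be parsed."""


@dataclass(frozen=True)
class GenomicVariant:
    """A single-nucleotide variant in genomic coordinates."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: Optional[str] = None

    def __post_init__(self):
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(
                f"alleles must be single nucleotides in ACGT, got "
                f"{self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


def variant_key(variant: GenomicVariant) -> tuple:
    """Identity key used for all dedup/overlap operations.

    Two variants overlap iff their keys are equal.
    """
    return (variant.chrom, variant.pos, variant.ref, variant.alt)


@dataclass(frozen=True)
class TranscriptModel:
    """A canonical transcript: ordered CDS exons on the genome.

    ``exons`` are 1-based inclusive (start, end) genomic intervals stored in
    genomic ascending order; transcript orientation is given by ``strand``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple  # of (start, end) pairs, genomic ascending order

    def __post_init__(self):
        if self.strand not in "+-":
            raise TranscriptModelError(f"bad strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end or start <= prev_end:
                raise TranscriptModelError(
                    f"{self.transcript_id}: exons must be non-overlapping "
                    "and sorted"
                )
            prev_end = end
        if self.cds_length % 3 != 0:
            raise TranscriptModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def cds_positions(self) -> list:
        """Genomic positions of every CDS base, in transcript (5'→3') order."""
        positions = []
        for start, end in self.exons:
            positions.extend(range(start, end + 1))
        if self.strand == "-":
            positions.reverse()
        return positions


@dataclass(frozen=True)
class CodingEffect:
    """Transcript-level consequence of an SNV."""

    consequence: str
    cds_pos: int  # 1-based position in CDS
    codon_index: int  # 1-based codon number
    ref_codon: str
    alt_codon: str
    ref_aa: str  # single letter, '*' for stop
    alt_aa: str
    prev_aa: Optional[str]  # None at the N terminus
    next_aa: Optional[str]  # None at the C terminus
    codon_genomic_span: tuple = field(default=())  # 3 genomic positions, 5'→3'

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")


def parse_variants(vcf_path) -> list:
    """Parse SNVs from a VCF 4.x file.

    Returns a list of ``(GenomicVariant, info_dict)`` pairs. Multi-allelic
    records are split into one variant per alt allele; non-SNV records and
    records with non-ACGT alleles are skipped with a warning. INFO fields
    are carried verbatim (as strings/parsed values) for downstream curation.
    """
    import pysam

    out = []
    try:
        vcf = pysam.VariantFile(str(vcf_path))
    except Exception as exc:  # pragma: no cover - pysam error text varies
        raise VCFParseError(f"cannot open VCF {vcf_path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            ref = rec.ref
            if ref is None or len(ref) != 1:
                warnings.warn(
                    f"skipping non-SNV record at {rec.chrom}:{rec.pos} "
                    f"(ref={ref!r})"
                )
                continue
            info = dict(rec.info)
            for alt in rec.alts or ():
                if len(alt) != 1:
                    warnings.warn(
                        f"skipping non-SNV alt {alt!r} at {rec.chrom}:{rec.pos}"
                    )
                    continue
                if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
                    warnings.warn(
                        f"skipping non-ACGT allele {ref}>{alt} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                    continue
                out.append(
                    (
                        GenomicVariant(rec.chrom, rec.pos, ref, alt, rec.id),
                        info,
                    )
                )
    return out


def project_to_cds(variant: GenomicVariant, transcript: TranscriptModel):
    """1-based CDS coordinate of the variant, or None if outside all exons.

    On the minus strand the CDS coordinate counts from the 3'-most genomic
    exon (transcript 5' end).
    """
    if variant.chrom != transcript.chrom:
        return None
    offset = 0
    if transcript.strand == "+":
        for start, end in transcript.exons:
            if start <= variant.pos <= end:
                return offset + (variant.pos - start) + 1
            offset += end - start + 1
    else:
        for start, end in reversed(transcript.exons):
            if start <= variant.pos <= end:
                return offset + (end - variant.pos) + 1
            offset += end - start + 1
    return None


def _consequence(ref_aa: str, alt_aa: str, codon_index: int) -> str:
    if codon_index == 1 and alt_aa != "M":
        return "start_lost"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    if ref_aa != alt_aa:
        return "missense"
    return "synonymous"


def call_coding_effect(
    variant: GenomicVariant,
    transcript: TranscriptModel,
    genome,
) -> CodingEffect:
    """Compute the coding consequence of an SNV on a transcript.

    ``genome`` is a mapping-like accessor of chromosome name to sequence
    (e.g. a :class:`pyfaidx.Fasta` or a plain dict of strings). Positions
    outside the CDS yield a ``non_coding`` effect.
    """
    cds_pos = project_to_cds(variant, transcript)
    if cds_pos is None:
        return CodingEffect(
            consequence="non_coding",
            cds_pos=0,
            codon_index=0,
            ref_codon="",
            alt_codon="",
            ref_aa="",
            alt_aa="",
            prev_aa=None,
            next_aa=None,
        )

    positions = transcript.cds_positions()
    chrom_seq = genome[variant.chrom]
    cds = "".join(
        str(chrom_seq[p - 1]).upper() for p in positions
    )
    if transcript.strand == "-":
        cds = "".join(COMPLEMENT[b] for b in cds)

    ref_in_cds = (
        variant.ref
        if transcript.strand == "+"
        else COMPLEMENT[variant.ref]
    )
    alt_in_cds = (
        variant.alt
        if transcript.strand == "+"
        else COMPLEMENT[variant.alt]
    )
    if cds[cds_pos - 1] != ref_in_cds:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} genome base "
            f"{cds[cds_pos - 1]} (CDS strand) != variant ref "
            f"{ref_in_cds}"
        )

    codon_index = (cds_pos - 1) // 3 + 1
    codon_start = (codon_index - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    within = (cds_pos - 1) % 3
    alt_codon = (
        ref_codon[:within] + alt_in_cds + ref_codon[within + 1 :]
    )

    protein = str(Seq(cds).translate())
    ref_aa = protein[codon_index - 1]
    alt_aa = str(Seq(alt_codon).translate())
    prev_aa = protein[codon_index - 2] if codon_index > 1 else None
    next_aa = (
        protein[codon_index] if codon_index < len(protein) else None
    )

    span = tuple(positions[codon_start : codon_start + 3])
    return CodingEffect(
        consequence=_consequence(ref_aa, alt_aa, codon_index),
        cds_pos=cds_pos,
        codon_index=codon_index,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        prev_aa=prev_aa,
        next_aa=next_aa,
        codon_genomic_span=span,
    )


def select_canonical(transcripts: list) -> dict:
    """Pick one canonical transcript per gene.

    ``transcripts`` is a list of (TranscriptModel, is_tagged_canonical)
    pairs. Preference: tagged canonical, else longest CDS, ties broken
    lexicographically by transcript id.
    """
    by_gene: dict = {}
    for tx, tagged in transcripts:
        by_gene.setdefault(tx.gene_id, []).append((tx, tagged))
    chosen = {}
    for gene, group in by_gene.items():
        group.sort(key=lambda t: (-int(t[1]), -t[0].cds_length, t[0].transcript_id))
        chosen[gene] = group[0][0]
    return chosen


def load_transcripts(gff3_path) -> dict:
    """Load canonical transcripts from a GFF3 file.

    Expects gene → mRNA → CDS features with ID/Parent attributes; an mRNA
    with attribute ``tag=canonical`` is preferred. Returns a mapping
    gene id → TranscriptModel.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcripts = []
    for mrna in db.features_of_type("mRNA"):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        cds = sorted(
            db.children(mrna, featuretype="CDS"), key=lambda f: f.start
        )
        if not cds:
            continue
        exons = tuple((c.start, c.end) for c in cds)
        tx = TranscriptModel(
            gene_id=gene_id,
            transcript_id=mrna.id,
            chrom=mrna.seqid,
            strand=mrna.strand,
            exons=exons,
        )
        tagged = "canonical" in mrna.attributes.get("tag", [])
        transcripts.append((tx, tagged))
    return select_canonical(transcripts)
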