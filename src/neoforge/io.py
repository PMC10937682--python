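"""Readers and writers for the standard formats the pipeline touches.

FASTA, GTF (CDS subset), VCF v4.x with per-sample AD, RSEM-style
expression TSV, and the tab-separated neoantigen catalog.  All readers
accept plain or gzip-compressed files.  Coordinates are 1-based
inclusive throughout, matching the VCF and GTF standards.

GTF dialect: attributes are parsed as ``key "value";`` pairs; GFF3 is
not supported.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import pysam
from Bio import SeqIO

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

_NT_ALPHABET = set("ACGTUNRYSWKMBDHV")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

STOP_CODONS = ("TAA", "TAG", "TGA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record; sequence stored uppercase."""

    id: str
    sequence: str


@dataclass(frozen=True)
class TranscriptModel:
    """A coding transcript: spliced CDS plus downstream 3'-UTR sequence.

    ``cds_intervals`` are 1-based inclusive genomic intervals ordered
    5'->3' in transcript orientation (descending genomic start on the
    minus strand).  ``cds_seq`` is the stranded, spliced coding
    sequence excluding the stop codon; ``utr3_seq`` is everything
    downstream of the CDS on the mature transcript (the generator puts
    the stop codon at its start).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple
    cds_seq: str
    utr3_seq: str = ""

    def validate(self) -> None:
        from .peptides import translate  # local import to avoid a cycle

        if self.strand not in "+-":
            raise ValidationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        ivs = self.cds_intervals
        if not ivs:
            raise ValidationError(f"{self.transcript_id}: no CDS intervals")
        for s, e in ivs:
            if s > e:
                raise ValidationError(f"{self.transcript_id}: interval {s}>{e}")
        genomic_sorted = sorted(ivs)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.transcript_id}: overlapping CDS intervals")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if tuple(expected) != tuple(ivs):
            raise ValidationError(
                f"{self.transcript_id}: intervals not ordered 5'->3' for strand {self.strand}"
            )
        span = sum(e - s + 1 for s, e in ivs)
        if span != len(self.cds_seq):
            raise ValidationError(
                f"{self.transcript_id}: interval span {span} != CDS length {len(self.cds_seq)}"
            )
        if len(self.cds_seq) % 3 != 0:
            raise ValidationError(f"{self.transcript_id}: CDS length not a multiple of 3")
        if not self.cds_seq.startswith("ATG"):
            raise ValidationError(f"{self.transcript_id}: CDS does not start with ATG")
        for i in range(0, len(self.cds_seq), 3):
            if self.cds_seq[i : i + 3] in STOP_CODONS:
                raise ValidationError(
                    f"{self.transcript_id}: in-frame stop at CDS nt {i + 1}"
                )

    # -- coordinate mapping -------------------------------------------------

    def cds_position(self, pos: int) -> Optional[int]:
        """Genomic position -> 1-based index into ``cds_seq``; None if outside."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                return offset + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            offset += e - s + 1
        return None

    def genomic_position(self, idx: int) -> int:
        """Inverse of :meth:`cds_position` for 1 <= idx <= len(cds_seq)."""
        offset = 0
        for s, e in self.cds_intervals:
            width = e - s + 1
            if idx <= offset + width:
                k = idx - offset
                return s + k - 1 if self.strand == "+" else e - k + 1
            offset += width
        raise ValueError(f"CDS index {idx} out of range for {self.transcript_id}")


@dataclass(frozen=True)
class SomaticVariant:
    """One called variant with alt-read support in a named sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | insertion | deletion
    alt_reads: int
    sample: str = ""

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def validate(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self}: ref == alt")
        if self.alt_reads < 0:
            raise ValidationError(f"{self}: negative alt_reads")
        expected = classify_alleles(self.ref, self.alt)
        if expected != self.vclass:
            raise ValidationError(f"{self}: vclass {self.vclass} != {expected}")


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        if alt[0] != ref[0]:
            raise ValidationError(f"insertion {ref}>{alt} lacks shared first base")
        return "insertion"
    if len(ref) > len(alt):
        if alt and alt[0] != ref[0]:
            raise ValidationError(f"deletion {ref}>{alt} lacks shared first base")
        return "deletion"
    raise ValidationError(f"unsupported allele pair {ref}>{alt} (MNV?)")


@dataclass
class ExpressionTable:
    """gene_id -> TPM mapping (RSEM-style gene-level quantification)."""

    tpm: dict

    def __post_init__(self):
        for g, v in self.tpm.items():
            if v < 0:
                raise ValidationError(f"negative TPM for {g}")

    def get(self, gene_id: str):
        return self.tpm.get(gene_id)

    def __len__(self):
        return len(self.tpm)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path, kind: str = "nucleotide") -> list:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; ids must be unique and non-empty; the
    alphabet is checked against ``kind`` (``nucleotide``, ``protein``
    or ``None`` to skip the check).
    """
    alphabet = {"nucleotide": _NT_ALPHABET, "protein": _AA_ALPHABET, None: None}[kind]
    records = []
    seen = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not rec.id:
                raise FormatError(f"{path}: record with empty id")
            if rec.id in seen:
                raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
            if not seq:
                raise FormatError(f"{path}: empty sequence for {rec.id!r}")
            if alphabet is not None:
                for i, ch in enumerate(seq, start=1):
                    if ch not in alphabet:
                        raise FormatError(
                            f"{path}: non-IUPAC character {ch!r} in {rec.id!r} at position {i}"
                        )
            seen.add(rec.id)
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def fasta_mapping(fasta) -> Mapping[str, str]:
    """Accept a path, a mapping, or a list of SequenceRecord."""
    if isinstance(fasta, (str, Path)):
        fasta = read_fasta(fasta)
    if isinstance(fasta, Mapping):
        return fasta
    return {r.id: r.sequence for r in fasta}


# ---------------------------------------------------------------------------
# GTF (CDS subset)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_cds(path, fasta, strict: bool = False) -> list:
    """Assemble :class:`TranscriptModel` objects from GTF ``CDS`` (and
    optional ``three_prime_utr``) features plus genome sequences.

    Transcripts violating the CDS invariants are skipped with a logged
    warning; ``strict=True`` upgrades this to an error.
    """
    seqs = fasta_mapping(fasta)
    cds_by_tx: dict = {}
    utr_by_tx: dict = {}
    meta: dict = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = cols[:9]
            if feature not in ("CDS", "three_prime_utr"):
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            if "transcript_id" not in attr:
                raise FormatError(f"{path}:{lineno}: missing transcript_id attribute")
            if "gene_id" not in attr:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            tid = attr["transcript_id"]
            s, e = int(start), int(end)
            if chrom not in seqs:
                raise FormatError(f"{path}:{lineno}: unknown sequence {chrom!r}")
            if not (1 <= s <= e <= len(seqs[chrom])):
                raise FormatError(
                    f"{path}:{lineno}: interval [{s},{e}] outside {chrom} bounds"
                )
            meta.setdefault(tid, (attr["gene_id"], chrom, strand))
            if meta[tid] != (attr["gene_id"], chrom, strand):
                raise FormatError(f"{path}:{lineno}: inconsistent attributes for {tid}")
            target = cds_by_tx if feature == "CDS" else utr_by_tx
            target.setdefault(tid, []).append((s, e))

    out = []
    for tid in sorted(cds_by_tx):
        gene_id, chrom, strand = meta[tid]
        ivs = sorted(cds_by_tx[tid])
        if strand == "-":
            ivs = ivs[::-1]
        seq = seqs[chrom]
        chunks = [seq[s - 1 : e] for s, e in ivs]
        if strand == "-":
            chunks = [reverse_complement(c) for c in chunks]
        cds_seq = "".join(chunks)
        utr_ivs = sorted(utr_by_tx.get(tid, []))
        if strand == "-":
            utr_ivs = utr_ivs[::-1]
        utr_chunks = [seq[s - 1 : e] for s, e in utr_ivs]
        if strand == "-":
            utr_chunks = [reverse_complement(c) for c in utr_chunks]
        tx = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            cds_intervals=tuple(ivs),
            cds_seq=cds_seq,
            utr3_seq="".join(utr_chunks),
        )
        try:
            tx.validate()
        except ValidationError as exc:
            if strict:
                raise
            logger.warning("skipping transcript %s: %s", tid, exc)
            continue
        out.append(tx)
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path, sample: str) -> list:
    """Read a VCF into :class:`SomaticVariant` objects for one sample.

    ``alt_reads`` is taken from the sample's AD field (alt depth).
    Multi-allelic records are rejected; decompose them upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"{path}: cannot parse VCF: {exc}") from exc
    if sample not in list(vf.header.samples):
        raise FormatError(
            f"{path}: sample {sample!r} not in VCF (has: {list(vf.header.samples)})"
        )
    variants = []
    for rec in vf:
        where = f"{path}: record {rec.chrom}:{rec.pos}"
        if not rec.alts:
            raise FormatError(f"{where}: missing ALT allele")
        if len(rec.alts) > 1:
            raise FormatError(
                f"{where}: multi-allelic ALT {','.join(rec.alts)}; "
                "decompose the record into bi-allelic form first"
            )
        fmt = rec.samples[sample]
        ad = fmt.get("AD")
        if ad is None or len(ad) < 2 or ad[1] is None:
            raise FormatError(f"{where}: missing AD for sample {sample!r}")
        ref, alt = rec.ref.upper(), rec.alts[0].upper()
        try:
            vclass = classify_alleles(ref, alt)
        except ValidationError as exc:
            raise FormatError(f"{where}: {exc}") from exc
        variants.append(
            SomaticVariant(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=ref,
                alt=alt,
                vclass=vclass,
                alt_reads=int(ad[1]),
                sample=sample,
            )
        )
    return variants


VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]


def write_vcf(variants: Iterable[SomaticVariant], path, sample: str,
              contigs: Optional[Mapping[str, int]] = None,
              depths: Optional[Mapping[tuple, int]] = None) -> None:
    """Write a minimal, deterministic single-sample VCF (plain text).

    ``depths`` optionally maps variant keys to total depth; ref depth is
    derived as depth - alt_reads (floored at 0).
    """
    lines = list(VCF_HEADER_LINES)
    for name in sorted(contigs or {}):
        lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample)
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        total = (depths or {}).get(v.key, v.alt_reads * 2)
        ref_reads = max(total - v.alt_reads, 0)
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT:AD\t"
            f"0/1:{ref_reads},{v.alt_reads}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path) -> ExpressionTable:
    """RSEM-style TSV with columns ``gene_id`` and ``TPM`` (extras ignored)."""
    import pandas as pd

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene_id" not in cols or "tpm" not in cols:
        raise FormatError(
            f"{path}: need columns gene_id and TPM, found {list(df.columns)}"
        )
    genes = df[cols["gene_id"]].astype(str)
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    values = df[cols["tpm"]].astype(float)
    if (values < 0).any():
        raise FormatError(f"{path}: negative TPM values")
    return ExpressionTable(dict(zip(genes, values)))


def write_expression_tsv(table: ExpressionTable, path) -> None:
    lines = ["gene_id\tTPM"]
    for g in sorted(table.tpm):
        lines.append(f"{g}\t{table.tpm[g]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Catalog TSV
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = [
    "peptide", "length", "allele", "percent_rank", "ic50_nm", "gene_id",
    "transcript_id", "variant", "vclass", "tpm", "wes_alt_reads",
    "rna_alt_reads", "class",
]


@dataclass(frozen=True)
class CatalogRow:
    """One row of the final catalog TSV (flat, serializable form)."""

    peptide: str
    length: int
    allele: str
    percent_rank: float
    ic50_nm: float
    gene_id: str
    transcript_id: str
    variant: str  # chrom:pos:ref>alt
    vclass: str
    tpm: float
    wes_alt_reads: int
    rna_alt_reads: int
    klass: str  # shared | unique_A | unique_B | unassigned


def write_catalog(rows: Iterable[CatalogRow], path) -> None:
    """Write catalog rows as a deterministic TSV sorted by
    (gene_id, variant, peptide, allele)."""
    rows = sorted(rows, key=lambda r: (r.gene_id, r.variant, r.peptide, r.allele))
    lines = ["\t".join(CATALOG_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join([
                r.peptide, str(r.length), r.allele,
                f"{r.percent_rank:.10g}", f"{r.ic50_nm:.10g}",
                r.gene_id, r.transcript_id, r.variant, r.vclass,
                f"{r.tpm:.10g}", str(r.wes_alt_reads), str(r.rna_alt_reads),
                r.klass,
            ])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog(path) -> list:
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CATALOG_COLUMNS:
            raise FormatError(f"{path}: unexpected catalog header {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(CATALOG_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            rows.append(
                CatalogRow(
                    peptide=parts[0], length=int(parts[1]), allele=parts[2],
                    percent_rank=float(parts[3]), ic50_nm=float(parts[4]),
                    gene_id=parts[5], transcript_id=parts[6], variant=parts[7],
                    vclass=parts[8], tpm=float(parts[9]),
                    wes_alt_reads=int(parts[10]), rna_alt_reads=int(parts[11]),
                    klass=parts[12],
                )
            )
    return rows
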