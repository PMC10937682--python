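"""Synthetic-data generators with recorded ground truth.

Everything the pipeline consumes can be generated here: a toy
transcriptome (FASTA + GTF), planted somatic/germline variants with
read support (tumor A, tumor B = superset of A, matched normal), RNA
validation calls and expression tables, and a survival cohort with a
latent factor coupling the cDC1 and CD8-effector signature scores.

All generators are pure functions of their seed and parameters, and
the expected peptide sets are computed by the independent naive oracle
(:mod:`neoforge.oracle`), never by the pipeline under test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import oracle
from .binding import DEFAULT_RANK_MAX, predict_toy
from .errors import NeoforgeError
from .io import (
    ExpressionTable,
    SequenceRecord,
    SomaticVariant,
    TranscriptModel,
    classify_alleles,
    reverse_complement,
    write_expression_tsv,
    write_vcf,
)
from .stats import CD8_EFFECTOR_SIGNATURE_GENES, CDC1_SIGNATURE_GENES

logger = logging.getLogger(__name__)

_SENSE_CODONS = sorted(
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
    if c not in ("TAA", "TAG", "TGA")
)
_STOPS = ("TAA", "TAG", "TGA")
# suffix containing a stop codon in all three reading frames
_TRIFRAME_STOP = "TAACTAACTAAC"

SAMPLE_A = "TUMOR_A"
SAMPLE_B = "TUMOR_B"
SAMPLE_NORMAL = "NORMAL"


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTranscriptome:
    records: List[SequenceRecord]
    gtf_text: str
    transcripts: List[TranscriptModel]

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {r.id: len(r.sequence) for r in self.records}

    def write(self, out_dir) -> Tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
        gtf = out_dir / "annotation.gtf"
        with open(fasta, "w") as fh:
            for r in self.records:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.sequence), 60):
                    fh.write(r.sequence[i : i + 60] + "\n")
        gtf.write_text(self.gtf_text)
        return fasta, gtf


def generate_transcriptome(seed: int, n_genes: int = 10,
                           cds_len_range: Tuple[int, int] = (60, 240),
                           utr3_len: int = 60) -> SyntheticTranscriptome:
    """One single-transcript gene per contig; both strands represented;
    longer CDSs get a short intron to exercise spliced assembly.

    Each CDS starts with ATG, contains no in-frame stop, and is followed
    by a stop codon plus a 3'-UTR ending in a stop-in-every-frame
    cassette (so frameshift read-through terminates)."""
    lo, hi = cds_len_range
    if lo < 60 or lo % 3 or hi % 3 or hi < lo:
        raise ValueError("cds_len_range must be multiples of 3, >= 60")
    if utr3_len < len(_TRIFRAME_STOP):
        raise ValueError(f"utr3_len must be >= {len(_TRIFRAME_STOP)}")
    rng = np.random.default_rng(seed)
    records, gtf_lines, transcripts = [], [], []
    pad = 10
    for i in range(1, n_genes + 1):
        chrom = f"chr{i:03d}"
        gene_id, tx_id = f"gene{i:03d}", f"tx{i:03d}"
        strand = "+" if i % 2 == 1 else "-"
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        cds = "ATG" + "".join(rng.choice(_SENSE_CODONS, size=n_codons - 1))
        stop = str(rng.choice(_STOPS))
        utr_core = "".join(rng.choice(list("ACGT"), size=utr3_len - 3 - len(_TRIFRAME_STOP)))
        utr3 = stop + utr_core + _TRIFRAME_STOP  # stop codon leads the 3' region
        # optionally split the CDS with a small intron
        if n_codons >= 30:
            cut = int(rng.integers(9, len(cds) - 9))
            intron = "GT" + "".join(rng.choice(list("ACGT"), size=6)) + "AG"
            region = cds[:cut] + intron + cds[cut:] + utr3
            cds_blocks = [(1, cut), (cut + len(intron) + 1, len(cds) + len(intron))]
        else:
            region = cds + utr3
            cds_blocks = [(1, len(cds))]
        utr_block = (len(region) - len(utr3) + 1, len(region))
        m = len(region)
        contig_len = pad + m + pad

        def to_genomic(s, e):
            if strand == "+":
                return (pad + s, pad + e)
            return (m + pad + 1 - e, m + pad + 1 - s)

        contig_fwd = (
            "".join(rng.choice(list("ACGT"), size=pad))
            + region
            + "".join(rng.choice(list("ACGT"), size=pad))
        )
        contig = contig_fwd if strand == "+" else reverse_complement(contig_fwd)
        records.append(SequenceRecord(chrom, contig))

        attrs = f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
        g_cds = [to_genomic(s, e) for s, e in cds_blocks]
        for s, e in sorted(g_cds):
            gtf_lines.append(
                f"{chrom}\tneoforge\tCDS\t{s}\t{e}\t.\t{strand}\t0\t{attrs}"
            )
        us, ue = to_genomic(*utr_block)
        gtf_lines.append(
            f"{chrom}\tneoforge\tthree_prime_utr\t{us}\t{ue}\t.\t{strand}\t0\t{attrs}"
        )
        ordered = sorted(g_cds) if strand == "+" else sorted(g_cds, reverse=True)
        tx = TranscriptModel(
            transcript_id=tx_id, gene_id=gene_id, chrom=chrom, strand=strand,
            cds_intervals=tuple(ordered), cds_seq=cds, utr3_seq=utr3,
        )
        tx.validate()
        transcripts.append(tx)
    return SyntheticTranscriptome(records, "\n".join(gtf_lines) + "\n", transcripts)


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------


@dataclass
class PlantedVariant:
    """One planted variant: genomic VCF form + the stranded CDS edit it
    came from, per-sample read support, and oracle-expected peptides."""

    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    transcript_id: str
    gene_id: str
    consequence: str  # missense | synonymous | frameshift | inframe_indel | germline
    cds_start: int
    cds_ref: str
    cds_alt: str
    lines: Tuple[str, ...]  # subset of ("A", "B"); empty for germline-only
    wes_alt: Dict[str, int] = field(default_factory=dict)  # sample -> alt reads
    rna_alt: Dict[str, int] = field(default_factory=dict)
    expressed: bool = True
    oracle_peptides: frozenset = frozenset()
    tpm: float = 0.0

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)

    def as_somatic(self, sample: str, alt_reads: int) -> SomaticVariant:
        return SomaticVariant(self.chrom, self.pos, self.ref, self.alt,
                              self.vclass, alt_reads, sample)


@dataclass
class GroundTruth:
    """Recorded design of a planted dataset."""

    transcriptome: SyntheticTranscriptome
    planted: List[PlantedVariant]
    shared_design: int
    uniqueB_design: int
    cohort_params: Optional[dict] = None

    @property
    def somatic(self) -> List[PlantedVariant]:
        return [p for p in self.planted if p.consequence != "germline"]

    @property
    def germline(self) -> List[PlantedVariant]:
        return [p for p in self.planted if p.consequence == "germline"]

    def expected_catalog_sequences(self, line: str,
                                   rank_max: float = DEFAULT_RANK_MAX,
                                   min_wes: int = 5, min_rna: int = 3) -> set:
        """Peptide sequences the full pipeline should report for a line,
        derived purely from the planted design and the oracle."""
        sample = SAMPLE_A if line == "A" else SAMPLE_B
        seqs = set()
        for p in self.somatic:
            if line not in p.lines or not p.expressed:
                continue
            if p.wes_alt.get(sample, 0) < min_wes:
                continue
            if p.rna_alt.get(sample, 0) < min_rna:
                continue
            for pep in p.oracle_peptides:
                if any(predict_toy(pep, a).percent_rank <= rank_max
                       for a in ("H2-Kb", "H2-Db")):
                    seqs.add(pep)
        return seqs


def _stranded_blocks(tx: TranscriptModel) -> List[Tuple[int, int]]:
    blocks, offset = [], 0
    for s, e in tx.cds_intervals:
        w = e - s + 1
        blocks.append((offset + 1, offset + w))
        offset += w
    return blocks


def _block_of(blocks, start, length):
    for lo, hi in blocks:
        if lo <= start and start + length - 1 <= hi:
            return True
    return False


def _edit_to_vcf(tx: TranscriptModel, start: int, s_ref: str, s_alt: str):
    """Stranded CDS edit -> genomic (pos, ref, alt) in VCF orientation."""
    if tx.strand == "+":
        pos = tx.genomic_position(start)
        return pos, s_ref, s_alt
    pos = tx.genomic_position(start + len(s_ref) - 1)
    return pos, reverse_complement(s_ref), reverse_complement(s_alt)


_MAX_TRIES = 200


def _craft_edit(rng, tx: TranscriptModel, consequence: str):
    """Draw a stranded CDS edit of the requested consequence that sits
    inside a single CDS interval and is VCF-anchorable on either strand."""
    cds = tx.cds_seq
    blocks = _stranded_blocks(tx)
    n_codons = len(cds) // 3
    from .oracle import naive_translate, _CODONS

    for _ in range(_MAX_TRIES):
        if consequence in ("missense", "synonymous", "germline"):
            c = int(rng.integers(2, n_codons))  # codons 2..n-1
            p = int(rng.integers(0, 3))
            i = (c - 1) * 3 + p + 1
            if not _block_of(blocks, i, 1):
                continue
            old_codon = cds[(c - 1) * 3 : c * 3]
            b = str(rng.choice([x for x in "ACGT" if x != cds[i - 1]]))
            new_codon = old_codon[:p] + b + old_codon[p + 1 :]
            if new_codon in _STOPS:
                continue
            same_aa = _CODONS[new_codon] == _CODONS[old_codon]
            if consequence == "synonymous" and not same_aa:
                continue
            if consequence != "synonymous" and same_aa:
                continue
            return i, cds[i - 1], b
        j = int(rng.integers(6, len(cds) - 5))  # edit site, clear of termini
        ins_len = 3 if consequence == "inframe_indel" else int(rng.integers(1, 3))
        if consequence == "frameshift" and bool(rng.integers(0, 2)):
            # deletion of ins_len bases
            if tx.strand == "+":
                start, ref, alt = j - 1, cds[j - 2 : j - 1 + ins_len], cds[j - 2]
            else:
                start, ref, alt = j, cds[j - 1 : j + ins_len], cds[j + ins_len - 1]
        else:
            ins = ("".join(rng.choice(list("ACGT"), size=ins_len))
                   if consequence == "frameshift"
                   else str(rng.choice(_SENSE_CODONS)))
            if tx.strand == "+":
                start, ref, alt = j, cds[j - 1], cds[j - 1] + ins
            else:
                start, ref, alt = j + 1, cds[j], ins + cds[j]
        if not _block_of(blocks, start, len(ref)):
            continue
        return start, ref, alt
    raise NeoforgeError(
        f"could not craft a {consequence} edit on {tx.transcript_id} "
        f"after {_MAX_TRIES} tries"
    )


def _draw_support(rng, mean: float, minimum: int) -> int:
    for _ in range(_MAX_TRIES):
        n = int(rng.poisson(mean))
        if n >= minimum:
            return n
    return minimum


def plant_variants(seed: int, transcriptome: SyntheticTranscriptome,
                   n_missense: int = 6, n_synonymous: int = 0,
                   n_frameshift: int = 0, n_inframe: int = 0,
                   n_germline: int = 0, shared_fraction: float = 0.5,
                   frac_low_support: float = 0.0,
                   ensure_strong_binder: bool = False,
                   mean_depth: float = 20.0) -> GroundTruth:
    """Plant variants (one per transcript) across two tumor lines.

    Line B carries all of line A's somatic variants plus extras
    (B-only), mirroring a hypermutated derivative of the parental line.
    Germline variants appear in both tumors AND the normal.  WES alt
    reads are Poisson(mean_depth) redrawn to >= 5 except for a
    ``frac_low_support`` fraction forced to 1-4 reads.  With
    ``ensure_strong_binder`` each coding variant is redrawn until the
    oracle finds at least one toy strong-binder peptide."""
    rng = np.random.default_rng(seed)
    txs = list(transcriptome.transcripts)
    plan = (["missense"] * n_missense + ["synonymous"] * n_synonymous
            + ["frameshift"] * n_frameshift + ["inframe_indel"] * n_inframe
            + ["germline"] * n_germline)
    if len(plan) > len(txs):
        raise NeoforgeError(
            f"{len(plan)} variants requested but only {len(txs)} transcripts"
        )
    order = rng.permutation(len(txs))[: len(plan)]

    planted: List[PlantedVariant] = []
    for consequence, ti in zip(plan, order):
        tx = txs[ti]
        for attempt in range(_MAX_TRIES):
            start, s_ref, s_alt = _craft_edit(rng, tx, consequence)
            peps = frozenset(
                oracle.expected_peptides(tx.cds_seq, tx.utr3_seq, start, s_ref, s_alt)
            )
            if consequence in ("synonymous", "germline"):
                break
            if not ensure_strong_binder:
                break
            if any(predict_toy(p, a).percent_rank <= DEFAULT_RANK_MAX
                   for p in peps for a in ("H2-Kb", "H2-Db")):
                break
        else:
            raise NeoforgeError(
                f"no strong-binder-producing {consequence} edit found on "
                f"{tx.transcript_id} after {_MAX_TRIES} attempts"
            )
        pos, ref, alt = _edit_to_vcf(tx, start, s_ref, s_alt)
        planted.append(PlantedVariant(
            chrom=tx.chrom, pos=pos, ref=ref, alt=alt,
            vclass=classify_alleles(ref, alt),
            transcript_id=tx.transcript_id, gene_id=tx.gene_id,
            consequence=consequence, cds_start=start, cds_ref=s_ref,
            cds_alt=s_alt, lines=(), oracle_peptides=peps,
        ))

    somatic = [p for p in planted if p.consequence != "germline"]
    n_shared = int(round(shared_fraction * len(somatic)))
    shared_idx = set(rng.permutation(len(somatic))[:n_shared].tolist())
    n_low = int(round(frac_low_support * len(somatic)))
    low_idx = set(rng.permutation(len(somatic))[:n_low].tolist())
    for i, p in enumerate(somatic):
        p.lines = ("A", "B") if i in shared_idx else ("B",)
        for line in p.lines:
            sample = SAMPLE_A if line == "A" else SAMPLE_B
            if i in low_idx:
                p.wes_alt[sample] = int(rng.integers(1, 5))
            else:
                p.wes_alt[sample] = _draw_support(rng, mean_depth, 5)
    for p in planted:
        if p.consequence == "germline":
            p.lines = ()
            for sample in (SAMPLE_A, SAMPLE_B, SAMPLE_NORMAL):
                p.wes_alt[sample] = _draw_support(rng, mean_depth, 1)

    return GroundTruth(
        transcriptome=transcriptome,
        planted=planted,
        shared_design=n_shared,
        uniqueB_design=len(somatic) - n_shared,
    )


def write_variant_files(truth: GroundTruth, out_dir) -> Dict[str, Path]:
    """Write tumor_A.vcf, tumor_B.vcf and normal.vcf for a planted design."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = truth.transcriptome.contig_lengths
    paths = {}
    for name, sample, selector in (
        ("tumor_A", SAMPLE_A, lambda p: "A" in p.lines or p.consequence == "germline"),
        ("tumor_B", SAMPLE_B, lambda p: "B" in p.lines or p.consequence == "germline"),
        ("normal", SAMPLE_NORMAL, lambda p: p.consequence == "germline"),
    ):
        variants = [p.as_somatic(sample, p.wes_alt[sample])
                    for p in truth.planted if selector(p)]
        path = out_dir / f"{name}.vcf"
        write_vcf(variants, path, sample, contigs=contigs)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# RNA support and expression
# ---------------------------------------------------------------------------


def simulate_rna_support(seed: int, truth: GroundTruth,
                         expressed_fraction: float = 1.0, depth: int = 100,
                         frac_low_rna: float = 0.0,
                         ) -> Dict[str, Tuple[List[SomaticVariant], ExpressionTable]]:
    """RNA-level evidence per line: variant calls with alt-read support
    (Binomial(depth, 0.5), redrawn to >= 3 unless forced to 1-2 reads)
    and a gene-level TPM table (LogNormal for expressed genes, 0
    otherwise).  Mutates ``truth`` in place to record expression flags,
    RNA read counts and TPM."""
    rng = np.random.default_rng(seed)
    somatic = truth.somatic
    for p in somatic:
        p.expressed = bool(rng.random() < expressed_fraction)
    n_low = int(round(frac_low_rna * len(somatic)))
    low_idx = set(rng.permutation(len(somatic))[:n_low].tolist())

    gene_tpm: Dict[str, float] = {}
    for tx in truth.transcriptome.transcripts:
        gene_tpm[tx.gene_id] = float(rng.lognormal(2.0, 1.0))
    for p in somatic:
        if not p.expressed:
            gene_tpm[p.gene_id] = 0.0
        p.tpm = gene_tpm[p.gene_id]

    out = {}
    for line, sample in (("A", SAMPLE_A), ("B", SAMPLE_B)):
        calls = []
        for i, p in enumerate(somatic):
            if line not in p.lines or not p.expressed:
                continue
            if i in low_idx:
                reads = int(rng.integers(1, 3))
            else:
                reads = 0
                for _ in range(_MAX_TRIES):
                    reads = int(rng.binomial(depth, 0.5))
                    if reads >= 3:
                        break
            p.rna_alt[sample] = reads
            calls.append(p.as_somatic(sample, reads))
        out[line] = (calls, ExpressionTable(dict(gene_tpm)))
    return out


def write_rna_files(truth: GroundTruth, rna, out_dir) -> Dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = truth.transcriptome.contig_lengths
    paths = {}
    for line, sample in (("A", SAMPLE_A), ("B", SAMPLE_B)):
        calls, expr = rna[line]
        vcf_path = out_dir / f"rna_{line}.vcf"
        tsv_path = out_dir / f"expression_{line}.tsv"
        write_vcf(calls, vcf_path, sample, contigs=contigs,
                  depths={v.key: 100 for v in calls})
        write_expression_tsv(expr, tsv_path)
        paths[f"rna_{line}"] = vcf_path
        paths[f"expression_{line}"] = tsv_path
    return paths


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def simulate_cohort(seed: int, n: int = 500, beta: float = 1.0,
                    hr: float = 2.0, baseline_hazard: float = 0.02,
                    censor_hazard_frac: float = 0.25,
                    ) -> Tuple[pd.DataFrame, dict]:
    """Cohort with a latent factor coupling the two signature scores.

    Per sample: latent f ~ N(0,1); every signature gene z = beta*f + eps
    with eps ~ N(0,1), then re-standardized to cohort z-scores.  TMB is
    LogNormal, independent of f.  Survival is exponential with the
    hazard multiplied by ``hr`` for the planted low-f half (low latent
    cDC1 -> worse outcome); censoring is an independent exponential."""
    if n < 4:
        raise ValueError("cohort needs n >= 4")
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    genes = list(CDC1_SIGNATURE_GENES) + list(CD8_EFFECTOR_SIGNATURE_GENES)
    data = {}
    for g in genes:
        z = beta * f + rng.standard_normal(n)
        data[g] = (z - z.mean()) / z.std()
    tmb = rng.lognormal(1.0, 0.5, n)
    low = f <= np.median(f)
    hazard = baseline_hazard * np.where(low, hr, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.exponential(1.0 / (baseline_hazard * censor_hazard_frac), n)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    df = pd.DataFrame({
        "sample_id": [f"S{i:04d}" for i in range(n)],
        "tmb": tmb,
        "time_months": time,
        "event": event,
        **data,
    })
    params = {"n": n, "beta": beta, "hr": hr, "latent": f, "low_group": low}
    return df, params


def write_cohort_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
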