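"""Variant-evidence filter cascade: germline subtraction, WES altered-read
threshold, RNA-seq altered-allele validation, and TPM attachment.

Both read-support thresholds are inclusive (>=): 5 altered WES reads,
3 altered RNA reads.  Germline matching is allele-exact — matching on
position alone would delete genuine somatic alleles at polymorphic
sites."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

from .errors import NeoforgeError
from .io import ExpressionTable, SomaticVariant

logger = logging.getLogger(__name__)

DEFAULT_MIN_WES_ALT = 5
DEFAULT_MIN_RNA_ALT = 3


@dataclass
class VariantEvidence:
    """A somatic variant together with WES/RNA read support and TPM."""

    variant: SomaticVariant
    wes_alt_reads: int
    rna_alt_reads: int = 0
    germline: bool = False
    tpm: Optional[float] = None
    transcript_id: Optional[str] = None
    gene_id: Optional[str] = None


def subtract_germline(tumor: Iterable[SomaticVariant],
                      normal: Iterable[SomaticVariant]) -> list:
    """Remove tumor variants with an exact (chrom,pos,ref,alt) match in
    the matched normal; order preserved."""
    normal_keys = {v.key for v in normal}
    out = []
    for v in tumor:
        if v.key in normal_keys:
            logger.debug("germline subtraction drops %s", v)
            continue
        out.append(v)
    return out


def filter_wes_support(variants: Iterable[SomaticVariant],
                       min_alt: int = DEFAULT_MIN_WES_ALT) -> list:
    """Keep variants with alt_reads >= min_alt (inclusive)."""
    out = []
    for v in variants:
        if v.alt_reads >= min_alt:
            out.append(v)
        else:
            logger.debug("WES support filter drops %s (%d < %d)",
                         v, v.alt_reads, min_alt)
    return out


def validate_rna(wes_passed: Iterable[SomaticVariant],
                 rna: Iterable[SomaticVariant],
                 min_alt: int = DEFAULT_MIN_RNA_ALT) -> list:
    """WES-anchored join against RNA-seq variant calls.

    Keeps WES-passed variants that have an exact allele match in the RNA
    calls with alt_reads >= min_alt; the returned evidence carries both
    read counts.  RNA-only variants are never emitted."""
    rna_by_key = {v.key: v for v in rna}
    out = []
    for v in wes_passed:
        match = rna_by_key.get(v.key)
        if match is None:
            logger.debug("RNA validation drops %s (absent from RNA calls)", v)
            continue
        if match.alt_reads < min_alt:
            logger.debug("RNA validation drops %s (%d < %d altered reads)",
                         v, match.alt_reads, min_alt)
            continue
        out.append(VariantEvidence(variant=v, wes_alt_reads=v.alt_reads,
                                   rna_alt_reads=match.alt_reads))
    return out


def attach_tpm(evidence: Iterable[VariantEvidence], expr: ExpressionTable,
               tx_index: Mapping[str, str]) -> list:
    """Attach gene-level TPM to each evidence via its transcript.

    ``tx_index`` maps transcript_id -> gene_id.  A gene absent from the
    expression table gets TPM 0 with a warning; an evidence whose
    transcript is unmapped is an error."""
    out = []
    missing_genes = set()
    for ev in evidence:
        if ev.transcript_id is None or ev.transcript_id not in tx_index:
            raise NeoforgeError(
                f"evidence for {ev.variant} has unmapped transcript "
                f"{ev.transcript_id!r}"
            )
        gene_id = tx_index[ev.transcript_id]
        tpm = expr.get(gene_id)
        if tpm is None:
            missing_genes.add(gene_id)
            tpm = 0.0
        out.append(replace(ev, gene_id=gene_id, tpm=float(tpm)))
    if missing_genes:
        logger.warning("genes absent from expression table (TPM set to 0): %s",
                       ", ".join(sorted(missing_genes)))
    return out
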