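"""Join peptides, binding predictions and expression evidence into the
final neoantigen catalog and classify entries as shared/unique between
two cell lines.

Shared/unique membership is keyed on peptide sequence: identical
peptides arising from different genomic events are immunologically one
entity."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .binding import DEFAULT_RANK_MAX, BindingPrediction
from .errors import NeoforgeError
from .filters import VariantEvidence
from .io import CatalogRow
from .peptides import NeoPeptide

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NeoantigenRecord:
    """One catalog entry: peptide + best-allele binding + expression."""

    peptide: NeoPeptide
    binding: BindingPrediction
    tpm: float
    wes_alt_reads: int
    rna_alt_reads: int
    line: str
    klass: str = "unassigned"  # shared | unique_A | unique_B | unassigned

    def to_row(self) -> CatalogRow:
        v = self.peptide.variant
        return CatalogRow(
            peptide=self.peptide.sequence,
            length=len(self.peptide.sequence),
            allele=self.binding.allele,
            percent_rank=self.binding.percent_rank,
            ic50_nm=self.binding.ic50_nm,
            gene_id=self.peptide.gene_id,
            transcript_id=self.peptide.transcript_id,
            variant=f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}",
            vclass=v.vclass,
            tpm=self.tpm,
            wes_alt_reads=self.wes_alt_reads,
            rna_alt_reads=self.rna_alt_reads,
            klass=self.klass,
        )


def build_catalog(evidence: Iterable[VariantEvidence],
                  peptides: Iterable[NeoPeptide],
                  bindings: Iterable[BindingPrediction],
                  line: str,
                  rank_max: float = DEFAULT_RANK_MAX) -> List[NeoantigenRecord]:
    """Inner-join evidence -> peptides -> bindings; keep strong binders
    (any-allele %rank <= rank_max, best allele reported); one record per
    peptide sequence per line (duplicate provenances logged)."""
    ev_by_variant: Dict[tuple, VariantEvidence] = {}
    for ev in evidence:
        ev_by_variant[ev.variant.key] = ev
    binds_by_pep: Dict[str, List[BindingPrediction]] = {}
    for b in bindings:
        binds_by_pep.setdefault(b.peptide, []).append(b)

    ordered = sorted(peptides,
                     key=lambda p: (p.gene_id, p.variant.key, p.sequence))
    records: Dict[str, NeoantigenRecord] = {}
    for pep in ordered:
        ev = ev_by_variant.get(pep.variant.key)
        if ev is None:
            continue  # variant removed by an upstream filter
        preds = binds_by_pep.get(pep.sequence)
        if not preds:
            raise NeoforgeError(
                f"no binding prediction for peptide {pep.sequence!r}; "
                "the predictor must cover every enumerated peptide"
            )
        best = min(preds, key=lambda p: (p.percent_rank, p.allele))
        if best.percent_rank > rank_max:
            continue
        if pep.sequence in records:
            logger.debug("peptide %s in line %s also produced by %s",
                         pep.sequence, line, pep.variant)
            continue
        records[pep.sequence] = NeoantigenRecord(
            peptide=pep,
            binding=best,
            tpm=ev.tpm if ev.tpm is not None else 0.0,
            wes_alt_reads=ev.wes_alt_reads,
            rna_alt_reads=ev.rna_alt_reads,
            line=line,
        )
    return [records[s] for s in sorted(records)]


def classify_shared_unique(cat_a: Iterable[NeoantigenRecord],
                           cat_b: Iterable[NeoantigenRecord]
                           ) -> Tuple[list, list, list]:
    """Partition two catalogs by peptide sequence.

    Returns (shared, unique_A, unique_B); ``shared`` holds the records
    from both lines (klass='shared'), the unique lists hold one line's
    records each."""
    cat_a, cat_b = list(cat_a), list(cat_b)
    seqs_a = {r.peptide.sequence for r in cat_a}
    seqs_b = {r.peptide.sequence for r in cat_b}
    shared_seqs = seqs_a & seqs_b
    shared = [replace(r, klass="shared") for r in cat_a + cat_b
              if r.peptide.sequence in shared_seqs]
    unique_a = [replace(r, klass="unique_A") for r in cat_a
                if r.peptide.sequence not in shared_seqs]
    unique_b = [replace(r, klass="unique_B") for r in cat_b
                if r.peptide.sequence not in shared_seqs]
    return shared, unique_a, unique_b


def venn_counts(shared, unique_a, unique_b) -> Tuple[int, int, int]:
    """Distinct-peptide counts for the shared/unique Venn diagram."""
    return (
        len({r.peptide.sequence for r in shared}),
        len({r.peptide.sequence for r in unique_a}),
        len({r.peptide.sequence for r in unique_b}),
    )


def scatter_table(records: Iterable[NeoantigenRecord]) -> pd.DataFrame:
    """TPM-vs-IC50 table, one row per record (log transforms are left to
    plotting)."""
    rows = [(r.peptide.sequence, r.klass, r.tpm, r.binding.ic50_nm)
            for r in records]
    return pd.DataFrame(rows, columns=["peptide", "class", "tpm", "ic50_nm"])
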