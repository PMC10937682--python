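"""Apply somatic variants to coding sequences and enumerate mutant
8-11-mer peptide windows overlapping the mutated residues.

Frameshift indels are translated through the original stop into the
3'-UTR sequence until the first downstream stop codon (or sequence
end, with a warning).  Stop-gain variants produce no novel residues
and therefore no peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Tuple

from Bio.Data import CodonTable

from .errors import VariantApplicationError
from .io import SomaticVariant, TranscriptModel, reverse_complement

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
STOP_CODONS = set(_TABLE.stop_codons)

DEFAULT_LENGTHS = (8, 9, 10, 11)


def translate(nt: str, stop_policy: str = "truncate_at_stop") -> str:
    """Translate ``nt`` with the standard genetic code, reading codons
    from position 1 and stopping before the first stop codon.  A
    trailing partial codon is ignored; an ambiguity code inside a
    consumed codon is an error."""
    if stop_policy != "truncate_at_stop":
        raise ValueError(f"unknown stop policy {stop_policy!r}")
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            break
        try:
            aa.append(CODON_TO_AA[codon])
        except KeyError:
            raise VariantApplicationError(
                f"untranslatable codon {codon!r} at nt {i + 1}"
            ) from None
    return "".join(aa)


@dataclass(frozen=True)
class MutantProtein:
    """Mutated protein plus the residue span that differs from wild type.

    ``mut_span`` is a 1-based inclusive (first, last) pair in ``mut_aa``
    or ``None`` when no residue differs (synonymous / stop-gain / clean
    in-frame deletion)."""

    transcript_id: str
    gene_id: str
    wt_aa: str
    mut_aa: str
    mut_span: Optional[Tuple[int, int]]
    variant: SomaticVariant


@dataclass(frozen=True)
class NeoPeptide:
    """One candidate mutant peptide window (8-11 residues)."""

    sequence: str
    transcript_id: str
    gene_id: str
    variant: SomaticVariant
    window_start: int  # 1-based offset into mut_aa
    n_mut_residues: int


def _common_prefix_len(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _diff_span(wt: str, mut: str) -> Optional[Tuple[int, int]]:
    """Residue span of mut differing from wt, by prefix/suffix trimming."""
    p = _common_prefix_len(wt, mut)
    s = 0
    while s < min(len(wt), len(mut)) - p and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]:
        s += 1
    first, last = p + 1, len(mut) - s
    if first > last:
        return None
    return (first, last)


def apply_variant(tx: TranscriptModel, v: SomaticVariant) -> Optional[MutantProtein]:
    """Apply ``v`` to ``tx``'s CDS and translate.

    Returns ``None`` (with a debug log) when the variant lies entirely
    outside the CDS.  Raises :class:`VariantApplicationError` on a ref
    mismatch or a variant spanning a CDS boundary.
    """
    ref_positions = range(v.pos, v.pos + len(v.ref))
    idx = [tx.cds_position(p) for p in ref_positions]
    if all(i is None for i in idx):
        logger.debug("%s outside CDS of %s", v, tx.transcript_id)
        return None
    if any(i is None for i in idx):
        raise VariantApplicationError(
            f"{v} spans a CDS boundary of {tx.transcript_id}"
        )
    lo, hi = min(idx), max(idx)
    if hi - lo + 1 != len(idx):
        raise VariantApplicationError(
            f"{v} maps to non-contiguous CDS positions in {tx.transcript_id}"
        )
    if tx.strand == "+":
        s_ref, s_alt = v.ref, v.alt
    else:
        s_ref, s_alt = reverse_complement(v.ref), reverse_complement(v.alt)
    observed = tx.cds_seq[lo - 1 : lo - 1 + len(s_ref)]
    if observed != s_ref:
        raise VariantApplicationError(
            f"{v}: transcript {tx.transcript_id} has {observed!r} at CDS nt {lo}, "
            f"expected {s_ref!r}"
        )
    edited = tx.cds_seq[: lo - 1] + s_alt + tx.cds_seq[lo - 1 + len(s_ref) :]
    wt_aa = translate(tx.cds_seq)
    frameshift = (len(s_ref) - len(s_alt)) % 3 != 0

    if frameshift:
        readthrough = edited + tx.utr3_seq
        mut_aa = translate(readthrough)
        if len(mut_aa) * 3 + 3 > len(readthrough):
            logger.warning(
                "%s: frameshift on %s reaches sequence end without a stop codon",
                v, tx.transcript_id,
            )
        # first actually-edited nt, skipping the shared anchor prefix
        fs_nt = lo + _common_prefix_len(s_ref, s_alt)
        fs_res = (fs_nt - 1) // 3 + 1
        span = (fs_res, len(mut_aa)) if fs_res <= len(mut_aa) else None
    else:
        mut_aa = translate(edited)
        span = _diff_span(wt_aa, mut_aa)
        if span is None and len(mut_aa) < len(wt_aa) and v.vclass == "SNV":
            logger.debug("%s: stop-gain on %s", v, tx.transcript_id)

    return MutantProtein(
        transcript_id=tx.transcript_id,
        gene_id=tx.gene_id,
        wt_aa=wt_aa,
        mut_aa=mut_aa,
        mut_span=span,
        variant=v,
    )


def enumerate_neoepitopes(mp: MutantProtein,
                          lengths: Iterable[int] = DEFAULT_LENGTHS) -> list:
    """All windows of the requested lengths inside ``mut_aa`` containing
    at least one mutated residue, minus any window whose sequence occurs
    in the wild-type protein.  Deduplicated on sequence (keeping the
    smallest window_start); ordered by (length, window_start)."""
    if mp.mut_span is None:
        return []
    a, b = mp.mut_span
    mut, wt = mp.mut_aa, mp.wt_aa
    out = []
    seen = set()
    for k in sorted(set(lengths)):
        if k < 1 or k > len(mut):
            continue
        for start in range(max(1, a - k + 1), min(b, len(mut) - k + 1) + 1):
            seq = mut[start - 1 : start - 1 + k]
            if seq in wt or seq in seen:
                continue
            seen.add(seq)
            n_mut = min(b, start + k - 1) - max(a, start) + 1
            out.append(
                NeoPeptide(
                    sequence=seq,
                    transcript_id=mp.transcript_id,
                    gene_id=mp.gene_id,
                    variant=mp.variant,
                    window_start=start,
                    n_mut_residues=n_mut,
                )
            )
    return out
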