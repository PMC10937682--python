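"""Naive string-edit oracle for expected mutant peptides.

Deliberately independent of :mod:`neoforge.peptides`: it works on
transcript-level (stranded) edits, uses its own hard-coded codon table,
and enumerates substrings directly.  The generator records expected
peptides with this oracle at generation time; equivalence with the
pipeline is the central acceptance property.
"""

_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
_CODONS = {a + b + c: _AA[16 * i + 4 * j + k]
           for i, a in enumerate(_BASES)
           for j, b in enumerate(_BASES)
           for k, c in enumerate(_BASES)}


def naive_translate(nt):
    aa = []
    for i in range(0, len(nt) - 2, 3):
        r = _CODONS[nt[i:i + 3]]
        if r == "*":
            break
        aa.append(r)
    return "".join(aa)


def _prefix(a, b):
    n = 0
    while n < min(len(a), len(b)) and a[n] == b[n]:
        n += 1
    return n


def expected_peptides(cds, utr3, start, ref, alt, lengths=(8, 9, 10, 11)):
    """Peptide set for a stranded CDS edit (1-based start, ref -> alt).

    Rebuilds the mutant protein by naive string edit, finds the changed
    residue region (frameshift: edit codon to end; otherwise
    prefix/suffix trimming), and keeps every 8-11-mer substring that
    overlaps it and is absent from the wild-type protein."""
    wt = naive_translate(cds)
    edited = cds[:start - 1] + alt + cds[start - 1 + len(ref):]
    if (len(ref) - len(alt)) % 3 != 0:
        mut = naive_translate(edited + utr3)
        first = (start + _prefix(ref, alt) - 1) // 3 + 1
        last = len(mut)
    else:
        mut = naive_translate(edited)
        p = _prefix(wt, mut)
        s = 0
        while s < min(len(wt), len(mut)) - p and wt[len(wt) - 1 - s] == mut[len(mut) - 1 - s]:
            s += 1
        first, last = p + 1, len(mut) - s
    if first > last:
        return set()
    peps = set()
    for k in lengths:
        for st in range(1, len(mut) - k + 2):
            if st + k - 1 >= first and st <= last:
                sub = mut[st - 1:st - 1 + k]
                if sub not in wt:
                    peps.add(sub)
    return peps
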