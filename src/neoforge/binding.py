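"""MHC class-I binding predictions: NetMHC-style table parsing, a
deterministic toy predictor, and the strong-binder filter.

The toy predictor is a two-anchor motif lookup and is explicitly
non-biological; it exists so the pipeline can be exercised end-to-end
without external software.  Real runs feed ``parse_netmhc_table`` the
output of NetMHC 4.0 / netMHCpan 4.0.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .errors import FormatError, ValidationError
from .io import _open_text

logger = logging.getLogger(__name__)

DEFAULT_ALLELES = ("H2-Kb", "H2-Db")
DEFAULT_RANK_MAX = 0.5

# anchor motifs for the toy predictor: (position-5 residues, C-terminal residues)
_TOY_ANCHORS = {
    "H2-Kb": (set("FY"), set("LMIV")),
    "H2-Db": (set("N"), set("MILV")),
}
_TOY_SCORES = {2: (0.1, 50.0), 1: (1.0, 500.0), 0: (50.0, 5000.0)}


@dataclass(frozen=True)
class BindingPrediction:
    """(peptide, allele) with %rank and IC50 in nM."""

    peptide: str
    allele: str
    percent_rank: float
    ic50_nm: float

    def validate(self) -> None:
        if not (8 <= len(self.peptide) <= 11):
            raise ValidationError(f"peptide {self.peptide!r} not length 8-11")
        if self.percent_rank <= 0:
            raise ValidationError(f"{self.peptide}: percent_rank must be > 0")
        if self.ic50_nm <= 0:
            raise ValidationError(f"{self.peptide}: ic50_nm must be > 0")


def normalize_allele(name: str) -> str:
    """Unify NetMHC allele spellings: 'H-2-Kb', 'H2-Kb', 'h2kb' -> 'H2-Kb'.

    Unrecognized names are returned stripped but otherwise unchanged."""
    key = re.sub(r"[^0-9A-Za-z]", "", name).lower()
    m = re.fullmatch(r"h2([a-z])([a-z0-9]*)", key)
    if m:
        return "H2-" + m.group(1).upper() + m.group(2)
    return name.strip()


_COLUMN_ALIASES = {
    "peptide": "peptide",
    "mhc": "allele",
    "allele": "allele",
    "%rank": "percent_rank",
    "rank": "percent_rank",
    "%rank_el": "percent_rank",
    "aff(nm)": "ic50_nm",
    "affinity(nm)": "ic50_nm",
    "affinity": "ic50_nm",
    "aff": "ic50_nm",
    "ic50": "ic50_nm",
}


def parse_netmhc_table(path, column_map: Optional[Mapping[str, str]] = None) -> list:
    """Parse a NetMHC-4.0-style whitespace-delimited table.

    Banner/comment lines starting with ``#`` or ``-`` are skipped; the
    first remaining line is taken as the header.  Required columns:
    peptide, MHC/Allele, %Rank, Aff(nM) (aliases accepted; override
    with ``column_map`` mapping header token -> field name)."""
    aliases = dict(_COLUMN_ALIASES)
    if column_map:
        aliases.update({k.lower(): v for k, v in column_map.items()})
    preds = []
    header = None
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("-"):
                continue
            tokens = line.split()
            if header is None:
                header = {}
                for i, tok in enumerate(tokens):
                    field = aliases.get(tok.lower())
                    if field is not None and field not in header:
                        header[field] = i
                missing = {"peptide", "allele", "percent_rank", "ic50_nm"} - set(header)
                if missing:
                    raise FormatError(
                        f"{path}:{lineno}: missing column(s) {sorted(missing)}; "
                        f"found columns {tokens}"
                    )
                ncols = len(tokens)
                continue
            if len(tokens) < ncols:
                raise FormatError(f"{path}:{lineno}: expected {ncols} columns")
            try:
                rank = float(tokens[header["percent_rank"]])
                ic50 = float(tokens[header["ic50_nm"]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric: {exc}") from None
            pred = BindingPrediction(
                peptide=tokens[header["peptide"]],
                allele=normalize_allele(tokens[header["allele"]]),
                percent_rank=rank,
                ic50_nm=ic50,
            )
            pred.validate()
            preds.append(pred)
    if header is None:
        raise FormatError(f"{path}: no header line found")
    return preds


def write_netmhc_table(preds: Iterable[BindingPrediction], path) -> None:
    """Write predictions in the documented table layout (round-trips
    through :func:`parse_netmhc_table`)."""
    lines = ["# neoforge binding predictions", "MHC Peptide %Rank Aff(nM)"]
    for p in preds:
        lines.append(f"{p.allele} {p.peptide} {p.percent_rank:.10g} {p.ic50_nm:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def predict_toy(peptide: str, allele: str) -> BindingPrediction:
    """Deterministic two-anchor motif predictor (non-biological stand-in).

    Anchors are position 5 and the C-terminus; 2 matches -> %rank 0.1 /
    50 nM, 1 match -> 1.0 / 500 nM, 0 -> 50.0 / 5000 nM."""
    allele = normalize_allele(allele)
    if allele not in _TOY_ANCHORS:
        raise ValidationError(f"unknown allele {allele!r} for toy predictor")
    if not (8 <= len(peptide) <= 11):
        raise ValidationError(f"peptide {peptide!r} not length 8-11")
    p5_set, ct_set = _TOY_ANCHORS[allele]
    n = (peptide[4] in p5_set) + (peptide[-1] in ct_set)
    rank, ic50 = _TOY_SCORES[n]
    return BindingPrediction(peptide=peptide, allele=allele,
                             percent_rank=rank, ic50_nm=ic50)


def filter_strong_binders(preds: Iterable[BindingPrediction],
                          rank_max: float = DEFAULT_RANK_MAX) -> list:
    """Keep predictions with %rank <= rank_max (inclusive).

    A peptide counts as a strong binder if ANY allele passes; use
    :func:`best_per_peptide` on the result to get the reported
    (minimum-rank) allele."""
    if rank_max <= 0:
        raise ValueError("rank_max must be > 0")
    return [p for p in preds if p.percent_rank <= rank_max]


def best_per_peptide(preds: Iterable[BindingPrediction]) -> dict:
    """Per-peptide minimum-rank prediction (ties broken by allele name)."""
    best: dict = {}
    for p in preds:
        cur = best.get(p.peptide)
        if cur is None or (p.percent_rank, p.allele) < (cur.percent_rank, cur.allele):
            best[p.peptide] = p
    return best
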