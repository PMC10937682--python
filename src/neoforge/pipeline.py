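"""End-to-end orchestration: read inputs, run the filter cascade, build
and compare the two catalogs, and write deterministic outputs plus a
JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml

from . import __version__
from .binding import (DEFAULT_ALLELES, DEFAULT_RANK_MAX, parse_netmhc_table,
                      predict_toy)
from .catalog import (NeoantigenRecord, build_catalog, classify_shared_unique,
                      venn_counts)
from .errors import NeoforgeError
from .filters import (DEFAULT_MIN_RNA_ALT, DEFAULT_MIN_WES_ALT, attach_tpm,
                      filter_wes_support, subtract_germline, validate_rna)
from .io import (read_expression_tsv, read_fasta, read_gtf_cds, read_vcf,
                 write_catalog)
from .peptides import DEFAULT_LENGTHS, apply_variant, enumerate_neoepitopes

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat run configuration; defaults are the published thresholds
    (%rank <= 0.5, >= 5 WES altered reads, >= 3 RNA altered reads,
    peptide lengths 8-11, alleles H2-Kb/H2-Db)."""

    genome_fasta: str = ""
    gtf: str = ""
    tumor_a_vcf: str = ""
    tumor_b_vcf: str = ""
    normal_vcf: str = ""
    rna_a_vcf: str = ""
    rna_b_vcf: str = ""
    expression_a_tsv: str = ""
    expression_b_tsv: str = ""
    netmhc_table: str = ""
    sample_a: str = "TUMOR_A"
    sample_b: str = "TUMOR_B"
    sample_normal: str = "NORMAL"
    line_a: str = "A"
    line_b: str = "B"
    min_wes_alt: int = DEFAULT_MIN_WES_ALT
    min_rna_alt: int = DEFAULT_MIN_RNA_ALT
    rank_max: float = DEFAULT_RANK_MAX
    lengths: tuple = DEFAULT_LENGTHS
    alleles: tuple = DEFAULT_ALLELES
    predictor: str = "toy"  # toy | netmhc-table
    out_dir: str = "neoforge_out"
    seed: int = 0

    def __post_init__(self):
        self.lengths = tuple(int(x) for x in self.lengths)
        self.alleles = tuple(self.alleles)
        if self.min_wes_alt < 0 or self.min_rna_alt < 0:
            raise ValueError("thresholds must be >= 0")
        if self.rank_max <= 0:
            raise ValueError("rank_max must be > 0")
        if any(not (1 <= k <= 15) for k in self.lengths):
            raise ValueError("peptide lengths must lie in [1, 15]")
        if any(k < 8 or k > 11 for k in self.lengths):
            logger.warning("peptide lengths %s outside the default 8-11 range",
                           self.lengths)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise NeoforgeError(f"{path}: config must be a flat key-value document")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise NeoforgeError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    catalog_a: List[NeoantigenRecord]
    catalog_b: List[NeoantigenRecord]
    shared: List[NeoantigenRecord]
    unique_a: List[NeoantigenRecord]
    unique_b: List[NeoantigenRecord]
    manifest: dict

    @property
    def venn(self) -> Tuple[int, int, int]:
        return venn_counts(self.shared, self.unique_a, self.unique_b)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(manifest, name, count):
    manifest["stages"].append({"stage": name, "count": count})
    logger.info("stage %-28s %6d records", name, count)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write catalogs, the comparison
    report and the run manifest under ``cfg.out_dir``.

    Stage order: read -> germline subtraction -> WES support filter ->
    peptide enumeration -> binding -> RNA validation -> TPM attach ->
    catalog -> shared/unique comparison."""
    manifest: dict = {
        "tool": "neoforge",
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "inputs": {},
        "stages": [],
    }
    input_paths = {
        "genome_fasta": cfg.genome_fasta, "gtf": cfg.gtf,
        "tumor_a_vcf": cfg.tumor_a_vcf, "tumor_b_vcf": cfg.tumor_b_vcf,
        "normal_vcf": cfg.normal_vcf, "rna_a_vcf": cfg.rna_a_vcf,
        "rna_b_vcf": cfg.rna_b_vcf, "expression_a_tsv": cfg.expression_a_tsv,
        "expression_b_tsv": cfg.expression_b_tsv,
    }
    if cfg.predictor == "netmhc-table":
        input_paths["netmhc_table"] = cfg.netmhc_table
    for key, path in input_paths.items():
        if not path:
            raise NeoforgeError(f"config is missing required input {key!r}")
        if not Path(path).exists():
            raise NeoforgeError(f"input {key} not found: {path}")
        manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    def guarded(stage_name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except NeoforgeError as exc:
            raise NeoforgeError(f"stage {stage_name!r} failed: {exc}") from exc

    # -- read -------------------------------------------------------------
    fasta = guarded("read", read_fasta, cfg.genome_fasta)
    transcripts = guarded("read", read_gtf_cds, cfg.gtf, fasta)
    tx_by_chrom: Dict[str, list] = {}
    for tx in transcripts:
        tx_by_chrom.setdefault(tx.chrom, []).append(tx)
    tx_index = {tx.transcript_id: tx.gene_id for tx in transcripts}
    _stage(manifest, "read_transcripts", len(transcripts))

    tumors = {
        "A": guarded("read", read_vcf, cfg.tumor_a_vcf, cfg.sample_a),
        "B": guarded("read", read_vcf, cfg.tumor_b_vcf, cfg.sample_b),
    }
    normal = guarded("read", read_vcf, cfg.normal_vcf, cfg.sample_normal)
    rna = {
        "A": guarded("read", read_vcf, cfg.rna_a_vcf, cfg.sample_a),
        "B": guarded("read", read_vcf, cfg.rna_b_vcf, cfg.sample_b),
    }
    expr = {
        "A": guarded("read", read_expression_tsv, cfg.expression_a_tsv),
        "B": guarded("read", read_expression_tsv, cfg.expression_b_tsv),
    }
    for line in ("A", "B"):
        _stage(manifest, f"read_tumor_{line}", len(tumors[line]))

    table_bindings = None
    if cfg.predictor == "netmhc-table":
        table_bindings = guarded("bind", parse_netmhc_table, cfg.netmhc_table)
    elif cfg.predictor != "toy":
        raise NeoforgeError(f"unknown predictor {cfg.predictor!r}")

    catalogs = {}
    for line in ("A", "B"):
        somatic = guarded("germline_subtraction", subtract_germline,
                          tumors[line], normal)
        _stage(manifest, f"germline_subtracted_{line}", len(somatic))
        supported = guarded("wes_support_filter", filter_wes_support,
                            somatic, cfg.min_wes_alt)
        _stage(manifest, f"wes_supported_{line}", len(supported))

        peptides, variant_tx = [], {}
        for v in supported:
            for tx in tx_by_chrom.get(v.chrom, []):
                mp = guarded("peptide_enumeration", apply_variant, tx, v)
                if mp is None:
                    continue
                variant_tx.setdefault(v.key, tx.transcript_id)
                peptides.extend(
                    guarded("peptide_enumeration", enumerate_neoepitopes,
                            mp, cfg.lengths))
        _stage(manifest, f"peptides_{line}", len(peptides))

        if table_bindings is not None:
            bindings = table_bindings
        else:
            bindings = [guarded("bind", predict_toy, p, a)
                        for p in sorted({p.sequence for p in peptides})
                        for a in cfg.alleles]
        _stage(manifest, f"bindings_{line}", len(bindings))

        evidence = guarded("rna_validation", validate_rna, supported,
                           rna[line], cfg.min_rna_alt)
        _stage(manifest, f"rna_validated_{line}", len(evidence))

        mapped = []
        for ev in evidence:
            tid = variant_tx.get(ev.variant.key)
            if tid is None:
                logger.debug("dropping evidence for %s: no CDS transcript",
                             ev.variant)
                continue
            mapped.append(replace(ev, transcript_id=tid))
        evidence = guarded("tpm_attach", attach_tpm, mapped, expr[line], tx_index)
        _stage(manifest, f"tpm_attached_{line}", len(evidence))

        label = cfg.line_a if line == "A" else cfg.line_b
        catalogs[line] = guarded("catalog", build_catalog, evidence, peptides,
                                 bindings, label, cfg.rank_max)
        _stage(manifest, f"catalog_{line}", len(catalogs[line]))

    shared, unique_a, unique_b = classify_shared_unique(catalogs["A"], catalogs["B"])
    venn = venn_counts(shared, unique_a, unique_b)
    manifest["venn"] = {"shared": venn[0], "unique_A": venn[1], "unique_B": venn[2]}

    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_line = {"A": [], "B": []}
    for rec in shared + unique_a + unique_b:
        key = "A" if rec.line == cfg.line_a else "B"
        by_line[key].append(rec)
    for line in ("A", "B"):
        write_catalog([r.to_row() for r in by_line[line]],
                      out_dir / f"catalog_{line}.tsv")
    (out_dir / "comparison.json").write_text(
        json.dumps(manifest["venn"], indent=2, sort_keys=True) + "\n")
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        catalog_a=catalogs["A"], catalog_b=catalogs["B"],
        shared=shared, unique_a=unique_a, unique_b=unique_b,
        manifest=manifest,
    )
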