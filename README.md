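# neoforge

A tested, reusable pipeline from somatic variant calls to an MHC
class-I-filtered, expression-validated neoantigen catalog for two
related tumor cell lines, plus the cohort signature-scoring and
survival statistics used to stratify patients by tumor mutational
burden (TMB) and dendritic-cell (cDC1) signature content.

The pipeline stages:

1. **Inputs** — genome FASTA, GTF (CDS features), tumor/normal/RNA VCFs
   with per-sample `AD` depths, RSEM-style gene TPM tables.
2. **Germline subtraction** — allele-exact removal of variants present
   in the matched normal.
3. **WES support filter** — keep variants with ≥ 5 altered reads.
4. **Peptide enumeration** — codon-aware variant application
   (SNV / in-frame indel / frameshift with 3'-UTR read-through),
   then all 8–11-mer windows overlapping a mutated residue, minus
   windows present in the wild-type protein.
5. **MHC-I binding** — NetMHC-style table parser or a built-in
   deterministic toy predictor; strong binders are %rank ≤ 0.5 on any
   allele (defaults H2-Kb, H2-Db).
6. **RNA validation** — WES-anchored match against RNA-seq variant
   calls with ≥ 3 altered reads; gene TPM attached.
7. **Catalog & comparison** — one record per peptide per line;
   shared / unique classification keyed on peptide sequence
   (Venn + TPM-vs-IC50 scatter table).

A first-class synthetic-data module generates every input with
recorded ground truth (planted variants, read support, expression,
a latent-factor cohort), and an independent ≤50-line naive oracle
computes the expected peptides so the pipeline can be verified against
it on every generated dataset.

The toy binding predictor is a two-anchor motif lookup and is **not
biological**; real analyses should parse NetMHC 4.0 / netMHCpan 4.0
output with `parse_netmhc_table`.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(oracle equivalence on 100 seeded datasets, closed-form window counts,
filter boundaries, strong-binder boundary, Venn recovery, cohort
statistics power/calibration, formula checks, byte-level determinism).

## CLI

```sh
# generate a complete synthetic dataset with ground truth
neoforge simulate --seed 7 --out data/ --ensure-strong-binder --cohort-n 500

# run the full pipeline from a flat YAML config (flags override)
neoforge run --config config.yaml --rank-max 0.5

# individual stages
neoforge call-peptides --fasta data/genome.fa --gtf data/annotation.gtf \
    --vcf data/tumor_B.vcf --sample TUMOR_B --out peptides.tsv
neoforge bind --peptides peptides.tsv --predictor toy --rank-max 0.5 --out binders.txt
neoforge filter --tumor-vcf data/tumor_B.vcf --normal-vcf data/normal.vcf \
    --rna-vcf data/rna_B.vcf --tumor-sample TUMOR_B --normal-sample NORMAL \
    --out evidence.tsv
neoforge compare --a out/catalog_A.tsv --b out/catalog_B.tsv
neoforge cohort --cohort data/cohort.tsv
```

The config file is a flat YAML document whose keys mirror
`neoforge.pipeline.PipelineConfig` (paths, `min_wes_alt`,
`min_rna_alt`, `rank_max`, `lengths`, `alleles`, `predictor`,
`out_dir`, `seed`).  `neoforge run` writes `catalog_A.tsv`,
`catalog_B.tsv`, `comparison.json` and a `manifest.json` recording the
config, input checksums and per-stage record counts; outputs are
byte-identical across reruns on identical inputs.

## Formats and conventions

- Coordinates are 1-based inclusive throughout (VCF/GTF convention).
- Multi-allelic VCF records are rejected (decompose upstream); indels
  must be left-aligned with an anchored first base.
- GTF attributes are `key "value";` pairs; GFF3 is not supported.
- All readers accept plain or gzip-compressed files.
- Median-split ties go to "low"; quartile membership is inclusive at
  the boundary with linear-interpolation quantiles (both
  config-exposed).
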