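import pathlib

import pytest

from neoforge.io import SomaticVariant, TranscriptModel
from neoforge.simulate import (generate_transcriptome, plant_variants,
                               simulate_rna_support, write_rna_files,
                               write_variant_files)


def make_tx(cds, utr3="TAACTAACTAAC", strand="+", chrom="c1",
            transcript_id="t1", gene_id="g1", offset=0):
    """Single-interval transcript whose CDS occupies genomic
    [offset+1, offset+len(cds)] (stranded sequence given directly)."""
    iv = (offset + 1, offset + len(cds))
    return TranscriptModel(transcript_id=transcript_id, gene_id=gene_id,
                           chrom=chrom, strand=strand, cds_intervals=(iv,),
                           cds_seq=cds, utr3_seq=utr3)


def snv(chrom, pos, ref, alt, alt_reads=10, sample="S"):
    return SomaticVariant(chrom, pos, ref, alt, "SNV", alt_reads, sample)


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """A complete on-disk synthetic dataset with its ground truth.

    Design: 10 somatic variants (missense/frameshift/in-frame), 40%%
    shared between lines A and B, 2 germline, everything expressed and
    strong-binder-producing."""
    out = tmp_path_factory.mktemp("dataset")
    trome = generate_transcriptome(11, n_genes=14)
    fasta, gtf = trome.write(out)
    truth = plant_variants(12, trome, n_missense=5, n_synonymous=1,
                           n_frameshift=2, n_inframe=1, n_germline=2,
                           shared_fraction=0.4, ensure_strong_binder=True)
    rna = simulate_rna_support(13, truth)
    paths = {"genome": fasta, "gtf": gtf}
    paths.update(write_variant_files(truth, out))
    paths.update(write_rna_files(truth, rna, out))
    return {"dir": out, "paths": paths, "truth": truth}


@pytest.fixture()
def pipeline_config(synthetic_dataset, tmp_path):
    from neoforge.pipeline import PipelineConfig

    p = synthetic_dataset["paths"]
    return PipelineConfig(
        genome_fasta=str(p["genome"]), gtf=str(p["gtf"]),
        tumor_a_vcf=str(p["tumor_A"]), tumor_b_vcf=str(p["tumor_B"]),
        normal_vcf=str(p["normal"]), rna_a_vcf=str(p["rna_A"]),
        rna_b_vcf=str(p["rna_B"]),
        expression_a_tsv=str(p["expression_A"]),
        expression_b_tsv=str(p["expression_B"]),
        out_dir=str(tmp_path / "out"),
    )
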