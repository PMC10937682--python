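import numpy as np
import pytest

from neoforge import oracle
from neoforge.errors import NeoforgeError
from neoforge.io import read_fasta, read_gtf_cds, read_vcf
from neoforge.peptides import translate
from neoforge.simulate import (SAMPLE_A, SAMPLE_B, SAMPLE_NORMAL,
                               generate_transcriptome, plant_variants,
                               simulate_cohort, simulate_rna_support,
                               write_rna_files, write_variant_files)
from neoforge.stats import (CD8_EFFECTOR_SIGNATURE_GENES,
                            CDC1_SIGNATURE_GENES, pearson_r)

# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


def test_transcriptome_deterministic(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        generate_transcriptome(3, n_genes=6).write(d)
    assert (d1 / "genome.fa").read_bytes() == (d2 / "genome.fa").read_bytes()
    assert (d1 / "annotation.gtf").read_bytes() == (d2 / "annotation.gtf").read_bytes()


def test_transcriptome_round_trips_through_strict_reader(tmp_path):
    trome = generate_transcriptome(4, n_genes=10)
    fasta, gtf = trome.write(tmp_path)
    txs = read_gtf_cds(gtf, read_fasta(fasta), strict=True)
    assert len(txs) == 10
    by_id = {t.transcript_id: t for t in txs}
    for tx in trome.transcripts:
        assert by_id[tx.transcript_id].cds_seq == tx.cds_seq
        assert by_id[tx.transcript_id].utr3_seq == tx.utr3_seq
        assert by_id[tx.transcript_id].cds_intervals == tx.cds_intervals


def test_transcriptome_both_strands_and_clean_translation():
    trome = generate_transcriptome(5, n_genes=8)
    strands = {t.strand for t in trome.transcripts}
    assert strands == {"+", "-"}
    for tx in trome.transcripts:
        aa = translate(tx.cds_seq)
        assert len(aa) == len(tx.cds_seq) // 3  # no internal stop
        assert aa.startswith("M")
        assert tx.utr3_seq[:3] in ("TAA", "TAG", "TGA")


def test_transcriptome_rejects_bad_params():
    with pytest.raises(ValueError):
        generate_transcriptome(1, cds_len_range=(30, 60))
    with pytest.raises(ValueError):
        generate_transcriptome(1, utr3_len=6)


# ---------------------------------------------------------------------------
# variant planting
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def planted():
    trome = generate_transcriptome(21, n_genes=14)
    truth = plant_variants(22, trome, n_missense=5, n_synonymous=2,
                           n_frameshift=2, n_inframe=1, n_germline=3,
                           shared_fraction=0.5)
    return trome, truth


def test_germline_variants_in_tumor_and_normal(planted, tmp_path):
    trome, truth = planted
    paths = write_variant_files(truth, tmp_path)
    normal = read_vcf(paths["normal"], SAMPLE_NORMAL)
    tumor_a = read_vcf(paths["tumor_A"], SAMPLE_A)
    tumor_b = read_vcf(paths["tumor_B"], SAMPLE_B)
    assert len(normal) == 3
    normal_keys = {v.key for v in normal}
    assert normal_keys <= {v.key for v in tumor_a}
    assert normal_keys <= {v.key for v in tumor_b}


def test_line_b_superset_of_line_a(planted):
    _, truth = planted
    a_keys = {p.key for p in truth.somatic if "A" in p.lines}
    b_keys = {p.key for p in truth.somatic if "B" in p.lines}
    assert a_keys <= b_keys
    assert truth.shared_design == len(a_keys) == 5
    assert truth.uniqueB_design == len(b_keys - a_keys) == 5


def test_synonymous_variants_have_no_expected_peptides(planted):
    _, truth = planted
    for p in truth.planted:
        if p.consequence == "synonymous":
            assert p.oracle_peptides == frozenset()


def test_planted_vcf_ref_matches_genome(planted):
    trome, truth = planted
    seqs = {r.id: r.sequence for r in trome.records}
    for p in truth.planted:
        assert seqs[p.chrom][p.pos - 1: p.pos - 1 + len(p.ref)] == p.ref


def test_oracle_peptides_overlap_edit(planted):
    _, truth = planted
    for p in truth.somatic:
        if p.consequence == "missense":
            assert p.oracle_peptides  # interior missense always yields some


def test_forced_low_support_exercises_filter():
    trome = generate_transcriptome(31, n_genes=10)
    truth = plant_variants(32, trome, n_missense=6, shared_fraction=1.0,
                           frac_low_support=0.5)
    low = [p for p in truth.somatic
           if any(v < 5 for v in p.wes_alt.values())]
    assert len(low) == 3
    for p in low:
        assert all(1 <= v <= 4 for v in p.wes_alt.values())


def test_too_many_variants_error():
    trome = generate_transcriptome(41, n_genes=3)
    with pytest.raises(NeoforgeError, match="transcripts"):
        plant_variants(42, trome, n_missense=10)


def test_plant_deterministic(tmp_path):
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        trome = generate_transcriptome(51, n_genes=8)
        truth = plant_variants(52, trome, n_missense=4, n_frameshift=2)
        write_variant_files(truth, d)
    for name in ("tumor_A.vcf", "tumor_B.vcf", "normal.vcf"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


# ---------------------------------------------------------------------------
# RNA support
# ---------------------------------------------------------------------------


def test_rna_all_expressed_all_called(planted, tmp_path):
    trome, truth = planted
    rna = simulate_rna_support(61, truth, expressed_fraction=1.0, depth=100)
    calls_b, expr_b = rna["B"]
    b_keys = {p.key for p in truth.somatic if "B" in p.lines}
    assert {v.key for v in calls_b} == b_keys
    assert all(v.alt_reads >= 3 for v in calls_b)
    tpms = list(expr_b.tpm.values())
    assert all(np.isfinite(t) and t >= 0 for t in tpms)


def test_rna_forced_low_reads_eliminated_by_validation():
    from neoforge.filters import validate_rna

    trome = generate_transcriptome(71, n_genes=10)
    truth = plant_variants(72, trome, n_missense=6, shared_fraction=1.0)
    rna = simulate_rna_support(73, truth, frac_low_rna=0.5)
    calls_a, _ = rna["A"]
    wes = [p.as_somatic(SAMPLE_A, p.wes_alt[SAMPLE_A]) for p in truth.somatic]
    evidence = validate_rna(wes, calls_a)
    forced = {v.key for v in calls_a if v.alt_reads < 3}
    assert len(forced) == 3
    assert all(e.variant.key not in forced for e in evidence)


def test_unexpressed_variants_absent_from_rna_and_tpm_zero():
    trome = generate_transcriptome(81, n_genes=12)
    truth = plant_variants(82, trome, n_missense=8, shared_fraction=1.0)
    rna = simulate_rna_support(83, truth, expressed_fraction=0.5)
    calls_a, expr = rna["A"]
    called = {v.key for v in calls_a}
    for p in truth.somatic:
        if not p.expressed:
            assert p.key not in called
            assert expr.get(p.gene_id) == 0.0


def test_rna_files_deterministic(planted, tmp_path):
    trome, truth = planted
    d1, d2 = tmp_path / "a", tmp_path / "b"
    for d in (d1, d2):
        rna = simulate_rna_support(91, truth)
        write_rna_files(truth, rna, d)
    for name in ("rna_A.vcf", "rna_B.vcf", "expression_A.tsv", "expression_B.tsv"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


# ---------------------------------------------------------------------------
# oracle self-checks
# ---------------------------------------------------------------------------


def test_oracle_translate_matches_pipeline_translate():
    rng = np.random.default_rng(5)
    for _ in range(50):
        nt = "".join(rng.choice(list("ACGT"), size=60))
        assert oracle.naive_translate(nt) == translate(nt)


def test_oracle_synonymous_empty():
    # ATG GCT -> GCA: synonymous
    assert oracle.expected_peptides("ATGGCTAAA", "TAA", 6, "T", "A") == set()


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def test_cohort_zscore_columns_standardized():
    df, _ = simulate_cohort(1, n=300)
    for g in CDC1_SIGNATURE_GENES + CD8_EFFECTOR_SIGNATURE_GENES:
        assert abs(df[g].mean()) < 1e-6
        assert abs(df[g].std(ddof=0) - 1) < 1e-6


def test_cohort_beta_zero_uncorrelated():
    df, _ = simulate_cohort(2, n=10_000, beta=0.0)
    cdc1 = df[list(CDC1_SIGNATURE_GENES)].mean(axis=1)
    cd8 = df[list(CD8_EFFECTOR_SIGNATURE_GENES)].mean(axis=1)
    r, _ = pearson_r(cdc1, cd8)
    assert abs(r) < 3 / np.sqrt(10_000)


def test_cohort_beta_one_powered():
    df, _ = simulate_cohort(3, n=500, beta=1.0)
    cdc1 = df[list(CDC1_SIGNATURE_GENES)].mean(axis=1)
    cd8 = df[list(CD8_EFFECTOR_SIGNATURE_GENES)].mean(axis=1)
    r, p = pearson_r(cdc1, cd8)
    assert r > 0
    assert p < 0.01


def test_cohort_deterministic():
    df1, _ = simulate_cohort(4, n=100)
    df2, _ = simulate_cohort(4, n=100)
    assert df1.equals(df2)


def test_cohort_survival_fields_valid():
    df, params = simulate_cohort(5, n=200, hr=2.0)
    assert (df["time_months"] > 0).all()
    assert set(df["event"]) <= {0, 1}
    assert params["low_group"].sum() == 100
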