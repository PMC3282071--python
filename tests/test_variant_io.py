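import pytest

from mendelseek.synthetic_data import build_transcript_fixture
from mendelseek.variant_io import (
    CohortManifest,
    Genotype,
    ManifestEntry,
    VariantParseError,
    load_transcript_dir,
    read_manifest,
    read_phenotype_table,
    read_variant_file,
    write_manifest,
    write_variant_file,
)

VCF_HEADER = "\n".join([
    "##fileformat=VCFv4.2",
    '##contig=<ID=chr1,length=1000000>',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="depth">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">',
    '##INFO=<ID=CSQCLS,Number=1,Type=String,Description="class">',
    '##INFO=<ID=RSID,Number=1,Type=String,Description="rsid">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
])


def write_vcf(tmp_path, body_lines, name="x.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + "\n" + "\n".join(body_lines) + "\n")
    return p


def test_single_biallelic_record(tmp_path):
    p = write_vcf(tmp_path, [
        "chr1\t100\t.\tA\tT\t.\t.\tDP=20;GENE=G1;CSQCLS=missense\tGT\t0/1",
    ])
    calls = read_variant_file(p, "S1")
    assert len(calls) == 1
    v = next(iter(calls))
    assert (v.pos, v.ref, v.alt, v.depth) == (100, "A", "T", 20)
    assert v.genotype == Genotype.het and v.gene_id == "G1"


def test_multiallelic_record_decomposes(tmp_path):
    p = write_vcf(tmp_path, ["chr1\t200\t.\tC\tT,G\t.\t.\tDP=30\tGT\t1/2"])
    calls = read_variant_file(p, "S1")
    assert {v.key for v in calls} == {("chr1", 200, "C", "T"), ("chr1", 200, "C", "G")}
    assert all(v.depth == 30 and v.genotype == Genotype.het for v in calls)


def test_missing_depth_defaults_to_zero_and_id_column_rsid(tmp_path):
    p = write_vcf(tmp_path, ["chr1\t300\trs123\tG\tA\t.\t.\tGENE=G2\tGT\t0/1"])
    v = next(iter(read_variant_file(p, "S1")))
    assert v.depth == 0 and v.dbsnp_id == "rs123"


def test_unknown_consequence_maps_to_other(tmp_path, caplog):
    p = write_vcf(tmp_path, ["chr1\t400\t.\tG\tA\t.\t.\tDP=9;CSQCLS=weird\tGT\t0/1"])
    with caplog.at_level("WARNING"):
        v = next(iter(read_variant_file(p, "S1")))
    assert str(v.consequence_label) == "other"
    assert any("weird" in r.message for r in caplog.records)


def test_malformed_vcf_raises_with_location(tmp_path):
    p = tmp_path / "bad.vcf"
    p.write_text("not a vcf at all\n")
    with pytest.raises(VariantParseError):
        read_variant_file(p, "S1")


def test_roundtrip_preserves_keys_and_depths(tmp_path, cohort11):
    calls = cohort11.affected["S2"]
    out = tmp_path / "s2.vcf"
    write_variant_file(calls, out, "S2")
    back = read_variant_file(out, "S2")
    assert {(v.key, v.depth) for v in back} == {(v.key, v.depth) for v in calls}


# -- phenotype table -------------------------------------------------------

def test_table1_row_count_matches_data_lines(table1):
    from importlib.resources import files

    text = (files("mendelseek.data") / "table1.tsv").read_text()
    n_data = len([ln for ln in text.strip().splitlines()[1:] if ln])
    assert len(table1) == n_data == 19


def test_table1_first_row_values(table1):
    r = table1[0]
    assert r.hgvs_c == "c.401T>C" and str(r.inheritance) == "de_novo"
    assert r.height_sd == pytest.approx(2.2) and r.ofc_sd == pytest.approx(0.3)


def test_nk_values_parse_to_none(table1):
    r15 = next(r for r in table1 if r.case_id == "15")
    assert r15.ofc_sd is None and str(r15.inheritance) == "unknown"
    assert r15.height_sd == pytest.approx(4.6)


def test_unparseable_sd_names_the_case(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "case_id\thgvs_c\tprotein_change\tinheritance\theight_sd\tofc_sd"
        "\tlearning_disability\tmalignancy\tdiscovery_case\n"
        "7\tc.1A>G\t\tnk\ttall\tnk\tnk\t\tfalse\n"
    )
    with pytest.raises(ValueError, match="case 7"):
        read_phenotype_table(p)


# -- manifest --------------------------------------------------------------

def test_manifest_roundtrip_and_validation(tmp_path):
    m = CohortManifest([
        ManifestEntry("S1", "F1", "affected", True),
        ManifestEntry("S1_mother", "F1", "mother"),
    ])
    p = tmp_path / "m.tsv"
    write_manifest(m, p)
    back = read_manifest(p)
    assert back.affected_ids == ["S1"]
    assert back.parents_of("S1") == {"mother": "S1_mother"}
    with pytest.raises(ValueError, match="no affected"):
        CohortManifest([ManifestEntry("X", "F9", "mother")])
    with pytest.raises(ValueError, match="duplicate"):
        CohortManifest([
            ManifestEntry("S1", "F1", "affected"), ManifestEntry("S1", "F1", "affected"),
        ])


# -- transcript fixture files ----------------------------------------------

def test_fixture_dir_roundtrip(tmp_path, model):
    build_transcript_fixture(tmp_path / "fx")
    loaded = load_transcript_dir(tmp_path / "fx")
    assert loaded.n_exons == model.n_exons == 20
    assert loaded.cds == model.cds
    assert loaded.premrna == model.premrna
    assert loaded.utr5_len == model.utr5_len
    for c in (1, 401, 2196, model.cds_len):
        assert loaded.genomic_of_coding(c) == model.genomic_of_coding(c)
    assert [d.name for d in loaded.domains] == ["SET", "post-SET"]
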