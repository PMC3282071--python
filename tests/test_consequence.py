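import numpy as np
import pytest
from Bio.Seq import Seq

from mendelseek.consequence import (
    EditKind,
    HgvsParseError,
    annotate_domain,
    classify,
    conservation_score,
    cpg_context,
    parse_hgvs_c,
    recurrence_report,
)
from mendelseek.synthetic_data import simulate_alignment
from mendelseek.transcript import CodingPosition, revcomp
from mendelseek.variant_io import ConsequenceLabel


# -- parsing ---------------------------------------------------------------

@pytest.mark.parametrize(
    "text, kind, start, end, bases",
    [
        ("c.2050C>T", EditKind.substitution, (2050, 0), (2050, 0), "C"),
        ("c.2204_2211dupAGGCTGAT", EditKind.duplication, (2204, 0), (2211, 0), "AGGCTGAT"),
        ("c.2230_2232dupATC", EditKind.duplication, (2230, 0), (2232, 0), "ATC"),
        (
            "c.2196-15_2196-2delTTCCTGTTGTTTCA",
            EditKind.deletion, (2196, -15), (2196, -2), "TTCCTGTTGTTTCA",
        ),
    ],
)
def test_parse_supported_forms(text, kind, start, end, bases):
    e = parse_hgvs_c(text)
    assert e.kind == kind
    assert (e.start.base, e.start.offset) == start
    assert (e.end.base, e.end.offset) == end
    assert e.ref_bases == bases


def test_parse_span_validates_against_given_bases():
    e = parse_hgvs_c("c.2196-15_2196-2delTTCCTGTTGTTTCA")
    assert e.span == 14
    with pytest.raises(HgvsParseError, match="span"):
        parse_hgvs_c("c.10_12delAGGC")


@pytest.mark.parametrize("bad", ["c.76_77inv", "p.R684C", "g.100A>T", "c.2050C>C"])
def test_unsupported_forms_raise_explicitly(bad):
    with pytest.raises(HgvsParseError):
        parse_hgvs_c(bad)


# -- classification against the fixture -----------------------------------

def oracle_protein_change(model, edit):
    """Independent check: translate the whole edited CDS with biopython."""
    c = edit.start.base
    cds = model.cds
    mutated = cds[: c - 1] + edit.inserted_bases + cds[c:]
    before = str(Seq(cds).translate())
    after = str(Seq(mutated).translate())
    n = (c - 1) // 3
    aa_b, aa_a = before[n], after[n]
    if aa_b == aa_a:
        return f"p.{aa_b}{n + 1}="
    return f"p.{aa_b}{n + 1}{'X' if aa_a == '*' else aa_a}"


def test_all_19_mutations_classify_and_substitutions_match_oracle(model, table1):
    truncating_cases = []
    for rec in table1:
        edit = parse_hgvs_c(rec.hgvs_c)
        call = classify(edit, model)
        if edit.kind == EditKind.substitution and not edit.is_intronic:
            assert call.protein_change == oracle_protein_change(model, edit)
        if rec.protein_change:
            assert call.protein_change == rec.protein_change
        if call.truncating:
            truncating_cases.append(rec.case_id)
    assert truncating_cases == ["14", "15", "16"]


def test_nonsense_in_last_exon_escapes_nmd(model):
    call = classify(parse_hgvs_c("c.2199C>G"), model)
    assert call.consequence_class == ConsequenceLabel.nonsense
    assert call.protein_change == "p.Y733X"
    assert call.in_last_exon and call.nmd_escape and call.truncating


def test_inframe_duplication_is_not_truncating(model):
    call = classify(parse_hgvs_c("c.2230_2232dupATC"), model)
    assert call.consequence_class == ConsequenceLabel.inframe_indel
    assert not call.truncating and not call.nmd_escape


def test_intronic_deletion_is_splice_region_and_site_ablating(model):
    call = classify(parse_hgvs_c("c.2196-15_2196-2delTTCCTGTTGTTTCA"), model)
    assert call.consequence_class == ConsequenceLabel.splice_region
    assert call.truncating and call.nmd_escape and call.in_last_exon


def test_deep_intronic_edit_is_intronic(model):
    call = classify(parse_hgvs_c("c.2196-60G>A"), model)
    assert call.consequence_class == ConsequenceLabel.intronic
    assert not call.truncating


def test_mismatched_reference_base_is_rejected(model):
    wrong_ref = "G" if model.cds[2049] != "G" else "T"
    with pytest.raises(ValueError, match="does not match"):
        classify(parse_hgvs_c(f"c.2050{wrong_ref}>A"), model)


def test_synonymous_substitution(model):
    # codon 684 CGC -> CGT still codes arginine
    call = classify(parse_hgvs_c("c.2052C>T"), model)
    assert call.consequence_class == ConsequenceLabel.synonymous


# -- domains ---------------------------------------------------------------

DOMAINS = [("SET", 612, 727), ("post-SET", 728, 746)]


@pytest.mark.parametrize("pos, name", [(682, "SET"), (745, "post-SET"), (1, None)])
def test_domain_lookup(pos, name):
    assert annotate_domain(pos, DOMAINS) == name


def test_overlapping_domains_rejected():
    with pytest.raises(ValueError, match="overlap"):
        annotate_domain(10, [("A", 1, 20), ("B", 15, 30)])


# -- CpG context -----------------------------------------------------------

def sub(pos, ref, alt):
    p = CodingPosition(pos)
    from mendelseek.consequence import HgvsEdit

    return HgvsEdit(EditKind.substitution, p, p, ref, alt)


def test_cpg_detection_both_strands():
    seq = "AACGAA"  # CG at 0-based 2..3
    assert cpg_context(sub(3, "C", "T"), seq)          # C followed by G
    assert cpg_context(sub(4, "G", "A"), seq)          # G preceded by C
    assert not cpg_context(sub(3, "C", "T"), "AACAAA")  # next base not G


def test_cpg_at_sequence_edge_is_false():
    assert not cpg_context(sub(6, "C", "T"), "AAAAAC")


def test_cpg_reverse_complement_symmetry():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    for i, base in enumerate(seq):
        if base not in "CG":
            continue
        alt = "T" if base == "C" else "A"
        fwd = cpg_context(sub(i + 1, base, alt), seq)
        j = len(seq) - 1 - i
        rc = revcomp(seq)
        rc_base = rc[j]
        rc_alt = "T" if rc_base == "C" else "A"
        assert fwd == cpg_context(sub(j + 1, rc_base, rc_alt), rc)


def test_r684c_sits_in_cpg_on_fixture(model):
    call = classify(parse_hgvs_c("c.2050C>T"), model)
    assert call.cpg_site
    # neighbouring non-CpG missense for contrast
    other = classify(parse_hgvs_c("c.2044G>A"), model)  # A682T, GCT codon
    assert not other.cpg_site


# -- conservation ----------------------------------------------------------

def test_conservation_fractions():
    aln = [("human", "MKV"), ("m1", "MKV"), ("m2", "MAV"), ("m3", "M-V")]
    assert conservation_score(1, aln) == 1.0
    assert conservation_score(2, aln) == 0.5  # gap excluded: 1 of 2 match
    assert conservation_score(3, aln) == 1.0
    with pytest.raises(ValueError):
        conservation_score(4, aln)


def test_conservation_invariant_to_homolog_order():
    aln = simulate_alignment(n_columns=50, n_homologs=5, identity=0.7, seed=9)
    shuffled = [aln[0]] + aln[:0:-1]
    for pos in (1, 10, 50):
        assert conservation_score(pos, aln) == conservation_score(pos, shuffled)


def test_simulated_alignment_recovers_target_identity():
    identity, n_cols, n_hom = 0.8, 200, 6
    aln = simulate_alignment(n_columns=n_cols, n_homologs=n_hom, identity=identity, seed=3)
    scores = [conservation_score(p, aln) for p in range(1, n_cols + 1)]
    mean = float(np.mean(scores))
    se = float(np.sqrt(identity * (1 - identity) / (n_cols * n_hom)))
    assert abs(mean - identity) < 3 * se


# -- recurrence ------------------------------------------------------------

def test_recurrence_top_row_is_the_hotspot(table1):
    rows = recurrence_report(table1)
    assert rows[0] == ("R684C", 4, 2)


def test_recurrence_all_unique_and_empty(table1):
    unique = [r for r in table1 if r.protein_change != "p.R684C"]
    assert all(n == 1 for _, n, _ in recurrence_report(unique))
    assert recurrence_report([]) == []
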