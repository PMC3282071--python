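import itertools
import math

import numpy as np
import pytest

from mendelseek.consequence import EditKind, HgvsEdit, parse_hgvs_c
from mendelseek.splice_consensus import (
    Mode,
    Pwm,
    SpliceScorer,
    Verdict,
    assess_variant,
    builtin_scorers,
    pct_change,
)
from mendelseek.transcript import CodingPosition

DELETION = "c.2196-15_2196-2delTTCCTGTTGTTTCA"


# -- pct change ------------------------------------------------------------

@pytest.mark.parametrize(
    "wt, var, expected",
    [(10.0, 7.9, -21.0), (10.0, 10.0, 0.0), (5.0, 6.5, 30.0)],
)
def test_pct_change_arithmetic(wt, var, expected):
    assert pct_change(wt, var) == pytest.approx(expected)


def test_pct_change_guards_zero_wildtype():
    assert math.isfinite(pct_change(0.0, 1.0))
    with pytest.raises(ValueError):
        pct_change(float("nan"), 1.0)


# -- PWM -------------------------------------------------------------------

def test_uniform_pwm_scores_zero_everywhere():
    pwm = Pwm(np.full((5, 4), 0.25))
    for w in ("AAAAA", "ACGTA", "GGGGG"):
        assert pwm.score(w) == pytest.approx(0.0)


def test_pwm_trained_on_one_sequence_maximises_it():
    # brute force over all 4^4 windows of length 4
    target = "GTAA"
    pwm = Pwm.train([target] * 50)
    best = max("".join(w) for w in itertools.product("ACGT", repeat=4))
    scores = {
        "".join(w): pwm.score("".join(w)) for w in itertools.product("ACGT", repeat=4)
    }
    assert max(scores, key=scores.get) == target


def test_gt_dominated_donor_prefers_gt_over_gc():
    seqs = ["AAGGTAAGT"] * 90 + ["AAGGCAAGT"] * 10
    pwm = Pwm.train(seqs)
    assert pwm.score("AAGGTAAGT") > pwm.score("AAGGCAAGT")


def test_pwm_rejects_bad_windows():
    pwm = Pwm.train(["ACGT"])
    with pytest.raises(ValueError):
        pwm.score("ACG")
    with pytest.raises(ValueError):
        pwm.score("ACGN")


# -- consensus procedure ---------------------------------------------------

def noop_edit(model, c=900):
    pos = CodingPosition(c)
    return HgvsEdit(EditKind.delins, pos, pos, inserted_bases=model.cds[c - 1])


def test_noop_edit_changes_nothing(model, scorers):
    v = assess_variant(noop_edit(model), model, scorers)
    assert not v.triggered and v.verdict == Verdict.not_disruptive
    assert all(s[2] == pytest.approx(0.0) for s in v.tier1_scores.values())


def test_acceptor_deletion_is_disruptive_wildtype_loss(model, scorers):
    v = assess_variant(parse_hgvs_c(DELETION), model, scorers)
    assert v.site_type == "acceptor"
    assert v.triggered and v.mode == Mode.wildtype_loss
    assert v.verdict == Verdict.disruptive
    assert v.tier2_scores is not None and len(v.tier2_scores) == 3
    assert all(s[2] < -20 for s in v.tier1_scores.values())


def test_exonic_substitution_far_from_sites_not_disruptive(model, scorers):
    # pick a substitution ~50 bases inside an exon (c.1980 sits mid-exon 18)
    ref = model.cds[1979]
    alt = "A" if ref != "A" else "G"
    v = assess_variant(parse_hgvs_c(f"c.1980{ref}>{alt}"), model, scorers)
    assert not v.triggered and v.verdict == Verdict.not_disruptive


def test_infinite_threshold_forces_not_disruptive(model, scorers):
    v = assess_variant(parse_hgvs_c(DELETION), model, scorers, threshold=float("inf"))
    assert not v.triggered and v.verdict == Verdict.not_disruptive


def test_zero_threshold_triggers_any_concordant_change(model, scorers):
    v = assess_variant(parse_hgvs_c(DELETION), model, scorers, threshold=0.0)
    assert v.triggered


def test_five_identical_scorers_trigger_implies_disruptive(model, scorers):
    clones = [scorers[0]] * 5
    v = assess_variant(parse_hgvs_c(DELETION), model, clones)
    assert v.triggered and v.verdict == Verdict.disruptive


def test_verdict_invariant_to_confirmatory_order(model, scorers):
    base = assess_variant(parse_hgvs_c(DELETION), model, scorers)
    for perm in itertools.permutations(scorers[2:]):
        v = assess_variant(parse_hgvs_c(DELETION), model, scorers[:2] + list(perm))
        assert v.verdict == base.verdict and v.triggered == base.triggered


class CountScorer:
    """Stub scorer: site strength = (signed) count of a base class."""

    def __init__(self, name, wanted):
        self.name = name
        self.wanted = wanted

    def score(self, window, site_type):
        return float(sum(1 for b in window if b in self.wanted))


def test_discordant_primary_directions_do_not_trigger(model):
    # the acceptor deletion removes pyrimidines: a pyrimidine-counting scorer
    # sees loss, a purine-counting scorer sees gain -> no concordant trigger
    pyr = CountScorer("pyr", "CT")
    pur = CountScorer("pur", "AG")
    v = assess_variant(parse_hgvs_c(DELETION), model, [pyr, pur, pyr, pur, pyr])
    assert not v.triggered and v.verdict == Verdict.not_disruptive


def test_scorer_training_is_deterministic():
    a = builtin_scorers(seed=5)
    b = builtin_scorers(seed=5)
    for sa, sb in zip(a, b):
        assert np.allclose(sa.matrices["donor"].freqs, sb.matrices["donor"].freqs)
        assert np.allclose(sa.matrices["acceptor"].freqs, sb.matrices["acceptor"].freqs)


def test_single_exon_model_has_no_assessable_site():
    from mendelseek.transcript import TranscriptModel

    m = TranscriptModel(
        chrom="c", strand="+", exons=[(0, 60)], cds="ATG" + "C" * 57,
        premrna="ATG" + "C" * 57, gene_start0=0,
    )
    with pytest.raises(ValueError, match="no assessable site"):
        assess_variant(noop_edit(m, c=30), m, builtin_scorers())
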