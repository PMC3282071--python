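import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mendelseek.filter_cascade import (
    FILTER_ORDER,
    FilterConfig,
    FilterReport,
    apply_filters,
    attrition_table,
)
from mendelseek.synthetic_data import SimulationConfig, simulate_cohort
from mendelseek.variant_io import ConsequenceLabel, VariantCall


def mk(depth=20, cls=None, rsid=None, gene="G1", pos=100, alt="T"):
    return VariantCall(
        sample_id="S1", chrom="chr1", pos=pos, ref="A", alt=alt, depth=depth,
        consequence_label=cls, dbsnp_id=rsid, gene_id=gene,
    )


def test_depth_boundary_at_least_15_reads():
    surv14, _ = apply_filters({mk(depth=14)})
    surv15, _ = apply_filters({mk(depth=15)})
    assert not surv14 and len(surv15) == 1


@pytest.mark.parametrize(
    "variant, removed_by",
    [
        (mk(cls=ConsequenceLabel.intronic), "class"),
        (mk(cls=ConsequenceLabel.synonymous), "class"),
        (mk(rsid="rs1"), "dbsnp"),
        (mk(gene="PSEUDO1"), "pseudogene"),
        (mk(pos=555), "panel"),
    ],
)
def test_each_filter_removes_its_target(variant, removed_by):
    cfg = FilterConfig(
        pseudogene_genes=frozenset({"PSEUDO1"}),
        panel_of_normals=frozenset({("chr1", 555, "A", "T")}),
    )
    surviving, report = apply_filters({variant}, cfg)
    assert not surviving
    removed = {name for name, _, n_rem, _ in report.rows if n_rem}
    assert removed == {removed_by}


def test_unannotated_variant_survives_class_filter():
    # absent consequence label is treated as 'other', never class-excluded
    surviving, _ = apply_filters({mk(cls=None)})
    assert len(surviving) == 1


def test_empty_input_gives_zero_report():
    surviving, report = apply_filters(set(), sample_id="S0")
    assert not surviving
    assert all(row[1:] == (0, 0, 0) for row in report.rows)


def brute_force_scan(variants, cfg):
    """Independent re-statement of the cascade as one boolean expression."""
    kept = set()
    for v in variants:
        if (
            v.depth >= cfg.min_depth
            and v.consequence_label not in cfg.excluded_classes
            and v.dbsnp_id is None
            and v.gene_id not in cfg.pseudogene_genes
            and v.key not in cfg.panel_of_normals
        ):
            kept.add(v)
    return kept


def test_cascade_matches_brute_force_scan_seed7():
    res = simulate_cohort(SimulationConfig(seed=7, n_background_variants=1000))
    cfg = FilterConfig()
    for sid, calls in res.affected.items():
        surviving, report = apply_filters(calls, cfg, sample_id=sid)
        assert surviving == brute_force_scan(calls, cfg)
        assert report.n_surviving == len(surviving)
        assert report.n_input == len(calls)


def test_predicate_order_independence(cohort11):
    calls = cohort11.affected["S1"]
    cfg = FilterConfig()
    surviving, _ = apply_filters(calls, cfg)
    # apply the same predicates in reverse order by hand
    pool = set(calls)
    for _, pred in reversed(cfg.predicates()):
        pool = {v for v in pool if pred(v)}
    assert pool == surviving


def test_idempotence(cohort11):
    surviving, _ = apply_filters(cohort11.affected["S3"])
    again, report = apply_filters(surviving)
    assert again == surviving
    assert all(n_rem == 0 for _, _, n_rem, _ in report.rows)


def test_monotonicity_in_depth_and_exclusions(cohort11):
    calls = cohort11.affected["S1"]
    lenient, _ = apply_filters(calls, FilterConfig(min_depth=5))
    strict, _ = apply_filters(calls, FilterConfig(min_depth=25))
    default, _ = apply_filters(calls, FilterConfig())
    assert strict <= default <= lenient
    some_gene = next(v.gene_id for v in default if v.gene_id)
    fewer, _ = apply_filters(
        calls, FilterConfig(pseudogene_genes=frozenset({some_gene}))
    )
    assert fewer < default


def test_attrition_table_consistency(cohort11):
    reports = [
        apply_filters(calls, sample_id=sid)[1]
        for sid, calls in sorted(cohort11.affected.items())
    ]
    text = attrition_table(reports)
    lines = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    for rep in reports:
        total = [ln for ln in lines if ln[0] == rep.sample_id and ln[1] == "total"]
        assert int(total[0][4]) == rep.n_surviving
    # inconsistent order rejected
    broken = FilterReport(sample_id="X", rows=[("panel", 0, 0, 0)])
    with pytest.raises(ValueError, match="filter order"):
        attrition_table([reports[0], broken])


variant_st = st.builds(
    mk,
    depth=st.integers(0, 60),
    cls=st.sampled_from([None, *ConsequenceLabel]),
    rsid=st.sampled_from([None, "rs1", "rs2"]),
    gene=st.sampled_from(["G1", "G2", "PSEUDO1"]),
    pos=st.integers(1, 500),
    alt=st.sampled_from(["T", "G", "C"]),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    variants=st.lists(variant_st, max_size=40).map(
        lambda vs: {v.key: v for v in vs}.values()  # unique keys per sample
    ),
    d_lo=st.integers(0, 20),
    d_hi=st.integers(20, 60),
)
def test_surviving_set_monotone_in_min_depth(variants, d_lo, d_hi):
    variants = set(variants)
    lo, _ = apply_filters(variants, FilterConfig(min_depth=d_lo), sample_id="S")
    hi, _ = apply_filters(variants, FilterConfig(min_depth=d_hi), sample_id="S")
    assert hi <= lo
    assert lo == brute_force_scan(variants, FilterConfig(min_depth=d_lo))


def test_report_rows_are_arithmetically_consistent(cohort11):
    _, report = apply_filters(cohort11.affected["S4"])
    assert [name for name, *_ in report.rows] == list(FILTER_ORDER)
    for name, before, removed, after in report.rows:
        assert after == before - removed
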