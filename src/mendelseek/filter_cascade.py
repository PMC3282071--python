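"""Variant-prioritisation filter cascade.

Five pure per-variant predicates, applied in a fixed reporting order:

1. ``depth``      — keep variants covered by at least ``min_depth`` reads;
2. ``class``      — drop excluded consequence classes (intronic, synonymous);
3. ``dbsnp``      — drop anything carrying a dbSNP id (known polymorphism);
4. ``pseudogene`` — drop variants in known pseudogenes;
5. ``panel``      — drop variant keys seen in the in-house panel of normals.

Because each predicate depends on one variant only, the surviving set is
order-independent; the ordered :class:`FilterReport` merely attributes each
removal to the first filter that rejects it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .variant_io import ConsequenceLabel, VariantCall

__all__ = ["FilterConfig", "FilterReport", "apply_filters", "attrition_table", "variant_key_str"]

FILTER_ORDER = ("depth", "class", "dbsnp", "pseudogene", "panel")


def variant_key_str(v: VariantCall) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 15
    excluded_classes: frozenset[ConsequenceLabel] = frozenset(
        {ConsequenceLabel.intronic, ConsequenceLabel.synonymous}
    )
    known_snp_ids: frozenset[str] = frozenset()
    pseudogene_genes: frozenset[str] = frozenset()
    panel_of_normals: frozenset[tuple[str, int, str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        bad = set(self.excluded_classes) - set(ConsequenceLabel)
        if bad:
            raise ValueError(f"unknown consequence classes {bad}")

    # -- predicates (True = variant survives) --------------------------------

    def pass_depth(self, v: VariantCall) -> bool:
        return v.depth >= self.min_depth

    def pass_class(self, v: VariantCall) -> bool:
        # absent labels are treated as 'other': never excluded by class
        return v.consequence_label not in self.excluded_classes

    def pass_dbsnp(self, v: VariantCall) -> bool:
        # any dbSNP id present excludes; the id set additionally excludes
        # variants matched by id when a lookup list is supplied
        if v.dbsnp_id is not None:
            return False
        return variant_key_str(v) not in self.known_snp_ids

    def pass_pseudogene(self, v: VariantCall) -> bool:
        return v.gene_id not in self.pseudogene_genes

    def pass_panel(self, v: VariantCall) -> bool:
        return v.key not in self.panel_of_normals

    def predicates(self):
        return (
            ("depth", self.pass_depth),
            ("class", self.pass_class),
            ("dbsnp", self.pass_dbsnp),
            ("pseudogene", self.pass_pseudogene),
            ("panel", self.pass_panel),
        )

    def passes_all(self, v: VariantCall) -> bool:
        return all(pred(v) for _, pred in self.predicates())


@dataclass
class FilterReport:
    sample_id: str
    rows: list[tuple[str, int, int, int]] = field(default_factory=list)
    # rows of (filter_name, n_before, n_removed, n_after)

    def __post_init__(self) -> None:
        for name, before, removed, after in self.rows:
            if after != before - removed:
                raise ValueError(f"inconsistent attrition row for filter {name!r}")

    @property
    def n_input(self) -> int:
        return self.rows[0][1] if self.rows else 0

    @property
    def n_surviving(self) -> int:
        return self.rows[-1][3] if self.rows else 0


def apply_filters(
    variants: set[VariantCall] | list[VariantCall],
    config: FilterConfig | None = None,
    sample_id: str | None = None,
) -> tuple[set[VariantCall], FilterReport]:
    """Apply the cascade; return survivors and the per-filter attrition report."""
    config = config or FilterConfig()
    pool = set(variants)
    if sample_id is None:
        sample_id = next(iter(pool)).sample_id if pool else "-"
    rows = []
    for name, pred in config.predicates():
        before = len(pool)
        pool = {v for v in pool if pred(v)}
        rows.append((name, before, before - len(pool), len(pool)))
    return pool, FilterReport(sample_id=sample_id, rows=rows)


def attrition_table(reports: list[FilterReport]) -> str:
    """Render per-sample attrition as TSV, one row per (sample, filter) plus totals."""
    orders = {tuple(name for name, *_ in r.rows) for r in reports}
    if len(orders) > 1:
        raise ValueError(f"reports disagree on filter order: {orders}")
    buf = io.StringIO()
    buf.write("sample_id\tfilter\tn_before\tn_removed\tn_after\n")
    for r in reports:
        for name, before, removed, after in r.rows:
            buf.write(f"{r.sample_id}\t{name}\t{before}\t{removed}\t{after}\n")
        buf.write(f"{r.sample_id}\ttotal\t{r.n_input}\t{r.n_input - r.n_surviving}\t{r.n_surviving}\n")
    return buf.getvalue()
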