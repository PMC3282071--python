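"""HGVS coding-variant parsing and consequence classification.

Parses the ``c.`` descriptions used in clinical mutation tables
(substitutions, deletions, duplications, insertions, delins; intronic offsets
allowed), maps them through a :class:`~mendelseek.transcript.TranscriptModel`,
and annotates each call with:

* consequence class (missense / nonsense / synonymous / frameshift /
  inframe_indel / splice_region / intronic),
* the protein change for substitutions (``p.R684C`` style, ``X`` for stop),
* protein-domain membership,
* CpG dinucleotide context (C>T at CpG and its reverse-strand mirror G>A are
  the classic deamination hotspots behind recurrent mutations),
* conservation of the affected residue across a homolog alignment,
* the last-exon rule for escape from nonsense-mediated decay (NMD): a
  truncating change confined to the final exon leaves no downstream
  exon-junction complex, so the transcript is predicted to persist.

"Truncating" means nonsense, frameshift, or a splice-region deletion that
removes part of the essential splice window (acceptor -12..-1 / donor +1..+6),
ablating the site.
"""

from __future__ import annotations

import enum
import re
from collections import defaultdict
from dataclasses import dataclass

from .transcript import CodingPosition, Domain, TranscriptModel, STANDARD_TABLE
from .variant_io import ConsequenceLabel, Inheritance, PhenotypeRecord

__all__ = [
    "EditKind",
    "HgvsEdit",
    "ConsequenceCall",
    "HgvsParseError",
    "parse_hgvs_c",
    "classify",
    "is_truncating",
    "annotate_domain",
    "cpg_context",
    "conservation_score",
    "recurrence_report",
]

# splice windows (intron offsets relative to the exon boundary)
SPLICE_REGION_WINDOW = 15        # |offset| <= 15 -> splice_region class
ACCEPTOR_ABLATION = (-12, -1)    # deleting any of these offsets kills the 3'ss
DONOR_ABLATION = (1, 6)          # ... or these, the 5'ss


class EditKind(enum.StrEnum):
    substitution = "substitution"
    deletion = "deletion"
    duplication = "duplication"
    insertion = "insertion"
    delins = "delins"


class HgvsParseError(ValueError):
    """Unsupported or inconsistent HGVS description."""


@dataclass(frozen=True)
class HgvsEdit:
    kind: EditKind
    start: CodingPosition
    end: CodingPosition
    ref_bases: str | None = None       # bases removed/substituted, as given
    inserted_bases: str | None = None  # bases added (alt for substitutions)

    @property
    def span(self) -> int:
        """Number of reference positions covered by the edit."""
        return (self.end.base + self.end.offset) - (self.start.base + self.start.offset) + 1

    @property
    def net_length_change(self) -> int:
        if self.kind == EditKind.substitution:
            return 0
        if self.kind == EditKind.deletion:
            return -self.span
        if self.kind == EditKind.duplication:
            return self.span
        if self.kind == EditKind.insertion:
            return len(self.inserted_bases or "")
        return len(self.inserted_bases or "") - self.span

    @property
    def is_intronic(self) -> bool:
        return self.start.is_intronic or self.end.is_intronic

    def __str__(self) -> str:
        if self.kind == EditKind.substitution:
            return f"c.{self.start}{self.ref_bases}>{self.inserted_bases}"
        span = str(self.start) if self.start == self.end else f"{self.start}_{self.end}"
        if self.kind == EditKind.deletion:
            return f"c.{span}del{self.ref_bases or ''}"
        if self.kind == EditKind.duplication:
            return f"c.{span}dup{self.ref_bases or ''}"
        if self.kind == EditKind.insertion:
            return f"c.{span}ins{self.inserted_bases}"
        return f"c.{span}delins{self.inserted_bases}"


@dataclass(frozen=True)
class ConsequenceCall:
    hgvs_c: str
    consequence_class: ConsequenceLabel
    protein_change: str | None = None
    exon_number: int | None = None
    in_last_exon: bool = False
    nmd_escape: bool = False
    domain_hit: str | None = None
    cpg_site: bool = False
    conservation: float | None = None
    truncating: bool = False


_POS = r"(\d+)([+-]\d+)?"
_SUB_RE = re.compile(rf"^c\.{_POS}([ACGT])>([ACGT])$", re.I)
_DUPDEL_RE = re.compile(rf"^c\.{_POS}(?:_{_POS})?(dup|del)([ACGT]+)?$", re.I)
_INS_RE = re.compile(rf"^c\.{_POS}_{_POS}(delins|ins)([ACGT]+)$", re.I)


def _cpos(base: str, off: str | None) -> CodingPosition:
    return CodingPosition(int(base), int(off) if off else 0)


def parse_hgvs_c(text: str) -> HgvsEdit:
    """Parse a coding-DNA HGVS description into a structured edit.

    Supported forms: ``c.2050C>T``, ``c.2204_2211dupAGGCTGAT``,
    ``c.2230_2232dupATC``, ``c.2196-15_2196-2delTTCCTGTTGTTTCA``,
    ``c.100_101insA``, ``c.100_102delinsTT``.  Anything else (inversions,
    protein-level, genomic-level) raises :class:`HgvsParseError`.
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        pos = _cpos(m.group(1), m.group(2))
        ref, alt = m.group(3).upper(), m.group(4).upper()
        if ref == alt:
            raise HgvsParseError(f"{text}: ref and alt are identical")
        return HgvsEdit(EditKind.substitution, pos, pos, ref, alt)
    m = _DUPDEL_RE.match(text)
    if m:
        start = _cpos(m.group(1), m.group(2))
        end = _cpos(m.group(3), m.group(4)) if m.group(3) else start
        kind = EditKind.duplication if m.group(5).lower() == "dup" else EditKind.deletion
        bases = m.group(6).upper() if m.group(6) else None
        edit = HgvsEdit(kind, start, end, ref_bases=bases)
        if edit.span < 1:
            raise HgvsParseError(f"{text}: end position precedes start")
        if bases is not None and len(bases) != edit.span:
            raise HgvsParseError(
                f"{text}: span {edit.span} does not match {len(bases)} given bases"
            )
        return edit
    m = _INS_RE.match(text)
    if m:
        start = _cpos(m.group(1), m.group(2))
        end = _cpos(m.group(3), m.group(4))
        bases = m.group(6).upper()
        if m.group(5).lower() == "ins":
            if (end.base + end.offset) - (start.base + start.offset) != 1:
                raise HgvsParseError(f"{text}: insertion flanks must be adjacent")
            return HgvsEdit(EditKind.insertion, start, end, inserted_bases=bases)
        edit = HgvsEdit(EditKind.delins, start, end, inserted_bases=bases)
        if edit.span < 1:
            raise HgvsParseError(f"{text}: end position precedes start")
        return edit
    raise HgvsParseError(f"unsupported HGVS description: {text!r}")


# --------------------------------------------------------------------------
# annotation helpers
# --------------------------------------------------------------------------

def annotate_domain(
    protein_position: int, domain_table: list[Domain] | list[tuple[str, int, int]]
) -> str | None:
    """Name of the protein domain containing a residue (inclusive ends)."""
    doms = [
        d if isinstance(d, Domain) else Domain(*d)
        for d in domain_table
    ]
    prev_end = 0
    for d in sorted(doms, key=lambda d: d.aa_start):
        if d.aa_start <= prev_end:
            raise ValueError(f"overlapping domain rows near {d.name}")
        prev_end = d.aa_end
    for d in doms:
        if d.aa_start <= protein_position <= d.aa_end:
            return d.name
    return None


def cpg_context(edit: HgvsEdit, seq_with_flanks: str, index: int | None = None) -> bool:
    """Whether a substitution's reference base sits in a CpG dinucleotide.

    True iff (ref is C and the next base is G) or (ref is G and the previous
    base is C) — the two strands of the same methylatable CpG.  ``index`` is
    the 0-based position of the substituted base in ``seq_with_flanks``
    (defaults to the coding position against a bare CDS).
    """
    if edit.kind != EditKind.substitution:
        raise ValueError("cpg_context is defined for substitutions only")
    if index is None:
        index = edit.start.base - 1
    seq = seq_with_flanks.upper()
    ref = (edit.ref_bases or "").upper()
    if ref == "C":
        return index + 1 < len(seq) and seq[index + 1] == "G"
    if ref == "G":
        return index - 1 >= 0 and seq[index - 1] == "C"
    return False


def conservation_score(
    protein_position: int, alignment: list[tuple[str, str]]
) -> float:
    """Fraction of non-gap homolog residues identical to the human residue.

    The human sequence is the first alignment row; ``protein_position`` is
    1-based in the ungapped human sequence and is mapped to its alignment
    column by skipping human gaps.
    """
    if not alignment:
        raise ValueError("empty alignment")
    human = alignment[0][1]
    seen = 0
    column = None
    for i, ch in enumerate(human):
        if ch != "-":
            seen += 1
            if seen == protein_position:
                column = i
                break
    if column is None:
        raise ValueError(
            f"protein position {protein_position} beyond human sequence length {seen}"
        )
    ref_aa = human[column]
    others = [s[column] for _, s in alignment[1:] if s[column] != "-"]
    if not others:
        return 0.0
    return sum(1 for a in others if a == ref_aa) / len(others)


def _splice_window_hit(edit: HgvsEdit, window: int = SPLICE_REGION_WINDOW) -> bool:
    offs = [p.offset for p in (edit.start, edit.end) if p.offset != 0]
    return any(abs(o) <= window for o in offs) or (
        # a deletion spanning from deep intron across the window
        edit.start.offset != 0 and edit.end.offset != 0
        and edit.start.offset < -window < edit.end.offset <= -1
    )


def is_truncating(edit: HgvsEdit, call_class: ConsequenceLabel) -> bool:
    """Nonsense, frameshift, or a splice-region deletion ablating a site."""
    if call_class in (ConsequenceLabel.nonsense, ConsequenceLabel.frameshift):
        return True
    if call_class != ConsequenceLabel.splice_region or edit.kind != EditKind.deletion:
        return False
    lo, hi = edit.start.offset, edit.end.offset
    if lo == 0 and hi == 0:
        return False
    a_lo, a_hi = ACCEPTOR_ABLATION
    d_lo, d_hi = DONOR_ABLATION
    deleted = set(range(lo, hi + 1))
    return bool(
        deleted & set(range(a_lo, a_hi + 1)) or deleted & set(range(d_lo, d_hi + 1))
    )


# --------------------------------------------------------------------------
# classification
# --------------------------------------------------------------------------

def classify(
    edit: HgvsEdit,
    model: TranscriptModel,
    alignment: list[tuple[str, str]] | None = None,
) -> ConsequenceCall:
    """Classify one HGVS edit against a transcript model.

    Substitutions are translated before/after; exonic indels are frameshift
    unless the net length change is a multiple of 3; edits with intronic
    offsets are splice_region within 15 bases of an exon boundary and
    intronic beyond.  NMD escape is granted to truncating changes confined
    to (or ablating the acceptor of) the last exon.
    """
    # anchor exon / last-exon status
    for p in (edit.start, edit.end):
        model._check_coding(p.base)
    exon_start = model.exon_number_of_coding(edit.start.base)
    exon_end = model.exon_number_of_coding(edit.end.base)
    in_last = exon_start == exon_end == model.last_exon_number

    protein_change: str | None = None
    domain_hit: str | None = None
    cpg = False
    conservation: float | None = None
    protein_pos: int | None = None

    if edit.is_intronic:
        cls = (
            ConsequenceLabel.splice_region
            if _splice_window_hit(edit)
            else ConsequenceLabel.intronic
        )
    elif edit.kind == EditKind.substitution:
        c = edit.start.base
        codon_n = (c - 1) // 3 + 1
        within = (c - 1) % 3
        codon = model.codon(codon_n)
        assert edit.ref_bases and edit.inserted_bases
        if codon[within] != edit.ref_bases:
            raise ValueError(
                f"{edit}: reference base {edit.ref_bases} does not match "
                f"transcript base {codon[within]} at c.{c}"
            )
        mutated = codon[:within] + edit.inserted_bases + codon[within + 1:]
        aa_ref = STANDARD_TABLE[codon]
        aa_alt = STANDARD_TABLE[mutated]
        protein_pos = codon_n
        if aa_alt == aa_ref:
            cls = ConsequenceLabel.synonymous
            protein_change = f"p.{aa_ref}{codon_n}="
        elif aa_alt == "*":
            cls = ConsequenceLabel.nonsense
            protein_change = f"p.{aa_ref}{codon_n}X"
        else:
            cls = ConsequenceLabel.missense
            protein_change = f"p.{aa_ref}{codon_n}{aa_alt}"
        seq, idx = model.cds, c - 1
        if model.premrna is not None:
            seq, idx = model.premrna, model.premrna_index_of_coding(edit.start)
        cpg = cpg_context(edit, seq, idx)
    else:
        # exonic indel; validate given bases against the CDS where possible
        if edit.ref_bases is not None and edit.kind in (
            EditKind.deletion, EditKind.duplication
        ):
            lo = edit.start.base - 1
            have = model.cds[lo : lo + edit.span]
            if have != edit.ref_bases:
                raise ValueError(
                    f"{edit}: given bases {edit.ref_bases} do not match "
                    f"transcript bases {have}"
                )
        cls = (
            ConsequenceLabel.inframe_indel
            if edit.net_length_change % 3 == 0
            else ConsequenceLabel.frameshift
        )
        protein_pos = (edit.start.base - 1) // 3 + 1

    truncating = is_truncating(edit, cls)
    if protein_pos is not None and model.domains:
        domain_hit = annotate_domain(protein_pos, model.domains)
    if protein_pos is not None and alignment is not None:
        conservation = conservation_score(protein_pos, alignment)

    return ConsequenceCall(
        hgvs_c=str(edit),
        consequence_class=cls,
        protein_change=protein_change,
        exon_number=exon_start,
        in_last_exon=in_last,
        nmd_escape=truncating and in_last,
        domain_hit=domain_hit,
        cpg_site=cpg,
        conservation=conservation,
        truncating=truncating,
    )


# --------------------------------------------------------------------------
# recurrence
# --------------------------------------------------------------------------

def recurrence_report(
    records: list[PhenotypeRecord],
) -> list[tuple[str, int, int]]:
    """Group cases by protein change (fallback: coding HGVS) and count.

    Returns (label, n_cases, n_de_novo) sorted by descending case count then
    label — the top row of a cohort with a mutational hotspot is the
    recurrent change.
    """
    groups: dict[str, list[PhenotypeRecord]] = defaultdict(list)
    for rec in records:
        label = rec.protein_change or rec.hgvs_c
        label = label.removeprefix("p.")
        groups[label].append(rec)
    rows = [
        (
            label,
            len(recs),
            sum(1 for r in recs if r.inheritance == Inheritance.de_novo),
        )
        for label, recs in groups.items()
    ]
    return sorted(rows, key=lambda r: (-r[1], r[0]))
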