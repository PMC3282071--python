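"""The discovery engine: cross-case gene intersection and trio confirmation.

In a dominant/de-novo rare-disease design, the causal gene is expected to
carry a qualifying variant in *every* affected, unrelated case — not the same
variant, just the same gene.  After the filter cascade, the candidate list is
the intersection of per-case hit-gene sets; with enough unrelated cases the
background intersects away and a single gene remains.

De novo status is then confirmed against parental samples: a variant is de
novo only when *both* parents demonstrably lack it (absent call AND adequate
site coverage); a missing parent or thin coverage leaves the call unresolved,
never de novo.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .variant_io import CohortManifest, Genotype, VariantCall

log = logging.getLogger(__name__)

__all__ = [
    "GeneHitMatrix",
    "InheritanceVerdict",
    "ParentEvidence",
    "InheritanceCall",
    "intersect_genes",
    "confirm_de_novo",
    "segregation_check",
]


@dataclass
class GeneHitMatrix:
    genes: list[str]
    samples: list[str]
    hits: list[list[bool]]  # [gene][sample]
    variant_index: dict[str, dict[str, list[tuple[str, int, str, str]]]]

    def __post_init__(self) -> None:
        for gi, g in enumerate(self.genes):
            for si, s in enumerate(self.samples):
                nonempty = bool(self.variant_index.get(g, {}).get(s))
                if self.hits[gi][si] != nonempty:
                    raise ValueError(f"hit matrix inconsistent at ({g}, {s})")


class InheritanceVerdict(enum.StrEnum):
    de_novo = "de_novo"
    inherited = "inherited"
    unresolved = "unresolved"


class ParentEvidence(enum.StrEnum):
    present = "present"
    absent = "absent"
    insufficient_depth = "insufficient_depth"
    missing = "missing"


@dataclass(frozen=True)
class InheritanceCall:
    variant_key: tuple[str, int, str, str]
    child_sample_id: str
    verdict: InheritanceVerdict
    parent_evidence: dict[str, ParentEvidence] = field(hash=False, default_factory=dict)


def intersect_genes(
    filtered: dict[str, set[VariantCall]],
    manifest: CohortManifest,
) -> tuple[GeneHitMatrix, list[str]]:
    """Genes with >=1 surviving variant in every affected sample.

    Variants without a gene id cannot participate and are counted in the log.
    Returns the full hit matrix over the union of hit genes plus the
    lexicographically sorted candidate list.
    """
    affected = [s for s in manifest.affected_ids if s in filtered]
    if not affected:
        raise ValueError("no affected samples with variant data")
    index: dict[str, dict[str, list]] = {}
    n_ungened = 0
    for sid in affected:
        for v in filtered[sid]:
            if v.gene_id is None:
                n_ungened += 1
                continue
            index.setdefault(v.gene_id, {}).setdefault(sid, []).append(v.key)
    if n_ungened:
        log.info("%d variants without gene_id ignored in intersection", n_ungened)
    genes = sorted(index)
    hits = [[bool(index[g].get(s)) for s in affected] for g in genes]
    matrix = GeneHitMatrix(genes=genes, samples=affected, hits=hits, variant_index=index)
    candidates = sorted(g for g in genes if all(index[g].get(s) for s in affected))
    return matrix, candidates


def confirm_de_novo(
    child_variants: list[VariantCall] | set[VariantCall],
    parent_calls: dict[str, set[VariantCall] | None],
    min_parent_depth: int = 15,
) -> list[InheritanceCall]:
    """Confirm de novo status of child variants against parental samples.

    ``parent_calls`` maps a parent label (e.g. ``mother``/``father``) to that
    parent's call set, or ``None`` when the sample is unavailable.  A parent
    VCF may include homozygous-reference records at sites of interest; these
    carry the coverage evidence needed to declare a variant *absent* (no
    carrier call at the key AND site depth >= ``min_parent_depth``).

    Verdicts: both parents absent -> de_novo; carried by either -> inherited;
    anything else (missing parent, thin coverage) -> unresolved.
    """
    indexed: dict[str, tuple[set, dict]] = {}
    for label, calls in parent_calls.items():
        if calls is None:
            continue
        carried = {
            v.key for v in calls if v.genotype in (Genotype.het, Genotype.hom_alt)
        }
        site_depth: dict[tuple[str, int], int] = {}
        for v in calls:
            site = (v.chrom, v.pos)
            site_depth[site] = max(site_depth.get(site, 0), v.depth)
        indexed[label] = (carried, site_depth)

    out = []
    for v in sorted(child_variants, key=lambda v: v.key):
        evidence: dict[str, ParentEvidence] = {}
        for label in sorted(parent_calls):
            if parent_calls[label] is None:
                evidence[label] = ParentEvidence.missing
                log.info("parent %s missing for %s; %s unresolved", label, v.sample_id, v.key)
                continue
            carried, site_depth = indexed[label]
            if v.key in carried:
                evidence[label] = ParentEvidence.present
            elif site_depth.get((v.chrom, v.pos), 0) >= min_parent_depth:
                evidence[label] = ParentEvidence.absent
            else:
                evidence[label] = ParentEvidence.insufficient_depth
        if any(e == ParentEvidence.present for e in evidence.values()):
            verdict = InheritanceVerdict.inherited
        elif (
            len(evidence) >= 2
            and all(e == ParentEvidence.absent for e in evidence.values())
        ):
            verdict = InheritanceVerdict.de_novo
        else:
            verdict = InheritanceVerdict.unresolved
        out.append(
            InheritanceCall(
                variant_key=v.key,
                child_sample_id=v.sample_id,
                verdict=verdict,
                parent_evidence=evidence,
            )
        )
    return out


def segregation_check(
    presence: dict[str, bool], affected: dict[str, bool]
) -> str:
    """Does the variant co-segregate with the phenotype in one family?

    Co-segregation means carrier status equals affection status for every
    family member with known status (vacuously true for an all-negative
    family).  Requires >=2 members.
    """
    members = sorted(set(presence) & set(affected))
    if len(members) < 2:
        raise ValueError("segregation check needs at least 2 family members")
    ok = all(presence[m] == affected[m] for m in members)
    return "co_segregates" if ok else "does_not_segregate"
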