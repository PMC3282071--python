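"""Deterministic generators for every input the pipeline consumes.

Everything here is synthetic and seeded: exome-style variant cohorts with a
planted causal gene, parental genotypes, a population control panel, the
constraint-built transcript fixture (an EZH2-like 20-exon gene on which every
bundled mutation-table claim holds by construction), splice-site training
sequences for the built-in PWM scorers, homolog alignments, and a
schema-compatible synthetic growth reference.

The cohort generator *enforces* the unique-causal-gene property: variants
that would survive the filter cascade are assigned only to genes that are
blocked in at least one other affected sample, so no background gene can
carry a surviving variant in every case.  This makes discovery deterministic;
pass ``enforce_unique_causal=False`` for honest stochastic backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import consequence
from .filter_cascade import FilterConfig
from .phenotype_stats import GrowthReference, ReferenceRow
from .transcript import Domain, TranscriptModel, STANDARD_TABLE
from .variant_io import (
    CohortManifest,
    ConsequenceLabel,
    Genotype,
    ManifestEntry,
    VariantCall,
    write_manifest,
    write_variant_file,
)

__all__ = [
    "SimulationConfig",
    "CohortResult",
    "FixtureConstraintError",
    "build_transcript_fixture",
    "fixture_alignment",
    "simulate_alignment",
    "simulate_site_training",
    "simulate_cohort",
    "simulate_controls",
    "make_growth_reference",
]

# the four mutations carried by the exome-sequenced index cases
DISCOVERY_MUTATIONS = (
    "c.836A>G",                  # missense
    "c.2050C>T",                 # missense at the CpG hotspot
    "c.2199C>G",                 # nonsense, last exon
    "c.2204_2211dupAGGCTGAT",    # frameshifting duplication, last exon
)

_BASES = "ACGT"
_BG_CONTIG = "chrSim"
_PLANTED_OFFSET = 60_000_000   # planted-gene locus window on chrSim
_BG_SPAN = 50_000_000
_FIXTURE_SEED = 20_110_001     # fixed: the fixture is one object, not per-run


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 11
    n_affected: int = 4
    n_background_variants: int = 5000
    fraction_dbsnp: float = 0.4
    fraction_low_depth: float = 0.1
    fraction_excluded_class: float = 0.2
    fraction_multiallelic: float = 0.001
    n_genes: int = 1000
    planted_gene: str = "GENE_CAUSAL"
    planted_mutations: tuple[str, ...] = DISCOVERY_MUTATIONS
    n_controls: int = 115
    # (mother available, father available) per affected; default mirrors a
    # 4-trio cohort with one father unsampled (7 of 8 parents)
    parent_availability: tuple[tuple[bool, bool], ...] = (
        (True, True), (True, True), (True, True), (True, False),
    )
    depth_mean: float = 60.0
    depth_dispersion: float = 5.0
    enforce_unique_causal: bool = True

    def __post_init__(self) -> None:
        for f in (
            self.fraction_dbsnp, self.fraction_low_depth,
            self.fraction_excluded_class, self.fraction_multiallelic,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_affected < 1:
            raise ValueError("need at least one affected sample")
        # with one affected sample there is nothing to intersect away, so
        # enforcement is vacuous; otherwise every sample needs at least one
        # background gene it is blocked from sharing with the full cohort
        if self.enforce_unique_causal and self.n_affected > 1:
            for i in range(self.n_affected):
                if not any(
                    g % self.n_affected != i for g in range(self.n_genes)
                ):
                    raise ValueError(
                        "n_genes too small to keep background genes out of "
                        "the full intersection"
                    )


@dataclass(frozen=True)
class PlantedVariant:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    hgvs_c: str
    gene_id: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class CohortResult:
    manifest: CohortManifest
    affected: dict[str, set[VariantCall]]
    parents: dict[str, set[VariantCall] | None]  # "<sid>_mother"/"<sid>_father"
    truth: list[PlantedVariant]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_manifest(self.manifest, out / "manifest.tsv")
        for sid, calls in self.affected.items():
            write_variant_file(calls, out / f"{sid}.vcf", sid)
        for pid, calls in self.parents.items():
            if calls is not None:
                write_variant_file(calls, out / f"{pid}.vcf", pid)
        with open(out / "truth.tsv", "w") as fh:
            fh.write("sample_id\tchrom\tpos\tref\talt\thgvs_c\tgene_id\n")
            for t in self.truth:
                fh.write(
                    f"{t.sample_id}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}"
                    f"\t{t.hgvs_c}\t{t.gene_id}\n"
                )


# ==========================================================================
# transcript fixture
# ==========================================================================

class FixtureConstraintError(AssertionError):
    """The constraint-built fixture violates a mutation-table claim."""


# codons pinned so that every bundled Table-1 mutation behaves as printed
_PINNED_CODONS = {
    1: "ATG",     # start
    134: "ATG",   # M134T via c.401T>C
    156: "AAG",   # K156E via c.466A>G
    279: "CAT",   # H279R via c.836A>G
    626: "GTG",   # V626M via c.1876G>A
    639: "AAG",   # K639E via c.1915A>G
    663: "TAC",   # Y663N via c.1987T>A
    664: "GAT",   # D664V via c.1991A>T
    682: "GCT",   # A682T via c.2044G>A
    684: "CGC",   # R684C via c.2050C>T (CpG: C2050 followed by G2051)
    695: "TCA",   # S695L via c.2084C>T
    733: "TAC",   # Y733X via c.2199C>G
    735: "AAG",   # bases 2204-2205 = A,G (head of the 8-bp duplication)
    736: "GCT",   # bases 2206-2208
    737: "GAT",   # bases 2209-2211 (tail of dup = ...GAT -> AGGCTGAT)
    741: "TAC",   # Y741C via c.2222A>G
    744: "ATC",   # the in-frame dupATC unit
    745: "GAA",   # E745K via c.2233G>A
    747: "TAA",   # stop
}
_N_CODONS = 747                  # 746 residues + stop; CDS = 2241 nt
_UTR5, _UTR3 = 100, 200
_INTRON_LEN = 200
_ACCEPTOR19_TAIL = "TCTT" + "C" + "TTCCTGTTGTTTCA" + "G"  # -20..-1 of intron 19
_DOMAINS = [Domain("SET", 612, 727), Domain("post-SET", 728, 746)]

_NONSTOP = [c for c, aa in STANDARD_TABLE.items() if aa != "*"]


def _build_cds(rng: np.random.Generator) -> str:
    codons = []
    for n in range(1, _N_CODONS + 1):
        codons.append(_PINNED_CODONS.get(n) or _NONSTOP[rng.integers(len(_NONSTOP))])
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int, probs=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(list(_BASES), size=n, p=list(probs)))


def _intron(rng: np.random.Generator, special_tail: str | None = None) -> str:
    # GT donor head, purine-biased interior, pyrimidine tract + AG acceptor
    tail = special_tail or (
        _random_seq(rng, 15, (0.07, 0.40, 0.07, 0.46)) + "TCCAG"
    )
    head = "GTAAGT"
    interior = _random_seq(rng, _INTRON_LEN - len(head) - len(tail), (0.35, 0.15, 0.35, 0.15))
    return head + interior + tail


def build_transcript_fixture(
    out_dir: str | Path | None = None,
) -> tuple[TranscriptModel, list[str]]:
    """Construct the EZH2-like 20-exon fixture and verify every table claim.

    The gene has one non-coding first exon, 19 coding exons, a SET domain at
    residues 612-727 and a post-SET domain at 728-746; intron 19 ends in the
    pyrimidine tract the bundled 14-bp intronic deletion removes.  Every
    bundled mutation is classified against the model and checked against its
    printed protein change; any violation raises
    :class:`FixtureConstraintError` rather than shipping a wrong fixture.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    cds = _build_cds(rng)

    # coding bases per exon: exons 2-18 carry 120 each, exon 19 carries
    # c.2041-2195, exon 20 the final 46 coding bases plus the 3' UTR
    coding_per_exon = [0] + [120] * 17 + [155, 46]
    assert sum(coding_per_exon) == len(cds)

    pieces: list[str] = []
    exon_bounds_pm: list[tuple[int, int]] = []
    cursor = 0
    consumed = 0
    for exon_no in range(1, 21):
        exon_seq = ""
        if exon_no == 1:
            exon_seq = _random_seq(rng, _UTR5)
        n_coding = coding_per_exon[exon_no - 1]
        exon_seq += cds[consumed : consumed + n_coding]
        consumed += n_coding
        if exon_no == 20:
            exon_seq += _random_seq(rng, _UTR3)
        pieces.append(exon_seq)
        exon_bounds_pm.append((cursor, cursor + len(exon_seq)))
        cursor += len(exon_seq)
        if exon_no < 20:
            intron = _intron(rng, _ACCEPTOR19_TAIL if exon_no == 19 else None)
            pieces.append(intron)
            cursor += len(intron)
    premrna = "".join(pieces)

    gene_start0 = 1_000_000  # genomic 1-based start 1,000,001 on chrSim
    exons = [(gene_start0 + s, gene_start0 + e) for s, e in exon_bounds_pm]
    model = TranscriptModel(
        chrom=_BG_CONTIG,
        strand="+",
        exons=exons,
        cds=cds,
        utr5_len=_UTR5,
        domains=list(_DOMAINS),
        premrna=premrna,
        gene_start0=gene_start0,
        gene_id="EZH2LIKE",
    )

    report = _check_fixture(model)
    if out_dir is not None:
        _write_fixture(model, report, Path(out_dir))
    return model, report


def _check_fixture(model: TranscriptModel) -> list[str]:
    from .variant_io import load_table1  # deferred: cheap, avoids cycles

    report: list[str] = []

    def check(cond: bool, msg: str) -> None:
        if not cond:
            raise FixtureConstraintError(msg)
        report.append(f"OK {msg}")

    check(model.n_exons == 20, "transcript has 20 exons")
    check(model.last_exon_number == 20, "last exon number is 20")
    check(model.codon(684) == "CGC", "codon 684 is CGC (arginine, CpG-bearing)")
    check(model.translate(model.codon(684)) == "R", "codon 684 translates to R")
    lo, _ = model.coding_exon_bounds(20)
    check(lo == 2196, "last exon coding sequence starts at c.2196")

    truncating: list[str] = []
    for rec in load_table1():
        edit = consequence.parse_hgvs_c(rec.hgvs_c)
        call = consequence.classify(edit, model)
        if rec.protein_change:
            check(
                call.protein_change == rec.protein_change,
                f"case {rec.case_id}: {rec.hgvs_c} -> {rec.protein_change}",
            )
        if call.truncating:
            truncating.append(rec.case_id)
            check(
                call.in_last_exon and call.nmd_escape,
                f"case {rec.case_id}: truncating change confined to last exon, NMD escape",
            )
        if rec.hgvs_c == "c.2050C>T":
            check(call.cpg_site, "R684C substitution sits in a CpG dinucleotide")
        if rec.protein_change == "p.A682T":
            check(call.domain_hit == "SET", "A682T maps to the SET domain")
        if rec.protein_change == "p.E745K":
            check(call.domain_hit == "post-SET", "E745K maps to the post-SET domain")
    check(
        truncating == ["14", "15", "16"],
        f"exactly the three expected truncating mutations (got cases {truncating})",
    )
    # the intronic deletion removes most of the polypyrimidine tract
    assert model.premrna is not None
    es = model.premrna_exon_bounds()[19][0]
    check(
        model.premrna[es - 15 : es - 1] == "TTCCTGTTGTTTCA",
        "intron 19 bases -15..-2 spell the deleted pyrimidine tract",
    )
    check(model.premrna[es - 2 : es] == "AG", "intron 19 ends with the canonical AG")
    return report


def _write_fixture(model: TranscriptModel, report: list[str], out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "exons.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\texon_number\tstrand\n")
        for i, (s, e) in enumerate(model.exons, start=1):
            fh.write(f"{model.chrom}\t{s + 1}\t{e}\t{i}\t{model.strand}\n")
    with open(out / "cds.fa", "w") as fh:
        fh.write(f">cds offset={model.utr5_len}\n")
        for i in range(0, len(model.cds), 60):
            fh.write(model.cds[i : i + 60] + "\n")
    with open(out / "domains.tsv", "w") as fh:
        fh.write("name\taa_start\taa_end\n")
        for d in model.domains:
            fh.write(f"{d.name}\t{d.aa_start}\t{d.aa_end}\n")
    assert model.premrna is not None and model.gene_start0 is not None
    with open(out / "premrna.fa", "w") as fh:
        fh.write(
            f">premrna chrom={model.chrom} start={model.gene_start0 + 1} "
            f"strand={model.strand}\n"
        )
        for i in range(0, len(model.premrna), 60):
            fh.write(model.premrna[i : i + 60] + "\n")
    (out / "constraints.txt").write_text("\n".join(report) + "\n")


_MODEL_CACHE: TranscriptModel | None = None


def cached_fixture_model() -> TranscriptModel:
    global _MODEL_CACHE
    if _MODEL_CACHE is None:
        _MODEL_CACHE, _ = build_transcript_fixture()
    return _MODEL_CACHE


# ==========================================================================
# alignments
# ==========================================================================

_AAS = "ACDEFGHIKLMNPQRSTVWY"


def simulate_alignment(
    n_columns: int = 200,
    n_homologs: int = 6,
    identity: float = 0.8,
    seed: int = 3,
    gap_fraction: float = 0.0,
) -> list[tuple[str, str]]:
    """A gapless-human protein alignment with i.i.d. per-column identity."""
    rng = np.random.default_rng(seed)
    human = "".join(rng.choice(list(_AAS), size=n_columns))
    rows = [("human", human)]
    for h in range(n_homologs):
        chars = []
        for aa in human:
            r = rng.random()
            if r < gap_fraction:
                chars.append("-")
            elif r < gap_fraction + identity * (1 - gap_fraction):
                chars.append(aa)
            else:
                chars.append(rng.choice([a for a in _AAS if a != aa]))
        rows.append((f"homolog{h + 1}", "".join(chars)))
    return rows


def fixture_alignment(
    model: TranscriptModel | None = None,
    n_homologs: int = 6,
    identity: float = 0.9,
    seed: int = 20_110_002,
) -> list[tuple[str, str]]:
    """Homolog alignment of the fixture protein with the mutated residues
    fully conserved (they are the catalytic-domain positions selection
    preserves across species)."""
    model = model or cached_fixture_model()
    human = model.translate()
    conserved = {134, 156, 279, 626, 639, 663, 664, 682, 684, 695, 733, 741, 744, 745}
    rng = np.random.default_rng(seed)
    rows = [("human", human)]
    for h in range(n_homologs):
        chars = []
        for i, aa in enumerate(human, start=1):
            if i in conserved or rng.random() < identity:
                chars.append(aa)
            else:
                chars.append(rng.choice([a for a in _AAS if a != aa]))
        rows.append((f"homolog{h + 1}", "".join(chars)))
    return rows


# ==========================================================================
# splice-site training sequences
# ==========================================================================

def _profile_draw(rng: np.random.Generator, profile: list[dict[str, float]]) -> str:
    out = []
    for col in profile:
        rest = (1.0 - sum(col.values())) / (4 - len(col)) if len(col) < 4 else 0.0
        probs = [col.get(b, rest) for b in _BASES]
        out.append(rng.choice(list(_BASES), p=probs))
    return "".join(out)


_DONOR_PROFILE = [  # positions -3..-1 (exon) then +1..+6 (intron)
    {"A": 0.35, "C": 0.35}, {"A": 0.60}, {"G": 0.80},
    {"G": 0.97}, {"T": 0.97}, {"A": 0.60}, {"A": 0.70}, {"G": 0.80}, {"T": 0.45},
]
_PY = {"C": 0.40, "T": 0.42}
_ACCEPTOR_PROFILE = (  # -20..-1 (intron) then +1..+3 (exon)
    [_PY] * 17 + [{"C": 0.70}, {"A": 0.95}, {"G": 0.97}]
    + [{"G": 0.50, "A": 0.25}, {}, {}]
)


def simulate_site_training(site_type: str, n: int = 200, seed: int = 0) -> list[str]:
    """Draw aligned example sequences of real-looking splice sites."""
    profile = {"donor": _DONOR_PROFILE, "acceptor": _ACCEPTOR_PROFILE}[site_type]
    rng = np.random.default_rng(seed)
    return [_profile_draw(rng, profile) for _ in range(n)]


# ==========================================================================
# cohort simulation
# ==========================================================================

def _nb_depths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def _planted_call(sample_id: str, hgvs: str, config: SimulationConfig,
                  rng: np.random.Generator) -> tuple[VariantCall, PlantedVariant]:
    edit = consequence.parse_hgvs_c(hgvs)
    cls = consequence.classify(edit, cached_fixture_model()).consequence_class
    pos = _PLANTED_OFFSET + edit.start.base + edit.start.offset
    if edit.kind == consequence.EditKind.substitution:
        ref, alt = edit.ref_bases or "A", edit.inserted_bases or "G"
    elif edit.kind == consequence.EditKind.duplication:
        seq = edit.ref_bases or "A" * edit.span
        ref, alt = seq[-1], seq[-1] + seq
    elif edit.kind == consequence.EditKind.deletion:
        seq = edit.ref_bases or "A" * edit.span
        anchor = "G" if seq[0] != "G" else "T"
        ref, alt = anchor + seq, anchor
    else:
        ref, alt = "A", "A" + (edit.inserted_bases or "T")
    depth = int(max(15, _nb_depths(rng, 1, config.depth_mean, config.depth_dispersion)[0]))
    call = VariantCall(
        sample_id=sample_id, chrom=_BG_CONTIG, pos=pos, ref=ref, alt=alt,
        depth=depth, genotype=Genotype.het, gene_id=config.planted_gene,
        consequence_label=cls, dbsnp_id=None,
    )
    truth = PlantedVariant(
        sample_id=sample_id, chrom=_BG_CONTIG, pos=pos, ref=ref, alt=alt,
        hgvs_c=hgvs, gene_id=config.planted_gene,
    )
    return call, truth


_BG_CLASS_POOL = [
    ConsequenceLabel.missense, ConsequenceLabel.other,
    ConsequenceLabel.inframe_indel, ConsequenceLabel.splice_region,
]
_BG_CLASS_P = [0.6, 0.2, 0.1, 0.1]
_EXCLUDED_POOL = [ConsequenceLabel.intronic, ConsequenceLabel.synonymous]


def _background_for_sample(
    sample_id: str, sample_index: int, config: SimulationConfig,
    rng: np.random.Generator,
) -> list[VariantCall]:
    n = config.n_background_variants
    # draw-with-margin then dedupe: collisions over 5e7 positions are rare
    raw = rng.integers(1, _BG_SPAN + 1, size=max(2 * n, n + 64))
    pos = np.unique(raw)
    if len(pos) < n:
        raise ValueError("background span too small for requested variant count")
    pos = pos[:n]
    is_dbsnp = rng.random(n) < config.fraction_dbsnp
    is_low = rng.random(n) < config.fraction_low_depth
    is_excl = rng.random(n) < config.fraction_excluded_class
    depths = _nb_depths(rng, n, config.depth_mean, config.depth_dispersion)
    depths = np.where(is_low, rng.integers(0, 15, size=n), depths)
    excl_cls = rng.choice(len(_EXCLUDED_POOL), size=n)
    kept_cls = rng.choice(len(_BG_CLASS_POOL), size=n, p=_BG_CLASS_P)
    ref_i = rng.integers(0, 4, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    hom = rng.random(n) < 0.1
    second_alt = rng.random(n) < config.fraction_multiallelic
    gene_pick = rng.integers(0, config.n_genes, size=n)  # used when unconstrained
    gene_pick_alt = rng.integers(0, config.n_genes - 1, size=n)

    cfg_filters = FilterConfig()
    allowed_genes = None
    if config.enforce_unique_causal and config.n_affected > 1:
        i = sample_index % config.n_affected
        allowed_genes = np.array(
            [g for g in range(config.n_genes) if g % config.n_affected != i]
        )
    calls: list[VariantCall] = []
    for k in range(n):
        cls = (
            _EXCLUDED_POOL[excl_cls[k]] if is_excl[k] else _BG_CLASS_POOL[kept_cls[k]]
        )
        depth = int(depths[k])
        rsid = f"rs{900000 + int(pos[k]) % 800000}" if is_dbsnp[k] else None
        survives = (
            depth >= cfg_filters.min_depth
            and cls not in cfg_filters.excluded_classes
            and rsid is None
        )
        if allowed_genes is not None and survives:
            # surviving background variants may only hit genes this sample
            # is allowed, so no background gene survives in every sample
            g = int(allowed_genes[gene_pick_alt[k] % len(allowed_genes)])
        else:
            g = int(gene_pick[k])
        ref = _BASES[ref_i[k]]
        alt = _BASES[(ref_i[k] + alt_shift[k]) % 4]
        common = dict(
            sample_id=sample_id, chrom=_BG_CONTIG, pos=int(pos[k]),
            ref=ref, alt=alt, depth=depth,
            genotype=Genotype.hom_alt if hom[k] else Genotype.het,
            gene_id=f"GENE{g:04d}", consequence_label=cls, dbsnp_id=rsid,
        )
        calls.append(VariantCall(**common))
        if second_alt[k]:
            alt2 = _BASES[(ref_i[k] + alt_shift[k] + 1) % 4]
            if alt2 != ref:
                calls.append(VariantCall(**{**common, "alt": alt2,
                                            "genotype": Genotype.het}))
    return calls


def simulate_cohort(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Simulate an affected cohort with parents and a planted causal gene.

    Each affected sample gets independent background variants plus exactly
    one clean (deep, non-excluded, dbSNP-free) variant in the planted gene;
    parents inherit roughly half of the child's background each and never
    carry the planted variant, but are deeply covered at its locus so absence
    is callable.  The same seed reproduces every file byte-for-byte.
    """
    config = config or SimulationConfig()
    entries: list[ManifestEntry] = []
    affected: dict[str, set[VariantCall]] = {}
    parents: dict[str, set[VariantCall] | None] = {}
    truth: list[PlantedVariant] = []

    for i in range(config.n_affected):
        sid = f"S{i + 1}"
        fam = f"F{i + 1}"
        entries.append(ManifestEntry(sid, fam, "affected", discovery_case=True))
        rng = np.random.default_rng([config.seed, i])
        bg = _background_for_sample(sid, i, config, rng)
        mut = config.planted_mutations[i % len(config.planted_mutations)]
        planted, t = _planted_call(sid, mut, config, rng)
        affected[sid] = set(bg) | {planted}
        truth.append(t)

        avail = (
            config.parent_availability[i]
            if i < len(config.parent_availability)
            else (True, True)
        )
        from_mother = rng.random(len(bg)) < 0.5
        for role, is_avail, mask in (
            ("mother", avail[0], from_mother),
            ("father", avail[1], ~from_mother),
        ):
            pid = f"{sid}_{role}"
            if not is_avail:
                parents[pid] = None
                continue
            entries.append(ManifestEntry(pid, fam, role))
            pcalls: set[VariantCall] = set()
            pdepths = _nb_depths(rng, len(bg), config.depth_mean, config.depth_dispersion)
            for v, owned, d in zip(bg, mask, pdepths):
                if owned:
                    pcalls.add(replace(v, sample_id=pid, depth=int(d),
                                       genotype=Genotype.het))
            # deep hom-ref coverage record at the planted locus
            ref_depth = int(max(15, _nb_depths(rng, 1, config.depth_mean,
                                               config.depth_dispersion)[0]))
            pcalls.add(replace(planted, sample_id=pid, depth=ref_depth,
                               genotype=Genotype.hom_ref))
            parents[pid] = pcalls

    result = CohortResult(
        manifest=CohortManifest(entries),
        affected=affected,
        parents=parents,
        truth=truth,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


def simulate_controls(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, set[VariantCall]]:
    """Population control panel over the planted-gene locus.

    Controls carry only benign-looking variation there — dbSNP-tagged or
    intronic/synonymous calls — and never any planted pathogenic key.
    """
    config = config or SimulationConfig()
    pathogenic_pos = {
        _PLANTED_OFFSET + consequence.parse_hgvs_c(m).start.base
        + consequence.parse_hgvs_c(m).start.offset
        for m in config.planted_mutations
    }
    out: dict[str, set[VariantCall]] = {}
    for j in range(config.n_controls):
        cid = f"C{j + 1:03d}"
        rng = np.random.default_rng([config.seed, 100_000 + j])
        k = int(rng.poisson(3))
        calls: set[VariantCall] = set()
        pool = [p for p in range(_PLANTED_OFFSET + 1, _PLANTED_OFFSET + 2500)
                if p not in pathogenic_pos]
        for pos in rng.choice(pool, size=min(k, len(pool)), replace=False):
            ref_i = int(rng.integers(0, 4))
            ref = _BASES[ref_i]
            alt = _BASES[(ref_i + int(rng.integers(1, 4))) % 4]
            benign_as_dbsnp = rng.random() < 0.5
            calls.add(VariantCall(
                sample_id=cid, chrom=_BG_CONTIG, pos=int(pos), ref=ref, alt=alt,
                depth=int(_nb_depths(rng, 1, config.depth_mean,
                                     config.depth_dispersion)[0]),
                genotype=Genotype.het, gene_id=config.planted_gene,
                consequence_label=(
                    ConsequenceLabel.missense if benign_as_dbsnp
                    else _EXCLUDED_POOL[int(rng.integers(0, 2))]
                ),
                dbsnp_id=f"rs{100000 + int(pos) % 90000}" if benign_as_dbsnp else None,
            ))
        out[cid] = calls
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        for cid, calls in out.items():
            write_variant_file(calls, outp / f"{cid}.vcf", cid)
    return out


# ==========================================================================
# growth reference
# ==========================================================================

def make_growth_reference() -> GrowthReference:
    """Synthetic growth reference (sex-averaged + per-sex rows, ages 0-18).

    Schema-compatible stand-in for licensed national growth charts: smooth
    invented means/SDs, one bucket per year of age, height and OFC in cm.
    """
    rows: list[ReferenceRow] = []
    for age in range(19):
        h_mean = 51.0 + 42.0 * np.log1p(age) / np.log(19.0) + 3.4 * age
        h_sd = 2.2 + 0.26 * age
        o_mean = 35.0 + 13.5 * np.log1p(age) / np.log(19.0)
        o_sd = 1.3 + 0.03 * age
        for sex, h_off, o_off in (
            ("sex-averaged", 0.0, 0.0), ("male", 0.8, 0.4), ("female", -0.8, -0.4),
        ):
            rows.append(ReferenceRow("height", age, age + 1, sex, h_mean + h_off, h_sd))
            rows.append(ReferenceRow("ofc", age, age + 1, sex, o_mean + o_off, o_sd))
    return GrowthReference(rows)
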