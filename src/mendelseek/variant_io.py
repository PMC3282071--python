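"""Read/write the pipeline's external formats into the shared domain types.

Variants travel as single-sample VCF 4.x (one file per individual).  Depth is
taken from ``INFO/DP`` (falling back to the sample ``FORMAT/DP``); the custom
INFO tags ``GENE`` (gene id), ``CSQCLS`` (upstream consequence class) and
``RSID`` (dbSNP id) carry the annotations the filter cascade consumes.  The
genotype-phenotype table, cohort manifest, exon table and domain table are
TSV; coding sequences and homolog alignments are FASTA.

Missing clinical values are written as ``nk`` (not known) and parsed to
``None`` — they never silently become 0.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO

from .transcript import Domain, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "ConsequenceLabel",
    "VariantCall",
    "ManifestEntry",
    "CohortManifest",
    "PhenotypeRecord",
    "VariantParseError",
    "read_variant_file",
    "write_variant_file",
    "read_manifest",
    "write_manifest",
    "read_phenotype_table",
    "load_table1",
    "read_alignment",
    "read_transcript_model",
    "load_transcript_dir",
]

DISCOVERY_CASES = ("3", "10", "14", "16")  # exome-sequenced index cases


class Genotype(enum.StrEnum):
    het = "het"
    hom_alt = "hom_alt"
    hom_ref = "hom_ref"
    missing = "missing"


class ConsequenceLabel(enum.StrEnum):
    intronic = "intronic"
    synonymous = "synonymous"
    missense = "missense"
    nonsense = "nonsense"
    frameshift = "frameshift"
    inframe_indel = "inframe_indel"
    splice_region = "splice_region"
    other = "other"


class Inheritance(enum.StrEnum):
    de_novo = "de_novo"
    familial = "familial"
    unknown = "unknown"


class VariantParseError(ValueError):
    """Malformed variant file, reporting the offending record."""


_DNA = set("ACGT")


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample (VCF conventions: 1-based pos)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int = 0
    genotype: Genotype = Genotype.missing
    gene_id: str | None = None
    consequence_label: ConsequenceLabel | None = None
    dbsnp_id: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise VariantParseError(f"empty allele at {self.chrom}:{self.pos}")
        if not (_DNA >= set(self.ref) and _DNA >= set(self.alt)):
            raise VariantParseError(
                f"non-ACGT allele {self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )
        if self.ref == self.alt:
            raise VariantParseError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1 or self.depth < 0:
            raise VariantParseError(f"bad pos/depth at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    family_id: str
    role: str  # affected | mother | father | control
    discovery_case: bool = False


@dataclass
class CohortManifest:
    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in manifest")
        affected_fams = {e.family_id for e in self.entries if e.role == "affected"}
        for e in self.entries:
            if e.role not in ("affected", "mother", "father", "control"):
                raise ValueError(f"unknown role {e.role!r} for {e.sample_id}")
            if e.role in ("mother", "father") and e.family_id not in affected_fams:
                raise ValueError(
                    f"parent {e.sample_id} has family {e.family_id} with no affected member"
                )

    def samples(self, role: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.role == role]

    @property
    def affected_ids(self) -> list[str]:
        return [e.sample_id for e in self.samples("affected")]

    def parents_of(self, affected_id: str) -> dict[str, str]:
        """role -> sample_id for the parents sharing the affected's family."""
        fam = next(e.family_id for e in self.entries if e.sample_id == affected_id)
        return {
            e.role: e.sample_id
            for e in self.entries
            if e.family_id == fam and e.role in ("mother", "father")
        }


@dataclass(frozen=True)
class PhenotypeRecord:
    case_id: str
    hgvs_c: str
    protein_change: str | None = None
    inheritance: Inheritance = Inheritance.unknown
    height_sd: float | None = None
    ofc_sd: float | None = None
    learning_disability: str = "unknown"  # no | mild | moderate | unknown
    malignancy: str | None = None
    discovery_case: bool = False


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_VCF_CONTIG_LEN = 200_000_000


def _vcf_header(sample_id: str, contigs: list[str]) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in contigs:
        h.contigs.add(c, length=_VCF_CONTIG_LEN)
    h.info.add("DP", 1, "Integer", "Read depth at the site")
    h.info.add("GENE", 1, "String", "Gene id the variant falls in")
    h.info.add("CSQCLS", 1, "String", "Consequence class from the upstream annotator")
    h.info.add("RSID", 1, "String", "dbSNP identifier")
    h.formats.add("GT", 1, "String", "Genotype")
    h.add_sample(sample_id)
    return h


def _genotype_for_allele(gt: tuple | None, allele_index: int) -> Genotype:
    if gt is None or all(a is None for a in gt):
        return Genotype.missing
    n = sum(1 for a in gt if a == allele_index)
    if n == 0:
        return Genotype.hom_ref
    if n == len([a for a in gt if a is not None]):
        return Genotype.hom_alt
    return Genotype.het


def read_variant_file(path: str | Path, sample_id: str) -> set[VariantCall]:
    """Parse a single-sample VCF into :class:`VariantCall`\\ s.

    Multi-allelic records are decomposed into one call per ALT allele; records
    with no depth annotation get depth 0; unknown ``CSQCLS`` values map to
    ``other`` with a logged warning.
    """
    calls: set[VariantCall] = set()
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VariantParseError(f"{path}: cannot open as VCF: {exc}") from exc
    with vf:
        recno = 0
        try:
            for rec in vf:
                recno += 1
                depth = rec.info.get("DP")
                if depth is None and rec.samples:
                    depth = next(iter(rec.samples.values())).get("DP")
                depth = int(depth) if depth is not None else 0
                csq_raw = rec.info.get("CSQCLS")
                csq: ConsequenceLabel | None = None
                if csq_raw is not None:
                    try:
                        csq = ConsequenceLabel(csq_raw)
                    except ValueError:
                        log.warning(
                            "%s record %d: unknown consequence %r mapped to 'other'",
                            path, recno, csq_raw,
                        )
                        csq = ConsequenceLabel.other
                rsid = rec.info.get("RSID")
                if rsid is None and rec.id and rec.id.startswith("rs"):
                    rsid = rec.id
                gt = None
                if rec.samples:
                    gt = next(iter(rec.samples.values())).get("GT")
                for j, alt in enumerate(rec.alts or (), start=1):
                    calls.add(
                        VariantCall(
                            sample_id=sample_id,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            depth=depth,
                            genotype=_genotype_for_allele(gt, j),
                            gene_id=rec.info.get("GENE"),
                            consequence_label=csq,
                            dbsnp_id=rsid,
                        )
                    )
        except VariantParseError:
            raise
        except Exception as exc:  # pysam raises assorted types on bad records
            raise VariantParseError(
                f"{path}: malformed VCF at record {recno + 1}: {exc}"
            ) from exc
    return calls


def write_variant_file(
    variants: set[VariantCall] | list[VariantCall],
    path: str | Path,
    sample_id: str,
) -> None:
    """Write calls as a sorted single-sample VCF (deterministic byte layout).

    Calls sharing (chrom, pos, ref) are merged into one multi-allelic record;
    the record DP is the max over the merged calls and site-level annotations
    (GENE, CSQCLS, RSID) are taken from the first call.
    """
    grouped: dict[tuple[str, int, str], list[VariantCall]] = {}
    for v in variants:
        grouped.setdefault((v.chrom, v.pos, v.ref), []).append(v)
    contigs = sorted({c for c, _, _ in grouped}) or ["chrSim"]
    header = _vcf_header(sample_id, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (chrom, pos, ref) in sorted(grouped):
            calls = sorted(grouped[(chrom, pos, ref)], key=lambda v: v.alt)
            alts = tuple(v.alt for v in calls)
            rec = out.new_record(contig=chrom, start=pos - 1, alleles=(ref, *alts))
            rec.info["DP"] = max(v.depth for v in calls)
            first = calls[0]
            if first.gene_id is not None:
                rec.info["GENE"] = first.gene_id
            if first.consequence_label is not None:
                rec.info["CSQCLS"] = str(first.consequence_label)
            if first.dbsnp_id is not None:
                rec.info["RSID"] = first.dbsnp_id
            carried = [
                j for j, v in enumerate(calls, start=1)
                if v.genotype in (Genotype.het, Genotype.hom_alt)
            ]
            if any(v.genotype == Genotype.missing for v in calls):
                gt: tuple = (None, None)
            elif not carried:
                gt = (0, 0)
            elif len(carried) >= 2:
                gt = (carried[0], carried[1])
            elif calls[carried[0] - 1].genotype == Genotype.hom_alt:
                gt = (carried[0], carried[0])
            else:
                gt = (0, carried[0])
            rec.samples[sample_id]["GT"] = gt
            out.write(rec)


# --------------------------------------------------------------------------
# manifest
# --------------------------------------------------------------------------

def read_manifest(path: str | Path) -> CohortManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "family_id", "role", "discovery_case"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest missing columns {required - set(df.columns)}")
    entries = [
        ManifestEntry(
            sample_id=r.sample_id,
            family_id=r.family_id,
            role=r.role,
            discovery_case=str(r.discovery_case).lower() in ("true", "1", "yes"),
        )
        for r in df.itertuples()
    ]
    return CohortManifest(entries)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "family_id": e.family_id,
                "role": e.role,
                "discovery_case": str(e.discovery_case).lower(),
            }
            for e in manifest.entries
        ]
    ).to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# phenotype table
# --------------------------------------------------------------------------

_NK = {"nk", "", "na", "none"}


def _parse_sd(raw: str, case_id: str, column: str) -> float | None:
    raw = raw.strip()
    if raw.lower() in _NK:
        return None
    try:
        return float(raw)  # handles the '+2.2' sign convention
    except ValueError as exc:
        raise ValueError(f"case {case_id}: unparseable {column} value {raw!r}") from exc


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Parse the genotype-phenotype TSV (one row per mutation-positive case)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for r in df.itertuples():
        inh = r.inheritance.strip().lower()
        records.append(
            PhenotypeRecord(
                case_id=r.case_id,
                hgvs_c=r.hgvs_c,
                protein_change=r.protein_change or None,
                inheritance=(
                    Inheritance.unknown if inh in _NK else Inheritance(inh)
                ),
                height_sd=_parse_sd(r.height_sd, r.case_id, "height_sd"),
                ofc_sd=_parse_sd(r.ofc_sd, r.case_id, "ofc_sd"),
                learning_disability=(
                    "unknown"
                    if r.learning_disability.strip().lower() in _NK
                    else r.learning_disability.strip().lower()
                ),
                malignancy=r.malignancy.strip() or None,
                discovery_case=str(r.discovery_case).lower() in ("true", "1", "yes"),
            )
        )
    ids = [rec.case_id for rec in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids in phenotype table")
    return records


def load_table1() -> list[PhenotypeRecord]:
    """The bundled 19-case EZH2 overgrowth genotype-phenotype table."""
    from importlib.resources import files

    return read_phenotype_table(files("mendelseek.data") / "table1.tsv")


# --------------------------------------------------------------------------
# FASTA / transcript model
# --------------------------------------------------------------------------

def read_alignment(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA multiple alignment as (id, sequence); human row first."""
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(s) for _, s in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: alignment rows have unequal lengths {lengths}")
    return rows


def _fasta_attr(description: str, key: str, default: str | None = None) -> str | None:
    for tok in description.split():
        if tok.startswith(f"{key}="):
            return tok.split("=", 1)[1]
    return default


def read_transcript_model(
    exon_table_path: str | Path,
    cds_fasta_path: str | Path,
    domain_table_path: str | Path | None = None,
    premrna_fasta_path: str | Path | None = None,
    gene_id: str = "GENE",
) -> TranscriptModel:
    """Assemble a :class:`TranscriptModel` from its on-disk parts.

    The exon table is TSV ``chrom  start  end  exon_number  strand`` with
    1-based inclusive coordinates; the CDS FASTA description may carry
    ``offset=<n>`` giving the 5' UTR length within the spliced transcript;
    the optional pre-mRNA FASTA carries ``start=<1-based genomic start>``.
    """
    df = pd.read_csv(exon_table_path, sep="\t", dtype=str)
    need = {"chrom", "start", "end", "exon_number", "strand"}
    if not need <= set(df.columns):
        raise ValueError(f"exon table missing columns {need - set(df.columns)}")
    strands = set(df["strand"])
    if len(strands) != 1:
        raise ValueError(f"inconsistent strands in exon table: {strands}")
    strand = strands.pop()
    df = df.assign(exon_number=df.exon_number.astype(int)).sort_values("exon_number")
    exons = [(int(r.start) - 1, int(r.end)) for r in df.itertuples()]
    chrom = df["chrom"].iloc[0]

    cds_rec = next(SeqIO.parse(str(cds_fasta_path), "fasta"))
    utr5_len = int(_fasta_attr(cds_rec.description, "offset", "0"))

    domains: list[Domain] = []
    if domain_table_path is not None:
        dd = pd.read_csv(domain_table_path, sep="\t", dtype=str)
        domains = [
            Domain(r.name, int(r.aa_start), int(r.aa_end))
            for r in dd.rename(columns={"domain": "name"}).itertuples()
        ]

    premrna = None
    gene_start0 = None
    if premrna_fasta_path is not None:
        rec = next(SeqIO.parse(str(premrna_fasta_path), "fasta"))
        premrna = str(rec.seq)
        start_attr = _fasta_attr(rec.description, "start")
        gene_start0 = int(start_attr) - 1 if start_attr else None

    return TranscriptModel(
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=str(cds_rec.seq),
        utr5_len=utr5_len,
        domains=domains,
        premrna=premrna,
        gene_start0=gene_start0,
        gene_id=gene_id,
    )


def load_transcript_dir(path: str | Path, gene_id: str = "GENE") -> TranscriptModel:
    """Load a fixture directory: exons.tsv, cds.fa, domains.tsv, premrna.fa."""
    p = Path(path)
    return read_transcript_model(
        p / "exons.tsv",
        p / "cds.fa",
        p / "domains.tsv" if (p / "domains.tsv").exists() else None,
        p / "premrna.fa" if (p / "premrna.fa").exists() else None,
        gene_id=gene_id,
    )
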