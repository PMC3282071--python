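"""Transcript coordinate engine.

A :class:`TranscriptModel` holds the exon structure, strand, coding sequence
and protein-domain intervals of one transcript, and is the single place where
coordinate systems are converted:

* genomic positions are 1-based (VCF/HGVS convention) at the public surface,
  0-based half-open internally;
* transcript positions are 0-based offsets into the spliced transcript;
* coding positions are 1-based HGVS ``c.`` coordinates, optionally carrying an
  intronic offset (``c.2196-15`` = 15 bases 5' of the first base of the exon
  that starts at c.2196).

An optional pre-mRNA sequence (transcript-sense, exons plus introns) enables
intron-aware operations (splice-window extraction, intron-offset resolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CodingPosition", "Domain", "TranscriptModel", "TranscriptError"]

STANDARD_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptError(ValueError):
    """Inconsistent transcript model or out-of-range coordinate."""


@dataclass(frozen=True, order=True)
class CodingPosition:
    """HGVS c. position: exonic anchor base plus optional intronic offset.

    ``offset == 0`` means the position is the anchor base itself (exonic);
    ``offset < 0`` counts into the upstream intron from the first base of the
    anchor's exon, ``offset > 0`` into the downstream intron from the last.
    """

    base: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.base < 1:
            raise TranscriptError(f"coding anchor must be >= 1, got {self.base}")

    @property
    def is_intronic(self) -> bool:
        return self.offset != 0

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"


@dataclass(frozen=True)
class Domain:
    name: str
    aa_start: int  # 1-based, inclusive
    aa_end: int    # inclusive


@dataclass
class TranscriptModel:
    chrom: str
    strand: str                      # '+' or '-'
    exons: list[tuple[int, int]]     # genomic 0-based half-open, 5'->3' transcript order
    cds: str
    utr5_len: int = 0
    domains: list[Domain] = field(default_factory=list)
    premrna: str | None = None       # transcript-sense pre-mRNA (exons + introns)
    gene_start0: int | None = None   # genomic 0-based start of the pre-mRNA span
    gene_id: str = "GENE"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise TranscriptError(f"strand must be '+' or '-', got {self.strand!r}")
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise TranscriptError(
                f"CDS length {len(self.cds)} is not divisible by 3"
            )
        spans = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise TranscriptError(f"overlapping exons {(s1, e1)} and {(s2, e2)}")
        for s, e in self.exons:
            if e <= s:
                raise TranscriptError(f"empty exon {(s, e)}")
        if self.utr5_len + len(self.cds) > self.transcript_length:
            raise TranscriptError("CDS does not fit inside the spliced transcript")
        names = [d.name for d in self.domains]
        prev_end = 0
        for d in sorted(self.domains, key=lambda d: d.aa_start):
            if d.aa_start <= prev_end:
                raise TranscriptError(f"overlapping domain rows near {d.name}")
            prev_end = d.aa_end
        if len(set(names)) != len(names):
            raise TranscriptError("duplicate domain names")
        if self.premrna is not None:
            self.premrna = self.premrna.upper()
            if self.strand != "+":
                raise TranscriptError("pre-mRNA sequence is only supported on '+' strand models")
            if self.gene_start0 is None:
                self.gene_start0 = min(s for s, _ in self.exons)
            span = max(e for _, e in self.exons) - self.gene_start0
            if len(self.premrna) < span:
                raise TranscriptError("pre-mRNA shorter than the genomic exon span")
            spliced = "".join(
                self.premrna[s - self.gene_start0 : e - self.gene_start0]
                for s, e in self.exons
            )
            cds_in_tx = spliced[self.utr5_len : self.utr5_len + len(self.cds)]
            if cds_in_tx != self.cds:
                raise TranscriptError("CDS does not match the exonic pre-mRNA slice")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def last_exon_number(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]

    @property
    def transcript_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def cds_len(self) -> int:
        return len(self.cds)

    @property
    def protein_length(self) -> int:
        n = len(self.cds) // 3
        return n - 1 if self.cds[-3:] in ("TAA", "TAG", "TGA") else n

    def _tx_starts(self) -> list[int]:
        starts, acc = [], 0
        for ln in self.exon_lengths:
            starts.append(acc)
            acc += ln
        return starts

    # -- genomic <-> transcript --------------------------------------------

    def tx_of_genomic(self, gpos1: int) -> int | None:
        """Spliced-transcript offset (0-based) of a 1-based genomic position."""
        g0 = gpos1 - 1
        for (s, e), t0 in zip(self.exons, self._tx_starts()):
            if s <= g0 < e:
                return t0 + (g0 - s if self.strand == "+" else e - 1 - g0)
        return None

    def genomic_of_tx(self, tpos: int) -> int:
        if tpos < 0 or tpos >= self.transcript_length:
            raise TranscriptError(f"transcript position {tpos} out of range")
        for (s, e), t0 in zip(self.exons, self._tx_starts()):
            ln = e - s
            if t0 <= tpos < t0 + ln:
                off = tpos - t0
                g0 = s + off if self.strand == "+" else e - 1 - off
                return g0 + 1
        raise AssertionError("unreachable")

    # -- coding coordinates ------------------------------------------------

    def _check_coding(self, c: int) -> None:
        if not 1 <= c <= len(self.cds):
            raise TranscriptError(f"coding position {c} outside CDS of length {len(self.cds)}")

    def tx_of_coding(self, c: int) -> int:
        self._check_coding(c)
        return self.utr5_len + c - 1

    def genomic_of_coding(self, pos: CodingPosition | int) -> int:
        """1-based genomic position of a coding position, intron offsets included."""
        if isinstance(pos, int):
            pos = CodingPosition(pos)
        anchor_g = self.genomic_of_tx(self.tx_of_coding(pos.base))
        if pos.offset == 0:
            return anchor_g
        step = pos.offset if self.strand == "+" else -pos.offset
        return anchor_g + step

    def coding_of_genomic(self, gpos1: int) -> int | None:
        t = self.tx_of_genomic(gpos1)
        if t is None:
            return None
        c = t - self.utr5_len + 1
        return c if 1 <= c <= len(self.cds) else None

    def exon_number_of_coding(self, c: int) -> int:
        t = self.tx_of_coding(c)
        for i, (t0, ln) in enumerate(zip(self._tx_starts(), self.exon_lengths), start=1):
            if t0 <= t < t0 + ln:
                return i
        raise AssertionError("unreachable")

    def coding_exon_bounds(self, exon_number: int) -> tuple[int | None, int | None]:
        """First/last coding position inside an exon (None if non-coding)."""
        t0 = self._tx_starts()[exon_number - 1]
        ln = self.exon_lengths[exon_number - 1]
        lo = max(t0, self.utr5_len)
        hi = min(t0 + ln, self.utr5_len + len(self.cds))
        if lo >= hi:
            return None, None
        return lo - self.utr5_len + 1, hi - self.utr5_len

    # -- pre-mRNA ----------------------------------------------------------

    def _require_premrna(self) -> str:
        if self.premrna is None:
            raise TranscriptError("operation requires a pre-mRNA sequence")
        return self.premrna

    def premrna_index_of_coding(self, pos: CodingPosition | int) -> int:
        """0-based index into the pre-mRNA of a coding position (offsets allowed)."""
        self._require_premrna()
        if isinstance(pos, int):
            pos = CodingPosition(pos)
        assert self.gene_start0 is not None
        return self.genomic_of_coding(pos) - 1 - self.gene_start0

    def premrna_exon_bounds(self) -> list[tuple[int, int]]:
        """Exon intervals (0-based half-open) on the pre-mRNA, transcript order."""
        self._require_premrna()
        assert self.gene_start0 is not None
        return [(s - self.gene_start0, e - self.gene_start0) for s, e in self.exons]

    # -- protein -----------------------------------------------------------

    def codon(self, n: int) -> str:
        """Codon ``n`` (1-based) of the CDS."""
        if not 1 <= n <= len(self.cds) // 3:
            raise TranscriptError(f"codon {n} outside CDS")
        return self.cds[3 * (n - 1) : 3 * n]

    def translate(self, seq: str | None = None) -> str:
        seq = self.cds if seq is None else seq.upper()
        aas = []
        for i in range(0, len(seq) - len(seq) % 3, 3):
            aa = STANDARD_TABLE[seq[i : i + 3]]
            if aa == "*":
                break
            aas.append(aa)
        return "".join(aas)
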