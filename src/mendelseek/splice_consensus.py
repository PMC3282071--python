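"""Two-tier splice-disruption consensus.

The assessment procedure mirrors clinical practice for intronic / near-exon
variants:

* **Tier 1** — two primary splice-site scorers evaluate the variant, both for
  weakening of the nearest annotated site (*wildtype loss*) and for creation
  of a new site nearby (*cryptic gain*).  The tier triggers only when BOTH
  primary scores change by more than the threshold (default 20%) in the same
  direction for at least one mode.
* **Tier 2** — three confirmatory scorers are then run; the verdict is
  ``disruptive`` only when all five scorers agree in direction (a consensus
  decrease of the wildtype site, or a consensus increase of a cryptic site).
  A triggered but non-unanimous assessment is ``indeterminate``; an
  untriggered one is ``not_disruptive``.

The built-in scorers are independently trained log2-odds position weight
matrices (PWMs) over donor (3 exonic + 6 intronic bases) and acceptor
(20 intronic + 3 exonic bases) windows; any object implementing
``score(window, site_type)`` with the same window geometry can stand in for
them, so externally computed scores can be wired through the same consensus.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .consequence import EditKind, HgvsEdit
from .transcript import TranscriptModel

__all__ = [
    "Pwm",
    "SpliceScorer",
    "SpliceVerdict",
    "Verdict",
    "Mode",
    "pct_change",
    "score_site",
    "builtin_scorers",
    "assess_variant",
]

DONOR_EXON, DONOR_INTRON = 3, 6          # window [ee-3, ee+6) around exon end
ACCEPTOR_INTRON, ACCEPTOR_EXON = 20, 3   # window [es-20, es+3) around exon start
WINDOW_LEN = {"donor": DONOR_EXON + DONOR_INTRON, "acceptor": ACCEPTOR_INTRON + ACCEPTOR_EXON}

_BASES = "ACGT"
_EPS = 1e-9


def pct_change(wt_score: float, var_score: float) -> float:
    """Signed relative change in percent, wildtype score as denominator.

    Negative = weakened site, positive = strengthened.  An epsilon guards
    near-zero wildtype scores (log-odds scales cross zero; see docs).
    """
    if not math.isfinite(wt_score):
        raise ValueError("wildtype score must be finite")
    return 100.0 * (var_score - wt_score) / max(abs(wt_score), _EPS)


class Pwm:
    """Log2-odds position weight matrix: score = sum log2(f[base,pos] / 0.25)."""

    def __init__(self, freqs: np.ndarray):
        freqs = np.asarray(freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4:
            raise ValueError("freqs must be (length, 4)")
        if not np.allclose(freqs.sum(axis=1), 1.0):
            raise ValueError("frequency rows must sum to 1")
        self.freqs = freqs
        self._log_odds = np.log2(freqs / 0.25)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @classmethod
    def train(cls, seqs: list[str], pseudocount: float = 0.5) -> "Pwm":
        if not seqs:
            raise ValueError("no training sequences")
        L = len(seqs[0])
        counts = np.full((L, 4), pseudocount, dtype=float)
        for s in seqs:
            s = s.upper()
            if len(s) != L:
                raise ValueError("training sequences have unequal lengths")
            for i, b in enumerate(s):
                if b not in _BASES:
                    raise ValueError(f"non-ACGT base {b!r} in training sequence")
                counts[i, _BASES.index(b)] += 1.0
        return cls(counts / counts.sum(axis=1, keepdims=True))

    def score(self, window: str) -> float:
        window = window.upper()
        if len(window) != self.length:
            raise ValueError(
                f"window length {len(window)} != PWM length {self.length}"
            )
        total = 0.0
        for i, b in enumerate(window):
            if b not in _BASES:
                raise ValueError(f"non-ACGT base {b!r} in window")
            total += self._log_odds[i, _BASES.index(b)]
        return float(total)


@dataclass
class SpliceScorer:
    """A named scorer holding one PWM per supported site type."""

    name: str
    matrices: dict[str, Pwm]  # site_type -> Pwm

    def supports(self, site_type: str) -> bool:
        return site_type in self.matrices

    def window_length(self, site_type: str) -> int:
        return self.matrices[site_type].length

    def score(self, window: str, site_type: str) -> float:
        if site_type not in self.matrices:
            raise ValueError(f"{self.name} does not score {site_type} sites")
        return self.matrices[site_type].score(window)


def score_site(scorer: SpliceScorer | Pwm, window: str, site_type: str = "donor") -> float:
    """Score one sequence window with a scorer or bare PWM."""
    if isinstance(scorer, Pwm):
        return scorer.score(window)
    return scorer.score(window, site_type)


def builtin_scorers(seed: int = 2011) -> list[SpliceScorer]:
    """Five independently trained PWM scorers (first two act as primary).

    Each is trained on its own simulated draw of donor/acceptor site examples
    with its own pseudocount, giving five correlated-but-distinct opinions of
    site strength, the shape the two-tier consensus expects.
    """
    from .synthetic_data import simulate_site_training  # avoid import cycle

    params = [  # (n_train, pseudocount)
        (240, 0.5), (180, 0.5), (200, 0.25), (160, 1.0), (220, 0.75),
    ]
    scorers = []
    for i, (n, pc) in enumerate(params):
        matrices = {
            st: Pwm.train(simulate_site_training(st, n=n, seed=seed * 100 + 10 * i + j), pc)
            for j, st in enumerate(("donor", "acceptor"))
        }
        scorers.append(SpliceScorer(name=f"pwm{i + 1}", matrices=matrices))
    return scorers


class Verdict(enum.StrEnum):
    disruptive = "disruptive"
    not_disruptive = "not_disruptive"
    indeterminate = "indeterminate"


class Mode(enum.StrEnum):
    wildtype_loss = "wildtype_loss"
    cryptic_gain = "cryptic_gain"


@dataclass
class SpliceVerdict:
    variant: str
    site_type: str
    site_pos: int  # pre-mRNA index of the assessed exon boundary
    tier1_scores: dict[str, tuple[float, float, float]]  # name -> (wt, var, pct)
    triggered: bool
    verdict: Verdict
    mode: Mode
    tier2_scores: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.triggered != (self.tier2_scores is not None):
            raise ValueError("tier-2 scores must be present iff tier 1 triggered")


# --------------------------------------------------------------------------
# variant application on the pre-mRNA
# --------------------------------------------------------------------------

def _edit_to_premrna(edit: HgvsEdit, model: TranscriptModel) -> tuple[int, int, str]:
    """(start, end, replacement) of the edit as a 0-based half-open splice
    on the pre-mRNA sequence."""
    i = model.premrna_index_of_coding(edit.start)
    j = model.premrna_index_of_coding(edit.end)
    pm = model.premrna or ""
    if edit.kind == EditKind.substitution:
        return i, i + 1, (edit.inserted_bases or "")
    if edit.kind == EditKind.deletion:
        return i, j + 1, ""
    if edit.kind == EditKind.duplication:
        dup = edit.ref_bases or pm[i : j + 1]
        return j + 1, j + 1, dup
    if edit.kind == EditKind.insertion:
        return i + 1, i + 1, edit.inserted_bases or ""
    return i, j + 1, edit.inserted_bases or ""  # delins


def _window(seq: str, boundary: int, site_type: str) -> str | None:
    if site_type == "acceptor":
        lo, hi = boundary - ACCEPTOR_INTRON, boundary + ACCEPTOR_EXON
    else:
        lo, hi = boundary - DONOR_EXON, boundary + DONOR_INTRON
    if lo < 0 or hi > len(seq):
        return None
    return seq[lo:hi]


def assess_variant(
    edit: HgvsEdit,
    model: TranscriptModel,
    scorers: list[SpliceScorer],
    threshold: float = 20.0,
    cryptic_radius: int = 25,
) -> SpliceVerdict:
    """Run the two-tier consensus for one variant.

    The first two scorers are primary, the rest confirmatory.  The nearest
    annotated exon boundary to the edit is assessed in wildtype-loss mode;
    cryptic-gain mode scans every candidate boundary position within
    ``cryptic_radius`` bases of the edit (leftmost best per scorer).
    """
    if len(scorers) < 2:
        raise ValueError("need at least two scorers (primaries)")
    pm = model.premrna
    if pm is None:
        raise ValueError("transcript model has no pre-mRNA sequence")
    a, b, repl = _edit_to_premrna(edit, model)
    net = len(repl) - (b - a)
    var_pm = pm[:a] + repl + pm[b:]

    # annotated boundaries: acceptors at exon starts (exon >= 2), donors at
    # exon ends (exon < last)
    bounds = model.premrna_exon_bounds()
    sites = [("acceptor", es) for es, _ in bounds[1:]] + [
        ("donor", ee) for _, ee in bounds[:-1]
    ]
    if not sites:
        raise ValueError("no assessable site: transcript has a single exon")

    def dist(p: int) -> int:
        if p < a:
            return a - p
        if p > b:
            return p - b
        return 0

    site_type, p = min(sites, key=lambda s: (dist(s[1]), s[1]))
    # boundary position in the variant sequence
    if p >= b:
        p_var = p + net
    elif p <= a:
        p_var = p
    else:
        p_var = a  # boundary erased by the edit; assess at the junction

    def loss_scores(sc: SpliceScorer) -> tuple[float, float, float]:
        wt_w = _window(pm, p, site_type)
        var_w = _window(var_pm, p_var, site_type)
        if wt_w is None or var_w is None:
            raise ValueError("no assessable site: window outside sequence")
        wt, var = sc.score(wt_w, site_type), sc.score(var_w, site_type)
        return wt, var, pct_change(wt, var)

    def gain_scores(sc: SpliceScorer) -> tuple[float, float, float]:
        best: tuple[float, int] | None = None  # (score, boundary)
        for q in range(a - cryptic_radius, b + net + cryptic_radius + 1):
            if q == p_var:
                continue  # novel positions only
            w = _window(var_pm, q, site_type)
            if w is None:
                continue
            s = sc.score(w, site_type)
            if best is None or s > best[0]:
                best = (s, q)
        if best is None:
            raise ValueError("no assessable site: window outside sequence")
        var_score, q = best
        q0 = q if q <= a else q - net
        q0 = min(max(q0, ACCEPTOR_INTRON), len(pm) - ACCEPTOR_EXON)
        wt_w = _window(pm, q0, site_type)
        wt_score = sc.score(wt_w, site_type) if wt_w is not None else 0.0
        return wt_score, var_score, pct_change(wt_score, var_score)

    # unique labels even if the same scorer object appears several times
    labels = []
    seen: dict[str, int] = {}
    for sc in scorers:
        seen[sc.name] = seen.get(sc.name, 0) + 1
        labels.append(sc.name if seen[sc.name] == 1 else f"{sc.name}#{seen[sc.name]}")

    primaries = list(zip(labels[:2], scorers[:2]))
    confirmatory = list(zip(labels[2:], scorers[2:]))
    t1_loss = {lb: loss_scores(sc) for lb, sc in primaries}
    t1_gain = {lb: gain_scores(sc) for lb, sc in primaries}

    loss_trig = all(s[2] < -threshold for s in t1_loss.values())
    gain_trig = all(s[2] > threshold for s in t1_gain.values())

    if loss_trig:
        mode, tier1 = Mode.wildtype_loss, t1_loss
    elif gain_trig:
        mode, tier1 = Mode.cryptic_gain, t1_gain
    else:
        return SpliceVerdict(
            variant=str(edit), site_type=site_type, site_pos=p,
            tier1_scores=t1_loss, triggered=False,
            verdict=Verdict.not_disruptive, mode=Mode.wildtype_loss,
        )

    score_fn = loss_scores if mode == Mode.wildtype_loss else gain_scores
    tier2 = {lb: score_fn(sc) for lb, sc in confirmatory}
    all_pct = [s[2] for s in tier1.values()] + [s[2] for s in tier2.values()]
    unanimous = (
        all(x < 0 for x in all_pct)
        if mode == Mode.wildtype_loss
        else all(x > 0 for x in all_pct)
    )
    return SpliceVerdict(
        variant=str(edit), site_type=site_type, site_pos=p,
        tier1_scores=tier1, triggered=True,
        verdict=Verdict.disruptive if unanimous else Verdict.indeterminate,
        mode=mode, tier2_scores=tier2,
    )
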