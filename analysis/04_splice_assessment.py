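#!/usr/bin/env python
"""Two-tier splice consensus on the intronic 14-bp acceptor deletion and,
for contrast, a deep-exonic substitution.  Writes splice_verdicts.tsv.
"""

from pathlib import Path

from mendelseek.consequence import parse_hgvs_c
from mendelseek.splice_consensus import assess_variant, builtin_scorers
from mendelseek.synthetic_data import cached_fixture_model

ROOT = Path(__file__).resolve().parent.parent / "results"

VARIANTS = [
    "c.2196-15_2196-2delTTCCTGTTGTTTCA",  # removes the polypyrimidine tract
    "c.1980G>A",                           # mid-exon, no site nearby (fixture base)
]


def main() -> None:
    ROOT.mkdir(exist_ok=True)
    model = cached_fixture_model()
    scorers = builtin_scorers()

    lines = ["variant\tsite_type\tmode\ttriggered\tverdict\tprimary_pct_changes"]
    for hgvs in VARIANTS:
        edit = parse_hgvs_c(hgvs)
        if edit.kind.value == "substitution" and not edit.is_intronic:
            # keep the control variant consistent with the fixture sequence
            ref = model.cds[edit.start.base - 1]
            alt = "A" if ref != "A" else "G"
            edit = parse_hgvs_c(f"c.{edit.start.base}{ref}>{alt}")
        v = assess_variant(edit, model, scorers)
        pcts = ", ".join(f"{s[2]:+.1f}%" for s in v.tier1_scores.values())
        lines.append(f"{v.variant}\t{v.site_type}\t{v.mode}\t{v.triggered}"
                     f"\t{v.verdict}\t{pcts}")
        print(f"{v.variant}: {v.verdict} ({v.mode}, primary changes {pcts})")
    (ROOT / "splice_verdicts.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
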