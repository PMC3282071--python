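#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes the constraint-checked transcript fixture, the 4-case discovery
cohort (seed 11, with parents and truth table), and the 115-sample control
panel under scratch/sim/ (bulky regenerable inputs, not analysis outputs).
"""

from pathlib import Path

from mendelseek.synthetic_data import (
    SimulationConfig,
    build_transcript_fixture,
    simulate_cohort,
    simulate_controls,
)

OUT = Path(__file__).resolve().parent.parent / "scratch" / "sim"


def main() -> None:
    _, report = build_transcript_fixture(OUT / "transcript")
    print(f"transcript fixture: {len(report)} constraints verified")

    cfg = SimulationConfig(seed=11)
    res = simulate_cohort(cfg, OUT / "cohort")
    n_parents = sum(1 for v in res.parents.values() if v is not None)
    print(
        f"cohort: {len(res.affected)} affected exomes "
        f"({cfg.n_background_variants} background variants each), "
        f"{n_parents}/8 parental samples, {len(res.truth)} planted mutations"
    )

    panel = simulate_controls(cfg, OUT / "controls")
    print(f"controls: {len(panel)} samples over the {cfg.planted_gene} locus")


if __name__ == "__main__":
    main()
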