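#!/usr/bin/env python
"""The discovery analysis: filter each affected exome, intersect hit genes
across cases, and confirm de novo status against the parents.

Reads scratch/sim/ (from 01_simulate_inputs.py), writes attrition.tsv,
candidates.tsv and de_novo.tsv under results/.
"""

from pathlib import Path

from mendelseek.filter_cascade import FilterConfig, apply_filters, attrition_table
from mendelseek.gene_intersection import confirm_de_novo, intersect_genes
from mendelseek.variant_io import read_manifest, read_variant_file

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT.parent / "scratch" / "sim"


def main() -> None:
    manifest = read_manifest(SIM / "cohort" / "manifest.tsv")
    cfg = FilterConfig()

    filtered, reports = {}, []
    for sid in manifest.affected_ids:
        calls = read_variant_file(SIM / "cohort" / f"{sid}.vcf", sid)
        surviving, rep = apply_filters(calls, cfg, sample_id=sid)
        filtered[sid] = surviving
        reports.append(rep)
        print(f"{sid}: {rep.n_input} variants -> {rep.n_surviving} after filters")
    (ROOT / "attrition.tsv").write_text(attrition_table(reports))

    matrix, candidates = intersect_genes(filtered, manifest)
    (ROOT / "candidates.tsv").write_text(
        "gene_id\n" + "".join(g + "\n" for g in candidates)
    )
    print(
        f"intersection over {len(matrix.samples)} cases: "
        f"{len(candidates)} candidate gene(s): {', '.join(candidates)}"
    )

    lines = ["sample_id\tchrom\tpos\tref\talt\tverdict\tmother\tfather"]
    truth = [
        ln.split("\t") for ln in
        (SIM / "cohort" / "truth.tsv").read_text().strip().splitlines()[1:]
    ]
    for sid, chrom, pos, ref, alt, hgvs, gene in truth:
        key = (chrom, int(pos), ref, alt)
        child = [v for v in filtered[sid] if v.key == key]
        parents = {}
        for role in ("mother", "father"):
            p = SIM / "cohort" / f"{sid}_{role}.vcf"
            parents[role] = (
                read_variant_file(p, f"{sid}_{role}") if p.exists() else None
            )
        call = confirm_de_novo(child, parents, min_parent_depth=cfg.min_depth)[0]
        ev = call.parent_evidence
        lines.append(
            f"{sid}\t{chrom}\t{pos}\t{ref}\t{alt}\t{call.verdict}"
            f"\t{ev['mother']}\t{ev['father']}"
        )
        print(f"{sid} {hgvs}: {call.verdict}")
    (ROOT / "de_novo.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
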