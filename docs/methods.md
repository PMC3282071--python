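# Methods

This note records the scientific model behind each stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical/design choices made where the procedure itself was open.

## Discovery model

The pipeline targets fully penetrant dominant disorders in unrelated
cases, most arising de novo. Under that model the causal gene must carry a
qualifying variant in every affected individual, while background
variation — enormous per exome but largely shared with databases or
shallow in coverage — intersects away across unrelated cases. The
candidate set is therefore a pure set intersection over post-filter hit
genes; no burden statistic or allele-frequency model is involved, and the
method's power comes entirely from the filter cascade and the number of
unrelated cases. Gene identity is the `GENE` string itself: inputs must
share a namespace, and no symbol aliasing is attempted. Compound
heterozygous and X-linked models are out of scope.

### Filter cascade

Five per-variant predicates, each configurable, defaults chosen for a
discovery screen on older short-read exomes:

* **depth ≥ 15 reads** — below this, heterozygous calls are unreliable;
  the same threshold is reused when declaring a variant *absent* in a
  parent. The depth is the site depth (`DP`), not the allele depth.
* **consequence class ∉ {intronic, synonymous}** — classes unlikely to be
  protein-relevant in a first screen. A variant with no class annotation
  is treated as `other` and kept, never silently excluded.
* **no dbSNP id** — any recorded id excludes, reproducing the blanket
  "known polymorphism" rule of early exome studies; a supplied lookup set
  (`chrom:pos:ref:alt` keys) additionally excludes when VCFs carry no id
  tags. With today's clinically contaminated dbSNP this rule is too
  aggressive; it is the configurable default, not a recommendation.
* **gene ∉ pseudogene list** — mismapping hotspot exclusion.
* **variant key ∉ panel of normals** — site-level recurrence across
  in-house exomes (here 45), which removes platform artefacts; matching
  is by exact key, not gene.

The predicates are independent, so the surviving set is order-invariant,
idempotent, and monotone in each parameter; the ordered attrition report
merely attributes each removal to the first rejecting filter.

### De novo and segregation

`de_novo` requires *positive evidence of absence* in both parents: no
carrier call at the key AND parental site depth ≥ `min_parent_depth`
(default 15). Parent VCFs may carry homozygous-reference records at sites
of interest to transport that coverage evidence. A missing parent or thin
coverage yields `unresolved` — by construction the verdict can never be
de novo with a missing datum. Segregation in a family is the strict
equality of carrier and affection status over all members with known
status, vacuously true in an all-negative family (documented edge case).

## Consequence annotation

HGVS `c.` descriptions are parsed into structured edits (substitution,
deletion, duplication, insertion, delins; intronic offsets as
anchor+offset pairs) and mapped through a transcript model that owns all
coordinate conversions (VCF/HGVS 1-based at the surface, 0-based
half-open internally). Classification rules:

* substitutions translate the affected codon before/after (same residue →
  synonymous; stop → nonsense; else missense, `p.R684C` style with `X`
  for stop);
* exonic indels are frameshift unless the net length change is a multiple
  of 3 (a duplication of *k* bases counts as an insertion of *k*);
* edits with intronic offsets are `splice_region` within 15 bases of an
  exon boundary and `intronic` beyond — the window follows common
  annotation practice, since no single standard exists;
* **truncating** = nonsense, frameshift, or a splice-region deletion that
  removes ≥1 base of the essential windows (acceptor −12…−1, donor
  +1…+6), i.e. ablates the site;
* **NMD escape**: a truncating change confined to (or ablating the
  acceptor of) the last exon leaves no exon-junction complex downstream
  of the premature stop, so the transcript escapes nonsense-mediated
  decay. The stricter 50-nt-from-last-junction rule is deliberately not
  the default: for the mutations handled here the two coincide, and the
  last-exon form states the biological argument directly. Including a
  last-exon-acceptor-ablating deletion among NMD-escaping truncating
  events is a package choice: the aberrant transcript either retains the
  terminal intron or uses a cryptic acceptor, in both cases altering only
  the final-exon product.
* **CpG context**: a substitution sits in a CpG when (ref C, next base G)
  or (ref G, previous base C) — the two strands of one methylatable
  dinucleotide, whose deamination explains recurrent C>T/G>A hotspots
  such as R684C. Computed on the pre-mRNA so exon-boundary neighbours are
  genomic, not spliced.
* **conservation**: fraction of non-gap homolog residues matching the
  human residue at the alignment column (human row first, gaps in the
  human row skipped when mapping positions). Order-invariant in the
  homolog rows.

Missense deleteriousness prediction (PolyPhen/SIFT-style) is external
tooling and out of scope.

## Splice consensus

Clinical splice assessment aggregates several predictors rather than
trusting one. The two-tier procedure: two *primary* scorers evaluate the
variant in two modes — weakening of the nearest annotated site
(wildtype loss) and creation of a novel site within ±25 bases of the edit
(cryptic gain; each scorer picks its own best novel position, leftmost on
ties). The tier triggers when **both** primary scores change by more than
the threshold (default 20%) *in the same direction* for at least one
mode; discordant directions do not trigger, because the consensus being
sought is directional. If triggered, three *confirmatory* scorers run and
the verdict is `disruptive` only on unanimous direction across all five
(any decrease for loss, any increase for gain); triggered but split is
`indeterminate`.

Percent change is `100·(s_var − s_wt)/max(|s_wt|, 1e-9)`. Log-odds scores
cross zero, where relative change is ill-defined; the ε-guard keeps the
sign and makes near-zero wildtype sites effectively always exceed the
threshold, which is the conservative direction (they reach tier 2, where
unanimity still gates the verdict). An absolute-difference mode can be
substituted by wrapping the scorers.

The five bundled scorers are log₂-odds PWMs (`Σ log₂(f/0.25)`, pseudocount
at training) over donor 9-mers (3 exonic + 6 intronic) and acceptor
23-mers (20 intronic + 3 exonic), each trained on its own simulated draw
of site examples with its own sample size and pseudocount. They are this
package's own scorers implementing a small protocol
(`score(window, site_type)`); any external predictor wired through that
protocol participates in the same consensus.

## Phenotype statistics

Measurements convert to SD (z) scores against a growth reference table
(age bucket × sex, mean and SD in cm). Threshold counts use the
comparison the clinical wording demands: "at least +2 SD" is `≥`, so a
child at exactly +2.0 is overgrown; "greater than +4 SD" is `>`. Missing
values (`nk`) are excluded from the statistic they would enter and the n
used is reported — they never become zeros. Study eligibility partitions
cases into `global` (height and OFC ≥ +2), `tall_only`,
`macrocephaly_only`, and `not_eligible`, with a missing measurement
treated as below threshold for category assignment only. The bundled
19-case table already carries SD units and bypasses conversion; the
shipped growth reference is a synthetic, schema-compatible stand-in
(national growth-chart data are licensed), adequate for exercising the
conversion arithmetic but not for clinical use. No age/sex
renormalisation is applied to tabulated SDs — they are consumed as
printed. LMS centile-curve modelling is out of scope.

## Synthetic data: what it emulates, what it does not

`simulate_cohort` emulates the *statistical shape* of a 4-case exome
discovery design: per sample, 5,000 background variants on one synthetic
contig (`chrSim`), 40% dbSNP-tagged, 10% low-depth (<15 reads), 20%
intronic/synonymous, depths negative-binomial (mean 60, dispersion 5 —
typical capture-exome coverage with realistic overdispersion), ~0.1%
multi-allelic sites, spread over 1,000 genes; plus exactly one clean
planted variant per case in the planted gene (by default the four
discovery mutations of the bundled table). Parents inherit about half of
the child's background each, never the planted variant, and are deeply
covered at its locus; one father is unsampled, mirroring a 7-of-8-parents
cohort. Controls (115) carry only dbSNP-tagged or intronic/synonymous
variation in the planted gene. The background proportions are invented —
no per-filter attrition counts are reproducible from real data — so the
simulation validates *machinery* (filters, intersection, trio logic),
not human genome statistics: real allele-frequency spectra, LD, gene
length variation, mapping artefacts and batch effects are all absent,
and passing tests say nothing about those.

The unique-causal-gene property is **enforced, not sampled**: variants
that would survive the cascade are assigned only to genes blocked in at
least one other affected sample (gene *g* is blocked in sample
`g mod n_affected`), so no background gene can survive in every case and
discovery is deterministic at every seed. At these densities (~2,100
surviving variants per sample over 1,000 genes) an unconstrained
background would put hundreds of genes in the full intersection — a
4-case cohort over a 1,000-gene universe is far below the diversity of a
real exome, and honest backgrounds are available via
`enforce_unique_causal=False` for power experiments.

The transcript fixture is built, not downloaded: a 20-exon gene (first
exon non-coding, 19 coding) whose 747-codon CDS pins exactly the codons
the bundled mutation table constrains (codon 684 = CGC, 733 = TAC, the
`AGGCTGAT` duplication unit, the intron-19 pyrimidine tract
`TTCCTGTTGTTTCA`, SET domain 612–727, post-SET 728–746, …), with all
other codons drawn from a fixed internal seed. The builder re-classifies
all 19 mutations and raises rather than emit a fixture on which any
printed protein change fails. It is a synthetic stand-in for the real
locus — the real genomic sequence is deliberately not bundled — so only
table-constrained positions are biologically meaningful.

## Determinism and problem sizes

Every generator output is a pure function of its seed (`numpy`
`default_rng` with spawn-style key lists; VCFs carry no timestamps), so
identical seeds give byte-identical files. The bundled analyses use the
cohort defaults above; the acceptance script re-runs discovery on 100
seeded cohorts and the filter-cascade oracle comparison on 10 cohorts of
1,000 background variants — sizes chosen to give exact (enforced)
properties many independent chances to fail while keeping a laptop run in
tens of seconds. The orchestrator (`mendelseek run`) writes its
reproducibility record (command, config snapshot, seed, input checksums,
timestamp) before finalising outputs; the record's timestamp is the one
intentionally non-deterministic output.

## Known limitations

* Intersection discovery assumes complete penetrance and annotation:
  one miscalled or unannotated causal variant in one case empties the
  candidate list.
* The dbSNP blanket exclusion would discard known pathogenic variants
  catalogued after submission to dbSNP.
* PWM scorers capture positional composition only — no pairwise
  dependencies (maximum-entropy style) and no branch-point model; their
  absolute scores are not comparable to any published predictor's.
* The splice assessment evaluates one site per variant (the nearest), in
  pre-mRNA coordinates on the sense strand; minus-strand models are
  supported for coordinate mapping but not for pre-mRNA-based scoring.
* `nk` inheritance entries make de novo counts lower bounds, which is how
  they are reported.
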