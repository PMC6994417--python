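# Methods

This note documents the models, conventions and design choices behind
`somatic_screen`: what the filtering cascades assume, what the
synthetic cohort generator does and does not emulate, and where the
design was genuinely open.

## Variant identity and coordinates

All set operations (panel-of-normals membership, RNA concordance,
recurrence) use the sample-agnostic key `(chrom, pos, ref, alt)` with
1-based, fully closed coordinates (VCF convention). Indel alleles are
reduced to minimal representation (shared suffix, then shared prefix,
trimmed) before keying, so differently padded representations of the
same event compare equal. Full left-alignment against the reference is
not performed: the generator emits minimal representations directly,
and consumers of external VCFs should left-align upstream
(`bcftools norm`) if their caller does not.

VAF is defined as `alt_reads / depth` with depth the total reads at the
site; a site with zero depth has VAF 0 by convention. The stored VAF is
validated against the counts to 1e-9 at construction and at I/O.

## The two cascades

Both cascades are pure conjunctions of per-variant gates, evaluated in
a fixed order (cheapest first). Every gate is evaluated for every
variant — there is no short-circuiting — so the trace records the full
cascade and gate order can never change the retained set, only which
gate is *attributed* with a rejection.

Inequality conventions differ deliberately between the cascades: the
discovery cascade uses strict thresholds (VAF > 10%, normal VAF < 3%,
tumor-only depth > 20 and VAF > 25%), while the targeted cascade uses
inclusive ones (VAF ≥ 10%, ≥ 3 variant reads), matching how each
stage's criteria are conventionally stated ("greater than" vs "at
least"). A 100-variant randomized boundary test pins the strict
semantics of the tumor-only gate.

Three evidence thresholds are not fully determined by the filter
definitions and are fixed here as named, overridable parameters:

- **Panel-of-normals membership** requires ≥ 2 variant-supporting reads
  in at least one normal. "Present in a normal" must tolerate
  reference-only coverage rows (depth recorded, zero alt reads) without
  polluting the panel, and a 1-read threshold would let sequencing
  noise in normals veto true somatic calls.
- **RNA concordance** likewise requires ≥ 2 supporting RNA reads at the
  identity key, and is applied only to patients who were RNA-sequenced
  (pass-through otherwise).
- **Hyperplastic-control subtraction** uses the same membership rule as
  the panel of normals.

The germline-database gate rejects dbSNP-listed or 1000-Genomes-
nonzero variants *unless* they are in COSMIC; since a later gate
requires COSMIC membership outright in both cascades, the exemption
never changes the retained set — both gates are still evaluated and
traced separately for auditability.

The 41-base context-uniqueness gate is an exact-match stand-in for
BLAT-style multi-mapping detection of captured pseudogenes: the
variant's 20-base-flank context must occur exactly once in the
reference, counting overlapping hits on both strands. (A true
odd-length reverse-complement palindrome cannot exist; the equality
guard merely keeps the rule total.) Exact matching is stricter than
BLAT's tolerant alignment, which is the right behaviour for the
synthetic reference where duplications are planted as exact copies;
against a real genome a practitioner would substitute an aligner-based
check behind the same interface.

Manual review of candidate calls (IGV-style curation) has no automated
counterpart here; on real data the cascades should be read as the
reproducible core of a screen whose final call set may still warrant
visual inspection.

## Functional consequence

Missense variants are kept when at least 4 of the 9 predictor slots
(Polyphen2, Polyphen2_HVAR, Polyphen2_HDIV, LRT, MutationTaster,
FATHMM, RadialSVM, LR, MutationAssessor) are damaging. A missing
prediction counts against the vote — the conservative reading of an
undefined case. Truncating and splice-disrupting variants pass the
consensus step unconditionally, since substitution predictors do not
score them. The consensus is applied after the targeted cascade and
before recurrence counting; the discovery burden statistics are
computed on cascade-retained variants without the vote, which matches
where each criterion belongs in the two-stage design (the vote is part
of the targeted recurrence analysis). Predictor outputs and ΔΔG values
are consumed as annotations, never computed.

Protein-stability classification is a pure threshold: destabilizing
iff ΔΔG < −0.5 kcal/mol (strict; −0.5 itself is non-destabilizing),
`not_applicable` when no ΔΔG is available.

## Survival estimation

The Kaplan–Meier estimator and the Mantel–Cox log-rank test are
implemented natively (the summed hypergeometric-variance form, not the
pooled (O−E)²/E approximation); `lifelines` appears only in the test
suite as an independent oracle, where both agree to machine precision
on randomized cohorts. Ties follow the standard convention: deaths
precede censorings at the same time. The median is the smallest event
time with S(t) ≤ 0.5, evaluated with a 1e-9 absolute tolerance because
a running float product of risk-ratios lands a hair under an exact 0.5;
a curve sitting exactly on a 0.5 plateau therefore reports the plateau
start. The interpolated midpoint rule (which would report 2.5 for four
uncensored times {1,2,3,4}) is deliberately not used; this
implementation reports 2, agreeing with `lifelines` and R `survival`.

## The synthetic cohort generator

The generator emulates a 71-tumor two-stage study: 21 discovery tumors
(4 with matched saliva normals, 18 RNA-sequenced) and 50 extension
tumors (8 matched), 20 unmatched donor normals forming the
panel of normals, and 8 hyperplastic lymph-node controls. All sequence
context lives on a 1-Mb uniform-random toy reference with one 2-kb
interval per panel gene (137 genes: 92 discovery + 45 literature) plus
off-panel "exome" filler genes; a spare region hosts duplicated
contexts.

Three planted variant classes define the recovery semantics:

- **Somatic** variants are constructed to survive both cascades: depth
  80–400×, VAF drawn above 25% (support recomputed so the strict gate
  holds after rounding), COSMIC member, zero population frequency,
  absent from every normal, unique context, nonsynonymous effect
  (70% missense / 10% stop-gain / 10% frameshift / 10% splice for
  unplanned genes), ≥ 4 damaging predictor calls. Per-gene
  mutated-sample counts follow the profile exactly via a
  capacity-aware assignment (discovery samples can host at most their
  profiled burden; extension samples are unconstrained), and each
  discovery sample is topped up with off-panel filler mutations to its
  exact profiled burden.
- **Germline** contaminants are drawn per tumor from a shared pool of
  300 common-SNP sites (dbSNP-listed, 1000-Genomes AF 2–45%, not in
  COSMIC), at ~50% VAF in tumor and matched normal alike.
- **Artifacts** are drawn from a shared pool of 100 recurrent-error
  sites, each planted with ≥ 2 supporting reads in at least one
  panel-of-normals donor and one hyperplastic control, so both
  cascades' subtraction gates remove them; the first five artifact
  contexts are additionally copied to a second locus to exercise the
  multi-mapping gate. Contamination defaults (50 germline + 20
  artifact variants per tumor) are large enough that any filter defect
  shows up as a nonzero contaminant survival count.

Substitutions are drawn with P(transition) = r/(1+r) for the profiled
Ti/Tv ratio r (reference value 1676/857 ≈ 1.9557) and
P(ref ∈ {G,C}) = `gc_bias`. The reference profile sets `gc_bias` = 0.65:
the emulated spectrum is G/C-targeted, and only the direction is a
stated property, so a moderately biased value was chosen once; tests
assert the direction, not the constant.

Because the planted structure is profile-driven and every gate outcome
is forced by construction, the recovered statistics (gene counts,
burden medians, survival medians) are invariant to the generator seed;
the seed only permutes positions, read counts and patient identities.

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: read-level errors and coverage
heterogeneity, trinucleotide signature structure, copy-number events,
subclonal VAF distributions, tumor-in-normal contamination, and
borderline variants that straddle gate thresholds. The recovery suite
demonstrates that the cascades implement their definitions exactly,
not that those definitions are optimally calibrated for a given assay.

## The synthetic clinical table

The generator constructs survival times so the published-style summary
statistics come out exactly rather than in expectation:

- Each group's Kaplan–Meier median is exact: after any early
  censorings the group's at-risk count is arranged to be even, and the
  median-rank death is placed exactly at the target time, so S first
  touches 0.5 there.
- The 36-month overall-survival estimate is exact. With no censoring
  before 36 months, S(36) over n patients can only be k/n, and 0.24 is
  not expressible over 61 — so the generator instead censors a block
  of patients at the start of follow-up (before the first event),
  shrinking the risk set to the smallest size where the target
  proportion is attainable (61 → 50 at risk; 38 deaths by 36 months
  gives S(36) = 12/50 = 0.24 exactly), and censors nobody else between
  then and 36 months.
- Within the feasible window, the mutated group is assigned the
  maximal number of deaths by 36 months and the wild-type group the
  minimal number: the planted effect is markedly inferior survival for
  the mutated group, and this allocation makes the log-rank contrast
  reflect it (reference fixture: χ² = 11.8, p ≈ 6 × 10⁻⁴).
- All times stay inside the configured follow-up range; survivors are
  censored after 36 months up to the range maximum.

The construction self-checks with the package's own estimator and
raises if the configured quantities are jointly infeasible at the
given group sizes.

## Profile constants

| Parameter | Default | Meaning |
|---|---|---|
| `exome_mb` | 54 | Callable exome size (Mb); ties the burden median of 135 to the rate median of 2.5/Mb |
| `titv_ratio` | 1676/857 | Target transition:transversion ratio of planted SNVs |
| `gc_bias` | 0.65 | P(reference base ∈ {G,C}) for planted SNVs |
| `germline_per_tumor` / `artifacts_per_tumor` | 50 / 20 | Contaminants per tumor table |
| `germline_pool` / `artifact_pool` | 300 / 100 | Shared contaminant site pools |
| `pon_min_alt_reads` / `rna_min_alt_reads` | 2 / 2 | Evidence thresholds (see cascades) |
| burden list | 21 values, median 135, range 6–204 | Individual values are synthetic subject to the profiled median and range only |

The per-sample burden list and the per-gene stability plan (missense
and destabilizing counts for FAT1, LATS1, STK3, TP53, TP63, ATM) are
fixed in the packaged profile so recurrence, burden and
destabilizing-fraction statistics are deterministic.

## Numerical and degenerate-input conventions

- Ti/Tv with zero transversions is undefined and flagged (`None`), not
  infinite; the truncated one-decimal rendering (1.9557 → 1.9) is
  emitted alongside full precision.
- Recurrence counts samples, not variants: multiple hits of one gene
  in one sample collapse to a single matrix entry; recurrent genes are
  ordered by count descending, then name.
- An empty cohort, a zero-SNV spectrum, an empty survival table, a
  log-rank with no events, and a panel overlap all raise rather than
  return sentinel values.
- Problem sizes throughout (1-Mb reference, 71 tumors, ~10k variant
  records, 61 clinical records) keep a full generate–filter–analyze
  cycle at a few seconds on one core.
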