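# Methods

This note documents the models and procedures implemented in `ampliprofile`,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Primer arithmetic

A degenerate primer is the equimolar mixture of the plain oligos obtained by
substituting each IUPAC code with one of its bases; its *degeneracy* is the
product of per-position code cardinalities. A primer is said to perfectly
match a template flank iff the template base lies in the primer code's base
set at every position — equivalently, iff some realization matches exactly.
Mismatch positions are reported as 0-based offsets from the primer's 5' end;
distance 0 to the 3' end denotes the terminal base, which matters because 3'
mismatches are the most disruptive to polymerase extension. Reverse primers
are stored 5'→3' as synthesized and compared against the reverse complement
of the plus-strand flank, so both senses share one coordinate convention.

Two counts are defined for a primer *set*: `unique_union` (strict
deduplicated union of realizations) and `combined_uniq` (sum of per-primer
realization counts, the figure conventionally tabulated for a combined row).
They differ only when members share a realization; in the packaged panel the
pooled-PCRs reverse trio shares exactly one oligo (`GGACTCGCTCTGGTTGTAGT`,
encoded by both r1 and r3), making the tally 22 against a union of 21.

Pool fractions follow the design rule that a primer (or primer pair)
expected to serve more target haplotypes is more concentrated:
`fraction_i = 100·w_i/Σw` with integer haplotype-count weights, rounded to
one decimal half away from zero. Rounding drift of the sum is bounded by
0.05 per member.

A target haplotype is always a *phased pair* of forward and reverse flanks.
Coverage matrices therefore score a PCR as matching a haplotype only when
both of its sides are perfectly matched, and summarise per haplotype the
number of perfectly matching PCRs (`pcr_match`) and their summed share of
the sequencing pool (`pool_match`).

## Amplification-bias model

PCR-cycle kinetics are not simulated. All bias is collapsed into one
end-point efficiency multiplier per allele and reaction, which is what read
proportions measure. For each side of the amplicon,

    side_score = max over same-sense primers of
                 concentration(primer) · λ^(internal mismatches) · λ₃^(3'-window mismatches)

and the reaction efficiency is the product of the two side scores. Mismatch
counts are those of the primer's best-matching realization. With the
`effective_concentration` flag (default on), the concentration of the
intended realization of a degenerate primer is its pool proportion divided
by the primer's degeneracy — the intended oligo is diluted among its
co-synthesized suboptimal variants. A perfectly matched non-degenerate
primer pair at proportion 1.0 therefore has efficiency exactly 1.

Defaults: λ = 0.2 per internal mismatch, λ₃ = 0.02 for mismatches within the
last w = 3 bases of the 3' end. These are calibration constants, not claims:
quantitative mismatch effects are context-dependent and no usable
mismatch-to-efficiency function exists. They were chosen once so that a
single degenerate pair over the default flank set spans slightly more than
two orders of magnitude in efficiency (125× between best and worst), the
regime reported for real multi-template amplicon assays of this family.

Reads are then a multinomial draw with probabilities proportional to
efficiency × copy number (copy 2 at a homozygous locus, else 1). Multi-PCR
assays first split the total depth across PCRs by their sequencing-pool
fractions, then draw each PCR independently.

## Synthetic data generator

`simulate_population` draws a pool of alleles (default 13) distributed
round-robin over loci (default 7; a 13-allele/7-locus pool leaves one locus
monomorphic, as happens in real multigene families), assigns each allele a
~230 bp random core framed by a phased flank haplotype, and samples diploid
genotypes per locus (uniform allele frequencies unless given). Default
study-scale conditions are 18 individuals and 2000 reads per
individual-strategy unit.

The default flank-haplotype set is built from the packaged panel:
frequent flanks recur on several haplotypes (mirroring the haplotype counts
behind the pool weights) and the forward/reverse pairing respects the phase
structure the multi-PCR design was built around — every haplotype except
one is perfectly amplifiable by at least one of the four low-degeneracy
primer pairs, and one haplotype (fd with rg) is perfectly matched only by
the weighted non-degenerate mix. That last haplotype reproduces the
empirical phenomenon of an allele that every simple strategy drops.

Artefacts are overlaid on sampled reads with per-read ground truth:

* **chimeras** (default rate 0.01/read): prefix of one parent + suffix of a
  second, distinct parent, parents drawn abundance-weighted, breakpoint
  uniform over the positions at which the product differs from both parents
  (a "crossover" inside a shared prefix or suffix would reproduce a parent
  sequence and is not a chimera);
* **substitutions** (1e-3/base) uniform over positions and alternative bases;
* **homopolymer indels** (0.02 per run ≥ 3): a run lengthened or shortened
  by one base — the dominant error mode of pyrosequencing chemistries.

All randomness flows from one seed through a single `numpy` generator;
outputs are byte-reproducible.

What the generator does *not* emulate: context-dependent efficiency shifts
(real efficiencies vary with the competing genotype; here they are fixed per
allele and strategy), quality scores, tag demultiplexing, primer-dimer and
off-target products, and chimera breakpoint hotspots. Passing benchmarks on
this generator therefore demonstrates correctness of the pipeline's logic
under the stated bias model, not performance on any particular real dataset.

## Validation protocol

Within each independent PCR, variants are dereplicated and ranked by count
(ties lexicographic, making every downstream decision order-invariant).
In descending rank:

1. a variant exactly reconstructable as `prefix(p1, k) + suffix(p2, len−k)`
   from two strictly more frequent variants of the same PCR is an artefact
   (chimera). The scan considers single crossovers only and returns the
   smallest breakpoint, parents tie-broken by rank; it is implemented via
   longest-common-prefix/suffix arrays, giving exact agreement with an
   exhaustive pair × breakpoint search at a fraction of the cost;
2. singletons are artefacts (the top variant of a PCR is exempt: it is
   scored as an allele regardless of count);
3. a variant with count > 1, within 2 differences of a higher-ranked variant
   of the same PCR and present in no independent PCR is an artefact.
   "Differences" are Levenshtein edit distances (computed with edlib), so
   equal-length variants reduce to Hamming distance and a homopolymer indel
   counts as one difference;
4. a variant more than 2 differences from every higher-ranked variant and
   present in no independent PCR is left unclassified for manual review;
5. the rest are allele candidates.

"Independent PCR" defaults to *any* other amplicon in the dataset, including
other individuals: in a low-diversity population every allele is expected in
several individuals, and across-individual replication substitutes for
systematic within-sample replication. A strict same-individual scope is
available (`scope="individual"`).

Allele scoring is two-pass. Pass 1 validates the most frequent variant of
every PCR. Pass 2 iterates amplicons in manifest order to a fixpoint: a
candidate whose sequence is already validated is called wherever its count
exceeds every artefact's count in that PCR. Candidates matching a validated
allele but out-counted by some artefact are logged for manual checking, with
`explanation=True` iff every out-counting artefact is a chimera of alleles
already called in that PCR; `accept_manual=True` promotes exactly those
entries, reproducing the operator's decision. Unclassified variants never
enter the validated set automatically.

## Efficiency statistics

The per-copy read fraction of allele *i* in an amplicon is
`%reads_i = 100·reads_i/(Σ_alleles reads · copy_i)`; only reads whose
sequence exactly matches a dataset-validated allele enter the numerator and
denominator. Crucially, these counts are taken from the raw reads of every
validated allele, *not* from per-amplicon call status: an allele validated
elsewhere but too rare to be scored in one amplicon still contributes its
small read count there. (The call-based view remains available on
`AlleleCallSet.calls`.) Copy number defaults to 1 for real data — locus
assignment within a multigene family is generally unknown — and is read
from the truth tables for synthetic runs.

Standardized amplification efficiency divides each allele's mean per-copy
fraction over its carriers by the minimum over alleles with nonzero means;
never-observed alleles get efficiency 0 and are excluded from the reference.
Strategy evenness is compared by a one-tailed F test on natural-log
standardized efficiencies (zeros excluded with a warning), F = var(A)/var(B)
against F(n_A−1, n_B−1).

Detection probability of an allele under a strategy is the fraction of its
carriers (per the *complete* profile — the union of all strategies' calls
per individual, the best available approximation to the true genotype) in
which the strategy called it. Profile completeness is the percentage of an
individual's complete profile recovered.

The allele-vs-artefact rank offset places the most frequent artefact of an
amplicon at zero; positive values mean the allele out-ranked every artefact.
In an amplicon with no artefact the reference rank is taken just below the
least frequent variant (n+1), keeping all offsets positive while preserving
the "larger is better" ordering.

One caveat for parameter-recovery exercises: under the penalty model,
alleles sharing a flank-mismatch profile have *identical* true
efficiencies. Element-level rank correlations between truth and estimate
are then capped below 1 by the ties themselves (with 7 of 13 alleles tied,
Spearman cannot exceed ≈0.9 however good the estimate), so recovery is
assessed between distinct true-efficiency classes and their mean estimated
efficiency.

## Coverage rarefaction

Each (individual, strategy) read pool — multi-PCR strategies are pooled
across their PCRs, matching how such amplicons share one tag in a
sequencing run — is bootstrapped (sampling with replacement, so nominal
depths above the real read count are allowed) over a depth grid, default
0–4500 in steps of 10 with 100 iterations. Per iteration, an allele of the
individual's full-data validated profile counts as scored when its exact
sequence is drawn at least `min_count` times (default 2, the singleton-rule
analogue; 1 is supported). Re-running the full cross-amplicon validation
inside every bootstrap iteration is neither possible (replication structure
changes under subsampling) nor what the exercise measures. Completeness is
averaged across iterations and individuals; the 95% CI is the 2.5/97.5
empirical percentile band (no CI method is canonical here; percentile bands
are assumption-free). Resampling uses one multinomial per unit and depth
over bins "each profile allele + everything else", which is exact for this
scoring rule and keeps the full default grid tractable. Curves are
deterministic for a fixed seed and independent of unit order (each strategy
gets a CRC-derived child seed).

Benchmark sizes: the packaged tests run the accumulation comparison on a
0–1500 × 50 grid with 40 iterations, where the qualitative result — all
mean curves non-decreasing, the conventional curve plateauing below both
pooled strategies — is already fully expressed; the defaults remain the
full grid.

## Numerical and degenerate-input conventions

* Dereplication ties: lexicographic; chimera tie-breaks: smallest
  breakpoint, then parent rank, deterministic.
* Fraction vectors must sum to 1 ± 0.01 (coverage matrices, PCR assays);
  pool-weight vectors must be positive integers.
* Zero-depth draws yield empty read sets; an all-zero efficiency vector at
  positive depth is an error (no amplifiable template).
* Empty amplicons contribute no classifications; an amplicon with zero
  allele reads is skipped (with a warning) by the fraction statistics.
* The F test refuses groups of fewer than two values or a zero-variance
  denominator.

## Known limitations

* Efficiencies are per-allele constants; competition effects beyond shared
  multinomial normalisation (primer depletion, inhibition, genotype-context
  shifts) are not modelled.
* The chimera filter tests exact single crossovers only; chimeras with
  additional polymerase errors appear as error-derivatives and are caught by
  the similarity or singleton rules instead.
* Copy numbers above 2 (co-amplifying duplicated loci sharing an allele
  sequence) are not represented.
* The rarefaction scoring rule is a per-iteration approximation of the full
  protocol; absolute plateau heights depend on `min_count`, though strategy
  orderings are stable to it.
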