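# ampliprofile

Amplicon genotyping of multigene families with PCR-bias-aware allele calling.

When a multigene family (MHC class I is the motivating case) is genotyped by
amplifying one exon across all its paralogous loci with a single degenerate
primer pair, alleles whose flanking sequences mismatch the primers amplify
orders of magnitude less efficiently than perfectly matched ones. The result
is allelic dropout that deeper sequencing cannot fix: a poorly amplified
allele gains reads with coverage, but rarely gains *rank*, and may stay below
the most common artefact. `ampliprofile` provides the computational machinery
to design around and to quantify this problem:

* **primer toolkit** — IUPAC degenerate-primer expansion and union counting,
  primer–template mismatch profiling (0-based 5' offsets, distance to the 3'
  end), haplotype coverage matrices for multi-PCR designs (`PCR match`,
  pool-weighted `pool match`), and weighted primer-pool design
  (`fraction_i = 100·w_i/Σw`, one-decimal half-away-from-zero rounding);
* **synthetic data** — a generator for diploid multi-locus genotypes and
  per-amplicon read sets with mismatch-driven amplification bias
  (per-mismatch penalty λ, harsher 3'-window penalty λ₃, effective primer
  concentration = pool proportion / degeneracy) plus pyrosequencing-style
  artefacts (single-crossover chimeras, substitutions, homopolymer indels),
  with complete per-read ground truth;
* **allele validation** — the replicate-aware protocol that does *not* assume
  alleles out-rank artefacts: per-PCR dereplication; chimera, singleton and
  low-frequency-similarity filtering (edit distance ≤ 2); cross-PCR
  replication; two-pass allele scoring (top variant per PCR, then rescue of
  known alleles above all artefacts) with a manual-check log;
* **efficiency statistics** — per-copy read fractions
  `%reads_i = 100·reads_i/(Σreads_alleles · copy_i)`, standardized
  amplification efficiencies (least amplified allele = 1), per-allele
  detection probabilities, profile completeness, allele-vs-top-artefact rank
  offsets, and the one-tailed F test on log efficiencies;
* **coverage rarefaction** — bootstrap subsampling of each amplicon over a
  depth grid with per-iteration allele scoring, yielding completeness
  accumulation curves with empirical 95% CIs.

Three amplification strategies are modelled throughout: `conventional` (one
highly degenerate pair), `pooled_pcrs` (several low-degeneracy pairs in
separate PCRs, pooled for sequencing by expected locus counts) and
`pooled_primers` (one PCR with a weighted mix of non-degenerate primers).
The published lynx MHC class I exon 2 panel ships as `ampliprofile.panels`.

## Worked example

```python
from ampliprofile import panels, simulate, validate
from ampliprofile import stats as st
from ampliprofile.primers import expand_degenerate, pool_fractions

# 1. primer arithmetic: the S in f1 encodes two oligos
print(sorted(expand_degenerate(panels.POOLED_PCRS_F1)))
# ['GCTCCCACTCCCTCAGGTAT', 'GCTCCCACTCCCTGAGGTAT']
print(pool_fractions([5, 2, 2, 1, 1]))
# [45.5, 18.2, 18.2, 9.1, 9.1]      <- forward-mix concentrations

# 2. simulate a small experiment and validate alleles
ds = simulate.simulate_dataset(n_individuals=6, n_loci=7,
                               allele_pool_size=13, depth=1500, seed=42)
cs = validate.validate_amplicons({rs.key: rs.reads for rs in ds.read_sets})
print(len(cs.alleles))
# 10                                 <- alleles validated across 36 amplicons

# 3. compare strategies
amplicons = {rs.key: rs.reads for rs in ds.read_sets}
complete = {g.individual_id: {c for k, called in cs.calls.items()
                              if k[0] == g.individual_id for c in called}
            for g in ds.genotypes}
for strat in ("conventional", "pooled_primers"):
    counts = st.strategy_allele_counts(amplicons, cs.alleles, strat)
    eff = st.standardized_efficiencies(counts, complete)
    det = st.detection_stats(cs.calls_by_individual(strat), complete)
    print(strat, round(eff.standardized_efficiency.max(), 1),
          round(det.per_individual.completeness_percent.mean(), 1))
# conventional 124.6 86.6
# pooled_primers 11.3 100.0
```

The last two lines are the story in miniature: under the degenerate pair the
best-amplified allele gets ~125× the per-copy reads of the worst and
individual profiles are ~87% complete, while the weighted non-degenerate mix
compresses the spread to ~11× and recovers every allele.

The same stages are scriptable via the CLI:

```bash
ampliprofile expand GCTCCCAYTCCYTGAKGTAT --count-only   # 8
ampliprofile design-pool 5 2 1 1 1 1 1
ampliprofile run --out runs/demo --seed 7               # simulate→validate→stats→rarefy
```

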