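"""Synthetic multigene-family genotypes and amplicon read sets.

The generator emulates the statistical structure of a deep amplicon-typing
experiment on a diploid multigene family: a pool of distinct alleles spread
over several paralogous loci, diploid genotypes drawn per locus, per-allele
amplification efficiencies driven by primer-flank mismatches and effective
primer concentration, multinomial read sampling at a chosen depth, and
pyrosequencing-style artefacts (single-breakpoint chimeras, base
substitutions, homopolymer indels).  Every read carries its ground truth so
that validation and statistics modules can be scored against it.

PCR-cycle kinetics are not simulated: all amplification bias is collapsed
into a single per-allele end-point efficiency multiplier, which is what read
proportions actually measure.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import iupac, panels
from .primers import CONVENTIONAL, STRATEGIES, PCRAssay, mismatch_profile

_BASES = np.array(list("ACGT"))
_HOMOPOLYMER = re.compile(r"(.)\1{2,}")


def _lcp(a: str, b: str) -> int:
    i, m = 0, min(len(a), len(b))
    while i < m and a[i] == b[i]:
        i += 1
    return i


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedAllele:
    """One allele: a core sequence framed by a phased pair of priming flanks."""

    allele_id: str
    core_sequence: str
    forward_flank: str
    reverse_flank: str  # plus strand, 3' end of the amplicon
    locus_id: str

    @property
    def sequence(self) -> str:
        """Full amplicon sequence including both priming regions."""
        return self.forward_flank + self.core_sequence + self.reverse_flank


@dataclass(frozen=True)
class IndividualGenotype:
    """Diploid genotype: one allele pair per locus."""

    individual_id: str
    loci: tuple[tuple[str, tuple[str, str]], ...]  # (locus_id, (allele, allele))

    def allele_ids(self) -> set[str]:
        return {a for _, pair in self.loci for a in pair}

    def copy_number(self, allele_id: str) -> int:
        """2 where the individual is homozygous for the allele at its locus, else 1 (0 if absent)."""
        for _, (a1, a2) in self.loci:
            if allele_id in (a1, a2):
                return 2 if a1 == a2 else 1
        return 0


@dataclass(frozen=True)
class EfficiencyModel:
    """Mismatch-driven amplification-efficiency model.

    Each internal primer-template mismatch multiplies an allele's efficiency
    by ``lambda_internal``; mismatches within the last ``three_prime_window``
    bases of the primer's 3' end multiply it by the much harsher
    ``lambda_three_prime`` (3'-terminal mismatches are the most disruptive to
    extension).  With ``effective_concentration`` set, the concentration of
    the best-matching realization of a degenerate primer is its pool
    proportion divided by the primer's degeneracy, modelling the dilution of
    the intended oligo among the suboptimal co-synthesized ones.  A perfectly
    matched non-degenerate primer pair at proportion 1.0 has efficiency 1.
    """

    lambda_internal: float = 0.2
    lambda_three_prime: float = 0.02
    three_prime_window: int = 3
    effective_concentration: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lambda_internal <= 1):
            raise ValueError("lambda_internal must be in (0, 1]")
        if not (0 < self.lambda_three_prime <= 1):
            raise ValueError("lambda_three_prime must be in (0, 1]")


@dataclass(frozen=True)
class ArtefactModel:
    """Rates of the artefact classes typical of 454-style amplicon runs."""

    chimera_rate: float = 0.01       # per read
    substitution_rate: float = 1e-3  # per base
    homopolymer_indel_rate: float = 0.02  # per homopolymer run >= 3

    def __post_init__(self) -> None:
        for r in (self.chimera_rate, self.substitution_rate, self.homopolymer_indel_rate):
            if not (0 <= r <= 1):
                raise ValueError("artefact rates must lie in [0, 1]")


@dataclass(frozen=True)
class ReadOrigin:
    """Ground truth for one read."""

    allele_id: str | None = None
    parents: tuple[str, str] | None = None
    breakpoint: int | None = None
    errored: bool = False

    @property
    def kind(self) -> str:
        if self.parents is not None:
            return "chimera"
        return "error" if self.errored else "allele"


@dataclass
class AmpliconReadSet:
    """All reads from one (individual, strategy, PCR) combination, with truth."""

    individual_id: str
    strategy: str
    pcr_id: str
    reads: list[str]
    origins: list[ReadOrigin]

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.origins):
            raise ValueError("truth table must cover every read")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.individual_id, self.strategy, self.pcr_id)

    def read_ids(self) -> list[str]:
        stem = f"{self.individual_id}_{self.strategy}_{self.pcr_id}"
        return [f"{stem}_{i:06d}" for i in range(len(self.reads))]


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

# phased (forward, reverse) flank combinations, as indices into the panel's
# non-degenerate primer lists (fa..fe / ra..rg).  Frequent flanks recur on
# several haplotypes, matching the haplotype counts behind the pool weights,
# and the pairing respects the phase structure the multi-PCR design was built
# around: every pair but one is perfectly matched by at least one of the four
# low-degeneracy primer pairs, while (fd, rg) is perfectly matched only by
# the non-degenerate primer mix -- the analogue of the alleles that drop out
# of every strategy except the weighted-pool one.
_DEFAULT_FLANK_PAIRS = (
    (0, 0), (0, 0), (0, 1), (0, 2), (0, 3),
    (1, 0), (1, 1),
    (2, 4), (2, 5), (2, 0),
    (3, 6),
    (4, 0), (4, 1),
)


def default_flank_haplotypes(n: int = 13) -> list[tuple[str, str]]:
    """Phased (forward, reverse) flank pairs built from the packaged panel.

    Forward flanks are the plus-strand targets of the five non-degenerate
    forward primers; reverse flanks are the plus-strand complements of the
    seven non-degenerate reverse primers.  The two sides are combined into
    phase haplotypes (a flank haplotype is always the pair, never two
    independent sides): common flanks recur across haplotypes and the
    pairing keeps almost every haplotype perfectly amplifiable by at least
    one of the four low-degeneracy primer pairs, with one haplotype perfectly
    matched only by the weighted non-degenerate mix.  Against the single
    degenerate pair the set spans perfect matches down to three internal
    mismatches, driving the >2 orders-of-magnitude efficiency spread the
    generator aims to emulate.
    """
    fwd = [p.sequence for p in panels.POOLED_PRIMERS_F]
    rev = [iupac.reverse_complement(p.sequence) for p in panels.POOLED_PRIMERS_R]
    pairs = [
        _DEFAULT_FLANK_PAIRS[i % len(_DEFAULT_FLANK_PAIRS)] for i in range(n)
    ]
    return [(fwd[i], rev[j]) for i, j in pairs]


def min_loci_for_profile(n_alleles: int) -> int:
    """Smallest number of loci a diploid profile of ``n_alleles`` distinct alleles allows."""
    if n_alleles < 0:
        raise ValueError("allele count must be non-negative")
    return math.ceil(n_alleles / 2)


def _random_core(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_population(
    n_individuals: int = 18,
    n_loci: int = 7,
    allele_pool_size: int = 13,
    flank_haplotypes: Sequence[tuple[str, str]] | None = None,
    allele_frequencies: Mapping[str, Sequence[float]] | None = None,
    seed: int | np.random.Generator = 0,
    core_length: int = 230,
) -> tuple[dict[str, SimulatedAllele], list[IndividualGenotype]]:
    """Draw an allele pool and diploid multi-locus genotypes.

    Alleles are assigned to loci round-robin (each locus owns its own subset
    of the pool) and each individual draws two alleles per locus,
    independently and with the locus' allele frequencies (uniform by
    default).  Deterministic for a fixed seed.
    """
    if allele_pool_size < n_loci:
        raise ValueError("allele_pool_size must be >= n_loci")
    rng = _rng(seed)
    flanks = list(flank_haplotypes or default_flank_haplotypes(allele_pool_size))

    cores: set[str] = set()
    alleles: dict[str, SimulatedAllele] = {}
    for i in range(allele_pool_size):
        core = _random_core(rng, core_length)
        while core in cores:  # pairwise-distinct cores
            core = _random_core(rng, core_length)
        cores.add(core)
        fwd, rev = flanks[i % len(flanks)]
        aid = f"A{i:02d}"
        alleles[aid] = SimulatedAllele(aid, core, fwd, rev, f"L{i % n_loci}")

    by_locus: dict[str, list[str]] = {}
    for aid, al in alleles.items():
        by_locus.setdefault(al.locus_id, []).append(aid)

    freqs: dict[str, np.ndarray] = {}
    for locus, members in by_locus.items():
        if allele_frequencies and locus in allele_frequencies:
            p = np.asarray(allele_frequencies[locus], dtype=float)
            if len(p) != len(members):
                raise ValueError(f"frequency vector length mismatch at {locus}")
            if abs(p.sum() - 1.0) > 1e-6:
                raise ValueError(f"allele frequencies at {locus} sum to {p.sum()}, not 1")
        else:
            p = np.full(len(members), 1.0 / len(members))
        freqs[locus] = p

    genotypes = []
    for j in range(n_individuals):
        loci = []
        for locus in sorted(by_locus):
            members = by_locus[locus]
            pair = tuple(rng.choice(members, size=2, p=freqs[locus]))
            loci.append((locus, (str(pair[0]), str(pair[1]))))
        genotypes.append(IndividualGenotype(f"ind{j:02d}", tuple(loci)))
    return alleles, genotypes


# ---------------------------------------------------------------------------
# amplification efficiency
# ---------------------------------------------------------------------------

def _side_score(
    members: Iterable[tuple], flank: str, model: EfficiencyModel
) -> float:
    """Best over the reaction's same-sense primers of concentration x penalties."""
    best = 0.0
    for primer, proportion in members:
        conc = proportion / (primer.degeneracy if model.effective_concentration else 1.0)
        report = mismatch_profile(primer, flank)
        score = conc
        length = len(primer.sequence)
        for pos in report.mismatch_positions:
            if length - 1 - pos < model.three_prime_window:
                score *= model.lambda_three_prime
            else:
                score *= model.lambda_internal
        best = max(best, score)
    return best


def pcr_efficiency(
    allele: SimulatedAllele, pcr: PCRAssay, model: EfficiencyModel
) -> float:
    """End-point amplification efficiency of one allele in one reaction.

    Product of the best forward-side and best reverse-side scores, where each
    side score is the primer's effective concentration multiplied by the
    per-mismatch penalties of its best-matching realization.
    """
    fwd = _side_score(pcr.forward, allele.forward_flank, model)
    rev = _side_score(pcr.reverse, allele.reverse_flank, model)
    return fwd * rev


def allele_efficiency(
    allele: SimulatedAllele,
    assay: Sequence[PCRAssay],
    model: EfficiencyModel,
) -> np.ndarray:
    """Per-PCR efficiencies of an allele under a strategy's assay.

    Single-PCR strategies return a length-1 vector.  For the pooled-PCRs
    assay the read-sampling stage draws each PCR's depth share from the
    sequencing-pool fractions, so efficiencies are kept per PCR here.
    """
    return np.array([pcr_efficiency(allele, pcr, model) for pcr in assay])


def strategy_efficiency(
    allele: SimulatedAllele,
    assay: Sequence[PCRAssay],
    model: EfficiencyModel,
) -> float:
    """Pool-fraction-weighted efficiency across an assay's PCRs (scalar truth value)."""
    effs = allele_efficiency(allele, assay, model)
    fracs = np.array([p.fraction for p in assay])
    return float(effs @ fracs)


# ---------------------------------------------------------------------------
# read sampling and artefacts
# ---------------------------------------------------------------------------

def sample_amplicon_reads(
    genotype: IndividualGenotype,
    alleles: Mapping[str, SimulatedAllele],
    efficiencies: Mapping[str, float],
    depth: int,
    seed: int | np.random.Generator,
    strategy: str = CONVENTIONAL,
    pcr_id: str = "pcr1",
) -> AmpliconReadSet:
    """Draw reads from one PCR as a multinomial over the individual's allele copies.

    Sampling probability is proportional to efficiency x copy number, so the
    expected per-copy read fraction is proportional to efficiency.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = _rng(seed)
    ids = sorted(genotype.allele_ids())
    weights = np.array(
        [efficiencies[a] * genotype.copy_number(a) for a in ids], dtype=float
    )
    if depth > 0 and (len(weights) == 0 or weights.sum() <= 0):
        raise ValueError(
            f"no amplifiable template for {genotype.individual_id}: "
            "all efficiencies are zero"
        )
    reads: list[str] = []
    origins: list[ReadOrigin] = []
    if depth > 0:
        counts = rng.multinomial(depth, weights / weights.sum())
        for aid, n in zip(ids, counts):
            seq = alleles[aid].sequence
            reads.extend([seq] * int(n))
            origins.extend([ReadOrigin(allele_id=aid)] * int(n))
    return AmpliconReadSet(genotype.individual_id, strategy, pcr_id, reads, origins)


def _substitute(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for pos in positions:
        alts = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alts[rng.integers(0, 3)]
    return "".join(chars)


def _homopolymer_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Lengthen or shorten each homopolymer run >= 3 by one base with prob ``rate``."""
    out = []
    last = 0
    for m in _HOMOPOLYMER.finditer(seq):
        out.append(seq[last:m.start()])
        run = m.group(0)
        if rng.random() < rate:
            if rng.random() < 0.5:
                run = run + run[0]
            else:
                run = run[:-1]
        out.append(run)
        last = m.end()
    out.append(seq[last:])
    return "".join(out)


def inject_artefacts(
    read_set: AmpliconReadSet,
    model: ArtefactModel,
    seed: int | np.random.Generator,
) -> AmpliconReadSet:
    """Overlay chimeras, substitutions and homopolymer indels on a read set.

    Chimeric reads replace sampled reads: a prefix of one parent joined to the
    suffix of a second, distinct parent at a uniform random breakpoint, with
    parents drawn abundance-weighted from the pre-artefact reads (chimera
    formation requires at least two distinct parent sequences).  Substitutions
    are uniform over positions and alternative bases; homopolymer indels
    lengthen or shorten a run of three or more identical bases by one.  The
    truth table is updated alongside.
    """
    rng = _rng(seed)
    reads = list(read_set.reads)
    origins = list(read_set.origins)
    n = len(reads)
    parent_seqs = list(read_set.reads)
    parent_origins = list(read_set.origins)
    distinct_parents = len(set(parent_seqs)) >= 2

    if model.chimera_rate > 0 and distinct_parents and n > 0:
        chimeric = np.flatnonzero(rng.random(n) < model.chimera_rate)
        for idx in chimeric:
            for _ in range(100):
                i1, i2 = rng.integers(0, n, size=2)
                p1, p2 = parent_seqs[i1], parent_seqs[i2]
                if p1 == p2:
                    continue
                # breakpoints inside the parents' shared prefix or suffix yield a
                # product identical to a parent, i.e. not a chimera at all
                lo = _lcp(p1, p2) + 1
                hi = min(len(p1), len(p2)) - 1
                if len(p1) == len(p2):
                    hi = min(hi, len(p1) - _lcp(p1[::-1], p2[::-1]) - 1)
                if lo <= hi:
                    break
            else:
                continue
            k = int(rng.integers(lo, hi + 1))
            reads[idx] = p1[:k] + p2[k:]
            origins[idx] = ReadOrigin(
                parents=(
                    parent_origins[i1].allele_id or "?",
                    parent_origins[i2].allele_id or "?",
                ),
                breakpoint=k,
            )

    for idx in range(n):
        seq = reads[idx]
        mutated = seq
        if model.substitution_rate > 0:
            n_subs = rng.binomial(len(mutated), model.substitution_rate)
            if n_subs:
                mutated = _substitute(mutated, int(n_subs), rng)
        if model.homopolymer_indel_rate > 0:
            mutated = _homopolymer_indels(mutated, model.homopolymer_indel_rate, rng)
        if mutated != seq:
            reads[idx] = mutated
            origins[idx] = replace(origins[idx], errored=True)

    return AmpliconReadSet(
        read_set.individual_id, read_set.strategy, read_set.pcr_id, reads, origins
    )


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """A full synthetic experiment: truth plus per-amplicon read sets."""

    alleles: dict[str, SimulatedAllele]
    genotypes: list[IndividualGenotype]
    read_sets: list[AmpliconReadSet]
    efficiency_model: EfficiencyModel
    artefact_model: ArtefactModel
    #: (strategy, allele_id) -> pool-fraction-weighted truth efficiency
    true_efficiencies: dict[tuple[str, str], float] = field(default_factory=dict)

    def truth_profiles(self) -> dict[str, set[str]]:
        return {g.individual_id: g.allele_ids() for g in self.genotypes}

    def sequence_to_allele(self) -> dict[str, str]:
        return {a.sequence: aid for aid, a in self.alleles.items()}

    def chimeric_sequences(self) -> set[str]:
        return {
            r
            for rs in self.read_sets
            for r, o in zip(rs.reads, rs.origins)
            if o.kind == "chimera"
        }


def simulate_individual_reads(
    genotype: IndividualGenotype,
    alleles: Mapping[str, SimulatedAllele],
    strategy: str,
    assay: Sequence[PCRAssay],
    model: EfficiencyModel,
    depth: int,
    seed: int | np.random.Generator,
) -> list[AmpliconReadSet]:
    """Simulate one individual under one strategy (one read set per PCR).

    For multi-PCR assays the total depth is first split across PCRs by their
    sequencing-pool fractions, then each PCR samples its own multinomial.
    """
    rng = _rng(seed)
    carried = sorted(genotype.allele_ids())
    per_pcr_eff = {
        pcr.name: {a: pcr_efficiency(alleles[a], pcr, model) for a in carried}
        for pcr in assay
    }
    fracs = np.array([p.fraction for p in assay], dtype=float)
    depths = rng.multinomial(depth, fracs / fracs.sum()) if len(assay) > 1 else [depth]
    out = []
    for pcr, d in zip(assay, depths):
        out.append(
            sample_amplicon_reads(
                genotype, alleles, per_pcr_eff[pcr.name], int(d), rng,
                strategy=strategy, pcr_id=pcr.name,
            )
        )
    return out


def simulate_dataset(
    n_individuals: int = 18,
    n_loci: int = 7,
    allele_pool_size: int = 13,
    depth: int = 2000,
    seed: int = 0,
    efficiency_model: EfficiencyModel | None = None,
    artefact_model: ArtefactModel | None = None,
    strategies: Sequence[str] = STRATEGIES,
    flank_haplotypes: Sequence[tuple[str, str]] | None = None,
    core_length: int = 230,
) -> SimulatedDataset:
    """Run the full generator: population, per-strategy amplicons, artefacts."""
    emodel = efficiency_model or EfficiencyModel()
    amodel = artefact_model or ArtefactModel()
    rng = np.random.default_rng(seed)
    alleles, genotypes = simulate_population(
        n_individuals, n_loci, allele_pool_size,
        flank_haplotypes=flank_haplotypes, seed=rng, core_length=core_length,
    )
    read_sets: list[AmpliconReadSet] = []
    true_eff: dict[tuple[str, str], float] = {}
    for strategy in strategies:
        assay = panels.assay_for(strategy)
        for aid, allele in alleles.items():
            true_eff[(strategy, aid)] = strategy_efficiency(allele, assay, emodel)
        for genotype in genotypes:
            for rs in simulate_individual_reads(
                genotype, alleles, strategy, assay, emodel, depth, rng
            ):
                read_sets.append(inject_artefacts(rs, amodel, rng))
    return SimulatedDataset(alleles, genotypes, read_sets, emodel, amodel, true_eff)
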