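"""Degenerate-primer arithmetic, mismatch profiling and pool design.

This module covers the book-keeping needed to reason about multi-template PCR
assays on a multigene family: how many distinct oligos a degenerate primer
set synthesizes, how each primer aligns against each known flanking haplotype,
and how a set of complementary primers (or independent PCRs) covers the
haplotype space when mixed at weighted concentrations.

Conventions
-----------
* Primers are stored 5'->3' as synthesized.  Forward primers are compared
  directly against the plus-strand flank; reverse primers are compared against
  the reverse complement of the plus-strand flank.
* A degenerate primer "perfectly matches" a template iff some plain-DNA
  realization of it matches exactly, which is equivalent to the template base
  lying within the primer code's base set at every position.
* Mismatch positions are 0-based offsets from the primer's 5' end; a distance
  of 0 to the 3' end denotes the terminal 3' base.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import iupac

FORWARD = "forward"
REVERSE = "reverse"

CONVENTIONAL = "conventional"
POOLED_PCRS = "pooled_pcrs"
POOLED_PRIMERS = "pooled_primers"
STRATEGIES = (CONVENTIONAL, POOLED_PCRS, POOLED_PRIMERS)


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded oligo with sense and strategy membership."""

    name: str
    short_name: str
    sequence: str
    sense: str
    strategy: str = ""

    def __post_init__(self) -> None:
        iupac.validate(self.sequence)
        if self.sense not in (FORWARD, REVERSE):
            raise ValueError(f"sense must be '{FORWARD}' or '{REVERSE}', got {self.sense!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        """Number of distinct plain oligos this primer synthesizes."""
        return iupac.degeneracy(self.sequence)

    def expansions(self) -> set[str]:
        return iupac.expand(self.sequence)


@dataclass(frozen=True)
class MismatchReport:
    """Alignment of one primer against one resolved template flank."""

    primer_name: str
    template_id: str
    mismatch_count: int
    mismatch_positions: tuple[int, ...]
    min_distance_to_3prime: int
    perfect: bool


def expand_degenerate(primer: DegeneratePrimer) -> set[str]:
    """All distinct plain-DNA realizations of a degenerate primer."""
    return primer.expansions()


def unique_union(primers: Sequence[DegeneratePrimer]) -> set[str]:
    """Deduplicated union of the realizations of several same-sense primers."""
    if not primers:
        raise ValueError("unique_union requires at least one primer")
    senses = {p.sense for p in primers}
    if len(senses) > 1:
        raise ValueError("unique_union requires primers of the same sense")
    out: set[str] = set()
    for p in primers:
        out |= p.expansions()
    return out


def combined_uniq(primers: Sequence[DegeneratePrimer]) -> int:
    """Combined-set tally of plain oligos across a primer set.

    Sums the per-primer realization counts, i.e. the number of distinct oligo
    species each synthesis contributes, counted per primer.  This is the
    figure conventionally tabulated for a "consensus" row summarising a primer
    set; it exceeds ``len(unique_union(...))`` when two members encode a common
    realization (for the pooled-PCRs reverse trio here, exactly one oligo is
    shared, so the tally is 22 against a strict union of 21).
    """
    if not primers:
        raise ValueError("combined_uniq requires at least one primer")
    return sum(p.degeneracy for p in primers)


def mismatch_profile(
    primer: DegeneratePrimer, template_flank: str, template_id: str = ""
) -> MismatchReport:
    """Profile primer-template mismatches over a resolved flank.

    ``template_flank`` is the plus-strand priming region, same length as the
    primer.  Reverse primers are compared against its reverse complement so
    that position 0 is always the primer's 5' end.  A position matches iff the
    template base is within the IUPAC set of the primer code; a degenerate
    primer is therefore perfect iff some realization matches exactly.
    """
    if len(template_flank) != len(primer.sequence):
        raise ValueError(
            f"template flank length {len(template_flank)} != primer length "
            f"{len(primer.sequence)} for {primer.name}"
        )
    if not iupac.is_plain(template_flank):
        raise ValueError(
            f"template flank for {template_id or primer.name} contains ambiguity "
            "codes; templates must be resolved to plain A/C/G/T"
        )
    template = template_flank
    if primer.sense == REVERSE:
        template = iupac.reverse_complement(template_flank)
    positions = tuple(
        i
        for i, (code, base) in enumerate(zip(primer.sequence, template))
        if not iupac.matches(code, base)
    )
    length = len(primer.sequence)
    min_d3 = min((length - 1 - p for p in positions), default=length)
    return MismatchReport(
        primer_name=primer.name,
        template_id=template_id,
        mismatch_count=len(positions),
        mismatch_positions=positions,
        min_distance_to_3prime=min_d3,
        perfect=not positions,
    )


def pool_fractions(weights: Sequence[int]) -> list[float]:
    """Percent concentrations from integer haplotype-count weights.

    ``fractions[i] = 100 * weights[i] / sum(weights)`` rounded to one decimal,
    half away from zero, preserving weight order.  The more haplotypes a
    primer (or primer pair) is expected to target, the more concentrated it is
    in the pool.
    """
    if not weights:
        raise ValueError("empty weight vector")
    for w in weights:
        if int(w) != w or w < 1:
            raise ValueError(f"weights must be positive integers, got {w!r}")
    total = sum(weights)
    return [
        float(
            (Decimal(100 * int(w)) / Decimal(total)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for w in weights
    ]


@dataclass(frozen=True)
class PrimerPool:
    """Primers mixed in one reaction at haplotype-count-weighted concentrations."""

    members: tuple[DegeneratePrimer, ...]
    weights: tuple[int, ...]
    fractions: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.members) != len(self.weights):
            raise ValueError("one weight per pool member required")
        object.__setattr__(self, "fractions", tuple(pool_fractions(self.weights)))

    def proportions(self) -> list[float]:
        """Exact (unrounded) pool proportions summing to 1."""
        total = sum(self.weights)
        return [w / total for w in self.weights]


@dataclass(frozen=True)
class PCRAssay:
    """One PCR: forward/reverse primer sets at within-reaction proportions.

    ``fraction`` is the share of this PCR's product in the final sequencing
    pool (1.0 for single-PCR strategies).  ``forward``/``reverse`` list
    ``(primer, proportion)`` pairs; proportions within each side sum to 1.
    """

    name: str
    forward: tuple[tuple[DegeneratePrimer, float], ...]
    reverse: tuple[tuple[DegeneratePrimer, float], ...]
    fraction: float = 1.0

    def __post_init__(self) -> None:
        for side in (self.forward, self.reverse):
            if not side:
                raise ValueError(f"PCR {self.name} needs at least one primer per side")
            s = sum(frac for _, frac in side)
            if abs(s - 1.0) > 0.01:
                raise ValueError(
                    f"within-reaction primer proportions of PCR {self.name} sum to {s}, not 1"
                )

    def perfectly_matches(self, forward_flank: str, reverse_flank: str) -> bool:
        """True iff some forward and some reverse member are perfect for the haplotype."""
        fwd = any(
            mismatch_profile(p, forward_flank).perfect for p, _ in self.forward
        )
        rev = any(
            mismatch_profile(p, reverse_flank).perfect for p, _ in self.reverse
        )
        return fwd and rev


@dataclass
class CoverageMatrix:
    """Per-PCR x per-haplotype mismatch reports with coverage summaries.

    ``pcr_match[h]`` counts PCRs whose forward and reverse primers both
    perfectly match haplotype ``h``; ``pool_match[h]`` sums the sequencing-pool
    fractions of those PCRs (1.0 = perfectly matched in every PCR).
    """

    pcrs: tuple[PCRAssay, ...]
    haplotype_ids: tuple[str, ...]
    reports: dict[tuple[str, str], tuple[MismatchReport, MismatchReport]]
    pcr_match: dict[str, int]
    pool_match: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (PCR, haplotype)."""
        rows = []
        for pcr in self.pcrs:
            for hid in self.haplotype_ids:
                fwd, rev = self.reports[(pcr.name, hid)]
                rows.append(
                    {
                        "pcr": pcr.name,
                        "fraction": pcr.fraction,
                        "haplotype": hid,
                        "mismatches_f": fwd.mismatch_count,
                        "mismatches_r": rev.mismatch_count,
                        "perfect": fwd.perfect and rev.perfect,
                        "pcr_match": self.pcr_match[hid],
                        "pool_match": self.pool_match[hid],
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _best_report(
    primers: Iterable[tuple[DegeneratePrimer, float]], flank: str, hid: str
) -> MismatchReport:
    """Report of the best-matching (fewest mismatches) primer on one side."""
    reports = [mismatch_profile(p, flank, hid) for p, _ in primers]
    return min(reports, key=lambda r: (r.mismatch_count, r.primer_name))


def build_coverage_matrix(
    pcrs: Sequence[PCRAssay],
    haplotypes: Sequence[tuple[str, str, str]],
) -> CoverageMatrix:
    """Coverage of flank haplotypes by a set of PCRs pooled for sequencing.

    ``haplotypes`` lists ``(id, forward_flank, reverse_flank)`` with both
    flanks given on the plus strand; treating the two flanks as one phased
    haplotype (never as independent sides) mirrors the design constraint that
    variants observed on the same haplotype must not be split across primers.
    """
    total = sum(p.fraction for p in pcrs)
    if abs(total - 1.0) > 0.01:
        raise ValueError(f"sequencing-pool fractions sum to {total}, not 1 +- 0.01")
    reports: dict[tuple[str, str], tuple[MismatchReport, MismatchReport]] = {}
    pcr_match: dict[str, int] = {}
    pool_match: dict[str, float] = {}
    hap_ids = tuple(h[0] for h in haplotypes)
    for hid, fwd_flank, rev_flank in haplotypes:
        n_match = 0
        w_match = 0.0
        for pcr in pcrs:
            fwd = _best_report(pcr.forward, fwd_flank, hid)
            rev = _best_report(pcr.reverse, rev_flank, hid)
            reports[(pcr.name, hid)] = (fwd, rev)
            if fwd.perfect and rev.perfect:
                n_match += 1
                w_match += pcr.fraction
        pcr_match[hid] = n_match
        pool_match[hid] = min(w_match, 1.0)
    return CoverageMatrix(tuple(pcrs), hap_ids, reports, pcr_match, pool_match)


def read_primer_tsv(path: str | Path) -> list[DegeneratePrimer]:
    """Read primers from a TSV with columns name, short_name, sequence, sense[, strategy]."""
    primers = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "short_name", "sequence", "sense"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"primer TSV must have columns {sorted(required)}")
        for row in reader:
            primers.append(
                DegeneratePrimer(
                    name=row["name"],
                    short_name=row["short_name"],
                    sequence=row["sequence"].strip().upper(),
                    sense=row["sense"].strip().lower(),
                    strategy=(row.get("strategy") or "").strip(),
                )
            )
    return primers


def write_primer_tsv(primers: Sequence[DegeneratePrimer], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "short_name", "sequence", "sense", "strategy"])
        for p in primers:
            writer.writerow([p.name, p.short_name, p.sequence, p.sense, p.strategy])
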