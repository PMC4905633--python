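"""Amplification-efficiency and profile-completeness statistics.

Core quantity: the per-copy read fraction of an allele within one amplicon,

    %reads_i = 100 * reads_i / (sum(reads over alleles) * copy_number_i),

with copy number 1 for heterozygous and 2 for homozygous loci (artefact reads
never enter the denominator).  Standardized amplification efficiency divides
each allele's mean per-copy fraction by that of the least amplified allele,
so the least amplified observed allele has efficiency 1 and ratios read
directly as fold differences in amplification.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .validate import ALLELE, ARTEFACT, VariantClassification

CopyNumber = Callable[[str, str], int]  # (individual, allele id) -> 1 or 2


def constant_copy_number(value: int = 1) -> CopyNumber:
    """Copy-number map defaulting to a constant (1 when locus assignment is unknown)."""
    return lambda individual, allele: value


def copy_number_from_genotypes(genotypes) -> CopyNumber:
    """Copy-number map backed by simulated truth genotypes."""
    table = {g.individual_id: g for g in genotypes}

    def lookup(individual: str, allele: str) -> int:
        g = table.get(individual)
        if g is None:
            return 1
        return g.copy_number(allele) or 1

    return lookup


def strategy_allele_counts(
    amplicons: Mapping[tuple[str, str, str], Sequence[str]],
    validated: Mapping[str, str],
    strategy: str,
) -> dict[str, dict[str, int]]:
    """Per-individual read counts of validated alleles under one strategy.

    Counts exact-sequence occurrences of every dataset-validated allele in
    the raw reads (all of the strategy's PCRs pooled per individual),
    regardless of whether the allele was formally called in that particular
    amplicon.  This is the input the efficiency statistics work from: an
    allele validated elsewhere but too rare to be scored in one amplicon
    still contributes its (small) read count there, instead of a
    call-dependent zero.  ``validated`` maps allele sequence -> allele id.
    """
    out: dict[str, dict[str, int]] = {}
    for (individual, strat, _), reads in amplicons.items():
        if strat != strategy:
            continue
        counts = Counter(reads)
        bucket = out.setdefault(individual, {})
        for seq, aid in validated.items():
            n = counts.get(seq, 0)
            if n:
                bucket[aid] = bucket.get(aid, 0) + n
    return out


def percent_reads_per_copy(
    allele_counts: Mapping[str, int],
    individual: str = "",
    copy_number: CopyNumber | None = None,
) -> dict[str, float]:
    """Per-copy read percentage of each allele within one amplicon.

    Only reads assigned to validated alleles enter the denominator.  An
    amplicon with zero allele reads is undefined and skipped with a warning.
    """
    copy_number = copy_number or constant_copy_number()
    total = sum(allele_counts.values())
    if total == 0:
        warnings.warn(f"amplicon of {individual or '<unknown>'} has no allele reads; skipped")
        return {}
    return {
        aid: 100.0 * n / (total * copy_number(individual, aid))
        for aid, n in allele_counts.items()
    }


def standardized_efficiencies(
    calls: Mapping[str, Mapping[str, int]],
    carriers: Mapping[str, set[str]],
    copy_number: CopyNumber | None = None,
) -> pd.DataFrame:
    """Standardized amplification efficiency per allele under one strategy.

    ``calls`` maps individual -> {allele id: reads under this strategy};
    ``carriers`` maps individual -> allele ids present in the individual's
    complete profile.  Each allele's per-copy fraction is averaged over the
    individuals that carry it (zero where carried but not detected), then
    divided by the minimum over alleles with nonzero means; never-observed
    alleles get efficiency 0 and are excluded from that minimum.
    """
    copy_number = copy_number or constant_copy_number()
    fractions: dict[str, list[float]] = {}
    for individual, profile in carriers.items():
        pct = percent_reads_per_copy(
            dict(calls.get(individual, {})), individual, copy_number
        ) if calls.get(individual) else {}
        for aid in profile:
            fractions.setdefault(aid, []).append(pct.get(aid, 0.0))
    means = {aid: float(np.mean(v)) for aid, v in fractions.items()}
    observed = [m for m in means.values() if m > 0]
    if len(observed) < 2:
        raise ValueError("standardization requires >= 2 alleles with nonzero reads")
    reference = min(observed)
    rows = [
        {
            "allele_id": aid,
            "percent_reads": means[aid],
            "standardized_efficiency": means[aid] / reference if means[aid] > 0 else 0.0,
            "n_amplicons": len(fractions[aid]),
        }
        for aid in sorted(means)
    ]
    return pd.DataFrame(rows)


@dataclass
class DetectionStats:
    """Per-allele detection probabilities and per-individual completeness."""

    per_allele: pd.DataFrame     # allele_id, n_carriers, n_detected, probability_of_detection
    per_individual: pd.DataFrame  # individual, alleles_present, alleles_detected, alleles_missed, completeness_percent


def detection_stats(
    strategy_calls: Mapping[str, set[str]],
    complete_profiles: Mapping[str, set[str]],
) -> DetectionStats:
    """Compare one strategy's per-individual calls with the complete profiles.

    The complete profile (the union of all strategies' calls per individual)
    is the best available approximation to the true genotype; the probability
    of detection of an allele is the fraction of its carriers in which the
    strategy scored it.
    """
    allele_rows = []
    all_alleles = sorted({a for p in complete_profiles.values() for a in p})
    for aid in all_alleles:
        carriers = [i for i, p in complete_profiles.items() if aid in p]
        detected = [i for i in carriers if aid in strategy_calls.get(i, set())]
        allele_rows.append(
            {
                "allele_id": aid,
                "n_carriers": len(carriers),
                "n_detected": len(detected),
                "probability_of_detection":
                    len(detected) / len(carriers) if carriers else np.nan,
            }
        )
    ind_rows = []
    for ind, profile in sorted(complete_profiles.items()):
        detected = strategy_calls.get(ind, set()) & profile
        present = len(profile)
        ind_rows.append(
            {
                "individual": ind,
                "alleles_present": present,
                "alleles_detected": len(detected),
                "alleles_missed": present - len(detected),
                "completeness_percent":
                    100.0 * len(detected) / present if present else np.nan,
            }
        )
    return DetectionStats(pd.DataFrame(allele_rows), pd.DataFrame(ind_rows))


def variance_ratio_test(
    log_efficiencies_a: Sequence[float],
    log_efficiencies_b: Sequence[float],
) -> tuple[float, float]:
    """One-tailed F test that group A's variance exceeds group B's.

    Inputs are log-transformed standardized efficiencies (log-normalising the
    heavily right-skewed efficiency distributions).  Returns
    ``(F, p)`` with ``F = var(A)/var(B)`` and ``p`` the upper-tail
    probability under ``F(n_A - 1, n_B - 1)``.
    """
    a = np.asarray(log_efficiencies_a, dtype=float)
    b = np.asarray(log_efficiencies_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    var_a = a.var(ddof=1)
    var_b = b.var(ddof=1)
    if var_b == 0:
        raise ValueError("zero variance in denominator group")
    f = var_a / var_b
    p = float(sps.f.sf(f, len(a) - 1, len(b) - 1))
    return float(f), p


def log_efficiencies(frame: pd.DataFrame) -> np.ndarray:
    """Natural-log standardized efficiencies; zeros are excluded with a warning."""
    eff = frame["standardized_efficiency"].to_numpy(dtype=float)
    if (eff == 0).any():
        warnings.warn(
            f"excluding {(eff == 0).sum()} zero-efficiency allele(s) from log transform"
        )
        eff = eff[eff > 0]
    return np.log(eff)


def rank_vs_top_artefact(
    classifications: Sequence[VariantClassification],
) -> dict[str, int]:
    """Signed rank of each called allele relative to the most frequent artefact.

    The most frequent artefact sits at zero, so a positive value means the
    allele out-ranked every artefact.  In an amplicon without artefacts every
    allele is positive, with the artefact placed virtually just below the
    least frequent variant (rank n+1), preserving the ordering semantics.
    """
    artefact_ranks = [c.variant.rank for c in classifications if c.cls == ARTEFACT]
    reference = min(artefact_ranks) if artefact_ranks else len(classifications) + 1
    return {
        c.variant.sequence: reference - c.variant.rank
        for c in classifications
        if c.cls == ALLELE
    }


def rank_vs_top_artefact_frame(
    classifications: Mapping[tuple, Sequence[VariantClassification]],
    allele_ids: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-form rank-offset table over all amplicons."""
    rows = []
    for (ind, strat, pcr), cl in classifications.items():
        for seq, offset in rank_vs_top_artefact(cl).items():
            rows.append(
                {
                    "individual": ind,
                    "strategy": strat,
                    "pcr_id": pcr,
                    "allele_id": (allele_ids or {}).get(seq, ""),
                    "rank_offset": offset,
                }
            )
    return pd.DataFrame(rows, columns=["individual", "strategy", "pcr_id", "allele_id", "rank_offset"])
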