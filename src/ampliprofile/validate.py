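"""Rule-based variant classification and allele scoring for amplicon genotyping.

The protocol assumes nothing about true alleles being more abundant than
artefacts — a necessity when amplification efficiencies differ by orders of
magnitude across alleles.  Within each independent PCR, dereplicated variants
are processed in descending read-count order:

1. a variant reconstructable as a single-crossover chimera of two more
   frequent variants in the same PCR is an artefact;
2. singletons (count 1) are artefacts;
3. more frequent variants (count > 1) within two differences of a
   higher-ranked variant and absent from every independent PCR are artefacts;
4. variants more than two differences from all higher-ranked variants and
   absent from every independent PCR are left unclassified for manual review;
5. everything else is an allele candidate.

Allele scoring then proceeds in two passes: the most frequent variant of
every PCR is scored as an allele; candidates matching an allele validated
elsewhere are scored wherever they out-count every artefact in their PCR, and
are logged for manual checking where they do not (with a flag marking the
cases explained away as chimeras of already-called alleles).

"Differences" are Levenshtein edit distances, so equal-length variants reduce
to Hamming distance while homopolymer indels count as single differences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

AmpliconKey = tuple[str, str, str]  # (individual_id, strategy, pcr_id)

ALLELE = "allele"
ARTEFACT = "artefact"
UNCLASSIFIED = "unclassified"
CANDIDATE = "candidate"

TOP_VARIANT = "top_variant"
KNOWN_ALLELE_RESCUE = "known_allele_rescue"
CHIMERA = "chimera"
SINGLETON = "singleton"
LOW_FREQ_SIMILAR = "low_freq_similar"
MANUAL_CHECK_PENDING = "manual_check_pending"

SCOPE_DATASET = "dataset"
SCOPE_INDIVIDUAL = "individual"


@dataclass(frozen=True)
class Variant:
    """A dereplicated sequence within one amplicon."""

    sequence: str
    count: int
    amplicon: AmpliconKey
    rank: int  # 1-based, by descending count, ties by sequence


@dataclass
class VariantClassification:
    variant: Variant
    cls: str
    reason: str
    chimera_parents: tuple[str, str, int] | None = None  # (parent1, parent2, breakpoint)
    replicated: bool = False


@dataclass(frozen=True)
class ManualCheck:
    amplicon: AmpliconKey
    sequence: str
    count: int
    explanation: bool  # True iff out-counting artefacts are chimeras of called alleles


@dataclass
class AlleleCallSet:
    """Dataset-wide validated alleles plus per-amplicon calls."""

    alleles: dict[str, str]  # sequence -> allele id
    calls: dict[AmpliconKey, dict[str, int]]  # allele id -> read count
    manual_log: list[ManualCheck]
    classifications: dict[AmpliconKey, list[VariantClassification]]

    def allele_sequences(self) -> dict[str, str]:
        """allele id -> sequence."""
        return {aid: seq for seq, aid in self.alleles.items()}

    def calls_by_individual(self, strategy: str | None = None) -> dict[str, set[str]]:
        """Union of called allele ids per individual, optionally per strategy."""
        out: dict[str, set[str]] = {}
        for (ind, strat, _), called in self.calls.items():
            if strategy is not None and strat != strategy:
                continue
            out.setdefault(ind, set()).update(called)
        return out


def dereplicate(reads: Iterable[str], amplicon: AmpliconKey = ("", "", "")) -> list[Variant]:
    """Collapse reads to ranked variants: descending count, ties lexicographic."""
    counts = Counter(reads)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        Variant(seq, n, amplicon, rank)
        for rank, (seq, n) in enumerate(ordered, start=1)
    ]


# ---------------------------------------------------------------------------
# chimera detection
# ---------------------------------------------------------------------------

def _resolve_chimera(
    length: int,
    lcp: np.ndarray,
    lcs: np.ndarray,
    lens: np.ndarray,
) -> tuple[int, int, int] | None:
    """Find the first single-crossover reconstruction from prefix/suffix overlaps.

    ``lcp[i]``/``lcs[i]`` are the longest common prefix/suffix of the variant
    with parent ``i`` (parents in rank order).  A breakpoint ``k`` with prefix
    parent ``i`` and suffix parent ``j`` is valid iff ``k <= lcp[i]`` and
    ``length - k <= lcs[j]`` and ``len(parent_j) == length``.  Returns the
    smallest valid breakpoint, tie-broken by parent rank, or ``None``.
    """
    n = len(lcp)
    if n == 0 or length < 2:
        return None
    valid_j = (lens == length) & (lcs >= 1)
    if not valid_j.any() or lcp.max(initial=0) < 1:
        return None
    kmin = np.maximum(1, length - lcs)
    # largest prefix overlap available from a parent other than j itself
    arg1 = int(lcp.argmax())
    max1 = int(lcp[arg1])
    max2 = int(np.delete(lcp, arg1).max(initial=0)) if n > 1 else 0
    cap = np.where(np.arange(n) == arg1, max2, max1)
    feasible = valid_j & (kmin <= length - 1) & (cap >= kmin)
    if not feasible.any():
        return None
    k_star = int(kmin[feasible].min())
    for i in np.flatnonzero(lcp >= k_star):
        for j in np.flatnonzero(valid_j & (kmin <= k_star)):
            if i != j:
                return int(i), int(j), k_star
    return None


def _lcp_len(a: str, b: str) -> int:
    i, m = 0, min(len(a), len(b))
    while i < m and a[i] == b[i]:
        i += 1
    return i


def detect_chimera(
    variant: str, higher_ranked: Sequence[str]
) -> tuple[str, str, int] | None:
    """Reconstruct ``variant`` as prefix(p1, k) + suffix(p2, len - k) if possible.

    Parents are searched in the given (rank) order; the reconstruction with
    the smallest breakpoint wins, parents tie-broken by rank.  The variant
    must differ from both parents (callers pass only more frequent, distinct
    variants).  Returns ``(parent1, parent2, breakpoint)`` or ``None``.
    """
    parents = [p for p in higher_ranked if p != variant]
    if not parents:
        return None
    lcp = np.array([_lcp_len(variant, p) for p in parents])
    lcs = np.array([_lcp_len(variant[::-1], p[::-1]) for p in parents])
    lens = np.array([len(p) for p in parents])
    hit = _resolve_chimera(len(variant), lcp, lcs, lens)
    if hit is None:
        return None
    i, j, k = hit
    return parents[i], parents[j], k


class _ChimeraScanner:
    """Vectorized prefix/suffix overlap computation over one amplicon's variants."""

    def __init__(self, sequences: Sequence[str]):
        n = len(sequences)
        self.lens = np.array([len(s) for s in sequences], dtype=np.int64)
        lmax = int(self.lens.max(initial=1))
        # parents padded with 255, queries padded with 0: padding never matches
        self.fwd = np.full((n, lmax), 255, dtype=np.uint8)
        self.rev = np.full((n, lmax), 255, dtype=np.uint8)
        self.qfwd = np.zeros((n, lmax), dtype=np.uint8)
        self.qrev = np.zeros((n, lmax), dtype=np.uint8)
        for i, s in enumerate(sequences):
            enc = np.frombuffer(s.encode(), dtype=np.uint8)
            self.fwd[i, : len(s)] = enc
            self.rev[i, : len(s)] = enc[::-1]
            self.qfwd[i, : len(s)] = enc
            self.qrev[i, : len(s)] = enc[::-1]

    def scan(self, idx: int, n_parents: int) -> tuple[int, int, int] | None:
        """Chimera resolution of variant ``idx`` against the first ``n_parents`` variants."""
        if n_parents == 0:
            return None
        lcp = (self.fwd[:n_parents] != self.qfwd[idx]).argmax(axis=1)
        lcs = (self.rev[:n_parents] != self.qrev[idx]).argmax(axis=1)
        return _resolve_chimera(
            int(self.lens[idx]), lcp, lcs, self.lens[:n_parents]
        )


# ---------------------------------------------------------------------------
# per-amplicon classification
# ---------------------------------------------------------------------------

def _within_edit_distance(a: str, b: str, k: int) -> bool:
    return edlib.align(a, b, mode="NW", k=k)["editDistance"] != -1


def classify_amplicon(
    variants: Sequence[Variant],
    is_replicated: Callable[[str], bool],
    max_similar_diff: int = 2,
) -> list[VariantClassification]:
    """Apply the artefact-filtering rules to one amplicon's ranked variants.

    ``is_replicated(seq)`` answers whether the sequence occurs in any
    independent PCR.  The top-ranked variant is always an allele (it is scored
    regardless of count); chimera parents are restricted to strictly more
    frequent variants of the same amplicon.
    """
    out: list[VariantClassification] = []
    if not variants:
        return out
    seqs = [v.sequence for v in variants]
    counts = [v.count for v in variants]
    scanner = _ChimeraScanner(seqs)
    for idx, v in enumerate(variants):
        # parents strictly more frequent: a prefix of the rank order
        m = 0
        while m < idx and counts[m] > v.count:
            m += 1
        replicated = is_replicated(v.sequence)
        if idx == 0:
            out.append(VariantClassification(v, ALLELE, TOP_VARIANT, replicated=replicated))
            continue
        hit = scanner.scan(idx, m)
        if hit is not None:
            i, j, k = hit
            out.append(
                VariantClassification(
                    v, ARTEFACT, CHIMERA,
                    chimera_parents=(seqs[i], seqs[j], k),
                    replicated=replicated,
                )
            )
            continue
        if v.count == 1:
            out.append(VariantClassification(v, ARTEFACT, SINGLETON, replicated=replicated))
            continue
        if replicated:
            out.append(VariantClassification(v, CANDIDATE, CANDIDATE, replicated=True))
            continue
        near = any(
            _within_edit_distance(v.sequence, seqs[h], max_similar_diff)
            for h in range(idx)
        )
        if near:
            out.append(VariantClassification(v, ARTEFACT, LOW_FREQ_SIMILAR))
        else:
            out.append(VariantClassification(v, UNCLASSIFIED, MANUAL_CHECK_PENDING))
    return out


def build_replication_index(
    amplicon_variants: Mapping[AmpliconKey, Sequence[Variant]],
    scope: str = SCOPE_DATASET,
) -> Callable[[str, AmpliconKey], bool]:
    """Index answering "is this sequence present in an independent PCR?".

    Default scope treats any other amplicon in the dataset — including other
    individuals — as an independent PCR (across-individual replication, in a
    population where every allele is expected in several individuals);
    ``scope="individual"`` restricts replication to the same individual's
    other PCRs.
    """
    if scope not in (SCOPE_DATASET, SCOPE_INDIVIDUAL):
        raise ValueError(f"unknown replication scope {scope!r}")
    presence: dict[str, set[AmpliconKey]] = {}
    for key, variants in amplicon_variants.items():
        for v in variants:
            presence.setdefault(v.sequence, set()).add(key)

    def is_replicated(seq: str, key: AmpliconKey) -> bool:
        others = presence.get(seq, set()) - {key}
        if scope == SCOPE_INDIVIDUAL:
            others = {k for k in others if k[0] == key[0]}
        return bool(others)

    return is_replicated


def classify_dataset(
    amplicons: Mapping[AmpliconKey, Sequence[str]],
    scope: str = SCOPE_DATASET,
    max_similar_diff: int = 2,
) -> dict[AmpliconKey, list[VariantClassification]]:
    """Dereplicate and classify every amplicon of a dataset."""
    variants = {key: dereplicate(reads, key) for key, reads in amplicons.items()}
    is_replicated = build_replication_index(variants, scope)
    return {
        key: classify_amplicon(
            vs, lambda s, k=key: is_replicated(s, k), max_similar_diff
        )
        for key, vs in variants.items()
    }


# ---------------------------------------------------------------------------
# dataset-wide allele calling
# ---------------------------------------------------------------------------

def call_alleles(
    classifications: Mapping[AmpliconKey, list[VariantClassification]],
    accept_manual: bool = False,
) -> AlleleCallSet:
    """Score alleles across all amplicons.

    Pass 1 validates the most frequent variant of every amplicon.  Pass 2
    iterates amplicons in their given order to a fixpoint: a candidate whose
    sequence is already validated is called wherever its count exceeds every
    artefact's count in that amplicon.  Candidates matching a validated
    allele but out-counted by some artefact go to the manual-check log, with
    ``explanation=True`` iff every out-counting artefact is a chimera of
    alleles already called in that amplicon; ``accept_manual`` promotes those
    explained entries, reproducing the operator's decision.  Unclassified
    variants never enter the validated set automatically.
    """
    classifications = {k: list(v) for k, v in classifications.items()}
    alleles: dict[str, str] = {}
    calls: dict[AmpliconKey, dict[str, int]] = {k: {} for k in classifications}

    def ensure_allele(seq: str) -> str:
        if seq not in alleles:
            alleles[seq] = f"AL{len(alleles) + 1:02d}"
        return alleles[seq]

    # pass 1: top variant of every amplicon
    for key, cl in classifications.items():
        for c in cl:
            if c.reason == TOP_VARIANT:
                aid = ensure_allele(c.variant.sequence)
                calls[key][aid] = c.variant.count

    def max_artefact_count(cl: list[VariantClassification]) -> int:
        return max((c.variant.count for c in cl if c.cls == ARTEFACT), default=0)

    # pass 2: rescue validated alleles above all artefacts, to a fixpoint
    changed = True
    while changed:
        changed = False
        for key, cl in classifications.items():
            cap = max_artefact_count(cl)
            for c in cl:
                if c.cls != CANDIDATE:
                    continue
                seq = c.variant.sequence
                if seq not in alleles:
                    continue
                aid = alleles[seq]
                if aid in calls[key]:
                    c.cls, c.reason = ALLELE, KNOWN_ALLELE_RESCUE
                    continue
                if c.variant.count > cap:
                    calls[key][aid] = c.variant.count
                    c.cls, c.reason = ALLELE, KNOWN_ALLELE_RESCUE
                    changed = True

    # resolve leftovers: manual-check log and unclassified candidates
    manual_log: list[ManualCheck] = []
    for key, cl in classifications.items():
        called_here = set(calls[key])
        for c in cl:
            if c.cls != CANDIDATE:
                continue
            seq = c.variant.sequence
            if seq in alleles:
                blockers = [
                    a for a in cl
                    if a.cls == ARTEFACT and a.variant.count >= c.variant.count
                ]
                explained = bool(blockers) and all(
                    b.reason == CHIMERA
                    and b.chimera_parents is not None
                    and all(
                        p in alleles and alleles[p] in called_here
                        for p in b.chimera_parents[:2]
                    )
                    for b in blockers
                )
                manual_log.append(
                    ManualCheck(key, seq, c.variant.count, explained)
                )
                if accept_manual and explained:
                    calls[key][alleles[seq]] = c.variant.count
                    c.cls, c.reason = ALLELE, KNOWN_ALLELE_RESCUE
                else:
                    c.cls, c.reason = UNCLASSIFIED, MANUAL_CHECK_PENDING
            else:
                manual_log.append(ManualCheck(key, seq, c.variant.count, False))
                c.cls, c.reason = UNCLASSIFIED, MANUAL_CHECK_PENDING

    return AlleleCallSet(alleles, calls, manual_log, classifications)


def validate_amplicons(
    amplicons: Mapping[AmpliconKey, Sequence[str]],
    scope: str = SCOPE_DATASET,
    max_similar_diff: int = 2,
    accept_manual: bool = False,
) -> AlleleCallSet:
    """End-to-end protocol: dereplicate, classify, and score alleles."""
    return call_alleles(
        classify_dataset(amplicons, scope, max_similar_diff),
        accept_manual=accept_manual,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def classifications_frame(callset: AlleleCallSet) -> pd.DataFrame:
    rows = []
    for key, cl in callset.classifications.items():
        ind, strat, pcr = key
        for c in cl:
            rows.append(
                {
                    "individual": ind,
                    "strategy": strat,
                    "pcr_id": pcr,
                    "rank": c.variant.rank,
                    "count": c.variant.count,
                    "class": c.cls,
                    "reason": c.reason,
                    "replicated": c.replicated,
                    "sequence": c.variant.sequence,
                }
            )
    return pd.DataFrame(rows)


def call_matrix(callset: AlleleCallSet) -> pd.DataFrame:
    """Individuals x alleles presence matrix (union over a strategy's PCRs per cell)."""
    per_ind: dict[tuple[str, str], set[str]] = {}
    for (ind, strat, _), called in callset.calls.items():
        per_ind.setdefault((ind, strat), set()).update(called)
    allele_ids = sorted(callset.allele_sequences())
    rows = []
    for (ind, strat), called in sorted(per_ind.items()):
        rows.append(
            {"individual": ind, "strategy": strat}
            | {aid: int(aid in called) for aid in allele_ids}
        )
    return pd.DataFrame(rows)


def write_validation_outputs(callset: AlleleCallSet, out_dir: str | Path) -> dict[str, Path]:
    """Write classifications, validated alleles, call matrix and manual log."""
    from .io import write_fasta  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "classifications": out / "classifications.tsv",
        "alleles": out / "validated_alleles.fasta",
        "call_matrix": out / "call_matrix.tsv",
        "manual_log": out / "manual_check.tsv",
    }
    classifications_frame(callset).to_csv(paths["classifications"], sep="\t", index=False)
    write_fasta(sorted(callset.allele_sequences().items()), paths["alleles"])
    call_matrix(callset).to_csv(paths["call_matrix"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "individual": m.amplicon[0],
                "strategy": m.amplicon[1],
                "pcr_id": m.amplicon[2],
                "count": m.count,
                "explanation": m.explanation,
                "sequence": m.sequence,
            }
            for m in callset.manual_log
        ],
        columns=["individual", "strategy", "pcr_id", "count", "explanation", "sequence"],
    ).to_csv(paths["manual_log"], sep="\t", index=False)
    return paths
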