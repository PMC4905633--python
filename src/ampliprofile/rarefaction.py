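"""Bootstrap coverage rarefaction of amplicon read sets.

Reads from each amplicon are resampled with replacement over a grid of
depths (bootstrapping, so depths above the amplicon's real read count are
allowed) and the individual's allelic profile is re-scored at each depth.
The resulting accumulation curves show how profile completeness grows with
coverage, and where it saturates, for each amplification strategy.

Per-iteration scoring cannot re-run the full cross-amplicon validation
protocol; an allele counts as scored when its exact sequence is drawn at
least ``min_count`` times (default 2, the analogue of the singleton rule;
``min_count=1`` is supported).
"""

from __future__ import annotations

import warnings
import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CoverageGrid:
    """Subsampling design: depths ``start..stop`` by ``step``, bootstrapped ``iterations`` times."""

    start: int = 0
    stop: int = 4500
    step: int = 10
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    def depths(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1, self.step)


@dataclass
class CompletenessCurve:
    """Mean completeness and empirical 95% CI per coverage for one strategy."""

    strategy: str
    coverage: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "strategy": self.strategy,
                "coverage": self.coverage,
                "mean_completeness": self.mean,
                "ci_lo": self.lo,
                "ci_hi": self.hi,
            }
        )


def subsample_score(
    reads: Iterable[str] | Mapping[str, int],
    depth: int,
    profile_sequences: set[str],
    min_count: int = 2,
    seed: int | np.random.Generator = 0,
) -> float:
    """Completeness of one bootstrap draw of ``depth`` reads from an amplicon.

    ``profile_sequences`` is the individual's validated allelic profile from
    the full-data run (the denominator).  Returns completeness percent; an
    empty read set at positive depth scores 0 with a warning.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = reads if isinstance(reads, Mapping) else Counter(reads)
    n_present = len(profile_sequences)
    if n_present == 0:
        return 100.0
    if depth == 0:
        return 0.0
    total = sum(counts.values())
    if total == 0:
        warnings.warn("empty read set subsampled at positive depth; completeness 0")
        return 0.0
    seqs = list(counts)
    p = np.array([counts[s] for s in seqs], dtype=float) / total
    draw = rng.multinomial(depth, p)
    drawn = {s: int(c) for s, c in zip(seqs, draw)}
    scored = sum(1 for s in profile_sequences if drawn.get(s, 0) >= min_count)
    return 100.0 * scored / n_present


def _unit_probabilities(
    counts: Mapping[str, int], profile_sequences: Sequence[str]
) -> np.ndarray | None:
    """Multinomial bin probabilities: one bin per profile allele plus a rest bin."""
    total = sum(counts.values())
    if total == 0:
        return None
    allele_counts = np.array([counts.get(s, 0) for s in profile_sequences], dtype=float)
    rest = total - allele_counts.sum()
    return np.append(allele_counts, rest) / total


def accumulation_curves(
    units: Mapping[tuple[str, str], tuple[Mapping[str, int], set[str]]],
    grid: CoverageGrid | None = None,
    min_count: int = 2,
) -> dict[str, CompletenessCurve]:
    """Completeness accumulation curves per strategy.

    ``units`` maps ``(strategy, individual)`` to ``(read counts, profile)``:
    the amplicon read multiset for that individual under that strategy (all
    of the strategy's PCRs pooled) and the individual's full-data validated
    profile (sequences).  At every depth on the grid, every unit is
    bootstrapped ``grid.iterations`` times; mean and the 2.5/97.5 empirical
    percentiles are taken across iterations and individuals.  Deterministic
    for a fixed ``grid.seed`` and independent of unit insertion order.
    """
    grid = grid or CoverageGrid()
    depths = grid.depths()
    by_strategy: dict[str, list[tuple[np.ndarray, int]]] = {}
    for (strategy, individual) in sorted(units):
        counts, profile = units[(strategy, individual)]
        profile_list = sorted(profile)
        p = _unit_probabilities(counts, profile_list)
        if p is None:
            warnings.warn(f"unit {(strategy, individual)} has no reads; scores 0")
        by_strategy.setdefault(strategy, []).append((p, len(profile_list)))

    curves: dict[str, CompletenessCurve] = {}
    for strategy in sorted(by_strategy):
        # stable per-strategy stream so curves ignore unit/strategy insertion order
        rng = np.random.default_rng((grid.seed, zlib.crc32(strategy.encode())))
        unit_specs = by_strategy[strategy]
        mean = np.zeros(len(depths))
        lo = np.zeros(len(depths))
        hi = np.zeros(len(depths))
        for d_idx, depth in enumerate(depths):
            scores = []
            for p, n_profile in unit_specs:
                if n_profile == 0:
                    scores.append(np.full(grid.iterations, 100.0))
                    continue
                if depth == 0 or p is None:
                    scores.append(np.zeros(grid.iterations))
                    continue
                draws = rng.multinomial(int(depth), p, size=grid.iterations)
                scored = (draws[:, :n_profile] >= min_count).sum(axis=1)
                scores.append(100.0 * scored / n_profile)
            allscores = np.concatenate(scores)
            mean[d_idx] = allscores.mean()
            lo[d_idx], hi[d_idx] = np.percentile(allscores, [2.5, 97.5])
        curves[strategy] = CompletenessCurve(strategy, depths.copy(), mean, lo, hi)
    return curves


def curves_frame(curves: Mapping[str, CompletenessCurve]) -> pd.DataFrame:
    return pd.concat(
        [curves[s].to_frame() for s in sorted(curves)], ignore_index=True
    )


def units_from_read_sets(
    read_sets,
    profiles: Mapping[str, set[str]],
) -> dict[tuple[str, str], tuple[Counter, set[str]]]:
    """Pool read sets into (strategy, individual) units for rarefaction.

    Multi-PCR strategies are pooled across their PCR ids (matching how such
    amplicons share one tag in the sequencing pool).  ``profiles`` maps
    individual -> validated allele sequences from the full-data run.
    """
    units: dict[tuple[str, str], Counter] = {}
    for rs in read_sets:
        units.setdefault((rs.strategy, rs.individual_id), Counter()).update(rs.reads)
    return {
        key: (counts, set(profiles.get(key[1], set())))
        for key, counts in units.items()
    }


def plot_curves(curves: Mapping[str, CompletenessCurve], path) -> None:
    """Render accumulation curves with CI ribbons to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for strategy in sorted(curves):
        c = curves[strategy]
        ax.plot(c.coverage, c.mean, label=strategy)
        ax.fill_between(c.coverage, c.lo, c.hi, alpha=0.2)
    ax.set_xlabel("coverage (reads)")
    ax.set_ylabel("profile completeness (%)")
    ax.set_ylim(0, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
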