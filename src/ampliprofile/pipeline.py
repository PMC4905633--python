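"""End-to-end workflow: simulate -> validate -> stats -> rarefy.

Every stage writes plain-text tables under the output directory and the
resolved configuration is persisted alongside, so each run is re-derivable
from its outputs.  Any stage failure aborts with a stage-named error.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io, rarefaction, simulate, stats, validate
from .primers import STRATEGIES

log = logging.getLogger("ampliprofile")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate(config: io.RunConfig, out: Path) -> simulate.SimulatedDataset:
    dataset = simulate.simulate_dataset(
        n_individuals=config.n_individuals,
        n_loci=config.n_loci,
        allele_pool_size=config.allele_pool_size,
        depth=config.depth,
        seed=config.seed,
        efficiency_model=simulate.EfficiencyModel(
            config.lambda_internal,
            config.lambda_three_prime,
            config.three_prime_window,
            config.effective_concentration,
        ),
        artefact_model=simulate.ArtefactModel(
            config.chimera_rate,
            config.substitution_rate,
            config.homopolymer_indel_rate,
        ),
        core_length=config.core_length,
    )
    io.write_dataset(dataset.read_sets, out)
    io.write_fasta(
        sorted((aid, a.sequence) for aid, a in dataset.alleles.items()),
        out / "true_alleles.fasta",
    )
    log.info(
        "simulated %d amplicons, %d reads",
        len(dataset.read_sets),
        sum(len(rs.reads) for rs in dataset.read_sets),
    )
    return dataset


@_stage("validate")
def _validate(config: io.RunConfig, dataset, out: Path) -> validate.AlleleCallSet:
    amplicons = {rs.key: rs.reads for rs in dataset.read_sets}
    callset = validate.validate_amplicons(
        amplicons,
        scope=config.replication_scope,
        max_similar_diff=config.max_similar_diff,
        accept_manual=config.accept_manual,
    )
    validate.write_validation_outputs(callset, out)
    counts = validate.classifications_frame(callset)["class"].value_counts().to_dict()
    log.info("validated %d alleles; variant classes: %s", len(callset.alleles), counts)
    return callset


@_stage("stats")
def _stats(config: io.RunConfig, dataset, callset, out: Path) -> None:
    copy_number_by_seq = stats.copy_number_from_genotypes(dataset.genotypes)
    seq_of = callset.allele_sequences()
    truth_seq_to_id = dataset.sequence_to_allele()

    def copy_number(individual: str, allele_id: str) -> int:
        truth_id = truth_seq_to_id.get(seq_of.get(allele_id, ""), "")
        return copy_number_by_seq(individual, truth_id) if truth_id else 1

    complete = {
        ind: set.union(*(p for p in (callset.calls_by_individual(s).get(ind, set())
                                     for s in STRATEGIES)))
        for ind in {g.individual_id for g in dataset.genotypes}
    }
    amplicons = {rs.key: rs.reads for rs in dataset.read_sets}
    eff_frames = []
    for strategy in STRATEGIES:
        counts = stats.strategy_allele_counts(amplicons, callset.alleles, strategy)
        frame = stats.standardized_efficiencies(counts, complete, copy_number)
        frame.insert(0, "strategy", strategy)
        eff_frames.append(frame)
        det = stats.detection_stats(callset.calls_by_individual(strategy), complete)
        det.per_allele.assign(strategy=strategy).to_csv(
            out / f"detection_alleles_{strategy}.tsv", sep="\t", index=False
        )
        det.per_individual.assign(strategy=strategy).to_csv(
            out / f"detection_individuals_{strategy}.tsv", sep="\t", index=False
        )
    pd.concat(eff_frames, ignore_index=True).to_csv(
        out / "allele_efficiencies.tsv", sep="\t", index=False
    )
    stats.rank_vs_top_artefact_frame(callset.classifications, callset.alleles).to_csv(
        out / "rank_vs_artefact.tsv", sep="\t", index=False
    )


@_stage("rarefy")
def _rarefy(config: io.RunConfig, dataset, callset, out: Path) -> None:
    profiles = {
        ind: {seq for seq, aid in callset.alleles.items()
              if aid in callset.calls_by_individual().get(ind, set())}
        for ind in {g.individual_id for g in dataset.genotypes}
    }
    units = rarefaction.units_from_read_sets(dataset.read_sets, profiles)
    grid = rarefaction.CoverageGrid(
        config.grid_start, config.grid_stop, config.grid_step,
        config.grid_iterations, config.seed,
    )
    curves = rarefaction.accumulation_curves(
        units, grid, min_count=config.rarefaction_min_count
    )
    rarefaction.curves_frame(curves).to_csv(
        out / "completeness_curves.tsv", sep="\t", index=False
    )


def run_pipeline(config: io.RunConfig, out_dir: str | Path) -> Path:
    """Run the full workflow into ``out_dir``; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        config.to_yaml(out / "config.yaml")
        dataset = _simulate(config, out)
        callset = _validate(config, dataset, out)
        _stats(config, dataset, callset, out)
        _rarefy(config, dataset, callset, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
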