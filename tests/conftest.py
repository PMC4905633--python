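"""Shared fixtures: a full-scale synthetic experiment used by several suites."""

from __future__ import annotations

import pytest

from ampliprofile import STRATEGIES, simulate, validate
from ampliprofile import stats as st

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_dataset():
    """Synthetic experiment at study scale: 18 diploid individuals, 7 loci,
    13 alleles, depth 2000, default efficiency/artefact models."""
    return simulate.simulate_dataset(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_callset(study_dataset):
    amplicons = {rs.key: rs.reads for rs in study_dataset.read_sets}
    return validate.validate_amplicons(amplicons)


@pytest.fixture(scope="session")
def study_truth_map(study_dataset, study_callset):
    """Map from call-time allele ids to simulator truth ids (None = artefact)."""
    seq2tid = study_dataset.sequence_to_allele()
    return {
        cid: seq2tid.get(seq)
        for cid, seq in study_callset.allele_sequences().items()
    }


@pytest.fixture(scope="session")
def study_efficiency_frames(study_dataset, study_callset, study_truth_map):
    """Estimated standardized-efficiency tables per strategy (read-count based)."""
    amplicons = {rs.key: rs.reads for rs in study_dataset.read_sets}
    truth_copy = st.copy_number_from_genotypes(study_dataset.genotypes)

    def copy_number(ind, cid):
        tid = study_truth_map.get(cid)
        return truth_copy(ind, tid) if tid else 1

    complete = {
        g.individual_id: {
            cid
            for key, called in study_callset.calls.items()
            if key[0] == g.individual_id
            for cid in called
        }
        for g in study_dataset.genotypes
    }
    frames = {}
    for strategy in STRATEGIES:
        counts = st.strategy_allele_counts(amplicons, study_callset.alleles, strategy)
        frames[strategy] = st.standardized_efficiencies(counts, complete, copy_number)
    return frames
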