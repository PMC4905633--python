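"""File formats and run configuration: FASTA, manifests, YAML config."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primers import STRATEGIES

MANIFEST_COLUMNS = ["individual_id", "strategy", "pcr_id", "fasta_path"]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as ``(id, sequence)``, uppercased with U normalised to T.

    A syntactically malformed file (sequence data before the first header)
    raises ``ValueError`` naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected a '>' header before sequence data"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA."""
    seq_records = [
        SeqRecord(Seq(seq), id=str(rid), description="") for rid, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate an amplicon manifest TSV.

    Columns: individual_id, strategy, pcr_id, fasta_path.  Keys must be
    unique, strategies must be from the known set, and FASTA paths (resolved
    relative to the manifest) must exist.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    keys = df[["individual_id", "strategy", "pcr_id"]].apply(tuple, axis=1)
    dupes = keys[keys.duplicated()]
    if len(dupes):
        raise ValueError(f"manifest {path} has duplicate amplicon keys: {list(dupes)[:3]}")
    bad = sorted(set(df["strategy"]) - set(STRATEGIES))
    if bad:
        raise ValueError(f"manifest {path} has unknown strategies: {bad}")
    if check_paths:
        for p in df["fasta_path"]:
            resolved = (path.parent / p) if not Path(p).is_absolute() else Path(p)
            if not resolved.exists():
                raise FileNotFoundError(f"manifest entry points to missing file: {resolved}")
    return df


def read_manifest_amplicons(path: str | Path) -> dict[tuple[str, str, str], list[str]]:
    """Load all amplicon read sets referenced by a manifest."""
    path = Path(path)
    df = load_manifest(path)
    out = {}
    for row in df.itertuples(index=False):
        p = Path(row.fasta_path)
        if not p.is_absolute():
            p = path.parent / p
        out[(row.individual_id, row.strategy, row.pcr_id)] = [
            seq for _, seq in read_fasta(p)
        ]
    return out


def write_dataset(read_sets, out_dir: str | Path) -> Path:
    """Write per-amplicon FASTA files, a manifest TSV and truth tables.

    One FASTA per amplicon under ``reads/``, read ids in headers; a
    ``manifest.tsv`` mapping (individual, strategy, pcr_id) to each file; a
    ``truth.tsv`` giving every read's ground truth.  Returns the manifest path.
    """
    out = Path(out_dir)
    reads_dir = out / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for rs in read_sets:
        fname = f"{rs.individual_id}_{rs.strategy}_{rs.pcr_id}.fasta"
        write_fasta(zip(rs.read_ids(), rs.reads), reads_dir / fname)
        manifest_rows.append(
            {
                "individual_id": rs.individual_id,
                "strategy": rs.strategy,
                "pcr_id": rs.pcr_id,
                "fasta_path": f"reads/{fname}",
            }
        )
        for rid, origin in zip(rs.read_ids(), rs.origins):
            truth_rows.append(
                {
                    "individual_id": rs.individual_id,
                    "strategy": rs.strategy,
                    "pcr_id": rs.pcr_id,
                    "read_id": rid,
                    "kind": origin.kind,
                    "allele_id": origin.allele_id or "",
                    "parent1": origin.parents[0] if origin.parents else "",
                    "parent2": origin.parents[1] if origin.parents else "",
                    "breakpoint": "" if origin.breakpoint is None else origin.breakpoint,
                    "errored": origin.errored,
                }
            )
    manifest_path = out / "manifest.tsv"
    pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS).to_csv(
        manifest_path, sep="\t", index=False
    )
    pd.DataFrame(truth_rows).to_csv(out / "truth.tsv", sep="\t", index=False)
    return manifest_path


@dataclass
class RunConfig:
    """Resolved configuration of an end-to-end run; serialized next to outputs."""

    # population / simulator
    n_individuals: int = 18
    n_loci: int = 7
    allele_pool_size: int = 13
    depth: int = 2000
    core_length: int = 230
    seed: int = 0
    # efficiency model
    lambda_internal: float = 0.2
    lambda_three_prime: float = 0.02
    three_prime_window: int = 3
    effective_concentration: bool = True
    # artefact model
    chimera_rate: float = 0.01
    substitution_rate: float = 1e-3
    homopolymer_indel_rate: float = 0.02
    # validation protocol
    max_similar_diff: int = 2
    replication_scope: str = "dataset"
    accept_manual: bool = False
    # rarefaction grid
    grid_start: int = 0
    grid_stop: int = 4500
    grid_step: int = 10
    grid_iterations: int = 100
    rarefaction_min_count: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
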