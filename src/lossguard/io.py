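"""Readers and writers for the external formats the pipeline touches.

Coordinate convention: HMMER's domtblout prints 1-based inclusive
coordinates; everything inside this package is 0-based half-open.  The
conversion happens here, at the parse boundary, and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

__all__ = [
    "DomtblRow",
    "DomainModel",
    "RunConfig",
    "read_domtblout",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_cutoffs_tsv",
    "write_cutoffs_tsv",
    "get_logger",
]

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str, level: str = "INFO") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


@dataclass(frozen=True)
class DomtblRow:
    """One per-domain hit row from HMMER3 ``--domtblout`` output.

    All intervals are 0-based half-open (converted from the printed
    1-based inclusive values).
    """

    target_id: str
    target_len: int
    query_id: str
    query_len: int
    full_evalue: float
    full_score: float
    dom_score: float
    hmm_interval: tuple[int, int]
    ali_interval: tuple[int, int]
    env_interval: tuple[int, int]


@dataclass
class DomainModel:
    """A detectable domain family: profile length, score cutoff and the
    consensus peptide used by the built-in toy detector."""

    domain_id: str
    model_length: int
    score_cutoff: float
    consensus_peptide: str = ""

    def __post_init__(self):
        if self.model_length < 1:
            raise ValueError(f"model_length must be >= 1, got {self.model_length}")
        if not pd.notna(self.score_cutoff) or self.score_cutoff in (float("inf"), float("-inf")):
            raise ValueError("score_cutoff must be finite")


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and knobs, loadable from versioned YAML."""

    schema_version: int = 1
    seed: int = 0
    min_supergroups: int = 3
    require_both_sides: bool = True
    leca_clade_mean_threshold: float = 0.15
    min_busco_absences_per_genome: int = 5
    max_mismatches: int = 0
    codon_table: int = 1
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.leca_clade_mean_threshold <= 1.0):
            raise ValueError("leca_clade_mean_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        version = data.get("schema_version", 1)
        if version != 1:
            raise ValueError(f"unsupported config schema_version: {version}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _to_half_open(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    return (start_1based - 1, end_inclusive)


def read_domtblout(path) -> list[DomtblRow]:
    """Parse a HMMER3 per-domain table (``hmmsearch --domtblout``).

    Comment lines start with ``#``; data rows are whitespace-delimited
    with the description as trailing free text.  Returns one
    :class:`DomtblRow` per domain hit.
    """
    rows: list[DomtblRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 22:
                raise ValueError(f"{path}:{lineno}: expected >= 22 whitespace-delimited fields, got {len(fields)}")
            try:
                rows.append(
                    DomtblRow(
                        target_id=fields[0],
                        target_len=int(fields[2]),
                        query_id=fields[3],
                        query_len=int(fields[5]),
                        full_evalue=float(fields[6]),
                        full_score=float(fields[7]),
                        dom_score=float(fields[13]),
                        hmm_interval=_to_half_open(int(fields[15]), int(fields[16])),
                        ali_interval=_to_half_open(int(fields[17]), int(fields[18])),
                        env_interval=_to_half_open(int(fields[19]), int(fields[20])),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed domtblout row ({exc})") from exc
    return rows


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a binary presence/absence matrix (rows: domains, cols: species).

    First column is ``domain_id``; the header row carries species ids;
    cells must be 0 or 1.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise ValueError("duplicate domain_id rows in matrix")
    if frame.columns.has_duplicates:
        raise ValueError("duplicate species_id columns in matrix")
    values = frame.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValueError("presence matrix cells must be 0 or 1")
    frame.index.name = "domain_id"
    return frame.astype("int8")


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    values = matrix.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValueError("presence matrix cells must be 0 or 1")
    out = matrix.copy()
    out.index.name = "domain_id"
    out.to_csv(path, sep="\t")


def read_cutoffs_tsv(path) -> dict[str, DomainModel]:
    """Read the per-domain cutoff table: ``domain_id, score_cutoff,
    model_length[, consensus_peptide]``."""
    frame = pd.read_csv(path, sep="\t", dtype={"domain_id": str})
    required = {"domain_id", "score_cutoff", "model_length"}
    if not required <= set(frame.columns):
        raise ValueError(f"cutoff table must have columns {sorted(required)}")
    if frame["domain_id"].duplicated().any():
        raise ValueError("duplicate domain_id in cutoff table")
    models = {}
    for row in frame.itertuples(index=False):
        models[row.domain_id] = DomainModel(
            domain_id=row.domain_id,
            model_length=int(row.model_length),
            score_cutoff=float(row.score_cutoff),
            consensus_peptide=str(getattr(row, "consensus_peptide", "") or ""),
        )
    return models


def write_cutoffs_tsv(models: Mapping[str, DomainModel], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "domain_id": m.domain_id,
                "score_cutoff": m.score_cutoff,
                "model_length": m.model_length,
                "consensus_peptide": m.consensus_peptide,
            }
            for m in models.values()
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict (Biopython-backed)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
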