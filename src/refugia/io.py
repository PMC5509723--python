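"""Readers, writers and dataset validation.

Formats: aligned FASTA + two-column TSV population map for sequences;
CSV (individuals x loci, entries 0/1/empty/NA) for dominant markers;
CSV with named variable columns plus lon/lat for the environment table.
All text I/O is UTF-8, comma-separated CSV with '.' decimals.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    AlignedSequenceSet,
    AlignmentError,
    BinaryMarkerMatrix,
    EnvTable,
    MappingError,
)

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def read_popmap(path) -> dict[str, str]:
    """Two-column TSV: sample_id <TAB> population."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise MappingError("population map must have two tab-separated columns")
    return dict(zip(df[0], df[1]))


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, pop in popmap.items():
            fh.write(f"{sid}\t{pop}\n")


def read_fasta_alignment(path, popmap_path) -> AlignedSequenceSet:
    """Load an aligned FASTA plus its population map.

    Raises :class:`AlignmentError` on unequal lengths and
    :class:`MappingError` when a record is absent from the map.
    """
    popmap = read_popmap(popmap_path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return AlignedSequenceSet(sample_ids=ids, sequences=seqs, population_of=popmap)


def write_fasta_alignment(aln: AlignedSequenceSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.sample_ids, aln.sequences)
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_marker_matrix(path, popmap_path) -> BinaryMarkerMatrix:
    """CSV with a header row of locus ids; first column individual ids.

    Entries must be 0, 1 or a missing token (empty cell or NA).
    """
    popmap = read_popmap(popmap_path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    calls = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        for i, val in enumerate(df[col]):
            v = val.strip()
            if v in MISSING_TOKENS:
                continue
            if v not in {"0", "1"}:
                raise ValueError(
                    f"non-binary entry {val!r} at individual "
                    f"{df.index[i]!r}, locus {col!r}"
                )
            calls[i, j] = float(v)
    return BinaryMarkerMatrix(
        individual_ids=[str(i) for i in df.index],
        locus_ids=[str(c) for c in df.columns],
        calls=calls,
        population_of=popmap,
    )


def write_marker_matrix(markers: BinaryMarkerMatrix, path) -> None:
    df = pd.DataFrame(
        markers.calls, index=markers.individual_ids, columns=markers.locus_ids
    )
    # 0/1 as integers, NaN as empty cell
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.to_csv(path)


def read_env_table(path, variables: list[str] | None = None) -> EnvTable:
    """Environment CSV: first column unit ids, then variables, lon, lat.

    If ``variables`` is None, every column other than lon/lat is retained,
    in file order.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    if variables is None:
        variables = [c for c in df.columns if c not in ("lon", "lat")]
    return EnvTable(data=df, variables=list(variables))


def write_env_table(env: EnvTable, path) -> None:
    cols = env.variables + ["lon", "lat"]
    env.data[cols].to_csv(path)


@dataclass
class ValidationReport:
    """Cross-dataset sanity summary; validation never mutates inputs."""

    shared_populations: list[str]
    markers_only: list[str]
    env_only: list[str]
    n_per_population: dict[str, int]
    monomorphic_loci: list[str]
    fatal: bool = False
    messages: list[str] = field(default_factory=list)


def validate_dataset(markers: BinaryMarkerMatrix, env: EnvTable) -> ValidationReport:
    """Check population-label agreement and report monomorphic loci."""
    mpops = set(markers.populations)
    epops = set(env.unit_ids)
    shared = sorted(mpops & epops)
    report = ValidationReport(
        shared_populations=shared,
        markers_only=sorted(mpops - epops),
        env_only=sorted(epops - mpops),
        n_per_population={
            p: int(len(ix)) for p, ix in markers.population_indices().items()
        },
        monomorphic_loci=[
            lid
            for j, lid in enumerate(markers.locus_ids)
            if _is_monomorphic(markers.calls[:, j])
        ],
    )
    if not shared:
        report.fatal = True
        report.messages.append(
            "no population labels shared between marker and environment data"
        )
    if report.markers_only:
        report.messages.append(
            f"populations absent from environment table: {report.markers_only}"
        )
    return report


def _is_monomorphic(col: np.ndarray) -> bool:
    vals = col[~np.isnan(col)]
    return vals.size == 0 or np.all(vals == vals[0])
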