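"""Core in-memory containers shared by every analysis stage.

The containers are deliberately thin: a validated bundle of numpy/pandas
objects plus the population mapping that almost every statistic needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VALID_BASES = set("ACGT-N")


class AlignmentError(ValueError):
    """Raised when sequences do not form a valid alignment."""


class MappingError(ValueError):
    """Raised when a sample cannot be mapped to a population."""


@dataclass
class AlignedSequenceSet:
    """Aligned haplotype/genotype sequences with population labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per sequence.
    sequences
        Equal-length strings over ``A C G T - N`` (lowercase accepted,
        normalized to uppercase).
    population_of
        Mapping from sample id to population label.
    """

    sample_ids: list[str]
    sequences: list[str]
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        self.sequences = [s.upper() for s in self.sequences]
        k = len(self.sequences[0])
        if k < 1:
            raise AlignmentError("zero-length sequences")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != k:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {k}"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise AlignmentError(f"sequence {sid!r} has invalid symbols {bad}")
        for sid in self.sample_ids:
            if sid not in self.population_of:
                raise MappingError(f"sample {sid!r} missing from population map")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        """Aligned length k (columns before any site filtering)."""
        return len(self.sequences[0])

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.sample_ids:
            seen.setdefault(self.population_of[sid], None)
        return list(seen)

    def to_matrix(self) -> np.ndarray:
        """Alignment as an (n, k) array of single-character strings."""
        return np.array([list(s) for s in self.sequences], dtype="U1")

    def subset(self, sample_ids: Sequence[str]) -> "AlignedSequenceSet":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return AlignedSequenceSet(
            sample_ids=list(sample_ids),
            sequences=[self.sequences[idx[s]] for s in sample_ids],
            population_of={s: self.population_of[s] for s in sample_ids},
        )

    def by_population(self) -> dict[str, "AlignedSequenceSet"]:
        out = {}
        for pop in self.populations:
            ids = [s for s in self.sample_ids if self.population_of[s] == pop]
            out[pop] = self.subset(ids)
        return out


@dataclass
class BinaryMarkerMatrix:
    """Individuals x dominant loci presence/absence calls.

    ``calls`` is a float array with entries 0.0, 1.0 or NaN (missing).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        n, L = self.calls.shape
        if n != len(self.individual_ids) or L != len(self.locus_ids):
            raise ValueError("calls shape inconsistent with id lists")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        ok = np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1)
        if not ok.all():
            raise ValueError("calls must be 0, 1 or missing")
        for sid in self.individual_ids:
            if sid not in self.population_of:
                raise MappingError(f"individual {sid!r} missing from population map")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid in self.individual_ids:
            seen.setdefault(self.population_of[sid], None)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        """Row indices of each population, in first-appearance order."""
        out: dict[str, list[int]] = {}
        for i, sid in enumerate(self.individual_ids):
            out.setdefault(self.population_of[sid], []).append(i)
        return {p: np.array(ix) for p, ix in out.items()}

    def missingness_per_locus(self) -> np.ndarray:
        return np.isnan(self.calls).mean(axis=0)


@dataclass
class EnvTable:
    """Per-population (or per-individual) environmental covariates.

    ``data`` holds one row per unit; ``variables`` are the retained
    environmental columns; lon/lat are carried separately as geography.
    """

    data: pd.DataFrame
    variables: list[str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicated unit ids in environment table")
        for col in self.variables + ["lon", "lat"]:
            if col not in self.data.columns:
                raise ValueError(f"missing column {col!r}")
            if self.data[col].isna().any():
                raise ValueError(f"missing values in retained variable {col!r}")

    @property
    def unit_ids(self) -> list[str]:
        return [str(u) for u in self.data.index]

    def env_matrix(self) -> np.ndarray:
        return self.data[self.variables].to_numpy(dtype=float)

    def geo_matrix(self) -> np.ndarray:
        return self.data[["lon", "lat"]].to_numpy(dtype=float)


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with per-population counts.

    ``counts`` is a (haplotype x population) DataFrame of non-negative ints.
    """

    haplotype_ids: list[str]
    counts: pd.DataFrame
    representative: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(self.haplotype_ids):
            raise ValueError("counts index must equal haplotype_ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative haplotype counts")

    @property
    def n_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def populations(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    def total_counts(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=1)

    def population_counts(self, pop: str) -> np.ndarray:
        return self.counts[pop].to_numpy()


@dataclass
class AnalysisConfig:
    """Run-wide configuration: seed plus per-stage parameter blocks."""

    random_seed: int = 0
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def stage(self, name: str) -> dict:
        return dict(self.params.get(name, {}))

    def rng(self, offset: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.random_seed + offset) % (2**31))
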