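"""In-memory containers shared by the simulator, statistics and I/O layers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["SequenceAlignment", "STRDataset", "DatasetBundle", "PopPartition"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SequenceAlignment:
    """Equal-length nucleotide sequences with per-copy population labels.

    Sequences are held as a (n_copies, n_sites) uint8 matrix with codes
    0..3 = A,C,G,T; values >= 4 mark non-ACGT symbols (gaps / ambiguity
    codes) in observed data.
    """

    names: list[str]
    pops: list[str]
    matrix: np.ndarray  # uint8, shape (n, L)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.names) != self.matrix.shape[0] or len(self.pops) != len(self.names):
            raise ValueError("names, pops and matrix rows must agree")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_strings(
        cls,
        records: Sequence[tuple[str, str]],
        pops: Mapping[str, str] | Sequence[str] | None = None,
    ) -> "SequenceAlignment":
        names = [name for name, _ in records]
        if records:
            L = len(records[0][1])
            for name, seq in records:
                if len(seq) != L:
                    raise ValueError(f"record {name!r} has length {len(seq)} != {L}")
        mat = np.full((len(records), len(records[0][1]) if records else 0), 4, np.uint8)
        for i, (_, seq) in enumerate(records):
            row = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            for code, b in enumerate(b"ACGT"):
                mat[i, row == b] = code
        if pops is None:
            plist = [""] * len(names)
        elif isinstance(pops, Mapping):
            plist = [pops[n] for n in names]
        else:
            plist = list(pops)
        return cls(names, plist, mat)

    def sequence(self, i: int) -> str:
        row = self.matrix[i]
        out = np.full(row.shape, ord("N"), np.uint8)
        ok = row < 4
        out[ok] = _BASES[row[ok]]
        return out.tobytes().decode()

    def subset(self, idx: Iterable[int]) -> "SequenceAlignment":
        idx = list(idx)
        return SequenceAlignment(
            [self.names[i] for i in idx],
            [self.pops[i] for i in idx],
            self.matrix[idx],
        )

    def by_population(self, label: str) -> "SequenceAlignment":
        return self.subset([i for i, p in enumerate(self.pops) if p == label])


@dataclass
class STRDataset:
    """Integer allele sizes (repeat units) per gene copy x locus.

    Missing alleles are coded as -1 (Genepop '000').
    """

    names: list[str]
    pops: list[str]
    matrix: np.ndarray  # int, shape (n_copies, n_loci)
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("STR matrix must be 2-D")
        if len(self.names) != self.matrix.shape[0] or len(self.pops) != len(self.names):
            raise ValueError("names, pops and matrix rows must agree")
        if not self.locus_names:
            self.locus_names = [f"L{j + 1:02d}" for j in range(self.matrix.shape[1])]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[1]

    def by_population(self, label: str) -> np.ndarray:
        mask = np.array([p == label for p in self.pops])
        return self.matrix[mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.locus_names)
        df.insert(0, "population", self.pops)
        df.insert(0, "copy", self.names)
        return df


@dataclass
class PopPartition:
    """Assignment of gene copies to populations, plus the pair list used for
    pairwise statistics."""

    labels: list[str]
    pairs: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "PopPartition":
        uniq = sorted(set(labels))
        pairs = [(a, b) for i, a in enumerate(uniq) for b in uniq[i + 1 :]]
        return cls(list(uniq), pairs)


@dataclass
class DatasetBundle:
    """Paired mtDNA alignment + microsatellite table + provenance for one
    (real or simulated) dataset."""

    mt: SequenceAlignment
    strs: STRDataset
    provenance: dict = field(default_factory=dict)

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.mt.pops) | set(self.strs.pops))
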