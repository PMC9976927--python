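"""Core genomic value types shared by every stage of the pipeline.

All coordinates inside the package are 0-based, half-open ``[start, end)``,
with strand one of ``+``, ``-`` or ``.`` (unstranded). File readers convert
from the on-disk convention (GTF and wiggle are 1-based) at the boundary, so
no other module ever sees a 1-based coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and "." not in (self.strand, other.strand):
            if self.strand != other.strand:
                return False
        return self.start < other.end and other.start < self.end

    def intersection(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom,
            max(self.start, other.start),
            min(self.end, other.end),
            self.strand,
        )


class GenomeSequence:
    """Chromosome name -> upper-case nucleotide string.

    Lookups outside chromosome bounds raise; this is how downstream filters
    notice malformed annotations rather than silently truncating.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: Dict[str, str] = {}
        for name, seq in sequences.items():
            if name in self._seqs:
                raise ValueError(f"duplicate chromosome {name!r}")
            self._seqs[name] = seq.upper()

    def chromosomes(self) -> Tuple[str, ...]:
        return tuple(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self._seqs.get(iv.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(seq):
            raise IndexError(
                f"interval [{iv.start},{iv.end}) beyond {iv.chrom} length {len(seq)}"
            )
        return seq[iv.start : iv.end]

    def items(self) -> Iterable[Tuple[str, str]]:
        return self._seqs.items()


@dataclass
class _StrandSignal:
    """Sorted sparse coverage on one (chrom, strand)."""

    positions: np.ndarray  # int64, sorted, unique
    values: np.ndarray  # float64, >= 0
    cumulative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cumulative = np.concatenate([[0.0], np.cumsum(self.values)])


class SignalTrack:
    """Strand-resolved sparse per-base read coverage.

    Window sums use a cumulative-sum over the sorted sparse positions, so a
    query is two binary searches regardless of window length.
    """

    def __init__(self, genome_build: str = "synthetic"):
        self.genome_build = genome_build
        self._data: Dict[Tuple[str, str], _StrandSignal] = {}

    def add(
        self,
        chrom: str,
        strand: str,
        positions: np.ndarray,
        values: np.ndarray,
    ) -> None:
        """Add coverage for one (chrom, strand); merges with existing data.

        Conflicting duplicate declarations for the same position raise.
        """
        if strand not in ("+", "-"):
            raise ValueError("signal strand must be + or -")
        positions = np.asarray(positions, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if positions.shape != values.shape:
            raise ValueError("positions and values length mismatch")
        if np.any(values < 0):
            raise ValueError("coverage values must be non-negative")
        key = (chrom, strand)
        if key in self._data:
            prev = self._data[key]
            both = np.concatenate([prev.positions, positions])
            vals = np.concatenate([prev.values, values])
        else:
            both, vals = positions, values
        order = np.argsort(both, kind="stable")
        both, vals = both[order], vals[order]
        dup = both[1:] == both[:-1]
        if np.any(dup):
            i = np.nonzero(dup)[0]
            if np.any(vals[i] != vals[i + 1]):
                pos = both[i[0]]
                raise ValueError(
                    f"conflicting coverage declarations at {chrom}:{pos} ({strand})"
                )
            keep = np.concatenate([~dup, [True]])
            both, vals = both[keep], vals[keep]
        mask = vals != 0
        self._data[key] = _StrandSignal(both[mask], vals[mask])

    def keys(self) -> Tuple[Tuple[str, str], ...]:
        return tuple(self._data)

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of coverage over ``[start, end)`` on one strand."""
        sig = self._data.get((chrom, strand))
        if sig is None or start >= end:
            return 0.0
        lo = np.searchsorted(sig.positions, start, side="left")
        hi = np.searchsorted(sig.positions, end, side="left")
        return float(sig.cumulative[hi] - sig.cumulative[lo])

    def total(self) -> float:
        return float(sum(s.values.sum() for s in self._data.values()))

    def arrays(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        sig = self._data.get((chrom, strand))
        if sig is None:
            return np.empty(0, dtype=np.int64), np.empty(0)
        return sig.positions, sig.values
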