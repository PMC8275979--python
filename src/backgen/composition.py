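"""Nucleotide composition: k-mer counts, %GC and sliding-window %GC profiles.

IUPAC policy: only G, C and the strong code S count toward %GC; the
denominator is always the full residue count. Ambiguity codes are treated
as literal symbols in k-mer counting (no expansion into ACGT possibilities),
which is what exact-count-preserving shuffling requires.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from statistics import fmean, pstdev
from typing import Union

from .seqio import SequenceRecord

GC_RESIDUES = frozenset("GCS")

SeqLike = Union[str, SequenceRecord]


def _residues(seq: SeqLike) -> str:
    return seq.residues if isinstance(seq, SequenceRecord) else seq


@dataclass(frozen=True)
class KmerProfile:
    """Exact counts of all overlapping length-k substrings of one sequence."""

    k: int
    counts: dict[str, int]
    total: int

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerProfile):
            return NotImplemented
        return self.k == other.k and self.counts == other.counts


@dataclass(frozen=True)
class GCWindowProfile:
    """Per-window %GC values of a sequence with their mean and population SD.

    Windows are 0-based half-open ``[offset, offset + window_size)`` at
    offsets 0, step, 2*step, ... while they fit inside the sequence; a
    sequence shorter than one window contributes a single whole-sequence
    window.
    """

    window_size: int
    step: int
    values: tuple[float, ...]
    mean: float
    sd: float


def gc_fraction(seq: SeqLike) -> float:
    """Fraction of residues counting as G/C (G, C or S) over the full length."""
    residues = _residues(seq)
    if not residues:
        raise ValueError("cannot compute GC fraction of an empty sequence")
    return sum(1 for r in residues if r in GC_RESIDUES) / len(residues)


def gc_bin(seq: SeqLike) -> int:
    """Integer 1%-GC bin: floor(100 * gc_fraction), with GC = 1.0 in bin 100.

    Computed in integer arithmetic (100 * strong count // length) so bins
    are exact where floating-point floor(100 * f) would misplace edge cases.
    """
    residues = _residues(seq)
    if not residues:
        raise ValueError("cannot bin an empty sequence")
    strong = sum(1 for r in residues if r in GC_RESIDUES)
    return (100 * strong) // len(residues)


def kmer_profile(seq: SeqLike, k: int) -> KmerProfile:
    """Counts of every overlapping length-k substring.

    For a sequence of length L the total is max(L - k + 1, 0); when k > L
    the profile is empty rather than an error.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    residues = _residues(seq)
    n = len(residues) - k + 1
    if n <= 0:
        return KmerProfile(k=k, counts={}, total=0)
    counts = Counter(residues[i : i + k] for i in range(n))
    return KmerProfile(k=k, counts=dict(counts), total=n)


def window_spans(length: int, window_size: int, step: int) -> list[tuple[int, int]]:
    """Half-open spans of full sliding windows; one whole-sequence span if L < W."""
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    if length < window_size:
        return [(0, length)]
    return [
        (off, off + window_size)
        for off in range(0, length - window_size + 1, step)
    ]


def gc_window_profile(
    seq: SeqLike, window_size: int = 100, step: int = 50
) -> GCWindowProfile:
    """Sliding-window %GC profile (values in [0, 100]).

    The number of windows is floor((L - W)/S) + 1 for L >= W; trailing
    partial windows are not emitted so every value covers exactly W bp.
    The SD is the population (divide-by-n) standard deviation: the windows
    are the complete profile, not a sample.
    """
    residues = _residues(seq)
    values = tuple(
        100.0 * gc_fraction(residues[a:b])
        for a, b in window_spans(len(residues), window_size, step)
    )
    return GCWindowProfile(
        window_size=window_size,
        step=step,
        values=values,
        mean=fmean(values),
        sd=pstdev(values),
    )
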