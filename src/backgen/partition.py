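"""Tile a genome FASTA into fixed-size bins to build background pools.

Each contig is cut into non-overlapping bins of ``bin_size`` bp (0-based,
half-open coordinates); bins with too high a fraction of N residues are
discarded so assembly gaps do not flood the low-GC bins. The five bin sizes
commonly used for precomputed pools are 100, 250, 500, 750 and 1000 bp, but
any positive size works. Only the forward strand is emitted: %GC is
strand-symmetric, so reverse complements add no matching power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Optional, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

STANDARD_BIN_SIZES = (100, 250, 500, 750, 1000)


@dataclass(frozen=True)
class PartitionConfig:
    """Genome partitioning parameters.

    max_n_fraction: bins whose N fraction exceeds this are dropped.
    drop_remainder: whether the short final bin of each contig is discarded.
    """

    bin_size: int
    max_n_fraction: float = 0.1
    drop_remainder: bool = True
    emit_bed: bool = False

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")


def partition_genome(
    genome: Sequence[SequenceRecord], config: PartitionConfig
) -> list[SequenceRecord]:
    """Cut every contig into bins ``[i*b, (i+1)*b)``; identifiers are
    ``contig:start-end``.

    With ``drop_remainder=False`` the final short bin is kept too (if at
    least 1 bp and passing the N filter). Emits a warning when no bin
    survives.
    """
    if len(genome) == 0:
        raise ValueError("genome has no contigs")
    bins: list[SequenceRecord] = []
    b = config.bin_size
    for contig in genome:
        length = len(contig.residues)
        starts = list(range(0, (length // b) * b, b))
        if not config.drop_remainder and (length % b or length < b):
            starts.append((length // b) * b)
        for start in starts:
            end = min(start + b, length)
            if end <= start:
                continue
            piece = contig.residues[start:end]
            if piece.count("N") / len(piece) > config.max_n_fraction:
                continue
            bins.append(
                SequenceRecord(f"{contig.identifier}:{start}-{end}", "", piece)
            )
    if not bins:
        logger.warning(
            "no bins emitted: bin_size=%d exceeds every contig length or all "
            "bins failed the N filter",
            b,
        )
    return bins


def write_bed(bins: Iterable[SequenceRecord], handle: IO[str]) -> int:
    """Write bin coordinates as BED3 (identifiers are ``contig:start-end``)."""
    n = 0
    for rec in bins:
        contig, span = rec.identifier.rsplit(":", 1)
        start, end = span.split("-")
        handle.write(f"{contig}\t{start}\t{end}\n")
        n += 1
    return n


class GenomePartitioner(TransformerMixin, BaseEstimator):
    """Transformer tiling contigs into fixed-size background-pool bins."""

    def __init__(
        self,
        bin_size: int = 500,
        max_n_fraction: float = 0.1,
        drop_remainder: bool = True,
    ):
        self.bin_size = bin_size
        self.max_n_fraction = max_n_fraction
        self.drop_remainder = drop_remainder

    def _config(self) -> PartitionConfig:
        return PartitionConfig(
            bin_size=self.bin_size,
            max_n_fraction=self.max_n_fraction,
            drop_remainder=self.drop_remainder,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None) -> "GenomePartitioner":
        self._config()
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        return partition_genome(list(X), self._config())
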