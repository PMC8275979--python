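"""Synthetic foregrounds, background pools and genomes for testing and demos.

These generators emulate the inputs of a motif-enrichment study: a
foreground set (e.g. ChIP-seq peak sequences) with a controllable %GC mean
and optional within-sequence GC gradient, a background pool spanning all 1%
GC bins, and a toy genome with GC-patterned contigs and N-gap stretches for
the partitioner. Every generator is fully determined by its seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .seqio import SequenceRecord

_AT = np.array(["A", "T"])
_GC = np.array(["G", "C"])


def _draw_sequence(
    length: int, gc_per_base: np.ndarray, rng: np.random.Generator
) -> str:
    is_gc = rng.random(length) < gc_per_base
    strong = rng.integers(2, size=length)
    chars = np.where(is_gc, _GC[strong], _AT[strong])
    return "".join(chars)


def random_foregrounds(
    n: int,
    length_range: tuple[int, int] = (200, 200),
    gc: float = 0.5,
    gc_gradient: Optional[tuple[float, float]] = None,
    seed: Optional[int] = None,
    prefix: str = "fg",
) -> list[SequenceRecord]:
    """Random foreground sequences with target %GC composition.

    Each base is drawn independently with P(G or C) = ``gc``; with
    ``gc_gradient=(g0, g1)`` the probability ramps linearly from g0 at the
    5' end to g1 at the 3' end, giving every sequence a heterogeneous
    sliding-window profile.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if gc_gradient is None:
            probs = np.full(length, gc)
        else:
            probs = np.linspace(gc_gradient[0], gc_gradient[1], length)
        records.append(
            SequenceRecord(
                f"{prefix}_{i + 1}",
                f"synthetic gc={gc if gc_gradient is None else gc_gradient}",
                _draw_sequence(length, probs, rng),
            )
        )
    return records


def pool_spanning_gc_bins(
    per_bin: int = 10,
    length: int = 100,
    seed: Optional[int] = None,
    prefix: str = "pool",
) -> list[SequenceRecord]:
    """A background pool with ``per_bin`` sequences in EVERY 1%-GC bin 0..100.

    Sequences of length ``length`` (a multiple of 100 keeps bins exact) are
    built with exactly round(bin * length / 100) strong residues at random
    positions, so bin membership is by construction, not by sampling.
    """
    if length % 100:
        raise ValueError("length must be a multiple of 100 for exact bin placement")
    rng = np.random.default_rng(seed)
    records = []
    for b in range(101):
        n_gc = round(b * length / 100)
        for j in range(per_bin):
            chars = np.concatenate(
                [
                    _GC[rng.integers(2, size=n_gc)],
                    _AT[rng.integers(2, size=length - n_gc)],
                ]
            )
            rng.shuffle(chars)
            records.append(
                SequenceRecord(f"{prefix}_gc{b}_{j + 1}", "", "".join(chars))
            )
    return records


def synthetic_genome(
    n_contigs: int = 3,
    contig_length: int = 10_000,
    gc_block: int = 1000,
    gc_levels: Sequence[float] = (0.3, 0.6),
    n_gap_length: int = 200,
    n_gaps_per_contig: int = 2,
    seed: Optional[int] = None,
) -> list[SequenceRecord]:
    """A toy genome: contigs of alternating GC-level blocks with N gaps.

    Blocks of ``gc_block`` bp alternate between the ``gc_levels`` so the
    genome covers a range of GC bins after partitioning; ``n_gaps_per_contig``
    runs of N of length ``n_gap_length`` are overwritten at random positions
    to mimic assembly gaps.
    """
    rng = np.random.default_rng(seed)
    contigs = []
    for c in range(n_contigs):
        probs = np.empty(contig_length)
        for start in range(0, contig_length, gc_block):
            level = gc_levels[(start // gc_block) % len(gc_levels)]
            probs[start : start + gc_block] = level
        chars = list(_draw_sequence(contig_length, probs, rng))
        for _ in range(n_gaps_per_contig):
            gap_start = int(rng.integers(0, max(contig_length - n_gap_length, 1)))
            chars[gap_start : gap_start + n_gap_length] = "N" * min(
                n_gap_length, contig_length - gap_start
            )
        contigs.append(
            SequenceRecord(f"contig_{c + 1}", "synthetic genome contig", "".join(chars))
        )
    return contigs
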