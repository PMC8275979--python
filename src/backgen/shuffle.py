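"""Synthetic background models: global and sliding-window k-let shuffling.

A k-let shuffle rearranges a sequence while preserving the exact counts of
all its length-k substrings (and hence of every shorter substring too).
For k >= 2 this is done by the Euler-path construction on the de Bruijn
multigraph of the sequence: vertices are the (k-1)-lets, each k-let
occurrence is a directed edge from its (k-1)-prefix to its (k-1)-suffix,
and every k-let-preserving rearrangement corresponds to an Eulerian walk
from the first (k-1)-let to the last one.

Sampling is exactly uniform over valid rearrangements: a uniformly random
in-arborescence toward the terminal vertex is drawn with Wilson's
loop-erased-random-walk algorithm (edge-multiplicity-weighted), its edges
are fixed as each vertex's last exit, the remaining out-edges are uniformly
ordered, and the Eulerian walk spells the output. By the BEST theorem this
walk always exists and uses every edge, and each valid output string is
spelled by the same number of (arborescence, ordering) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .composition import window_spans
from .seqio import SequenceRecord


@dataclass(frozen=True)
class ShuffleConfig:
    """Parameters of the two shuffling models.

    k is the k-let order; window_size/step only apply to the windowed model;
    replicates is the number of background sequences emitted per input.
    """

    k: int = 1
    window_size: int = 100
    step: int = 50
    seed: Optional[int] = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.window_size < self.k:
            raise ValueError(
                f"window_size ({self.window_size}) must be >= k ({self.k}) "
                "so every window can be shuffled at order k"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _sample_arborescence(
    adjacency: dict[str, list[str]], root: str, rng: np.random.Generator
) -> dict[str, str]:
    """Uniform random in-arborescence toward ``root`` (Wilson's algorithm).

    Transitions are weighted by edge multiplicity, which makes the result
    uniform over multigraph arborescences. Returns vertex -> parent.
    """
    next_v: dict[str, str] = {}
    in_tree = {root}
    for u in adjacency:
        v = u
        while v not in in_tree:
            succ = adjacency[v]
            next_v[v] = succ[rng.integers(len(succ))]
            v = next_v[v]
        v = u
        while v not in in_tree:
            in_tree.add(v)
            v = next_v[v]
    return {u: p for u, p in next_v.items() if u != root}


def _euler_shuffle(residues: str, k: int, rng: np.random.Generator) -> str:
    start = residues[: k - 1]
    end = residues[-(k - 1):]
    adjacency: dict[str, list[str]] = {}
    for i in range(len(residues) - k + 1):
        adjacency.setdefault(residues[i : i + k - 1], []).append(
            residues[i + 1 : i + k]
        )
    parent = _sample_arborescence(adjacency, end, rng)
    # Order out-edges per vertex: uniform permutation, the arborescence edge
    # (one occurrence) reserved as the final exit.
    order: dict[str, list[str]] = {}
    for u, succ in adjacency.items():
        succ = list(succ)
        if u in parent:
            succ.remove(parent[u])
        succ = [succ[i] for i in rng.permutation(len(succ))]
        if u in parent:
            succ.append(parent[u])
        order[u] = succ
    cursor = {u: 0 for u in order}
    out = list(start)
    v = start
    while True:
        edges = order.get(v)
        if edges is None or cursor[v] >= len(edges):
            break
        nxt = edges[cursor[v]]
        cursor[v] += 1
        out.append(nxt[-1])
        v = nxt
    return "".join(out)


def klet_shuffle_str(residues: str, k: int, rng: np.random.Generator) -> str:
    """k-let-preserving shuffle of a plain string; see module docstring."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(residues):
        return residues
    if k == 1:
        chars = np.array(list(residues))
        return "".join(chars[rng.permutation(len(chars))])
    return _euler_shuffle(residues, k, rng)


def klet_shuffle(
    record: SequenceRecord, k: int, rng: np.random.Generator
) -> SequenceRecord:
    """Return a record whose residues are a uniform k-let-preserving shuffle.

    The output has identical length and identical j-mer counts for every
    j <= k; for k >= 2 the first and last (k-1)-lets are fixed (they are the
    endpoints of the Eulerian walk). A record shorter than k+1 residues is
    returned with unchanged residues.
    """
    return SequenceRecord(
        record.identifier, record.description, klet_shuffle_str(record.residues, k, rng)
    )


def window_shuffle_str(
    residues: str, config: ShuffleConfig, rng: np.random.Generator
) -> str:
    """Sliding-window k-let shuffle of a plain string.

    Windows at offsets 0, S, 2S, ... are k-let-shuffled sequentially IN
    PLACE, so with overlapping windows (S < W) later windows re-shuffle the
    overlap seen after earlier shuffles. Residues past the last full window
    are shuffled as a shrunk tail window. Global mononucleotide counts are
    always conserved exactly; local k-let counts are only guaranteed for the
    last window that touched each region.
    """
    chars = list(residues)
    length = len(chars)
    spans = window_spans(length, config.window_size, config.step)
    covered_end = spans[-1][1]
    if covered_end < length:
        spans.append((spans[-1][0] + config.step, length))
    for a, b in spans:
        chars[a:b] = klet_shuffle_str("".join(chars[a:b]), config.k, rng)
    return "".join(chars)


def window_shuffle(
    record: SequenceRecord, config: ShuffleConfig, rng: np.random.Generator
) -> SequenceRecord:
    """Sliding-window k-let shuffle of a record; see :func:`window_shuffle_str`."""
    return SequenceRecord(
        record.identifier,
        record.description,
        window_shuffle_str(record.residues, config, rng),
    )


def _record_rng(base: int, index: int, replicate: int) -> np.random.Generator:
    # Per-record substreams keyed by (base seed, record index, replicate) so
    # output is invariant to batch splitting.
    return np.random.default_rng([base, index, replicate])


def _resolve_base_seed(seed: Optional[int]) -> int:
    if seed is not None:
        return int(seed)
    return int(np.random.SeedSequence().generate_state(1)[0])


def generate_shuffled_set(
    records: Sequence[SequenceRecord],
    config: ShuffleConfig,
    mode: Literal["global", "windowed"] = "global",
) -> list[SequenceRecord]:
    """Batch driver: ``replicates`` shuffled backgrounds per input record.

    Output identifiers are ``<input id>_shuf_<replicate>``; the description
    records the model and its parameters. Deterministic given ``config.seed``.
    """
    if mode not in ("global", "windowed"):
        raise ValueError(f"unknown shuffle mode {mode!r}")
    base = _resolve_base_seed(config.seed)
    out: list[SequenceRecord] = []
    for idx, rec in enumerate(records):
        for rep in range(1, config.replicates + 1):
            rng = _record_rng(base, idx, rep)
            if mode == "global":
                residues = klet_shuffle_str(rec.residues, config.k, rng)
                desc = f"k-let shuffle k={config.k}"
            else:
                residues = window_shuffle_str(rec.residues, config, rng)
                desc = (
                    f"windowed k-let shuffle k={config.k} "
                    f"W={config.window_size} S={config.step}"
                )
            out.append(
                SequenceRecord(
                    f"{rec.identifier}_shuf_{rep}",
                    f"{desc} replicate={rep} source={rec.identifier}",
                    residues,
                )
            )
    return out


class KLetShuffler(TransformerMixin, BaseEstimator):
    """Transformer emitting k-let-preserving shuffled backgrounds.

    Parameters
    ----------
    k : int, default=1
        Order of the shuffle; k-mer counts up to this order are conserved
        exactly in each output.
    replicates : int, default=1
        Background sequences emitted per input sequence.
    random_state : int or None
        Seed for the (otherwise entropy-seeded) generator.
    """

    def __init__(self, k: int = 1, replicates: int = 1, random_state: Optional[int] = None):
        self.k = k
        self.replicates = replicates
        self.random_state = random_state

    def _config(self) -> ShuffleConfig:
        return ShuffleConfig(
            k=self.k,
            window_size=max(100, self.k),
            seed=self.random_state,
            replicates=self.replicates,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None) -> "KLetShuffler":
        self._config()  # parameter validation only; the model is stateless
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        return generate_shuffled_set(list(X), self._config(), mode="global")


class SlidingWindowShuffler(TransformerMixin, BaseEstimator):
    """Transformer shuffling k-lets within a sliding window.

    Conserves local k-mer composition per window (W bp windows advancing by
    S bp) and global mononucleotide counts exactly.
    """

    def __init__(
        self,
        k: int = 1,
        window_size: int = 100,
        step: int = 50,
        replicates: int = 1,
        random_state: Optional[int] = None,
    ):
        self.k = k
        self.window_size = window_size
        self.step = step
        self.replicates = replicates
        self.random_state = random_state

    def _config(self) -> ShuffleConfig:
        return ShuffleConfig(
            k=self.k,
            window_size=self.window_size,
            step=self.step,
            seed=self.random_state,
            replicates=self.replicates,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None) -> "SlidingWindowShuffler":
        self._config()
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        return generate_shuffled_set(list(X), self._config(), mode="windowed")
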