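"""Genomic background models: 1%-GC-bin matching and windowed %GC matching.

Both models draw real sequences from a user-supplied background pool
(typically fixed-size genome partition bins, see :mod:`backgen.partition`)
instead of synthesizing sequence. The global model pairs each foreground
sequence with a pool sequence from the same integer 1%-GC bin; the windowed
model requires the candidate's whole sliding-window %GC profile to sit
inside the foreground's mean +/- m*sd band (default m = 2.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .composition import gc_bin, gc_window_profile
from .seqio import SequenceRecord


class EmptyPoolError(ValueError):
    """Raised when no background pool sequences are available."""


@dataclass
class MatchConfig:
    """Parameters of the genomic matching models.

    sd_multiplier is the half-width of the windowed acceptance band in
    foreground-profile standard deviations; max_bin_distance bounds the
    fallback ring search of the GC-bin model (0 disables fallback).
    """

    sd_multiplier: float = 2.6
    window_size: int = 100
    step: int = 50
    with_replacement: bool = True
    max_bin_distance: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")
        if self.max_bin_distance < 0:
            raise ValueError("max_bin_distance must be >= 0")
        if self.window_size < 1 or self.step < 1:
            raise ValueError("window_size and step must be positive")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one foreground sequence against the pool."""

    foreground_id: str
    background: Optional[SequenceRecord]
    bin_distance: int = 0
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.accepted == (self.background is None):
            raise ValueError("background must be present iff accepted")


@dataclass
class GCBinIndex:
    """Background pool partitioned into the 101 integer %GC bins 0..100."""

    bins: dict[int, list[SequenceRecord]] = field(default_factory=dict)
    pool_size: int = 0

    def remove(self, b: int, idx: int) -> None:
        del self.bins[b][idx]
        self.pool_size -= 1


def build_gc_index(pool: Iterable[SequenceRecord]) -> GCBinIndex:
    """Assign each pool record to its 1%-GC bin (floor rule, GC=1 in bin 100)."""
    index = GCBinIndex()
    for rec in pool:
        index.bins.setdefault(gc_bin(rec), []).append(rec)
        index.pool_size += 1
    if index.pool_size == 0:
        raise EmptyPoolError("background pool is empty")
    return index


def match_gc_bin(
    foreground: SequenceRecord,
    index: GCBinIndex,
    config: MatchConfig,
    rng: np.random.Generator,
) -> MatchResult:
    """Draw a uniformly random pool sequence from the foreground's GC bin.

    If the bin is empty, bins at distance 1, 2, ... up to
    ``config.max_bin_distance`` are searched (the two bins at each distance
    are pooled before sampling) and the distance used is reported. Without
    replacement the chosen record is removed from the index.
    """
    target = gc_bin(foreground)
    for dist in range(config.max_bin_distance + 1):
        candidates: list[tuple[int, int]] = []  # (bin, position)
        bins = {target - dist, target + dist}
        for b in bins:
            if 0 <= b <= 100:
                candidates.extend((b, i) for i in range(len(index.bins.get(b, ()))))
        if candidates:
            b, i = candidates[rng.integers(len(candidates))]
            chosen = index.bins[b][i]
            if not config.with_replacement:
                index.remove(b, i)
            return MatchResult(foreground.identifier, chosen, bin_distance=dist)
    return MatchResult(foreground.identifier, None, bin_distance=0, accepted=False)


def windowed_acceptance_band(
    foreground: SequenceRecord, config: MatchConfig
) -> tuple[float, float]:
    """[mean - m*sd, mean + m*sd] over the foreground's window %GC values."""
    prof = gc_window_profile(foreground, config.window_size, config.step)
    half = config.sd_multiplier * prof.sd
    return prof.mean - half, prof.mean + half


def match_windowed(
    foreground: SequenceRecord,
    pool: Sequence[SequenceRecord],
    config: MatchConfig,
    rng: np.random.Generator,
    _pool_values: Optional[list[tuple[float, ...]]] = None,
) -> MatchResult:
    """Draw a pool sequence whose window %GC profile fits the foreground band.

    A candidate is accepted when EVERY one of its window %GC values lies in
    the foreground's [mean - m*sd, mean + m*sd] band; the match is a uniform
    draw over accepted candidates. With a homogeneous foreground (sd = 0)
    the band degenerates to a point. ``_pool_values`` lets batch callers
    precompute candidate window values once.
    """
    if len(pool) == 0:
        raise EmptyPoolError("background pool is empty")
    lo, hi = windowed_acceptance_band(foreground, config)
    if _pool_values is None:
        _pool_values = [
            gc_window_profile(c, config.window_size, config.step).values for c in pool
        ]
    accepted = [
        i for i, vals in enumerate(_pool_values) if all(lo <= v <= hi for v in vals)
    ]
    if not accepted:
        return MatchResult(foreground.identifier, None, accepted=False)
    i = accepted[rng.integers(len(accepted))]
    return MatchResult(foreground.identifier, pool[i], bin_distance=0)


def match_all(
    foregrounds: Sequence[SequenceRecord],
    pool: Sequence[SequenceRecord],
    config: MatchConfig,
    mode: Literal["global", "windowed"] = "global",
) -> list[MatchResult]:
    """One :class:`MatchResult` per foreground, in input order."""
    if mode not in ("global", "windowed"):
        raise ValueError(f"unknown match mode {mode!r}")
    if len(pool) == 0:
        raise EmptyPoolError("background pool is empty")
    rng = np.random.default_rng(config.seed)
    if mode == "global":
        index = build_gc_index(pool)
        return [match_gc_bin(fg, index, config, rng) for fg in foregrounds]
    remaining = list(pool)
    values = [
        gc_window_profile(c, config.window_size, config.step).values
        for c in remaining
    ]
    results: list[MatchResult] = []
    for fg in foregrounds:
        if not remaining:
            results.append(MatchResult(fg.identifier, None, accepted=False))
            continue
        res = match_windowed(fg, remaining, config, rng, _pool_values=values)
        if res.accepted and not config.with_replacement:
            i = remaining.index(res.background)
            del remaining[i]
            del values[i]
        results.append(res)
    return results


def generate_matched_set(
    foregrounds: Sequence[SequenceRecord],
    pool: Sequence[SequenceRecord],
    config: MatchConfig,
    mode: Literal["global", "windowed"] = "global",
) -> tuple[list[SequenceRecord], list[str]]:
    """Batch driver: one match attempt per foreground sequence.

    Returns the accepted background records (identifiers encode the pool
    record and matched foreground) and the list of unmatched foreground
    identifiers. Deterministic given ``config.seed``.
    """
    results = match_all(foregrounds, pool, config, mode)
    backgrounds: list[SequenceRecord] = []
    unmatched: list[str] = []
    for res in results:
        if not res.accepted:
            unmatched.append(res.foreground_id)
            continue
        bg = res.background
        backgrounds.append(
            SequenceRecord(
                bg.identifier,
                f"matched_to={res.foreground_id} bin_distance={res.bin_distance}",
                bg.residues,
            )
        )
    return backgrounds, unmatched


class GCBinMatcher(BaseEstimator):
    """Select pool sequences matching foreground %GC in 1% bins.

    Fit on the background pool (builds the GC-bin index), then transform a
    foreground set into matched backgrounds. After ``transform``,
    ``results_`` holds one :class:`MatchResult` per foreground and
    ``unmatched_ids_`` the foregrounds no bin within range could serve.
    """

    def __init__(
        self,
        with_replacement: bool = True,
        max_bin_distance: int = 100,
        random_state: Optional[int] = None,
    ):
        self.with_replacement = with_replacement
        self.max_bin_distance = max_bin_distance
        self.random_state = random_state

    def _config(self) -> MatchConfig:
        return MatchConfig(
            with_replacement=self.with_replacement,
            max_bin_distance=self.max_bin_distance,
            seed=self.random_state,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None) -> "GCBinMatcher":
        self.pool_ = list(X)
        build_gc_index(self.pool_)  # validates non-emptiness
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        if not hasattr(self, "pool_"):
            raise RuntimeError("GCBinMatcher must be fit on a background pool first")
        self.results_ = match_all(list(X), self.pool_, self._config(), mode="global")
        self.unmatched_ids_ = [r.foreground_id for r in self.results_ if not r.accepted]
        return [
            SequenceRecord(
                r.background.identifier,
                f"matched_to={r.foreground_id} bin_distance={r.bin_distance}",
                r.background.residues,
            )
            for r in self.results_
            if r.accepted
        ]


class WindowedGCMatcher(BaseEstimator):
    """Select pool sequences whose windowed %GC profile matches the foreground.

    Fit precomputes the pool's window %GC values; transform accepts, for each
    foreground, the candidates whose every window value lies within the
    foreground's mean +/- ``sd_multiplier`` * sd band and samples one.
    """

    def __init__(
        self,
        sd_multiplier: float = 2.6,
        window_size: int = 100,
        step: int = 50,
        with_replacement: bool = True,
        random_state: Optional[int] = None,
    ):
        self.sd_multiplier = sd_multiplier
        self.window_size = window_size
        self.step = step
        self.with_replacement = with_replacement
        self.random_state = random_state

    def _config(self) -> MatchConfig:
        return MatchConfig(
            sd_multiplier=self.sd_multiplier,
            window_size=self.window_size,
            step=self.step,
            with_replacement=self.with_replacement,
            seed=self.random_state,
        )

    def fit(self, X: Iterable[SequenceRecord], y=None) -> "WindowedGCMatcher":
        self.pool_ = list(X)
        if not self.pool_:
            raise EmptyPoolError("background pool is empty")
        return self

    def transform(self, X: Sequence[SequenceRecord]) -> list[SequenceRecord]:
        if not hasattr(self, "pool_"):
            raise RuntimeError("WindowedGCMatcher must be fit on a background pool first")
        self.results_ = match_all(list(X), self.pool_, self._config(), mode="windowed")
        self.unmatched_ids_ = [r.foreground_id for r in self.results_ if not r.accepted]
        return [
            SequenceRecord(
                r.background.identifier,
                f"matched_to={r.foreground_id}",
                r.background.residues,
            )
            for r in self.results_
            if r.accepted
        ]
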