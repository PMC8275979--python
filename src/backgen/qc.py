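"""Quality control: distribution comparisons between foreground and background.

Four comparisons are computed — %GC density over 1% bins, dinucleotide
content over the full IUPAC alphabet, dinucleotide content restricted to
A/C/G/T, and the length distribution — and each is scored with four
similarity metrics: mean absolute error between the two frequency vectors,
and three goodness-of-fit statistics (Pearson's chi-squared, the
log-likelihood-ratio G statistic, and the Cressie-Read power divergence at
lambda = 2/3). The goodness-of-fit statistics are computed on counts, with
the background counts rescaled to the foreground total; they are reported
as raw statistics, not tests, since degrees of freedom after pooling sparse
bins are ill-defined.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import power_divergence
from sklearn.metrics import mean_absolute_error as _sk_mae

from .composition import gc_bin
from .seqio import SequenceRecord

CRESSIE_READ_LAMBDA = 2.0 / 3.0
ACGT = frozenset("ACGT")

COMPARISONS = ("gc_density", "dinucleotide_iupac", "dinucleotide_acgt", "length")


class UndefinedStatisticError(ValueError):
    """Raised when expected = 0 but observed > 0 makes the statistics undefined."""


# ---------------------------------------------------------------------------
# binned count / frequency builders


def _normalize(counts: Mapping, labels: Sequence) -> dict:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no observations to normalize")
    return {lab: counts.get(lab, 0) / total for lab in labels}


def gc_bin_counts(records: Sequence[SequenceRecord]) -> Counter:
    """Number of records per integer 1%-GC bin (one bin per record)."""
    if len(records) == 0:
        raise ValueError("no records")
    return Counter(gc_bin(r) for r in records)


def bin_gc_density(records: Sequence[SequenceRecord]) -> dict[int, float]:
    """Relative frequency of records per 1%-GC bin, over labels 0..100."""
    return _normalize(gc_bin_counts(records), range(101))


def dinucleotide_counts(
    records: Sequence[SequenceRecord], alphabet_mode: Literal["iupac", "acgt"] = "iupac"
) -> Counter:
    """Pooled overlapping dinucleotide counts across records.

    Counting never crosses record boundaries. In ``acgt`` mode dinucleotides
    containing any ambiguity code are excluded.
    """
    if alphabet_mode not in ("iupac", "acgt"):
        raise ValueError(f"unknown alphabet_mode {alphabet_mode!r}")
    counts: Counter = Counter()
    for rec in records:
        s = rec.residues
        for i in range(len(s) - 1):
            d = s[i : i + 2]
            if alphabet_mode == "acgt" and (d[0] not in ACGT or d[1] not in ACGT):
                continue
            counts[d] += 1
    return counts


def dinucleotide_frequencies(
    records: Sequence[SequenceRecord], alphabet_mode: Literal["iupac", "acgt"] = "iupac"
) -> dict[str, float]:
    """Pooled dinucleotide relative frequencies over the observed label set."""
    if len(records) == 0:
        raise ValueError("no records")
    counts = dinucleotide_counts(records, alphabet_mode)
    if not counts:
        raise ValueError(
            f"no dinucleotides survive in {alphabet_mode!r} mode for these records"
        )
    return _normalize(counts, sorted(counts))


def length_counts(records: Sequence[SequenceRecord], bin_width: int = 10) -> Counter:
    """Number of records per half-open length bin [i*w, (i+1)*w), keyed by i*w."""
    if bin_width < 1:
        raise ValueError("bin_width must be positive")
    return Counter((len(r) // bin_width) * bin_width for r in records)


def length_distribution(
    records: Sequence[SequenceRecord], bin_width: int = 10
) -> dict[int, float]:
    """Relative frequency of records per length bin."""
    if len(records) == 0:
        raise ValueError("no records")
    counts = length_counts(records, bin_width)
    return _normalize(counts, sorted(counts))


# ---------------------------------------------------------------------------
# metrics


def mean_absolute_error(
    observed: Mapping, expected: Mapping
) -> float:
    """(1/n) sum |o_i - e_i| over the shared label set.

    The two mappings must carry identical label sets.
    """
    if set(observed) != set(expected):
        raise ValueError("observed and expected label sets differ")
    labels = sorted(observed)
    return float(
        _sk_mae([observed[l] for l in labels], [expected[l] for l in labels])
    )


def rescale_expected(
    observed: Sequence[float], expected: Sequence[float]
) -> np.ndarray:
    """Rescale expected so its total equals the observed total."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if expected.sum() == 0:
        raise ValueError("expected vector sums to zero")
    return expected * (observed.sum() / expected.sum())


def gof_statistics(
    observed: Sequence[float],
    expected: Sequence[float],
    lambda_: float = CRESSIE_READ_LAMBDA,
) -> dict[str, float]:
    """Pearson chi2, G statistic and Cressie-Read divergence of O against E.

    E is first rescaled to the O total (the divergences require matched
    totals). Cells where both O and E are 0 are dropped; a cell with E = 0
    but O > 0 raises :class:`UndefinedStatisticError`.
    """
    obs = np.asarray(observed, dtype=float)
    exp = rescale_expected(obs, expected)
    keep = ~((obs == 0) & (exp == 0))
    obs, exp = obs[keep], exp[keep]
    bad = (exp == 0) & (obs > 0)
    if bad.any():
        raise UndefinedStatisticError(
            f"{int(bad.sum())} cell(s) have expected = 0 but observed > 0"
        )
    return {
        "pearson_chi2": float(power_divergence(obs, exp, lambda_=1.0).statistic),
        "g_statistic": float(power_divergence(obs, exp, lambda_=0.0).statistic),
        "cressie_read": float(power_divergence(obs, exp, lambda_=lambda_).statistic),
        "lambda": lambda_,
    }


def pool_sparse_cells(
    observed: Sequence[float], expected: Sequence[float], threshold: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge all cells with expected count < threshold into one pooled cell.

    Used before the goodness-of-fit statistics when sparse or empty
    background bins would otherwise leave them undefined.
    """
    obs = np.asarray(observed, dtype=float)
    exp = rescale_expected(obs, expected)
    sparse = exp < threshold
    if sparse.sum() <= 1:
        return obs, exp
    keep_o, keep_e = obs[~sparse], exp[~sparse]
    return (
        np.append(keep_o, obs[sparse].sum()),
        np.append(keep_e, exp[sparse].sum()),
    )


# ---------------------------------------------------------------------------
# report


@dataclass(frozen=True)
class ComparisonMetrics:
    """The four similarity metrics for one foreground/background comparison."""

    mae: float
    pearson_chi2: float
    g_statistic: float
    cressie_read: float
    lambda_: float = CRESSIE_READ_LAMBDA
    undefined_labels: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "mae": self.mae,
            "pearson_chi2": self.pearson_chi2,
            "g_statistic": self.g_statistic,
            "cressie_read": self.cressie_read,
            "lambda": self.lambda_,
        }
        if self.undefined_labels:
            d["undefined_labels"] = list(self.undefined_labels)
        return d


@dataclass
class QCReport:
    """Metrics plus the tabular data behind each of the four QC plots."""

    metrics: dict[str, ComparisonMetrics]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {name: m.to_dict() for name, m in self.metrics.items()}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        for name, table in self.tables.items():
            table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)


def _compare(
    fg_counts: Counter,
    bg_counts: Counter,
    lambda_: float,
    pool_sparse: bool,
) -> tuple[ComparisonMetrics, pd.DataFrame]:
    labels = sorted(set(fg_counts) | set(bg_counts))
    obs = np.array([fg_counts.get(l, 0) for l in labels], dtype=float)
    exp_raw = np.array([bg_counts.get(l, 0) for l in labels], dtype=float)
    fg_freq = obs / obs.sum()
    bg_freq = exp_raw / exp_raw.sum()
    mae = float(_sk_mae(fg_freq, bg_freq))
    exp = rescale_expected(obs, exp_raw)
    undefined = tuple(
        l for l, o, e in zip(labels, obs, exp) if e == 0 and o > 0
    )
    o_use, e_use = (obs, exp)
    if pool_sparse:
        o_use, e_use = pool_sparse_cells(obs, exp)
        undefined = ()
    if undefined:
        stats = {
            "pearson_chi2": math.nan,
            "g_statistic": math.nan,
            "cressie_read": math.nan,
            "lambda": lambda_,
        }
    else:
        stats = gof_statistics(o_use, e_use, lambda_)
    table = pd.DataFrame(
        {
            "label": labels,
            "foreground_count": obs,
            "background_count": exp_raw,
            "foreground_freq": fg_freq,
            "background_freq": bg_freq,
        }
    )
    return (
        ComparisonMetrics(
            mae=mae,
            pearson_chi2=stats["pearson_chi2"],
            g_statistic=stats["g_statistic"],
            cressie_read=stats["cressie_read"],
            lambda_=lambda_,
            undefined_labels=undefined,
        ),
        table,
    )


def build_qc_report(
    foregrounds: Sequence[SequenceRecord],
    backgrounds: Sequence[SequenceRecord],
    lambda_: float = CRESSIE_READ_LAMBDA,
    length_bin_width: int = 10,
    pool_sparse: bool = False,
) -> QCReport:
    """Run all four comparisons and apply all four metrics to each.

    With ``pool_sparse`` the cells whose rescaled background count is below
    5 are merged before the goodness-of-fit statistics; otherwise cells with
    zero background but nonzero foreground leave those statistics undefined
    (NaN) and are flagged in ``undefined_labels``.
    """
    if len(foregrounds) == 0 or len(backgrounds) == 0:
        raise ValueError("both foreground and background sets must be non-empty")
    pairs = {
        "gc_density": (gc_bin_counts(foregrounds), gc_bin_counts(backgrounds)),
        "dinucleotide_iupac": (
            dinucleotide_counts(foregrounds, "iupac"),
            dinucleotide_counts(backgrounds, "iupac"),
        ),
        "dinucleotide_acgt": (
            dinucleotide_counts(foregrounds, "acgt"),
            dinucleotide_counts(backgrounds, "acgt"),
        ),
        "length": (
            length_counts(foregrounds, length_bin_width),
            length_counts(backgrounds, length_bin_width),
        ),
    }
    metrics: dict[str, ComparisonMetrics] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name, (fg_c, bg_c) in pairs.items():
        metrics[name], tables[name] = _compare(fg_c, bg_c, lambda_, pool_sparse)
    return QCReport(metrics=metrics, tables=tables)
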