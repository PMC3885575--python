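"""Identity-stratified evaluation and model comparison.

Each test query is assigned its maximal test-to-training sequence identity
(MTTSI): the highest global-alignment percent identity to any of the
predictor's positive training sequences.  Results are binned into eight
MTTSI ranges ([0,30), then decades to [90,100]); precision and recall are
computed per enzyme per bin and macro-averaged over the enzymes for which
they are defined.  Models are compared by paired t-test on per-enzyme
metrics and by the Wilcoxon rank-sum test on grouped values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io import SequenceRecord
from .scoring import global_identity

__all__ = [
    "MTTSI_BINS",
    "PredictionResult",
    "BinMetrics",
    "compute_mttsi",
    "bin_of",
    "bin_results",
    "macro_average",
    "paired_t_test",
    "rank_sum_test",
]

# Left-closed bins; the last includes 100.
MTTSI_BINS: list[tuple[float, float]] = [
    (0, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, 90), (90, 100),
]


def bin_label(bounds: tuple[float, float]) -> str:
    lo, hi = bounds
    return f"[{lo:g},{hi:g}{']' if hi == 100 else ')'}"


def compute_mttsi(
    query: SequenceRecord | str,
    training_positives: Sequence[SequenceRecord | str],
) -> float:
    """Max global-alignment identity (%) of the query to any training positive."""
    if not training_positives:
        raise ValueError("empty training reference set")
    return max(global_identity(query, t, denominator="alignment") for t in training_positives)


def bin_of(mttsi: float) -> int:
    """Index of the MTTSI bin containing the value (left-closed convention)."""
    if not 0 <= mttsi <= 100:
        raise ValueError(f"MTTSI {mttsi} outside [0, 100]")
    for i, (lo, hi) in enumerate(MTTSI_BINS):
        if lo <= mttsi < hi or (hi == 100 and mttsi == 100):
            return i
    raise AssertionError("unreachable")


@dataclass
class PredictionResult:
    """One (query, enzyme predictor) outcome with its MTTSI."""

    query_id: str
    target_ec: str
    true_label: int
    predicted_label: int
    vote_fraction: float
    mttsi: float

    def __post_init__(self) -> None:
        if not 0 <= self.mttsi <= 100:
            raise ValueError(f"MTTSI {self.mttsi} outside [0, 100]")


@dataclass
class BinMetrics:
    """Confusion counts and metrics of one predictor in one MTTSI bin."""

    label: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def precision_defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def recall_defined(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if self.precision_defined else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if self.recall_defined else None

    @property
    def f_measure(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        return 2 * p * r / (p + r)


def bin_results(results: Sequence[PredictionResult]) -> list[BinMetrics]:
    """Partition one predictor's results into the eight MTTSI bins."""
    bins = [BinMetrics(label=bin_label(b)) for b in MTTSI_BINS]
    for r in results:
        m = bins[bin_of(r.mttsi)]
        if r.true_label and r.predicted_label:
            m.tp += 1
        elif not r.true_label and r.predicted_label:
            m.fp += 1
        elif r.true_label and not r.predicted_label:
            m.fn += 1
        else:
            m.tn += 1
    return bins


@dataclass
class MacroBin:
    """Unweighted per-bin mean over enzymes with a defined metric."""

    label: str
    mean: Optional[float]
    ci_halfwidth: Optional[float]
    n_enzymes: int


def macro_average(
    per_enzyme_bins: Sequence[Sequence[BinMetrics]],
    metric: str = "precision",
) -> list[MacroBin]:
    """Average a metric over enzymes per bin, with normal-approximation 95% CI.

    Enzymes for which the metric is undefined in a bin are excluded from that
    bin's average; a bin with no defined enzyme is reported with mean None.
    A single-enzyme bin gets CI half-width 0 by convention.
    """
    out: list[MacroBin] = []
    for b in range(len(MTTSI_BINS)):
        values = []
        for enzyme_bins in per_enzyme_bins:
            v = getattr(enzyme_bins[b], metric)
            if v is not None:
                values.append(v)
        if not values:
            out.append(MacroBin(label=bin_label(MTTSI_BINS[b]), mean=None, ci_halfwidth=None, n_enzymes=0))
            continue
        arr = np.asarray(values)
        mean = float(arr.mean())
        if arr.size > 1:
            half = 1.96 * float(arr.std(ddof=1)) / math.sqrt(arr.size)
        else:
            half = 0.0
        out.append(MacroBin(label=bin_label(MTTSI_BINS[b]), mean=mean, ci_halfwidth=half, n_enzymes=arr.size))
    return out


def paired_t_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on per-enzyme metric values.

    Zero-variance differences degenerate: p = 1 when all differences are 0,
    p = 0 (t infinite) when they are a constant non-zero shift.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples of size >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def rank_sum_test(group_1: Sequence[float], group_2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test with tie correction."""
    if len(group_1) == 0 or len(group_2) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(group_1, group_2, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
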