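"""Superfamily-level analyses of functional diversity and rf-SDR composition.

A superfamily's functional entropy S_func is the Shannon entropy (natural
log) of its predictor counts over distinct third-digit EC prefixes; the
thresholds 0.5 and 1.5 nats split superfamilies into least / moderately /
highly diverged classes (matching one, two-to-four and more-than-four
distinct EC3 prefixes at equal frequencies).  A parallel fourth-digit
classification uses raw distinct-EC4 counts (1–5 / 6–10 / >10).  Amino-acid
propensity compares rf-SDR residue composition with the representative
domains' background, and per-category selection fractions measure how many
of an enzyme's ASRs or LBRs the forest picked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotation import SiteSets
from .io import AA20, SequenceRecord
from .models import RfSdrSet

__all__ = [
    "DiversitySummary",
    "PropensityTable",
    "functional_entropy",
    "classify_diversity",
    "aa_propensity",
    "site_fraction_selected",
    "box_stats",
]

S_FUNC_LOW = 0.5
S_FUNC_HIGH = 1.5
EC4_LOW = 5
EC4_HIGH = 10


def functional_entropy(roster_ecs: Sequence[str]) -> float:
    """S_func = −Σ (n_abc/N)·ln(n_abc/N) over third-digit EC prefixes."""
    if not roster_ecs:
        raise ValueError("empty roster")
    counts: dict[str, int] = {}
    for ec in roster_ecs:
        prefix = ".".join(ec.split(".")[:3])
        counts[prefix] = counts.get(prefix, 0) + 1
    N = len(roster_ecs)
    return -sum((c / N) * math.log(c / N) for c in counts.values()) + 0.0


@dataclass
class DiversitySummary:
    """Functional-diversity census of one superfamily's predictor roster."""

    superfamily: str
    n_predictors: int
    ec3_counts: dict[str, int]
    s_func: float
    class_3: str = ""
    ec4_count: int = 0
    class_4: str = ""


def classify_diversity(summary: DiversitySummary) -> tuple[str, str]:
    """Label diversity classes from S_func thresholds and EC4 counts."""
    if summary.s_func < S_FUNC_LOW:
        summary.class_3 = "low"
    elif summary.s_func < S_FUNC_HIGH:
        summary.class_3 = "medium"
    else:
        summary.class_3 = "high"
    if summary.ec4_count <= EC4_LOW:
        summary.class_4 = "low"
    elif summary.ec4_count <= EC4_HIGH:
        summary.class_4 = "medium"
    else:
        summary.class_4 = "high"
    return summary.class_3, summary.class_4


def summarize_diversity(superfamily: str, roster_ecs: Sequence[str]) -> DiversitySummary:
    counts: dict[str, int] = {}
    for ec in roster_ecs:
        prefix = ".".join(ec.split(".")[:3])
        counts[prefix] = counts.get(prefix, 0) + 1
    summary = DiversitySummary(
        superfamily=superfamily,
        n_predictors=len(roster_ecs),
        ec3_counts=counts,
        s_func=functional_entropy(roster_ecs),
        ec4_count=len(set(roster_ecs)),
    )
    classify_diversity(summary)
    return summary


@dataclass
class PropensityTable:
    """Per-residue rf-SDR propensity: SDR fraction ÷ background fraction."""

    sdr_fraction: dict[str, float]
    background_fraction: dict[str, float]
    propensity: dict[str, Optional[float]]  # None where background is absent


def aa_propensity(
    rf_sdr_sets: Mapping[str, RfSdrSet],
    representatives: Mapping[str, SequenceRecord],
) -> PropensityTable:
    """Amino-acid propensity of rf-SDR residues, pooled over enzymes.

    The numerator counts each enzyme's representative residues at its rf-SDR
    positions; the denominator counts all residues of all representative
    domains.  A residue missing from the background has undefined propensity.
    """
    sdr_counts = {aa: 0 for aa in AA20}
    bg_counts = {aa: 0 for aa in AA20}
    n_sdr = 0
    for ec, sdrs in rf_sdr_sets.items():
        rep = representatives[ec]
        for pos in sdrs.positions:
            aa = rep.sequence[pos]
            if aa in sdr_counts:
                sdr_counts[aa] += 1
                n_sdr += 1
    for rep in representatives.values():
        for aa in rep.sequence:
            if aa in bg_counts:
                bg_counts[aa] += 1
    if n_sdr == 0:
        raise ValueError("no rf-SDR residues pooled; propensity undefined")
    n_bg = sum(bg_counts.values())
    sdr_frac = {aa: sdr_counts[aa] / n_sdr for aa in AA20}
    bg_frac = {aa: bg_counts[aa] / n_bg for aa in AA20}
    propensity: dict[str, Optional[float]] = {}
    for aa in AA20:
        propensity[aa] = sdr_frac[aa] / bg_frac[aa] if bg_frac[aa] > 0 else None
    return PropensityTable(sdr_fraction=sdr_frac, background_fraction=bg_frac, propensity=propensity)


def site_fraction_selected(
    rf_sdrs: RfSdrSet,
    sites: SiteSets,
    category: str,
) -> float:
    """Fraction of an enzyme's ASRs (or LBRs) selected as rf-SDRs.

    Raises on an empty category set; callers skip such enzymes (they carry
    no information about that category).
    """
    if category not in {"asr", "lbr"}:
        raise ValueError(f"category must be asr or lbr, got {category!r}")
    cat_set = getattr(sites, category)
    if not cat_set:
        raise ValueError(f"enzyme has no annotated {category.upper()} positions")
    return len(rf_sdrs.positions & cat_set) / len(cat_set)


def superfamily_fraction(
    per_enzyme: Mapping[str, tuple[RfSdrSet, SiteSets]],
    category: str,
) -> Optional[float]:
    """Mean selected fraction over the superfamily's enzymes with that category."""
    values = []
    for ec, (sdrs, sites) in per_enzyme.items():
        if getattr(sites, category):
            values.append(site_fraction_selected(sdrs, sites, category))
    return float(np.mean(values)) if values else None


@dataclass
class BoxStats:
    """Distribution summary matching a 10/25/50/75/90-percentile box plot."""

    n: int
    p10: float
    p25: float
    median: float
    p75: float
    p90: float


def box_stats(values: Sequence[float]) -> BoxStats:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to summarize")
    p10, p25, p50, p75, p90 = np.percentile(arr, [10, 25, 50, 75, 90])
    return BoxStats(n=arr.size, p10=float(p10), p25=float(p25), median=float(p50), p75=float(p75), p90=float(p90))
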