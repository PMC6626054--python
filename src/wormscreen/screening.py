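"""Screening decisions: assay quality, compound scoring and hit calling.

A screen compares each compound-treated group of disease-model worms to
the untreated (vehicle) disease-model control on the same plate. The
readout per compound is the ratio of duration-weighted mean speeds
(treated / untreated); a compound is a *hit* when its ratio is at least
that of the positive-control compound (rapamycin in the reference
screen), compared at the table's printed precision (2 decimals) so "as
effective as" includes printed ties.

Assay quality between the healthy and disease reference groups uses the
Z'-factor screening-window statistic

    Z' = 1 - 3 (SD_healthy + SD_disease) / |Ave_healthy - Ave_disease|

with the duration-weighted mean and SD of each group. Z' <= 1 always;
Z' > 0.5 is conventionally an excellent assay window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import GroupSummary, SpeedRecord

__all__ = [
    "ZPrimeResult",
    "ScreenResult",
    "DoseResponseTable",
    "zprime",
    "ratio_to_control",
    "call_hits",
    "dose_response",
    "compare_groups",
    "hill_multiplier",
]


@dataclass(frozen=True)
class ZPrimeResult:
    zprime: float
    healthy_label: str
    disease_label: str
    #: (Ave_healthy, Ave_disease, SD_healthy, SD_disease) as used
    components: tuple[float, float, float, float]


@dataclass(frozen=True)
class ScreenResult:
    """One row of a screen table: compound, ratio to untreated control,
    1-based rank (descending by ratio) and the hit flag."""

    compound: str
    ratio: float
    rank: int
    is_hit: bool


@dataclass(frozen=True)
class DoseResponseTable:
    compound: str
    doses_um: tuple[float, ...]
    summaries: tuple[GroupSummary, ...]
    monotone_increasing: bool
    monotone_decreasing: bool


def zprime(healthy: GroupSummary, disease: GroupSummary) -> ZPrimeResult:
    """Z'-factor separation between the two reference groups.

    The denominator takes the absolute mean difference so the group order
    is irrelevant. Equal means leave the separation undefined and raise.
    """
    sep = abs(healthy.mean_mm_s - disease.mean_mm_s)
    if sep == 0:
        raise ValueError("Z'-factor undefined: group means are equal")
    z = 1.0 - 3.0 * (healthy.sd_mm_s + disease.sd_mm_s) / sep
    return ZPrimeResult(
        zprime=float(z),
        healthy_label=healthy.label,
        disease_label=disease.label,
        components=(healthy.mean_mm_s, disease.mean_mm_s, healthy.sd_mm_s, disease.sd_mm_s),
    )


def ratio_to_control(treated: GroupSummary, control: GroupSummary) -> float:
    """Treated / untreated ratio of duration-weighted mean speeds."""
    if control.mean_mm_s <= 0:
        raise ValueError("control group mean must be positive")
    return treated.mean_mm_s / control.mean_mm_s


def call_hits(
    screen: list[tuple[str, float]],
    positive_control_ratio: float,
    round_digits: int = 2,
) -> list[ScreenResult]:
    """Rank compounds by ratio and flag hits.

    A hit is a compound whose ratio, rounded to ``round_digits``, is at
    least the equally rounded positive-control ratio ("as effective as or
    more effective than" the positive control). The controls themselves
    are not part of ``screen``. Output is sorted descending by ratio,
    ties in input order; ranks are 1-based.
    """
    if not screen:
        raise ValueError("empty screen")
    if positive_control_ratio <= 0:
        raise ValueError("positive_control_ratio must be positive")
    threshold = round(positive_control_ratio, round_digits)
    order = sorted(
        range(len(screen)), key=lambda i: (-round(screen[i][1], 10), i)
    )
    results = []
    for rank, i in enumerate(order, start=1):
        name, ratio = screen[i]
        if ratio < 0:
            raise ValueError(f"negative ratio for {name!r}")
        results.append(
            ScreenResult(
                compound=name,
                ratio=float(ratio),
                rank=rank,
                is_hit=bool(round(ratio, round_digits) >= threshold),
            )
        )
    return results


def dose_response(
    summaries: list[GroupSummary], doses_um: list[float], compound: str = ""
) -> DoseResponseTable:
    """Tabulate mean +/- SEM across a dose series and flag monotone trends.

    ``monotone_increasing`` is True iff the duration-weighted means are
    non-decreasing in dose (the signature of an effective rescue);
    ``monotone_decreasing`` covers paralytic controls. A flat series
    satisfies both.
    """
    if len(summaries) != len(doses_um):
        raise ValueError("one summary per dose required")
    if len(doses_um) < 2:
        raise ValueError("need at least 2 doses")
    d = np.asarray(doses_um, dtype=float)
    if np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing")
    means = np.array([s.mean_mm_s for s in summaries])
    diffs = np.diff(means)
    return DoseResponseTable(
        compound=compound,
        doses_um=tuple(float(x) for x in d),
        summaries=tuple(summaries),
        monotone_increasing=bool(np.all(diffs >= 0)),
        monotone_decreasing=bool(np.all(diffs <= 0)),
    )


def compare_groups(
    a: list[SpeedRecord], b: list[SpeedRecord], welch: bool = False
) -> tuple[float, float]:
    """Two-sample t test on per-animal speeds; returns (statistic, p).

    Student's pooled-variance test by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 animals")
    va = np.array([r.speed_mm_s for r in a])
    vb = np.array([r.speed_mm_s for r in b])
    if va.std() == 0 and vb.std() == 0 and va.mean() == vb.mean():
        return 0.0, 1.0  # identical degenerate samples
    res = sps.ttest_ind(va, vb, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def hill_multiplier(
    dose_um: float, emax: float, ec50_um: float, hill_n: float = 1.0
) -> float:
    """Hill-type dose-effect model for the simulator's speed multiplier.

    Returns ``1 + (emax - 1) * d^n / (d^n + ec50^n)``: no effect at dose
    0, saturating at ``emax`` (rescue for emax > 1, paralysis for
    emax < 1, e.g. a levamisole-like series).
    """
    if dose_um < 0 or ec50_um <= 0 or hill_n <= 0:
        raise ValueError("dose must be >= 0; ec50 and hill_n positive")
    if dose_um == 0:
        return 1.0
    dn = dose_um**hill_n
    return 1.0 + (emax - 1.0) * dn / (dn + ec50_um**hill_n)
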