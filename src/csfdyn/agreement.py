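"""Method-comparison statistics for paired CSF parameter sets.

Compares per-subject cycle parameters measured by two acquisitions (e.g.
gated CINE against real-time phase contrast): a cardiac-rate mismatch
filter (two acquisitions of the same subject minutes apart are only
comparable when the heart rate was stable), percentage Bland-Altman
agreement, and a normality-gated correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .cycles import CycleParameters


@dataclass(frozen=True)
class PairedParameters:
    """Per-subject cycle parameters from two methods."""

    subject: str
    a: CycleParameters
    b: CycleParameters


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff_percent: float
    loa_low_percent: float
    loa_high_percent: float
    n: int


def bpm_mismatch_filter(
    pairs: Sequence[PairedParameters],
    threshold_percent: float = 10.0,
) -> tuple[list[PairedParameters], list[PairedParameters]]:
    """Exclude subjects whose heart rate differed between acquisitions.

    BPM = 60/Tc per method; a subject is excluded when |BPM_a - BPM_b|
    relative to the pair mean exceeds the threshold (default 10%). The
    criterion is symmetric in the two methods.
    """
    kept, excluded = [], []
    for pair in pairs:
        if pair.a.tc <= 0 or pair.b.tc <= 0:
            raise ValueError(f"subject {pair.subject}: non-positive Tc")
        bpm_a, bpm_b = 60.0 / pair.a.tc, 60.0 / pair.b.tc
        rel = abs(bpm_a - bpm_b) / ((bpm_a + bpm_b) / 2.0) * 100.0
        (excluded if rel > threshold_percent else kept).append(pair)
    return kept, excluded


def bland_altman_percent(a, b) -> BlandAltmanResult:
    """Percentage Bland-Altman agreement between paired measurements.

    Per pair, d = 100*(a-b)/mean(a,b); the bias is mean(d) and the limits
    of agreement are mean(d) +/- 1.96*SD(d). Pairs with zero mean are
    dropped with a warning (the percentage difference is undefined there).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be paired 1-D arrays")
    mean = (a + b) / 2.0
    ok = mean != 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} pair(s) with zero mean",
                      stacklevel=2)
    a, b, mean = a[ok], b[ok], mean[ok]
    if a.size < 2:
        raise ValueError("need at least 2 usable pairs")
    d = 100.0 * (a - b) / mean
    sd = float(d.std(ddof=1))
    m = float(d.mean())
    return BlandAltmanResult(m, m - 1.96 * sd, m + 1.96 * sd, int(a.size))


def paired_correlation(a, b, alpha: float = 0.05) -> tuple[float, float, str]:
    """Correlation between paired measurements, normality-gated.

    Shapiro-Wilk on both samples selects Pearson (both normal at
    ``alpha``) or Spearman otherwise. Returns (r, two-sided p, method).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant input")
    normal = (stats.shapiro(a).pvalue > alpha) and (stats.shapiro(b).pvalue > alpha)
    if normal:
        res = stats.pearsonr(a, b)
        return float(res.statistic), float(res.pvalue), "pearson"
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue), "spearman"
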