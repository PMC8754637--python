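"""Closed-form qPCR quantifications.

Relative expression by the 2^-dCT method, ChIP enrichment as percent of
input (with dilution-adjusted input Ct), ratios of enrichment signals with
first-order error propagation, transcription-shutoff decay profiles with a
log-linear half-life fit, and the one-tailed two-sample Student t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CtMeasurement",
    "relative_expression_dct",
    "percent_input",
    "signal_ratio",
    "decay_profile",
    "one_tailed_t_test",
]


@dataclass(frozen=True)
class CtMeasurement:
    sample_id: str
    target: str
    ct: float
    role: str  # target | reference | ip | input
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be finite and positive, got {self.ct}")
        if self.role not in ("target", "reference", "ip", "input"):
            raise ValueError(f"invalid role {self.role!r}")


def relative_expression_dct(ct_target: float, ct_reference: float) -> float:
    """Relative expression 2^-(ct_target - ct_reference)."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(ct_target - ct_reference)


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP enrichment as percent of input.

    The input Ct is first adjusted for the fraction of chromatin it
    represents: ``ct_input - log2(1 / input_fraction)``; the result is
    ``100 * 2^(adjusted - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    adjusted = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted - ct_ip)


def signal_ratio(
    numerator: np.ndarray, denominator: np.ndarray
) -> tuple[float, float]:
    """Ratio of means of two paired enrichment measurements, with SEM.

    The SEM is propagated to first order:
    ``ratio * sqrt(cv_num**2 + cv_den**2)`` with cv = SEM / mean.
    """
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    mean_n, mean_d = num.mean(), den.mean()
    if mean_d == 0:
        raise ValueError("zero denominator mean")
    sem_n = num.std(ddof=1) / math.sqrt(len(num)) if len(num) > 1 else 0.0
    sem_d = den.std(ddof=1) / math.sqrt(len(den)) if len(den) > 1 else 0.0
    ratio = mean_n / mean_d
    sem = abs(ratio) * math.sqrt((sem_n / mean_n) ** 2 + (sem_d / mean_d) ** 2)
    return float(ratio), float(sem)


def decay_profile(
    values: np.ndarray,
    timepoints: np.ndarray,
    t0_index: int = 0,
    fit_half_life: bool = True,
) -> tuple[np.ndarray, float]:
    """Relative-remaining RNA series after transcription shutoff.

    Each value is divided by the value at *t0_index*.  The half-life is the
    least-squares fit of ``ln(relative)`` against time over positive values,
    ``t_half = ln 2 / |slope|``; a non-decaying series yields ``inf``.
    """
    values = np.asarray(values, dtype=float)
    timepoints = np.asarray(timepoints, dtype=float)
    v0 = values[t0_index]
    if v0 <= 0:
        raise ValueError("value at t0 must be positive")
    relative = values / v0
    half_life = math.nan
    if fit_half_life:
        ok = relative > 0
        if ok.sum() >= 2:
            slope, _ = np.polyfit(timepoints[ok], np.log(relative[ok]), 1)
            half_life = math.inf if slope == 0 else math.log(2) / abs(slope)
        else:
            half_life = math.inf
    return relative, float(half_life)


def one_tailed_t_test(
    group_a: np.ndarray, group_b: np.ndarray, direction: str = "greater"
) -> tuple[float, float]:
    """Two-sample pooled-variance Student t-test, one-tailed.

    ``direction="greater"`` tests mean(A) > mean(B), ``"less"`` the reverse.
    Degenerate zero-variance groups follow the conventions: equal means give
    p = 0.5; unequal means give p -> 0 or 1 by direction.
    """
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 0.5
        sign = a.mean() > b.mean()
        p = 0.0 if (sign == (direction == "greater")) else 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), p
    res = stats.ttest_ind(a, b, equal_var=True, alternative=direction)
    return float(res.statistic), float(res.pvalue)
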