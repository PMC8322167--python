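"""System-characterization metrics and the paired-design power analysis.

SNR is defined as 20·log10(mean/std) of a constant-load impedance series;
calibration accuracy is the held-out mean relative agreement of a linear
fit across known resistor loads; temporal stability is the coefficient of
variation over a ~3 min window. The sample-size calculation inverts the
paired t-test power function (noncentral-t, not the normal approximation —
the t correction matters at the n this study operates at).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("bim")


def snr_db(series) -> float:
    """20·log10(|mean|/std) with sample (n−1) std; +inf for zero std."""
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValidationError("SNR needs ≥ 2 values")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValidationError("SNR undefined for zero-mean series")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        logger.warning("zero std: SNR is infinite")
        return float("inf")
    return 20.0 * float(np.log10(abs(mean) / sd))


def coefficient_of_variation(series, timestamps=None,
                             window_s: float = 180.0) -> float:
    """Temporal stability: 100·std/mean (%) over a time window.

    With ``timestamps`` given, only samples inside the first ``window_s``
    of the series are used (the ~3 min stability window); otherwise the
    whole series is taken as the window.
    """
    x = np.asarray(series, dtype=float)
    if timestamps is not None:
        t = np.asarray(timestamps, dtype=float)
        x = x[(t >= t[0]) & (t < t[0] + window_s)]
    if len(x) < 2:
        raise ValidationError("CV needs ≥ 2 values in the window")
    mean = float(np.mean(x))
    if mean == 0.0:
        raise ValidationError("CV undefined for zero-mean window")
    return 100.0 * float(np.std(x, ddof=1)) / abs(mean)


@dataclass
class CalibrationFit:
    """Linear map from measured to true ohms, with held-out accuracy."""

    slope: float
    intercept: float
    residuals: np.ndarray
    accuracy_percent: float = float("nan")

    def predict(self, measured):
        return self.slope * np.asarray(measured, dtype=float) + self.intercept


def calibrate_linear(measured, truth, holdout_measured=None,
                     holdout_truth=None) -> CalibrationFit:
    """Least-squares linear calibration across known resistor loads.

    ``accuracy = 100·(1 − mean(|predicted − true| / true))`` over the
    held-out loads (mean relative error, not worst case).
    """
    m = np.asarray(measured, dtype=float)
    t = np.asarray(truth, dtype=float)
    if len(m) < 2 or len(m) != len(t):
        raise ValidationError("need ≥ 2 paired calibration points")
    if np.ptp(m) == 0:
        raise ValidationError("identical calibration loads: fit undefined")
    slope, intercept = np.polyfit(m, t, 1)
    fit = CalibrationFit(float(slope), float(intercept),
                         t - (slope * m + intercept))
    if holdout_measured is not None:
        pred = fit.predict(holdout_measured)
        true = np.asarray(holdout_truth, dtype=float)
        rel = np.abs(pred - true) / true
        fit.accuracy_percent = 100.0 * (1.0 - float(np.mean(rel)))
    return fit


def paired_power(n: int, effect_size: float, alpha: float = 0.05,
                 tails: int = 2) -> float:
    """Power of a paired t-test at ``n`` pairs and effect size d."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = abs(effect_size) * np.sqrt(n)
    if tails == 2:
        tc = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(1.0 - stats.nct.cdf(tc, df, nc)
                     + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.ppf(1.0 - alpha, df)
    return float(1.0 - stats.nct.cdf(tc, df, nc))


def paired_sample_size(mean_diff: float, sd_diff: float, alpha: float = 0.05,
                       power: float = 0.95, tails: int = 2,
                       max_n: int = 1_000_000) -> int:
    """Smallest n pairs giving a paired t-test at least the target power.

    Iterates the noncentral-t power expression upward from n = 2 (the
    df ≥ 1 floor). Raises if the target is unattainable below ``max_n``.
    """
    if mean_diff == 0:
        raise ValidationError("mean_diff must be nonzero")
    if sd_diff <= 0:
        raise ValidationError("sd_diff must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    if not 0 < power < 1:
        raise ValidationError("power must be in (0, 1)")
    if tails not in (1, 2):
        raise ValidationError("tails must be 1 or 2")
    d = abs(mean_diff) / sd_diff
    for n in range(2, max_n + 1):
        if paired_power(n, d, alpha, tails) >= power:
            return n
    raise ValidationError(
        f"power {power} unattainable at d={d} within n ≤ {max_n}")
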