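"""Channel-variance statistics separating focal from global events.

A focal event perturbs the sectors nearest the lesion far more than the
opposite ones, so the across-channel variance of ΔZ is large; a global
event moves every sector together and the variance collapses to the noise
floor. Three complementary tests quantify this: Levene's test on the
pooled per-channel ΔZ values (robust to non-normality at small n), Welch's
unequal-variance t-test on the per-subject single-value variances, and an
analysis of means (ANOM) of the per-event standard deviations against the
grand mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("bim")

ANOM_ALPHA = 0.05


@dataclass
class AnomResult:
    grand_mean: float
    group_means: dict           # event -> mean std
    decision_limits: dict       # event -> (lower, upper)
    flagged_events: list = field(default_factory=list)
    alpha: float = ANOM_ALPHA


@dataclass
class VarianceSummary:
    """Cohort-level focal/global variance comparison."""

    per_subject_event_variance: dict   # (subject, event) -> ohms^2
    levene: tuple = None               # (W, p)
    welch: tuple = None                # (t, df, p)
    anom: AnomResult = None


def channel_variance(delta_z) -> float:
    """Unbiased (n−1) sample variance of a channel ΔZ vector, ohms²."""
    dz = np.asarray(delta_z, dtype=float)
    dz = dz[np.isfinite(dz)]
    if len(dz) < 2:
        return float("nan")
    return float(np.var(dz, ddof=1))


def levene_test(groups, center: str = "mean"):
    """Classical Levene W with F-distribution p-value.

    ``center='mean'`` is the classical mean-centered statistic;
    ``'median'`` gives the Brown–Forsythe variant. Degenerate zero-spread
    groups everywhere yield (nan, nan).
    """
    if center not in ("mean", "median"):
        raise ValidationError("center must be 'mean' or 'median'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need ≥ 2 groups with ≥ 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        logger.warning("Levene undefined: zero spread in every group")
        return float("nan"), float("nan")
    devs = [np.abs(g - (np.mean(g) if center == "mean" else np.median(g)))
            for g in groups]
    if all(np.ptp(d) == 0 for d in devs):
        # no within-group spread of deviations: W is 0 or infinite
        if np.ptp([np.mean(d) for d in devs]) == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    w, p = stats.levene(*groups, center=center)
    return float(w), float(p)


def welch_t(group_a, group_b):
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need ≥ 2 values per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa ** 2 / (len(a) - 1) + sb ** 2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def anom_std(event_stds: dict, alpha: float = ANOM_ALPHA) -> AnomResult:
    """Analysis of means of per-event standard deviations.

    ``event_stds`` maps event name -> collection of per-subject stds.
    Each event's mean std is compared to the grand mean against decision
    limits ``grand ± h·s_pooled·sqrt((k−1)/(k·n))`` with ``h`` a
    Bonferroni-adjusted two-sided t quantile at ``df = Σ(n_i − 1)``.
    Unbalanced groups use their own n in the limits, with a warning.
    """
    events = list(event_stds)
    if len(events) < 2:
        raise ValidationError("ANOM needs ≥ 2 event classes")
    groups = {e: np.asarray(event_stds[e], dtype=float) for e in events}
    ns = {e: len(g) for e, g in groups.items()}
    if any(n < 2 for n in ns.values()):
        raise ValidationError("ANOM needs ≥ 2 subjects per event")
    if len(set(ns.values())) > 1:
        logger.warning("ANOM: unbalanced groups %s; per-group limits", ns)
    k = len(events)
    df = sum(n - 1 for n in ns.values())
    grand = float(np.mean(np.concatenate(list(groups.values()))))
    s_pooled = float(np.sqrt(
        sum((ns[e] - 1) * np.var(groups[e], ddof=1) for e in events) / df))
    h = float(stats.t.ppf(1.0 - alpha / (2.0 * k), df))
    means, limits, flagged = {}, {}, []
    for e in events:
        n = ns[e]
        half = h * s_pooled * np.sqrt((k - 1) / (k * n))
        means[e] = float(np.mean(groups[e]))
        limits[e] = (grand - half, grand + half)
        if not limits[e][0] <= means[e] <= limits[e][1]:
            flagged.append(e)
    return AnomResult(grand, means, limits, flagged, alpha)


def summarize_cohort_variance(delta_z_by_event: dict,
                              focal_event: str = "inflation",
                              global_event: str = "global_terminal",
                              alpha: float = ANOM_ALPHA) -> VarianceSummary:
    """Full variance analysis from per-event per-subject ΔZ vectors.

    ``delta_z_by_event`` maps event name -> (n_subjects, 8) ΔZ array.
    Levene compares the pooled focal vs global per-channel values; Welch
    compares the per-subject single-value variances; ANOM screens every
    event's std against the grand mean.
    """
    variances = {}
    stds = {}
    for event, arr in delta_z_by_event.items():
        arr = np.asarray(arr, dtype=float)
        vs = [channel_variance(arr[i]) for i in range(arr.shape[0])]
        stds[event] = [float(np.sqrt(v)) for v in vs if np.isfinite(v)]
        for i, v in enumerate(vs):
            variances[(i, event)] = v
    pooled = {e: np.asarray(a, dtype=float).ravel()
              for e, a in delta_z_by_event.items()}
    pooled = {e: v[np.isfinite(v)] for e, v in pooled.items()}
    lev = levene_test([pooled[focal_event], pooled[global_event]])
    welch = welch_t(
        [variances[(i, focal_event)] for i in
         range(np.asarray(delta_z_by_event[focal_event]).shape[0])],
        [variances[(i, global_event)] for i in
         range(np.asarray(delta_z_by_event[global_event]).shape[0])])
    anom = anom_std(stds, alpha) if len(stds) >= 2 else None
    return VarianceSummary(variances, lev, welch, anom)
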