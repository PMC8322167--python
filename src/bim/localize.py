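"""Localization: nΔZ maps and the 1/3–2/3 focal/global classifier.

Within one event, the eight-channel ΔZ vector is rescaled to a nΔZ map on
[0, 1] (min–max; excluded channels stay missing). Maps are averaged
elementwise across subjects, and classified: an element below 1/3 marks a
focal low-impedance (hemorrhagic) injury at the map minimum, an element
above 2/3 a focal high-impedance (ischemia-model) injury at the maximum,
and a map confined to the middle band is a global event.

Min–max rescaling is deliberate: the source convention "normalized by the
highest channel, ranging 0–1" cannot reach 0 by division for positive
vectors and breaks for sign-mixed ones, so the 0–1 range is realised by
min–max instead. Two consequences are handled explicitly:

* a vector whose spread is within measurement noise (a global event) would
  have noise blown up to a full 0–1 range; such maps are flagged degenerate
  and set to 0.5 everywhere (``noise_scale`` sets the floor);
* a clean focal map pins one element at 0 and another at 1, so both
  thresholds fire; the focal element is then the one deviating most from
  the map *median*, the outlier against the majority background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import N_CHANNELS, ValidationError

logger = logging.getLogger("bim")

LOW_THRESHOLD = 1.0 / 3.0
HIGH_THRESHOLD = 2.0 / 3.0

#: Dynamic range below this many noise standard deviations is treated as a
#: degenerate (uniform) map.
DEGENERATE_RANGE_SD = 6.0

LABEL_FOCAL_HIGH = "focal_high_z"
LABEL_FOCAL_LOW = "focal_low_z"
LABEL_GLOBAL = "global"


@dataclass
class Classification:
    label: str
    element: int = None  # 1–8, set iff focal
    degenerate: bool = False


@dataclass
class LocalizationMap:
    """Per-event localization product: subject maps, mean map, label."""

    phase_name: str
    subject_maps: np.ndarray       # (n_subjects, 8), NaN = missing
    mean_map: np.ndarray           # (8,)
    classification: Classification = None
    subject_classifications: list = field(default_factory=list)


def normalize_deltas(delta_z, noise_scale: float = None) -> np.ndarray:
    """Min–max rescale an 8-channel ΔZ vector to nΔZ ∈ [0, 1].

    Missing (NaN) channels are carried as missing. All-equal values — or a
    dynamic range below ``DEGENERATE_RANGE_SD × noise_scale`` when a noise
    scale is supplied — yield the degenerate all-0.5 map with a warning.
    """
    dz = np.asarray(delta_z, dtype=float)
    if dz.shape != (N_CHANNELS,):
        raise ValidationError("delta_z must be a length-8 vector")
    usable = np.isfinite(dz)
    if usable.sum() < 2:
        raise ValidationError("need ≥ 2 usable channels to normalize")
    lo = np.nanmin(dz)
    hi = np.nanmax(dz)
    rng = hi - lo
    floor = 0.0 if noise_scale is None else DEGENERATE_RANGE_SD * noise_scale
    if rng == 0.0 or rng <= floor:
        logger.info("degenerate nΔZ map: range %.3g within noise floor "
                    "%.3g; returning uniform 0.5", rng, floor)
        out = np.where(usable, 0.5, np.nan)
        return out
    return (dz - lo) / rng


def cohort_mean_map(subject_maps) -> np.ndarray:
    """Elementwise missing-aware mean of per-subject nΔZ maps."""
    maps = np.asarray(subject_maps, dtype=float)
    if maps.ndim == 1:
        maps = maps[None, :]
    if maps.shape[0] < 1:
        raise ValidationError("need at least one subject map")
    with np.errstate(invalid="ignore"):
        return np.nanmean(maps, axis=0)


def classify_event(mean_map, low: float = LOW_THRESHOLD,
                   high: float = HIGH_THRESHOLD) -> Classification:
    """Label a mean nΔZ map focal-low / focal-high / global.

    Any element < ``low`` nominates the map minimum as a focal
    low-impedance element; any element > ``high`` nominates the maximum as
    focal high-impedance. If both bands are occupied, the element farther
    from the map median wins. All elements inside the band → global.
    """
    m = np.asarray(mean_map, dtype=float)
    defined = np.isfinite(m)
    if defined.sum() < 2:
        raise ValidationError("need ≥ 2 defined elements to classify")
    vals = m[defined]
    if np.all(vals == 0.5):
        logger.info("degenerate all-0.5 map classified global")
        return Classification(LABEL_GLOBAL, degenerate=True)
    has_low = bool(np.nanmin(m) < low)
    has_high = bool(np.nanmax(m) > high)
    argmin = int(np.nanargmin(m)) + 1
    argmax = int(np.nanargmax(m)) + 1
    if has_low and has_high:
        med = float(np.median(vals))
        dev_low = abs(float(np.nanmin(m)) - med)
        dev_high = abs(float(np.nanmax(m)) - med)
        if dev_high >= dev_low:
            return Classification(LABEL_FOCAL_HIGH, argmax)
        return Classification(LABEL_FOCAL_LOW, argmin)
    if has_high:
        return Classification(LABEL_FOCAL_HIGH, argmax)
    if has_low:
        return Classification(LABEL_FOCAL_LOW, argmin)
    return Classification(LABEL_GLOBAL)


def localize_event(phase_name: str, subject_deltas, noise_scales=None,
                   per_subject: bool = False) -> LocalizationMap:
    """Build the localization product for one event across subjects.

    ``subject_deltas`` is (n_subjects, 8) ΔZ in ohms; ``noise_scales`` the
    per-subject ΔZ noise floors (ohms) used to flag degenerate maps. The
    classifier runs on the cohort mean map (the event maps of a cohort
    study are cohort means); ``per_subject=True`` additionally classifies
    each subject's own map, the single-patient mode.
    """
    deltas = np.asarray(subject_deltas, dtype=float)
    if deltas.ndim == 1:
        deltas = deltas[None, :]
    n = deltas.shape[0]
    scales = ([None] * n if noise_scales is None
              else list(np.asarray(noise_scales, dtype=float)))
    maps = np.vstack([normalize_deltas(deltas[i], scales[i])
                      for i in range(n)])
    mean_map = cohort_mean_map(maps)
    loc = LocalizationMap(phase_name, maps, mean_map,
                          classify_event(mean_map))
    if per_subject:
        loc.subject_classifications = [classify_event(maps[i])
                                       for i in range(n)]
    return loc
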