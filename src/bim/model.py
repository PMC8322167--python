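"""Model/Results interface over the monitoring pipeline.

``SubjectInjuryModel`` wraps one subject's recording: ``fit()`` runs
filtering, de-trending and event-metric extraction and returns a
``SubjectInjuryResults`` carrying per-event ΔZ/ΔICP/DI estimates,
detection records and a ``summary()`` table. ``CohortInjuryModel``
aggregates subjects: DI comparison between injury types, nΔZ localization
maps with the focal/global classifier, and the channel-variance test
battery. Simulation hangs off :mod:`bim.simulate`; ``run_cohort`` goes
from a scenario template to a fitted cohort in one call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import localize as _localize
from . import metrics as _metrics
from . import preprocess as _preprocess
from . import variance_stats as _variance
from .io import (
    FOCAL_PHASES,
    GLOBAL_PHASES,
    N_CHANNELS,
    InjuryProtocol,
    MultiChannelRecording,
    default_protocol,
    read_recording,
)
from .metrics import DETECTION_THRESHOLD_OHM, Detection, EventMetrics
from .preprocess import BaselineError

logger = logging.getLogger("bim")


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the analysis chain (ohms, seconds)."""

    detection_threshold_ohm: float = DETECTION_THRESHOLD_OHM
    ct_pad_s: float = _preprocess.CT_PAD_S
    step_window_s: float = _preprocess.STEP_WINDOW_S
    step_threshold_ohm: float = _preprocess.STEP_THRESHOLD_OHM
    max_masked_fraction: float = _preprocess.MAX_MASKED_FRACTION
    max_unrepaired_steps: int = _preprocess.MAX_UNREPAIRED_STEPS
    baseline_fit_window_s: float = _preprocess.BASELINE_FIT_WINDOW_S
    icc_guard_s: float = _metrics.ICC_GUARD_S
    detrend: bool = True
    closest_channel: int = None  # 1-8; None -> strongest responding channel
    anom_alpha: float = _variance.ANOM_ALPHA


class SubjectInjuryModel:
    """Per-subject analysis model over a multichannel recording."""

    def __init__(self, recording: MultiChannelRecording,
                 protocol: InjuryProtocol = None,
                 config: AnalysisConfig = None):
        self.recording = recording
        self.protocol = protocol or default_protocol()
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(cls, path, protocol=None, config=None):
        return cls(read_recording(path), protocol, config)

    # -- internals ---------------------------------------------------------

    def _noise_scale(self, recording) -> float:
        """Per-subject ΔZ noise floor (ohms) from baseline slot repeatability.

        RMS over channels of the residual std of late-baseline slot means
        around their linear trend, times √2 (a ΔZ subtracts two such
        quantities).
        """
        b0, b1 = self.protocol.phase_window("baseline")
        lo = max(b0, b1 - self.config.baseline_fit_window_s)
        resid_vars = []
        for tr in recording.traces:
            mids, means, _ = tr.slot_means()
            keep = (mids >= lo) & (mids < b1)
            if keep.sum() < 3:
                continue
            t, z = mids[keep], means[keep]
            slope, icept = np.polyfit(t, z, 1)
            r = z - (slope * t + icept)
            resid_vars.append(np.var(r, ddof=2 if len(r) > 2 else 1))
        if not resid_vars:
            return 0.0
        return float(np.sqrt(2.0 * np.mean(resid_vars)))

    def fit(self) -> "SubjectInjuryResults":
        cfg = self.config
        filtered, quality, detections = _preprocess.preprocess_recording(
            self.recording, self.protocol, cfg.ct_pad_s, cfg.step_window_s,
            cfg.step_threshold_ohm, cfg.max_masked_fraction,
            cfg.max_unrepaired_steps)

        # de-trended traces for the inflation analysis
        _, baseline_end = self.protocol.phase_window("baseline")
        detrended_traces, detrend_fits = [], {}
        if cfg.detrend:
            for tr in filtered.traces:
                try:
                    dtr, fit = _preprocess.detrend_baseline(
                        tr, baseline_end, cfg.baseline_fit_window_s)
                except BaselineError:
                    logger.warning("channel %d: baseline unusable, kept "
                                   "non-detrended", tr.channel_id)
                    dtr, fit = tr.copy(), None
                detrended_traces.append(dtr)
                detrend_fits[tr.channel_id] = fit

        events = {}
        for p in self.protocol.phases:
            if p.name == "baseline":
                continue
            events[p.name] = _metrics.compute_event_metrics(
                filtered, self.protocol, p.name, quality_report=quality,
                icc_guard_s=cfg.icc_guard_s)

        inflation_detrended = None
        if cfg.detrend and "inflation" in self.protocol.phase_names():
            inflation_detrended = _metrics.compute_event_metrics(
                filtered, self.protocol, "inflation",
                traces=detrended_traces, quality_report=quality,
                icc_guard_s=cfg.icc_guard_s)

        detections_out = {}
        if "inflation" in self.protocol.phase_names():
            raw_em = events["inflation"]
            em = inflation_detrended or raw_em
            deltas = _metrics.step_deltas(em)
            times = self.protocol.step_times("inflation")
            vols = em.volumes_ml
            detections_out["mean-channel"] = _metrics.detect_volume_change(
                deltas, vols, times, cfg.detection_threshold_ohm,
                "mean-channel")
            closest = cfg.closest_channel
            if closest is None and np.isfinite(em.delta_z).any():
                closest = int(np.nanargmax(np.abs(em.delta_z))) + 1
            if closest is not None:
                detections_out["closest-channel"] = (
                    _metrics.detect_volume_change(
                        deltas, vols, times, cfg.detection_threshold_ohm,
                        "closest-channel", closest))
            detections_out["non-detrended"] = _metrics.detect_volume_change(
                _metrics.step_deltas(raw_em), vols, times,
                cfg.detection_threshold_ohm, "non-detrended")
            em.detections = detections_out

        return SubjectInjuryResults(
            model=self, filtered=filtered, quality_report=quality,
            step_detections=detections, events=events,
            inflation_detrended=inflation_detrended,
            detrend_fits=detrend_fits, detections=detections_out,
            noise_scale_ohm=self._noise_scale(filtered))


@dataclass
class SubjectInjuryResults:
    """Fitted per-subject estimates, quality audit and detections."""

    model: SubjectInjuryModel
    filtered: MultiChannelRecording
    quality_report: object
    step_detections: dict
    events: dict                    # phase -> EventMetrics (raw ΔZ)
    inflation_detrended: EventMetrics
    detrend_fits: dict
    detections: dict                # mode -> Detection
    noise_scale_ohm: float

    @property
    def subject_id(self) -> str:
        return str(self.filtered.metadata.get("subject_id", "?"))

    def event_delta_z(self, phase_name: str) -> np.ndarray:
        """ΔZ vector used for cross-subject analysis: de-trended for
        inflation (when available), raw otherwise."""
        if phase_name == "inflation" and self.inflation_detrended is not None:
            return self.inflation_detrended.delta_z
        return self.events[phase_name].delta_z

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, em in self.events.items():
            rows.append({
                "subject": self.subject_id, "phase": name,
                "delta_icp_mmhg": em.delta_icp,
                "mean_delta_z_ohm": float(np.nanmean(em.delta_z))
                if np.isfinite(em.delta_z).any() else np.nan,
                "subject_di": em.subject_di(),
                "mean_pearson_r": em.mean_pearson_r(),
                "n_usable_channels": len(em.usable_channels),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [f"Subject injury analysis — {self.subject_id}",
                 "=" * 48,
                 self.to_frame().to_string(index=False,
                                           float_format=lambda v: f"{v:.3f}")]
        if self.detections:
            lines.append("")
            lines.append("Inflation volume-change detection "
                         f"(threshold {self.model.config.detection_threshold_ohm} Ω):")
            for mode, det in self.detections.items():
                if det.detected:
                    lines.append(f"  {mode:>16}: detected at "
                                 f"{det.detection_volume_ml:.2f} mL "
                                 f"(t = {det.detection_time_s:.0f} s)")
                else:
                    lines.append(f"  {mode:>16}: not detected")
        excl = [e for e in self.quality_report.entries if e.excluded]
        lines.append("")
        lines.append(f"Excluded channel-phase traces: {len(excl)}")
        for e in excl:
            lines.append(f"  ch{e.channel_id} {e.phase_name}: "
                         f"{e.exclusion_reason}")
        return "\n".join(lines)


class CohortInjuryModel:
    """Across-subject analysis: DI separation, localization, variance."""

    def __init__(self, recordings, protocol: InjuryProtocol = None,
                 config: AnalysisConfig = None):
        self.recordings = list(recordings)
        self.protocol = protocol or default_protocol()
        self.config = config or AnalysisConfig()

    @classmethod
    def from_directory(cls, path, protocol=None, config=None):
        from pathlib import Path
        subdirs = sorted(d for d in Path(path).iterdir()
                         if (d / "channels.csv").exists())
        return cls([read_recording(d) for d in subdirs], protocol, config)

    def fit(self) -> "CohortInjuryResults":
        subject_results = [
            SubjectInjuryModel(rec, self.protocol, self.config).fit()
            for rec in self.recordings]

        table = pd.concat([r.to_frame() for r in subject_results],
                          ignore_index=True)

        # localization maps per event
        phases = [p.name for p in self.protocol.phases if p.name != "baseline"]
        noise_scales = [r.noise_scale_ohm for r in subject_results]
        maps = {}
        for name in phases:
            deltas = np.vstack([r.event_delta_z(name)
                                for r in subject_results])
            maps[name] = _localize.localize_event(
                name, deltas, noise_scales, per_subject=True)

        # variance battery (focal inflation vs terminal global)
        dz_by_event = {
            name: np.vstack([r.event_delta_z(name) for r in subject_results])
            for name in phases}
        variance = None
        if "inflation" in dz_by_event and "global_terminal" in dz_by_event:
            variance = _variance.summarize_cohort_variance(
                dz_by_event, "inflation", "global_terminal",
                self.config.anom_alpha)

        # paired DI comparison between the two focal injury types
        di_comparison = None
        if {"inflation", "hematoma"} <= set(phases):
            di_inf = np.array([r.events["inflation"].subject_di()
                               for r in subject_results])
            di_hem = np.array([r.events["hematoma"].subject_di()
                               for r in subject_results])
            ok = np.isfinite(di_inf) & np.isfinite(di_hem)
            if ok.sum() >= 2:
                t, p = _sps.ttest_rel(di_inf[ok], di_hem[ok])
                di_comparison = {
                    "mean_di_inflation": float(np.mean(di_inf[ok])),
                    "mean_di_hematoma": float(np.mean(di_hem[ok])),
                    "t": float(t), "p": float(p), "n": int(ok.sum()),
                }

        return CohortInjuryResults(
            model=self, subjects=subject_results, table=table,
            localization=maps, variance=variance,
            di_comparison=di_comparison,
            delta_z_by_event=dz_by_event)


@dataclass
class CohortInjuryResults:
    """Cohort-level estimates, maps and tests."""

    model: CohortInjuryModel
    subjects: list
    table: pd.DataFrame
    localization: dict              # phase -> LocalizationMap
    variance: object
    di_comparison: dict
    delta_z_by_event: dict

    def detection_volumes(self, mode: str = "mean-channel") -> np.ndarray:
        vols = []
        for r in self.subjects:
            det = r.detections.get(mode)
            if det is not None and det.detected:
                vols.append(det.detection_volume_ml)
        return np.asarray(vols)

    def detection_rate(self, mode: str = "mean-channel") -> float:
        dets = [r.detections.get(mode) for r in self.subjects]
        dets = [d for d in dets if d is not None]
        if not dets:
            return float("nan")
        return float(np.mean([d.detected for d in dets]))

    def long_format(self) -> pd.DataFrame:
        """Tidy per-channel table (subject, event, element, ΔZ, DI, r).

        One row per subject × event × element — the layout expected by
        external mixed-model tooling (subject as a random effect, injury
        and element as fixed effects).
        """
        rows = []
        for r in self.subjects:
            for name, em in r.events.items():
                dz = r.event_delta_z(name)
                for c in range(N_CHANNELS):
                    rows.append({
                        "subject": r.subject_id, "event": name,
                        "element": c + 1, "delta_z_ohm": dz[c],
                        "di_ohm_per_mmhg": em.di[c],
                        "pearson_r": em.pearson_r[c],
                        "delta_icp_mmhg": em.delta_icp,
                    })
        return pd.DataFrame(rows)

    def mean_map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: loc.mean_map for name, loc in self.localization.items()},
            index=[f"element_{c}" for c in range(1, N_CHANNELS + 1)]).T

    def to_dict(self) -> dict:
        out = {
            "n_subjects": len(self.subjects),
            "di_comparison": self.di_comparison,
            "detection": {
                mode: {
                    "rate": self.detection_rate(mode),
                    "mean_volume_ml":
                        float(np.mean(self.detection_volumes(mode)))
                        if len(self.detection_volumes(mode)) else None,
                } for mode in ("mean-channel", "closest-channel",
                               "non-detrended")},
            "localization": {
                name: {
                    "label": loc.classification.label,
                    "element": loc.classification.element,
                    "mean_map": [round(float(v), 4) for v in loc.mean_map],
                } for name, loc in self.localization.items()},
        }
        if self.variance is not None:
            v = self.variance
            out["variance"] = {
                "levene_W": v.levene[0], "levene_p": v.levene[1],
                "welch_t": v.welch[0], "welch_df": v.welch[1],
                "welch_p": v.welch[2],
                "anom_flagged": v.anom.flagged_events if v.anom else [],
            }
        return out

    def summary(self) -> str:
        lines = [f"Cohort injury analysis — n = {len(self.subjects)} subjects",
                 "=" * 56]
        agg = (self.table.groupby("phase", sort=False)
               [["delta_icp_mmhg", "mean_delta_z_ohm", "subject_di",
                 "mean_pearson_r"]].mean())
        lines.append(agg.to_string(float_format=lambda v: f"{v:.3f}"))
        if self.di_comparison:
            c = self.di_comparison
            lines.append("")
            lines.append(
                f"Paired DI, inflation vs hematoma: "
                f"{c['mean_di_inflation']:.3f} vs {c['mean_di_hematoma']:.3f} "
                f"Ω/mmHg (t = {c['t']:.2f}, p = {c['p']:.2g}, n = {c['n']})")
        for mode in ("mean-channel", "closest-channel", "non-detrended"):
            vols = self.detection_volumes(mode)
            if len(vols):
                lines.append(
                    f"Detection ({mode}): {len(vols)}/{len(self.subjects)} "
                    f"subjects at {np.mean(vols):.2f} ± {np.std(vols):.2f} mL")
        lines.append("")
        lines.append("Localization (cohort mean nΔZ classifier):")
        for name, loc in self.localization.items():
            cl = loc.classification
            el = f", element {cl.element}" if cl.element else ""
            lines.append(f"  {name:>16}: {cl.label}{el}")
        if self.variance is not None:
            v = self.variance
            lines.append("")
            lines.append(
                f"Focal vs global variance: Levene W = {v.levene[0]:.1f} "
                f"(p = {v.levene[1]:.2g}); Welch t = {v.welch[0]:.2f}, "
                f"df = {v.welch[1]:.1f} (p = {v.welch[2]:.2g})")
            if v.anom is not None:
                lines.append(f"ANOM flagged events: "
                             f"{', '.join(v.anom.flagged_events) or 'none'}")
        return "\n".join(lines)

    # -- plotting ---------------------------------------------------------

    def plot_maps(self, path=None):
        """Heatmap of cohort-mean nΔZ per event (elements × events)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.mean_map_frame()
        fig, ax = plt.subplots(figsize=(7, 3))
        im = ax.imshow(frame.to_numpy(), vmin=0, vmax=1, cmap="viridis",
                       aspect="auto")
        ax.set_xticks(range(N_CHANNELS),
                      [str(c) for c in range(1, N_CHANNELS + 1)])
        ax.set_yticks(range(len(frame.index)), list(frame.index))
        ax.set_xlabel("element")
        fig.colorbar(im, ax=ax, label="mean nΔZ")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig

    def plot_detection(self, path=None, mode: str = "mean-channel"):
        """Per-subject detection signal vs volume with the threshold line."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        thr = self.model.config.detection_threshold_ohm
        for r in self.subjects:
            em = r.inflation_detrended or r.events.get("inflation")
            if em is None:
                continue
            deltas = em.z_vn - em.z_v0[None, :]
            with np.errstate(invalid="ignore"):
                sig = np.nanmean(deltas, axis=1)
            ax.plot(em.volumes_ml, sig, marker="o", ms=3, lw=1,
                    label=r.subject_id)
        ax.axhline(thr, color="red", lw=1.5,
                   label=f"threshold {thr} Ω")
        ax.set_xlabel("balloon volume (mL)")
        ax.set_ylabel("mean de-trended ΔZ (Ω)")
        ax.legend(fontsize=6, ncol=2)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def run_cohort(scenario_template=None, n_subjects: int = 9, seed: int = 0,
               config: AnalysisConfig = None, out_dir=None):
    """Simulate a cohort and fit the full analysis chain.

    Returns ``(CohortInjuryResults, scenarios)``. The designated
    closest-channel for detection is the scenario's inclusion sector (the
    known-lesion-location mode). With ``out_dir`` set, recording bundles
    and the cohort summary JSON are written there.
    """
    from .simulate import InjuryScenario, synthesize_cohort
    from .io import write_recording
    import json
    from pathlib import Path

    template = scenario_template or InjuryScenario()
    recs, scenarios = synthesize_cohort(template, n_subjects, seed)
    cfg = config or AnalysisConfig()
    if cfg.closest_channel is None:
        cfg.closest_channel = template.inclusion_sector
    results = CohortInjuryModel(recs, template.protocol, cfg).fit()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in recs:
            write_recording(rec, out / rec.metadata["subject_id"])
        with open(out / "cohort_summary.json", "w") as fh:
            json.dump(results.to_dict(), fh, indent=2, default=str)
    return results, scenarios
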