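"""End-to-end session fitting, multi-subject runs, and run reports.

:class:`PhotometrySession` is the central modelling object: it is built
from a spectral frame series, a reference set, and a stimulation protocol,
and ``fit()`` executes unmix -> ratio -> baseline -> dF/F0 -> epoch
summaries, returning a :class:`SessionResults` with the estimates and a
``summary()`` table.  :func:`run_pipeline` drives many subjects (simulated
from a preset, or loaded from files), assembles dose-response tables, runs
the statistics matching the design, and emits a machine-readable report
that embeds the fully resolved configuration and seed so every run is
reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import epochs as _ep
from . import stats as _stats
from . import synthetic as _syn
from . import traces as _tr
from .spectra import (
    ReferenceSet,
    SpectralFrameSeries,
    read_frame_series,
    read_reference_spectra,
    write_frame_series,
    write_reference_spectra,
)
from .unmix import UnmixingModel, UnmixingResults

__all__ = [
    "PhotometrySession",
    "SessionResults",
    "PipelineConfig",
    "run_pipeline",
    "simulate_subjects",
    "generate_fixture_bundle",
]

logger = logging.getLogger(__name__)


class PhotometrySession:
    """One recording (real or synthetic) ready to be fitted end to end.

    Parameters
    ----------
    series
        Background-subtracted frames x wavelengths recording.
    refset
        Reference emission spectra; fluorophore ids name the channels.
    protocol
        Stimulation protocol aligned to the recording's time base.
    sensors, control
        Channel names: the sensor channel(s) of interest and the control
        fluorophore used as the ratiometric denominator.
    """

    def __init__(
        self,
        series: SpectralFrameSeries,
        refset: ReferenceSet,
        protocol: _syn.ProtocolSpec,
        sensors: Sequence[str],
        control: str,
        subject=None,
        background=None,
    ) -> None:
        if background is not None:
            from .spectra import subtract_background

            series = subtract_background(series, background)
        names = refset.fluorophores
        for ch in [*sensors, control]:
            if ch not in names:
                raise KeyError(f"channel {ch!r} not in reference set {names}")
        self.series = series
        self.refset = refset
        self.protocol = protocol
        self.sensors = list(sensors)
        self.control = control
        self.subject = subject

    @classmethod
    def from_simulated(cls, sim: _syn.SimulatedSession, subject=None):
        return cls(
            sim.series, sim.refset, sim.protocol, sim.sensors, sim.control,
            subject=subject,
        )

    def fit(
        self,
        method: str = "nnls",
        baseline_window: tuple = (0.0, 60.0),
        window_policy: str = "last_half_mean",
        mode: str = "ratio_first",
        control_floor: float = 0.1,
    ) -> "SessionResults":
        """Run the full per-subject analysis.

        ``mode='ratio_first'`` (default) fits the bleaching baseline to the
        sensor/control ratio, inheriting the ratio's common-mode artifact
        cancellation; ``mode='per_channel'`` fits a baseline to each
        unmixed coefficient first and forms the ratio of the two
        baseline-normalized channels afterwards.
        """
        if mode not in ("ratio_first", "per_channel"):
            raise ValueError("mode must be 'ratio_first' or 'per_channel'")
        unmix_res = UnmixingModel(self.series, self.refset, method).fit()
        traces = unmix_res.traces
        dff: dict[str, _tr.DffTrace] = {}
        ratios: dict[str, _tr.RatioTrace] = {}
        baselines: dict[str, _tr.BaselineFit] = {}
        if mode == "ratio_first":
            for sensor in self.sensors:
                ratio = _tr.ratio_trace(traces, sensor, self.control, control_floor)
                fit = _tr.fit_baseline(ratio, baseline_window, self.protocol)
                d = _tr.compute_dff(ratio, fit)
                ratios[sensor], baselines[sensor], dff[sensor] = ratio, fit, d
        else:
            t = traces.frame_times
            ctl_fit = _tr.fit_baseline(
                (t, traces.channel(self.control)), baseline_window, self.protocol
            )
            ctl_dff = _tr.compute_dff((t, traces.channel(self.control)), ctl_fit)
            for sensor in self.sensors:
                fit = _tr.fit_baseline(
                    (t, traces.channel(sensor)), baseline_window, self.protocol
                )
                sen_dff = _tr.compute_dff((t, traces.channel(sensor)), fit)
                ratio_vals = 100.0 * (
                    (1.0 + sen_dff.values / 100.0)
                    / (1.0 + ctl_dff.values / 100.0)
                    - 1.0
                )
                baselines[sensor] = fit
                dff[sensor] = _tr.DffTrace(
                    frame_times=t,
                    values=ratio_vals,
                    valid=sen_dff.valid & ctl_dff.valid,
                    source_id=f"{sensor}/{self.control}",
                    baseline=fit,
                )
        summaries = []
        for i, ep in enumerate(self.protocol.epochs):
            for sensor in self.sensors:
                summaries.append(
                    _ep.summarize_epoch(
                        dff[sensor],
                        ep,
                        window_policy,
                        epoch_index=i,
                        subject=self.subject,
                        channel=sensor,
                    )
                )
        return SessionResults(
            session=self,
            unmixing=unmix_res,
            ratios=ratios,
            baselines=baselines,
            dff=dff,
            epoch_summaries=summaries,
            fit_params={
                "method": method,
                "baseline_window": tuple(baseline_window),
                "window_policy": window_policy,
                "mode": mode,
                "control_floor": control_floor,
            },
        )


@dataclass
class SessionResults:
    """Fitted per-subject results: traces, baselines, dF/F0, epoch table."""

    session: PhotometrySession
    unmixing: UnmixingResults
    ratios: dict
    baselines: dict
    dff: dict
    epoch_summaries: list
    fit_params: dict

    def epoch_table(self) -> pd.DataFrame:
        return _ep.summaries_to_frame(self.epoch_summaries)

    def summary(self) -> str:
        lines = [
            f"Photometry session (subject={self.session.subject})",
            f"  sensors: {self.session.sensors}   control: {self.session.control}",
            f"  fit: {self.fit_params}",
            "  "
            + self.unmixing.summary().replace("\n", "\n  "),
            "  epoch summaries (percent change):",
        ]
        for s in self.epoch_summaries:
            tag = s.label if s.label is not None else f"{s.intensity_ua:g} uA"
            lines.append(
                f"    epoch {s.epoch_index} [{tag}] {s.channel}: "
                f"{s.percent_change:+.3f} % ({s.window_policy})"
            )
        return "\n".join(lines)

    def plot(self, sensor: str | None = None, ax=None):
        """Plot dF/F0 with stimulation epochs shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        names = [sensor] if sensor else list(self.dff)
        for name in names:
            d = self.dff[name]
            ax.plot(d.frame_times, d.values, lw=0.7, label=d.source_id)
        for ep in self.session.protocol.epochs:
            ax.axvspan(ep.start_s, ep.end_s, color="0.85", zorder=0)
        ax.axhline(0.0, color="0.6", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("dF/F0 (%)")
        ax.legend(frameon=False)
        return ax


class PipelineConfig(BaseModel):
    """Validated configuration of a multi-subject pipeline run."""

    preset: Optional[str] = None
    frames_csv: Optional[str] = None
    reference_csv: Optional[str] = None
    protocol_json: Optional[str] = None
    background_csv: Optional[str] = None
    sensors: Optional[list[str]] = None
    control: Optional[str] = None
    n_subjects: int = Field(default=1, ge=1)
    seed: int = Field(default=0, ge=0, lt=2**31)
    method: Literal["nnls", "ols"] = "nnls"
    baseline_window: tuple[float, float] = (0.0, 60.0)
    window_policy: Literal["full_epoch_mean", "last_half_mean", "peak"] = (
        "last_half_mean"
    )
    mode: Literal["ratio_first", "per_channel"] = "ratio_first"
    control_floor: float = Field(default=0.1, gt=0.0, lt=1.0)
    stats_design: Literal["auto", "rm_dunnett", "paired_t", "oneway_tukey", "none"] = (
        "auto"
    )
    frame_rate: float = Field(default=25.0, gt=0.0)
    grid_step_nm: float = Field(default=1.0, gt=0.0)
    inter_epoch_gap_s: Optional[float] = None
    noise_scale: float = Field(default=1.0, ge=0.0)
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check_source(self):
        if self.preset is None:
            missing = [
                k
                for k in ("frames_csv", "reference_csv", "protocol_json",
                          "sensors", "control")
                if getattr(self, k) is None
            ]
            if missing:
                raise ValueError(
                    f"either 'preset' or file inputs are required; missing {missing}"
                )
        return self


def simulate_subjects(config: PipelineConfig):
    """Yield (subject_index, condition, SimulatedSession) for a preset run."""
    preset = _syn.get_preset(config.preset)
    conditions = preset.condition_names or [None]
    for subj in range(config.n_subjects):
        for cond in conditions:
            sim = _syn.simulate_session(
                preset,
                seed=_syn.subject_seed(config.seed, subj),
                condition=cond,
                frame_rate=config.frame_rate,
                grid_step_nm=config.grid_step_nm,
                inter_epoch_gap_s=config.inter_epoch_gap_s,
                noise_scale=config.noise_scale,
                window_policy=config.window_policy,
            )
            yield subj, cond, sim


def _fit_kwargs(config: PipelineConfig) -> dict:
    return dict(
        method=config.method,
        baseline_window=config.baseline_window,
        window_policy=config.window_policy,
        mode=config.mode,
        control_floor=config.control_floor,
    )


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a full run and return (and optionally write) the report."""
    report: dict = {"config": json.loads(config.model_dump_json())}
    all_summaries: list = []
    recovery: list = []
    try:
        if config.preset is not None:
            preset = _syn.get_preset(config.preset)
            sensors = preset.sensors
            for subj, cond, sim in simulate_subjects(config):
                logger.info(
                    "stage=fit subject=%s condition=%s preset=%s",
                    subj, cond, config.preset,
                )
                res = PhotometrySession.from_simulated(sim, subject=subj).fit(
                    **_fit_kwargs(config)
                )
                for s in res.epoch_summaries:
                    if cond is not None:
                        s = _ep.EpochSummary(
                            epoch_index=s.epoch_index,
                            intensity_ua=s.intensity_ua,
                            channel=s.channel,
                            percent_change=s.percent_change,
                            window_policy=s.window_policy,
                            window=s.window,
                            subject=s.subject,
                            label=cond,
                        )
                    all_summaries.append(s)
                    truth = sim.truth.true_ratio_effect_pct[s.epoch_index][s.channel]
                    recovery.append(
                        {
                            "subject": subj,
                            "condition": cond,
                            "channel": s.channel,
                            "epoch_index": s.epoch_index,
                            "intensity_uA": s.intensity_ua,
                            "recovered_pct": s.percent_change,
                            "true_pct": truth,
                            "error_pct": s.percent_change - truth,
                        }
                    )
        else:
            from .spectra import read_background

            series = read_frame_series(
                config.frames_csv,
                background_subtracted=config.background_csv is None,
            )
            refset = read_reference_spectra(config.reference_csv)
            with open(config.protocol_json) as fh:
                protocol = _syn.ProtocolSpec.from_dict(json.load(fh))
            background = (
                read_background(config.background_csv)
                if config.background_csv
                else None
            )
            sensors = config.sensors
            res = PhotometrySession(
                series, refset, protocol, sensors, config.control,
                subject=0, background=background,
            ).fit(**_fit_kwargs(config))
            all_summaries.extend(res.epoch_summaries)
    except Exception as exc:  # annotate the failing stage for the CLI
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    report["epoch_summaries"] = _ep.summaries_to_frame(all_summaries).to_dict(
        orient="records"
    )
    if recovery:
        report["recovery"] = recovery
        errs = np.array([r["error_pct"] for r in recovery])
        report["recovery_error"] = {
            "mean_abs": float(np.mean(np.abs(errs))),
            "max_abs": float(np.max(np.abs(errs))),
        }

    # dose-response per channel (labelled condition runs tabulate by label)
    by_channel: dict[str, list] = {}
    for s in all_summaries:
        by_channel.setdefault(s.channel, []).append(s)
    labelled = any(s.label is not None for s in all_summaries)
    dose: dict[str, dict] = {}
    for ch, summ in by_channel.items():
        if labelled:
            df = _ep.summaries_to_frame(summ)
            tab = (
                df.groupby("label")["percent_change"]
                .agg(["mean", "sem", "count"])
                .reset_index()
            )
            dose[ch] = {"by_condition": tab.to_dict(orient="records")}
        else:
            dr = _ep.dose_response(summ)
            dose[ch] = dr.summary().to_dict(orient="records")
    report["dose_response"] = dose

    report["stats"] = _run_stats(config, all_summaries, by_channel, labelled)
    report = _round_floats(report)
    if config.out_dir is not None:
        _write_outputs(config, report, all_summaries)
    return report


def _run_stats(config, all_summaries, by_channel, labelled) -> dict:
    design = config.stats_design
    out: dict = {}
    if design == "none" or not all_summaries:
        return out
    try:
        if labelled and design in ("auto", "oneway_tukey"):
            for ch, summ in by_channel.items():
                df = _ep.summaries_to_frame(summ)
                labels = sorted(df["label"].unique())
                groups = [
                    df[df["label"] == lb]["percent_change"].to_numpy()
                    for lb in labels
                ]
                if all(g.size >= 2 for g in groups) and len(groups) >= 2:
                    out[f"oneway_tukey[{ch}]"] = _stats.oneway_anova_tukey(
                        groups, labels=labels
                    ).to_dict()
        elif not labelled:
            tables = {
                ch: _ep.dose_response(summ).table()
                for ch, summ in by_channel.items()
            }
            if design in ("auto", "rm_dunnett"):
                for ch, tab in tables.items():
                    if tab.shape[0] >= 3 and tab.shape[1] >= 2:
                        out[f"rm_dunnett[{ch}]"] = _stats.rm_anova_dunnett(
                            tab, seed=config.seed
                        ).to_dict()
            if design in ("auto", "paired_t") and len(tables) == 2:
                (ch_a, tab_a), (ch_b, tab_b) = sorted(tables.items())
                for intensity in tab_a.columns:
                    res = _stats.paired_t(
                        tab_a[intensity].to_numpy(), tab_b[intensity].to_numpy()
                    )
                    out[f"paired_t[{ch_a}-{ch_b}][{intensity:g}uA]"] = res.to_dict()
    except ValueError as exc:
        out["skipped"] = str(exc)
    return out


def _write_outputs(config, report, all_summaries) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _ep.summaries_to_frame(all_summaries).to_csv(
        out / "epoch_summaries.csv", index=False
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("stage=write out_dir=%s", out)


def generate_fixture_bundle(out_dir, seed: int = 0) -> dict:
    """Write one small scaled-down subject per preset (CI-sized fixtures).

    Each preset directory holds frames.csv, reference.csv, protocol.json
    and truth.json in the documented schemas.  Deterministic per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict = {}
    for name in _syn.list_presets():
        preset = _syn.get_preset(name)
        conditions = preset.condition_names or [None]
        pdir = out / name
        pdir.mkdir(exist_ok=True)
        files = []
        for cond in conditions:
            sim = _syn.simulate_session(
                preset,
                seed=_syn.subject_seed(seed, 0),
                condition=cond,
                frame_rate=5.0,
                grid_step_nm=2.0,
                inter_epoch_gap_s=60.0 if preset.conditions is None else None,
            )
            tag = "" if cond is None else f"{cond}."
            write_frame_series(sim.series, pdir / f"{tag}frames.csv")
            write_reference_spectra(sim.refset, pdir / f"{tag}reference.csv")
            with open(pdir / f"{tag}protocol.json", "w") as fh:
                json.dump(sim.protocol.to_dict(), fh, indent=1, sort_keys=True)
            with open(pdir / f"{tag}truth.json", "w") as fh:
                json.dump(
                    _round_floats(sim.truth.to_dict(include_traces=True)),
                    fh, sort_keys=True,
                )
            files.extend(
                f"{tag}{base}" for base in
                ("frames.csv", "reference.csv", "protocol.json", "truth.json")
            )
        written[name] = files
    return written
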