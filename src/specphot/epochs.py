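"""Stimulation-epoch response quantification and cross-condition tables.

Each stimulation epoch is summarized to one percent-change number per
channel under a window policy: ``last_half_mean`` (default — the last 30 s
of a 60-s train, where slow-onset responses have plateaued),
``full_epoch_mean``, or ``peak`` (the signed extremum within the epoch).
Summaries are aggregated per subject (mirroring the n = animals
convention), then assembled into intensity dose-response tables and, for
simultaneous dual-sensor recordings, paired excitation/inhibition
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import StimulusEpoch, response_window
from .traces import DffTrace

__all__ = [
    "EpochSummary",
    "DoseResponse",
    "EIComparison",
    "WINDOW_POLICIES",
    "summarize_epoch",
    "dose_response",
    "ei_comparison",
]

WINDOW_POLICIES = ("full_epoch_mean", "last_half_mean", "peak")


@dataclass(frozen=True)
class EpochSummary:
    """One epoch x channel percent-change summary."""

    epoch_index: int
    intensity_ua: float
    channel: str
    percent_change: float
    window_policy: str
    window: tuple
    subject: int | str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.percent_change):
            raise ValueError("percent_change must be finite")


def summarize_epoch(
    dff: DffTrace,
    epoch: StimulusEpoch,
    window_policy: str = "last_half_mean",
    epoch_index: int = 0,
    subject=None,
    channel: str | None = None,
) -> EpochSummary:
    """Summarize a dF/F0 trace over one stimulation epoch."""
    if window_policy not in WINDOW_POLICIES:
        raise ValueError(f"window_policy must be one of {WINDOW_POLICIES}")
    t = dff.frame_times
    dt = float(t[1] - t[0]) if t.size > 1 else 0.0
    if epoch.start_s < t[0] - 1e-9 or epoch.end_s > t[-1] + dt + 1e-9:
        raise ValueError("epoch extends beyond the trace extent")
    lo, hi = response_window(epoch, window_policy)
    mask = dff.valid & (t >= lo) & (t < hi)
    if not np.any(mask):
        raise ValueError("no valid frames in the summary window")
    vals = dff.values[mask]
    if window_policy == "peak":
        pct = float(vals[np.argmax(np.abs(vals))])
    else:
        pct = float(np.mean(vals))
    return EpochSummary(
        epoch_index=epoch_index,
        intensity_ua=float(epoch.intensity_ua),
        channel=channel if channel is not None else dff.source_id,
        percent_change=pct,
        window_policy=window_policy,
        window=(lo, hi),
        subject=subject,
        label=epoch.label,
    )


def summaries_to_frame(summaries) -> pd.DataFrame:
    rows = [
        {
            "subject": s.subject,
            "channel": s.channel,
            "epoch_index": s.epoch_index,
            "intensity_uA": s.intensity_ua,
            "label": s.label,
            "percent_change": s.percent_change,
            "policy": s.window_policy,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


@dataclass
class DoseResponse:
    """Per-intensity subject-level percent changes with mean +/- sem."""

    channel: str
    intensities: list  # sorted intensities (uA)
    values: dict  # intensity -> np.ndarray of per-subject values
    subjects: dict  # intensity -> list of subject ids

    def mean(self, intensity: float) -> float:
        return float(np.mean(self.values[intensity]))

    def sem(self, intensity: float) -> float:
        v = self.values[intensity]
        if v.size < 2:
            return float("nan")  # undefined for a single subject
        return float(np.std(v, ddof=1) / np.sqrt(v.size))

    def n(self, intensity: float) -> int:
        return int(self.values[intensity].size)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intensity_uA": self.intensities,
                "mean": [self.mean(i) for i in self.intensities],
                "sem": [self.sem(i) for i in self.intensities],
                "n": [self.n(i) for i in self.intensities],
            }
        )

    def table(self) -> pd.DataFrame:
        """Subjects x intensities wide table (input for repeated-measures tests)."""
        frames = {}
        for i in self.intensities:
            frames[i] = pd.Series(self.values[i], index=self.subjects[i])
        return pd.DataFrame(frames)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = [self.mean(i) for i in self.intensities]
        sems = [self.sem(i) for i in self.intensities]
        ax.errorbar(self.intensities, means, yerr=sems, marker="o", capsize=3)
        ax.set_xlabel("stimulation intensity (uA)")
        ax.set_ylabel(f"{self.channel} percent change (%)")
        ax.axhline(0.0, color="0.6", lw=0.5)
        return ax


def dose_response(summaries) -> DoseResponse:
    """Assemble per-subject epoch summaries into a dose-response table.

    Multi-trial subjects are averaged within subject first.  All subjects
    must contribute the same set of intensities.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no epoch summaries given")
    channels = {s.channel for s in summaries}
    if len(channels) != 1:
        raise ValueError(f"summaries mix channels: {sorted(channels)}")
    df = summaries_to_frame(summaries)
    per = (
        df.groupby(["subject", "intensity_uA"], dropna=False)["percent_change"]
        .mean()
        .reset_index()
    )
    sets = per.groupby("subject")["intensity_uA"].apply(frozenset)
    if len(set(sets)) != 1:
        raise ValueError("inconsistent intensities across subjects")
    intensities = sorted(sets.iloc[0])
    values, subjects = {}, {}
    for i in intensities:
        sub = per[per["intensity_uA"] == i].sort_values("subject")
        values[i] = sub["percent_change"].to_numpy()
        subjects[i] = sub["subject"].tolist()
    return DoseResponse(
        channel=channels.pop(),
        intensities=intensities,
        values=values,
        subjects=subjects,
    )


@dataclass
class EIComparison:
    """Paired glutamate-vs-GABA percent changes per subject and intensity.

    ``difference = delta_glu - delta_gaba``; a negative difference means
    the glutamate (excitatory) signal is suppressed more than the GABA
    (inhibitory) one.
    """

    glu_channel: str
    gaba_channel: str
    table: pd.DataFrame  # columns: subject, intensity_uA, glu, gaba, difference

    def differences(self, intensity: float) -> np.ndarray:
        sub = self.table[self.table["intensity_uA"] == intensity]
        return sub["difference"].to_numpy()

    def paired(self, intensity: float) -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[self.table["intensity_uA"] == intensity]
        return sub["glu"].to_numpy(), sub["gaba"].to_numpy()

    @property
    def intensities(self) -> list:
        return sorted(self.table["intensity_uA"].unique())

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby("intensity_uA")
        return pd.DataFrame(
            {
                "mean_glu": g["glu"].mean(),
                "mean_gaba": g["gaba"].mean(),
                "mean_difference": g["difference"].mean(),
                "n": g["difference"].size(),
            }
        ).reset_index()


def ei_comparison(glu_summaries, gaba_summaries) -> EIComparison:
    """Pair same-subject, same-intensity summaries of the two sensors."""
    glu = summaries_to_frame(list(glu_summaries))
    gaba = summaries_to_frame(list(gaba_summaries))
    gch = glu["channel"].unique()
    bch = gaba["channel"].unique()
    if len(gch) != 1 or len(bch) != 1:
        raise ValueError("each side must be a single channel")
    key = ["subject", "intensity_uA"]
    glu_p = glu.groupby(key)["percent_change"].mean()
    gaba_p = gaba.groupby(key)["percent_change"].mean()
    if set(glu_p.index) != set(gaba_p.index):
        raise ValueError("unpaired subjects/intensities between channels")
    merged = pd.DataFrame({"glu": glu_p, "gaba": gaba_p}).reset_index()
    merged["difference"] = merged["glu"] - merged["gaba"]
    merged = merged.sort_values(key).reset_index(drop=True)
    return EIComparison(
        glu_channel=str(gch[0]), gaba_channel=str(bch[0]), table=merged
    )
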