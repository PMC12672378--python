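"""Synthetic recording sessions with known ground truth.

The generator emulates the structure of a spectrally resolved
fiber-photometry session during deep brain stimulation: a pre-stimulation
baseline minute, 60-s stimulation trains at increasing current intensity
separated by 5-min intervals, slow photobleaching, epoch-locked fractional
changes per fluorophore with first-order onset/offset kinetics, an additive
stimulation-artifact component on the sensor channel, and frame noise.
Each session carries a :class:`GroundTruthRecord` so recovery of the
downstream pipeline can be tested without any real data.

Per-channel true abundance is

    a(t) = a0 * (1 - b * t / 60) * (1 + e(t) / 100)

with linear bleaching fraction ``b`` per minute and ``e(t)`` the percent
effect, relaxing exponentially toward ``plateau + artifact`` during an
epoch (onset time constant) and back toward 0 afterwards (offset time
constant).  Frames are y(t) = sum_k a_k(t) * S_k(lambda) + noise.

Preset parameter tables live in one packaged, human-readable YAML file
(``data/presets.yaml``) so transcribed effect sizes are auditable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .spectra import (
    BUILTIN_SHAPE_PARAMS,
    EmissionSpectrum,
    ReferenceSet,
    SpectralFrameSeries,
    WavelengthGrid,
    peak_normalize,
    skewed_gaussian,
)

__all__ = [
    "StimulusEpoch",
    "ProtocolSpec",
    "ChannelDynamicsSpec",
    "NoiseSpec",
    "GroundTruthRecord",
    "TrueTraces",
    "SimulatedSession",
    "make_protocol",
    "simulate_true_traces",
    "synthesize_frames",
    "simulate_session",
    "load_presets",
    "get_preset",
    "list_presets",
    "Preset",
    "DEFAULT_WINDOW_POLICY",
    "subject_seed",
]

DEFAULT_WINDOW_POLICY = "last_half_mean"

_WAVEFORMS = ("monophasic-cathodic", "biphasic")


@dataclass(frozen=True)
class StimulusEpoch:
    """One stimulation train (or drug condition window, via ``label``)."""

    start_s: float
    duration_s: float
    frequency_hz: float = 130.0
    pulse_width_us: float = 60.0
    intensity_ua: float = 150.0
    waveform: str = "monophasic-cathodic"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")
        if self.frequency_hz <= 0:
            raise ValueError("stimulation frequency must be positive")
        if self.pulse_width_us * self.frequency_hz >= 1e6:
            raise ValueError("pulse width x frequency implies duty cycle >= 100%")
        if self.waveform not in _WAVEFORMS:
            raise ValueError(f"waveform must be one of {_WAVEFORMS}")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class ProtocolSpec:
    """Session layout: baseline, ordered stimulation epochs, total length."""

    pre_baseline_s: float
    epochs: tuple
    inter_epoch_gap_s: float
    total_duration_s: float

    def __post_init__(self) -> None:
        eps = tuple(self.epochs)
        if eps:
            if abs(eps[0].start_s - self.pre_baseline_s) > 1e-9:
                raise ValueError("first epoch must start at pre_baseline_s")
            for a, b in zip(eps, eps[1:]):
                if b.start_s < a.end_s:
                    raise ValueError("overlapping stimulation epochs")
            if eps[-1].end_s > self.total_duration_s + 1e-9:
                raise ValueError("protocol shorter than its last epoch")
        object.__setattr__(self, "epochs", eps)

    def to_dict(self) -> dict:
        return {
            "pre_baseline_s": self.pre_baseline_s,
            "inter_epoch_gap_s": self.inter_epoch_gap_s,
            "total_duration_s": self.total_duration_s,
            "epochs": [vars(e).copy() for e in self.epochs],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ProtocolSpec":
        return cls(
            pre_baseline_s=d["pre_baseline_s"],
            epochs=tuple(StimulusEpoch(**e) for e in d["epochs"]),
            inter_epoch_gap_s=d["inter_epoch_gap_s"],
            total_duration_s=d["total_duration_s"],
        )


def make_protocol(
    preset: str = "standard",
    *,
    pre_baseline_s: float = 60.0,
    epoch_duration_s: float = 60.0,
    intensities_ua: Sequence[float] = (100.0, 150.0, 200.0),
    frequency_hz: float | None = None,
    pulse_width_us: float = 60.0,
    inter_epoch_gap_s: float | None = None,
    tail_s: float = 60.0,
    waveform: str = "monophasic-cathodic",
    labels: Sequence[str] | None = None,
) -> ProtocolSpec:
    """Build a stimulation protocol.

    Presets: ``standard`` = 60-s baseline, then one 60-s train per entry of
    ``intensities_ua`` (default 100/150/200 uA, 130 Hz, 60 us) with 5-min
    gaps; ``lowfreq`` = identical but 20 Hz; ``single_epoch`` = one 120-s
    epoch at 150 uA after a 60-s baseline; ``baseline_only`` = no epochs.
    Keyword arguments override preset defaults.
    """
    if preset == "standard":
        freq = 130.0 if frequency_hz is None else frequency_hz
        gap = 300.0 if inter_epoch_gap_s is None else inter_epoch_gap_s
    elif preset == "lowfreq":
        freq = 20.0 if frequency_hz is None else frequency_hz
        gap = 300.0 if inter_epoch_gap_s is None else inter_epoch_gap_s
    elif preset == "single_epoch":
        freq = 130.0 if frequency_hz is None else frequency_hz
        gap = 0.0 if inter_epoch_gap_s is None else inter_epoch_gap_s
        intensities_ua = intensities_ua if len(intensities_ua) == 1 else (150.0,)
        epoch_duration_s = 120.0 if epoch_duration_s == 60.0 else epoch_duration_s
    elif preset == "baseline_only":
        intensities_ua = ()
        freq, gap = 130.0, 0.0
    else:
        raise ValueError(f"unknown protocol preset {preset!r}")

    epochs = []
    start = pre_baseline_s
    for i, amp in enumerate(intensities_ua):
        epochs.append(
            StimulusEpoch(
                start_s=start,
                duration_s=epoch_duration_s,
                frequency_hz=freq,
                pulse_width_us=pulse_width_us,
                intensity_ua=float(amp),
                waveform=waveform,
                label=None if labels is None else labels[i],
            )
        )
        start += epoch_duration_s + gap
    total = (epochs[-1].end_s if epochs else pre_baseline_s) + tail_s
    return ProtocolSpec(
        pre_baseline_s=pre_baseline_s,
        epochs=tuple(epochs),
        inter_epoch_gap_s=gap,
        total_duration_s=total,
    )


@dataclass(frozen=True)
class ChannelDynamicsSpec:
    """Ground-truth dynamics of one fluorophore channel.

    plateau_effect_pct and artifact_effect_pct are per-epoch percent
    changes at plateau (the artifact term mimics the small non-sensor
    fluorescence change seen with non-responsive parent fluorophores);
    they add inside e(t).  transient_bump is an optional brief initial
    excursion (amplitude_pct, width_s) at epoch onset.
    """

    name: str
    fluorophore: str
    baseline_amplitude: float
    bleach_fraction_per_min: float = 0.02
    plateau_effect_pct: tuple = ()
    artifact_effect_pct: tuple = ()
    onset_tau_s: float = 0.0
    offset_tau_s: float = 0.0
    transient_bump: tuple | None = None  # (amplitude_pct, width_s)
    bleach_model: str = "linear"  # or "exponential"

    def __post_init__(self) -> None:
        if self.baseline_amplitude <= 0:
            raise ValueError("baseline_amplitude must be positive")
        if self.onset_tau_s < 0 or self.offset_tau_s < 0:
            raise ValueError("time constants must be >= 0")
        if any(p <= -100 for p in self.plateau_effect_pct):
            raise ValueError("plateau_effect_pct must exceed -100")
        if self.bleach_model not in ("linear", "exponential"):
            raise ValueError("bleach_model must be 'linear' or 'exponential'")

    def effect_for_epoch(self, i: int) -> float:
        p = self.plateau_effect_pct[i] if i < len(self.plateau_effect_pct) else 0.0
        a = self.artifact_effect_pct[i] if i < len(self.artifact_effect_pct) else 0.0
        return float(p) + float(a)


@dataclass(frozen=True)
class NoiseSpec:
    """Frame-noise model: additive Gaussian plus optional sqrt-signal term."""

    additive_sd: float
    signal_scaled_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.signal_scaled_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class TrueTraces:
    """Noiseless per-channel abundances a_k(t) and percent effects e_k(t)."""

    frame_times: np.ndarray
    frame_rate: float
    abundance: dict  # channel -> a(t)
    effect_pct: dict  # channel -> e(t)
    dynamics: tuple  # ChannelDynamicsSpec, in channel order
    protocol: ProtocolSpec

    @property
    def channels(self) -> list[str]:
        return [d.name for d in self.dynamics]


def _effect_trace(
    t: np.ndarray, spec: ChannelDynamicsSpec, protocol: ProtocolSpec
) -> np.ndarray:
    """Piecewise first-order relaxation of e(t) across epoch boundaries."""
    e = np.zeros_like(t)
    boundaries = []  # (t_start, t_end, target, tau)
    prev_end = 0.0
    for i, ep in enumerate(protocol.epochs):
        boundaries.append((prev_end, ep.start_s, 0.0, spec.offset_tau_s))
        boundaries.append(
            (ep.start_s, ep.end_s, spec.effect_for_epoch(i), spec.onset_tau_s)
        )
        prev_end = ep.end_s
    boundaries.append((prev_end, np.inf, 0.0, spec.offset_tau_s))

    e0 = 0.0
    for t0, t1, target, tau in boundaries:
        mask = (t >= t0) & (t < t1)
        if tau == 0.0:
            e[mask] = target
            e_end = target
        else:
            e[mask] = target + (e0 - target) * np.exp(-(t[mask] - t0) / tau)
            e_end = (
                target
                if not np.isfinite(t1)
                else target + (e0 - target) * np.exp(-(t1 - t0) / tau)
            )
        e0 = e_end

    if spec.transient_bump is not None:
        amp, width = spec.transient_bump
        for ep in protocol.epochs:
            mask = (t >= ep.start_s) & (t < ep.end_s)
            e[mask] += amp * np.exp(-(t[mask] - ep.start_s) / width)
    return e


def _bleach_factor(t: np.ndarray, spec: ChannelDynamicsSpec) -> np.ndarray:
    b = spec.bleach_fraction_per_min
    if spec.bleach_model == "linear":
        return 1.0 - b * t / 60.0
    return np.exp(-b * t / 60.0)


def simulate_true_traces(
    dynamics: Sequence[ChannelDynamicsSpec],
    protocol: ProtocolSpec,
    frame_rate: float = 25.0,
) -> TrueTraces:
    """Noiseless coefficient traces for every channel of a session."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n = int(round(protocol.total_duration_s * frame_rate))
    t = np.arange(n) / frame_rate
    abundance, effect = {}, {}
    for spec in dynamics:
        e = _effect_trace(t, spec, protocol)
        a = spec.baseline_amplitude * _bleach_factor(t, spec) * (1.0 + e / 100.0)
        if np.any(a <= 0):
            raise ValueError(
                f"channel {spec.name!r}: bleaching drives abundance to zero "
                "within the session"
            )
        abundance[spec.name] = a
        effect[spec.name] = e
    return TrueTraces(
        frame_times=t,
        frame_rate=frame_rate,
        abundance=abundance,
        effect_pct=effect,
        dynamics=tuple(dynamics),
        protocol=protocol,
    )


def response_window(epoch: StimulusEpoch, policy: str) -> tuple[float, float]:
    """[t_start, t_end) summary window for an epoch under a window policy."""
    if policy == "last_half_mean":
        return (epoch.start_s + epoch.duration_s / 2.0, epoch.end_s)
    if policy in ("full_epoch_mean", "peak"):
        return (epoch.start_s, epoch.end_s)
    raise ValueError(f"unknown window policy {policy!r}")


@dataclass
class GroundTruthRecord:
    """Generator ground truth: noiseless traces and window-averaged effects.

    true_effect_pct[epoch][channel] is the window mean of e(t);
    true_ratio_effect_pct[epoch][sensor] is the window mean of the exact
    sensor/control ratio change 100*((1+e_s/100)/(1+e_c/100)-1), the
    quantity the ratiometric pipeline estimates.
    """

    traces: TrueTraces
    control: str
    window_policy: str
    true_effect_pct: list  # per epoch: {channel: pct}
    true_ratio_effect_pct: list  # per epoch: {sensor: pct}
    params: dict = field(default_factory=dict)

    @property
    def sensors(self) -> list[str]:
        return [c for c in self.traces.channels if c != self.control]

    def to_dict(self, include_traces: bool = True) -> dict:
        d = {
            "control": self.control,
            "window_policy": self.window_policy,
            "true_effect_pct": self.true_effect_pct,
            "true_ratio_effect_pct": self.true_ratio_effect_pct,
            "params": self.params,
        }
        if include_traces:
            d["frame_times"] = self.traces.frame_times.tolist()
            d["abundance"] = {
                k: v.tolist() for k, v in self.traces.abundance.items()
            }
            d["effect_pct"] = {
                k: v.tolist() for k, v in self.traces.effect_pct.items()
            }
        return d


def ground_truth_record(
    traces: TrueTraces,
    control: str,
    window_policy: str = DEFAULT_WINDOW_POLICY,
    params: dict | None = None,
) -> GroundTruthRecord:
    t = traces.frame_times
    per_epoch_effect, per_epoch_ratio = [], []
    e_c = traces.effect_pct[control]
    for ep in traces.protocol.epochs:
        lo, hi = response_window(ep, window_policy)
        mask = (t >= lo) & (t < hi)
        eff = {
            ch: float(np.mean(traces.effect_pct[ch][mask]))
            for ch in traces.channels
        }
        ratio = {}
        for ch in traces.channels:
            if ch == control:
                continue
            r = 100.0 * (
                (1.0 + traces.effect_pct[ch][mask] / 100.0)
                / (1.0 + e_c[mask] / 100.0)
                - 1.0
            )
            ratio[ch] = float(np.mean(r))
        per_epoch_effect.append(eff)
        per_epoch_ratio.append(ratio)
    return GroundTruthRecord(
        traces=traces,
        control=control,
        window_policy=window_policy,
        true_effect_pct=per_epoch_effect,
        true_ratio_effect_pct=per_epoch_ratio,
        params=params or {},
    )


def synthesize_frames(
    true_traces: TrueTraces,
    refset: ReferenceSet,
    noise: NoiseSpec,
    control: str | None = None,
    window_policy: str = DEFAULT_WINDOW_POLICY,
    params: dict | None = None,
) -> tuple[SpectralFrameSeries, GroundTruthRecord]:
    """Mix true traces through the reference spectra and add frame noise.

    The reference set's fluorophore ids must equal the channel names of
    ``true_traces`` (same set, any order).  Identical seeds give
    bit-identical frames.
    """
    channels = true_traces.channels
    if set(refset.fluorophores) != set(channels):
        raise ValueError(
            f"reference set channels {refset.fluorophores} do not match "
            f"trace channels {channels}"
        )
    refset = refset.subset(channels)
    A = np.column_stack([true_traces.abundance[c] for c in channels])
    clean = A @ refset.mixing_matrix.T
    rng = np.random.default_rng(noise.seed)
    frames = clean.copy()
    if noise.additive_sd > 0:
        frames += rng.normal(0.0, noise.additive_sd, size=clean.shape)
    if noise.signal_scaled_sd > 0:
        frames += rng.normal(0.0, 1.0, size=clean.shape) * (
            noise.signal_scaled_sd * np.sqrt(np.clip(clean, 0.0, None))
        )
    series = SpectralFrameSeries(
        grid=refset.grid,
        frame_times=true_traces.frame_times,
        frames=frames,
        frame_rate=true_traces.frame_rate,
        background_subtracted=True,
    )
    if control is None:
        control = channels[-1]
    truth = ground_truth_record(true_traces, control, window_policy, params)
    return series, truth


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    protocol_name: str
    control: str
    channel_params: dict  # channel -> raw dict from YAML
    conditions: dict | None = None  # condition -> {channel: [plateau per epoch]}

    @property
    def channels(self) -> list[str]:
        return list(self.channel_params)

    @property
    def sensors(self) -> list[str]:
        return [c for c in self.channels if c != self.control]

    @property
    def condition_names(self) -> list[str] | None:
        return None if self.conditions is None else list(self.conditions)

    def total_baseline_amplitude(self) -> float:
        return float(
            sum(p["baseline_amplitude"] for p in self.channel_params.values())
        )

    def dynamics(self, condition: str | None = None) -> list[ChannelDynamicsSpec]:
        specs = []
        for name, raw in self.channel_params.items():
            raw = dict(raw)
            plateau = raw.pop("plateau_effect_pct", [])
            if self.conditions is not None:
                if condition is None:
                    raise ValueError(
                        f"preset {self.name!r} requires a condition, one of "
                        f"{self.condition_names}"
                    )
                plateau = self.conditions[condition].get(name, [])
            bump = raw.pop("transient_bump", None)
            specs.append(
                ChannelDynamicsSpec(
                    name=name,
                    fluorophore=raw.pop("fluorophore"),
                    baseline_amplitude=raw.pop("baseline_amplitude"),
                    bleach_fraction_per_min=raw.pop("bleach_fraction_per_min", 0.02),
                    plateau_effect_pct=tuple(plateau),
                    artifact_effect_pct=tuple(raw.pop("artifact_effect_pct", [])),
                    onset_tau_s=raw.pop("onset_tau_s", 0.0),
                    offset_tau_s=raw.pop("offset_tau_s", 0.0),
                    transient_bump=None
                    if bump is None
                    else (bump["amplitude_pct"], bump["width_s"]),
                )
            )
            if raw:
                raise ValueError(f"unknown channel parameters: {sorted(raw)}")
        return specs

    def reference_set(self, grid_step_nm: float = 1.0) -> ReferenceSet:
        """Per-channel reference spectra, named by channel (not shape)."""
        wl = np.arange(480.0, 650.0 + grid_step_nm / 2, grid_step_nm)
        grid = WavelengthGrid(wl)
        spectra = []
        for name, raw in self.channel_params.items():
            shape = BUILTIN_SHAPE_PARAMS[raw["fluorophore"]]
            spectra.append(
                peak_normalize(
                    EmissionSpectrum(name, grid, skewed_gaussian(wl, *shape))
                )
            )
        return ReferenceSet.from_spectra(spectra)


def _presets_raw() -> dict:
    with (resources.files("specphot") / "data" / "presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_presets() -> dict:
    """The raw preset parameter tables (one packaged YAML file)."""
    return copy.deepcopy(_presets_raw())


def list_presets() -> list[str]:
    return list(_presets_raw())


def get_preset(name: str) -> Preset:
    raw = _presets_raw()
    if name not in raw:
        raise KeyError(f"unknown preset {name!r}; available: {list(raw)}")
    d = raw[name]
    return Preset(
        name=name,
        description=d.get("description", ""),
        protocol_name=d.get("protocol", "standard"),
        control=d["control"],
        channel_params=copy.deepcopy(d["channels"]),
        conditions=copy.deepcopy(d.get("conditions")),
    )


def subject_seed(seed: int, subject: int) -> int:
    """Deterministic per-subject seed derived from the run seed."""
    return int((int(seed) + int(subject)) % (2**31))


@dataclass
class SimulatedSession:
    """One synthetic recording: frames, references, protocol, ground truth."""

    series: SpectralFrameSeries
    refset: ReferenceSet
    protocol: ProtocolSpec
    truth: GroundTruthRecord
    preset: str
    condition: str | None = None
    seed: int = 0

    @property
    def control(self) -> str:
        return self.truth.control

    @property
    def sensors(self) -> list[str]:
        return self.truth.sensors


def simulate_session(
    preset: str | Preset,
    seed: int = 0,
    condition: str | None = None,
    frame_rate: float = 25.0,
    grid_step_nm: float = 1.0,
    inter_epoch_gap_s: float | None = None,
    noise_scale: float = 1.0,
    signal_scaled_sd: float = 0.0,
    window_policy: str = DEFAULT_WINDOW_POLICY,
) -> SimulatedSession:
    """Generate one synthetic subject session for a named preset.

    Default noise is additive Gaussian with sd = 1% of the summed channel
    baseline amplitudes; ``noise_scale=0`` gives a noiseless session.
    ``frame_rate``, ``grid_step_nm`` and ``inter_epoch_gap_s`` allow
    scaled-down sessions for quick tests.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    protocol = make_protocol(
        preset.protocol_name, inter_epoch_gap_s=inter_epoch_gap_s
    )
    if preset.conditions is not None and condition is None:
        raise ValueError(
            f"preset {preset.name!r} has conditions {preset.condition_names}; "
            "pass condition="
        )
    dyn = preset.dynamics(condition)
    traces = simulate_true_traces(dyn, protocol, frame_rate)
    refset = preset.reference_set(grid_step_nm)
    noise = NoiseSpec(
        additive_sd=0.01 * preset.total_baseline_amplitude() * noise_scale,
        signal_scaled_sd=signal_scaled_sd,
        seed=seed,
    )
    params = {
        "preset": preset.name,
        "condition": condition,
        "seed": seed,
        "frame_rate": frame_rate,
        "grid_step_nm": grid_step_nm,
        "noise_scale": noise_scale,
        "channels": copy.deepcopy(preset.channel_params),
    }
    series, truth = synthesize_frames(
        traces,
        refset,
        noise,
        control=preset.control,
        window_policy=window_policy,
        params=params,
    )
    return SimulatedSession(
        series=series,
        refset=refset,
        protocol=protocol,
        truth=truth,
        preset=preset.name,
        condition=condition,
        seed=seed,
    )
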