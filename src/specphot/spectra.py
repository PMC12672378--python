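"""Domain types and I/O for emission spectra and spectral frame series.

Spectrally resolved fiber photometry acquires a full fluorescence emission
spectrum per frame instead of a single band-integrated intensity.  This
module holds the wavelength axis, per-fluorophore reference emission shapes
:math:`S_k(\\lambda)`, the mixing matrix :math:`M` whose columns are those
shapes, and the frames x wavelengths intensity matrix of a recording, plus
the plain-text formats used to exchange them.

All intensities are arbitrary detector counts; no radiometric calibration
is applied anywhere in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "EmissionSpectrum",
    "ReferenceSet",
    "SpectralFrameSeries",
    "BackgroundSpectrum",
    "SingularReferenceError",
    "peak_normalize",
    "resample_to_grid",
    "subtract_background",
    "read_reference_spectra",
    "write_reference_spectra",
    "read_frame_series",
    "write_frame_series",
    "read_background",
    "skewed_gaussian",
    "builtin_reference_set",
    "BUILTIN_SHAPE_PARAMS",
]

#: Ill-conditioning above this raises; see ReferenceSet.
_SINGULAR_CONDITION = 1e12
#: Ill-conditioning above this only warns (unmixing still defined).
_WARN_CONDITION = 1e6


class SingularReferenceError(ValueError):
    """Raised when a reference set is rank deficient (singular reference set)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres (length >= 2)."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid needs at least 2 wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return self.wavelengths.size

    def matches(self, other: "WavelengthGrid", atol: float = 1e-9) -> bool:
        return len(self) == len(other) and np.allclose(
            self.wavelengths, other.wavelengths, rtol=0.0, atol=atol
        )


@dataclass(frozen=True)
class EmissionSpectrum:
    """One fluorophore's emission shape sampled on a wavelength grid."""

    fluorophore_id: str
    grid: WavelengthGrid
    intensities: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.grid),):
            raise ValueError("intensities length must match grid")
        if np.any(y < 0):
            raise ValueError("emission intensities must be non-negative")
        if self.normalized and y.max() != 1.0:
            raise ValueError("normalized spectrum must have max exactly 1")
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class BackgroundSpectrum:
    """Spectrometer background (room-lights-off) in the same counts as frames."""

    grid: WavelengthGrid
    intensities: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.grid),):
            raise ValueError("background length must match grid")
        object.__setattr__(self, "intensities", y)


def peak_normalize(spectrum: EmissionSpectrum) -> EmissionSpectrum:
    """Scale a spectrum so its maximum is exactly 1 (shape preserved)."""
    peak = float(np.max(spectrum.intensities))
    if peak <= 0:
        raise ValueError("cannot peak-normalize an all-zero spectrum")
    y = spectrum.intensities / peak
    # guard against rounding: the maximal element must be exactly 1
    y[np.argmax(y)] = 1.0
    return replace(spectrum, intensities=y, normalized=True)


def resample_to_grid(
    spectrum: EmissionSpectrum, target: WavelengthGrid
) -> EmissionSpectrum:
    """Linearly interpolate a spectrum onto ``target`` (no extrapolation).

    Linear (not spline) interpolation is used deliberately: it is monotone
    between samples and cannot overshoot into negative intensities.
    """
    src = spectrum.grid.wavelengths
    tgt = target.wavelengths
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ValueError(
            f"target grid [{tgt[0]}, {tgt[-1]}] extends beyond source "
            f"range [{src[0]}, {src[-1]}]"
        )
    y = np.interp(tgt, src, spectrum.intensities)
    return EmissionSpectrum(spectrum.fluorophore_id, target, y, normalized=False)


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered reference spectra on one shared grid and their mixing matrix.

    The mixing matrix M is (n_wavelengths x K) with column k the
    peak-normalized emission shape of fluorophore k; it must have full
    column rank for unmixing to be identifiable.
    """

    spectra: tuple
    mixing_matrix: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_spectra(cls, spectra: Sequence[EmissionSpectrum]) -> "ReferenceSet":
        if len(spectra) < 1:
            raise ValueError("reference set needs K >= 1 spectra")
        grid = spectra[0].grid
        normed = []
        for s in spectra:
            if not s.grid.matches(grid):
                raise ValueError("all reference spectra must share one grid")
            normed.append(s if s.normalized else peak_normalize(s))
        M = np.column_stack([s.intensities for s in normed])
        sv = np.linalg.svd(M, compute_uv=False)
        cond = np.inf if sv[-1] == 0 else float(sv[0] / sv[-1])
        if not np.isfinite(cond) or cond > _SINGULAR_CONDITION:
            raise SingularReferenceError(
                f"singular reference set (condition number {cond:.3g})"
            )
        if cond > _WARN_CONDITION:
            warnings.warn(
                f"reference set is ill-conditioned (condition number {cond:.3g})",
                stacklevel=2,
            )
        return cls(spectra=tuple(normed), mixing_matrix=M)

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    @property
    def fluorophores(self) -> list[str]:
        return [s.fluorophore_id for s in self.spectra]

    @property
    def n_fluorophores(self) -> int:
        return len(self.spectra)

    def condition_number(self) -> float:
        """Condition number of the L2-column-normalized mixing matrix."""
        M = self.mixing_matrix
        sv = np.linalg.svd(M / np.linalg.norm(M, axis=0), compute_uv=False)
        return float(sv[0] / sv[-1])

    def subset(self, fluorophores: Sequence[str]) -> "ReferenceSet":
        by_id = {s.fluorophore_id: s for s in self.spectra}
        missing = [f for f in fluorophores if f not in by_id]
        if missing:
            raise KeyError(f"fluorophores not in reference set: {missing}")
        return ReferenceSet.from_spectra([by_id[f] for f in fluorophores])


@dataclass(frozen=True)
class SpectralFrameSeries:
    """Time-lapsed emission spectra: one full spectrum per acquisition frame.

    frame_times are seconds from recording start and must agree with the
    nominal frame rate to one part in 1e6 per inter-frame interval (frames
    are hardware-triggered by TTL pulses, so the time base is rigid).
    Before background subtraction all counts are non-negative; afterwards
    small negative excursions are ordinary noise.
    """

    grid: WavelengthGrid
    frame_times: np.ndarray
    frames: np.ndarray
    frame_rate: float
    integration_time_ms: float = 30.0
    background_subtracted: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        F = np.asarray(self.frames, dtype=float)
        if F.ndim != 2 or F.shape != (t.size, len(self.grid)):
            raise ValueError("frames must be (n_frames, n_wavelengths)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(t)
        nominal = 1.0 / self.frame_rate
        if t.size >= 2 and np.any(np.abs(dt - nominal) > 1e-6 * nominal):
            raise ValueError("frame_times inconsistent with frame_rate (>1 ppm)")
        if not self.background_subtracted and np.any(F < 0):
            raise ValueError("negative counts before background subtraction")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "frames", F)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0])


def subtract_background(
    series: SpectralFrameSeries, bg: BackgroundSpectrum
) -> SpectralFrameSeries:
    """Subtract the spectrometer background spectrum from every frame."""
    if not series.grid.matches(bg.grid):
        raise ValueError("background grid does not match frame series grid")
    if series.background_subtracted:
        warnings.warn(
            "background already subtracted; subtracting again", stacklevel=2
        )
    return replace(
        series, frames=series.frames - bg.intensities, background_subtracted=True
    )


# ---------------------------------------------------------------------------
# Plain-text formats
# ---------------------------------------------------------------------------
# Reference spectra CSV: header "wavelength_nm,<fluor_1>,<fluor_2>,...",
# one row per wavelength.  Frame series CSV: header "time_s,<l1>,<l2>,..."
# with wavelengths in nm as column names, one row per frame.  Background
# CSV: "wavelength_nm,intensity".  Floats are written with repr precision
# so write -> read round-trips exactly.

_FLOAT_FMT = "%.17g"


def read_reference_spectra(path: str | Path) -> ReferenceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2 or df.columns[0] != "wavelength_nm":
        raise ValueError(
            "reference CSV must have header 'wavelength_nm,<fluor_1>,...'"
        )
    if df.shape[0] < 2:
        raise ValueError("reference CSV needs at least 2 wavelengths")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths in reference CSV must be strictly increasing")
    grid = WavelengthGrid(wl)
    spectra = []
    for name in df.columns[1:]:
        y = df[name].to_numpy(dtype=float)
        if np.all(y == 0):
            raise ValueError(f"all-zero reference column: {name!r}")
        spectra.append(peak_normalize(EmissionSpectrum(str(name), grid, y)))
    return ReferenceSet.from_spectra(spectra)


def write_reference_spectra(refset: ReferenceSet, path: str | Path) -> None:
    data = {"wavelength_nm": refset.grid.wavelengths}
    for s in refset.spectra:
        data[s.fluorophore_id] = s.intensities
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_frame_series(
    path: str | Path,
    frame_rate: float | None = None,
    background_subtracted: bool = True,
) -> SpectralFrameSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "time_s":
        raise ValueError("frame CSV must have header 'time_s,<l1>,<l2>,...'")
    t = df["time_s"].to_numpy(dtype=float)
    wl = np.array([float(c) for c in df.columns[1:]])
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    return SpectralFrameSeries(
        grid=WavelengthGrid(wl),
        frame_times=t,
        frames=df.iloc[:, 1:].to_numpy(dtype=float),
        frame_rate=frame_rate,
        background_subtracted=background_subtracted,
    )


def write_frame_series(series: SpectralFrameSeries, path: str | Path) -> None:
    cols = ["time_s"] + [repr(float(w)) for w in series.grid.wavelengths]
    df = pd.DataFrame(
        np.column_stack([series.frame_times, series.frames]), columns=cols
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_background(path: str | Path) -> BackgroundSpectrum:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["wavelength_nm", "intensity"]:
        raise ValueError("background CSV must have header 'wavelength_nm,intensity'")
    return BackgroundSpectrum(
        WavelengthGrid(df["wavelength_nm"].to_numpy(dtype=float)),
        df["intensity"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Built-in reference shapes
# ---------------------------------------------------------------------------
# The sensors' tabulated emission spectra are not published; these skewed
# Gaussians (narrower blue flank, long red tail, peaks at the fluorophores'
# nominal emission maxima) are documented approximations.  User-supplied
# reference files override them everywhere.

#: fluorophore -> (peak_nm, sigma_left_nm, sigma_right_nm)
BUILTIN_SHAPE_PARAMS: dict[str, tuple[float, float, float]] = {
    "gcamp": (512.0, 14.0, 36.0),
    "gfp": (510.0, 13.0, 30.0),
    "venus": (528.0, 14.0, 38.0),
    "tdtomato": (581.0, 13.0, 33.0),
}

_BUILTIN_GRID = np.arange(480.0, 651.0, 1.0)


def skewed_gaussian(
    wavelengths: np.ndarray, peak: float, sigma_left: float, sigma_right: float
) -> np.ndarray:
    """Two-sided Gaussian emission shape with unit peak."""
    wl = np.asarray(wavelengths, dtype=float)
    sigma = np.where(wl < peak, sigma_left, sigma_right)
    return np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


def _builtin_data_path(name: str) -> Path:
    return Path(resources.files("specphot") / "data" / name)


def builtin_reference_set(
    fluorophores: Sequence[str] | None = None,
) -> ReferenceSet:
    """Load the packaged approximate reference spectra (480-650 nm, 1 nm).

    Parameters
    ----------
    fluorophores
        Subset and order of fluorophores to keep; default all four
        (gcamp, gfp, venus, tdtomato).
    """
    refset = read_reference_spectra(_builtin_data_path("reference_spectra.csv"))
    if fluorophores is not None:
        refset = refset.subset(list(fluorophores))
    return refset


def _generate_builtin_csv(path: str | Path) -> None:
    """Regenerate the packaged reference CSV from BUILTIN_SHAPE_PARAMS."""
    grid = WavelengthGrid(_BUILTIN_GRID)
    spectra = [
        peak_normalize(EmissionSpectrum(name, grid, skewed_gaussian(grid.wavelengths, *p)))
        for name, p in BUILTIN_SHAPE_PARAMS.items()
    ]
    write_reference_spectra(ReferenceSet.from_spectra(spectra), path)
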