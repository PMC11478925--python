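"""Core data containers for single-voxel MRS signals and spectra.

Conventions used throughout the package:

* Time-domain signals (FIDs) are complex arrays sampled at ``dwell_s``.
* Frequency-domain spectra are stored frequency-ascending, which for 1H
  means ppm-ascending; display code reverses the axis (high ppm on the
  left) at render time only.
* The transmitter is assumed on-resonance with water, so the centre of
  the spectral window sits at 4.7 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

#: Gyromagnetic ratio of 1H in MHz/T.
GAMMA_1H_MHZ_PER_T = 42.577478

#: Chemical shift of water, used as the carrier reference (ppm).
WATER_PPM = 4.7


@dataclass(frozen=True)
class AcquisitionParams:
    """Single-voxel PRESS acquisition settings.

    Defaults correspond to a 1.5 T short-echo protocol: TE 30 ms,
    TR 1500 ms, 2048 complex points at ~1.024 Hz per point, cubic voxel,
    128 water-suppressed and 8 water-reference averages.
    """

    field_strength_t: float = 1.5
    te_ms: float = 30.0
    tr_ms: float = 1500.0
    n_points: int = 2048
    bandwidth_hz: float = 2097.152
    voxel_edge_cm: float = 2.0
    n_averages: int = 128
    n_water_averages: int = 8

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.te_ms <= 0:
            raise ValueError("te_ms must be positive")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be positive")

    @property
    def transmitter_freq_mhz(self) -> float:
        """Larmor frequency of 1H at this field strength (MHz)."""
        return GAMMA_1H_MHZ_PER_T * self.field_strength_t

    @property
    def hz_per_point(self) -> float:
        return self.bandwidth_hz / self.n_points

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.bandwidth_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dwell_s


SignalKind = Literal["water_suppressed", "water_reference"]


@dataclass
class TimeSignal:
    """A complex FID with its acquisition metadata."""

    samples: np.ndarray
    params: AcquisitionParams
    kind: SignalKind = "water_suppressed"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("FID samples must be one-dimensional")
        if len(self.samples) != self.params.n_points:
            raise ValueError(
                f"FID length {len(self.samples)} does not match "
                f"n_points {self.params.n_points}"
            )
        if self.kind not in ("water_suppressed", "water_reference"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    @property
    def dwell_s(self) -> float:
        return self.params.dwell_s

    def copy(self) -> "TimeSignal":
        return TimeSignal(self.samples.copy(), self.params, self.kind)


def ppm_axis(params: AcquisitionParams, n_total: int | None = None) -> np.ndarray:
    """Frequency-ascending ppm axis for a spectrum of ``n_total`` points.

    The carrier (0 Hz offset, centre bin after fftshift) maps to water at
    4.7 ppm; chemical shift increases with frequency offset.
    """
    n = params.n_points if n_total is None else n_total
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=params.dwell_s))
    return WATER_PPM + freqs / params.transmitter_freq_mhz


def ppm_to_hz(ppm: float | np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Offset from the carrier (water) in Hz for a chemical shift in ppm."""
    return (np.asarray(ppm, dtype=float) - WATER_PPM) * params.transmitter_freq_mhz


def hz_to_ppm(hz: float | np.ndarray, params: AcquisitionParams) -> np.ndarray:
    return WATER_PPM + np.asarray(hz, dtype=float) / params.transmitter_freq_mhz


NormalizationTag = Literal["raw", "water_normalized"]


@dataclass
class Spectrum:
    """A complex frequency-domain spectrum on an ascending ppm axis."""

    values: np.ndarray
    ppm: np.ndarray
    params: AcquisitionParams
    normalization: NormalizationTag = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.values.shape != self.ppm.shape:
            raise ValueError("spectrum values and ppm axis must have equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotonic")

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    @property
    def hz_per_point(self) -> float:
        return float(abs(self.ppm[1] - self.ppm[0]) * self.params.transmitter_freq_mhz)

    def window_mask(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        return (self.ppm >= lo_ppm) & (self.ppm <= hi_ppm)

    def copy(self) -> "Spectrum":
        return Spectrum(self.values.copy(), self.ppm.copy(), self.params, self.normalization)

    def with_values(self, values: np.ndarray, **kwargs) -> "Spectrum":
        spec = Spectrum(values, self.ppm.copy(), self.params, self.normalization)
        for k, v in kwargs.items():
            setattr(spec, k, v)
        return spec


__all__ = [
    "GAMMA_1H_MHZ_PER_T",
    "WATER_PPM",
    "AcquisitionParams",
    "TimeSignal",
    "Spectrum",
    "ppm_axis",
    "ppm_to_hz",
    "hz_to_ppm",
    "replace",
]
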