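"""Metabolite and macromolecule basis set for linear-combination fitting.

The default basis mirrors a short-echo (TE 30 ms) 1.5 T tumour basis:
16 metabolites, nine broad lipid/macromolecule (MM) components and a
negative creatine-CH2 correction singlet at 3.94 ppm, 26 components in
all.  Multiplets are approximated by small fixed peak lists (chemical
shift, relative amplitude, linewidth, lineshape); no density-matrix
simulation is attempted.  Peak amplitudes within a component are
normalised so the component FID starts at unit (signed) amplitude per
mM, which makes fitted amplitudes directly comparable to
concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core import WATER_PPM, AcquisitionParams, ppm_to_hz

MM_GROUP_CENTRES = {"MMLip09": 0.9, "MMLip13": 1.3, "MMLip20": 2.0}


@dataclass(frozen=True)
class Peak:
    """A single resonance line."""

    ppm: float
    amplitude: float
    linewidth_hz: float = 3.0
    lineshape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not 0.0 <= self.ppm <= 5.5:
            raise ValueError(f"chemical shift {self.ppm} ppm out of range")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth must be positive")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")


@dataclass(frozen=True)
class ResonanceModel:
    """A named basis component built from one or more peaks.

    ``tag`` is "metabolite", "mmlip" or "reference"; MM/lipid components
    additionally carry ``group`` (MMLip09 / MMLip13 / MMLip20), the
    nearest of 0.9, 1.3 and 2.0 ppm to the component's amplitude-weighted
    centre.
    """

    name: str
    peaks: tuple[Peak, ...]
    tag: str = "metabolite"
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"component {self.name!r} has no peaks")
        negatives = [p for p in self.peaks if p.amplitude < 0]
        if negatives and self.name != "-CrCH2":
            raise ValueError(
                f"negative amplitudes only permitted for -CrCH2, not {self.name!r}"
            )

    @property
    def centre_ppm(self) -> float:
        w = np.array([abs(p.amplitude) for p in self.peaks])
        c = np.array([p.ppm for p in self.peaks])
        return float(np.sum(w * c) / np.sum(w))

    def fid(self, params: AcquisitionParams, extra_broaden_hz: float = 0.0,
            shift_ppm: float = 0.0) -> np.ndarray:
        """Unit-concentration FID of this component.

        ``extra_broaden_hz`` adds Lorentzian damping; ``shift_ppm``
        displaces every peak (used by the fitter's frequency search).
        """
        t = params.time_axis()
        out = np.zeros(params.n_points, dtype=np.complex128)
        for p in self.peaks:
            df = ppm_to_hz(p.ppm + shift_ppm, params)
            osc = np.exp(2j * np.pi * df * t)
            if p.lineshape == "lorentzian":
                decay = np.exp(-np.pi * p.linewidth_hz * t)
            else:  # gaussian
                decay = np.exp(-((np.pi * p.linewidth_hz * t) ** 2) / (4.0 * np.log(2.0)))
            if extra_broaden_hz > 0:
                decay = decay * np.exp(-np.pi * extra_broaden_hz * t)
            out += p.amplitude * osc * decay
        return out


@dataclass
class BasisSet:
    """Ordered collection of uniquely named resonance models."""

    components: list[ResonanceModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        self._index = {c.name: i for i, c in enumerate(self.components)}

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self) -> Iterator[ResonanceModel]:
        return iter(self.components)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> ResonanceModel:
        try:
            return self.components[self._index[name]]
        except KeyError:
            raise KeyError(f"unknown basis component {name!r}") from None

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def metabolite_names(self) -> list[str]:
        return [c.name for c in self.components if c.tag == "metabolite"]

    def mmlip_names(self) -> list[str]:
        return [c.name for c in self.components if c.tag == "mmlip"]


def _normalise(peaks: list[tuple], lineshape: str = "lorentzian",
               linewidth: float = 3.0) -> tuple[Peak, ...]:
    """Scale amplitudes so |sum| = 1 (unit FID start per mM)."""
    total = abs(sum(a for _, a in peaks))
    return tuple(
        Peak(ppm, a / total, linewidth_hz=linewidth, lineshape=lineshape)
        for ppm, a in peaks
    )


# Approximate multiplet positions for the 16-metabolite short-echo basis.
# Amplitudes are proton-weight ratios within each component (normalised).
_METABOLITE_PEAKS: dict[str, list[tuple]] = {
    "Ala": [(1.47, 3.0), (3.78, 1.0)],
    "Asp": [(2.66, 1.0), (2.80, 1.0), (3.89, 1.0)],
    "Cr": [(3.03, 3.0), (3.91, 2.0)],
    "GPC": [(3.21, 9.0), (3.68, 2.0), (4.31, 2.0)],
    "PCh": [(3.22, 9.0), (3.59, 2.0), (4.17, 2.0)],
    "Glc": [(3.43, 2.0), (3.53, 1.0), (3.80, 2.0)],
    "Gln": [(2.13, 2.0), (2.45, 2.0), (3.77, 1.0)],
    "Glu": [(2.08, 2.0), (2.35, 2.0), (3.75, 1.0)],
    "Gua": [(3.78, 2.0)],
    "Gly": [(3.55, 2.0)],
    "Ins": [(3.52, 4.0), (3.61, 1.0), (4.05, 1.0)],
    "Lac": [(1.31, 3.0), (4.10, 1.0)],
    "NAA": [(2.01, 3.0), (2.49, 1.0), (2.67, 1.0), (4.38, 1.0)],
    "NAAG": [(2.04, 3.0), (2.18, 1.0), (4.38, 1.0)],
    "Scyllo": [(3.34, 6.0)],
    "Tau": [(3.25, 2.0), (3.42, 2.0)],
}

# Nine broad lipid / macromolecule components.  MM humps are wide
# Gaussians; mobile-lipid lines are narrower Lorentzians, with Lip13a/b
# differing in width as in standard short-echo bases.
_MMLIP_PEAKS: dict[str, list[tuple]] = {
    "MM09": [(0.91, 1.0)],
    "MM12": [(1.21, 1.0)],
    "MM14": [(1.43, 1.0)],
    "MM17": [(1.67, 1.0)],
    "MM20": [(2.08, 1.5), (2.25, 1.0)],
    "Lip09": [(0.89, 1.0)],
    "Lip13a": [(1.28, 1.0)],
    "Lip13b": [(1.30, 1.0)],
    "Lip20": [(2.04, 1.0)],
}
_MMLIP_SHAPES: dict[str, tuple[str, float]] = {
    "MM09": ("gaussian", 26.0),
    "MM12": ("gaussian", 24.0),
    "MM14": ("gaussian", 28.0),
    "MM17": ("gaussian", 28.0),
    "MM20": ("gaussian", 30.0),
    "Lip09": ("lorentzian", 14.0),
    "Lip13a": ("lorentzian", 12.0),
    "Lip13b": ("gaussian", 22.0),
    "Lip20": ("lorentzian", 16.0),
}


def nearest_mm_group(centre_ppm: float) -> str:
    """Nearest of the 0.9 / 1.3 / 2.0 ppm MM-lipid group centres."""
    return min(MM_GROUP_CENTRES, key=lambda g: abs(MM_GROUP_CENTRES[g] - centre_ppm))


def build_default_basis() -> BasisSet:
    """Construct the default 26-component basis.

    16 metabolites + 9 MM/lipid components + the negative -CrCH2
    singlet at 3.94 ppm that compensates the creatine CH2 signal lost
    to water suppression / exchange.
    """
    comps: list[ResonanceModel] = []
    for name, peaks in _METABOLITE_PEAKS.items():
        comps.append(ResonanceModel(name, _normalise(peaks), tag="metabolite"))
    for name, peaks in _MMLIP_PEAKS.items():
        shape, width = _MMLIP_SHAPES[name]
        model = ResonanceModel(
            name,
            _normalise(peaks, lineshape=shape, linewidth=width),
            tag="mmlip",
        )
        comps.append(
            ResonanceModel(name, model.peaks, tag="mmlip",
                           group=nearest_mm_group(model.centre_ppm))
        )
    comps.append(
        ResonanceModel(
            "-CrCH2",
            (Peak(3.94, -1.0, linewidth_hz=3.0),),
            tag="reference",
        )
    )
    return BasisSet(comps)


def water_component(linewidth_hz: float = 4.0) -> ResonanceModel:
    """Single water resonance at 4.7 ppm (unit amplitude per mM)."""
    return ResonanceModel("H2O", (Peak(WATER_PPM, 1.0, linewidth_hz=linewidth_hz),),
                          tag="reference")


__all__ = [
    "Peak",
    "ResonanceModel",
    "BasisSet",
    "build_default_basis",
    "water_component",
    "nearest_mm_group",
    "MM_GROUP_CENTRES",
]
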