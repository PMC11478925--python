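"""Forward simulation of single-voxel PRESS spectra and reader-study tables.

The generator is the inverse of the fitting stage: class-conditional
metabolite concentrations (mM) drive a sum of basis-component FIDs, to
which acquisition artifacts (zero/first-order phase error, an
exponentially decaying eddy-current phase, complex Gaussian noise) are
applied.  Every water-suppressed FID is paired with an 8-average water
reference carrying the same eddy-current phase, as acquired for eddy
current correction and internal concentration referencing.

Default class profiles emulate the qualitative metabolite patterns of
the three major childhood cerebellar tumours: medulloblastoma with high
choline, taurine present and low myo-inositol; ependymoma with high
myo-inositol and creatine; pilocytic astrocytoma with low creatine.
They are shipped as editable YAML configuration, not code constants.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .basis import BasisSet, build_default_basis, water_component
from .core import AcquisitionParams, TimeSignal, ppm_axis

TUMOUR_TYPES = ("PA", "EP", "MB")
REVIEW_STAGES = ("imaging", "imaging+MRS", "imaging+MRS+DSS")

#: Assumed pure-water concentration used for internal referencing (mM).
WATER_CONC_MM = 35880.0

#: Pivot for first-order phase terms (centre of the metabolite region).
PHASE_PIVOT_PPM = 3.0


@dataclass(frozen=True)
class ArtifactSettings:
    """Acquisition imperfections applied by the forward model."""

    phi0_deg: float = 0.0
    phi1_deg_per_ppm: float = 0.0
    eddy_amp_rad: float = 0.0
    eddy_decay_ms: float = 50.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.eddy_decay_ms <= 0:
            raise ValueError("eddy_decay_ms must be positive")


def validate_profile(profile: dict[str, float], basis: BasisSet) -> None:
    for name, conc in profile.items():
        if name not in basis:
            raise KeyError(f"unknown basis component {name!r} in profile")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}: {conc}")


def _eddy_phase(t: np.ndarray, artifacts: ArtifactSettings) -> np.ndarray:
    if artifacts.eddy_amp_rad == 0.0:
        return np.zeros_like(t)
    return artifacts.eddy_amp_rad * np.exp(-t / (artifacts.eddy_decay_ms * 1e-3))


def _apply_phi1(fid: np.ndarray, params: AcquisitionParams,
                phi1_deg_per_ppm: float) -> np.ndarray:
    """First-order (frequency-linear) phase error, pivot at 3.0 ppm."""
    if phi1_deg_per_ppm == 0.0:
        return fid
    spec = np.fft.fftshift(np.fft.fft(fid))
    ppm = ppm_axis(params, len(fid))
    phase = np.deg2rad(phi1_deg_per_ppm) * (ppm - PHASE_PIVOT_PPM)
    return np.fft.ifft(np.fft.ifftshift(spec * np.exp(1j * phase)))


def synthesize_fid(
    profile: dict[str, float],
    basis: BasisSet,
    params: AcquisitionParams | None = None,
    artifacts: ArtifactSettings | None = None,
    seed: int | np.random.Generator | None = 0,
    water_conc_mm: float = WATER_CONC_MM,
    water_linewidth_hz: float = 4.0,
) -> tuple[TimeSignal, TimeSignal]:
    """Simulate a (water-suppressed, water-reference) FID pair.

    The water reference contains a single 4.7 ppm resonance with
    amplitude proportional to the assumed water concentration and the
    same eddy-current phase as the suppressed acquisition; its noise is
    scaled for the smaller number of averages.
    """
    params = params or AcquisitionParams()
    artifacts = artifacts or ArtifactSettings()
    validate_profile(profile, basis)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    t = params.time_axis()
    fid = np.zeros(params.n_points, dtype=np.complex128)
    for name, conc in profile.items():
        if conc > 0:
            fid += conc * basis[name].fid(params)

    # phase-error chain: frequency-linear phase first, then the
    # time-dependent eddy phase, so the pointwise water-reference
    # correction inverts the eddy term exactly
    fid = _apply_phi1(fid, params, artifacts.phi1_deg_per_ppm)
    eddy = _eddy_phase(t, artifacts)
    fid = fid * np.exp(1j * (np.deg2rad(artifacts.phi0_deg) + eddy))

    water = water_conc_mm * water_component(water_linewidth_hz).fid(params)
    water = water * np.exp(1j * eddy)

    if artifacts.noise_sd > 0:
        noise = rng.normal(0.0, artifacts.noise_sd, (2, params.n_points))
        fid = fid + noise[0] + 1j * noise[1]
        # water reference: fewer averages -> sqrt scaling of the noise SD
        w_sd = artifacts.noise_sd * np.sqrt(params.n_averages / params.n_water_averages)
        wnoise = rng.normal(0.0, w_sd, (2, params.n_points))
        water = water + wnoise[0] + 1j * wnoise[1]

    return (
        TimeSignal(fid, params, "water_suppressed"),
        TimeSignal(water, params, "water_reference"),
    )


@dataclass
class ClassParams:
    """Class-conditional concentration distribution and artifact ranges."""

    tumour_type: str
    components: list[str]
    mean: np.ndarray
    cov: np.ndarray
    phi0_deg_range: tuple[float, float] = (-30.0, 30.0)
    phi1_deg_per_ppm_range: tuple[float, float] = (-5.0, 5.0)
    eddy_amp_rad_range: tuple[float, float] = (0.0, 0.8)
    eddy_decay_ms_range: tuple[float, float] = (20.0, 80.0)
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.mean.shape != (len(self.components),):
            raise ValueError("mean length must match component list")
        if self.cov.shape != (len(self.components),) * 2:
            raise ValueError("covariance shape must match component list")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.cov).min())
        if eigmin < -1e-8 * max(1.0, float(np.abs(self.cov).max())):
            raise ValueError("covariance must be positive semidefinite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def mean_profile(self) -> dict[str, float]:
        return dict(zip(self.components, self.mean))


def default_class_params(basis: BasisSet | None = None) -> list[ClassParams]:
    """Load the shipped PA/EP/MB class configuration."""
    basis = basis or build_default_basis()
    text = (importlib.resources.files("mrsdss") / "data" / "class_params.yaml").read_text()
    cfg = yaml.safe_load(text)
    art = cfg.get("artifacts", {})
    out = []
    for ttype in TUMOUR_TYPES:
        spec = cfg["classes"][ttype]
        comps = [n for n in basis.names if n in spec["mean_mM"]]
        mean = np.array([spec["mean_mM"][n] for n in comps], dtype=float)
        cv = float(spec.get("cv", 0.25))
        cov = np.diag((cv * mean) ** 2)
        out.append(
            ClassParams(
                tumour_type=ttype,
                components=comps,
                mean=mean,
                cov=cov,
                phi0_deg_range=tuple(art.get("phi0_deg", (-30.0, 30.0))),
                phi1_deg_per_ppm_range=tuple(art.get("phi1_deg_per_ppm", (-5.0, 5.0))),
                eddy_amp_rad_range=tuple(art.get("eddy_amp_rad", (0.0, 0.8))),
                eddy_decay_ms_range=tuple(art.get("eddy_decay_ms", (20.0, 80.0))),
                noise_sd=float(art.get("noise_sd", 0.5)),
            )
        )
    return out


def benchmark_profile() -> dict[str, float]:
    """Reference concentration profile for quantification-recovery
    benchmarks: the canonical markers (NAA, Cr, total choline) at
    healthy-brain-like levels, the remaining components at moderate
    levels, so the benchmark measures fitter accuracy rather than the
    information limit of near-absent signals."""
    return {
        "NAA": 8.0, "NAAG": 1.0, "Cr": 6.0, "GPC": 1.5, "PCh": 1.5,
        "Ins": 5.0, "Glu": 6.0, "Gln": 3.0, "Lac": 1.0, "Tau": 1.5,
        "Glc": 1.0, "Ala": 0.3, "Asp": 1.5, "Gua": 0.5, "Gly": 0.8,
        "Scyllo": 0.3,
        "MM09": 1.0, "MM12": 0.6, "MM14": 0.5, "MM17": 0.6, "MM20": 1.0,
        "Lip09": 0.5, "Lip13a": 0.7, "Lip13b": 0.5, "Lip20": 0.4,
        "-CrCH2": 0.6,
    }


@dataclass
class CohortSubject:
    subject_id: str
    tumour_type: str
    profile: dict[str, float]
    fid: TimeSignal
    water_ref: TimeSignal
    artifacts: ArtifactSettings


def _draw_profile(cp: ClassParams, rng: np.random.Generator,
                  max_attempts: int = 100) -> dict[str, float]:
    """Multivariate-normal draw, resampled (not clipped) on negativity."""
    for _ in range(max_attempts):
        draw = rng.multivariate_normal(cp.mean, cp.cov, method="svd")
        if np.all(draw >= 0):
            return dict(zip(cp.components, draw))
    # pathological configuration: fall back to component-wise resampling
    draw = np.clip(rng.multivariate_normal(cp.mean, cp.cov, method="svd"), 0.0, None)
    return dict(zip(cp.components, draw))


def sample_cohort(
    class_params: list[ClassParams],
    n_per_class: dict[str, int] | list[int],
    seed: int = 0,
    basis: BasisSet | None = None,
    params: AcquisitionParams | None = None,
) -> list[CohortSubject]:
    """Draw a seeded cohort of subjects with simulated FID pairs."""
    basis = basis or build_default_basis()
    params = params or AcquisitionParams()
    if isinstance(n_per_class, dict):
        counts = [n_per_class[cp.tumour_type] for cp in class_params]
    else:
        counts = list(n_per_class)
    if any(n < 1 for n in counts):
        raise ValueError("n_per_class entries must be >= 1")
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    idx = 0
    for cp, n in zip(class_params, counts):
        for _ in range(n):
            profile = _draw_profile(cp, rng)
            art = ArtifactSettings(
                phi0_deg=float(rng.uniform(*cp.phi0_deg_range)),
                phi1_deg_per_ppm=float(rng.uniform(*cp.phi1_deg_per_ppm_range)),
                eddy_amp_rad=float(rng.uniform(*cp.eddy_amp_rad_range)),
                eddy_decay_ms=float(rng.uniform(*cp.eddy_decay_ms_range)),
                noise_sd=cp.noise_sd,
            )
            fid, water = synthesize_fid(profile, basis, params, art, seed=rng)
            subjects.append(
                CohortSubject(f"S{idx:03d}", cp.tumour_type, profile, fid, water, art)
            )
            idx += 1
    return subjects


def _round_triple(truth_cert: float, w: float, truth_idx: int) -> list[int]:
    """Integer certainty triple summing to exactly 100."""
    truth_cert = int(round(np.clip(truth_cert, 0.0, 100.0)))
    rest = 100 - truth_cert
    second = int(round(rest * w))
    third = rest - second
    triple = [0, 0, 0]
    others = [i for i in range(3) if i != truth_idx]
    triple[truth_idx] = truth_cert
    triple[others[0]] = second
    triple[others[1]] = third
    return triple


def sample_certainty_table(
    truth_labels: list[str],
    stage_effects: float | list[float] = (0.0, 10.0, 8.0),
    seed: int = 0,
    n_raters: int = 3,
    baseline_mean: float = 45.0,
    baseline_sd: float = 12.0,
    noise_sd: float = 8.0,
) -> pd.DataFrame:
    """Simulate a three-stage radiologist certainty table.

    ``stage_effects`` gives the median shift of the correct-class
    certainty at each stage relative to the previous one (a scalar is
    broadcast to every transition; the first stage has no predecessor).
    Each emitted certainty triple over (PA, EP, MB) sums to 100.
    """
    n_stages = len(REVIEW_STAGES)
    if np.isscalar(stage_effects):
        effects = [0.0] + [float(stage_effects)] * (n_stages - 1)
    else:
        effects = list(stage_effects)
        if len(effects) == n_stages - 1:
            effects = [0.0] + effects
        if len(effects) != n_stages:
            raise ValueError("stage_effects must give one shift per transition")
    rng = np.random.default_rng(seed)
    rows = []
    for rater in range(1, n_raters + 1):
        for case_idx, truth in enumerate(truth_labels):
            truth_idx = TUMOUR_TYPES.index(truth)
            cert = float(rng.normal(baseline_mean, baseline_sd))
            w = float(rng.uniform(0.2, 0.8))
            for stage_i, stage in enumerate(REVIEW_STAGES):
                if stage_i > 0:
                    cert = cert + effects[stage_i] + float(rng.normal(0.0, noise_sd))
                triple = _round_triple(cert, w, truth_idx)
                rows.append(
                    {
                        "rater": f"Rad{rater}",
                        "case": f"C{case_idx:03d}",
                        "stage": stage,
                        "cert_PA": triple[0],
                        "cert_EP": triple[1],
                        "cert_MB": triple[2],
                        "truth": truth,
                    }
                )
    return pd.DataFrame(rows)


__all__ = [
    "TUMOUR_TYPES",
    "REVIEW_STAGES",
    "WATER_CONC_MM",
    "PHASE_PIVOT_PPM",
    "ArtifactSettings",
    "ClassParams",
    "benchmark_profile",
    "CohortSubject",
    "synthesize_fid",
    "sample_cohort",
    "sample_certainty_table",
    "default_class_params",
]
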