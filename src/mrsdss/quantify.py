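"""Linear-combination model fitting with a penalized-spline baseline.

The fitter models the real part of the phased spectrum over the fit
window as

    y(p) = sum_c a_c * B_c(p; shift, broaden) + baseline(p)

where the B_c are basis-component spectra regenerated through the same
forward model used for synthesis, ``shift`` (ppm) and ``broaden`` (Hz)
are shared nonlinear nuisance parameters, and the baseline is a cubic
B-spline with knots every 0.15 ppm whose curvature is penalized, the
penalty weight chosen by generalized cross-validation with a fixed
fallback.  Amplitudes are solved as a bound-constrained linear
subproblem (non-negative by default; the -CrCH2 component carries its
negative sign inside the basis shape) nested inside a small nonlinear
search, a variable-projection strategy.

Cramer-Rao lower bounds are computed from the Jacobian at the solution,
marginalized over all free parameters including the baseline
coefficients, and reported as percentages of the fitted amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize, nnls

from .basis import BasisSet
from .core import WATER_PPM, Spectrum

#: CRLB value reported when a bound is undefined or unidentifiable (%).
CRLB_UNDEFINED = 999.0


@dataclass(frozen=True)
class FitConfig:
    """Settings for the linear-combination fit."""

    window_ppm: tuple[float, float] = (0.2, 4.0)
    baseline: bool = True
    baseline_knot_spacing_ppm: float = 0.15
    baseline_lambda: float = 100.0
    baseline_lambda_gcv: bool = True
    max_shift_ppm: float = 0.05
    max_broaden_hz: float = 5.0
    fit_phase: bool = True
    max_phi0_deg: float = 45.0
    max_phi1_deg_per_ppm: float = 20.0
    nonneg: bool = True
    noise_region_ppm: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self) -> None:
        if self.baseline_knot_spacing_ppm <= 0:
            raise ValueError("baseline knot spacing must be positive")
        if self.window_ppm[0] >= self.window_ppm[1]:
            raise ValueError("fit window must be increasing (lo, hi)")


@dataclass
class QuantResult:
    """Outcome of a linear-combination fit."""

    amplitudes: dict[str, float]
    concentrations: dict[str, float] | None
    crlb_percent: dict[str, float] | None
    baseline_curve: np.ndarray
    residual: np.ndarray
    noise_sd: float
    fwhm_ppm: float
    snr: float
    converged: bool
    flags: list[str] = field(default_factory=list)
    shift_ppm: float = 0.0
    broaden_hz: float = 0.0
    phi0_deg: float = 0.0
    phi1_deg_per_ppm: float = 0.0
    window_ppm_axis: np.ndarray | None = None
    component_tags: dict[str, str] = field(default_factory=dict)
    component_groups: dict[str, str | None] = field(default_factory=dict)
    # fit internals retained for CRLB computation
    _design: np.ndarray | None = None
    _nonlinear_cols: np.ndarray | None = None
    _amp_values: np.ndarray | None = None
    _penalty: np.ndarray | None = None


def _spline_design(ppm: np.ndarray, window: tuple[float, float],
                   spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix and second-difference penalty."""
    lo, hi = window
    n_int = max(1, int(np.ceil((hi - lo) / spacing)))
    knots = np.linspace(lo, hi, n_int + 1)
    t = np.r_[[lo] * 3, knots, [hi] * 3]
    S = BSpline.design_matrix(np.clip(ppm, lo, hi), t, 3).toarray()
    n_coef = S.shape[1]
    D2 = np.diff(np.eye(n_coef), n=2, axis=0)
    return S, D2


class _BasisEvaluator:
    """Vectorized construction of the windowed real basis matrix.

    Flattens every peak of every component into arrays once, then each
    (shift, broaden) evaluation is one batched complex exponential plus
    one batched FFT.  Results are cached on the rounded parameter pair
    since the nonlinear search revisits nearby points.
    """

    def __init__(self, spec: Spectrum, basis: BasisSet, mask: np.ndarray):
        params = spec.params
        self.n_total = len(spec.values)
        self.n_points = params.n_points
        self.mask = mask
        self.f0 = params.transmitter_freq_mhz
        self.t = params.time_axis()
        ppm, amp, lw, gauss, comp = [], [], [], [], []
        for j, c in enumerate(basis):
            for p in c.peaks:
                ppm.append(p.ppm)
                amp.append(p.amplitude)
                lw.append(p.linewidth_hz)
                gauss.append(p.lineshape == "gaussian")
                comp.append(j)
        self.peak_ppm = np.array(ppm)
        self.peak_amp = np.array(amp)
        self.peak_lw = np.array(lw)
        self.gauss = np.array(gauss)
        self.indicator = np.zeros((len(basis), len(ppm)))
        self.indicator[comp, np.arange(len(ppm))] = 1.0
        self._cache: dict[tuple[float, float], np.ndarray] = {}

    def __call__(self, shift_ppm: float, broaden_hz: float) -> np.ndarray:
        key = (round(shift_ppm, 6), round(broaden_hz, 5))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        t = self.t
        df = (self.peak_ppm + shift_ppm - WATER_PPM) * self.f0
        rate = np.where(self.gauss, 0.0, np.pi * self.peak_lw)
        arg = (2j * np.pi * df - rate - np.pi * broaden_hz)[:, None] * t[None, :]
        E = np.exp(arg)
        if self.gauss.any():
            g = self.gauss
            E[g] *= np.exp(-((np.pi * self.peak_lw[g, None] * t[None, :]) ** 2)
                           / (4.0 * np.log(2.0)))
        fids = (self.peak_amp[:, None] * E)
        comp_fids = self.indicator @ fids
        if self.n_total > self.n_points:
            padded = np.zeros((comp_fids.shape[0], self.n_total), dtype=complex)
            padded[:, : self.n_points] = comp_fids
            comp_fids = padded
        spec_rows = np.fft.fftshift(np.fft.fft(comp_fids, axis=1), axes=1).real
        out = spec_rows[:, self.mask].T.copy()
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = out
        return out


class _BaselineProjector:
    """Profiles the penalized spline out of the linear subproblem.

    With augmented rows for the curvature penalty, the optimal spline
    coefficients for any amplitude vector are a linear map, so the
    amplitude problem reduces to a plain NNLS against the projected
    design — much faster than a joint bound-constrained solve.
    """

    def __init__(self, S: np.ndarray | None, D2: np.ndarray | None,
                 n_data: int, lam: float):
        self.n_data = n_data
        if S is None:
            self.S = None
            return
        self.S = S
        n_pen = D2.shape[0]
        S_aug = np.vstack([S, np.sqrt(lam) * D2])
        self.S_aug = S_aug
        G = S_aug.T @ S_aug + 1e-10 * np.eye(S.shape[1])
        self.solve_c = np.linalg.solve(G, S_aug.T)        # c = solve_c @ r_aug
        self.Q = np.eye(n_data + n_pen) - S_aug @ self.solve_c

    def augment(self, M: np.ndarray) -> np.ndarray:
        if self.S is None:
            return M
        pad = np.zeros((self.S_aug.shape[0] - self.n_data,)
                       + ((M.shape[1],) if M.ndim == 2 else ()))
        return np.vstack([M, pad]) if M.ndim == 2 else np.r_[M, pad]


def _solve_amplitudes(B: np.ndarray, proj: _BaselineProjector,
                      y: np.ndarray, nonneg: bool):
    """Penalized linear subproblem, spline profiled out analytically."""
    n_amp = B.shape[1]
    B_aug = proj.augment(B)
    y_aug = proj.augment(y)
    if proj.S is not None:
        QB = proj.Q @ B_aug
        Qy = proj.Q @ y_aug
    else:
        QB, Qy = B_aug, y_aug
    if nonneg:
        a, _ = nnls(QB, Qy)
        success = True
    else:
        a = np.linalg.lstsq(QB, Qy, rcond=None)[0]
        success = True
    if proj.S is not None:
        c = proj.solve_c @ (y_aug - B_aug @ a)
        x = np.r_[a, c]
        A = np.hstack([B, proj.S])
    else:
        x = a
        A = B
    data_resid = y - A @ x
    return x, A, data_resid, float(np.sum(data_resid**2)), success


def _gcv_lambda(B: np.ndarray, S: np.ndarray, D2: np.ndarray, y: np.ndarray,
                fallback: float) -> float:
    """Pick the baseline penalty by GCV on the unconstrained problem."""
    n_amp = B.shape[1]
    A = np.hstack([B, S])
    AtA = A.T @ A
    Aty = A.T @ y
    DtD = np.zeros_like(AtA)
    DtD[n_amp:, n_amp:] = D2.T @ D2
    n = len(y)
    best_lam, best_gcv = fallback, np.inf
    for lam in np.logspace(-1, 5, 7):
        try:
            M = np.linalg.solve(AtA + lam * DtD + 1e-10 * np.eye(len(AtA)), AtA)
        except np.linalg.LinAlgError:
            continue
        edof = float(np.trace(M))
        x = np.linalg.solve(AtA + lam * DtD + 1e-10 * np.eye(len(AtA)), Aty)
        rss = float(np.sum((y - A @ x) ** 2))
        denom = (n - edof) ** 2
        if denom <= 0:
            continue
        gcv = n * rss / denom
        if np.isfinite(gcv) and gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return best_lam


def estimate_fwhm_ppm(ppm: np.ndarray, signal: np.ndarray) -> float:
    """FWHM of the tallest peak, by linear interpolation of half-maximum
    crossings."""
    i = int(np.argmax(signal))
    peak = signal[i]
    if peak <= 0:
        return float("nan")
    half = peak / 2.0
    lo = i
    while lo > 0 and signal[lo] > half:
        lo -= 1
    hi = i
    while hi < len(signal) - 1 and signal[hi] > half:
        hi += 1
    if signal[lo] > half or signal[hi] > half:
        return float("nan")

    def cross(a: int, b: int) -> float:
        if signal[b] == signal[a]:
            return ppm[a]
        f = (half - signal[a]) / (signal[b] - signal[a])
        return ppm[a] + f * (ppm[b] - ppm[a])

    return float(abs(cross(hi - 1, hi) - cross(lo, lo + 1)))


def fit_linear_combination(spec: Spectrum, basis: BasisSet,
                           cfg: FitConfig | None = None) -> QuantResult:
    """Fit the spectrum's real part by a linear combination of basis
    components plus a penalized spline baseline."""
    cfg = cfg or FitConfig()
    if len(basis) == 0:
        raise ValueError("basis set is empty")
    mask = spec.window_mask(*cfg.window_ppm)
    if mask.sum() < len(basis) + 4:
        raise ValueError("fit window outside or too small for the spectral axis")
    vals_w = spec.values[mask]
    ppm_w = spec.ppm[mask]
    rel_w = ppm_w - 3.0  # first-order phase pivot

    def data(phi0: float, phi1: float) -> np.ndarray:
        phase = np.deg2rad(phi0) + np.deg2rad(phi1) * rel_w
        return (vals_w * np.exp(-1j * phase)).real

    if cfg.baseline:
        S, D2 = _spline_design(ppm_w, cfg.window_ppm, cfg.baseline_knot_spacing_ppm)
    else:
        S, D2 = None, None

    lam = cfg.baseline_lambda
    basis_at = _BasisEvaluator(spec, basis, mask)
    proj = _BaselineProjector(S, D2, int(mask.sum()), lam)

    def clip_params(p: np.ndarray) -> tuple[float, float, float, float]:
        shift = float(np.clip(p[0], -cfg.max_shift_ppm, cfg.max_shift_ppm))
        broaden = float(np.clip(p[1], 0.0, cfg.max_broaden_hz))
        if len(p) > 2:
            phi0 = float(np.clip(p[2], -cfg.max_phi0_deg, cfg.max_phi0_deg))
            phi1 = float(np.clip(p[3], -cfg.max_phi1_deg_per_ppm,
                                 cfg.max_phi1_deg_per_ppm))
        else:
            phi0, phi1 = 0.0, 0.0
        return shift, broaden, phi0, phi1

    def cost(p: np.ndarray) -> float:
        shift, broaden, phi0, phi1 = clip_params(p)
        B = basis_at(shift, broaden)
        _, _, _, rss, _ = _solve_amplitudes(B, proj, data(phi0, phi1), cfg.nonneg)
        return rss

    converged = True
    n_free = 4 if cfg.fit_phase else 2
    if cfg.max_shift_ppm > 0 or cfg.max_broaden_hz > 0 or cfg.fit_phase:
        shifts = np.linspace(-cfg.max_shift_ppm, cfg.max_shift_ppm, 3) \
            if cfg.max_shift_ppm > 0 else np.array([0.0])
        broadens = np.linspace(0.0, cfg.max_broaden_hz, 3) \
            if cfg.max_broaden_hz > 0 else np.array([0.0])
        grid = [(s, b) for s in shifts for b in broadens]
        costs = [cost(np.array(p)) for p in grid]
        p_grid = np.array(grid[int(np.argmin(costs))])
        p0 = np.r_[p_grid, 0.0, 0.0][:n_free]
        res = minimize(cost, p0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-12,
                                "maxiter": 80 * n_free})
        converged = bool(res.fun <= min(costs) + 1e-12 or res.success)
        p_best = res.x if res.fun <= min(costs) else p0
        shift, broaden, phi0, phi1 = clip_params(p_best)
    else:
        shift, broaden, phi0, phi1 = 0.0, 0.0, 0.0, 0.0

    y = data(phi0, phi1)
    B = basis_at(shift, broaden)
    if cfg.baseline and cfg.baseline_lambda_gcv:
        lam = _gcv_lambda(B, S, D2, y, cfg.baseline_lambda)
        proj = _BaselineProjector(S, D2, int(mask.sum()), lam)
    x, A, resid, rss, success = _solve_amplitudes(B, proj, y, cfg.nonneg)
    n_amp = len(basis)
    amps = dict(zip(basis.names, x[:n_amp]))
    baseline_curve = S @ x[n_amp:] if cfg.baseline else np.zeros_like(y)
    model_signal = B @ x[:n_amp]

    noise_mask = (ppm_w >= cfg.noise_region_ppm[0]) & (ppm_w <= cfg.noise_region_ppm[1])
    if noise_mask.sum() >= 8:
        noise_sd = float(np.std(resid[noise_mask], ddof=1))
    else:
        noise_sd = float(np.std(resid, ddof=1))
    snr = float(model_signal.max() / (2.0 * noise_sd)) if noise_sd > 0 else np.inf
    # linewidth diagnostic from the strongest single metabolite
    # component, so neither broad MM humps nor multiplet-cluster
    # envelopes masquerade as the spectral resolution
    metab_idx = [j for j, c in enumerate(basis) if c.tag == "metabolite"]
    best_height, fwhm = 0.0, float("nan")
    for j in metab_idx:
        curve = B[:, j] * x[j]
        h = float(curve.max())
        if h > best_height:
            best_height = h
            fwhm = estimate_fwhm_ppm(ppm_w, curve)
    if not metab_idx or best_height <= 0:
        fwhm = estimate_fwhm_ppm(ppm_w, model_signal)

    # finite-difference columns for the shared nonlinear parameters,
    # used when marginalizing the CRLBs
    nl_cols = []
    a_vec = x[:n_amp]
    if cfg.max_shift_ppm > 0:
        d = 1e-3
        nl_cols.append((basis_at(shift + d, broaden) @ a_vec - model_signal) / d)
    if cfg.max_broaden_hz > 0:
        d = 1e-2
        nl_cols.append((basis_at(shift, broaden + d) @ a_vec - model_signal) / d)
    if cfg.fit_phase:
        d = 1e-2
        nl_cols.append((data(phi0 + d, phi1) - y) / d)
        nl_cols.append((data(phi0, phi1 + d) - y) / d)
    nl = np.column_stack(nl_cols) if nl_cols else None

    flags = [] if success else ["solver"]
    result = QuantResult(
        amplitudes=amps,
        concentrations=None,
        crlb_percent=None,
        baseline_curve=baseline_curve,
        residual=resid,
        noise_sd=noise_sd,
        fwhm_ppm=fwhm,
        snr=snr,
        converged=converged and success,
        flags=flags,
        shift_ppm=shift,
        broaden_hz=broaden,
        phi0_deg=phi0,
        phi1_deg_per_ppm=phi1,
        window_ppm_axis=ppm_w,
        component_tags={c.name: c.tag for c in basis},
        component_groups={c.name: c.group for c in basis},
        _design=A,
        _nonlinear_cols=nl,
        _amp_values=a_vec,
        _penalty=_penalty_matrix(n_amp, D2, lam) if cfg.baseline else None,
    )
    result.crlb_percent = compute_crlb(result)
    return result


def _penalty_matrix(n_amp: int, D2: np.ndarray, lam: float) -> np.ndarray:
    n_base = D2.shape[1]
    P = np.zeros((n_amp + n_base,) * 2)
    P[n_amp:, n_amp:] = lam * (D2.T @ D2)
    return P


def amplitude_covariance(result: QuantResult, noise_sd: float | None = None
                         ) -> np.ndarray:
    """Covariance matrix of the fitted amplitudes (basis order).

    Built from the information matrix of all free parameters —
    amplitudes, baseline spline coefficients and the shared
    shift/broadening terms — with the baseline curvature penalty
    included as prior information, as in regularized fitters.
    """
    sigma = result.noise_sd if noise_sd is None else noise_sd
    cov, _ = _parameter_covariance(result)
    n_amp = len(result.amplitudes)
    return cov[:n_amp, :n_amp] * sigma**2


def _parameter_covariance(result: QuantResult) -> tuple[np.ndarray, bool]:
    if result._design is None:
        raise ValueError("fit internals unavailable; rerun fit_linear_combination")
    J = result._design
    if result._nonlinear_cols is not None:
        J = np.hstack([J, result._nonlinear_cols])
    F = J.T @ J
    if result._penalty is not None:
        n_pen = result._penalty.shape[0]
        F[:n_pen, :n_pen] += result._penalty
    try:
        cond = np.linalg.cond(F)
    except np.linalg.LinAlgError:
        cond = np.inf
    singular = not np.isfinite(cond) or cond > 1e14
    if singular:
        cov = np.linalg.pinv(F, rcond=1e-12)
    else:
        cov = np.linalg.inv(F)
    return cov, singular


def compute_crlb(result: QuantResult, noise_sd: float | None = None) -> dict[str, float]:
    """Cramer-Rao lower bounds (%) for each component amplitude.

    The information matrix includes every free parameter: amplitudes,
    baseline spline coefficients (with their curvature penalty acting
    as prior information) and the shared shift/broadening terms.  A
    singular information matrix falls back to the pseudo-inverse and
    sets the ``crlb_singular`` flag; undefined bounds are reported as
    999%.
    """
    sigma = result.noise_sd if noise_sd is None else noise_sd
    if sigma <= 0:
        raise ValueError("noise SD must be positive")
    J = result._design
    if result._nonlinear_cols is not None:
        J = np.hstack([J, result._nonlinear_cols])
    F = J.T @ J
    if result._penalty is not None:
        n_pen = result._penalty.shape[0]
        F[:n_pen, :n_pen] += result._penalty
    names = list(result.amplitudes)
    n_amp = len(names)
    try:
        cond = np.linalg.cond(F)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e14:
        cov = np.linalg.pinv(F, rcond=1e-12)
        if "crlb_singular" not in result.flags:
            result.flags.append("crlb_singular")
    else:
        cov = np.linalg.inv(F)
    var = np.clip(np.diag(cov)[:n_amp], 0.0, None)
    crlb = {}
    for i, name in enumerate(names):
        a = result.amplitudes[name]
        if abs(a) < 1e-12 or not np.isfinite(var[i]):
            crlb[name] = CRLB_UNDEFINED
            continue
        value = 100.0 * np.sqrt(var[i]) * sigma / abs(a)
        crlb[name] = float(min(value, CRLB_UNDEFINED))
    if "crlb_singular" in result.flags:
        # non-identifiable directions: flag every component whose
        # variance the pseudo-inverse could not bound
        null_dim = F.shape[0] - np.linalg.matrix_rank(F, tol=1e-9 * np.abs(F).max())
        if null_dim > 0:
            U = np.linalg.svd(F)[0][:, F.shape[0] - null_dim:]
            bad = np.abs(U[:n_amp]).max(axis=1) > 1e-6
            for i, name in enumerate(names):
                if bad[i]:
                    crlb[name] = CRLB_UNDEFINED
    result.crlb_percent = crlb
    return crlb


def water_amplitude(water_spec: Spectrum) -> float:
    """Water amplitude in FID units (the t=0 value, |mean of spectrum|)."""
    return float(abs(water_spec.values.sum()) / len(water_spec.values))


def water_reference_scale(result: QuantResult, water_spec: Spectrum,
                          water_conc_mm: float = 35880.0,
                          proton_correction: dict[str, float] | None = None
                          ) -> QuantResult:
    """Convert fitted amplitudes to mM against the unsuppressed water
    reference, with an assumed water concentration of 35,880 mM."""
    a_water = water_amplitude(water_spec)
    if a_water <= 0:
        raise ValueError("water reference amplitude must be positive")
    corr = proton_correction or {}
    conc = {
        name: a / a_water * water_conc_mm * corr.get(name, 1.0)
        for name, a in result.amplitudes.items()
    }
    return replace(result, concentrations=conc)


def group_mmlip(result: QuantResult):
    """Collapse the 9 MM/lipid components into the MMLip09/13/20 group
    variables, yielding the 19-variable feature vector.

    Metabolite concentrations pass through unchanged; -CrCH2 is
    excluded; a group's CRLB is the minimum over its members (the group
    is quantifiable if any member is).  Feature order is canonical
    (sorted metabolite names, then MMLip09/13/20), so it does not depend
    on basis component order.
    """
    from .classify import FeatureVector

    values = result.concentrations if result.concentrations is not None \
        else result.amplitudes
    names: list[str] = []
    out: list[float] = []
    crlb: dict[str, float] = {}
    src_crlb = result.crlb_percent or {}
    metabolites = sorted(n for n, t in result.component_tags.items()
                         if t == "metabolite")
    for name in metabolites:
        if name not in values:
            raise KeyError(f"missing component {name!r} in fit result")
        names.append(name)
        out.append(float(values[name]))
        if name in src_crlb:
            crlb[name] = src_crlb[name]
    for gname in ("MMLip09", "MMLip13", "MMLip20"):
        members = [n for n, t in result.component_tags.items()
                   if t == "mmlip" and result.component_groups.get(n) == gname]
        if not members:
            raise KeyError(f"no members found for group {gname}")
        names.append(gname)
        out.append(float(sum(values[m] for m in members)))
        member_crlbs = [src_crlb[m] for m in members if m in src_crlb]
        if member_crlbs:
            crlb[gname] = float(min(member_crlbs))
    return FeatureVector(names=tuple(names), values=np.array(out),
                         crlb=crlb or None)


__all__ = [
    "CRLB_UNDEFINED",
    "FitConfig",
    "QuantResult",
    "fit_linear_combination",
    "compute_crlb",
    "amplitude_covariance",
    "water_amplitude",
    "water_reference_scale",
    "group_mmlip",
    "estimate_fwhm_ppm",
]
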