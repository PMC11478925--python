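"""Decision-support output: class mean spectra and the three-panel
report (standardized metabolite profile, DF-score scatter with decision
boundaries, index spectrum against class means).

Spectra entering ``mean_class_spectra`` must be baseline-subtracted and
water-normalized; confidence bands are point-wise t-intervals by
default (bootstrap percentile bands behind a flag).  Spectra are drawn
over 0.5-4.3 ppm with ppm decreasing to the right, the conventional MRS
display.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy import stats as sstats

from .classify import (ClassificationResult, ClassifierModel, FeatureVector,
                       decision_boundaries, standardize)
from .core import Spectrum

DISPLAY_PPM = (0.5, 4.3)

_CLASS_COLORS = {"PA": "#1f77b4", "EP": "#2ca02c", "MB": "#9467bd"}


@dataclass
class ClassMeanSpectra:
    """Per-class mean real spectra with 95% CI half-widths."""

    ppm: np.ndarray
    means: dict[str, np.ndarray]
    ci_half: dict[str, np.ndarray]
    counts: dict[str, int]


def mean_class_spectra(
    spectra: list[Spectrum],
    labels: list[str],
    method: str = "t",
    n_boot: int = 500,
    seed: int = 0,
) -> ClassMeanSpectra:
    """Point-wise class means with 95% confidence bands.

    All spectra must be water-normalized and share a common ppm grid
    (spectra on other grids are resampled by linear interpolation).
    """
    if len(spectra) != len(labels):
        raise ValueError("one label per spectrum required")
    for s in spectra:
        if s.normalization != "water_normalized":
            raise ValueError("spectra must be water-normalized before averaging")
    ppm = spectra[0].ppm
    rows = []
    for s in spectra:
        if len(s.ppm) == len(ppm) and np.allclose(s.ppm, ppm):
            rows.append(s.real)
        else:
            rows.append(np.interp(ppm, s.ppm, s.real))
    stack = np.asarray(rows)
    means, ci, counts = {}, {}, {}
    rng = np.random.default_rng(seed)
    for lab in sorted(set(labels)):
        sel = stack[np.asarray(labels) == lab]
        n = len(sel)
        if n < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 spectra")
        m = sel.mean(axis=0)
        if method == "t":
            half = sstats.t.ppf(0.975, n - 1) * sel.std(axis=0, ddof=1) / np.sqrt(n)
        elif method == "bootstrap":
            boot = np.array([
                sel[rng.integers(0, n, n)].mean(axis=0) for _ in range(n_boot)
            ])
            lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
            half = np.maximum(hi - m, m - lo)  # band always contains the mean
        else:
            raise ValueError(f"unknown CI method {method!r}")
        means[lab], ci[lab], counts[lab] = m, half, n
    return ClassMeanSpectra(ppm=ppm, means=means, ci_half=ci, counts=counts)


def render_dss(
    case_result: ClassificationResult,
    model: ClassifierModel,
    class_means: ClassMeanSpectra,
    out_path: str | Path,
    case_features: FeatureVector | None = None,
    case_spectrum: Spectrum | None = None,
    training_df_scores: dict[str, np.ndarray] | None = None,
    case_id: str = "index",
) -> dict:
    """Write the three-panel decision-support figure and JSON sidecar.

    Panels: (1) the standardized feature values fed to the classifier,
    (2) DF-score scatter with decision boundaries and the index case
    marked, (3) the index spectrum (red) over the class mean spectra
    with shaded 95% CIs.  Returns the sidecar dictionary.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, 3, figsize=(15, 4.2))

    # panel 1: standardized metabolite profile (z-scores)
    ax = axes[0]
    if case_features is not None:
        z = standardize(case_features, model)
        ax.barh(np.arange(len(z)), z, color="#d62728")
        ax.set_yticks(np.arange(len(z)))
        ax.set_yticklabels(model.feature_names, fontsize=6)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("z-score (training-standardized)")
    ax.set_title("Metabolite profile")

    # panel 2: DF scores, boundaries, index case
    ax = axes[1]
    pts = np.vstack([v for v in (training_df_scores or {}).values()]) \
        if training_df_scores else None
    lims = 1.15 * float(np.abs(pts).max()) if pts is not None and len(pts) else 8.0
    lims = max(lims, 1.15 * float(np.abs(case_result.df_scores).max()), 4.0)
    bounds = decision_boundaries(model, (-lims, lims), (-lims, lims))
    for pair, line in bounds.items():
        ax.plot(line[:, 0], line[:, 1], "k--", lw=0.8)
    for lab, scores in (training_df_scores or {}).items():
        scores = np.atleast_2d(scores)
        ax.scatter(scores[:, 0], scores[:, 1], s=18, alpha=0.7,
                   facecolors="none", edgecolors=_CLASS_COLORS.get(lab, "gray"),
                   label=lab)
    ax.scatter(*case_result.df_scores, marker="*", s=180, color="#d62728",
               zorder=5, label=case_id)
    ax.set_xlim(-lims, lims)
    ax.set_ylim(-lims, lims)
    ax.set_xlabel("DF1")
    ax.set_ylabel("DF2")
    ax.legend(fontsize=6, loc="best")
    ax.set_title("D.F. scores")

    # panel 3: index spectrum vs class means
    ax = axes[2]
    sel = (class_means.ppm >= DISPLAY_PPM[0]) & (class_means.ppm <= DISPLAY_PPM[1])
    for lab in class_means.means:
        m = class_means.means[lab][sel]
        h = class_means.ci_half[lab][sel]
        ax.plot(class_means.ppm[sel], m, color=_CLASS_COLORS.get(lab, "gray"),
                lw=0.8, label=f"{lab} mean (n={class_means.counts[lab]})")
        ax.fill_between(class_means.ppm[sel], m - h, m + h,
                        color=_CLASS_COLORS.get(lab, "gray"), alpha=0.25, lw=0)
    if case_spectrum is not None:
        csel = (case_spectrum.ppm >= DISPLAY_PPM[0]) & (case_spectrum.ppm <= DISPLAY_PPM[1])
        ax.plot(case_spectrum.ppm[csel], case_spectrum.real[csel],
                color="#d62728", lw=1.0, label=case_id)
    ax.invert_xaxis()  # high ppm on the left
    ax.set_xlabel("chemical shift (ppm)")
    ax.legend(fontsize=6)
    ax.set_title("Spectra")

    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    sidecar = {
        "case": case_id,
        "predicted": case_result.predicted,
        "posteriors": case_result.posteriors,
        "df_scores": [float(v) for v in case_result.df_scores],
        "boundary_distance": case_result.boundary_distance,
        "nearest_class": case_result.predicted,
    }
    sidecar_path = out_path.with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return sidecar


__all__ = ["ClassMeanSpectra", "mean_class_spectra", "render_dss", "DISPLAY_PPM"]
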