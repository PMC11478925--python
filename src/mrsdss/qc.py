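"""Quality control and CRLB-based feature selection.

Two gates operate at different levels:

* ``spectrum_qc`` rejects whole spectra whose fit diagnostics indicate
  unusable data (low SNR, broad lines, non-convergence), mirroring the
  attrition from acquired to analysed cases.
* ``select_features`` keeps a feature only if its CRLB is below the
  threshold (default 30%) in at least ``min_subjects`` (default 2)
  subjects across the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .quantify import QuantResult


@dataclass(frozen=True)
class QCCriteria:
    crlb_threshold: float = 30.0
    min_subjects: int = 2
    min_snr: float = 4.0
    max_fwhm_ppm: float = 0.1

    def __post_init__(self) -> None:
        if self.crlb_threshold <= 0:
            raise ValueError("crlb_threshold must be positive")
        if self.min_subjects < 1:
            raise ValueError("min_subjects must be >= 1")


@dataclass(frozen=True)
class QCReport:
    passed: bool
    reasons: tuple[str, ...]


def spectrum_qc(result: QuantResult, criteria: QCCriteria | None = None) -> QCReport:
    """Spectrum-level gate: SNR, linewidth and convergence."""
    criteria = criteria or QCCriteria()
    reasons: list[str] = []
    if result.snr < criteria.min_snr:
        reasons.append("SNR")
    if result.fwhm_ppm > criteria.max_fwhm_ppm or result.fwhm_ppm != result.fwhm_ppm:
        reasons.append("FWHM")
    if not result.converged:
        reasons.append("NONCONVERGED")
    return QCReport(passed=not reasons, reasons=tuple(reasons))


def crlb_table(feature_vectors) -> pd.DataFrame:
    """Stack per-subject grouped CRLBs into a subjects x features table."""
    rows = []
    for fv in feature_vectors:
        if fv.crlb is None:
            raise ValueError("feature vector carries no CRLBs")
        rows.append(pd.Series(fv.crlb))
    return pd.DataFrame(rows).reset_index(drop=True)


def select_features(crlbs: pd.DataFrame, criteria: QCCriteria | None = None
                    ) -> list[str]:
    """Features with CRLB below threshold in at least ``min_subjects``.

    ``crlbs`` is a subjects x features table of CRLB percentages (group
    variables already collapsed, with group CRLB = min over members).
    """
    criteria = criteria or QCCriteria()
    if len(crlbs) == 0:
        raise ValueError("empty cohort")
    ok = (crlbs < criteria.crlb_threshold).sum(axis=0)
    return [str(f) for f in crlbs.columns if ok[f] >= criteria.min_subjects]


__all__ = ["QCCriteria", "QCReport", "spectrum_qc", "select_features", "crlb_table"]
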