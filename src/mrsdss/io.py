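"""Text FID format, cohort manifests, configuration and the pipeline
runner.

FID files use a simple line-oriented dialect (in the spirit of
LCModel's RAW text files): a header block of ``key = value`` lines
between ``$FID`` and ``$END``, followed by one ``index real imag`` row
per complex sample at 17 significant digits, which round-trips IEEE
doubles exactly.  CRLF and LF line endings are both accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .basis import build_default_basis
from .classify import FeatureVector, evaluate_classifier, train_lda
from .core import AcquisitionParams, TimeSignal
from .preprocess import auto_phase, eddy_current_correct, to_spectrum, water_normalize
from .qc import QCCriteria, crlb_table, select_features, spectrum_qc
from .quantify import (FitConfig, fit_linear_combination, group_mmlip,
                       water_reference_scale)
from .report import mean_class_spectra, render_dss
from .synthesize import default_class_params, sample_cohort

log = logging.getLogger("mrsdss")

_HEADER_FIELDS = (
    "field_strength_t", "te_ms", "tr_ms", "n_points", "bandwidth_hz",
    "voxel_edge_cm", "n_averages", "n_water_averages",
)


def write_fid(signal: TimeSignal, path: str | Path) -> Path:
    """Write a FID in the text dialect (lossless, 17 significant digits)."""
    path = Path(path)
    p = signal.params
    lines = ["$FID"]
    lines.append(f" format_version = 1")
    lines.append(f" kind = {signal.kind}")
    lines.append(f" transmitter_mhz = {p.transmitter_freq_mhz:.9f}")
    lines.append(f" dwell_s = {p.dwell_s:.17g}")
    for name in _HEADER_FIELDS:
        lines.append(f" {name} = {getattr(p, name)}")
    lines.append("$END")
    for i, v in enumerate(signal.samples):
        lines.append(f"{i} {v.real:.17g} {v.imag:.17g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_fid(path: str | Path) -> TimeSignal:
    """Parse a text FID; validates the header against the body length."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.replace("\r\n", "\n").split("\n")]
    lines = [ln for ln in lines if ln]
    if not lines or lines[0] != "$FID":
        raise ValueError(f"{path}: missing $FID header")
    try:
        end = lines.index("$END")
    except ValueError:
        raise ValueError(f"{path}: missing $END header terminator") from None
    header: dict[str, str] = {}
    for ln in lines[1:end]:
        if "=" not in ln:
            raise ValueError(f"{path}: malformed header line {ln!r}")
        key, _, val = ln.partition("=")
        header[key.strip()] = val.strip()
    required = set(_HEADER_FIELDS) | {"kind"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"{path}: missing header fields {sorted(missing)}")
    params = AcquisitionParams(
        field_strength_t=float(header["field_strength_t"]),
        te_ms=float(header["te_ms"]),
        tr_ms=float(header["tr_ms"]),
        n_points=int(header["n_points"]),
        bandwidth_hz=float(header["bandwidth_hz"]),
        voxel_edge_cm=float(header["voxel_edge_cm"]),
        n_averages=int(header["n_averages"]),
        n_water_averages=int(header["n_water_averages"]),
    )
    rows = lines[end + 1:]
    if len(rows) != params.n_points:
        raise ValueError(
            f"{path}: header n_points = {params.n_points} but body has "
            f"{len(rows)} samples"
        )
    data = np.empty(params.n_points, dtype=np.complex128)
    for ln in rows:
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"{path}: malformed sample row {ln!r}")
        data[int(parts[0])] = float(parts[1]) + 1j * float(parts[2])
    return TimeSignal(data, params, header["kind"])  # type: ignore[arg-type]


def write_cohort(subjects, out_dir: str | Path) -> Path:
    """Write per-subject FID pairs plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        fid_path = out_dir / f"{s.subject_id}_metab.fid"
        water_path = out_dir / f"{s.subject_id}_water.fid"
        write_fid(s.fid, fid_path)
        write_fid(s.water_ref, water_path)
        rows.append({
            "subject": s.subject_id,
            "tumour_type": s.tumour_type,
            "fid_path": fid_path.name,
            "water_path": water_path.name,
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path: str | Path):
    """Load (subject, type, fid, water) tuples from a manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path)
    out = []
    for _, row in table.iterrows():
        out.append((
            row["subject"], row["tumour_type"],
            read_fid(base / row["fid_path"]),
            read_fid(base / row["water_path"]),
        ))
    return out


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full synthetic run."""

    out_dir: str = "mrsdss_run"
    seed: int = 0
    n_train: dict = field(default_factory=lambda: {"PA": 12, "EP": 4, "MB": 18})
    n_test: dict = field(default_factory=lambda: {"PA": 16, "EP": 3, "MB": 14})
    apply_qc: bool = True
    feature_selection: bool = True
    render_reports: bool = False
    shrinkage: float = 0.1
    fit: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    acquisition: dict = field(default_factory=dict)

    def fit_config(self) -> FitConfig:
        return FitConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in self.fit.items()})

    def qc_criteria(self) -> QCCriteria:
        return QCCriteria(**self.qc)

    def acquisition_params(self) -> AcquisitionParams:
        return AcquisitionParams(**self.acquisition)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls(**(yaml.safe_load(text) or {}))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _quantify_subject(fid, water, basis, fit_cfg):
    """Preprocess + fit one subject; returns (result, features, spectra)."""
    corrected = eddy_current_correct(fid, water)
    water_corr = eddy_current_correct(water, water)
    spec = to_spectrum(corrected)
    spec, _, _ = auto_phase(spec)
    water_spec = to_spectrum(water_corr)
    result = fit_linear_combination(spec, basis, fit_cfg)
    result = water_reference_scale(result, water_spec)
    features = group_mmlip(result)
    return result, features, spec, water_spec


def process_cohort(subjects_or_tuples, basis=None, fit_cfg: FitConfig | None = None):
    """Quantify every subject of a cohort.

    Accepts either ``CohortSubject`` objects or (subject, type, fid,
    water) tuples; returns a list of per-subject records.
    """
    basis = basis or build_default_basis()
    fit_cfg = fit_cfg or FitConfig()
    records = []
    for item in subjects_or_tuples:
        if hasattr(item, "subject_id"):
            sid, ttype, fid, water = item.subject_id, item.tumour_type, item.fid, item.water_ref
        else:
            sid, ttype, fid, water = item
        t0 = time.perf_counter()
        result, features, spec, water_spec = _quantify_subject(fid, water, basis, fit_cfg)
        features.subject = sid
        log.info("quantified %s (%s) in %.2fs", sid, ttype, time.perf_counter() - t0)
        records.append({
            "subject": sid,
            "tumour_type": ttype,
            "result": result,
            "features": features,
            "spectrum": spec,
            "water_spectrum": water_spec,
        })
    return records


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate, preprocess, fit, QC, train, classify and report.

    Stage order mirrors clinical use: process -> fit -> QC ->
    standardize -> classify -> report.  Every output is stamped with the
    config hash and seed, and rerunning an identical config reproduces
    identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    basis = build_default_basis()
    class_params = default_class_params(basis)
    fit_cfg = config.fit_config()
    criteria = config.qc_criteria()

    acq = config.acquisition_params()
    log.info("simulating cohorts (seed=%d)", config.seed)
    train_subjects = sample_cohort(class_params, config.n_train, seed=config.seed,
                                   params=acq)
    test_subjects = sample_cohort(class_params, config.n_test, seed=config.seed + 1,
                                  params=acq)
    write_cohort(train_subjects, out_dir / "train")
    write_cohort(test_subjects, out_dir / "test")

    train_rec = process_cohort(train_subjects, basis, fit_cfg)
    test_rec = process_cohort(test_subjects, basis, fit_cfg)

    if config.apply_qc:
        def keep(recs):
            kept = []
            for r in recs:
                rep = spectrum_qc(r["result"], criteria)
                r["qc"] = rep
                if rep.passed:
                    kept.append(r)
            return kept
        train_kept = keep(train_rec)
        test_kept = keep(test_rec)
    else:
        train_kept, test_kept = list(train_rec), list(test_rec)
        for r in train_rec + test_rec:
            r["qc"] = None

    if not train_kept or not test_kept:
        raise RuntimeError("QC removed every subject; cannot continue")

    feats = [r["features"] for r in train_kept]
    if config.feature_selection:
        selected = select_features(crlb_table(feats), criteria)
        if len(selected) < 2:
            raise RuntimeError("fewer than two features survived selection")
    else:
        selected = list(feats[0].names)

    def matrix(recs):
        X = np.array([
            FeatureVector(r["features"].names, r["features"].values)
            .reorder(tuple(selected))
            for r in recs
        ])
        y = [r["tumour_type"] for r in recs]
        return X, y

    X_train, y_train = matrix(train_kept)
    X_test, y_test = matrix(test_kept)
    model = train_lda(X_train, y_train, feature_names=tuple(selected),
                      shrinkage=config.shrinkage)
    evaluation = evaluate_classifier(model, X_test, y_test)

    pred_rows = []
    for rec, res in zip(test_kept, evaluation.results):
        pred_rows.append({
            "subject": rec["subject"],
            "truth": rec["tumour_type"],
            "predicted": res.predicted,
            "post_PA": res.posteriors.get("PA"),
            "post_EP": res.posteriors.get("EP"),
            "post_MB": res.posteriors.get("MB"),
            "DF1": float(res.df_scores[0]),
            "DF2": float(res.df_scores[1]),
        })
    predictions = pd.DataFrame(pred_rows)
    predictions.to_csv(out_dir / "predictions.csv", index=False,
                       float_format="%.10g")

    model_json = {
        "feature_names": list(model.feature_names),
        "mu": model.mu.tolist(),
        "sigma": model.sigma.tolist(),
        "class_labels": list(model.class_labels),
        "class_means": model.class_means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "priors": model.priors.tolist(),
        "projection": model.projection.tolist(),
        "shrinkage": model.shrinkage,
    }
    (out_dir / "model.json").write_text(json.dumps(model_json, indent=1))

    if config.render_reports:
        norm_specs, labels = [], []
        for r in train_kept:
            spec = r["spectrum"]
            base = np.zeros(len(spec.values))
            mask = spec.window_mask(*fit_cfg.window_ppm)
            base[mask] = r["result"].baseline_curve
            sub = spec.with_values(spec.values - base)
            norm_specs.append(water_normalize(sub, r["water_spectrum"]))
            labels.append(r["tumour_type"])
        class_means = mean_class_spectra(norm_specs, labels)
        train_scores: dict[str, list] = {}
        for rec in train_kept:
            from .classify import apply_lda
            r = apply_lda(model, FeatureVector(rec["features"].names,
                                               rec["features"].values))
            train_scores.setdefault(rec["tumour_type"], []).append(r.df_scores)
        train_scores = {k: np.array(v) for k, v in train_scores.items()}
        rec0, res0 = test_kept[0], evaluation.results[0]
        spec0 = rec0["spectrum"]
        base0 = np.zeros(len(spec0.values))
        mask0 = spec0.window_mask(*fit_cfg.window_ppm)
        base0[mask0] = rec0["result"].baseline_curve
        case_spec = water_normalize(spec0.with_values(spec0.values - base0),
                                    rec0["water_spectrum"])
        render_dss(res0, model, class_means, out_dir / "dss_case.png",
                   case_features=FeatureVector(rec0["features"].names,
                                               rec0["features"].values),
                   case_spectrum=case_spec,
                   training_df_scores=train_scores,
                   case_id=rec0["subject"])

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_train_simulated": sum(config.n_train.values()),
        "n_test_simulated": sum(config.n_test.values()),
        "n_train_after_qc": len(train_kept),
        "n_test_after_qc": len(test_kept),
        "selected_features": list(selected),
        "accuracy_percent": evaluation.accuracy_percent,
        "accuracy_exact": evaluation.accuracy_exact,
        "n_correct": evaluation.n_correct,
        "n_total": evaluation.n_total,
        "confusion": {t: evaluation.confusion.loc[t].to_dict()
                      for t in evaluation.confusion.index},
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    (out_dir / "config.yaml").write_text(config.to_yaml())
    return manifest


__all__ = [
    "write_fid",
    "read_fid",
    "write_cohort",
    "read_cohort",
    "PipelineConfig",
    "process_cohort",
    "run_pipeline",
]
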