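"""File formats, configuration and the batch pipeline.

The ingestion boundary is a CSV of integrated isotopologue fractions —
one row per sample with columns ``sample_id, m0 ... m5`` and optional
per-sample infusion rates — plus a YAML run configuration holding the
ion formula, tracer protocol and fit settings.  ``run_pipeline`` chains
the full per-sample analysis (natural-abundance correction, odd/even
decoding, exact matrix solution, bounded MFA regression, confidence
intervals, precision scores, residual verdict) and writes CSV and JSON
reports; one failing sample is reported, not fatal for the batch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mid import (
    MID,
    IonFormula,
    correct_natural_abundance,
    decode_combined_mid,
    enrichments_from_decoded,
    normalize,
)
from .model import FitConfig, KetoneFluxModel
from .network import TracerProtocol
from .twopool import solve_two_pool

__all__ = [
    "SampleRecord",
    "RunConfig",
    "read_samples",
    "load_run_config",
    "run_pipeline",
]

logger = logging.getLogger("ketoflux")

_MID_COLUMNS = ["m0", "m1", "m2", "m3", "m4", "m5"]
_KNOWN_CONFIG_KEYS = {
    "samples_corrected", "ion_formula", "protocol", "fit", "output_dir",
    "clip_warn_threshold", "with_confidence_intervals",
}
_KNOWN_PROTOCOL_KEYS = {
    "rinf_acac", "rinf_bhb", "measured_conc_acac", "theoretical_conc_acac",
    "measured_conc_bhb", "theoretical_conc_bhb",
}
_KNOWN_FORMULA_KEYS = {"fragment", "n_carbon", "abundance_13c"}


class SchemaError(ValueError):
    """Input file or configuration violates the published schema."""


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    mid: MID
    rinf_acac: float | None = None
    rinf_bhb: float | None = None


def read_samples(path) -> list[SampleRecord]:
    """Read and validate the sample CSV.

    Requires ``sample_id`` and ``m0..m5``; per-sample ``rinf_acac`` /
    ``rinf_bhb`` columns are optional and override the protocol rates.
    Rows with non-numeric, negative or all-zero channels raise a
    :class:`SchemaError` naming the sample.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"sample file not found: {path}")
    frame = pd.read_csv(path)
    missing = [c for c in ["sample_id", *_MID_COLUMNS] if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in frame.iterrows():
        sid = str(row["sample_id"])
        try:
            values = np.array([float(row[c]) for c in _MID_COLUMNS])
        except (TypeError, ValueError) as err:
            raise SchemaError(f"{path}: non-numeric channel in sample "
                              f"{sid!r}: {err}") from None
        if np.any(~np.isfinite(values)):
            raise SchemaError(f"{path}: non-finite channel in sample {sid!r}")
        if np.any(values < 0):
            raise SchemaError(f"{path}: negative channel in sample {sid!r}")
        if values.sum() <= 0:
            raise SchemaError(f"{path}: zero total signal in sample {sid!r}")
        rates = {}
        for key in ("rinf_acac", "rinf_bhb"):
            if key in frame.columns and pd.notna(row[key]):
                rate = float(row[key])
                if rate <= 0:
                    raise SchemaError(f"{path}: non-positive {key} in "
                                      f"sample {sid!r}")
                rates[key] = rate
        records.append(SampleRecord(sample_id=sid, mid=normalize(values),
                                    **rates))
    return records


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration.

    ``samples_corrected`` declares whether the CSV already contains
    natural-abundance-corrected fractions; if False the configured ion
    formula is used to correct each sample before decoding.
    """

    protocol: TracerProtocol = field(default_factory=TracerProtocol)
    fit: FitConfig = field(default_factory=FitConfig)
    ion_formula: IonFormula = field(
        default_factory=IonFormula.carbon_skeleton)
    samples_corrected: bool = True
    clip_warn_threshold: float = 0.005
    with_confidence_intervals: bool = True
    output_dir: Path = Path("ketoflux_out")


def _build_formula(spec: dict) -> IonFormula:
    unknown = set(spec) - _KNOWN_FORMULA_KEYS
    if unknown:
        raise SchemaError(f"unknown ion_formula keys: {sorted(unknown)}")
    if "fragment" in spec:
        return IonFormula.bhb_ion(spec["fragment"])
    return IonFormula.carbon_skeleton(
        n_carbon=spec.get("n_carbon", 4),
        abundance=spec.get("abundance_13c", 0.0107),
    )


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration; unknown keys are
    rejected rather than ignored."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config root must be a mapping")
    unknown = set(raw) - _KNOWN_CONFIG_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    proto_spec = raw.get("protocol", {})
    unknown = set(proto_spec) - _KNOWN_PROTOCOL_KEYS
    if unknown:
        raise SchemaError(f"{path}: unknown protocol keys {sorted(unknown)}")
    protocol = TracerProtocol(**proto_spec)
    fit_spec = raw.get("fit", {})
    try:
        fit = FitConfig(**fit_spec)
    except TypeError as err:
        raise SchemaError(f"{path}: invalid fit settings: {err}") from None
    return RunConfig(
        protocol=protocol,
        fit=fit,
        ion_formula=_build_formula(raw.get("ion_formula", {})),
        samples_corrected=bool(raw.get("samples_corrected", True)),
        clip_warn_threshold=float(raw.get("clip_warn_threshold", 0.005)),
        with_confidence_intervals=bool(
            raw.get("with_confidence_intervals", True)),
        output_dir=Path(raw.get("output_dir", "ketoflux_out")),
    )


def analyse_sample(record: SampleRecord, cfg: RunConfig) -> dict:
    """Full per-sample analysis chain; returns a JSON-serializable
    report."""
    from dataclasses import replace

    mid = record.mid
    if not cfg.samples_corrected:
        mid = correct_natural_abundance(mid, cfg.ion_formula,
                                        cfg.clip_warn_threshold)
    else:
        logger.info("sample %s: natural-abundance correction skipped "
                    "(samples declared corrected)", record.sample_id)
    decoded = decode_combined_mid(mid)
    enrich = enrichments_from_decoded(decoded)
    protocol = cfg.protocol
    if record.rinf_acac is not None:
        protocol = replace(protocol, rinf_acac=record.rinf_acac)
    if record.rinf_bhb is not None:
        protocol = replace(protocol, rinf_bhb=record.rinf_bhb)
    matrix = solve_two_pool(enrich, protocol.effective_rinf_acac,
                            protocol.effective_rinf_bhb,
                            pool_ratio_acac=decoded.acac_fraction)
    fit = KetoneFluxModel(mid, protocol, cfg.fit).fit()
    report = {
        "sample_id": record.sample_id,
        "acac_fraction": decoded.acac_fraction,
        "enrichments": {
            "acac_m2": enrich.acac_m2, "bhb_m2": enrich.bhb_m2,
            "acac_m4": enrich.acac_m4, "bhb_m4": enrich.bhb_m4,
        },
        "matrix": matrix.flux.as_dict(),
        "matrix_implausible": matrix.implausible,
        "matrix_condition_number": matrix.condition_number,
        "mfa": fit.params.to_dict(),
        "ssr": fit.ssr,
        "dof": fit.dof,
        "residual_report": fit.residual_report(),
    }
    if cfg.with_confidence_intervals:
        ci, score = {}, {}
        for name in ("ra_acac", "ra_bhb", "ri_acac", "ri_bhb",
                     "rd_acac", "rd_bhb"):
            lo, hi = fit.conf_int(name)
            v = getattr(fit.flux, name)
            ci[name] = [lo, hi]
            try:
                from .model import precision_score
                score[name] = precision_score(v, min(lo, v), max(hi, v))
            except ValueError:
                score[name] = None
        report["confidence_intervals"] = ci
        report["precision_scores"] = score
    return report


def run_pipeline(samples_path, cfg: RunConfig) -> dict:
    """Analyse every sample in a CSV and write CSV + JSON reports.

    Returns ``{"reports": [...], "errors": [...], "paths": {...}}``.
    A failing sample is isolated: its error is recorded and the rest of
    the batch proceeds.  The process exit status (via the CLI) is
    non-zero if any sample errored.
    """
    records = read_samples(samples_path)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "ketoflux.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    reports, errors = [], []
    try:
        for record in records:
            try:
                reports.append(analyse_sample(record, cfg))
                logger.info("sample %s: ok", record.sample_id)
            except Exception as err:
                errors.append({"sample_id": record.sample_id,
                               "error": str(err)})
                logger.error("sample %s: %s", record.sample_id, err)
    finally:
        logger.removeHandler(handler)
        handler.close()

    json_path = out / "report.json"
    with open(json_path, "w") as fh:
        json.dump({"reports": reports, "errors": errors}, fh, indent=2,
                  default=float)
    rows = []
    for rep in reports:
        row = {"sample_id": rep["sample_id"],
               "verdict": rep["residual_report"]["verdict"],
               "ssr": rep["ssr"]}
        for k, v in rep["mfa"].items():
            row[f"mfa_{k}"] = v
        for k, v in rep["matrix"].items():
            row[f"matrix_{k}"] = v
        if "confidence_intervals" in rep:
            for k, (lo, hi) in rep["confidence_intervals"].items():
                row[f"{k}_lb"], row[f"{k}_ub"] = lo, hi
                row[f"{k}_score"] = rep["precision_scores"][k]
        rows.append(row)
    csv_path = out / "report.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return {
        "reports": reports,
        "errors": errors,
        "paths": {"json": json_path, "csv": csv_path, "log": log_path},
    }
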