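"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages: simulate (or load) a cohort → derive/choose biomarker cut-offs →
classify A/T/N and apply the exclusion cascade → compute composite risk
scores → association battery → ROC model ladder. Every stage writes CSV
artifacts; the manifest records config hash, seeds, row counts and file
digests so identical configs reproduce identical outputs.

A single master seed fans out to per-stage seeds by stable hashing of the
stage name, so stages stay reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import atn, cohort_io, risk_scores, roc, stats, synthetic, thresholds

logger = logging.getLogger("atnpredict")

__all__ = [
    "PipelineConfigError",
    "RunManifest",
    "load_cohort_config",
    "derive_stage_seed",
    "run_pipeline",
]


class PipelineConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int]
    row_counts: dict[str, int] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    cutoffs: dict[str, float] = field(default_factory=dict)
    timestamp: str = ""
    package_version: str = "0.1.0"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def derive_stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{stage}:{master_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _parse_combo(key: str) -> synthetic.Combination:
    key = key.strip().upper()
    if len(key) != 6 or key[0] != "A" or key[2] != "T" or key[4] != "N":
        raise PipelineConfigError(f"bad combination key {key!r}; expected e.g. 'A+T-N-'")
    return tuple(key[i] == "+" for i in (1, 3, 5))  # type: ignore[return-value]


def load_cohort_config(source: str | Path | Mapping[str, Any],
                       seed: int | None = None) -> synthetic.CohortConfig:
    """Build a :class:`synthetic.CohortConfig` from a YAML file or mapping.

    Omitted sections fall back to the published defaults; ``seed`` overrides
    the file's seed when given.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    kwargs: dict[str, Any] = {}
    if "combination_counts" in raw:
        kwargs["combination_counts"] = {
            _parse_combo(k): int(v) for k, v in raw["combination_counts"].items()}
    if "exclusion_counts" in raw:
        ec = raw["exclusion_counts"]
        kwargs["exclusion_counts"] = (
            int(ec["dementia_mci"]), int(ec["cdr"]), int(ec["missing_atn"]))
    if "group_marginals" in raw:
        marg = {}
        for group, values in raw["group_marginals"].items():
            fields = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in values.items()}
            marg[group] = synthetic.CovariateMarginals(**fields)
        kwargs["group_marginals"] = marg
    for key in ("site_count", "abeta_cutoff", "ptau_cutoff",
                "abeta_margin_scale", "ptau_margin_scale", "scheltens_max",
                "missing_rate"):
        if key in raw:
            kwargs[key] = raw[key]
    kwargs["seed"] = int(seed if seed is not None else raw.get("seed", 0))
    return synthetic.CohortConfig(**kwargs)


def _resolve_cutoff(section: Mapping[str, Any], analyte: str,
                    values: np.ndarray, seed: int) -> thresholds.CutoffRule:
    method = section.get("method", "fixed")
    direction = "below" if analyte == "abeta42" else "above"
    if method == "fixed":
        default = (thresholds.ABETA42_CUTOFF if analyte == "abeta42"
                   else thresholds.PTAU_CUTOFF)
        return thresholds.CutoffRule(analyte, float(section.get("value", default)),
                                     direction, "fixed")
    gmm = section.get("gmm", {})
    fit = thresholds.fit_two_component_mixture(
        values, seed=int(gmm.get("seed", seed)),
        n_starts=int(gmm.get("n_starts", 10)), tol=float(gmm.get("tol", 1e-8)))
    if method == "intersection":
        return thresholds.intersection_cutoff(fit, analyte)
    if method == "mean_sd":
        return thresholds.mean_sd_cutoff(
            fit, component=section.get("component", "lower"),
            k_sd=float(section.get("k_sd", 2.0)), analyte=analyte)
    raise PipelineConfigError(f"unknown cut-off method {method!r}")


_DEFAULT_EXPOSURES = ("apoe4_carrier", "family_history", "bmi",
                      "wml_fraction", "mmse_total")


def run_pipeline(config: str | Path | Mapping[str, Any]) -> RunManifest:
    """Execute simulate → cutoffs → classify → score → analyze → roc.

    The config must contain ``seed``, ``output_dir`` and a ``thresholds``
    section, plus either an ``input`` cohort CSV or a ``simulate`` section;
    validation happens before any stage runs.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    else:
        cfg = dict(config)

    for required in ("seed", "output_dir", "thresholds"):
        if required not in cfg:
            raise PipelineConfigError(f"config is missing the {required!r} section")
    if "input" not in cfg and "simulate" not in cfg:
        raise PipelineConfigError("config needs either 'input' or 'simulate'")

    master_seed = int(cfg["seed"])
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stage_seeds = {s: derive_stage_seed(master_seed, s)
                   for s in ("simulate", "cutoffs")}
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest = RunManifest(config_hash=config_hash, master_seed=master_seed,
                           stage_seeds=stage_seeds,
                           timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))

    # --- simulate or load -------------------------------------------------
    if "input" in cfg:
        result = cohort_io.read_cohort(cfg["input"])
        if result.errors:
            logger.warning("rejected %d rows on read", result.n_rejected)
        records = result.records
    else:
        sim_cfg = cfg.get("simulate") or {}
        cohort_config = load_cohort_config(sim_cfg, seed=stage_seeds["simulate"])
        records = synthetic.generate_cohort(cohort_config)
    cohort_path = out_dir / "cohort.csv"
    cohort_io.write_table(records, cohort_path)
    manifest.row_counts["cohort"] = len(records)
    logger.info("stage simulate/load: %d records", len(records))

    # --- cut-offs ---------------------------------------------------------
    thr_cfg = cfg["thresholds"]
    frame = cohort_io.records_to_frame(records)
    abeta_vals = frame["csf_abeta42"].astype(float).dropna().to_numpy()
    ptau_vals = frame["csf_ptau"].astype(float).dropna().to_numpy()
    abeta_rule = _resolve_cutoff(thr_cfg.get("abeta42", {}), "abeta42",
                                 abeta_vals, stage_seeds["cutoffs"])
    ptau_rule = _resolve_cutoff(thr_cfg.get("ptau", {}), "ptau",
                                ptau_vals, stage_seeds["cutoffs"])
    manifest.cutoffs = {"abeta42": abeta_rule.threshold, "ptau": ptau_rule.threshold}
    logger.info("stage cutoffs: abeta42=%.1f ptau=%.1f",
                abeta_rule.threshold, ptau_rule.threshold)

    # --- classify + exclusions -------------------------------------------
    statuses = atn.classify_cohort(records, abeta_rule, ptau_rule)
    analytic, report = atn.apply_exclusions(records, statuses)
    manifest.row_counts.update(
        n_dementia_mci=report.n_dementia_mci, n_cdr=report.n_cdr,
        n_missing_atn=report.n_missing_atn, n_analytic=report.n_analytic)
    logger.info("stage classify: analytic n=%d (excluded %d/%d/%d)",
                report.n_analytic, report.n_dementia_mci, report.n_cdr,
                report.n_missing_atn)
    pd.DataFrame([
        {"stage": "input", "n": report.n_input},
        {"stage": "dementia_or_mci_dx", "n": report.n_dementia_mci},
        {"stage": "cdr_ge_0.5", "n": report.n_cdr},
        {"stage": "missing_atn", "n": report.n_missing_atn},
        {"stage": "analytic", "n": report.n_analytic},
    ]).to_csv(out_dir / "exclusions.csv", index=False)

    a_records = [r for r, _ in analytic]
    a_statuses = [s for _, s in analytic]

    # --- risk scores ------------------------------------------------------
    scores = risk_scores.score_cohort(a_records)
    analysis = stats.build_analysis_frame(a_records, a_statuses, scores)
    analysis.to_csv(out_dir / "atn_scored.csv", index=False)
    manifest.row_counts["scored"] = len(analysis)

    # --- association battery ---------------------------------------------
    exposures = cfg.get("analyze", {}).get("exposures", list(_DEFAULT_EXPOSURES))
    assoc_rows = []
    for exposure in exposures:
        for outcome in ("a_pos", "t_pos", "n_pos"):
            try:
                r = stats.fit_pathology_logistic(analysis, outcome, exposure)
                assoc_rows.append(dataclasses.asdict(r))
            except stats.NonEstimableError as exc:
                logger.warning("logistic %s ~ %s: %s", outcome, exposure, exc)
        try:
            for r in stats.fit_multinomial(analysis, exposure):
                assoc_rows.append(dataclasses.asdict(r))
        except stats.NonEstimableError as exc:
            logger.warning("multinomial ~ %s: %s", exposure, exc)
    pd.DataFrame(assoc_rows).to_csv(out_dir / "associations.csv", index=False)
    manifest.row_counts["associations"] = len(assoc_rows)

    # --- ROC ladder -------------------------------------------------------
    contrasts = cfg.get("roc", {}).get(
        "contrasts", [g for g in stats.GROUP_ORDER[1:]])
    roc_rows = []
    for contrast in contrasts:
        try:
            for res in roc.run_roc_battery(analysis, contrast):
                roc_rows.append({
                    "contrast": res.contrast, "model_id": res.model_id,
                    "auc": res.auc, "auc_ci_low": res.auc_ci_low,
                    "auc_ci_high": res.auc_ci_high,
                    "n_cases": res.n_cases, "n_controls": res.n_controls,
                    "p_vs_basic": res.p_vs_basic})
        except stats.NonEstimableError as exc:
            logger.warning("roc %s: %s", contrast, exc)
    pd.DataFrame(roc_rows).to_csv(out_dir / "roc_results.csv", index=False)
    manifest.row_counts["roc_models"] = len(roc_rows)

    for name in ("cohort.csv", "exclusions.csv", "atn_scored.csv",
                 "associations.csv", "roc_results.csv"):
        manifest.file_digests[name] = _sha256_file(out_dir / name)
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
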