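"""Config-driven orchestration: extraction -> signature -> validation report.

The pipeline mirrors a two-stage radiomics study:

``run_extraction``
    Read every case's volume and rater masks, resample all cases to the
    dataset's per-axis minimum spacing (or an explicit target), merge the
    rater masks under the 5% rule, extract the 620-feature panel and write
    one feature table CSV.

``run_analysis``
    Split the main-site patients 1:1 into training (TC) and internal
    validation (IVC) cohorts by surgery date (earlier half trains, ties
    broken by case id); fit the LASSO-Cox signature on TC; score and
    median-split everyone; per-cohort Kaplan-Meier/log-rank, C-index with
    bootstrap CI and 18/36-month NNE AUCs; fit the combined
    (signature + clinical) and clinical-only Cox models, build the
    nomogram, compare models with DeLong at each horizon and check
    calibration with the Hosmer-Lemeshow test.  Everything lands in one
    deterministic JSON report.

All randomness (bootstrap, simulation) derives from the config seed, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import volume_io
from .features import FEATURE_NAMES, extract_all
from .prognostic import (
    build_nomogram,
    calibration,
    code_clinical,
    delong_compare,
    fit_cox,
    timedep_auc_nne,
)
from .signature import (
    fit_lasso_cox,
    harrell_c,
    kaplan_meier,
    logrank_test,
    median_split,
)
from .volume_io import read_mask, read_volume, resample_to_spacing

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"

CLINICAL_COVARIATES = [
    "age", "figo_stage", "preop_ca125", "postop_ca125",
    "residual", "tumor_side", "menopause",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML via :meth:`from_yaml`."""

    cases: list[dict]                  # id, volume, mask_a/mask_b or mask, [adjudicated]
    clinical_csv: str | None = None    # case_id, time, event, surgery_date, covariates
    output_dir: str = "radsurv_out"
    target_spacing: str | tuple[float, float, float] = "auto-min"
    mask_merge_threshold: float = 0.05
    n_bins: int = 32
    horizons: tuple[float, float] = (18.0, 36.0)
    n_bootstrap: int = 1000
    seed: int = 0
    external_label: str | None = None  # cohort column value mapped to IEVC

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "horizons" in raw:
            raw["horizons"] = tuple(raw["horizons"])
        if isinstance(raw.get("target_spacing"), list):
            raw["target_spacing"] = tuple(raw["target_spacing"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# stage 1: feature extraction
# ---------------------------------------------------------------------------

def _load_case(case: dict, threshold: float):
    vol = read_volume(case["volume"])
    if "mask" in case:
        mask = read_mask(case["mask"])
    else:
        pair = volume_io.RaterPair(read_mask(case["mask_a"]),
                                   read_mask(case["mask_b"]))
        adj = read_mask(case["adjudicated"]) if "adjudicated" in case else None
        mask = volume_io.merge_masks(pair, threshold, adj)
    if vol.shape != mask.shape:
        raise ValueError(f"case {case['id']}: volume/mask grids differ")
    return vol, mask


def run_extraction(config: PipelineConfig) -> tuple[Path, list[str]]:
    """Extract the 620-feature panel for every case; returns (csv, failures)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    loaded: dict[str, tuple] = {}
    failures: list[str] = []
    for case in config.cases:
        cid = str(case["id"])
        try:
            loaded[cid] = _load_case(case, config.mask_merge_threshold)
        except Exception as exc:
            logger.error("case %s failed to load: %s", cid, exc)
            failures.append(cid)

    if not loaded:
        raise RuntimeError("no case could be loaded")

    if config.target_spacing == "auto-min":
        target = volume_io.dataset_min_spacing(v for v, _ in loaded.values())
    else:
        target = tuple(config.target_spacing)  # type: ignore[arg-type]
    logger.info("common target spacing: %s mm", target)

    rows = {}
    for cid, (vol, mask) in loaded.items():
        t0 = _time.perf_counter()
        try:
            rvol, rmask = resample_to_spacing(vol, mask, target)
            assert rvol.spacing == tuple(target)
            rows[cid] = extract_all(rvol, rmask, config.n_bins)
            logger.info("case %s: 620 features in %.2fs",
                        cid, _time.perf_counter() - t0)
        except Exception as exc:
            logger.error("case %s failed: %s", cid, exc)
            failures.append(cid)

    table = pd.DataFrame(rows).T.reindex(columns=FEATURE_NAMES)
    table.index.name = "case_id"
    table = table.sort_index()
    csv_path = out_dir / "features.csv"
    table.to_csv(csv_path, float_format="%.12g")
    if failures:
        logger.warning("%d case(s) failed: %s", len(failures), failures)
    return csv_path, failures


# ---------------------------------------------------------------------------
# stage 2: survival analysis
# ---------------------------------------------------------------------------

def assign_cohorts(clinical: pd.DataFrame, external_label: str | None = None
                   ) -> pd.Series:
    """TC/IVC 1:1 split by surgery date (stable, ties by case id).

    Rows whose ``cohort`` column equals ``external_label`` become IEVC and
    are excluded from the split.
    """
    cohort = pd.Series("", index=clinical.index, dtype=object)
    internal = clinical.index
    if external_label is not None and "cohort" in clinical:
        ext = clinical["cohort"] == external_label
        cohort[ext] = "IEVC"
        internal = clinical.index[~ext]
    sub = clinical.loc[internal]
    order = sub.sort_values(["surgery_date", "case_id"], kind="stable").index
    n_tc = (len(order) + 1) // 2
    cohort[order[:n_tc]] = "TC"
    cohort[order[n_tc:]] = "IVC"
    return cohort


def _cohort_block(sig, time, event, tc_median, horizons, n_boot, seed):
    strat = median_split(sig, tc_median)
    block: dict = {"n": int(len(sig)), "n_events": int(event.sum()),
                   "n_high_risk": int(strat.is_high.sum())}
    if strat.is_high.any() and (~strat.is_high).any():
        chi2, p = logrank_test((time[strat.is_high], event[strat.is_high]),
                               (time[~strat.is_high], event[~strat.is_high]))
        block["logrank_chi2"], block["logrank_p"] = chi2, p
    c, ci = harrell_c(sig, (time, event), n_boot=n_boot, seed=seed)
    block["c_index"] = c
    block["c_index_ci"] = list(ci)
    km = kaplan_meier((time, event))
    block["km_survival_at_horizon"] = {
        str(h): float(km.predict(h)) for h in horizons}
    for h in horizons:
        try:
            roc = timedep_auc_nne(sig, (time, event), h)
            block[f"auc_{int(h)}m"] = roc.auc
        except ValueError as exc:
            block[f"auc_{int(h)}m"] = None
            logger.warning("AUC at %s months unavailable: %s", h, exc)
    return block


def _horizon_binary(time, event, t):
    """Case/control labels at horizon t; censored-before-t excluded."""
    case = (event == 1) & (time <= t)
    control = time > t
    evaluable = case | control
    return evaluable, case[evaluable].astype(int)


def run_analysis(config: PipelineConfig, features_csv: str | Path | None = None
                 ) -> Path:
    """Run the full survival analysis; returns the report JSON path."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    features_csv = Path(features_csv or out_dir / "features.csv")
    feats = pd.read_csv(features_csv, index_col="case_id")
    feats.index = feats.index.astype(str)
    if config.clinical_csv is None:
        raise ValueError("clinical_csv is required for analysis")
    clinical = pd.read_csv(config.clinical_csv)
    clinical["case_id"] = clinical["case_id"].astype(str)
    clinical = clinical[clinical["case_id"].isin(feats.index)].reset_index(drop=True)
    clinical = code_clinical(clinical)

    cohort = assign_cohorts(clinical, config.external_label)
    clinical = clinical.assign(cohort_assigned=cohort.values)
    X = feats.loc[clinical["case_id"]].reset_index(drop=True)
    time = clinical["time"].to_numpy(float)
    event = clinical["event"].to_numpy(int)
    is_tc = (clinical["cohort_assigned"] == "TC").to_numpy()

    rng = np.random.default_rng(config.seed)
    seeds = {k: int(rng.integers(2**31))
             for k in ("boot_tc", "boot_ivc", "boot_ievc", "boot_models")}

    # --- radiomic signature -----------------------------------------------
    sig_fit = fit_lasso_cox(X[is_tc].reset_index(drop=True),
                            (time[is_tc], event[is_tc]))
    signature = np.asarray(sig_fit.signature(X), dtype=float)
    tc_median = float(np.median(signature[is_tc]))

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "horizons_months": list(config.horizons),
        "signature": {
            "lambda": sig_fit.lambda_,
            "n_selected": sig_fit.n_selected,
            "coefficients": {k: float(v)
                             for k, v in sig_fit.coefficients.items()},
            "tc_median": tc_median,
        },
        "cohorts": {},
    }

    for label, sel, skey in (("TC", is_tc, "boot_tc"),
                             ("IVC", ~is_tc & (cohort != "IEVC").values, "boot_ivc"),
                             ("IEVC", (cohort == "IEVC").values, "boot_ievc")):
        if sel.sum() == 0:
            continue
        report["cohorts"][label] = _cohort_block(
            signature[sel], time[sel], event[sel], tc_median,
            config.horizons, config.n_bootstrap, seeds[skey])

    # --- multivariable models on TC ---------------------------------------
    clin_cols = [c for c in CLINICAL_COVARIATES if c in clinical.columns]
    combined = clinical[clin_cols].copy()
    combined.insert(0, "radiomic_signature", signature)
    tc_surv = (time[is_tc], event[is_tc])

    models: dict = {}
    try:
        full_fit = fit_cox(combined[is_tc].reset_index(drop=True), tc_surv)
        clin_fit = fit_cox(clinical.loc[is_tc, clin_cols].reset_index(drop=True),
                           tc_surv)
        ranges = {c: (float(combined[c].min()), float(combined[c].max()))
                  for c in combined.columns}
        nomogram = build_nomogram(full_fit, ranges, config.horizons)
        models["nomogram_coefficients"] = {
            k: float(v) for k, v in full_fit.coefficients.items()}
        models["clinical_coefficients"] = {
            k: float(v) for k, v in clin_fit.coefficients.items()}
        nomo_table = nomogram.to_table()
        nomo_table.to_csv(out_dir / "nomogram_points.csv", index=False,
                          float_format="%.10g")

        for h in config.horizons:
            key = f"{int(h)}m"
            p_full = 1.0 - full_fit.predict_survival(combined[is_tc], h)
            p_clin = 1.0 - clin_fit.predict_survival(clinical.loc[is_tc, clin_cols], h)
            evaluable, label_bin = _horizon_binary(time[is_tc], event[is_tc], h)
            if 0 < label_bin.sum() < len(label_bin):
                try:
                    auc_a, auc_b, p = delong_compare(
                        p_full[evaluable], p_clin[evaluable], label_bin)
                    models[f"delong_{key}"] = {
                        "auc_nomogram": auc_a, "auc_clinical": auc_b, "p": p}
                except ValueError as exc:
                    logger.warning("DeLong at %s months skipped: %s", h, exc)
            try:
                cal = calibration(p_full, tc_surv, h)
                models[f"calibration_{key}"] = {
                    "hl_chi2": cal.hl_chi2, "hl_p": cal.hl_p,
                    "bins": cal.bins.to_dict("records")}
            except ValueError as exc:
                logger.warning("calibration at %s months skipped: %s", h, exc)
                models[f"calibration_{key}"] = None
    except RuntimeError as exc:
        logger.warning("multivariable modelling skipped: %s", exc)
        models["error"] = str(exc)
    report["models"] = models

    # deterministic serialisation
    def _round(o):
        if isinstance(o, float):
            return round(o, 10)
        if isinstance(o, dict):
            return {k: _round(v) for k, v in o.items()}
        if isinstance(o, list):
            return [_round(v) for v in o]
        return o

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(_round(report), sort_keys=True, indent=2))
    (out_dir / "signature.json").write_text(sig_fit.to_json(tc_median))
    return report_path
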