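"""End-to-end pipeline: simulate -> features -> screen -> cluster -> fit ->
calibrate -> report.

Each stage seeds its randomness from the master seed, logs what it did,
and writes its artifact under the output directory with the run id.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import calibrate as cal
from . import cohort as syn
from .decorrelate import assignments_frame, decorrelate as _decorrelate
from . import io as nio
from . import lasso
from . import screen as scr
from .config import RunConfig
from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    table: nio.FeatureTable
    screen: pd.DataFrame
    clusters: pd.DataFrame
    candidates: list[str]
    split: lasso.SplitPlan
    ensemble: lasso.BootstrapEnsemble
    final_rows: list[lasso.FinalModelRow]
    final_fit: lasso.LassoFit
    calibration: cal.CalibrationTable
    report: str


def select_candidates(
    table: nio.FeatureTable,
    screen_df: pd.DataFrame,
    train_ids: list[str],
    config: RunConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Assemble the multivariate candidate list.

    Dosimetric variables of the endpoint's structures are decorrelated per
    structure on the *training* rows, keeping one representative per
    cluster (best |rs| with the endpoint).  Clinical variables enter when
    they passed the univariate screen; the exclusion list (by default dose
    per fraction and fraction number, which duplicate treatment days) is
    removed last.
    """
    structures = config.endpoint_structures.get(config.endpoint)
    if structures is None:
        raise DataError(f"no structure mapping for endpoint {config.endpoint!r}")
    rs_map = dict(zip(screen_df["feature"], screen_df["rs"]))

    assignments = []
    reduced: list[str] = []
    train = table.data.loc[train_ids]
    for s in structures:
        cols = [c for c in table.dosimetric if c.startswith(f"{s}_")]
        if not cols:
            raise DataError(f"no dosimetric features for structure {s!r}")
        constant = [c for c in cols if train[c].nunique() <= 1]
        if constant:
            logger.info("dropping constant dosimetric feature(s): %s", constant)
            cols = [c for c in cols if c not in constant]
        if len(cols) == 1:
            reduced.extend(cols)
            continue
        rs_sub = {c: rs_map.get(c, 0.0) for c in cols}
        rs_sub = {c: 0.0 if pd.isna(v) else v for c, v in rs_sub.items()}
        asg, reps = _decorrelate(
            train[cols], rs_sub, threshold=config.correlation_threshold
        )
        assignments.extend(asg)
        reduced.extend(reps)

    passed = set(scr.candidate_features(screen_df))
    clinical = [c for c in table.clinical if c in passed]
    candidates = [*reduced, *clinical]
    candidates = [c for c in candidates if c not in config.exclude_features]
    # drop anything constant on the training rows: uninformative and
    # breaks standardization-based selection
    candidates = [c for c in candidates if train[c].nunique() > 1]
    return assignments_frame(assignments), candidates


def run_pipeline(config: RunConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rid = config.run_id
    t0 = time.time()

    # -- data ---------------------------------------------------------------
    if config.synthetic_n_patients is not None:
        spec = syn.default_spec(
            n_patients=config.synthetic_n_patients, seed=config.stage_seed("simulate")
        )
        cohort = syn.generate_cohort(spec)
        dvhs, records, grades = list(cohort.dvhs), list(cohort.clinical), cohort.grades
        nio.write_dvh_csv(dvhs, out / f"{rid}_dvh.csv")
        nio.write_clinical_csv(records, out / f"{rid}_clinical.csv", grades=grades)
        syn.write_truth_json(cohort.truth, out / f"{rid}_truth.json")
        logger.info("simulated cohort of %d patients", len(records))
    else:
        dvhs = nio.read_dvh_csv(config.dvh_csv)
        records, grades = nio.read_clinical_csv(config.clinical_csv)
    if config.endpoint not in grades.columns:
        raise DataError(f"no grades for endpoint {config.endpoint!r}")

    # -- features -----------------------------------------------------------
    table = nio.build_feature_table(
        dvhs,
        records,
        grades=grades,
        alpha_beta=config.alpha_beta,
        dx_grid=config.dx_grid,
        fractional_on_physical=config.fractional_on_physical,
    )
    nio.write_feature_csv(table, out / f"{rid}_features.csv")

    endpoint = config.endpoint
    g = table.grades(endpoint)
    y = table.binary(endpoint)

    # -- univariate screen --------------------------------------------------
    screen_df = scr.screen_features(
        table.data[table.feature_names],
        g,
        endpoint,
        alpha=config.screening_alpha,
        always_include=config.always_include,
    )
    screen_df.to_csv(out / f"{rid}_screen.csv", index=False)

    # -- split + decorrelation ---------------------------------------------
    subtype = {r.patient_id: r.subtype for r in records}
    outcome = {pid: int(v) for pid, v in y.items()}
    split = lasso.stratified_split(
        list(table.data.index),
        subtype,
        outcome,
        fractions=config.split_fractions,
        seed=config.stage_seed("split"),
    )
    clusters_df, candidates = select_candidates(
        table, screen_df, list(split.train_ids), config
    )
    clusters_df.to_csv(out / f"{rid}_clusters.csv", index=False)
    logger.info("candidate features: %s", candidates)

    # -- bootstrap LASSO ----------------------------------------------------
    X_train = table.data.loc[list(split.train_ids), candidates]
    X_val = table.data.loc[list(split.validation_ids), candidates]
    y_train = y.loc[list(split.train_ids)].to_numpy()
    y_val = y.loc[list(split.validation_ids)].to_numpy()
    ensemble = lasso.bootstrap_ensemble(
        X_train,
        y_train,
        X_val,
        y_val,
        n_boot=config.n_boot,
        lambda_rule=config.lambda_rule,
        seed=config.stage_seed("bootstrap"),
        run_id=rid,
    )
    ensemble.selection_counts.to_frame().reset_index(names="feature").to_csv(
        out / f"{rid}_selection_frequency.csv", index=False
    )
    ensemble.pair_counts.to_csv(out / f"{rid}_pair_frequency.csv")
    final_rows, final_fit = lasso.final_model(
        X_train, y_train, ensemble, config.lambda_rule, seed=config.stage_seed("final")
    )
    lasso.final_model_frame(final_rows).to_csv(out / f"{rid}_final_model.csv", index=False)
    with open(out / f"{rid}_ensemble.json", "w") as fh:
        json.dump(
            {
                "run_id": rid,
                "seed": config.seed,
                "n_boot": ensemble.n_boot,
                "mean_auc": ensemble.mean_auc,
                "sd_auc": ensemble.sd_auc,
                "n_redrawn": ensemble.n_redrawn,
                "candidates": candidates,
                "selection_counts": ensemble.selection_counts.to_dict(),
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    # -- calibration + report ----------------------------------------------
    preds = final_fit.predict_proba(X_val)
    calibration = cal.calibration_bins(
        preds,
        y_val,
        n_bins=config.calibration_bins,
        patient_ids=list(split.validation_ids),
        run_id=rid,
    )
    calibration.table.to_csv(out / f"{rid}_calibration.csv", index=False)

    report = cal.build_report(
        rid,
        ensemble,
        final_rows,
        calibration,
        screen_df,
        clusters_df,
        config={
            "endpoint": endpoint,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "screening_alpha": config.screening_alpha,
            "correlation_threshold": config.correlation_threshold,
            "lambda_rule": config.lambda_rule,
        },
    )
    (out / f"{rid}_report.md").write_text(report)
    logger.info("pipeline finished in %.1f s", time.time() - t0)

    return PipelineResult(
        config=config,
        table=table,
        screen=screen_df,
        clusters=clusters_df,
        candidates=candidates,
        split=split,
        ensemble=ensemble,
        final_rows=final_rows,
        final_fit=final_fit,
        calibration=calibration,
        report=report,
    )
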