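"""End-to-end orchestration: simulate -> preprocess -> split -> select ->
train -> evaluate -> platform transfer -> report.

Every stage draws from an explicit seed (simulation / split / selection are
independent so each source of randomness can be pinned separately), and a
manifest of every parameter and output digest is written so a run can be
reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as spio
from .classifier import (
    PenaltySpec,
    FittedModel,
    evaluate,
    fit_glm,
    loocv_evaluate,
    predict_scores,
    report_from_scores,
    stratified_split,
)
from .cohortsim import (
    ROLE_BLANK,
    ROLE_QC,
    ROLE_STUDY,
    CLINICAL_COLUMNS,
    CohortConfig,
    FeatureTable,
    add_internal_standard,
    simulate_cohort,
    simulate_targeted_remeasurement,
)
from .cohort_stats import (
    group_summary,
    severity_and_survival_contrasts,
    univariate_marker_table,
)
from .panel_select import SelectionParams, SelectionResult, select_panel
from .preprocess import (
    FeatureFilterParams,
    apply_transform,
    filter_features,
    fit_transform,
    internal_standard_normalize,
    merge_coeluting_features,
    qc_normalize,
    subtract_blank,
)

log = logging.getLogger(__name__)


@dataclass
class TransferConfig:
    """Targeted low-resolution re-measurement settings."""

    n_shock: int = 32
    n_nonshock: int = 30
    cv_noise: float = 0.15
    loading_cv: float = 0.10
    train_frac: float = 0.7


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults reproduce the packaged demo."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    filter_params: FeatureFilterParams = field(default_factory=FeatureFilterParams)
    selection: SelectionParams = field(default_factory=SelectionParams)
    penalty: PenaltySpec = field(default_factory=lambda: PenaltySpec(kind="elastic_net", C=None))
    train_frac: float = 0.7
    seed_split: int = 1
    seed_selection: int = 2
    transfer: TransferConfig = field(default_factory=TransferConfig)
    feature_table_path: str | None = None   # load instead of simulating
    sample_table_path: str | None = None
    outdir: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            cohort=CohortConfig(**raw.get("cohort", {})),
            filter_params=FeatureFilterParams(**raw.get("filter_params", {})),
            selection=SelectionParams(**raw.get("selection", {})),
            penalty=PenaltySpec(**raw.get("penalty", {})) if "penalty" in raw
            else PenaltySpec(kind="elastic_net", C=None),
            train_frac=raw.get("train_frac", 0.7),
            seed_split=raw.get("seed_split", 1),
            seed_selection=raw.get("seed_selection", 2),
            transfer=TransferConfig(**raw.get("transfer", {})),
            feature_table_path=raw.get("feature_table_path"),
            sample_table_path=raw.get("sample_table_path"),
            outdir=raw.get("outdir"),
        )


def _asdict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return clean(d)


# ---------------------------------------------------------------------------

def preprocess_table(table: FeatureTable, samples: pd.DataFrame,
                     params: FeatureFilterParams) -> FeatureTable:
    """Standard cleaning chain on the untargeted table.

    Filter on intensity/SNR (evaluated on study samples), remove blank
    background, merge coeluting features, correct QC drift, then drop
    non-study injections.
    """
    study_ids = list(samples.index[samples["role"] == ROLE_STUDY])
    blank_ids = list(samples.index[samples["role"] == ROLE_BLANK])
    table = filter_features(table, params=params,
                            study_ids=[s for s in study_ids if s in table.intensities.index])
    if blank_ids:
        table = subtract_blank(table, blank_ids, params)
    table = merge_coeluting_features(table, params)
    n_qc = int((samples["role"] == ROLE_QC).sum())
    if n_qc >= 3:
        table = qc_normalize(table, samples)
    else:
        log.warning("fewer than 3 QC injections; drift correction skipped")
    keep = [s for s in table.intensities.index if s in study_ids]
    return table.restrict(sample_ids=keep)


def _train_and_eval(train_tab: pd.DataFrame, test_tab: pd.DataFrame,
                    y_train, y_test, penalty: PenaltySpec):
    """Fit transform+model on train, report resubstitution, LOOCV and test."""
    state = fit_transform(train_tab)
    Xtr = apply_transform(state, train_tab)
    model = fit_glm(Xtr, y_train, penalty)
    model.transform = state
    train_report = evaluate(model, Xtr, y_train)
    loocv_report = loocv_evaluate(train_tab, y_train, refit_transform=True)
    Xte = apply_transform(state, test_tab)
    test_report = evaluate(model, Xte, y_test)
    return model, train_report, loocv_report, test_report


def _intercept_only(y_train) -> FittedModel:
    p = float(np.mean(np.asarray(y_train) == "shock")) if np.asarray(y_train).dtype.kind in "OUS" \
        else float(np.mean(y_train))
    p = min(max(p, 1e-6), 1 - 1e-6)
    return FittedModel(float(np.log(p / (1 - p))), np.array([]), [])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole workflow; returns the report bundle and, when
    ``config.outdir`` is set, writes every artifact plus a manifest."""
    bundle: dict = {}
    stage = "simulate"
    try:
        if config.feature_table_path:
            table = spio.read_feature_table(config.feature_table_path)
            samples = spio.read_sample_table(config.sample_table_path)
            truth = None
        else:
            table, samples, truth = simulate_cohort(config.cohort)
        bundle["truth"] = truth

        stage = "preprocess"
        clean = preprocess_table(table, samples, config.filter_params)
        study = samples.loc[clean.intensities.index]
        y_all = study["label"]

        stage = "split"
        train_ids, test_ids = stratified_split(study, config.train_frac, config.seed_split)
        y_train, y_test = y_all[train_ids], y_all[test_ids]

        stage = "select"
        sel_params = dataclasses.replace(config.selection, seed=config.seed_selection)
        state0 = fit_transform(clean.intensities.loc[train_ids])
        Xtr_full = apply_transform(state0, clean.intensities.loc[train_ids])
        selection = select_panel(Xtr_full, y_train, sel_params)
        bundle["selection"] = selection
        panel = selection.panel or selection.candidates

        stage = "train"
        if panel:
            model, train_rep, loocv_rep, test_rep = _train_and_eval(
                clean.intensities.loc[train_ids, panel],
                clean.intensities.loc[test_ids, panel],
                y_train, y_test, config.penalty,
            )
        else:  # no informative features survived selection
            model = _intercept_only(y_train)
            scores_tr = np.full(len(train_ids), predict_scores(model, np.empty((1, 0)))[0])
            scores_te = np.full(len(test_ids), scores_tr[0])
            train_rep = report_from_scores(scores_tr, y_train)
            loocv_rep = train_rep
            test_rep = report_from_scores(scores_te, y_test)
        bundle["model"] = model
        bundle["panel"] = panel
        bundle["train_report"] = train_rep
        bundle["loocv_report"] = loocv_rep
        bundle["test_report"] = test_rep

        stage = "clinical_model"
        clin = study[list(CLINICAL_COLUMNS)].astype(float)
        if clin.notna().all().all():
            _, clin_train, clin_loocv, clin_test = _train_and_eval(
                clin.loc[train_ids], clin.loc[test_ids], y_train, y_test,
                PenaltySpec(kind="l2", C=1.0),
            )
            bundle["clinical_train_report"] = clin_train
            bundle["clinical_test_report"] = clin_test

        stage = "stats"
        clin_cols = [c for c in CLINICAL_COLUMNS if c in study.columns]
        if clin_cols and study[clin_cols].notna().all().all():
            bundle["clinical_summary"] = group_summary(study, clin_cols)
        if panel:
            logX = np.log10(clean.intensities[panel].where(clean.intensities[panel] > 0))
            bundle["univariate"] = univariate_marker_table(logX, y_all)
            bundle["contrasts"] = severity_and_survival_contrasts(logX, samples, panel)

        stage = "transfer"
        if panel:
            bundle["transfer"] = _transfer_experiment(clean, samples, panel, config)

        stage = "report"
        if config.outdir:
            _write_bundle(bundle, config)
        return bundle
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _transfer_experiment(clean: FeatureTable, samples: pd.DataFrame,
                         panel: list[str], config: RunConfig) -> dict:
    """Re-measure the panel on the low-resolution platform and re-train.

    The remeasured table gets per-sample loading variation plus a spiked
    internal standard; IS normalization removes the loading factor before
    the transfer model is fit on its own 70/30 split.
    """
    tc = config.transfer
    seed = config.cohort.seed + 7919
    counts = samples.loc[clean.intensities.index, "label"].value_counts()
    n_shock = min(tc.n_shock, int(counts.get("shock", 0)))
    n_nonshock = min(tc.n_nonshock, int(counts.get("nonshock", 0)))
    lrms = simulate_targeted_remeasurement(
        clean, samples, panel, tc.cv_noise, n_shock, n_nonshock, seed)
    lrms = add_internal_standard(lrms, seed + 1, loading_cv=tc.loading_cv)
    lrms = internal_standard_normalize(lrms, "IS_PC_d7")
    sub = samples.loc[lrms.intensities.index]
    tr_ids, te_ids = stratified_split(sub, tc.train_frac, config.seed_split + 1)
    y_tr, y_te = sub.loc[tr_ids, "label"], sub.loc[te_ids, "label"]
    model, train_rep, loocv_rep, test_rep = _train_and_eval(
        lrms.intensities.loc[tr_ids], lrms.intensities.loc[te_ids],
        y_tr, y_te, config.penalty)
    return {
        "n_samples": len(lrms.intensities),
        "model": model,
        "train_report": train_rep,
        "loocv_report": loocv_rep,
        "test_report": test_rep,
    }


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    spio.write_model(bundle["model"], out / "model.json")
    if isinstance(bundle.get("selection"), SelectionResult):
        spio.write_selection(bundle["selection"], out / "selection.json")
        if bundle["selection"].trace:
            from .panel_select import plot_trace
            plot_trace(bundle["selection"], out / "elimination_trace.png")
    report_keys = ("train_report", "loocv_report", "test_report",
                   "clinical_train_report", "clinical_test_report")
    rows = []
    for key in report_keys:
        if key in bundle:
            spio.write_report(bundle[key], out / f"{key}.json")
            rows.append({"report": key, **bundle[key].to_dict()})
    if bundle.get("transfer"):
        rows.append({"report": "transfer_test_report",
                     **bundle["transfer"]["test_report"].to_dict()})
    pd.DataFrame(rows).to_csv(out / "reports.csv", index=False)
    spio.write_roc_points(bundle["test_report"], out / "test_roc.csv")
    if bundle.get("univariate") is not None:
        bundle["univariate"].to_csv(out / "univariate_markers.csv")
    if bundle.get("contrasts") is not None:
        bundle["contrasts"].to_csv(out / "severity_survival_contrasts.csv", index=False)
        per_marker = {
            f: df.drop(columns="feature_id").to_dict(orient="records")
            for f, df in bundle["contrasts"].groupby("feature_id")
        }
        (out / "marker_contrasts.json").write_text(
            json.dumps(per_marker, indent=2, sort_keys=True, default=float))
    if bundle.get("clinical_summary") is not None:
        bundle["clinical_summary"].to_csv(out / "clinical_summary.csv")
    if bundle.get("transfer"):
        spio.write_report(bundle["transfer"]["test_report"], out / "transfer_test_report.json")
    summary = summarize(bundle)
    (out / "summary.txt").write_text(summary)
    manifest = {
        "config": _asdict(config),
        "panel": bundle.get("panel", []),
        "outputs": {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                    for p in sorted(out.iterdir()) if p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def summarize(bundle: dict) -> str:
    """Human-readable run summary."""
    lines = ["septic-shock metabolite-panel pipeline", "=" * 40]
    panel = bundle.get("panel", [])
    sel = bundle.get("selection")
    if sel is not None and len(sel.candidates):
        lines.append(f"candidates after frequency selection : {len(sel.candidates)}")
    lines.append(f"final panel size                     : {len(panel)}")
    for key, label in (("train_report", "train (resubstitution)"),
                       ("loocv_report", "train (LOOCV)"),
                       ("test_report", "test"),
                       ("clinical_test_report", "clinical covariates, test")):
        rep = bundle.get(key)
        if rep is None:
            continue
        d = rep.to_dict()
        lines.append(
            f"{label:<37}: acc {d['accuracy']}%  sens {d['sensitivity']}%  "
            f"spec {d['specificity']}%  AUROC {d['auroc']}"
        )
    if bundle.get("transfer"):
        d = bundle["transfer"]["test_report"].to_dict()
        lines.append(
            f"{'targeted platform (LRMS), test':<37}: acc {d['accuracy']}%  "
            f"sens {d['sensitivity']}%  spec {d['specificity']}%  AUROC {d['auroc']}"
        )
    return "\n".join(lines) + "\n"
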