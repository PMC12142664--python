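"""CSV/JSON interchange for tables, panels, models and reports.

A FeatureTable is written as two CSVs: the intensity matrix (first column
``sample_id``, one column per feature id) and a sidecar feature-annotation
table (``feature_id``, ``mz``, ``rt`` and any extra columns, e.g. ``snr``).
SampleTables are plain CSVs keyed by ``sample_id``. An MRM panel is a CSV
with one row per transition (``feature_id``, ``precursor_mz``,
``product_mz``); several transitions may map to one metabolite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import FittedModel, PerformanceReport
from .cohortsim import FeatureTable, validate_sample_table
from .panel_select import SelectionResult
from .preprocess import TransformState


# ---------------------------------------------------------------------------
# feature / sample tables

def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write ``<path>`` (intensities) and ``<stem>.features.csv`` sidecar."""
    path = Path(path)
    table.intensities.rename_axis("sample_id").to_csv(path)
    table.features.rename_axis("feature_id").to_csv(_sidecar(path))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".features.csv") if path.suffix == ".csv" \
        else Path(str(path) + ".features.csv")


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers, check raw
        header = fh.readline().rstrip("\n").split(",")[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValueError(f"{path}: duplicate feature id {name!r}")
        seen.add(name)
    inten = pd.read_csv(path, index_col="sample_id")
    bad = inten.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    nonnum = inten.notna() & bad.isna()
    if nonnum.any().any():
        r, c = np.argwhere(nonnum.to_numpy())[0]
        # +2: header line plus 1-based counting
        raise ValueError(f"{path}: non-numeric intensity at line {r + 2}, column {inten.columns[c]!r}")
    feats = pd.read_csv(_sidecar(path), index_col="feature_id")
    return FeatureTable(bad.astype(float), feats)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples.rename_axis("sample_id").to_csv(path)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, index_col="sample_id")
    if samples.index.duplicated().any():
        dup = samples.index[samples.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    validate_sample_table(samples)
    return samples


# ---------------------------------------------------------------------------
# MRM panel

def read_mrm_panel(path: str | Path) -> pd.DataFrame:
    """Transitions grouped per metabolite feature.

    Returns a frame indexed by feature_id with ``n_transitions`` and the
    transition lists; several precursor->product transitions per metabolite
    are expected.
    """
    raw = pd.read_csv(path)
    required = {"feature_id", "precursor_mz", "product_mz"}
    if not required.issubset(raw.columns):
        raise ValueError(f"{path}: MRM panel needs columns {sorted(required)}")
    for col in ("precursor_mz", "product_mz"):
        bad = pd.to_numeric(raw[col], errors="coerce").isna() & raw[col].notna()
        if bad.any():
            raise ValueError(f"{path}: non-numeric {col} at line {int(np.flatnonzero(bad)[0]) + 2}")
    grouped = raw.groupby("feature_id").agg(
        n_transitions=("product_mz", "size"),
        precursor_mz=("precursor_mz", lambda s: sorted(s.astype(float))),
        product_mz=("product_mz", lambda s: sorted(s.astype(float))),
    )
    return grouped


# ---------------------------------------------------------------------------
# models / selection results / reports

def model_to_dict(model: FittedModel) -> dict:
    d = {
        "intercept": model.intercept,
        "coefficients": dict(zip(model.feature_ids, model.coefficients.tolist())),
        "feature_ids": list(model.feature_ids),
        "threshold": model.threshold,
    }
    if model.transform is not None:
        t = model.transform
        d["transform"] = {
            "floor": t.floor[t.feature_ids].to_dict(),
            "mean": t.mean[t.feature_ids].to_dict(),
            "sd": t.sd[t.feature_ids].to_dict(),
            "feature_ids": list(t.feature_ids),
            "dropped": list(t.dropped),
        }
    return d


def model_from_dict(d: dict) -> FittedModel:
    transform = None
    if "transform" in d:
        t = d["transform"]
        transform = TransformState(
            floor=pd.Series(t["floor"]), mean=pd.Series(t["mean"]),
            sd=pd.Series(t["sd"]), feature_ids=list(t["feature_ids"]),
            dropped=list(t["dropped"]),
        )
    return FittedModel(
        intercept=d["intercept"],
        coefficients=np.array([d["coefficients"][f] for f in d["feature_ids"]]),
        feature_ids=list(d["feature_ids"]),
        transform=transform,
        threshold=d.get("threshold", 0.5),
    )


def write_model(model: FittedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2, sort_keys=True))


def read_model(path: str | Path) -> FittedModel:
    return model_from_dict(json.loads(Path(path).read_text()))


def selection_to_dict(result: SelectionResult) -> dict:
    return {
        "frequency": {k: int(v) for k, v in result.frequency.dropna().items()},
        "weight_sum": {k: float(v) for k, v in result.weight_sum.dropna().items()},
        "candidates": list(result.candidates),
        "trace": [[int(n), f, float(m)] for n, f, m in result.trace],
        "panel": list(result.panel),
    }


def write_selection(result: SelectionResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(selection_to_dict(result), indent=2, sort_keys=True))


def report_to_dict(report: PerformanceReport) -> dict:
    return report.to_dict()


def write_report(report: PerformanceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=True))


def write_roc_points(report: PerformanceReport, path: str | Path) -> None:
    pd.DataFrame(report.roc_points, columns=["fpr", "tpr"]).to_csv(path, index=False)
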