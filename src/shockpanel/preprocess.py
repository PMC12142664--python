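"""Feature-table cleaning and normalization.

The rules implemented here are the table-level processing steps applied
after vendor peak picking: absolute-intensity and signal-to-noise
filtering, procedural-blank background removal, grouping of coeluting
near-isobaric features within a ppm/retention-time window, pooled-QC
drift correction, internal-standard normalization for the targeted
platform, and the train-fitted log10/autoscale transform that produces
the model matrix.

All threshold comparisons are strict (">" / "<"). The QC drift correction
follows the QC-RLSC pattern: a locally weighted curve through the QC
intensities versus injection order, by which every sample is divided; a
feature is left untouched whenever correction would *increase* its QC
relative standard deviation, so the correction is non-degrading by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohortsim import ROLE_QC, FeatureTable

log = logging.getLogger(__name__)


@dataclass
class FeatureFilterParams:
    """Thresholds for feature-level quality filtering.

    min_intensity/min_snr gate extraction (strict >); ppm_tol/rt_tol define
    the coelution window (strict <); blank_fold is the study/blank mean
    ratio a feature must exceed to survive background subtraction.
    """

    min_intensity: float = 100_000.0
    min_snr: float = 10.0
    ppm_tol: float = 5.0
    rt_tol: float = 0.5
    blank_fold: float = 3.0

    def __post_init__(self) -> None:
        for name in ("min_intensity", "min_snr", "ppm_tol", "rt_tol", "blank_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# filtering

def filter_features(
    table: FeatureTable,
    snr: pd.Series | None = None,
    params: FeatureFilterParams | None = None,
    study_ids: list[str] | None = None,
) -> FeatureTable:
    """Keep features with max study intensity > min_intensity and SNR > min_snr.

    ``snr`` defaults to the table's own ``snr`` annotation. The intensity
    criterion is evaluated on each feature's maximum across ``study_ids``
    (all samples if not given).
    """
    params = params or FeatureFilterParams()
    if snr is None:
        if "snr" not in table.features.columns:
            raise ValueError("no snr annotation on table and none supplied")
        snr = table.features["snr"]
    missing = [f for f in table.feature_ids if f not in snr.index]
    if missing:
        raise ValueError(f"snr missing for features: {missing[:5]}")
    inten = table.intensities if study_ids is None else table.intensities.loc[study_ids]
    max_int = inten.max(axis=0, skipna=True).fillna(0.0)
    keep = (max_int > params.min_intensity) & (snr.loc[table.feature_ids] > params.min_snr)
    kept = [f for f in table.feature_ids if keep[f]]
    for f in table.feature_ids:
        if not keep[f]:
            log.info("filter_features dropped %s (max=%.3g, snr=%.3g)",
                     f, max_int[f], snr[f])
    return table.restrict(feature_ids=kept)


def subtract_blank(
    table: FeatureTable,
    blank_ids: list[str],
    params: FeatureFilterParams | None = None,
) -> FeatureTable:
    """Remove background features and drop the blank injections.

    A feature is background when its mean study intensity does not exceed
    ``blank_fold`` times its mean blank intensity.
    """
    params = params or FeatureFilterParams()
    if not blank_ids:
        raise ValueError("blank_ids must be non-empty")
    missing = set(blank_ids) - set(table.intensities.index)
    if missing:
        raise KeyError(f"blank samples not in table: {sorted(missing)}")
    study_rows = table.intensities.drop(index=list(blank_ids))
    blank_mean = table.intensities.loc[list(blank_ids)].mean(axis=0, skipna=True).fillna(0.0)
    study_mean = study_rows.mean(axis=0, skipna=True).fillna(0.0)
    keep = study_mean > params.blank_fold * blank_mean
    kept = [f for f in table.feature_ids if keep[f]]
    for f in table.feature_ids:
        if not keep[f]:
            log.info("subtract_blank dropped %s (study mean %.3g <= %g x blank %.3g)",
                     f, study_mean[f], params.blank_fold, blank_mean[f])
    out = table.restrict(feature_ids=kept)
    return FeatureTable(out.intensities.drop(index=list(blank_ids)), out.features)


# ---------------------------------------------------------------------------
# coelution merging

def merge_coeluting_features(
    table: FeatureTable,
    params: FeatureFilterParams | None = None,
) -> FeatureTable:
    """Single-linkage grouping of features within the m/z ppm and RT windows.

    Two features are linked when |dmz|/mz < ppm_tol (ppm, evaluated against
    the smaller mz) and |drt| < rt_tol; connected components are merged.
    Each group becomes one feature: per-sample maximum intensity over the
    members, intensity-weighted mean m/z and RT, and the id of the most
    intense member.
    """
    params = params or FeatureFilterParams()
    n = len(table.feature_ids)
    if n == 0:
        return table
    mz = table.features["mz"].to_numpy(dtype=float)
    rt = table.features["rt"].to_numpy(dtype=float)
    order = np.argsort(mz)
    rows, cols = [], []
    # sweep over mz-sorted features; the ppm window is tiny so each feature
    # only needs to look at a short run of neighbours
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            if (mz[j] - mz[i]) / mz[i] >= params.ppm_tol * 1e-6:
                break
            if abs(rt[i] - rt[j]) < params.rt_tol:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp == n:
        return table

    inten = table.intensities.to_numpy(dtype=float)
    mean_int = np.nanmean(np.where(np.isnan(inten), 0.0, inten), axis=0)
    new_cols, new_ids, new_mz, new_rt, new_extra = [], [], [], [], []
    extra_cols = [c for c in table.features.columns if c not in ("mz", "rt")]
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        rep = members[np.argmax(mean_int[members])]
        w = mean_int[members]
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1.0 / len(members))
        block = inten[:, members]
        all_nan = np.all(np.isnan(block), axis=1)
        merged = np.max(np.where(np.isnan(block), -np.inf, block), axis=1)
        merged = np.where(all_nan, np.nan, merged)
        new_cols.append(merged)
        new_ids.append(table.feature_ids[rep])
        new_mz.append(float(w @ mz[members]))
        new_rt.append(float(w @ rt[members]))
        new_extra.append(table.features.iloc[rep][extra_cols])
        if len(members) > 1:
            log.info("merged %d coeluting features into %s",
                     len(members), table.feature_ids[rep])
    feat = pd.DataFrame({"mz": new_mz, "rt": new_rt},
                        index=pd.Index(new_ids, name=table.features.index.name))
    for c in extra_cols:
        feat[c] = [e[c] for e in new_extra]
    inten_df = pd.DataFrame(np.column_stack(new_cols),
                            index=table.intensities.index, columns=new_ids)
    # keep the original column order of the representatives
    rep_order = [f for f in table.feature_ids if f in set(new_ids)]
    return FeatureTable(inten_df[rep_order], feat.loc[rep_order])


# ---------------------------------------------------------------------------
# pooled-QC drift correction

def qc_normalize(table: FeatureTable, samples: pd.DataFrame) -> FeatureTable:
    """Divide every sample by a per-feature drift curve fit through the QCs.

    The curve is a LOWESS fit of QC intensity against injection order
    (linear interpolation when fewer than 5 QCs are available), evaluated
    at every injection and clamped to the QC range at the run's edges.
    After division the feature is rescaled to its QC median. Features whose
    QC relative standard deviation would increase are left unchanged.
    """
    qc_ids = samples.index[samples["role"] == ROLE_QC]
    qc_ids = [s for s in qc_ids if s in table.intensities.index]
    orders_qc = samples.loc[qc_ids, "injection_order"].to_numpy(dtype=float)
    if len(qc_ids) < 3 or len(np.unique(orders_qc)) < 3:
        raise ValueError(
            "qc_normalize needs >= 3 QC samples with distinct injection orders; "
            "skip normalization explicitly if the run has fewer"
        )
    common = [s for s in table.intensities.index if s in samples.index]
    if len(common) != len(table.intensities.index):
        raise KeyError("all table samples must appear in the sample table")
    orders_all = samples.loc[table.intensities.index, "injection_order"].to_numpy(dtype=float)

    out = table.intensities.copy()
    qc_pos = np.argsort(orders_qc)
    x_qc = orders_qc[qc_pos]
    qc_mask = table.intensities.index.isin(qc_ids)
    qc_row_order = np.array([list(table.intensities.index).index(s) for s in qc_ids])
    for f in table.feature_ids:
        y_qc = table.intensities[f].to_numpy(dtype=float)[qc_row_order][qc_pos]
        ok = np.isfinite(y_qc) & (y_qc > 0)
        if ok.sum() < 3:
            continue
        curve = _drift_curve(x_qc[ok], y_qc[ok], orders_all)
        if curve is None or np.any(~np.isfinite(curve)) or np.any(curve <= 0):
            continue
        col = table.intensities[f].to_numpy(dtype=float)
        corrected = col / curve
        qc_med = np.nanmedian(corrected[qc_mask])
        if not np.isfinite(qc_med) or qc_med <= 0:
            continue
        corrected *= np.nanmedian(y_qc[ok]) / qc_med
        if _rsd(corrected[qc_mask]) <= _rsd(col[qc_mask]) + 1e-12:
            out[f] = corrected
    return FeatureTable(out, table.features.copy())


def _drift_curve(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray) -> np.ndarray | None:
    """Smooth positive drift curve through (x, y), evaluated at x_eval."""
    if len(x) >= 5:
        fit = lowess(y, x, frac=2 / 3, it=0, return_sorted=True)
        xs, ys = fit[:, 0], fit[:, 1]
    else:
        xs, ys = x, y
    curve = np.interp(np.clip(x_eval, xs[0], xs[-1]), xs, ys)
    return curve


def _rsd(v: np.ndarray) -> float:
    v = v[np.isfinite(v)]
    if len(v) < 2 or np.mean(v) == 0:
        return np.inf
    return float(np.std(v, ddof=1) / np.mean(v))


# ---------------------------------------------------------------------------
# internal-standard normalization (targeted platform)

def internal_standard_normalize(table: FeatureTable, is_feature: str) -> FeatureTable:
    """Divide every sample by its spiked internal-standard intensity.

    The IS column is consumed (it would be identically 1) and dropped.
    """
    if is_feature not in table.intensities.columns:
        raise KeyError(f"internal standard {is_feature!r} not in table")
    is_vals = table.intensities[is_feature]
    bad = is_vals.index[~np.isfinite(is_vals) | (is_vals <= 0)]
    if len(bad):
        raise ValueError(f"internal standard missing or zero in samples: {list(bad)}")
    inten = table.intensities.div(is_vals, axis=0).drop(columns=[is_feature])
    return FeatureTable(inten, table.features.drop(index=[is_feature]))


# ---------------------------------------------------------------------------
# model-matrix transform (train-fitted)

@dataclass
class TransformState:
    """Per-feature log10 + autoscaling parameters learned on training data.

    ``floor`` (half the minimum positive training intensity) imputes
    missing/non-positive values before the log; ``mean``/``sd`` are the
    training statistics of the logged values; zero-variance features are
    dropped and recorded.
    """

    floor: pd.Series
    mean: pd.Series
    sd: pd.Series
    feature_ids: list[str]
    dropped: list[str]


def fit_transform(train: FeatureTable | pd.DataFrame) -> TransformState:
    inten = train.intensities if isinstance(train, FeatureTable) else train
    if len(inten) < 2:
        raise ValueError("need at least 2 training samples")
    vals = inten.to_numpy(dtype=float)
    pos = np.where(vals > 0, vals, np.nan)
    with np.errstate(all="ignore"):
        floor = np.nanmin(pos, axis=0) / 2.0
    floor = np.where(np.isfinite(floor), floor, 1.0)
    logv = np.log10(np.where(np.isfinite(vals) & (vals > 0), vals, floor[None, :]))
    mean = logv.mean(axis=0)
    sd = logv.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [f for f, k in zip(inten.columns, keep) if not k]
    for f in dropped:
        log.warning("fit_transform dropped zero-variance feature %s", f)
    cols = pd.Index(inten.columns)
    return TransformState(
        floor=pd.Series(floor, index=cols),
        mean=pd.Series(mean, index=cols),
        sd=pd.Series(sd, index=cols),
        feature_ids=[f for f, k in zip(cols, keep) if k],
        dropped=dropped,
    )


def apply_transform(state: TransformState, table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Model matrix: floor-impute, log10, center and scale with train stats."""
    inten = table.intensities if isinstance(table, FeatureTable) else table
    missing = [f for f in state.feature_ids if f not in inten.columns]
    if missing:
        raise KeyError(f"table lacks transformed features: {missing[:5]}")
    sub = inten[state.feature_ids]
    vals = sub.to_numpy(dtype=float)
    floor = state.floor[state.feature_ids].to_numpy()
    logv = np.log10(np.where(np.isfinite(vals) & (vals > 0), vals, floor[None, :]))
    z = (logv - state.mean[state.feature_ids].to_numpy()) / state.sd[state.feature_ids].to_numpy()
    return pd.DataFrame(z, index=sub.index, columns=state.feature_ids)
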