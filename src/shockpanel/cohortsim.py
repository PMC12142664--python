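"""Synthetic LC-MS cohort generator.

Emulates the data structure of a single-center septic-shock metabolomics
study: an untargeted serum feature table over ~2892 ion features for a
124-patient emergency-department cohort (32 septic shock vs 92 nonseptic
shock, the latter pooled from noninfectious controls, nonseptic infection
and nonshock sepsis), with pooled-QC injections tracking instrument drift,
a procedural blank, weakly informative clinical covariates, 28-day
survival coupled to the planted metabolic signal, and a smaller targeted
re-measurement on a second (low-resolution) platform.

A configurable subset of features ("markers") carries a class-dependent
mean shift on the log10-intensity scale; severity subgroups receive graded
fractions of that shift so that severity/survival contrasts exist by
construction. The marker feature ids and effect signs are returned as
ground truth so selection recall can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# core containers

ROLE_STUDY = "study"
ROLE_QC = "qc"
ROLE_BLANK = "blank"

SUBGROUPS = ("control", "infection", "sepsis", "shock")
#: fraction of the full marker shift received by each severity subgroup
SEVERITY_FRACTION = {"control": 0.0, "infection": 1 / 3, "sepsis": 2 / 3, "shock": 1.0}

CLINICAL_COLUMNS = ("crp", "pct", "lactate", "wbc")


@dataclass
class FeatureTable:
    """Samples x ion-features intensity matrix with per-feature annotation.

    ``intensities`` is indexed by sample id with one column per feature id;
    missing (below detection) values are NaN. ``features`` is indexed by
    feature id and carries at least ``mz`` (Th) and ``rt`` (min); the
    simulator also attaches ``snr``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.features.index):
            raise ValueError("intensity columns and feature annotation index disagree")
        if self.features.index.duplicated().any():
            dupes = self.features.index[self.features.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)}")
        if self.intensities.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if not {"mz", "rt"}.issubset(self.features.columns):
            raise ValueError("feature annotation must provide mz and rt")
        if (self.features["mz"] <= 0).any():
            raise ValueError("mz must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("rt must be non-negative")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def restrict(self, sample_ids=None, feature_ids=None) -> "FeatureTable":
        """Sub-table on the given samples and/or features (order preserved)."""
        inten = self.intensities
        feats = self.features
        if sample_ids is not None:
            missing = set(sample_ids) - set(inten.index)
            if missing:
                raise KeyError(f"unknown sample ids: {sorted(missing)}")
            inten = inten.loc[list(sample_ids)]
        if feature_ids is not None:
            missing = set(feature_ids) - set(inten.columns)
            if missing:
                raise KeyError(f"unknown feature ids: {sorted(missing)}")
            inten = inten[list(feature_ids)]
            feats = feats.loc[list(feature_ids)]
        return FeatureTable(inten.copy(), feats.copy())


def validate_sample_table(samples: pd.DataFrame) -> None:
    """Check the SampleTable contract (roles, labels, injection orders)."""
    required = {"role", "label", "subgroup", "survival28", "injection_order"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if samples["injection_order"].duplicated().any():
        raise ValueError("injection_order values must be unique")
    study = samples[samples["role"] == ROLE_STUDY]
    if study["label"].isna().any():
        raise ValueError("every study sample needs a class label")
    bad = study[(study["label"] == "shock") != (study["subgroup"] == "shock")]
    if len(bad):
        raise ValueError(f"label/subgroup mismatch for samples {list(bad.index)}")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class CohortConfig:
    """Parameters of the simulated discovery cohort.

    Subgroup sizes default to the enrollment diagram (28 noninfectious
    controls, 34 nonseptic infections, 32 nonshock sepsis, 32 septic shock);
    the clinical table instead reports 92 nonshock patients in total, so the
    28/32/32 variant is available by setting ``n_infection=32``.
    """

    n_shock: int = 32
    n_control: int = 28
    n_infection: int = 34
    n_sepsis_nonshock: int = 32
    n_features: int = 2892
    n_markers: int = 22
    n_markers_up: int = 9
    marker_effect: float = 1.5          # Cohen's d, shock vs pooled nonshock, log10 scale
    baseline_log_mean: float = 5.5      # log10 intensity location across features
    baseline_log_sd: float = 0.35       # within-feature biological SD (log10)
    feature_spread_sd: float = 0.6      # between-feature spread of log10 means
    marker_effect_cv: float = 0.25      # per-marker lognormal spread of the effect size (mean 1)
    response_mean: float = 0.75         # mean of the per-patient Beta response factor
    response_sd: float = 0.25           # SD of each response factor (0 = homogeneous response)
    n_response_axes: int = 6            # independent pathway axes the markers load on
    qc_every: int = 10                  # a pooled-QC injection after every k study injections
    qc_noise_sd: float = 0.05           # technical SD of QC replicates (log10)
    drift_amplitude: float = 0.10       # fractional intensity change across the run
    missing_rate: float = 0.02          # left-censoring probability per intensity
    background_frac: float = 0.02       # fraction of non-marker features that are blank-level background
    mortality_rate_shock: float = 0.375
    mortality_rate_nonshock: float = 0.228
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_shock, self.n_control, self.n_infection,
                  self.n_sepsis_nonshock, self.n_features, self.n_markers,
                  self.n_markers_up)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_markers > self.n_features:
            raise ValueError("n_markers cannot exceed n_features")
        if self.n_markers_up > self.n_markers:
            raise ValueError("n_markers_up cannot exceed n_markers")
        if self.marker_effect < 0:
            raise ValueError("marker_effect must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.marker_effect_cv < 0:
            raise ValueError("marker_effect_cv must be non-negative")
        if not 0 < self.response_mean <= 1:
            raise ValueError("response_mean must lie in (0, 1]")
        if self.response_sd < 0:
            raise ValueError("response_sd must be non-negative")
        if self.response_sd ** 2 >= self.response_mean * (1 - self.response_mean) \
                and self.response_sd > 0:
            raise ValueError("response_sd too large for a Beta response factor")
        if self.n_response_axes < 1:
            raise ValueError("n_response_axes must be >= 1")
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")

    @property
    def n_study(self) -> int:
        return self.n_shock + self.n_control + self.n_infection + self.n_sepsis_nonshock

    def subgroup_counts(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "infection": self.n_infection,
            "sepsis": self.n_sepsis_nonshock,
            "shock": self.n_shock,
        }


def _response_beta_params(config: CohortConfig) -> tuple[float, float] | None:
    """(alpha, beta) of the per-patient response factor, or None if fixed."""
    mu, sd = config.response_mean, config.response_sd
    if sd == 0:
        return None
    nu = mu * (1 - mu) / sd ** 2 - 1
    return mu * nu, (1 - mu) * nu


def _expected_cohens_d(delta: float, config: CohortConfig) -> float:
    """Shock-vs-pooled-nonshock standardized difference (equal-n pooling)
    implied by a raw log10 shift ``delta``.

    Accounts for the graded severity fractions and the per-patient response
    factor, both of which add between-patient variance on top of the
    biological SD.
    """
    counts = config.subgroup_counts()
    n_non = counts["control"] + counts["infection"] + counts["sepsis"]
    mu_r, var_r = config.response_mean, config.response_sd ** 2
    s2 = config.baseline_log_sd ** 2
    if n_non == 0:
        return delta * mu_r / math.sqrt(s2 + delta ** 2 * var_r)
    fr = np.array([SEVERITY_FRACTION[g] for g in ("control", "infection", "sepsis")])
    w = np.array([counts["control"], counts["infection"], counts["sepsis"]], dtype=float)
    w /= w.sum()
    mbar = float(w @ fr)
    # E[(f*r)^2] - E[f*r]^2 over the nonshock pool
    e_f2 = float(w @ fr ** 2)
    var_non = delta ** 2 * (e_f2 * (var_r + mu_r ** 2) - (mbar * mu_r) ** 2)
    var_shock = delta ** 2 * var_r
    pooled = math.sqrt(s2 + (var_shock + var_non) / 2.0)
    return delta * mu_r * (1 - mbar) / pooled


def _marker_shift(config: CohortConfig) -> float:
    """Raw log10 shift between a fully responding shock patient and a
    control, solved so the planted Cohen's d equals ``marker_effect``."""
    d = config.marker_effect
    if d == 0:
        return 0.0
    from scipy.optimize import brentq

    hi = 1.0
    while _expected_cohens_d(hi, config) < d:
        hi *= 2.0
        if hi > 1e3:
            raise ValueError(
                "marker_effect unattainable under the configured severity "
                "gradient and response heterogeneity"
            )
    return float(brentq(lambda x: _expected_cohens_d(x, config) - d, 0.0, hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# simulation

def _drift_factor(order: np.ndarray, n_total: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative drift across the run: 1 at the first injection,
    1 + amplitude at the last, with a mild sinusoidal wobble."""
    t = (order - 1) / max(n_total - 1, 1)
    return 1.0 + amplitude * (t + 0.1 * np.sin(2 * np.pi * t)) / 1.0


def simulate_cohort(config: CohortConfig):
    """Generate (FeatureTable, SampleTable, ground_truth).

    ground_truth is a dict with the planted marker ids, their effect signs
    (+1 shifted up in shock, -1 shifted down), the background feature ids
    and the log10 shift applied.
    """
    rng = np.random.default_rng(config.seed)
    n_feat = config.n_features

    feature_ids = [f"F{i + 1:04d}" for i in range(n_feat)]
    mz = rng.uniform(70.0, 1000.0, n_feat)
    rt = rng.uniform(0.5, 20.0, n_feat)
    snr = 10.0 ** rng.normal(1.7, 0.4, n_feat)  # median ~50, some below 10
    base_mean = rng.normal(config.baseline_log_mean, config.feature_spread_sd, n_feat)

    marker_idx = rng.choice(n_feat, size=config.n_markers, replace=False)
    # panel metabolites are, by construction, confidently detected compounds:
    # keep their SNR and abundance clear of the extraction thresholds
    snr[marker_idx] = np.maximum(snr[marker_idx], 15.0)
    base_mean[marker_idx] = np.maximum(base_mean[marker_idx],
                                       config.baseline_log_mean - 0.3)
    signs = np.zeros(n_feat)
    signs[marker_idx[: config.n_markers_up]] = 1.0
    signs[marker_idx[config.n_markers_up:]] = -1.0
    delta = _marker_shift(config)

    non_marker = np.setdiff1d(np.arange(n_feat), marker_idx)
    n_bg = int(round(config.background_frac * len(non_marker)))
    background_idx = rng.choice(non_marker, size=n_bg, replace=False) if n_bg else np.array([], dtype=int)

    # --- sample bookkeeping -------------------------------------------------
    subgroups: list[str] = []
    for g in SUBGROUPS:
        subgroups += [g] * config.subgroup_counts()[g]
    subgroups = list(np.array(subgroups)[rng.permutation(len(subgroups))])
    study_ids = [f"S{i + 1:03d}" for i in range(len(subgroups))]

    # injection sequence: blank first, then study samples with a pooled QC
    # after every qc_every-th study injection (plus one leading QC)
    records = []
    order = 1
    records.append(("BLANK1", ROLE_BLANK, None, None, None, order)); order += 1
    qc_n = 1
    records.append((f"QC{qc_n:02d}", ROLE_QC, None, None, None, order)); order += 1
    for k, (sid, grp) in enumerate(zip(study_ids, subgroups), start=1):
        label = "shock" if grp == "shock" else "nonshock"
        records.append((sid, ROLE_STUDY, label, grp, None, order)); order += 1
        if k % config.qc_every == 0 or k == len(study_ids):
            qc_n += 1
            records.append((f"QC{qc_n:02d}", ROLE_QC, None, None, None, order)); order += 1
    samples = pd.DataFrame(
        records,
        columns=["sample_id", "role", "label", "subgroup", "survival28", "injection_order"],
    ).set_index("sample_id")
    n_inject = len(samples)

    # --- log-intensity matrix ----------------------------------------------
    frac = samples["subgroup"].map(SEVERITY_FRACTION).to_numpy(dtype=float)
    log_m = np.tile(base_mean, (n_inject, 1))
    is_study = (samples["role"] == ROLE_STUDY).to_numpy()
    is_qc = (samples["role"] == ROLE_QC).to_numpy()
    is_blank = (samples["role"] == ROLE_BLANK).to_numpy()

    # per-marker effect heterogeneity (mean-one lognormal) and a shared
    # per-patient severity factor: a patient's overall metabolic response
    # moves up- and down-markers jointly, giving the within-class marker
    # correlation real panels show; the per-marker within-class SD stays
    # baseline_log_sd, so the marginal Cohen's d stays calibrated
    if config.marker_effect_cv > 0:
        s_het = math.sqrt(math.log(1.0 + config.marker_effect_cv ** 2))
        effect_mult = np.ones(n_feat)
        effect_mult[marker_idx] = np.exp(rng.normal(-s_het ** 2 / 2, s_het, len(marker_idx)))
    else:
        effect_mult = np.ones(n_feat)
    delta_f = signs * delta * effect_mult

    # per-patient, per-pathway response factors: disease severity expresses
    # the metabolic shift to a patient-specific degree along a handful of
    # partially independent pathway axes; markers load round-robin on the
    # axes. This leaves borderline patients at every panel size while each
    # marker keeps unique information beyond its axis-mates.
    n_study = int(is_study.sum())
    n_axes = min(config.n_response_axes, max(config.n_markers, 1))
    ab = _response_beta_params(config)
    response = (rng.beta(ab[0], ab[1], (n_study, n_axes)) if ab is not None
                else np.full((n_study, n_axes), config.response_mean))
    axis_of = np.zeros(n_feat, dtype=int)
    axis_of[marker_idx] = np.arange(len(marker_idx)) % n_axes
    resp_f = response[:, axis_of]          # (n_study, n_feat)
    log_m[is_study] += frac[is_study, None] * resp_f * delta_f[None, :]
    log_m[is_study] += rng.normal(0.0, config.baseline_log_sd, (n_study, n_feat))

    # QCs: pooled mean of the study population plus small technical noise
    counts = config.subgroup_counts()
    w = np.array([counts[g] for g in SUBGROUPS], dtype=float)
    w /= w.sum() if w.sum() else 1.0
    pooled_frac = float(w @ np.array([SEVERITY_FRACTION[g] for g in SUBGROUPS]))
    log_m[is_qc] += pooled_frac * config.response_mean * delta_f[None, :]
    log_m[is_qc] += rng.normal(0.0, config.qc_noise_sd, (is_qc.sum(), n_feat))

    # procedural blank: near-zero background except for designated
    # background features, which sit at study-level intensity
    blank_log = base_mean - 2.5 + rng.normal(0.0, 0.2, n_feat)
    blank_log[background_idx] = base_mean[background_idx] + rng.normal(0.0, 0.1, len(background_idx))
    log_m[is_blank] = blank_log

    inten = 10.0 ** log_m
    inten *= _drift_factor(samples["injection_order"].to_numpy(dtype=float),
                           n_inject, config.drift_amplitude)[:, None]

    # left-censoring at a per-feature detection limit (study + QC only)
    if config.missing_rate > 0:
        censorable = is_study | is_qc
        limits = np.nanquantile(inten[censorable], config.missing_rate, axis=0)
        censored = inten < limits[None, :]
        censored[~censorable] = False
        inten[censored] = np.nan

    intensities = pd.DataFrame(inten, index=samples.index, columns=feature_ids)
    features = pd.DataFrame({"mz": mz, "rt": rt, "snr": snr},
                            index=pd.Index(feature_ids, name="feature_id"))
    table = FeatureTable(intensities, features)

    # --- 28-day survival coupled to the planted marker score ----------------
    marker_ids = [feature_ids[i] for i in marker_idx]
    study_mask = samples["role"] == ROLE_STUDY
    score = _marker_score(np.log10(np.where(np.isnan(inten), limits[None, :] / 2, inten)
                                   if config.missing_rate > 0 else inten),
                          signs)[study_mask.to_numpy()]
    score_z = (score - score.mean()) / (score.std() or 1.0)
    surv = pd.Series(index=samples.index, dtype=object)
    labels = samples.loc[study_mask, "label"]
    for label, rate in (("shock", config.mortality_rate_shock),
                        ("nonshock", config.mortality_rate_nonshock)):
        m = (labels == label).to_numpy()
        if not m.any():
            continue
        z = score_z[m]
        icpt = _solve_logit_intercept(z, rate)
        p_death = 1.0 / (1.0 + np.exp(-(icpt + z)))
        died = rng.random(m.sum()) < p_death
        surv.loc[labels.index[m]] = np.where(died, "dead", "alive")
    samples["survival28"] = surv

    _attach_clinical(samples, rng)
    validate_sample_table(samples)

    truth = {
        "marker_ids": marker_ids,
        "signs": {feature_ids[i]: int(signs[i]) for i in marker_idx},
        "background_ids": [feature_ids[i] for i in background_idx],
        "log10_shift": delta,
    }
    return table, samples, truth


def _marker_score(log_inten: np.ndarray, signs: np.ndarray) -> np.ndarray:
    m = signs != 0
    if not m.any():
        return np.zeros(log_inten.shape[0])
    return log_inten[:, m] @ signs[m]


def _solve_logit_intercept(z: np.ndarray, target_rate: float) -> float:
    """Intercept a such that mean(sigmoid(a + z)) == target_rate (bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if np.mean(1.0 / (1.0 + np.exp(-(mid + z)))) < target_rate:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _attach_clinical(samples: pd.DataFrame, rng: np.random.Generator) -> None:
    """Weakly informative admission covariates (CRP, PCT, lactate, WBC),
    log-normal around the clinical table's group means."""
    params = {  # (nonshock mean, shock mean, log10 sd)
        "crp": (10.2, 14.3, 0.30),
        "pct": (3.7, 9.3, 0.45),
        "lactate": (20.1, 43.5, 0.25),
        "wbc": (10900.0, 16400.0, 0.20),
    }
    study = samples["role"] == ROLE_STUDY
    shock = (samples["label"] == "shock") & study
    for col, (m0, m1, sd) in params.items():
        vals = pd.Series(np.nan, index=samples.index)
        for mask, m in ((study & ~shock, m0), (shock, m1)):
            n = int(mask.sum())
            if n:
                vals.loc[mask] = 10.0 ** rng.normal(np.log10(m), sd, n)
        samples[col] = vals


# ---------------------------------------------------------------------------
# targeted (low-resolution platform) re-measurement

def simulate_targeted_remeasurement(
    table: FeatureTable,
    samples: pd.DataFrame,
    panel: list[str],
    cv_noise: float,
    n_shock: int,
    n_nonshock: int,
    seed: int,
) -> FeatureTable:
    """Re-measure a metabolite panel on a second platform.

    Subsamples ``n_shock`` shock and ``n_nonshock`` nonshock study samples,
    keeps only the panel features, and multiplies each intensity by an
    independent mean-one lognormal error with coefficient of variation
    ``cv_noise`` (the platform-transfer measurement error). ``cv_noise=0``
    reproduces the source values exactly.
    """
    unknown = [f for f in panel if f not in table.intensities.columns]
    if unknown:
        raise KeyError(f"panel features not in table: {unknown}")
    if cv_noise < 0:
        raise ValueError("cv_noise must be non-negative")
    rng = np.random.default_rng(seed)
    study = samples[samples["role"] == ROLE_STUDY]
    picks: list[str] = []
    for label, n in (("shock", n_shock), ("nonshock", n_nonshock)):
        pool = study.index[study["label"] == label].to_numpy()
        if n > len(pool):
            raise ValueError(f"requested {n} {label} samples, only {len(pool)} available")
        picks += sorted(rng.choice(pool, size=n, replace=False))
    out = table.restrict(sample_ids=picks, feature_ids=list(panel))
    if cv_noise > 0:
        sigma = math.sqrt(math.log(1.0 + cv_noise ** 2))
        err = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, out.intensities.shape))
        out = FeatureTable(out.intensities * err, out.features)
    return out


def add_internal_standard(
    table: FeatureTable,
    seed: int,
    loading_cv: float = 0.10,
    is_id: str = "IS_PC_d7",
    is_level: float = 1e6,
) -> FeatureTable:
    """Inject a spiked internal standard plus per-sample loading variation.

    Every sample's intensities (including the added IS column, nominally at
    the 2-ppm spike level) are multiplied by a lognormal per-sample loading
    factor, emulating injection-volume/ionization variation that
    internal-standard normalization is meant to remove.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + loading_cv ** 2)) if loading_cv > 0 else 0.0
    loading = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, len(table.intensities)))
    inten = table.intensities.mul(loading, axis=0)
    inten[is_id] = is_level * loading
    feats = pd.concat([
        table.features,
        pd.DataFrame({"mz": [746.6], "rt": [15.0], "snr": [1000.0]}, index=[is_id]),
    ])
    feats.index.name = table.features.index.name
    return FeatureTable(inten, feats)
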