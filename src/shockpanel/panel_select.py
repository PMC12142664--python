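"""Two-step metabolite-panel selection.

Step 1 — frequency-based stability selection: a sparsity-penalized
(elastic-net) binomial model is fit on 20 class-stratified 90% subsamples
of the training set; a feature "receives weight" in an iteration when its
coefficient is nonzero, and features weighted in at least 10 of the 20
iterations (frequency >= 50%) are retained as candidates. Without
sparsity every feature would receive weight in every iteration and the
frequency rule would be vacuous; a pure L1 penalty errs the other way,
because once a handful of correlated markers explain the training labels
it zeroes the rest. The elastic net's grouping effect keeps correlated
markers in together, and its strength is calibrated once per selection
run so each resampled fit assigns weight to roughly ``per_iter_nonzero``
features — the count-controlled form of stability selection.

Step 2 — greedy sequential backward elimination: starting from the
candidates, the least contributing feature (smallest |coefficient| on
standardized inputs) is removed one at a time; each visited subset is
scored by leave-one-out cross-validation on the training set, and the
subset with the best score (ties broken toward fewer features) becomes
the final panel.

All randomness is driven by the seed in SelectionParams; feature-level
ties break lexicographically by feature id so runs are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import SGDClassifier

from .classifier import PenaltySpec, _labels_to_binary, fit_glm, loocv_evaluate

log = logging.getLogger(__name__)

WEIGHT_EPS = 1e-8


@dataclass
class SelectionParams:
    """Knobs of the two-step selection."""

    n_iter: int = 20
    subsample_frac: float = 0.9
    min_count: int = 10
    elimination_metric: str = "accuracy"   # or "auroc"
    seed: int = 0
    per_iter_nonzero: int = 100            # target weighted-feature count per iteration
    selection_penalty: PenaltySpec = None  # sparsity penalty for step 1
    elimination_penalty: PenaltySpec = None  # shrinkage for step 2 refits

    def __post_init__(self) -> None:
        if not 1 <= self.min_count <= self.n_iter:
            raise ValueError("min_count must lie in [1, n_iter]")
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must lie in (0, 1]")
        if self.elimination_metric not in ("accuracy", "auroc"):
            raise ValueError("elimination_metric must be 'accuracy' or 'auroc'")
        if self.per_iter_nonzero < 1:
            raise ValueError("per_iter_nonzero must be positive")
        if self.selection_penalty is None:
            # C=None: strength auto-calibrated to per_iter_nonzero
            self.selection_penalty = PenaltySpec(kind="elastic_net", l1_ratio=0.5,
                                                 C=None, seed=self.seed)
        if self.elimination_penalty is None:
            # strong ridge keeps per-fold refits stable when the candidate
            # count approaches the sample count
            self.elimination_penalty = PenaltySpec(kind="l2", C=0.05, seed=self.seed)


@dataclass
class SelectionResult:
    """Outcome of one or both selection steps."""

    frequency: pd.Series              # per feature: iterations with nonzero weight
    weight_sum: pd.Series             # per feature: summed |coefficient|
    candidates: list[str]
    trace: list[tuple[int, str | None, float]] = field(default_factory=list)
    panel: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# step 1: frequency-based stability selection

def _stratified_subsample(y: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    """Indices of ceil(frac*n) samples with per-class largest-remainder
    allocation, at least 2 per class."""
    n = len(y)
    target = int(np.ceil(frac * n))
    classes, counts = np.unique(y, return_counts=True)
    exact = counts * target / n
    base = np.floor(exact).astype(int)
    rem = target - base.sum()
    order = np.argsort(-(exact - base))
    base[order[:rem]] += 1
    base = np.maximum(base, np.minimum(2, counts))
    idx: list[int] = []
    for cls, k in zip(classes, base):
        pool = np.flatnonzero(y == cls)
        idx += list(rng.choice(pool, size=min(k, len(pool)), replace=False))
    return np.sort(np.array(idx))


def _sparse_coefs(Xv: np.ndarray, yv: np.ndarray, l1_ratio: float,
                  alpha: float, seed: int) -> np.ndarray:
    est = SGDClassifier(loss="log_loss", penalty="elasticnet", l1_ratio=l1_ratio,
                        alpha=alpha, max_iter=500, tol=1e-3, random_state=seed)
    est.fit(Xv, yv)
    return est.coef_.ravel()


def _calibrate_alpha(Xv: np.ndarray, yv: np.ndarray, l1_ratio: float,
                     target: int, seed: int) -> float:
    """Penalty strength whose fit assigns weight to ~``target`` features.

    Scans a descending alpha grid (nonzero counts grow as alpha shrinks)
    and returns the grid point closest to the target on the log scale.
    """
    target = min(target, Xv.shape[1])
    grid = np.logspace(0.5, -4, 19)
    counts: list[int] = []
    for a in grid:
        nz = int((np.abs(_sparse_coefs(Xv, yv, l1_ratio, a, seed)) > WEIGHT_EPS).sum())
        counts.append(nz)
        if nz >= 2 * target:
            break
    gap = np.abs(np.log((np.array(counts) + 1) / (target + 1)))
    best = float(grid[int(np.argmin(gap))])
    log.info("stability-selection alpha calibrated to %.4g (%d nonzero, target %d)",
             best, counts[int(np.argmin(gap))], target)
    return best


def frequency_select(X: pd.DataFrame, y, params: SelectionParams | None = None) -> SelectionResult:
    """Accumulate nonzero-coefficient counts over resampled sparse fits."""
    params = params or SelectionParams()
    yv = _labels_to_binary(y)
    if len(X) != len(yv):
        raise ValueError("X rows and y length differ")
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(params.seed)
    freq = pd.Series(0, index=X.columns, dtype=int)
    wsum = pd.Series(0.0, index=X.columns)
    pen = params.selection_penalty
    use_sgd = pen.kind == "elastic_net" and pen.C is None
    if use_sgd:
        alpha = _calibrate_alpha(X.to_numpy(dtype=float), yv, pen.l1_ratio,
                                 params.per_iter_nonzero, pen.seed)
    for it in range(params.n_iter):
        for attempt in range(10):
            idx = _stratified_subsample(yv, params.subsample_frac, rng)
            if min(np.bincount(yv[idx], minlength=2)) >= 2:
                break
            log.info("iteration %d: degenerate subsample, redrawing", it)
        if use_sgd:
            coefs = _sparse_coefs(X.iloc[idx].to_numpy(dtype=float), yv[idx],
                                  pen.l1_ratio, alpha, pen.seed + it)
        else:
            coefs = fit_glm(X.iloc[idx], yv[idx], pen).coefficients
        nonzero = np.abs(coefs) > WEIGHT_EPS
        freq[nonzero] += 1
        wsum += np.abs(coefs)
    candidates = sorted(freq.index[freq >= params.min_count])
    return SelectionResult(frequency=freq, weight_sum=wsum, candidates=candidates)


# ---------------------------------------------------------------------------
# step 2: sequential backward elimination

def _cv_metric(X: pd.DataFrame, y: np.ndarray, params: SelectionParams) -> float:
    rep = loocv_evaluate(X, y, params.elimination_penalty)
    return rep.accuracy if params.elimination_metric == "accuracy" else rep.auroc


def backward_eliminate(
    X: pd.DataFrame,
    y,
    candidates: list[str],
    params: SelectionParams | None = None,
) -> SelectionResult:
    """Greedy removal of the least contributing feature, tracking the
    cross-validated metric of every visited subset.

    The trace rows are (subset size, feature removed to reach it, metric);
    the first row is the full candidate set with no removal. The panel is
    the visited subset with maximal metric; ties go to the smaller subset,
    i.e. the later trace entry.
    """
    params = params or SelectionParams()
    if not candidates:
        raise ValueError("candidate set is empty")
    missing = [f for f in candidates if f not in X.columns]
    if missing:
        raise KeyError(f"candidates not in X: {missing[:5]}")
    yv = _labels_to_binary(y)
    current = sorted(candidates)
    trace: list[tuple[int, str | None, float]] = []
    subsets: list[list[str]] = []

    trace.append((len(current), None, _cv_metric(X[current], yv, params)))
    subsets.append(list(current))
    while len(current) > 1:
        model = fit_glm(X[current], yv, params.elimination_penalty)
        contrib = pd.Series(np.abs(model.coefficients), index=current)
        # least contributing; lexicographic tie-break on feature id
        weakest = contrib.sort_values(kind="mergesort").index[0]
        current = [f for f in current if f != weakest]
        trace.append((len(current), weakest, _cv_metric(X[current], yv, params)))
        subsets.append(list(current))

    metrics = np.array([m for _, _, m in trace])
    best = int(np.flatnonzero(metrics == metrics.max())[-1])  # ties -> smallest subset
    panel = subsets[best]
    freq = pd.Series(np.nan, index=X.columns)
    return SelectionResult(frequency=freq, weight_sum=freq.copy(),
                           candidates=list(candidates), trace=trace, panel=panel)


def plot_trace(result: SelectionResult, path) -> None:
    """Cross-validated metric versus subset size (elimination trace)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sizes = [n for n, _, _ in result.trace]
    metrics = [m for _, _, m in result.trace]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(sizes, metrics, marker="o", ms=3)
    if result.panel:
        ax.axvline(len(result.panel), ls="--", color="crimson", lw=1,
                   label=f"panel ({len(result.panel)})")
        ax.legend(frameon=False)
    ax.set_xlabel("features retained")
    ax.set_ylabel("cross-validated metric")
    ax.invert_xaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def select_panel(X: pd.DataFrame, y, params: SelectionParams | None = None) -> SelectionResult:
    """Run both steps and merge the results into one SelectionResult."""
    params = params or SelectionParams()
    step1 = frequency_select(X, y, params)
    if not step1.candidates:
        return step1
    step2 = backward_eliminate(X, y, step1.candidates, params)
    return SelectionResult(
        frequency=step1.frequency,
        weight_sum=step1.weight_sum,
        candidates=step1.candidates,
        trace=step2.trace,
        panel=step2.panel,
    )
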