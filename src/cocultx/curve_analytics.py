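"""Whole-curve shape analytics: alignment, ordination, PERMANOVA, classification.

To compare curve *shapes* rather than timing, every curve is shifted so its
fluorescence peak sits at day 0, binned to a daily grid from 10 days before
the peak to 80 days after (91 features), gap-filled by linear interpolation
(nearest-value fill at the edges), and standardized per grid day (z-scores).
On that matrix the module runs PCA ordination, a permutational multivariate
ANOVA (PERMANOVA, the adonis pseudo-F on Euclidean distances), stratified
10-fold random-forest strain classification with per-day feature importance,
and Pearson correlations between per-culture scalars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from cocultx.io_model import CurveSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-10, 80)  # integer days relative to the peak, inclusive


@dataclass
class AlignedMatrix:
    """Peak-aligned, daily-gridded curve matrix (samples x grid days)."""

    sample_ids: list[str]
    grid: np.ndarray  # integer days relative to peak
    values: np.ndarray  # (n_samples, n_days)
    standardized: bool = False
    constant_columns: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.grid)


@dataclass(frozen=True)
class OrdinationResult:
    sample_ids: list[str]
    scores: np.ndarray  # (n_samples, k)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray  # (k, n_features)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_permutations: int
    df_between: int
    df_within: int


@dataclass(frozen=True)
class ClassificationResult:
    target: str
    fold_accuracy: np.ndarray
    mean_accuracy: float
    confusion: pd.DataFrame
    importance: pd.Series  # mean per grid-day over repeated refits
    n_folds: int
    n_repeats: int


def align_and_grid(
    curves: dict[str, CurveSeries],
    peaks: dict[str, tuple[float, float]],
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> AlignedMatrix:
    """Shift curves to peak day 0 and average onto a daily grid.

    Day bins are half-open [d, d+1) labelled d; multiple observations in a
    bin are averaged (the rolling per-day mean); interior gaps are linearly
    interpolated and edges extended with the nearest observed value.  A curve
    with no observation inside the window is excluded with a warning.
    """
    lo, hi = window
    grid = np.arange(lo, hi + 1)
    rows, ids = [], []
    for cid, curve in curves.items():
        _, tmax = peaks[cid]
        rel = curve.times - tmax
        day_bin = np.floor(rel).astype(int)
        inside = (day_bin >= lo) & (day_bin <= hi)
        if not inside.any():
            logger.warning("curve %r has no points in window %s; excluded", cid, window)
            continue
        binned = pd.Series(curve.fluorescence[inside]).groupby(day_bin[inside]).mean()
        col = pd.Series(np.nan, index=grid, dtype=float)
        col.loc[binned.index] = binned.values
        col = col.interpolate(method="linear", limit_area="inside")
        col = col.ffill().bfill()  # nearest-value edge fill
        rows.append(col.to_numpy())
        ids.append(cid)
    if not rows:
        raise ValueError("no curves with in-window observations")
    return AlignedMatrix(
        sample_ids=ids,
        grid=grid,
        values=np.vstack(rows),
        provenance={"window": window, "bin": "floor-day mean", "interp": "linear+edge-nearest"},
    )


def standardize(matrix: AlignedMatrix) -> AlignedMatrix:
    """Per-column z-scores (population SD); constant columns set to 0, flagged.

    Idempotent: standardizing an already-standardized matrix is a no-op up to
    floating point.
    """
    x = matrix.values
    if x.shape[0] < 2:
        raise ValueError("standardization needs >= 2 samples")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population convention, as in sklearn's StandardScaler
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    z = (x - mean) / sd_safe
    z[:, constant] = 0.0
    return AlignedMatrix(
        sample_ids=list(matrix.sample_ids),
        grid=matrix.grid.copy(),
        values=z,
        standardized=True,
        constant_columns=constant,
        provenance={**matrix.provenance, "standardized": True},
    )


def pca(matrix: AlignedMatrix, k: int = 2) -> OrdinationResult:
    """Principal-component ordination of the standardized matrix.

    Component signs are fixed by forcing the largest-|loading| entry of each
    component positive, for determinism across platforms.
    """
    x = matrix.values
    n, p = x.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_features)={min(n - 1, p)}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return OrdinationResult(
        sample_ids=list(matrix.sample_ids),
        scores=scores,
        explained_variance_ratio=model.explained_variance_ratio_,
        loadings=loadings,
    )


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Between/within sums of squares from a squared distance matrix.

    Uses the distance-based identity SS_total = sum_{i<j} d_ij^2 / N and
    SS_within = sum over groups of within-group pairwise d^2 / n_g.
    """
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def permanova(
    matrix: AlignedMatrix | np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (adonis) on Euclidean distances.

    pseudo-F = (SS_between/(k-1)) / (SS_within/(N-k)); R2 = SS_between /
    SS_total; p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under seeded label
    permutation, so p is never exactly 0.
    """
    x = matrix.values if isinstance(matrix, AlignedMatrix) else np.asarray(matrix, float)
    labels = np.asarray(labels)
    if len(labels) != x.shape[0]:
        raise ValueError("labels length must match number of samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n, k = len(labels), len(uniq)
    diff = x[:, None, :] - x[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    ss_b, ss_w = _permanova_ss(d2, labels)
    f_obs = (ss_b / (k - 1)) / (ss_w / (n - k))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pb, pw = _permanova_ss(d2, perm)
        f_perm = (pb / (k - 1)) / (pw / (n - k))
        if f_perm >= f_obs:
            exceed += 1
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r2=float(ss_b / (ss_b + ss_w)),
        p=float((1 + exceed) / (1 + n_perm)),
        n_permutations=n_perm,
        df_between=k - 1,
        df_within=n - k,
    )


def rf_classify(
    matrix: AlignedMatrix,
    labels,
    folds: int = 10,
    n_repeats: int = 30,
    seed: int | None = None,
    n_estimators: int = 100,
) -> ClassificationResult:
    """Stratified k-fold random-forest classification of curve shapes.

    Accuracy is estimated by stratified cross-validation; per-day feature
    importances are averaged over ``n_repeats`` refits on the full matrix
    (different forest seeds).  If the rarest class has fewer members than
    ``folds``, the fold count is reduced with a warning.
    """
    y = np.asarray(labels)
    x = matrix.values
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("classification needs >= 2 classes")
    eff_folds = min(folds, int(counts.min()))
    if eff_folds < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, eff_folds)
    if eff_folds < 2:
        raise ValueError("smallest class has < 2 members")
    rng = np.random.default_rng(seed)
    cv_seed = int(rng.integers(2**31 - 1))
    cv = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=cv_seed)
    fold_acc = np.empty(eff_folds)
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for i, (tr, te) in enumerate(cv.split(x, y)):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        fold_acc[i] = float(np.mean(pred == y[te]))
        for truth, hat in zip(y[te], pred):
            confusion.loc[truth, hat] += 1
    importances = np.zeros(x.shape[1])
    for _ in range(n_repeats):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31 - 1))
        )
        clf.fit(x, y)
        importances += clf.feature_importances_
    importances /= n_repeats
    return ClassificationResult(
        target="",
        fold_accuracy=fold_acc,
        mean_accuracy=float(fold_acc.mean()),
        confusion=confusion,
        importance=pd.Series(importances, index=matrix.grid),
        n_folds=eff_folds,
        n_repeats=n_repeats,
    )


def correlate(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
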