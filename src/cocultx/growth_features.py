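"""Growth-phase feature extraction: rate, lag and peak per culture.

The batch-culture growth model is N_t = N_0 * exp(mu * (t - L)): log-linear
regression of ln(FL) on time over the detected exponential window gives the
growth rate mu (slope, per day); the lag L follows from the intercept against
the first observed fluorescence.  A fit is accepted only when the window's
R^2 exceeds 0.9.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cocultx.io_model import CurveSeries, NoSignalError

logger = logging.getLogger(__name__)

R2_THRESHOLD = 0.9
MIN_WINDOW = 4  # r2 on 3 points is uninformative


class GrowthUndetectedError(ValueError):
    """No log-linear window with r2 > 0.9 and positive slope was found."""


@dataclass(frozen=True)
class GrowthFit:
    """Growth-phase parameters for one culture.

    mu: growth rate (1/day); lag: days; n0_fit: exp(intercept), the
    back-extrapolated level at t = 0; flmax/tmax: fluorescence peak;
    r2: coefficient of determination of the log-linear fit; window:
    (first, last) indices (inclusive) of the detected-point series used.
    """

    culture_id: str
    mu: float
    lag: float
    n0_fit: float
    flmax: float
    tmax: float
    r2: float
    window: tuple[int, int]


def find_peak(curve: CurveSeries) -> tuple[float, float]:
    """Maximum observed fluorescence and the earliest day attaining it."""
    det = curve.detected
    if len(det) == 0:
        raise NoSignalError(f"{curve.culture_id}: no fluorescence above detection")
    i = int(np.argmax(det.fluorescence))  # argmax returns first maximal index
    return float(det.fluorescence[i]), float(det.times[i])


def _loglinear(t: np.ndarray, logfl: np.ndarray):
    res = stats.linregress(t, logfl)
    return res.slope, res.intercept, res.rvalue**2


def detect_growth_phase(curve: CurveSeries) -> tuple[int, int]:
    """Find the exponential-growth window ending at the peak.

    Works on detected (above-floor) points only.  Starting from the first
    point, the window [start .. peak] is shrunk from the front until the
    log-linear regression attains r2 > 0.9 with positive slope (window
    length >= 4); front points are then trimmed further as long as doing so
    strictly improves r2, so a flat lag prefix that merely dilutes an
    otherwise clean exponential segment is excluded rather than biasing the
    slope.  Indices refer to the detected sub-series.
    """
    det = curve.detected
    _, tmax = find_peak(curve)
    ipeak = int(np.searchsorted(det.times, tmax))
    if ipeak + 1 < MIN_WINDOW:
        raise GrowthUndetectedError(
            f"{curve.culture_id}: fewer than {MIN_WINDOW} points up to the peak"
        )
    logfl = np.log(det.fluorescence[: ipeak + 1])
    t = det.times[: ipeak + 1]
    for start in range(0, ipeak + 2 - MIN_WINDOW):
        slope, _, r2 = _loglinear(t[start:], logfl[start:])
        if r2 > R2_THRESHOLD and slope > 0:
            # Refinement: trim the window ends while r2 strictly improves.
            # Front drops remove a flat lag prefix that would bias the slope
            # low; a single end drop removes the observed peak sample when it
            # already sits on the decline branch (true peak between samples).
            end, end_drops = ipeak, 0
            improved = True
            while improved and end - start + 1 > MIN_WINDOW:
                improved = False
                for s2, e2 in ((start + 1, end), (start, end - 1)):
                    if e2 - s2 + 1 < MIN_WINDOW or (e2 < end and end_drops >= 1):
                        continue
                    slope2, _, r2_next = _loglinear(t[s2 : e2 + 1], logfl[s2 : e2 + 1])
                    if r2_next > r2 and slope2 > 0:
                        if e2 < end:
                            end_drops += 1
                        start, end, r2 = s2, e2, r2_next
                        improved = True
                        break
            return (start, end)
    raise GrowthUndetectedError(
        f"{curve.culture_id}: no window of >= {MIN_WINDOW} points with "
        f"r2 > {R2_THRESHOLD} and positive slope"
    )


def fit_growth(curve: CurveSeries, window: tuple[int, int] | None = None) -> GrowthFit:
    """OLS of ln(FL) on t over the growth window.

    mu is the slope; lag L = (ln(FL_first_observed) - intercept) / mu,
    clipped below at 0 (the regression line back-crosses the starting level
    at t = L under the model N_t = N_0 exp(mu (t - L))).
    """
    if window is None:
        window = detect_growth_phase(curve)
    det = curve.detected
    first, last = window
    t = det.times[first : last + 1]
    if len(np.unique(t)) < 2:
        raise ValueError(f"{curve.culture_id}: singular design (all times equal)")
    logfl = np.log(det.fluorescence[first : last + 1])
    slope, intercept, r2 = _loglinear(t, logfl)
    flmax, tmax = find_peak(curve)
    fl_first = det.fluorescence[0]
    lag = (np.log(fl_first) - intercept) / slope if slope != 0 else 0.0
    return GrowthFit(
        culture_id=curve.culture_id,
        mu=float(slope),
        lag=float(max(lag, 0.0)),
        n0_fit=float(np.exp(intercept)),
        flmax=flmax,
        tmax=tmax,
        r2=float(r2),
        window=window,
    )


def extract_features(curves: dict[str, CurveSeries]) -> pd.DataFrame:
    """Per-culture feature table: mu, lag, flmax, tmax, r2, status.

    Cultures where growth cannot be detected are kept with status
    'growth_undetected' and NaN rate columns (peak still reported when it
    exists), so exclusions stay visible downstream.
    """
    rows = []
    for cid, curve in curves.items():
        row: dict = {"culture_id": cid}
        try:
            flmax, tmax = find_peak(curve)
            row.update(flmax=flmax, tmax=tmax)
        except NoSignalError:
            row.update(flmax=np.nan, tmax=np.nan, status="no_signal")
            rows.append(row)
            continue
        try:
            fit = fit_growth(curve)
            row.update(mu=fit.mu, lag=fit.lag, r2=fit.r2, status="ok")
        except (GrowthUndetectedError, ValueError) as exc:
            logger.warning("growth fit failed for %r: %s", cid, exc)
            row.update(mu=np.nan, lag=np.nan, r2=np.nan, status="growth_undetected")
        rows.append(row)
    cols = ["culture_id", "mu", "lag", "flmax", "tmax", "r2", "status"]
    return pd.DataFrame(rows).reindex(columns=cols)


def compare_groups(values, groups) -> dict:
    """One-way ANOVA plus Bonferroni-corrected pairwise Welch-free t-tests.

    Groups with fewer than 2 values are dropped with a warning.  Pairwise
    two-sample t-tests are multiplied by the number of pairs and capped at 1.
    Returns {'anova': {'F', 'p'}, 'pairwise': DataFrame, 'groups_used': [...]}.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    by_group: dict = {}
    for g in pd.unique(groups):
        vals = values[(groups == g) & np.isfinite(values)]
        if len(vals) < 2:
            logger.warning("group %r dropped: fewer than 2 values", g)
            continue
        by_group[g] = vals
    if len(by_group) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    names = list(by_group)
    f_stat, p_val = stats.f_oneway(*by_group.values())
    pairs = list(itertools.combinations(names, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_ind(by_group[a], by_group[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_corrected": float(min(p * n_pairs, 1.0)),
            }
        )
    return {
        "anova": {"F": float(f_stat), "p": float(p_val)},
        "pairwise": pd.DataFrame(rows),
        "groups_used": names,
    }
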