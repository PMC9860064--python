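"""Mortality-model fitting for the post-peak decline phase.

Four descriptive mortality laws are fitted to peak-normalized fluorescence
y(tau) = FL / FL_max over tau = t - t_max (days since decline onset):

- exponential      y = exp(-a tau)                   (1 free parameter)
- bi-exponential   y = f exp(-a1 tau) + (1-f) exp(-a2 tau)   (3)
- harmonic         y = 1 / (1 + a tau)               (1)
- Weibull          y = exp(-a tau^n)                 (2, rate form)

Each model is fitted by bounded nonlinear least squares (dogbox trust region)
with a soft-L1 robust loss (residual scale 0.1), multi-started from the
all-0.5 vector plus seeded uniform draws within bounds; the start with the
lowest plain-residual RMSE wins.  Model comparison uses RMSE and Gaussian
BIC = m ln(RSS/m) + k ln(m).

The Weibull shape parameter n classifies mortality dynamics: n > 1 means the
instantaneous death rate accelerates as starvation proceeds (damage
accumulation), n < 1 means it decelerates (acclimation / hardening of the
survivors).  The decimal reduction time t_d = (ln(10^d) / a)^(1/n) is the
time for the signal to fall by d factors of 10; equivalently, in the scale
parameterization y = exp(-(tau/a')^n) with a' = a^(-1/n), it is
a' * (-ln(10^-d))^(1/n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from cocultx.io_model import CurveSeries

logger = logging.getLogger(__name__)

MODELS = ("exponential", "biexponential", "harmonic", "weibull")

# free-parameter count per model
N_PARAMS = {"exponential": 1, "biexponential": 3, "harmonic": 1, "weibull": 2}

RATE_MAX = 50.0
SHAPE_MIN, SHAPE_MAX = 0.01, 10.0

# per-model box bounds, parameter order as in ModelParams.values
BOUNDS = {
    "exponential": (np.array([0.0]), np.array([RATE_MAX])),
    "biexponential": (np.array([0.0, 0.0, 0.0]), np.array([1.0, RATE_MAX, RATE_MAX])),
    "harmonic": (np.array([0.0]), np.array([RATE_MAX])),
    "weibull": (np.array([0.0, SHAPE_MIN]), np.array([RATE_MAX, SHAPE_MAX])),
}

SOFT_L1_SCALE = 0.1
DEFAULT_STARTS = 50


class DeclineUndetectedError(ValueError):
    """Fewer than 5 usable post-peak points."""


@dataclass(frozen=True)
class DeclinePhase:
    """Normalized decline phase of one culture: y(tau), y(0) = 1."""

    culture_id: str
    tau: np.ndarray  # days since decline onset, >= 0, strictly increasing
    y: np.ndarray  # FL / FLmax, below-detection points already excluded

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "y", y)
        if len(tau) != len(y):
            raise ValueError(f"{self.culture_id}: tau/y length mismatch")
        if len(tau) < 5:
            raise DeclineUndetectedError(
                f"{self.culture_id}: need >= 5 decline points, got {len(tau)}"
            )
        if np.any(tau < 0) or np.any(np.diff(tau) <= 0):
            raise ValueError(f"{self.culture_id}: tau must be >= 0 and strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.tau)


@dataclass(frozen=True)
class ModelParams:
    """Fitted parameters of one mortality model.

    exponential/harmonic: a; weibull: a (rate coefficient, day^-n) and
    n (shape); biexponential: f (fraction of the first subpopulation) with
    rates a1 >= a2 (enforced by post-hoc swap for identifiability).
    """

    model: str
    a: float | None = None
    f: float | None = None
    a1: float | None = None
    a2: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")

    @property
    def values(self) -> np.ndarray:
        """Parameter vector in fitting order."""
        if self.model == "exponential" or self.model == "harmonic":
            return np.array([self.a])
        if self.model == "biexponential":
            return np.array([self.f, self.a1, self.a2])
        return np.array([self.a, self.n])

    @classmethod
    def from_vector(cls, model: str, vec: np.ndarray) -> "ModelParams":
        if model in ("exponential", "harmonic"):
            return cls(model, a=float(vec[0]))
        if model == "biexponential":
            return cls(model, f=float(vec[0]), a1=float(vec[1]), a2=float(vec[2]))
        return cls(model, a=float(vec[0]), n=float(vec[1]))

    @property
    def k(self) -> int:
        return N_PARAMS[self.model]

    def canonical(self) -> "ModelParams":
        """Bi-exponential label-swap so that a1 >= a2."""
        if self.model == "biexponential" and self.a1 < self.a2:
            return replace(self, f=1.0 - self.f, a1=self.a2, a2=self.a1)
        return self

    @property
    def weibull_scale(self) -> float:
        """Scale-form coefficient a' with y = exp(-(tau/a')^n); a' = a^(-1/n)."""
        if self.model != "weibull":
            raise ValueError("scale conversion applies to the Weibull model only")
        return float(self.a ** (-1.0 / self.n))


@dataclass(frozen=True)
class ModelFit:
    """One model's fit to one decline phase."""

    culture_id: str
    params: ModelParams
    rmse: float
    bic: float
    converged: bool
    n_starts_used: int
    seed: int | None = None


@dataclass(frozen=True)
class DeathStats:
    """Decimal-reduction-time statistics from a Weibull fit."""

    td: float  # days to reduce the signal by d factors of 10
    d: float
    shape_class: str  # accelerating (n>1) / decelerating (n<1) / constant

    @staticmethod
    def classify_shape(n: float, tol: float = 0.05) -> str:
        if abs(n - 1.0) <= tol:
            return "constant"
        return "accelerating" if n > 1.0 else "decelerating"


def extract_decline(curve: CurveSeries, peak: tuple[float, float]) -> DeclinePhase:
    """Normalize the post-peak portion of a curve: tau = t - tmax, y = FL/FLmax.

    Below-detection points are excluded (the gap stays in tau); fewer than 5
    usable points raises :class:`DeclineUndetectedError`.
    """
    flmax, tmax = peak
    keep = (curve.times >= tmax) & ~curve.below_detection
    if int(keep.sum()) < 5:
        raise DeclineUndetectedError(
            f"{curve.culture_id}: only {int(keep.sum())} usable points after the peak"
        )
    return DeclinePhase(
        culture_id=curve.culture_id,
        tau=curve.times[keep] - tmax,
        y=curve.fluorescence[keep] / flmax,
    )


def model_eval(params: ModelParams, tau) -> np.ndarray:
    """Evaluate a mortality model at tau (days since decline onset)."""
    tau = np.asarray(tau, dtype=float)
    m = params.model
    if m == "exponential":
        return np.exp(-params.a * tau)
    if m == "biexponential":
        return params.f * np.exp(-params.a1 * tau) + (1.0 - params.f) * np.exp(
            -params.a2 * tau
        )
    if m == "harmonic":
        return 1.0 / (1.0 + params.a * tau)
    # weibull, rate form; tau=0 with n<1 would be 0^negative without the guard
    with np.errstate(invalid="ignore"):
        out = np.exp(-params.a * np.power(tau, params.n))
    return np.where(tau == 0.0, 1.0, out)


def rmse(params: ModelParams, phase: DeclinePhase) -> float:
    """Plain (unweighted) root-mean-square error on normalized fluorescence."""
    resid = phase.y - model_eval(params, phase.tau)
    return float(np.sqrt(np.mean(resid**2)))


def bic(params: ModelParams, phase: DeclinePhase) -> float:
    """Gaussian BIC = m ln(RSS/m) + k ln(m); -inf sentinel for a perfect fit.

    An RMSE at float-noise level (< 1e-12 on the normalized scale) counts as
    perfect: below that the Gaussian likelihood is meaningless and comparing
    BICs would rank models by rounding error rather than parsimony.
    """
    m = phase.n_points
    resid = phase.y - model_eval(params, phase.tau)
    rss = float(np.sum(resid**2))
    if rss <= m * 1e-24:
        return float("-inf")
    return float(m * np.log(rss / m) + params.k * np.log(m))


def fit_decline(
    phase: DeclinePhase,
    model: str,
    n_random_starts: int = DEFAULT_STARTS,
    seed: int | None = None,
) -> ModelFit:
    """Robust multi-start bounded least squares for one mortality model.

    Starts are the all-0.5 vector followed by ``n_random_starts`` uniform
    draws within bounds (seeded).  Optimization minimizes the soft-L1 loss
    (f_scale 0.1) with the dogbox method; the winning start is the one whose
    *plain* RMSE is lowest, ties broken by earlier start index.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    lo, hi = BOUNDS[model]
    rng = np.random.default_rng(seed)
    starts = [np.full(len(lo), 0.5)]
    starts += [rng.uniform(lo, hi) for _ in range(n_random_starts)]
    # dogbox needs a strictly interior start for a lower-bound-active point
    eps = 1e-9

    def residuals(vec: np.ndarray) -> np.ndarray:
        return model_eval(ModelParams.from_vector(model, vec), phase.tau) - phase.y

    best: tuple[float, int, ModelParams] | None = None
    n_converged = 0
    for i, x0 in enumerate(starts):
        x0 = np.clip(x0, lo + eps, hi - eps)
        try:
            sol = least_squares(
                residuals,
                x0,
                bounds=(lo, hi),
                method="dogbox",
                loss="soft_l1",
                f_scale=SOFT_L1_SCALE,
            )
        except Exception:  # pragma: no cover - scipy failures are data-dependent
            continue
        if not sol.success:
            continue
        n_converged += 1
        cand = ModelParams.from_vector(model, sol.x)
        cand_rmse = rmse(cand, phase)
        if best is None or cand_rmse < best[0]:
            best = (cand_rmse, i, cand)
    if best is None:
        return ModelFit(
            culture_id=phase.culture_id,
            params=ModelParams.from_vector(model, np.full(len(lo), np.nan)),
            rmse=float("nan"),
            bic=float("nan"),
            converged=False,
            n_starts_used=len(starts),
            seed=seed,
        )
    _, _, params = best
    params = params.canonical()
    return ModelFit(
        culture_id=phase.culture_id,
        params=params,
        rmse=rmse(params, phase),
        bic=bic(params, phase),
        converged=True,
        n_starts_used=len(starts),
        seed=seed,
    )


def weibull_td(params: ModelParams, d: float = 2.0) -> float:
    """Time (days) for a d-decade reduction under a fitted Weibull law.

    td = (ln(10^d) / a)^(1/n); satisfies model_eval(params, td) = 10^-d.
    """
    if params.model != "weibull":
        raise ValueError("decimal reduction time is defined for the Weibull model")
    if params.a <= 0 or params.n <= 0 or d <= 0:
        raise ValueError("require a > 0, n > 0, d > 0")
    return float((d * np.log(10.0) / params.a) ** (1.0 / params.n))


def death_stats(params: ModelParams, d: float = 2.0) -> DeathStats:
    return DeathStats(
        td=weibull_td(params, d),
        d=d,
        shape_class=DeathStats.classify_shape(params.n),
    )


def fit_all(
    phase: DeclinePhase,
    n_random_starts: int = DEFAULT_STARTS,
    seed: int | None = None,
) -> dict:
    """Fit all four models with per-model seeds derived from a shared base.

    Returns {'fits': {model: ModelFit}, 'best_rmse': model, 'best_bic': model}.
    Deterministic given seed.
    """
    fits: dict[str, ModelFit] = {}
    for i, model in enumerate(MODELS):
        sub_seed = None if seed is None else seed + i
        fits[model] = fit_decline(phase, model, n_random_starts, sub_seed)
    converged = {m: f for m, f in fits.items() if f.converged}
    best_rmse = min(converged, key=lambda m: converged[m].rmse) if converged else None
    # BIC ties (e.g. several exact fits at the -inf sentinel) resolve to the
    # most parsimonious model, then to Table-order
    best_bic = (
        min(converged, key=lambda m: (converged[m].bic, N_PARAMS[m], MODELS.index(m)))
        if converged
        else None
    )
    return {"fits": fits, "best_rmse": best_rmse, "best_bic": best_bic}


def fits_table(all_fits: dict[str, dict]) -> pd.DataFrame:
    """Flatten {culture_id: fit_all(...) result} into a tidy table."""
    rows = []
    for cid, res in all_fits.items():
        for model, fit in res["fits"].items():
            p = fit.params
            row = {
                "culture_id": cid,
                "model": model,
                "a": p.a,
                "f": p.f,
                "a1": p.a1,
                "a2": p.a2,
                "n": p.n,
                "rmse": fit.rmse,
                "bic": fit.bic,
                "converged": fit.converged,
                "best_rmse": model == res["best_rmse"],
                "best_bic": model == res["best_bic"],
                "seed": fit.seed,
            }
            if model == "weibull" and fit.converged and p.a > 0:
                row["td2"] = weibull_td(p, 2.0)
                row["shape_class"] = DeathStats.classify_shape(p.n)
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_fits(fits: pd.DataFrame, metadata: pd.DataFrame) -> dict:
    """Group-level summary of decline fits (axenic vs co-culture, per strain).

    Expects the tidy table from :func:`fits_table` and a metadata frame with
    culture_id / pro_strain / alt_strain.  Reports mean +/- SD of the Weibull
    shape n and td2 and per-model RMSE by treatment group and by phototroph
    strain, shape-class counts, and a two-sample t-test of n between axenic
    phototroph cultures and co-cultures.
    """
    meta = metadata.copy()
    meta["treatment"] = np.where(
        (meta["pro_strain"] != "none") & (meta["alt_strain"] != "none"),
        "coculture",
        np.where(meta["pro_strain"] != "none", "axenic_pro", "axenic_alt"),
    )
    df = fits.merge(meta[["culture_id", "treatment", "pro_strain"]], on="culture_id")

    def _ms(x):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            return {"mean": float("nan"), "sd": float("nan"), "n": 0}
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0, "n": int(len(x))}

    wb = df[(df["model"] == "weibull") & df["converged"]]
    out: dict = {"by_treatment": {}, "by_pro_strain": {}, "rmse_by_model": {}}
    for treat, grp in wb.groupby("treatment"):
        out["by_treatment"][treat] = {
            "shape_n": _ms(grp["n"]),
            "td2": _ms(grp.get("td2", pd.Series(dtype=float))),
            "shape_class_counts": grp.get("shape_class", pd.Series(dtype=str))
            .value_counts()
            .to_dict(),
        }
    for strain, grp in wb[wb["pro_strain"] != "none"].groupby("pro_strain"):
        out["by_pro_strain"][strain] = {"shape_n": _ms(grp["n"]), "td2": _ms(grp.get("td2", pd.Series(dtype=float)))}
    for (model, treat), grp in df[df["converged"]].groupby(["model", "treatment"]):
        out["rmse_by_model"].setdefault(model, {})[treat] = _ms(grp["rmse"])
    ax = wb.loc[wb["treatment"] == "axenic_pro", "n"].dropna()
    co = wb.loc[wb["treatment"] == "coculture", "n"].dropna()
    if len(ax) >= 2 and len(co) >= 2:
        t, p = stats.ttest_ind(ax, co)
        out["shape_ttest_axenic_vs_coculture"] = {"t": float(t), "p": float(p)}
    return out
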