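"""Ground-truth simulator of the 5x5 co-culture study design.

Emulates long-term batch co-cultures of five *Prochlorococcus* strains with
five *Alteromonas* strains plus axenic controls, in triplicate, followed by
near-daily bulk fluorescence for ~140 days:

- each curve is a piecewise trajectory — flat at the inoculation level until
  the lag ends, exponential rise at rate mu to the peak, then decline under a
  strain-specific mortality law — with multiplicative lognormal measurement
  noise and a detection floor;
- phototroph strain determines the decline shape (axenic declines are fast
  and accelerating, Weibull shape ~2.1; co-culture declines are slow and
  decelerating, shape ~0.4), while the heterotroph strain has a null effect
  on decline, mirroring the asymmetry of the real system;
- flow-cytometry counts at days 60/100/140 are generated budget-downward:
  a latent total N biomass (capped at the 100 umol N/L supplied) is split
  between populations (heterotroph fraction centred near 0.75 in co-culture)
  and converted to cells/ml through the same quotas the analysis uses, so
  feasibility and the configured synergy fold-changes hold by construction.

Every generating parameter is recorded in a ground-truth table; the whole
ExperimentSet is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cocultx.decline_models import ModelParams, model_eval
from cocultx.io_model import (
    ALT_STRAINS,
    PRO_STRAINS,
    CellCountRecord,
    CultureMetadata,
    CurveSeries,
    ExperimentSet,
)
from cocultx.nitrogen_budget import DEFAULT_QUOTAS, MW_N

GROWTH_DECADES = 100.0  # FLmax / FL0 during the exponential rise

# latent N-biomass distribution per sampled day (umol N/L): means for
# co-culture totals, axenic-alt totals and axenic-pro totals, alt fraction
COUNT_DAY_PARAMS = {
    60.0: {"ax_alt": 32.0, "ax_pro": 0.01, "frac_alt": 0.76},
    100.0: {"ax_alt": 8.0, "ax_pro": 0.005, "frac_alt": 0.76},
    140.0: {"ax_alt": 2.0, "ax_pro": 0.002, "frac_alt": 0.76},
}
# per-phototroph-strain synergy of the heterotroph (log2FC of alt biomass in
# co-culture vs axenic alt): three mutually synergistic strains, two not
ALT_BENEFIT_LOG2FC = {
    "MED4": 1.3,
    "MIT0604": 1.3,
    "NATL2A": 1.3,
    "MIT9312": -0.2,
    "MIT9313": -0.2,
}
BIOMASS_CV = 0.30  # replicate-level lognormal CV of latent biomass


@dataclass(frozen=True)
class StrainProfile:
    """Generating parameters for one strain.

    growth: (mu /day, lag days, FLmax au).  ``decline`` is the axenic
    mortality law; ``coculture_decline`` (phototrophs only) replaces it when
    the strain is paired, and ``coculture_lag_penalty`` adds to the lag.
    """

    strain: str
    role: str  # 'phototroph' | 'heterotroph'
    mu: float
    lag: float
    flmax: float
    decline: ModelParams
    coculture_decline: ModelParams | None = None
    coculture_lag_penalty: float = 0.0
    bump: tuple[float, float, float] | None = None  # (log-amplitude, center tau, width)


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs; defaults are the conditions being emulated."""

    replicates: int = 3
    duration: float = 140.0
    sampling_interval: float = 1.0
    sampling_jitter: float = 0.1  # uniform +/- days on each sample time
    noise_cv: float = 0.05  # multiplicative lognormal CV
    detection_floor: float = 1.0  # au
    seed: int = 0
    n_total: float = 100.0  # umol N / L
    count_days: tuple[float, ...] = (60.0, 100.0, 140.0)
    param_jitter_cv: float = 0.05  # replicate-level jitter on decline params
    enable_bumps: bool = False  # secondary-growth deviations (off by default)

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("replicates, duration, sampling_interval must be positive")
        if self.noise_cv < 0 or self.n_total <= 0:
            raise ValueError("noise_cv must be >= 0 and n_total > 0")


def _weibull_from_td2(shape: float, td2: float) -> ModelParams:
    """Weibull rate coefficient from a target 2-decade reduction time."""
    a = 2.0 * np.log(10.0) / td2**shape
    return ModelParams("weibull", a=a, n=shape)


def default_library(seed: int = 0) -> dict[str, StrainProfile]:
    """The ten default strain profiles (5 phototrophs + 5 heterotrophs).

    Phototroph axenic Weibull shapes are drawn around 2.1 (SD 0.9, clipped
    above 1.1) with 2-decade reduction times near 12.6 days; co-culture
    shapes around 0.4 (SD 0.2, clipped above 0.05) with td2 near 316 days.
    MIT9313 carries a 10-day co-culture lag penalty (delayed-growth
    phenotype).  Heterotroph profiles are dim, slowly declining background
    signals that never alter the phototroph's decline.
    """
    rng = np.random.default_rng(seed)
    library: dict[str, StrainProfile] = {}
    # growth parameters share one centre across phototroph strains (growth in
    # these conditions is strain-similar; the strain signal lives in the
    # decline law), with per-culture variation added at simulation time
    for strain in PRO_STRAINS:
        ax_shape = max(float(rng.normal(2.1, 0.9)), 1.1)
        co_shape = max(float(rng.normal(0.4, 0.2)), 0.05)
        ax_td2 = max(float(rng.normal(12.6, 3.9)), 4.0)
        co_td2 = max(float(rng.lognormal(np.log(300.0), 0.5)), 60.0)
        library[strain] = StrainProfile(
            strain=strain,
            role="phototroph",
            mu=0.4,
            lag=2.5,
            flmax=300.0,
            decline=_weibull_from_td2(ax_shape, ax_td2),
            coculture_decline=_weibull_from_td2(co_shape, co_td2),
            coculture_lag_penalty=10.0 if strain == "MIT9313" else 0.0,
        )
    for strain in ALT_STRAINS:
        library[strain] = StrainProfile(
            strain=strain,
            role="heterotroph",
            mu=float(rng.uniform(0.5, 1.0)),
            lag=float(rng.uniform(0.5, 2.0)),
            flmax=float(rng.uniform(3.0, 6.0)),  # dim: no chlorophyll signal
            decline=ModelParams("exponential", a=float(rng.uniform(0.005, 0.02))),
        )
    return library


def trajectory(
    times: np.ndarray,
    mu: float,
    lag: float,
    flmax: float,
    decline: ModelParams,
    bump: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Noise-free piecewise trajectory: flat, exponential rise, decline."""
    times = np.asarray(times, dtype=float)
    fl0 = flmax / GROWTH_DECADES
    tmax = lag + np.log(GROWTH_DECADES) / mu
    fl = np.where(
        times < lag,
        fl0,
        np.where(
            times <= tmax,
            fl0 * np.exp(mu * (times - lag)),
            flmax * model_eval(decline, np.maximum(times - tmax, 0.0)),
        ),
    )
    if bump is not None:
        amp, center, width = bump
        tau = np.maximum(times - tmax, 0.0)
        fl = fl * np.exp(amp * np.exp(-0.5 * ((tau - center) / width) ** 2) * (times > tmax))
    return fl


def simulate_curve(
    pro: StrainProfile | None,
    alt: StrainProfile | None,
    config: SimConfig,
    seed: int,
    culture_id: str = "sim",
) -> tuple[CurveSeries, dict]:
    """One culture's noisy fluorescence series plus its ground-truth record.

    In co-culture the phototroph dominates the chlorophyll signal; its
    co-culture decline law and lag penalty apply.  Axenic heterotrophs give
    their own dim trajectory.
    """
    if pro is None and alt is None:
        raise ValueError("at least one strain profile required")
    rng = np.random.default_rng(seed)
    lead = pro if pro is not None else alt
    coculture = pro is not None and alt is not None
    decline = (
        pro.coculture_decline
        if (coculture and pro.coculture_decline is not None)
        else lead.decline
    )
    lag = lead.lag + (lead.coculture_lag_penalty if coculture else 0.0)
    # per-culture biological variation: growth parameters vary culture to
    # culture (not strain-linked), decline parameters get a small jitter
    mu, flmax = lead.mu, lead.flmax
    if config.param_jitter_cv > 0:
        sg_mu = np.sqrt(np.log1p(0.08**2))
        sg_fl = np.sqrt(np.log1p(0.20**2))
        mu = float(mu * rng.lognormal(-0.5 * sg_mu**2, sg_mu))
        flmax = float(flmax * rng.lognormal(-0.5 * sg_fl**2, sg_fl))
        lag = float(max(lag + rng.uniform(-1.0, 1.0), 0.3))
        sig = np.sqrt(np.log1p(config.param_jitter_cv**2))
        jitter = lambda v: float(v * rng.lognormal(-0.5 * sig**2, sig))  # noqa: E731
        vals = {
            k: (jitter(v) if isinstance(v, float) else v)
            for k, v in decline.__dict__.items()
            if k != "model" and v is not None
        }
        if "f" in vals:
            vals["f"] = min(max(vals["f"], 0.0), 1.0)
        decline = replace(decline, **vals)
    bump = lead.bump if config.enable_bumps else None

    n_samples = int(np.floor(config.duration / config.sampling_interval)) + 1
    base = np.arange(n_samples) * config.sampling_interval
    t = base + rng.uniform(-config.sampling_jitter, config.sampling_jitter, n_samples)
    t[0] = 0.0
    t = np.maximum.accumulate(np.maximum(t, 0.0))
    t = np.unique(t)

    clean = trajectory(t, mu, lag, flmax, decline, bump)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv**2))
        clean = clean * rng.lognormal(-0.5 * sigma**2, sigma, len(t))
    below = clean < config.detection_floor
    observed = np.where(below, config.detection_floor, clean)
    curve = CurveSeries(culture_id, t, observed, below)
    truth = {
        "culture_id": culture_id,
        "pro_strain": pro.strain if pro else "none",
        "alt_strain": alt.strain if alt else "none",
        "mu": mu,
        "lag": lag,
        "flmax": flmax,
        "tmax": lag + np.log(GROWTH_DECADES) / mu,
        "decline_model": decline.model,
        "decline_params": {
            k: v for k, v in decline.__dict__.items() if k != "model" and v is not None
        },
        "seed": seed,
    }
    return curve, truth


def _simulate_counts(
    meta: CultureMetadata, config: SimConfig, rng: np.random.Generator
) -> tuple[list[CellCountRecord], list[dict]]:
    """Budget-downward counts: latent biomass -> cells via quotas."""
    recs: list[CellCountRecord] = []
    truth: list[dict] = []
    sig = np.sqrt(np.log1p(BIOMASS_CV**2))
    lognoise = lambda: float(rng.lognormal(-0.5 * sig**2, sig))  # noqa: E731
    for day in config.count_days:
        pars = COUNT_DAY_PARAMS.get(day, COUNT_DAY_PARAMS[60.0])
        if meta.treatment == "axenic_pro":
            pro_b, alt_b = pars["ax_pro"] * lognoise(), 0.0
        elif meta.treatment == "axenic_alt":
            pro_b, alt_b = 0.0, pars["ax_alt"] * lognoise()
        else:
            alt_b = pars["ax_alt"] * 2.0 ** ALT_BENEFIT_LOG2FC[meta.pro_strain] * lognoise()
            frac = min(max(rng.normal(pars["frac_alt"], 0.08), 0.4), 0.95)
            pro_b = alt_b * (1.0 - frac) / frac
        total = pro_b + alt_b
        if total > config.n_total:  # closed budget: cap and rescale
            scale = config.n_total / total * (1.0 - 1e-9)
            pro_b, alt_b = pro_b * scale, alt_b * scale
        if meta.pro_strain != "none":
            cells = pro_b * MW_N / (DEFAULT_QUOTAS[meta.pro_strain] * 1e-6)
            recs.append(CellCountRecord(meta.culture_id, day, "prochlorococcus", cells))
        if meta.alt_strain != "none":
            cells = alt_b * MW_N / (DEFAULT_QUOTAS[meta.alt_strain] * 1e-6)
            recs.append(CellCountRecord(meta.culture_id, day, "alteromonas", cells))
        truth.append(
            {
                "culture_id": meta.culture_id,
                "day": day,
                "pro_biomass": pro_b,
                "alt_biomass": alt_b,
            }
        )
    return recs, truth


def simulate_experiment(
    config: SimConfig | None = None,
    library: dict[str, StrainProfile] | None = None,
) -> ExperimentSet:
    """Full 5x5 design: 25 co-culture combinations + axenic controls, in
    triplicate, with counts at the configured sampling days.

    The returned ExperimentSet's provenance holds the seed and the per-curve
    and per-count ground-truth tables.
    """
    config = config or SimConfig()
    library = library or default_library()
    pros = [p for p in library.values() if p.role == "phototroph"]
    alts = [p for p in library.values() if p.role == "heterotroph"]

    combos: list[tuple[StrainProfile | None, StrainProfile | None]] = []
    combos += [(p, a) for p in pros for a in alts]
    combos += [(p, None) for p in pros]
    combos += [(None, a) for a in alts]

    n_cultures = len(combos) * config.replicates
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * n_cultures) % (2**31)
    metadata: dict[str, CultureMetadata] = {}
    curves: dict[str, CurveSeries] = {}
    counts: list[CellCountRecord] = []
    truth_curves: list[dict] = []
    truth_counts: list[dict] = []
    i = 0
    for pro, alt in combos:
        for rep in range(1, config.replicates + 1):
            ps = pro.strain if pro else "none"
            as_ = alt.strain if alt else "none"
            cid = f"{ps}_{as_}_r{rep}"
            meta = CultureMetadata(cid, ps, as_, rep, "E1")
            curve, truth = simulate_curve(pro, alt, config, int(seeds[i]), cid)
            rec, ct = _simulate_counts(
                meta, config, np.random.default_rng(int(seeds[n_cultures + i]))
            )
            metadata[cid] = meta
            curves[cid] = curve
            counts.extend(rec)
            truth_curves.append(truth)
            truth_counts.extend(ct)
            i += 1
    return ExperimentSet(
        metadata,
        curves,
        counts,
        provenance={
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in config.__dict__.items()
            },
            "truth_curves": truth_curves,
            "truth_counts": truth_counts,
        },
    )
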