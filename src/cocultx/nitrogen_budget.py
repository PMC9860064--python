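"""Nitrogen-quota biomass accounting and synergy fold-change calls.

Flow-cytometry cell counts are converted to nitrogen biomass through
per-strain cellular N quotas (fg N per cell):

    biomass [umol N/L] = X [cells/ml] * Q_N [fg/cell] * 1e-9 [fmol -> umol]
                         / 1e-3 [ml -> L] / MW_N [g/mol]
                       = X * Q_N * 1e-6 / MW_N

The carrying capacity of a culture at a sampled day is the total N retained
in cell biomass, bounded by the 100 uM ammonium supplied in the low-N medium
(Pro99-LowN).  Quotas default to the lower end of measured values — 7 fg
N/cell for high-light *Prochlorococcus* (MED4, MIT9312, MIT0604), 10.5 for
NATL2A, 14 for MIT9313, 13 for all *Alteromonas* — since larger quotas push
the implied biomass above the available N.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cocultx.io_model import ALT_STRAINS, CellCountRecord, CultureMetadata

logger = logging.getLogger(__name__)

MW_N = 14.0  # g/mol
TOTAL_AVAILABLE_N = 100.0  # umol N / L in Pro99-LowN

DEFAULT_QUOTAS: dict[str, float] = {
    "MED4": 7.0,
    "MIT9312": 7.0,
    "MIT0604": 7.0,
    "NATL2A": 10.5,
    "MIT9313": 14.0,
    **{s: 13.0 for s in ALT_STRAINS},
}


class QuotaMissingError(KeyError):
    """A counted strain has no N quota."""


@dataclass(frozen=True)
class QuotaTable:
    """Strain -> cellular N quota (fg N per cell)."""

    quotas: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_QUOTAS))
    mw_n: float = MW_N

    def __post_init__(self) -> None:
        if any(q <= 0 for q in self.quotas.values()):
            raise ValueError("all quotas must be > 0")

    def __getitem__(self, strain: str) -> float:
        try:
            return self.quotas[strain]
        except KeyError as exc:
            raise QuotaMissingError(f"no N quota for strain {strain!r}") from exc


@dataclass(frozen=True)
class NBudget:
    """Nitrogen biomass of one culture at one sampled day (umol N/L)."""

    culture_id: str
    day: float
    pro_biomass: float
    alt_biomass: float
    total_available_n: float = TOTAL_AVAILABLE_N

    @property
    def total(self) -> float:
        return self.pro_biomass + self.alt_biomass

    @property
    def fraction_alt(self) -> float:
        return self.alt_biomass / self.total if self.total > 0 else 0.0

    @property
    def feasible(self) -> bool:
        return self.total <= self.total_available_n


@dataclass(frozen=True)
class SynergyCall:
    """log2 fold change of one population's biomass, co-culture vs axenic."""

    direction: str  # 'alt_on_pro' (effect of Alteromonas on Pro) | 'pro_on_alt'
    log2fc: float
    p_corrected: float
    call: str  # synergistic | neutral | competitive
    negative_trend: bool = False


def cells_to_biomass(x, q_n: float, mw_n: float = MW_N):
    """Convert cells/ml to umol N/L: X * Q_N * 1e-6 / MW_N."""
    if q_n <= 0:
        raise ValueError("Q_N must be > 0")
    return np.asarray(x, dtype=float) * q_n * 1e-6 / mw_n if np.ndim(x) else float(x) * q_n * 1e-6 / mw_n


def budget(
    counts: list[CellCountRecord],
    meta: CultureMetadata,
    quotas: QuotaTable | None = None,
    total_available_n: float = TOTAL_AVAILABLE_N,
) -> NBudget:
    """Per-population and total N biomass for one culture at one sampled day."""
    quotas = quotas or QuotaTable()
    if not counts:
        raise ValueError("no counts supplied")
    days = {c.day for c in counts}
    if len(days) != 1:
        raise ValueError(f"counts span multiple days: {sorted(days)}")
    pro = alt = 0.0
    for rec in counts:
        if rec.culture_id != meta.culture_id:
            raise ValueError("count does not belong to this culture")
        if rec.population == "prochlorococcus":
            if meta.pro_strain == "none":
                raise QuotaMissingError("prochlorococcus counted in a culture with no phototroph strain")
            pro += cells_to_biomass(rec.cells_per_ml, quotas[meta.pro_strain], quotas.mw_n)
        else:
            if meta.alt_strain == "none":
                raise QuotaMissingError("alteromonas counted in a culture with no heterotroph strain")
            alt += cells_to_biomass(rec.cells_per_ml, quotas[meta.alt_strain], quotas.mw_n)
    nb = NBudget(meta.culture_id, float(days.pop()), pro, alt, total_available_n)
    if not nb.feasible:
        logger.warning(
            "%s day %g: total biomass %.2f umol N/L exceeds available %.0f",
            nb.culture_id, nb.day, nb.total, total_available_n,
        )
    return nb


def budget_table(
    counts: list[CellCountRecord],
    metadata: dict[str, CultureMetadata],
    quotas: QuotaTable | None = None,
    total_available_n: float = TOTAL_AVAILABLE_N,
) -> pd.DataFrame:
    """Tidy N-budget table: one row per (culture, day)."""
    rows = []
    by_key: dict[tuple[str, float], list[CellCountRecord]] = {}
    for rec in counts:
        by_key.setdefault((rec.culture_id, rec.day), []).append(rec)
    for (cid, day), recs in sorted(by_key.items()):
        nb = budget(recs, metadata[cid], quotas, total_available_n)
        m = metadata[cid]
        rows.append(
            {
                "culture_id": cid,
                "day": day,
                "treatment": m.treatment,
                "pro_strain": m.pro_strain,
                "alt_strain": m.alt_strain,
                "pro_biomass": nb.pro_biomass,
                "alt_biomass": nb.alt_biomass,
                "total_biomass": nb.total,
                "fraction_alt": nb.fraction_alt,
                "feasible": nb.feasible,
            }
        )
    return pd.DataFrame(rows)


def quota_sensitivity(
    counts: list[CellCountRecord],
    meta: CultureMetadata,
    pro_quotas,
    alt_quotas,
    total_available_n: float = TOTAL_AVAILABLE_N,
) -> pd.DataFrame:
    """Recompute one culture-day budget on a grid of (pro, alt) quotas.

    Returns one row per quota combination with the implied total biomass and
    the feasibility flag (total <= available N); feasibility is monotone
    non-increasing in each quota since biomass is linear in Q_N.
    """
    rows = []
    for qp, qa in itertools.product(pro_quotas, alt_quotas):
        q = QuotaTable({**DEFAULT_QUOTAS, meta.pro_strain: qp, meta.alt_strain: qa})
        nb = budget(counts, meta, q, total_available_n)
        rows.append(
            {
                "pro_quota": qp,
                "alt_quota": qa,
                "total_biomass": nb.total,
                "feasible": nb.feasible,
            }
        )
    return pd.DataFrame(rows, columns=["pro_quota", "alt_quota", "total_biomass", "feasible"])


def synergy_log2fc(
    co_biomass,
    ax_biomass,
    direction: str = "pro_on_alt",
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> SynergyCall:
    """Synergy call from per-replicate biomasses (umol N/L), co vs axenic.

    log2fc = log2(mean_co / mean_ax); significance by a two-sample t-test on
    log2 biomasses, Bonferroni-multiplied by ``n_comparisons`` (the strain-pair
    family size).  Significant positive -> synergistic, significant negative ->
    competitive; otherwise neutral (with a negative_trend flag when the point
    estimate is negative).
    """
    co = np.asarray(co_biomass, dtype=float)
    ax = np.asarray(ax_biomass, dtype=float)
    for name, arr in (("co", co), ("ax", ax)):
        bad = arr <= 0
        if bad.any():
            logger.warning("%s arm: %d non-positive biomass value(s) excluded", name, bad.sum())
    co = co[co > 0]
    ax = ax[ax > 0]
    if len(co) < 2 or len(ax) < 2:
        raise ValueError("need >= 2 positive replicates in each arm")
    log2fc = float(np.log2(np.mean(co) / np.mean(ax)))
    _, p = stats.ttest_ind(np.log2(co), np.log2(ax))
    p_corr = float(min(p * n_comparisons, 1.0))
    if p_corr < alpha and log2fc > 0:
        call = "synergistic"
    elif p_corr < alpha and log2fc < 0:
        call = "competitive"
    else:
        call = "neutral"
    return SynergyCall(
        direction=direction,
        log2fc=log2fc,
        p_corrected=p_corr,
        call=call,
        negative_trend=(call == "neutral" and log2fc < 0),
    )


def synergy_table(budgets: pd.DataFrame) -> pd.DataFrame:
    """All same-strain synergy calls from a tidy budget table.

    For each (day, pro_strain, alt_strain) co-culture cell, compares
    - alt biomass in co-culture vs the same alt strain grown axenically
      (direction pro_on_alt), and
    - pro biomass in co-culture vs the same pro strain grown axenically
      (direction alt_on_pro),
    Bonferroni-correcting within each (day, direction) family.
    """
    rows = []
    for day, day_df in budgets.groupby("day"):
        co = day_df[day_df["treatment"] == "coculture"]
        ax_alt = day_df[day_df["treatment"] == "axenic_alt"]
        ax_pro = day_df[day_df["treatment"] == "axenic_pro"]
        pairs = co.groupby(["pro_strain", "alt_strain"])
        n_family = pairs.ngroups
        for (ps, as_), grp in pairs:
            for direction, co_col, ax_df, ax_col, ax_key in (
                ("pro_on_alt", "alt_biomass", ax_alt, "alt_biomass", as_),
                ("alt_on_pro", "pro_biomass", ax_pro, "pro_biomass", ps),
            ):
                ax_match = ax_df[
                    (ax_df["alt_strain"] == ax_key) if direction == "pro_on_alt"
                    else (ax_df["pro_strain"] == ax_key)
                ]
                try:
                    call = synergy_log2fc(
                        grp[co_col], ax_match[ax_col], direction, n_comparisons=n_family
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "day": day,
                        "pro_strain": ps,
                        "alt_strain": as_,
                        "direction": direction,
                        "log2fc": call.log2fc,
                        "p_corrected": call.p_corrected,
                        "call": call.call,
                        "negative_trend": call.negative_trend,
                    }
                )
    return pd.DataFrame(rows)
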