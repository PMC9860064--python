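"""One-call orchestration of the full co-culture analysis.

Runs, in order: growth-feature extraction, four-model decline fitting with
group summaries, nitrogen budgeting with synergy calls, peak-aligned matrix
construction, PCA, PERMANOVA, random-forest strain classification, and the
shape/biomass correlations; writes per-stage CSV tables plus a JSON report
of the headline statistics.  Deterministic given the config seed (stage
seeds are derived as seed + stage index).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cocultx import curve_analytics, decline_models, growth_features, nitrogen_budget
from cocultx.io_model import ExperimentSet, read_experiment, write_results

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int
    out_dir: str | Path | None = None
    models: tuple[str, ...] = decline_models.MODELS
    n_starts: int = 20
    window: tuple[int, int] = curve_analytics.DEFAULT_WINDOW
    folds: int = 10
    rf_repeats: int = 30
    n_permutations: int = 999
    total_available_n: float = nitrogen_budget.TOTAL_AVAILABLE_N
    quotas: dict[str, float] = field(
        default_factory=lambda: dict(nitrogen_budget.DEFAULT_QUOTAS)
    )

    # input paths; ignored when an ExperimentSet is passed directly
    curves_path: str | None = None
    metadata_path: str | None = None
    counts_path: str | None = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(config: RunConfig, expset: ExperimentSet | None = None) -> dict:
    """Execute the full analysis; returns the report bundle.

    The report contains headline statistics (group shape means, td2, RMSE by
    model and treatment, synergy calls, PERMANOVA, CV accuracies), per-stage
    timings and an exclusion log.  When ``config.out_dir`` is set, tables and
    the JSON report are written there.
    """
    if expset is None:
        expset = read_experiment(
            config.curves_path, config.metadata_path, config.counts_path
        )
    report: dict = {"seed": config.seed, "stages": {}, "exclusions": []}
    tables: dict[str, pd.DataFrame] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    _flush_partial()
                    raise StageError(name, exc) from exc

        return _Timer()

    def _flush_partial():
        if config.out_dir is not None and tables:
            write_results(tables, config.out_dir)

    meta_df = expset.metadata_frame()

    with _stage("features"):
        features = growth_features.extract_features(expset.curves)
        tables["features"] = features
        for _, row in features[features["status"] != "ok"].iterrows():
            report["exclusions"].append(
                {"stage": "features", "culture_id": row["culture_id"], "reason": row["status"]}
            )
        ok = features[features["status"] == "ok"]
        fmeta = ok.merge(meta_df, on="culture_id")
        fmeta["treatment"] = [
            expset.metadata[c].treatment for c in fmeta["culture_id"]
        ]
        report["stages"]["features"] = {
            "n_fitted": int(len(ok)),
            "mu_by_treatment": {
                t: float(g["mu"].mean()) for t, g in fmeta.groupby("treatment")
            },
        }

    with _stage("decline_fits"):
        all_fits: dict[str, dict] = {}
        peaks: dict[str, tuple[float, float]] = {}
        for i, (cid, curve) in enumerate(sorted(expset.curves.items())):
            try:
                peak = growth_features.find_peak(curve)
            except Exception:
                report["exclusions"].append(
                    {"stage": "decline_fits", "culture_id": cid, "reason": "no_signal"}
                )
                continue
            peaks[cid] = peak
            try:
                phase = decline_models.extract_decline(curve, peak)
            except decline_models.DeclineUndetectedError:
                report["exclusions"].append(
                    {"stage": "decline_fits", "culture_id": cid, "reason": "decline_undetected"}
                )
                continue
            all_fits[cid] = decline_models.fit_all(
                phase, config.n_starts, seed=config.seed + 1 + i
            )
        fits = decline_models.fits_table(all_fits)
        tables["decline_fits"] = fits
        summary = decline_models.summarize_fits(fits, meta_df)
        report["stages"]["decline"] = summary

    with _stage("nitrogen_budget"):
        if expset.counts:
            quotas = nitrogen_budget.QuotaTable(config.quotas)
            budgets = nitrogen_budget.budget_table(
                expset.counts, expset.metadata, quotas, config.total_available_n
            )
            tables["budgets"] = budgets
            synergy = nitrogen_budget.synergy_table(budgets)
            tables["synergy"] = synergy
            by_day = {}
            for day, grp in budgets.groupby("day"):
                co = grp[grp["treatment"] == "coculture"]
                by_day[str(day)] = {
                    "coculture_total_mean": float(co["total_biomass"].mean()),
                    "coculture_fraction_alt_mean": float(co["fraction_alt"].mean()),
                    "axenic_alt_total_mean": float(
                        grp.loc[grp["treatment"] == "axenic_alt", "total_biomass"].mean()
                    ),
                    "axenic_pro_total_mean": float(
                        grp.loc[grp["treatment"] == "axenic_pro", "total_biomass"].mean()
                    ),
                    "all_feasible": bool(grp["feasible"].all()),
                }
            report["stages"]["budget"] = {
                "by_day": by_day,
                "synergy_calls": synergy["call"].value_counts().to_dict()
                if len(synergy)
                else {},
            }
        else:
            report["stages"]["budget"] = {"skipped": "no counts"}

    with _stage("curve_shape"):
        usable = {c: expset.curves[c] for c in peaks}
        aligned = curve_analytics.align_and_grid(usable, peaks, config.window)
        std = curve_analytics.standardize(aligned)
        ord_res = curve_analytics.pca(std, k=2)
        labels_pro = np.array(
            [expset.metadata[c].pro_strain for c in std.sample_ids]
        )
        coc = np.array(
            [expset.metadata[c].treatment == "coculture" for c in std.sample_ids]
        )
        report["stages"]["ordination"] = {
            "explained_variance_ratio": [float(v) for v in ord_res.explained_variance_ratio],
        }
        perm_labels = labels_pro[coc]
        sub = std.values[coc]
        perm = curve_analytics.permanova(
            sub, perm_labels, n_perm=config.n_permutations, seed=config.seed + 100
        )
        report["stages"]["permanova"] = {
            "pseudo_F": perm.pseudo_f,
            "R2": perm.r2,
            "p": perm.p,
            "df": [perm.df_between, perm.df_within],
        }
        cls_res = {}
        co_matrix = curve_analytics.AlignedMatrix(
            sample_ids=[s for s, c in zip(std.sample_ids, coc) if c],
            grid=std.grid,
            values=sub,
            standardized=True,
        )
        for target, lbl in (
            ("pro_strain", labels_pro[coc]),
            (
                "alt_strain",
                np.array([expset.metadata[c].alt_strain for c in co_matrix.sample_ids]),
            ),
        ):
            res = curve_analytics.rf_classify(
                co_matrix,
                lbl,
                folds=config.folds,
                n_repeats=config.rf_repeats,
                seed=config.seed + 200,
            )
            cls_res[target] = {
                "mean_accuracy": res.mean_accuracy,
                "top_importance_days": [
                    int(d) for d in res.importance.nlargest(5).index
                ],
            }
        report["stages"]["classification"] = cls_res

    with _stage("correlations"):
        report["stages"]["correlations"] = {}
        if expset.counts and "decline_fits" in tables and len(tables["decline_fits"]):
            wb = tables["decline_fits"]
            wb = wb[(wb["model"] == "weibull") & wb["converged"]]
            day0 = min(b.day for b in expset.counts)
            bud = tables.get("budgets")
            if bud is not None:
                b60 = bud[bud["day"] == day0].set_index("culture_id")["total_biomass"]
                merged = wb.set_index("culture_id").join(b60, how="inner").dropna(
                    subset=["n", "total_biomass"]
                )
                co_ids = [
                    c
                    for c in merged.index
                    if expset.metadata[c].treatment == "coculture"
                ]
                merged = merged.loc[co_ids]
                if len(merged) >= 3 and merged["n"].std() > 0:
                    r_n, p_n = curve_analytics.correlate(
                        merged["total_biomass"], merged["n"]
                    )
                    r_e, p_e = curve_analytics.correlate(
                        merged["total_biomass"], merged["rmse"]
                    )
                    report["stages"]["correlations"] = {
                        "day": float(day0),
                        "biomass_vs_shape": {"r": r_n, "p": p_n},
                        "biomass_vs_rmse": {"r": r_e, "p": p_e},
                    }

    report["timings_s"] = timings
    if config.out_dir is not None:
        out = Path(config.out_dir)
        files = write_results(tables, out, extra_manifest={"seed": config.seed})
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        report["files"] = {**files, "report": str(report_path)}
    return report
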