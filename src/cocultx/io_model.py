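"""Core data types and validated tidy-CSV I/O.

Canonical on-disk dialect (UTF-8, ``.`` decimal separator, long format):

- ``curves.csv``:   ``culture_id,day,fluorescence`` — one row per observation,
- ``metadata.csv``: ``culture_id,experiment,pro_strain,alt_strain,replicate``,
- ``counts.csv``:   ``culture_id,day,population,cells_per_ml``.

Days are real numbers measured from inoculation (day 0).  Fluorescence values
at or below zero are retained on load but flagged below-detection; log-domain
operations downstream must exclude them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRO_STRAINS = ("MED4", "MIT9312", "MIT0604", "NATL2A", "MIT9313")
ALT_STRAINS = ("HOT1A3", "BS11", "ATCC27126", "AltDE1", "AltDE")

CURVES_COLUMNS = ("culture_id", "day", "fluorescence")
METADATA_COLUMNS = ("culture_id", "experiment", "pro_strain", "alt_strain", "replicate")
COUNTS_COLUMNS = ("culture_id", "day", "population", "cells_per_ml")

POPULATIONS = ("prochlorococcus", "alteromonas")


class FormatError(ValueError):
    """A delimited input file does not match the documented dialect."""


class IntegrityError(ValueError):
    """Referential-integrity violation between tables (orphan culture_id)."""


class NoSignalError(ValueError):
    """A curve carries no usable (positive) fluorescence signal."""


@dataclass(frozen=True)
class CultureMetadata:
    """One culture's identity: strains, replicate and experiment label.

    ``treatment`` is derived: 'coculture' iff both strains are present,
    otherwise 'axenic_pro' / 'axenic_alt'.
    """

    culture_id: str
    pro_strain: str  # one of PRO_STRAINS or "none"
    alt_strain: str  # one of ALT_STRAINS or "none"
    replicate: int
    experiment: str = "E1"

    def __post_init__(self) -> None:
        if self.pro_strain == "none" and self.alt_strain == "none":
            raise ValueError(f"{self.culture_id}: at least one strain required")
        if self.pro_strain not in PRO_STRAINS + ("none",):
            raise ValueError(f"{self.culture_id}: unknown pro_strain {self.pro_strain!r}")
        if self.alt_strain not in ALT_STRAINS + ("none",):
            raise ValueError(f"{self.culture_id}: unknown alt_strain {self.alt_strain!r}")
        if self.replicate < 1:
            raise ValueError(f"{self.culture_id}: replicate must be a positive integer")

    @property
    def treatment(self) -> str:
        if self.pro_strain != "none" and self.alt_strain != "none":
            return "coculture"
        return "axenic_pro" if self.pro_strain != "none" else "axenic_alt"


@dataclass(frozen=True)
class CurveSeries:
    """One culture's fluorescence time series.

    ``times`` are days since inoculation, strictly increasing; ``fluorescence``
    is in arbitrary units.  ``below_detection`` marks values <= 0 (or below an
    explicit detection floor) which must be excluded from log-domain work.
    """

    culture_id: str
    times: np.ndarray
    fluorescence: np.ndarray
    below_detection: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        fl = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", fl)
        if t.ndim != 1 or fl.ndim != 1 or len(t) != len(fl):
            raise ValueError(f"{self.culture_id}: times/fluorescence length mismatch")
        if len(t) and (np.any(~np.isfinite(t)) or np.any(t < 0)):
            raise ValueError(f"{self.culture_id}: times must be finite and non-negative")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.culture_id}: times must be strictly increasing")
        bd = self.below_detection
        if bd is None:
            bd = fl <= 0
        bd = np.asarray(bd, dtype=bool)
        if len(bd) != len(t):
            raise ValueError(f"{self.culture_id}: below_detection length mismatch")
        object.__setattr__(self, "below_detection", bd)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def detected(self) -> "CurveSeries":
        """The sub-series of points above the detection floor."""
        keep = ~self.below_detection
        return CurveSeries(
            self.culture_id,
            self.times[keep],
            self.fluorescence[keep],
            np.zeros(int(keep.sum()), dtype=bool),
        )


@dataclass(frozen=True)
class CellCountRecord:
    """A flow-cytometry count for one population at one sampled day."""

    culture_id: str
    day: float
    population: str  # 'prochlorococcus' | 'alteromonas'
    cells_per_ml: float

    def __post_init__(self) -> None:
        if self.population not in POPULATIONS:
            raise ValueError(f"{self.culture_id}: unknown population {self.population!r}")
        if not np.isfinite(self.cells_per_ml) or self.cells_per_ml < 0:
            raise ValueError(f"{self.culture_id}: count must be finite and >= 0")


@dataclass
class ExperimentSet:
    """A validated bundle: metadata, curves, counts and config provenance."""

    metadata: dict[str, CultureMetadata]
    curves: dict[str, CurveSeries]
    counts: list[CellCountRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.curves:
            if cid not in self.metadata:
                raise IntegrityError(f"curve {cid!r} has no metadata row")
        for rec in self.counts:
            if rec.culture_id not in self.metadata:
                raise IntegrityError(f"count for {rec.culture_id!r} has no metadata row")

    @property
    def culture_ids(self) -> list[str]:
        return list(self.curves)

    def curves_frame(self) -> pd.DataFrame:
        rows = []
        for cid, c in self.curves.items():
            rows.append(
                pd.DataFrame(
                    {"culture_id": cid, "day": c.times, "fluorescence": c.fluorescence}
                )
            )
        if not rows:
            return pd.DataFrame(columns=list(CURVES_COLUMNS))
        return pd.concat(rows, ignore_index=True)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "culture_id": m.culture_id,
                    "experiment": m.experiment,
                    "pro_strain": m.pro_strain,
                    "alt_strain": m.alt_strain,
                    "replicate": m.replicate,
                }
                for m in self.metadata.values()
            ],
            columns=list(METADATA_COLUMNS),
        )

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "culture_id": r.culture_id,
                    "day": r.day,
                    "population": r.population,
                    "cells_per_ml": r.cells_per_ml,
                }
                for r in self.counts
            ],
            columns=list(COUNTS_COLUMNS),
        )


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_experiment(
    curves_path,
    metadata_path,
    counts_path=None,
    provenance: Mapping | None = None,
) -> ExperimentSet:
    """Read and validate a curves/metadata(/counts) CSV trio.

    Rows failing invariants are rejected with row-level diagnostics: a curve
    with non-monotone times is dropped (warning logged) while the rest load;
    a curve or count whose ``culture_id`` has no metadata row raises
    :class:`IntegrityError`.
    """
    meta_df = pd.read_csv(metadata_path)
    _require_columns(meta_df, METADATA_COLUMNS, metadata_path)
    metadata: dict[str, CultureMetadata] = {}
    for _, row in meta_df.iterrows():
        m = CultureMetadata(
            culture_id=str(row["culture_id"]),
            pro_strain=str(row["pro_strain"]),
            alt_strain=str(row["alt_strain"]),
            replicate=int(row["replicate"]),
            experiment=str(row["experiment"]),
        )
        if m.culture_id in metadata:
            raise FormatError(f"{metadata_path}: duplicate culture_id {m.culture_id!r}")
        metadata[m.culture_id] = m

    curves_df = pd.read_csv(curves_path)
    _require_columns(curves_df, CURVES_COLUMNS, curves_path)
    orphans = set(curves_df["culture_id"].astype(str)) - set(metadata)
    if orphans:
        raise IntegrityError(
            f"{curves_path}: culture_id(s) absent from metadata: {sorted(orphans)}"
        )
    curves: dict[str, CurveSeries] = {}
    for cid, grp in curves_df.groupby("culture_id", sort=False):
        grp = grp.sort_values("day", kind="stable")
        try:
            curves[str(cid)] = CurveSeries(
                str(cid),
                grp["day"].to_numpy(dtype=float),
                grp["fluorescence"].to_numpy(dtype=float),
            )
        except ValueError as exc:
            logger.warning("curve %r rejected: %s", cid, exc)

    counts: list[CellCountRecord] = []
    if counts_path is not None:
        counts_df = pd.read_csv(counts_path)
        _require_columns(counts_df, COUNTS_COLUMNS, counts_path)
        count_orphans = set(counts_df["culture_id"].astype(str)) - set(metadata)
        if count_orphans:
            raise IntegrityError(
                f"{counts_path}: culture_id(s) absent from metadata: {sorted(count_orphans)}"
            )
        for _, row in counts_df.iterrows():
            counts.append(
                CellCountRecord(
                    culture_id=str(row["culture_id"]),
                    day=float(row["day"]),
                    population=str(row["population"]),
                    cells_per_ml=float(row["cells_per_ml"]),
                )
            )

    return ExperimentSet(metadata, curves, counts, dict(provenance or {}))


def write_experiment(expset: ExperimentSet, out_dir) -> dict[str, str]:
    """Write an ExperimentSet back to the canonical CSV trio; returns a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "curves": expset.curves_frame(),
        "metadata": expset.metadata_frame(),
    }
    if expset.counts:
        tables["counts"] = expset.counts_frame()
    return write_results(tables, out, extra_manifest={"provenance": expset.provenance})


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    extra_manifest: Mapping | None = None,
) -> dict[str, str]:
    """Write named result tables as CSV plus a JSON run manifest.

    Floats are written with 17 significant digits so a re-read reproduces
    values well past the 12-digit round-trip contract.
    """
    from cocultx import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package_version": __version__, "tables": {}}
    if extra_manifest:
        manifest.update(extra_manifest)
    for name, df in tables.items():
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.17g")
        manifest["tables"][name] = {"file": path.name, "rows": int(len(df))}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    files = {name: str(out / f"{name}.csv") for name in tables}
    files["manifest"] = str(manifest_path)
    return files
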