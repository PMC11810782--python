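"""Bulk membrane solubilization from dithionite-quench fluorescence pairs.

Dithionite chemically reduces fluorescent lipid headgroups it can reach: both
leaflets of an open polymer nanodisc, but only the outer leaflet of a sealed
vesicle. A labeled membrane is read once after polymer solubilization (fl1)
and once after dithionite addition (fl2). Doubling fl2 reconstructs the total
vesicular fluorescence, so the fraction of membrane converted to nanodiscs is

    bulk solubilization [%] = 100 - (2 * fl2 / fl1) * 100

Because both readings come from the same well, multiplicative well-to-well
variation (sample amount, labeling) cancels in the ratio; this is what makes
the assay quantitative at plate scale.

A second, GFP-based readout quantifies extraction of a specific GFP-tagged
protein as the percentage of pre-solubilization GFP fluorescence remaining in
the cleared (post-ultracentrifugation) fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QuenchMeasurement",
    "SolubilizationResult",
    "InvalidMeasurementError",
    "bulk_solubilization",
    "aggregate_solubilization",
    "gfp_extraction_efficiency",
    "read_plate_csv",
    "write_results_csv",
]


class InvalidMeasurementError(ValueError):
    """Raised for measurements that cannot yield a solubilization value (fl1 <= 0)."""


@dataclass(frozen=True)
class QuenchMeasurement:
    """One pre/post-dithionite fluorescence pair for a sample well."""

    sample_id: str
    fl1: float  # fluorescence before dithionite, arbitrary units
    fl2: float  # fluorescence after dithionite
    replicate: int = 1
    condition: str = ""


@dataclass(frozen=True)
class SolubilizationResult:
    """Percent solubilization for one measurement (or condition aggregate)."""

    sample_id: str
    percent: float
    raw: float = float("nan")
    clamped: bool = False
    mean: float | None = None
    sd: float | None = None
    n: int = 1


def bulk_solubilization(
    m: QuenchMeasurement, clamp: bool = True, background: float = 0.0
) -> SolubilizationResult:
    """Percent of labeled membrane solubilized into nanodiscs.

    Computes ``100 - (2 * fl2 / fl1) * 100``. Under measurement noise (or
    incomplete labeling) the raw value can leave [0, 100]; by default it is
    clamped to the physical range and flagged, so plate-scale screens complete
    without manual intervention. ``background`` (a blank-well reading) is
    subtracted from both readings before the ratio; it is 0 by default.
    """
    fl1 = m.fl1 - background
    fl2 = m.fl2 - background
    if not math.isfinite(fl1) or fl1 <= 0:
        raise InvalidMeasurementError(
            f"{m.sample_id}: background-corrected fl1 must be positive, got {fl1}"
        )
    if not math.isfinite(fl2):
        raise InvalidMeasurementError(f"{m.sample_id}: fl2 must be finite, got {m.fl2}")
    if m.fl2 < 0:
        raise InvalidMeasurementError(f"{m.sample_id}: fl2 must be >= 0, got {m.fl2}")
    fl2 = max(fl2, 0.0)  # blank can exceed a fully quenched well
    raw = 100.0 - (2.0 * fl2 / fl1) * 100.0
    out_of_range = raw < 0.0 or raw > 100.0
    percent = min(100.0, max(0.0, raw)) if clamp else raw
    return SolubilizationResult(m.sample_id, percent, raw=raw, clamped=out_of_range)


def aggregate_solubilization(
    results: Sequence[SolubilizationResult], sd_single: float = 0.0
) -> SolubilizationResult:
    """Mean and sample (n-1) standard deviation across replicate results.

    ``sd_single`` is reported for the degenerate single-replicate case, where
    the sample standard deviation is undefined; 0 by default.
    """
    if not results:
        raise InvalidMeasurementError("no replicate results to aggregate")
    vals = np.array([r.percent for r in results], dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float(sd_single)
    return SolubilizationResult(
        sample_id=results[0].sample_id,
        percent=mean,
        clamped=any(r.clamped for r in results),
        mean=mean,
        sd=sd,
        n=len(vals),
    )


def gfp_extraction_efficiency(
    fl_pre: float, fl_post: float, clamp: bool = True
) -> SolubilizationResult:
    """Percent GFP fluorescence retained after solubilization and clearing.

    ``100 * fl_post / fl_pre``, clamped to [0, 100] with a flag when the raw
    ratio exceeds the physical range.
    """
    if not math.isfinite(fl_pre) or fl_pre <= 0:
        raise InvalidMeasurementError(f"fl_pre must be positive, got {fl_pre}")
    raw = 100.0 * fl_post / fl_pre
    out_of_range = raw < 0.0 or raw > 100.0
    percent = min(100.0, max(0.0, raw)) if clamp else raw
    return SolubilizationResult("gfp", percent, raw=raw, clamped=out_of_range)


# -- plate IO ------------------------------------------------------------------


def read_plate_csv(path: str | Path) -> list[QuenchMeasurement]:
    """Read plate-reader pairs from CSV (sample_id, condition, replicate, fl1, fl2)."""
    df = pd.read_csv(path)
    required = {"sample_id", "fl1", "fl2"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidMeasurementError(f"plate CSV missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            QuenchMeasurement(
                sample_id=str(r["sample_id"]),
                fl1=float(r["fl1"]),
                fl2=float(r["fl2"]),
                replicate=int(r.get("replicate", 1)),
                condition=str(r.get("condition", "")),
            )
        )
    return out


def process_plate(
    measurements: Iterable[QuenchMeasurement], clamp: bool = True
) -> pd.DataFrame:
    """Per-condition mean/sd table from a plate of quench measurements."""
    rows = []
    by_cond: dict[str, list[SolubilizationResult]] = {}
    for m in measurements:
        res = bulk_solubilization(m, clamp=clamp)
        by_cond.setdefault(m.condition or m.sample_id, []).append(res)
        rows.append((m.condition or m.sample_id, m.sample_id, res.percent, res.raw, res.clamped))
    per = pd.DataFrame(rows, columns=["condition", "sample_id", "percent", "raw", "clamped"])
    agg_rows = []
    for cond, results in by_cond.items():
        a = aggregate_solubilization(results)
        agg_rows.append((cond, a.mean, a.sd, a.n, a.clamped))
    agg = pd.DataFrame(agg_rows, columns=["condition", "mean", "sd", "n", "any_clamped"])
    return per.merge(agg, on="condition")


def write_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, index=False)
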