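"""Building the searchable solubilization database.

Per protein, LFQ intensities are averaged across retained replicates on the
linear scale, and the condition with the highest mean is scaled to 100%, all
others relative to it. "Not detected" is represented as NaN throughout —
distinct from 0% — so the query layer can display absence honestly.

Averaging excludes zeros inside a retained condition (a zero encodes
left-censoring, not an abundance of zero); the number of such excluded cells
is logged in the database provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITION_CLASSES, DETERGENT_CLASS, polymer_conditions
from .ingest import LfqTable

__all__ = [
    "ExtractionProfile",
    "SolubilizationDatabase",
    "ProfileError",
    "average_replicates",
    "median_center",
    "build_profiles",
    "best_condition_counts",
    "detection_overlap",
    "organelle_coverage",
    "save_database",
    "load_database",
]

DB_VERSION = "1"


class ProfileError(ValueError):
    """Raised on inconsistent inputs to database construction."""


@dataclass(frozen=True)
class ExtractionProfile:
    """One protein's relative extraction efficiency across conditions.

    ``relative`` maps each *detected* condition to a value in (0, 100] with
    the maximum exactly 100; undetected conditions are simply absent.
    """

    gene: str
    protein_id: str
    relative: Mapping[str, float]
    mean_lfq: Mapping[str, float]
    best_condition: str
    tie: bool = False

    @property
    def detected_conditions(self) -> frozenset:
        return frozenset(self.relative)


@dataclass
class SolubilizationDatabase:
    """Gene-keyed extraction profiles over the screened conditions.

    ``profiles`` is a gene x condition matrix of relative efficiencies in
    (0, 100] with NaN for not-detected; each row's max over detected
    conditions is exactly 100. ``meta`` carries optional per-gene annotation
    (protein_id, organelles, membrane_class, tmd_count, mw_kda).
    """

    profiles: pd.DataFrame
    mean_lfq: pd.DataFrame
    best_condition: pd.Series
    tie: pd.Series
    condition_classes: dict = field(default_factory=dict)
    meta: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)
    version: str = DB_VERSION

    def __post_init__(self) -> None:
        if self.profiles.index.duplicated().any():
            raise ProfileError("duplicate genes in database")
        vals = self.profiles.to_numpy()
        if np.nanmax(vals, initial=0.0) > 100.0 + 1e-9:
            raise ProfileError("relative efficiency above 100")
        rows = ~np.all(np.isnan(vals), axis=1)
        if rows.any():
            row_max = np.nanmax(vals[rows], axis=1)
            if not np.allclose(row_max, 100.0):
                raise ProfileError("every detected row must have max exactly 100")

    @property
    def conditions(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.profiles.index)

    def profile(self, gene: str) -> ExtractionProfile:
        row = self.profiles.loc[gene]
        detected = row.dropna()
        return ExtractionProfile(
            gene=gene,
            protein_id=(
                str(self.meta.at[gene, "protein_id"])
                if self.meta is not None and "protein_id" in self.meta.columns
                else gene
            ),
            relative=dict(detected),
            mean_lfq=dict(self.mean_lfq.loc[gene].dropna()),
            best_condition=str(self.best_condition.loc[gene]),
            tie=bool(self.tie.loc[gene]),
        )


def median_center(table: LfqTable) -> LfqTable:
    """Optional sample-level normalization: equalize per-column medians.

    Each sample column is scaled so the median of its positive intensities
    matches the grand median over all columns. Off by default in the build
    pipeline; provided for sensitivity analysis of column-loading effects.
    """
    out = table.copy()
    mat = out.intensities.to_numpy(float)
    medians = np.array(
        [np.median(col[col > 0]) if (col > 0).any() else np.nan for col in mat.T]
    )
    grand = np.nanmedian(medians)
    scale = np.where(np.isnan(medians), 1.0, grand / medians)
    out.intensities = pd.DataFrame(
        mat * scale[None, :], index=out.intensities.index, columns=out.intensities.columns
    )
    out.log.append({"op": "median_center", "grand_median": float(grand)})
    return out


def average_replicates(table: LfqTable, log_scale: bool = False) -> pd.DataFrame:
    """Mean LFQ per protein x condition on the linear intensity scale.

    Uses the retention mask from the biological-replicate filter when
    present: masked (protein, condition) cells propagate as NaN. Zeros inside
    a retained condition are excluded from the mean (they encode censoring).
    Without a mask, a condition counts as detected if any replicate is
    positive. ``log_scale=True`` averages log10 intensities instead
    (a geometric mean), for sensitivity analysis.
    """
    conditions = table.conditions
    out = pd.DataFrame(np.nan, index=table.intensities.index, columns=conditions)
    for cond in conditions:
        cols = table.sample_columns(cond)
        block = table.intensities[cols].to_numpy(float)
        pos = block > 0
        npos = pos.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if log_scale:
                logs = np.where(pos, np.log10(np.where(pos, block, 1.0)), 0.0)
                means = np.where(
                    npos > 0, 10 ** (logs.sum(axis=1) / np.maximum(npos, 1)), np.nan
                )
            else:
                means = np.where(npos > 0, block.sum(axis=1) / np.maximum(npos, 1), np.nan)
        if table.retention is not None:
            means = np.where(table.retention[cond].to_numpy(), means, np.nan)
        out[cond] = means
    return out


def build_profiles(
    means: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    condition_classes: Mapping[str, str] | None = None,
    provenance: Mapping | None = None,
) -> SolubilizationDatabase:
    """Max-normalize condition means into a solubilization database.

    Each detected condition becomes ``100 * mean / max(mean)``; the best
    condition is the argmax, with exact ties broken lexicographically and
    flagged. Proteins with no detected condition are rejected.
    """
    if means.isna().all(axis=1).any():
        bad = list(means.index[means.isna().all(axis=1)])
        raise ProfileError(f"proteins with no detected condition: {bad[:5]}")

    vals = means.to_numpy(float)
    row_max = np.nanmax(vals, axis=1)
    # divide first: x/x == 1 exactly, so the best condition is exactly 100
    rel = 100.0 * (vals / row_max[:, None])
    profiles = pd.DataFrame(rel, index=means.index, columns=means.columns)

    best, tie = [], []
    for i in range(len(means)):
        at_max = np.isclose(vals[i], row_max[i]) & ~np.isnan(vals[i])
        winners = sorted(means.columns[at_max])
        best.append(winners[0])
        tie.append(len(winners) > 1)

    # key the database by gene, resolving collisions with the protein id
    if meta is not None and "gene" in meta.columns:
        genes = []
        seen: dict[str, int] = {}
        for pid in means.index:
            g = str(meta.at[pid, "gene"]) or str(pid)
            if g in seen:
                g = f"{g}_{pid}"
            seen[g] = 1
            genes.append(g)
        index = pd.Index(genes, name="gene")
        dbmeta = meta.copy()
        dbmeta.insert(0, "protein_id", dbmeta.index)
        dbmeta.index = index
    else:
        index = means.index.rename("gene")
        dbmeta = None if meta is None else meta.copy()

    cmap = dict(condition_classes) if condition_classes is not None else {
        c: CONDITION_CLASSES.get(c, "unknown") for c in means.columns
    }
    prov = dict(provenance or {})
    prov.setdefault("n_proteins", len(means))
    return SolubilizationDatabase(
        profiles=profiles.set_axis(index, axis=0),
        mean_lfq=means.set_axis(index, axis=0),
        best_condition=pd.Series(best, index=index, name="best_condition"),
        tie=pd.Series(tie, index=index, name="tie"),
        condition_classes=cmap,
        meta=dbmeta,
        provenance=prov,
    )


def best_condition_counts(db: SolubilizationDatabase) -> dict[str, int]:
    """Number of proteins best solubilized under each condition.

    Ties count toward their lexicographically first condition (the stored
    best), so counts always sum to the number of proteins.
    """
    counts = {c: 0 for c in db.conditions}
    for c in db.best_condition:
        counts[c] += 1
    return counts


def detection_overlap(
    db: SolubilizationDatabase, class_map: Mapping[str, str] | None = None
) -> dict:
    """Detection-set overlaps between condition classes.

    A protein is detected in a class if detected in >= 1 member condition.
    Reports per-class counts, class-exclusive counts, the set detected in
    every individual condition, and the polymer-only set (detected in at
    least one polymer condition and in no detergent condition).
    """
    cmap = dict(class_map) if class_map is not None else dict(db.condition_classes)
    missing = [c for c in db.conditions if c not in cmap]
    if missing:
        raise ProfileError(f"conditions lacking a class: {missing}")

    detected = db.profiles.notna()
    classes = sorted(set(cmap.values()))
    class_sets = {
        k: set(detected.index[detected[[c for c in db.conditions if cmap[c] == k]].any(axis=1)])
        for k in classes
    }
    all_conditions = set(detected.index[detected.all(axis=1)])
    polymers = [c for c in db.conditions if cmap[c] != DETERGENT_CLASS]
    detergents = [c for c in db.conditions if cmap[c] == DETERGENT_CLASS]
    polymer_any = set(detected.index[detected[polymers].any(axis=1)]) if polymers else set()
    detergent_any = set(detected.index[detected[detergents].any(axis=1)]) if detergents else set()
    exclusive = {
        k: sum(
            1
            for g in class_sets[k]
            if all(g not in class_sets[j] for j in classes if j != k)
        )
        for k in classes
    }
    return {
        "n_proteins": len(detected),
        "per_class": {k: len(v) for k, v in class_sets.items()},
        "exclusive_per_class": exclusive,
        "all_conditions": len(all_conditions),
        "map_only": len(polymer_any - detergent_any),
        "detergent_only": len(detergent_any - polymer_any),
    }


def organelle_coverage(db: SolubilizationDatabase) -> dict[str, int]:
    """Protein counts per organelle; multi-organelle proteins count once each.

    Proteins without organelle annotation fall under ``unassigned``.
    """
    if db.meta is None or "organelles" not in db.meta.columns:
        raise ProfileError("database has no organelle annotations")
    counts: dict[str, int] = {}
    for v in db.meta["organelles"]:
        labels = [s for s in str(v).split(";") if s]
        if not labels:
            counts["unassigned"] = counts.get("unassigned", 0) + 1
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    return counts


# -- serialization -------------------------------------------------------------


def save_database(db: SolubilizationDatabase, path: str | Path) -> None:
    """Write the database as a versioned long-format TSV + JSON metadata sidecar.

    Only detected (gene, condition) cells are written; the loader
    reconstructs the NaN grid from the condition list in the metadata.
    """
    path = Path(path)
    rows = []
    for gene in db.genes:
        for cond in db.conditions:
            rel = db.profiles.at[gene, cond]
            if np.isnan(rel):
                continue
            rows.append(
                (
                    gene,
                    cond,
                    repr(float(rel)),
                    repr(float(db.mean_lfq.at[gene, cond])),
                    int(db.best_condition.at[gene] == cond),
                    int(db.tie.at[gene]),
                )
            )
    long = pd.DataFrame(
        rows,
        columns=["gene", "condition", "relative_percent", "mean_lfq", "best_flag", "tie_flag"],
    )
    long.to_csv(path, sep="\t", index=False)

    meta_records = None
    if db.meta is not None:
        meta_records = {
            str(g): {k: _jsonable(v) for k, v in rec.items()}
            for g, rec in db.meta.to_dict(orient="index").items()
        }
    sidecar = {
        "version": db.version,
        "conditions": db.conditions,
        "condition_classes": db.condition_classes,
        "provenance": db.provenance,
        "meta": meta_records,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def load_database(path: str | Path) -> SolubilizationDatabase:
    path = Path(path)
    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    if sidecar["version"] != DB_VERSION:
        raise ProfileError(
            f"database version {sidecar['version']!r} not supported (expected {DB_VERSION!r})"
        )
    long = pd.read_csv(
        path,
        sep="\t",
        dtype={"gene": str, "condition": str, "best_flag": int, "tie_flag": int},
        converters={"relative_percent": float, "mean_lfq": float},
    )
    conditions = sidecar["conditions"]
    genes = list(dict.fromkeys(long["gene"]))
    profiles = pd.DataFrame(np.nan, index=pd.Index(genes, name="gene"), columns=conditions)
    mean_lfq = profiles.copy()
    best = pd.Series("", index=profiles.index, name="best_condition")
    tie = pd.Series(False, index=profiles.index, name="tie")
    for _, r in long.iterrows():
        profiles.at[r["gene"], r["condition"]] = r["relative_percent"]
        mean_lfq.at[r["gene"], r["condition"]] = r["mean_lfq"]
        tie.at[r["gene"]] = bool(r["tie_flag"])
        if r["best_flag"]:
            best.at[r["gene"]] = r["condition"]
    meta = None
    if sidecar.get("meta") is not None:
        meta = pd.DataFrame.from_dict(sidecar["meta"], orient="index")
        meta.index.name = "gene"
        meta = meta.loc[profiles.index]
    return SolubilizationDatabase(
        profiles=profiles,
        mean_lfq=mean_lfq,
        best_condition=best,
        tie=tie,
        condition_classes=sidecar["condition_classes"],
        meta=meta,
        provenance=sidecar["provenance"],
        version=sidecar["version"],
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, float) and np.isnan(v):
        return None
    return v
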