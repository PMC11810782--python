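"""Programmatic and command-line query layer over a built database.

The query layer is strictly read-only: results mirror the stored database
values bit-exactly, with no recomputation at query time. Gene matching is
case-insensitive; ambiguous matches are reported, never auto-resolved.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics
from .profiledb import SolubilizationDatabase, load_database, save_database

__all__ = [
    "QueryResult",
    "GeneNotFoundError",
    "AmbiguousGeneError",
    "lookup",
    "lookup_complex",
    "export",
]


class GeneNotFoundError(KeyError):
    def __init__(self, gene: str, suggestions: Sequence[str]):
        self.gene = gene
        self.suggestions = list(suggestions)
        hint = f" (did you mean: {', '.join(self.suggestions)}?)" if self.suggestions else ""
        super().__init__(f"gene {gene!r} not in database{hint}")


class AmbiguousGeneError(KeyError):
    def __init__(self, gene: str, candidates: Sequence[str]):
        self.gene = gene
        self.candidates = list(candidates)
        super().__init__(
            f"gene {gene!r} matches several entries: {', '.join(self.candidates)}"
        )


@dataclass(frozen=True)
class QueryResult:
    """One gene's stored extraction profile, as held in the database."""

    gene: str
    relative: Mapping[str, float]  # condition -> percent; absent = not detected
    best_condition: str
    tie: bool
    organelles: tuple
    not_detected: tuple

    def as_dict(self) -> dict:
        return {
            "gene": self.gene,
            "relative": dict(self.relative),
            "best_condition": self.best_condition,
            "tie": self.tie,
            "organelles": list(self.organelles),
            "not_detected": list(self.not_detected),
        }


def _resolve_gene(db: SolubilizationDatabase, gene: str) -> str:
    exact = [g for g in db.genes if g == gene]
    if exact:
        return exact[0]
    ci = [g for g in db.genes if g.lower() == gene.lower()]
    if len(ci) == 1:
        return ci[0]
    if len(ci) > 1:
        raise AmbiguousGeneError(gene, ci)
    suggestions = difflib.get_close_matches(gene.upper(), [g.upper() for g in db.genes], n=3)
    by_upper = {g.upper(): g for g in db.genes}
    raise GeneNotFoundError(gene, [by_upper[s] for s in suggestions if s in by_upper])


def lookup(db: SolubilizationDatabase, gene: str) -> QueryResult:
    """Fetch one gene's profile (case-insensitive; suggestions on miss)."""
    g = _resolve_gene(db, gene)
    row = db.profiles.loc[g]
    detected = row.dropna()
    organelles: tuple = ()
    if db.meta is not None and "organelles" in db.meta.columns:
        v = db.meta.at[g, "organelles"]
        organelles = tuple(s for s in str(v).split(";") if s) if v is not None else ()
    return QueryResult(
        gene=g,
        relative={c: float(v) for c, v in detected.items()},
        best_condition=str(db.best_condition.at[g]),
        tie=bool(db.tie.at[g]),
        organelles=organelles,
        not_detected=tuple(c for c in db.conditions if c not in detected.index),
    )


def lookup_complex(
    db: SolubilizationDatabase, genes: Sequence[str], missing: str = "error"
) -> pd.DataFrame:
    """Ranked per-condition solubilization index for a multiprotein complex.

    Gene names are resolved case-insensitively, then delegated to
    :func:`mapscreen.metrics.index_profile`, so the returned indices agree
    exactly with the metrics module.
    """
    resolved = [_resolve_gene(db, g) for g in genes]
    return metrics.index_profile(db, resolved, missing=missing)


def export(db: SolubilizationDatabase, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the full database as TSV (+ metadata sidecar) or a single JSON."""
    path = Path(path)
    if fmt == "tsv":
        save_database(db, path)
    elif fmt == "json":
        payload = {
            "version": db.version,
            "conditions": db.conditions,
            "condition_classes": db.condition_classes,
            "provenance": db.provenance,
            "profiles": {
                g: {
                    c: (None if np.isnan(db.profiles.at[g, c]) else float(db.profiles.at[g, c]))
                    for c in db.conditions
                }
                for g in db.genes
            },
            "best_condition": {g: str(db.best_condition.at[g]) for g in db.genes},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path
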