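"""Parsing and filtering of label-free quantitative (LFQ) protein tables.

The module reads protein-group tables in the MaxQuant ``proteinGroups``
dialect (one ``LFQ intensity <sample>`` column per condition x replicate),
applies the screen's filtering rules — decoy/contaminant removal and the
"detected in both biological replicates" rule — and attaches membrane and
organelle annotations from a UniProt-derived table.

Intensities are carried on the linear LFQ scale; a stored value of 0 means
"not detected" and is never treated as an abundance. Filters never mutate
their input and log in/out counts on the returned table.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SampleKey",
    "LfqTable",
    "AnnotationTable",
    "IngestError",
    "ORGANELLE_VOCAB",
    "MEMBRANE_CLASSES",
    "DEFAULT_SAMPLE_PATTERN",
    "read_proteingroups",
    "write_proteingroups",
    "read_annotations",
    "write_annotations",
    "filter_decoys_contaminants",
    "filter_bio_replicates",
    "annotate_membrane",
]

LFQ_PREFIX = "LFQ intensity "

#: Regex template mapping an LFQ sample name to (condition, bio, tech).
#: MaxQuant column naming is site-specific, so the pattern is configurable.
DEFAULT_SAMPLE_PATTERN = r"^(?P<condition>.+)_bio(?P<bio>\d+)_tech(?P<tech>\d+)$"

ORGANELLE_VOCAB = (
    "PM",
    "ER",
    "mitochondria-inner",
    "mitochondria-outer",
    "nucleus",
    "lysosome",
    "Golgi",
    "autophagosome",
    "endosome",
    "peroxisome",
    "SV",
)

MEMBRANE_CLASSES = ("integral", "peripheral", "none")

MANDATORY_COLUMNS = ("Protein IDs",)


class IngestError(ValueError):
    """Raised on malformed input tables or invalid filter parameters."""


class SampleKey(NamedTuple):
    """Identity of one LFQ sample column: condition x biological x technical replicate."""

    condition: str
    bio_rep: int
    tech_rep: int

    @property
    def label(self) -> str:
        return f"{self.condition}_bio{self.bio_rep}_tech{self.tech_rep}"


def parse_sample_name(name: str, pattern: str = DEFAULT_SAMPLE_PATTERN) -> SampleKey:
    m = re.match(pattern, name)
    if m is None:
        raise IngestError(f"sample name {name!r} does not match pattern {pattern!r}")
    return SampleKey(m.group("condition"), int(m.group("bio")), int(m.group("tech")))


@dataclass
class LfqTable:
    """Protein x sample intensity matrix with sample and protein metadata.

    Attributes
    ----------
    intensities
        DataFrame indexed by protein-group id, one column per sample label,
        non-negative floats; 0 encodes not-detected.
    samples
        DataFrame indexed by sample label with columns ``condition``,
        ``bio_rep``, ``tech_rep``.
    meta
        Per-protein metadata: ``accessions`` (semicolon-joined), ``gene``,
        ``mw_kda``, ``is_decoy``, ``is_contaminant``; annotation adds
        ``organelles``, ``membrane_class``, ``tmd_count``.
    retention
        Optional boolean protein x condition mask produced by
        :func:`filter_bio_replicates`; ``False`` marks conditions where the
        protein failed the biological-replicate detection rule.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    meta: pd.DataFrame
    retention: pd.DataFrame | None = None
    review: pd.DataFrame | None = None
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.samples.index.duplicated().any():
            raise IngestError("duplicate sample columns")
        if not self.intensities.columns.equals(self.samples.index):
            raise IngestError("intensity columns and sample metadata disagree")
        if not self.intensities.index.equals(self.meta.index):
            raise IngestError("intensity rows and protein metadata disagree")
        if (self.intensities.to_numpy() < 0).any():
            raise IngestError("negative LFQ intensity")
        keys = list(
            zip(self.samples["condition"], self.samples["bio_rep"], self.samples["tech_rep"])
        )
        if len(set(keys)) != len(keys):
            raise IngestError("duplicate (condition, bio_rep, tech_rep) sample keys")

    # -- convenience accessors -------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.samples["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    def sample_columns(self, condition: str, bio_rep: int | None = None) -> list[str]:
        sel = self.samples["condition"] == condition
        if bio_rep is not None:
            sel &= self.samples["bio_rep"] == bio_rep
        return list(self.samples.index[sel])

    def bio_reps(self, condition: str) -> list[int]:
        return sorted(self.samples.loc[self.samples["condition"] == condition, "bio_rep"].unique())

    def n_tech(self, condition: str, bio_rep: int) -> int:
        return len(self.sample_columns(condition, bio_rep))

    def detected(self) -> pd.DataFrame:
        """Boolean detection matrix (LFQ > 0)."""
        return self.intensities > 0

    def copy(self) -> "LfqTable":
        return LfqTable(
            intensities=self.intensities.copy(),
            samples=self.samples.copy(),
            meta=self.meta.copy(),
            retention=None if self.retention is None else self.retention.copy(),
            review=None if self.review is None else self.review.copy(),
            log=list(self.log),
        )

    def _with(self, **kw) -> "LfqTable":
        out = self.copy()
        for k, v in kw.items():
            setattr(out, k, v)
        return out


@dataclass
class AnnotationTable:
    """UniProt-derived membrane/organelle annotation, keyed by accession.

    Columns: ``gene``, ``organelles`` (semicolon-joined labels from
    :data:`ORGANELLE_VOCAB`, possibly empty), ``membrane_class`` (one of
    :data:`MEMBRANE_CLASSES`), ``tmd_count``, ``mw_kda``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise IngestError("duplicate accessions in annotation table")
        bad = set(self.table["membrane_class"]) - set(MEMBRANE_CLASSES)
        if bad:
            raise IngestError(f"unknown membrane classes: {sorted(bad)}")

    def organelle_sets(self) -> dict[str, frozenset]:
        return {
            acc: frozenset(s for s in str(v).split(";") if s)
            for acc, v in self.table["organelles"].items()
        }

    def by_gene(self) -> pd.Series:
        """Map gene name -> list of accessions (for fallback matching)."""
        return self.table.groupby("gene").apply(lambda d: list(d.index))


# -- proteinGroups dialect IO --------------------------------------------------


def read_proteingroups(
    path: str | Path, sample_pattern: str = DEFAULT_SAMPLE_PATTERN
) -> LfqTable:
    """Read a TSV in the MaxQuant ``proteinGroups`` dialect.

    Decoy rows (``Reverse == '+'``) and contaminant rows
    (``Potential contaminant == '+'``) are flagged, not dropped. Blank LFQ
    cells parse as 0 (the dialect's not-detected convention); any other
    non-numeric cell is rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise IngestError(f"duplicate columns in {path.name}: {dupes}")
    missing = [c for c in MANDATORY_COLUMNS if c not in header]
    if missing:
        raise IngestError(f"missing mandatory columns: {missing}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lfq_cols = [c for c in df.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise IngestError("no 'LFQ intensity' columns found")
    keys = [parse_sample_name(c[len(LFQ_PREFIX) :], sample_pattern) for c in lfq_cols]

    ids = df["Protein IDs"].str.split(";").str[0]
    if ids.duplicated().any():
        raise IngestError("duplicate protein group ids")
    parsed = {}
    for col, key in zip(lfq_cols, keys):
        try:
            # Python float() is correctly-rounded, so repr-written values
            # round-trip bit-exactly (pandas' fast parser does not guarantee this)
            vals = np.array([float(v) if v != "" else 0.0 for v in df[col]])
        except (ValueError, TypeError) as exc:
            raise IngestError(f"malformed numeric cell in column {col!r}: {exc}") from None
        parsed[key.label] = vals
    inten = pd.DataFrame(parsed, index=pd.Index(ids, name="protein_id"))

    samples = pd.DataFrame(
        {
            "condition": [k.condition for k in keys],
            "bio_rep": [k.bio_rep for k in keys],
            "tech_rep": [k.tech_rep for k in keys],
        },
        index=pd.Index([k.label for k in keys], name="sample"),
    )

    def flag(col: str) -> pd.Series:
        if col in df.columns:
            return (df[col].str.strip() == "+").to_numpy()
        return np.zeros(len(df), dtype=bool)

    meta = pd.DataFrame(
        {
            "accessions": df["Protein IDs"].to_numpy(),
            "gene": df.get("Gene names", pd.Series([""] * len(df))).to_numpy(),
            "mw_kda": np.array(
                [
                    float(v) if v not in ("", None) else float("nan")
                    for v in df.get("Mol. weight [kDa]", pd.Series([""] * len(df)))
                ]
            ),
            "is_decoy": flag("Reverse"),
            "is_contaminant": flag("Potential contaminant"),
        },
        index=inten.index,
    )
    table = LfqTable(intensities=inten, samples=samples, meta=meta)
    table.log.append({"op": "read_proteingroups", "path": str(path), "rows": len(inten)})
    return table


def write_proteingroups(table: LfqTable, path: str | Path) -> None:
    """Serialize an :class:`LfqTable` back to the proteinGroups TSV dialect.

    LFQ cells are written in shortest-round-trip float form (``repr``) so a
    write/read cycle reproduces intensities bit-exactly.
    """
    cols = {
        "Protein IDs": table.meta["accessions"].to_numpy(),
        "Gene names": table.meta["gene"].to_numpy(),
        "Mol. weight [kDa]": [repr(float(v)) for v in table.meta["mw_kda"]],
        "Reverse": np.where(table.meta["is_decoy"], "+", ""),
        "Potential contaminant": np.where(table.meta["is_contaminant"], "+", ""),
    }
    for col in table.intensities.columns:
        cols[LFQ_PREFIX + col] = [repr(float(v)) for v in table.intensities[col]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["tmd_count"] = df["tmd_count"].astype(int)
    df["mw_kda"] = np.array([float(v) for v in df["mw_kda"]])
    return AnnotationTable(df.set_index("accession"))


def write_annotations(ann: AnnotationTable, path: str | Path) -> None:
    out = ann.table.reset_index().copy()
    out["mw_kda"] = [repr(float(v)) for v in out["mw_kda"]]
    out.to_csv(path, sep="\t", index=False)


# -- filters -------------------------------------------------------------------


def filter_decoys_contaminants(table: LfqTable) -> LfqTable:
    """Drop rows flagged as decoy (reverse) or potential contaminant."""
    keep = ~(table.meta["is_decoy"] | table.meta["is_contaminant"])
    out = LfqTable(
        intensities=table.intensities.loc[keep].copy(),
        samples=table.samples.copy(),
        meta=table.meta.loc[keep].copy(),
        retention=None if table.retention is None else table.retention.loc[keep].copy(),
        review=table.review,
        log=list(table.log),
    )
    out.log.append(
        {
            "op": "filter_decoys_contaminants",
            "rows_in": len(table.intensities),
            "rows_out": int(keep.sum()),
            "decoys_removed": int(table.meta["is_decoy"].sum()),
            "contaminants_removed": int((table.meta["is_contaminant"] & ~table.meta["is_decoy"]).sum()),
        }
    )
    return out


def filter_bio_replicates(table: LfqTable, min_tech_detected: int = 1) -> LfqTable:
    """Apply the "detected in both biological replicates" rule per condition.

    A protein is *retained for a condition* only if, in every biological
    replicate of that condition, it is detected (LFQ > 0) in at least
    ``min_tech_detected`` technical replicates. A protein row survives
    globally if retained in at least one condition; the per-condition
    retention mask is stored on the returned table and drives downstream
    replicate averaging.
    """
    conditions = table.conditions
    for cond in conditions:
        for b in table.bio_reps(cond):
            if min_tech_detected > table.n_tech(cond, b):
                raise IngestError(
                    f"min_tech_detected={min_tech_detected} exceeds the "
                    f"{table.n_tech(cond, b)} technical replicates of {cond} bio{b}"
                )
    det = table.detected()
    retention = pd.DataFrame(True, index=table.intensities.index, columns=conditions)
    for cond in conditions:
        for b in table.bio_reps(cond):
            cols = table.sample_columns(cond, b)
            retention[cond] &= det[cols].sum(axis=1) >= min_tech_detected
    keep = retention.any(axis=1)
    out = LfqTable(
        intensities=table.intensities.loc[keep].copy(),
        samples=table.samples.copy(),
        meta=table.meta.loc[keep].copy(),
        retention=retention.loc[keep],
        review=table.review,
        log=list(table.log),
    )
    out.log.append(
        {
            "op": "filter_bio_replicates",
            "min_tech_detected": min_tech_detected,
            "rows_in": len(table.intensities),
            "rows_out": int(keep.sum()),
            "masked_cells": int((~retention.loc[keep]).sum().sum()),
        }
    )
    return out


def annotate_membrane(
    table: LfqTable,
    ann: AnnotationTable,
    overrides: pd.DataFrame | None = None,
) -> LfqTable:
    """Restrict the table to annotated membrane proteins and attach annotations.

    Matching is by accession first, gene name second; ambiguous gene matches
    and rows without any match are routed to the ``review`` list rather than
    silently dropped. Proteins whose membrane class is ``none`` (soluble) are
    excluded and likewise listed for review. An optional ``overrides`` frame
    (columns ``protein_id``, ``action`` in {include, exclude}) externalizes
    manual curation.
    """
    by_gene = {}
    for acc, row in ann.table.iterrows():
        by_gene.setdefault(row["gene"], []).append(acc)

    matched_acc: dict[str, str] = {}
    review_rows: list[dict] = []
    for pid in table.intensities.index:
        accs = [a for a in str(table.meta.at[pid, "accessions"]).split(";") if a]
        hit = next((a for a in accs if a in ann.table.index), None)
        if hit is None:
            gene = table.meta.at[pid, "gene"]
            cands = by_gene.get(gene, [])
            if len(cands) == 1:
                hit = cands[0]
            elif len(cands) > 1:
                review_rows.append(
                    {"protein_id": pid, "reason": "ambiguous gene match", "candidates": ";".join(cands)}
                )
                continue
            else:
                review_rows.append({"protein_id": pid, "reason": "unannotated", "candidates": ""})
                continue
        if ann.table.at[hit, "membrane_class"] == "none":
            review_rows.append({"protein_id": pid, "reason": "non-membrane", "candidates": hit})
            continue
        matched_acc[pid] = hit

    include, exclude = set(), set()
    if overrides is not None:
        for _, r in overrides.iterrows():
            (include if r["action"] == "include" else exclude).add(r["protein_id"])
    keep_ids = [
        pid
        for pid in table.intensities.index
        if (pid in matched_acc or pid in include) and pid not in exclude
    ]

    meta = table.meta.loc[keep_ids].copy()
    for col, default in (
        ("organelles", ""),
        ("membrane_class", "none"),
        ("tmd_count", 0),
    ):
        meta[col] = default
    for pid in keep_ids:
        hit = matched_acc.get(pid)
        if hit is None:
            continue  # force-included without annotation
        meta.at[pid, "organelles"] = ann.table.at[hit, "organelles"]
        meta.at[pid, "membrane_class"] = ann.table.at[hit, "membrane_class"]
        meta.at[pid, "tmd_count"] = int(ann.table.at[hit, "tmd_count"])
        meta.at[pid, "mw_kda"] = float(ann.table.at[hit, "mw_kda"])

    review = pd.DataFrame(review_rows, columns=["protein_id", "reason", "candidates"])
    out = LfqTable(
        intensities=table.intensities.loc[keep_ids].copy(),
        samples=table.samples.copy(),
        meta=meta,
        retention=None if table.retention is None else table.retention.loc[keep_ids].copy(),
        review=review,
        log=list(table.log),
    )
    out.log.append(
        {
            "op": "annotate_membrane",
            "rows_in": len(table.intensities),
            "rows_out": len(keep_ids),
            "review": len(review),
        }
    )
    return out
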