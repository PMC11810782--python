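"""Secondary analyses over the solubilization database.

* solubilization index: the mean of a protein set's scaled extraction values
  in a condition, (sum_i x_i) / n — a single number ranking conditions for a
  multiprotein complex;
* replicate reproducibility: squared Pearson correlation between biological
  replicates' log10 mean intensities;
* stratification of best-solubilized proteins by molecular weight or
  transmembrane-helix count;
* agglomerative clustering of conditions on their extraction profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .conditions import DETERGENT_CLASS
from .ingest import LfqTable
from .profiledb import SolubilizationDatabase

__all__ = [
    "MissingGeneError",
    "MetricsError",
    "ReplicateR2",
    "ConditionDendrogram",
    "StratificationResult",
    "solubilization_index",
    "index_profile",
    "replicate_r2",
    "reproducibility_report",
    "stratify",
    "cluster_conditions",
    "MW_BINS",
    "TMD_BINS",
]

# left-closed, right-open bin edges; labels mirror the screen's figures
MW_BINS = ((0.0, 40.0, "<40"), (40.0, math.inf, ">=40"))
TMD_BINS = ((0, 1, "0"), (1, 6, "1-5"), (6, math.inf, ">5"))


class MetricsError(ValueError):
    pass


class MissingGeneError(MetricsError):
    """Raised when a complex query names genes absent from the database."""

    def __init__(self, genes: Sequence[str], condition: str | None = None):
        self.genes = list(genes)
        self.condition = condition
        where = f" in condition {condition}" if condition else ""
        super().__init__(f"genes not available{where}: {', '.join(self.genes)}")


def _query_values(
    db: SolubilizationDatabase, genes: Sequence[str], condition: str, missing: str
) -> np.ndarray:
    if not genes:
        raise MetricsError("empty complex query")
    if missing not in ("error", "zero"):
        raise MetricsError(f"unknown missing-gene policy {missing!r}")
    absent = [g for g in genes if g not in db.profiles.index]
    vals, undetected = [], []
    for g in genes:
        if g in absent:
            continue
        v = db.profiles.at[g, condition]
        if np.isnan(v):
            undetected.append(g)
        else:
            vals.append(float(v))
    problems = absent + undetected
    if problems and missing == "error":
        raise MissingGeneError(problems, condition)
    vals.extend(0.0 for _ in problems)
    return np.asarray(vals)


def solubilization_index(
    db: SolubilizationDatabase,
    genes: Sequence[str],
    condition: str,
    missing: str = "error",
) -> float:
    """Mean scaled extraction value of a protein set in one condition.

    ``missing='error'`` (default) raises :class:`MissingGeneError` listing
    every unresolvable gene; ``missing='zero'`` scores absent/undetected
    members as 0, a conservative lower bound on the complex's extractability.
    """
    if condition not in db.profiles.columns:
        raise MetricsError(f"unknown condition {condition!r}")
    vals = _query_values(db, genes, condition, missing)
    return float(vals.mean())


def index_profile(
    db: SolubilizationDatabase, genes: Sequence[str], missing: str = "error"
) -> pd.DataFrame:
    """Solubilization index per condition, ranked best-first.

    Columns: ``index``, ``rank`` (descending index, lexicographic
    tie-break), ``class`` and ``class_best`` (True on the top condition of
    each chemistry class).
    """
    rows = []
    for cond in db.conditions:
        rows.append((cond, solubilization_index(db, genes, cond, missing)))
    out = pd.DataFrame(rows, columns=["condition", "index"]).set_index("condition")
    out["class"] = [db.condition_classes.get(c, "unknown") for c in out.index]
    order = sorted(out.index, key=lambda c: (-out.at[c, "index"], c))
    out["rank"] = [order.index(c) + 1 for c in out.index]
    out["class_best"] = False
    for k in out["class"].unique():
        members = out.index[out["class"] == k]
        top = min(members, key=lambda c: (-out.at[c, "index"], c))
        out.at[top, "class_best"] = True
    return out.loc[order]


@dataclass(frozen=True)
class ReplicateR2:
    """Reproducibility of one condition across its two biological replicates."""

    condition: str
    r2: float
    n_proteins: int
    transform: str = "log10"


def replicate_r2(table: LfqTable, condition: str, transform: str = "log10") -> ReplicateR2:
    """Squared Pearson correlation between biological-replicate mean intensities.

    Each biological replicate's value per protein is the mean over its
    positive technical replicates; proteins positive in both biological
    replicates enter the correlation after log10 transform (LFQ spans
    decades, so correlation on the linear scale would be dominated by a few
    abundant proteins). Requires exactly two biological replicates.
    """
    bios = table.bio_reps(condition)
    if len(bios) != 2:
        raise MetricsError(f"{condition}: expected 2 biological replicates, found {len(bios)}")
    vecs = []
    for b in bios:
        block = table.intensities[table.sample_columns(condition, b)].to_numpy()
        pos = block > 0
        npos = pos.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vecs.append(np.where(npos > 0, block.sum(axis=1) / np.maximum(npos, 1), np.nan))
    x, y = vecs
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < 3:
        raise MetricsError(f"{condition}: fewer than 3 proteins detected in both replicates")
    x, y = x[both], y[both]
    if transform == "log10":
        x, y = np.log10(x), np.log10(y)
    elif transform != "linear":
        raise MetricsError(f"unknown transform {transform!r}")
    r = np.corrcoef(x, y)[0, 1]
    return ReplicateR2(condition=condition, r2=float(r * r), n_proteins=int(both.sum()), transform=transform)


def reproducibility_report(table: LfqTable, transform: str = "log10") -> pd.DataFrame:
    entries = [replicate_r2(table, c, transform) for c in table.conditions]
    return pd.DataFrame(
        {
            "condition": [e.condition for e in entries],
            "r2": [e.r2 for e in entries],
            "n_proteins": [e.n_proteins for e in entries],
            "transform": transform,
        }
    ).set_index("condition")


@dataclass
class StratificationResult:
    """Best-solubilized protein counts per bin x condition, with fractions."""

    by: str
    counts: pd.DataFrame  # bins x conditions
    frac_within_condition: pd.DataFrame
    frac_within_bin: pd.DataFrame


def stratify(
    db: SolubilizationDatabase,
    by: str = "mw",
    bins: Sequence[tuple] | None = None,
) -> StratificationResult:
    """Bin best-solubilized proteins by molecular weight or TMD count.

    Bins are left-closed/right-open triples (low, high, label); defaults are
    MW {<40, >=40 kDa} and TMD {0, 1-5, >5}. Both within-condition and
    within-bin fractions are emitted, since either normalization is a
    legitimate reading of a population-distribution plot.
    """
    if db.meta is None:
        raise MetricsError("database has no annotation metadata to stratify on")
    if by == "mw":
        column, spec = "mw_kda", MW_BINS
    elif by == "tmd":
        column, spec = "tmd_count", TMD_BINS
    else:
        raise MetricsError(f"unknown stratification key {by!r} (use 'mw' or 'tmd')")
    if bins is not None:
        spec = tuple(bins)
    for lo, hi, _ in spec:
        if hi <= lo:
            raise MetricsError(f"invalid bin ({lo}, {hi})")
    if column not in db.meta.columns:
        raise MetricsError(f"annotation column {column!r} missing")

    labels = [b[2] for b in spec]
    counts = pd.DataFrame(0, index=pd.Index(labels, name=by), columns=db.conditions)
    for gene in db.genes:
        v = db.meta.at[gene, column]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        cond = db.best_condition.at[gene]
        for lo, hi, lab in spec:
            if lo <= v < hi:
                counts.at[lab, cond] += 1
                break
    cond_tot = counts.sum(axis=0).replace(0, np.nan)
    bin_tot = counts.sum(axis=1).replace(0, np.nan)
    return StratificationResult(
        by=by,
        counts=counts,
        frac_within_condition=counts / cond_tot,
        frac_within_bin=counts.div(bin_tot, axis=0),
    )


@dataclass
class ConditionDendrogram:
    """Agglomerative clustering of conditions on their extraction profiles."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    metric: str
    method: str
    distances: pd.DataFrame  # pairwise condition distances

    def cophenetic(self) -> pd.DataFrame:
        coph = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def merge_order(self) -> list[tuple[frozenset, float]]:
        """Clusters in merge order as (member set, merge distance)."""
        n = len(self.labels)
        members: dict[int, frozenset] = {i: frozenset([self.labels[i]]) for i in range(n)}
        out = []
        for i, (a, b, d, _) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            out.append((merged, float(d)))
        return out

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _pairwise_correlation_distance(mat: np.ndarray) -> np.ndarray:
    """Correlation distance with pairwise-complete observations.

    Not-detected cells (NaN) are excluded pairwise rather than imputed, so
    shared absence cannot manufacture similarity. Pairs with < 3 shared
    proteins get the maximal distance 2.
    """
    n = mat.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(mat[:, i]) & ~np.isnan(mat[:, j])
            if both.sum() < 3:
                d = 2.0
            else:
                x, y = mat[both, i], mat[both, j]
                sx, sy = x.std(), y.std()
                if sx == 0 or sy == 0:
                    d = 0.0 if np.allclose(x, y) else 2.0
                else:
                    d = 1.0 - float(np.corrcoef(x, y)[0, 1])
            D[i, j] = D[j, i] = max(d, 0.0)
    return D


def cluster_conditions(
    db: SolubilizationDatabase, metric: str = "correlation", method: str = "average"
) -> ConditionDendrogram:
    """Hierarchically cluster conditions by their per-protein profiles.

    Conditions are observations, proteins features. Defaults: correlation
    distance with pairwise-complete handling of not-detected cells, average
    linkage. Conditions are ordered lexicographically before clustering so
    the result is invariant to input column order.
    """
    labels = sorted(db.conditions)
    if len(labels) < 2:
        raise MetricsError("need at least 2 conditions to cluster")
    mat = db.profiles[labels].to_numpy(float)
    if mat.shape[0] < 2:
        raise MetricsError("need at least 2 proteins as clustering features")
    finite = mat[~np.isnan(mat)]
    if finite.size and np.allclose(finite, finite.flat[0]):
        raise MetricsError("all-constant profile matrix cannot be clustered")
    if metric == "correlation":
        D = _pairwise_correlation_distance(mat)
    elif metric == "euclidean":
        filled = np.nan_to_num(mat, nan=0.0)
        diff = filled[:, :, None] - filled[:, None, :]
        D = np.sqrt((diff**2).sum(axis=0))
    else:
        raise MetricsError(f"unknown metric {metric!r}")
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    return ConditionDendrogram(
        linkage=Z,
        labels=labels,
        metric=metric,
        method=method,
        distances=pd.DataFrame(D, index=labels, columns=labels),
    )
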