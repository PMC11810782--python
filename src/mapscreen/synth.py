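"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of a polymer extraction
screen — an LFQ protein-group table over 11 polymer + 2 detergent conditions
with 2 biological x 4 technical replicates, UniProt-style membrane/organelle
annotations, dithionite quench plate readings, and single-particle
photobleaching traces — so the whole pipeline is testable without external
mass-spectrometry or imaging data.

Noise structure of the LFQ simulator:

* biological noise is one log-normal factor per (protein, condition,
  biological replicate), shared by all technical replicates of that
  preparation (nested design), so replicate-to-replicate R^2 is governed by
  the biological CV independently of the technical CV;
* technical noise is an independent log-normal factor per measurement;
* missingness is left-censoring at a detection threshold
  (missing-not-at-random), mimicking low-abundance dropout.

All log-normal factors have mean 1, so expectations stay on the true scale.
Every generator takes one explicit seed and is bit-reproducible; there is no
global random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import CONDITION_CLASSES, DEFAULT_CONDITIONS
from .ingest import (
    AnnotationTable,
    LfqTable,
    ORGANELLE_VOCAB,
    write_annotations,
    write_proteingroups,
)
from .photobleach import BleachTrace, OligomerDistribution
from .quench import QuenchMeasurement

__all__ = [
    "SyntheticGroundTruth",
    "NoiseModel",
    "simulate_ground_truth",
    "simulate_lfq_table",
    "simulate_annotations",
    "simulate_quench",
    "simulate_traces",
    "detection_threshold_for_censoring",
    "write_fixture_set",
]


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors with E[x] = 1 and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True extraction behavior of one simulated protein."""

    protein_id: str
    gene: str
    true_efficiency: Mapping[str, float]  # condition -> fraction in [0, 1]
    base_abundance: float  # LFQ units at efficiency 1
    mw_kda: float
    tmd_count: int
    organelles: frozenset
    is_membrane: bool
    is_contaminant: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        for cond, e in self.true_efficiency.items():
            if not (0.0 <= e <= 1.0):
                raise ValueError(f"{self.protein_id}: efficiency {e} for {cond} not in [0,1]")
        if self.base_abundance <= 0:
            raise ValueError(f"{self.protein_id}: base_abundance must be positive")

    @property
    def best_condition(self) -> str:
        # deterministic: lexicographically first argmax
        best = max(self.true_efficiency.values())
        return min(c for c, e in self.true_efficiency.items() if e == best)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise and censoring parameters for the LFQ simulator.

    ``cv_technical``/``cv_biological`` are coefficients of variation of the
    multiplicative log-normal factors; ``detection_threshold`` left-censors
    intensities to 0. Observed CVs for LFQ screens are not published for this
    design, so the defaults (0.1 technical, 0.2 biological) are conventional
    placeholders, exposed here rather than hard-coded downstream.
    """

    cv_technical: float = 0.1
    cv_biological: float = 0.2
    detection_threshold: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_technical < 0 or self.cv_biological < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.detection_threshold < 0:
            raise ValueError("detection threshold must be >= 0")


def simulate_ground_truth(
    n_proteins: int,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    seed: int = 0,
    frac_membrane: float = 0.85,
    frac_decoy: float = 0.05,
    frac_contaminant: float = 0.03,
) -> list[SyntheticGroundTruth]:
    """Draw a ground-truth protein set with one clearly best condition each.

    Effect-size model: each protein is assigned a single preferred condition;
    its efficiency there is U(0.4, 0.95) and every other condition is an
    independent U(0.1, 0.7) fraction *of the best* — i.e. non-best conditions
    extract 10-70% as much, the spread seen between polymers in real profiles.
    Base abundance is log-uniform over ~3 decades (10^N(6.5, 0.9)), molecular
    weight log-normal around ~55 kDa, and transmembrane-helix counts 1-14 for
    integral proteins. Decoy and contaminant rows are flagged extra rows, so
    the decoy/contaminant filter is exercised on every fixture.
    """
    if n_proteins < 1:
        raise ValueError("need at least one protein")
    conditions = list(conditions)
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be unique")
    rng = np.random.default_rng(seed)
    out: list[SyntheticGroundTruth] = []
    for i in range(n_proteins):
        pid = f"SYN{i:04d}"
        gene = f"GENE{i:04d}"
        is_decoy = rng.random() < frac_decoy
        is_cont = (not is_decoy) and rng.random() < frac_contaminant
        is_membrane = (not is_decoy) and (not is_cont) and rng.random() < frac_membrane
        best_idx = int(rng.integers(len(conditions)))
        best_eff = float(rng.uniform(0.4, 0.95))
        rel = rng.uniform(0.1, 0.7, size=len(conditions))
        eff = {c: float(best_eff * r) for c, r in zip(conditions, rel)}
        eff[conditions[best_idx]] = best_eff
        mw = float(np.exp(rng.normal(np.log(55.0), 0.5)))
        if is_membrane and rng.random() < 0.8:
            tmd = int(rng.integers(1, 15))
            membrane = True
        elif is_membrane:
            tmd = 0  # peripheral / monotopic
            membrane = True
        else:
            tmd = 0
            membrane = False
        n_org = 2 if rng.random() < 0.2 else 1
        organelles = frozenset(rng.choice(ORGANELLE_VOCAB, size=n_org, replace=False))
        out.append(
            SyntheticGroundTruth(
                protein_id=pid,
                gene=gene,
                true_efficiency=eff,
                base_abundance=float(10 ** rng.normal(6.5, 0.9)),
                mw_kda=mw,
                tmd_count=tmd,
                organelles=organelles if membrane else frozenset(),
                is_membrane=membrane,
                is_contaminant=is_cont,
                is_decoy=is_decoy,
            )
        )
    return out


def detection_threshold_for_censoring(
    truth: Sequence[SyntheticGroundTruth],
    conditions: Sequence[str],
    censored_fraction: float,
) -> float:
    """Threshold whose left-censoring hits ~the requested fraction of values.

    Computed as the quantile of the *noise-free* intensity surface
    (abundance x efficiency over protein x condition), so it depends only on
    the ground truth, not on any noisy realization.
    """
    if not (0.0 <= censored_fraction < 1.0):
        raise ValueError("censored_fraction must be in [0, 1)")
    if censored_fraction == 0.0:
        return 0.0
    vals = np.array(
        [t.base_abundance * t.true_efficiency[c] for t in truth for c in conditions]
    )
    return float(np.quantile(vals, censored_fraction))


def simulate_lfq_table(
    truth: Sequence[SyntheticGroundTruth],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_bio: int = 2,
    n_tech: int = 4,
    noise: NoiseModel = NoiseModel(),
) -> LfqTable:
    """Simulate a proteinGroups-style LFQ table from ground truth.

    Measured intensity = base_abundance x true_efficiency x biological factor
    (shared within a biological replicate) x technical factor, with values
    below the detection threshold recorded as 0. Deterministic given
    ``noise.seed``.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty ground-truth set")
    ids = [t.protein_id for t in truth]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in ground truth")
    conditions = list(conditions)
    if len(set(conditions)) != len(conditions):
        raise ValueError("condition labels must be unique")
    if n_bio < 1 or n_tech < 1:
        raise ValueError("need at least one biological and one technical replicate")

    rng = np.random.default_rng(noise.seed)
    P, C = len(truth), len(conditions)
    eff = np.array([[t.true_efficiency[c] for c in conditions] for t in truth])
    base = np.array([t.base_abundance for t in truth])
    bio = _mean_one_lognormal(rng, noise.cv_biological, (P, C, n_bio))
    tech = _mean_one_lognormal(rng, noise.cv_technical, (P, C, n_bio, n_tech))
    meas = base[:, None, None, None] * eff[:, :, None, None] * bio[..., None] * tech
    meas[meas < noise.detection_threshold] = 0.0

    columns, data = [], {}
    for ci, cond in enumerate(conditions):
        for b in range(n_bio):
            for tr in range(n_tech):
                label = f"{cond}_bio{b + 1}_tech{tr + 1}"
                columns.append((label, cond, b + 1, tr + 1))
                data[label] = meas[:, ci, b, tr]
    inten = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))
    samples = pd.DataFrame(
        {
            "condition": [c[1] for c in columns],
            "bio_rep": [c[2] for c in columns],
            "tech_rep": [c[3] for c in columns],
        },
        index=pd.Index([c[0] for c in columns], name="sample"),
    )
    meta = pd.DataFrame(
        {
            "accessions": ids,
            "gene": [t.gene for t in truth],
            "mw_kda": [t.mw_kda for t in truth],
            "is_decoy": [t.is_decoy for t in truth],
            "is_contaminant": [t.is_contaminant for t in truth],
        },
        index=inten.index,
    )
    table = LfqTable(intensities=inten, samples=samples, meta=meta)
    table.log.append(
        {
            "op": "simulate_lfq_table",
            "n_proteins": P,
            "n_conditions": C,
            "n_bio": n_bio,
            "n_tech": n_tech,
            "seed": noise.seed,
        }
    )
    return table


def simulate_annotations(truth: Sequence[SyntheticGroundTruth]) -> AnnotationTable:
    """Build the UniProt-style annotation table matching a ground-truth set."""
    rows = []
    for t in truth:
        if t.is_membrane:
            membrane_class = "integral" if t.tmd_count > 0 else "peripheral"
        else:
            membrane_class = "none"
        rows.append(
            {
                "accession": t.protein_id,
                "gene": t.gene,
                "organelles": ";".join(sorted(t.organelles)),
                "membrane_class": membrane_class,
                "tmd_count": t.tmd_count,
                "mw_kda": t.mw_kda,
            }
        )
    return AnnotationTable(pd.DataFrame(rows).set_index("accession"))


def simulate_quench(
    fl_total: float,
    disc_fraction: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    sample_id: str = "well",
    replicate: int = 1,
    condition: str = "",
) -> QuenchMeasurement:
    """Simulate one pre/post-dithionite reading pair.

    Leaflet model: discs are fully quenched, sealed vesicles lose only their
    outer leaflet, so fl2 = fl_total x (1 - disc_fraction) / 2. Noise has two
    parts at CV ``noise_cv``: a per-well scale factor (sample amount and
    labeling) multiplying *both* readings — the component the ratio assay is
    built to cancel — and a quench-step variability factor on fl2 alone,
    which is the noise that actually propagates into the readout.
    """
    if fl_total <= 0:
        raise ValueError("fl_total must be positive")
    if not (0.0 <= disc_fraction <= 1.0):
        raise ValueError("disc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    well = float(_mean_one_lognormal(rng, noise_cv, ()))
    quench = float(_mean_one_lognormal(rng, noise_cv, ()))
    fl1 = fl_total * well
    fl2 = fl_total * (1.0 - disc_fraction) / 2.0 * well * quench
    return QuenchMeasurement(
        sample_id=sample_id, fl1=fl1, fl2=fl2, replicate=replicate, condition=condition
    )


def simulate_traces(
    dist: OligomerDistribution | Sequence[float],
    p_mat: float,
    n_particles: int,
    step_height: float = 5.0,
    noise_sd: float = 1.0,
    frames: int = 200,
    seed: int = 0,
) -> list[BleachTrace]:
    """Simulate photobleaching traces from a copy-number distribution.

    Each particle draws a true copy number m from ``dist`` and a fluorescent
    count k ~ Binomial(m, p_mat) conditioned on k >= 1 — dark particles are
    dropped at generation time because an imaging surface only captures
    fluorescent discs. The trace is a decreasing staircase of k steps of
    ``step_height`` with bleach times uniform over distinct frames, plus
    Gaussian noise. The drawn k is stored as ``truth_steps``.
    """
    probs = dist.probs if isinstance(dist, OligomerDistribution) else np.asarray(dist, float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("distribution must be a probability vector over 1..K")
    if not (0.0 < p_mat <= 1.0):
        raise ValueError("p_mat must be in (0, 1]")
    if n_particles < 1:
        raise ValueError("need at least one particle")
    if frames < 10:
        raise ValueError("need at least 10 frames")

    from scipy import stats  # local import keeps module load light

    K = len(probs)
    # joint weights over (m, k>=1); sampling from this IS the conditioning
    pairs, weights = [], []
    for m in range(1, K + 1):
        if probs[m - 1] <= 0:
            continue
        for k in range(1, m + 1):
            pairs.append((m, k))
            weights.append(probs[m - 1] * stats.binom.pmf(k, m, p_mat))
    weights = np.asarray(weights)
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_particles, p=weights)
    traces = []
    for i, j in enumerate(idx):
        _, k = pairs[j]
        times = np.sort(rng.choice(np.arange(1, frames), size=k, replace=False))
        y = np.full(frames, k * step_height)
        for s, t in enumerate(times):
            y[t:] = (k - s - 1) * step_height
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, frames)
        traces.append(BleachTrace(particle_id=f"p{i:05d}", intensity=y, truth_steps=int(k)))
    return traces


# -- fixture bundle ------------------------------------------------------------


def write_fixture_set(
    outdir: str | Path,
    n_proteins: int = 200,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    n_bio: int = 2,
    n_tech: int = 4,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> dict:
    """Write a complete synthetic input set plus a JSON ground-truth manifest.

    Produces ``proteingroups.tsv``, ``annotations.tsv``, ``quench_plate.csv``,
    ``traces.csv`` and ``manifest.json`` under ``outdir``; returns the
    manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_ground_truth(n_proteins, conditions, seed=seed)
    table = simulate_lfq_table(truth, conditions, n_bio, n_tech, noise)
    write_proteingroups(table, outdir / "proteingroups.tsv")
    write_annotations(simulate_annotations(truth), outdir / "annotations.tsv")

    rng = np.random.default_rng(seed + 1)
    plate_rows = []
    for cond in conditions:
        d = float(rng.uniform(0.2, 0.95))
        for rep in range(1, 4):
            m = simulate_quench(
                1000.0, d, noise_cv=0.05, seed=int(rng.integers(2**31)),
                sample_id=f"{cond}_r{rep}", replicate=rep, condition=cond,
            )
            plate_rows.append((m.sample_id, m.condition, m.replicate, m.fl1, m.fl2))
    pd.DataFrame(
        plate_rows, columns=["sample_id", "condition", "replicate", "fl1", "fl2"]
    ).to_csv(outdir / "quench_plate.csv", index=False)

    dist = OligomerDistribution(probs=np.array([0.4, 0.3, 0.2, 0.1]), p_mat=0.8)
    traces = simulate_traces(dist, p_mat=0.8, n_particles=300, seed=seed + 2)
    from .photobleach import write_traces_csv

    write_traces_csv(traces, outdir / "traces.csv")

    manifest = {
        "seed": seed,
        "n_proteins": n_proteins,
        "conditions": list(conditions),
        "condition_classes": {c: CONDITION_CLASSES.get(c, "unknown") for c in conditions},
        "n_bio": n_bio,
        "n_tech": n_tech,
        "noise": {
            "cv_technical": noise.cv_technical,
            "cv_biological": noise.cv_biological,
            "detection_threshold": noise.detection_threshold,
            "seed": noise.seed,
        },
        "oligomer_truth": {"probs": [0.4, 0.3, 0.2, 0.1], "p_mat": 0.8},
        "proteins": {
            t.protein_id: {
                "gene": t.gene,
                "true_efficiency": dict(t.true_efficiency),
                "base_abundance": t.base_abundance,
                "mw_kda": t.mw_kda,
                "tmd_count": t.tmd_count,
                "organelles": sorted(t.organelles),
                "is_membrane": t.is_membrane,
                "is_contaminant": t.is_contaminant,
                "is_decoy": t.is_decoy,
            }
            for t in truth
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
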