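import numpy as np
import pandas as pd
import pytest

from mapscreen import ingest, profiledb, synth


@pytest.fixture(scope="session")
def truth_small():
    return synth.simulate_ground_truth(60, seed=11)


@pytest.fixture(scope="session")
def zero_noise_table(truth_small):
    noise = synth.NoiseModel(cv_technical=0.0, cv_biological=0.0, detection_threshold=0.0, seed=5)
    return synth.simulate_lfq_table(truth_small, noise=noise)


@pytest.fixture(scope="session")
def zero_noise_db(truth_small, zero_noise_table):
    table = ingest.filter_decoys_contaminants(zero_noise_table)
    table = ingest.filter_bio_replicates(table)
    ann = synth.simulate_annotations(truth_small)
    table = ingest.annotate_membrane(table, ann)
    means = profiledb.average_replicates(table)
    return profiledb.build_profiles(means, meta=table.meta)


def build_lfq_table(values, conditions, n_bio, n_tech, meta=None):
    """Construct an LfqTable from a dict protein -> flat replicate values.

    Replicate order is condition-major, then bio, then tech.
    """
    labels, cond_l, bio_l, tech_l = [], [], [], []
    for c in conditions:
        for b in range(1, n_bio + 1):
            for t in range(1, n_tech + 1):
                labels.append(f"{c}_bio{b}_tech{t}")
                cond_l.append(c)
                bio_l.append(b)
                tech_l.append(t)
    inten = pd.DataFrame(
        {lab: [values[p][i] for p in values] for i, lab in enumerate(labels)},
        index=pd.Index(list(values), name="protein_id"),
    )
    samples = pd.DataFrame(
        {"condition": cond_l, "bio_rep": bio_l, "tech_rep": tech_l},
        index=pd.Index(labels, name="sample"),
    )
    if meta is None:
        meta = pd.DataFrame(
            {
                "accessions": list(values),
                "gene": list(values),
                "mw_kda": np.full(len(values), 50.0),
                "is_decoy": False,
                "is_contaminant": False,
            },
            index=inten.index,
        )
    return ingest.LfqTable(intensities=inten, samples=samples, meta=meta)


def make_database(profiles: pd.DataFrame, meta: pd.DataFrame | None = None,
                  condition_classes=None):
    """Build a SolubilizationDatabase straight from a relative-percent matrix."""
    vals = profiles.to_numpy(float)
    best, tie = [], []
    for i in range(len(profiles)):
        row = vals[i]
        mx = np.nanmax(row)
        winners = sorted(profiles.columns[np.isclose(row, mx) & ~np.isnan(row)])
        best.append(winners[0])
        tie.append(len(winners) > 1)
    return profiledb.SolubilizationDatabase(
        profiles=profiles,
        mean_lfq=profiles * 1e4,
        best_condition=pd.Series(best, index=profiles.index),
        tie=pd.Series(tie, index=profiles.index),
        condition_classes=condition_classes
        or {c: "polymer" for c in profiles.columns},
        meta=meta,
    )
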