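"""Database construction: averaging, max-normalization, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_lfq_table, make_database
from mapscreen import ingest, profiledb, synth
from mapscreen.profiledb import (
    ProfileError,
    average_replicates,
    best_condition_counts,
    build_profiles,
    detection_overlap,
    load_database,
    organelle_coverage,
    save_database,
)


def test_average_replicates_constant_and_bio_means():
    table = build_lfq_table(
        {
            "const": [2e6] * 8,
            "split": [1e6] * 4 + [3e6] * 4,  # bio means 1e6 and 3e6
        },
        conditions=["A"],
        n_bio=2,
        n_tech=4,
    )
    filtered = ingest.filter_bio_replicates(table)
    means = average_replicates(filtered)
    assert means.at["const", "A"] == pytest.approx(2e6)
    assert means.at["split", "A"] == pytest.approx(2e6)


def test_average_excludes_censored_zeros_and_masks_conditions():
    table = build_lfq_table(
        {"p": [2e6, 2e6, 2e6, 0.0] + [2e6] * 4 + [0.0] * 8},
        conditions=["A", "B"],
        n_bio=2,
        n_tech=4,
    )
    filtered = ingest.filter_bio_replicates(table)
    means = average_replicates(filtered)
    assert means.at["p", "A"] == pytest.approx(2e6)  # the zero is censoring, not signal
    assert np.isnan(means.at["p", "B"])  # masked condition propagates as not-detected


def test_build_profiles_hand_normalization():
    means = pd.DataFrame(
        {"A": [2e6], "B": [1e6], "C": [5e5]}, index=pd.Index(["g"], name="protein")
    )
    db = build_profiles(means)
    assert db.profiles.loc["g"].tolist() == pytest.approx([100.0, 50.0, 25.0])
    assert db.best_condition.at["g"] == "A"
    assert not db.tie.at["g"]


def test_build_profiles_ties_and_single_condition():
    means = pd.DataFrame(
        {"A": [1e6, np.nan], "B": [1e6, 2e6]}, index=pd.Index(["t", "s"], name="p")
    )
    db = build_profiles(means)
    assert db.tie.at["t"] and db.best_condition.at["t"] == "A"  # lexicographic
    assert db.profiles.at["t", "B"] == 100.0
    assert db.best_condition.at["s"] == "B" and db.profiles.at["s", "B"] == 100.0
    with pytest.raises(ProfileError):
        build_profiles(pd.DataFrame({"A": [np.nan]}, index=["empty"]))


@settings(derandomize=True, max_examples=30)
@given(scale=st.floats(1e-3, 1e3))
def test_profile_scale_invariance(scale):
    means = pd.DataFrame({"A": [4e6], "B": [1e6]}, index=["g"])
    a = build_profiles(means).profiles
    b = build_profiles(means * scale).profiles
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_normalization_is_a_fixed_point():
    means = pd.DataFrame({"A": [8e5, 3e6], "B": [2e5, 6e6]}, index=["g1", "g2"])
    once = build_profiles(means).profiles
    twice = build_profiles(once).profiles  # rescaled percentages re-normalize to themselves
    assert np.allclose(once.to_numpy(), twice.to_numpy())


def test_best_condition_counts_sum_and_empty():
    profiles = pd.DataFrame(
        {"A": [100.0, 100.0, 100.0, 50.0], "B": [20.0, 30.0, np.nan, 100.0]},
        index=pd.Index(list("wxyz"), name="gene"),
    )
    db = make_database(profiles)
    counts = best_condition_counts(db)
    assert counts == {"A": 3, "B": 1}
    assert sum(counts.values()) == len(db.genes)


def test_zero_noise_profiles_recover_ground_truth(truth_small, zero_noise_db):
    by_gene = {t.gene: t for t in truth_small}
    for gene in zero_noise_db.genes:
        t = by_gene[gene]
        best = max(t.true_efficiency.values())
        for cond in zero_noise_db.conditions:
            expected = 100.0 * t.true_efficiency[cond] / best
            got = zero_noise_db.profiles.at[gene, cond]
            if expected == 0.0:
                assert np.isnan(got)  # zero efficiency is censored at source
            else:
                assert got == pytest.approx(expected, abs=1e-9)
        assert zero_noise_db.best_condition.at[gene] == t.best_condition


def test_detection_overlap_matches_hand_enumerated_venn():
    # 10 proteins with constructed detection sets over 2 polymers + 1 detergent
    cols = ["P1", "P2", "DET"]
    rows = {
        "a": [100, 50, 20],   # everywhere
        "b": [100, 50, 20],   # everywhere
        "c": [100, np.nan, np.nan],  # polymer-only
        "d": [np.nan, 100, np.nan],  # polymer-only
        "e": [100, 100, np.nan],     # polymer-only (tie)
        "f": [np.nan, np.nan, 100],  # detergent-only
        "g": [100, np.nan, 50],
        "h": [np.nan, 100, 50],
        "i": [100, 50, 20],   # everywhere
        "j": [50, 100, 20],   # everywhere
    }
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    db = make_database(
        profiles, condition_classes={"P1": "SMA", "P2": "AASTY", "DET": "detergent"}
    )
    report = detection_overlap(db)
    assert report["n_proteins"] == 10
    assert report["all_conditions"] == 4  # a, b, i, j
    assert report["map_only"] == 3  # c, d, e
    assert report["detergent_only"] == 1  # f
    assert report["per_class"] == {"SMA": 7, "AASTY": 7, "detergent": 7}
    assert report["exclusive_per_class"] == {"SMA": 1, "AASTY": 1, "detergent": 1}


def test_detection_overlap_requires_classes():
    db = make_database(pd.DataFrame({"A": [100.0]}, index=["g"]))
    with pytest.raises(ProfileError):
        detection_overlap(db, class_map={})


def test_organelle_coverage_counts_multi_residents_once_per_organelle():
    profiles = pd.DataFrame({"A": [100.0, 100.0, 100.0]}, index=["g1", "g2", "g3"])
    meta = pd.DataFrame(
        {"organelles": ["ER;Golgi", "PM", ""]}, index=profiles.index
    )
    counts = organelle_coverage(make_database(profiles, meta=meta))
    assert counts == {"ER": 1, "Golgi": 1, "PM": 1, "unassigned": 1}


def test_synthetic_organelle_coverage_matches_manifest(truth_small, zero_noise_db):
    by_gene = {t.gene: t for t in truth_small}
    expected: dict[str, int] = {}
    for gene in zero_noise_db.genes:
        for org in by_gene[gene].organelles:
            expected[org] = expected.get(org, 0) + 1
    got = organelle_coverage(zero_noise_db)
    got.pop("unassigned", None)
    assert got == expected


def test_database_save_load_round_trip(zero_noise_db, tmp_path):
    path = tmp_path / "db.tsv"
    save_database(zero_noise_db, path)
    back = load_database(path)
    assert back.profiles.equals(zero_noise_db.profiles)
    assert back.mean_lfq.equals(zero_noise_db.mean_lfq)
    assert back.best_condition.equals(zero_noise_db.best_condition)
    assert back.tie.equals(zero_noise_db.tie)
    assert back.condition_classes == zero_noise_db.condition_classes


def test_log_scale_averaging_is_the_geometric_mean():
    table = build_lfq_table(
        {"p": [1e4, 1e6, 1e4, 1e6]}, conditions=["A"], n_bio=2, n_tech=2
    )
    means = average_replicates(table, log_scale=True)
    assert means.at["p", "A"] == pytest.approx(1e5)  # geometric, not arithmetic
    assert average_replicates(table).at["p", "A"] == pytest.approx(5.05e5)


def test_median_center_equalizes_column_medians():
    table = build_lfq_table(
        {f"p{i}": [v, 10 * v] for i, v in enumerate([1e5, 2e5, 3e5])},
        conditions=["A"], n_bio=2, n_tech=1,
    )
    centered = profiledb.median_center(table)
    cols = centered.intensities.to_numpy()
    assert np.median(cols[:, 0]) == pytest.approx(np.median(cols[:, 1]))
    # original untouched
    assert table.intensities.iloc[0, 1] == pytest.approx(1e6)
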