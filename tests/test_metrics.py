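"""Solubilization index, replicate R^2, stratification, condition clustering."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_lfq_table, make_database
from mapscreen import ingest, synth
from mapscreen.metrics import (
    MetricsError,
    MissingGeneError,
    cluster_conditions,
    index_profile,
    replicate_r2,
    solubilization_index,
    stratify,
)


@pytest.fixture()
def small_db():
    profiles = pd.DataFrame(
        {
            "A": [100.0, 80.0, 100.0],
            "B": [60.0, 40.0, 100.0],
            "C": [np.nan, 100.0, 100.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return make_database(
        profiles, condition_classes={"A": "SMA", "B": "SMA", "C": "detergent"}
    )


def test_index_is_the_hand_computed_mean(small_db):
    assert solubilization_index(small_db, ["g1"], "A") == 100.0  # n=1 identity
    assert solubilization_index(small_db, ["g1", "g2"], "A") == pytest.approx(90.0)
    assert solubilization_index(small_db, ["g1", "g2"], "B") == pytest.approx(50.0)
    # upper bound attained only when every member is best-extracted there
    assert solubilization_index(small_db, ["g3"], "C") == 100.0


def test_index_bounds_between_member_values(small_db):
    vals = [100.0, 80.0]
    idx = solubilization_index(small_db, ["g1", "g2"], "A")
    assert min(vals) <= idx <= max(vals)


def test_missing_gene_policy(small_db):
    with pytest.raises(MissingGeneError) as err:
        solubilization_index(small_db, ["g1", "nope"], "A")
    assert "nope" in str(err.value)
    # not-detected member under the zero policy drags the average down
    assert solubilization_index(small_db, ["g1", "g2"], "C", missing="zero") == pytest.approx(50.0)
    with pytest.raises(MetricsError):
        solubilization_index(small_db, [], "A")
    with pytest.raises(MetricsError):
        solubilization_index(small_db, ["g1"], "Z")


def test_index_profile_ranking_and_class_best(small_db):
    prof = index_profile(small_db, ["g1", "g2"], missing="zero")
    assert prof.at["A", "index"] == pytest.approx(90.0)
    assert list(prof.index[:2]) == ["A", "B"]  # ranked descending, ties lexicographic
    assert prof.at["A", "class_best"] and not prof.at["B", "class_best"]
    assert prof.at["C", "class_best"]  # best of its own (detergent) class
    # whole-database query in one condition is the mean of its scaled values
    full = index_profile(small_db, ["g1", "g2", "g3"], missing="zero")
    assert full.at["B", "index"] == pytest.approx((60 + 40 + 100) / 3)


def test_r2_identity_and_affine_invariance():
    rng = np.random.default_rng(0)
    base = 10 ** rng.uniform(5, 8, 50)
    table = build_lfq_table(
        {f"p{i}": [base[i]] * 2 + [base[i]] * 2 for i in range(50)},
        conditions=["A"], n_bio=2, n_tech=2,
    )
    assert replicate_r2(table, "A").r2 == pytest.approx(1.0)
    scaled = build_lfq_table(
        {f"p{i}": [base[i]] * 2 + [2 * base[i]] * 2 for i in range(50)},
        conditions=["A"], n_bio=2, n_tech=2,
    )
    assert replicate_r2(scaled, "A").r2 == pytest.approx(1.0)  # scale-free


def test_r2_near_zero_for_independent_replicates():
    rng = np.random.default_rng(42)
    a, b = 10 ** rng.normal(6, 1, 1000), 10 ** rng.normal(6, 1, 1000)
    table = build_lfq_table(
        {f"p{i}": [a[i], b[i]] for i in range(1000)}, conditions=["A"], n_bio=2, n_tech=1
    )
    assert replicate_r2(table, "A").r2 < 0.02


def test_r2_requires_two_bio_reps_and_enough_proteins():
    table = build_lfq_table({"p": [1.0, 1.0]}, ["A"], n_bio=2, n_tech=1)
    with pytest.raises(MetricsError):
        replicate_r2(table, "A")  # only 1 shared protein
    one_bio = build_lfq_table({"p": [1.0, 1.0]}, ["A"], n_bio=1, n_tech=2)
    with pytest.raises(MetricsError):
        replicate_r2(one_bio, "A")


def test_stratify_boundary_conventions():
    profiles = pd.DataFrame(
        {"A": [100.0, 100.0, 50.0], "B": [50.0, 50.0, 100.0]},
        index=pd.Index(["small", "edge", "big"], name="gene"),
    )
    meta = pd.DataFrame(
        {"mw_kda": [39.9, 40.0, 120.0], "tmd_count": [0, 1, 7]}, index=profiles.index
    )
    db = make_database(profiles, meta=meta)
    mw = stratify(db, by="mw")
    assert mw.counts.at["<40", "A"] == 1  # 39.9 falls below the edge
    assert mw.counts.at[">=40", "A"] == 1  # 40.0 is left-closed into the upper bin
    assert mw.counts.at[">=40", "B"] == 1
    tmd = stratify(db, by="tmd")
    assert tmd.counts.at["0", "A"] == 1
    assert tmd.counts.at["1-5", "A"] == 1
    assert tmd.counts.at[">5", "B"] == 1
    # counts sum to the number of best-assigned proteins in every condition
    assert mw.counts.sum().sum() == len(db.genes)
    with pytest.raises(MetricsError):
        stratify(db, by="charge")


def test_stratify_matches_brute_force_tally(truth_small, zero_noise_db):
    res = stratify(zero_noise_db, by="tmd")
    by_gene = {t.gene: t for t in truth_small}
    for gene in zero_noise_db.genes:
        t = by_gene[gene]
        lab = "0" if t.tmd_count == 0 else ("1-5" if t.tmd_count <= 5 else ">5")
        cond = zero_noise_db.best_condition.at[gene]
        assert res.counts.at[lab, cond] >= 1  # tallied in its own cell
    assert res.counts.sum().sum() == len(zero_noise_db.genes)


def _three_condition_db(seed):
    rng = np.random.default_rng(seed)
    base = rng.uniform(10, 100, 40)
    third = rng.uniform(10, 100, 40)
    mat = np.column_stack([base, base, third])
    mat = 100 * mat / mat.max(axis=1, keepdims=True)
    profiles = pd.DataFrame(mat, columns=["A", "B", "C"],
                            index=[f"g{i}" for i in range(40)])
    return make_database(profiles)


def test_identical_conditions_merge_first_at_zero_distance():
    for seed in range(5):
        dend = cluster_conditions(_three_condition_db(seed))
        first, dist = dend.merge_order()[0]
        assert first == frozenset({"A", "B"})
        assert dist == pytest.approx(0.0, abs=1e-9)


def test_clustering_brute_force_distances():
    db = _three_condition_db(7)
    dend = cluster_conditions(db)
    mat = db.profiles.to_numpy()
    for i, a in enumerate(["A", "B", "C"]):
        for j, b in enumerate(["A", "B", "C"]):
            if i < j:
                expected = 1 - np.corrcoef(mat[:, i], mat[:, j])[0, 1]
                assert dend.distances.at[a, b] == pytest.approx(expected, abs=1e-12)


def test_clustering_invariant_to_condition_order():
    db = _three_condition_db(3)
    shuffled = make_database(db.profiles[["C", "A", "B"]])
    a = cluster_conditions(db)
    b = cluster_conditions(shuffled)
    assert a.labels == b.labels
    assert np.allclose(a.linkage[:, 2], b.linkage[:, 2])


def test_clustering_degenerate_inputs():
    single_protein = make_database(
        pd.DataFrame({"A": [100.0], "B": [50.0]}, index=["g"])
    )
    with pytest.raises(MetricsError):
        cluster_conditions(single_protein)
    constant = make_database(
        pd.DataFrame({"A": [100.0, 100.0], "B": [100.0, 100.0]}, index=["g1", "g2"])
    )
    with pytest.raises(MetricsError):
        cluster_conditions(constant)


def test_newick_export_contains_all_conditions():
    dend = cluster_conditions(_three_condition_db(1))
    nwk = dend.to_newick()
    assert nwk.endswith(";")
    for cond in ["A", "B", "C"]:
        assert cond in nwk
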