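"""proteinGroups parsing and the screen's filtering rules."""

import numpy as np
import pandas as pd
import pytest

from conftest import build_lfq_table
from mapscreen import ingest, synth
from mapscreen.ingest import (
    IngestError,
    annotate_membrane,
    filter_bio_replicates,
    filter_decoys_contaminants,
    parse_sample_name,
    read_proteingroups,
    write_proteingroups,
)

PG_HEADER = (
    "Protein IDs\tGene names\tMol. weight [kDa]\tReverse\tPotential contaminant\t"
    "LFQ intensity A_bio1_tech1\tLFQ intensity A_bio1_tech2\t"
    "LFQ intensity A_bio2_tech1\tLFQ intensity A_bio2_tech2\n"
)


def _write_fixture(path):
    rows = []
    for i in range(10):
        rev = "+" if i in (0, 1) else ""
        con = "+" if i == 2 else ""
        rows.append(f"P{i}\tG{i}\t50.0\t{rev}\t{con}\t1e6\t1e6\t1e6\t1e6")
    path.write_text(PG_HEADER + "\n".join(rows) + "\n")


def test_sample_name_parsing():
    key = parse_sample_name("CS80_bio2_tech3")
    assert (key.condition, key.bio_rep, key.tech_rep) == ("CS80", 2, 3)
    with pytest.raises(IngestError):
        parse_sample_name("CS80-rep2")


def test_read_flags_decoys_and_contaminants(tmp_path):
    p = tmp_path / "pg.tsv"
    _write_fixture(p)
    table = read_proteingroups(p)
    assert len(table.intensities) == 10
    assert int(table.meta["is_decoy"].sum()) == 2
    assert int(table.meta["is_contaminant"].sum()) == 1
    filtered = filter_decoys_contaminants(table)
    assert len(filtered.intensities) == 7
    # idempotent, and the original is untouched
    assert len(filter_decoys_contaminants(filtered).intensities) == 7
    assert len(table.intensities) == 10


def test_blank_lfq_cell_reads_as_not_detected(tmp_path):
    p = tmp_path / "pg.tsv"
    p.write_text(PG_HEADER + "P0\tG0\t50.0\t\t\t\t2e6\t3e6\t4e6\n")
    table = read_proteingroups(p)
    assert table.intensities.iloc[0, 0] == 0.0


def test_malformed_inputs_rejected(tmp_path):
    p = tmp_path / "pg.tsv"
    p.write_text(PG_HEADER + "P0\tG0\t50.0\t\t\tnot_a_number\t2e6\t3e6\t4e6\n")
    with pytest.raises(IngestError, match="malformed numeric"):
        read_proteingroups(p)
    p.write_text("Gene names\tLFQ intensity A_bio1_tech1\nG0\t1\n")
    with pytest.raises(IngestError, match="mandatory"):
        read_proteingroups(p)
    dup = PG_HEADER.rstrip("\n") + "\tLFQ intensity A_bio1_tech1\n"
    p.write_text(dup + "P0\tG0\t50.0\t\t\t1\t1\t1\t1\t1\n")
    with pytest.raises(IngestError, match="duplicate columns"):
        read_proteingroups(p)


def test_write_read_round_trip_is_bit_exact(truth_small, tmp_path):
    table = synth.simulate_lfq_table(truth_small, noise=synth.NoiseModel(seed=2))
    path = tmp_path / "pg.tsv"
    write_proteingroups(table, path)
    back = read_proteingroups(path)
    assert back.intensities.equals(table.intensities)
    assert back.meta.equals(table.meta)
    assert back.samples.equals(table.samples)


def test_bio_replicate_rule_on_hand_fixture():
    # 2 conditions x 2 bio x 4 tech; condition-major replicate order
    zeros, ones = [0.0] * 4, [1e6] * 4
    table = build_lfq_table(
        {
            "only_bio1": ones + zeros + ones + zeros,  # never in bio2 -> dropped
            "one_condition": ones + ones + zeros + zeros,  # A only -> kept, masked in B
            "everywhere": ones * 4,  # kept everywhere
        },
        conditions=["A", "B"],
        n_bio=2,
        n_tech=4,
    )
    out = filter_bio_replicates(table, min_tech_detected=1)
    assert list(out.intensities.index) == ["one_condition", "everywhere"]
    assert bool(out.retention.at["one_condition", "A"]) is True
    assert bool(out.retention.at["one_condition", "B"]) is False
    assert out.retention.loc["everywhere"].all()


def test_min_tech_detected_threshold():
    # detected in 2/4 technical replicates of each bio rep
    two_of_four = [1e6, 1e6, 0.0, 0.0]
    table = build_lfq_table(
        {"p": two_of_four * 2}, conditions=["A"], n_bio=2, n_tech=4
    )
    assert len(filter_bio_replicates(table, min_tech_detected=2).intensities) == 1
    assert len(filter_bio_replicates(table, min_tech_detected=3).intensities) == 0
    with pytest.raises(IngestError):
        filter_bio_replicates(table, min_tech_detected=5)


def test_zero_noise_synthetic_data_survives_replicate_filter(zero_noise_table):
    clean = filter_decoys_contaminants(zero_noise_table)
    out = filter_bio_replicates(clean)
    assert len(out.intensities) == len(clean.intensities)
    assert out.retention.to_numpy().all()


def test_filters_commute(truth_small):
    noise = synth.NoiseModel(detection_threshold=2e5, seed=3)
    table = synth.simulate_lfq_table(truth_small, noise=noise)
    ab = filter_bio_replicates(filter_decoys_contaminants(table))
    ba = filter_decoys_contaminants(filter_bio_replicates(table))
    assert ab.intensities.equals(ba.intensities)
    assert ab.retention.equals(ba.retention)


def test_annotate_membrane_keeps_all_organelle_labels(truth_small, zero_noise_table):
    ann = synth.simulate_annotations(truth_small)
    clean = filter_bio_replicates(filter_decoys_contaminants(zero_noise_table))
    out = annotate_membrane(clean, ann)
    truth_membrane = {t.protein_id for t in truth_small if t.is_membrane}
    assert set(out.intensities.index) == truth_membrane & set(clean.intensities.index)
    multi = [t for t in truth_small if t.is_membrane and len(t.organelles) == 2]
    for t in multi:
        if t.protein_id in out.intensities.index:
            labels = set(out.meta.at[t.protein_id, "organelles"].split(";"))
            assert labels == set(t.organelles)
    # soluble proteins are reviewed, not silently dropped
    soluble = {t.protein_id for t in truth_small if not t.is_membrane} & set(
        clean.intensities.index
    )
    reviewed = set(out.review["protein_id"])
    assert soluble <= reviewed


def test_annotate_membrane_overrides():
    table = build_lfq_table({"p1": [1e6] * 4, "p2": [1e6] * 4}, ["A"], 2, 2)
    ann = ingest.AnnotationTable(
        pd.DataFrame(
            {
                "gene": ["p1", "p2"],
                "organelles": ["ER", "PM"],
                "membrane_class": ["integral", "integral"],
                "tmd_count": [2, 1],
                "mw_kda": [50.0, 60.0],
            },
            index=pd.Index(["p1", "p2"], name="accession"),
        )
    )
    overrides = pd.DataFrame({"protein_id": ["p2"], "action": ["exclude"]})
    out = annotate_membrane(table, ann, overrides)
    assert list(out.intensities.index) == ["p1"]
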