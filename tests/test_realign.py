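"""clean, flip and the full realign pipeline."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from allelign import DatasetSpec, Registry, VariantRecord, flip_record, realign_dataset
from allelign.errors import EmptyInputWarning, MissingColumn, NonFiniteStatistic
from allelign.realign import clean, flip_frame, write_reassignment_file
from allelign.simulate import generate_cohort_set


def _frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"])


def _clean_oracle(rows):
    """Brute-force bucket assignment from the stated rules.

    Returns per-row bucket labels using plain dict multimaps, independent of
    the pipeline implementation.
    """
    labels = {}
    biallelic = {}
    for i, (chrom, pos, rid, a1, a2) in enumerate(rows):
        ok = a1 in set("ACGT") and a2 in set("ACGT") and a1 != a2
        biallelic[i] = ok
        if not ok:
            labels[i] = "non_biallelic"
    id_positions = {}
    for i, (chrom, pos, rid, a1, a2) in enumerate(rows):
        if biallelic[i]:
            id_positions.setdefault(rid, set()).add((chrom, pos))
    bad_positions = set()
    for rid, positions in id_positions.items():
        if len(positions) >= 2:
            bad_positions |= positions
    for i, (chrom, pos, rid, a1, a2) in enumerate(rows):
        if biallelic[i] and (chrom, pos) in bad_positions:
            labels[i] = "invalid"
    seen = set()
    survivors = {}
    for i, (chrom, pos, rid, a1, a2) in enumerate(rows):
        if i in labels:
            continue
        key = (chrom, pos, a1, a2)
        if key in seen:
            labels[i] = "duplicates"
        else:
            seen.add(key)
            survivors.setdefault((chrom, pos), []).append(i)
    for pos_key, idxs in survivors.items():
        if len(idxs) > 1:  # multiallelic by rows
            for i in idxs:
                labels[i] = "invalid"
    for i in range(len(rows)):
        labels.setdefault(i, "valid")
    return labels


def _assert_matches_oracle(rows):
    result = clean(_frame(rows))
    oracle = _clean_oracle(rows)
    got = {}
    for name, bucket in [
        ("valid", result.valid),
        ("invalid", result.invalid_multi_indexed),
        ("duplicates", result.duplicates),
        ("non_biallelic", result.non_biallelic),
    ]:
        for i in bucket.index:
            got[i] = name
    assert got == oracle


def test_clean_multi_indexed_id_invalidates_all_its_positions():
    rows = [
        ("1", 1000, "rs10", "A", "G"),
        ("1", 2000, "rs10", "C", "T"),
        ("1", 3000, "rs22", "A", "C"),
    ]
    result = clean(_frame(rows))
    assert list(result.valid["id"]) == ["rs22"]
    assert sorted(result.invalid_multi_indexed["pos"]) == [1000, 2000]
    _assert_matches_oracle(rows)


def test_clean_keeps_first_exact_duplicate():
    rows = [("1", 500, "rs5", "A", "G"), ("1", 500, "rs5", "A", "G")]
    result = clean(_frame(rows))
    assert list(result.valid.index) == [0]
    assert list(result.duplicates.index) == [1]
    _assert_matches_oracle(rows)


def test_clean_routes_multiallelic_positions_out_of_valid():
    rows = [("1", 700, "rs7", "A", "G"), ("1", 700, "rs8", "A", "C")]
    result = clean(_frame(rows))
    assert len(result.valid) == 0
    assert len(result.invalid_multi_indexed) == 2
    _assert_matches_oracle(rows)


def test_clean_cross_chromosome_multi_indexing_is_detected():
    rows = [("1", 1000, "rs1", "A", "G"), ("2", 5000, "rs1", "C", "T")]
    result = clean(_frame(rows))
    assert len(result.valid) == 0
    assert len(result.invalid_multi_indexed) == 2


clean_rows = st.lists(
    st.tuples(
        st.sampled_from(["1", "2"]),
        st.integers(min_value=1, max_value=8),
        st.sampled_from(["rs1", "rs2", "rs3", "rs4"]),
        st.sampled_from(["A", "C", "G", "T", "AT", "-", "a"]),
        st.sampled_from(["A", "C", "G", "T", "I", "."]),
    ),
    max_size=12,
)


@given(clean_rows)
def test_clean_partitions_input_and_matches_brute_force(rows):
    rows = [(c, p, r, a1.upper(), a2.upper()) for c, p, r, a1, a2 in rows]
    result = clean(_frame(rows))
    assert result.n_input == len(rows)
    buckets = [
        set(result.valid.index),
        set(result.invalid_multi_indexed.index),
        set(result.duplicates.index),
        set(result.non_biallelic.index),
    ]
    assert sum(len(b) for b in buckets) == len(rows)
    assert set.union(set(), *buckets) == set(range(len(rows)))
    if len(result.valid):
        assert not result.valid.duplicated(subset=["chrom", "pos"]).any()
        assert (result.valid.groupby("id")[["chrom", "pos"]].nunique() <= 1).all().all()
    _assert_matches_oracle(rows)


# ------------------------------------------------------------------- flipping


def test_flip_record_beta_scale():
    rec = VariantRecord(
        "1", 100, "A", "G", "rs1",
        stats={"effect_size": 0.5, "effect_allele_freq": 0.3, "p_value": 1e-5},
    )
    flipped = flip_record(rec, "beta")
    assert (flipped.a1, flipped.a2) == ("G", "A")
    assert flipped.stats["effect_size"] == -0.5
    assert flipped.stats["effect_allele_freq"] == pytest.approx(0.7, abs=1e-12)
    assert flipped.stats["p_value"] == 1e-5  # never altered


def test_flip_record_odds_ratio_scale():
    rec = VariantRecord("1", 100, "A", "G", stats={"effect_size": 2.0})
    assert flip_record(rec, "odds_ratio").stats["effect_size"] == pytest.approx(0.5)
    with pytest.raises(NonFiniteStatistic):
        flip_record(
            VariantRecord("1", 100, "A", "G", stats={"effect_size": 0.0}), "odds_ratio"
        )


@pytest.mark.parametrize("scale", ["beta", "odds_ratio", "none"])
@given(
    beta=st.floats(min_value=-5, max_value=5, allow_nan=False).filter(lambda b: abs(b) > 1e-6),
    freq=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
)
def test_flip_is_an_involution_and_conserves_statistics(scale, beta, freq):
    rec = VariantRecord(
        "2", 42, "C", "T", "rs9", stats={"effect_size": beta, "effect_allele_freq": freq}
    )
    once = flip_record(rec, scale)
    twice = flip_record(once, scale)
    assert (twice.a1, twice.a2) == (rec.a1, rec.a2)
    assert twice.stats["effect_size"] == pytest.approx(beta, rel=1e-12, abs=1e-12)
    assert twice.stats["effect_allele_freq"] == pytest.approx(freq, abs=1e-12)
    assert once.stats["effect_allele_freq"] + freq == pytest.approx(1.0, abs=1e-12)
    if scale == "beta":
        assert once.stats["effect_size"] + beta == pytest.approx(0.0, abs=1e-12)


def test_flip_frame_rejects_non_finite_statistics():
    df = pd.DataFrame(
        {"chrom": ["1"], "pos": [1], "id": ["r"], "a1": ["A"], "a2": ["G"],
         "effect_size": [np.nan], "effect_allele_freq": [0.2]}
    )
    with pytest.raises(NonFiniteStatistic):
        flip_frame(df, "beta")


# ------------------------------------------------------------ realign pipeline


@pytest.fixture()
def pair(tmp_path):
    cohorts = generate_cohort_set(
        seed=3, n_variants=400, n_shared=300, flip_rate=0.25,
        n_multi_indexed=4, n_duplicates=3, n_samples=10, n_cohorts=2,
        outdir=tmp_path / "fix",
    )
    registry = Registry.create(tmp_path, "reg")
    return cohorts, registry, tmp_path


def test_first_dataset_against_fresh_registry_reassigns_nothing(pair):
    cohorts, registry, tmp = pair
    res = realign_dataset(cohorts.specs["cohortA"], registry, outdir=tmp / "out")
    assert res.n_reassigned == 0
    assert res.n_registered == res.n_identified


def test_planted_flip_count_is_recovered_exactly(pair):
    cohorts, registry, tmp = pair
    realign_dataset(cohorts.specs["cohortA"], registry, outdir=tmp / "out")
    res_b = realign_dataset(cohorts.specs["cohortB"], registry, outdir=tmp / "out")
    assert res_b.n_reassigned == cohorts.truth.n_flipped("cohortB")
    assert res_b.n_registered == 400 - 300  # cohort-private variants are novel


def test_clean_bookkeeping_matches_planted_corruptions(pair):
    cohorts, registry, tmp = pair
    res = realign_dataset(cohorts.specs["cohortA"], registry, outdir=tmp / "out")
    assert res.n_invalid == 2 * len(cohorts.truth.multi_indexed_ids)
    assert res.n_duplicates == len(cohorts.truth.duplicate_ids)


def test_realigning_own_output_is_idempotent(pair):
    cohorts, registry, tmp = pair
    spec_a = cohorts.specs["cohortA"]
    realign_dataset(spec_a, registry, outdir=tmp / "out")
    spec_b = cohorts.specs["cohortB"]
    res_b = realign_dataset(spec_b, registry, outdir=tmp / "out")
    assert res_b.n_reassigned > 0

    again_a = DatasetSpec(
        path=str(tmp / "out" / "cohortA" / "cohortA.realigned.tsv"),
        format="sumstats", dataset_label="againA",
        columns=dict(spec_a.columns), effect_scale="beta",
    )
    res = realign_dataset(again_a, registry, outdir=tmp / "out2")
    assert (res.n_reassigned, res.n_registered) == (0, 0)

    again_b = DatasetSpec(
        path=str(tmp / "out" / "cohortB" / "cohortB.realigned.pvar"),
        format="pvar", dataset_label="againB",
    )
    res = realign_dataset(again_b, registry, outdir=tmp / "out2")
    assert (res.n_reassigned, res.n_registered) == (0, 0)


def test_reassignment_file_lists_exactly_the_flipped_variants(pair):
    cohorts, registry, tmp = pair
    realign_dataset(cohorts.specs["cohortA"], registry, outdir=tmp / "out")
    res_b = realign_dataset(cohorts.specs["cohortB"], registry, outdir=tmp / "out")
    path = tmp / "out" / "cohortB" / "cohortB.reassignment.tsv"
    rows = pd.read_csv(path, sep="\t", header=None, names=["id", "new_alt"], dtype=str)
    assert len(rows) == res_b.n_reassigned
    # sorted by (chrom, pos): IDs are CHR_POS_REF_ALT so recompute and compare
    reassign = res_b.reassignment_rows
    assert list(rows["id"]) == list(reassign["id"])
    assert (reassign.groupby("chrom")["pos"].apply(lambda s: s.is_monotonic_increasing)).all()
    # every listed ALT is the registry's ALT at that site
    for _, row in reassign.head(20).iterrows():
        part = registry.partition(row["chrom"])
        assert part.loc[part["pos"] == row["pos"], "alt"].iloc[0] == row["new_alt"]


def test_reassignment_file_is_written_empty_when_nothing_flips(tmp_path):
    cohorts = generate_cohort_set(
        seed=5, n_variants=50, n_shared=40, flip_rate=0.0, n_multi_indexed=0,
        n_duplicates=0, n_samples=5, n_cohorts=2, outdir=tmp_path / "fix",
    )
    registry = Registry.create(tmp_path, "reg")
    realign_dataset(cohorts.specs["cohortA"], registry, outdir=tmp_path / "out")
    res = realign_dataset(cohorts.specs["cohortB"], registry, outdir=tmp_path / "out")
    assert res.n_reassigned == 0
    path = tmp_path / "out" / "cohortB" / "cohortB.reassignment.tsv"
    assert path.exists() and path.read_text() == ""


def test_chromosome_restriction_processes_only_that_chromosome(pair):
    cohorts, registry, tmp = pair
    res = realign_dataset(
        cohorts.specs["cohortA"], registry, outdir=tmp / "out", chrom="chr7"
    )
    assert set(res.realigned_records["chrom"]) <= {"7"}
    reports = list((tmp / "out" / "cohortA").glob("chr*.identified.tsv"))
    assert [p.name for p in reports] == ["chr7.identified.tsv"]


def test_missing_mandatory_column_is_reported_by_role(pair):
    cohorts, registry, tmp = pair
    spec = cohorts.specs["cohortA"]
    cols = {k: v for k, v in spec.columns.items() if k != "effect_allele"}
    bad = DatasetSpec(
        path=spec.path, format="sumstats", dataset_label="bad", columns=cols
    )
    with pytest.raises(MissingColumn, match="effect_allele"):
        realign_dataset(bad, registry, outdir=tmp / "out")


def test_empty_input_warns_and_emits_empty_artifacts(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("CHR\tBP\tSNP\tEA\tOA\n1\t100\trs1\tAT\tG\n")
    spec = DatasetSpec(
        path=str(path), format="sumstats", dataset_label="empty",
        columns={"chrom": "CHR", "pos": "BP", "id": "SNP",
                 "effect_allele": "EA", "other_allele": "OA"},
    )
    registry = Registry.create(tmp_path, "reg")
    with pytest.warns(EmptyInputWarning):
        res = realign_dataset(spec, registry, outdir=tmp_path / "out")
    assert res.n_identified == 0
    assert (tmp_path / "out" / "empty" / "chr1.identified.tsv").exists()


def test_mismatched_records_are_excluded_and_reported(tmp_path):
    first = tmp_path / "first.tsv"
    first.write_text("CHR\tBP\tSNP\tEA\tOA\n1\t100\trs1\tA\tG\n")
    second = tmp_path / "second.tsv"
    second.write_text("CHR\tBP\tSNP\tEA\tOA\n1\t100\tother1\tT\tC\n")
    cols = {"chrom": "CHR", "pos": "BP", "id": "SNP",
            "effect_allele": "EA", "other_allele": "OA"}
    registry = Registry.create(tmp_path, "reg")
    realign_dataset(
        DatasetSpec(path=str(first), format="sumstats", dataset_label="d1", columns=cols),
        registry, outdir=tmp_path / "out",
    )
    res = realign_dataset(
        DatasetSpec(path=str(second), format="sumstats", dataset_label="d2", columns=cols),
        registry, outdir=tmp_path / "out",
    )
    assert res.n_mismatched == 1
    assert len(res.realigned_records) == 0
    mismatch = pd.read_csv(
        tmp_path / "out" / "d2" / "chr1.mismatched.tsv", sep="\t", comment="#"
    )
    assert list(mismatch["original_id"]) == ["other1"]
    # the conflicting pair was never registered: the registry still holds A->G
    assert registry.partition("1").iloc[0]["ref"] == "G"


def test_bim_round_trip(tmp_path):
    bim = tmp_path / "geno.bim"
    bim.write_text("1\tvar1\t0\t100\tA\tG\n2\tvar2\t0\t200\tC\tT\n")
    registry = Registry.create(tmp_path, "reg")
    spec = DatasetSpec(path=str(bim), format="bim", dataset_label="g")
    res = realign_dataset(spec, registry, outdir=tmp_path / "out")
    assert res.n_identified == 2 and res.n_registered == 2
    out = tmp_path / "out" / "g" / "g.realigned.bim"
    again = DatasetSpec(path=str(out), format="bim", dataset_label="g2")
    res2 = realign_dataset(again, registry, outdir=tmp_path / "out2")
    assert (res2.n_reassigned, res2.n_registered) == (0, 0)


def test_write_reassignment_file_single_reverse_variant(tmp_path):
    first = tmp_path / "first.pvar"
    first.write_text("#CHROM\tPOS\tID\tREF\tALT\n1\t100\trs0\tT\tC\n")
    second = tmp_path / "second.pvar"
    second.write_text("#CHROM\tPOS\tID\tREF\tALT\n1\t100\trs9\tC\tT\n")
    registry = Registry.create(tmp_path, "reg")
    realign_dataset(DatasetSpec(path=str(first), format="pvar", dataset_label="a"), registry)
    res = realign_dataset(DatasetSpec(path=str(second), format="pvar", dataset_label="b"), registry)
    out = write_reassignment_file(res, tmp_path / "re.tsv")
    assert out.read_text() == "rs9\tC\n"
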