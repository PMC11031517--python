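"""Score-table validation, aggregation arithmetic, Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from panospec import (
    ReaderScoreTable,
    aggregate_scores,
    compare_modalities,
    load_scores,
    simulate_scores,
    wilcoxon_signed_rank,
)
from panospec.reader_stats import CRITERIA, MODALITIES, results_frame


def _table_from_vectors(rows):
    """rows: list of (modality, criterion, {reader: list of 17 scores})."""
    records = []
    for modality, criterion, by_reader in rows:
        for reader, scores in by_reader.items():
            for case, s in enumerate(scores, start=1):
                records.append((reader, f"C{case:02d}", modality, criterion, s))
    return ReaderScoreTable(pd.DataFrame(records, columns=["reader", "case", "modality", "criterion", "score"]))


def scores_with_mean(total, n=17):
    """Integer 1-5 score vector of length n with sum `total`."""
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


# ---------------------------------------------------------------- loading

def test_load_full_study_table(tmp_path):
    table = simulate_scores(n_readers=3, n_cases=17, seed=1)
    path = tmp_path / "scores.csv"
    table.records.to_csv(path, index=False)
    loaded = load_scores(path)
    assert len(loaded) == 3 * 17 * 5 * 5 == 1275


def test_invalid_score_named_in_error():
    df = simulate_scores(n_readers=1, n_cases=2, seed=0).records.copy()
    df.loc[3, "score"] = 6
    with pytest.raises(ValueError, match=r"1\.\.5.*\[3\]"):
        ReaderScoreTable(df)


def test_duplicate_key_rejected():
    df = simulate_scores(n_readers=1, n_cases=2, seed=0).records
    dup = pd.concat([df, df.iloc[[0]]], ignore_index=True)
    with pytest.raises(ValueError, match="duplicate"):
        ReaderScoreTable(dup)


def test_unknown_modality_rejected():
    df = simulate_scores(n_readers=1, n_cases=1, seed=0).records.copy()
    df.loc[0, "modality"] = "CBCT"
    with pytest.raises(ValueError, match="modality"):
        ReaderScoreTable(df)


# ---------------------------------------------------------------- aggregation

def test_across_reader_average_of_reported_reader_means():
    """With 17 cases, reader means are multiples of 1/17; the across-reader
    average of three reader means 2.35 / 3.53 / 4.06 rounds to 3.31, and of
    4.71 / 5.00 / 4.88 to 4.86."""
    rows = [
        ("PAN", "bone_quality",
         {"R1": scores_with_mean(40), "R2": scores_with_mean(60), "R3": scores_with_mean(69)}),
        ("PETI_BONE", "bone_quality",
         {"R1": scores_with_mean(80), "R2": scores_with_mean(85), "R3": scores_with_mean(83)}),
    ]
    agg = aggregate_scores(_table_from_vectors(rows))
    means = agg.per_reader["mean"]
    assert round(means.loc[("PAN", "bone_quality", "R1")], 2) == 2.35
    assert round(means.loc[("PAN", "bone_quality", "R3")], 2) == 4.06
    assert round(agg.average.loc[("PAN", "bone_quality"), "average"], 2) == 3.31
    assert round(agg.average.loc[("PETI_BONE", "bone_quality"), "average"], 2) == 4.86


def test_degenerate_all_fives():
    rows = [("PETI_BONE", c, {r: [5] * 17 for r in ("R1", "R2", "R3")}) for c in CRITERIA]
    agg = aggregate_scores(_table_from_vectors(rows))
    assert np.all(agg.per_reader["mean"] == 5.0)
    assert np.all(agg.per_reader["sd"] == 0.0)
    assert agg.total_points["PETI_BONE"] == pytest.approx(25 * 3)


def test_total_points_is_sum_of_criterion_entries():
    table = simulate_scores(seed=3)
    agg = aggregate_scores(table)
    for modality in MODALITIES:
        per_crit = agg.per_reader["mean"].loc[modality].groupby(level="criterion").sum()
        assert agg.total_points[modality] == pytest.approx(per_crit.sum())
        lo, hi = 5 * 3, 25 * 3
        assert lo <= agg.total_points[modality] <= hi


# ---------------------------------------------------------------- wilcoxon

def _brute_force_two_sided_p(d):
    """Enumerate all sign assignments on the observed mid-ranks (oracle)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2.0
    hits = 0
    total = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
        total += 1
    return hits / total


def test_worked_example_exact_p():
    """Five all-positive unit differences: two-sided exact p = 2/32 = 0.0625."""
    res = wilcoxon_signed_rank((2, 3, 4, 5, 6), (1, 2, 3, 4, 5))
    assert res.p_value == pytest.approx(0.0625, abs=1e-12)
    assert res.direction == "positive"
    assert res.n == 5
    assert res.statistic == 0.0  # W- = 0


def test_all_tied_pairs_raise():
    with pytest.raises(ValueError, match="no nonzero pairs"):
        wilcoxon_signed_rank([3, 3, 4], [3, 3, 4])


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_exact_p_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=10)
    y = rng.normal(size=10)
    res = wilcoxon_signed_rank(x, y)
    assert res.method == "exact"
    assert res.p_value == pytest.approx(_brute_force_two_sided_p(x - y), abs=1e-12)


@pytest.mark.parametrize("seed", [10, 11])
def test_exact_p_with_tied_ordinal_scores(seed):
    """Mid-rank enumeration stays exact for tied integer differences."""
    rng = np.random.default_rng(seed)
    x = rng.integers(1, 6, size=12)
    y = rng.integers(1, 6, size=12)
    d = (x - y)[(x - y) != 0]
    if len(d) == 0:
        pytest.skip("degenerate draw")
    res = wilcoxon_signed_rank(x, y)
    assert res.p_value == pytest.approx(_brute_force_two_sided_p(x - y), abs=1e-12)


def test_exact_p_matches_scipy_without_ties():
    rng = np.random.default_rng(7)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    ours = wilcoxon_signed_rank(x, y)
    ref = scipy_wilcoxon(x, y, alternative="two-sided", method="exact")
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
    assert ours.statistic == pytest.approx(ref.statistic)


def test_large_n_normal_approximation_matches_scipy():
    rng = np.random.default_rng(8)
    x = rng.integers(1, 6, size=60).astype(float)
    y = rng.integers(1, 6, size=60).astype(float)
    ours = wilcoxon_signed_rank(x, y)
    assert ours.method == "normal-approx"
    ref = scipy_wilcoxon(x, y, alternative="two-sided", method="approx", correction=True)
    assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_rank_sum_identity_and_swap_symmetry():
    rng = np.random.default_rng(12)
    for _ in range(20):
        n = int(rng.integers(2, 25))
        x = rng.integers(1, 6, size=n).astype(float)
        y = rng.integers(1, 6, size=n).astype(float)
        d = x - y
        d = d[d != 0]
        if len(d) == 0:
            continue
        from panospec.reader_stats import _signed_ranks

        ranks, _ = _signed_ranks(d)
        w_plus = ranks[d > 0].sum()
        w_minus = ranks[d < 0].sum()
        m = len(d)
        assert w_plus + w_minus == pytest.approx(m * (m + 1) / 2)
        assert wilcoxon_signed_rank(x, y).p_value == pytest.approx(
            wilcoxon_signed_rank(y, x).p_value, abs=1e-12
        )


# ---------------------------------------------------------------- comparisons

def test_plus_one_shift_all_significant_positive():
    shifts = {m: 1 for m in MODALITIES if m != "PAN"}
    table = simulate_scores(modality_shift=shifts, seed=5)
    results = compare_modalities(table)
    assert len(results) == 4 * 5
    assert all(r.significant for r in results)
    assert all(r.direction == "positive" for r in results)


def test_identical_copy_flagged_untestable():
    shifts = {m: 0 for m in MODALITIES if m != "PAN"}  # exact copies of baseline
    table = simulate_scores(modality_shift=shifts, seed=6)
    results = compare_modalities(table)
    assert len(results) == 4 * 5
    assert all(r.untestable for r in results)
    frame = results_frame(results)
    assert frame["untestable"].all()


def test_baseline_only_table_gives_empty_results():
    table = simulate_scores(seed=7)
    pan_only = ReaderScoreTable(table.records[table.records["modality"] == "PAN"])
    assert compare_modalities(pan_only) == []


def test_missing_pairs_listed():
    table = simulate_scores(n_readers=1, n_cases=3, seed=8).records
    drop = (table["modality"] == "PVMI40") & (table["case"] == "C02")
    broken = ReaderScoreTable(table[~drop])
    with pytest.raises(ValueError, match="unpaired.*C02"):
        compare_modalities(broken)


def test_missing_baseline_rejected():
    table = simulate_scores(seed=9).records
    no_pan = ReaderScoreTable(table[table["modality"] != "PAN"])
    with pytest.raises(ValueError, match="baseline"):
        compare_modalities(no_pan)


def test_holm_correction_is_more_conservative():
    shifts = {"PETI_BONE": 1}
    table = simulate_scores(modality_shift=shifts, seed=10)
    raw = compare_modalities(table, correction=None)
    holm = compare_modalities(table, correction="holm")
    raw_sig = {r.label for r in raw if r.significant}
    holm_sig = {r.label for r in holm if r.significant}
    assert holm_sig <= raw_sig
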