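"""Summary statistics, percentage tables and the end-to-end pipeline."""


import numpy as np
import pytest
from scipy import stats as sps

from voicediary import (
    DiaryDataset,
    ErrorModelConfig,
    category_percentages,
    PairClassification,
    generate_cohort,
    match_counterparts,
    median_iqr,
    paired_t,
    partial_attempt_summary,
    percentage,
    run_pipeline,
    timestamp_agreement,
    use_summary,
    write_diary,
)
from voicediary.classify import ItemClassification

from conftest import make_entry, ts


# ---------------------------------------------------------------------------
# median / IQR and paired t


def test_median_iqr_hand_example():
    out = median_iqr([1, 2, 3, 4, 5])
    assert (out["median"], out["q1"], out["q3"]) == (3.0, 2.0, 4.0)


@pytest.mark.parametrize("seed", range(10))
def test_median_iqr_agrees_with_numpy_percentile_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = rng.integers(0, 40, size=rng.integers(1, 30)).tolist()
    out = median_iqr(vals)
    q1, med, q3 = np.percentile(np.sort(vals), [25, 50, 75])
    assert (out["q1"], out["median"], out["q3"]) == (q1, med, q3)


def test_paired_t_zero_difference():
    out = paired_t([3, 4, 5], [3, 4, 5])
    assert out["t"] == 0.0 and out["p"] == 1.0


@pytest.mark.parametrize("seed", range(10))
def test_paired_t_agrees_with_scipy_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 30))
    x = rng.normal(10, 3, n)
    y = x + rng.normal(1, 2, n)
    out = paired_t(x, y)
    ref = sps.ttest_rel(x, y)
    assert out["t"] == pytest.approx(ref.statistic)
    assert out["p"] == pytest.approx(ref.pvalue)


# ---------------------------------------------------------------------------
# use summary


def test_use_summary_equal_counts_gives_t_zero():
    alexa = DiaryDataset(
        [make_entry(f"A{i}", "alexa", ts(i * 60), ts(i * 60), pid=f"P{i%2}")
         for i in range(4)]
    )
    web = DiaryDataset(
        [make_entry(f"W{i}", "web", ts(i * 60), ts(i * 60 + 10), pid=f"P{i%2}")
         for i in range(4)]
    )
    out = use_summary(alexa, web)
    assert out["alexa"]["median"] == out["web"]["median"] == 2
    assert out["paired_t"]["t"] == 0.0 and out["paired_t"]["p"] == 1.0


def test_use_summary_single_participant_omits_t_test():
    alexa = DiaryDataset([make_entry("A1", "alexa", ts(0), ts(0))])
    web = DiaryDataset([make_entry("W1", "web", ts(0), ts(10))])
    out = use_summary(alexa, web)
    assert out["paired_t"] is None and "warning" in out


def test_use_summary_counts_submitted_only(noiseless_config):
    alexa, web, _ = generate_cohort(6, 7, 2.0, noiseless_config, seed=3)
    out = use_summary(alexa, web)
    assert out["alexa"]["median"] == out["web"]["median"]
    assert out["alexa_counts"] == out["web_counts"]


# ---------------------------------------------------------------------------
# timestamp agreement


def _agreement_fixture(per_participant_exact):
    """Build pairs and datasets realizing given per-participant
    (n_exact, n_total) tuples."""
    alexa_entries, web_entries = [], []
    k = 0
    for pid, (n_exact, n_total) in per_participant_exact.items():
        for j in range(n_total):
            exact = j < n_exact
            a_in = ts(k * 60) if exact else ts(k * 60 + 3)
            alexa_entries.append(
                make_entry(f"A{k}", "alexa", a_in, ts(k * 60 + 1), pid=pid)
            )
            web_entries.append(
                make_entry(f"W{k}", "web", ts(k * 60), ts(k * 60 + 10), pid=pid)
            )
            k += 1
    alexa, web = DiaryDataset(alexa_entries), DiaryDataset(web_entries)
    return match_counterparts(alexa, web), alexa, web


def test_all_exact_pairs():
    pairs, alexa, web = _agreement_fixture({"P1": (3, 3)})
    out = timestamp_agreement(pairs, alexa, web)
    assert out["proportion_exact"] == 1.0
    assert (out["bland_altman"]["diff_minutes"] == 0).all()


def test_overall_proportion_from_counts():
    # 222 exact of 310 -> 0.716 at 3 decimal places
    pairs, alexa, web = _agreement_fixture({"P1": (222, 310)})
    out = timestamp_agreement(pairs, alexa, web)
    assert out["n_exact"] == 222 and out["n_pairs"] == 310
    assert round(out["proportion_exact"], 3) == 0.716


def test_per_participant_median_proportion():
    pairs, alexa, web = _agreement_fixture(
        {"P1": (1, 2), "P2": (2, 3), "P3": (3, 3)}
    )
    out = timestamp_agreement(pairs, alexa, web)
    assert out["per_participant"]["median"] == pytest.approx(2 / 3)
    assert out["per_participant"]["q1"] == pytest.approx((0.5 + 2 / 3) / 2)


def test_bland_altman_one_row_per_pair_signed_difference():
    pairs, alexa, web = _agreement_fixture({"P1": (1, 4)})
    out = timestamp_agreement(pairs, alexa, web)
    table = out["bland_altman"]
    assert len(table) == len(pairs)
    assert set(table["diff_minutes"]) == {0.0, 3.0}  # alexa minus web


def test_empty_pairs_rejected():
    alexa = DiaryDataset([make_entry("A1", "alexa", ts(0), ts(0))])
    web = DiaryDataset([make_entry("W1", "web", ts(0), ts(10))])
    with pytest.raises(ValueError):
        timestamp_agreement([], alexa, web)


# ---------------------------------------------------------------------------
# category percentages


def _pc(categories, different_event=False, to_two_count=0):
    if different_event:
        return PairClassification(pair=None, different_event=True)
    items = []
    n_to_two = 0
    for c in categories:
        kwargs = {}
        if c <= 8:
            kwargs = dict(web_index=0, alexa_index=0)
        elif c in (9, 10):
            kwargs = dict(alexa_index=0)
        else:
            kwargs = dict(web_index=0)
        if c == 5 and n_to_two < to_two_count:
            kwargs["is_to_two"] = True
            n_to_two += 1
        items.append(ItemClassification(c, **kwargs))
    return PairClassification(pair=None, different_event=False, items=items)


def test_percentage_helper_matches_printed_convention():
    out = percentage(357, 588)
    assert out["pct_1dp"] == 60.7
    assert percentage(40, 59)["pct_int"] == 68
    assert percentage(0, 0) is None


def test_all_same_items_give_100_percent_and_empty_differing_table():
    out = category_percentages([_pc([1, 1]), _pc([1])])
    assert out["same_of_web_items"]["pct"] == 100.0
    assert out["n_differing_items"] == 0
    assert all(v is None for v in out["differing"].values())


def test_category_table_counts_and_denominators():
    classifications = [
        _pc([1, 3, 5, 5], to_two_count=1),
        _pc([1, 8, 9, 11]),
        _pc([], different_event=True),
        _pc([10, 2]),
    ]
    out = category_percentages(classifications)
    assert out["n_pairs_reviewed"] == 4
    assert out["different_event"]["numerator"] == 1
    # aligned: 1,3,5,5,1,8,2 (7 items); extras: 9,10 alexa-side, 11 web-side
    assert out["n_web_items"] == 8
    assert out["n_alexa_items"] == 9
    assert out["counts"]["same_semantically"] == 2
    assert out["n_differing_items"] == 4  # 3, 5, 5, 2
    assert out["differing"]["alexa_less_detail"]["numerator"] == 1
    assert out["to_two_of_alexa_misspellings"]["numerator"] == 1
    assert out["to_two_of_alexa_misspellings"]["denominator"] == 2
    assert out["major_issue_of_alexa_items"]["numerator"] == 1


def test_category_table_cross_foots_with_pipeline_classes(noiseless_config):
    alexa, web, _ = generate_cohort(5, 7, 2.0, noiseless_config, seed=6)
    report = run_pipeline(alexa, web)
    cats = report["categories"]
    counts = cats["counts"]
    aligned = sum(
        counts[name]
        for name in ("same_semantically", "different_detail", "alexa_less_detail",
                     "alexa_more_detail", "alexa_misspelling", "web_misspelling",
                     "alexa_entry_issue", "major_entry_issue")
    )
    assert cats["n_web_items"] == aligned + counts["extra_web_item"]
    assert cats["n_alexa_items"] == (
        aligned + counts["extra_alexa_garbage"] + counts["extra_alexa_food"]
    )


# ---------------------------------------------------------------------------
# partial attempts


def test_partial_attempt_median_hand_example():
    entries = []
    for pid, n_partial in (("P1", 1), ("P2", 6), ("P3", 9)):
        for j in range(n_partial):
            entries.append(
                make_entry(f"{pid}x{j}", "alexa", ts(j), ts(j), (),
                           pid=pid, status="partial")
            )
        entries.append(make_entry(f"{pid}s", "alexa", ts(50), ts(50), pid=pid))
    out = partial_attempt_summary(DiaryDataset(entries))
    assert out["median"] == 6 and (out["q1"], out["q3"]) == (3.5, 7.5)


def test_no_partial_entries_gives_median_zero():
    ds = DiaryDataset([make_entry("A1", "alexa", ts(0), ts(0))])
    assert partial_attempt_summary(ds)["median"] == 0


# ---------------------------------------------------------------------------
# pipeline


def test_noiseless_pipeline_end_to_end(noiseless_config):
    alexa, web, truth = generate_cohort(8, 7, 2.0, noiseless_config, seed=21)
    report = run_pipeline(alexa, web)
    assert report["n_pairs"] == len(truth.links)
    assert report["n_pairs_step1"] == report["n_pairs"]
    assert report["timestamp_agreement"]["proportion_exact"] == 1.0
    cats = report["categories"]
    assert cats["same_of_web_items"]["pct"] == 100.0
    assert cats["same_of_alexa_items"]["pct"] == 100.0
    assert report["wordsets"]["total_web_only"] == 0
    assert report["wordsets"]["total_alexa_only"] == 0


def test_pipeline_outputs_byte_identical_across_runs(tmp_path):
    alexa, web, _ = generate_cohort(6, 7, 2.5, ErrorModelConfig(), seed=13)
    d1, d2 = tmp_path / "r1", tmp_path / "r2"
    write_diary(alexa, tmp_path / "alexa.csv")
    write_diary(web, tmp_path / "web.csv")
    run_pipeline(tmp_path / "alexa.csv", tmp_path / "web.csv", out_dir=d1)
    run_pipeline(tmp_path / "alexa.csv", tmp_path / "web.csv", out_dir=d2)
    for name in ("pairs.csv", "wordsets.csv", "classes.csv", "bland_altman.csv",
                 "report.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name


def test_pipeline_percentages_track_generator_truth():
    """Report category proportions land near the realized generator rates."""
    cfg = ErrorModelConfig(p_partial=0.0, p_no_web=0.0, p_timestamp_misheard=0.0)
    alexa, web, truth = generate_cohort(40, 7, 2.5, cfg, seed=17)
    report = run_pipeline(alexa, web)
    n_items = sum(v for c, v in truth.true_rates.items() if c != 11)
    p_true = truth.true_rates[1] / n_items
    got = report["categories"]["same_of_alexa_items"]["pct"] / 100
    assert abs(got - p_true) < 0.05


def test_pipeline_stage_errors_name_the_stage(tmp_path):
    with pytest.raises(RuntimeError, match="read\\(alexa\\)"):
        run_pipeline(tmp_path / "missing.csv", tmp_path / "missing2.csv")
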