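import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from repdil.quantify import ExpressionTable
from repdil.stats import (
    StatsConfig,
    dunn_test,
    run_tests,
    select_tests,
    stats_table,
)


def _expr(groups: dict[str, list[float]], gene="G", pairs=False) -> ExpressionTable:
    rows = []
    for g, vals in groups.items():
        for i, v in enumerate(vals, start=1):
            rows.append((g, str(i), str(i) if pairs else None, gene, 2.0**v, v))
    data = pd.DataFrame(
        rows,
        columns=["group", "replicate_id", "pair_id", "gene", "norm_expr",
                 "log2_norm_expr"],
    )
    return ExpressionTable(data=data, genes=[gene])


@pytest.mark.parametrize(
    "n,family,mode,paired,expected",
    [
        (2, "parametric", "all_to_one", False, "Welch t-test"),
        (2, "parametric", "all_to_one", True, "paired t-test"),
        (4, "parametric", "all_to_one", False, "Dunnett many-to-one"),
        (4, "parametric", "all_pairs", False, "Tukey HSD"),
        (4, "parametric", "selected_pairs", False, "Welch t-test"),
        (2, "nonparametric", "all_to_one", False, "Mann-Whitney U"),
        (2, "nonparametric", "all_to_one", True, "Wilcoxon signed-rank"),
        (4, "nonparametric", "all_pairs", False, "Dunn post-hoc"),
        (4, "nonparametric", "selected_pairs", False, "Mann-Whitney U"),
    ],
)
def test_select_tests_plan(n, family, mode, paired, expected):
    cfg = StatsConfig(
        family=family, comparisons=mode, paired=paired,
        selected=[("a", "b")] if mode == "selected_pairs" else None,
    )
    assert select_tests(n, cfg).pairwise == expected


def test_selected_pairs_requires_selection():
    with pytest.raises(ValueError):
        StatsConfig(comparisons="selected_pairs")
    with pytest.raises(ValueError):
        StatsConfig(comparisons="all_pairs", selected=[("a", "b")])


def test_kruskal_dunn_reported_for_nonparametric_multigroup():
    rng = np.random.default_rng(0)
    expr = _expr({g: list(rng.normal(0, 1, 6)) for g in "ABCD"})
    cfg = StatsConfig(family="nonparametric", comparisons="all_pairs")
    res = run_tests(expr, cfg)[0]
    assert res.omnibus_test[0] == "Kruskal-Wallis"
    assert len(res.comparisons) == 6
    assert all(c.test_name == "Dunn post-hoc test" for c in res.comparisons)


def test_dunn_two_groups_matches_kruskal_chi2():
    """For 2 groups Dunn's z^2 equals the Kruskal-Wallis H statistic."""
    rng = np.random.default_rng(1)
    a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 6)
    (p_dunn,) = dunn_test([a, b], [(0, 1)])
    h = sps.kruskal(a, b).statistic
    assert p_dunn == pytest.approx(2 * sps.norm.sf(np.sqrt(h)), abs=1e-12)


def test_large_shift_detected_small_shift_with_identical_data_not():
    rng = np.random.default_rng(2)
    base = rng.normal(0, 0.2, 9)
    expr = _expr({"A": list(base), "B": list(base + 3.0)})
    for family in ("parametric", "nonparametric"):
        cfg = StatsConfig(family=family, comparisons="all_to_one")
        res = run_tests(expr, cfg)[0]
        assert res.comparisons[0].significant

    same = _expr({"A": [1.0] * 4, "B": [1.0] * 4})
    with pytest.warns(UserWarning, match="degenerate"):
        res = run_tests(same, StatsConfig())[0]
    assert not res.comparisons[0].significant
    assert res.comparisons[0].p_adjusted == 1.0


def test_tests_use_log_scale_hence_scale_equivariant():
    rng = np.random.default_rng(3)
    vals = {g: list(rng.normal(0, 1, 5)) for g in "AB"}
    e1 = _expr(vals)
    e2 = _expr({g: [v + np.log2(1000) for v in vs] for g, vs in vals.items()})
    for family in ("parametric", "nonparametric"):
        cfg = StatsConfig(family=family, comparisons="all_to_one")
        p1 = run_tests(e1, cfg)[0].comparisons[0].p_raw
        p2 = run_tests(e2, cfg)[0].comparisons[0].p_raw
        assert p1 == pytest.approx(p2, abs=1e-12)


def test_holm_never_below_raw_and_labels_monotone():
    rng = np.random.default_rng(4)
    expr = _expr(
        {"A": list(rng.normal(0, 1, 6)), "B": list(rng.normal(1, 1, 6)),
         "C": list(rng.normal(2, 1, 6)), "D": list(rng.normal(0.2, 1, 6))}
    )
    cfg = StatsConfig(family="nonparametric", comparisons="all_pairs")
    res = run_tests(expr, cfg)[0]
    for c in res.comparisons:
        assert c.p_adjusted >= c.p_raw - 1e-15
        if c.p_adjusted < 0.001:
            assert c.label == "***"
        elif c.p_adjusted < 0.01:
            assert c.label == "**"
        elif c.p_adjusted < 0.05:
            assert c.label == "*"
        else:
            assert c.label == "ns"
        assert c.significant == (c.p_adjusted < cfg.alpha)


def test_paired_tests_and_fallback():
    rng = np.random.default_rng(5)
    base = rng.normal(0, 1, 8)
    expr = _expr({"A": list(base), "B": list(base + 0.5)}, pairs=True)
    cfg = StatsConfig(comparisons="all_to_one", paired=True)
    res = run_tests(expr, cfg)[0]
    assert res.comparisons[0].test_name == "paired t-test"
    p_paired = res.comparisons[0].p_raw
    # strong pairing: the paired test is far more sensitive than Welch
    p_welch = sps.ttest_ind(base, base + 0.5, equal_var=False).pvalue
    assert p_paired < p_welch

    broken = _expr({"A": list(base), "B": list(base + 0.5)}, pairs=False)
    with pytest.warns(UserWarning, match="incomplete Pairs"):
        res = run_tests(broken, cfg)[0]
    assert res.comparisons[0].test_name == "Welch t-test"


def test_dunnett_compares_all_to_first_group():
    rng = np.random.default_rng(6)
    expr = _expr(
        {"ref": list(rng.normal(0, 0.3, 6)), "t1": list(rng.normal(2, 0.3, 6)),
         "t2": list(rng.normal(0, 0.3, 6))}
    )
    cfg = StatsConfig(family="parametric", comparisons="all_to_one")
    res = run_tests(expr, cfg)[0]
    assert [(c.group_a, c.group_b) for c in res.comparisons] == [
        ("ref", "t1"), ("ref", "t2")
    ]
    assert res.comparisons[0].significant and not res.comparisons[1].significant
    assert res.comparisons[0].test_name.startswith("Dunnett")


def test_undersized_groups_dropped():
    expr = _expr({"A": [0.1, 0.2, 0.3], "B": [1.0], "C": [0.5, 0.9, 0.1]})
    cfg = StatsConfig(family="parametric", comparisons="all_pairs")
    res = run_tests(expr, cfg)[0]
    groups = {g for c in res.comparisons for g in (c.group_a, c.group_b)}
    assert groups == {"A", "C"}
    assert any("dropped" in n for n in res.notes)


def test_stats_table_layout():
    expr = _expr({"A": [0.0, 0.1, 0.2], "B": [1.0, 1.1, 1.2]})
    res = run_tests(expr, StatsConfig())
    table = stats_table(res)
    assert list(table.columns) == [
        "gene", "group_a", "group_b", "test", "p_raw", "p_adjusted",
        "significant", "label",
    ]
    assert len(table) == 1
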