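"""Automated group-comparison statistics on log-transformed expression.

All tests run on log2 normalized expression, never on linear values:
qPCR expression ratios are approximately log-normal, so parametric tests
are only defensible after the log transform.  The user chooses the broad
family (parametric / nonparametric) and the comparison mode; the concrete
test is then selected automatically:

====================  ==========================  ===========================
comparison            parametric                  nonparametric
====================  ==========================  ===========================
2 groups              Welch t (paired t)          Mann-Whitney U (Wilcoxon
                                                  signed-rank when paired)
>2, all to one        Dunnett many-to-one         Kruskal-Wallis + Dunn
                                                  (many-to-one), Holm
>2, all pairs         Tukey HSD                   Kruskal-Wallis + Dunn
                                                  (all pairs), Holm
>2, selected pairs    Welch t + Holm              Mann-Whitney + Holm
====================  ==========================  ===========================

Dunnett and Tukey p-values are already familywise-adjusted by
construction; everything else uses the Holm step-down adjustment.
Multiplicity is controlled within each gene, matching per-plot
annotation.  The Dunn post-hoc test (rank z statistics with tie
correction) is implemented here directly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quantify import ExpressionTable

__all__ = [
    "StatsConfig",
    "Comparison",
    "StatsResult",
    "TestPlan",
    "select_tests",
    "run_tests",
    "dunn_test",
    "stats_table",
]


@dataclass
class StatsConfig:
    family: str = "parametric"  # or "nonparametric"
    comparisons: str = "all_to_one"  # all_to_one | all_pairs | selected_pairs
    selected: list[tuple[str, str]] | None = None
    alpha: float = 0.05
    paired: bool = False
    label_style: str = "asterisks"  # or "p_values"

    def __post_init__(self) -> None:
        if self.family not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown test family {self.family!r}")
        if self.comparisons not in ("all_to_one", "all_pairs", "selected_pairs"):
            raise ValueError(f"unknown comparison mode {self.comparisons!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if (self.comparisons == "selected_pairs") != bool(self.selected):
            raise ValueError(
                "'selected' pairs must be given exactly when "
                "comparisons='selected_pairs'"
            )


@dataclass
class Comparison:
    group_a: str
    group_b: str
    test_name: str
    p_raw: float
    p_adjusted: float
    significant: bool
    label: str


@dataclass
class StatsResult:
    gene: str
    omnibus_test: tuple[str, float] | None
    comparisons: list[Comparison]
    notes: list[str] = field(default_factory=list)

    def test_names(self) -> list[str]:
        names = []
        if self.omnibus_test is not None:
            names.append(self.omnibus_test[0])
        for c in self.comparisons:
            if c.test_name not in names:
                names.append(c.test_name)
        return names


@dataclass
class TestPlan:
    omnibus: str | None
    pairwise: str
    adjustment: str


def select_tests(n_groups: int, cfg: StatsConfig) -> TestPlan:
    """Resolve the concrete tests for a group count and configuration."""
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if cfg.family == "parametric":
        if n_groups == 2:
            return TestPlan(None, "paired t-test" if cfg.paired else "Welch t-test", "none")
        if cfg.comparisons == "all_to_one":
            return TestPlan(None, "Dunnett many-to-one", "Dunnett")
        if cfg.comparisons == "all_pairs":
            return TestPlan(None, "Tukey HSD", "Tukey")
        return TestPlan(None, "Welch t-test", "Holm")
    if n_groups == 2:
        return TestPlan(
            None,
            "Wilcoxon signed-rank" if cfg.paired else "Mann-Whitney U",
            "none",
        )
    if cfg.comparisons == "selected_pairs":
        return TestPlan(None, "Mann-Whitney U", "Holm")
    return TestPlan("Kruskal-Wallis", "Dunn post-hoc", "Holm")


def _label(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    return "*" if p_adj < 0.05 else "ns"


def _degenerate(groups: list[np.ndarray]) -> bool:
    pooled = np.concatenate(groups)
    return bool(np.all(pooled == pooled[0]))


def dunn_test(
    groups: list[np.ndarray], pairs: list[tuple[int, int]]
) -> list[float]:
    """Raw two-sided p-values of Dunn's rank z test for the given pairs.

    Pooled ranks with the usual tie correction; ``pairs`` index into
    ``groups``.  Adjustment for multiplicity is the caller's business.
    """
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))
    ]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pvals = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        if se == 0:
            pvals.append(1.0)
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / se
        pvals.append(float(2.0 * sps.norm.sf(abs(z))))
    return pvals


def _paired_arrays(
    sub: pd.DataFrame, ga: str, gb: str
) -> tuple[np.ndarray, np.ndarray] | None:
    a = sub[sub["group"] == ga].set_index("pair_id")["value"]
    b = sub[sub["group"] == gb].set_index("pair_id")["value"]
    if a.index.hasnans or b.index.hasnans or (None in a.index) or (None in b.index):
        return None
    common = [p for p in a.index if p in b.index]
    if len(common) != len(a) or len(common) != len(b) or len(common) < 2:
        return None
    return a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)


def run_tests(expr: ExpressionTable, cfg: StatsConfig) -> list[StatsResult]:
    """Run the configured comparisons per gene on log2 expression."""
    results = []
    for gene in expr.genes:
        sub = expr.gene_values(gene, scale="log2")
        if sub.empty:
            warnings.warn(f"no expression values for {gene!r}; skipped", stacklevel=2)
            continue
        res = _run_gene(gene, sub, cfg)
        if res is not None:
            results.append(res)
    return results


def _run_gene(gene: str, sub: pd.DataFrame, cfg: StatsConfig) -> StatsResult | None:
    notes: list[str] = []
    group_order = list(dict.fromkeys(sub["group"]))
    sizes = sub.groupby("group", sort=False)["value"].size()
    small = [g for g in group_order if sizes[g] < 2]
    if small:
        notes.append(f"groups {small} dropped (<2 replicates)")
        group_order = [g for g in group_order if g not in small]
    if len(group_order) < 2:
        warnings.warn(
            f"{gene!r}: fewer than 2 usable groups; gene skipped", stacklevel=2
        )
        return None
    data = {
        g: sub.loc[sub["group"] == g, "value"].to_numpy(float)
        for g in group_order
    }
    if cfg.comparisons == "all_to_one":
        ref = group_order[0]
        pairs = [(ref, g) for g in group_order[1:]]
    elif cfg.comparisons == "all_pairs":
        pairs = list(itertools.combinations(group_order, 2))
    else:
        pairs = []
        for a, b in cfg.selected or []:
            if a in data and b in data:
                pairs.append((a, b))
            else:
                notes.append(f"selected pair ({a}, {b}) not available; skipped")
        if not pairs:
            warnings.warn(
                f"{gene!r}: no usable selected pairs; gene skipped", stacklevel=2
            )
            return None

    if _degenerate(list(data.values())):
        warnings.warn(
            f"{gene!r}: all values identical; degenerate data, p set to 1",
            stacklevel=2,
        )
        comps = [
            Comparison(a, b, "degenerate (constant data)", 1.0, 1.0, False, "ns")
            for a, b in pairs
        ]
        return StatsResult(gene, None, comps, notes)

    paired = cfg.paired
    if paired:
        for a, b in pairs:
            if _paired_arrays(sub, a, b) is None:
                paired = False
                notes.append(
                    "incomplete Pairs column; fell back to unpaired tests"
                )
                warnings.warn(notes[-1] + f" for {gene!r}", stacklevel=2)
                break

    omnibus = None
    n_groups = len(group_order)
    if cfg.family == "parametric":
        if n_groups > 2 and cfg.comparisons == "all_to_one":
            ref = group_order[0]
            others = group_order[1:]
            dres = sps.dunnett(
                *[data[g] for g in others], control=data[ref]
            )
            p_adj = np.asarray(dres.pvalue, float)
            comps = _build(pairs, p_adj, p_adj, "Dunnett many-to-one t-test", cfg.alpha)
        elif n_groups > 2 and cfg.comparisons == "all_pairs":
            tres = sps.tukey_hsd(*[data[g] for g in group_order])
            gi = {g: i for i, g in enumerate(group_order)}
            p_adj = np.array([tres.pvalue[gi[a], gi[b]] for a, b in pairs])
            comps = _build(pairs, p_adj, p_adj, "Tukey HSD", cfg.alpha)
        else:
            name = "paired t-test" if paired else "Welch t-test"
            p_raw = []
            for a, b in pairs:
                if paired:
                    xa, xb = _paired_arrays(sub, a, b)
                    p = sps.ttest_rel(xa, xb).pvalue
                else:
                    p = sps.ttest_ind(data[a], data[b], equal_var=False).pvalue
                p_raw.append(_clean_p(p))
            p_adj = _holm(p_raw)
            comps = _build(pairs, p_raw, p_adj, name, cfg.alpha)
    else:
        if n_groups > 2 and cfg.comparisons in ("all_to_one", "all_pairs"):
            kw = sps.kruskal(*[data[g] for g in group_order])
            omnibus = ("Kruskal-Wallis", float(kw.pvalue))
            gi = {g: i for i, g in enumerate(group_order)}
            p_raw = dunn_test(
                [data[g] for g in group_order],
                [(gi[a], gi[b]) for a, b in pairs],
            )
            p_adj = _holm(p_raw)
            comps = _build(pairs, p_raw, p_adj, "Dunn post-hoc test", cfg.alpha)
        else:
            name = "Wilcoxon signed-rank test" if paired else "Mann-Whitney U test"
            p_raw = []
            for a, b in pairs:
                if paired:
                    xa, xb = _paired_arrays(sub, a, b)
                    diffs = xa - xb
                    if np.all(diffs == 0):
                        p = 1.0
                    else:
                        p = sps.wilcoxon(xa, xb).pvalue
                else:
                    p = sps.mannwhitneyu(
                        data[a], data[b], alternative="two-sided"
                    ).pvalue
                p_raw.append(_clean_p(p))
            p_adj = _holm(p_raw)
            comps = _build(pairs, p_raw, p_adj, name, cfg.alpha)
    return StatsResult(gene, omnibus, comps, notes)


def _clean_p(p: float) -> float:
    return 1.0 if np.isnan(p) else float(min(max(p, 0.0), 1.0))


def _holm(p_raw) -> np.ndarray:
    p_raw = np.asarray(p_raw, float)
    if len(p_raw) == 1:
        return p_raw.copy()
    return multipletests(p_raw, method="holm")[1]


def _build(pairs, p_raw, p_adj, name, alpha) -> list[Comparison]:
    out = []
    for (a, b), pr, pa in zip(pairs, np.asarray(p_raw, float), np.asarray(p_adj, float)):
        pa = _clean_p(pa)
        pr = _clean_p(pr)
        out.append(Comparison(a, b, name, pr, pa, bool(pa < alpha), _label(pa)))
    return out


def stats_table(results: list[StatsResult]) -> pd.DataFrame:
    """Flatten results to the exported CSV layout."""
    rows = []
    for r in results:
        for c in r.comparisons:
            rows.append(
                (r.gene, c.group_a, c.group_b, c.test_name, c.p_raw,
                 c.p_adjusted, c.significant, c.label)
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "group_a", "group_b", "test", "p_raw", "p_adjusted",
                 "significant", "label"],
    )
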