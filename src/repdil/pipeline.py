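"""End-to-end orchestration: Cq table -> fits -> expression -> statistics.

`analyze_cq_dataset` is the programmatic equivalent of the CLI's ``run``
command for raw Cq input; `analyze_precalc_dataset` covers precalculated
relative expression values.  Both return an :class:`AnalysisResult`
bundling everything the report module exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .curves import (
    AmpliconFit,
    CqCqFit,
    cqcq_fit,
    fit_collinear,
    fits_table,
    flag_outliers,
)
from .data_io import Dataset
from .imputation import ImputationReport, impute_reference_cq
from .quantify import (
    ExpressionTable,
    normalize_expression,
    passthrough_precalc,
    relative_quantities,
)
from .stats import StatsConfig, StatsResult, run_tests, stats_table

__all__ = ["AnalysisResult", "analyze_cq_dataset", "analyze_precalc_dataset"]


@dataclass
class AnalysisResult:
    expression: ExpressionTable
    fits: list[AmpliconFit] = field(default_factory=list)
    cqcq: list[CqCqFit] = field(default_factory=list)
    stats: list[StatsResult] = field(default_factory=list)
    imputation: ImputationReport | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {"expression": self.expression.data}
        if self.fits:
            out["fits"] = fits_table(self.fits)
        if self.stats:
            out["stats"] = stats_table(self.stats)
        return out


def _pairs_map(ds: Dataset) -> dict[tuple[str, str], str]:
    pairs = {}
    for _, row in ds.wells.drop_duplicates(["group", "replicate_id"]).iterrows():
        if row["pair_id"] is not None and not pd.isna(row["pair_id"]):
            pairs[(row["group"], row["replicate_id"])] = str(row["pair_id"])
    return pairs


def analyze_cq_dataset(
    ds: Dataset,
    impute: bool = False,
    impute_k: int = 5,
    seed: int = 0,
    outlier_threshold: float = 3.0,
    scaling_group: str | None = None,
    stats_config: StatsConfig | None = None,
) -> AnalysisResult:
    """Full dilution-replicate analysis of a cq-mode dataset."""
    if ds.mode != "cq":
        raise ValueError("analyze_cq_dataset requires a cq-mode dataset")
    imp_report = None
    if impute:
        ds, imp_report = impute_reference_cq(ds, k_donors=impute_k, seed=seed)
    fits = [
        flag_outliers(fit_collinear(ds, amp), threshold=outlier_threshold)
        for amp in ds.amplicons
    ]
    by_amp = {f.amplicon: f for f in fits}
    rq = {f.amplicon: relative_quantities(f) for f in fits}
    expr = normalize_expression(
        rq,
        reference_genes=ds.reference_genes,
        pairs=_pairs_map(ds),
        scaling_group=scaling_group,
    )
    cqcq = [
        cqcq_fit(by_amp[goi], by_amp[rg])
        for goi in ds.genes_of_interest
        for rg in ds.reference_genes
    ]
    stats = run_tests(expr, stats_config) if stats_config else []
    return AnalysisResult(
        expression=expr, fits=fits, cqcq=cqcq, stats=stats, imputation=imp_report
    )


def analyze_precalc_dataset(
    ds: Dataset, stats_config: StatsConfig | None = None
) -> AnalysisResult:
    """Statistics/plots pipeline for precalculated expression values."""
    expr = passthrough_precalc(ds)
    stats = run_tests(expr, stats_config) if stats_config else []
    return AnalysisResult(expression=expr, stats=stats)
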