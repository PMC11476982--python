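"""Relative quantification and multi-reference-gene normalization.

From the collinear fit of one amplicon, the relative template quantity of
replicate ``r`` against a reference replicate follows from the intercept
difference divided by the shared slope:

    log10(Q_r) = (a_ref - a_r) / b

(one extra cycle at efficiency 2 means half the template).  Normalized
expression of a gene of interest is its quantity divided by the geometric
mean of the reference-gene quantities of the same replicate — geometric,
not arithmetic, averaging is the appropriate way to combine reference
genes.  Finally all values of a gene are rescaled so that the geometric
mean over the scaling-reference group equals 1 (log2 mean 0); the choice
of scaling group moves every value by a common factor and leaves all
group contrasts unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import AmpliconFit
from .data_io import Dataset

__all__ = [
    "ExpressionTable",
    "relative_quantities",
    "normalize_expression",
    "passthrough_precalc",
]

RepKey = tuple[str, str]


@dataclass
class ExpressionTable:
    """Per-replicate normalized expression, linear and log2 scale.

    ``data`` columns: group, replicate_id, pair_id, gene, norm_expr,
    log2_norm_expr.
    """

    data: pd.DataFrame
    genes: list[str]
    scaling_reference: str | None = None
    rq: dict[str, dict[RepKey, float]] = field(default_factory=dict)

    def gene_values(self, gene: str, scale: str = "log2") -> pd.DataFrame:
        col = "log2_norm_expr" if scale == "log2" else "norm_expr"
        sub = self.data[self.data["gene"] == gene]
        return sub[["group", "replicate_id", "pair_id", col]].rename(
            columns={col: "value"}
        )


def relative_quantities(
    fit: AmpliconFit, reference_replicate: RepKey | None = None
) -> dict[RepKey, float]:
    """Relative quantity per replicate from intercept differences.

    ``reference_replicate`` defaults to the first fitted replicate and
    gets quantity 1; its choice only rescales all quantities by a common
    factor.
    """
    if reference_replicate is None:
        reference_replicate = next(iter(fit.intercepts_a))
    if reference_replicate not in fit.intercepts_a:
        raise ValueError(
            f"reference replicate {reference_replicate} not fitted for "
            f"{fit.amplicon!r}"
        )
    a_ref = fit.intercepts_a[reference_replicate]
    return {
        r: 10.0 ** ((a_ref - a_r) / fit.slope_b)
        for r, a_r in fit.intercepts_a.items()
    }


def _geomean(values) -> float:
    arr = np.asarray(list(values), float)
    return float(np.exp(np.mean(np.log(arr))))


def normalize_expression(
    rq_tables: dict[str, dict[RepKey, float]],
    reference_genes: list[str],
    pairs: dict[RepKey, str] | None = None,
    scaling_group: str | None = None,
) -> ExpressionTable:
    """Normalize gene-of-interest quantities against the reference genes.

    Per replicate the normalization factor is the geometric mean of its
    reference-gene quantities; normalized expression is then rescaled so
    the geometric mean of the scaling-reference group is 1 per gene.
    ``scaling_group`` defaults to the group of the first replicate seen.
    """
    if not reference_genes:
        raise ValueError("at least one reference gene is required")
    missing_rg = [g for g in reference_genes if g not in rq_tables]
    if missing_rg:
        raise ValueError(f"no quantities for reference genes {missing_rg}")
    gois = [a for a in rq_tables if a not in reference_genes]
    pairs = pairs or {}

    # replicate order: first appearance across reference-gene tables
    rep_order: dict[RepKey, None] = {}
    for g in reference_genes:
        for k in rq_tables[g]:
            rep_order.setdefault(k, None)
    if scaling_group is None:
        scaling_group = next(iter(rep_order))[0]

    rows = []
    for gene in gois:
        per_rep = {}
        for key in rep_order:
            if key not in rq_tables[gene]:
                warnings.warn(
                    f"replicate {key} has no quantity for {gene!r}; "
                    "dropped from this gene",
                    stacklevel=2,
                )
                continue
            rg_qs = [
                rq_tables[g][key] for g in reference_genes if key in rq_tables[g]
            ]
            if not rg_qs:
                raise ValueError(
                    f"replicate {key} has no reference-gene quantity; "
                    "cannot normalize"
                )
            per_rep[key] = rq_tables[gene][key] / _geomean(rg_qs)
        ref_vals = [v for (grp, _), v in per_rep.items() if grp == scaling_group]
        if not ref_vals:
            raise ValueError(
                f"scaling-reference group {scaling_group!r} has no values "
                f"for {gene!r}"
            )
        scale = _geomean(ref_vals)
        for (grp, rep), v in per_rep.items():
            n = v / scale
            rows.append((grp, rep, pairs.get((grp, rep)), gene, n, math.log2(n)))
    data = pd.DataFrame(
        rows,
        columns=["group", "replicate_id", "pair_id", "gene", "norm_expr", "log2_norm_expr"],
    )
    return ExpressionTable(
        data=data, genes=gois, scaling_reference=scaling_group, rq=dict(rq_tables)
    )


def passthrough_precalc(ds: Dataset) -> ExpressionTable:
    """Wrap precalculated linear expression values as an ExpressionTable.

    Values are taken as given (no rescaling); only the log2 column is
    computed, so the same statistics and plots apply downstream.
    """
    if ds.mode != "precalculated":
        raise ValueError("passthrough_precalc requires precalculated mode")
    data = ds.wells.rename(columns={"amplicon": "gene", "expression": "norm_expr"})
    data = data[data["norm_expr"].notna()].copy()
    data["log2_norm_expr"] = np.log2(data["norm_expr"].to_numpy(float))
    data = data[
        ["group", "replicate_id", "pair_id", "gene", "norm_expr", "log2_norm_expr"]
    ].reset_index(drop=True)
    first_group = data["group"].iloc[0] if len(data) else None
    return ExpressionTable(
        data=data, genes=list(ds.amplicons), scaling_reference=first_group
    )
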