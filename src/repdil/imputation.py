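"""Weighted predictive-mean-matching imputation of reference-gene Cq values.

For every missing reference-gene cell the observed Cq values of that
amplicon are regressed (OLS) on the predictors available in the same
plate row — log10 of the dilution factor plus the Cq values of all other
amplicons.  The missing cell's Cq is predicted, the ``k_donors`` observed
rows with the closest predictions form the donor pool, one donor is drawn
with probability proportional to the inverse prediction distance, and the
donor's *observed* Cq is imputed.  Imputed values therefore never leave
the observed Cq range of the amplicon.

This is single imputation: one completed dataset is returned and fed to
the curve fits.  Genes of interest are never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import Dataset

__all__ = ["ImputationReport", "InsufficientDonorsError", "impute_reference_cq"]

#: Refuse imputation when a reference-gene column is missing more than this.
HARD_MISSING_LIMIT = 0.5
#: Warn when a reference-gene column is missing more than this.
WARN_MISSING_LIMIT = 0.3


class InsufficientDonorsError(ValueError):
    """Too few observed rows to form a donor pool for an amplicon."""


@dataclass
class ImputationReport:
    # (group, replicate, dilution, amplicon, imputed_cq, donor_count)
    imputed_cells: list[tuple] = field(default_factory=list)
    fraction_missing_before: dict[str, float] = field(default_factory=dict)


def _wide(ds: Dataset) -> pd.DataFrame:
    w = ds.wells.copy()
    w["pair_id"] = w["pair_id"].map(lambda p: "" if p is None or pd.isna(p) else str(p))
    wide = w.pivot(
        index=["group", "replicate_id", "pair_id", "dilution"],
        columns="amplicon",
        values="cq",
    ).reset_index()
    wide.columns.name = None
    return wide


def impute_reference_cq(
    ds: Dataset, k_donors: int = 5, seed: int = 0
) -> tuple[Dataset, ImputationReport]:
    """Impute missing reference-gene Cq cells by weighted PMM.

    Deterministic for a fixed ``seed``.  Returns the completed dataset and
    a report of the imputed cells.  A reference-gene column missing more
    than 50% of its cells is refused outright; above 30% a warning is
    issued.  Datasets without missing reference-gene cells are returned
    unchanged.
    """
    if ds.mode != "cq":
        raise ValueError("imputation applies to cq-mode datasets only")
    report = ImputationReport()
    w = ds.wells
    is_rg = w["amplicon"].isin(ds.reference_genes)
    for rg in ds.reference_genes:
        col = w.loc[w["amplicon"] == rg, "cq"]
        report.fraction_missing_before[rg] = float(col.isna().mean())
    n_missing = int((is_rg & w["cq"].isna()).sum())
    if n_missing == 0:
        return ds, report
    for rg, frac in report.fraction_missing_before.items():
        if frac > HARD_MISSING_LIMIT:
            raise ValueError(
                f"reference gene {rg!r} is missing {frac:.0%} of its Cq "
                f"values (> {HARD_MISSING_LIMIT:.0%}); imputation of so many "
                "missing values would be unreliable — refusing"
            )
        if frac > WARN_MISSING_LIMIT:
            warnings.warn(
                f"reference gene {rg!r} is missing {frac:.0%} of its Cq "
                "values; imputed results may be unreliable",
                stacklevel=2,
            )

    rng = np.random.default_rng(seed)
    wide = _wide(ds)
    wide["_logd"] = np.log10(wide["dilution"].to_numpy(float))
    filled: dict[tuple, float] = {}

    for rg in ds.reference_genes:
        target = wide[rg]
        observed = wide.index[target.notna()]
        missing = wide.index[target.isna()]
        if len(missing) == 0:
            continue
        if len(observed) < max(k_donors + 1, 5):
            raise InsufficientDonorsError(
                f"reference gene {rg!r} has only {len(observed)} observed "
                f"rows; need >= {max(k_donors + 1, 5)} to impute"
            )
        others = [a for a in ds.amplicons if a != rg]
        for i in sorted(missing):
            predictors = ["_logd"] + [
                a for a in others if pd.notna(wide.at[i, a])
            ]
            donors = [
                j
                for j in observed
                if all(pd.notna(wide.at[j, a]) for a in predictors)
            ]
            if len(donors) < k_donors:
                donors = list(observed)  # degrade to dilution-only predictor
                predictors = ["_logd"]
            x = wide.loc[donors, predictors].to_numpy(float)
            y = wide.loc[donors, rg].to_numpy(float)
            x1 = np.column_stack([np.ones(len(x)), x])
            beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
            yhat_donors = x1 @ beta
            x_rec = np.concatenate(
                [[1.0], wide.loc[i, predictors].to_numpy(float)]
            )
            yhat_rec = float(x_rec @ beta)
            dist = np.abs(yhat_donors - yhat_rec)
            pool = np.argsort(dist, kind="stable")[: min(k_donors, len(donors))]
            dpool = dist[pool]
            weights = 1.0 / np.maximum(dpool, 1e-12)
            weights /= weights.sum()
            choice = pool[rng.choice(len(pool), p=weights)]
            value = float(y[choice])
            key = (
                wide.at[i, "group"],
                wide.at[i, "replicate_id"],
                float(wide.at[i, "dilution"]),
                rg,
            )
            filled[key] = value
            report.imputed_cells.append((*key, value, len(pool)))

    new_wells = w.copy()
    for (group, rep, dil, amp), value in filled.items():
        sel = (
            (new_wells["group"] == group)
            & (new_wells["replicate_id"] == rep)
            & (new_wells["dilution"] == dil)
            & (new_wells["amplicon"] == amp)
        )
        new_wells.loc[sel, "cq"] = value
    out = Dataset(
        wells=new_wells,
        amplicons=ds.amplicons,
        reference_genes=ds.reference_genes,
        mode=ds.mode,
        pairs_present=ds.pairs_present,
    )
    return out, report
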