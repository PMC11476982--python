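"""Collinear standard-curve fitting and efficiency estimation.

In the dilution-replicate design every biological replicate is run as a
short serial-dilution series (e.g. factors 1, 5, 25) and all series of
one amplicon are fit jointly by ordinary least squares with a single
shared slope and one intercept per replicate:

    Cq_{r,d} = a_r + b * log10(D_d) + eps

The shared slope ``b`` (cycles per log10 dilution) yields the
amplification efficiency ``E = 10^(1/b)``; because the model regresses
Cq on the dilution *factor* (larger = more dilute) the slope is positive,
whereas the classical standard-curve convention regresses Cq on log10
*concentration* and reports ``E = 10^(-1/slope)`` — the two agree exactly
(see :func:`classical_efficiency`).

Intercept differences between replicates encode their relative template
quantities and feed the quantification step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .data_io import Dataset, _fit_eligible_replicates

__all__ = [
    "AmpliconFit",
    "CqCqFit",
    "fit_collinear",
    "flag_outliers",
    "refit_without_outliers",
    "cqcq_fit",
    "classical_efficiency",
    "fits_table",
]

RepKey = tuple[str, str]

#: Advisory efficiency sanity bounds; values outside trigger a warning only.
E_WARN_LOW = 1.6
E_WARN_HIGH = 2.1


@dataclass
class AmpliconFit:
    """Result of the shared-slope least-squares fit for one amplicon."""

    amplicon: str
    slope_b: float  # cycles per log10(dilution factor), > 0
    intercepts_a: dict[RepKey, float]  # Cq at dilution factor 1
    efficiency_E: float  # 10 ** (1 / slope_b)
    r_squared: float
    slope_se: float
    residuals: pd.Series  # indexed like `wells`
    wells: pd.DataFrame = field(repr=False)  # wells used in the fit
    outlier_flags: pd.Series | None = field(default=None, repr=False)
    n_wells_used: int = 0
    _sm_results: object = field(default=None, repr=False, compare=False)

    @property
    def replicates(self) -> list[RepKey]:
        return list(self.intercepts_a)


@dataclass
class CqCqFit:
    """Line parameters of the diagnostic Cq(GOI)-vs-Cq(RG) plot."""

    goi: str
    rg: str
    slope_ratio: float  # slope_b(goi) / slope_b(rg)
    offsets: dict[RepKey, float]  # vertical offset per replicate, cycles


def _design_matrix(
    sub: pd.DataFrame, reps: list[RepKey]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Indicator-coded design: one intercept column per replicate + log10(D)."""
    key = list(zip(sub["group"], sub["replicate_id"]))
    idx = {k: j for j, k in enumerate(reps)}
    n, p = len(sub), len(reps) + 1
    x = np.zeros((n, p))
    for i, k in enumerate(key):
        x[i, idx[k]] = 1.0
    x[:, -1] = np.log10(sub["dilution"].to_numpy(float))
    names = [f"rep[{g}_{r}]" for g, r in reps] + ["log10_dilution"]
    return x, sub["cq"].to_numpy(float), names


def fit_collinear(ds: Dataset, amplicon: str) -> AmpliconFit:
    """Fit the collinear dilution-replicate standard curve for one amplicon.

    Uses all wells of the amplicon belonging to fit-eligible replicates
    (>= 2 distinct dilutions with observed Cq).  Returns the shared slope,
    per-replicate intercepts, the efficiency ``E = 10^(1/b)``, the
    centered R-squared, the slope standard error, and per-well residuals.
    """
    if amplicon not in ds.amplicons:
        raise ValueError(f"unknown amplicon {amplicon!r}")
    eligible = _fit_eligible_replicates(ds, amplicon)
    if not eligible:
        raise ValueError(
            f"no fit-eligible replicate for {amplicon!r} "
            "(need >=2 distinct dilutions with observed Cq)"
        )
    w = ds.wells
    mask = (
        (w["amplicon"] == amplicon)
        & w["cq"].notna()
        & pd.Series(
            list(zip(w["group"], w["replicate_id"])), index=w.index
        ).isin(eligible)
    )
    sub = w.loc[mask]
    x, y, names = _design_matrix(sub, eligible)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"design matrix for {amplicon!r} is rank-deficient "
            "(e.g. only one dilution level present)"
        )
    res = sm.OLS(y, pd.DataFrame(x, index=sub.index, columns=names)).fit()
    slope = float(res.params.iloc[-1])
    if slope <= 0:
        warnings.warn(
            f"{amplicon}: fitted slope {slope:.3g} is not positive; "
            "Cq should rise with dilution",
            stacklevel=2,
        )
    efficiency = 10.0 ** (1.0 / slope)
    if not E_WARN_LOW <= efficiency <= E_WARN_HIGH:
        warnings.warn(
            f"{amplicon}: efficiency {efficiency:.3f} outside the usual "
            f"[{E_WARN_LOW}, {E_WARN_HIGH}] range",
            stacklevel=2,
        )
    ybar = y.mean()
    sst = float(((y - ybar) ** 2).sum())
    ssr = float((res.resid**2).sum())
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    intercepts = {k: float(res.params.iloc[j]) for j, k in enumerate(eligible)}
    return AmpliconFit(
        amplicon=amplicon,
        slope_b=slope,
        intercepts_a=intercepts,
        efficiency_E=efficiency,
        r_squared=r2,
        slope_se=float(res.bse.iloc[-1]),
        residuals=pd.Series(res.resid, index=sub.index),
        wells=sub,
        n_wells_used=len(sub),
        _sm_results=res,
    )


def flag_outliers(fit: AmpliconFit, threshold: float = 3.0) -> AmpliconFit:
    """Flag wells whose externally studentized residual exceeds ``threshold``.

    Flags are advisory: nothing is removed.  With fewer than 3 residual
    degrees of freedom no flagging is attempted.
    """
    res = fit._sm_results
    if res is None or res.df_resid < 3:
        warnings.warn(
            f"{fit.amplicon}: insufficient residual degrees of freedom for "
            "outlier detection; no wells flagged",
            stacklevel=2,
        )
        flags = pd.Series(False, index=fit.residuals.index)
        return replace(fit, outlier_flags=flags)
    if math.isinf(threshold):
        flags = pd.Series(False, index=fit.residuals.index)
        return replace(fit, outlier_flags=flags)
    student = res.get_influence().resid_studentized_external
    flags = pd.Series(np.abs(student) > threshold, index=fit.residuals.index)
    return replace(fit, outlier_flags=flags)


def refit_without_outliers(ds: Dataset, fit: AmpliconFit) -> AmpliconFit:
    """Refit once with flagged wells excluded (explicit request only)."""
    if fit.outlier_flags is None or not fit.outlier_flags.any():
        return fit
    keep = fit.outlier_flags.index[~fit.outlier_flags]
    trimmed = Dataset(
        wells=pd.concat(
            [
                ds.wells[ds.wells["amplicon"] != fit.amplicon],
                ds.wells.loc[keep],
            ]
        ).sort_index(),
        amplicons=ds.amplicons,
        reference_genes=ds.reference_genes,
        mode=ds.mode,
        pairs_present=ds.pairs_present,
    )
    return fit_collinear(trimmed, fit.amplicon)


def cqcq_fit(fit_goi: AmpliconFit, fit_rg: AmpliconFit) -> CqCqFit:
    """Derive the Cq-Cq diagnostic line from two collinear fits.

    Eliminating log10(D) between the two standard-curve equations gives
    Cq_goi = (b_goi/b_rg) * Cq_rg + (a_goi,r - (b_goi/b_rg) * a_rg,r)
    for each replicate r: a family of parallel lines whose slope is the
    ratio of amplification slopes.
    """
    common = [k for k in fit_goi.intercepts_a if k in fit_rg.intercepts_a]
    if not common:
        raise ValueError(
            f"no shared replicates between {fit_goi.amplicon!r} and "
            f"{fit_rg.amplicon!r}"
        )
    ratio = fit_goi.slope_b / fit_rg.slope_b
    offsets = {
        k: fit_goi.intercepts_a[k] - ratio * fit_rg.intercepts_a[k]
        for k in common
    }
    return CqCqFit(
        goi=fit_goi.amplicon, rg=fit_rg.amplicon, slope_ratio=ratio, offsets=offsets
    )


def classical_efficiency(dilution_series: list[tuple[float, float]]) -> float:
    """Efficiency from a classical standard curve: ``E = 10^(-1/slope)``.

    ``dilution_series`` holds (concentration, Cq) points; Cq is regressed
    on log10(concentration), whose slope is negative.  Comparison utility
    only — the main pipeline uses the collinear fit.
    """
    if len(dilution_series) < 3:
        raise ValueError("classical standard curve needs >= 3 points")
    conc, cq = np.asarray(dilution_series, float).T
    if len(np.unique(conc)) < 2:
        raise ValueError("concentrations must not all be identical")
    slope = sps.linregress(np.log10(conc), cq).slope
    return 10.0 ** (-1.0 / slope)


def fits_table(fits: list[AmpliconFit]) -> pd.DataFrame:
    """Per-amplicon summary table (slope, E, R^2, SE, n, outliers)."""
    return pd.DataFrame(
        {
            "amplicon": [f.amplicon for f in fits],
            "slope": [f.slope_b for f in fits],
            "efficiency": [f.efficiency_E for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "n_wells": [f.n_wells_used for f in fits],
            "n_outlier_flags": [
                0 if f.outlier_flags is None else int(f.outlier_flags.sum())
                for f in fits
            ],
        }
    )
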