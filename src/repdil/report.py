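"""Publication-style expression plots, diagnostic plots and file export.

Four plot types are offered per gene of interest — all-points dot plots,
dot plots with mean +/- SD, bar graphs with mean +/- SD and box plots —
in log2 or linear scale.  Significance bars are drawn above the groups
for significant comparisons (asterisk style) or for all tested
comparisons (p-value style), and the names of the statistical tests that
produced them are listed below the plot.  Means and SDs are computed on
the displayed scale; the tests behind the annotations always used the
log2 values.

Diagnostic plots show, per amplicon, the Cq-vs-log10(dilution) wells with
the fitted family of parallel standard curves (slope, efficiency and R^2
annotated, flagged outliers marked) and, per gene/reference pair, the
derived Cq-Cq lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages
from matplotlib.figure import Figure

from . import data_io
from .curves import AmpliconFit, CqCqFit
from .quantify import ExpressionTable
from .stats import StatsResult

__all__ = ["PlotConfig", "plot_expression", "plot_diagnostics", "export_all"]

PLOT_TYPES = ("dots_all", "dots_mean_sd", "bars_mean_sd", "box")


@dataclass
class PlotConfig:
    plot_type: str = "dots_all"
    scale: str = "log2"  # or "linear"
    font_size: float = 11.0
    palette: str = "Set2"
    significance_style: str = "asterisks"  # or "p_values"
    sig_bar_spacing: float = 0.08  # fraction of the value range per tier
    image_size: tuple[float, float] = (5.0, 4.0)
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.plot_type not in PLOT_TYPES:
            raise ValueError(f"unknown plot type {self.plot_type!r}")
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        for name in ("font_size", "sig_bar_spacing", "dpi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.image_size):
            raise ValueError("image_size must be positive")


def _group_positions(values: pd.DataFrame) -> tuple[list[str], dict[str, int]]:
    groups = list(dict.fromkeys(values["group"]))
    return groups, {g: i for i, g in enumerate(groups)}


def plot_expression(
    expr: ExpressionTable,
    stats: list[StatsResult] | None,
    cfg: PlotConfig,
) -> dict[str, Figure]:
    """One figure per gene of interest, with significance annotations."""
    by_gene = {r.gene: r for r in stats} if stats else {}
    figures: dict[str, Figure] = {}
    for gene in expr.genes:
        values = expr.gene_values(gene, scale=cfg.scale)
        if values.empty:
            continue
        figures[gene] = _plot_gene(gene, values, by_gene.get(gene), cfg, expr)
    return figures


def _plot_gene(
    gene: str,
    values: pd.DataFrame,
    result: StatsResult | None,
    cfg: PlotConfig,
    expr: ExpressionTable,
) -> Figure:
    plt.rcParams.update({"font.size": cfg.font_size})
    fig, ax = plt.subplots(figsize=cfg.image_size)
    groups, pos = _group_positions(values)
    cmap = plt.get_cmap(cfg.palette)
    colors = [cmap(i % getattr(cmap, "N", 8)) for i in range(len(groups))]

    grouped = [values.loc[values["group"] == g, "value"].to_numpy(float) for g in groups]
    if cfg.plot_type == "box":
        ax.boxplot(grouped, positions=range(len(groups)), widths=0.6,
                   patch_artist=True)
    else:
        for i, (g, arr) in enumerate(zip(groups, grouped)):
            if cfg.plot_type in ("dots_mean_sd", "bars_mean_sd"):
                m, s = float(np.mean(arr)), float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
                if cfg.plot_type == "bars_mean_sd":
                    ax.bar(i, m, width=0.6, color=colors[i], alpha=0.8)
                else:
                    ax.plot(i, m, "o", color=colors[i], markersize=8)
                ax.errorbar(i, m, yerr=s, color="black", capsize=4, lw=1.2)
            else:  # dots_all: deterministic horizontal spread
                off = np.linspace(-0.18, 0.18, len(arr)) if len(arr) > 1 else [0.0]
                ax.plot(i + np.asarray(off), arr, "o", color=colors[i], alpha=0.85)

    ax.set_xticks(range(len(groups)))
    ax.set_xticklabels(groups, rotation=30, ha="right")
    unit = "log2 relative expression" if cfg.scale == "log2" else "relative expression"
    ax.set_ylabel(unit)
    ax.set_title(gene)

    caption = None
    if result is not None:
        _draw_significance(ax, result, pos, values, cfg)
        caption = "Statistical tests: " + ", ".join(result.test_names())
        if expr.scaling_reference:
            caption += f"; scaled to group {expr.scaling_reference!r}"
    if cfg.plot_type in ("dots_mean_sd", "bars_mean_sd"):
        note = f"error bars: SD of {unit}"
        caption = note if caption is None else caption + f"; {note}"
    if caption:
        fig.text(0.02, 0.01, caption, fontsize=max(cfg.font_size - 3, 5), wrap=True)
    fig.tight_layout(rect=(0, 0.05, 1, 1))
    return fig


def _draw_significance(ax, result: StatsResult, pos, values, cfg: PlotConfig) -> None:
    shown = [
        c for c in result.comparisons
        if (cfg.significance_style == "p_values" or c.significant)
        and c.group_a in pos and c.group_b in pos
    ]
    if not shown:
        return
    v = values["value"].to_numpy(float)
    top, span = float(np.max(v)), float(np.ptp(v)) or 1.0
    step = span * cfg.sig_bar_spacing
    for tier, c in enumerate(shown):
        y = top + step * (1.5 + tier)
        x1, x2 = sorted((pos[c.group_a], pos[c.group_b]))
        ax.plot([x1, x1, x2, x2], [y, y + step / 4, y + step / 4, y],
                color="black", lw=1.0)
        text = c.label if cfg.significance_style == "asterisks" else f"p={c.p_adjusted:.3g}"
        ax.text((x1 + x2) / 2, y + step / 3, text, ha="center",
                fontsize=max(cfg.font_size - 2, 6))
    ax.set_ylim(top=top + step * (len(shown) + 3))


def plot_diagnostics(
    fits: list[AmpliconFit], cqcq: list[CqCqFit] | None = None
) -> dict[str, Figure]:
    """Standard-curve and Cq-Cq diagnostic figures keyed by name."""
    figures: dict[str, Figure] = {}
    for fit in fits:
        fig, ax = plt.subplots(figsize=(5, 4))
        cmap = plt.get_cmap("tab10")
        logd = np.log10(fit.wells["dilution"].to_numpy(float))
        grid = np.linspace(logd.min(), logd.max(), 2)
        for i, (key, a) in enumerate(fit.intercepts_a.items()):
            sel = (
                (fit.wells["group"] == key[0])
                & (fit.wells["replicate_id"] == key[1])
            )
            pts = fit.wells[sel]
            color = cmap(i % 10)
            ax.plot(np.log10(pts["dilution"]), pts["cq"], "o", color=color,
                    label=f"{key[0]}_{key[1]}")
            ax.plot(grid, a + fit.slope_b * grid, "-", color=color, lw=1)
        if fit.outlier_flags is not None and fit.outlier_flags.any():
            out = fit.wells.loc[fit.outlier_flags[fit.outlier_flags].index]
            ax.plot(np.log10(out["dilution"]), out["cq"], "x", color="red",
                    markersize=12, mew=2, label="outlier")
        ax.set_xlabel("log10(dilution factor)")
        ax.set_ylabel("Cq")
        ax.set_title(
            f"{fit.amplicon}: slope={fit.slope_b:.3f}, "
            f"E={fit.efficiency_E:.3f}, R²={fit.r_squared:.4f}"
        )
        if len(fit.intercepts_a) <= 12:
            ax.legend(fontsize=6)
        fig.tight_layout()
        figures[f"curve_{fit.amplicon}"] = fig

    for cc in cqcq or []:
        fig, ax = plt.subplots(figsize=(5, 4))
        grid = np.linspace(0, 1, 2)
        for i, (key, off) in enumerate(cc.offsets.items()):
            ax.plot(grid, off + cc.slope_ratio * grid, "-",
                    color=plt.get_cmap("tab10")(i % 10), lw=1,
                    label=f"{key[0]}_{key[1]}")
        ax.set_xlabel(f"Cq({cc.rg})")
        ax.set_ylabel(f"Cq({cc.goi})")
        ax.set_title(f"{cc.goi} vs {cc.rg}: slope ratio={cc.slope_ratio:.4f}")
        if len(cc.offsets) <= 12:
            ax.legend(fontsize=6)
        fig.tight_layout()
        figures[f"cqcq_{cc.goi}_vs_{cc.rg}"] = fig
    return figures


def export_all(
    figures: dict[str, Figure],
    tables: dict[str, pd.DataFrame],
    outdir: str | Path,
    dataset_name: str,
    cfg: PlotConfig | None = None,
) -> list[Path]:
    """Write a multi-page PDF, per-gene PNGs and CSV tables.

    Filenames follow ``<dataset>_<plot_type>[_log].<ext>``; PNGs of one
    plot type live in a subdirectory of the same name.  PDF timestamps
    are suppressed so identical inputs yield identical bytes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = cfg or PlotConfig()
    suffix = f"_{cfg.plot_type}" + ("_log" if cfg.scale == "log2" else "")
    written: list[Path] = []

    if figures:
        pdf_path = outdir / f"{dataset_name}{suffix}.pdf"
        with PdfPages(pdf_path, metadata={"CreationDate": None}) as pdf:
            for fig in figures.values():
                pdf.savefig(fig)
        written.append(pdf_path)
        png_dir = outdir / f"{dataset_name}{suffix}_png"
        png_dir.mkdir(exist_ok=True)
        for name, fig in figures.items():
            p = png_dir / f"{dataset_name}_{name}{suffix}.png"
            fig.savefig(p, dpi=cfg.dpi)
            written.append(p)
    for name, table in tables.items():
        p = outdir / f"{dataset_name}_{name}.csv"
        data_io.write_table(table, p)
        written.append(p)
    return written
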