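"""Synthetic dilution-replicate qPCR datasets with known ground truth.

The generative model follows the exponential-amplification assumption
behind standard-curve qPCR analysis: a template present at relative
quantity ``Q`` and diluted by factor ``D`` crosses the fluorescence
threshold at

    Cq = baseline_cq - log10(Q)/log10(E) + log10(D)/log10(E) + eps,

where ``E`` is the per-cycle amplification efficiency (2 = perfect
doubling) and ``eps`` is i.i.d. Gaussian measurement noise on the cycle
scale.  With ``E = 2`` each halving of template costs exactly one cycle
and a fivefold dilution costs log2(5) ~ 2.32 cycles.

Missing values, when requested, are injected completely at random and
only into reference-gene cells, mirroring the scope of the downstream
imputation step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import Dataset

__all__ = ["GroundTruth", "make_ground_truth", "simulate"]

RepKey = tuple[str, str]


@dataclass
class GroundTruth:
    """Parameters of one simulated dilution-replicate experiment.

    ``quantities`` maps (group, replicate_id) -> amplicon -> true relative
    template quantity; ``efficiencies`` and ``baseline_cq`` are per
    amplicon.  ``reference_genes`` must be a prefix of ``amplicons``.
    """

    amplicons: list[str]
    reference_genes: list[str]
    efficiencies: dict[str, float]
    quantities: dict[RepKey, dict[str, float]]
    baseline_cq: dict[str, float]
    dilution_factors: list[float] = field(default_factory=lambda: [1.0, 5.0, 25.0])
    noise_sd: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    pairs: dict[RepKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for amp, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency of {amp!r} must be in (1, 2], got {e}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(d <= 0 for d in self.dilution_factors):
            raise ValueError("dilution factors must be positive")
        for qmap in self.quantities.values():
            if any(q <= 0 for q in qmap.values()):
                raise ValueError("true quantities must be positive")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["quantities"] = {f"{g}_{r}": v for (g, r), v in self.quantities.items()}
        d["pairs"] = {f"{g}_{r}": v for (g, r), v in self.pairs.items()}
        Path(path).write_text(json.dumps(d, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        from .data_io import split_replicate_name

        d["quantities"] = {
            split_replicate_name(k): v for k, v in d["quantities"].items()
        }
        d["pairs"] = {split_replicate_name(k): v for k, v in d["pairs"].items()}
        return cls(**d)


def make_ground_truth(
    group_quantities: dict[str, dict[str, float]],
    n_replicates: int = 3,
    efficiencies: dict[str, float] | None = None,
    reference_genes: list[str] | None = None,
    baseline_cq: float | dict[str, float] = 20.0,
    dilution_factors: list[float] = (1.0, 5.0, 25.0),
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    paired: bool = False,
) -> GroundTruth:
    """Build a :class:`GroundTruth` for a balanced one-factor design.

    ``group_quantities`` maps group name -> amplicon -> true quantity;
    every group gets ``n_replicates`` biological replicates with that
    quantity.  The amplicon order is taken from the first group's map;
    reference genes default to the single first amplicon.
    """
    amplicons = list(next(iter(group_quantities.values())))
    if reference_genes is None:
        reference_genes = [amplicons[0]]
    if efficiencies is None:
        efficiencies = {a: 2.0 for a in amplicons}
    if not isinstance(baseline_cq, dict):
        baseline_cq = {a: float(baseline_cq) for a in amplicons}
    quantities: dict[RepKey, dict[str, float]] = {}
    pairs: dict[RepKey, str] = {}
    for group, qmap in group_quantities.items():
        for i in range(1, n_replicates + 1):
            quantities[(group, str(i))] = dict(qmap)
            if paired:
                pairs[(group, str(i))] = str(i)
    return GroundTruth(
        amplicons=amplicons,
        reference_genes=list(reference_genes),
        efficiencies=dict(efficiencies),
        quantities=quantities,
        baseline_cq=baseline_cq,
        dilution_factors=list(dilution_factors),
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
        pairs=pairs,
    )


def simulate(gt: GroundTruth) -> tuple[Dataset, GroundTruth]:
    """Generate a cq-mode :class:`~repdil.data_io.Dataset` from ground truth.

    Deterministic for a fixed ``gt.seed``; noise and missingness are the
    only random elements.
    """
    rng = np.random.default_rng(gt.seed)
    rows = []
    for (group, rep), qmap in gt.quantities.items():
        pair = gt.pairs.get((group, rep))
        for d in gt.dilution_factors:
            for amp in gt.amplicons:
                e = gt.efficiencies[amp]
                q = qmap[amp]
                cq = (
                    gt.baseline_cq[amp]
                    - math.log10(q) / math.log10(e)
                    + math.log10(d) / math.log10(e)
                )
                rows.append((group, rep, pair, float(d), amp, cq))
    wells = pd.DataFrame(
        rows,
        columns=["group", "replicate_id", "pair_id", "dilution", "amplicon", "cq"],
    )
    if gt.noise_sd > 0:
        wells["cq"] = wells["cq"] + rng.normal(0.0, gt.noise_sd, size=len(wells))
    if gt.missing_rate > 0:
        is_rg = wells["amplicon"].isin(gt.reference_genes).to_numpy()
        drop = rng.random(len(wells)) < gt.missing_rate
        wells.loc[is_rg & drop, "cq"] = np.nan
    # long format ordered by amplicon as the serialized header would be
    wells["amplicon"] = pd.Categorical(wells["amplicon"], categories=gt.amplicons)
    wells = wells.sort_values("amplicon", kind="stable").reset_index(drop=True)
    wells["amplicon"] = wells["amplicon"].astype(str)
    ds = Dataset(
        wells=wells,
        amplicons=list(gt.amplicons),
        reference_genes=list(gt.reference_genes),
        mode="cq",
        pairs_present=bool(gt.pairs),
    )
    return ds, gt
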