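"""Variant panels: consensus ΔΔG aggregation and curve comparison.

Stability-change predictors (sequence- or structure-based ΔΔG tools) are
external; their per-variant outputs arrive as a TSV and are aggregated here
into a consensus mean ± SD. The sign convention follows the stabilization
convention: positive ΔΔG = stabilizing, negative = destabilizing. The
consensus value anchors the variant's folding-energy curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from statistics import mean, stdev

import numpy as np
import pandas as pd

from .energetics import FoldingEnergyCurve, PhOptimum, ph_optimum
from .structures import VariantSpec


@dataclass(frozen=True)
class ConsensusDdg:
    """Consensus folding free-energy change for one substitution.

    ``variants`` is a tuple to accommodate multi-variant (haplotype)
    entries whose ΔΔG is the sum of the individual changes.
    """

    variants: tuple[VariantSpec, ...]
    values: tuple[float, ...]
    average: float
    sd: float
    predictors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values:
            avg, sd = consensus_ddg(self.values) if len(self.values) > 1 else (
                self.values[0], 0.0)
            if abs(avg - self.average) > 1e-9 or abs(sd - self.sd) > 1e-9:
                raise ValueError(
                    "stored average/SD inconsistent with the value list"
                )

    @property
    def label(self) -> str:
        return "+".join(str(v) for v in self.variants)


def consensus_ddg(values: list[float] | tuple[float, ...]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation of predictor ΔΔGs."""
    if len(values) < 2:
        raise ValueError("consensus needs at least two predictor values")
    return float(mean(values)), float(stdev(values))


def combine_variants(ddgs: list[ConsensusDdg]) -> float:
    """Total ΔΔG of a multi-variant: the sum of the individual averages."""
    if not ddgs:
        raise ValueError("need at least one variant")
    return float(sum(d.average for d in ddgs))


def read_predictor_table(
    path: str | Path, positive_stabilizing: bool = True
) -> dict[str, ConsensusDdg]:
    """Read a per-variant, per-predictor ΔΔG TSV (variant, predictor, ddg).

    ``positive_stabilizing=False`` flips the sign of files written in the
    opposite convention. Returns a mapping from variant label to consensus.
    """
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "predictor": str})
    required = {"variant", "predictor", "ddg"}
    if not required.issubset(df.columns):
        raise ValueError(f"predictor table needs columns {sorted(required)}")
    sign = 1.0 if positive_stabilizing else -1.0
    out: dict[str, ConsensusDdg] = {}
    for label, grp in df.groupby("variant", sort=False):
        values = tuple(sign * float(v) for v in grp["ddg"])
        specs = tuple(VariantSpec.parse(p) for p in label.split("+"))
        avg, sd = consensus_ddg(values) if len(values) > 1 else (values[0], 0.0)
        out[label] = ConsensusDdg(
            specs, values, avg, sd, tuple(grp["predictor"])
        )
    return out


def write_consensus_tsv(consensus: dict[str, ConsensusDdg], path: str | Path) -> None:
    rows = [
        {
            "variant": c.label,
            "avg_ddg": c.average,
            "sd": c.sd,
            "n_predictors": len(c.values),
        }
        for c in consensus.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.4g")


def load_reference_consensus() -> pd.DataFrame:
    """Published consensus predictor averages for pigmentation-protein
    variants (protein, variant, avg_ddg, sd), bundled with the package."""
    with resources.files("phfold.data").joinpath(
        "melanosome_variant_ddg.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


# --- curve comparison ---------------------------------------------------

#: |ΔpH optimum| at or below which two curves count as "unshifted"
UNSHIFTED_THRESHOLD = 0.2


@dataclass(frozen=True)
class CurveComparison:
    """Wild-type vs. variant folding-energy curve comparison."""

    delta_ph_optimum: float
    wt_optimum: PhOptimum
    variant_optimum: PhOptimum
    difference: np.ndarray  # variant − wild type, per grid point
    shift_label: str  # optimum shifted acidic / shifted basic / unshifted
    destabilized_at_neutral: bool


def compare_curves(
    wild_type: FoldingEnergyCurve, variant: FoldingEnergyCurve
) -> CurveComparison:
    """Compare curves on a shared grid: optimum shift and pointwise change.

    ``destabilized_at_neutral`` is True when the variant's ΔΔG at pH 7 (or
    the nearest grid point) lies above the wild type's.
    """
    if wild_type.grid != variant.grid:
        raise ValueError("curves must share the pH grid")
    wt_opt = ph_optimum(wild_type)
    var_opt = ph_optimum(variant)
    dopt = var_opt.ph - wt_opt.ph
    if abs(dopt) <= UNSHIFTED_THRESHOLD:
        label = "unshifted"
    elif dopt < 0:
        label = "optimum shifted acidic"
    else:
        label = "optimum shifted basic"
    ph = wild_type.grid.values
    k7 = int(np.argmin(np.abs(ph - 7.0)))
    return CurveComparison(
        delta_ph_optimum=float(dopt),
        wt_optimum=wt_opt,
        variant_optimum=var_opt,
        difference=variant.ddg - wild_type.ddg,
        shift_label=label,
        destabilized_at_neutral=bool(variant.ddg[k7] > wild_type.ddg[k7]),
    )
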