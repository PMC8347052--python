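"""pH dependence of the folding free energy (Wyman linkage).

The proton-linkage relation ties the pH derivative of the folding free
energy to the difference in protons bound between folded and unfolded
states. With Δq(pH) = Q_folded − Q_unfolded the pH-dependent part of the
folding free energy is

    ΔΔG(pH) = ln(10) · kT · ∫_{pH0}^{pH} Δq dpH + constant,

more negative meaning more stable. The constant anchors the curve at the
start of the pH window: zero for a wild-type protein (no absolute folding
free energies are available) and a predicted mutational ΔΔG for variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .constants import CLASS_GROUPS, DEFAULT_KT, LN10
from .titration import PhGrid, TitrationResult


@dataclass
class ChargeDifference:
    """Folded-minus-unfolded net charge on a shared pH grid.

    ``per_site`` (n_pH, n_sites) is retained so the free energy can be
    decomposed by residue class.
    """

    grid: PhGrid
    dq: np.ndarray
    per_site: np.ndarray | None = None
    site_classes: list[str] | None = None

    def __post_init__(self) -> None:
        self.dq = np.asarray(self.dq, dtype=float)
        if self.dq.shape != (len(self.grid),):
            raise ValueError("dq length does not match the grid")


@dataclass
class FoldingEnergyCurve:
    """ΔΔG_folding(pH) in kcal/mol, anchored at the grid's start pH."""

    grid: PhGrid
    ddg: np.ndarray
    constant: float
    kT: float
    provenance: dict = field(default_factory=dict)
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ddg = np.asarray(self.ddg, dtype=float)
        if self.ddg.shape != (len(self.grid),):
            raise ValueError("ddg length does not match the grid")
        if not np.all(np.isfinite(self.ddg)):
            raise ValueError("ddg must be finite")

    def to_frame(self) -> pd.DataFrame:
        cols = {"pH": self.grid.values, "ddG_kcal_mol": self.ddg}
        if self.sd is not None:
            cols["sd"] = self.sd
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def charge_difference(
    folded: TitrationResult, unfolded: TitrationResult
) -> ChargeDifference:
    """Pointwise Q_folded − Q_unfolded; grids and site sets must match."""
    if folded.grid != unfolded.grid:
        raise ValueError("folded and unfolded grids differ")
    if folded.site_ids != unfolded.site_ids:
        raise ValueError("folded and unfolded site inventories differ")
    per_site = folded.q - unfolded.q
    return ChargeDifference(
        folded.grid,
        per_site.sum(axis=1) if per_site.size else np.zeros(len(folded.grid)),
        per_site=per_site,
        site_classes=[s.site_class for s in folded.sites],
    )


def _integrate(dq: np.ndarray, grid: PhGrid, kT: float, method: str) -> np.ndarray:
    if method == "trapezoid":
        inner = cumulative_trapezoid(dq, dx=grid.step, initial=0.0)
    elif method == "rectangle":
        # left-Riemann sum, literal reading of "sum of Δq·dpH"
        inner = np.concatenate(([0.0], np.cumsum(dq[:-1]) * grid.step))
    else:
        raise ValueError(f"unknown integration method {method!r}")
    return LN10 * kT * inner


def folding_energy(
    delta: ChargeDifference,
    kT: float = DEFAULT_KT,
    constant: float = 0.0,
    method: str = "trapezoid",
    provenance: dict | None = None,
) -> FoldingEnergyCurve:
    """Integrate Δq over pH into ΔΔG_folding (anchored at the start pH)."""
    ddg = _integrate(delta.dq, delta.grid, kT, method) + constant
    return FoldingEnergyCurve(
        delta.grid, ddg, constant, kT, provenance=dict(provenance or {})
    )


@dataclass(frozen=True)
class PhOptimum:
    """pH of maximal stability (minimal ΔΔG) with a boundary flag."""

    ph: float
    ddg: float
    boundary: str | None = None  # "<=start" / ">=end" when on the grid edge

    @property
    def interior(self) -> bool:
        return self.boundary is None


def ph_optimum(curve: FoldingEnergyCurve) -> PhOptimum:
    """Grid pH minimising ΔΔG; ties break toward the lowest pH."""
    k = int(np.argmin(curve.ddg))  # argmin returns the first minimum
    ph = curve.grid.values
    boundary = None
    if k == 0:
        boundary = "<=start"
    elif k == len(ph) - 1:
        boundary = ">=end"
    return PhOptimum(float(ph[k]), float(curve.ddg[k]), boundary)


def class_decomposition(
    folded: TitrationResult,
    unfolded: TitrationResult,
    kT: float = DEFAULT_KT,
    method: str = "trapezoid",
) -> dict[str, FoldingEnergyCurve]:
    """Per-residue-class ΔΔG curves (constant 0) that sum to the total.

    Classes are grouped as acidic (Asp/Glu/Cys/Tyr/C-term), His, and basic
    (Lys/Arg/N-term); each site's Δq_i is integrated separately and summed
    within its group.
    """
    delta = charge_difference(folded, unfolded)
    out: dict[str, FoldingEnergyCurve] = {}
    for group, members in CLASS_GROUPS.items():
        if delta.per_site is not None and delta.per_site.size:
            mask = np.array([c in members for c in delta.site_classes])
            dq = delta.per_site[:, mask].sum(axis=1)
        else:
            dq = np.zeros(len(delta.grid))
        out[group] = FoldingEnergyCurve(
            delta.grid,
            _integrate(dq, delta.grid, kT, method),
            0.0,
            kT,
            provenance={"class_group": group},
        )
    return out


# --- ensemble averaging -------------------------------------------------


def average_titrations(members: Sequence[TitrationResult]) -> tuple[TitrationResult, np.ndarray]:
    """Snapshot-average titration: pointwise mean theta, plus the SD of Q.

    Averaging is done on the charge curves before any integration, matching
    a protocol that averages net charge over structural snapshots. Returns
    (averaged result, per-pH standard deviation of Q).
    """
    if not members:
        raise ValueError("need at least one member")
    first = members[0]
    for m in members[1:]:
        if m.grid != first.grid:
            raise ValueError("ensemble members must share the pH grid")
        if m.site_ids != first.site_ids:
            raise ValueError("ensemble members must share the site inventory")
    theta = np.mean([m.theta for m in members], axis=0)
    q_sd = np.std([m.Q for m in members], axis=0, ddof=0)
    avg = TitrationResult(
        first.grid, list(first.sites), theta, first.state,
        solver=f"ensemble({first.solver})x{len(members)}",
    )
    return avg, q_sd


def average_curves(members: Sequence[FoldingEnergyCurve]) -> FoldingEnergyCurve:
    """Pointwise mean and SD of energy curves sharing a grid."""
    if not members:
        raise ValueError("need at least one member")
    first = members[0]
    for m in members[1:]:
        if m.grid != first.grid:
            raise ValueError("ensemble members must share the pH grid")
    ddg = np.mean([m.ddg for m in members], axis=0)
    sd = np.std([m.ddg for m in members], axis=0, ddof=0)
    return FoldingEnergyCurve(
        first.grid, ddg, float(np.mean([m.constant for m in members])),
        first.kT, provenance={"ensemble_size": len(members)}, sd=sd,
    )
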