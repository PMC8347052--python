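"""Protonation equilibria of interacting titratable sites.

The folded state is modelled as N two-state sites with intrinsic pKas and a
pairwise screened-Coulomb coupling matrix W (kcal/mol between unit charges).
The microstate free energy, in units of kT, is

    G(x)/kT = ln10 * sum_i x_i (pH - pKa_int,i)
              + (1/kT) * sum_{i<j} W_ij q_i(x_i) q_j(x_j)

with protonation indicators x_i in {0,1} and site charges
q_i = q_deprot,i + x_i (acids: -1/0, bases: 0/+1). Three solvers are
provided: exact enumeration over the 2^N microstates (the reference
oracle), a damped self-consistent mean field, and single-flip Metropolis
Monte Carlo. The unfolded state is treated as independent sites at
unperturbed model pKas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import softmax

from .constants import (
    CLASH_FLOOR_A,
    COULOMB_KCAL_A,
    DEFAULT_IONIC_STRENGTH,
    DEFAULT_KT,
    DEFAULT_T,
    ENUMERATION_CAP,
    LN10,
    debye_kappa,
)
from .structures import TitratableSite


@dataclass(frozen=True)
class PhGrid:
    """Uniform inclusive pH grid."""

    start: float = 4.0
    end: float = 8.0
    step: float = 0.1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("grid start must be below end")
        if self.step <= 0:
            raise ValueError("grid step must be positive")
        n = (self.end - self.start) / self.step
        if abs(n - round(n)) > 1e-8:
            raise ValueError("(end - start) / step must be an integer")

    @property
    def n_points(self) -> int:
        return round((self.end - self.start) / self.step) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)

    def __len__(self) -> int:
        return self.n_points


@dataclass
class TitrationResult:
    """Per-site protonation probabilities and net charge on a pH grid.

    ``theta`` and ``q`` have shape (n_pH, n_sites); ``Q`` is their row sum
    of charges. ``converged`` flags each grid point (always True for the
    exact and independent solvers). ``theta_se`` holds MC standard errors.
    """

    grid: PhGrid
    sites: list[TitratableSite]
    theta: np.ndarray
    state: str
    solver: str
    converged: np.ndarray = field(default=None)  # type: ignore[assignment]
    theta_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (len(self.grid), len(self.sites)):
            raise ValueError(
                f"theta shape {self.theta.shape} != "
                f"({len(self.grid)}, {len(self.sites)})"
            )
        if self.converged is None:
            self.converged = np.ones(len(self.grid), dtype=bool)

    @property
    def q(self) -> np.ndarray:
        q_dep = np.array([s.q_deprotonated for s in self.sites], dtype=float)
        return q_dep[None, :] + self.theta

    @property
    def Q(self) -> np.ndarray:
        if not self.sites:
            return np.zeros(len(self.grid))
        return self.q.sum(axis=1)

    @property
    def site_ids(self) -> list[tuple[str, int, str]]:
        return [s.site_id for s in self.sites]

    def site_index(self, site_id: tuple[str, int, str]) -> int:
        try:
            return self.site_ids.index(tuple(site_id))
        except ValueError:
            raise KeyError(f"site {site_id} not in result") from None

    def to_frame(self) -> pd.DataFrame:
        cols = {"pH": self.grid.values, "Q": self.Q}
        for k, s in enumerate(self.sites):
            cols[f"theta_{s.chain}_{s.resnum}_{s.resname}"] = self.theta[:, k]
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


# --- coupling matrix ----------------------------------------------------


def interaction_matrix(
    sites: list[TitratableSite],
    dielectric: float,
    ionic_strength: float = DEFAULT_IONIC_STRENGTH,
    temperature: float = DEFAULT_T,
    clash_floor: float = CLASH_FLOOR_A,
) -> np.ndarray:
    """Screened-Coulomb coupling between unit charges, in kcal/mol.

    W_ij = 332.0636 / (eps * r_ij) * exp(-kappa * r_ij), r_ij in Å, with
    kappa = 0 at zero ionic strength. Distances below ``clash_floor`` are
    clamped upward; exactly coincident centers are an error.
    """
    if not sites:
        raise ValueError("need at least one site")
    coords = np.array([s.center for s in sites], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    n = len(sites)
    coincident = np.argwhere((r < 1e-9) & ~np.eye(n, dtype=bool))
    if coincident.size:
        i, j = coincident[0]
        raise ValueError(
            f"coincident charge centers: {sites[i].site_id} and {sites[j].site_id}"
        )
    r_eff = np.maximum(r, clash_floor)
    kappa = debye_kappa(ionic_strength, dielectric, temperature)
    with np.errstate(divide="ignore"):
        W = COULOMB_KCAL_A / (dielectric * r_eff) * np.exp(-kappa * r_eff)
    np.fill_diagonal(W, 0.0)
    return W


def _check_W(sites: list[TitratableSite], W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    n = len(sites)
    if W.shape != (n, n):
        raise ValueError(f"W shape {W.shape} does not match {n} sites")
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if not np.all(np.isfinite(W)):
        raise ValueError("W must be finite")
    return W


# --- solvers ------------------------------------------------------------


def _site_arrays(sites: list[TitratableSite]):
    pk = np.array([s.intrinsic_pka for s in sites], dtype=float)
    q_dep = np.array([s.q_deprotonated for s in sites], dtype=float)
    return pk, q_dep


def _independent_theta(pk: np.ndarray, ph: np.ndarray) -> np.ndarray:
    """Henderson–Hasselbalch protonation probability, shape (n_pH, n)."""
    return 1.0 / (1.0 + 10.0 ** (ph[:, None] - pk[None, :]))


def enumerate_titration(
    sites: list[TitratableSite],
    W: np.ndarray,
    grid: PhGrid,
    kT: float = DEFAULT_KT,
    state: str = "folded",
) -> TitrationResult:
    """Exact Boltzmann average over all 2^N protonation microstates."""
    n = len(sites)
    if n == 0:
        return TitrationResult(grid, [], np.zeros((len(grid), 0)), state, "enumerate")
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"{n} sites exceeds the enumeration cap ({ENUMERATION_CAP}); "
            "use meanfield_titration or mc_titration"
        )
    W = _check_W(sites, W)
    pk, q_dep = _site_arrays(sites)

    states = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1  # (S, n)
    q_states = states + q_dep[None, :]
    e_coup = 0.5 * np.einsum("si,ij,sj->s", q_states, W, q_states)  # kcal/mol
    ph = grid.values
    # -G/kT per state and pH
    logw = (
        -LN10 * (states.sum(axis=1)[:, None] * ph[None, :]
                 - (states @ pk)[:, None])
        - (e_coup / kT)[:, None]
    )
    w = softmax(logw, axis=0)  # (S, n_pH)
    theta = np.einsum("sp,si->pi", w, states)
    return TitrationResult(grid, list(sites), theta, state, "enumerate")


def meanfield_titration(
    sites: list[TitratableSite],
    W: np.ndarray,
    grid: PhGrid,
    kT: float = DEFAULT_KT,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    damping: float = 0.5,
    state: str = "folded",
) -> TitrationResult:
    """Self-consistent mean-field titration, swept from low to high pH.

    Each site sees its neighbours' mean charges:
        theta_i = 1 / (1 + 10^(pH - pKa_int,i - Delta_i)),
        Delta_i = -(1/(kT ln10)) * sum_j W_ij <q_j>.
    Fixed-point iteration with damping (weight on the previous iterate);
    non-converged grid points are flagged and the damping is escalated to
    0.9 before giving up.
    """
    n = len(sites)
    if n == 0:
        raise ValueError("need at least one site")
    W = _check_W(sites, W)
    pk, q_dep = _site_arrays(sites)
    ph = grid.values
    theta = np.empty((len(grid), n))
    converged = np.zeros(len(grid), dtype=bool)

    th = _independent_theta(pk, ph[:1])[0]  # cold start at the first point
    for p, ph_p in enumerate(ph):
        th_p = th.copy()  # warm start from the previous grid point
        for alpha in (damping, 0.9):
            cur = th_p.copy()
            for _ in range(max_iter):
                q = q_dep + cur
                delta = -(W @ q) / (kT * LN10)
                target = 1.0 / (1.0 + 10.0 ** (ph_p - pk - delta))
                new = alpha * cur + (1.0 - alpha) * target
                if np.max(np.abs(new - cur)) < tol:
                    cur = new
                    converged[p] = True
                    break
                cur = new
            if converged[p]:
                break
        # one final undamped application of the fixed-point map; at the
        # converged point it is a no-op to within tol, and for W = 0 it
        # lands exactly on the Henderson-Hasselbalch value
        q = q_dep + cur
        delta = -(W @ q) / (kT * LN10)
        cur = 1.0 / (1.0 + 10.0 ** (ph_p - pk - delta))
        theta[p] = cur
        th = cur
    return TitrationResult(
        grid, list(sites), theta, state, "meanfield", converged=converged
    )


def mc_titration(
    sites: list[TitratableSite],
    W: np.ndarray,
    grid: PhGrid,
    kT: float = DEFAULT_KT,
    sweeps: int = 10_000,
    burn_in: int | None = None,
    seed: int | None = None,
    state: str = "folded",
) -> TitrationResult:
    """Single-flip Metropolis sampling of protonation microstates.

    ``burn_in`` defaults to 20% of ``sweeps``. Results are reproducible for
    a fixed seed; ``theta_se`` carries batch-means standard errors.
    """
    from ._mc import _mc_sweep_grid

    if seed is None:
        raise ValueError("mc_titration requires an explicit seed")
    if burn_in is None:
        burn_in = sweeps // 5
    if not sweeps > burn_in:
        raise ValueError("sweeps must exceed burn_in")
    n = len(sites)
    if n == 0:
        raise ValueError("need at least one site")
    W = _check_W(sites, W)
    pk, q_dep = _site_arrays(sites)
    theta, theta_se = _mc_sweep_grid(
        pk, q_dep, W, grid.values, kT, sweeps, burn_in, seed & 0x7FFFFFFF
    )
    return TitrationResult(
        grid, list(sites), theta, state, "mc", theta_se=theta_se
    )


def independent_titration(
    sites: list[TitratableSite],
    pkas: np.ndarray | list[float],
    grid: PhGrid,
    state: str = "folded",
) -> TitrationResult:
    """Independent Henderson–Hasselbalch curves at the supplied pKas."""
    pkas = np.asarray(pkas, dtype=float)
    if pkas.shape != (len(sites),):
        raise ValueError("need one pKa per site")
    theta = _independent_theta(pkas, grid.values)
    return TitrationResult(grid, list(sites), theta, state, "independent")


def unfolded_titration(
    sites: list[TitratableSite],
    model_table: dict[str, float] | None = None,
    grid: PhGrid = PhGrid(),
) -> TitrationResult:
    """Unfolded-state titration: independent sites at unperturbed model pKas.

    ``model_table`` maps class labels to model pKas and must cover every
    class present; by default each site's own ``model_pka`` is used.
    """
    if model_table is not None:
        missing = sorted({s.site_class for s in sites} - set(model_table))
        if missing:
            raise ValueError(f"model pKa table missing classes: {missing}")
        pkas = [model_table[s.site_class] for s in sites]
    else:
        pkas = [s.model_pka for s in sites]
    return independent_titration(sites, pkas, grid, state="unfolded")


# --- apparent pKa -------------------------------------------------------


@dataclass(frozen=True)
class ApparentPka:
    """Half-protonation point of a site's titration curve.

    ``value`` is NaN when the curve does not cross theta = 0.5 inside the
    grid; ``bracket`` then records which side it lies on ("<start"/">end").
    """

    value: float
    bracket: str | None = None

    @property
    def in_range(self) -> bool:
        return self.bracket is None


def apparent_pka(result: TitrationResult, site_id: tuple[str, int, str]) -> ApparentPka:
    """pH at theta = 0.5 by linear interpolation between grid points."""
    i = result.site_index(site_id)
    th = result.theta[:, i]
    ph = result.grid.values
    if th[0] < 0.5:  # already deprotonated at the acidic end
        return ApparentPka(float("nan"), f"<{ph[0]:g}")
    if th[-1] > 0.5:
        return ApparentPka(float("nan"), f">{ph[-1]:g}")
    k = int(np.argmax(th <= 0.5))
    if th[k] == 0.5:
        return ApparentPka(float(ph[k]))
    # th[k-1] > 0.5 >= th[k]
    frac = (th[k - 1] - 0.5) / (th[k - 1] - th[k])
    return ApparentPka(float(ph[k - 1] + frac * (ph[k] - ph[k - 1])))


# --- external pKa tables ------------------------------------------------


def read_pka_table(
    path: str | Path, sites: list[TitratableSite]
) -> dict[tuple[str, int, str], float]:
    """Read a per-site pKa TSV (chain, resnum, resname, pka).

    Every site must be covered exactly once; unmatched, duplicate or
    non-numeric rows are errors. The mapping can be applied to either state
    via :func:`phfold.structures.with_intrinsic_pkas` /
    :func:`phfold.structures.with_model_pkas`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "resname": str})
    required = {"chain", "resnum", "resname", "pka"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"pKa table {path} must have columns {sorted(required)}"
        )
    known = {s.site_id for s in sites}
    out: dict[tuple[str, int, str], float] = {}
    for _, row in df.iterrows():
        key = (str(row["chain"]), int(row["resnum"]), str(row["resname"]).upper())
        if key not in known:
            raise ValueError(f"pKa table row {key} matches no known site")
        if key in out:
            raise ValueError(f"duplicate pKa table row for site {key}")
        try:
            pka = float(row["pka"])
        except (TypeError, ValueError):
            raise ValueError(f"non-numeric pKa for site {key}") from None
        if not np.isfinite(pka):
            raise ValueError(f"non-numeric pKa for site {key}")
        out[key] = pka
    missing = sorted(known - set(out))
    if missing:
        raise ValueError(f"pKa table missing sites: {missing}")
    return out
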