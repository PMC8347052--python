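"""Desk-scale synthetic fixtures with exact ground truth.

Generates toy "proteins": syntactically valid PDB files whose titratable
side chains sit at randomized positions in a box, together with a table of
planted folded-state pKas. Two named scenarios emulate the perturbation
patterns seen in membrane transport proteins of acidifying organelles:

* ``positive_regulator`` — acid-rich, folded Asp/Glu pKas shifted upward,
  so the stability optimum falls at acidic pH;
* ``neutral_optimum`` — His-rich, folded His pKas shifted in both
  directions so the optimum falls in the neutral 6.5–8 window.

Planted pKas can be imposed directly as intrinsic values ("planted" mode,
exact ground truth, coupling off) or combined with the geometric coupling
matrix ("coupled" mode) for oracle and snapshot-jitter experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_MODEL_PKA, TITRATABLE_CLASSES
from .structures import (
    ProteinStructure,
    Residue,
    TitratableSite,
    VariantSpec,
    extract_sites,
)

#: the nine predictor labels used for synthetic consensus files
PREDICTOR_NAMES = tuple(f"predictor_{i}" for i in range(1, 10))

# side-chain atoms written for each titratable class: (atom, offset) pairs;
# the class's charge-center atoms are placed symmetrically about the planted
# point so the extracted center reproduces it exactly
_SIDE_ATOMS: dict[str, list[tuple[str, tuple[float, float, float]]]] = {
    "ASP": [("CB", (-1.5, 0.0, 0.6)), ("CG", (-0.7, 0.0, 0.3)),
            ("OD1", (0.6, 0.0, 0.0)), ("OD2", (-0.6, 0.0, 0.0))],
    "GLU": [("CB", (-2.0, 0.0, 0.6)), ("CG", (-1.4, 0.0, 0.4)),
            ("CD", (-0.7, 0.0, 0.2)),
            ("OE1", (0.6, 0.0, 0.0)), ("OE2", (-0.6, 0.0, 0.0))],
    "HIS": [("CB", (-1.8, 0.0, 0.8)), ("CG", (-1.1, 0.0, 0.4)),
            ("ND1", (1.1, 0.0, 0.0)), ("NE2", (-1.1, 0.0, 0.0))],
    "LYS": [("CB", (-2.5, 0.0, 0.8)), ("NZ", (0.0, 0.0, 0.0))],
    "ARG": [("CB", (-2.5, 0.0, 0.8)), ("CZ", (0.0, 0.0, 0.0))],
    "CYS": [("CB", (-1.2, 0.0, 0.5)), ("SG", (0.0, 0.0, 0.0))],
    "TYR": [("CB", (-2.8, 0.0, 0.8)), ("OH", (0.0, 0.0, 0.0))],
}


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for one toy protein with planted folded-state pKa shifts."""

    name: str
    site_counts: dict[str, int]
    pka_shifts: dict[str, float]  # class -> uniform shift
    per_site_shifts: dict[str, tuple[float, ...]] = field(default_factory=dict)
    box_size: float = 40.0
    min_separation: float = 7.0
    jitter_sd: float = 0.5
    n_snapshots: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation < 2.0:
            raise ValueError("minimum separation must be at least the clash floor")
        if any(c < 0 for c in self.site_counts.values()):
            raise ValueError("site counts must be non-negative")
        for cls in list(self.site_counts) + list(self.pka_shifts):
            if cls not in TITRATABLE_CLASSES:
                raise ValueError(f"unknown titratable class {cls!r}")

    def folded_pka(self, cls: str, index_in_class: int) -> float:
        base = DEFAULT_MODEL_PKA[cls]
        if cls in self.per_site_shifts:
            shifts = self.per_site_shifts[cls]
            return base + shifts[index_in_class % len(shifts)]
        return base + self.pka_shifts.get(cls, 0.0)


def scenario_positive_regulator(seed: int) -> ScenarioSpec:
    """Acid-shifted scenario: folded Asp/Glu pKas raised by +1.5.

    Δq > 0 throughout the acidic window, so stability is maximal at the
    acidic end — the profile expected of a positive pH regulator.
    """
    return ScenarioSpec(
        name="positive_regulator",
        site_counts={"ASP": 3, "GLU": 3, "HIS": 2, "LYS": 2},
        pka_shifts={"ASP": 1.5, "GLU": 1.5},
        seed=seed,
    )


def scenario_neutral_optimum(seed: int) -> ScenarioSpec:
    """His-shifted scenario with an interior optimum in the 6.5–8 window.

    Three His are down-shifted (−1.0) and two up-shifted (+2.0): Δq is
    negative below ~6.6 and positive above, so ΔΔG has an interior minimum
    near neutral pH — the profile expected of proteins working in mature,
    near-neutral organelles.
    """
    return ScenarioSpec(
        name="neutral_optimum",
        site_counts={"HIS": 5, "ASP": 2, "GLU": 2, "LYS": 2},
        pka_shifts={},
        per_site_shifts={"HIS": (-1.0, 2.0, -1.0, 2.0, -1.0)},
        seed=seed,
    )


# --- placement and structure assembly -----------------------------------


def _place_centers(
    n: int, box: float, min_sep: float, rng: np.random.Generator,
    max_tries: int = 20_000,
) -> np.ndarray:
    pts: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(pts) == n:
            break
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n:
        raise RuntimeError(
            f"could not place {n} sites with separation {min_sep} Å "
            f"in a {box} Å box after {max_tries} tries"
        )
    return np.array(pts) if pts else np.zeros((0, 3))


def _residue(name: str, number: int, base: np.ndarray,
             center: np.ndarray | None) -> Residue:
    atoms = {
        "N": base + np.array([-1.2, 0.8, 0.0]),
        "CA": base.copy(),
        "C": base + np.array([1.3, 0.6, 0.0]),
        "O": base + np.array([1.5, 1.8, 0.0]),
    }
    if name == "ALA":
        atoms["CB"] = base + np.array([-0.3, -1.3, 0.6])
    else:
        for atom, off in _SIDE_ATOMS[name]:
            atoms[atom] = center + np.asarray(off)
    return Residue(name, number, atoms)


def build_toy_protein(spec: ScenarioSpec) -> tuple[ProteinStructure, pd.DataFrame]:
    """Assemble the toy structure and its ground-truth pKa table.

    Titratable residues alternate with Ala spacers along the chain; each
    titratable side chain is placed so its extracted charge center equals
    the planted coordinate. The truth table has one row per planted site:
    chain, resnum, resname, class, folded_pka, model_pka, x, y, z.
    """
    rng = np.random.default_rng(spec.seed)
    plan: list[tuple[str, float]] = []  # (class, folded pKa), in chain order
    for cls in sorted(spec.site_counts):
        for k in range(spec.site_counts[cls]):
            plan.append((cls, spec.folded_pka(cls, k)))
    centers = _place_centers(
        len(plan), spec.box_size, spec.min_separation, rng
    )

    residues: list[Residue] = []
    rows: list[dict] = []
    number = 0
    spine = rng.uniform(5.0, spec.box_size - 5.0, size=3)
    for k, (cls, folded_pka) in enumerate(plan):
        number += 1
        residues.append(_residue("ALA", number, spine + number * 3.8, None))
        number += 1
        residues.append(_residue(cls, number, centers[k] + np.array([-2.0, -1.0, 0.0]),
                                 centers[k]))
        rows.append({
            "chain": "A", "resnum": number, "resname": cls, "class": cls,
            "folded_pka": folded_pka, "model_pka": DEFAULT_MODEL_PKA[cls],
            "x": centers[k][0], "y": centers[k][1], "z": centers[k][2],
        })
    number += 1
    residues.append(_residue("ALA", number, spine + number * 3.8, None))

    structure = ProteinStructure("A", residues)
    truth = pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "class",
                       "folded_pka", "model_pka", "x", "y", "z"],
    )
    return structure, truth


def planted_sites(
    structure: ProteinStructure, truth: pd.DataFrame
) -> list[TitratableSite]:
    """Extract sites and impose the planted folded pKas as intrinsic pKas."""
    sites = extract_sites(structure)
    planted = {
        (str(r.chain), int(r.resnum), str(r.resname)): float(r.folded_pka)
        for r in truth.itertuples()
    }
    out = []
    for s in sites:
        if s.site_id not in planted:
            raise ValueError(f"site {s.site_id} not present in the truth table")
        out.append(replace(s, intrinsic_pka=planted[s.site_id]))
    return out


def jitter_structure(
    structure: ProteinStructure, sd: float, rng: np.random.Generator
) -> ProteinStructure:
    """Isotropic Gaussian jitter of all atom coordinates (a pseudo-snapshot)."""
    out = structure.copy()
    for res in out.residues:
        for name in res.atoms:
            res.atoms[name] = res.atoms[name] + rng.normal(0.0, sd, size=3)
        if res.center_override is not None:
            res.center_override = res.center_override + rng.normal(0.0, sd, size=3)
    return out


# --- PDB output ---------------------------------------------------------

_ELEMENT = {"N": "N", "O": "O", "C": "C", "S": "S"}


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal, syntactically valid single-chain PDB file."""
    lines = []
    serial = 0
    for res in structure.residues:
        for name, xyz in res.atoms.items():
            serial += 1
            element = _ELEMENT.get(name[0], name[0])
            atom_field = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {serial:5d} {atom_field}{'':1s}{res.name:>3s} "
                f"{structure.chain_id}{res.number:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_toy_protein(
    spec: ScenarioSpec, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the scenario's PDB and ground-truth TSV; reproducible per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    structure, truth = build_toy_protein(spec)
    pdb_path = out_dir / f"{spec.name}_seed{spec.seed}.pdb"
    truth_path = out_dir / f"{spec.name}_seed{spec.seed}_truth.tsv"
    write_pdb(structure, pdb_path)
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return pdb_path, truth_path


# --- random oracle fixtures ---------------------------------------------


def random_fixture(
    seed: int,
    n_sites: tuple[int, int] = (4, 12),
    shift_range: float = 1.0,
    classes: tuple[str, ...] = ("ASP", "GLU", "HIS", "LYS", "ARG", "TYR", "CYS"),
) -> ScenarioSpec:
    """A random mixed-class scenario with uniform per-site intrinsic shifts
    in [−shift_range, +shift_range]; used for solver-equivalence oracles."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_sites[0], n_sites[1] + 1))
    chosen = rng.choice(len(classes), size=n)
    counts: dict[str, int] = {}
    for idx in chosen:
        cls = classes[idx]
        counts[cls] = counts.get(cls, 0) + 1
    per_site = {
        cls: tuple(rng.uniform(-shift_range, shift_range, size=c))
        for cls, c in counts.items()
    }
    return ScenarioSpec(
        name=f"random_{seed}",
        site_counts=counts,
        pka_shifts={},
        per_site_shifts=per_site,
        seed=seed,
    )


# --- predictor files ----------------------------------------------------


def generate_predictor_file(
    variants: list[tuple[VariantSpec, float]],
    seed: int,
    noise_sd: float = 0.5,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-variant, per-predictor ΔΔG values around planted true values.

    Each of the nine synthetic predictors reports the planted ΔΔG plus
    Gaussian noise of the given SD (kcal/mol). Written as a TSV with
    columns variant, predictor, ddg when ``path`` is given.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for variant, true_ddg in variants:
        for name in PREDICTOR_NAMES:
            rows.append({
                "variant": str(variant),
                "predictor": name,
                "ddg": true_ddg + rng.normal(0.0, noise_sd),
            })
    df = pd.DataFrame(rows, columns=["variant", "predictor", "ddg"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df
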