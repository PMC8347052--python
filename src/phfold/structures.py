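"""Protein structures, titratable-site extraction and in-silico variants.

The structure model is deliberately minimal: one chain, ordered residues,
per-residue atom coordinates. Titratable side chains (Asp, Glu, His, Cys,
Tyr, Lys, Arg, plus optional chain termini) are reduced to a single charge
center each, following the usual one-point-per-site reduction used by
continuum pKa solvers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1, seq3

from .constants import (
    ACID,
    CHARGE_CENTER_ATOMS,
    DEFAULT_MODEL_PKA,
    TITRATABLE_CLASSES,
)

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class Residue:
    """One amino-acid residue: 3-letter name, author number, atom coords."""

    name: str
    number: int
    atoms: dict[str, np.ndarray]
    # set by apply_variant: charge center inherited from the replaced side chain
    center_override: np.ndarray | None = None

    def copy(self) -> "Residue":
        return Residue(
            self.name,
            self.number,
            {k: v.copy() for k, v in self.atoms.items()},
            None if self.center_override is None else self.center_override.copy(),
        )


@dataclass
class ProteinStructure:
    """A single chain of residues with Cartesian coordinates in Å."""

    chain_id: str
    residues: list[Residue]

    @property
    def sequence(self) -> str:
        return "".join(seq1(r.name) for r in self.residues)

    def residue_by_number(self, number: int) -> Residue:
        for r in self.residues:
            if r.number == number:
                return r
        raise KeyError(f"no residue numbered {number} in chain {self.chain_id}")

    def copy(self) -> "ProteinStructure":
        return ProteinStructure(self.chain_id, [r.copy() for r in self.residues])

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError("residue numbers must be strictly increasing")
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"residue {r.name}{r.number} has no atoms")


@dataclass(frozen=True)
class TitratableSite:
    """One ionizable group reduced to a point charge center.

    ``site_class`` is one of the keys of
    :data:`phfold.constants.TITRATABLE_CLASSES`. Acids carry charge −1 when
    deprotonated and 0 when protonated; bases 0 and +1. ``model_pka`` is the
    unperturbed reference-compound value; ``intrinsic_pka`` is the value the
    folded-state solvers use before site–site coupling is applied.
    """

    chain: str
    resnum: int
    resname: str
    site_class: str
    polarity: str
    center: tuple[float, float, float]
    model_pka: float
    intrinsic_pka: float

    def __post_init__(self) -> None:
        if self.site_class not in TITRATABLE_CLASSES:
            raise ValueError(f"unknown titratable class {self.site_class!r}")
        expected = TITRATABLE_CLASSES[self.site_class][0]
        if self.polarity != expected:
            raise ValueError(
                f"{self.site_class} must have polarity {expected!r}, "
                f"got {self.polarity!r}"
            )
        if not 0.0 <= self.model_pka <= 14.0:
            raise ValueError(f"model pKa {self.model_pka} outside [0, 14]")

    @property
    def q_protonated(self) -> int:
        return 0 if self.polarity == ACID else 1

    @property
    def q_deprotonated(self) -> int:
        return -1 if self.polarity == ACID else 0

    @property
    def site_id(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)


_VARIANT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantSpec:
    """An amino-acid substitution in WposM notation (e.g. ``A481T``)."""

    wt: str
    position: int
    mutant: str

    @classmethod
    def parse(cls, text: str) -> "VariantSpec":
        m = _VARIANT_RE.match(text.strip().upper())
        if not m:
            raise ValueError(f"cannot parse variant {text!r} (expected e.g. A481T)")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:
        return f"{self.wt}{self.position}{self.mutant}"

    @property
    def reverse(self) -> "VariantSpec":
        return VariantSpec(self.mutant, self.position, self.wt)


# --- parsing ------------------------------------------------------------


def parse_structure(path: str | Path, chain: str | None = None) -> ProteinStructure:
    """Read the first model of a PDB file into a :class:`ProteinStructure`.

    Waters and heteroatoms are dropped; disordered atoms resolve to the
    highest-occupancy alternate location (Biopython's default selection).
    Only one chain is kept: ``chain`` if given, else the first chain that
    contains standard residues.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    parser = PDBParser(QUIET=True)
    try:
        model = next(parser.get_structure(path.stem, str(path)).get_models())
    except (StopIteration, Exception) as exc:  # Biopython raises bare Exception
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc

    chains = [c for c in model if chain is None or c.id == chain]
    if chain is not None and not chains:
        raise ValueError(f"chain {chain!r} not found in {path}")

    for ch in chains:
        residues = []
        for res in ch:
            if res.id[0] != " " or not is_aa(res, standard=True):
                continue
            atoms = {a.get_name(): np.asarray(a.get_coord(), dtype=float)
                     for a in res}
            residues.append(Residue(res.get_resname().upper(), res.id[1], atoms))
        if residues:
            return ProteinStructure(ch.id, residues)
    raise ValueError(f"no standard amino-acid residues found in {path}")


# --- site extraction ----------------------------------------------------


def _side_chain_center(res: Residue) -> np.ndarray | None:
    side = [xyz for name, xyz in res.atoms.items() if name not in _BACKBONE]
    if side:
        return np.mean(side, axis=0)
    for fallback in ("CB", "CA"):
        if fallback in res.atoms:
            return res.atoms[fallback]
    return None


def _charge_center(res: Residue) -> np.ndarray:
    """Charge center per class convention, falling back with a warning."""
    if res.center_override is not None:
        return res.center_override
    wanted = CHARGE_CENTER_ATOMS.get(res.name)
    if wanted is not None and all(a in res.atoms for a in wanted):
        return np.mean([res.atoms[a] for a in wanted], axis=0)
    center = _side_chain_center(res)
    if center is None:
        raise ValueError(
            f"residue {res.name}{res.number} has no atoms usable as a charge center"
        )
    warnings.warn(
        f"residue {res.name}{res.number}: charge-center atoms "
        f"{wanted} missing; using side-chain centroid fallback",
        stacklevel=2,
    )
    return center


def extract_sites(
    structure: ProteinStructure,
    include_termini: bool = False,
    model_pka: dict[str, float] | None = None,
) -> list[TitratableSite]:
    """Enumerate titratable sites of a structure, sorted by residue number.

    ``model_pka`` overrides entries of the default model-pKa table. Intrinsic
    (folded-state) pKas are initialised to the model values; callers impose
    perturbations either through the coupling matrix or by replacing the
    intrinsic values (e.g. from an external pKa table or a planted fixture).
    """
    table = dict(DEFAULT_MODEL_PKA)
    if model_pka:
        table.update(model_pka)

    sites: list[TitratableSite] = []

    def _mk(cls: str, res: Residue, center: np.ndarray) -> TitratableSite:
        pol = TITRATABLE_CLASSES[cls][0]
        return TitratableSite(
            chain=structure.chain_id,
            resnum=res.number,
            resname=res.name if cls not in ("NTERM", "CTERM") else cls,
            site_class=cls,
            polarity=pol,
            center=tuple(float(x) for x in center),
            model_pka=table[cls],
            intrinsic_pka=table[cls],
        )

    if include_termini and structure.residues:
        first = structure.residues[0]
        n_center = first.atoms.get("N", _side_chain_center(first))
        sites.append(_mk("NTERM", first, n_center))

    for res in structure.residues:
        if res.name in CHARGE_CENTER_ATOMS:
            sites.append(_mk(res.name, res, _charge_center(res)))

    if include_termini and structure.residues:
        last = structure.residues[-1]
        if "O" in last.atoms and "OXT" in last.atoms:
            c_center = (last.atoms["O"] + last.atoms["OXT"]) / 2.0
        else:
            c_center = last.atoms.get("O", _side_chain_center(last))
        sites.append(_mk("CTERM", last, c_center))

    sites.sort(key=lambda s: (s.chain, s.resnum, s.site_class))
    return sites


# --- variants -----------------------------------------------------------


def apply_variant(structure: ProteinStructure, variant: VariantSpec) -> ProteinStructure:
    """Apply a substitution as a residue-name edit (no geometry rebuild).

    The mutated residue keeps the wild-type atoms; if the new residue type is
    titratable, its site inherits the replaced side chain's charge center
    (falling back to Cβ, then Cα). The input structure is not modified.
    """
    out = structure.copy()
    try:
        res = out.residue_by_number(variant.position)
    except KeyError as exc:
        raise ValueError(f"variant {variant}: {exc}") from exc
    found = seq1(res.name)
    if found != variant.wt:
        raise ValueError(
            f"variant {variant}: wild-type mismatch at position "
            f"{variant.position} (expected {variant.wt}, found {found})"
        )
    new_name = seq3(variant.mutant).upper()
    if new_name in CHARGE_CENTER_ATOMS or res.name in CHARGE_CENTER_ATOMS:
        # inherit the replaced side chain's charge center so the mutated
        # site has a deterministic position without geometry rebuilding;
        # kept even on site removal so the reverse variant restores it
        if res.name in CHARGE_CENTER_ATOMS or res.center_override is not None:
            center = _charge_center(res)
        else:
            center = _side_chain_center(res)
            if center is None:
                center = res.atoms.get("CB", res.atoms.get("CA"))
        res.center_override = np.asarray(center, dtype=float)
    res.name = new_name
    return out


# --- I/O ----------------------------------------------------------------

SITE_TSV_COLUMNS = [
    "chain", "resnum", "resname", "class", "polarity", "x", "y", "z", "model_pka",
]


def write_sites_tsv(sites: list[TitratableSite], path: str | Path) -> None:
    import pandas as pd

    rows = [
        {
            "chain": s.chain,
            "resnum": s.resnum,
            "resname": s.resname,
            "class": s.site_class,
            "polarity": s.polarity,
            "x": s.center[0],
            "y": s.center[1],
            "z": s.center[2],
            "model_pka": s.model_pka,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def with_intrinsic_pkas(
    sites: list[TitratableSite], pkas: dict[tuple[str, int, str], float]
) -> list[TitratableSite]:
    """Return sites with intrinsic (folded) pKas replaced per site id."""
    missing = [s.site_id for s in sites if s.site_id not in pkas]
    if missing:
        raise ValueError(f"no pKa supplied for sites: {missing}")
    return [replace(s, intrinsic_pka=float(pkas[s.site_id])) for s in sites]


def with_model_pkas(
    sites: list[TitratableSite], pkas: dict[tuple[str, int, str], float]
) -> list[TitratableSite]:
    """Return sites with model (unfolded) pKas replaced per site id."""
    missing = [s.site_id for s in sites if s.site_id not in pkas]
    if missing:
        raise ValueError(f"no pKa supplied for sites: {missing}")
    return [replace(s, model_pka=float(pkas[s.site_id])) for s in sites]
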