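"""Atomic-model I/O and residue bookkeeping.

Models are held as a flat atom table (one row per atom, altlocs included)
plus unit-cell geometry. Residues are addressed by ``(chain, resnum)``
throughout the package; insertion codes are rejected on input because the
downstream per-residue tracks have no way to address them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
import numpy as np
import pandas as pd

from .errors import InsertionCodeError, InvariantViolationError, ModelIOError

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ATOM_COLUMNS = [
    "chain",
    "resnum",
    "resname",
    "atom",
    "altloc",
    "element",
    "x",
    "y",
    "z",
    "occupancy",
]


class ResidueKey(NamedTuple):
    """Address of one residue: chain identifier + 1-based residue number."""

    chain: str
    resnum: int


@dataclass
class AtomicModel:
    """Atom table + crystal frame.

    ``atoms`` columns: chain, resnum, resname, atom, altloc, element,
    x, y, z, occupancy.  ``cell`` is (a, b, c, alpha, beta, gamma) in
    Angstroms / degrees; ``spacegroup`` a Hermann-Mauguin symbol.
    ``cell`` may be None for solution-only models (flagged, not fatal:
    a synthetic cell can be injected before any map work).
    """

    atoms: pd.DataFrame
    cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str = "P 1"

    def __post_init__(self) -> None:
        missing = [c for c in ATOM_COLUMNS if c not in self.atoms.columns]
        if missing:
            raise InvariantViolationError(f"atom table missing columns {missing}")
        occ = self.atoms["occupancy"].to_numpy(float)
        if ((occ < 0) | (occ > 1)).any():
            raise InvariantViolationError("occupancies must lie in [0, 1]")
        if self.cell is not None:
            a, b, c, al, be, ga = self.cell
            if min(a, b, c) <= 0 or not all(0 < x < 180 for x in (al, be, ga)):
                raise InvariantViolationError(f"invalid unit cell {self.cell}")

    # -- residue-level views -------------------------------------------------

    def residue_keys(self, include_waters: bool = False) -> list[ResidueKey]:
        """Residue addresses in file order (waters excluded by default)."""
        df = self.atoms
        if not include_waters:
            df = df[~df["resname"].isin(WATER_NAMES)]
        seen: dict[ResidueKey, None] = {}
        for ch, rn in zip(df["chain"], df["resnum"]):
            seen.setdefault(ResidueKey(str(ch), int(rn)))
        return list(seen)

    def is_water(self) -> pd.Series:
        return self.atoms["resname"].isin(WATER_NAMES)

    def with_cell(self, cell, spacegroup: str = "P 1") -> "AtomicModel":
        return replace(self, cell=tuple(cell), spacegroup=spacegroup)

    def gemmi_cell(self) -> gemmi.UnitCell:
        if self.cell is None:
            raise InvariantViolationError("model has no unit cell")
        return gemmi.UnitCell(*self.cell)


def _infer_element(atom_name: str, resname: str) -> str:
    """PDB element columns absent: fall back to the atom-name convention.

    Within amino-acid residues, names like ' CA ' are carbons, never calcium.
    """
    name = atom_name.strip()
    if not name:
        raise ModelIOError("atom with empty name")
    if name[0].isdigit():  # e.g. 1HB
        name = name.lstrip("0123456789")
    two = name[:2].capitalize()
    if two in ("Se", "Fe", "Zn", "Mg", "Mn", "Cl", "Br", "Na", "Ca") and resname not in _AA3:
        return two
    return name[0].upper()


_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "UNK",
}


def read_model(path: str | Path, fmt: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    All ATOM/HETATM records of the first model are kept, altlocs included.
    Waters stay in the table (flagged by residue name) so difference-map
    bookkeeping can see them; :func:`heavy_atoms` excludes them.
    Inputs containing insertion codes are rejected.
    """
    path = Path(path)
    try:
        if fmt is None:
            st = gemmi.read_structure(str(path))
        else:
            gfmt = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}[fmt]
            st = gemmi.read_structure(str(path), format=gfmt)
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ModelIOError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise ModelIOError(f"{path}: no models found")

    rows = []
    for chain in st[0]:
        for res in chain:
            icode = res.seqid.icode
            if icode not in (" ", "", "\x00"):
                raise InsertionCodeError(
                    f"{path}: residue {chain.name} {res.seqid.num}{icode} has an "
                    "insertion code; renumber the model before use"
                )
            for atom in res:
                el = atom.element.name
                if not el or el == "X":
                    el = _infer_element(atom.name, res.name)
                rows.append(
                    (
                        chain.name,
                        res.seqid.num,
                        res.name,
                        atom.name,
                        atom.altloc if atom.altloc != "\x00" else "",
                        el,
                        atom.pos.x,
                        atom.pos.y,
                        atom.pos.z,
                        atom.occ,
                    )
                )
    if not rows:
        raise ModelIOError(f"{path}: no atoms found")
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)

    cell = None
    c = st.cell
    if c.a > 1.0 and c.b > 1.0 and c.c > 1.0:  # gemmi's dummy cell is 1,1,1
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    sg = st.spacegroup_hm or "P 1"
    return AtomicModel(atoms=atoms, cell=cell, spacegroup=sg)


def write_model(model: AtomicModel, path: str | Path) -> None:
    """Write the model as PDB (``.pdb``) or mmCIF (``.cif``/``.mmcif``)."""
    st = gemmi.Structure()
    st.name = "allonet"
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    st.spacegroup_hm = model.spacegroup
    gm = gemmi.Model("1")
    for ch_name, ch_df in model.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(ch_name))
        for (rn, resname), r_df in ch_df.groupby(["resnum", "resname"], sort=False):
            res = gemmi.Residue()
            res.name = str(resname)
            res.seqid = gemmi.SeqId(int(rn), " ")
            if resname in WATER_NAMES:
                res.het_flag = "H"
            for row in r_df.itertuples():
                a = gemmi.Atom()
                a.name = row.atom
                a.element = gemmi.Element(row.element)
                a.altloc = row.altloc or "\x00"
                a.pos = gemmi.Position(row.x, row.y, row.z)
                a.occ = float(row.occupancy)
                res.add_atom(a)
            chain.add_residue(res)
        gm.add_chain(chain)
    st.add_model(gm)
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


def heavy_atoms(model: AtomicModel) -> pd.DataFrame:
    """Protein heavy atoms: hydrogens/deuteriums and water residues excluded.

    Returns the atom-table subset (input order preserved) with a ``key``
    column of :class:`ResidueKey`. All altloc copies are kept so periodic
    distance tests see every modelled conformation.
    """
    df = model.atoms
    keep = ~df["element"].isin(["H", "D"]) & ~df["resname"].isin(WATER_NAMES)
    out = df[keep].copy()
    out["key"] = [ResidueKey(str(c), int(r)) for c, r in zip(out["chain"], out["resnum"])]
    return out


def heavy_atom_counts(model: AtomicModel) -> dict[ResidueKey, int]:
    """Number of heavy atoms per (non-water) residue, altlocs counted once each."""
    ha = heavy_atoms(model)
    counts: dict[ResidueKey, int] = {}
    for key in ha["key"]:
        counts[key] = counts.get(key, 0) + 1
    return counts
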