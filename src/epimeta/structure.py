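"""Antigen structure handling: parsing, geometric centers, solvent exposure.

An antigen is represented by its standard amino-acid residues only, each
carrying the full set of heavy-atom coordinates.  Two derived per-residue
quantities drive the rest of the pipeline:

* the geometric center (unweighted mean of all heavy atoms), used as the
  residue's point location for spatial clustering of predicted epitopes;
* the relative solvent accessibility (RSA), used to count surface-exposed
  residues ``R``, which sets the dynamic prediction threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.StructureBuilder import StructureBuilder

log = logging.getLogger(__name__)

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Theoretical maximum accessible surface areas (A^2) per residue type
# (Tien et al. 2013), used to normalize ASA into relative accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
GENERIC_MAX_ASA = 197.0  # fallback for non-standard residue types


@dataclass(frozen=True)
class ResidueId:
    """Identity of one residue: chain, author residue number, insertion code.

    ``resname`` is carried for reporting but excluded from equality/hashing so
    that residues referenced by annotation or score files (which may omit the
    residue type) match structure residues by position alone.
    """

    chain: str
    seqnum: int
    icode: str = ""
    resname: str = field(default="", compare=False)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def __str__(self) -> str:  # e.g. A:100A:ASN
        ic = self.icode or ""
        return f"{self.chain}:{self.seqnum}{ic}" + (f":{self.resname}" if self.resname else "")


@dataclass
class AntigenStructure:
    """Parsed antigen: ordered residues with heavy-atom coordinates."""

    residues: list[ResidueId]
    coords: list[np.ndarray]          # per residue: (n_atoms, 3) in Angstrom
    elements: list[list[str]]         # per residue: element symbol per atom
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def centers(self) -> np.ndarray:
        """(n_residues, 3) array of all-heavy-atom geometric centers."""
        return np.array([geometric_center(c) for c in self.coords])

    def sequence(self, chain: str | None = None) -> str:
        """One-letter sequence in file order (optionally one chain)."""
        return "".join(
            THREE_TO_ONE.get(r.resname, "X")
            for r in self.residues
            if chain is None or r.chain == chain
        )

    def index(self) -> dict[tuple[str, int, str], int]:
        return {r.key: i for i, r in enumerate(self.residues)}


@dataclass
class SurfaceProfile:
    """Per-residue relative solvent accessibility and the surface count R."""

    rsa: np.ndarray
    is_surface: np.ndarray
    rsa_threshold: float

    @property
    def R(self) -> int:
        return int(self.is_surface.sum())


def geometric_center(coords: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Unweighted mean of a residue's heavy-atom coordinates (Angstrom)."""
    arr = np.asarray(coords, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric center of a residue with no atoms")
    return arr.reshape(-1, 3).mean(axis=0)


def _first_altloc_atoms(residue) -> list:
    """Heavy atoms of a residue, keeping the first alternate location only."""
    atoms = []
    for atom in residue:
        if atom.is_disordered():
            alt_ids = sorted(atom.disordered_get_id_list())
            atom = atom.disordered_get(alt_ids[0])
        if (atom.element or "").upper() in ("H", "D"):
            continue
        atoms.append(atom)
    return atoms


def parse_structure(
    path: str | Path,
    chains: Iterable[str] | str | None = None,
) -> AntigenStructure:
    """Parse a PDB file into an :class:`AntigenStructure`.

    Only standard amino-acid residues of the selected chains are kept (waters,
    ligands and other heteroatoms are dropped; non-standard residues are
    dropped with a warning).  Only the first NMR model is read; for alternate
    locations the first altloc is kept; hydrogens are ignored.  Residue order
    follows the file.

    Parameters
    ----------
    path
        PDB-format file.
    chains
        Chain id, iterable of chain ids, or None for all chains.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(chains, str):
        chains = [chains]
    wanted = None if chains is None else list(chains)

    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure(path.stem, str(path)).get_models())
    present = [c.id for c in model]
    if wanted is not None:
        missing = [c for c in wanted if c not in present]
        if missing:
            raise ValueError(f"chain(s) {missing} not present in {path} (has {present})")

    residues: list[ResidueId] = []
    coords: list[np.ndarray] = []
    elements: list[list[str]] = []
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for res in chain:
            hetflag, seqnum, icode = res.id
            if hetflag != " ":
                continue  # water / ligand
            if res.get_resname() not in STANDARD_AA3:
                log.warning("dropping non-standard residue %s %s%s in %s",
                            res.get_resname(), seqnum, icode.strip(), path.name)
                continue
            atoms = _first_altloc_atoms(res)
            if not atoms:
                continue
            residues.append(ResidueId(chain.id, int(seqnum), icode.strip(),
                                      res.get_resname()))
            coords.append(np.array([a.coord for a in atoms], dtype=float))
            elements.append([a.element or "C" for a in atoms])

    if not residues:
        raise ValueError(f"no standard amino-acid residues after filtering in {path}")
    sel = ",".join(wanted) if wanted is not None else "*"
    return AntigenStructure(residues, coords, elements, source=f"{path.name}:{sel}")


def _as_biopdb(structure: AntigenStructure):
    """Rebuild a Bio.PDB entity from the array representation (for SASA)."""
    sb = StructureBuilder()
    sb.init_structure("antigen")
    sb.init_model(0)
    sb.init_seg("    ")
    current_chain = None
    serial = 1
    for rid, xyz, elems in zip(structure.residues, structure.coords, structure.elements):
        if rid.chain != current_chain:
            sb.init_chain(rid.chain)
            current_chain = rid.chain
        sb.init_residue(rid.resname or "GLY", " ", rid.seqnum, rid.icode or " ")
        for j, (pos, el) in enumerate(zip(xyz, elems)):
            name = f"{el}{j + 1}"[:4]
            sb.init_atom(name, np.asarray(pos, dtype=float), 0.0, 1.0, " ",
                         name.ljust(4), serial, element=el.upper())
            serial += 1
    return sb.get_structure()


def surface_profile(
    structure: AntigenStructure,
    rsa_threshold: float = 0.05,
    probe_radius: float = 1.4,
    n_points: int = 200,
) -> SurfaceProfile:
    """Per-residue RSA by the rolling-probe (Shrake-Rupley) method.

    RSA is the residue's accessible surface area divided by its residue-type
    theoretical maximum; a residue is flagged surface-exposed when RSA is at
    least ``rsa_threshold`` (default 5%).  The count of flagged residues is
    the ``R`` of the dynamic prediction threshold.
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    entity = _as_biopdb(structure)
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(entity, level="R")
    sasa = np.array([res.sasa for res in entity.get_residues()], dtype=float)

    max_asa = np.empty(len(structure))
    for i, rid in enumerate(structure.residues):
        if rid.resname in MAX_ASA:
            max_asa[i] = MAX_ASA[rid.resname]
        else:
            warnings.warn(f"no reference max ASA for residue type {rid.resname!r}; "
                          f"using generic {GENERIC_MAX_ASA}")
            max_asa[i] = GENERIC_MAX_ASA
    rsa = sasa / max_asa
    return SurfaceProfile(rsa=rsa, is_surface=rsa >= rsa_threshold,
                          rsa_threshold=rsa_threshold)


def surface_table(structure: AntigenStructure, profile: SurfaceProfile) -> pd.DataFrame:
    """Per-residue surface report: ids, RSA, surface flag, geometric center."""
    centers = structure.centers
    return pd.DataFrame({
        "chain": [r.chain for r in structure.residues],
        "seqnum": [r.seqnum for r in structure.residues],
        "icode": [r.icode for r in structure.residues],
        "resname": [r.resname for r in structure.residues],
        "rsa": profile.rsa,
        "is_surface": profile.is_surface.astype(int),
        "cx": centers[:, 0],
        "cy": centers[:, 1],
        "cz": centers[:, 2],
    })
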