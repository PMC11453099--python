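"""Shared fixtures: hand-written PDB snippets and synthetic structures."""

from __future__ import annotations

import numpy as np
import pytest

from epimeta.structure import AntigenStructure, ResidueId, THREE_TO_ONE

ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def pdb_atom(serial, name, resname, chain, seqnum, x, y, z,
             icode=" ", altloc=" ", element=None, record="ATOM"):
    """One fixed-width PDB coordinate record."""
    element = element or name.strip()[0]
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record:<6s}{serial:5d} {name_f:<4s}{altloc}{resname:>3s} "
            f"{chain}{seqnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}")


def write_pdb(path, lines):
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


@pytest.fixture
def three_ala_pdb(tmp_path):
    """Three alanine residues, one CA + CB each, known coordinates."""
    lines = []
    serial = 1
    for i in range(3):
        lines.append(pdb_atom(serial, "CA", "ALA", "A", i + 1, i * 3.8, 0.0, 0.0))
        serial += 1
        lines.append(pdb_atom(serial, "CB", "ALA", "A", i + 1, i * 3.8, 1.5, 0.0))
        serial += 1
    return write_pdb(tmp_path / "three_ala.pdb", lines)


@pytest.fixture
def three_ala_with_het_pdb(tmp_path):
    """Same three alanines plus a water and a ligand heteroatom."""
    lines = []
    serial = 1
    for i in range(3):
        lines.append(pdb_atom(serial, "CA", "ALA", "A", i + 1, i * 3.8, 0.0, 0.0))
        serial += 1
        lines.append(pdb_atom(serial, "CB", "ALA", "A", i + 1, i * 3.8, 1.5, 0.0))
        serial += 1
    lines.append(pdb_atom(serial, "O", "HOH", "A", 90, 20.0, 20.0, 20.0,
                          record="HETATM"))
    lines.append(pdb_atom(serial + 1, "C1", "NAG", "A", 91, 25.0, 20.0, 20.0,
                          record="HETATM"))
    return write_pdb(tmp_path / "three_ala_het.pdb", lines)


def pseudo_structure(coords, chain="A", start=1, resnames=None,
                     source="test") -> AntigenStructure:
    """Single-pseudo-atom structure from an (n,3) coordinate array."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    resnames = resnames or ["ALA"] * n
    return AntigenStructure(
        residues=[ResidueId(chain, start + i, "", resnames[i]) for i in range(n)],
        coords=[coords[i].reshape(1, 3) for i in range(n)],
        elements=[["C"]] * n,
        source=source,
    )


def seq_structure(seq: str, chain="A", start=1) -> AntigenStructure:
    """Pseudo-atom structure whose resnames spell a one-letter sequence."""
    coords = np.column_stack([np.arange(len(seq)) * 3.8,
                              np.zeros(len(seq)), np.zeros(len(seq))])
    return pseudo_structure(coords, chain=chain, start=start,
                            resnames=[ONE_TO_THREE[c] for c in seq])
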