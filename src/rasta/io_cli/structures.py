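"""PDB input and bead-model coordinate files.

``read_structure`` turns a PDB file into a bead model with one bead per
heavy atom.  The declared selection policy is:

* first model only;
* hydrogens and deuteriums excluded (by element);
* water and all other HETATM records excluded (solvent, ions, ligands);
* alternate locations resolved to the highest occupancy, ties broken by
  altloc identifier order.

Bead models are written as PDB-compatible coordinate files (one ``ATOM``
pseudo-atom per bead, carbon element) so standard viewers display them;
height and width are carried in ``REMARK 99`` lines and round-trip.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from rasta.bead_model import BeadModel, default_width_for_fwhm

__all__ = ["read_structure", "write_beadmodel_pdb", "read_beadmodel_pdb"]

_HYDROGEN_ELEMENTS = {"H", "D"}
_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """Malformed or unusable structure file."""


def read_structure(
    path: "str | Path",
    height: float = 7.0,
    width: float | None = None,
) -> BeadModel:
    """One Gaussian bead per heavy atom of a PDB file.

    See the module docstring for the atom selection policy.  Raises
    :class:`StructureParseError` if the file is malformed or contains no
    heavy atoms.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        try:
            structure = parser.get_structure(path.stem, str(path))
        except Exception as exc:  # Bio.PDB raises assorted exception types
            raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    models = list(structure.get_models())
    if not models:
        raise StructureParseError(f"{path} contains no models")
    coords: list[np.ndarray] = []
    for chain in models[0]:
        for residue in chain:
            hetflag = residue.id[0].strip()
            if hetflag:  # "W" for waters, "H_XXX" for other HETATM
                continue
            if residue.get_resname().strip() in _WATER_RESNAMES:
                continue
            for atom in residue.get_list():
                coords_atom = _select_altloc(atom)
                if coords_atom is None:
                    continue
                coords.append(coords_atom)
    if not coords:
        raise StructureParseError(f"{path} contains no heavy atoms")
    if width is None:
        width = default_width_for_fwhm(2.0)
    return BeadModel(positions=np.array(coords), height=height, width=width)


def _select_altloc(atom) -> "np.ndarray | None":
    """Highest-occupancy altloc (ties: first altloc id); None for H/D."""
    if atom.is_disordered():
        children = sorted(
            atom.disordered_get_list(),
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        atom = children[0]
    element = (atom.element or "").strip().upper()
    if element in _HYDROGEN_ELEMENTS:
        return None
    if not element:  # fall back to the atom name
        name = atom.get_name().strip()
        if name[:1] in _HYDROGEN_ELEMENTS:
            return None
    return np.asarray(atom.get_coord(), dtype=np.float64)


def write_beadmodel_pdb(model: BeadModel, path: "str | Path") -> None:
    """Write beads as ATOM pseudo-atoms with height/width REMARK lines."""
    path = Path(path)
    lines = [
        f"REMARK  99 RASTA BEAD MODEL M {model.m}",
        f"REMARK  99 RASTA BEAD HEIGHT {model.height:.8g}",
        f"REMARK  99 RASTA BEAD WIDTH {model.width:.8g}",
    ]
    for i, (x, y, z) in enumerate(model.positions, start=1):
        serial = i % 100000
        resseq = ((i - 1) // 1) % 10000
        lines.append(
            f"ATOM  {serial:5d}  C   BEA A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_beadmodel_pdb(path: "str | Path") -> BeadModel:
    """Read a bead model written by :func:`write_beadmodel_pdb`.

    Also accepts plain PDB coordinate files (then default height/width).
    """
    path = Path(path)
    height = 7.0
    width = default_width_for_fwhm(2.0)
    coords: list[tuple[float, float, float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("REMARK  99 RASTA BEAD HEIGHT"):
            height = float(line.split()[-1])
        elif line.startswith("REMARK  99 RASTA BEAD WIDTH"):
            width = float(line.split()[-1])
        elif line.startswith(("ATOM  ", "HETATM")):
            try:
                coords.append(
                    (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                )
            except ValueError as exc:
                raise StructureParseError(
                    f"{path}:{lineno}: bad coordinate field: {exc}"
                ) from exc
    if not coords:
        raise StructureParseError(f"{path} contains no coordinates")
    return BeadModel(positions=np.array(coords), height=height, width=width)
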