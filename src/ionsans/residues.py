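"""Residue hydrogen templates for heavy-atom structures.

Deposited channel models contain no hydrogens, so attached-hydrogen counts are
reconstructed per heavy atom from the residue chemistry at neutral pH:
Asp/Glu carboxylates and C-terminal carboxylates are ionized (no labile H),
Lys is protonated (3 labile H on NZ), Arg is protonated (5 labile H on the
guanidinium), His carries a single labile H on one imidazole nitrogen.

Each entry maps an atom name to ``(n_attached_H, n_labile_H)``; hydrogens
bound to carbon are non-labile, those bound to N/O/S exchange with solvent.
"""

from __future__ import annotations

# Backbone shared by all amino acids (glycine/proline special-cased below).
_BACKBONE = {"N": (1, 1), "CA": (1, 0), "C": (0, 0), "O": (0, 0), "OXT": (0, 0)}


def _res(side: dict[str, tuple[int, int]], **backbone_over) -> dict[str, tuple[int, int]]:
    d = dict(_BACKBONE)
    d.update(backbone_over)
    d.update(side)
    return d


RESIDUE_H: dict[str, dict[str, tuple[int, int]]] = {
    "ALA": _res({"CB": (3, 0)}),
    "ARG": _res({"CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "NE": (1, 1),
                 "CZ": (0, 0), "NH1": (2, 2), "NH2": (2, 2)}),
    "ASN": _res({"CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "ND2": (2, 2)}),
    "ASP": _res({"CB": (2, 0), "CG": (0, 0), "OD1": (0, 0), "OD2": (0, 0)}),
    "CYS": _res({"CB": (2, 0), "SG": (1, 1)}),
    "GLN": _res({"CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0), "NE2": (2, 2)}),
    "GLU": _res({"CB": (2, 0), "CG": (2, 0), "CD": (0, 0), "OE1": (0, 0), "OE2": (0, 0)}),
    "GLY": _res({}, CA=(2, 0)),
    "HIS": _res({"CB": (2, 0), "CG": (0, 0), "ND1": (1, 1), "CD2": (1, 0),
                 "CE1": (1, 0), "NE2": (0, 0)}),
    "ILE": _res({"CB": (1, 0), "CG1": (2, 0), "CG2": (3, 0), "CD1": (3, 0)}),
    "LEU": _res({"CB": (2, 0), "CG": (1, 0), "CD1": (3, 0), "CD2": (3, 0)}),
    "LYS": _res({"CB": (2, 0), "CG": (2, 0), "CD": (2, 0), "CE": (2, 0), "NZ": (3, 3)}),
    "MET": _res({"CB": (2, 0), "CG": (2, 0), "SD": (0, 0), "CE": (3, 0)}),
    "PHE": _res({"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0),
                 "CE1": (1, 0), "CE2": (1, 0), "CZ": (1, 0)}),
    "PRO": _res({"CB": (2, 0), "CG": (2, 0), "CD": (2, 0)}, N=(0, 0)),
    "SER": _res({"CB": (2, 0), "OG": (1, 1)}),
    "THR": _res({"CB": (1, 0), "OG1": (1, 1), "CG2": (3, 0)}),
    "TRP": _res({"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (0, 0),
                 "NE1": (1, 1), "CE2": (0, 0), "CE3": (1, 0), "CZ2": (1, 0),
                 "CZ3": (1, 0), "CH2": (1, 0)}),
    "TYR": _res({"CB": (2, 0), "CG": (0, 0), "CD1": (1, 0), "CD2": (1, 0),
                 "CE1": (1, 0), "CE2": (1, 0), "CZ": (0, 0), "OH": (1, 1)}),
    "VAL": _res({"CB": (1, 0), "CG1": (3, 0), "CG2": (3, 0)}),
    "HOH": {"O": (2, 2)},
}

# Per-residue (backbone, sidechain) labile hydrogen counts, derived from the
# atom templates above; convenient for composition-level arithmetic.
LABILE_H: dict[str, tuple[int, int]] = {}
for _name, _tmpl in RESIDUE_H.items():
    _bb = sum(lab for atom, (_n, lab) in _tmpl.items() if atom in _BACKBONE)
    _sc = sum(lab for atom, (_n, lab) in _tmpl.items() if atom not in _BACKBONE)
    LABILE_H[_name] = (_bb, _sc)

STANDARD_AMINO_ACIDS = tuple(n for n in RESIDUE_H if n != "HOH")

BACKBONE_ATOMS = frozenset(_BACKBONE)


def attached_hydrogens(residue_name: str, atom_name: str) -> tuple[int, int]:
    """``(n_attached_H, n_labile_H)`` for a heavy atom, (0, 0) if unknown."""
    tmpl = RESIDUE_H.get(residue_name.upper())
    if tmpl is None:
        return (0, 0)
    return tmpl.get(atom_name.upper(), (0, 0))


def residue_mass(residue_name: str) -> float:
    """Average residue mass within a chain (heavy atoms + template H), g/mol."""
    from .elements import ATOMIC_MASS

    tmpl = RESIDUE_H.get(residue_name.upper())
    if tmpl is None:
        return 0.0
    total = 0.0
    for atom, (n_h, _lab) in tmpl.items():
        if atom == "OXT":
            continue
        total += ATOMIC_MASS[_element_of(atom)] + n_h * ATOMIC_MASS["H"]
    return total


def _element_of(atom_name: str) -> str:
    # Amino-acid heavy atoms: first letter after any leading digits.
    head = atom_name.upper().lstrip("0123456789")
    return head[0] if head else "C"
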