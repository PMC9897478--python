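"""Atomic coordinate models: I/O, selections, superposition, weighted geometry.

A :class:`StructureModel` is a flat, ordered table of atom records backed by
numpy arrays, which keeps selections and geometry vectorized while the
:class:`AtomRecord` view preserves a familiar per-atom interface.  PDB and
mmCIF parsing is delegated to gemmi; writing uses the fixed-width PDB format
directly so round-trip precision is explicit (1e-3 A).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .elements import NEUTRON_B, mass_of

__all__ = [
    "AtomRecord",
    "StructureModel",
    "SuperpositionResult",
    "read_structure",
    "write_pdb",
    "parse_selection",
    "select",
    "center_of_mass",
    "radius_of_gyration",
    "superpose",
    "apply_superposition",
    "pairwise_min_distance",
]


@dataclass
class AtomRecord:
    """One atom of a structure; coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    altloc: str = ""
    occupancy: float = 1.0
    coordinates: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if self.element and self.element.upper() not in NEUTRON_B and self.element.upper() != "D":
            warnings.warn(
                f"element {self.element!r} (atom {self.name}) has no scattering-length entry; "
                "it will scatter with zero length",
                stacklevel=2,
            )


class StructureModel:
    """Ordered collection of atoms with vectorized column access."""

    def __init__(self, atoms: Iterable[AtomRecord], title: str = "", source_path: str = ""):
        records = list(atoms)
        self.title = title
        self.source_path = source_path
        n = len(records)
        self.serial = np.array([a.serial for a in records], dtype=int)
        self.name = np.array([a.name for a in records], dtype="U6")
        self.element = np.array([a.element.upper() for a in records], dtype="U2")
        self.residue_name = np.array([a.residue_name for a in records], dtype="U5")
        self.residue_number = np.array([a.residue_number for a in records], dtype=int)
        self.chain_id = np.array([a.chain_id for a in records], dtype="U2")
        self.altloc = np.array([a.altloc for a in records], dtype="U1")
        self.occupancy = np.array([a.occupancy for a in records], dtype=float)
        self.is_hetero = np.array([a.is_hetero for a in records], dtype=bool)
        self.coords = (
            np.array([a.coordinates for a in records], dtype=float)
            if n
            else np.zeros((0, 3))
        )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.serial)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def __getitem__(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_name=str(self.residue_name[i]),
            residue_number=int(self.residue_number[i]),
            chain_id=str(self.chain_id[i]),
            altloc=str(self.altloc[i]),
            occupancy=float(self.occupancy[i]),
            coordinates=self.coords[i].copy(),
            is_hetero=bool(self.is_hetero[i]),
        )

    def __iter__(self) -> Iterator[AtomRecord]:
        for i in range(len(self)):
            yield self[i]

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self)

    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.element])

    def subset(self, indices: Sequence[int] | np.ndarray) -> "StructureModel":
        """New model with the selected atoms, original order preserved."""
        idx = np.asarray(indices, dtype=int)
        out = StructureModel([], title=self.title, source_path=self.source_path)
        for attr in ("serial", "name", "element", "residue_name", "residue_number",
                     "chain_id", "altloc", "occupancy", "is_hetero"):
            setattr(out, attr, getattr(self, attr)[idx].copy())
        out.coords = self.coords[idx].copy()
        return out

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy sharing all identities but with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise ValueError(f"coordinate shape {coords.shape} != {self.coords.shape}")
        out = self.subset(np.arange(len(self)))
        out.coords = coords.copy()
        return out

    def copy(self) -> "StructureModel":
        return self.subset(np.arange(len(self)))

    # -- convenience geometry ----------------------------------------------
    def select(self, expr) -> np.ndarray:
        return select(self, expr)

    def center_of_mass(self, indices=None, weighting: str = "mass", contrast=None) -> np.ndarray:
        return center_of_mass(self, indices, weighting=weighting, contrast=contrast)

    def radius_of_gyration(self, indices=None, weighting: str = "mass", contrast=None) -> float:
        return radius_of_gyration(self, indices, weighting=weighting, contrast=contrast)

    def __repr__(self) -> str:
        chains = sorted(set(self.chain_id))
        return f"<StructureModel {self.title!r}: {len(self)} atoms, chains {chains}>"


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

_ALTLOC_POLICIES = ("highest_occupancy", "first", "all")


def read_structure(path, altloc_policy: str = "highest_occupancy", model: str = "first"):
    """Read a PDB or mmCIF file into one :class:`StructureModel` (or a list).

    Ions and other heteroatoms are retained as hetero records.  Multi-model
    files return the first model unless ``model='all'``.  Altloc groups are
    resolved to a single atom per the policy: ``highest_occupancy`` keeps the
    most occupied alternative (ties broken by altloc letter), ``first`` keeps
    the first encountered, ``all`` keeps every alternative.
    """
    import gemmi

    if altloc_policy not in _ALTLOC_POLICIES:
        raise ValueError(f"altloc_policy must be one of {_ALTLOC_POLICIES}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc

    models = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element warnings handled in bulk below
        for gm in st:
            records: list[AtomRecord] = []
            for chain in gm:
                for residue in chain:
                    het = residue.het_flag == "H"
                    for atom in residue:
                        records.append(
                            AtomRecord(
                                serial=atom.serial,
                                name=atom.name,
                                element=atom.element.name.upper(),
                                residue_name=residue.name,
                                residue_number=residue.seqid.num,
                                chain_id=chain.name,
                                altloc=atom.altloc if atom.altloc else "",
                                occupancy=min(max(atom.occ, 0.0), 1.0),
                                coordinates=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                                is_hetero=het,
                            )
                        )
            if altloc_policy != "all":
                records = _resolve_altlocs(records, altloc_policy)
            models.append(StructureModel(records, title=st.name or path.stem, source_path=str(path)))
            if model == "first":
                break
    unknown = sorted(
        {e for m in models for e in m.element if e and e not in NEUTRON_B}
    )
    if unknown:
        warnings.warn(
            f"{path.name}: elements with no scattering-length entry kept with zero length: {unknown}",
            stacklevel=2,
        )
    if not models or all(len(m) == 0 for m in models):
        raise ValueError(f"{path}: no atom records found")
    return models if model == "all" else models[0]


def _resolve_altlocs(records: list[AtomRecord], policy: str) -> list[AtomRecord]:
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    order: list[tuple] = []
    for i, rec in enumerate(records):
        key = (rec.chain_id, rec.residue_number, rec.residue_name, rec.name)
        if key not in best:
            best[key] = (i, rec)
            order.append(key)
        elif policy == "highest_occupancy":
            _, cur = best[key]
            if (rec.occupancy, -ord(rec.altloc or "~")) > (cur.occupancy, -ord(cur.altloc or "~")):
                best[key] = (best[key][0], rec)
    return [best[k][1] for k in order]


def write_pdb(structure: StructureModel, path, *, frames: np.ndarray | None = None) -> None:
    """Write a (possibly multi-model) PDB file.

    ``frames`` — optional (n_frames, n_atoms, 3) array; when given, one MODEL
    block per frame is written using the structure's atom identities.
    """
    path = Path(path)
    coord_sets = frames if frames is not None else structure.coords[None]
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:70]}\n")
        multi = len(coord_sets) > 1
        for m, coords in enumerate(coord_sets, start=1):
            if multi:
                fh.write(f"MODEL     {m:4d}\n")
            for i in range(len(structure)):
                fh.write(_pdb_atom_line(structure, i, coords[i]))
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def _pdb_atom_line(s: StructureModel, i: int, xyz: np.ndarray) -> str:
    record = "HETATM" if s.is_hetero[i] else "ATOM  "
    name = str(s.name[i])
    # PDB column convention: 1-3 character names start in column 14.
    name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    elem = str(s.element[i])[:2].rjust(2)
    return (
        f"{record}{int(s.serial[i]) % 100000:5d} {name_field}{str(s.altloc[i]) or ' '}"
        f"{str(s.residue_name[i]):<4s}{str(s.chain_id[i])[:1] or 'A'}"
        f"{int(s.residue_number[i]) % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{float(s.occupancy[i]):6.2f}{0.0:6.2f}"
        f"          {elem}\n"
    )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_KEYWORDS = {"and", "or", "not", "(", ")"}
_FLAGS = {
    "all", "none", "protein", "hetero", "water", "calpha", "backbone",
    "sidechain", "heavy", "hydrogen", "sidechain-o",
}
_FIELDS = {"chain", "resid", "resname", "name", "element"}


class SelectionExpr:
    """Parsed selection expression; evaluates to a boolean mask on any model."""

    def __init__(self, node):
        self._node = node

    def mask(self, structure: StructureModel) -> np.ndarray:
        return _eval_node(self._node, structure)

    def indices(self, structure: StructureModel) -> np.ndarray:
        return np.flatnonzero(self.mask(structure))

    def __and__(self, other: "SelectionExpr") -> "SelectionExpr":
        return SelectionExpr(("and", self._node, other._node))

    def __or__(self, other: "SelectionExpr") -> "SelectionExpr":
        return SelectionExpr(("or", self._node, other._node))

    def __invert__(self) -> "SelectionExpr":
        return SelectionExpr(("not", self._node))


def parse_selection(text: str) -> SelectionExpr:
    """Parse a selection string such as ``"chain A and resid 340-360 and name CA"``."""
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise ValueError("empty selection expression")
    node, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in selection: {' '.join(tokens[pos:])!r}")
    return SelectionExpr(node)


def _parse_or(tokens, pos):
    node, pos = _parse_and(tokens, pos)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        rhs, pos = _parse_and(tokens, pos + 1)
        node = ("or", node, rhs)
    return node, pos


def _parse_and(tokens, pos):
    node, pos = _parse_factor(tokens, pos)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        rhs, pos = _parse_factor(tokens, pos + 1)
        node = ("and", node, rhs)
    return node, pos


def _parse_factor(tokens, pos):
    if pos >= len(tokens):
        raise ValueError("unexpected end of selection expression")
    tok = tokens[pos].lower()
    if tok == "not":
        node, pos = _parse_factor(tokens, pos + 1)
        return ("not", node), pos
    if tok == "(":
        node, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ValueError("unbalanced parenthesis in selection")
        return node, pos + 1
    if tok in _FLAGS:
        return ("flag", tok), pos + 1
    if tok in _FIELDS:
        values = []
        pos += 1
        while pos < len(tokens) and tokens[pos].lower() not in _KEYWORDS \
                and tokens[pos].lower() not in _FLAGS and tokens[pos].lower() not in _FIELDS:
            values.append(tokens[pos])
            pos += 1
        if not values:
            raise ValueError(f"selection field {tok!r} needs at least one value")
        return ("field", tok, values), pos
    raise ValueError(f"unrecognized selection token {tokens[pos]!r}")


def _eval_node(node, s: StructureModel) -> np.ndarray:
    op = node[0]
    if op == "and":
        return _eval_node(node[1], s) & _eval_node(node[2], s)
    if op == "or":
        return _eval_node(node[1], s) | _eval_node(node[2], s)
    if op == "not":
        return ~_eval_node(node[1], s)
    if op == "flag":
        return _eval_flag(node[1], s)
    if op == "field":
        return _eval_field(node[1], node[2], s)
    raise AssertionError(node)


def _eval_flag(flag: str, s: StructureModel) -> np.ndarray:
    n = len(s)
    if flag == "all":
        return np.ones(n, dtype=bool)
    if flag == "none":
        return np.zeros(n, dtype=bool)
    if flag == "hetero":
        return s.is_hetero.copy()
    if flag == "water":
        return np.isin(s.residue_name, ("HOH", "WAT", "TIP3"))
    if flag == "protein":
        return ~s.is_hetero & ~np.isin(s.residue_name, ("HOH", "WAT", "TIP3"))
    if flag == "hydrogen":
        return np.isin(s.element, ("H", "D"))
    if flag == "heavy":
        return ~np.isin(s.element, ("H", "D"))
    backbone = np.isin(s.name, ("N", "CA", "C", "O", "OXT")) & ~s.is_hetero
    if flag == "backbone":
        return backbone
    if flag == "calpha":
        return (s.name == "CA") & ~s.is_hetero
    if flag == "sidechain":
        return _eval_flag("protein", s) & ~backbone
    if flag == "sidechain-o":
        return _eval_flag("sidechain", s) & (s.element == "O")
    raise AssertionError(flag)


def _eval_field(fieldname: str, values: list[str], s: StructureModel) -> np.ndarray:
    if fieldname == "chain":
        return np.isin(s.chain_id, [v for v in values])
    if fieldname == "resname":
        return np.isin(s.residue_name, [v.upper() for v in values])
    if fieldname == "name":
        return np.isin(s.name, [v.upper() for v in values])
    if fieldname == "element":
        return np.isin(s.element, [v.upper() for v in values])
    if fieldname == "resid":
        mask = np.zeros(len(s), dtype=bool)
        for v in values:
            for part in v.split(","):
                if not part:
                    continue
                m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", part)
                if m is None:
                    raise ValueError(f"bad resid range {part!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (s.residue_number >= lo) & (s.residue_number <= hi)
        return mask
    raise AssertionError(fieldname)


def select(structure: StructureModel, expr) -> np.ndarray:
    """Evaluate a selection to an order-preserving index array.

    ``expr`` may be a selection string, a :class:`SelectionExpr`, a boolean
    mask, an index sequence, or None (meaning all atoms).
    """
    if expr is None:
        return np.arange(len(structure))
    if isinstance(expr, str):
        expr = parse_selection(expr)
    if isinstance(expr, SelectionExpr):
        return expr.indices(structure)
    arr = np.asarray(expr)
    if arr.dtype == bool:
        if arr.shape != (len(structure),):
            raise ValueError("boolean selection mask has wrong length")
        return np.flatnonzero(arr)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# Weighted geometry
# ---------------------------------------------------------------------------

def _weights(structure: StructureModel, idx: np.ndarray, weighting: str, contrast) -> np.ndarray:
    if weighting == "uniform":
        return np.ones(len(idx))
    if weighting == "mass":
        return structure.masses()[idx]
    if weighting == "excess_b":
        if contrast is None:
            raise ValueError("excess_b weighting requires a ContrastModel")
        from .scattering import excess_scattering_lengths

        return excess_scattering_lengths(structure, contrast)[idx]
    raise ValueError(f"unknown weighting {weighting!r}")


def center_of_mass(structure, indices=None, weighting="mass", contrast=None) -> np.ndarray:
    idx = select(structure, indices)
    if len(idx) == 0:
        raise ValueError("center_of_mass: empty selection")
    w = _weights(structure, idx, weighting, contrast)
    total = w.sum()
    if total == 0:
        raise ValueError("center_of_mass: weights sum to zero")
    return (structure.coords[idx] * w[:, None]).sum(axis=0) / total


def radius_of_gyration(structure, indices=None, weighting="mass", contrast=None) -> float:
    """Weighted radius of gyration sqrt(sum w |r - rbar|^2 / sum w), A."""
    idx = select(structure, indices)
    if len(idx) == 0:
        raise ValueError("radius_of_gyration: empty selection")
    if len(idx) == 1:
        warnings.warn("radius_of_gyration of a single atom is 0", stacklevel=2)
        return 0.0
    w = _weights(structure, idx, weighting, contrast)
    com = (structure.coords[idx] * w[:, None]).sum(axis=0) / w.sum()
    d2 = ((structure.coords[idx] - com) ** 2).sum(axis=1)
    return float(np.sqrt((w * d2).sum() / w.sum()))


@dataclass
class SuperpositionResult:
    """Rigid-body fit mapping mobile onto reference: x' = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def superpose(mobile, reference, indices=None, ref_indices=None) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of mobile onto reference.

    ``mobile``/``reference`` may be StructureModel or (n, 3) coordinate
    arrays; selections must have equal size with 1:1 correspondence.
    """
    P = mobile.coords if isinstance(mobile, StructureModel) else np.asarray(mobile, dtype=float)
    Q = reference.coords if isinstance(reference, StructureModel) else np.asarray(reference, dtype=float)
    idx_p = select(mobile, indices) if isinstance(mobile, StructureModel) else (
        np.arange(len(P)) if indices is None else np.asarray(indices, int))
    if ref_indices is None:
        ref_indices = indices
    idx_q = select(reference, ref_indices) if isinstance(reference, StructureModel) else (
        np.arange(len(Q)) if ref_indices is None else np.asarray(ref_indices, int))
    P, Q = P[idx_p], Q[idx_q]
    if P.shape != Q.shape:
        raise ValueError(f"selection size mismatch: {P.shape[0]} vs {Q.shape[0]} atoms")
    if len(P) < 3:
        raise ValueError("superposition needs at least 3 atom pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum() / len(P)))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(result: SuperpositionResult, coords_or_structure):
    """Apply a fitted rigid transform to coordinates or a whole structure."""
    if isinstance(coords_or_structure, StructureModel):
        new = coords_or_structure.coords @ result.rotation.T + result.translation
        return coords_or_structure.with_coords(new)
    coords = np.asarray(coords_or_structure, dtype=float)
    return coords @ result.rotation.T + result.translation


def pairwise_min_distance(structure, indices_a, indices_b, structure_b=None) -> float:
    """Minimum cross-pair Euclidean distance between two selections, A."""
    from scipy.spatial.distance import cdist

    other = structure_b if structure_b is not None else structure
    ia = select(structure, indices_a)
    ib = select(other, indices_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("pairwise_min_distance: empty selection")
    d = cdist(structure.coords[ia], other.coords[ib])
    dmin = float(d.min())
    if dmin == 0.0 and structure_b is None and len(np.intersect1d(ia, ib)):
        warnings.warn("selections share atoms; minimum distance is 0", stacklevel=2)
    return dmin
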