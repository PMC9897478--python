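"""Pore-radius profiles of channel models along the pseudo-symmetry axis.

The profile is the HOLE/CHAP-style clearance function: at each position z
along the channel axis, the largest sphere centered in the plane z (within
``max_offaxis`` of the axis) that touches no atom, i.e.

    radius(z) = max_{|c_xy| <= max_offaxis} min_i ( |c - x_i| - r_vdw,i )

maximized over a fixed polar candidate lattice plus a seeded compass-search
refinement, and clipped to a bulk cutoff where the pore opens to solvent.
The z origin is anchored at the 9' hydrophobic gate by convention (mean z of
the anchor residue's C-alpha atoms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import vdw_radius_of
from .model import StructureModel, center_of_mass, select

__all__ = ["AxisFrame", "PoreProfile", "channel_axis", "pore_profile",
           "profile_statistics", "write_profile"]


@dataclass
class AxisFrame:
    """Channel axis: origin point, unit direction (+z toward extracellular)."""

    origin: np.ndarray
    axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(self.axis)
        if norm == 0:
            raise ValueError("axis vector must be nonzero")
        self.axis = self.axis / norm

    def to_frame(self, coords: np.ndarray) -> np.ndarray:
        """Express coordinates in the axis frame (axis along +z)."""
        e3 = self.axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(e3 @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ref, e3)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(e3, e1)
        R = np.vstack([e1, e2, e3])
        return (np.asarray(coords, dtype=float) - self.origin) @ R.T


@dataclass
class PoreProfile:
    """radius(z) along the pore, with the optimized center path."""

    z: np.ndarray
    radius: np.ndarray
    center_path: np.ndarray
    atom_subset: str = "heavy"
    bulk_flag: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(self.radius < 0):
            raise ValueError("pore radii must be nonnegative")

    def min_radius(self, z_lo: float = -np.inf, z_hi: float = np.inf) -> float:
        mask = (self.z >= z_lo) & (self.z <= z_hi)
        return float(self.radius[mask].min())


def channel_axis(structure: StructureModel, method: str = "inertia",
                 selection=None, bottom_selection=None, top_selection=None) -> AxisFrame:
    """Determine the channel axis.

    ``inertia``: principal (largest-variance) axis of the C-alpha set (or of
    ``selection``), which for an elongated pentamer is the pore axis; an
    ambiguity error is raised when the structure is near-spherical.
    ``selection-com-line``: line through the centers of mass of
    ``bottom_selection`` (e.g. TMD) and ``top_selection`` (e.g. ECD), oriented
    bottom -> top so the extracellular side has larger z.
    """
    if method == "selection-com-line":
        if bottom_selection is None or top_selection is None:
            raise ValueError("selection-com-line needs bottom_selection and top_selection")
        a = center_of_mass(structure, bottom_selection, weighting="uniform")
        b = center_of_mass(structure, top_selection, weighting="uniform")
        return AxisFrame(origin=a, axis=b - a)
    if method != "inertia":
        raise ValueError(f"unknown axis method {method!r}")
    if selection is None:
        idx = select(structure, "calpha")
        if len(idx) == 0:
            idx = select(structure, "all")
    else:
        idx = select(structure, selection)
    coords = structure.coords[idx]
    com = coords.mean(axis=0)
    cov = np.cov((coords - com).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] < 1.25 * evals[-2]:
        raise ValueError(
            "inertia axis is ambiguous (near-spherical mass distribution); "
            "use method='selection-com-line'"
        )
    axis = evecs[:, -1]
    if top_selection is not None:
        top = center_of_mass(structure, top_selection, weighting="uniform")
        if (top - com) @ axis < 0:
            axis = -axis
    return AxisFrame(origin=com, axis=axis)


def _clearance(centers_xy: np.ndarray, z: float, atoms_xyz: np.ndarray,
               radii: np.ndarray) -> np.ndarray:
    """min_i(|c - x_i| - r_i) for each candidate center (vectorized)."""
    c = np.column_stack([centers_xy, np.full(len(centers_xy), z)])
    d = np.sqrt(((c[:, None, :] - atoms_xyz[None, :, :]) ** 2).sum(axis=2))
    return (d - radii[None, :]).min(axis=1)


def pore_profile(structure: StructureModel, axis: AxisFrame,
                 z_range: tuple[float, float] | None = None, step: float = 0.5,
                 max_offaxis: float = 6.0, radii_table=None,
                 atom_subset: str = "heavy", bulk_cutoff: float = 12.0,
                 anchor_selection=None, n_refine_seeds: int = 8,
                 rng_seed: int = 2022) -> PoreProfile:
    """Compute a pore-radius profile along the axis.

    The candidate lattice per slice is polar with fixed radial step 0.5 A and
    24 angles (nested across ``max_offaxis`` values, which makes the profile
    monotone under relaxation of the off-axis bound); the best lattice points
    seed a compass-search refinement.  ``anchor_selection`` (e.g. C-alpha of
    the 9' gate residues) re-zeroes the z grid at its mean z.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    subset_expr = {"heavy": "heavy", "backbone": "backbone"}.get(atom_subset)
    if subset_expr is None:
        raise ValueError("atom_subset must be 'heavy' or 'backbone'")
    idx = select(structure, subset_expr)
    if len(idx) == 0:
        raise ValueError("no atoms in the requested subset")
    local = axis.to_frame(structure.coords[idx])
    if radii_table is None:
        radii = np.array([vdw_radius_of(e) for e in structure.element[idx]])
    else:
        radii = np.array([radii_table.get(str(e), vdw_radius_of(e))
                          for e in structure.element[idx]])

    z_anchor = 0.0
    if anchor_selection is not None:
        aidx = select(structure, anchor_selection)
        if len(aidx) == 0:
            raise ValueError("anchor selection is empty")
        z_anchor = float(axis.to_frame(structure.coords[aidx])[:, 2].mean())

    if z_range is None:
        z_lo, z_hi = float(local[:, 2].min()), float(local[:, 2].max())
    else:
        z_lo, z_hi = z_range
        z_lo, z_hi = z_lo + z_anchor, z_hi + z_anchor
    n_z = int(np.floor((z_hi - z_lo) / step)) + 1
    z_grid = z_lo + step * np.arange(n_z)

    # fixed polar lattice: nested in max_offaxis by construction
    lat_r = np.arange(0.0, max_offaxis + 1e-9, 0.5)
    lat_t = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    lattice = [np.zeros((1, 2))]
    for rr in lat_r[1:]:
        lattice.append(np.column_stack([rr * np.cos(lat_t), rr * np.sin(lat_t)]))
    lattice = np.vstack(lattice)

    rng = np.random.default_rng(rng_seed)
    radii_out = np.zeros(n_z)
    centers_out = np.zeros((n_z, 3))
    bulk = np.zeros(n_z, dtype=bool)
    reach = bulk_cutoff + float(radii.max())
    for k, z in enumerate(z_grid):
        near = np.abs(local[:, 2] - z) <= reach
        atoms = local[near]
        arad = radii[near]
        if len(atoms) == 0:
            radii_out[k] = bulk_cutoff
            centers_out[k] = [0.0, 0.0, z]
            bulk[k] = True
            continue
        clear = _clearance(lattice, z, atoms, arad)
        order = np.argsort(clear)[::-1]
        seeds = lattice[order[:n_refine_seeds]]
        # deterministic jitter diversifies seeds that collapse onto the axis
        seeds = seeds + rng.normal(scale=0.05, size=seeds.shape)
        best_val = float(clear.max())
        best_xy = lattice[int(order[0])]
        for s in seeds:
            val, xy = _compass_search(s, z, atoms, arad, max_offaxis)
            if val > best_val:
                best_val, best_xy = val, xy
        if best_val >= bulk_cutoff:
            best_val = bulk_cutoff
            bulk[k] = True
        radii_out[k] = max(best_val, 0.0)
        centers_out[k] = [best_xy[0], best_xy[1], z]
    return PoreProfile(z=z_grid - z_anchor, radius=radii_out, center_path=centers_out,
                       atom_subset=atom_subset, bulk_flag=bulk)


def _compass_search(start_xy: np.ndarray, z: float, atoms: np.ndarray,
                    radii: np.ndarray, max_offaxis: float,
                    step0: float = 0.25, tol: float = 1e-4) -> tuple[float, np.ndarray]:
    xy = np.asarray(start_xy, dtype=float)
    if np.linalg.norm(xy) > max_offaxis:
        xy = xy * (max_offaxis / np.linalg.norm(xy))
    best = float(_clearance(xy[None], z, atoms, radii)[0])
    h = step0
    dirs = np.array([[1, 0], [-1, 0], [0, 1], [0, -1],
                     [1, 1], [1, -1], [-1, 1], [-1, -1]], dtype=float)
    dirs[4:] /= np.sqrt(2.0)
    while h > tol:
        cand = xy + h * dirs
        norms = np.linalg.norm(cand, axis=1)
        ok = norms <= max_offaxis
        if ok.any():
            vals = _clearance(cand[ok], z, atoms, radii)
            j = int(np.argmax(vals))
            if vals[j] > best:
                best = float(vals[j])
                xy = cand[ok][j]
                continue
        h *= 0.5
    return best, xy


def profile_statistics(profiles: list[PoreProfile]) -> dict[str, np.ndarray]:
    """Elementwise mean, SD, min and max of profiles on a common z grid."""
    if not profiles:
        raise ValueError("no profiles given")
    z0 = profiles[0].z
    for p in profiles[1:]:
        if len(p.z) != len(z0) or not np.allclose(p.z, z0):
            raise ValueError("profiles are not on a common z grid")
    stack = np.vstack([p.radius for p in profiles])
    return {
        "z": z0.copy(),
        "mean": stack.mean(axis=0),
        "sd": stack.std(axis=0),
        "min": stack.min(axis=0),
        "max": stack.max(axis=0),
    }


def write_profile(profile: PoreProfile, path) -> None:
    """TSV export: z, radius, center x, center y."""
    with open(path, "w") as fh:
        fh.write("z\tradius\tx\ty\n")
        for z, r, c in zip(profile.z, profile.radius, profile.center_path):
            fh.write(f"{z:.3f}\t{r:.4f}\t{c[0]:.3f}\t{c[1]:.3f}\n")
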