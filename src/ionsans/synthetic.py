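"""Synthetic toy channels, lobe-motion trajectories, and noisy SANS data.

The toy channel emulates the architecture of a pentameric ligand-gated ion
channel with peripheral amino-terminal domains: a C5-symmetric core of four
transmembrane rods per subunit plus an extracellular annular blob, and two
mobile peripheral lobes per subunit (NTD1-like, outer and lower; NTD2-like,
inner and upper).  Defaults are scaled to the real system (about 2,500
pseudo-atoms, Rg near 50 A, Dmax near 160 A).  All generators are
deterministic given (spec, seed).

Domain labelling uses residue-number ranges, stable under relabelling:
TMD rods 1-4, ECD 10-59, NTD1 100-139, NTD2 200-239 within each chain A-E.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ensemble import Trajectory
from .model import AtomRecord, StructureModel, radius_of_gyration, select
from .scattering import ContrastModel, ScatteringCurve, debye_curve

__all__ = [
    "ToyChannelSpec",
    "LobeWalkSpec",
    "build_toy_channel",
    "lobe_selection",
    "lobe_labels",
    "perturb_lobes",
    "lobe_walk_trajectory",
    "simulate_sans",
]

_CHAINS = "ABCDEFGHIJ"

NTD1_RESID = (100, 139)
NTD2_RESID = (200, 239)
TMD_RESID = (1, 4)
ECD_RESID = (10, 59)


@dataclass
class ToyChannelSpec:
    """Parameters of the C_n-symmetric toy channel."""

    n_subunits: int = 5
    # TMD: four helix-like rods per subunit
    rod_radii: tuple = (9.0, 14.0, 19.0, 24.0)       # distance from axis, A
    rod_z: tuple = (-34.0, 0.0)                      # z extent of the rods
    rod_atoms: int = 20                              # pseudo-atoms per rod
    # ECD: annular blob per subunit
    ecd_atoms: int = 220
    ecd_radial: tuple = (14.0, 32.0)
    ecd_z: tuple = (5.0, 60.0)
    # peripheral lobes (NTD1-like and NTD2-like)
    ntd1_center: tuple = (50.0, 78.0)                # (r_xy, z) of the cluster center
    ntd2_center: tuple = (32.0, 100.0)
    lobe_radius: float = 8.0                         # cluster radius, A
    lobe_atoms: int = 90
    lobe_azimuth_offset: float = 10.0                # degrees from subunit direction
    atom_weight: float = 1.0                         # uniform excess scattering weight
    mode: str = "uniform"                            # 'uniform' or 'alanine'
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_subunits", "rod_atoms", "ecd_atoms", "lobe_atoms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LobeWalkSpec:
    """Bounded mean-reverting random walk of the peripheral lobes.

    Per-frame steps are drawn per lobe in cylindrical coordinates with the
    given step sigmas, pulled back toward the start with strength
    ``mean_reversion`` (an Ornstein-Uhlenbeck-like discrete walk) and
    reflected at the bounds, which must enclose the starting positions.
    """

    sigma_r: float = 1.5          # A / frame
    sigma_z: float = 1.5
    sigma_azimuth: float = 1.0    # degrees / frame
    mean_reversion: float = 0.05  # fraction of the offset removed per frame
    bounds_r: tuple = (-12.0, 18.0)   # relative to the starting r_xy
    bounds_z: tuple = (-18.0, 12.0)
    bounds_azimuth: tuple = (-15.0, 15.0)
    n_frames: int = 50
    dt_ns: float = 10.0
    seed: int = 11

    def __post_init__(self) -> None:
        for b in (self.bounds_r, self.bounds_z, self.bounds_azimuth):
            if not b[0] <= 0.0 <= b[1]:
                raise ValueError("walk bounds must enclose the starting position")
        if not 0.0 <= self.mean_reversion <= 1.0:
            raise ValueError("mean_reversion must be in [0, 1]")


def _subunit_atoms(spec: ToyChannelSpec, rng: np.random.Generator):
    """Pseudo-atom positions and residue ids of one subunit at azimuth 0."""
    coords = []
    resids = []
    # TMD rods
    z = np.linspace(spec.rod_z[0], spec.rod_z[1], spec.rod_atoms)
    for m, rho in enumerate(spec.rod_radii):
        phi = np.deg2rad(8.0 * m)  # stagger rods around the subunit direction
        xs = np.full_like(z, rho * np.cos(phi))
        ys = np.full_like(z, rho * np.sin(phi))
        coords.append(np.column_stack([xs, ys, z]))
        resids.append(np.full(spec.rod_atoms, TMD_RESID[0] + m))
    # ECD annular wedge
    r = rng.uniform(spec.ecd_radial[0], spec.ecd_radial[1], spec.ecd_atoms)
    th = rng.uniform(-np.pi / spec.n_subunits, np.pi / spec.n_subunits, spec.ecd_atoms)
    ze = rng.uniform(spec.ecd_z[0], spec.ecd_z[1], spec.ecd_atoms)
    coords.append(np.column_stack([r * np.cos(th), r * np.sin(th), ze]))
    resids.append(ECD_RESID[0] + (np.arange(spec.ecd_atoms) * (ECD_RESID[1] - ECD_RESID[0] + 1))
                  // spec.ecd_atoms)
    # lobes: uniform balls
    for (r0, z0), base in ((spec.ntd1_center, NTD1_RESID[0]), (spec.ntd2_center, NTD2_RESID[0])):
        phi = np.deg2rad(spec.lobe_azimuth_offset)
        center = np.array([r0 * np.cos(phi), r0 * np.sin(phi), z0])
        u = rng.normal(size=(spec.lobe_atoms, 3))
        u /= np.linalg.norm(u, axis=1)[:, None]
        rad = spec.lobe_radius * rng.uniform(0, 1, spec.lobe_atoms) ** (1 / 3)
        coords.append(center + u * rad[:, None])
        resids.append(base + (np.arange(spec.lobe_atoms) * 40) // spec.lobe_atoms)
    return np.vstack(coords), np.concatenate(resids)


_ALA_CYCLE = ("N", "CA", "C", "O", "CB")


def build_toy_channel(spec: ToyChannelSpec | None = None):
    """Build the toy channel; returns (StructureModel, ground_truth dict).

    The assembly is exactly C_n-symmetric: one subunit is generated from the
    seeded RNG and rotated into the remaining chains.  Ground truth reports
    the weighted Rg, center of mass, maximum pair distance, and per-lobe
    cluster centers, all computed from the generated coordinates.
    """
    spec = spec or ToyChannelSpec()
    rng = np.random.default_rng(spec.seed)
    sub_coords, sub_resids = _subunit_atoms(spec, rng)
    records = []
    serial = 1
    all_coords = []
    for s in range(spec.n_subunits):
        ang = 2.0 * np.pi * s / spec.n_subunits
        c, sn = np.cos(ang), np.sin(ang)
        R = np.array([[c, -sn, 0.0], [sn, c, 0.0], [0.0, 0.0, 1.0]])
        coords = sub_coords @ R.T
        all_coords.append(coords)
        chain = _CHAINS[s]
        within_res: dict[int, int] = {}
        for i, (xyz, resid) in enumerate(zip(coords, sub_resids)):
            if spec.mode == "alanine":
                name = _ALA_CYCLE[i % 5]
                resname = "ALA"
                element = "N" if name == "N" else ("O" if name == "O" else "C")
                resid = i // 5 + 1  # one pseudo-alanine per 5 pseudo-atoms
            else:
                # unique atom names within each residue keep PDB round-trips lossless
                k = within_res.get(int(resid), 0)
                within_res[int(resid)] = k + 1
                name = f"C{k + 1}"
                resname = _domain_of_resid(int(resid))
                element = "C"
            records.append(AtomRecord(
                serial=serial, name=name, element=element, residue_name=resname,
                residue_number=int(resid), chain_id=chain, coordinates=xyz,
            ))
            serial += 1
    structure = StructureModel(records, title=f"toy C{spec.n_subunits} channel")
    weights = np.full(len(structure), spec.atom_weight)
    coords = structure.coords
    com = coords.mean(axis=0)
    rg = float(np.sqrt(((coords - com) ** 2).sum(axis=1).mean()))
    dmax = _max_pair_distance(coords)
    lobe_centers = {}
    for label in lobe_labels(structure):
        idx = select(structure, lobe_selection(*label))
        lobe_centers[label] = coords[idx].mean(axis=0)
    truth = {
        "rg": rg,
        "com": com,
        "dmax": dmax,
        "lobe_centers": lobe_centers,
        "weights": weights,
        "n_atoms": len(structure),
    }
    return structure, truth


def _domain_of_resid(resid: int) -> str:
    if TMD_RESID[0] <= resid <= TMD_RESID[1]:
        return "TMD"
    if ECD_RESID[0] <= resid <= ECD_RESID[1]:
        return "ECD"
    if NTD1_RESID[0] <= resid <= NTD1_RESID[1]:
        return "NT1"
    return "NT2"


def _max_pair_distance(coords: np.ndarray) -> float:
    from scipy.spatial import ConvexHull
    from scipy.spatial.distance import pdist

    if len(coords) > 500:
        hull = ConvexHull(coords)
        pts = coords[hull.vertices]
    else:
        pts = coords
    return float(pdist(pts).max())


def lobe_selection(lobe: str, chain: str) -> str:
    """Selection string for one peripheral lobe ('NTD1' or 'NTD2') of a chain."""
    ranges = {"NTD1": NTD1_RESID, "NTD2": NTD2_RESID}
    if lobe not in ranges:
        raise KeyError(f"unknown lobe label {lobe!r} (expected 'NTD1' or 'NTD2')")
    lo, hi = ranges[lobe]
    return f"chain {chain} and resid {lo}-{hi}"


def lobe_labels(structure: StructureModel) -> list[tuple[str, str]]:
    """All (lobe, chain) labels present in a toy structure."""
    chains = sorted(set(str(c) for c in structure.chain_id))
    labels = []
    for chain in chains:
        for lobe in ("NTD1", "NTD2"):
            if len(select(structure, lobe_selection(lobe, chain))):
                labels.append((lobe, chain))
    return labels


def perturb_lobes(structure: StructureModel, displacements: dict) -> StructureModel:
    """Rigidly translate named lobes; the core is untouched.

    ``displacements`` maps (lobe, chain) labels to (dr, dz) or
    (dr, dz, dazimuth_deg) cylindrical offsets of the cluster center about
    the z axis: dr > 0 moves the lobe outward, dz < 0 down toward the
    membrane.
    """
    coords = structure.coords.copy()
    for label, disp in displacements.items():
        lobe, chain = label
        idx = select(structure, lobe_selection(lobe, chain))
        if len(idx) == 0:
            raise KeyError(f"lobe {label!r} not found in structure")
        dr, dz = disp[0], disp[1]
        dphi = np.deg2rad(disp[2]) if len(disp) > 2 else 0.0
        center = coords[idx].mean(axis=0)
        r0 = np.hypot(center[0], center[1])
        phi0 = np.arctan2(center[1], center[0])
        new_center = np.array([
            (r0 + dr) * np.cos(phi0 + dphi),
            (r0 + dr) * np.sin(phi0 + dphi),
            center[2] + dz,
        ])
        coords[idx] += new_center - center
    return structure.with_coords(coords)


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflect into [lo, hi]; at most a few bounces for sane steps
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def lobe_walk_trajectory(structure: StructureModel, walk: LobeWalkSpec | None = None,
                         lobes: list | None = None) -> Trajectory:
    """Seeded bounded mean-reverting random walk of the peripheral lobes.

    Each lobe's cluster center performs an independent discrete
    Ornstein-Uhlenbeck walk in (r_xy, z, azimuth) about its starting value,
    reflected at the bounds; lobe clusters translate rigidly and the core
    stays static.  Frame times advance by ``dt_ns``.
    """
    walk = walk or LobeWalkSpec()
    labels = lobes if lobes is not None else lobe_labels(structure)
    rng = np.random.default_rng(walk.seed)
    frames = np.repeat(structure.coords[None], walk.n_frames, axis=0)
    kappa = walk.mean_reversion
    for label in labels:
        idx = select(structure, lobe_selection(*label))
        if len(idx) == 0:
            raise KeyError(f"lobe {label!r} not found in structure")
        offset = np.zeros(3)  # (dr, dz, dphi_deg) relative to start
        sigmas = np.array([walk.sigma_r, walk.sigma_z, walk.sigma_azimuth])
        bounds = (walk.bounds_r, walk.bounds_z, walk.bounds_azimuth)
        base = structure.coords[idx]
        center = base.mean(axis=0)
        r0 = np.hypot(center[0], center[1])
        phi0 = np.arctan2(center[1], center[0])
        for k in range(walk.n_frames):
            offset = offset * (1.0 - kappa) + rng.normal(scale=sigmas)
            offset = np.array([
                _reflect(offset[j], bounds[j][0], bounds[j][1]) for j in range(3)
            ])
            if not offset.any():  # sigma = 0: bit-identical static frames
                continue
            phi = phi0 + np.deg2rad(offset[2])
            new_center = np.array([
                (r0 + offset[0]) * np.cos(phi),
                (r0 + offset[0]) * np.sin(phi),
                center[2] + offset[1],
            ])
            frames[k, idx] = base + (new_center - center)
    times = walk.dt_ns * np.arange(walk.n_frames, dtype=float)
    return Trajectory(structure, frames, times)


def simulate_sans(structure: StructureModel, contrast: ContrastModel | None = None,
                  q: np.ndarray | None = None, weights: np.ndarray | None = None,
                  rel_floor: float = 0.01, counting_scale: float = 0.01,
                  exposure: float = 1.0, bin_width: float = 0.5,
                  seed: int | np.random.Generator = 0) -> ScatteringCurve:
    """Noisy SANS measurement of a structure (fixture, not an instrument model).

    Gaussian noise with sigma_k^2 = (rel_floor * I_k)^2 +
    (counting_scale * sqrt(I_k I_0) / exposure)^2 — a relative floor plus a
    counting-statistics-like term that grows in relative terms where the
    signal is weak.  The sigma column reports the generating sigma.
    """
    if rel_floor < 0 or counting_scale < 0 or exposure <= 0:
        raise ValueError("noise parameters must be nonnegative, exposure positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ideal = debye_curve(structure, contrast, q=q, bin_width=bin_width, weights=weights)
    i0 = float(ideal.intensity[0])
    sigma = np.sqrt(
        (rel_floor * ideal.intensity) ** 2
        + (counting_scale * np.sqrt(np.abs(ideal.intensity) * abs(i0)) / exposure) ** 2
    )
    if np.all(sigma == 0):
        return ScatteringCurve(ideal.q, ideal.intensity.copy(),
                               None, {"kind": "simulated", "noise": "none"})
    sigma = np.maximum(sigma, 1e-15)
    noisy = ideal.intensity + rng.normal(scale=sigma)
    return ScatteringCurve(ideal.q, noisy, sigma,
                           {"kind": "simulated", "rel_floor": rel_floor,
                            "counting_scale": counting_scale, "exposure": exposure})
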