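"""Trajectory-level analysis: RMSD/RMSF, domain tracking, SANS ranking, PCA.

Frames are plain (n_frames, n_atoms, 3) arrays over a shared topology, read
from multi-model PDB or XYZ frame series; the analyses mirror standard
MD-postprocessing practice (align on a stable core, measure the mobile
domains) so that peripheral-domain motions are reported in cylindrical
coordinates about the channel axis and ensembles can be ranked by goodness
of fit to a measured scattering curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import StructureModel, apply_superposition, select, superpose, write_pdb
from .pore import AxisFrame, channel_axis
from .scattering import ContrastModel, ScatteringCurve, debye_curve, fit_scale_background

__all__ = [
    "Trajectory",
    "Landscape",
    "load_trajectory",
    "write_trajectory",
    "rmsd_series",
    "rmsf",
    "domain_track",
    "rank_frames_by_sans",
    "pca_landscape",
    "project_onto_landscape",
]


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology; times in ns."""

    topology: StructureModel
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology) \
                or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (n_frames, {len(self.topology)}, 3), got {self.frames.shape}"
            )
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.frames):
                raise ValueError("times length must match frame count")
            if np.any(np.diff(self.times) < 0):
                raise ValueError("times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame(self, i: int) -> StructureModel:
        return self.topology.with_coords(self.frames[i])

    def strided(self, stride: int) -> "Trajectory":
        return Trajectory(self.topology, self.frames[::stride], self.times[::stride])


def load_trajectory(topology_path, frames_path=None, fmt: str | None = None,
                    stride: int = 1) -> Trajectory:
    """Load a trajectory from a multi-model PDB or an XYZ frame series.

    With only ``topology_path`` given, a multi-model PDB supplies both the
    topology (first model) and the frames.  ``fmt`` is inferred from the
    suffix when omitted.
    """
    from .model import read_structure

    topology_path = str(topology_path)
    if frames_path is None:
        models = read_structure(topology_path, model="all")
        top = models[0]
        for k, m in enumerate(models):
            if len(m) != len(top):
                raise ValueError(f"frame {k} has {len(m)} atoms, topology has {len(top)}")
        frames = np.array([m.coords for m in models])
        return Trajectory(top, frames[::stride])
    top = read_structure(topology_path)
    fmt = fmt or ("xyz" if str(frames_path).endswith(".xyz") else "pdb")
    if fmt == "xyz":
        frames = _read_xyz_frames(frames_path)
    elif fmt == "pdb":
        models = read_structure(frames_path, model="all")
        frames = np.array([m.coords for m in models])
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")
    for k, f in enumerate(frames):
        if len(f) != len(top):
            raise ValueError(f"frame {k} has {len(f)} atoms, topology has {len(top)}")
    return Trajectory(top, np.asarray(frames)[::stride])


def _read_xyz_frames(path) -> np.ndarray:
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: bad XYZ atom count at line {i + 1}") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated XYZ frame at line {i + 1}")
        coords = np.array([[float(x) for x in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no XYZ frames found")
    n0 = len(frames[0])
    for k, f in enumerate(frames):
        if len(f) != n0:
            raise ValueError(f"{path}: frame {k} has {len(f)} atoms, expected {n0}")
    return np.array(frames)


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    path = str(path)
    fmt = fmt or ("xyz" if path.endswith(".xyz") else "pdb")
    if fmt == "pdb":
        write_pdb(traj.topology, path, frames=traj.frames)
    elif fmt == "xyz":
        with open(path, "w") as fh:
            names = traj.topology.element
            for k, coords in enumerate(traj.frames):
                fh.write(f"{len(coords)}\nframe {k}\n")
                for e, xyz in zip(names, coords):
                    fh.write(f"{e or 'C'} {xyz[0]:.4f} {xyz[1]:.4f} {xyz[2]:.4f}\n")
    else:
        raise ValueError(f"unsupported trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def rmsd_series(traj: Trajectory, fit_selection, measure_selection=None,
                reference: StructureModel | int = 0) -> np.ndarray:
    """Per-frame RMSD over ``measure_selection`` after aligning on ``fit_selection``."""
    ref = traj.frame(reference) if isinstance(reference, int) else reference
    fit_idx = select(traj.topology, fit_selection)
    meas_idx = fit_idx if measure_selection is None else select(traj.topology, measure_selection)
    if len(fit_idx) == 0 or len(meas_idx) == 0:
        raise ValueError("empty selection in rmsd_series")
    ref_fit = ref.coords[fit_idx]
    ref_meas = ref.coords[meas_idx]
    out = np.zeros(len(traj))
    for k, coords in enumerate(traj.frames):
        sup = superpose(coords[fit_idx], ref_fit)
        moved = apply_superposition(sup, coords[meas_idx])
        out[k] = np.sqrt(((moved - ref_meas) ** 2).sum() / len(meas_idx))
    return out


def rmsf(traj: Trajectory, selection, align_selection=None,
         per_residue: bool = True):
    """RMS fluctuation about the time-mean after per-frame alignment.

    Frames are aligned on ``align_selection`` (default: the measured selection
    itself, matching the convention of aligning a loop on itself), the mean
    conformation computed, and per-atom fluctuations averaged per residue when
    ``per_residue``.
    """
    idx = select(traj.topology, selection)
    align_idx = idx if align_selection is None else select(traj.topology, align_selection)
    if len(idx) == 0:
        raise ValueError("empty selection in rmsf")
    if len(traj) < 2:
        warnings.warn("rmsf of a single frame is zero", stacklevel=2)
        fluct = np.zeros(len(idx))
    else:
        ref_align = traj.frames[0][align_idx]
        aligned = np.zeros((len(traj), len(idx), 3))
        for k, coords in enumerate(traj.frames):
            sup = superpose(coords[align_idx], ref_align)
            aligned[k] = apply_superposition(sup, coords[idx])
        mean = aligned.mean(axis=0)
        fluct2 = ((aligned - mean) ** 2).sum(axis=2).mean(axis=0)
        fluct = np.sqrt(fluct2)
    if not per_residue:
        return fluct
    resids = traj.topology.residue_number[idx]
    chains = traj.topology.chain_id[idx]
    keys = list(dict.fromkeys(zip(chains, resids)))
    values = []
    for ch, rn in keys:
        m = (chains == ch) & (resids == rn)
        values.append(float(np.sqrt((fluct[m] ** 2).mean())))
    return pd.DataFrame({"chain": [k[0] for k in keys],
                         "resid": [k[1] for k in keys],
                         "rmsf": values})


# ---------------------------------------------------------------------------
# Domain tracking
# ---------------------------------------------------------------------------

def domain_track(traj: Trajectory, domains: dict, axis: AxisFrame | None = None,
                 core_selection=None) -> pd.DataFrame:
    """Track domain centers of mass in cylindrical coordinates about the axis.

    ``domains`` maps labels to selections.  With ``core_selection`` given, the
    axis is recomputed per frame from the core (default behavior for mobile
    assemblies); otherwise the fixed ``axis`` is used for every frame.
    Returns a tidy frame with columns (frame, time, domain, r_xy, z).
    """
    if axis is None and core_selection is None:
        raise ValueError("domain_track needs an axis or a core_selection")
    dom_idx = {}
    for label, sel in domains.items():
        idx = select(traj.topology, sel)
        if len(idx) == 0:
            raise ValueError(f"domain {label!r}: empty selection")
        dom_idx[label] = idx
    masses = traj.topology.masses()
    rows = []
    for k, coords in enumerate(traj.frames):
        if core_selection is not None:
            frame_model = traj.topology.with_coords(coords)
            fr_axis = channel_axis(frame_model, selection=core_selection)
        else:
            fr_axis = axis
        for label, idx in dom_idx.items():
            w = masses[idx]
            com = (coords[idx] * w[:, None]).sum(axis=0) / w.sum()
            local = fr_axis.to_frame(com[None])[0]
            rows.append({
                "frame": k,
                "time": float(traj.times[k]),
                "domain": label,
                "r_xy": float(np.hypot(local[0], local[1])),
                "z": float(local[2]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SANS ranking
# ---------------------------------------------------------------------------

def rank_frames_by_sans(traj: Trajectory, contrast: ContrastModel | None,
                        data: ScatteringCurve, stride: int = 1,
                        weights: np.ndarray | None = None,
                        bin_width: float = 0.5) -> pd.DataFrame:
    """Fit every sampled frame's predicted curve to the data; rank by chi^2.

    Returns a DataFrame (frame, chi2, scale, background) sorted ascending by
    chi^2; ties within 0.01 keep input order (stable sort).
    """
    if data.sigma is None:
        raise ValueError("data curve needs uncertainties for ranking")
    rows = []
    for k in range(0, len(traj), stride):
        frame = traj.frame(k)
        model = debye_curve(frame, contrast, q=data.q, bin_width=bin_width,
                            weights=weights)
        fit = fit_scale_background(model, data)
        rows.append({"frame": k, "chi2": fit.chi2_reduced,
                     "scale": fit.scale, "background": fit.background})
    df = pd.DataFrame(rows)
    df["chi2_key"] = np.round(df["chi2"] / 0.01) * 0.01
    df = df.sort_values("chi2_key", kind="stable").drop(columns="chi2_key")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# PCA landscape
# ---------------------------------------------------------------------------

@dataclass
class Landscape:
    """Cartesian PCA of aligned conformations over a selection."""

    mean: np.ndarray                 # (m, 3) mean conformation
    components: np.ndarray           # (k, 3m) orthonormal basis rows
    eigenvalues: np.ndarray          # variances along components, A^2
    projections: np.ndarray          # (n_frames, k)
    reference: np.ndarray            # (m, 3) alignment reference
    labels: list = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


def _gather_aligned(trajs, idx, reference_coords) -> np.ndarray:
    rows = []
    for traj in trajs:
        for coords in traj.frames:
            sup = superpose(coords[idx], reference_coords)
            rows.append(apply_superposition(sup, coords[idx]))
    return np.array(rows)


def pca_landscape(trajs: list[Trajectory] | Trajectory, selection,
                  reference: StructureModel | None = None,
                  atom_weights: np.ndarray | None = None) -> Landscape:
    """Cartesian-coordinate PCA over frames of one or more trajectories.

    Frames are superposed on the reference (default: first frame of the first
    trajectory) over ``selection``, flattened, and eigendecomposed.  Unweighted
    by default; ``atom_weights`` (e.g. masses) applies sqrt-weighting.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs or sum(len(t) for t in trajs) < 2:
        raise ValueError("pca_landscape needs at least 2 frames in total")
    top = trajs[0].topology
    idx = select(top, selection)
    if len(idx) == 0:
        raise ValueError("empty selection for PCA")
    ref = reference if reference is not None else trajs[0].frame(0)
    ref_coords = ref.coords if len(ref) == len(idx) else ref.coords[idx]
    aligned = _gather_aligned(trajs, idx, ref_coords)
    n, m, _ = aligned.shape
    X = aligned.reshape(n, 3 * m)
    if atom_weights is not None:
        w = np.repeat(np.sqrt(np.asarray(atom_weights, dtype=float)[idx]), 3)
        X = X * w[None, :]
    mean_flat = X.mean(axis=0)
    Xc = X - mean_flat
    # economy SVD: eigenvalues of the covariance are s^2 / (n - 1)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s ** 2 / max(n - 1, 1)
    projections = Xc @ Vt.T
    labels = []
    for t_i, traj in enumerate(trajs):
        labels.extend([(t_i, k) for k in range(len(traj))])
    return Landscape(
        mean=mean_flat.reshape(m, 3), components=Vt, eigenvalues=eigenvalues,
        projections=projections, reference=ref_coords.copy(), labels=labels,
        annotations={"selection_indices": idx},
    )


def project_onto_landscape(landscape: Landscape, frames, annotation=None) -> pd.DataFrame:
    """Project structures/frames onto a stored landscape basis.

    ``frames`` may be a Trajectory, a StructureModel, or an (n, m, 3) array
    over the landscape's selection.  Each conformation is superposed on the
    stored alignment reference before projection, so the result is invariant
    to rigid pre-transformation of the input.
    """
    idx = landscape.annotations.get("selection_indices")
    if isinstance(frames, Trajectory):
        coords = frames.frames[:, idx, :]
    elif isinstance(frames, StructureModel):
        coords = frames.coords[idx][None]
    else:
        coords = np.asarray(frames, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    m = landscape.reference.shape[0]
    if coords.shape[1] != m:
        raise ValueError(f"expected {m} atoms per conformation, got {coords.shape[1]}")
    rows = []
    for conf in coords:
        sup = superpose(conf, landscape.reference)
        aligned = apply_superposition(sup, conf).reshape(-1)
        proj = (aligned - landscape.mean.reshape(-1)) @ landscape.components.T
        rows.append(proj)
    proj = np.array(rows)
    df = pd.DataFrame({f"pc{i + 1}": proj[:, i] for i in range(min(proj.shape[1], 10))})
    if annotation is not None:
        ann = np.atleast_1d(annotation)
        if len(ann) != len(df):
            raise ValueError("annotation length must match the number of conformations")
        df["annotation"] = ann
    return df
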