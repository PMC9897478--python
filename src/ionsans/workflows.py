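"""End-to-end orchestration: structure-vs-data reports and ensemble fitting.

These functions bind the analysis modules into the two standard workflows —
comparing candidate static models against a measured curve (Guinier, MW,
P(r), per-model chi^2 table) and ranking trajectory frames by goodness of
fit with a PCA landscape annotation.  Reports are machine-readable (JSON +
TSV) and embed the fully resolved configuration, since several analysis
settings (Guinier window, exchange fraction) have no universal convention.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ensemble as ens
from . import pddf as pddf_mod
from .model import read_structure, write_pdb
from .scattering import (
    ContrastModel,
    debye_curve,
    fit_scale_background,
    guinier_fit,
    molecular_weight_from_i0,
    read_curve,
)

__all__ = ["RunConfig", "run_structure_vs_sans", "run_ensemble_fit"]


@dataclass
class RunConfig:
    """Resolved settings for a report run; persisted alongside outputs."""

    structures: list = field(default_factory=list)
    curve: str | None = None
    trajectory: str | None = None
    topology: str | None = None
    output_dir: str = "ionsans-out"
    # contrast
    d2o_fraction: float = 1.0
    exchanged_fraction: float = 0.90
    shielded_selection: str | None = None
    uniform_weights: bool = False     # toy models: unit scattering weight per atom
    # analysis settings
    qrg_limit: float = 1.3
    concentration: float | None = None   # mg/mL, for MW from I(0)
    ift_dmax: float | None = None
    ift_bins: int = 100
    bin_width: float = 0.5
    stride: int = 1
    pca_selection: str = "all"
    seed: int = 0
    make_plots: bool = True

    def contrast(self) -> ContrastModel:
        return ContrastModel(
            d2o_fraction=self.d2o_fraction,
            exchanged_fraction=self.exchanged_fraction,
            shielded_selection=self.shielded_selection,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def run_structure_vs_sans(config: RunConfig) -> dict:
    """Compare candidate structures against one measured curve.

    Produces Guinier parameters (and MW when a concentration is given), an
    IFT P(r) of the data, and a per-model table of predicted-curve chi^2 and
    model P(r) tail statistics, ranked best-first.  Writes report.json,
    models.tsv and optional plots under ``config.output_dir``.
    """
    if not config.structures or config.curve is None:
        raise ValueError("run_structure_vs_sans needs >= 1 structure and a curve")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = read_curve(config.curve)
    contrast = config.contrast()

    report: dict = {"config": config.as_dict(), "curve": str(config.curve)}
    gres = guinier_fit(data, qrg_limit=config.qrg_limit)
    report["guinier"] = {
        "rg": gres.rg, "rg_err": gres.rg_err, "i0": gres.i0, "i0_err": gres.i0_err,
        "n_points": gres.n_points, "qrg_max_used": gres.qrg_max_used,
    }

    models = []
    for spath in config.structures:
        structure = read_structure(spath)
        weights = np.ones(len(structure)) if config.uniform_weights else None
        model_curve = debye_curve(structure, None if config.uniform_weights else contrast,
                                  q=data.q, bin_width=config.bin_width, weights=weights)
        fit = fit_scale_background(model_curve, data)
        mp = pddf_mod.model_pddf(structure, None if config.uniform_weights else contrast,
                                 weights=weights)
        entry = {
            "structure": str(spath),
            "chi2": fit.chi2_reduced,
            "scale": fit.scale,
            "background": fit.background,
            "model_rg_coordinates": structure.radius_of_gyration(
                weighting="uniform" if config.uniform_weights else "mass"),
            "model_dmax": mp.dmax,
        }
        if config.concentration is not None and not config.uniform_weights:
            entry["mw_kda"] = molecular_weight_from_i0(
                gres.i0, config.concentration, contrast, structure)
        models.append(entry)
    models.sort(key=lambda e: e["chi2"])
    report["models"] = models

    if config.ift_dmax is not None and data.sigma is not None:
        pd_ift, fit = pddf_mod.ift(data, config.ift_dmax, n_bins=config.ift_bins)
        report["ift"] = {"dmax": pd_ift.dmax, "rg_from_pr": pd_ift.rg(),
                         "chi2": fit.chi2_reduced, "alpha": pd_ift.metadata["alpha"]}
        pddf_mod.write_pddf(pd_ift, out / "data_pddf.out")

    with open(out / "models.tsv", "w") as fh:
        cols = ["structure", "chi2", "scale", "background", "model_rg_coordinates", "model_dmax"]
        fh.write("\t".join(cols) + "\n")
        for e in models:
            fh.write("\t".join(f"{e[c]:.6g}" if isinstance(e[c], float) else str(e[c])
                               for c in cols) + "\n")
    _write_json(report, out / "report.json")
    if config.make_plots:
        _plot_fits(config, data, out)
    return report


def _plot_fits(config: RunConfig, data, out: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:  # plotting is best-effort
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(data.q, data.intensity, yerr=data.sigma, fmt=".", ms=2, lw=0.5,
                color="k", label="data")
    contrast = config.contrast()
    for spath in config.structures:
        structure = read_structure(spath)
        weights = np.ones(len(structure)) if config.uniform_weights else None
        mc = debye_curve(structure, None if config.uniform_weights else contrast,
                         q=data.q, bin_width=config.bin_width, weights=weights)
        fit = fit_scale_background(mc, data)
        ax.plot(mc.q, fit.scale * mc.intensity + fit.background,
                label=f"{Path(spath).stem} (chi2={fit.chi2_reduced:.1f})")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$Q$ ($\mathrm{\AA}^{-1}$)")
    ax.set_ylabel(r"$I(Q)$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "fits.png", dpi=150)
    plt.close(fig)


def run_ensemble_fit(config: RunConfig) -> dict:
    """Rank trajectory frames against a measured curve; annotate a landscape.

    Writes ranking.tsv, the best frame as best_frame.pdb, PCA projections
    with per-frame chi^2 annotation (projections.tsv) and report.json.
    """
    if config.trajectory is None or config.curve is None:
        raise ValueError("run_ensemble_fit needs a trajectory and a curve")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = read_curve(config.curve)
    traj = ens.load_trajectory(config.topology or config.trajectory,
                               None if config.topology is None else config.trajectory)
    contrast = None if config.uniform_weights else config.contrast()
    weights = np.ones(len(traj.topology)) if config.uniform_weights else None
    ranking = ens.rank_frames_by_sans(traj, contrast, data, stride=config.stride,
                                      weights=weights, bin_width=config.bin_width)
    ranking.to_csv(out / "ranking.tsv", sep="\t", index=False, float_format="%.6g")
    best = int(ranking.iloc[0]["frame"])
    write_pdb(traj.frame(best), out / "best_frame.pdb")

    report = {"config": config.as_dict(),
              "n_frames_ranked": int(len(ranking)),
              "best_frame": best,
              "best_chi2": float(ranking.iloc[0]["chi2"]),
              "worst_chi2": float(ranking.iloc[-1]["chi2"])}
    if len(traj) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            landscape = ens.pca_landscape(traj, config.pca_selection)
        chi2_by_frame = ranking.set_index("frame")["chi2"]
        sampled = sorted(chi2_by_frame.index)
        proj = ens.project_onto_landscape(
            landscape, traj.frames[sampled][:, landscape.annotations["selection_indices"], :],
            annotation=chi2_by_frame.loc[sampled].to_numpy())
        proj.insert(0, "frame", sampled)
        proj.to_csv(out / "projections.tsv", sep="\t", index=False, float_format="%.6g")
        evr = landscape.explained_variance_ratio()
        report["pca"] = {"explained_variance_ratio_pc1": float(evr[0]),
                         "explained_variance_ratio_pc2": float(evr[1]) if len(evr) > 1 else 0.0}
    _write_json(report, out / "report.json")
    return report
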