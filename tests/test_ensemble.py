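"""Trajectory analysis: RMSD/RMSF, domain tracking, SANS ranking, PCA."""

import numpy as np
import pandas as pd
import pytest

from ionsans.ensemble import (
    Trajectory,
    domain_track,
    load_trajectory,
    pca_landscape,
    project_onto_landscape,
    rank_frames_by_sans,
    rmsd_series,
    rmsf,
    write_trajectory,
)
from ionsans.model import select
from ionsans.pore import AxisFrame
from ionsans.scattering import debye_curve
from ionsans.synthetic import (
    build_toy_channel,
    lobe_labels,
    lobe_selection,
    perturb_lobes,
    simulate_sans,
)

from conftest import random_rotation

CORE = "resname TMD ECD"


@pytest.fixture(scope="module")
def small_toy():
    from ionsans.synthetic import ToyChannelSpec

    return build_toy_channel(ToyChannelSpec(ecd_atoms=60, lobe_atoms=30, rod_atoms=8))[0]


class TestTrajectoryIO:
    def test_multi_model_pdb(self, tmp_path, small_toy):
        frames = np.stack([small_toy.coords + np.array([i, 0.0, 0.0])
                           for i in range(3)])
        traj = Trajectory(small_toy, frames)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = load_trajectory(path)
        assert back.n_frames == 3
        np.testing.assert_allclose(back.frames, frames, atol=1.5e-3)

    def test_stride(self, tmp_path, small_toy):
        frames = np.repeat(small_toy.coords[None], 101, axis=0)
        traj = Trajectory(small_toy, frames)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        assert load_trajectory(path, stride=10).n_frames == 11

    def test_xyz_round_trip(self, tmp_path, small_toy):
        frames = np.stack([small_toy.coords, small_toy.coords * 1.01])
        traj = Trajectory(small_toy, frames)
        top_path = tmp_path / "top.pdb"
        xyz_path = tmp_path / "frames.xyz"
        from ionsans.model import write_pdb

        write_pdb(small_toy, top_path)
        write_trajectory(traj, xyz_path)
        back = load_trajectory(top_path, xyz_path)
        assert back.n_frames == 2
        np.testing.assert_allclose(back.frames, frames, atol=2e-3)

    def test_atom_count_mismatch_names_frame(self, tmp_path, small_toy):
        xyz_path = tmp_path / "bad.xyz"
        with open(xyz_path, "w") as fh:
            fh.write("2\nframe 0\nC 0 0 0\nC 1 0 0\n")
            fh.write("3\nframe 1\nC 0 0 0\nC 1 0 0\nC 2 0 0\n")
        from ionsans.model import write_pdb

        top_path = tmp_path / "top.pdb"
        write_pdb(small_toy.subset([0, 1]), top_path)
        with pytest.raises(ValueError, match="frame 1"):
            load_trajectory(top_path, xyz_path)

    def test_times_validation(self, small_toy):
        frames = np.repeat(small_toy.coords[None], 3, axis=0)
        with pytest.raises(ValueError, match="nondecreasing"):
            Trajectory(small_toy, frames, times=[2.0, 1.0, 0.0])


class TestRmsd:
    def test_reference_frame_zero(self, small_toy):
        rng = np.random.default_rng(0)
        frames = np.stack([small_toy.coords + rng.normal(scale=0.5, size=small_toy.coords.shape)
                           for _ in range(4)])
        frames[0] = small_toy.coords
        traj = Trajectory(small_toy, frames)
        series = rmsd_series(traj, "all", reference=0)
        assert series[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(series[1:] > 0)

    def test_rigid_motion_gives_zero(self, small_toy, rng):
        frames = []
        for _ in range(5):
            R = random_rotation(rng)
            frames.append(small_toy.coords @ R.T + rng.uniform(-10, 10, 3))
        traj = Trajectory(small_toy, np.stack(frames))
        series = rmsd_series(traj, "all", reference=small_toy)
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_scripted_lobe_translation(self, toy_structure):
        moved = perturb_lobes(toy_structure, {("NTD1", "A"): (8.0, 0.0)})
        traj = Trajectory(toy_structure, np.stack([toy_structure.coords, moved.coords]))
        series = rmsd_series(traj, CORE, lobe_selection("NTD1", "A"), reference=0)
        assert series[1] == pytest.approx(8.0, abs=0.01)


class TestRmsf:
    def test_static_trajectory_zero(self, small_toy):
        traj = Trajectory(small_toy, np.repeat(small_toy.coords[None], 5, axis=0))
        out = rmsf(traj, "resname TMD", per_residue=False)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_gaussian_jitter_closed_form(self, small_toy):
        sigma = 0.8
        rng = np.random.default_rng(3)
        core_idx = select(small_toy, "resname TMD")
        n_frames = 400
        frames = np.repeat(small_toy.coords[None], n_frames, axis=0)
        frames += rng.normal(scale=sigma, size=frames.shape)
        traj = Trajectory(small_toy, frames)
        out = rmsf(traj, "resname TMD", align_selection="all", per_residue=False)
        # i.i.d. jitter per axis -> RMSF -> sigma * sqrt(3)
        assert out.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_per_residue_output(self, small_toy):
        rng = np.random.default_rng(1)
        frames = np.repeat(small_toy.coords[None], 10, axis=0)
        frames += rng.normal(scale=0.3, size=frames.shape)
        traj = Trajectory(small_toy, frames)
        df = rmsf(traj, "resname TMD")
        assert isinstance(df, pd.DataFrame)
        assert set(df.columns) == {"chain", "resid", "rmsf"}
        assert (df["rmsf"] > 0).all()

    def test_single_frame_warns(self, small_toy):
        traj = Trajectory(small_toy, small_toy.coords[None])
        with pytest.warns(UserWarning):
            out = rmsf(traj, "resname TMD", per_residue=False)
        np.testing.assert_allclose(out, 0.0)


class TestDomainTrack:
    def test_on_axis_domain_r_zero(self, small_toy):
        traj = Trajectory(small_toy, small_toy.coords[None])
        axis = AxisFrame(origin=[0, 0, 0], axis=[0, 0, 1])
        # the full pentamer's COM lies on the symmetry axis
        df = domain_track(traj, {"all": "all"}, axis=axis)
        assert df["r_xy"].iloc[0] == pytest.approx(0.0, abs=1e-6)

    def test_out_and_down_recovered(self, toy_structure):
        moved = perturb_lobes(toy_structure, {("NTD1", "B"): (10.0, -8.0)})
        traj = Trajectory(toy_structure, np.stack([toy_structure.coords, moved.coords]))
        df = domain_track(traj, {"NTD1-B": lobe_selection("NTD1", "B")},
                          core_selection=CORE)
        d_r = df[df.frame == 1]["r_xy"].iloc[0] - df[df.frame == 0]["r_xy"].iloc[0]
        d_z = df[df.frame == 1]["z"].iloc[0] - df[df.frame == 0]["z"].iloc[0]
        assert d_r == pytest.approx(10.0, abs=1e-6)
        assert abs(d_z) == pytest.approx(8.0, abs=1e-6)

    def test_static_frames_zero_variance(self, toy_structure):
        traj = Trajectory(toy_structure, np.repeat(toy_structure.coords[None], 4, axis=0))
        doms = {f"{l}-{c}": lobe_selection(l, c) for l, c in lobe_labels(toy_structure)}
        df = domain_track(traj, doms, core_selection=CORE)
        for _, grp in df.groupby("domain"):
            assert grp["r_xy"].std() == pytest.approx(0.0, abs=1e-9)
            assert grp["z"].std() == pytest.approx(0.0, abs=1e-9)

    def test_r_invariant_under_axial_rotation(self, toy_structure):
        ang = np.deg2rad(37.0)
        R = np.array([[np.cos(ang), -np.sin(ang), 0],
                      [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
        rotated = toy_structure.with_coords(toy_structure.coords @ R.T)
        axis = AxisFrame(origin=[0, 0, 0], axis=[0, 0, 1])
        sel = lobe_selection("NTD1", "A")
        t1 = Trajectory(toy_structure, toy_structure.coords[None])
        t2 = Trajectory(rotated, rotated.coords[None])
        df1 = domain_track(t1, {"d": sel}, axis=axis)
        df2 = domain_track(t2, {"d": sel}, axis=axis)
        assert df1["r_xy"].iloc[0] == pytest.approx(df2["r_xy"].iloc[0], abs=1e-9)
        assert df1["z"].iloc[0] == pytest.approx(df2["z"].iloc[0], abs=1e-9)

    def test_empty_domain_raises(self, small_toy):
        traj = Trajectory(small_toy, small_toy.coords[None])
        with pytest.raises(ValueError, match="empty"):
            domain_track(traj, {"x": "resname NOPE"},
                         axis=AxisFrame(origin=[0, 0, 0], axis=[0, 0, 1]))


@pytest.fixture(scope="module")
def planted_setup():
    st, _ = build_toy_channel()
    planted = perturb_lobes(st, {("NTD1", "A"): (10.0, -8.0),
                                 ("NTD1", "C"): (10.0, -8.0)})
    rng = np.random.default_rng(42)
    frames = [st.coords, planted.coords]
    for _ in range(8):
        disp = {lb: (rng.normal(0, 4), rng.normal(0, 4))
                for lb in lobe_labels(st)}
        frames.append(perturb_lobes(st, disp).coords)
    traj = Trajectory(st, np.stack(frames))
    return st, planted, traj


class TestRankFrames:
    def test_noiseless_planted_frame_ranks_first(self, planted_setup):
        st, planted, traj = planted_setup
        w = np.ones(len(st))
        data = debye_curve(planted, weights=w)
        ranked = rank_frames_by_sans(traj, None, data, weights=w)
        assert int(ranked.iloc[0]["frame"]) == 1
        assert ranked.iloc[0]["chi2"] == pytest.approx(0.0, abs=1e-12)

    def test_ordering_invariant_under_data_rescale(self, planted_setup):
        from ionsans.scattering import ScatteringCurve

        st, planted, traj = planted_setup
        w = np.ones(len(st))
        data = simulate_sans(planted, weights=w, seed=9)
        r1 = rank_frames_by_sans(traj, None, data, weights=w)
        scaled = ScatteringCurve(data.q, 5.0 * data.intensity, 5.0 * data.sigma)
        r2 = rank_frames_by_sans(traj, None, scaled, weights=w)
        assert list(r1["frame"]) == list(r2["frame"])
        np.testing.assert_allclose(r1["chi2"], r2["chi2"], rtol=1e-9)

    def test_best_not_worse_than_first_frame(self, planted_setup):
        st, planted, traj = planted_setup
        w = np.ones(len(st))
        data = simulate_sans(planted, weights=w, seed=10)
        ranked = rank_frames_by_sans(traj, None, data, weights=w)
        chi2_start = float(ranked.loc[ranked["frame"] == 0, "chi2"].iloc[0])
        assert ranked.iloc[0]["chi2"] <= chi2_start


def _two_cluster_trajs(n_per=12, seed=0):
    st, _ = build_toy_channel()
    rng = np.random.default_rng(seed)
    ntd1 = [lb for lb in lobe_labels(st) if lb[0] == "NTD1"]

    def jittered(base_disp):
        disp = {lb: (base_disp[0] + rng.normal(0, 0.8),
                     base_disp[1] + rng.normal(0, 0.8)) for lb in ntd1}
        return perturb_lobes(st, disp).coords

    compact = np.stack([jittered((0.0, 0.0)) for _ in range(n_per)])
    extended = np.stack([jittered((14.0, -10.0)) for _ in range(n_per)])
    return st, Trajectory(st, compact), Trajectory(st, extended)


class TestPca:
    def test_single_mode_explains_all_variance(self, small_toy):
        direction = np.zeros_like(small_toy.coords)
        direction[:10, 0] = 1.0
        amplitudes = np.linspace(-3, 3, 7)
        frames = np.stack([small_toy.coords + a * direction for a in amplitudes])
        traj = Trajectory(small_toy, frames)
        # no alignment drift: variance entirely along one Cartesian mode
        lds = pca_landscape(traj, "resname TMD ECD NT1 NT2")
        evr = lds.explained_variance_ratio()
        assert evr[0] > 0.999

    def test_basis_orthonormal_and_variance_sum(self):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        G = lds.components @ lds.components.T
        np.testing.assert_allclose(G, np.eye(len(G)), atol=1e-8)
        total_var = lds.projections.var(axis=0, ddof=1).sum()
        assert lds.eigenvalues.sum() == pytest.approx(total_var, rel=1e-6)

    def test_two_clusters_separate_on_pc1(self):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        n = len(t1)
        pc1_a = lds.projections[:n, 0]
        pc1_b = lds.projections[n:, 0]
        lo_a, hi_a = pc1_a.min(), pc1_a.max()
        lo_b, hi_b = pc1_b.min(), pc1_b.max()
        assert hi_a < lo_b or hi_b < lo_a  # linearly separable along PC1

    def test_mean_projects_to_origin(self):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        df = project_onto_landscape(lds, lds.mean[None])
        assert abs(df["pc1"].iloc[0]) < 1e-6

    def test_training_frame_reproduces_projection(self):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        idx = lds.annotations["selection_indices"]
        df = project_onto_landscape(lds, t1.frames[:, idx, :])
        np.testing.assert_allclose(df["pc1"], lds.projections[:len(t1), 0], atol=1e-8)

    def test_projection_rigid_invariance(self, rng):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        idx = lds.annotations["selection_indices"]
        conf = t2.frames[3][idx]
        R = random_rotation(rng)
        moved = conf @ R.T + [12.0, 0.0, -4.0]
        p0 = project_onto_landscape(lds, conf[None])
        p1 = project_onto_landscape(lds, moved[None])
        assert p1["pc1"].iloc[0] == pytest.approx(p0["pc1"].iloc[0], abs=1e-6)

    def test_annotation_column(self):
        st, t1, t2 = _two_cluster_trajs()
        lds = pca_landscape([t1, t2], "all")
        idx = lds.annotations["selection_indices"]
        chi2 = np.arange(len(t1), dtype=float)
        df = project_onto_landscape(lds, t1.frames[:, idx, :], annotation=chi2)
        np.testing.assert_allclose(df["annotation"], chi2)
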