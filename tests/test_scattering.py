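"""Contrast model, Debye prediction, Guinier, MW, and curve arithmetic."""

import numpy as np
import pytest

from ionsans.elements import NEUTRON_B, solvent_scattering_length_density
from ionsans.model import AtomRecord, StructureModel
from ionsans.residues import LABILE_H, RESIDUE_H
from ionsans.scattering import (
    ContrastModel,
    ScatteringCurve,
    debye_curve,
    excess_scattering_lengths,
    fit_scale_background,
    guinier_fit,
    labile_hydrogen_count,
    merge_curves,
    molecular_weight_from_i0,
    read_curve,
    sequence_mass,
    subtract_constant,
    write_curve,
)

from conftest import random_rotation


def _chain_structure(resnames):
    """Linear chain with one full residue template per entry, 4 A apart."""
    recs = []
    serial = 1
    for r, resname in enumerate(resnames):
        for j, atom in enumerate(RESIDUE_H[resname]):
            if atom == "OXT":
                continue
            elem = atom.lstrip("0123456789")[0]
            recs.append(AtomRecord(serial, atom, elem, resname, r + 1, "A",
                                   coordinates=[4.0 * r, 0.1 * j, 0.0]))
            serial += 1
    return StructureModel(recs)


class TestLabileHydrogens:
    def test_proline_backbone_has_no_amide_h(self):
        assert LABILE_H["PRO"][0] == 0

    def test_arginine_sidechain_five_labile(self):
        assert LABILE_H["ARG"][1] == 5

    def test_total_deuterium_matches_hand_count(self):
        resnames = ["GLY", "ALA", "SER", "ARG", "PRO", "GLU", "LYS", "TRP", "THR", "ASN"]
        s = _chain_structure(resnames)
        contrast = ContrastModel(d2o_fraction=1.0, exchanged_fraction=1.0)
        comp = labile_hydrogen_count(s, contrast)
        expected = sum(LABILE_H[r][0] + LABILE_H[r][1] for r in resnames)
        assert comp.total_deuterium == pytest.approx(expected)

    def test_shielding_prevents_exchange(self):
        s = _chain_structure(["SER", "SER"])
        contrast = ContrastModel(exchanged_fraction=1.0, shielded_selection="resid 1")
        comp = labile_hydrogen_count(s, contrast)
        in_res1 = s.residue_number == 1
        assert np.all(comp.f_deuterated[in_res1] == 0.0)
        assert np.all(comp.f_deuterated[~in_res1] == 1.0)

    def test_unknown_residue_warns_zero(self):
        s = StructureModel([AtomRecord(1, "C1", "C", "XXX", 1, "A")])
        with pytest.warns(UserWarning, match="unknown residues"):
            comp = labile_hydrogen_count(s, ContrastModel())
        assert comp.n_attached[0] == 0


class TestExcessScatteringLength:
    def test_matched_atom_has_zero_contrast(self):
        rho = solvent_scattering_length_density(1.0)
        vol = 10.0
        contrast = ContrastModel(b_table={"C": rho * vol, "H": NEUTRON_B["H"],
                                          "D": NEUTRON_B["D"]},
                                 volume_table={"C0": vol})
        s = StructureModel([AtomRecord(1, "C", "C", "UNX", 1, "A", is_hetero=True)])
        db = excess_scattering_lengths(s, contrast)
        assert db[0] == pytest.approx(0.0, abs=1e-12)

    def test_linear_in_d2o_fraction(self):
        s = _chain_structure(["ALA", "GLU", "LYS"])
        db = {}
        for f in (0.0, 0.5, 1.0):
            db[f] = excess_scattering_lengths(
                s, ContrastModel(d2o_fraction=f, exchanged_fraction=0.9))
        np.testing.assert_allclose(db[0.5], 0.5 * (db[0.0] + db[1.0]), atol=1e-12)

    def test_structure_matches_composition_route(self):
        """Per-atom summation equals the independent residue-composition sum."""
        from ionsans.scattering import _composition_contrast

        resnames = ["ALA"] * 5 + ["GLU"] * 3 + ["ARG"] * 2
        s = _chain_structure(resnames)
        contrast = ContrastModel()
        per_atom = float(excess_scattering_lengths(s, contrast).sum())
        comp_b, comp_mass = _composition_contrast(
            {"ALA": 5, "GLU": 3, "ARG": 2}, contrast)
        assert per_atom == pytest.approx(comp_b, rel=1e-9)
        assert sequence_mass(s) == pytest.approx(comp_mass, rel=1e-9)


def _point_structure(points):
    return StructureModel([
        AtomRecord(i + 1, "C1", "C", "UNK", i + 1, "A", coordinates=p)
        for i, p in enumerate(points)
    ])


class TestDebye:
    def test_single_atom_flat(self):
        s = _point_structure([[0, 0, 0]])
        c = debye_curve(s, weights=np.array([1.0]), q=np.linspace(0, 0.5, 20))
        np.testing.assert_allclose(c.intensity, 1.0)

    def test_two_atom_closed_form(self):
        d = 10.0
        s = _point_structure([[0, 0, 0], [d, 0, 0]])
        q = np.linspace(0.0, 0.5, 40)
        c = debye_curve(s, weights=np.ones(2), q=q, bin_width=0.01)
        with np.errstate(invalid="ignore"):
            expected = 2.0 + 2.0 * np.sinc(q * d / np.pi)
        np.testing.assert_allclose(c.intensity, expected, rtol=1e-6)
        assert c.intensity[0] == pytest.approx(4.0)

    def test_histogram_matches_exact_double_sum(self, rng):
        pts = rng.uniform(-30, 30, (300, 3))
        s = _point_structure(pts)
        q = np.linspace(0.0, 0.5, 50)
        w = rng.uniform(0.5, 1.5, 300)
        hist = debye_curve(s, q=q, weights=w, bin_width=0.5)
        exact = debye_curve(s, q=q, weights=w, exact=True)
        rel = np.abs(hist.intensity - exact.intensity) / np.abs(exact.intensity)
        assert rel.max() < 0.002

    @pytest.mark.parametrize("bin_width", [0.5, 0.25, 0.1])
    def test_monotone_convergence_to_exact(self, rng, bin_width):
        pts = np.random.default_rng(7).uniform(-20, 20, (150, 3))
        s = _point_structure(pts)
        q = np.linspace(0.0, 0.5, 30)
        exact = debye_curve(s, q=q, exact=True)
        approx = debye_curve(s, q=q, bin_width=bin_width)
        err = np.max(np.abs(approx.intensity - exact.intensity) / np.abs(exact.intensity))
        # frozen per-resolution ceilings: errors shrink with the bin width
        ceiling = {0.5: 2e-4, 0.25: 5e-5, 0.1: 5e-6}[bin_width]
        assert err < ceiling

    def test_i0_identity(self, toy_structure):
        w = np.ones(len(toy_structure))
        c = debye_curve(toy_structure, weights=w, q=np.array([0.0, 0.01]))
        assert c.intensity[0] == pytest.approx(w.sum() ** 2, rel=1e-9)

    def test_rigid_invariance(self, rng):
        pts = rng.uniform(-15, 15, (100, 3))
        s = _point_structure(pts)
        R = random_rotation(rng)
        s2 = s.with_coords(pts @ R.T + [10.0, -5.0, 2.0])
        q = np.linspace(0.0, 0.4, 25)
        c1 = debye_curve(s, q=q)
        c2 = debye_curve(s2, q=q)
        np.testing.assert_allclose(c1.intensity, c2.intensity, rtol=1e-7)


class TestGuinier:
    def test_exact_gaussian_recovery(self):
        rg, i0 = 50.0, 1.0
        q = np.linspace(0.002, 0.05, 100)
        curve = ScatteringCurve(q, i0 * np.exp(-(q * rg) ** 2 / 3.0),
                                np.full(100, 1e-4))
        res = guinier_fit(curve, qrg_limit=1.3)
        assert res.rg == pytest.approx(rg, abs=1e-6)
        assert res.i0 == pytest.approx(i0, abs=1e-6)
        assert res.qrg_max_used <= 1.3 + 1e-9

    def test_noiseless_toy_curve_matches_coordinate_rg(self, toy_structure, toy_truth):
        c = debye_curve(toy_structure, weights=np.ones(len(toy_structure)))
        res = guinier_fit(c, qrg_limit=1.0)
        assert res.rg == pytest.approx(toy_truth["rg"], rel=0.005)

    def test_no_guinier_regime_raises(self):
        q = np.linspace(0.005, 0.05, 50)
        curve = ScatteringCurve(q, 1.0 + 10.0 * q ** 2, np.full(50, 1e-3))
        with pytest.raises(ValueError, match="Guinier"):
            guinier_fit(curve)


class TestMolecularWeight:
    def test_concentration_linearity(self):
        comp = {"ALA": 100}
        contrast = ContrastModel()
        mw1 = molecular_weight_from_i0(0.05, 1.0, contrast, comp)
        mw2 = molecular_weight_from_i0(0.05, 2.0, contrast, comp)
        assert mw1 == pytest.approx(2.0 * mw2)

    def test_absolute_scale_self_consistency(self):
        """MW recovered from an I(0) generated with the same physics."""
        from ionsans.elements import AVOGADRO
        from ionsans.scattering import _composition_contrast

        comp = {"ALA": 150, "GLY": 80, "LEU": 120, "GLU": 60, "LYS": 60}
        contrast = ContrastModel()
        db_fm, mass = _composition_contrast(comp, contrast)
        c_mg_ml = 3.0
        db_per_gram = db_fm * 1e-13 * AVOGADRO / mass
        i0 = (c_mg_ml * 1e-3) * db_per_gram ** 2 * mass / AVOGADRO
        mw = molecular_weight_from_i0(i0, c_mg_ml, contrast, comp)
        assert mw == pytest.approx(mass / 1000.0, rel=0.02)

    def test_zero_contrast_raises(self):
        contrast = ContrastModel(
            b_table={"H": 0.0, "D": 0.0, "C": 0.0, "N": 0.0, "O": 0.0},
            volume_table={"N1": 0.0, "C2": 0.0, "C0": 0.0, "O0": 0.0})
        with pytest.raises(ValueError):
            molecular_weight_from_i0(0.05, 1.0, contrast, {"GLY": 10})


class TestFitScaleBackground:
    def _noisy(self, seed, scale=2.5, background=0.01):
        q = np.geomspace(0.006, 0.3, 120)
        model = ScatteringCurve(q, np.exp(-(q * 45.0) ** 2 / 3.0) + 0.001,
                                np.full(120, 1e-6))
        rng = np.random.default_rng(seed)
        sigma = 0.02 * model.intensity + 1e-5
        data = ScatteringCurve(q, scale * model.intensity + background
                               + rng.normal(scale=sigma), sigma)
        return model, data

    def test_self_fit_is_exact(self):
        model, _ = self._noisy(0)
        data = ScatteringCurve(model.q, model.intensity, np.full(len(model), 1e-3))
        res = fit_scale_background(model, data)
        assert res.scale == pytest.approx(1.0, abs=1e-9)
        assert res.background == pytest.approx(0.0, abs=1e-12)
        assert res.chi2_reduced == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_background_recovery(self, seed):
        model, data = self._noisy(seed)
        res = fit_scale_background(model, data)
        assert abs(res.scale - 2.5) < 3.0 * res.scale_err
        assert abs(res.background - 0.01) < 3.0 * res.background_err

    def test_chi2_invariant_under_common_rescale(self):
        model, data = self._noisy(3)
        res1 = fit_scale_background(model, data)
        scaled = ScatteringCurve(data.q, 7.0 * data.intensity, 7.0 * data.sigma)
        res2 = fit_scale_background(model, scaled)
        assert res2.chi2_reduced == pytest.approx(res1.chi2_reduced, rel=1e-9)

    def test_too_few_points_raises(self):
        model, data = self._noisy(0)
        short = ScatteringCurve(data.q[:2], data.intensity[:2], data.sigma[:2])
        with pytest.raises(ValueError, match="overlap"):
            fit_scale_background(model, short)


class TestCurveArithmetic:
    def _curve(self, q0, q1, n, level=1.0, seed=0):
        q = np.linspace(q0, q1, n)
        rng = np.random.default_rng(seed)
        i = level * np.exp(-(q * 30) ** 2 / 3) + 0.003
        return ScatteringCurve(q, i, np.full(n, 1e-3))

    def test_merge_with_itself_is_identity(self):
        c = self._curve(0.01, 0.3, 80)
        merged = merge_curves(c, 0.1, c)
        np.testing.assert_allclose(merged.q, c.q)
        np.testing.assert_allclose(merged.intensity, c.intensity)

    def test_merge_switches_at_limit(self):
        low = self._curve(0.005, 0.12, 60, level=1.0)
        high = self._curve(0.06, 0.35, 80, level=2.0)
        merged = merge_curves(low, 0.09, high)
        assert np.all(np.diff(merged.q) > 0)
        n_low = int((low.q <= 0.09).sum())
        n_high = int((high.q > 0.09).sum())
        assert len(merged) == n_low + n_high
        assert merged.q[n_low - 1] <= 0.09 < merged.q[n_low]

    def test_subtract_constant_round_trip(self):
        c = self._curve(0.01, 0.3, 50)
        out = subtract_constant(subtract_constant(c, 0.005), -0.005)
        np.testing.assert_allclose(out.intensity, c.intensity, atol=1e-15)
        np.testing.assert_allclose(out.sigma, c.sigma)

    def test_subtract_auto_estimates_flat_tail(self, rng):
        q = np.linspace(0.01, 0.4, 200)
        i = np.exp(-(q * 40) ** 2 / 3) + 0.003
        noise = rng.normal(scale=1e-4, size=200)
        c = ScatteringCurve(q, i + noise, np.full(200, 1e-4))
        out = subtract_constant(c)
        est = c.intensity.mean() - out.intensity.mean()
        se = 1e-4 / np.sqrt(20)
        assert abs(est - 0.003) < 4 * se + 1e-5

    def test_curve_file_round_trip(self, tmp_path):
        c = self._curve(0.01, 0.3, 40)
        c.metadata["condition"] = "Ca2+"
        path = tmp_path / "curve.dat"
        write_curve(c, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.q, c.q, rtol=1e-7)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-7)
        np.testing.assert_allclose(back.sigma, c.sigma, rtol=1e-7)
        assert back.metadata["condition"] == "Ca2+"

    def test_validation(self):
        with pytest.raises(ValueError):
            ScatteringCurve([0.1, 0.1], [1, 1], [0.1, 0.1])
        with pytest.raises(ValueError):
            ScatteringCurve([0.1, 0.2], [1, 1], [0.1, -0.1])
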