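"""Generators: closed-form oracles, conservation laws, reproducibility."""
import numpy as np
import pandas as pd
import pytest

from tpmflex import (CoiledCoilParams, TransitionSpec, WLCParams,
                     gen_coiled_coil, gen_dissociation_curve, gen_dsc_curve,
                     gen_motility_curve, gen_nem_line, gen_wlc_ensemble,
                     hill_velocity, sample_vmf_cos, vmf_mean_cos)
from tpmflex.synthetic import R_GAS, dsc_excess_heat_capacity


class TestVMFSampler:
    @pytest.mark.parametrize("kappa", [2.0, 10.0, 100.0])
    def test_mean_cos_matches_closed_form(self, kappa):
        """Empirical <cos theta> agrees with coth(k) - 1/k within 3 SE at 1e5."""
        rng = np.random.default_rng(7)
        c = sample_vmf_cos(kappa, 100_000, rng)
        se = c.std(ddof=1) / np.sqrt(len(c))
        assert abs(c.mean() - vmf_mean_cos(kappa)) < 3 * se

    def test_closed_form_values(self):
        # coth(10) - 1/10 ~ 0.9000 ; kappa = 161/1.4 = 115 -> ~ 1 - 1/115
        assert vmf_mean_cos(10.0) == pytest.approx(0.9000, abs=1e-4)
        kappa = 161.0 / 1.4
        assert vmf_mean_cos(kappa) == pytest.approx(1.0 - 1.0 / kappa, abs=1e-6)
        assert vmf_mean_cos(kappa) == pytest.approx(0.99130, abs=1e-4)


class TestWLC:
    def test_rigid_rod_limit(self):
        """kappa -> inf: all chains straight, all tangent dot products 1."""
        nodes = gen_wlc_ensemble(WLCParams(n_chains=20, n_segments=10,
                                           persistence_length=1e12, seed=0))
        t = np.diff(nodes, axis=1)
        t /= np.linalg.norm(t, axis=2, keepdims=True)
        dots = np.einsum("nkj,nj->nk", t, t[:, 0])
        assert dots.min() > 1.0 - 1e-6

    def test_starts_at_origin_along_z(self):
        nodes = gen_wlc_ensemble(WLCParams(n_chains=5, n_segments=4, seed=3))
        assert np.allclose(nodes[:, 0], 0.0)
        first_t = nodes[:, 1] - nodes[:, 0]
        assert np.allclose(first_t / np.linalg.norm(first_t, axis=1, keepdims=True),
                           [0.0, 0.0, 1.0])

    def test_tangent_correlation_decay(self):
        """<t(0) . t(kb)> = (coth k - 1/k)^k, agreeing with exp(-s/L) for stiff chains."""
        p = WLCParams(n_chains=4000, n_segments=12, segment_length=1.0,
                      persistence_length=60.0, seed=5)
        nodes = gen_wlc_ensemble(p)
        t = np.diff(nodes, axis=1)
        t /= np.linalg.norm(t, axis=2, keepdims=True)
        m = vmf_mean_cos(p.kappa)
        for k in (1, 4, 8):
            emp = np.einsum("nj,nj->n", t[:, 0], t[:, k]).mean()
            se = np.einsum("nj,nj->n", t[:, 0], t[:, k]).std() / np.sqrt(p.n_chains)
            assert emp == pytest.approx(m**k, abs=4 * se + 1e-4)
            assert m**k == pytest.approx(
                np.exp(-k * p.segment_length / p.persistence_length), rel=0.02)

    def test_intrinsic_curvature_bends_mean_shape(self):
        """A deterministic per-joint bend curves the noise-free chain."""
        p = WLCParams(n_chains=1, n_segments=20, segment_length=1.0,
                      persistence_length=1e12, intrinsic_curvature=0.1, seed=0)
        nodes = gen_wlc_ensemble(p)[0]
        end_to_end = np.linalg.norm(nodes[-1] - nodes[0])
        # a circular arc of total angle 1.9 rad is notably shorter than 20
        assert end_to_end < 19.0
        t = np.diff(nodes, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        angles = np.arccos(np.clip(np.einsum("kj,kj->k", t[:-1], t[1:]), -1, 1))
        # residual random bend at kappa = 1e12 is ~1e-6 rad
        assert np.allclose(angles, 0.1, atol=1e-4)

    def test_reproducible_and_param_validation(self):
        p = WLCParams(n_chains=10, n_segments=5, seed=9)
        assert np.array_equal(gen_wlc_ensemble(p), gen_wlc_ensemble(p))
        with pytest.raises(ValueError):
            WLCParams(segment_length=-1.0)
        with pytest.raises(ValueError):
            WLCParams(persistence_length=0.0)
        with pytest.raises(ValueError):
            WLCParams(n_segments=1)


class TestCoiledCoil:
    def test_two_chains_correct_length(self):
        frame = gen_coiled_coil(CoiledCoilParams(n_residues=284))
        assert sorted(frame.chain_ids()) == ["A", "B"]
        for cid in "AB":
            assert frame.chains[cid].n_residues == 284

    def test_zero_radius_axis_on_z(self):
        """Degenerate superhelix radius: windowed centroids sit on the z axis."""
        frame = gen_coiled_coil(CoiledCoilParams(n_residues=40,
                                                 superhelix_radius=0.0))
        ca = frame.ca_coords("A")
        # mean over any full turn window lies within 0.05 A = 0.005 nm of z
        centroids = np.array([ca[i:i + 11].mean(axis=0) for i in range(25)])
        assert np.abs(centroids[:, :2]).max() < 0.05  # nm
        rise = np.diff(ca[:, 2]).mean()
        assert rise * 10 == pytest.approx(1.56, abs=0.05)  # A per residue

    def test_deterministic(self):
        p = CoiledCoilParams(n_residues=30)
        a = gen_coiled_coil(p).ca_coords("A")
        b = gen_coiled_coil(p).ca_coords("A")
        assert np.array_equal(a, b)


class TestDSCGenerator:
    def test_peak_at_tm_with_closed_form_height(self):
        """Single transition: peak at Tm, height dHcal dHvH / (4 R Tm^2)."""
        tr = TransitionSpec(Tm=41.5, dH_cal=640.0, dH_vH=640.0)
        grid = np.arange(20.0, 65.0, 0.01)
        curve = gen_dsc_curve([tr], grid)
        i = curve["Cp_excess"].idxmax()
        assert curve["T_C"][i] == pytest.approx(41.5, abs=0.02)
        h_expect = 640.0 * 640.0 / (4 * R_GAS * (41.5 + 273.15) ** 2)
        assert h_expect == pytest.approx(124.4, abs=0.1)
        assert curve["Cp_excess"].max() == pytest.approx(h_expect, rel=1e-4)

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 3.0])
    def test_integral_conserves_dh_cal_independent_of_vh(self, ratio):
        trs = [TransitionSpec(Tm=40.0, dH_cal=500.0, dH_vH=500.0 * ratio),
               TransitionSpec(Tm=50.0, dH_cal=300.0, dH_vH=300.0 * ratio)]
        grid = np.arange(-20.0, 110.0, 0.02)
        with np.errstate(over="ignore"):
            curve = gen_dsc_curve(trs, grid)
        total = np.trapezoid(curve["Cp_excess"], curve["T_C"])
        assert total == pytest.approx(800.0, rel=0.01)

    def test_three_domain_curve_integrates_to_total(self):
        trs = [TransitionSpec(33.7, 100.0, 100.0),
               TransitionSpec(41.5, 640.0, 640.0),
               TransitionSpec(49.7, 415.0, 415.0)]
        grid = np.arange(0.0, 90.0, 0.02)
        curve = gen_dsc_curve(trs, grid)
        total = np.trapezoid(curve["Cp_excess"], curve["T_C"])
        assert total == pytest.approx(1155.0, rel=0.01)

    def test_grid_not_spanning_warns(self):
        tr = TransitionSpec(Tm=41.5, dH_cal=640.0, dH_vH=640.0)
        with pytest.warns(UserWarning, match="does not span"):
            gen_dsc_curve([tr], np.arange(35.0, 45.0, 0.1))


class TestCurveGenerators:
    def test_hill_midpoint_saturation_and_relaxation(self):
        assert hill_velocity(6.13, 5.8, 6.13, 3.1) == pytest.approx(2.9)
        # pCa 5.0 is saturating for these parameters
        assert hill_velocity(5.0, 5.8, 6.13, 3.1) == pytest.approx(5.8, abs=0.01)
        assert hill_velocity(12.0, 5.8, 6.13, 3.1) == pytest.approx(0.0, abs=1e-9)

    def test_motility_noise_clip_and_replicates(self):
        df = gen_motility_curve(5.8, 6.13, 3.1, np.arange(4, 7.1, 0.5),
                                noise_sd=2.0, replicates=3, seed=1)
        assert (df["velocity"] >= 0).all()
        assert len(df) == 3 * len(np.arange(4, 7.1, 0.5))

    def test_dissociation_midpoint_and_asymptotes(self):
        grid = np.array([0.0, 20.0, 46.14, 70.0, 100.0])
        df = gen_dissociation_curve(46.14, 1.0, grid)
        y = float(df.set_index("T_C")["scattering"].loc[46.14])
        assert y == pytest.approx(0.5, abs=1e-12)
        assert df["scattering"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert df["scattering"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_dissociation_crosses_half_near_midpoint(self):
        df = gen_dissociation_curve(46.14, 1.0, np.arange(35.0, 60.01, 0.25))
        above = df[df["scattering"] > 0.5]["T_C"].max()
        below = df[df["scattering"] < 0.5]["T_C"].min()
        assert 46.0 <= above <= 46.25
        assert 46.0 <= below <= 46.25

    def test_nem_line_values(self):
        df = gen_nem_line(8.0, 20.0, [0.0, 10.0, 20.0, 30.0])
        assert df["velocity"].tolist() == [8.0, 4.0, 0.0, 0.0]

    def test_generators_bit_reproducible(self):
        a = gen_motility_curve(5.8, 6.13, 3.1, [4, 5, 6, 7], noise_sd=0.2, seed=5)
        b = gen_motility_curve(5.8, 6.13, 3.1, [4, 5, 6, 7], noise_sd=0.2, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = gen_dissociation_curve(46.0, 1.0, [40, 45, 50], noise_sd=0.1, seed=5)
        d = gen_dissociation_curve(46.0, 1.0, [40, 45, 50], noise_sd=0.1, seed=5)
        pd.testing.assert_frame_equal(c, d)
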