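"""Tangent-correlation persistence-length estimator."""
import numpy as np
import pandas as pd
import pytest

from tpmflex import (WLCParams, estimate_stiffness_from_skeletons,
                     fit_persistence, gen_wlc_ensemble,
                     nearest_neighbor_persistence, superpose_first_segments,
                     tangent_correlation)
from tpmflex.skeleton import SkeletonFrame


def _rigid_rod_skeletons(n_frames=5, n_nodes=10):
    nodes = np.zeros((n_nodes, 3))
    nodes[:, 2] = np.arange(n_nodes) * 1.4
    return [SkeletonFrame.from_nodes(nodes.copy()) for _ in range(n_frames)]


def _skeletons_from_wlc(params):
    return [SkeletonFrame.from_nodes(n) for n in gen_wlc_ensemble(params)]


class TestSuperposition:
    def test_identical_frames_stay_identical(self):
        sks = _rigid_rod_skeletons()
        aligned = superpose_first_segments(sks)
        for a, b in zip(aligned[1:], aligned[:1] * len(aligned)):
            assert np.allclose(a.nodes, b.nodes, atol=1e-9)

    def test_random_rigid_motions_removed(self, random_rigid_motion):
        """Copies of one skeleton under random rigid motions realign exactly."""
        rng = np.random.default_rng(8)
        base = np.cumsum(rng.normal(size=(12, 3)), axis=0)
        sks = []
        for _ in range(6):
            A = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(A)
            if np.linalg.det(Q) < 0:
                Q[:, 0] = -Q[:, 0]
            t = rng.normal(scale=10.0, size=3)
            sks.append(SkeletonFrame.from_nodes(base @ Q.T + t))
        aligned = superpose_first_segments(sks, mode="first-two-segments")
        ref = aligned[0].nodes
        for sk in aligned[1:]:
            rmsd = np.sqrt(((sk.nodes - ref) ** 2).sum(axis=1).mean())
            assert rmsd < 1e-6

    def test_torsion_about_first_segment(self):
        """Frames differing by spin about the first tangent are distinguished
        by the triad mode (via node 2) but not by the first-segment mode."""
        nodes = np.array([[0, 0, 0], [0, 0, 1.0], [0.5, 0, 2.0], [1.0, 0, 3.0]])
        ang = 0.8
        Rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                       [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        sks = [SkeletonFrame.from_nodes(nodes),
               SkeletonFrame.from_nodes(nodes @ Rz.T)]
        lit = superpose_first_segments(sks, mode="first-segment")
        assert not np.allclose(lit[0].nodes, lit[1].nodes, atol=1e-6)
        tri = superpose_first_segments(sks, mode="first-two-segments")
        assert np.allclose(tri[0].nodes, tri[1].nodes, atol=1e-6)

    def test_too_few_nodes_for_triad_mode(self):
        nodes = np.array([[0, 0, 0], [0, 0, 1.0]])
        sks = [SkeletonFrame.from_nodes(nodes)] * 3
        with pytest.raises(ValueError):
            superpose_first_segments(sks, mode="first-two-segments")


class TestTangentCorrelation:
    def test_rigid_rod_correlation_is_one(self):
        aligned = superpose_first_segments(_rigid_rod_skeletons())
        _, profile = tangent_correlation(aligned)
        assert np.allclose(profile["C"], 1.0, atol=1e-12)
        assert np.allclose(profile["lnC"], 0.0, atol=1e-12)

    def test_tangents_unit_norm_and_count(self, wlc_skeletons):
        aligned = superpose_first_segments(wlc_skeletons[:50])
        field, profile = tangent_correlation(aligned)
        assert field.tangents.shape[1] == wlc_skeletons[0].n_nodes - 1
        norms = np.linalg.norm(field.tangents, axis=2)
        assert np.allclose(norms, 1.0, atol=1e-9)
        assert (profile["C"] <= 1.0 + 1e-9).all()

    def test_wlc_log_profile_near_linear(self, wlc_skeletons):
        aligned = superpose_first_segments(wlc_skeletons, mode="first-segment")
        _, profile = tangent_correlation(aligned)
        # ln C(s) ~ -s/L over s <~ L/3
        s, lnC = profile["s"].to_numpy(), profile["lnC"].to_numpy()
        keep = s <= 161 / 3
        slope = np.polyfit(s[keep], lnC[keep], 1)[0]
        assert -1.0 / slope == pytest.approx(161.0, rel=0.10)

    def test_zero_length_segment_error(self):
        nodes = np.array([[0, 0, 0], [0, 0, 1.0], [0, 0, 1.0], [0, 0, 2.0]])
        sk = SkeletonFrame(nodes=nodes, arc_s=np.array([0.0, 1.0, 1.5, 2.5]))
        with pytest.raises(ValueError, match="zero-length"):
            tangent_correlation([sk, sk])


class TestFitPersistence:
    def test_exact_lines_reproduce_printed_stiffness(self):
        """Slope -1/L with kBT = 4.1 pN nm maps 161/218/203 nm onto
        660/894/832 pN nm^2."""
        s = np.linspace(0.7, 40, 29)
        for L, K in [(161.0, 660.0), (218.0, 894.0), (203.0, 832.0)]:
            prof = pd.DataFrame({"s": s, "C": np.exp(-s / L)})
            fit = fit_persistence(prof, fit_range=(0, 40))
            assert fit.L_p == pytest.approx(L, rel=1e-9)
            assert fit.K == pytest.approx(K, abs=0.5)
            assert fit.K / fit.L_p == pytest.approx(fit.kBT, rel=1e-12)

    def test_flat_profile_flags_infinite(self):
        s = np.linspace(1, 30, 20)
        fit = fit_persistence(pd.DataFrame({"s": s, "C": np.ones_like(s)}),
                              fit_range=(0, 30))
        assert fit.infinite and np.isinf(fit.L_p) and np.isinf(fit.K)

    def test_nonpositive_points_excluded_and_counted(self):
        s = np.linspace(1, 30, 20)
        C = np.exp(-s / 50.0)
        C[-3:] = -0.01
        fit = fit_persistence(pd.DataFrame({"s": s, "C": C}), fit_range=(0, 30))
        assert fit.n_excluded == 3
        assert fit.L_p == pytest.approx(50.0, rel=1e-6)

    def test_free_intercept_option(self):
        s = np.linspace(1, 30, 20)
        prof = pd.DataFrame({"s": s, "C": np.exp(-s / 100.0 - 0.05)})
        fit = fit_persistence(prof, fit_range=(0, 30), through_origin=False)
        assert fit.L_p == pytest.approx(100.0, rel=1e-6)
        assert fit.intercept == pytest.approx(-0.05, abs=1e-9)


class TestEndToEnd:
    @pytest.mark.parametrize("L_true", [161.0, 218.0])
    def test_wlc_parameter_recovery(self, L_true):
        """Generator ground truth recovered within 10%."""
        params = WLCParams(n_chains=3000, n_segments=30, segment_length=1.4,
                           persistence_length=L_true, seed=21)
        sks = _skeletons_from_wlc(params)
        fit, report = estimate_stiffness_from_skeletons(
            sks, mode="first-segment", fit_range=(0, 30))
        assert fit.L_p == pytest.approx(L_true, rel=0.10)
        assert report["n_frames"] == 3000

    def test_rigid_rod_infinite_flag(self):
        fit, _ = estimate_stiffness_from_skeletons(_rigid_rod_skeletons())
        assert fit.infinite

    def test_global_rigid_motion_invariance(self, wlc_skeletons,
                                            random_rigid_motion):
        """One fixed rotation+translation applied to every frame changes
        L_p by < 0.1%."""
        Q, t = random_rigid_motion
        sub = wlc_skeletons[:800]
        moved = [SkeletonFrame.from_nodes(sk.nodes @ Q.T + t) for sk in sub]
        fit0, _ = estimate_stiffness_from_skeletons(sub, fit_range=(0, 30))
        fit1, _ = estimate_stiffness_from_skeletons(moved, fit_range=(0, 30))
        assert fit1.L_p == pytest.approx(fit0.L_p, rel=1e-3)

    def test_coordinate_scaling(self, wlc_skeletons):
        """Scaling all coordinates by c scales L_p and K by c at fixed kBT."""
        sub = wlc_skeletons[:800]
        scaled = [SkeletonFrame.from_nodes(2.0 * sk.nodes) for sk in sub]
        fit0, _ = estimate_stiffness_from_skeletons(sub, mode="first-segment")
        fit1, _ = estimate_stiffness_from_skeletons(scaled, mode="first-segment")
        assert fit1.L_p == pytest.approx(2.0 * fit0.L_p, rel=1e-6)
        assert fit1.K == pytest.approx(2.0 * fit0.K, rel=1e-6)

    def test_consistency_with_ensemble_size(self):
        """Bias shrinks (or stays small) as the ensemble grows."""
        errs = {}
        for n in (300, 3000):
            sks = _skeletons_from_wlc(WLCParams(n_chains=n, seed=33))
            fit, _ = estimate_stiffness_from_skeletons(
                sks, mode="first-segment", fit_range=(0, 30))
            errs[n] = abs(fit.L_p - 161.0) / 161.0
        assert errs[3000] < 0.10
        assert errs[300] < 0.25

    def test_nearest_neighbor_estimator_agrees(self, wlc_skeletons):
        L = nearest_neighbor_persistence(wlc_skeletons)
        assert L == pytest.approx(161.0, rel=0.05)
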