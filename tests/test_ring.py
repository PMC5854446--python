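"""Ring reaction-diffusion model: geometry, transport, oracle equivalences."""

import numpy as np
import pytest

from chemosense import (
    DimensionlessTransport,
    GradientProfile,
    GradientShape,
    RingGrid,
    SpatialTrajectory,
    StepStimulus,
    Topology,
    input_profile,
    ring_laplacian,
    simulate_point,
    simulate_ring,
    summarize_traj,
)
from conftest import CANONICAL


class TestGrid:
    def test_front_back_split_even(self):
        for N in (4, 20, 64):
            g = RingGrid(N)
            assert g.front_mask.sum() == N // 2
            assert g.back_mask.sum() == N // 2
            assert not np.any(g.axial_offsets == 0.0)

    def test_odd_or_tiny_rejected(self):
        with pytest.raises(ValueError):
            RingGrid(21)
        with pytest.raises(ValueError):
            RingGrid(2)

    def test_spacing_is_circumference_over_n(self):
        assert RingGrid(20).spacing == pytest.approx(np.pi / 20)


class TestInputProfile:
    def test_zero_slope_uniform(self):
        g = RingGrid(20)
        prof = GradientProfile(alpha=0.0)
        for tau in (-5.0, 0.0, 3.0, 50.0):
            assert np.allclose(input_profile(prof, tau, g, 0.5), prof.I_L)

    def test_linear_clamp_hand_values(self):
        g = RingGrid(20)
        prof = GradientProfile(alpha=0.001, I_L=0.5, T_s=10.0)
        I = input_profile(prof, 2.0, g, 0.5)
        i_front = np.argmax(g.axial_offsets)
        i_back = np.argmin(g.axial_offsets)
        assert I[i_front] == pytest.approx(0.503, abs=1e-3)
        assert I[i_back] == pytest.approx(0.501, abs=1e-3)

    def test_whole_cell_at_plateau_after_exit(self):
        g = RingGrid(20)
        beta, prof = 0.5, GradientProfile(alpha=0.001, T_s=10.0)
        tau = (beta * prof.T_s + 0.5) / beta + 1e-9
        assert np.allclose(input_profile(prof, tau, g, beta), prof.I_H)

    def test_exponential_matches_linear_log_slope_at_baseline(self):
        lin = GradientProfile(shape=GradientShape.LINEAR, alpha=0.001)
        exp = GradientProfile(shape=GradientShape.EXPONENTIAL, alpha=0.001)
        x = np.array([1e-4])
        dlin = (lin.field_at(x, 1.0) - lin.I_L) / lin.I_L
        dexp = np.log(exp.field_at(x, 1.0) / exp.I_L)
        assert dlin == pytest.approx(dexp, rel=1e-3)

    def test_step_profile(self):
        g = RingGrid(20)
        prof = GradientProfile(shape=GradientShape.STEP, I_L=0.5, I_H_step=1.0)
        I = input_profile(prof, 0.0, g, 1.0)
        assert set(np.round(I, 12)) == {0.5, 1.0}


class TestLaplacian:
    def test_uniform_field_zero(self):
        g = RingGrid(16)
        assert np.allclose(ring_laplacian(np.full(16, 3.7), 1.0, g), 0.0)

    def test_conservation(self):
        g = RingGrid(32)
        v = np.random.default_rng(0).uniform(size=32)
        assert abs(ring_laplacian(v, 2.5, g).sum()) < 1e-12 * np.abs(v).max()

    def test_eigenmode_decay_matches_continuum(self):
        g = RingGrid(64)
        v = np.cos(g.angles)
        out = ring_laplacian(v, 1.0, g)
        ratio = out / v
        assert np.allclose(ratio, -4.0, rtol=2e-3)


class TestSimulateRing:
    def test_uniform_input_preserves_symmetry(self):
        prof = GradientProfile(alpha=0.0)
        tr = simulate_ring(CANONICAL, Topology.IFF,
                           DimensionlessTransport(1.0, 1.0, 1.0, 0.0), prof,
                           RingGrid(8), tau_end=5.0)
        assert np.allclose(tr.C, tr.C[0, 0], atol=1e-7)
        assert np.allclose(tr.front_C, tr.back_C, atol=1e-6)

    def test_point_model_oracle_without_diffusion(self):
        """With D'=0 each compartment is an independent point cell whose
        input steps from I_L to I_H when it crosses the step front."""
        beta = 0.5
        prof = GradientProfile(shape=GradientShape.STEP, I_L=0.5, I_H_step=0.6)
        grid = RingGrid(8)
        tr = simulate_ring(CANONICAL, Topology.IFF,
                           DimensionlessTransport(beta, 0.0, 0.0, 0.0), prof,
                           grid, tau_end=12.0, rtol=1e-10, atol=1e-12)
        for i in np.where(grid.back_mask)[0]:
            tau_cross = -grid.axial_offsets[i] / beta
            stim = StepStimulus(I_L=0.5, I_H=0.6, tau_step=tau_cross,
                                tau_end=12.0)
            pt = simulate_point(CANONICAL, Topology.IFF, stim,
                                rtol=1e-10, atol=1e-12)
            interp = np.interp(tr.times, pt.times, pt.C)
            assert np.max(np.abs(tr.C[:, i] - interp)) < 1e-5

    def test_fixed_step_matches_adaptive(self, screened_iff):
        prof = GradientProfile()
        grid = RingGrid(20)
        tp = DimensionlessTransport(0.25, 1.0, 100.0, 0.0)
        p = screened_iff[0]
        tr_a = simulate_ring(p, Topology.IFF, tp, prof, grid)
        tr_f = simulate_ring(p, Topology.IFF, tp, prof, grid, method="fixed")
        assert np.max(np.abs(tr_a.C - tr_f.C)) < 1e-5

    def test_output_homogenized_by_fast_output_diffusion(self):
        prof = GradientProfile()
        grid = RingGrid(20)
        contrast = {}
        for D_C in (0.0, 100.0):
            tr = simulate_ring(CANONICAL, Topology.IFF,
                               DimensionlessTransport(0.125, 1.0, 100.0, D_C),
                               prof, grid)
            contrast[D_C] = np.max(np.abs(tr.front_C - tr.back_C) / (grid.N * tr.mean_C))
        assert contrast[100.0] < 0.02 * contrast[0.0]

    def test_front_leads_back(self, screened_iff):
        """Moving up-gradient, the front half's output peaks before the back
        half's (it meets the chemoattractant first)."""
        tr = simulate_ring(screened_iff[0], Topology.IFF,
                           DimensionlessTransport(0.125, 1.0, 1.0, 0.0),
                           GradientProfile(), RingGrid(20))
        assert tr.times[np.argmax(tr.front_C)] < tr.times[np.argmax(tr.back_C)]

    def test_noise_hooks_require_fixed_method(self):
        class Hooks:
            def modify_input(self, tau, x, I):
                return I

            def params_at(self, tau, base):
                return base

        with pytest.raises(ValueError):
            simulate_ring(CANONICAL, Topology.IFF,
                          DimensionlessTransport(1, 0, 0, 0),
                          GradientProfile(), RingGrid(8), tau_end=1.0,
                          noise_hooks=Hooks(), method="adaptive")


class TestSummaries:
    def _make(self, C, N):
        grid = RingGrid(N)
        t = np.arange(C.shape[0], dtype=float)
        return SpatialTrajectory(times=t, A=np.zeros_like(C),
                                 B=np.zeros_like(C), C=C, grid=grid,
                                 baseline_C=C[0].copy()), grid

    def test_uniform_summaries(self):
        traj, grid = self._make(np.full((3, 4), 0.5), 4)
        mean, front, back = summarize_traj(traj, grid)
        assert np.allclose(mean, 0.5)
        assert np.allclose(front, 1.0)
        assert np.allclose(back, 1.0)

    def test_hand_summed_front_back(self):
        grid = RingGrid(4)
        C = np.where(grid.front_mask, 0.6, 0.4)[None, :].repeat(2, axis=0)
        traj, grid = self._make(C, 4)
        mean, front, back = summarize_traj(traj, grid)
        assert np.allclose(mean, 0.5)
        assert np.allclose(front, 1.2)
        assert np.allclose(back, 0.8)

    def test_partition_identity(self):
        rng = np.random.default_rng(3)
        traj, grid = self._make(rng.uniform(0.1, 0.9, size=(5, 20)), 20)
        mean, front, back = summarize_traj(traj, grid)
        assert np.allclose(mean, (front + back) / grid.N)
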