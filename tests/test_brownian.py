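import math

import numpy as np
import pytest
from scipy import stats

from synaptrap.analysis import compute_msd
from synaptrap.brownian import (BoundaryPolicy, apply_cleft_boundaries,
                                apply_membrane_boundaries, gaussian_step,
                                wrap_toroidal)
from synaptrap.geometry import SpineGeometry, build_cleft_geometry


class TestGaussianStep:
    def test_zero_diffusion_is_static(self, rng):
        pos = rng.normal(size=(100, 2))
        out = gaussian_step(pos, 0.0, 1e-6, rng)
        np.testing.assert_array_equal(out, pos)

    def test_step_standard_deviation(self, rng):
        """D = 0.45 µm²/s at 1 µs: per-axis sd = sqrt(2 D dt) ~ 0.949 nm."""
        pos = np.zeros((200_000, 2))
        out = gaussian_step(pos, 0.45, 1e-6, rng)
        assert out.std() == pytest.approx(math.sqrt(0.9), rel=0.01)

    def test_immobile_mask(self, rng):
        pos = np.zeros((10, 2))
        mobile = np.zeros(10, dtype=bool)
        mobile[:5] = True
        out = gaussian_step(pos, 0.45, 1e-6, rng, mobile=mobile)
        assert np.all(out[5:] == 0)
        assert np.all(out[:5] != 0)

    def test_free_msd_recovers_diffusion_coefficient(self, rng):
        """Ensemble MSD of free 2D walkers is 4 D t; the fitted D is
        within 5% of the input."""
        n, steps, dt, D = 400, 400, 1e-6, 0.45
        traj = np.zeros((n, steps + 1, 2))
        pos = np.zeros((n, 2))
        for i in range(steps):
            pos = gaussian_step(pos, D, dt, rng)
            traj[:, i + 1] = pos
        t = np.arange(steps + 1) * dt
        _, D_fit = compute_msd(t, traj)
        assert D_fit == pytest.approx(D, rel=0.05)


class TestMembraneBoundaries:
    def test_wrap_preserves_uniform_density(self, rng, ref_geom):
        """Occupancy of a long toroidal trajectory stays uniform
        (chi-square test on a coarse grid)."""
        pol = BoundaryPolicy(p_reflect=0.0)
        n = 3000
        pos = rng.uniform(-ref_geom.L_side / 2, ref_geom.L_side / 2, (n, 2))
        for _ in range(200):
            prop = gaussian_step(pos, 20.0, 1e-6, rng)  # big steps
            pos = apply_membrane_boundaries(pos, prop, pol, ref_geom, rng)
        half = ref_geom.L_side / 2
        assert np.all(np.abs(pos) <= half)
        counts, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=4,
                                      range=[[-half, half], [-half, half]])
        chi2 = ((counts - n / 16) ** 2 / (n / 16)).sum()
        assert chi2 < stats.chi2.ppf(0.999, 15)

    def test_open_boundary_returns_wrapped_proposal(self, rng, ref_geom):
        pol = BoundaryPolicy(p_reflect=0.0)
        prev = np.array([[0.0, 0.0]])
        prop = np.array([[ref_geom.L_side * 0.75, 5.0]])
        out = apply_membrane_boundaries(prev, prop, pol, ref_geom, rng)
        assert out[0, 0] == pytest.approx(-ref_geom.L_side * 0.25)
        assert out[0, 1] == 5.0

    def test_radial_fold_on_reflection(self, rng, ref_geom):
        """prev at r=290, proposal at r=300 with r_PSD=295.4 and certain
        reflection: final radius 2*295.4 - 300 = 290.8 on the bearing."""
        pol = BoundaryPolicy(p_reflect=1.0)
        bearing = np.array([math.cos(0.7), math.sin(0.7)])
        prev = (290.0 * bearing)[None, :]
        prop = (300.0 * bearing)[None, :]
        out = apply_membrane_boundaries(prev, prop, pol, ref_geom, rng)
        r_out = np.hypot(out[0, 0], out[0, 1])
        assert r_out == pytest.approx(2 * ref_geom.r_PSD - 300.0, abs=1e-9)
        np.testing.assert_allclose(out[0] / r_out, bearing, rtol=1e-12)

    def test_partial_reflection_is_bernoulli(self, rng, ref_geom):
        """Half of outward crossings reflect at p_reflect = 0.5."""
        pol = BoundaryPolicy(p_reflect=0.5)
        n = 20_000
        bearing = rng.normal(size=(n, 2))
        bearing /= np.linalg.norm(bearing, axis=1, keepdims=True)
        prev = 294.0 * bearing
        prop = 297.0 * bearing
        out = apply_membrane_boundaries(prev, prop, pol, ref_geom, rng)
        r_out = np.hypot(out[:, 0], out[:, 1])
        frac = (r_out < ref_geom.r_PSD).mean()
        assert frac == pytest.approx(0.5, abs=0.015)

    def test_inward_crossings_always_stand(self, rng, ref_geom):
        pol = BoundaryPolicy(p_reflect=1.0)
        bearing = np.array([[1.0, 0.0]])
        out = apply_membrane_boundaries(300.0 * bearing, 290.0 * bearing,
                                        pol, ref_geom, rng)
        assert np.hypot(*out[0]) == pytest.approx(290.0)

    def test_p_reflect_validated(self):
        with pytest.raises(ValueError):
            BoundaryPolicy(p_reflect=1.5)

    def test_corral_msd_saturates(self, rng):
        """A walker confined to a 300 nm circular corral has an MSD that
        levels off below the squared corral diameter, while the free MSD
        keeps growing linearly."""
        corral = SpineGeometry(V_spine=0.5, A_spine=3.05, A_PSD=0.28,
                               r_PSD=300.0, A_ESM=2.77, L_side=1746.0,
                               psd_fraction=0.09, d_neck=872.5,
                               d_half=583.95)
        pol = BoundaryPolicy(p_reflect=1.0)
        n, steps, dt = 300, 3000, 1e-6
        pos = np.zeros((n, 2))
        traj = np.zeros((n, steps + 1, 2))
        free = np.zeros((n, 2))
        traj_free = np.zeros_like(traj)
        for i in range(steps):
            prop = gaussian_step(pos, 10.0, dt, rng)
            pos = apply_membrane_boundaries(pos, prop, pol, corral, rng)
            traj[:, i + 1] = pos
            free = gaussian_step(free, 10.0, dt, rng)
            traj_free[:, i + 1] = free
        t = np.arange(steps + 1) * dt
        msd, _ = compute_msd(t, traj)
        msd_free, D_fit = compute_msd(t, traj_free)
        assert msd[-1, 1] < (2 * 300.0) ** 2
        # confined curve flattens: last-quarter growth is a small
        # fraction of the free-diffusion growth over the same span
        grow_conf = msd[-1, 1] - msd[3 * steps // 4, 1]
        grow_free = msd_free[-1, 1] - msd_free[3 * steps // 4, 1]
        assert grow_conf < 0.2 * grow_free
        assert msd_free[-1, 1] > 2.0 * msd[-1, 1]


class TestCleftBoundaries:
    def test_floor_mirror(self):
        c = build_cleft_geometry()
        prev = np.array([[0.0, 0.0, 2.0]])
        prop = np.array([[0.0, 0.0, -1.0]])
        out, absorbed = apply_cleft_boundaries(prev, prop, c)
        assert out[0, 2] == pytest.approx(1.0)
        assert not absorbed[0]

    def test_ceiling_mirror_repeated(self):
        c = build_cleft_geometry()
        out, _ = apply_cleft_boundaries(
            np.array([[0.0, 0.0, 10.0]]), np.array([[0.0, 0.0, 50.0]]), c)
        assert 0.0 <= out[0, 2] <= c.height

    def test_side_wall_absorbs(self):
        c = build_cleft_geometry()
        out, absorbed = apply_cleft_boundaries(
            np.array([[340.0, 0.0, 5.0]]), np.array([[360.0, 0.0, 5.0]]), c)
        assert absorbed[0]

    def test_all_glutamate_eventually_absorbed(self, rng):
        """Without receptors the free glutamate count is non-increasing
        and tends to zero."""
        c = build_cleft_geometry(n_glutamate=500)
        pos = np.tile(np.array(c.release_point), (500, 1))
        alive = np.ones(500, dtype=bool)
        counts = [500]
        sd = math.sqrt(2.0 * c.D_glu * 1e9 * 1e-6)
        for _ in range(2000):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            prop = pos[idx] + rng.normal(0, sd, (idx.size, 3))
            out, absorbed = apply_cleft_boundaries(pos[idx], prop, c)
            pos[idx] = out
            alive[idx[absorbed]] = False
            counts.append(int(alive.sum()))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0


def test_wrap_toroidal_identity_inside():
    x = np.array([[10.0, -20.0]])
    np.testing.assert_allclose(wrap_toroidal(x, 100.0), x)
    np.testing.assert_allclose(wrap_toroidal(np.array([[60.0, 0.0]]), 100.0),
                               [[-40.0, 0.0]])
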