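import math

import numpy as np
import pytest
from scipy.linalg import expm

from synaptrap.reactions import (GLU_PER_STATE, JONAS_RATES_25C,
                                 KineticScheme, ReactionSpec,
                                 bind_bimolecular, binding_radius_from_rate,
                                 jonas_scheme, q10_adjust,
                                 rate_from_binding_radius, smoluchowski_rate,
                                 step_first_order)

# published rate <-> radius pairs at 1 µs steps
RATES_VS_SIGMA_D045 = {0.1: 2550, 0.2: 20300, 0.3: 67300, 0.4: 154000,
                       0.5: 289000, 0.6: 473000, 0.7: 700000, 0.8: 963000,
                       0.9: 1253000, 1.0: 1590000}
RATES_VS_D_SIGMA05 = {0.1: 185000, 0.2: 245000, 0.3: 271000, 0.4: 285000,
                      0.5: 293000, 0.6: 298000, 0.7: 301000, 0.8: 303000,
                      0.9: 306000, 1.0: 307000}

# printed temperature-adjusted constants (Q10 = 3 over 15 °C)
ADJUSTED_PRINTED = {
    "k_plus1": 23.85e6, "k_minus1": 22.14e3, "k_plus2": 147.57e6,
    "k_minus2": 16.94e3, "k_plus3": 6.6e6, "k_minus3": 237.46,
    "alpha": 22.03e3, "beta": 4676.54, "alpha1": 15.02e3, "beta1": 203.69,
    "alpha2": 893.74, "beta2": 3.78, "alpha3": 91.97, "beta3": 20.78,
    "alpha4": 87.3, "beta4": 989.35,
}


class TestCalibration:
    @pytest.mark.parametrize("sigma,expected",
                             sorted(RATES_VS_SIGMA_D045.items()))
    def test_rate_table_vs_sigma(self, sigma, expected):
        """Published radius->rate pairs at D = 0.45 µm²/s, 1 µs steps,
        reproduced within 5%."""
        got = rate_from_binding_radius(sigma, 0.45, 1e-6)
        assert got == pytest.approx(expected, rel=0.05)

    @pytest.mark.parametrize("D,expected", sorted(RATES_VS_D_SIGMA05.items()))
    def test_rate_table_vs_diffusion(self, D, expected):
        """Published rate vs diffusion coefficient at sigma = 0.5 nm,
        reproduced within 5%."""
        got = rate_from_binding_radius(0.5, D, 1e-6)
        assert got == pytest.approx(expected, rel=0.05)

    def test_anchor_pairs_tight(self):
        """The two anchor calibrations agree within 2%."""
        assert binding_radius_from_rate(289000, 0.45, 1e-6) == \
            pytest.approx(0.5, rel=0.02)
        assert rate_from_binding_radius(0.5, 0.5, 1e-6) == \
            pytest.approx(293000, rel=0.02)

    def test_monotone_in_sigma_and_D(self):
        ks = [rate_from_binding_radius(s, 0.45, 1e-6)
              for s in sorted(RATES_VS_SIGMA_D045)]
        assert all(b > a for a, b in zip(ks, ks[1:]))
        kd = [rate_from_binding_radius(0.5, D, 1e-6)
              for D in sorted(RATES_VS_D_SIGMA05)]
        assert all(b > a for a, b in zip(kd, kd[1:]))

    def test_smoluchowski_limit_small_dt(self):
        """As dt -> 0 the calibration converges to 4 pi D sigma N_A."""
        got = rate_from_binding_radius(0.5, 0.45, 1e-10)
        assert got == pytest.approx(smoluchowski_rate(0.5, 0.45), rel=0.02)

    def test_round_trip_identity(self):
        for k in (2550, 289000, 1590000):
            sig = binding_radius_from_rate(k, 0.45, 1e-6)
            back = rate_from_binding_radius(sig, 0.45, 1e-6)
            assert back == pytest.approx(k, rel=1e-5)

    def test_degenerate_inputs(self):
        assert rate_from_binding_radius(0.0, 0.45, 1e-6) == 0.0
        assert binding_radius_from_rate(0.0, 0.45, 1e-6) == 0.0
        with pytest.raises(ValueError):
            rate_from_binding_radius(-1.0, 0.45, 1e-6)
        with pytest.raises(ValueError):
            binding_radius_from_rate(1e5, 0.45, -1e-6)

    def test_reaction_spec_consistency(self):
        spec = ReactionSpec.from_rate(289000, 0.45, 1e-6)
        assert spec.sigma_bind == pytest.approx(0.5, rel=0.02)
        assert spec.sigma_unbind == spec.sigma_bind
        spec2 = ReactionSpec.from_radius(0.5, 0.45, 1e-6)
        assert spec2.rate_k == pytest.approx(289000, rel=0.02)

    def test_brute_force_pair_oracle(self):
        """Independent oracle: a periodic box of Brownian walkers around
        a static absorbing trap realises the calibrated rate within
        sampling error.  Absorbed walkers respawn uniformly; the rate is
        normalised by the far-field density."""
        sigma, D, dt = 1.0, 0.45, 1e-6
        k_pred = rate_from_binding_radius(sigma, D, dt)  # M^-1 s^-1
        k_pred_nm3 = k_pred / (6.02214076e23 * 1e-24)    # nm^3/s
        s = math.sqrt(2.0 * D * 1e6 * dt)
        L = 24.0 * s                                     # box side, nm
        n, n_steps = 3000, 12_000
        rng = np.random.default_rng(42)
        pos = rng.uniform(-L / 2, L / 2, (n, 3))
        absorbed_total = 0
        far_density = []
        for step in range(n_steps):
            pos += rng.normal(0, s, (n, 3))
            pos = (pos + L / 2) % L - L / 2
            r2 = (pos ** 2).sum(axis=1)
            hit = r2 < sigma ** 2
            n_hit = int(hit.sum())
            if n_hit:
                absorbed_total += n_hit
                pos[hit] = rng.uniform(-L / 2, L / 2, (n_hit, 3))
            if step % 50 == 0:
                far = (np.abs(pos) > L / 4).any(axis=1)
                shell_vol = L ** 3 - (L / 2) ** 3
                far_density.append(far.sum() / shell_vol)
        rho = float(np.mean(far_density))
        k_meas = absorbed_total / (n_steps * dt * rho)
        assert k_meas == pytest.approx(k_pred_nm3, rel=0.05)


class TestQ10:
    @pytest.mark.parametrize("name,printed", sorted(ADJUSTED_PRINTED.items()))
    def test_adjusted_table(self, name, printed):
        """Every temperature-adjusted constant equals the original times
        3^1.5, matching the printed values within 0.1%."""
        got = q10_adjust(JONAS_RATES_25C[name], 3.0, 15.0)
        assert got == pytest.approx(printed, rel=1e-3)
        assert got == pytest.approx(JONAS_RATES_25C[name] * 3.0 ** 1.5,
                                    rel=1e-12)

    def test_no_temperature_change(self):
        assert q10_adjust(123.0, 3.0, 0.0) == 123.0

    def test_q10_must_be_positive(self):
        with pytest.raises(ValueError):
            q10_adjust(1.0, 0.0, 10.0)


class TestKineticScheme:
    def test_binding_and_release_structure(self):
        """Exactly three glutamate-consuming transitions (C0->C1,
        C1->C2, C3->C4) and their three reverses release one glutamate;
        opening requires the double-bound state."""
        sch = jonas_scheme()
        binds = sch.binding_transitions()
        assert [(i, j) for i, j, _ in binds] == [(0, 1), (1, 2), (4, 5)]
        rel = sch.release_mask()
        assert rel.sum() == 3
        assert rel[1, 0] and rel[2, 1] and rel[5, 4]
        R = sch.first_order_matrix()
        # opening C2 -> O and closing O -> C2
        assert R[2, 3] == JONAS_RATES_25C["alpha"]
        assert R[3, 2] == JONAS_RATES_25C["beta"]
        # glutamate occupancy bookkeeping per state
        np.testing.assert_array_equal(GLU_PER_STATE, [0, 1, 2, 2, 1, 2, 2])

    def test_rate_matrix_folds_concentration(self):
        sch = jonas_scheme()
        R = sch.rate_matrix(1e-3)
        assert R[0, 1] == pytest.approx(JONAS_RATES_25C["k_plus1"] * 1e-3)
        assert R[1, 2] == pytest.approx(JONAS_RATES_25C["k_plus2"] * 1e-3)


class TestBindBimolecular:
    def test_no_pairs_beyond_sigma(self, rng):
        a = np.array([[0.0, 0.0], [10.0, 0.0]])
        b = np.array([[5.0, 0.0]])
        assert bind_bimolecular(a, b, 1.0) == []

    def test_single_pair_within_sigma(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.4, 0.0]])
        assert bind_bimolecular(a, b, 0.5) == [(0, 0)]

    def test_greedy_nearest_matching(self):
        """Two A compete for one B: the closer A wins; the loser pairs
        with the remaining B."""
        a = np.array([[0.0, 0.0], [0.3, 0.0]])
        b = np.array([[0.2, 0.0], [0.9, 0.0]])
        got = dict(bind_bimolecular(a, b, 1.0))
        assert got == {1: 0, 0: 1}

    def test_one_partner_per_step(self, rng):
        a = rng.uniform(0, 2, (50, 2))
        b = rng.uniform(0, 2, (50, 2))
        pairs = bind_bimolecular(a, b, 1.5)
        assert len({i for i, _ in pairs}) == len(pairs)
        assert len({j for _, j in pairs}) == len(pairs)


class TestStepFirstOrder:
    def test_zero_rates_no_change(self, rng):
        sch = KineticScheme({k: 0.0 for k in JONAS_RATES_25C})
        states = np.zeros(100, dtype=np.int64)
        new, rel = step_first_order(states, sch, 1e-6, rng)
        np.testing.assert_array_equal(new, states)
        assert not rel.any()

    def test_single_rate_transition_fraction(self, rng):
        """With one outgoing rate k the per-step transition fraction is
        1 - exp(-k dt) within binomial error."""
        consts = {k: 0.0 for k in JONAS_RATES_25C}
        consts["alpha1"] = 5e4  # C1 -> C3
        sch = KineticScheme(consts)
        states = np.ones(40_000, dtype=np.int64)
        new, _ = step_first_order(states, sch, 1e-6, rng)
        frac = (new == 4).mean()
        p = 1 - math.exp(-5e4 * 1e-6)
        assert frac == pytest.approx(p, abs=3 * math.sqrt(p / 40_000))

    def test_occupancies_match_master_equation(self, rng):
        """Stochastic single-jump propagation at a fixed well-mixed
        glutamate concentration tracks the 7-state master-equation
        solution within Monte-Carlo error (3 sigma)."""
        sch = jonas_scheme(temperature_adjusted=True)
        conc = 3e-4  # 0.3 mM keeps K dt << 1 (single-jump bias small)
        dt, n_steps, n = 5e-7, 600, 3000
        states = np.zeros(n, dtype=np.int64)
        R = sch.rate_matrix(conc)
        Q = R.T - np.diag(R.sum(axis=1))
        checkpoints = {150, 300, 600}
        for step in range(1, n_steps + 1):
            states, _ = step_first_order(states, sch, dt, rng, conc)
            if step in checkpoints:
                p_ode = expm(Q * step * dt) @ np.eye(7)[0]
                occ = np.bincount(states, minlength=7) / n
                se = np.sqrt(np.maximum(p_ode * (1 - p_ode), 1e-8) / n)
                assert np.all(np.abs(occ - p_ode) < 3.5 * se + 0.5 / n), \
                    (step, occ, p_ode)

    def test_release_flags_on_unbinding(self, rng):
        """A receptor forced through C1 -> C0 releases one glutamate."""
        consts = {k: 0.0 for k in JONAS_RATES_25C}
        consts["k_minus1"] = 1e9
        sch = KineticScheme(consts)
        states = np.ones(10, dtype=np.int64)
        with pytest.warns(RuntimeWarning):
            new, rel = step_first_order(states, sch, 1e-6, rng)
        assert np.all(new == 0)
        assert rel.all()
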