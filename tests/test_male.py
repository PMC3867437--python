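"""Male fitness: paternity certainty, pairing table, enumeration-oracle
agreement, symmetry and advantage signs."""

import numpy as np
import pytest

from coopbreed import (ClampWarning, ModelParams, PopulationState,
                       male_advantage, male_profile, pairing_table,
                       paternity_certainty, sample_params,
                       uniform_simplex_state)
from coopbreed.female import (coalition_partner_prob, fitness_cm, fitness_im,
                              fitness_om, female_profile)


class TestPaternityCertainty:
    def test_no_epm_certain(self, midpoint):
        p = midpoint.replace(e_coal=0.0, e_noncoal=0.0)
        assert paternity_certainty(p, 0.37) == 1.0

    def test_endpoints(self, midpoint):
        assert paternity_certainty(midpoint, 1.0) == 1.0 - midpoint.e_coal
        assert paternity_certainty(midpoint, 0.0) == 1.0 - midpoint.e_noncoal

    def test_arithmetic_and_monotone_in_q(self, midpoint):
        p = midpoint.replace(e_coal=0.02, e_noncoal=0.15)
        assert np.isclose(paternity_certainty(p, 0.4),
                          1 - (0.4 * 0.02 + 0.6 * 0.15))
        qs = np.linspace(0, 1, 21)
        pis = [paternity_certainty(p, q) for q in qs]
        assert all(b >= a for a, b in zip(pis, pis[1:]))


class TestPairingTable:
    def test_independence_without_assortment(self, midpoint, mixed_state):
        tbl = pairing_table(midpoint.replace(a_assort=0.0), mixed_state)
        f = np.array([0.3, 0.3, 0.4])
        assert np.allclose(tbl.joint[:, 0], f * 0.5)
        assert np.allclose(tbl.joint[:, 1], f * 0.5)

    def test_no_coalition_males_empty_column(self, midpoint):
        state = PopulationState(0.3, 0.3, 0.4, 0.0)
        tbl = pairing_table(midpoint, state)
        assert np.all(tbl.joint[:, 0] == 0.0)

    def test_clamped_corner_keeps_marginals(self, midpoint):
        p = midpoint.replace(a_assort=1.0)
        state = PopulationState(0.6, 0.2, 0.2, 0.5)  # demand 0.6 > supply 0.5
        with pytest.warns(ClampWarning):
            tbl = pairing_table(p, state)
        assert tbl.clamped
        assert np.isclose(tbl.joint[0, 0], 0.5)
        assert np.allclose(tbl.joint[1:, 0], 0.0)
        assert np.allclose(tbl.joint.sum(axis=1), [0.6, 0.2, 0.2])
        assert np.allclose(tbl.joint.sum(axis=0), [0.5, 0.5])

    def test_marginals_always_exact(self, table_ranges, rng):
        import warnings
        for p in sample_params(table_ranges, 30, 9):
            state = uniform_simplex_state(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ClampWarning)
                tbl = pairing_table(p, state)
            assert np.all(tbl.joint >= 0)
            assert np.allclose(tbl.joint.sum(axis=1),
                               [state.x_cm, state.y_om, state.z_im], atol=1e-10)
            assert np.allclose(tbl.joint.sum(axis=0),
                               [state.q_coal, 1 - state.q_coal], atol=1e-10)


def enumeration_oracle(p: ModelParams, state: PopulationState):
    """Exhaustive sum over (partnered?, paired female strategy) branches,
    written independently of the implementation's algebra."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClampWarning)
        tbl = pairing_table(p, state)
    pi = 1.0 - (state.q_coal * p.e_coal + (1.0 - state.q_coal) * p.e_noncoal)
    w_mean = female_profile(p, state).w_mean
    freqs = np.array([state.x_cm, state.y_om, state.z_im])

    def female_w(strategy_idx, care):
        f = [fitness_cm, fitness_om, None][strategy_idx]
        if strategy_idx == 2:
            return fitness_im(p, care)
        return f(p, state, care)

    def cond(col):
        mass = col.sum()
        return col / mass if mass > 1e-15 else freqs

    w_coal = 0.0
    pm = coalition_partner_prob(p, state.q_coal)
    for partnered, weight in ((True, pm), (False, 1.0 - pm)):
        care = p.b_coal if partnered else p.b_noncoal
        epm = p.e_coal if partnered else p.e_noncoal
        branch = epm * w_mean
        c = cond(tbl.joint[:, 0])
        for idx in range(3):
            branch += pi * c[idx] * female_w(idx, care)
        w_coal += weight * branch
    c = cond(tbl.joint[:, 1])
    w_non = p.e_noncoal * w_mean
    for idx in range(3):
        w_non += pi * c[idx] * female_w(idx, p.b_noncoal)
    return w_coal, w_non


class TestMaleFitness:
    def test_enumeration_oracle_agreement(self, table_ranges, rng):
        """Implementation equals the exhaustive branch sum at random points
        (including assortative ones)."""
        import warnings
        for p in sample_params(table_ranges, 25, 13):
            state = uniform_simplex_state(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ClampWarning)
                prof = male_profile(p, state)
            w_coal, w_non = enumeration_oracle(p, state)
            assert np.isclose(prof.w_coal, w_coal, rtol=1e-12, atol=1e-12)
            assert np.isclose(prof.w_noncoal, w_non, rtol=1e-12, atol=1e-12)

    def test_midpoint_enumeration_point(self, midpoint):
        state = PopulationState(1 / 3, 1 / 3, 1 / 3, 0.5)
        prof = male_profile(midpoint.replace(r_kin=0.0, a_assort=0.0), state)
        w_coal, w_non = enumeration_oracle(
            midpoint.replace(r_kin=0.0, a_assort=0.0), state)
        assert np.isclose(prof.advantage, w_coal - w_non, atol=1e-12)

    def test_indistinguishable_types_zero_advantage(self, table_ranges, rng):
        """Equal care and EPM parameters give exactly zero advantage for any
        state and kin-selection level (no male-female assortment)."""
        for p in sample_params(table_ranges.fix(a_assort=0.0), 50, 21):
            p = p.replace(e_coal=p.e_noncoal, b_noncoal=p.b_coal)
            state = uniform_simplex_state(rng)
            assert abs(male_advantage(p, state)) < 1e-12

    def test_full_kin_selection_always_partnered(self, midpoint, mixed_state):
        p = midpoint.replace(r_kin=1.0)
        # partnered with certainty: fitness equals the partnered branch
        prof = male_profile(p, mixed_state)
        from coopbreed.male import pairing_table as pt, paternity_certainty as pc
        tbl = pt(p, mixed_state)
        cond = tbl.conditional_female("Coal")
        w = [fitness_cm(p, mixed_state, p.b_coal),
             fitness_om(p, mixed_state, p.b_coal),
             fitness_im(p, p.b_coal)]
        expected = pc(p, mixed_state.q_coal) * float(cond @ np.array(w)) \
            + p.e_coal * female_profile(p, mixed_state).w_mean
        assert np.isclose(prof.w_coal, expected, atol=1e-12)

    def test_no_epm_no_coalition_males(self, midpoint):
        p = midpoint.replace(e_noncoal=0.0, e_coal=0.0)
        state = PopulationState(0.3, 0.3, 0.4, 0.0)
        prof = male_profile(p, state)
        assert prof.pi_paternity == 1.0
        w = np.array([fitness_cm(p, state, p.b_noncoal),
                      fitness_om(p, state, p.b_noncoal),
                      fitness_im(p, p.b_noncoal)])
        assert np.isclose(prof.w_noncoal, float(np.array([0.3, 0.3, 0.4]) @ w))


class TestAdvantage:
    def test_epm_gap_disfavors_coalition(self, midpoint, mixed_state):
        """With no care advantage, extra-pair matings by Non-coalition Males
        are the primary obstacle for Coalition Males."""
        p = midpoint.replace(b_coal=midpoint.b_noncoal, e_coal=0.0,
                             e_noncoal=0.2, r_kin=0.0, a_assort=0.0)
        assert male_advantage(p, mixed_state) < 0

    def test_assortment_expands_coalition_scope(self, table_ranges, rng):
        """Averaged over random draws, adding male-female assortment at
        fixed kin selection raises the Coalition-Male advantage."""
        import warnings
        diffs = []
        for p in sample_params(table_ranges.fix(r_kin=0.6, a_assort=0.0), 100, 31):
            state = uniform_simplex_state(rng)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ClampWarning)
                with_a = male_advantage(p.replace(a_assort=0.75), state)
                without = male_advantage(p, state)
            diffs.append(with_a - without)
        assert np.mean(diffs) > 0

    def test_advantage_continuous_in_parameters(self, midpoint, mixed_state):
        base = male_advantage(midpoint, mixed_state)
        for field in ("e_noncoal", "b_coal", "r_kin", "a_assort", "sf"):
            bumped = midpoint.replace(**{field: getattr(midpoint, field) + 1e-7})
            assert abs(male_advantage(bumped, mixed_state) - base) < 1e-3
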