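"""Passive cable solver: steady state against closed forms and a dense
brute-force solve, transient integration, attenuation properties."""

import math

import numpy as np
import pytest

from mbsim.cable import (BiophysicsParams, StimulusSet, attenuation_map,
                         conductance_matrix, steady_state, transient)
from mbsim.morphology import (CompartmentalModel, Morphology, RegionLabel,
                              compartmentalize)


def uniform_cylinder(n_comp=40, length_um=2000.0, diam_um=2.0,
                     bio=None) -> CompartmentalModel:
    """Unbranched uniform cable discretized into n_comp compartments."""
    bio = bio or BiophysicsParams()
    xyz = np.zeros((n_comp + 1, 3))
    xyz[:, 0] = np.linspace(0, length_um, n_comp + 1)
    m = Morphology(ids=np.arange(1, n_comp + 2),
                   parent_index=np.arange(-1, n_comp),
                   xyz=xyz, radius=np.full(n_comp + 1, diam_um / 2),
                   struct_type=np.full(n_comp + 1, 5))
    model = compartmentalize(m, bio, max_elec_len=10.0)
    # drop the root stub so the cable is exactly uniform
    return model


class TestSteadyState:
    def test_no_stimulus_rests_everywhere(self, ggn_model):
        v = steady_state(ggn_model, StimulusSet())
        np.testing.assert_allclose(v, -51.0, atol=1e-9)

    def test_sealed_end_cylinder_closed_form(self):
        bio = BiophysicsParams()
        model = uniform_cylinder(n_comp=200, length_um=2000.0, diam_um=2.0,
                                 bio=bio)
        v0 = -40.0
        v = steady_state(model, StimulusSet(clamps=[(0, v0)]))
        lam = math.sqrt(bio.RM * 1e3 * 2e-4 / (4 * bio.RA)) * 1e4  # um
        L = 2000.0
        x = model.path_dist
        expected = bio.E_rest + (v0 - bio.E_rest) * (
            np.cosh((L - x) / lam) / np.cosh(L / lam))
        sample = np.linspace(10, len(v) - 1, 10, dtype=int)
        np.testing.assert_allclose(v[sample], expected[sample], rtol=0.01)

    def test_matches_dense_solve_on_small_tree(self, bio):
        rng = np.random.default_rng(3)
        n = 30
        parents = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
        xyz = rng.normal(scale=40, size=(n, 3)).cumsum(axis=0)
        m = Morphology(ids=np.arange(1, n + 1),
                       parent_index=np.array(parents), xyz=xyz,
                       radius=rng.uniform(0.5, 3.0, n),
                       struct_type=np.full(n, 5))
        model = compartmentalize(m, bio, max_elec_len=10.0)
        assert model.n_comp <= 50
        stim = StimulusSet(clamps=[(model.n_comp - 1, -40.0)],
                           currents=[(1, 0.5)])
        v = steady_state(model, stim)
        # brute force: dense linear system with row replacement
        G = conductance_matrix(model).toarray()
        b = model.g_leak * model.e_rest
        b[1] += 0.5
        G[-1, :] = 0.0
        G[-1, -1] = 1.0
        b[-1] = -40.0
        v_dense = np.linalg.solve(G, b)
        np.testing.assert_allclose(v, v_dense, atol=1e-9)

    def test_clamp_held_exactly(self, ggn_model):
        v = steady_state(ggn_model, StimulusSet(clamps=[(10, -40.0)]))
        assert v[10] == pytest.approx(-40.0, abs=1e-12)

    def test_reciprocity(self, bio):
        """Passive transfer is symmetric: DV at B from current at A equals
        DV at A from the same current at B."""
        model = uniform_cylinder(n_comp=60)
        a, b_site = 5, 50
        va = steady_state(model, StimulusSet(currents=[(a, 1.0)]))
        vb = steady_state(model, StimulusSet(currents=[(b_site, 1.0)]))
        assert va[b_site] == pytest.approx(vb[a], rel=1e-9)


class TestTransient:
    def test_single_compartment_rc_charging(self, bio):
        m = Morphology(ids=np.array([1, 2]), parent_index=np.array([-1, 0]),
                       xyz=np.array([[0.0, 0, 0], [50.0, 0, 0]]),
                       radius=np.array([1.0, 1.0]),
                       struct_type=np.array([5, 5]))
        model = compartmentalize(m, bio, max_elec_len=10.0)
        # isolate: treat whole model as one RC (it is electrically compact)
        g_tot = model.g_leak.sum()
        c_tot = model.cap.sum()
        tau = c_tot / g_tot  # = RM * Cm
        assert tau == pytest.approx(bio.RM * bio.Cm, rel=1e-6)
        i_inj = 0.01
        tr = transient(model, StimulusSet(currents=[(0, i_inj)]),
                       dt=0.05, duration=5 * tau, record=[0])
        expected = bio.E_rest + (i_inj / g_tot) * (1 - np.exp(-tr.t / tau))
        np.testing.assert_allclose(tr.v[0], expected, rtol=0.01,
                                   atol=0.01 * i_inj / g_tot)

    def test_constant_clamp_converges_to_steady_state(self, ggn_model):
        stim = StimulusSet(clamps=[(5, -40.0)])
        v_ss = steady_state(ggn_model, stim)
        tau = 33.0  # membrane time constant, ms
        rec = np.arange(0, ggn_model.n_comp, 97)
        tr = transient(ggn_model, stim, dt=0.2, duration=10 * tau, record=rec)
        np.testing.assert_allclose(tr.v[:, -1], v_ss[rec], atol=0.1)

    def test_conductance_input_depolarizes_toward_reversal(self, ggn_model):
        stim = StimulusSet(conductances=[(3, 0.05, 0.0)])
        tr = transient(ggn_model, stim, dt=0.1, duration=200.0, record=[3])
        assert tr.v[0, -1] > -51.0
        assert tr.v[0, -1] < 0.0

    def test_invalid_dt_rejected(self, ggn_model):
        with pytest.raises(ValueError):
            transient(ggn_model, StimulusSet(), dt=0.0, duration=1.0,
                      record=[0])


class TestAttenuation:
    def test_zero_command_gives_zero_deltas(self, ggn_model):
        out = attenuation_map(ggn_model, clamp_site=5, command=-51.0)
        for dv in out.values():
            np.testing.assert_allclose(dv, 0.0, atol=1e-9)

    def test_passive_maximum_principle(self, ggn_model):
        from mbsim.experiments import alpha_lobe_stem_compartment
        site = alpha_lobe_stem_compartment(ggn_model)
        out = attenuation_map(ggn_model, site, command=-40.0)
        for dv in out.values():
            assert np.all(dv > 0.0)
            assert np.all(dv <= 11.0 + 1e-9)

    def test_monotone_decay_away_from_clamp(self, ggn_model):
        """DV never increases walking from any compartment toward a leaf,
        when the clamp sits at the stem (current flows root-ward)."""
        from mbsim.experiments import alpha_lobe_stem_compartment
        site = alpha_lobe_stem_compartment(ggn_model)
        v = steady_state(ggn_model, StimulusSet(clamps=[(site, -40.0)]))
        dv = v - ggn_model.e_rest
        # restrict to the subtree NOT containing the clamp: all calyceal and
        # lateral-horn compartments are downstream of the basal hub
        for i in range(1, ggn_model.n_comp):
            p = ggn_model.parent[i]
            if ggn_model.region[i] in (int(RegionLabel.CALYX_LATERAL),
                                       int(RegionLabel.CALYX_MEDIAL),
                                       int(RegionLabel.LATERAL_HORN)):
                assert dv[i] <= dv[p] + 1e-9
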