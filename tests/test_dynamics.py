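import numpy as np
import pytest

import picmelt as pm
from picmelt.params import KB, SimulationConfig
from picmelt.topology import CGTopology, TERM_PROTEIN_LOCAL


def harmonic_dimer(k=20.0):
    """Two beads joined by a single harmonic bond (3D oscillator pair)."""
    topo = CGTopology()
    topo.add_bead("A", 0, "CA", "G", np.zeros(3))
    topo.add_bead("A", 1, "CA", "G", np.array([3.8, 0.0, 0.0]))
    topo.bonds.append((0, 1, 3.8, k, TERM_PROTEIN_LOCAL))
    topo.chain_table["A"] = "protein-A"
    return topo


class TestIntegrator:
    def test_same_seed_bit_identical(self, bdna10):
        topo, x = bdna10
        cfg = SimulationConfig(n_steps=2000, save_interval=100, seed=42)
        t1 = pm.run_langevin(x, topo, None, None, cfg)
        t2 = pm.run_langevin(x, topo, None, None, cfg)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.energy_terms, t2.energy_terms)

    def test_different_seeds_differ(self, bdna10):
        topo, x = bdna10
        t1 = pm.run_langevin(x, topo, None, None,
                             SimulationConfig(n_steps=500, seed=1))
        t2 = pm.run_langevin(x, topo, None, None,
                             SimulationConfig(n_steps=500, seed=2))
        assert not np.array_equal(t1.frames[-1], t2.frames[-1])

    def test_zero_temperature_at_minimum_is_static(self):
        topo = harmonic_dimer()
        x = topo.native_coords()
        cfg = SimulationConfig(n_steps=500, save_interval=50, seed=0,
                               temperature=0.0)
        traj = pm.run_langevin(x, topo, None, None, cfg,
                               velocities=np.zeros((2, 3)))
        assert np.allclose(traj.frames[-1], x, atol=1e-10)

    @pytest.mark.parametrize("temperature", [150.0, 300.0, 600.0])
    def test_equipartition_harmonic_system(self, temperature):
        """Mean kinetic energy per DOF equals k_B T / 2 within 3 s.e.m."""
        topo = harmonic_dimer()
        x = topo.native_coords()
        cfg = SimulationConfig(n_steps=120_000, save_interval=40, seed=7,
                               temperature=temperature, timestep=0.05,
                               friction=0.5)
        traj = pm.run_langevin(x, topo, None, None, cfg)
        ke = traj.kinetic[traj.n_frames // 5:]
        per_dof = ke / 6.0
        target = 0.5 * KB * temperature
        # frames are fairly decorrelated at this saving interval; use a
        # conservative effective-sample correction
        n_eff = len(per_dof) / 4.0
        sem = per_dof.std() / np.sqrt(n_eff)
        assert abs(per_dof.mean() - target) < 3 * sem + 1e-6

    def test_zero_friction_conserves_energy(self):
        """NVE limit: total energy drift is O(dt^2) on a Go dimer."""
        topo = harmonic_dimer()
        x = topo.native_coords() + np.array([[0.0, 0, 0], [0.4, 0, 0]])
        cfg = SimulationConfig(n_steps=5000, save_interval=10, seed=0,
                               friction=0.0, timestep=0.05)
        v0 = np.zeros((2, 3)); v0[1, 1] = 0.05
        traj = pm.run_langevin(x, topo, None, None, cfg, velocities=v0)
        etot = traj.potential_energy() + traj.kinetic
        assert etot.std() / max(abs(etot.mean()), 1e-9) < 1e-3

    def test_divergence_reported_with_step(self, bdna10):
        topo, x = bdna10
        bad = x.copy()
        cfg = SimulationConfig(n_steps=1000, save_interval=100, seed=0,
                               timestep=15.0)  # absurd timestep
        with pytest.raises((pm.IntegrationError, ValueError)):
            pm.run_langevin(bad, topo, None, None, cfg)

    def test_kinetic_temperature_estimator(self, bdna20):
        topo, x = bdna20
        cfg = SimulationConfig(n_steps=40_000, save_interval=100, seed=3)
        traj = pm.run_langevin(x, topo, None, None, cfg)
        tk = traj.kinetic_temperature()[traj.n_frames // 4:]
        assert tk.mean() == pytest.approx(300.0, rel=0.03)


class TestAnneal:
    def test_constant_schedule_equals_plain_run(self, bdna10):
        topo, x = bdna10
        cfg = SimulationConfig(n_steps=2000, save_interval=100, seed=5)
        t1 = pm.run_langevin(x, topo, None, None, cfg)
        cfg2 = SimulationConfig(n_steps=2000, save_interval=100, seed=5,
                                anneal_schedule=[(0, 300.0), (2000, 300.0)])
        t2 = pm.anneal(x, topo, None, None, cfg2)
        assert np.array_equal(t1.frames, t2.frames)

    def test_quench_reduces_fluctuations(self, bdna10):
        """300 K -> 1 K quench then a hold at 1 K: the final segment has
        much smaller fluctuations than the starting segment."""
        topo, x = bdna10
        sched = pm.quench_schedule(20_000, 20_000)
        cfg = SimulationConfig(n_steps=40_000, save_interval=100, seed=9,
                               anneal_schedule=sched)
        traj = pm.anneal(x, topo, None, None, cfg)
        def rmsf(seg):
            mean = seg.mean(axis=0)
            return np.sqrt(((seg - mean) ** 2).sum(axis=2).mean())
        start = traj.frames[5:80]
        end = traj.frames[-75:]
        assert rmsf(end) < 0.3 * rmsf(start)

    def test_schedule_ending_at_zero_kelvin_damps_velocities(self):
        topo = harmonic_dimer()
        x = topo.native_coords()
        cfg = SimulationConfig(
            n_steps=20_000, save_interval=500, seed=1,
            anneal_schedule=[(0, 300.0), (10_000, 0.0)])
        traj = pm.anneal(x, topo, None, None, cfg)
        v = traj.final_velocities
        assert np.abs(v).max() < 1e-2

    def test_invalid_schedule_rejected(self):
        cfg = SimulationConfig(anneal_schedule=[(100, 300.0), (0, 1.0)])
        with pytest.raises(ValueError):
            cfg.validate()


class TestMismatch:
    def test_window_disables_exactly_its_pairs(self, toy_pic):
        topo = toy_pic.topology
        seq = toy_pic.sequence
        mm = pm.apply_mismatch(topo, seq)
        n_off = sum(1 for p in mm.wc_pairs if not p.enabled)
        assert n_off == 15
        # non-template bases in the window are now non-complementary
        for k, p in enumerate(mm.wc_pairs):
            if not p.enabled:
                a = mm.beads[p.base_i].identity
                b = mm.beads[p.base_j].identity
                from picmelt.sequences import is_wc_pair
                assert not is_wc_pair(a, b)

    def test_empty_region_rejected(self, toy_pic):
        with pytest.raises(ValueError):
            pm.apply_mismatch(toy_pic.topology, toy_pic.sequence,
                              region=(7, 7))

    def test_region_outside_dna_rejected(self, toy_pic):
        with pytest.raises((ValueError, IndexError)):
            pm.apply_mismatch(toy_pic.topology, toy_pic.sequence,
                              region=(900, 930))

    def test_apply_then_revert_is_identity(self, toy_pic):
        topo = toy_pic.topology
        mm = pm.apply_mismatch(topo, toy_pic.sequence)
        back = pm.revert_mismatch(mm, toy_pic.sequence)
        assert all(p.enabled == q.enabled
                   for p, q in zip(back.wc_pairs, topo.wc_pairs))
        assert [b.identity for b in back.beads] == \
               [b.identity for b in topo.beads]

    def test_revert_without_mismatch_warns_identity(self, toy_pic):
        with pytest.warns(UserWarning, match="no mismatch"):
            out = pm.revert_mismatch(toy_pic.topology, toy_pic.sequence)
        assert out.n_beads == toy_pic.topology.n_beads

    def test_revert_is_idempotent(self, toy_pic):
        mm = pm.apply_mismatch(toy_pic.topology, toy_pic.sequence)
        once = pm.revert_mismatch(mm, toy_pic.sequence)
        with pytest.warns(UserWarning):
            twice = pm.revert_mismatch(once, toy_pic.sequence)
        assert [b.identity for b in once.beads] == \
               [b.identity for b in twice.beads]

    def test_explicit_mismatch_string_used(self, toy_pic):
        seq = toy_pic.sequence
        idxs = seq.mismatch_positions()
        # choose a string that is nowhere complementary to the template
        s = "".join(seq.template_strand[i] for i in idxs)
        mm = pm.apply_mismatch(toy_pic.topology, seq, mismatch_string=s)
        assert sum(1 for p in mm.wc_pairs if not p.enabled) == len(idxs)
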