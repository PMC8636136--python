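import numpy as np
import pytest

import picmelt as pm
from picmelt.contacts import (CalibrationProbe, ContactRecord,
                              brute_force_contacts, build_contact_sets,
                              detect_native_contacts, ewing_selector,
                              weaken_contacts)
from picmelt.topology import CGTopology


def random_instance(seed, n_protein, n_dna):
    """Random small protein+DNA bead cloud for detection tests."""
    rng = np.random.default_rng(seed)
    topo = CGTopology()
    for k in range(n_protein):
        topo.add_bead("A", k, "CA", "G", rng.uniform(-15, 15, 3))
    for k in range(n_dna):
        kind = ["P", "S", "B"][k % 3]
        topo.add_bead("T", k, kind, "A", rng.uniform(-15, 15, 3))
    topo.chain_table = {"A": "protein-A", "T": "template"}
    return topo, topo.native_coords()


class TestDetection:
    @pytest.mark.parametrize("seed", range(50))
    def test_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_p = int(rng.integers(1, 25))
        n_d = int(rng.integers(1, 50 - n_p + 1))
        topo, x = random_instance(seed, n_p, n_d)
        cutoff = float(rng.uniform(3.0, 12.0))
        assert detect_native_contacts(topo, x, cutoff) == \
            brute_force_contacts(topo, x, cutoff)

    def test_distant_chains_give_empty_list(self):
        topo = CGTopology()
        topo.add_bead("A", 0, "CA", "G", [0.0, 0, 0])
        topo.add_bead("T", 0, "B", "A", [100.0, 0, 0])
        topo.chain_table = {"A": "protein-A", "T": "template"}
        assert detect_native_contacts(topo, topo.native_coords(), 6.5) == []

    def test_missing_chain_class_is_error(self):
        topo = CGTopology()
        topo.add_bead("A", 0, "CA", "G", [0.0, 0, 0])
        with pytest.raises(ValueError, match="protein and DNA"):
            detect_native_contacts(topo, topo.native_coords(), 6.5)

    def test_heavy_atom_mode_wider_than_bead_mode(self):
        """A pair whose heavy atoms touch counts even when the bead
        centroids are beyond the cutoff."""
        topo = CGTopology()
        topo.add_bead("A", 0, "CA", "G", [0.0, 0, 0])
        topo.add_bead("T", 0, "B", "A", [8.0, 0, 0])
        topo.chain_table = {"A": "protein-A", "T": "template"}
        x = topo.native_coords()
        groups = [np.array([[0.0, 0, 0], [3.0, 0, 0]]),
                  np.array([[8.0, 0, 0], [5.0, 0, 0]])]
        assert detect_native_contacts(topo, x, 6.5) == []
        found = detect_native_contacts(topo, x, 6.5, bead_atoms=groups)
        assert [(i, j) for i, j, _ in found] == [(0, 1)]
        assert found[0][2] == pytest.approx(8.0)  # r0 is the bead distance


class TestSetAlgebra:
    def test_identical_lists_collapse(self):
        lst = [(0, 10, 5.0), (1, 11, 6.0)]
        sets = build_contact_sets(lst, lst, lst)
        assert len(sets.union_set) == 2
        assert len(sets.cc_specific) == 0
        assert len(sets.oc_set) == 2
        assert len(sets.itc_unique) == 0

    def test_disjoint_lists_sizes_add(self):
        cc = [(0, 10, 5.0), (1, 10, 5.0), (2, 10, 5.0)]
        oc = [(3, 11, 5.0), (4, 11, 5.0)]
        itc = [(5, 12, 5.0), (6, 12, 5.0), (7, 12, 5.0), (8, 12, 5.0)]
        sets = build_contact_sets(cc, oc, itc)
        assert len(sets.union_set) == 9
        assert len(sets.cc_specific) == 3
        assert len(sets.itc_unique) == 4
        sets.validate()

    def test_prescribed_paper_structure(self, toy_pic):
        """The 92/22/118 prescription with 19-of-22 overlap gives
        cc_specific = 92 and itc_unique = 99 by construction and by
        recount."""
        rep = toy_pic.contact_sets.report
        assert (rep["n_cc"], rep["n_oc"], rep["n_itc"]) == (92, 22, 118)
        assert rep["oc_in_itc"] == 19
        cs = toy_pic.contact_sets
        # recount independently from the records' source_states
        recount_cc = sum(1 for r in cs.union_set
                         if r.source_states == {"CC"})
        recount_itc = sum(1 for r in cs.union_set
                          if r.source_states == {"ITC"})
        assert recount_cc == len(cs.cc_specific) == 92
        assert recount_itc == len(cs.itc_unique) == 99

    def test_r0_priority_and_conflict_warning(self):
        cc = [(0, 10, 5.0)]
        itc = [(0, 10, 9.0)]
        with pytest.warns(UserWarning, match="differs"):
            sets = build_contact_sets(cc, [], itc)
        assert sets.union_set[0].r0 == 5.0  # CC priority

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            build_contact_sets([], [], [])

    def test_tsv_round_trip(self, toy_pic, tmp_path):
        p = tmp_path / "c.tsv"
        cs = toy_pic.contact_sets
        cs.to_tsv(p)
        back = pm.ContactSets.from_tsv(p)
        assert len(back.union_set) == len(cs.union_set)
        assert np.array_equal(back.cc_specific, cs.cc_specific)
        r0a = [r.r0 for r in cs.union_set]
        r0b = [r.r0 for r in back.union_set]
        assert np.allclose(r0a, r0b)


class TestWeaken:
    def test_factor_one_is_identity(self, toy_pic):
        cs = toy_pic.contact_sets
        out = weaken_contacts(cs, toy_pic.ewing_subset, 1.0)
        assert [r.epsilon for r in out.union_set] == \
               [r.epsilon for r in cs.union_set]

    def test_exactly_selected_records_scaled(self, toy_pic):
        cs = toy_pic.contact_sets
        idx = [0, 5, 7]
        out = weaken_contacts(cs, idx, 0.5)
        changed = [k for k, (a, b) in
                   enumerate(zip(out.union_set, cs.union_set))
                   if a.epsilon != b.epsilon]
        assert changed == idx
        for k in idx:
            assert out.union_set[k].epsilon == pytest.approx(
                0.5 * cs.union_set[k].epsilon)

    def test_original_object_unmodified(self, toy_pic):
        cs = toy_pic.contact_sets
        eps_before = [r.epsilon for r in cs.union_set]
        weaken_contacts(cs, [0, 1], 0.0)
        assert [r.epsilon for r in cs.union_set] == eps_before

    def test_factor_zero_removes_exactly_that_go_energy(self, toy_pic):
        """Energy-decomposition oracle: zeroing a subset changes any
        configuration's energy by exactly minus that subset's Go term."""
        pic = toy_pic
        cs = pic.contact_sets
        idx = list(map(int, pic.ewing_subset))
        x = pic.reference_set.coords["OC"]
        e_full = pm.total_energy_forces(x, pic.topology, cs)[0]
        weak = weaken_contacts(cs, idx, 0.0)
        e_weak = pm.total_energy_forces(x, pic.topology, weak)[0]
        manual = sum(
            pm.go_contact_energy(
                np.linalg.norm(x[r.bead_i] - x[r.bead_j]), r.r0, r.epsilon)
            for r in (cs.union_set[k] for k in idx))
        assert e_full.protein_dna_go - e_weak.protein_dna_go == \
            pytest.approx(manual, rel=1e-6)
        # all other terms untouched
        assert e_full.electrostatics == pytest.approx(e_weak.electrostatics)
        assert e_full.excluded_volume == pytest.approx(e_weak.excluded_volume)

    def test_empty_selection_warns(self, toy_pic):
        with pytest.warns(UserWarning, match="empty"):
            weaken_contacts(toy_pic.contact_sets, [], 0.5)

    def test_invalid_factor_rejected(self, toy_pic):
        with pytest.raises(ValueError):
            weaken_contacts(toy_pic.contact_sets, [0], 1.5)

    def test_ewing_selector_matches_oc_only_records(self, toy_pic):
        cs = toy_pic.contact_sets
        sel = [k for k, r in enumerate(cs.union_set) if ewing_selector(r)]
        assert sel == list(map(int, toy_pic.ewing_subset))


class TestRecordValidation:
    @pytest.mark.parametrize("kw", [
        {"r0": -1.0}, {"r0": 0.0}, {"epsilon": 0.0},
        {"source_states": frozenset()}])
    def test_invalid_records_rejected(self, kw):
        base = dict(bead_i=0, bead_j=1, r0=5.0, epsilon=1.2,
                    source_states=frozenset({"CC"}))
        base.update(kw)
        with pytest.raises(ValueError):
            ContactRecord(**base)


@pytest.fixture(scope="module")
def probe_system():
    """Tiny free pair whose contact survival crosses 50% at an epsilon
    found by an independent scan."""
    topo = CGTopology()
    topo.add_bead("A", 0, "CA", "G", [0.0, 0.0, 0.0])
    topo.add_bead("T", 0, "B", "A", [5.0, 0.0, 0.0])
    topo.chain_table = {"A": "protein-A", "T": "template"}
    refset = pm.ReferenceStructureSet(
        topology=topo, coords={"OC": topo.native_coords()})
    union = [ContactRecord(0, 1, 5.0, 1.0, {"OC"})]
    sets = pm.ContactSets(union_set=union, oc_set=np.array([0]))
    return refset, sets


class TestCalibration:
    def test_returns_smallest_epsilon_matching_scan_oracle(self,
                                                           probe_system):
        refset, sets = probe_system
        probes = [CalibrationProbe("OC", [0], "maintained")]
        cfg = pm.SimulationConfig(n_steps=6000, save_interval=100)
        candidates = [0.3, 0.8, 1.5, 3.0, 6.0]
        seeds = (0, 1, 2)
        # independent oracle: direct scan with the same runs
        from picmelt.analysis import contact_fraction
        surv = {}
        for eps in candidates:
            import copy
            work = copy.deepcopy(sets)
            work.union_set[0].epsilon = eps
            vals = []
            for seed in seeds:
                c = pm.SimulationConfig(n_steps=6000, save_interval=100,
                                        seed=seed)
                traj = pm.run_langevin(refset.coords["OC"], refset.topology,
                                       work, None, c)
                vals.append(np.mean([contact_fraction(f, work.union_set)
                                     for f in traj.frames]))
            surv[eps] = float(np.mean(vals))
        expected = min((e for e in candidates if surv[e] >= 0.5),
                       default=None)
        assert expected is not None, "oracle scan found no passing epsilon"
        chosen, report = pm.calibrate_epsilon(
            refset, sets, probes, candidates, config=cfg, seeds=seeds)
        assert chosen == expected

    def test_loss_condition_fails_for_enormous_epsilon(self, probe_system):
        refset, sets = probe_system
        probes = [CalibrationProbe("OC", [0], "lost")]
        cfg = pm.SimulationConfig(n_steps=4000, save_interval=100)
        from picmelt.contacts import CalibrationError
        with pytest.raises(CalibrationError):
            pm.calibrate_epsilon(refset, sets, probes, [50.0, 100.0],
                                 config=cfg, seeds=(0,))

    def test_mutation_deletes_contacts_and_flips_charge(self, toy_pic):
        """Charge-flip probes: the mutated residues' DNA contacts are
        removed, so a 'lost' requirement on them passes trivially, as in
        charge-reversal mutants."""
        cs = toy_pic.contact_sets
        k = int(toy_pic.ewing_subset[0])
        bead = cs.union_set[k].bead_i
        probe = CalibrationProbe("OC", [k], "lost", mutation=[bead])
        cfg = pm.SimulationConfig(n_steps=500, save_interval=100)
        chosen, rep = pm.calibrate_epsilon(
            toy_pic.reference_set, cs, [probe], [1.2], config=cfg,
            seeds=(0,))
        assert chosen == 1.2
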