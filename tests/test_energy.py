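import numpy as np
import pytest

import picmelt as pm
from picmelt.energy import assemble_system
from picmelt.params import DNAParams, EnergyParams

from conftest import numerical_forces


class TestGoContact:
    def test_minimum_is_minus_eps_at_r0(self):
        assert pm.go_contact_energy(5.0, 5.0, 1.2) == pytest.approx(-1.2)

    def test_vanishes_at_infinity(self):
        assert pm.go_contact_energy(500.0, 5.0, 1.2) == pytest.approx(
            0.0, abs=1e-9)

    def test_zero_crossing_at_analytic_root(self):
        # 5 x^12 = 6 x^10  =>  r = r0 sqrt(5/6)
        r0 = 7.3
        r_cross = r0 * np.sqrt(5.0 / 6.0)
        assert pm.go_contact_energy(r_cross, r0, 2.0) == pytest.approx(
            0.0, abs=1e-12)
        assert pm.go_contact_energy(0.99 * r_cross, r0, 2.0) > 0
        assert pm.go_contact_energy(1.01 * r_cross, r0, 2.0) < 0

    def test_finite_at_zero_distance(self):
        u = pm.go_contact_energy(0.0, 5.0, 1.2)
        assert np.isfinite(u) and u > 0


class TestDebyeHuckel:
    def test_zero_charge_gives_zero(self):
        p = EnergyParams()
        assert pm.debye_huckel_energy(5.0, 0.0, 1.0, p) == 0.0

    def test_debye_length_200mM_300K(self):
        # lambda_D = 3.04 / sqrt(I[M]) at eps_r 78: about 6.8 A
        lam = EnergyParams(salt_mM=200, temperature=300,
                           dielectric=78.0).debye_length()
        assert lam == pytest.approx(6.8, abs=0.1)

    def test_opposite_charges_attract_and_decay_to_zero(self):
        p = EnergyParams()
        r = np.linspace(2.0, p.dh_cutoff - 0.01, 50)
        u = pm.debye_huckel_energy(r, +1.0, -1.0, p)
        assert np.all(u < 0)
        assert np.all(np.diff(u) > 0)  # monotonically toward zero
        assert pm.debye_huckel_energy(p.dh_cutoff + 1, 1, -1, p) == 0.0

    def test_shift_makes_cutoff_continuous(self):
        p = EnergyParams()
        eps = 1e-6
        below = pm.debye_huckel_energy(p.dh_cutoff - eps, 1, -1, p)
        assert below == pytest.approx(0.0, abs=1e-6)


class TestDNAEnergy:
    def test_built_duplex_is_bonded_minimum(self, bdna20):
        topo, x = bdna20
        br = pm.dna_energy(x, topo)
        assert br.dna_bonded == pytest.approx(0.0, abs=1e-8)
        # stacking and pairing sit at their native minima
        n_stack = sum(1 for p in topo.pairs_1210 if p[4] == 3)
        d = DNAParams()
        assert br.dna_stacking == pytest.approx(-n_stack * d.eps_stack,
                                                rel=1e-9)

    def test_pairing_locality_when_pair_pulled_apart(self, bdna10):
        topo, x0 = bdna10
        br0 = pm.dna_energy(x0, topo)
        k = 4
        p = topo.wc_pairs[k]
        x = x0.copy()
        # displace one base bead 10 A along the pair axis
        axis = x[p.base_j] - x[p.base_i]
        axis /= np.linalg.norm(axis)
        x[p.base_j] += 10.0 * axis
        br = pm.dna_energy(x, topo)
        gc = topo.beads[p.base_i].identity in "GC"
        d = DNAParams()
        eps = d.eps_bp_gc if gc else d.eps_bp_gc * d.at_gc_ratio
        # that pair's well is lost (its energy was ~ -eps, now ~ 0);
        # other pairs unchanged, so the pairing term rises by ~ eps
        assert br.dna_pairing - br0.dna_pairing == pytest.approx(eps,
                                                                 rel=0.05)

    def test_gc_deeper_than_at_by_configured_ratio(self):
        d = DNAParams()
        topo_gc, x_gc = pm.build_bdna("GGGG")
        topo_at, x_at = pm.build_bdna("AAAA")
        e_gc = pm.dna_energy(x_gc, topo_gc).dna_pairing
        e_at = pm.dna_energy(x_at, topo_at).dna_pairing
        assert e_at / e_gc == pytest.approx(d.at_gc_ratio, rel=1e-6)

    def test_non_complementary_enabled_pair_rejected(self, bdna10):
        topo, x = bdna10
        bad = topo.copy()
        bad.beads[bad.wc_pairs[0].base_i].identity = "A"
        bad.beads[bad.wc_pairs[0].base_j].identity = "A"
        with pytest.raises(ValueError, match="non-complementary"):
            pm.dna_energy(x, bad)


class TestForcesAndInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_forces_match_central_differences(self, bdna10, seed):
        topo, x0 = bdna10
        system = assemble_system(topo)
        rng = np.random.default_rng(seed)
        x = x0 + rng.normal(0, 0.4, x0.shape)
        _, f = system.energy_forces(x)
        num = numerical_forces(system, x)
        scale = np.abs(num).max()
        assert np.abs(f - num).max() / scale < 1e-4

    def test_forces_with_contacts_and_restraints(self, toy_pic):
        from picmelt.protocols import toy_system
        system = toy_system(toy_pic, state="OC")
        rng = np.random.default_rng(0)
        x = toy_pic.reference_set.coords["OC"] + rng.normal(
            0, 0.2, (system.n_beads, 3))
        # subsample beads for the numerical check (full system is large)
        _, f = system.energy_forces(x)
        h = 1e-5
        sel = rng.choice(system.n_beads, size=40, replace=False)
        for i in sel:
            for k in range(3):
                xp = x.copy(); xp[i, k] += h
                xm = x.copy(); xm[i, k] -= h
                num = -(system.energy(xp).total
                        - system.energy(xm).total) / (2 * h)
                assert f[i, k] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_energy_invariant_under_rigid_motion(self, bdna10):
        topo, x = bdna10
        from scipy.spatial.transform import Rotation
        e0 = pm.total_energy_forces(x, topo)[0].total
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0])
        x2 = rot.apply(x) + np.array([11.0, -3.0, 7.0])
        e2, f2 = pm.total_energy_forces(x2, topo)
        assert e2.total == pytest.approx(e0, rel=1e-8)
        # net force vanishes under translation invariance
        assert np.abs(f2.sum(axis=0)).max() < 1e-7

    def test_energy_additivity_of_distant_copies(self, bdna10):
        topo, x = bdna10
        e1 = pm.total_energy_forces(x, topo)[0].total
        # duplicate the topology shifted far beyond all cutoffs
        import copy
        double = copy.deepcopy(topo)
        n = topo.n_beads
        for b in topo.beads:
            double.add_bead(b.chain_id + "2", b.residue_index, b.kind,
                            b.identity, b.position + 500.0, b.charge)
        for i, j, r0, k, t in topo.bonds:
            double.bonds.append((i + n, j + n, r0, k, t))
        for i, j, k2, t0, kk, t in [(a, b, c, d, e, f) for
                                    (a, b, c, d, e, f) in topo.angles]:
            double.angles.append((i + n, j + n, k2 + n, t0, kk, t))
        for q in topo.dihedrals:
            double.dihedrals.append((q[0] + n, q[1] + n, q[2] + n,
                                     q[3] + n, q[4], q[5], q[6]))
        for i, j, r0, e, t in topo.pairs_1210:
            double.pairs_1210.append((i + n, j + n, r0, e, t))
        import dataclasses
        for p in topo.wc_pairs:
            double.wc_pairs.append(dataclasses.replace(
                p, base_i=p.base_i + n, base_j=p.base_j + n,
                sugar_i=p.sugar_i + n, sugar_j=p.sugar_j + n))
        x2 = np.vstack([x, x + 500.0])
        e2 = pm.total_energy_forces(x2, double)[0].total
        assert e2 == pytest.approx(2 * e1, rel=1e-9)

    def test_breakdown_total_equals_sum_of_terms(self, bdna10):
        topo, x = bdna10
        br = pm.total_energy_forces(x + 0.1, topo)[0]
        assert br.total == pytest.approx(br.as_array().sum(), rel=1e-12)

    def test_pure_go_protein_minimum_is_reference(self, toy_pic):
        # with charges zeroed and no protein-DNA contacts, protein-only
        # forces vanish at the reference structure
        topo = toy_pic.topology.copy()
        for b in topo.beads:
            b.charge = 0.0
        system = assemble_system(topo)
        _, f = system.energy_forces(topo.native_coords())
        prot = topo.protein_bead_ids()
        # residual forces come only from tiny EV tails
        assert np.abs(f[prot]).max() < 0.5
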