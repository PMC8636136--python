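"""CG energy function: Go contacts, simplified 3SPN-style DNA terms,
excluded volume and Debye–Hückel electrostatics.

The protein–DNA contact potential is the structure-based 12-10 well

    U(r) = ε_go [ 5 (r0/r)^12 − 6 (r0/r)^10 ]

with minimum −ε_go at the native distance r0.  DNA base pairing uses the
same well modulated by a Gaussian gate on the two sugar–base···base
angles, which penalizes non-facing/non-coplanar geometries; G·C wells are
deeper than A·T.  Electrostatics is a screened Coulomb interaction with
the Debye length set by salt and temperature, shifted to zero at the
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, TYPE_CHECKING

import numpy as np

from . import _kernels
from .params import COULOMB, EnergyParams
from .topology import (
    CGTopology, N_TERMS, TERM_NAMES, TERM_DNA_BONDED, TERM_DNA_PAIRING,
    TERM_DNA_STACKING, TERM_PROTEIN_DNA_GO,
)

if TYPE_CHECKING:
    from .contacts import ContactSets


# ---------------------------------------------------------------------------
# scalar reference potentials
# ---------------------------------------------------------------------------

def go_contact_energy(r, r0, eps):
    """12-10 structure-based contact well, kcal/mol.

    Minimum −eps at r = r0, zero crossing at r0·√(5/6), → 0 as r → ∞.
    Below 0.6·r0 the potential continues linearly (finite at r = 0).
    """
    r = np.asarray(r, dtype=float)
    rmin = _kernels.CLAMP_FRAC * r0
    rr = np.maximum(r, rmin)
    x = r0 / rr
    u = eps * (5.0 * x ** 12 - 6.0 * x ** 10)
    du = 60.0 * eps * (x ** 10 - x ** 12) / rr
    u = np.where(r <= rmin, u + du * (r - rmin), u)
    return u if u.ndim else float(u)


def debye_huckel_energy(r, q1, q2, params: EnergyParams):
    """Screened Coulomb energy q1·q2·(C/εr)·exp(−r/λ_D)/r, kcal/mol,
    shifted to reach zero continuously at the cutoff."""
    r = np.asarray(r, dtype=float)
    lam = params.debye_length()
    k = COULOMB / params.dielectric
    u = k * q1 * q2 * np.exp(-r / lam) / r
    shift = k * q1 * q2 * np.exp(-params.dh_cutoff / lam) / params.dh_cutoff
    u = np.where(r < params.dh_cutoff, u - shift, 0.0)
    return u if u.ndim else float(u)


# ---------------------------------------------------------------------------
# energy breakdown
# ---------------------------------------------------------------------------

@dataclass
class EnergyBreakdown:
    protein_local: float = 0.0
    protein_go: float = 0.0
    dna_bonded: float = 0.0
    dna_stacking: float = 0.0
    dna_pairing: float = 0.0
    protein_dna_go: float = 0.0
    excluded_volume: float = 0.0
    electrostatics: float = 0.0
    restraint: float = 0.0

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in TERM_NAMES)

    @classmethod
    def from_array(cls, terms: np.ndarray) -> "EnergyBreakdown":
        return cls(**{name: float(terms[i]) for i, name in enumerate(TERM_NAMES)})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in TERM_NAMES])


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

def _empty_i(shape):
    return np.empty(shape, dtype=np.int64)


@dataclass
class AssembledSystem:
    """Flat-array view of a topology + contact set + parameters, ready for
    the numba kernels."""

    n_beads: int
    masses: np.ndarray
    bonds_idx: np.ndarray; bonds_r0: np.ndarray; bonds_k: np.ndarray; bonds_term: np.ndarray
    angles_idx: np.ndarray; angles_t0: np.ndarray; angles_k: np.ndarray; angles_term: np.ndarray
    dihs_idx: np.ndarray; dihs_p0: np.ndarray; dihs_k: np.ndarray; dihs_term: np.ndarray
    pairs_idx: np.ndarray; pairs_r0: np.ndarray; pairs_eps: np.ndarray; pairs_term: np.ndarray
    wc_base: np.ndarray; wc_sugar: np.ndarray; wc_r0: np.ndarray
    wc_eps: np.ndarray; wc_ti0: np.ndarray; wc_tj0: np.ndarray; wc_sig: np.ndarray
    sigma: np.ndarray; eps_ev: float; ev_cap: float
    charges: np.ndarray; k_dh: float; lam: float; dh_cut: float
    excl_ev: np.ndarray; excl_dh: np.ndarray
    res_idx: np.ndarray; res_ref: np.ndarray; res_k: np.ndarray
    ev_cutoff: float

    def _kernel_args(self, x, f, ev_pairs, dh_pairs):
        return (x, f,
                self.bonds_idx, self.bonds_r0, self.bonds_k, self.bonds_term,
                self.angles_idx, self.angles_t0, self.angles_k, self.angles_term,
                self.dihs_idx, self.dihs_p0, self.dihs_k, self.dihs_term,
                self.pairs_idx, self.pairs_r0, self.pairs_eps, self.pairs_term,
                self.wc_base, self.wc_sugar, self.wc_r0, self.wc_eps,
                self.wc_ti0, self.wc_tj0, self.wc_sig,
                self.sigma, self.eps_ev, self.ev_cap,
                self.charges, self.k_dh, self.lam, self.dh_cut,
                ev_pairs, dh_pairs,
                self.res_idx, self.res_ref, self.res_k)

    def energy_forces(self, coords: np.ndarray):
        """Exact energy breakdown and analytic forces (kcal/mol, kcal/mol/Å)."""
        x = np.ascontiguousarray(coords, dtype=float)
        f = np.zeros_like(x)
        ev_pairs, dh_pairs = _kernels.build_neighbor_pairs(
            x, self.ev_cutoff, self.dh_cut, self.excl_ev, self.excl_dh,
            self.charges)
        terms = _kernels.compute_forces(
            *self._kernel_args(x, f, ev_pairs, dh_pairs))
        return EnergyBreakdown.from_array(terms), f

    def energy(self, coords: np.ndarray) -> EnergyBreakdown:
        return self.energy_forces(coords)[0]

    def add_restraints(self, bead_ids, ref_coords, k: float) -> None:
        """Append harmonic position restraints (k in kcal/mol/Å^2)."""
        bead_ids = np.asarray(bead_ids, dtype=np.int64)
        ref = np.ascontiguousarray(ref_coords, dtype=float).reshape(-1, 3)
        self.res_idx = np.concatenate([self.res_idx, bead_ids])
        self.res_ref = np.vstack([self.res_ref, ref])
        self.res_k = np.concatenate(
            [self.res_k, np.full(len(bead_ids), float(k))])


def assemble_system(topology: CGTopology,
                    contacts: Optional["ContactSets"] = None,
                    params: Optional[EnergyParams] = None) -> AssembledSystem:
    """Flatten a topology (+ optional protein–DNA contact set) into kernel
    arrays.  Excluded-volume exclusions: bonded graph distance ≤ 3, every
    pair that already carries an explicit well (Go, stacking, pairing),
    and any extra exclusions recorded on the topology.  Debye–Hückel
    exclusions: bonded graph distance ≤ 2."""
    if params is None:
        params = EnergyParams()
    topology.validate()
    n = topology.n_beads

    def arrs(rows, nidx):
        if not rows:
            return (_empty_i((0, nidx)), np.empty(0), np.empty(0),
                    _empty_i(0))
        a = np.array([r[:nidx] for r in rows], dtype=np.int64)
        v0 = np.array([r[nidx] for r in rows], dtype=float)
        k = np.array([r[nidx + 1] for r in rows], dtype=float)
        t = np.array([r[nidx + 2] for r in rows], dtype=np.int64)
        return a, v0, k, t

    bonds_idx, bonds_r0, bonds_k, bonds_term = arrs(topology.bonds, 2)
    angles_idx, angles_t0, angles_k, angles_term = arrs(topology.angles, 3)
    dihs_idx, dihs_p0, dihs_k, dihs_term = arrs(topology.dihedrals, 4)

    pair_rows = list(topology.pairs_1210)
    if contacts is not None:
        for rec in contacts.union_set:
            pair_rows.append((rec.bead_i, rec.bead_j, rec.r0, rec.epsilon,
                              TERM_PROTEIN_DNA_GO))
    if pair_rows:
        pairs_idx = np.array([r[:2] for r in pair_rows], dtype=np.int64)
        pairs_r0 = np.array([r[2] for r in pair_rows], dtype=float)
        pairs_eps = np.array([r[3] for r in pair_rows], dtype=float)
        pairs_term = np.array([r[4] for r in pair_rows], dtype=np.int64)
    else:
        pairs_idx, pairs_r0 = _empty_i((0, 2)), np.empty(0)
        pairs_eps, pairs_term = np.empty(0), _empty_i(0)

    # Watson-Crick pairing arrays; disabled pairs get eps 0
    wcs = topology.wc_pairs
    nw = len(wcs)
    wc_base = _empty_i((nw, 2)); wc_sugar = _empty_i((nw, 2))
    wc_r0 = np.empty(nw); wc_eps = np.empty(nw)
    wc_ti0 = np.empty(nw); wc_tj0 = np.empty(nw)
    wc_sig = np.full(nw, params.dna.bp_angle_width)
    for i, p in enumerate(wcs):
        wc_base[i] = (p.base_i, p.base_j)
        wc_sugar[i] = (p.sugar_i, p.sugar_j)
        wc_r0[i] = p.r0
        wc_ti0[i], wc_tj0[i] = p.theta_i0, p.theta_j0
        if not p.enabled:
            # mismatched position: pure repulsion of amplitude eps_mismatch
            wc_eps[i] = -params.dna.eps_mismatch
        else:
            ident = topology.beads[p.base_i].identity
            gc = ident in ("G", "C")
            wc_eps[i] = params.dna.eps_bp_gc * (
                1.0 if gc else params.dna.at_gc_ratio)

    sigma = np.array([params.ev_radii[b.kind] for b in topology.beads])
    charges = topology.charges()

    # exclusion matrices from the bonded graph
    excl_ev = np.zeros((n, n), dtype=np.uint8)
    excl_dh = np.zeros((n, n), dtype=np.uint8)
    adj = [[] for _ in range(n)]
    for i, j, *_ in topology.bonds:
        adj[i].append(j); adj[j].append(i)
    for i in range(n):
        seen = {i: 0}
        frontier = [i]
        for depth in (1, 2, 3):
            nxt = []
            for u in frontier:
                for w in adj[u]:
                    if w not in seen:
                        seen[w] = depth
                        nxt.append(w)
            frontier = nxt
        for w, depth in seen.items():
            if w == i:
                continue
            excl_ev[i, w] = excl_ev[w, i] = 1
            if depth <= 2:
                excl_dh[i, w] = excl_dh[w, i] = 1
    for i, j, *_ in pair_rows:
        excl_ev[i, j] = excl_ev[j, i] = 1
    for p in wcs:
        # paired bases interact through the pairing well, mismatched ones
        # through the dedicated mismatch repulsion — either way no EV
        excl_ev[p.base_i, p.base_j] = excl_ev[p.base_j, p.base_i] = 1
    for i, j in topology.extra_ev_exclusions:
        excl_ev[i, j] = excl_ev[j, i] = 1

    ev_cutoff = 2.0 * 2.0 * float(sigma.max())
    return AssembledSystem(
        n_beads=n, masses=topology.masses(),
        bonds_idx=bonds_idx, bonds_r0=bonds_r0, bonds_k=bonds_k,
        bonds_term=bonds_term,
        angles_idx=angles_idx, angles_t0=angles_t0, angles_k=angles_k,
        angles_term=angles_term,
        dihs_idx=dihs_idx, dihs_p0=dihs_p0, dihs_k=dihs_k,
        dihs_term=dihs_term,
        pairs_idx=pairs_idx, pairs_r0=pairs_r0, pairs_eps=pairs_eps,
        pairs_term=pairs_term,
        wc_base=wc_base, wc_sugar=wc_sugar, wc_r0=wc_r0, wc_eps=wc_eps,
        wc_ti0=wc_ti0, wc_tj0=wc_tj0, wc_sig=wc_sig,
        sigma=sigma, eps_ev=params.eps_ev, ev_cap=params.ev_cap,
        charges=charges, k_dh=COULOMB / params.dielectric,
        lam=params.debye_length(), dh_cut=params.dh_cutoff,
        excl_ev=excl_ev, excl_dh=excl_dh,
        res_idx=_empty_i(0), res_ref=np.empty((0, 3)), res_k=np.empty(0),
        ev_cutoff=ev_cutoff)


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def total_energy_forces(coords, topology: CGTopology,
                        contacts: Optional["ContactSets"] = None,
                        params: Optional[EnergyParams] = None):
    """Total CG energy breakdown and per-bead analytic forces."""
    system = assemble_system(topology, contacts, params)
    return system.energy_forces(coords)


def dna_energy(coords, topology: CGTopology,
               params: Optional[EnergyParams] = None) -> EnergyBreakdown:
    """DNA-only slice of the energy breakdown (bonded, stacking, pairing);
    other terms are zeroed in the returned object."""
    full = total_energy_forces(coords, topology, None, params)[0]
    out = EnergyBreakdown()
    out.dna_bonded = full.dna_bonded
    out.dna_stacking = full.dna_stacking
    out.dna_pairing = full.dna_pairing
    return out
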