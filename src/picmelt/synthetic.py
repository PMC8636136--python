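"""Download-free toy systems with the statistical structure the pipeline
analysis assumes.

Two generators live here:

* :func:`build_bdna` — an idealized B-form duplex of arbitrary sequence
  (fiber-diffraction rise 3.38 Å and twist 34.3°/bp), used for the
  duplex break-rate calibration runs.  Native bonded values are taken
  from the built geometry, so the built duplex is a minimum of the DNA
  bonded energy by construction.

* :func:`build_toy_pic` — a multi-chain "clamp" scaffold plus promoter
  duplex in three labeled reference poses emulating the closed (CC),
  open (OC) and initially transcribing (ITC) complexes.  The poses are
  generated by smoothly bending the downstream arm of the duplex into
  the clamp; the returned contact sets reproduce a prescribed size and
  overlap structure exactly (by default the 92 / 22 / 118 sets with 19
  of the 22 OC contacts shared with ITC).  A flexible gate flap crosses
  the arm's swing path so that reaching the threaded (ITC-like) pose
  geometrically requires the gate to be displaced, and a small group of
  OC-only contacts (the E-wing analog) tethers the arm in the OC pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .contacts import ContactRecord, ContactSets, build_contact_sets
from .params import DNAParams, ProteinParams
from .sequences import PromoterSequence
from .topology import (
    CGTopology, ReferenceStructureSet, TERM_DNA_BONDED, TERM_DNA_STACKING,
    TERM_PROTEIN_GO, TERM_PROTEIN_LOCAL, WCPair,
)

PROTEIN_CHARGE = {"K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0}

# helix placement constants (Å / rad): bead radii from the helix axis and
# angular offsets of sugar/phosphate relative to the base
_R_BASE, _R_SUGAR, _R_PHOS = 2.4, 6.9, 8.9
_SUGAR_SHIFT = 0.30


class ToySpecError(ValueError):
    """Prescribed toy-system structure is unsatisfiable."""


# ---------------------------------------------------------------------------
# duplex construction
# ---------------------------------------------------------------------------

def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return 3.0 * u * u - 2.0 * u * u * u


def _frames(length: int, rise: float, beta_fn):
    """Per-nucleotide frames along a centerline bent in the y–z plane.

    The centerline starts at the origin heading −z; ``beta_fn(s)`` gives
    the bend angle (rad, toward −y) at arc length s = i·rise.
    """
    origins = np.zeros((length, 3))
    e3 = np.zeros((length, 3))
    pos = np.zeros(3)
    for i in range(length):
        s = i * rise
        b = beta_fn(s)
        t = np.array([0.0, -math.sin(b), -math.cos(b)])
        e3[i] = t
        origins[i] = pos
        bm = beta_fn(s + 0.5 * rise)
        tm = np.array([0.0, -math.sin(bm), -math.cos(bm)])
        pos = pos + rise * tm
    e1 = np.tile(np.array([1.0, 0.0, 0.0]), (length, 1))
    e2 = np.cross(e3, e1)
    return origins, e1, e2, e3


def _place_duplex(length: int, rise: float, twist_rad: float, frames):
    """Bead coordinates for both strands on the given frames.

    Returns (coords, index maps); coords rows follow the canonical order
    template 5'→3' then non-template 5'→3', with [P], S, B per
    nucleotide (5'-terminal phosphates absent).
    """
    origins, e1, e2, e3 = frames

    def ring(i, radius, ang):
        return origins[i] + radius * (math.cos(ang) * e1[i]
                                      + math.sin(ang) * e2[i])

    coords: List[np.ndarray] = []
    tpl = {"P": [-1] * length, "S": [0] * length, "B": [0] * length}
    ntl = {"P": [-1] * length, "S": [0] * length, "B": [0] * length}

    for i in range(length):
        phi = -i * twist_rad
        if i > 0:
            p = ring(i, _R_PHOS, phi - _SUGAR_SHIFT + 0.5 * twist_rad) \
                - 0.5 * rise * e3[i]
            tpl["P"][i] = len(coords); coords.append(p)
        tpl["S"][i] = len(coords); coords.append(ring(i, _R_SUGAR,
                                                      phi - _SUGAR_SHIFT))
        tpl["B"][i] = len(coords); coords.append(ring(i, _R_BASE, phi))

    for m in range(length):
        i = length - 1 - m            # paired template index
        chi = -i * twist_rad + math.pi
        if m > 0:
            p = ring(i, _R_PHOS, chi + _SUGAR_SHIFT - 0.5 * twist_rad) \
                + 0.5 * rise * e3[i]
            ntl["P"][m] = len(coords); coords.append(p)
        ntl["S"][m] = len(coords); coords.append(ring(i, _R_SUGAR,
                                                      chi + _SUGAR_SHIFT))
        ntl["B"][m] = len(coords); coords.append(ring(i, _R_BASE, chi))

    return np.asarray(coords), tpl, ntl


def _duplex_topology(seq: PromoterSequence, coords, tpl, ntl,
                     dna: DNAParams, phosphate_charge: float) -> CGTopology:
    """Topology with native values measured from the given coordinates."""
    topo = CGTopology()
    topo.sequence = seq
    topo.chain_table = {"T": "template", "N": "non_template"}
    length = len(seq)
    x = np.asarray(coords)

    for i in range(length):
        base = seq.template_strand[i]
        if tpl["P"][i] >= 0:
            topo.add_bead("T", i, "P", base, x[tpl["P"][i]], phosphate_charge)
        topo.add_bead("T", i, "S", base, x[tpl["S"][i]])
        topo.add_bead("T", i, "B", base, x[tpl["B"][i]])
    for m in range(length):
        base = seq.non_template_strand[m]
        if ntl["P"][m] >= 0:
            topo.add_bead("N", m, "P", base, x[ntl["P"][m]], phosphate_charge)
        topo.add_bead("N", m, "S", base, x[ntl["S"][m]])
        topo.add_bead("N", m, "B", base, x[ntl["B"][m]])

    # bead ids in topology order equal the placement order
    def dist(i, j):
        return float(np.linalg.norm(x[i] - x[j]))

    def ang(i, j, k):
        u, v = x[i] - x[j], x[k] - x[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1, 1)))

    def dih(i, j, k, l):
        b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))

    for maps in (tpl, ntl):
        P, S, B = maps["P"], maps["S"], maps["B"]
        for i in range(length):
            if P[i] >= 0:
                topo.bonds.append((P[i], S[i], dist(P[i], S[i]),
                                   dna.k_bond, TERM_DNA_BONDED))
            topo.bonds.append((S[i], B[i], dist(S[i], B[i]),
                               dna.k_bond, TERM_DNA_BONDED))
            if i + 1 < length:
                topo.bonds.append((S[i], P[i + 1], dist(S[i], P[i + 1]),
                                   dna.k_bond, TERM_DNA_BONDED))
                topo.pairs_1210.append((B[i], B[i + 1],
                                        dist(B[i], B[i + 1]),
                                        dna.eps_stack, TERM_DNA_STACKING))
        for i in range(length):
            trips = []
            if P[i] >= 0:
                trips.append((P[i], S[i], B[i]))
            if i + 1 < length:
                trips.append((B[i], S[i], P[i + 1]))
                if P[i] >= 0:
                    trips.append((P[i], S[i], P[i + 1]))
                trips.append((S[i], P[i + 1], S[i + 1]))
            for t in trips:
                topo.angles.append((*t, ang(*t), dna.k_angle,
                                    TERM_DNA_BONDED))
        for i in range(length - 1):
            quads = []
            if P[i] >= 0:
                quads.append((P[i], S[i], P[i + 1], S[i + 1]))
            if i + 2 < length:
                quads.append((S[i], P[i + 1], S[i + 1], P[i + 2]))
            for q in quads:
                topo.dihedrals.append((*q, dih(*q), dna.k_dihedral,
                                       TERM_DNA_BONDED))

    for i in range(length):
        m = length - 1 - i
        topo.wc_pairs.append(WCPair(
            base_i=tpl["B"][i], base_j=ntl["B"][m],
            sugar_i=tpl["S"][i], sugar_j=ntl["S"][m], r0=1.0))
    topo.measure_wc_geometry(x)
    return topo


def build_bdna(sequence, rise: float = 3.38, twist: float = 34.3,
               dna_params: Optional[DNAParams] = None,
               phosphate_charge: float = -0.6,
               bend_fn=None) -> Tuple[CGTopology, np.ndarray]:
    """Idealized B-form duplex for an arbitrary sequence.

    ``sequence`` is a base string (template strand 5'→3') or a
    :class:`PromoterSequence`.  All base–base pair distances are equal
    by construction and native bonded values are measured from the built
    geometry, so the output is a minimum of the DNA bonded energy.
    """
    if isinstance(sequence, PromoterSequence):
        seq = sequence
    else:
        seq = PromoterSequence.from_template(str(sequence))
    if len(seq) == 0:
        raise ValueError("sequence must be non-empty")
    if dna_params is None:
        dna_params = DNAParams()
    twist_rad = math.radians(twist)
    beta = bend_fn if bend_fn is not None else (lambda s: 0.0)
    frames = _frames(len(seq), rise, beta)
    coords, tpl, ntl = _place_duplex(len(seq), rise, twist_rad, frames)
    topo = _duplex_topology(seq, coords, tpl, ntl, dna_params,
                            phosphate_charge)
    return topo, topo.native_coords()


# ---------------------------------------------------------------------------
# toy PIC
# ---------------------------------------------------------------------------

@dataclass
class ToyGeometry:
    """Geometric layout of the toy clamp; arc length s runs 5'→3' along
    the template strand (s = 0 at the upstream end)."""

    rise: float = 3.38
    twist: float = 34.3
    alpha1_deg: float = 25.0       # CC→OC bend of the downstream arm
    ramp1: Tuple[float, float] = (38.0, 74.0)
    alpha2_deg: float = 45.0       # additional OC→ITC bend
    # the second bend extends nearly to the downstream tip so that
    # threading proceeds as a continuous zipper (no long straight lever
    # arm that would have to swing without any contact gradient)
    ramp2: Tuple[float, float] = (82.0, 150.0)
    offset: float = 14.0           # lateral (±x) stand-off of protein rows
    row_step: float = 3.6
    row_spread: float = 5.5        # spacing of stacked rows, Å
    anchor_s: Tuple[float, float] = (6.0, 34.0)
    persistent_s: Tuple[float, float] = (62.0, 82.0)
    ewing_s: Tuple[float, float] = (128.0, 142.0)
    cradle_s: Tuple[float, float] = (90.0, 170.0)
    liner_s: Tuple[float, float] = (88.0, 170.0)
    backstop_offset: float = 14.5
    s_gate: float = 138.0
    swing_fraction: float = 0.68   # gate sits at this fraction of the swing
    flap_beads: int = 6
    gate_enabled: bool = True      # False parks the flap outside the slot
    contact_cap: float = 8.0       # candidate-pair distance cap, Å
    exclusion_margin: float = 1.45  # "not formed" distance margin
    jitter: float = 0.25           # seeded protein-placement jitter, Å


@dataclass
class ToySystemSpec:
    """Prescription for the toy clamp + promoter system."""

    duplex_length: int = 52
    sequence: str = "random"
    tss_index: int = 35
    clamp_size: Optional[int] = None       # None → determined by geometry
    n_states: int = 3
    contact_sizes: Tuple[int, int, int] = (92, 22, 118)
    oc_itc_overlap: int = 19
    n_anchors: int = 12
    gate_loop: Tuple[int, int] = (1, 6)    # flap residue interval (open part)
    mismatch_window: Tuple[int, int] = (-9, 7)
    eps_go: float = 1.2
    # per-contact depth of the three E-wing-analog (OC-only) contacts;
    # they stand in for the collective DNA–E-wing contact network, so
    # each toy contact is deeper than a single calibrated contact
    ewing_epsilon: float = 8.0
    geometry: ToyGeometry = field(default_factory=ToyGeometry)

    def validate(self) -> None:
        n_cc, n_oc, n_itc = self.contact_sizes
        if self.n_states not in (1, 3):
            raise ToySpecError("n_states must be 1 or 3")
        if min(self.contact_sizes) < 0 or self.oc_itc_overlap < 0:
            raise ToySpecError("contact sizes must be non-negative")
        if self.oc_itc_overlap > min(n_oc, n_itc):
            raise ToySpecError(
                f"overlap {self.oc_itc_overlap} exceeds min(|OC|, |ITC|) "
                f"= {min(n_oc, n_itc)}")
        if self.duplex_length < 4:
            raise ToySpecError("duplex too short")


@dataclass
class ToyPIC:
    """Generated toy system: reference poses, contact sets and the bead
    groups the protocols and the gate analysis need."""

    reference_set: ReferenceStructureSet
    contact_sets: ContactSets
    sequence: PromoterSequence
    spec: ToySystemSpec
    gate_groups: Tuple[np.ndarray, np.ndarray] = (None, None)
    flap_bead_ids: np.ndarray = None
    scaffold_bead_ids: np.ndarray = None
    ewing_subset: np.ndarray = None        # union indices of the OC-only set
    info: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.reference_set, self.contact_sets))

    @property
    def topology(self) -> CGTopology:
        return self.reference_set.topology


def _row_positions(centerline, e2, s_range, step, ox, oy, rng, jitter,
                   rise):
    """Bead positions offset from a pose centerline by ox·x̂ plus oy
    along the pose's local in-plane normal."""
    lo, hi = s_range
    out = []
    seen = set()
    s = lo
    while s <= hi + 1e-9:
        i = min(int(round(s / rise)), len(centerline) - 1)
        if i not in seen:          # one bead per nucleotide station
            seen.add(i)
            p = centerline[i] + np.array([ox, 0.0, 0.0]) + oy * e2[i]
            out.append(p + rng.normal(0.0, jitter, 3))
        s += step
    return out


def _add_protein_chain(topo, chain_id, positions, identities,
                       prot: ProteinParams, k_angle=None):
    ids = []
    x = [np.asarray(p, dtype=float) for p in positions]
    for k, p in enumerate(x):
        ident = identities[k] if k < len(identities) else "G"
        ids.append(topo.add_bead(chain_id, k, "CA", ident, p,
                                 PROTEIN_CHARGE.get(ident, 0.0)))
    if k_angle is None:
        k_angle = prot.k_angle
    def d(a, b):
        return float(np.linalg.norm(x[a] - x[b]))
    for k in range(len(x) - 1):
        topo.bonds.append((ids[k], ids[k + 1], d(k, k + 1),
                           prot.k_bond, TERM_PROTEIN_LOCAL))
    for k in range(len(x) - 2):
        u, v = x[k] - x[k + 1], x[k + 2] - x[k + 1]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        topo.angles.append((ids[k], ids[k + 1], ids[k + 2],
                            float(np.arccos(np.clip(c, -1, 1))),
                            k_angle, TERM_PROTEIN_LOCAL))
    return ids


def build_toy_pic(spec: Optional[ToySystemSpec] = None,
                  seed: int = 0) -> ToyPIC:
    """Generate the toy clamp + promoter system.

    Deterministic for a given seed; different seeds jitter the protein
    bead placement (and the random promoter sequence) but preserve the
    prescribed contact-set structure exactly.  Raises
    :class:`ToySpecError` when the prescribed sizes/overlaps cannot be
    realized by the geometry.
    """
    if spec is None:
        spec = ToySystemSpec()
    spec.validate()
    g = spec.geometry
    rng = np.random.default_rng(seed)
    L = spec.duplex_length
    rise, twist_rad = g.rise, math.radians(g.twist)

    if spec.sequence == "random":
        seq = PromoterSequence.random(L, seed=int(rng.integers(2 ** 31)),
                                      tss_index=spec.tss_index,
                                      mismatch_region=spec.mismatch_window)
    else:
        seq = PromoterSequence.from_template(
            spec.sequence, tss_index=spec.tss_index,
            mismatch_region=spec.mismatch_window)

    a1, a2 = math.radians(g.alpha1_deg), math.radians(g.alpha2_deg)
    r1a, r1b = g.ramp1
    r2a, r2b = g.ramp2

    def beta_cc(s):
        return 0.0

    def beta_oc(s):
        return a1 * float(_smoothstep((s - r1a) / (r1b - r1a)))

    def beta_half(s):
        return beta_oc(s) + g.swing_fraction * a2 * float(
            _smoothstep((s - r2a) / (r2b - r2a)))

    def beta_itc(s):
        return beta_oc(s) + a2 * float(_smoothstep((s - r2a) / (r2b - r2a)))

    poses = {}
    centers = {}
    normals = {}
    for name, fn in (("CC", beta_cc), ("OC", beta_oc), ("ITC", beta_itc)):
        frames = _frames(L, rise, fn)
        coords, tpl, ntl = _place_duplex(L, rise, twist_rad, frames)
        poses[name] = coords
        centers[name] = frames[0]
        normals[name] = frames[2]
    half_frames = _frames(L, rise, beta_half)
    centers["half"] = half_frames[0]
    normals["half"] = half_frames[2]

    # topology (natives from the relaxed, straight CC pose)
    topo = _duplex_topology(seq, poses["CC"],
                            *_maps_for(L), DNAParams(), -0.6)
    n_dna = topo.n_beads

    prot = ProteinParams()
    group_ids: Dict[str, List[int]] = {}

    def add_rows(name_prefix, pose, s_range, identities_fn,
                 oy_levels=(0.0,), step=None):
        ids = []
        rows = [(side * g.offset, oy)
                for side in (+1, -1) for oy in oy_levels]
        for nrow, (ox, oy) in enumerate(rows):
            pos = _row_positions(centers[pose], normals[pose], s_range,
                                 step or g.row_step, ox, oy, rng,
                                 g.jitter, rise)
            idents = identities_fn(len(pos), ox)
            cid = f"{name_prefix}{nrow}"
            topo.chain_table[cid] = f"clamp-{name_prefix}"
            ids += _add_protein_chain(topo, cid, pos, idents, prot)
        return ids

    plain = lambda n, side: ["G"] * n
    charged_alt = lambda n, side: ["K" if k % 2 == 0 else "G"
                                   for k in range(n)]
    charged_all = lambda n, side: ["K"] * n
    # E-wing analog is electrically neutral: its hold on the DNA is the
    # Go-contact tether under test, not an electrostatic trap
    ewing_idents = lambda n, side: (["N", "T"] * ((n + 1) // 2))[:n]

    group_ids["anchor"] = add_rows("ANC", "CC", g.anchor_s, plain)
    sp = g.row_spread
    group_ids["cradle"] = add_rows("CRD", "CC", g.cradle_s, plain,
                                   oy_levels=(-sp, 0.0, sp))
    group_ids["persist"] = add_rows("PER", "OC", g.persistent_s, plain,
                                    oy_levels=(0.0, sp))
    group_ids["ewing"] = add_rows("EWG", "OC", g.ewing_s, ewing_idents)
    group_ids["liner"] = add_rows("LIN", "ITC", g.liner_s, charged_all,
                                  oy_levels=(0.0, sp), step=3.2)

    # charged guide rows flanking the swing corridor at intermediate
    # bend fractions: they extend the electrostatic funnel so the
    # downstream arm is pulled continuously from the OC pose to the ITC
    # pose instead of losing the gradient mid-swing (they sit at ±offset
    # in x, outside the duplex cross-section, and never block the path)
    for nrow, frac in enumerate((0.33, 0.66)):
        def beta_guide(s, frac=frac):
            return beta_oc(s) + frac * a2 * float(
                _smoothstep((s - r2a) / (r2b - r2a)))
        gf = _frames(L, rise, beta_guide)
        for side in (+1, -1):
            # only where the intermediate poses have separated from the
            # OC/ITC rows by more than a bead diameter, and past the
            # gate flap's station
            pos = _row_positions(gf[0], gf[2], (143.0, 168.0), g.row_step,
                                 side * g.offset, 0.0, rng, g.jitter, rise)
            cid = f"GDE{nrow}{'p' if side > 0 else 'm'}"
            topo.chain_table[cid] = "clamp-GDE"
            group_ids.setdefault("guide", []).extend(_add_protein_chain(
                topo, cid, pos, charged_alt(len(pos), side), prot))

    # backstop row on the far side of the ITC path (opposite the approach)
    i_bs = [min(int(round(s / rise)), L - 1)
            for s in np.arange(g.liner_s[0], g.liner_s[1] + 1e-9, g.row_step)]
    bs_pos = []
    for i in i_bs:
        u = centers["OC"][i] - centers["ITC"][i]
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-9 else np.array([0.0, 1.0, 0.0])
        bs_pos.append(centers["ITC"][i] - g.backstop_offset * u
                      + rng.normal(0.0, g.jitter, 3))
    topo.chain_table["BSTp"] = "clamp-BST"
    group_ids["backstop"] = _add_protein_chain(
        topo, "BSTp", bs_pos, charged_all(len(bs_pos), +1), prot)

    # gate flap: a flexible bar crossing the swing path at s_gate.  Its
    # native position is tilted toward the approach side so that the
    # arriving DNA folds it back against its own surface (the analog of
    # the fork loop ending up inside the bubble) instead of pinning it
    # against the far wall.
    i_g = min(int(round(g.s_gate / rise)), L - 1)
    u_app = centers["OC"][i_g] - centers["ITC"][i_g]
    u_app = u_app / max(np.linalg.norm(u_app), 1e-9)
    q = centers["half"][i_g] + 3.5 * u_app
    if not g.gate_enabled:
        q = q + np.array([55.0, 0.0, 0.0])
    flap_pos = [q + np.array([-g.offset + 1.0 + g.row_step * k, 0.0, 0.0])
                + rng.normal(0.0, g.jitter, 3)
                for k in range(g.flap_beads)]
    # the gate flap is a floppy loop: soft bending lets it swing open
    # thermally or under the push of arriving DNA
    topo.chain_table["GTE"] = "gate-flap"
    flap_ids = _add_protein_chain(topo, "GTE", flap_pos,
                                  plain(g.flap_beads, +1), prot,
                                  k_angle=1.5)

    # B-linker analog: small scaffold group past the flap tip
    blk_pos = [q + np.array([g.offset + 1.5 + 3.8 * k, 0.0, 0.0])
               + rng.normal(0.0, g.jitter, 3) for k in range(4)]
    topo.chain_table["BLK"] = "clamp-BLK"
    blk_ids = _add_protein_chain(topo, "BLK", blk_pos, plain(4, +1), prot)

    # weak Go contacts keeping the flap nominally closed: base to nearest
    # scaffold bead (strong) and tip to the B-linker group (weak)
    all_x = topo.native_coords()
    scaffold = [b.bead_id for b in topo.beads
                if b.kind == "CA" and b.bead_id not in flap_ids]
    sc_tree = cKDTree(all_x[scaffold])
    _, near = sc_tree.query(all_x[flap_ids[0]])
    topo.pairs_1210.append((flap_ids[0], scaffold[int(near)],
                            float(np.linalg.norm(
                                all_x[flap_ids[0]] - all_x[scaffold[int(near)]])),
                            2.0, TERM_PROTEIN_GO))
    topo.pairs_1210.append((flap_ids[-1], blk_ids[0],
                            float(np.linalg.norm(
                                all_x[flap_ids[-1]] - all_x[blk_ids[0]])),
                            0.2, TERM_PROTEIN_GO))

    # per-state full coordinates: protein beads identical across states
    prot_x = all_x[n_dna:]
    state_coords = {}
    for name in ("CC", "OC", "ITC"):
        state_coords[name] = np.vstack([poses[name], prot_x])
    if spec.n_states == 1:
        state_coords = {"CC": state_coords["CC"]}

    refset = ReferenceStructureSet(
        topology=topo, coords=state_coords,
        provenance={s: f"toy clamp seed={seed}" for s in state_coords})

    contact_sets, ewing_subset = _select_contacts(
        spec, topo, state_coords, flap_ids, n_dna)

    flap_arr = np.asarray(flap_ids, dtype=int)
    lo, hi = spec.gate_loop
    gate_group = flap_arr[lo:hi]
    pic = ToyPIC(
        reference_set=refset, contact_sets=contact_sets, sequence=seq,
        spec=spec,
        gate_groups=(gate_group, np.asarray(blk_ids, dtype=int)),
        flap_bead_ids=flap_arr,
        scaffold_bead_ids=np.asarray(scaffold, dtype=int),
        ewing_subset=ewing_subset,
        info={"n_dna_beads": n_dna, "n_protein_beads": len(prot_x),
              "clamp_size": len(prot_x), "seed": seed,
              "gate_site_template_index": i_g})
    return pic


def _maps_for(L):
    """Recompute the bead index maps implied by the canonical ordering."""
    tpl = {"P": [-1] * L, "S": [0] * L, "B": [0] * L}
    ntl = {"P": [-1] * L, "S": [0] * L, "B": [0] * L}
    k = 0
    for i in range(L):
        if i > 0:
            tpl["P"][i] = k; k += 1
        tpl["S"][i] = k; k += 1
        tpl["B"][i] = k; k += 1
    for m in range(L):
        if m > 0:
            ntl["P"][m] = k; k += 1
        ntl["S"][m] = k; k += 1
        ntl["B"][m] = k; k += 1
    return tpl, ntl


def _select_contacts(spec: ToySystemSpec, topo, state_coords, flap_ids,
                     n_dna):
    """Pick protein–DNA pairs realizing the prescribed per-state lists."""
    g = spec.geometry
    cap, margin = g.contact_cap, g.exclusion_margin
    n_cc, n_oc, n_itc = spec.contact_sizes
    n_shared = spec.oc_itc_overlap
    n_oc_only = n_oc - n_shared
    n_itc_only = n_itc - n_shared

    if spec.n_states == 1:
        x = state_coords["CC"]
        prot = [b.bead_id for b in topo.beads
                if b.kind == "CA" and b.bead_id not in flap_ids]
        tree = cKDTree(x[:n_dna])
        cand = []
        for p in prot:
            for loc in tree.query_ball_point(x[p], cap):
                cand.append((float(np.linalg.norm(x[p] - x[loc])), p, loc))
        cand.sort()
        if len(cand) < n_cc:
            raise ToySpecError(
                f"only {len(cand)} candidate contacts for prescribed {n_cc}")
        cc = [(p, d, r) for r, p, d in [(c[0], c[1], c[2])
                                        for c in cand[:n_cc]]]
        sets = build_contact_sets(cc, [], [], epsilon=spec.eps_go)
        return sets, np.empty(0, dtype=int)

    xs = {s: state_coords[s] for s in ("CC", "OC", "ITC")}
    prot = [b.bead_id for b in topo.beads
            if b.kind == "CA" and b.bead_id not in flap_ids]
    trees = {s: cKDTree(xs[s][:n_dna]) for s in xs}

    def dists(p, d):
        return {s: float(np.linalg.norm(xs[s][p] - xs[s][d])) for s in xs}

    pools = {"cc": [], "oc_only": [], "shared": [], "itc_only": [],
             "anchor": []}
    seen = set()
    for p in prot:
        hits = set()
        for s in xs:
            hits.update(trees[s].query_ball_point(xs[s][p], cap))
        for d in hits:
            if (p, d) in seen:
                continue
            seen.add((p, d))
            dd = dists(p, d)
            dcc, doc, ditc = dd["CC"], dd["OC"], dd["ITC"]
            if doc <= cap and 0.8 * doc <= ditc <= 1.1 * doc \
                    and dcc >= margin * doc:
                pools["shared"].append((doc, p, d))
            elif doc <= cap and dcc >= margin * doc and ditc >= margin * doc:
                pools["oc_only"].append((doc, p, d))
            elif dcc <= cap and doc >= margin * dcc and ditc >= margin * dcc:
                pools["cc"].append((dcc, p, d))
            elif ditc <= cap and dcc >= margin * ditc and doc >= margin * ditc:
                pools["itc_only"].append((ditc, p, d))
            elif dcc <= cap and doc <= 1.1 * dcc and ditc <= 1.1 * dcc:
                pools["anchor"].append((dcc, p, d))

    need = {"cc": n_cc, "oc_only": n_oc_only, "shared": n_shared,
            "itc_only": n_itc_only}
    short = {k: (len(pools[k]), v) for k, v in need.items()
             if len(pools[k]) < v}
    if short:
        raise ToySpecError(
            "prescribed contact structure unsatisfiable; candidate pool "
            f"shortfalls (have, need): {short}")

    take = {k: sorted(pools[k])[:v] for k, v in need.items()}
    cc_list = [(p, d, r) for r, p, d in take["cc"]]
    shared_list = [(p, d, r) for r, p, d in take["shared"]]
    ocset = [(p, d, r) for r, p, d in take["oc_only"]] + shared_list
    itc_shared = [(p, d, float(np.linalg.norm(xs["ITC"][p] - xs["ITC"][d])))
                  for _, p, d in take["shared"]]
    itcset = itc_shared + [(p, d, r) for r, p, d in take["itc_only"]]

    sets = build_contact_sets(cc_list, ocset, itcset, epsilon=spec.eps_go)

    # upstream anchor contacts present in every state: union members that
    # belong to no characteristic subset
    n_anchor = min(spec.n_anchors, len(pools["anchor"]))
    for r, p, d in sorted(pools["anchor"])[:n_anchor]:
        sets.union_set.append(ContactRecord(
            p, d, r, spec.eps_go, frozenset({"CC", "OC", "ITC"})))
    sets.report["n_anchor"] = n_anchor
    sets.validate()

    ewing_subset = np.array(
        [k for k, rec in enumerate(sets.union_set)
         if rec.source_states == frozenset({"OC"})], dtype=int)
    for k in ewing_subset:
        sets.union_set[int(k)].epsilon = spec.ewing_epsilon
    return sets, ewing_subset


def perturb_to_state(reference_coords: np.ndarray,
                     target_records: Sequence[ContactRecord],
                     noise: float = 0.3, seed: int = 0,
                     known_contacts: Optional[ContactSets] = None
                     ) -> np.ndarray:
    """Gaussian-perturbed copy of a reference pose.

    At the default noise the returned coordinates form ≥90% of the
    target set's contacts while contacts exclusive to other states stay
    unformed, which gives ground-truth frames for state-assignment
    tests.  Contact-formation fractions decrease monotonically (on
    average) with the noise amplitude.
    """
    if known_contacts is not None:
        known = {(r.bead_i, r.bead_j) for r in known_contacts.union_set}
        bad = [(r.bead_i, r.bead_j) for r in target_records
               if (r.bead_i, r.bead_j) not in known]
        if bad:
            raise ValueError(f"target contains unknown contacts: {bad[:5]}")
    rng = np.random.default_rng(seed)
    out = np.asarray(reference_coords, dtype=float).copy()
    out += rng.normal(0.0, noise, out.shape)
    return out
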