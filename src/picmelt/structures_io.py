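"""Reading reference structures and mapping them to the CG representation.

Proteins map to one bead per residue at the Cα position.  Nucleotides
map to three beads placed at heavy-atom group centroids: phosphate
(P, OP1, OP2, O5'), sugar (C1'–C5', O4') and base (ring heavy atoms).
Protein charges follow the fixed-charge convention +1 on Lys/Arg, −1 on
Asp/Glu; phosphates carry the counterion-condensation charge −0.6 e.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb_io
import biotite.structure.io.pdbx as pdbx_io

from .analysis import kabsch_rmsd
from .params import DNAParams, ProteinParams
from .sequences import PromoterSequence
from .topology import (
    CGTopology, ReferenceStructureSet, TERM_DNA_BONDED, TERM_DNA_STACKING,
    TERM_PROTEIN_GO, TERM_PROTEIN_LOCAL,
)

PHOSPHATE_ATOMS = ("P", "OP1", "OP2", "O5'", "O1P", "O2P")
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'")
PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

AA_CHARGE = {"LYS": 1.0, "ARG": 1.0, "ASP": -1.0, "GLU": -1.0}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
NUC_NAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T",
             "A": "A", "C": "C", "G": "G", "T": "T", "U": "U"}


class FormatError(ValueError):
    pass


class MappingError(ValueError):
    pass


class CompositionError(ValueError):
    pass


def read_structure(path) -> struc.AtomArray:
    """Read a PDB or mmCIF file into a biotite AtomArray.

    Altlocs are resolved to the highest-occupancy conformer; water and
    hydrogens are dropped.  Missing residues are whatever the file
    lacks — they are reported downstream, never rebuilt.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
            f = pdbx_io.CIFFile.read(str(path))
            atoms = pdbx_io.get_structure(f, model=1, altloc="occupancy")
        else:
            f = pdb_io.PDBFile.read(str(path))
            atoms = pdb_io.get_structure(f, model=1, altloc="occupancy")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    atoms = atoms[~struc.filter_solvent(atoms)]
    atoms = atoms[atoms.element != "H"]
    if atoms.array_length() == 0:
        raise ValueError(f"{path} contains no atoms")
    return atoms


def coarse_grain(atoms: struc.AtomArray,
                 dna_params: Optional[DNAParams] = None,
                 protein_params: Optional[ProteinParams] = None,
                 phosphate_charge: float = -0.6,
                 ) -> Tuple[CGTopology, np.ndarray, List[List[np.ndarray]]]:
    """Map an atomic model to the CG representation.

    Returns (topology, coordinates, per-bead heavy-atom coordinate
    groups).  The atom groups are kept so that contact detection can run
    on heavy atoms while energies use bead positions.  Native bonded
    values are measured from the mapped geometry.  Raises
    :class:`MappingError` when a residue provides none of its mapped
    atoms.
    """
    if dna_params is None:
        dna_params = DNAParams()
    if protein_params is None:
        protein_params = ProteinParams()
    topo = CGTopology()
    coords: List[np.ndarray] = []
    atom_groups: List[List[np.ndarray]] = []

    chain_dna: Dict[str, list] = {}
    chain_protein: Dict[str, list] = {}

    for chain_id in np.unique(atoms.chain_id):
        chain = atoms[atoms.chain_id == chain_id]
        res_ids = np.unique(chain.res_id)
        gaps = np.flatnonzero(np.diff(res_ids) > 1)
        if gaps.size:
            missing = [f"{res_ids[g] + 1}-{res_ids[g + 1] - 1}"
                       for g in gaps]
            warnings.warn(
                f"chain {chain_id}: residues {', '.join(missing)} are "
                "missing from the model and are excluded from all energy "
                "terms (they are not rebuilt)", stacklevel=2)
        for local_index, rid in enumerate(res_ids):
            res = chain[chain.res_id == rid]
            name = res.res_name[0]
            if name in NUC_NAMES:
                beads = _map_nucleotide(topo, coords, atom_groups, res,
                                        str(chain_id), local_index,
                                        NUC_NAMES[name], phosphate_charge)
                chain_dna.setdefault(str(chain_id), []).append(beads)
            elif name in THREE_TO_ONE:
                ca = res[res.atom_name == "CA"]
                if ca.array_length() == 0:
                    raise MappingError(
                        f"residue {name} {rid} chain {chain_id} has no CA")
                one = THREE_TO_ONE[name]
                bid = topo.add_bead(str(chain_id), local_index, "CA", one,
                                    ca.coord[0],
                                    AA_CHARGE.get(name, 0.0))
                coords.append(np.asarray(ca.coord[0], dtype=float))
                atom_groups.append([np.asarray(res.coord, dtype=float)])
                chain_protein.setdefault(str(chain_id), []).append(bid)
            else:
                continue  # heteroatoms/ligands are skipped

    x = np.asarray(coords)
    _add_protein_terms(topo, chain_protein, x, protein_params)
    _add_dna_terms(topo, chain_dna, x, dna_params)
    for cid in chain_protein:
        topo.chain_table.setdefault(cid, f"protein-{cid}")
    for cid in chain_dna:
        topo.chain_table.setdefault(cid, f"nucleic-{cid}")
    flat_groups = [np.vstack(g) for g in atom_groups]
    return topo, x, flat_groups


def _map_nucleotide(topo, coords, atom_groups, res, chain_id, idx, base,
                    phosphate_charge):
    """Place P/S/B beads at heavy-atom group centroids; the 5'-terminal
    phosphate is simply absent when the structure lacks it."""
    beads = {}
    names = res.atom_name
    groups = {
        "P": res[np.isin(names, PHOSPHATE_ATOMS)],
        "S": res[np.isin(names, SUGAR_ATOMS)],
        "B": res[np.isin(names,
                         PURINE_RING if base in "AG" else PYRIMIDINE_RING)],
    }
    if all(g.array_length() == 0 for g in groups.values()):
        raise MappingError(
            f"nucleotide {base} {res.res_id[0]} chain {chain_id} has no "
            "mapped heavy atoms")
    for kind in ("P", "S", "B"):
        g = groups[kind]
        if g.array_length() == 0:
            if kind == "P":
                continue
            raise MappingError(
                f"nucleotide {base} {res.res_id[0]} chain {chain_id} "
                f"missing all {kind}-group atoms")
        centroid = g.coord.mean(axis=0)
        charge = phosphate_charge if kind == "P" else 0.0
        bid = topo.add_bead(chain_id, idx, kind, base, centroid, charge)
        coords.append(np.asarray(centroid, dtype=float))
        atom_groups.append([np.asarray(g.coord, dtype=float)])
        beads[kind] = bid
    return beads


def _geom(x):
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

    return dist, ang, dih


def _add_protein_terms(topo, chain_protein, x, prot: ProteinParams):
    dist, ang, dih = _geom(x)
    for cid, ids in chain_protein.items():
        for a, b in zip(ids, ids[1:]):
            topo.bonds.append((a, b, dist(a, b), prot.k_bond,
                               TERM_PROTEIN_LOCAL))
        for a, b, c in zip(ids, ids[1:], ids[2:]):
            topo.angles.append((a, b, c, ang(a, b, c), prot.k_angle,
                                TERM_PROTEIN_LOCAL))
        for a, b, c, d in zip(ids, ids[1:], ids[2:], ids[3:]):
            topo.dihedrals.append((a, b, c, d, dih(a, b, c, d),
                                   prot.k_dihedral, TERM_PROTEIN_LOCAL))
    # intra/inter-chain native contacts (|i-j| >= 3 within a chain)
    all_ids = [i for ids in chain_protein.values() for i in ids]
    pos = {i: k for cid, ids in chain_protein.items()
           for k, i in enumerate(ids)}
    chain_of = {i: cid for cid, ids in chain_protein.items() for i in ids}
    from scipy.spatial import cKDTree
    if not all_ids:
        return
    tree = cKDTree(x[all_ids])
    for a_loc, b_loc in tree.query_pairs(prot.contact_cutoff):
        a, b = all_ids[a_loc], all_ids[b_loc]
        if chain_of[a] == chain_of[b] and abs(pos[a] - pos[b]) < 3:
            continue
        topo.pairs_1210.append((a, b, dist(a, b), prot.eps_intra,
                                TERM_PROTEIN_GO))


def _add_dna_terms(topo, chain_dna, x, dna: DNAParams):
    dist, ang, dih = _geom(x)
    for cid, nucleotides in chain_dna.items():
        for k, nt in enumerate(nucleotides):
            if "P" in nt:
                topo.bonds.append((nt["P"], nt["S"], dist(nt["P"], nt["S"]),
                                   dna.k_bond, TERM_DNA_BONDED))
                topo.angles.append((nt["P"], nt["S"], nt["B"],
                                    ang(nt["P"], nt["S"], nt["B"]),
                                    dna.k_angle, TERM_DNA_BONDED))
            topo.bonds.append((nt["S"], nt["B"], dist(nt["S"], nt["B"]),
                               dna.k_bond, TERM_DNA_BONDED))
            if k + 1 < len(nucleotides):
                nxt = nucleotides[k + 1]
                if "P" in nxt:
                    topo.bonds.append((nt["S"], nxt["P"],
                                       dist(nt["S"], nxt["P"]),
                                       dna.k_bond, TERM_DNA_BONDED))
                    topo.angles.append((nt["B"], nt["S"], nxt["P"],
                                        ang(nt["B"], nt["S"], nxt["P"]),
                                        dna.k_angle, TERM_DNA_BONDED))
                    topo.angles.append((nt["S"], nxt["P"], nxt["S"],
                                        ang(nt["S"], nxt["P"], nxt["S"]),
                                        dna.k_angle, TERM_DNA_BONDED))
                topo.pairs_1210.append((nt["B"], nxt["B"],
                                        dist(nt["B"], nxt["B"]),
                                        dna.eps_stack, TERM_DNA_STACKING))


def pair_dna_strands(topo: CGTopology, coords,
                     template_chain: str, non_template_chain: str,
                     max_pair_distance: float = 12.0) -> None:
    """Mark chain roles and build the Watson–Crick pair table by pairing
    complementary bases between the two chains (closest base beads)."""
    from .sequences import is_wc_pair
    from .topology import WCPair
    topo.chain_table[template_chain] = "template"
    topo.chain_table[non_template_chain] = "non_template"
    x = np.asarray(coords)

    def strand(cid):
        by_res: Dict[int, Dict[str, int]] = {}
        for b in topo.beads:
            if b.chain_id == cid:
                by_res.setdefault(b.residue_index, {})[b.kind] = b.bead_id
        return [by_res[k] for k in sorted(by_res)]

    tpl, ntl = strand(template_chain), strand(non_template_chain)
    used = set()
    for nt in tpl:
        bi, si = nt.get("B"), nt.get("S")
        if bi is None:
            continue
        best, best_d = None, max_pair_distance
        for mt in ntl:
            bj = mt.get("B")
            if bj is None or bj in used:
                continue
            if not is_wc_pair(topo.beads[bi].identity,
                              topo.beads[bj].identity):
                continue
            d = float(np.linalg.norm(x[bi] - x[bj]))
            if d < best_d:
                best, best_d = mt, d
        if best is not None:
            used.add(best["B"])
            topo.wc_pairs.append(WCPair(bi, best["B"], si, best["S"], 1.0))
    topo.measure_wc_geometry(x)


def build_reference_set(cc, oc, itc) -> ReferenceStructureSet:
    """Assemble CC/OC/ITC coarse-grained structures into one reference
    set on the CC topology.

    Each argument is a (topology, coords) tuple.  Protein beads are
    matched across states by (chain role, residue index, identity);
    states may model different subsets of residues — beads missing from
    a state keep their CC coordinates and are reported in
    ``unreconciled``.  Raises :class:`CompositionError` when matched
    residues disagree in identity.
    """
    topo_cc, x_cc = cc
    out_coords = {"CC": np.asarray(x_cc, dtype=float)}
    unreconciled: List[str] = []

    def key_map(topo):
        m = {}
        for b in topo.beads:
            # DNA chains are matched by role (template/non-template) so
            # that differently labeled chains across depositions line up;
            # protein chains are matched by chain id
            role = topo.chain_table.get(b.chain_id, b.chain_id)
            key_chain = role if role in ("template", "non_template") \
                else b.chain_id
            m[(key_chain, b.residue_index, b.kind)] = b
        return m

    ref_map = key_map(topo_cc)
    for state, (topo_s, x_s) in (("OC", oc), ("ITC", itc)):
        x_s = np.asarray(x_s, dtype=float)
        smap = key_map(topo_s)
        xyz = np.array(out_coords["CC"], copy=True)
        for key, bead in ref_map.items():
            other = smap.get(key)
            if other is None:
                unreconciled.append(f"{state}: missing {key}")
                continue
            if bead.kind == "CA" and other.identity != bead.identity:
                raise CompositionError(
                    f"protein sequences disagree at {key}: "
                    f"{bead.identity} vs {other.identity} in {state}")
            xyz[bead.bead_id] = x_s[other.bead_id]
        out_coords[state] = xyz
    return ReferenceStructureSet(topology=topo_cc, coords=out_coords,
                                 unreconciled=unreconciled)


def reference_rmsds(refset: ReferenceStructureSet) -> Dict[str, float]:
    """Pairwise protein-only RMSDs (Kabsch, DNA excluded) between the
    reference states."""
    sel = refset.topology.protein_bead_ids()
    out = {}
    states = refset.states
    for i, a in enumerate(states):
        for b in states[i + 1:]:
            out[f"{a}-{b}"] = kabsch_rmsd(refset.coords[a],
                                          refset.coords[b], sel)
    return out


# ---------------------------------------------------------------------------
# CG structure IO (one pseudo-atom per bead)
# ---------------------------------------------------------------------------

_KIND_ATOM = {"CA": "CA", "P": "P", "S": "S", "B": "B"}
_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


_CHAIN_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
                   "abcdefghijklmnopqrstuvwxyz0123456789")


def write_cg_pdb(path, topology: CGTopology, coords) -> None:
    """Write a CG structure as PDB with the bead kind in the atom-name
    field (coordinates at PDB precision, 0.001 Å).  Multi-character
    chain ids are mapped deterministically onto one-character PDB chain
    ids in order of first appearance."""
    x = np.asarray(coords, dtype=float)
    n = topology.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = x.astype(np.float32)
    chain_map = {}
    for b in topology.beads:
        if b.chain_id not in chain_map:
            if len(b.chain_id) == 1:
                chain_map[b.chain_id] = b.chain_id
            else:
                used = set(chain_map.values())
                chain_map[b.chain_id] = next(
                    c for c in _CHAIN_ALPHABET if c not in used)
    for k, b in enumerate(topology.beads):
        atoms.chain_id[k] = chain_map[b.chain_id]
        atoms.res_id[k] = b.residue_index + 1
        atoms.atom_name[k] = _KIND_ATOM[b.kind]
        if b.kind == "CA":
            atoms.res_name[k] = _ONE_TO_THREE.get(b.identity, "GLY")
            atoms.element[k] = "C"
        else:
            atoms.res_name[k] = "D" + b.identity
            atoms.element[k] = {"P": "P", "S": "C", "B": "N"}[b.kind]
        atoms.hetero[k] = False
    f = pdb_io.PDBFile()
    pdb_io.set_structure(f, atoms)
    f.write(str(path))


def read_cg_pdb(path) -> Tuple[List[dict], np.ndarray]:
    """Read back a CG-PDB written by :func:`write_cg_pdb`.

    Returns a list of bead descriptors (chain, residue index, kind,
    identity) and the coordinate array; it does not reconstruct bonded
    terms (the generator, not the file, owns those)."""
    f = pdb_io.PDBFile.read(str(path))
    atoms = pdb_io.get_structure(f, model=1)
    beads = []
    for k in range(atoms.array_length()):
        name = str(atoms.atom_name[k])
        res = str(atoms.res_name[k])
        if name == "CA":
            ident = THREE_TO_ONE.get(res, "G")
            kind = "CA"
        else:
            kind = name
            ident = res[-1]
        beads.append({"chain_id": str(atoms.chain_id[k]),
                      "residue_index": int(atoms.res_id[k]) - 1,
                      "kind": kind, "identity": ident})
    return beads, np.asarray(atoms.coord, dtype=float)
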