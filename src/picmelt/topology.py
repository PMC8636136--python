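"""Coarse-grained topology containers.

A protein residue maps to one CA bead at its Cα position; a nucleotide
maps to three beads — phosphate (P), sugar (S) and base (B) — placed at
the centroids of the corresponding heavy-atom groups.  The topology holds
the bonded terms with their native values (taken from the reference
geometry), the Watson–Crick pair table and per-chain roles; coordinates
travel separately as ``(n_beads, 3)`` arrays.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .sequences import PromoterSequence, is_wc_pair

BEAD_KINDS = ("CA", "P", "S", "B")

#: bead masses in amu-like units (only ratios matter for Langevin sampling)
BEAD_MASSES = {"CA": 110.0, "P": 95.0, "S": 99.0, "B": 120.0}

# energy-breakdown term indices shared with the kernels
TERM_PROTEIN_LOCAL = 0
TERM_PROTEIN_GO = 1
TERM_DNA_BONDED = 2
TERM_DNA_STACKING = 3
TERM_DNA_PAIRING = 4
TERM_PROTEIN_DNA_GO = 5
TERM_EXCLUDED_VOLUME = 6
TERM_ELECTROSTATICS = 7
TERM_RESTRAINT = 8
N_TERMS = 9

TERM_NAMES = (
    "protein_local", "protein_go", "dna_bonded", "dna_stacking",
    "dna_pairing", "protein_dna_go", "excluded_volume", "electrostatics",
    "restraint",
)


@dataclass
class CGBead:
    bead_id: int
    chain_id: str
    residue_index: int
    kind: str                 # CA | P | S | B
    identity: str             # amino-acid or base code
    charge: float = 0.0
    position: Optional[np.ndarray] = None  # native coordinate, Å

    def __post_init__(self):
        if self.kind not in BEAD_KINDS:
            raise ValueError(f"unknown bead kind {self.kind!r}")


@dataclass
class WCPair:
    """One Watson–Crick pair: base beads, flanking sugar beads (for the
    orientation gate), native base–base distance and native gate angles."""

    base_i: int
    base_j: int
    sugar_i: int
    sugar_j: int
    r0: float
    theta_i0: float = 0.0     # native angle S_i–B_i–B_j, rad
    theta_j0: float = 0.0     # native angle S_j–B_j–B_i, rad
    enabled: bool = True


@dataclass
class CGTopology:
    """Beads plus every intramolecular interaction term with native values.

    Protein–DNA Go contacts are *not* stored here — they live in a
    :class:`picmelt.contacts.ContactSets` and are combined with the
    topology when an energy model is assembled.
    """

    beads: List[CGBead] = field(default_factory=list)
    chain_table: Dict[str, str] = field(default_factory=dict)  # id -> role

    # bonded terms: index tuples + native value + force constant + term id
    bonds: List[Tuple[int, int, float, float, int]] = field(default_factory=list)
    angles: List[Tuple[int, int, int, float, float, int]] = field(default_factory=list)
    dihedrals: List[Tuple[int, int, int, int, float, float, int]] = field(default_factory=list)

    # generic 12-10 pair wells: (i, j, r0, eps, term id)
    pairs_1210: List[Tuple[int, int, float, float, int]] = field(default_factory=list)

    wc_pairs: List[WCPair] = field(default_factory=list)

    # extra pairs excluded from excluded volume (beyond the automatic rules)
    extra_ev_exclusions: List[Tuple[int, int]] = field(default_factory=list)

    # promoter bookkeeping for mismatch protocols
    sequence: Optional[PromoterSequence] = None
    mismatch_backup: Optional[dict] = None

    # --- construction helpers ------------------------------------------
    def add_bead(self, chain_id: str, residue_index: int, kind: str,
                 identity: str, position, charge: float = 0.0) -> int:
        bid = len(self.beads)
        self.beads.append(CGBead(bid, chain_id, residue_index, kind,
                                 identity, charge,
                                 np.asarray(position, dtype=float)))
        return bid

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def native_coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([BEAD_MASSES[b.kind] for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def kinds(self) -> List[str]:
        return [b.kind for b in self.beads]

    def beads_of_chain(self, chain_id: str) -> List[int]:
        return [b.bead_id for b in self.beads if b.chain_id == chain_id]

    def protein_bead_ids(self) -> np.ndarray:
        return np.array([b.bead_id for b in self.beads if b.kind == "CA"],
                        dtype=int)

    def dna_bead_ids(self) -> np.ndarray:
        return np.array([b.bead_id for b in self.beads if b.kind != "CA"],
                        dtype=int)

    def validate(self) -> None:
        n = self.n_beads
        for tup in self.bonds:
            i, j, r0, k, _ = tup
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond {tup} references missing bead")
            if not (np.isfinite(r0) and r0 > 0 and k > 0):
                raise ValueError(f"bond {tup} has invalid native value")
        for tup in self.angles:
            if not all(0 <= x < n for x in tup[:3]):
                raise ValueError(f"angle {tup} references missing bead")
        for tup in self.dihedrals:
            if not all(0 <= x < n for x in tup[:4]):
                raise ValueError(f"dihedral {tup} references missing bead")
        for p in self.wc_pairs:
            for x in (p.base_i, p.base_j, p.sugar_i, p.sugar_j):
                if not 0 <= x < n:
                    raise ValueError("wc_pair references missing bead")
            if p.enabled:
                a = self.beads[p.base_i].identity
                b = self.beads[p.base_j].identity
                if not is_wc_pair(a, b):
                    raise ValueError(
                        f"enabled wc_pair {p.base_i}-{p.base_j} is "
                        f"non-complementary ({a}·{b})")

    def measure_wc_geometry(self, coords: np.ndarray) -> None:
        """Fill each pair's native distance and gate angles from ``coords``."""
        for p in self.wc_pairs:
            bi, bj = coords[p.base_i], coords[p.base_j]
            si, sj = coords[p.sugar_i], coords[p.sugar_j]
            p.r0 = float(np.linalg.norm(bi - bj))
            p.theta_i0 = _angle(si, bi, bj)
            p.theta_j0 = _angle(sj, bj, bi)

    def copy(self) -> "CGTopology":
        return copy.deepcopy(self)


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosv, -1.0, 1.0)))


@dataclass
class ReferenceStructureSet:
    """Per-state coordinates (e.g. CC / OC / ITC) on one shared topology."""

    topology: CGTopology
    coords: Dict[str, np.ndarray] = field(default_factory=dict)
    provenance: Dict[str, str] = field(default_factory=dict)
    unreconciled: List[str] = field(default_factory=list)

    def __post_init__(self):
        n = self.topology.n_beads
        for state, xyz in self.coords.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (n, 3):
                raise ValueError(
                    f"state {state!r} has {xyz.shape} coordinates for "
                    f"{n} beads")
            self.coords[state] = xyz

    @property
    def states(self) -> List[str]:
        return list(self.coords)
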