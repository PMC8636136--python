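"""Protein–DNA native contacts: detection, set algebra, calibration.

State-specific contact sets are the reaction coordinates of the whole
analysis: a closed-complex (CC) set that is specific to CC, an
open-complex (OC) set that is mostly contained in the initially
transcribing complex (ITC) set, and the ITC-unique remainder.  The union
of the per-state lists doubles as the structure-based contact potential
between protein and DNA.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

STATE_ORDER = ("CC", "OC", "ITC")


@dataclass
class ContactRecord:
    bead_i: int                    # protein bead id
    bead_j: int                    # DNA bead id
    r0: float                      # native distance, Å
    epsilon: float = 1.2           # kcal/mol
    source_states: frozenset = frozenset()

    def __post_init__(self):
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.source_states = frozenset(self.source_states)
        if not self.source_states:
            raise ValueError("source_states must be non-empty")


@dataclass
class ContactSets:
    """Union contact list plus the state-characteristic index subsets."""

    union_set: List[ContactRecord]
    cc_specific: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    oc_set: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    itc_unique: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    report: dict = field(default_factory=dict)

    def records(self, subset: Union[str, Sequence[int]]) -> List[ContactRecord]:
        if isinstance(subset, str):
            subset = getattr(self, subset)
        return [self.union_set[int(k)] for k in subset]

    def subset_for_state(self, state: str) -> np.ndarray:
        return {"CC": self.cc_specific, "OC": self.oc_set,
                "ITC": self.itc_unique}[state]

    def validate(self) -> None:
        cc = set(map(int, self.cc_specific))
        others = set(map(int, self.oc_set)) | set(map(int, self.itc_unique))
        if cc & others:
            raise ValueError("cc_specific overlaps the OC/ITC subsets")
        for rec in self.union_set:
            if not rec.source_states:
                raise ValueError("union member belongs to no state")

    # ------ serialization (TSV: bead_i, bead_j, r0, epsilon, states) ----
    def to_tsv(self, path) -> None:
        import pandas as pd
        subs = {"cc_specific": set(map(int, self.cc_specific)),
                "oc_set": set(map(int, self.oc_set)),
                "itc_unique": set(map(int, self.itc_unique))}
        rows = []
        for k, rec in enumerate(self.union_set):
            rows.append({
                "bead_i": rec.bead_i, "bead_j": rec.bead_j,
                "r0": rec.r0, "epsilon": rec.epsilon,
                "states": "|".join(s for s in STATE_ORDER
                                   if s in rec.source_states),
                **{name: int(k in idx) for name, idx in subs.items()}})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ContactSets":
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        union = [ContactRecord(int(r.bead_i), int(r.bead_j), float(r.r0),
                               float(r.epsilon),
                               frozenset(str(r.states).split("|")))
                 for r in df.itertuples()]
        out = cls(union_set=union)
        for name in ("cc_specific", "oc_set", "itc_unique"):
            out.__setattr__(name, np.flatnonzero(df[name].to_numpy()))
        return out


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_native_contacts(topology, coords, cutoff: float = 6.5,
                           bead_atoms: Optional[Sequence[np.ndarray]] = None
                           ) -> List[Tuple[int, int, float]]:
    """Native protein–DNA contacts in one reference structure.

    A protein bead and a DNA bead are in contact when at least one pair
    of their heavy atoms lies within ``cutoff``; ``bead_atoms`` maps each
    bead to its heavy-atom coordinates.  Without it (pure CG input, as
    for the toy systems) the bead–bead distance itself is tested against
    the cutoff.  The recorded native distance r0 is always the CG
    bead–bead distance.

    Returns (protein bead, DNA bead, r0) tuples sorted by bead ids.
    """
    coords = np.asarray(coords, dtype=float)
    prot = topology.protein_bead_ids()
    dna = topology.dna_bead_ids()
    if prot.size == 0 or dna.size == 0:
        raise ValueError("structure must contain both protein and DNA chains")

    found = set()
    if bead_atoms is None:
        tree = cKDTree(coords[dna])
        for bi in prot:
            for loc in tree.query_ball_point(coords[bi], cutoff):
                found.add((int(bi), int(dna[loc])))
    else:
        atom_xyz, atom_bead = [], []
        for bj in dna:
            for a in np.atleast_2d(bead_atoms[bj]):
                atom_xyz.append(a)
                atom_bead.append(int(bj))
        tree = cKDTree(np.asarray(atom_xyz))
        atom_bead = np.asarray(atom_bead)
        for bi in prot:
            hits = set()
            for a in np.atleast_2d(bead_atoms[bi]):
                hits.update(tree.query_ball_point(a, cutoff))
            for loc in hits:
                found.add((int(bi), int(atom_bead[loc])))
    out = []
    for bi, bj in sorted(found):
        out.append((bi, bj, float(np.linalg.norm(coords[bi] - coords[bj]))))
    return out


def brute_force_contacts(topology, coords, cutoff: float = 6.5
                         ) -> List[Tuple[int, int, float]]:
    """All-pairs reference scan (independent of the tree-based detector)."""
    coords = np.asarray(coords, dtype=float)
    out = []
    for bi in topology.protein_bead_ids():
        for bj in topology.dna_bead_ids():
            r = float(np.linalg.norm(coords[bi] - coords[bj]))
            if r <= cutoff:
                out.append((int(bi), int(bj), r))
    return sorted(out)


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

def build_contact_sets(cc_list: Iterable, oc_list: Iterable,
                       itc_list: Iterable, epsilon: float = 1.2,
                       r0_conflict_tol: float = 2.0) -> ContactSets:
    """Merge per-state contact lists into the union set plus subsets.

    The union takes r0 from the first state containing the pair, in
    CC < OC < ITC priority; conflicting r0 values differing by more than
    ``r0_conflict_tol`` across states trigger a warning (priority rule
    still applies).  Subsets: ``cc_specific`` = CC pairs absent from
    OC ∪ ITC, ``oc_set`` = all OC pairs, ``itc_unique`` = ITC pairs
    absent from OC ∪ CC.
    """
    state_lists = {"CC": list(cc_list), "OC": list(oc_list),
                   "ITC": list(itc_list)}
    if all(len(v) == 0 for v in state_lists.values()):
        raise ValueError("at least one state list must be non-empty")

    union: dict = {}
    for state in STATE_ORDER:
        for item in state_lists[state]:
            if isinstance(item, ContactRecord):
                key, r0 = (item.bead_i, item.bead_j), item.r0
                eps = item.epsilon
            else:
                bi, bj, r0 = item
                key, eps = (int(bi), int(bj)), epsilon
            if key not in union:
                union[key] = ContactRecord(key[0], key[1], float(r0), eps,
                                           frozenset({state}))
            else:
                rec = union[key]
                if abs(rec.r0 - r0) > r0_conflict_tol:
                    warnings.warn(
                        f"contact {key} native distance differs by "
                        f"{abs(rec.r0 - r0):.2f} Å between states; keeping "
                        f"the higher-priority value {rec.r0:.2f} Å",
                        stacklevel=2)
                rec.source_states = rec.source_states | {state}

    keys = list(union)
    index = {k: i for i, k in enumerate(keys)}
    records = [union[k] for k in keys]

    def key_of(item):
        if isinstance(item, ContactRecord):
            return (item.bead_i, item.bead_j)
        return (int(item[0]), int(item[1]))

    sets = {s: {key_of(it) for it in state_lists[s]} for s in STATE_ORDER}
    cc_specific = sorted(index[k] for k in
                         sets["CC"] - sets["OC"] - sets["ITC"])
    oc_set = sorted(index[k] for k in sets["OC"])
    itc_unique = sorted(index[k] for k in
                        sets["ITC"] - sets["OC"] - sets["CC"])
    n_oc_in_itc = len(sets["OC"] & sets["ITC"])
    report = {
        "n_union": len(records),
        "n_cc": len(sets["CC"]), "n_oc": len(sets["OC"]),
        "n_itc": len(sets["ITC"]),
        "n_cc_specific": len(cc_specific),
        "n_itc_unique": len(itc_unique),
        "oc_in_itc": n_oc_in_itc,
        "oc_in_itc_fraction": (n_oc_in_itc / len(sets["OC"])
                               if sets["OC"] else float("nan")),
    }
    out = ContactSets(union_set=records,
                      cc_specific=np.asarray(cc_specific, dtype=int),
                      oc_set=np.asarray(oc_set, dtype=int),
                      itc_unique=np.asarray(itc_unique, dtype=int),
                      report=report)
    out.validate()
    return out


def weaken_contacts(contacts: ContactSets,
                    selector: Union[Sequence[int], Callable[[ContactRecord], bool]],
                    factor: float) -> ContactSets:
    """Return a copy with epsilon of the selected records scaled by
    ``factor`` (0 ≤ factor ≤ 1); the input object is unmodified.
    ``selector`` is an index sequence or a predicate over records."""
    if not 0.0 <= factor <= 1.0:
        raise ValueError("factor must be in [0, 1]")
    out = copy.deepcopy(contacts)
    if callable(selector):
        idx = [k for k, rec in enumerate(out.union_set) if selector(rec)]
    else:
        idx = [int(k) for k in selector]
    if not idx:
        warnings.warn("weaken_contacts: empty selection", stacklevel=2)
    for k in idx:
        rec = out.union_set[k]
        # keep epsilon strictly positive so the record stays well-formed;
        # a tiny epsilon is energetically indistinguishable from zero
        rec.epsilon = max(rec.epsilon * factor, 1.0e-12)
    return out


def ewing_selector(rec: ContactRecord) -> bool:
    """Contacts formed in OC but not retained in ITC — the analog of the
    DNA–TFIIE E-wing contact whose disruption licenses the final descent
    of the template strand."""
    return rec.source_states == frozenset({"OC"})


# ---------------------------------------------------------------------------
# epsilon calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationProbe:
    """One calibration condition: in ``state``, the contacts selected by
    ``subset`` must end up ``required`` ∈ {"maintained", "lost"} (mean
    survival fraction ≥/< ``survival_threshold`` over a probe run).
    ``mutation`` lists protein bead ids to charge-flip (+1 → −1) with
    their DNA contacts deleted, emulating charge-reversal mutants."""

    state: str
    subset: Sequence[int]
    required: str = "maintained"
    mutation: Optional[Sequence[int]] = None

    def __post_init__(self):
        if self.required not in ("maintained", "lost"):
            raise ValueError("required must be 'maintained' or 'lost'")


def calibrate_epsilon(reference_set, contacts: ContactSets,
                      probes: Sequence[CalibrationProbe],
                      candidates: Sequence[float],
                      params=None, config=None, seeds: Sequence[int] = (0,),
                      survival_threshold: float = 0.5,
                      formation_factor: float = 1.2):
    """Scan candidate Go-contact depths and return the smallest ε
    satisfying every probe, with a per-probe survival report.

    For each candidate ε the union contact potential is rescaled to
    depth ε, a short equilibrium Langevin run is made from each probe's
    state coordinates (applying the probe's mutation if any), and the
    time-mean fraction of formed contacts in the probe subset is scored.
    "maintained" demands survival ≥ threshold, "lost" demands < threshold.

    Raises :class:`CalibrationError` when no candidate satisfies all
    probes, naming the violated conditions.
    """
    from .analysis import contact_fraction
    from .dynamics import run_langevin
    from .params import SimulationConfig

    if config is None:
        config = SimulationConfig(n_steps=20_000, save_interval=200)
    candidates = sorted(float(c) for c in candidates)
    report = []
    chosen = None
    for eps in candidates:
        ok = True
        for p_id, probe in enumerate(probes):
            work = copy.deepcopy(contacts)
            for rec in work.union_set:
                rec.epsilon = eps
            topo = reference_set.topology
            if probe.mutation:
                mut = set(int(b) for b in probe.mutation)
                topo = topo.copy()
                for b in mut:
                    topo.beads[b].charge = -abs(topo.beads[b].charge) \
                        if topo.beads[b].charge != 0 else -1.0
                keep = [rec for rec in work.union_set
                        if rec.bead_i not in mut]
                kept_keys = {(r.bead_i, r.bead_j) for r in keep}
                old = work.union_set
                remap = {}
                for k, rec in enumerate(old):
                    if (rec.bead_i, rec.bead_j) in kept_keys:
                        remap[k] = len(remap)
                work.union_set = keep
                for name in ("cc_specific", "oc_set", "itc_unique"):
                    idx = [remap[int(k)] for k in getattr(work, name)
                           if int(k) in remap]
                    setattr(work, name, np.asarray(idx, dtype=int))
                probe_subset = [remap[int(k)] for k in probe.subset
                                if int(k) in remap]
            else:
                probe_subset = [int(k) for k in probe.subset]
            survs = []
            for seed in seeds:
                cfg = SimulationConfig(**{**config.__dict__, "seed": int(seed)})
                traj = run_langevin(reference_set.coords[probe.state], topo,
                                    work, params, cfg)
                recs = [work.union_set[k] for k in probe_subset]
                if recs:
                    fr = [contact_fraction(frame, recs, formation_factor)
                          for frame in traj.frames]
                    survs.append(float(np.mean(fr)))
                else:
                    survs.append(0.0)  # all probe contacts deleted by mutation
            surv = float(np.mean(survs)) if survs else 0.0
            passed = (surv >= survival_threshold
                      if probe.required == "maintained"
                      else surv < survival_threshold)
            report.append({"epsilon": eps, "probe": p_id,
                           "state": probe.state, "required": probe.required,
                           "survival": surv, "passed": passed})
            ok = ok and passed
        if ok and chosen is None:
            chosen = eps
    if chosen is None:
        failing = sorted({r["probe"] for r in report if not r["passed"]})
        raise CalibrationError(
            f"no candidate epsilon satisfies all probes; failing probe "
            f"indices: {failing}", report)
    return chosen, report


class CalibrationError(RuntimeError):
    def __init__(self, msg, report=None):
        super().__init__(msg)
        self.report = report
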