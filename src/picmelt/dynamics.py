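"""Langevin dynamics and the run protocols operating on topologies.

The integrator is a BAOAB splitting of the Langevin equation: half-kick,
half-drift, Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick.
In the zero-friction limit it reduces to velocity Verlet and conserves
energy to O(dt²); at finite friction the configurational distribution it
samples is accurate to high order in the timestep.  Temperature
protocols (e.g. the 300 K → 1 K quench used to prepare low-fluctuation
structures for export) are expressed as piecewise-linear annealing
schedules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .energy import AssembledSystem, EnergyBreakdown, assemble_system
from .params import KB, EnergyParams, SimulationConfig
from .sequences import COMPLEMENT, PromoterSequence
from .topology import CGTopology, TERM_NAMES


class IntegrationError(RuntimeError):
    """Raised when the energy diverges during integration."""

    def __init__(self, step: int):
        super().__init__(f"energy diverged at integration step {step}")
        self.step = step


@dataclass
class Trajectory:
    """Saved frames with per-frame energy breakdowns.

    ``frames`` has shape (n_frames, n_beads, 3); frame 0 is the initial
    configuration, subsequent frames are saved every
    ``config.save_interval`` steps.
    """

    frames: np.ndarray
    energy_terms: np.ndarray          # (n_frames, N_TERMS)
    kinetic: np.ndarray               # (n_frames,)
    config: SimulationConfig
    n_beads: int = 0
    final_velocities: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.n_beads = self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def seed(self) -> int:
        return self.config.seed

    def breakdown(self, frame: int) -> EnergyBreakdown:
        return EnergyBreakdown.from_array(self.energy_terms[frame])

    def potential_energy(self) -> np.ndarray:
        return self.energy_terms.sum(axis=1)

    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature per frame, K (KE per DOF /
        (k_B/2))."""
        ndof = 3 * self.n_beads
        return 2.0 * self.kinetic / (ndof * KB)

    # ------ export ------------------------------------------------------
    def save_dcd(self, path) -> None:
        """Write frames as a DCD coordinate file."""
        from mdtraj.formats import DCDTrajectoryFile
        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(np.asarray(self.frames, dtype=np.float32))

    def save_energy_tsv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.energy_terms, columns=list(TERM_NAMES))
        df.insert(0, "frame", np.arange(self.n_frames))
        df["kinetic"] = self.kinetic
        df.to_csv(path, sep="\t", index=False)

    def save_restart(self, path) -> None:
        """Write the final coordinates/velocities for run continuation."""
        np.savez(path, coords=self.frames[-1],
                 velocities=self.final_velocities,
                 seed=self.config.seed)

    @staticmethod
    def load_restart(path):
        """Read a restart file -> (coords, velocities)."""
        data = np.load(path)
        return data["coords"], data["velocities"]


def _temperature_schedule(config: SimulationConfig) -> np.ndarray:
    n = config.n_steps
    if config.anneal_schedule is None:
        return np.full(n, float(config.temperature))
    pts = [(int(s), float(t)) for s, t in config.anneal_schedule]
    if pts[0][0] > 0:
        pts.insert(0, (0, pts[0][1]))
    steps = np.arange(n)
    xp = [p[0] for p in pts]
    fp = [p[1] for p in pts]
    return np.interp(steps, xp, fp)


def run_langevin(coords,
                 topology: CGTopology,
                 contacts=None,
                 params: Optional[EnergyParams] = None,
                 config: Optional[SimulationConfig] = None,
                 *,
                 system: Optional[AssembledSystem] = None,
                 velocities: Optional[np.ndarray] = None,
                 energy_limit: float = 1.0e8) -> Trajectory:
    """Propagate the system with BAOAB Langevin dynamics.

    Identical seeds give bit-identical trajectories.  ``system`` may be a
    pre-assembled :class:`AssembledSystem` (e.g. carrying extra position
    restraints); otherwise one is assembled from ``topology`` +
    ``contacts`` + ``params``.
    """
    if config is None:
        config = SimulationConfig()
    config.validate()
    if params is None:
        params = EnergyParams()
    if system is None:
        system = assemble_system(topology, contacts, params)

    x0 = np.ascontiguousarray(coords, dtype=float)
    if x0.shape != (system.n_beads, 3):
        raise ValueError("coordinate shape does not match topology")
    br0, f0 = system.energy_forces(x0)
    if not np.isfinite(br0.total) or not np.all(np.isfinite(f0)):
        raise ValueError("forces are not finite at the initial coordinates")

    tsched = _temperature_schedule(config)
    use_v0 = velocities is not None
    v0 = (np.ascontiguousarray(velocities, dtype=float) if use_v0
          else np.zeros((system.n_beads, 3)))

    frames, eterms, kins, vfin, status = _kernels.run_baoab(
        x0, system.masses, config.timestep, config.friction, tsched,
        config.save_interval, int(config.seed) & 0x7FFFFFFF,
        system.bonds_idx, system.bonds_r0, system.bonds_k, system.bonds_term,
        system.angles_idx, system.angles_t0, system.angles_k, system.angles_term,
        system.dihs_idx, system.dihs_p0, system.dihs_k, system.dihs_term,
        system.pairs_idx, system.pairs_r0, system.pairs_eps, system.pairs_term,
        system.wc_base, system.wc_sugar, system.wc_r0, system.wc_eps,
        system.wc_ti0, system.wc_tj0, system.wc_sig,
        system.sigma, system.eps_ev, system.ev_cap,
        system.charges, system.k_dh, system.lam, system.dh_cut,
        system.excl_ev, system.excl_dh,
        system.res_idx, system.res_ref, system.res_k,
        system.ev_cutoff, 3.5, 60,
        v0, use_v0, energy_limit)
    if status >= 0:
        raise IntegrationError(int(status))
    return Trajectory(frames=frames, energy_terms=eterms, kinetic=kins,
                      config=config, final_velocities=vfin)


def anneal(coords, topology: CGTopology, contacts=None,
           params: Optional[EnergyParams] = None,
           config: Optional[SimulationConfig] = None,
           schedule=None, **kw) -> Trajectory:
    """Annealing run with a piecewise-linear temperature schedule.

    The reference protocol for preparing export structures is a quench
    from 300 K to 1 K over the run followed by an equal-length hold at
    1 K, which damps local fluctuations while preserving the sampled
    conformation.
    """
    if config is None:
        config = SimulationConfig()
    if schedule is not None:
        config = SimulationConfig(**{**config.__dict__,
                                     "anneal_schedule": list(schedule)})
    if config.anneal_schedule is None:
        raise ValueError("anneal requires an anneal_schedule")
    return run_langevin(coords, topology, contacts, params, config, **kw)


def quench_schedule(n_quench: int, n_hold: int,
                    t_start: float = 300.0, t_end: float = 1.0):
    """Schedule for the standard quench protocol: linear t_start → t_end
    over ``n_quench`` steps, then hold at ``t_end`` for ``n_hold``."""
    return [(0, t_start), (n_quench, t_end), (n_quench + n_hold, t_end)]


# ---------------------------------------------------------------------------
# mismatch protocols
# ---------------------------------------------------------------------------

def _template_pair_map(topology: CGTopology) -> dict:
    """Map template-strand residue index -> wc_pair list position."""
    tpl_chains = {cid for cid, role in topology.chain_table.items()
                  if role == "template"}
    out = {}
    for k, p in enumerate(topology.wc_pairs):
        bead = topology.beads[p.base_i]
        if bead.chain_id in tpl_chains:
            out[bead.residue_index] = k
        else:
            bead_j = topology.beads[p.base_j]
            if bead_j.chain_id in tpl_chains:
                out[bead_j.residue_index] = k
    return out


def apply_mismatch(topology: CGTopology, sequence: PromoterSequence,
                   region=None, mismatch_string: Optional[str] = None
                   ) -> CGTopology:
    """Introduce a non-complementary window into the duplex.

    Each non-template base in the window is replaced (by default with the
    identity of the opposing template base, which guarantees
    non-complementarity; an explicit ``mismatch_string`` 5'→3' along the
    template window may be supplied instead) and the corresponding
    Watson–Crick pairing terms are disabled.  Coordinates are untouched —
    melting has to happen dynamically.
    """
    if region is None:
        region = sequence.mismatch_region
    if region is None:
        raise ValueError("no mismatch region given")
    idxs = sequence.interval_indices(*region)
    if not idxs:
        raise ValueError("mismatch region is empty")
    pair_map = _template_pair_map(topology)
    missing = [i for i in idxs if i not in pair_map]
    if missing:
        raise ValueError(f"mismatch region outside the DNA: indices {missing}")
    if mismatch_string is not None and len(mismatch_string) != len(idxs):
        raise ValueError("mismatch_string length does not match the region")

    out = topology.copy()
    backup = {}
    for w, i in enumerate(idxs):
        k = pair_map[i]
        p = out.wc_pairs[k]
        tpl_bead = out.beads[p.base_i]
        nt_pos = p.base_j
        if tpl_bead.chain_id not in {c for c, r in out.chain_table.items()
                                     if r == "template"}:
            tpl_bead = out.beads[p.base_j]
            nt_pos = p.base_i
        nt_bead = out.beads[nt_pos]
        backup[k] = (nt_pos, nt_bead.identity, p.enabled)
        new_base = (mismatch_string[w] if mismatch_string is not None
                    else tpl_bead.identity)
        if COMPLEMENT[new_base] == tpl_bead.identity:
            raise ValueError(
                f"mismatch base {new_base} at window position {w} is "
                "complementary to the template")
        nt_bead.identity = new_base
        p.enabled = False
    out.mismatch_backup = backup
    return out


def revert_mismatch(topology: CGTopology,
                    sequence: PromoterSequence) -> CGTopology:
    """Restore the original base identities and re-enable pairing in the
    mismatch window.  Coordinates are untouched: re-pairing must occur
    dynamically in a subsequent run.  Idempotent; warns if no mismatch is
    present."""
    if topology.mismatch_backup is None:
        warnings.warn("revert_mismatch: topology carries no mismatch",
                      stacklevel=2)
        return topology.copy()
    out = topology.copy()
    for k, (nt_pos, identity, enabled) in out.mismatch_backup.items():
        out.beads[nt_pos].identity = identity
        out.wc_pairs[k].enabled = enabled
    out.mismatch_backup = None
    return out
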