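"""End-to-end run protocols on the toy pre-initiation complex.

Two composite protocols mirror the promoter-opening pathway:

* CC→OC: introduce a mismatch window into the closed-complex duplex,
  run until the complex pauses in a pre-OC/OC-like state, revert the
  sequence to fully complementary, and follow the partial re-pairing of
  the bubble.

* OC→ITC: equilibrium runs from the OC-like pose, optionally with the
  E-wing-analog contacts weakened or with the gate flap restrained shut;
  terminal states, gate-opening events and intermediate dwells are
  extracted from the trajectories.

All randomness is seed-derived; a manifest re-run with the same seeds
reproduces its outputs bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__ as _pkg_version
from .analysis import (AnalysisParams, assign_state, bubble_trace,
                       estimate_gate_open_distance, gate_distance_series,
                       state_fractions)
from .contacts import ContactSets, weaken_contacts
from .dynamics import apply_mismatch, revert_mismatch, run_langevin
from .energy import assemble_system
from .params import EnergyParams, SimulationConfig
from .synthetic import ToyPIC

SCAFFOLD_RESTRAINT_K = 2.0   # kcal/mol/Å^2, holds the clamp scaffold
GATE_RESTRAINT_K = 10.0      # kcal/mol/Å^2, pins the flap shut

# a mismatch window counts as melted when the late-time mean bubble
# reaches this fraction of the window (the window-edge pairs breathe,
# so the full window is never continuously broken)
MELT_FRACTION = 0.75

# protocol-default Langevin friction, 1/τ: transport-limited stages use
# lower friction than the generic default purely for sampling efficiency
MELT_FRICTION = 0.1
THREADING_FRICTION = 0.05


@dataclass
class RunManifest:
    protocol: str
    seeds: List[int]
    config: dict
    version: str = _pkg_version
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


@dataclass
class EnsembleSummary:
    n_runs: int
    terminal_labels: List[str]
    transition_counts: Dict[str, int]
    bubble_mean_sd: Dict[str, tuple] = field(default_factory=dict)
    diverged: List[int] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if sum(self.transition_counts.values()) != self.n_runs:
            raise ValueError("transition counts do not sum to n_runs")


def toy_system(pic: ToyPIC, contacts: Optional[ContactSets] = None,
               params: Optional[EnergyParams] = None,
               restrain_scaffold: bool = True,
               restrain_gate: bool = False,
               state: str = "CC"):
    """Assemble the toy PIC for simulation.

    The clamp scaffold (every protein bead except the gate flap) is held
    by weak position restraints at its reference coordinates — the toy
    clamp stands in for the bulk of a large rigid complex, and pinning
    it keeps the reference poses meaningful in the laboratory frame.
    ``restrain_gate`` additionally pins the flap, the "gate shut"
    control.
    """
    if contacts is None:
        contacts = pic.contact_sets
    if params is None:
        params = EnergyParams()
    system = assemble_system(pic.topology, contacts, params)
    ref = pic.reference_set.coords[state]
    if restrain_scaffold:
        ids = pic.scaffold_bead_ids
        system.add_restraints(ids, ref[ids], SCAFFOLD_RESTRAINT_K)
    if restrain_gate:
        ids = pic.flap_bead_ids
        system.add_restraints(ids, pic.reference_set.coords["CC"][ids],
                              GATE_RESTRAINT_K)
    return system


def _seeds(seeds, n_runs, base=0):
    if seeds is not None:
        seeds = [int(s) for s in seeds]
        if len(seeds) != n_runs:
            raise ValueError("need one seed per run")
        return seeds
    return [int(base) + 7919 * k for k in range(n_runs)]


def _terminal_label(labels: Sequence[str], tail_fraction=0.1) -> str:
    tail = labels[-max(1, int(len(labels) * tail_fraction)):]
    vals, counts = np.unique(tail, return_counts=True)
    return str(vals[np.argmax(counts)])


def _label_run(frames, pic, contacts, aparams: AnalysisParams):
    from .analysis import contact_fraction
    trace = state_fractions(frames, contacts, aparams.formation_factor)
    ew = [contacts.union_set[int(k)] for k in pic.ewing_subset]
    if ew:
        trace.ewing_formed = np.array(
            [contact_fraction(f, ew, aparams.formation_factor) >= 0.5
             for f in frames])
    gd = gate_distance_series(frames, pic.gate_groups)
    cutoff = (aparams.gate_open_distance
              if aparams.gate_open_distance is not None
              else estimate_gate_open_distance(gd))
    trace.gate_open = gd > cutoff
    labels = assign_state(trace, aparams)
    return trace, labels, gd


def protocol_cc_to_oc(pic: ToyPIC, n_runs: int = 10,
                      steps_melt: int = 60_000,
                      steps_revert: int = 60_000,
                      seeds: Optional[Sequence[int]] = None,
                      params: Optional[EnergyParams] = None,
                      aparams: Optional[AnalysisParams] = None,
                      config: Optional[SimulationConfig] = None,
                      pause_dwell_fraction: float = 0.1):
    """Mismatch-melt runs from the CC pose followed by sequence revert.

    Per run: apply the mismatch window → Langevin run of ``steps_melt``
    → (pause detection: the assigned label must be stable over the dwell
    window; in the desk-scale toy the revert is triggered at the end of
    the melt stage regardless, with the dwell recorded) → revert the
    sequence → run ``steps_revert`` more.  Returns (EnsembleSummary,
    per-run trajectory dict).
    """
    if params is None:
        params = EnergyParams()
    if aparams is None:
        aparams = AnalysisParams()
    if config is None:
        config = SimulationConfig(save_interval=500,
                                  friction=MELT_FRICTION)
    seeds = _seeds(seeds, n_runs, base=config.seed)
    window = pic.sequence.mismatch_region
    n_window = len(pic.sequence.mismatch_positions())

    topo_mm = apply_mismatch(pic.topology, pic.sequence, window)
    topo_rev = revert_mismatch(topo_mm, pic.sequence)

    sys_mm = toy_system_with_topology(pic, topo_mm, params)
    sys_rev = toy_system_with_topology(pic, topo_rev, params)

    labels_final, runs, diverged = [], {}, []
    melted_flags, bubble_post = [], []
    wc_window = [pic.sequence.mismatch_positions()]
    win_idx = wc_window[0]
    for k, seed in enumerate(seeds):
        cfg1 = SimulationConfig(**{**config.__dict__, "seed": seed,
                                   "n_steps": steps_melt})
        try:
            t1 = run_langevin(pic.reference_set.coords["CC"], topo_mm,
                              pic.contact_sets, params, cfg1, system=sys_mm)
        except Exception:
            diverged.append(k)
            continue
        bt1 = bubble_trace(t1.frames, topo_mm, aparams.break_threshold,
                           window=win_idx)
        melt_tail = bt1.counts[-max(1, len(bt1.counts) // 4):]
        melted = float(np.mean(melt_tail)) >= MELT_FRACTION * n_window
        melted_flags.append(bool(melted))

        _, labels1, _ = _label_run(t1.frames, pic, pic.contact_sets, aparams)
        dwell = max(1, int(len(labels1) * pause_dwell_fraction))
        paused = len(set(labels1[-dwell:])) == 1

        cfg2 = SimulationConfig(**{**config.__dict__, "seed": seed + 1,
                                   "n_steps": steps_revert})
        try:
            t2 = run_langevin(t1.frames[-1], topo_rev, pic.contact_sets,
                              params, cfg2, system=sys_rev,
                              velocities=t1.final_velocities)
        except Exception:
            diverged.append(k)
            continue
        bt2 = bubble_trace(t2.frames, topo_rev, aparams.break_threshold,
                           window=win_idx)
        post = bt2.counts[-max(1, len(bt2.counts) // 4):]
        bubble_post.append((float(np.mean(post)), float(np.std(post))))
        _, labels2, _ = _label_run(t2.frames, pic, pic.contact_sets, aparams)
        labels_final.append(labels2[-1] if labels2 else "unassigned")
        runs[k] = {"melt": t1, "revert": t2, "paused": paused,
                   "bubble_melt": bt1, "bubble_revert": bt2,
                   "labels_melt": labels1, "labels_revert": labels2}

    counts: Dict[str, int] = {}
    for lab in labels_final:
        counts[lab] = counts.get(lab, 0) + 1
    for k in diverged:
        counts["diverged"] = counts.get("diverged", 0) + 1
    summary = EnsembleSummary(
        n_runs=len(seeds), terminal_labels=labels_final,
        transition_counts=counts, diverged=diverged,
        extra={
            "melted_runs": int(sum(melted_flags)),
            "n_window": n_window,
            "mean_bubble_melt": float(np.mean(
                [np.mean(r["bubble_melt"].counts[-len(r["bubble_melt"].counts)//4:])
                 for r in runs.values()])) if runs else float("nan"),
            "mean_bubble_post_revert": float(np.mean(
                [b[0] for b in bubble_post])) if bubble_post else float("nan"),
        })
    summary.validate()
    return summary, runs


def toy_system_with_topology(pic: ToyPIC, topology, params,
                             restrain_gate: bool = False):
    """Assemble a (possibly mismatch-modified) topology with the toy
    scaffold restraints."""
    system = assemble_system(topology, pic.contact_sets, params)
    ref = pic.reference_set.coords["CC"]
    ids = pic.scaffold_bead_ids
    system.add_restraints(ids, ref[ids], SCAFFOLD_RESTRAINT_K)
    if restrain_gate:
        fids = pic.flap_bead_ids
        system.add_restraints(fids, ref[fids], GATE_RESTRAINT_K)
    return system


def protocol_oc_to_itc(pic: ToyPIC, n_runs: int = 10,
                       steps: int = 100_000,
                       weaken: Optional[float] = None,
                       restrain_gate: bool = False,
                       seeds: Optional[Sequence[int]] = None,
                       params: Optional[EnergyParams] = None,
                       aparams: Optional[AnalysisParams] = None,
                       config: Optional[SimulationConfig] = None):
    """Equilibrium runs from the OC-like pose toward the threaded
    (ITC-like) pose.

    ``weaken`` scales the E-wing-analog contacts (OC-only set) by the
    given factor before the runs; ``restrain_gate`` pins the gate flap
    at its closed reference position.  Gate-opening events and
    intermediate (I1/I2) dwell fractions are extracted per run.
    """
    if params is None:
        params = EnergyParams()
    if aparams is None:
        aparams = AnalysisParams()
    if config is None:
        config = SimulationConfig(save_interval=500,
                                  friction=THREADING_FRICTION)
    seeds = _seeds(seeds, n_runs, base=config.seed)

    contacts = pic.contact_sets
    if weaken is not None:
        contacts = weaken_contacts(contacts, pic.ewing_subset, weaken)
    system = assemble_system(pic.topology, contacts, params)
    ref = pic.reference_set.coords
    ids = pic.scaffold_bead_ids
    system.add_restraints(ids, ref["CC"][ids], SCAFFOLD_RESTRAINT_K)
    if restrain_gate:
        fids = pic.flap_bead_ids
        system.add_restraints(fids, ref["CC"][fids], GATE_RESTRAINT_K)

    labels_final, runs, diverged = [], {}, []
    for k, seed in enumerate(seeds):
        cfg = SimulationConfig(**{**config.__dict__, "seed": seed,
                                  "n_steps": steps})
        try:
            traj = run_langevin(ref["OC"], pic.topology, contacts, params,
                                cfg, system=system)
        except Exception:
            diverged.append(k)
            continue
        trace, labels, gd = _label_run(traj.frames, pic, contacts, aparams)
        labels_final.append(_terminal_label(labels))
        runs[k] = {"trajectory": traj, "labels": labels,
                   "gate_distance": gd, "trace": trace,
                   "i2_dwell": float(np.mean([l == "I2" for l in labels])),
                   "gate_open_fraction": float(np.mean(trace.gate_open))}

    counts: Dict[str, int] = {}
    for lab in labels_final:
        counts[lab] = counts.get(lab, 0) + 1
    for k in diverged:
        counts["diverged"] = counts.get("diverged", 0) + 1
    n_itc = counts.get("ITC", 0)
    summary = EnsembleSummary(
        n_runs=len(seeds), terminal_labels=labels_final,
        transition_counts=counts, diverged=diverged,
        extra={"reached_itc": n_itc,
               "weaken": weaken, "restrain_gate": restrain_gate,
               "mean_i2_dwell": float(np.mean(
                   [r["i2_dwell"] for r in runs.values()])) if runs else 0.0})
    summary.validate()
    return summary, runs


def report(summary: EnsembleSummary, runs: dict, outdir,
           make_plots: bool = True) -> dict:
    """Write a machine-readable summary (JSON) and, optionally, per-run
    diagnostic plots.  Idempotent: re-running overwrites identical
    content for identical inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_runs": summary.n_runs,
        "terminal_labels": summary.terminal_labels,
        "transition_counts": summary.transition_counts,
        "diverged": summary.diverged,
        "extra": summary.extra,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    if make_plots and runs:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from .analysis import moving_average
        fig, axes = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
        for k, r in runs.items():
            if "trace" in r:
                axes[0].plot(r["trace"].f_itc, alpha=0.6, lw=0.8)
                axes[1].plot(r["gate_distance"], alpha=0.4, lw=0.8)
                if len(r["gate_distance"]) >= 11:
                    axes[1].plot(moving_average(r["gate_distance"], 11),
                                 lw=1.2)
            elif "bubble_melt" in r:
                n1 = len(r["bubble_melt"].counts)
                axes[0].plot(np.arange(n1), r["bubble_melt"].counts,
                             alpha=0.6, lw=0.8)
                axes[0].plot(n1 + np.arange(len(r["bubble_revert"].counts)),
                             r["bubble_revert"].counts, alpha=0.6, lw=0.8)
        axes[0].set_ylabel("f_ITC / bubble (bp)")
        axes[1].set_ylabel("gate distance (Å)")
        axes[1].set_xlabel("frame")
        fig.tight_layout()
        fig.savefig(outdir / "traces.png", dpi=120)
        plt.close(fig)
    return payload
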