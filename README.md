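# picmelt

Coarse-grained simulation and analysis of promoter DNA opening in RNA
polymerase II pre-initiation complexes (PICs).

During transcription initiation the promoter duplex inside the PIC
melts: the closed complex (CC, intact duplex) becomes the open complex
(OC, a small ~6-bp bubble with the template strand near the active
site) and then the initially transcribing complex (ITC, a ~13-bp bubble
with RNA synthesis begun).  `picmelt` provides, for structural
biologists and modelers of protein–DNA machines, the full simulation
and analysis machinery to study this process at residue resolution:

* a Cα / three-site-per-nucleotide coarse-grained energy model with a
  structure-based protein–DNA contact potential
  U(r) = ε_go [5 (r⁰/r)¹² − 6 (r⁰/r)¹⁰] (ε_go = 1.2 kcal/mol),
  a simplified 3SPN-style DNA model with orientation-gated Watson–Crick
  pairing, excluded volume, and Debye–Hückel electrostatics (200 mM,
  300 K by default);
* BAOAB Langevin dynamics with mismatch-melt, sequence-revert and
  temperature-quench protocols;
* the trajectory statistics of promoter opening: DNA-bubble size
  (base–base distance > 6.2 Å, a threshold calibrated so an intact
  duplex exceeds it only ~0.3% of the time), per-state native-contact
  fractions f_CC / f_OC / f_ITC, discrete state assignment
  (CC / pre-OC / OC / I1 / I2 / ITC), and the fork-loop gate distance;
* a synthetic three-state toy PIC (a clamp scaffold with a melting
  window, an E-wing-analog tether and a gate loop) so that every
  pipeline stage is testable without downloading structures.

## Worked example

Build an ideal 20-bp duplex, run equilibrium Langevin dynamics at
300 K / 200 mM, and measure the base-pair opening statistics:

```python
import picmelt as pm

topo, coords = pm.build_bdna("ACGTACGTACGTACGTACGT")
cfg = pm.SimulationConfig(n_steps=200_000, save_interval=200, seed=1)
traj = pm.run_langevin(coords, topo, None, pm.EnergyParams(), cfg)

frames = traj.frames[traj.n_frames // 5:]          # discard equilibration
trace = pm.bubble_trace(frames, topo, break_threshold=6.2)
print(f"break rate : {100 * trace.break_rate:.2f} %")
print(f"mean bubble: {trace.counts.mean():.2f} bp")
print(f"kinetic T  : {traj.kinetic_temperature()[-100:].mean():.0f} K")
```

```
break rate : 0.44 %
mean bubble: 0.09 bp
kinetic T  : 299 K
```

The break rate is the fraction of (frame, pair) events whose base–base
distance exceeds 6.2 Å — for an intact duplex this is the ~0.3%-level
false-positive rate of the bubble criterion, so the mean "bubble" of a
healthy duplex is a fraction of a base pair, and the kinetic
temperature sits at the thermostat setpoint (within the ~1% integrator
bias at the default timestep).

The three-state toy system and the opening protocols:

```python
from picmelt import protocols as pr

pic = pm.build_toy_pic(seed=0)
summary, runs = pr.protocol_cc_to_oc(pic, n_runs=3, steps_melt=50_000,
                                     steps_revert=50_000)
print(summary.extra["melted_runs"], "of 3 runs melted the 15-bp window")
print(f"bubble before/after revert: "
      f"{summary.extra['mean_bubble_melt']:.1f} / "
      f"{summary.extra['mean_bubble_post_revert']:.1f} bp")
```

```
3 of 3 runs melted the 15-bp window
bubble before/after revert: 12.1 / 0.0 bp
```

With the mismatch in place the window melts to ~12 of its 15 pairs (the
edge pairs keep breathing); after the sequence is reverted the bubble
re-anneals completely in this short toy run, mirroring the partial
re-pairing seen after reverting a mismatch-opened promoter.

A command-line interface mirrors the library:

```bash
picmelt prepare --seed 0 --outdir prepared     # toy poses + contact TSV
picmelt simulate --protocol oc-to-itc --n-runs 10 --weaken 0.0
picmelt analyze runs/equilibrium.dcd --out per_frame.tsv
```

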