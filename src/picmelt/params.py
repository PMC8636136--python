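"""Force-field, simulation and analysis parameter containers.

Units used throughout the package: lengths in Å, energies in kcal/mol,
temperatures in K, charges in elementary charges, time in the reduced
Langevin time unit τ (masses in amu-like units so that a Cα–Cα bond
vibrates with a period of a few τ).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Coulomb constant e^2/(4 pi eps0), kcal·Å/mol/e^2 (vacuum).
COULOMB = 332.0637


@dataclass
class DNAParams:
    """Bonded and base-interaction constants of the simplified 3SPN-style
    DNA model.

    The Watson–Crick pairing depth ``eps_bp_gc`` is the single calibration
    knob of the DNA model: it is tuned (see
    :func:`picmelt.analysis.calibrate_break_threshold` and the duplex
    break-rate calibration in the docs) so that a free duplex at 300 K and
    200 mM salt shows a per-pair opening rate of ~0.3% under the 6.2 Å
    base–base distance criterion.  A·T pairs use ``at_gc_ratio`` times the
    G·C depth (two vs three hydrogen bonds).
    """

    k_bond: float = 60.0           # kcal/mol/Å^2, backbone harmonic bonds
    k_angle: float = 12.0          # kcal/mol/rad^2
    k_dihedral: float = 1.0        # kcal/mol, periodic native-biased
    eps_stack: float = 5.0         # kcal/mol, intra-strand base stacking well
    eps_bp_gc: float = 7.5         # kcal/mol, G·C pairing depth (calibrated)
    at_gc_ratio: float = 2.0 / 3.0  # A·T depth relative to G·C
    bp_angle_width: float = 0.45   # rad, width of the pairing angular gate
    eps_mismatch: float = 4.0      # kcal/mol, steric repulsion amplitude of
                                   # a non-complementary (mismatched) pair


@dataclass
class ProteinParams:
    """AICG2+-inspired Cα Go-model constants (simplified local terms)."""

    k_bond: float = 100.0     # kcal/mol/Å^2
    k_angle: float = 20.0     # kcal/mol/rad^2
    k_dihedral: float = 1.0   # kcal/mol
    eps_intra: float = 0.8    # kcal/mol, intra-protein native contact depth
    contact_cutoff: float = 8.0  # Å, Cα–Cα native-contact detection


@dataclass
class EnergyParams:
    """All force-field constants of the CG energy function."""

    eps_go: float = 1.2            # kcal/mol, protein–DNA Go contact depth
    salt_mM: float = 200.0         # monovalent salt concentration
    temperature: float = 300.0     # K (reference T for DH screening)
    dielectric: float = 78.0       # relative permittivity
    dh_cutoff: float = 21.0        # Å (>= 3 Debye lengths at 200 mM)
    eps_ev: float = 0.2            # kcal/mol, excluded-volume prefactor
    ev_radii: dict = field(default_factory=lambda: {
        "CA": 2.2, "P": 2.0, "S": 2.2, "B": 2.5})
    ev_cap: float = 100.0          # kcal/mol, repulsion cap near r=0
    phosphate_charge: float = -0.6  # e, counterion-condensation convention
    dna: DNAParams = field(default_factory=DNAParams)
    protein: ProteinParams = field(default_factory=ProteinParams)
    contact_cutoff: float = 6.5    # Å, heavy-atom protein–DNA contact detection

    def debye_length(self) -> float:
        """Debye screening length in Å for the configured salt/T/εr."""
        # λ_D = sqrt(εr ε0 kB T / (2 NA e^2 I)); in convenient units this is
        # λ_D = sqrt(εr kB T / (8 π COULOMB_vac I_Å)) with I in beads/Å^3.
        ionic_m = self.salt_mM / 1000.0  # mol/L
        # number density of ions, Å^-3: I[M] * NA / 1e27
        rho = ionic_m * 6.02214076e-4  # = NA/1e27 * I
        lam2 = self.dielectric * KB * self.temperature / (
            4.0 * 3.141592653589793 * COULOMB * 2.0 * rho)
        return lam2 ** 0.5

    def bjerrum_length(self) -> float:
        """Bjerrum length in Å."""
        return COULOMB / (self.dielectric * KB * self.temperature)


@dataclass
class SimulationConfig:
    """Langevin run configuration.

    ``anneal_schedule`` is a list of (step, temperature) pairs; temperature
    is linearly interpolated between points and held constant after the
    last one.  If absent the run is isothermal at ``temperature``.
    """

    timestep: float = 0.2          # reduced time units
    friction: float = 0.25         # 1/τ
    temperature: float = 300.0     # K
    n_steps: int = 100_000
    seed: int = 0
    save_interval: int = 100       # steps between saved frames
    anneal_schedule: Optional[list] = None

    def validate(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        if self.save_interval <= 0:
            raise ValueError("save_interval must be positive")
        if self.anneal_schedule is not None:
            steps = [s for s, _ in self.anneal_schedule]
            temps = [t for _, t in self.anneal_schedule]
            if any(t < 0 for t in temps):
                raise ValueError("schedule temperatures must be >= 0")
            if steps != sorted(steps):
                raise ValueError("schedule must be step-ordered")


@dataclass
class AnalysisParams:
    """Trajectory-statistics parameters.

    ``break_threshold`` is the base–base CG distance beyond which a
    Watson–Crick pair counts as broken (default 6.2 Å, calibrated to a
    ~0.3% false-positive rate on an intact duplex).  ``ma_window`` is the
    centered moving-average window used for plotted time series.
    """

    break_threshold: float = 6.2   # Å
    ma_window: int = 11            # frames, must be odd
    formation_factor: float = 1.2  # contact formed if r <= factor * r0
    # state-assignment fraction cutoffs
    f_cc_high: float = 0.6
    f_cc_low: float = 0.3
    f_oc_mid: float = 0.25
    f_oc_high: float = 0.7
    f_itc_mid: float = 0.25
    f_itc_high: float = 0.7
    gate_open_distance: Optional[float] = None  # Å; None → estimate from data

    def validate(self) -> None:
        if self.break_threshold <= 0:
            raise ValueError("break_threshold must be positive")
        if self.ma_window % 2 == 0:
            raise ValueError("ma_window must be odd")


def _to_dict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_dict(v) for k, v in dataclasses.asdict(obj).items()}
    return obj


def save_params(params, path) -> None:
    """Write any parameter dataclass to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_dict(params), fh, sort_keys=False)


def load_energy_params(path) -> EnergyParams:
    """Read an :class:`EnergyParams` from YAML, filling defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    dna = DNAParams(**raw.pop("dna", {}))
    protein = ProteinParams(**raw.pop("protein", {}))
    return EnergyParams(dna=dna, protein=protein, **raw)
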