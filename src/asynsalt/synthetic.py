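"""Synthetic plate-reader data and small MC test systems.

No deposited dataset accompanies the salt-series experiments, so everything
the analysis pipeline consumes is generated here with a known ground truth:

* seeded ThT plates whose underlying k2*k_plus product decays log-linearly
  with NaCl concentration and whose wells at or above an inhibition threshold
  stay flat for the whole experiment horizon;
* per-well baseline/amplitude variation plus multiplicative and additive
  Gaussian noise resembling plate-reader traces;
* configuration files for the constant-pH MC systems (full 208-tail system,
  a 32-tail desk preset at the same grafting density, and single-site /
  non-interacting oracle micro-systems).

Every generated dataset ships its truth table; recovery tests compare
against that, never against hard-coded numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticParams, closed_form_mass

__all__ = [
    "Condition",
    "NoiseModel",
    "PlateSpec",
    "DEFAULT_SALTS_MM",
    "make_salt_series",
    "simulate_plate",
    "make_mc_fixtures",
]

#: NaCl series of the seeded experiments (mM).
DEFAULT_SALTS_MM: tuple[float, ...] = (0, 20, 40, 80, 120, 200, 500, 1200)
#: Seed concentrations in monomer equivalents (µM).
DEFAULT_SEEDS_UM: tuple[float, ...] = (0.005, 0.05)


@dataclass(frozen=True)
class Condition:
    monomer_uM: float
    seed_uM: float
    salt_mM: float
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 3:
            raise ValueError("at least three replicates per condition")


@dataclass(frozen=True)
class NoiseModel:
    """Plate-reader noise: F = baseline + amplitude*M_frac*(1+eps_m) + eps_a."""

    multiplicative_sd: float = 0.01
    additive_sd_frac: float = 0.005  # fraction of amplitude
    baseline: float = 100.0  # a.u.
    amplitude: float = 900.0  # a.u.
    well_variation: float = 0.05  # relative spread of baseline/amplitude


@dataclass
class PlateSpec:
    conditions: list[Condition]
    true_params: dict[tuple[float, float], KineticParams]  # (seed_uM, salt_mM)
    noise: NoiseModel = field(default_factory=NoiseModel)
    t_end: float = 64.0  # h
    dt: float = 0.25  # h
    rng_seed: int = 0

    @property
    def t_grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.dt, self.dt)


def make_salt_series(
    base_k2kplus: float = 1e17,
    decay_log10_per_mM: float = 0.015,
    salts_mM: Sequence[float] = DEFAULT_SALTS_MM,
    inhibition_threshold_mM: float = 200.0,
    monomer_uM: float = 5.0,
    seeds_uM: Sequence[float] = DEFAULT_SEEDS_UM,
    n_replicates: int = 3,
    seed_length: float = 500.0,
    n_2: float = 2.0,
    noise: NoiseModel | None = None,
    rng_seed: int = 0,
) -> PlateSpec:
    """Seeded salt-series plate specification.

    The true k2*k_plus product decays log-linearly with salt below the
    inhibition threshold; at or above it the secondary-nucleation rate is
    zeroed so the wells stay flat (fibril formation completely inhibited over
    the experiment horizon).  Defaults mirror the seeded experiments: 5 µM
    monomer, seeds at 0.005 and 0.05 µM monomer equivalents, salts from 0 to
    1,200 mM, at least three replicates.

    ``base_k2kplus`` is in M^(-n2-1) h^-2; internally the elongation rate is
    pinned to 1 (only the product and k_plus*P0 are identifiable), so
    k_2 = k2kplus numerically.
    """
    if decay_log10_per_mM < 0:
        raise ValueError("decay must be >= 0")
    conditions: list[Condition] = []
    true_params: dict[tuple[float, float], KineticParams] = {}
    m0 = monomer_uM * 1e-6
    for seed_uM in seeds_uM:
        M0 = seed_uM * 1e-6
        P0 = M0 / seed_length
        for salt in salts_mM:
            conditions.append(Condition(monomer_uM, seed_uM, salt, n_replicates))
            if salt >= inhibition_threshold_mM:
                k2 = 0.0
                M0_c, P0_c = (M0, P0) if M0 > 0 else (0.0, 0.0)
            else:
                k2 = base_k2kplus * 10.0 ** (-decay_log10_per_mM * salt)
                M0_c, P0_c = M0, P0
            true_params[(seed_uM, salt)] = KineticParams(
                k_n=0.0, k_2=k2, k_plus=1.0, n_c=2.0, n_2=n_2,
                m0=m0, M0=M0_c, P0=P0_c,
            )
    return PlateSpec(
        conditions=conditions,
        true_params=true_params,
        noise=noise or NoiseModel(),
        rng_seed=rng_seed,
    )


def simulate_plate(
    spec: PlateSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a plate: returns (plate, metadata, truth) tables.

    * plate — wide format: ``time_h`` column plus one fluorescence column per
      well (a.u.);
    * metadata — one row per well: monomer_uM, seed_uM, salt_mM, replicate;
    * truth — one row per condition with every generating parameter,
      including the per-well baselines/amplitudes actually drawn.

    Noise model: F = b_w + a_w * M_frac(t) * (1 + eps_mult) + eps_add with
    iid Gaussian eps; per-well baseline b_w and amplitude a_w are drawn once
    per well around the configured values.  Fixed ``rng_seed`` makes the
    plate bit-reproducible.
    """
    rng = np.random.default_rng(spec.rng_seed)
    t = spec.t_grid
    noise = spec.noise
    plate: dict[str, np.ndarray] = {"time_h": t}
    meta_rows = []
    truth_rows = []
    well_no = 0
    for cond in spec.conditions:
        key = (cond.seed_uM, cond.salt_mM)
        p = spec.true_params[key]
        m_frac = closed_form_mass(p, t).M_frac
        # seeds contribute ThT signal from t=0; report the fibril mass curve
        for rep in range(1, cond.n_replicates + 1):
            well_no += 1
            well = f"W{well_no:03d}"
            b = noise.baseline * (1 + noise.well_variation * rng.standard_normal())
            a = noise.amplitude * (1 + noise.well_variation * rng.standard_normal())
            eps_m = noise.multiplicative_sd * rng.standard_normal(len(t))
            eps_a = noise.additive_sd_frac * a * rng.standard_normal(len(t))
            plate[well] = b + a * m_frac * (1 + eps_m) + eps_a
            meta_rows.append(
                dict(well=well, monomer_uM=cond.monomer_uM, seed_uM=cond.seed_uM,
                     salt_mM=cond.salt_mM, replicate=rep)
            )
            truth_rows.append(
                dict(well=well, seed_uM=cond.seed_uM, salt_mM=cond.salt_mM,
                     replicate=rep, k2kplus=p.k_2 * p.k_plus, k_plus=p.k_plus,
                     n_2=p.n_2, n_c=p.n_c, m0_M=p.m0, M0_M=p.M0, P0_M=p.P0,
                     baseline=b, amplitude=a,
                     aggregating=p.k_2 > 0)
            )
    return (
        pd.DataFrame(plate),
        pd.DataFrame(meta_rows),
        pd.DataFrame(truth_rows),
    )


_MC_COMMON = {
    "area_per_tail_A2": 1200.0,
    "pH": 5.5,
    "temperature_K": 300.0,
    "bjerrum_A": 7.0,
    "eps_lj": 0.05,
    "sigma_A": 4.0,
    "bond_req_A": 4.1,
    "bond_k": 0.76,
}


def make_mc_fixtures(out_dir: str | Path, seed: int = 0) -> list[Path]:
    """Write plain-text key=value configs for the MC systems.

    Emits the full 208-tail system, the 32-tail desk preset at the same
    1/1,200 Å^-2 grafting density, and two oracle micro-systems (a single
    titratable bead for the Henderson-Hasselbalch check and a single
    non-interacting bead for the ideal-gas check).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(name: str, extra: dict) -> None:
        cfg = dict(_MC_COMMON)
        cfg.update(extra)
        cfg["rng_seed"] = seed
        lines = [f"{k} = {v}" for k, v in cfg.items()]
        path = out / name
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    # the free chain needs ~1,500 sweeps to finish burrowing into the brush
    # at 20 mM, hence the long equilibration
    for name, n_tails in (("mc_full.cfg", 208), ("mc_desk.cfg", 32)):
        write(name, {
            "system": "slit",
            "n_grafted": n_tails,
            "tail_sequence": "packaged:asyn_ctail",
            "free_sequence": "packaged:asyn",
            "c_salt_M": 0.02,
            "n_equil_sweeps": 1600,
            "n_prod_sweeps": 2400,
            "sample_every": 2,
            "n_runs": 2,
            "elec_cutoff": "auto",
        })
    write("mc_oracle_titration.cfg", {
        "system": "single_titratable_bead",
        "residue": "E",
        "c_salt_M": 0.15,
        "n_equil_sweeps": 100,
        "n_prod_sweeps": 2000,
        "sample_every": 1,
        "n_runs": 1,
    })
    write("mc_oracle_ideal.cfg", {
        "system": "single_free_bead",
        "c_salt_M": 0.15,
        "n_equil_sweeps": 100,
        "n_prod_sweeps": 2000,
        "sample_every": 1,
        "n_runs": 1,
    })
    return written
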