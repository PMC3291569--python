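"""Forward simulation of everything the analysis pipeline consumes.

Generates steady-state exponentially growing populations with multifork
replication from known ground-truth (tau, C, D), then derives the synthetic
measurements each analysis stage reads: replication run-out DNA histograms
with multiplicative Gaussian fluorescence noise, log-normally varying cell
sizes growing exponentially within the cycle, and long-format qPCR tables
whose Cq values are consistent with the declared amplification efficiencies
plus Gaussian cycle noise.  Every generator is bit-reproducible given the
config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import CellCycleParams, ori_ter_ratio, state_at_age
from .runout import RunoutHistogram

__all__ = [
    "SimulationConfig",
    "sample_ages",
    "simulate_population",
    "simulate_runout_histogram",
    "simulate_qpcr",
    "config_to_dict",
    "config_from_dict",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and noise levels for one simulated experiment.

    Defaults mirror a fast-growing wild-type culture in rich medium:
    tau ≈ 24 min with C ≈ 44 min and D ≈ 24 min (overlapping rounds,
    (C+D)/tau ≈ 2.8, run-out classes at 4 and 8 chromosomes), ~6% flow
    fluorescence CV, newborn area ~3 µm² with 10% birth-size CV, and 0.05
    cycles of qPCR Cq noise.
    """

    params: CellCycleParams
    n_cells: int = 20_000
    fluorescence_cv: float = 0.06
    fluorescence_unit: float = 1.0
    size_birth_mean: float = 3.0
    size_birth_cv: float = 0.10
    cq_sd: float = 0.05
    eff_ori: float = 2.0
    eff_ter: float = 2.0
    n_biological: int = 3
    n_technical: int = 3
    dnaa_concentration: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("fluorescence_cv", "size_birth_cv", "cq_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fluorescence_unit <= 0 or self.size_birth_mean <= 0:
            raise ValueError("fluorescence_unit and size_birth_mean must be positive")
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate counts must be >= 1")


def sample_ages(n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. cell ages from the steady-state distribution.

    Inverse-CDF sampling: ``a = -log2(1 - u/2)`` with ``u`` uniform on
    [0, 1), the exact inverse of ``age_cdf``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    u = np.random.default_rng(seed).random(n)
    return -np.log2(1.0 - u / 2.0)


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Per-cell table of a steady-state population.

    Columns: ``age, size, origins, fork_pairs, genome_equivalents,
    dnaa_molecules``.  Size grows exponentially within the cycle
    (``birth_size · 2^age``) with log-normal birth-size variation; DnaA is a
    constant areal concentration times size (mutant and wild-type cells share
    the concentration, so small cells hold proportionally less DnaA).
    """
    rng = np.random.default_rng(config.seed)
    ages = sample_ages(config.n_cells, seed=int(rng.integers(2**31)))
    if config.size_birth_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.size_birth_cv**2))
        mu = math.log(config.size_birth_mean) - 0.5 * sigma**2
        birth = rng.lognormal(mean=mu, sigma=sigma, size=config.n_cells)
    else:
        birth = np.full(config.n_cells, config.size_birth_mean)
    size = birth * 2.0**ages
    states = [state_at_age(a, config.params) for a in ages]
    return pd.DataFrame(
        {
            "age": ages,
            "size": size,
            "origins": [s.origins for s in states],
            "fork_pairs": [s.fork_pairs for s in states],
            "genome_equivalents": [s.genome_equivalents for s in states],
            "dnaa_molecules": config.dnaa_concentration * size,
        }
    )


def simulate_runout_histogram(config: SimulationConfig, n_bins: int = 128) -> RunoutHistogram:
    """Run-out DNA-content histogram of a simulated population.

    Run-out is complete: each cell finishes all active forks without new
    initiations, ending with one fully replicated chromosome per origin it
    held at drug addition.  Measured fluorescence is
    ``unit · chromosomes · (1 + eps)`` with ``eps ~ N(0, cv)``, histogrammed
    on ``n_bins`` equal-width bins over the observed range.
    """
    rng = np.random.default_rng(config.seed)
    ages = sample_ages(config.n_cells, seed=int(rng.integers(2**31)))
    origins = np.array([state_at_age(a, config.params).origins for a in ages], float)
    noise = 1.0 + config.fluorescence_cv * rng.standard_normal(config.n_cells)
    fluor = config.fluorescence_unit * origins * noise
    counts, edges = np.histogram(fluor, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RunoutHistogram(bin_centers=centers, counts=counts.astype(float))


def simulate_qpcr(config: SimulationConfig, sample_id: str = "sim") -> pd.DataFrame:
    """Long-format qPCR table for one sample plus its 1:1 calibrator.

    The sample's ori:ter template ratio is the model's ``2^(C/tau)``; the
    calibrator has equal ori and ter template (at a different total input, as
    a real run-out DNA prep would).  Ideal Cq values follow
    ``Cq = Cq0 - ln(template)/ln(E)`` for each target's declared efficiency;
    each of ``n_biological × n_technical`` wells adds ``N(0, cq_sd)`` noise.
    Columns match :func:`oricycle.qpcr.pfaffl_from_table`.
    """
    rng = np.random.default_rng(config.seed + 1)
    ratio = ori_ter_ratio(config.params)
    cq0 = 15.0
    cal_input = 0.8  # arbitrary calibrator template amount
    ideal = {
        ("ori", "sample"): cq0 - math.log(ratio) / math.log(config.eff_ori),
        ("ter", "sample"): cq0,
        ("ori", "calibrator"): cq0 - math.log(cal_input) / math.log(config.eff_ori),
        ("ter", "calibrator"): cq0 - math.log(cal_input) / math.log(config.eff_ter),
    }
    eff = {"ori": config.eff_ori, "ter": config.eff_ter}
    rows = []
    n_wells = config.n_biological * config.n_technical
    for (target, role), cq in ideal.items():
        sid = sample_id if role == "sample" else f"{sample_id}-calibrator"
        noise = rng.normal(0.0, config.cq_sd, size=n_wells) if config.cq_sd > 0 else np.zeros(n_wells)
        for w in range(n_wells):
            rows.append(
                {
                    "sample_id": sid,
                    "target": target,
                    "role": role,
                    "cq": cq + noise[w],
                    "efficiency": eff[target],
                }
            )
    return pd.DataFrame(rows)


_CONFIG_KEYS = {
    "tau_min": ("params", "tau"),
    "c_min": ("params", "c_period"),
    "d_min": ("params", "d_period"),
    "n_cells": ("n_cells", None),
    "fluor_cv": ("fluorescence_cv", None),
    "size_mean": ("size_birth_mean", None),
    "size_cv": ("size_birth_cv", None),
    "cq_sd": ("cq_sd", None),
    "seed": ("seed", None),
}


def config_to_dict(config: SimulationConfig) -> dict:
    """Flat key-value form of a config (for YAML round-tripping)."""
    return {
        "tau_min": config.params.tau,
        "c_min": config.params.c_period,
        "d_min": config.params.d_period,
        "n_cells": config.n_cells,
        "fluor_cv": config.fluorescence_cv,
        "size_mean": config.size_birth_mean,
        "size_cv": config.size_birth_cv,
        "cq_sd": config.cq_sd,
        "seed": config.seed,
    }


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from the flat key-value form; unknown keys rejected."""
    unknown = set(d) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    for k in ("tau_min", "c_min", "d_min"):
        if k not in d:
            raise ValueError(f"simulation config missing required key {k!r}")
    params = CellCycleParams(
        tau=float(d["tau_min"]), c_period=float(d["c_min"]), d_period=float(d["d_min"])
    )
    cfg = SimulationConfig(params=params)
    updates = {}
    for key, (attr, _) in _CONFIG_KEYS.items():
        if key in d and attr != "params":
            value = d[key]
            updates[attr] = int(value) if attr in ("n_cells", "seed") else float(value)
    return replace(cfg, **updates)
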