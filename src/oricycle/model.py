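"""Closed-form steady-state mathematics of the bacterial cell cycle.

The Cooper–Helmstetter model describes a steady-state exponential culture in
which every cell grows with mass doubling time ``tau``, replicates its
chromosome in a fixed time ``C`` (elongation) and divides a fixed time ``D``
after replication terminates.  When ``C + D > tau`` replication rounds overlap
("multifork" replication) and origins come in powers of two.

All durations are in minutes.  Cell age is dimensionless in ``[0, 1)`` with
0 = birth and 1 = division.  In a steady-state exponential culture the age
distribution is not uniform: young cells are over-represented because every
division creates two newborns, giving the density ``p(a) = 2 ln2 · 2^(-a)``.

Key relations (all invertible, all used by the inference modules):

====================  =====================================
origin:terminus ratio  ``ori/ter = 2^(C/tau)``
origins per cell       ``O = 2^((C+D)/tau)``
initiation age         ``a_i = ceil(r) - r`` with ``r = (C+D)/tau``
mean genome content    ``G = tau/(C ln2) · (2^((C+D)/tau) - 2^(D/tau))``
====================  =====================================
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "CellCycleParams",
    "PerAgeState",
    "age_pdf",
    "age_cdf",
    "ori_ter_ratio",
    "c_period_from_ratio",
    "origins_per_cell",
    "d_period",
    "model_initiation_age",
    "state_at_age",
    "mean_genome_equivalents",
    "period_from_frequency",
    "circular_age_distance",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CellCycleParams:
    """The (tau, C, D) triple, in minutes, driving all cell-cycle math.

    Parameters
    ----------
    tau
        Mass doubling time of the steady-state culture.
    c_period
        Chromosome replication (elongation) time C.
    d_period
        Time between replication termination and cell division, D.
    """

    tau: float
    c_period: float
    d_period: float

    def __post_init__(self) -> None:
        for name in ("tau", "c_period", "d_period"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.c_period < 0:
            raise ValueError(f"c_period must be >= 0, got {self.c_period}")
        if self.d_period < 0:
            raise ValueError(f"d_period must be >= 0, got {self.d_period}")
        if self.c_period == 0:
            # Degenerate instant replication: permitted for testing, but any
            # real measurement with C = 0 is suspect.
            warnings.warn(
                "c_period = 0 is a degenerate (instant-replication) limit",
                stacklevel=2,
            )

    @property
    def rounds(self) -> float:
        """(C + D)/tau — number of cell cycles spanned by one replication
        round plus the division delay."""
        return (self.c_period + self.d_period) / self.tau


@dataclass(frozen=True)
class PerAgeState:
    """Replication state of a single cell at a given age."""

    origins: int
    fork_pairs: int
    genome_equivalents: float


def _check_age(age: float, *, closed_right: bool = False) -> float:
    hi_ok = age <= 1 if closed_right else age < 1
    if not (0 <= age and hi_ok and math.isfinite(age)):
        rng = "[0, 1]" if closed_right else "[0, 1)"
        raise ValueError(f"cell age must lie in {rng}, got {age!r}")
    return float(age)


def age_pdf(age: float) -> float:
    """Steady-state exponential age density ``2 ln2 · 2^(-a)``.

    Normalized over [0, 1]; decreasing from ``2 ln2`` at birth to ``ln2`` at
    division (newborns are twice as frequent as dividing cells).
    """
    a = _check_age(age)
    return 2.0 * _LN2 * 2.0 ** (-a)


def age_cdf(age: float) -> float:
    """Fraction of cells younger than ``age``: ``2 (1 - 2^(-a))``."""
    a = _check_age(age, closed_right=True)
    return 2.0 * (1.0 - 2.0 ** (-a))


def ori_ter_ratio(params: CellCycleParams) -> float:
    """Marker-frequency origin:terminus ratio, ``2^(C/tau)``.

    Origin-proximal DNA is over-represented in a replicating population
    because every cell carries origins for the whole C period but a freshly
    duplicated terminus only at the end of it.
    """
    return 2.0 ** (params.c_period / params.tau)


def c_period_from_ratio(ratio: float, tau: float) -> float:
    """Invert the marker-frequency relation: ``C = tau · log2(ori/ter)``."""
    if not (ratio >= 1 and math.isfinite(ratio)):
        raise ValueError(
            f"ori/ter ratio must be >= 1 for a replicating steady state, got {ratio!r}"
        )
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    return tau * math.log2(ratio)


def origins_per_cell(params: CellCycleParams) -> float:
    """Population-mean origins per cell, ``2^((C+D)/tau)``."""
    return 2.0 ** params.rounds


def d_period(origins: float, tau: float, c_period: float) -> tuple[float, bool]:
    """Invert origins-per-cell for D: ``D = tau · log2(origins) - C``.

    Returns ``(D, ok)``; ``ok`` is False when the implied D is negative,
    which flags inconsistent measurements (origins too low for the measured
    C) rather than silently clipping.
    """
    if origins < 1:
        raise ValueError(f"mean origins per cell must be >= 1, got {origins}")
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    d = tau * math.log2(origins) - c_period
    if d < -1e-9 * max(tau, c_period):  # beyond roundoff of the inversion
        warnings.warn(
            f"implied D period is negative ({d:.3g} min); origins per cell "
            "and C period are mutually inconsistent",
            stacklevel=2,
        )
        return d, False
    return d, True


def model_initiation_age(params: CellCycleParams) -> float:
    """Model-predicted cell age at which all origins fire.

    An initiation event must precede its eventual division by exactly
    ``C + D`` minutes, so with ``r = (C+D)/tau`` the firing age is
    ``a_i = ceil(r) - r`` (0 when r is an integer: initiation at birth).
    """
    r = params.rounds
    a_i = math.ceil(r) - r
    # guard against float representation of integer r
    if a_i >= 1.0:
        a_i -= 1.0
    return a_i


def _active_rounds(age: float, params: CellCycleParams) -> list[float]:
    """Fork progress fractions of all replication rounds active at ``age``,
    sorted oldest (furthest along) first."""
    if params.c_period == 0:
        return []
    a_i = model_initiation_age(params)
    c = params.c_period / params.tau  # replication time in cycle units
    j0 = 0 if age >= a_i else 1  # this cycle's round fired yet?
    xs = []
    j = j0
    while True:
        x = (age - a_i + j) / c
        if x >= 1.0:  # round completed; all older rounds completed too
            break
        if x > 0.0:
            xs.append(x)
        j += 1
    return sorted(xs, reverse=True)


def state_at_age(age: float, params: CellCycleParams) -> PerAgeState:
    """Origins, fork pairs and genome equivalents of a cell at ``age``.

    Origins double synchronously at the initiation age and halve at division:
    ``2^(ceil(r)-1)`` before initiation, ``2^ceil(r)`` after.  Fork counts
    and DNA content follow from enumerating every replication round active at
    this age (a round initiated ``C + D`` before its division runs for C with
    linear fork progress).  With ``m`` nested rounds at progress fractions
    ``x_1 > ... > x_m`` on each of ``B`` chromosome backbones:

    - genome equivalents = ``B (1 + sum_i 2^(i-1) x_i)``
    - fork pairs = ``B (2^m - 1)``
    """
    a = _check_age(age)
    r = params.rounds
    n = math.ceil(r)
    a_i = model_initiation_age(params)
    origins = 2 ** max(n - 1, 0) if a < a_i else 2 ** n
    xs = _active_rounds(a, params)
    m = len(xs)
    backbones = origins // (2 ** m)
    genome = backbones * (1.0 + sum(2 ** i * x for i, x in enumerate(xs)))
    fork_pairs = backbones * (2 ** m - 1)
    return PerAgeState(origins=origins, fork_pairs=fork_pairs, genome_equivalents=genome)


def mean_genome_equivalents(params: CellCycleParams) -> float:
    """Population-mean DNA content in genome equivalents.

    Closed form ``G = tau/(C ln2) · (2^((C+D)/tau) - 2^(D/tau))``; equals the
    age-distribution average of per-cell genome equivalents.  The C -> 0
    limit is ``2^(D/tau)`` (every cell holds fully replicated chromosomes).
    """
    tau, c, d = params.tau, params.c_period, params.d_period
    if c == 0:
        return 2.0 ** (d / tau)
    return tau / (c * _LN2) * (2.0 ** ((c + d) / tau) - 2.0 ** (d / tau))


def period_from_frequency(frequency: float) -> float:
    """Age at which an end-of-cycle period begins, from its cell frequency.

    A marker present during ``[a1, 1]`` (e.g. the FtsZ ring during the Z
    period) is seen in a fraction ``f = 2^(1-a1) - 1`` of a steady-state
    population; inverting gives ``a1 = 1 - log2(1 + f)``.
    """
    if not (0 <= frequency <= 1):
        raise ValueError(f"frequency must lie in [0, 1], got {frequency!r}")
    return 1.0 - math.log2(1.0 + frequency)


def circular_age_distance(a: float, b: float) -> float:
    """Distance between two cell ages on the unit circle.

    Ages wrap at division: when ``(C+D)/tau`` sits near an integer, an
    initiation age just below 1 and one just above 0 describe nearly the same
    event, so comparisons use ``min(|Δ|, 1 - |Δ|)``.
    """
    d = abs(a - b) % 1.0
    return min(d, 1.0 - d)
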