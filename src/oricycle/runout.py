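"""Replication run-out histogram analysis.

Blocking new initiations and division (rifampicin + cephalexin in
*E. coli*, chloramphenicol in *B. subtilis*) lets already-fired forks finish,
leaving each cell with as many fully replicated chromosomes as it had origins
at drug addition.  A DNA-content histogram of the treated population then
resolves into peaks at integer (power-of-two) chromosome numbers.  The
fraction of cells in the lower of two adjacent peaks is the uninitiated
fraction ``F`` — cells that had not yet fired at drug addition — and the
steady-state age distribution converts ``F`` to the initiation age:

    F = age_cdf(a_i)  =>  a_i = -log2(1 - F/2)

Ranking cells by size as a stand-in for ranking by age maps the initiation
age onto an empirical size distribution, giving the cell size at initiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError, UnsupportedProfileError, ValidationError
from .model import age_cdf

__all__ = [
    "RunoutHistogram",
    "PloidyMixture",
    "SizeSample",
    "fit_ploidy_mixture",
    "fraction_uninitiated",
    "initiation_age_from_F",
    "mean_chromosomes",
    "initiation_size",
    "initiation_delay",
]

DEFAULT_CHROMOSOME_SET = (2, 4, 8, 16)


@dataclass(frozen=True)
class RunoutHistogram:
    """Binned DNA-content data: fluorescence bin centers and event counts."""

    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_centers", np.asarray(self.bin_centers, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, float))
        if self.bin_centers.ndim != 1 or self.bin_centers.shape != self.counts.shape:
            raise ValidationError("bin_centers and counts must be 1-D and equal length")
        if len(self.bin_centers) < 8:
            raise ValidationError("histogram needs at least 8 bins")
        if not np.all(np.diff(self.bin_centers) > 0):
            raise ValidationError("bin_centers must be strictly increasing")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValidationError("counts must be finite and non-negative")
        if self.counts.sum() <= 0:
            raise ValidationError("histogram has zero total count")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def edges(self) -> np.ndarray:
        """Bin edges reconstructed from centers (midpoints, extrapolated ends)."""
        c = self.bin_centers
        mid = 0.5 * (c[:-1] + c[1:])
        first = c[0] - (mid[0] - c[0])
        last = c[-1] + (c[-1] - mid[-1])
        return np.concatenate([[first], mid, [last]])


@dataclass(frozen=True)
class PloidyMixture:
    """Decomposition of a run-out histogram into integer-chromosome classes.

    ``classes`` is an ascending list of ``(chromosomes, fraction)`` pairs,
    ``unit_fluorescence`` the shared fluorescence per chromosome equivalent,
    and ``cv`` the shared coefficient of variation of the per-class Gaussian.
    """

    classes: tuple[tuple[int, float], ...]
    unit_fluorescence: float
    cv: float

    def __post_init__(self) -> None:
        chroms = [c for c, _ in self.classes]
        fracs = [f for _, f in self.classes]
        if not chroms:
            raise ValidationError("mixture needs at least one class")
        if sorted(set(chroms)) != chroms:
            raise ValidationError("chromosome numbers must be distinct and ascending")
        if any(c <= 0 for c in chroms):
            raise ValidationError("chromosome numbers must be positive integers")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ValidationError(f"fractions must sum to 1, got {sum(fracs)}")
        if self.cv <= 0:
            raise ValidationError("cv must be positive")


@dataclass(frozen=True)
class SizeSample:
    """Empirical distribution of cell cross-sectional areas (µm²)."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "areas", np.asarray(self.areas, float))
        if self.areas.size == 0:
            raise ValidationError("size sample is empty")
        if not np.all(np.isfinite(self.areas)) or np.any(self.areas <= 0):
            raise ValidationError("areas must be finite and positive")


def _mixture_mass(
    edges: np.ndarray, chroms: np.ndarray, fracs: np.ndarray, unit: float, cv: float
) -> np.ndarray:
    """Per-bin probability mass of the constrained Gaussian mixture."""
    mass = np.zeros(len(edges) - 1)
    for k, f in zip(chroms, fracs):
        mu = k * unit
        sd = cv * mu
        cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
        mass += f * np.diff(cdf)
    return mass


def _fit_at_unit(
    hist: RunoutHistogram,
    chroms: np.ndarray,
    unit0: float,
    cv0: float,
) -> tuple[float, np.ndarray, float, float]:
    """Weighted least-squares fit with fixed class set, free (unit, cv,
    fractions).  Returns (cost, fractions, unit, cv)."""
    edges = hist.edges()
    obs = hist.counts / hist.total
    n = hist.total

    # initial fractions: observed mass nearest each class mean
    centers = hist.bin_centers
    d = np.abs(centers[:, None] - (chroms * unit0)[None, :])
    nearest = np.argmin(d, axis=1)
    f0 = np.array([obs[nearest == i].sum() for i in range(len(chroms))])
    f0 = np.clip(f0, 1e-3, None)
    f0 /= f0.sum()

    def unpack(theta):
        unit = math.exp(theta[0])
        cv = math.exp(theta[1])
        logits = np.concatenate([theta[2:], [0.0]])
        w = np.exp(logits - logits.max())
        return unit, cv, w / w.sum()

    def resid(theta):
        unit, cv, fracs = unpack(theta)
        model = _mixture_mass(edges, chroms, fracs, unit, cv)
        # Poisson-motivated weights: var(obs_i) ~ p_i / n
        return (obs - model) / np.sqrt((model + 1e-8) / n)

    theta0 = np.concatenate(
        [[math.log(unit0), math.log(cv0)], np.log(f0[:-1]) - math.log(f0[-1])]
    )
    lo = np.full_like(theta0, -np.inf)
    hi = np.full_like(theta0, np.inf)
    lo[1], hi[1] = math.log(1e-3), math.log(0.5)  # cv bounds
    lo[0], hi[0] = theta0[0] - math.log(1.6), theta0[0] + math.log(1.6)
    try:
        sol = optimize.least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-12)
    except Exception as exc:  # pragma: no cover - scipy internal failure
        raise EstimationError(f"mixture fit failed: {exc}") from exc
    unit, cv, fracs = unpack(sol.x)
    return float(sol.cost), fracs, unit, cv


def _candidate_units(hist: RunoutHistogram, allowed: Sequence[int]) -> list[float]:
    """Candidate fluorescence-per-chromosome scales from histogram peaks."""
    counts = hist.counts
    # light smoothing to suppress single-bin noise
    if len(counts) >= 16:
        kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    else:
        smooth = counts.astype(float)
    interior = (smooth[1:-1] >= smooth[:-2]) & (smooth[1:-1] >= smooth[2:])
    idx = np.where(interior)[0] + 1
    if idx.size == 0:
        idx = np.array([int(np.argmax(smooth))])
    # two most massive peaks
    idx = idx[np.argsort(smooth[idx])[::-1][:2]]
    units: list[float] = []
    for i in idx:
        pos = hist.bin_centers[i]
        for k in allowed:
            u = pos / k
            if all(abs(math.log(u / v)) > 0.05 for v in units):
                units.append(u)
    return units


def fit_ploidy_mixture(
    hist: RunoutHistogram,
    allowed_chromosomes: Iterable[int] = DEFAULT_CHROMOSOME_SET,
    *,
    unit_hint: float | None = None,
    min_fraction: float = 0.01,
) -> PloidyMixture:
    """Fit integer-chromosome Gaussian classes to a run-out histogram.

    Component means are pinned to ``chromosomes × unit_fluorescence`` with a
    single fitted scale and one shared CV; fractions live on the simplex.
    The objective is Poisson-weighted least squares between the model's
    per-bin mass and the normalized histogram.  Classes ending below
    ``min_fraction`` of the mass are pruned and the rest renormalized, so
    shoulder artifacts do not masquerade as ploidy classes.

    Because the fluorescence axis is arbitrary, a two-peak histogram fits
    equally well under any adjacent pair from ``allowed_chromosomes`` (pure
    scale ambiguity).  ``unit_hint`` — a calibrated fluorescence per genome
    equivalent, e.g. from a reference standard — resolves the tie; without it
    the smallest consistent chromosome labels are chosen.
    """
    allowed = sorted(set(int(k) for k in allowed_chromosomes))
    if not allowed or any(k <= 0 for k in allowed):
        raise ValidationError("allowed_chromosomes must be positive integers")
    chroms = np.array(allowed, float)

    results = []
    for unit0 in _candidate_units(hist, allowed):
        try:
            cost, fracs, unit, cv = _fit_at_unit(hist, chroms, unit0, 0.06)
        except EstimationError:
            continue
        kept = [(int(k), float(f)) for k, f in zip(allowed, fracs) if f >= min_fraction]
        if not kept:
            continue
        tot = sum(f for _, f in kept)
        kept = [(k, f / tot) for k, f in kept]
        results.append((cost, kept, unit, cv))
    if not results:
        raise EstimationError("ploidy mixture fit failed for every candidate scale")

    best_cost = min(r[0] for r in results)
    # ties within 1% relative cost are the scale ambiguity
    tied = [r for r in results if r[0] <= best_cost * 1.01 + 1e-12]
    if unit_hint is not None:
        tied.sort(key=lambda r: abs(math.log(r[2] / unit_hint)))
    else:
        tied.sort(key=lambda r: sum(k for k, _ in r[1]))
    _, classes, unit, cv = tied[0]
    return PloidyMixture(classes=tuple(classes), unit_fluorescence=unit, cv=cv)


def fraction_uninitiated(mix: PloidyMixture) -> float:
    """Uninitiated fraction ``F``: mass of the lower peak of a two-peak
    run-out profile whose chromosome numbers differ by a factor of two.

    Cells that initiated before drug addition carry twice the DNA of those
    that had not.  Profiles with more than two classes (three run-out peaks)
    are rejected: the two-peak inversion does not apply.
    """
    if len(mix.classes) != 2:
        raise UnsupportedProfileError(
            f"uninitiated fraction needs exactly two ploidy classes, got "
            f"{len(mix.classes)}: the two-peak inversion does not apply"
        )
    (k1, f1), (k2, _) = mix.classes
    if k2 != 2 * k1:
        raise UnsupportedProfileError(
            f"ploidy classes {k1} and {k2} do not differ by a factor of 2"
        )
    return f1


def initiation_age_from_F(F: float) -> float:
    """Initiation age from the uninitiated fraction: ``a_i = -log2(1 - F/2)``.

    In steady state the uninitiated cells are exactly those younger than the
    initiation age, so ``F = age_cdf(a_i)``; this is the inverse.
    """
    if not (0 <= F < 1):
        raise ValueError(f"uninitiated fraction must lie in [0, 1), got {F!r}")
    return -math.log2(1.0 - F / 2.0)


def mean_chromosomes(mix: PloidyMixture) -> float:
    """Fraction-weighted mean chromosome number = mean origins per cell at
    drug addition (run-out converts each origin into one full chromosome)."""
    return sum(k * f for k, f in mix.classes)


def initiation_size(a_i: float, sizes: SizeSample) -> float:
    """Cell size (cross-sectional area, µm²) at the initiation age.

    Cells ranked by size stand in for cells ranked by age, so the size at
    initiation is the empirical quantile of the size sample at probability
    ``age_cdf(a_i)``, with linear interpolation between order statistics.
    """
    if not (0 <= a_i <= 1):
        raise ValueError(f"initiation age must lie in [0, 1], got {a_i!r}")
    p = age_cdf(a_i)
    return float(np.quantile(np.sort(sizes.areas, kind="stable"), p))


def initiation_delay(
    age_mut: float, tau_mut: float, age_wt: float, tau_wt: float
) -> float:
    """Absolute initiation delay in minutes between two strains.

    Converts each initiation age to time-from-birth (``a_i · tau``) and
    returns the mutant-minus-reference difference.
    """
    for tau in (tau_mut, tau_wt):
        if tau <= 0:
            raise ValueError(f"generation time must be positive, got {tau}")
    return age_mut * tau_mut - age_wt * tau_wt
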