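# Methods

## Model

`oricycle` assumes a steady-state exponential culture in the
Cooper–Helmstetter sense: every cell doubles its mass in τ minutes,
replicates the chromosome in a fixed C minutes, and divides exactly D
minutes after termination.  Division is symmetric and initiation is
perfectly synchronous across all origins in a cell, so origin numbers are
powers of two.  Ages are dimensionless in [0, 1) and the population age
density is p(a) = 2 ln2 · 2⁻ᵃ — newborns are twice as frequent as dividing
cells because each division produces two daughters.

With r = (C+D)/τ, an initiation must precede the division it commits by
exactly C + D, which pins the firing age at a_i = ⌈r⌉ − r.  Enumerating the
replication rounds active at an age (a round fired at a_i in each earlier
cycle, fork progress linear over C) gives per-age origin counts, fork
pairs and DNA content: with m nested rounds at progress x₁ > … > x_m on each
of B chromosome backbones, DNA = B(1 + Σᵢ 2^(i−1) xᵢ) genome equivalents.
The population mean has the closed form τ/(C ln2)(2^((C+D)/τ) − 2^(D/τ)),
which the tests check against quadrature over the age distribution and
against Monte-Carlo population averages.

Ages are compared on the unit circle (min(|Δ|, 1−|Δ|)): when r sits near an
integer, initiation wraps across division and ages like 0.93 and 0.08
describe nearly the same event.

## Inference chain

**C period.**  The ori/ter marker ratio of exponential cells equals
2^(C/τ).  qPCR quantification cycles for ori- and ter-proximal amplicons
are converted to a ratio with the Pfaffl efficiency-corrected formula
against a calibrator of true ratio 1 (run-out cells or spore DNA).
Technical replicates are averaged on the Cq scale — Cq is the log-domain
quantity.  Amplification efficiencies are user inputs in (1, 2], default 2
(perfect doubling); standard-curve estimation is out of scope.

**D period.**  Mean origins per cell equals 2^((C+D)/τ), so
D = τ·log2(origins) − C.  A negative implied D is flagged (returned with a
False status and a warning), never clipped: it signals mutually
inconsistent measurements.

**Initiation age.**  A run-out histogram is fitted as a mixture of Gaussian
classes whose means are pinned to integer chromosome numbers times one
fitted fluorescence unit, with one shared CV; fractions live on the
simplex.  The objective is Poisson-weighted least squares against the
normalized histogram, initialized from the two most massive local maxima;
classes below 1% of the mass are pruned before any downstream check so
shoulder artifacts cannot masquerade as ploidy classes.  Because the
fluorescence axis is arbitrary, a two-peak histogram fits equally well
under any adjacent pair from the allowed set {2, 4, 8, 16}; an optional
`unit_hint` (calibrated fluorescence per genome equivalent, as a reference
standard provides on a real cytometer) resolves the tie, otherwise the
smallest consistent labels are chosen.  The uninitiated fraction F is the
lower-class mass of a two-peak profile — profiles with three or more peaks
are rejected, since the two-peak inversion does not apply — and
a_i = −log2(1 − F/2), the exact inverse of the steady-state age CDF under
once-per-cycle initiation.  F is taken from fitted peak areas, not raw
event counts.

**Initiation size.**  Cells ranked by size stand in for cells ranked by
age, so size at initiation is the empirical quantile of the area sample at
probability age_cdf(a_i), with linear interpolation between order
statistics (type-7 style) and stable sorting for ties.  Initiation delays
between strains are differences of absolute time from birth, a_i·τ; the
alternative Δa·τ differs only within printed rounding for the tabulated
strains, and a·τ is the quantity with time units.

**DnaA.**  Blot ratios are loading-control-corrected and compared only
within one normalization basis (OD → concentration, cell count → per-cell
amount).  Absolute molecules per cell require a literature baseline that is
always a caller-supplied parameter; DnaA per origin is that estimate
divided by measured origins per cell.  Relative mass is the inverse ratio
of hemocytometer counts at matched OD (tolerance 5%).

## Synthetic data

The generator draws ages by inverse CDF (a = −log2(1 − u/2)), grows size
exponentially within the cycle (birth size · 2ᵃ) with log-normal birth-size
variation, sets DnaA to a constant areal concentration times size, and
derives each measurement from the per-age model state.  Run-out is
complete: each cell ends with one fully replicated chromosome per origin,
measured as unit · chromosomes · (1 + ε), ε ~ N(0, cv).  qPCR tables are
generated from template quantities consistent with the declared
efficiencies plus N(0, cq_sd) per-well noise, with the calibrator at a
different total input, as a real DNA prep would be.  Defaults are a
fast-growth rich-medium condition — τ = 24 min, C = 43.8 min, D = 23.7 min
(r ≈ 2.8, run-out classes at 4 and 8), 20,000 events, 6% fluorescence CV,
newborn area 3 µm² with 10% CV, 0.05-cycle Cq noise, 3 biological × 3
technical qPCR replicates.  All generators are bit-reproducible given the
config and seed.

Not emulated: initiation asynchrony, division noise, debris/doublet events,
photodetector nonlinearity, incomplete drug action, cell-to-cell C-period
variability.  Passing recovery tests therefore demonstrates correctness of
the inversion chain under the model's own assumptions, not robustness to
every artifact of real cytometry or qPCR.

## Numerical choices

- Mixture fitting: `scipy.optimize.least_squares` on (log unit, log CV,
  fraction logits); CV bounded to [10⁻³, 0.5]; the unit is bounded within
  ×1.6 of each candidate initialization so candidate assignments stay
  distinct; per-bin model mass uses Gaussian CDF differences over bin
  edges.  Fits are attempted from every (peak, allowed-class) candidate
  scale and the lowest-cost solution wins; costs tied within 1% are the
  scale ambiguity and are broken as described above.
- Degenerate C = 0 (instant replication) is permitted for testing and
  flagged with a warning wherever it arises.
- Implied-D negativity is tested against a 10⁻⁹-relative threshold so
  floating-point roundoff of the exact inverse identity does not trigger
  the inconsistency flag.
- Histograms require ≥ 8 strictly increasing bins and positive total count.

## Problem sizes

Recovery tests use 20,000 cells per histogram (the scale of a routine flow
acquisition), 10⁵ draws for Monte-Carlo checks of the closed forms, and
three seeds for the full-chain recovery condition (C within ±1.5 min, D
within ±2 min, a_i within 0.05 circular at 6% CV and 0.05-cycle Cq noise).
At these noise levels the qPCR term dominates the C-period error
(σ_C ≈ τ · 2σ_Cq/√9 ≈ 0.8 min).

## Known limitations

- The two-peak F inversion cannot handle three-peak run-out profiles
  (slow-growth or very fast-growth regimes); such data yield origins per
  cell and mean DNA content but no initiation age, and the package raises
  a dedicated error rather than extrapolating.
- Without a unit hint, ploidy labels are identified only up to the
  power-of-two scale ambiguity; fractions, F and a_i are unaffected but
  absolute origins per cell (hence D) require the calibrated scale.
- The steady-state assumptions (balanced growth, synchronous initiation,
  fixed C and D) are load-bearing; cultures leaving balanced growth or
  initiating asynchronously violate the inversion formulas.
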