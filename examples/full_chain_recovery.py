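"""Full-chain parameter recovery on synthetic data.

Generates every measurement the pipeline consumes — a noisy run-out
histogram and a noisy qPCR table — from known ground truth, then runs the
analysis chain and compares the recovered (C, D, initiation age) with the
generator's truth.
"""

from oricycle import (
    CellCycleParams,
    SimulationConfig,
    circular_age_distance,
    fit_ploidy_mixture,
    fraction_uninitiated,
    infer_c_and_d,
    initiation_age_from_F,
    mean_chromosomes,
    model_initiation_age,
    pfaffl_from_table,
    simulate_qpcr,
    simulate_runout_histogram,
)

truth = CellCycleParams(tau=24.0, c_period=43.8, d_period=23.7)
cfg = SimulationConfig(
    params=truth, n_cells=20_000, fluorescence_cv=0.06, cq_sd=0.05, seed=1
)

ratio = pfaffl_from_table(simulate_qpcr(cfg))["sim"]
mix = fit_ploidy_mixture(simulate_runout_histogram(cfg), unit_hint=cfg.fluorescence_unit)
origins = mean_chromosomes(mix)
c, d, ok = infer_c_and_d(ratio, origins, truth.tau)
a_i = initiation_age_from_F(fraction_uninitiated(mix))

print(f"ori/ter ratio (Pfaffl)  = {ratio:.3f}")
print(f"origins per cell        = {origins:.2f}")
print(f"C period  recovered {c:5.1f} min   truth {truth.c_period} min")
print(f"D period  recovered {d:5.1f} min   truth {truth.d_period} min")
print(f"initiation age recovered {a_i:.3f}  truth {model_initiation_age(truth):.3f} "
      f"(circular error {circular_age_distance(a_i, model_initiation_age(truth)):.4f})")
print()
print("Recovery errors reflect 0.05-cycle qPCR noise and 6% fluorescence CV")
print("at 20,000 cells; repeat with other seeds to see the spread.")
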