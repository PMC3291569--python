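"""DnaA levels, DnaA per origin and relative cell mass.

Small-cell mutants keep the wild-type DnaA *concentration* but, being ~30%
smaller, hold ~30% less DnaA *per cell* — the difference between normalizing
immunoblot loading to optical density vs to cell number.  Hemocytometer
counts at matched OD give relative mass, and an absolute per-cell estimate
divided by origins per cell gives DnaA per origin.
"""

from oricycle import (
    BlotMeasurement,
    CountMeasurement,
    NormalizationBasis,
    dnaa_per_ori,
    relative_dnaa_level,
    relative_mass_per_cell,
)

od = NormalizationBasis.OPTICAL_DENSITY
cells = NormalizationBasis.CELL_COUNT

# per-OD lanes: equal biomass loaded -> compares concentration
conc = relative_dnaa_level(
    BlotMeasurement(98.0, 100.0, od, 0.3), BlotMeasurement(100.0, 100.0, od, 0.3)
)
# per-cell lanes: equal cell number loaded -> compares amount per cell
per_cell = relative_dnaa_level(
    BlotMeasurement(70.0, 100.0, cells, 8.0e8), BlotMeasurement(100.0, 100.0, cells, 6.4e8)
)
print(f"mutant/wt DnaA concentration = {conc:.2f}")
print(f"mutant/wt DnaA per cell      = {per_cell:.2f}")

mass = relative_mass_per_cell(CountMeasurement(6.4e8, 0.3), CountMeasurement(7.8e8, 0.3))
print(f"relative mass per cell       = {mass:.2f}  (more cells at equal OD)")

# absolute accounting requires a literature baseline for molecules/cell
print(f"DnaA per origin at 1400 molecules/cell and 7 origins = "
      f"{dnaa_per_ori(1400.0, 7.0):.0f}")
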