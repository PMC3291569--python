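"""Per-strain cell-cycle reports from file-based inputs.

Orchestrates the full chain for each strain listed in a YAML config:

1. Pfaffl qPCR -> ori/ter ratio -> C period (``C = tau log2(ratio)``)
2. run-out histogram -> ploidy mixture -> origins/cell -> D period
3. two-class mixtures -> uninitiated fraction F -> initiation age a_i
4. optional size sample -> size at initiation; optional hemocytometer
   counts -> relative mass; optional absolute DnaA per cell -> DnaA/origin

Config layout::

    reference: WT            # strain id used for delays / relative mass
    strains:
      - id: WT
        tau_min: 25.4
        qpcr_csv: wt_qpcr.csv
        runout_csv: wt_runout.csv
        sizes_csv: wt_sizes.csv           # optional
        unit_hint: 1.0                    # optional fluorescence/genome
        counts: {cells_per_ml: 6.4e8, od: 0.3}   # optional
        dnaa_per_cell: 1400               # optional, molecules/cell
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .abundance import CountMeasurement, dnaa_per_ori, relative_mass_per_cell
from .errors import ParseError, ValidationError
from .qpcr import infer_c_and_d, pfaffl_from_table
from .runout import (
    fit_ploidy_mixture,
    fraction_uninitiated,
    initiation_age_from_F,
    initiation_delay,
    initiation_size,
    mean_chromosomes,
)

__all__ = ["CellCycleReport", "run_report", "reports_to_frame", "write_reports"]

log = logging.getLogger("oricycle")


@dataclass(frozen=True)
class CellCycleReport:
    """One strain's inferred cell-cycle parameters (a Table-shaped row)."""

    strain_id: str
    tau: float
    ori_ter: float
    origins_per_cell: float
    c_period: float
    d_period: float
    initiation_age: float
    initiation_size: float | None = None
    dnaa_per_ori: float | None = None
    relative_mass: float | None = None
    initiation_delay_min: float | None = None
    d_period_ok: bool = True


def _strain_report(entry: dict, base: Path) -> tuple[CellCycleReport, dict]:
    for key in ("id", "tau_min", "qpcr_csv", "runout_csv"):
        if key not in entry:
            raise ParseError(f"strain entry missing required key {key!r}: {entry}")
    tau = float(entry["tau_min"])
    if tau <= 0:
        raise ValidationError(f"strain {entry['id']}: tau_min must be positive")

    qpcr = _io.read_qpcr(base / entry["qpcr_csv"])
    ratios = pfaffl_from_table(qpcr)
    ratio = sum(ratios.values()) / len(ratios)

    hist = _io.read_histogram(base / entry["runout_csv"])
    mix = fit_ploidy_mixture(hist, unit_hint=entry.get("unit_hint"))
    origins = mean_chromosomes(mix)
    c, d, ok = infer_c_and_d(ratio, origins, tau)
    a_i = initiation_age_from_F(fraction_uninitiated(mix))

    size_i = None
    if entry.get("sizes_csv"):
        size_i = initiation_size(a_i, _io.read_sizes(base / entry["sizes_csv"]))

    per_ori = None
    if entry.get("dnaa_per_cell") is not None:
        per_ori = dnaa_per_ori(float(entry["dnaa_per_cell"]), origins)

    report = CellCycleReport(
        strain_id=str(entry["id"]),
        tau=tau,
        ori_ter=ratio,
        origins_per_cell=origins,
        c_period=c,
        d_period=d,
        initiation_age=a_i,
        initiation_size=size_i,
        dnaa_per_ori=per_ori,
        d_period_ok=ok,
    )
    log.info(
        "strain %s: ori/ter=%.3f origins=%.2f C=%.1f D=%.1f a_i=%.3f",
        report.strain_id, ratio, origins, c, d, a_i,
    )
    return report, entry


def run_report(config_path: str | Path) -> list[CellCycleReport]:
    """Run the full chain for every strain in a YAML config.

    The reference strain (``reference`` key, default: first strain) anchors
    relative mass and initiation delays.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise ParseError(f"config file not found: {config_path}")
    try:
        config = yaml.safe_load(config_path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"could not parse {config_path}: {exc}") from exc
    if not isinstance(config, dict) or not config.get("strains"):
        raise ParseError(f"{config_path}: config must contain a non-empty 'strains' list")

    base = config_path.parent
    results = [_strain_report(entry, base) for entry in config["strains"]]

    ref_id = config.get("reference", results[0][0].strain_id)
    ref = {r.strain_id: (r, e) for r, e in results}.get(str(ref_id))
    if ref is None:
        raise ValidationError(f"reference strain {ref_id!r} not among strains")
    ref_report, ref_entry = ref

    out = []
    for report, entry in results:
        rel_mass = None
        if entry.get("counts") and ref_entry.get("counts"):
            rel_mass = relative_mass_per_cell(
                CountMeasurement(**ref_entry["counts"]),
                CountMeasurement(**entry["counts"]),
            )
        delay = None
        if report.strain_id != ref_report.strain_id:
            delay = initiation_delay(
                report.initiation_age, report.tau,
                ref_report.initiation_age, ref_report.tau,
            )
        out.append(
            dataclasses.replace(report, relative_mass=rel_mass, initiation_delay_min=delay)
        )
    return out


_ROUNDING = {  # human-readable (CSV) precision; JSON keeps full precision
    "tau": 1, "ori_ter": 2, "origins_per_cell": 2, "c_period": 1,
    "d_period": 1, "initiation_age": 2, "initiation_size": 2,
    "dnaa_per_ori": 0, "relative_mass": 2, "initiation_delay_min": 1,
}


def reports_to_frame(reports: list[CellCycleReport], *, rounded: bool = True) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in reports]
    df = pd.DataFrame(rows)
    if rounded:
        for col, nd in _ROUNDING.items():
            if col in df.columns:
                df[col] = df[col].round(nd)
    return df


def write_reports(reports: list[CellCycleReport], path: str | Path, fmt: str = "json") -> None:
    """Serialize reports as JSON (full precision) or CSV (table precision)."""
    path = Path(path)
    if fmt == "json":
        payload = [dataclasses.asdict(r) for r in reports]
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        reports_to_frame(reports).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'json' or 'csv')")
    log.info("wrote %s (%s, %d strains)", path, fmt, len(reports))
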