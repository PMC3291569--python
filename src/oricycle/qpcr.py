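"""Pfaffl relative quantification of ori/ter marker frequency.

Origin- and terminus-proximal amplicons are quantified by qPCR in the sample
of interest and in a calibrator whose true ori:ter ratio is 1 (replication
run-out cells or spore DNA).  The efficiency-corrected ratio is

    ratio = E_ori^(Cq_ori,cal - Cq_ori,sample) / E_ter^(Cq_ter,cal - Cq_ter,sample)

with per-cycle amplification efficiencies ``E`` in (1, 2].  The ratio feeds
the marker-frequency relation ``C = tau · log2(ratio)``; combined with mean
origins per cell from run-out flow cytometry this yields the D period.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ParseError, ValidationError
from .model import c_period_from_ratio, d_period

__all__ = [
    "QpcrMarkerData",
    "pfaffl_ori_ter_ratio",
    "infer_c_and_d",
    "pfaffl_from_table",
    "QPCR_COLUMNS",
]

QPCR_COLUMNS = ("sample_id", "target", "role", "cq", "efficiency")


@dataclass(frozen=True)
class QpcrMarkerData:
    """Quantification cycles and efficiencies for one sample/calibrator pair.

    Technical replicates should be averaged on the Cq scale (the log-domain
    quantity) before constructing this record.
    """

    cq_ori_sample: float
    cq_ter_sample: float
    cq_ori_calibrator: float
    cq_ter_calibrator: float
    eff_ori: float = 2.0
    eff_ter: float = 2.0

    def __post_init__(self) -> None:
        for name in ("cq_ori_sample", "cq_ter_sample", "cq_ori_calibrator", "cq_ter_calibrator"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        for name in ("eff_ori", "eff_ter"):
            e = getattr(self, name)
            if not (1.0 < e <= 2.0):
                raise ValidationError(
                    f"{name} must be a per-cycle efficiency in (1, 2], got {e!r}"
                )


def pfaffl_ori_ter_ratio(data: QpcrMarkerData) -> float:
    """Efficiency-corrected ori/ter ratio normalized to a 1:1 calibrator."""
    dcq_ori = data.cq_ori_calibrator - data.cq_ori_sample
    dcq_ter = data.cq_ter_calibrator - data.cq_ter_sample
    return data.eff_ori ** dcq_ori / data.eff_ter ** dcq_ter


def infer_c_and_d(
    ratio: float, origins: float, tau: float
) -> tuple[float, float, bool]:
    """C and D periods from an ori/ter ratio and mean origins per cell.

    ``C = tau · log2(ratio)``; ``D = tau · log2(origins) - C``.  Returns
    ``(C, D, ok)`` where ``ok`` is False when the implied D is negative
    (mutually inconsistent measurements).
    """
    c = c_period_from_ratio(ratio, tau)
    if c == 0:
        warnings.warn(
            "ori/ter ratio of 1 implies a degenerate C period of 0",
            stacklevel=2,
        )
    d, ok = d_period(origins, tau, c)
    return c, d, ok


def pfaffl_from_table(table: pd.DataFrame) -> dict[str, float]:
    """Per-sample Pfaffl ori/ter ratios from a long-format qPCR table.

    Expected columns: ``sample_id, target (ori|ter), role (sample|calibrator),
    cq, efficiency``.  Replicate rows (same sample/target/role) are averaged
    on the Cq scale.  All samples share the table's calibrator rows.
    """
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"qPCR table missing columns: {missing}")
    bad_target = set(table["target"]) - {"ori", "ter"}
    if bad_target:
        raise ParseError(f"unknown qPCR targets: {sorted(bad_target)}")
    bad_role = set(table["role"]) - {"sample", "calibrator"}
    if bad_role:
        raise ParseError(f"unknown qPCR roles: {sorted(bad_role)}")

    cal = table[table["role"] == "calibrator"]
    if cal.empty:
        raise ParseError("qPCR table has no calibrator rows")
    cal_cq = cal.groupby("target")["cq"].mean()
    eff = table.groupby("target")["efficiency"].mean()
    for t in ("ori", "ter"):
        if t not in cal_cq.index:
            raise ParseError(f"calibrator lacks {t!r} rows")

    out: dict[str, float] = {}
    samples = table[table["role"] == "sample"]
    for sid, grp in samples.groupby("sample_id"):
        cq = grp.groupby("target")["cq"].mean()
        if "ori" not in cq.index or "ter" not in cq.index:
            raise ParseError(f"sample {sid!r} lacks ori or ter rows")
        data = QpcrMarkerData(
            cq_ori_sample=float(cq["ori"]),
            cq_ter_sample=float(cq["ter"]),
            cq_ori_calibrator=float(cal_cq["ori"]),
            cq_ter_calibrator=float(cal_cq["ter"]),
            eff_ori=float(eff["ori"]),
            eff_ter=float(eff["ter"]),
        )
        out[str(sid)] = pfaffl_ori_ter_ratio(data)
    if not out:
        raise ParseError("qPCR table has no sample rows")
    return out
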