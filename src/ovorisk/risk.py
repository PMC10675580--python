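"""Non-carcinogenic dietary risk from metals in eggs: THQ and TTHQ.

The Target Hazard Quotient for a metal compares the chronic daily intake
through egg consumption against its oral reference dose:

    THQ = (EF · ED · IR · C) / (BW · AT · RfD)

with EF exposure frequency (days/year), ED exposure duration (years),
IR egg intake rate (kg/person/day), C the metal concentration in the eaten
fraction (mg/kg), BW body weight (kg), AT averaging time (days) and RfD the
oral reference dose (mg/kg/day).  With the default adult parameters
AT = EF·ED so the time factor cancels and THQ = C·IR/(BW·RfD).  Summing over
metals gives the Total THQ; TTHQ ≤ 1 means no anticipated non-carcinogenic
risk, TTHQ > 1 flags potential adverse effects.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .concentration import ElementTable, substitute_nondetects

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureParams:
    """Adult chronic-exposure defaults: lifetime daily egg consumption."""

    ef: float = 365.0            # exposure frequency, days/year
    ed: float = 75.88            # exposure duration, years (adult lifetime)
    ir: float = 0.0328           # egg intake rate, kg/person/day
    bw: float = 70.0             # body weight, kg
    at: float = 365.0 * 75.88    # averaging time, days

    def __post_init__(self) -> None:
        for name in ("ef", "ed", "ir", "bw", "at"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


#: oral reference doses, µg/kg/day (converted to mg/kg/day inside compute_thq)
DEFAULT_RFD_UG: dict[str, float] = {
    "Al": 1000.0, "Cr": 1500.0, "Mn": 140.0, "Co": 43.0,
    "Ni": 20.0, "Cu": 40.0, "Zn": 300.0, "As": 0.304,
    "Cd": 1.0, "Sn": 0.3, "Hg": 0.571, "Pb": 3.57,
}


class RfDRegistry(dict):
    """metal symbol → oral reference dose in µg/kg/day (all > 0)."""

    def __init__(self, doses: Mapping[str, float] | None = None):
        doses = dict(DEFAULT_RFD_UG if doses is None else doses)
        bad = {m: v for m, v in doses.items() if not v > 0}
        if bad:
            raise ValueError(f"reference doses must be > 0: {bad}")
        super().__init__(doses)


def compute_thq(
    conc: float,
    metal: str,
    params: ExposureParams | None = None,
    rfd: Mapping[str, float] | None = None,
) -> float:
    """THQ (dimensionless) for one metal concentration in mg/kg."""
    params = params or ExposureParams()
    rfd = rfd if rfd is not None else RfDRegistry()
    if metal not in rfd:
        raise KeyError(
            f"no oral reference dose for {metal!r}; known metals: "
            f"{sorted(rfd)}"
        )
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    rfd_mg = rfd[metal] / 1000.0  # µg/kg/day -> mg/kg/day
    return (params.ef * params.ed * params.ir * conc) / (
        params.bw * params.at * rfd_mg
    )


def compute_tthq(
    thqs: Mapping[str, float] | Iterable[tuple[str, float]],
) -> tuple[float, bool]:
    """Sum per-metal THQs; the risk flag is True iff TTHQ > 1."""
    pairs = list(thqs.items()) if isinstance(thqs, Mapping) else list(thqs)
    if not pairs:
        raise ValueError("at least one per-metal THQ is required")
    metals = [m for m, _ in pairs]
    if len(metals) != len(set(metals)):
        dupes = sorted({m for m in metals if metals.count(m) > 1})
        raise ValueError(f"duplicated metals would double count: {dupes}")
    tthq = float(sum(v for _, v in pairs))
    return tthq, tthq > 1.0


@dataclass
class THQReport:
    """Per-egg THQ breakdown plus rearing-system summaries.

    per_sample: one row per egg — sample_id, system, per-metal concentration
    used (mg/kg) and THQ, TTHQ and risk_flag.  summary: min/mean/max TTHQ per
    rearing system.  metals: the metals that entered the sum.
    """

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    metals: list[str]

    def __post_init__(self) -> None:
        thq_cols = [f"THQ_{m}" for m in self.metals]
        total = self.per_sample[thq_cols].sum(axis=1).to_numpy()
        if not np.allclose(total, self.per_sample["TTHQ"].to_numpy()):
            raise ValueError("TTHQ must equal the sum of per-metal THQs")
        if (self.per_sample[thq_cols].to_numpy() < 0).any():
            raise ValueError("THQ values must be >= 0")
        expect = self.per_sample["TTHQ"].to_numpy() > 1.0
        if not (self.per_sample["risk_flag"].to_numpy() == expect).all():
            raise ValueError("risk_flag must be TTHQ > 1 exactly")


def edible_concentration(
    white: pd.Series | None,
    yolk: pd.Series | None,
    rule: str = "mean",
    white_mass_fraction: float = 0.5,
) -> pd.Series:
    """Combine white and yolk concentrations into the eaten fraction.

    'mean' averages the two components; 'mass_weighted' weights white by
    ``white_mass_fraction`` (dry-mass basis).  A missing component falls
    back to the other one.
    """
    if white is None and yolk is None:
        raise ValueError("an egg needs at least one edible component")
    if white is None:
        return yolk
    if yolk is None:
        return white
    if rule == "mean":
        w = 0.5
    elif rule == "mass_weighted":
        if not 0 < white_mass_fraction < 1:
            raise ValueError("white_mass_fraction must be in (0, 1)")
        w = white_mass_fraction
    else:
        raise ValueError(f"unknown edible rule {rule!r}")
    return w * white + (1 - w) * yolk


def risk_by_group(
    table: ElementTable,
    params: ExposureParams | None = None,
    rfd: Mapping[str, float] | None = None,
    edible_rule: str = "mean",
    white_mass_fraction: float = 0.5,
    metals: Sequence[str] | None = None,
    moisture_factor: float | None = None,
) -> THQReport:
    """Per-egg THQ/TTHQ on the edible fraction, summarized by system.

    Shell rows are excluded from exposure (not eaten).  Metals present in
    the reference-dose registry but absent from the table are skipped with
    a warning, never imputed.  ``moisture_factor`` optionally rescales the
    dry-weight concentrations to a fresh-weight basis (default off).
    """
    params = params or ExposureParams()
    rfd = rfd if rfd is not None else RfDRegistry()
    if table.has_nondetects():
        logger.info("non-detects present; applying the zero policy for risk")
        table = substitute_nondetects(table, "zero")

    wanted = list(metals) if metals is not None else sorted(rfd)
    used = [m for m in wanted if m in table.elements and m in rfd]
    skipped = [m for m in wanted if m not in used]
    if skipped:
        warnings.warn(
            f"metals without concentration data or reference dose skipped: "
            f"{skipped}", stacklevel=2,
        )
    if not used:
        raise ValueError("no metal with both concentrations and a reference dose")

    rows = []
    for sample_id, egg in table.data.groupby("sample_id", sort=True):
        parts = {p: sub.iloc[0] for p, sub in egg.groupby("egg_part")}
        white = parts.get("white")
        yolk = parts.get("yolk")
        if white is None and yolk is None:
            warnings.warn(
                f"egg {sample_id!r} lacks both edible parts; skipped",
                stacklevel=2,
            )
            continue
        conc = edible_concentration(
            white[used] if white is not None else None,
            yolk[used] if yolk is not None else None,
            rule=edible_rule,
            white_mass_fraction=white_mass_fraction,
        ).astype(float)
        if moisture_factor is not None:
            conc = conc * moisture_factor
        rec: dict = {
            "sample_id": sample_id,
            "system": egg["system"].iloc[0],
        }
        thqs = {}
        for m in used:
            rec[f"C_{m}"] = conc[m]
            thqs[m] = compute_thq(conc[m], m, params, rfd)
            rec[f"THQ_{m}"] = thqs[m]
        rec["TTHQ"], rec["risk_flag"] = compute_tthq(thqs)
        rows.append(rec)

    per_sample = pd.DataFrame(rows)
    summary = (
        per_sample.groupby("system")["TTHQ"]
        .agg(["min", "mean", "max", "count"])
        .reset_index()
    )
    return THQReport(per_sample=per_sample, summary=summary, metals=used)
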