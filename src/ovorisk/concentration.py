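"""Element tables, digestion-record conversion and non-detect handling.

Concentrations are carried end-to-end in mg/kg dry weight (1 µg/g == 1 mg/kg),
digest-solution concentrations in µg/L, solution volumes in L and dry sample
masses in g.  Unit conversions live here and nowhere else.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, ElementPanel

logger = logging.getLogger(__name__)

PARTS = ("white", "yolk", "shell")
SYSTEMS = ("home", "commercial")
META_COLS = ("sample_id", "egg_part", "system")

#: strings read as a non-detect cell in CSV input
ND_TOKENS = ("", "ND", "nd", "N.D.", "<LOD")

ND_POLICIES = ("zero", "half_lod", "drop")


@dataclass
class DigestionRecord:
    """One acid-digest measurement for a single dried sample.

    ``solution_conc`` is the metal concentration measured in the digest
    solution (µg/L) — named so because the chemical symbol Cs (caesium) is
    also an element column elsewhere.  ``volume`` is the made-up solution
    volume (L) and ``dry_mass`` the dry sample mass (g).
    """

    sample_id: str
    solution_conc: float
    volume: float
    dry_mass: float
    nondetect: bool = False

    def validate(self) -> None:
        if not self.volume > 0:
            raise ValueError(f"volume must be > 0, got {self.volume}")
        if not self.dry_mass > 0:
            raise ValueError(f"dry_mass must be > 0, got {self.dry_mass}")
        if not self.nondetect and self.solution_conc < 0:
            raise ValueError(
                f"solution_conc must be >= 0 unless flagged non-detect, "
                f"got {self.solution_conc}"
            )


def convert_concentration(rec: DigestionRecord) -> float:
    """Tissue concentration in µg/g dry weight: Ct = Cs·Vs / Wt.

    A non-detect record stays a non-detect: NaN is returned so the flag can
    be propagated by the caller.
    """
    rec.validate()
    if rec.nondetect:
        return math.nan
    return rec.solution_conc * rec.volume / rec.dry_mass


@dataclass
class ElementTable:
    """Samples × elements concentration matrix with per-cell non-detect flags.

    ``data`` holds the metadata columns (sample_id, egg_part, system) followed
    by one float64 column per element; non-detect cells are NaN in ``data``
    and True in the boolean mask ``nd`` (element columns only, same index).
    ``lod`` optionally maps element → limit of detection (mg/kg) for
    half-LOD substitution.  ``attrs`` carries generator provenance such as
    injected-outlier ids.
    """

    data: pd.DataFrame
    nd: pd.DataFrame
    lod: dict[str, float] | None = None
    panel: ElementPanel = field(default_factory=lambda: DEFAULT_PANEL)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def elements(self) -> list[str]:
        return [c for c in self.data.columns if c not in META_COLS]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def matrix(self) -> pd.DataFrame:
        """Numeric element matrix indexed by 'sample_id:egg_part'."""
        idx = self.data["sample_id"].astype(str) + ":" + self.data["egg_part"]
        out = self.data[self.elements].copy()
        out.index = pd.Index(idx, name="sample")
        return out

    def validate(self) -> None:
        missing = [c for c in META_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing metadata columns: {missing}")
        if self.data[list(META_COLS)].isna().any().any():
            raise ValueError("metadata columns must be non-missing")
        bad_part = set(self.data["egg_part"]) - set(PARTS)
        if bad_part:
            raise ValueError(f"unknown egg_part values: {sorted(bad_part)}")
        bad_sys = set(self.data["system"]) - set(SYSTEMS)
        if bad_sys:
            raise ValueError(f"unknown system values: {sorted(bad_sys)}")
        dup = self.data.duplicated(subset=["sample_id", "egg_part"])
        if dup.any():
            pairs = self.data.loc[dup, ["sample_id", "egg_part"]].values.tolist()
            raise ValueError(f"duplicated (sample_id, egg_part) pairs: {pairs}")
        unknown = [e for e in self.elements if e not in self.panel]
        if unknown:
            raise ValueError(f"elements outside the declared panel: {unknown}")
        vals = self.data[self.elements].to_numpy(float)
        if np.nanmin(vals, initial=0) < 0:
            raise ValueError("negative concentrations are not allowed")
        if list(self.nd.columns) != self.elements or len(self.nd) != len(self.data):
            raise ValueError("nd mask must mirror the element columns")
        # every ND cell must carry no numeric value
        masked = self.data[self.elements].to_numpy(float)[self.nd.to_numpy(bool)]
        if masked.size and not np.isnan(masked).all():
            raise ValueError("non-detect cells must hold NaN, not numbers")

    def has_nondetects(self) -> bool:
        return bool(self.nd.to_numpy(bool).any())

    def copy(self) -> "ElementTable":
        return ElementTable(
            self.data.copy(), self.nd.copy(),
            lod=dict(self.lod) if self.lod else None,
            panel=self.panel, attrs=dict(self.attrs),
        )


# -- CSV I/O ----------------------------------------------------------
def read_element_table(
    path: str | Path, panel: ElementPanel = DEFAULT_PANEL
) -> ElementTable:
    """Read a comma-separated, UTF-8, '.'-decimal element table.

    'ND'-like and empty cells become non-detect flags.  Unknown element
    columns are dropped with a warning; thousands separators are rejected
    (a cell like "15,373.56" fails float parsing by design).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in META_COLS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing metadata columns: {missing}")
    element_cols = []
    for col in raw.columns:
        if col in META_COLS:
            continue
        if col not in panel:
            warnings.warn(f"unknown element column {col!r} excluded", stacklevel=2)
            continue
        element_cols.append(col)

    data = raw[list(META_COLS)].copy()
    nd = pd.DataFrame(False, index=raw.index, columns=element_cols)
    for col in element_cols:
        cells = raw[col].str.strip()
        is_nd = cells.isin(ND_TOKENS)
        vals = np.full(len(cells), np.nan)
        for i, (cell, flag) in enumerate(zip(cells, is_nd)):
            if not flag:
                vals[i] = float(cell)  # raises on thousands separators
        data[col] = vals
        nd[col] = is_nd.to_numpy()
    return ElementTable(data, nd, panel=panel)


def write_element_table(table: ElementTable, path: str | Path) -> None:
    """Write the table; non-detect cells are written as 'ND'.

    Numeric cells are serialized with shortest round-trip repr so a
    read→write→read cycle is bit-exact.
    """
    out = table.data[list(META_COLS)].copy()
    nd = table.nd.to_numpy(bool)
    for j, col in enumerate(table.elements):
        vals = table.data[col].to_numpy(float)
        out[col] = [
            "ND" if nd[i, j] else repr(float(v)) for i, v in enumerate(vals)
        ]
    out.to_csv(path, index=False)


# -- non-detect substitution ------------------------------------------
def substitute_nondetects(
    table: ElementTable,
    policy: str = "zero",
    lod: Mapping[str, float] | None = None,
) -> ElementTable:
    """Resolve non-detect flags under a substitution policy.

    zero     — replace by 0 (conservative under-count for risk scoring)
    half_lod — replace by LOD/2 (needs an LOD map, argument or table.lod)
    drop     — leave the cell empty; downstream summaries exclude it
    """
    if policy not in ND_POLICIES:
        raise ValueError(f"policy must be one of {ND_POLICIES}, got {policy!r}")
    out = table.copy()
    mask = out.nd.to_numpy(bool)
    n_sub = int(mask.sum())
    if policy == "half_lod":
        lod = lod if lod is not None else table.lod
        if lod is None:
            raise ValueError("half_lod policy requires an LOD map")
        flagged_elems = [e for j, e in enumerate(out.elements) if mask[:, j].any()]
        absent = [e for e in flagged_elems if e not in lod]
        if absent:
            raise ValueError(f"no LOD supplied for flagged elements: {absent}")
    for j, col in enumerate(out.elements):
        if not mask[:, j].any():
            continue
        if policy == "zero":
            out.data.loc[mask[:, j], col] = 0.0
        elif policy == "half_lod":
            out.data.loc[mask[:, j], col] = lod[col] / 2.0
        # drop: keep NaN
    out.nd.loc[:, :] = False
    logger.info("substituted %d non-detect cells with policy=%s", n_sub, policy)
    return out


# -- summaries --------------------------------------------------------
def summarize_elements(
    table: ElementTable,
    by: Sequence[str] | None = ("egg_part",),
) -> pd.DataFrame:
    """Min/max/mean (and n) per element per group, NaN cells excluded.

    Empty (element, group) cells are reported as missing, never as zero.
    Returns a long-format frame with one row per (group, element).
    """
    by = list(by) if by else []
    bad = [c for c in by if c not in META_COLS]
    if bad:
        raise ValueError(f"grouping columns must be metadata columns, got {bad}")
    values = table.data[by + table.elements]
    if by:
        grouped = values.groupby(by, observed=True)
    else:
        grouped = [((), values)]
        grouped = dict(grouped).items()
    rows = []
    for key, frame in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for el in table.elements:
            col = frame[el].dropna()
            rec = dict(zip(by, key))
            rec["element"] = el
            rec["n"] = int(col.size)
            rec["min"] = col.min() if col.size else np.nan
            rec["max"] = col.max() if col.size else np.nan
            rec["mean"] = col.mean() if col.size else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)
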