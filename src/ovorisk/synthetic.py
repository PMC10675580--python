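"""Synthetic egg-composition generator.

Stands in for the study's raw ICP-MS data (not deposited): 70 eggs by
default (55 home, 15 commercial), three component samples each (white,
yolk, shell), 64 elements.  Marginals are lognormal — concentrations are
positive and right-skewed — calibrated so each (element, part, system) cell
hits its target mean, with the spread solved from reported min–max
envelopes where available (≈99% of mass inside) and a default geometric SD
of 1.8 otherwise.  Cross-element correlation is realized through a Gaussian
copula with sparse common-factor blocks; left-censoring (non-detects) and a
small number of extreme outlier samples are injected on top.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .concentration import ElementTable
from .panel import DEFAULT_PANEL, ElementPanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------
@dataclass(frozen=True)
class CellParams:
    mu: float      # lognormal location (log mg/kg)
    sigma: float   # lognormal scale (log units)


class CalibrationTable:
    """Per (element, part, system) lognormal parameters from target means.

    The spread comes from a reported (min, max) envelope when both ends are
    present (the log-range spans 2·z_range sigmas), from a one-sided solve
    when only a max is reported, and from ``default_gsd`` otherwise.
    Rearing-system effects enter as multiplicative factors: the reported
    per-system means divided by their egg-count-weighted pool.
    """

    PARTS = ("white", "yolk", "shell")
    SYSTEMS = ("home", "commercial")

    def __init__(self, raw: dict, panel: ElementPanel = DEFAULT_PANEL):
        self.raw = raw
        self.panel = panel
        self.n_eggs: dict[str, int] = dict(raw.get("n_eggs", {"home": 55, "commercial": 15}))
        self.default_gsd = float(raw.get("default_gsd", 1.8))
        self.z_range = float(raw.get("z_range", 2.5758))
        self.group_means = dict(raw.get("group_means", {}))
        self._nd = dict(raw.get("nd", {}))
        self._group_nd = dict(raw.get("group_nd", {}))
        self.blocks: list[dict] = list(raw.get("blocks", []))
        self.outlier_spec = dict(raw.get("outliers", {"count": 3, "sd": 10.0, "n_elements": 8}))
        self._validate()
        self._cells: dict[tuple[str, str, str], CellParams] = {}

    @classmethod
    def default(cls, panel: ElementPanel = DEFAULT_PANEL) -> "CalibrationTable":
        text = resources.files("ovorisk.data").joinpath("calibration.yaml").read_text()
        return cls(yaml.safe_load(text), panel=panel)

    @classmethod
    def from_yaml(cls, path: str | Path, panel: ElementPanel = DEFAULT_PANEL) -> "CalibrationTable":
        return cls(yaml.safe_load(Path(path).read_text()), panel=panel)

    def _validate(self) -> None:
        for e, entry in self.raw.get("elements", {}).items():
            for part, cell in entry.get("parts", {}).items():
                m = cell.get("mean")
                lo, hi = cell.get("min"), cell.get("max")
                if m is None or m < 0:
                    raise ValueError(f"{e}/{part}: mean must be >= 0")
                if lo is not None and hi is not None and not lo <= m <= hi:
                    raise ValueError(f"{e}/{part}: mean outside (min, max)")

    # -- lookups -------------------------------------------------------
    def _entry(self, element: str) -> dict:
        entry = self.raw.get("elements", {}).get(element)
        if entry is not None:
            return entry
        group = self.panel.group_of(element)
        if group in self.group_means:
            m = float(self.group_means[group])
            return {"parts": {p: {"mean": m} for p in self.PARTS}}
        raise KeyError(f"no calibration and no group default for element {element!r}")

    def nd_rate(self, element: str) -> float:
        if element in self._nd:
            return float(self._nd[element])
        return float(self._group_nd.get(self.panel.group_of(element), 0.0))

    def _sigma(self, mean: float, lo: float | None, hi: float | None) -> float:
        default = math.log(self.default_gsd)
        if lo is not None and hi is not None and lo > 0:
            return (math.log(hi) - math.log(lo)) / (2 * self.z_range)
        if hi is not None and hi > mean > 0:
            # solve ln(max) = mu + z*sigma with mu = ln(mean) - sigma^2/2
            z = self.z_range
            disc = z * z - 2 * (math.log(hi) - math.log(mean))
            if disc > 0:
                return z - math.sqrt(disc)
        return default

    def system_factor(self, element: str, system: str) -> float:
        entry = self._entry(element)
        sys_means = entry.get("systems")
        if not sys_means:
            return 1.0
        n = self.n_eggs
        total = sum(n.values())
        pooled = sum(n[s] * float(sys_means[s]) for s in sys_means) / total
        return float(sys_means[system]) / pooled

    def cell(self, element: str, part: str, system: str) -> CellParams:
        key = (element, part, system)
        if key not in self._cells:
            entry = self._entry(element)
            cell = entry["parts"].get(part)
            if cell is None:
                raise KeyError(f"no calibration for {element!r} part {part!r}")
            mean = float(cell["mean"]) * self.system_factor(element, system)
            sigma = self._sigma(float(cell["mean"]), cell.get("min"), cell.get("max"))
            if mean <= 0:  # degenerate target: park far below any LOD
                self._cells[key] = CellParams(mu=-np.inf, sigma=sigma)
            else:
                self._cells[key] = CellParams(mu=math.log(mean) - sigma**2 / 2, sigma=sigma)
        return self._cells[key]


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------
@dataclass
class SyntheticConfig:
    """Everything that determines one synthetic dataset.

    ``n_eggs`` per rearing system; ``elements`` defaults to the full
    64-element panel; ``blocks`` are copula common-factor blocks
    (name, element → signed loading); ``outlier_*`` control injected
    extreme samples; ``seed`` makes the dataset bit-reproducible.
    """

    calibration: CalibrationTable = field(default_factory=CalibrationTable.default)
    n_eggs: dict[str, int] | None = None
    elements: tuple[str, ...] | None = None
    blocks: list[dict] | None = None
    outlier_count: int | None = None
    outlier_sd: float | None = None
    outlier_n_elements: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        cal = self.calibration
        if self.n_eggs is None:
            self.n_eggs = dict(cal.n_eggs)
        if self.elements is None:
            self.elements = tuple(cal.panel.symbols)
        if self.blocks is None:
            self.blocks = [dict(b) for b in cal.blocks]
        spec = cal.outlier_spec
        if self.outlier_count is None:
            self.outlier_count = int(spec.get("count", 3))
        if self.outlier_sd is None:
            self.outlier_sd = float(spec.get("sd", 10.0))
        if self.outlier_n_elements is None:
            self.outlier_n_elements = int(spec.get("n_elements", 8))
        for s, n in self.n_eggs.items():
            if n < 1:
                raise ValueError(f"n_eggs[{s!r}] must be >= 1")
        for b in self.blocks:
            loadings = np.array(list(b["loadings"].values()), float)
            if (np.abs(loadings) > 1).any():
                raise ValueError(f"block {b.get('name')}: |loading| must be <= 1")
            unknown = [e for e in b["loadings"] if e not in self.elements]
            if unknown:
                raise ValueError(f"block {b.get('name')}: unknown elements {unknown}")


# ---------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------
def _loading_matrix(config: SyntheticConfig) -> np.ndarray:
    """(p, B) signed copula loadings; rows are checked for unit-variance room."""
    p = len(config.elements)
    B = len(config.blocks)
    L = np.zeros((p, B))
    col = {e: j for j, e in enumerate(config.elements)}
    for b, block in enumerate(config.blocks):
        for e, lam in block["loadings"].items():
            L[col[e], b] = float(lam)
    ss = (L**2).sum(axis=1)
    if (ss > 1).any():
        bad = [config.elements[j] for j in np.flatnonzero(ss > 1)]
        raise ValueError(f"summed squared loadings exceed 1 for {bad}")
    return L


def generate(config: SyntheticConfig, seed: int | None = None) -> ElementTable:
    """Draw one synthetic dataset: 3 rows (white, yolk, shell) per egg.

    The returned table carries the injected-outlier row ids in
    ``table.attrs['outliers']`` and a per-element LOD map for half-LOD
    substitution of the censored cells.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cal = config.calibration
    elements = list(config.elements)
    p = len(elements)

    meta = []
    prefix = {"home": "H", "commercial": "C"}
    for system in ("home", "commercial"):
        for i in range(config.n_eggs.get(system, 0)):
            sid = f"{prefix[system]}{i + 1:03d}"
            for part in ("white", "yolk", "shell"):
                meta.append((sid, part, system))
    n = len(meta)

    L = _loading_matrix(config)
    resid = np.sqrt(1.0 - (L**2).sum(axis=1))
    factors = rng.standard_normal((n, L.shape[1])) if L.shape[1] else np.zeros((n, 0))
    eps = rng.standard_normal((n, p))
    Z = factors @ L.T + eps * resid  # standard-normal marginals, block-correlated

    mu = np.empty((n, p))
    sigma = np.empty((n, p))
    for j, e in enumerate(elements):
        for i, (_, part, system) in enumerate(meta):
            c = cal.cell(e, part, system)
            mu[i, j] = c.mu
            sigma[i, j] = c.sigma
    values = np.exp(mu + sigma * Z)

    # left-censor at the per-cell nd_rate quantile (marginals are standard
    # normal on the latent scale, so the censored fraction equals nd_rate)
    nd = np.zeros((n, p), bool)
    lod: dict[str, float] = {}
    for j, e in enumerate(elements):
        rate = cal.nd_rate(e)
        if rate <= 0:
            continue
        zq = stats.norm.ppf(rate)
        nd[:, j] = Z[:, j] < zq
        lod[e] = float(np.exp(mu[:, j] + sigma[:, j] * zq).max())

    # outliers: a few whole rows perturbed by +outlier_sd on random elements
    outlier_rows = []
    if config.outlier_count:
        rows = rng.choice(n, size=config.outlier_count, replace=False)
        for i in rows:
            cols = rng.choice(p, size=min(config.outlier_n_elements, p), replace=False)
            values[i, cols] = np.exp(mu[i, cols] + sigma[i, cols] * config.outlier_sd)
            nd[i, cols] = False
            outlier_rows.append(f"{meta[i][0]}:{meta[i][1]}")

    values[nd] = np.nan
    data = pd.DataFrame(meta, columns=["sample_id", "egg_part", "system"])
    data[elements] = values
    nd_frame = pd.DataFrame(nd, columns=elements)
    table = ElementTable(
        data, nd_frame, lod=lod or None, panel=cal.panel,
        attrs={"outliers": outlier_rows, "seed": int(config.seed if seed is None else seed)},
    )
    logger.info("generated %d rows x %d elements (%d ND, %d outliers)",
                n, p, int(nd.sum()), len(outlier_rows))
    return table


# ---------------------------------------------------------------------
# discriminative structure
# ---------------------------------------------------------------------
#: rearing-system marker elements with the sign of their association
#: (+1 elevated in home/backyard eggs, -1 elevated in commercial eggs)
DEFAULT_MARKERS: dict[str, int] = {
    "Li": +1, "Eu": +1, "Ba": +1, "As": +1, "V": +1, "Sc": +1, "Bi": +1,
    "Cd": +1, "Co": -1, "Ca": -1, "Ge": -1, "Rb": -1, "Mg": -1, "Hg": -1,
    "K": -1, "Cr": -1, "Al": -1,
}


@dataclass
class StructureSpec:
    """Marker signal to superimpose on a generated table.

    ``markers`` maps element → ±1 (sign of the home-system association);
    ``shift_sd`` is the standardized (log-scale) mean difference between the
    systems per marker.  ``cu_mg_loading`` rebuilds the Cu latent variable
    as -loading × the Mg latent plus fresh-scaled residual, producing an
    almost perfect negative rank correlation at high loadings.
    """

    markers: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    shift_sd: float = 0.5
    cu_mg_loading: float | None = None


def inject_structure(
    table: ElementTable,
    spec: StructureSpec,
    calibration: CalibrationTable | None = None,
) -> ElementTable:
    """Superimpose rearing-system marker shifts (and a Cu–Mg block).

    Marker cells of home-system rows are multiplied by
    exp(sign · shift_sd · sigma_cell), a mean shift of ``shift_sd`` SD on
    the log scale.  Works on any generated table; ND cells stay ND.
    """
    cal = calibration or CalibrationTable.default()
    unknown = [e for e in spec.markers if e not in table.elements]
    if unknown:
        raise ValueError(f"unknown marker elements: {unknown}")
    out = table.copy()
    home = (out.data["system"] == "home").to_numpy()
    for e, sign in spec.markers.items():
        if sign not in (-1, +1):
            raise ValueError(f"marker sign for {e!r} must be +1 or -1")
        sig = np.array([
            cal.cell(e, part, system).sigma
            for part, system in zip(out.data["egg_part"], out.data["system"])
        ])
        shift = np.where(home, np.exp(sign * spec.shift_sd * sig), 1.0)
        out.data[e] = out.data[e].to_numpy() * shift

    if spec.cu_mg_loading is not None:
        lam = float(spec.cu_mg_loading)
        if not 0 < abs(lam) <= 1:
            raise ValueError("cu_mg_loading must be in (0, 1]")
        z = {}
        for e in ("Cu", "Mg"):
            mu = np.empty(len(out.data))
            sg = np.empty(len(out.data))
            for i, (part, system) in enumerate(zip(out.data["egg_part"], out.data["system"])):
                c = cal.cell(e, part, system)
                mu[i], sg[i] = c.mu, c.sigma
            with np.errstate(invalid="ignore"):
                z[e] = ((np.log(out.data[e].to_numpy()) - mu) / sg, mu, sg)
        z_mg = z["Mg"][0]
        z_cu_old, mu_cu, sg_cu = z["Cu"]
        z_cu = -abs(lam) * z_mg + math.sqrt(1 - lam**2) * z_cu_old
        vals = np.exp(mu_cu + sg_cu * z_cu)
        keep_nd = out.nd["Cu"].to_numpy()
        vals[keep_nd | np.isnan(z_mg)] = np.nan
        out.data["Cu"] = vals
    return out
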