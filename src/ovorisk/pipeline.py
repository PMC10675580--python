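"""End-to-end reproduction pipeline.

Runs the full analysis in the study's order — generate (or load) the
element table, summarize, PCA on everything, trim score-space outliers,
PCA again, THQ/TTHQ risk scoring, then the two sparse PLS-DA tasks (egg
part; rearing system) — and writes every stage's artifacts plus a JSON
manifest with seeds and content hashes to a plain output directory.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concentration import (
    ElementTable, read_element_table, substitute_nondetects,
    summarize_elements, write_element_table,
)
from .pca import flag_outliers, pca_fit, variable_contributions
from .plsda import cross_validate, evaluate_holdout, plsda_fit
from .risk import ExposureParams, RfDRegistry, risk_by_group
from .synthetic import (
    CalibrationTable, StructureSpec, SyntheticConfig, generate, inject_structure,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "generate", "summarize", "pca_full", "outliers",
    "pca_trimmed", "risk", "plsda_part", "plsda_system",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproduction run: data source, policies, model settings, output."""

    outdir: str | Path = "ovorisk_run"
    source: str = "synthetic"            # "synthetic" or a CSV path
    seed: int = 0
    nd_policy: str = "zero"
    system_shift_sd: float = 0.5         # marker signal injected on synthetic data
    outlier_dims: int = 2
    outlier_quantile: float = 0.999
    outlier_ids: list[str] | None = None  # manual override of the trimming
    edible_rule: str = "mean"
    risk_metals: list[str] | None = None
    tune: bool = False
    folds: int = 5
    repeats: int = 10
    ncomp_grid: list[int] = field(default_factory=lambda: [1, 2, 3])
    keepx_grid: list[int] = field(
        default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 17, 20, 30, 50]
    )
    part_model: dict = field(
        default_factory=lambda: {"ncomp": 2, "keepx": [2, 1], "distance": "centroid"}
    )
    system_model: dict = field(
        default_factory=lambda: {"ncomp": 3, "keepx": [7, 5, 5], "distance": "centroid"}
    )
    train_frac: float = 0.7
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_pca(outdir: Path, tag: str, model) -> list[Path]:
    paths = []
    for name, frame in (
        ("scores", model.scores), ("loadings", model.loadings),
        ("contributions", model.contributions),
    ):
        p = outdir / f"{tag}_{name}.csv"
        frame.to_csv(p)
        paths.append(p)
    p = outdir / f"{tag}_variance.json"
    p.write_text(json.dumps(
        {"eigenvalues": model.eigenvalues.tolist(),
         "var_explained_pct": model.var_explained.tolist()}, indent=2))
    paths.append(p)
    return paths


def _plsda_task(outdir, tag, X, y, cfg, mcfg, seed):
    paths = []
    ncomp, keepx, dist = mcfg["ncomp"], mcfg["keepx"], mcfg["distance"]
    if cfg.tune:
        cv = cross_validate(
            X, y, ncomp_grid=cfg.ncomp_grid, keepx_grid=cfg.keepx_grid,
            folds=cfg.folds, repeats=cfg.repeats, seed=seed,
        )
        p = outdir / f"{tag}_cv_grid.csv"
        cv.grid.to_csv(p, index=False)
        paths.append(p)
        ncomp, keepx, dist = cv.best["ncomp"], cv.best["keepx"], cv.best["distance"]
    report, model = evaluate_holdout(
        X, y, ncomp=ncomp, keepx=keepx, distance=dist,
        train_frac=cfg.train_frac, seed=seed,
    )
    p = outdir / f"{tag}_report.json"
    p.write_text(json.dumps({
        "ncomp": int(ncomp),
        "keepx": list(np.atleast_1d(keepx).astype(int).tolist()),
        "distance": dist,
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "confusion": report.confusion.to_dict(),
        "selected": {f"comp{h + 1}": model.selected(h) for h in range(model.ncomp)},
    }, indent=2))
    paths.append(p)
    p = outdir / f"{tag}_scores.csv"
    pd.DataFrame(model.x_scores_,
                 columns=[f"comp{h + 1}" for h in range(model.ncomp)]
                 ).assign(label=model.y_train_).to_csv(p, index=False)
    paths.append(p)
    return paths


def reproduce(config: RunConfig) -> dict:
    """Run the configured stages and return the manifest (also written)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "ovorisk_version": __version__,
        "seed": config.seed,
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in asdict(config).items()},
        "stages": {},
    }
    outputs: dict[str, list[Path]] = {}

    def run_stage(name, fn):
        if name not in config.stages:
            return None
        try:
            paths = fn()
        except Exception as exc:  # halt with a stage-named error
            raise StageError(name, exc) from exc
        outputs[name] = paths
        manifest["stages"][name] = {
            str(p.relative_to(outdir)): _sha256(p) for p in paths
        }
        logger.info("stage %s: %d artifact(s)", name, len(paths))
        return paths

    # -- data ---------------------------------------------------------
    state: dict = {}

    def st_generate():
        if config.source == "synthetic":
            cal = CalibrationTable.default()
            table = generate(SyntheticConfig(calibration=cal, seed=config.seed))
            table = inject_structure(
                table, StructureSpec(shift_sd=config.system_shift_sd), cal)
        else:
            table = read_element_table(config.source)
        state["table_raw"] = table
        state["table"] = substitute_nondetects(table, config.nd_policy)
        p = outdir / "table.csv"
        write_element_table(table, p)
        paths = [p]
        if table.lod:
            p2 = outdir / "lod.json"
            p2.write_text(json.dumps(table.lod, indent=2, sort_keys=True))
            paths.append(p2)
        return paths

    def st_summarize():
        summary = summarize_elements(state["table"], by=("egg_part", "system"))
        p = outdir / "summary.csv"
        summary.to_csv(p, index=False)
        return [p]

    def st_pca_full():
        X = state["table"].matrix().dropna(axis=0)
        state["pca_full"] = pca_fit(X)
        state["X_full"] = X
        return _write_pca(outdir, "pca_full", state["pca_full"])

    def st_outliers():
        if config.outlier_ids is not None:
            flagged = list(config.outlier_ids)
            report = {"flagged": flagged, "rule": "manual"}
        else:
            rep = flag_outliers(
                state["pca_full"], dims=config.outlier_dims,
                quantile=config.outlier_quantile)
            flagged = rep.flagged
            report = {
                "flagged": flagged, "rule": "mahalanobis",
                "dims": rep.dims, "quantile": rep.quantile, "cutoff": rep.cutoff,
            }
        state["flagged"] = flagged
        p = outdir / "outliers.json"
        p.write_text(json.dumps(report, indent=2))
        return [p]

    def st_pca_trimmed():
        keep = [i for i in state["X_full"].index if i not in set(state["flagged"])]
        Xt = state["X_full"].loc[keep]
        state["X_trimmed"] = Xt
        state["pca_trimmed"] = pca_fit(Xt)
        return _write_pca(outdir, "pca_trimmed", state["pca_trimmed"])

    def st_risk():
        report = risk_by_group(
            state["table"], params=ExposureParams(), rfd=RfDRegistry(),
            edible_rule=config.edible_rule, metals=config.risk_metals,
        )
        p1 = outdir / "thq_per_sample.csv"
        report.per_sample.to_csv(p1, index=False)
        p2 = outdir / "thq_summary.csv"
        report.summary.to_csv(p2, index=False)
        return [p1, p2]

    def _task_data():
        table = state["table"]
        X = table.matrix().dropna(axis=0)
        if "flagged" in state:
            X = X.loc[[i for i in X.index if i not in set(state["flagged"])]]
        meta = table.data.set_index(
            table.data["sample_id"].astype(str) + ":" + table.data["egg_part"]
        ).loc[X.index]
        return X, meta

    def st_plsda_part():
        X, meta = _task_data()
        return _plsda_task(outdir, "plsda_part", X, meta["egg_part"].to_numpy(),
                           config, config.part_model, config.seed)

    def st_plsda_system():
        X, meta = _task_data()
        return _plsda_task(outdir, "plsda_system", X, meta["system"].to_numpy(),
                           config, config.system_model, config.seed + 1)

    run_stage("generate", st_generate)
    run_stage("summarize", st_summarize)
    run_stage("pca_full", st_pca_full)
    run_stage("outliers", st_outliers)
    run_stage("pca_trimmed", st_pca_trimmed)
    run_stage("risk", st_risk)
    run_stage("plsda_part", st_plsda_part)
    run_stage("plsda_system", st_plsda_system)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
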