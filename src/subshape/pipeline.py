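"""Stage orchestration: simulate -> extract -> stats -> classify.

Each stage reads only the previous stage's persisted outputs inside the
work directory, writes its own outputs plus a manifest entry, and is
fully reproducible: identical config + seed give identical output
checksums (timestamps live only in the manifest).

Work directory layout::

    cohort/     meshes, covariates.csv, ground_truth.json, manifest.json
    features/   features.csv (+ exclusions.csv)
    stats/      volume_effects.csv, glm_*.csv, tmap_*.vtk
    classify/   evaluation.json, roc_*.csv, importance.csv, overlays
    manifest.json, run.log
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import ShapeFeatureTable, extract_features
from .forest import FeatureMatrix, evaluate_feature_subsets, importance_to_surfaces
from .glm import MassUnivariateGLM, ModelSpec
from .mesh import save_mesh_with_scalars
from .synthetic import CohortBundle, CohortConfig, simulate_cohort

__all__ = ["RunConfig", "run_stage", "report"]

log = logging.getLogger("subshape")

STAGES = ("simulate", "extract", "stats", "classify")

_SCHEMA = {
    "seed": int,
    "cohort": dict,
    "features": dict,
    "stats": dict,
    "classify": dict,
}
_FEATURES_DEFAULTS = {"correspondence_mode": "given", "n_sections": 12,
                      "demons_iterations": 20}
_STATS_DEFAULTS = {"main_effects": ["HIVStatus"],
                   "outcomes": ["volume", "RD", "JD"], "q_threshold": 0.05}
_CLASSIFY_DEFAULTS = {"n_trees": 5000, "mtry": None, "scheme": "stratified2fold",
                      "B": 1000, "feature_subsets": ["all", "RD", "JD", "volume"],
                      "label": "HIVStatus"}


@dataclass
class RunConfig:
    """Validated end-to-end run configuration with documented defaults."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: dict = field(default_factory=lambda: dict(_FEATURES_DEFAULTS))
    stats: dict = field(default_factory=lambda: dict(_STATS_DEFAULTS))
    classify: dict = field(default_factory=lambda: dict(_CLASSIFY_DEFAULTS))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key, typ in _SCHEMA.items():
            if key in d and not isinstance(d[key], typ):
                raise ValueError(f"config field {key!r} must be a {typ.__name__}")
        cohort = CohortConfig.from_dict(d.get("cohort", {}))
        out = cls(seed=int(d.get("seed", 0)), cohort=cohort)
        for section, defaults in (("features", _FEATURES_DEFAULTS),
                                  ("stats", _STATS_DEFAULTS),
                                  ("classify", _CLASSIFY_DEFAULTS)):
            given = d.get(section, {})
            bad = set(given) - set(defaults)
            if bad:
                raise ValueError(f"unknown {section} config field(s): {sorted(bad)}")
            merged = dict(defaults)
            merged.update(given)
            setattr(out, section, merged)
        return out

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort": self.cohort.to_dict(),
            "features": self.features,
            "stats": self.stats,
            "classify": self.classify,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _checksum_dir(d: Path) -> dict:
    return {
        str(p.relative_to(d)): _sha256(p)
        for p in sorted(d.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "run.log")
    }


def _require(workdir: Path, sub: str, producing_stage: str) -> Path:
    p = workdir / sub
    if not p.exists():
        raise FileNotFoundError(
            f"missing {sub!r}: run the {producing_stage!r} stage first"
        )
    return p


def _load_specs(stats_cfg: dict) -> list[ModelSpec]:
    return [
        ModelSpec(outcome, main)
        for main in stats_cfg["main_effects"]
        for outcome in stats_cfg["outcomes"]
    ]


def _stage_simulate(config: RunConfig, workdir: Path) -> None:
    simulate_cohort(config.cohort, seed=config.seed, outdir=workdir / "cohort")


def _stage_extract(config: RunConfig, workdir: Path) -> None:
    bundle = CohortBundle.load(_require(workdir, "cohort", "simulate"))
    extract_features(
        bundle,
        correspondence_mode=config.features["correspondence_mode"],
        n_sections=config.features["n_sections"],
        register_kwargs={"demons_iterations": config.features["demons_iterations"]}
        if config.features["correspondence_mode"] == "estimated" else None,
        outdir=workdir / "features",
    )


def _stage_stats(config: RunConfig, workdir: Path) -> None:
    cohort_dir = _require(workdir, "cohort", "simulate")
    feat_dir = _require(workdir, "features", "extract")
    bundle = CohortBundle.load(cohort_dir)
    table = ShapeFeatureTable.from_csv(feat_dir / "features.csv")
    model = MassUnivariateGLM(table, bundle.covariates, _load_specs(config.stats))
    results = model.fit(q_threshold=config.stats["q_threshold"])
    results.save(workdir / "stats", templates=bundle.templates)
    counts = results.significant_vertex_counts()
    counts.to_csv(workdir / "stats" / "significant_vertex_counts.csv", index=False)


def _stage_classify(config: RunConfig, workdir: Path) -> None:
    cohort_dir = _require(workdir, "cohort", "simulate")
    feat_dir = _require(workdir, "features", "extract")
    bundle = CohortBundle.load(cohort_dir)
    table = ShapeFeatureTable.from_csv(feat_dir / "features.csv")
    cfg = config.classify
    fm = FeatureMatrix.from_feature_table(table, bundle.covariates, label=cfg["label"])
    evals = evaluate_feature_subsets(
        fm, subsets=tuple(cfg["feature_subsets"]), scheme=cfg["scheme"],
        seed=config.seed, n_trees=cfg["n_trees"], mtry=cfg["mtry"], B=cfg["B"],
    )
    out = workdir / "classify"
    out.mkdir(parents=True, exist_ok=True)
    (out / "evaluation.json").write_text(
        json.dumps([e.to_record() for e in evals], indent=1)
    )
    for e in evals:
        pd.DataFrame(e.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{e.feature_subset}.csv", index=False
        )
        if e.importance_table is not None and e.feature_subset == "all":
            e.importance_table.to_csv(out / "importance.csv", index=False)
            overlays, summary = importance_to_surfaces(
                e.importance_table, bundle.templates
            )
            summary.to_csv(out / "importance_by_region.csv", index=False)
            for (s, kind), ov in overlays.items():
                save_mesh_with_scalars(
                    bundle.templates[s], [ov], out / f"importance_{s}_{kind}.vtk"
                )


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "stats": _stage_stats,
    "classify": _stage_classify,
}


def run_stage(stage: str, config: RunConfig | dict, workdir,
              verbose: bool = False) -> dict:
    """Run one stage (or ``'all'``); returns the updated run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    if stage != "all" and stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES + ('all',)}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if verbose and not log.handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    log_path = workdir / "run.log"
    stages = STAGES if stage == "all" else (stage,)
    manifest_path = workdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists()
        else {"config_hash": config.hash(), "version": __version__,
              "log": str(log_path), "stages": {}}
    )
    if manifest["config_hash"] != config.hash():
        manifest = {"config_hash": config.hash(), "version": __version__,
                    "log": str(log_path), "stages": {}}
    with open(log_path, "a") as fh:
        for st in stages:
            t0 = time.time()
            _STAGE_FNS[st](config, workdir)
            elapsed = time.time() - t0
            line = f"stage={st} elapsed={elapsed:.2f}s config={config.hash()}"
            fh.write(line + "\n")
            log.info(line)
            manifest["stages"][st] = {
                "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "elapsed_s": round(elapsed, 3),
            }
    manifest["files"] = _checksum_dir(workdir)
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(workdir) -> dict:
    """Assemble a run summary (dict + Markdown written to the workdir).

    Sections covered: volume effect table, significant-vertex counts per
    structure and measure, classifier AUC/p/q per feature subset, and
    per-region importance averages.  Stages that have not run are marked
    absent rather than failing.
    """
    workdir = Path(workdir)
    if not workdir.exists() or not any(workdir.iterdir()):
        raise FileNotFoundError(f"no completed stages under {workdir}")
    out: dict = {"workdir": str(workdir)}
    md = ["# subshape run report", ""]

    stats_dir = workdir / "stats"
    vol = stats_dir / "volume_effects.csv"
    if vol.exists():
        df = pd.read_csv(vol)
        out["volume_effects"] = df.to_dict("records")
        md += ["## Volume effects", df.to_markdown(index=False), ""]
    else:
        out["volume_effects"] = None
        md += ["## Volume effects", "_absent (stats stage not run)_", ""]

    counts = stats_dir / "significant_vertex_counts.csv"
    if counts.exists():
        df = pd.read_csv(counts)
        out["significant_vertex_counts"] = df.to_dict("records")
        md += ["## Significant vertices per surface", df.to_markdown(index=False), ""]
    else:
        out["significant_vertex_counts"] = None
        md += ["## Significant vertices per surface", "_absent_", ""]

    ev = workdir / "classify" / "evaluation.json"
    if ev.exists():
        recs = json.loads(ev.read_text())
        out["classification"] = recs
        df = pd.DataFrame(recs)[["feature_subset", "scheme", "auc", "p_value", "q_value"]]
        md += ["## Classification", df.to_markdown(index=False), ""]
    else:
        out["classification"] = None
        md += ["## Classification", "_absent (classify stage not run)_", ""]

    imp = workdir / "classify" / "importance_by_region.csv"
    if imp.exists():
        df = pd.read_csv(imp)
        out["importance_by_region"] = df.to_dict("records")
        md += ["## Mean importance by region", df.to_markdown(index=False), ""]
    else:
        out["importance_by_region"] = None

    overlays = sorted(str(p.relative_to(workdir))
                      for p in workdir.rglob("*.vtk"))
    out["overlays"] = overlays
    if overlays:
        md += ["## Overlays", *[f"- {p}" for p in overlays], ""]

    (workdir / "report.md").write_text("\n".join(md))
    (workdir / "report.json").write_text(json.dumps(out, indent=1))
    return out
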