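"""Stage-wise pipeline orchestration with cached intermediates.

Stages: ``simulate`` (phantom cohort) -> ``preprocess`` (isotropic resample
+ z-normalisation) -> ``static`` (484 features x 4 phases) -> ``dynamic``
(9680 features) -> ``model`` (SR/DR/DSR signatures on the training split)
-> ``evaluate`` (validation report). Each stage writes its artifacts under
``out_dir/<stage>/`` together with a provenance JSON holding a content hash
of its configuration and its upstream's hash; re-running with an unchanged
configuration is a no-op.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import modeling, synthetic
from .dynamic_features import dynamic_matrix
from .preprocess import (
    PHASE_NAMES,
    PhaseStack,
    load_phase_stack,
    resample_isotropic,
    znormalize,
)
from .static_features import extract_static_vector

log = logging.getLogger("dynrad")

STAGES = ("simulate", "preprocess", "static", "dynamic", "model", "evaluate")

__all__ = ["PipelineConfig", "ConfigError", "MissingArtifactError",
           "load_config", "run_stage", "STAGES"]


class ConfigError(ValueError):
    """Configuration does not validate against the schema."""


class MissingArtifactError(FileNotFoundError):
    """A required upstream stage artifact does not exist."""


def _strict(cls, data: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as e:
        raise ConfigError(str(e)) from e


@dataclass
class SimulateOptions:
    n_patients: int = 16
    prevalence: float = 0.4
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    lesion_radius_range: tuple[float, float] = (5.0, 8.0)
    noise_sigma: float = 5.0
    noise_model: str = "gaussian"


@dataclass
class PreprocessOptions:
    region: str = "whole-volume"          # statistics region for z-normalisation
    n_levels: int = 64
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    time_grid: tuple[float, float, float, float] = (1.0, 2.0, 3.0, 4.0)


@dataclass
class DynamicOptions:
    racr_denominator: str = "series-mean"
    corrected_curvature: bool = False


@dataclass
class ModelOptions:
    alpha: float = 0.05
    cv_folds: int = 5
    cv_repeats: int = 5
    icc_threshold: float = 0.8
    icc_jitter_mm: float = 0.0            # 0 disables the reader-variant ICC filter
    icc_n_patients: int = 6
    validation_fraction: float = 0.3


@dataclass
class PipelineConfig:
    out_dir: str = "dynrad_run"
    seed: int = 0
    manifest: str | None = None           # real-data manifest; None -> simulate
    wavelet: str = "coif1"
    simulate: SimulateOptions = field(default_factory=SimulateOptions)
    preprocess: PreprocessOptions = field(default_factory=PreprocessOptions)
    dynamic: DynamicOptions = field(default_factory=DynamicOptions)
    model: ModelOptions = field(default_factory=ModelOptions)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sub = {
            "simulate": SimulateOptions,
            "preprocess": PreprocessOptions,
            "dynamic": DynamicOptions,
            "model": ModelOptions,
        }
        parsed = {}
        for key, klass in sub.items():
            if key in data:
                parsed[key] = _strict(klass, dict(data.pop(key) or {}), key)
        cfg = _strict(cls, {**data, **parsed}, "config")
        for key, klass in sub.items():
            val = getattr(cfg, key)
            if isinstance(val, dict):
                setattr(cfg, key, _strict(klass, val, key))
        return cfg

    def stage_dict(self, stage: str) -> dict:
        base = {"seed": self.seed, "manifest": self.manifest, "wavelet": self.wavelet}
        per_stage = {
            "simulate": ["simulate"],
            "preprocess": ["simulate", "preprocess"],
            "static": ["simulate", "preprocess", "model"],
            "dynamic": ["simulate", "preprocess", "dynamic"],
            "model": ["simulate", "preprocess", "dynamic", "model"],
            "evaluate": ["simulate", "preprocess", "dynamic", "model"],
        }
        for key in per_stage[stage]:
            base[key] = dataclasses.asdict(getattr(self, key))
        return base


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return PipelineConfig.from_dict(data)


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    return Path(cfg.out_dir) / stage


def _provenance(cfg: PipelineConfig, stage: str, upstream: str | None) -> dict:
    prov = {"stage": stage, "config": cfg.stage_dict(stage), "seed": cfg.seed}
    if upstream:
        up = _stage_dir(cfg, upstream) / "provenance.json"
        if not up.exists():
            raise MissingArtifactError(
                f"stage '{stage}' requires upstream stage '{upstream}' to have run")
        prov["upstream_hash"] = json.loads(up.read_text())["hash"]
    prov["hash"] = _hash(prov)
    return prov


def _up_to_date(dirpath: Path, prov: dict) -> bool:
    p = dirpath / "provenance.json"
    return p.exists() and json.loads(p.read_text())["hash"] == prov["hash"]


def _finish(dirpath: Path, prov: dict) -> None:
    (dirpath / "provenance.json").write_text(json.dumps(prov, indent=2))


def _load_manifest(cfg: PipelineConfig) -> pd.DataFrame:
    path = cfg.manifest or str(_stage_dir(cfg, "simulate") / "manifest.csv")
    if not Path(path).exists():
        raise MissingArtifactError(f"cohort manifest not found: {path}")
    return pd.read_csv(path)


def _load_preprocessed(cfg: PipelineConfig) -> tuple[list[PhaseStack], pd.DataFrame]:
    pdir = _stage_dir(cfg, "preprocess")
    manifest_path = pdir / "cohort.csv"
    if not manifest_path.exists():
        raise MissingArtifactError("preprocess stage has not produced its cohort table")
    manifest = pd.read_csv(manifest_path)
    stacks = []
    for pid in manifest["patient_id"]:
        sidecar = json.loads((pdir / f"{pid}_stack.json").read_text())
        vol_paths = [sidecar["paths"][f"{n}_img"] for n in PHASE_NAMES]
        msk_paths = [sidecar["paths"][f"{n}_msk"] for n in PHASE_NAMES]
        stack = load_phase_stack(vol_paths, msk_paths, sidecar["time_grid"])
        stack.meta.update(sidecar.get("meta", {}))
        stacks.append(stack)
    return stacks, manifest


def _extract_phase_table(stacks, manifest, cfg) -> pd.DataFrame:
    rows = []
    for stack in stacks:
        row = {}
        for phase, vol, msk in zip(PHASE_NAMES, stack.volumes, stack.masks):
            sv = extract_static_vector(vol, msk, phase, cfg.preprocess.n_levels,
                                       wavelet=cfg.wavelet)
            for name, cat, val in zip(sv.names, sv.categories, sv.values):
                row[f"{phase}__{cat}__{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows, index=manifest["patient_id"])


def _split(manifest: pd.DataFrame, cfg: PipelineConfig):
    rng = np.random.default_rng(cfg.seed)
    y = manifest["label"].to_numpy()
    idx = np.arange(len(y))
    val = []
    for cls in (0, 1):
        cls_idx = idx[y == cls]
        n_val = max(1, round(len(cls_idx) * cfg.model.validation_fraction))
        val.extend(rng.choice(cls_idx, size=n_val, replace=False))
    val = np.sort(np.asarray(val))
    train = np.setdiff1d(idx, val)
    return train, val


def run_stage(stage: str, cfg: PipelineConfig) -> Path:
    """Run (or skip, if cached) one pipeline stage; returns its directory."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage: {stage}")
    upstream = {None: None, "simulate": None, "preprocess": "simulate" if cfg.manifest is None else None,
                "static": "preprocess", "dynamic": "static", "model": "dynamic",
                "evaluate": "model"}[stage]
    prov = _provenance(cfg, stage, upstream)
    out = _stage_dir(cfg, stage)
    if _up_to_date(out, prov):
        log.info("stage %s: cached, skipping", stage)
        return out
    out.mkdir(parents=True, exist_ok=True)

    if stage == "simulate":
        sim = cfg.simulate
        config = synthetic.SyntheticCohortConfig(
            n_patients=sim.n_patients, prevalence=sim.prevalence,
            volume_shape=tuple(sim.volume_shape),
            lesion_radius_range=tuple(sim.lesion_radius_range),
            noise_sigma=sim.noise_sigma, noise_model=sim.noise_model,
            time_grid=tuple(cfg.preprocess.time_grid), seed=cfg.seed,
        )
        stacks, labels, _ = synthetic.generate_cohort(config)
        synthetic.write_cohort(stacks, labels, out)

    elif stage == "preprocess":
        manifest = _load_manifest(cfg)
        rows = []
        from .preprocess import save_stack
        for _, rec in manifest.iterrows():
            stack = load_phase_stack(
                [rec[f"{n}_image"] for n in PHASE_NAMES],
                [rec[f"{n}_mask"] for n in PHASE_NAMES],
                cfg.preprocess.time_grid,
            )
            stack = resample_isotropic(stack, tuple(cfg.preprocess.target_spacing))
            stack.volumes = [
                znormalize(v, cfg.preprocess.region, m)
                for v, m in zip(stack.volumes, stack.masks)
            ]
            stack.meta.update({"patient_id": rec["patient_id"], "label": int(rec["label"])})
            save_stack(stack, out, rec["patient_id"])
            rows.append({"patient_id": rec["patient_id"], "label": int(rec["label"])})
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)

    elif stage == "static":
        stacks, manifest = _load_preprocessed(cfg)
        from .static_features import default_roster
        default_roster().to_json(out / "feature_roster.json")
        table = _extract_phase_table(stacks, manifest, cfg)
        table.to_csv(out / "static_features.csv")
        if cfg.model.icc_jitter_mm > 0:
            n_icc = min(cfg.model.icc_n_patients, len(stacks))
            for tag, offset in (("r1b", 1), ("r2", 2)):
                variants = []
                for stack in stacks[:n_icc]:
                    va, vb = synthetic.generate_reader_variants(
                        stack, cfg.model.icc_jitter_mm, seed=cfg.seed + offset)
                    variants.append(va if tag == "r1b" else vb)
                sub = _extract_phase_table(variants, manifest.iloc[:n_icc], cfg)
                sub.to_csv(out / f"static_features_{tag}.csv")

    elif stage == "dynamic":
        sdir = _stage_dir(cfg, "static")
        fpath = sdir / "static_features.csv"
        if not fpath.exists():
            raise MissingArtifactError("static feature table missing")
        static = pd.read_csv(fpath, index_col=0)
        phase_mats = []
        for phase in PHASE_NAMES:
            pref = f"{phase}__"
            cols = [c for c in static.columns if c.startswith(pref)]
            m = static[cols].copy()
            m.columns = [c[len(pref):] for c in cols]
            phase_mats.append(m)
        dyn = dynamic_matrix(
            phase_mats, cfg.preprocess.time_grid,
            racr_denominator=cfg.dynamic.racr_denominator,
            corrected_curvature=cfg.dynamic.corrected_curvature,
        )
        dyn.to_csv(out / "dynamic_features.csv")
        with open(out / "dynamic_provenance.json", "w") as fh:
            json.dump({"time_grid": list(cfg.preprocess.time_grid),
                       **dataclasses.asdict(cfg.dynamic)}, fh, indent=2)

    elif stage == "model":
        sdir, ddir = _stage_dir(cfg, "static"), _stage_dir(cfg, "dynamic")
        for p in (sdir / "static_features.csv", ddir / "dynamic_features.csv"):
            if not p.exists():
                raise MissingArtifactError(f"missing upstream table: {p}")
        static = pd.read_csv(sdir / "static_features.csv", index_col=0)
        dyn = pd.read_csv(ddir / "dynamic_features.csv", index_col=0)
        manifest = pd.read_csv(_stage_dir(cfg, "preprocess") / "cohort.csv")
        y = manifest["label"].to_numpy()
        if cfg.model.icc_jitter_mm > 0:
            r1b = pd.read_csv(sdir / "static_features_r1b.csv", index_col=0)
            r2 = pd.read_csv(sdir / "static_features_r2.csv", index_col=0)
            n_icc = len(r1b)
            icc = modeling.icc_filter(static.iloc[:n_icc], r1b, r2,
                                      cfg.model.icc_threshold)
            keep = icc.index[icc["passed"]]
            icc.to_csv(out / "icc_table.csv")
            static = static[[c for c in static.columns if c in set(keep)]]
        train, val = _split(manifest, cfg)
        np.save(out / "train_idx.npy", train)
        np.save(out / "val_idx.npy", val)
        mo = cfg.model
        kw = dict(alpha=mo.alpha, cv_folds=mo.cv_folds, cv_repeats=mo.cv_repeats,
                  seed=cfg.seed)
        sr = modeling.build_signature(static.iloc[train], y[train], "SR", **kw)
        dr = modeling.build_signature(dyn.iloc[train], y[train], "DR", **kw)
        union = list(dict.fromkeys(sr.feature_names + dr.feature_names))
        combined = pd.concat([static, dyn], axis=1)
        dsr = modeling.build_signature(combined.iloc[train][union], y[train], "DSR", **kw)
        for model in (sr, dr, dsr):
            model.to_json(out / f"signature_{model.signature_type}.json")

    elif stage == "evaluate":
        mdir = _stage_dir(cfg, "model")
        if not (mdir / "signature_SR.json").exists():
            raise MissingArtifactError("model stage artifacts missing")
        static = pd.read_csv(_stage_dir(cfg, "static") / "static_features.csv", index_col=0)
        dyn = pd.read_csv(_stage_dir(cfg, "dynamic") / "dynamic_features.csv", index_col=0)
        manifest = pd.read_csv(_stage_dir(cfg, "preprocess") / "cohort.csv")
        y = manifest["label"].to_numpy()
        val = np.load(mdir / "val_idx.npy")
        combined = pd.concat([static, dyn], axis=1)
        results = {}
        scores = {}
        for sig, table in (("SR", static), ("DR", dyn), ("DSR", combined)):
            model = modeling.SignatureModel.from_json(mdir / f"signature_{sig}.json")
            rep = modeling.evaluate(model, table.iloc[val], y[val])
            rep.roc.to_csv(out / f"roc_{sig}.csv", index=False)
            rep.pr.to_csv(out / f"pr_{sig}.csv", index=False)
            results[sig] = rep.summary()
            scores[sig] = model.predict_proba(table.iloc[val])
        results["p_SR_vs_DR"] = modeling.compare_auc(scores["SR"], scores["DR"], y[val])
        results["p_SR_vs_DSR"] = modeling.compare_auc(scores["SR"], scores["DSR"], y[val])
        (out / "evaluation.json").write_text(json.dumps(results, indent=2))

    _finish(out, prov)
    log.info("stage %s: done -> %s", stage, out)
    return out
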