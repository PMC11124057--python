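"""End-to-end orchestration: simulate -> featurize -> select -> tune ->
ensemble -> predict, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .config import EngineConfig
from .features import (
    DescriptorEngine,
    build_feature_table,
    r2_profile,
    select_sigma_points,
    target_vector,
)
from .modeling import (
    SplitSpec,
    build_ensemble,
    fit_candidates,
    predict_solubility,
    rmsd,
    save_model_card,
    split_dataset,
    tune,
)
from .simulate import (
    GeneratorConfig,
    gen_calibration_series,
    gen_fusion_data,
    gen_sigma_profiles,
    gen_solubility_dataset,
    gen_systems,
)

DEFAULT_CONFIG = {
    "seed": 0,
    "n_records": 600,
    "noise_sd_dex": 0.1,
    "n_trials": 100,
    "r2_threshold": 0.4,
    "split_fractions": [0.70, 0.15, 0.15],
    "temperature_predict": 298.15,
}


@dataclass
class RunManifest:
    """Record of one pipeline run sufficient to reproduce it."""

    config: dict
    config_hash: str
    seed: int
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def load_config(path: str | Path | None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg.update(yaml.safe_load(fh) or {})
    return cfg


def simulate_bundle(outdir: str | Path, config: dict) -> dict[str, Path]:
    """Write the full synthetic CSV bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gc = GeneratorConfig(
        seed=int(config["seed"]),
        n_records=int(config["n_records"]),
        noise_sd_dex=float(config["noise_sd_dex"]),
    )
    profiles = gen_sigma_profiles(gc)
    fusion = gen_fusion_data(gc)
    records, truth = gen_solubility_dataset(gc, profiles, fusion)
    systems = {r.system.system_id: r.system for r in records}
    for s in gen_systems(gc):
        systems.setdefault(s.system_id, s)
    calib = gen_calibration_series(seed=gc.seed)
    paths = {
        "profiles": outdir / "profiles",
        "fusion": outdir / "fusion.csv",
        "systems": outdir / "systems.csv",
        "records": outdir / "records.csv",
        "truth": outdir / "truth.csv",
        "calibration": outdir / "calibration.csv",
    }
    io.write_profiles(profiles, paths["profiles"])
    io.write_fusion(fusion, paths["fusion"])
    io.write_systems(list(systems.values()), paths["systems"])
    io.write_records(records, paths["records"])
    truth.to_csv(paths["truth"])
    io.write_calibration(calib, paths["calibration"])
    return paths


def run_pipeline(
    config_path: str | Path | None = None,
    workdir: str | Path = "runs/run0",
    config_overrides: dict | None = None,
) -> RunManifest:
    """Execute the full pipeline and write artifacts + manifest.

    Stages: simulate (if no input bundle configured) -> featurize ->
    select -> tune -> ensemble -> predict.  Any stage failure raises
    with the stage name in the message.
    """
    config = load_config(config_path)
    config.update(config_overrides or {})
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = RunManifest(
        config=config,
        config_hash=hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
        seed=seed,
    )

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Timer()

    with stage("simulate"):
        bundle_dir = config.get("bundle_dir")
        if bundle_dir is None:
            paths = simulate_bundle(workdir / "bundle", config)
        else:
            bundle_dir = Path(bundle_dir)
            paths = {
                "profiles": bundle_dir / "profiles",
                "fusion": bundle_dir / "fusion.csv",
                "systems": bundle_dir / "systems.csv",
                "records": bundle_dir / "records.csv",
            }
            for key in ("fusion", "systems", "records"):
                if not paths[key].exists():
                    raise FileNotFoundError(f"missing input {paths[key]}")
        profiles = io.read_profiles(paths["profiles"])
        fusion = io.read_fusion(paths["fusion"])
        systems = io.read_systems(paths["systems"])
        records = io.read_records(paths["records"], systems)
        for key, p in paths.items():
            if Path(p).is_file():
                manifest.input_digests[key] = _digest(Path(p))

    engine = DescriptorEngine(profiles, fusion, EngineConfig())

    with stage("featurize"):
        relpots = {
            r.record_id: engine.relative_potential(r.solute, r.system, r.T)
            for r in records
        }

    with stage("select"):
        non_des = [r for r in records if not r.is_des]
        des = [r for r in records if r.is_des]
        report = select_sigma_points(
            r2_profile(non_des, relpots),
            r2_profile(des, relpots),
            threshold=float(config["r2_threshold"]),
        )
        io.write_selection(report, workdir / "selection.csv")
        manifest.outputs["selection"] = str(workdir / "selection.csv")

    with stage("features"):
        table = build_feature_table(records, engine, report)
        y = target_vector(records)
        table.to_csv(workdir / "features.csv")

    with stage("tune"):
        train, test, val = split_dataset(
            records, SplitSpec(tuple(config["split_fractions"]), seed)
        )
        ids = {s: [r.record_id for r in part] for s, part in
               [("train", train), ("test", test), ("val", val)]}
        X = {k: table.loc[v].to_numpy() for k, v in ids.items()}
        Y = {k: y.loc[v].to_numpy() for k, v in ids.items()}
        candidates, trials = tune(
            X["train"], Y["train"], n_trials=int(config["n_trials"]), seed=seed
        )
        with open(workdir / "trials.log", "w") as fh:
            for t in trials:
                fh.write(f"{t.number}\t{t.value:.6f}\t{json.dumps(t.params)}\n")

    with stage("ensemble"):
        fit_candidates(candidates, X["train"], Y["train"], seed=seed)
        ensemble = build_ensemble(candidates, X["val"], Y["val"])
        save_model_card(
            workdir / "model.json",
            ensemble,
            extra={"seed": seed, "selection": list(report.selected_indices)},
        )
        manifest.outputs["model"] = str(workdir / "model.json")
        manifest.metrics["rmsd_train"] = rmsd(Y["train"], ensemble.predict(X["train"]))
        manifest.metrics["rmsd_test"] = rmsd(Y["test"], ensemble.predict(X["test"]))
        manifest.metrics["rmsd_val"] = rmsd(Y["val"], ensemble.predict(X["val"]))
        ss_res = np.sum((Y["test"] - ensemble.predict(X["test"])) ** 2)
        ss_tot = np.sum((Y["test"] - np.mean(Y["test"])) ** 2)
        manifest.metrics["r2_test"] = float(1.0 - ss_res / ss_tot)

    with stage("predict"):
        solutes = sorted(fusion)
        sweep = [
            s
            for s in systems.values()
            if s.is_des and s.hba == "ChCl" and s.hbd == "TEG" and s.ratio == 2.0
        ]
        preds = predict_solubility(
            ensemble,
            solutes,
            sweep or list(systems.values())[:4],
            float(config["temperature_predict"]),
            engine,
            report,
        )
        preds.to_csv(workdir / "predictions.csv", index=False)
        manifest.outputs["predictions"] = str(workdir / "predictions.csv")

    manifest.outputs["manifest"] = str(workdir / "manifest.json")
    for name in ("selection.csv", "features.csv", "predictions.csv"):
        manifest.input_digests[f"out:{name}"] = _digest(workdir / name)
    manifest.save(workdir / "manifest.json")
    return manifest
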