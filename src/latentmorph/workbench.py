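"""Pipeline orchestration: configuration, stage caching, and the full analysis run.

The pipeline chains the stages

    simulate -> train -> project -> direction -> edit -> analyze

over one declarative configuration. Every stage derives its seed from the
global seed, hashes its own configuration together with its inputs' hashes,
and caches its artifact; re-running an unchanged configuration is a no-op. A
JSON manifest records versions, seeds, and per-stage artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import morphometry as mm
from . import phantom as ph
from . import projection as pj
from . import semantics as sem
from . import stylegan as sg

PIPELINE_VERSION = "0.1.0"
STAGES = ("simulate", "train", "project", "direction", "edit", "analyze")


@dataclass
class SimulateConfig:
    n_per_cohort: int = 200
    size: int = 32
    contrast: str = "t1w_multiecho"
    noise_std: float = 0.02


@dataclass
class TrainStageConfig:
    kimg: float = 4.0
    batch_size: int = 16
    latent_dim: int = 64
    learning_rate: float = 0.0025
    r1_gamma: float = 1.0
    mirror: bool = True
    metric_interval: int = 100


@dataclass
class ProjectStageConfig:
    n_subjects: int = 10          # per cohort
    iterations: int = 150
    init_samples: int = 512
    init_top_k: int = 64
    lr_rampup_iters: int = 10
    lr_rampdown_iters: int = 40
    noise_ramp_iters: int = 40


@dataclass
class DirectionStageConfig:
    folds: int = 10
    svm_c: float = 1.0


@dataclass
class EditStageConfig:
    alpha_max: float | str = "auto"   # "auto": 2x the inter-cohort separation along n
    n_alphas: int = 5


@dataclass
class AnalyzeStageConfig:
    contrast: str = "t1w"


@dataclass
class PipelineConfig:
    seed: int = 0
    out_root: str = "pipeline_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    train: TrainStageConfig = field(default_factory=TrainStageConfig)
    project: ProjectStageConfig = field(default_factory=ProjectStageConfig)
    direction: DirectionStageConfig = field(default_factory=DirectionStageConfig)
    edit: EditStageConfig = field(default_factory=EditStageConfig)
    analyze: AnalyzeStageConfig = field(default_factory=AnalyzeStageConfig)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        sub = {"simulate": SimulateConfig, "train": TrainStageConfig,
               "project": ProjectStageConfig, "direction": DirectionStageConfig,
               "edit": EditStageConfig, "analyze": AnalyzeStageConfig}
        for key, klass in sub.items():
            if key in d:
                block = d.pop(key)
                if block is None:
                    raise ValueError(f"config stage block {key!r} is empty")
                kwargs[key] = klass(**block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d, **kwargs)

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    if path.suffix == ".npz":
        # hash array contents, not container bytes (zip members carry timestamps)
        with np.load(path, allow_pickle=False) as z:
            for key in sorted(z.files):
                arr = z[key]
                h.update(key.encode())
                h.update(str(arr.dtype).encode())
                h.update(str(arr.shape).encode())
                h.update(np.ascontiguousarray(arr).tobytes())
    else:
        with open(path, "rb") as f:
            for chunk in iter(lambda: f.read(1 << 20), b""):
                h.update(chunk)
    return h.hexdigest()


class _Log:
    """JSON-lines structured log."""

    def __init__(self, path: Path):
        self.path = path

    def __call__(self, record: dict) -> None:
        record = {"time": time.time(), **record}
        with open(self.path, "a") as f:
            f.write(json.dumps(record) + "\n")


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute (or resume from cache) the full pipeline; returns the manifest."""
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "pipeline.log.jsonl")
    manifest_path = out / "manifest.json"
    manifest = {"version": PIPELINE_VERSION, "seed": config.seed, "stages": {}}
    if manifest_path.exists() and not force:
        try:
            manifest = json.loads(manifest_path.read_text())
            manifest.setdefault("stages", {})
        except json.JSONDecodeError:
            pass

    def stage_done(name: str, cfg_hash: str) -> bool:
        entry = manifest["stages"].get(name)
        if not entry or entry.get("config_hash") != cfg_hash:
            return False
        artifact = out / entry["artifact"]
        return artifact.exists() and _hash_file(artifact) == entry["artifact_hash"]

    def record(name: str, cfg_hash: str, artifact: Path, extra: dict | None = None):
        manifest["stages"][name] = {
            "config_hash": cfg_hash,
            "artifact": artifact.name,
            "artifact_hash": _hash_file(artifact),
            "seed": config.stage_seed(name),
            "completed": True,
            **(extra or {}),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        log({"stage": name, "status": "complete", "seed": config.stage_seed(name)})

    contrast_short = "adc" if config.simulate.contrast == "adc" else "t1w"

    # ---- simulate
    sim_hash = _hash_obj([dataclasses.asdict(config.simulate), config.stage_seed("simulate")])
    sim_art = out / "cohorts.npz"
    if force or not stage_done("simulate", sim_hash):
        seed = config.stage_seed("simulate")
        cs = config.simulate
        hc = ph.sample_cohort(cs.n_per_cohort, "HC", contrast=cs.contrast, seed=seed,
                              size=cs.size, noise_std=cs.noise_std)
        ms = ph.sample_cohort(cs.n_per_cohort, "MS", contrast=cs.contrast, seed=seed + 1,
                              size=cs.size, noise_std=cs.noise_std)
        np.savez_compressed(
            sim_art,
            hc=np.stack([p.channels for p in hc]),
            ms=np.stack([p.channels for p in ms]),
            hc_bpf=np.array([ph.analytic_bpf(p) for p in hc]),
            ms_bpf=np.array([ph.analytic_bpf(p) for p in ms]),
        )
        record("simulate", sim_hash, sim_art)

    # ---- train
    data = np.load(sim_art)
    images = np.concatenate([data["hc"], data["ms"]])
    train_hash = _hash_obj([dataclasses.asdict(config.train), config.stage_seed("train"),
                            manifest["stages"]["simulate"]["artifact_hash"]])
    train_art = out / "generator.npz"
    if force or not stage_done("train", train_hash):
        tc = config.train
        cfg = sg.TrainConfig(kimg_budget=tc.kimg, batch_size=tc.batch_size,
                             learning_rate=tc.learning_rate, r1_gamma=tc.r1_gamma,
                             mirror_augment=tc.mirror, metric_interval=tc.metric_interval,
                             seed=config.stage_seed("train"))
        gcfg = sg.GeneratorConfig(resolution=config.simulate.size, latent_dim=tc.latent_dim,
                                  seed=config.stage_seed("train"))
        result = sg.train(images, cfg, gcfg, log_fn=log)
        sg.save_checkpoint(train_art, result.model, result.discriminator,
                           extra={"history_frechet": result.history["frechet"]})
        record("train", train_hash, train_art,
               {"final_frechet": result.history["frechet"][-1]})

    model, _, _ = sg.load_checkpoint(train_art)

    # ---- project
    proj_hash = _hash_obj([dataclasses.asdict(config.project), config.stage_seed("project"),
                           manifest["stages"]["train"]["artifact_hash"]])
    proj_art = out / "latents.npz"
    if force or not stage_done("project", proj_hash):
        pc = config.project
        seed = config.stage_seed("project")
        payload = {}
        for label in ("hc", "ms"):
            imgs = data[label][:pc.n_subjects]
            lats, sigmas = [], []
            for i, img in enumerate(imgs):
                cfg = pj.ProjectionConfig(
                    iterations=pc.iterations, init_samples=pc.init_samples,
                    init_top_k=pc.init_top_k, lr_rampup_iters=pc.lr_rampup_iters,
                    lr_rampdown_iters=pc.lr_rampdown_iters,
                    noise_ramp_iters=pc.noise_ramp_iters, seed=seed + i)
                res = pj.project(model, img, cfg)
                lats.append(res.wplus)
                sigmas.append(res.sigma_w)
                for li, nm in enumerate(res.noise_maps):
                    payload[f"noise_{label}_{i}_{li}"] = nm
            payload[f"wplus_{label}"] = np.stack(lats)
            payload[f"sigma_{label}"] = np.array(sigmas)
        np.savez_compressed(proj_art, **payload)
        record("project", proj_hash, proj_art)

    lat = np.load(proj_art)

    # ---- direction
    dir_hash = _hash_obj([dataclasses.asdict(config.direction), config.stage_seed("direction"),
                          manifest["stages"]["project"]["artifact_hash"]])
    dir_art = out / "direction.npz"
    if force or not stage_done("direction", dir_hash):
        dc = config.direction
        hc_flat = lat["wplus_hc"].reshape(len(lat["wplus_hc"]), -1)
        ms_flat = lat["wplus_ms"].reshape(len(lat["wplus_ms"]), -1)
        direction = sem.fit_direction(hc_flat, ms_flat, folds=dc.folds, attribute="MS",
                                      C=dc.svm_c, seed=config.stage_seed("direction"))
        np.savez(dir_art, n=direction.n, offset=direction.hyperplane_offset,
                 fold_accuracy=np.array(direction.cv_report.get("fold_accuracy", [])),
                 fold_cosines=np.array(direction.cv_report.get("fold_cosines", [])))
        record("direction", dir_hash, dir_art)

    dvec = np.load(dir_art)["n"]

    # ---- edit
    edit_hash = _hash_obj([dataclasses.asdict(config.edit), config.stage_seed("edit"),
                           manifest["stages"]["direction"]["artifact_hash"]])
    edit_art = out / "edited.npz"
    if force or not stage_done("edit", edit_hash):
        ec = config.edit
        hc_flat = lat["wplus_hc"].reshape(len(lat["wplus_hc"]), -1)
        ms_flat = lat["wplus_ms"].reshape(len(lat["wplus_ms"]), -1)
        if ec.alpha_max == "auto":
            separation = float(ms_flat.mean(axis=0) @ dvec - hc_flat.mean(axis=0) @ dvec)
            alpha_max = 2.0 * abs(separation)
        else:
            alpha_max = float(ec.alpha_max)
        grid_pos = np.linspace(0.0, alpha_max, config.edit.n_alphas)
        grid_neg = -grid_pos[::-1]
        payload = {"alpha_grid_pos": grid_pos, "alpha_grid_neg": grid_neg,
                   "alpha_max": np.array(alpha_max)}
        L, d = model.num_style_layers, model.cfg.latent_dim
        for label, grid in (("hc", grid_pos), ("ms", grid_neg)):
            n_sub = len(lat[f"wplus_{label}"])
            for i in range(n_sub):
                noise = [lat[f"noise_{label}_{i}_{li}"]
                         for li in range(len(model.synthesis.noise_shapes))]
                series = sem.manipulate(model, lat[f"wplus_{label}"][i], dvec, grid,
                                        noise_maps=noise)
                payload[f"series_{label}_{i}"] = np.stack(series.images)
        np.savez_compressed(edit_art, **payload)
        record("edit", edit_hash, edit_art, {"alpha_max": float(alpha_max)})

    edited = np.load(edit_art)

    # ---- analyze
    an_hash = _hash_obj([dataclasses.asdict(config.analyze), config.stage_seed("analyze"),
                         manifest["stages"]["edit"]["artifact_hash"]])
    an_art = out / "bpf_analysis.csv"
    if force or not stage_done("analyze", an_hash):
        rows = []
        summary = {}
        for label, gkey in (("hc", "alpha_grid_pos"), ("ms", "alpha_grid_neg")):
            grid = edited[gkey]
            baseline_idx = int(np.argmin(np.abs(grid)))
            n_sub = len(lat[f"wplus_{label}"])
            series = []
            for i in range(n_sub):
                imgs = list(edited[f"series_{label}_{i}"])
                series.append(sem.ManipulationSeries(
                    alpha_grid=grid, images=imgs, wplus_series=[None] * len(grid),
                    baseline_index=baseline_idx))
            curve = mm.bpf_curve(series, contrast=contrast_short,
                                 seed=config.stage_seed("analyze"))
            for j, alpha in enumerate(grid):
                for i in range(n_sub):
                    rows.append({"cohort": label.upper(), "subject": i,
                                 "alpha": float(alpha), "bpf": float(curve.bpf[i, j]),
                                 "p_value": float(curve.p_values[j])})
            sig = [float(grid[j]) for j in range(len(grid)) if curve.significant[j]]
            summary[label] = {
                "mean_bpf_baseline": float(curve.bpf[:, baseline_idx].mean()),
                "mean_bpf_extreme": float(
                    curve.bpf[:, -1 if label == "hc" else 0].mean()),
                "significance_onset_alpha": (min(sig, key=abs) if sig else None),
            }
        pd.DataFrame(rows).to_csv(an_art, index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        record("analyze", an_hash, an_art, {"summary": summary})

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
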